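"""Block-level behavioral metrics: matching, win-stay/lose-switch, repetition
indices, and the conditional-entropy family (ERDS / EODS / ERODS).

All probabilities are within-block plug-in frequencies (no smoothing).  Every
metric is either a defined float or :data:`numpy.nan`, which encodes
*undefined*: a decomposition component whose conditioner cell contains no
events is undefined rather than zero, and a computation over zero events is
undefined.  Entropies are in bits (log base 2) with the convention
``0·log2(0) = 0``.

The three entropy metrics are conditional entropies of the stay/switch
strategy ``str``:

* ``ERDS  = H(str | rew)``   — conditioned on win/lose in the previous trial;
* ``EODS  = H(str | opt)``   — conditioned on whether the previous choice was
  the better or worse option (or left/right side);
* ``ERODS = H(str | rew, opt)`` — conditioned on both.

Each decomposes by conditioner cell: e.g. ``ERODS_Wminus`` is the
joint-probability-weighted entropy of strategy after a loss on the worse
option, the component the parent entropy sums over, so
``ERODS = ERODS_Bplus + ERODS_Bminus + ERODS_Wplus + ERODS_Wminus`` exactly
whenever all parts are defined.  Lower values mean a more consistent local
strategy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import Block, derive_strategy_events, iter_blocks, retained

#: Metric columns of a metric table, in output order.
METRIC_COLUMNS = (
    "choice_fraction",
    "reward_fraction",
    "UM",
    "p_win",
    "p_stay",
    "WS",
    "LS",
    "RI_LR",
    "RI_B",
    "RI_W",
    "ERDS",
    "ERDS_plus",
    "ERDS_minus",
    "EODS",
    "EODS_B",
    "EODS_W",
    "EODS_LR",
    "ERODS",
    "ERODS_B",
    "ERODS_W",
    "ERODS_plus",
    "ERODS_minus",
    "ERODS_Bplus",
    "ERODS_Bminus",
    "ERODS_Wplus",
    "ERODS_Wminus",
)


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def matching_fractions(block: Block) -> tuple[float, float]:
    """Choice and reward fractions of a block, referenced to the better option.

    ``choice_fraction`` is the fraction of retained trials on which the better
    option was chosen; ``reward_fraction`` is the fraction of harvested
    rewards obtained on the better option.  With the better option as the
    reference, undermatching always shows up as choice_fraction below
    reward_fraction for reward fractions above one half, independent of which
    side or stimulus happens to be better.

    Returns ``(choice_fraction, reward_fraction)``; the reward fraction is
    undefined (NaN) when the block contains no rewards.
    """
    kept = retained(block.trials)
    if len(kept) == 0:
        return (float("nan"), float("nan"))
    on_better = (kept["choice"] == block.better_option).to_numpy()
    reward = kept["reward"].to_numpy()
    choice_fraction = float(on_better.mean())
    total = reward.sum()
    reward_fraction = float(reward[on_better].sum() / total) if total > 0 else float("nan")
    return choice_fraction, reward_fraction


def deviation_from_matching(choice_fraction: float, reward_fraction: float) -> float:
    """Per-block deviation from the matching law (negative = undermatching).

    ``UM = (choice_fraction − reward_fraction) × sign(reward_fraction − 0.5)``
    with ``sign(0) = 1``.  Undefined inputs propagate.
    """
    if np.isnan(choice_fraction) or np.isnan(reward_fraction):
        return float("nan")
    s = 1.0 if reward_fraction >= 0.5 else -1.0
    return (choice_fraction - reward_fraction) * s


# ---------------------------------------------------------------------------
# win-stay / lose-switch and repetition indices
# ---------------------------------------------------------------------------

def win_stay_lose_switch(events: pd.DataFrame):
    """Win-stay, lose-switch, and the marginal win/stay frequencies.

    ``WS = P(stay | win)`` and ``LS = P(switch | lose)``, with probabilities
    as frequencies over the block's strategy events.  ``WS`` is undefined if
    no event follows a win, ``LS`` if none follows a loss.

    Returns ``(WS, LS, p_win, p_stay)``.
    """
    n = len(events)
    if n == 0:
        return (float("nan"),) * 4
    stay = events["stay"].to_numpy()
    win = events["prev_win"].to_numpy()
    p_win = float(win.mean())
    p_stay = float(stay.mean())
    ws = float(stay[win].mean()) if win.any() else float("nan")
    ls = float((~stay[~win]).mean()) if (~win).any() else float("nan")
    return ws, ls, p_win, p_stay


def repetition_index(events: pd.DataFrame, attribute: str = "left_right"):
    """Excess probability of repeating a choice beyond chance.

    With ``attribute="left_right"`` returns the scalar
    ``RI_LR = p(stay) − (p(A)² + p(B)²)``, chance being the stay probability
    of an i.i.d. chooser with the block's marginal side frequencies.

    With ``attribute="better_worse"`` returns ``(RI_BW, RI_B, RI_W)`` where
    ``RI_B = P(better(t), better(t−1)) − P(better)²`` and analogously for the
    worse option, computed from joint event frequencies (marginals taken over
    the events' current trials); ``RI_BW = RI_B + RI_W`` by construction.
    """
    n = len(events)
    if n == 0:
        if attribute == "left_right":
            return float("nan")
        return (float("nan"),) * 3
    stay = events["stay"].to_numpy()
    if attribute == "left_right":
        p_a = float((events["choice"] == "A").mean())
        return float(stay.mean()) - (p_a**2 + (1 - p_a) ** 2)
    if attribute != "better_worse":
        raise ValueError(f"unknown attribute {attribute!r}")
    prev_b = events["prev_better"].to_numpy()
    cur_b = events["cur_better"].to_numpy()
    p_b = float(cur_b.mean())
    ri_b = float((prev_b & cur_b).mean()) - p_b**2
    ri_w = float((~prev_b & ~cur_b).mean()) - (1 - p_b) ** 2
    return ri_b + ri_w, ri_b, ri_w


# ---------------------------------------------------------------------------
# entropy family
# ---------------------------------------------------------------------------

def _plogp(p: np.ndarray) -> np.ndarray:
    # 0 * log2(0) := 0
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _cell_component(stay: np.ndarray, cell: np.ndarray, n_total: int) -> float:
    """Joint-weighted entropy contribution of one conditioner cell.

    ``−Σ_{s∈{stay,switch}} P(s, cell) · log2(P(s, cell) / P(cell))`` with
    probabilities as frequencies over all ``n_total`` events of the block.
    Undefined (NaN) when the cell holds no events.
    """
    n_cell = int(cell.sum())
    if n_cell == 0:
        return float("nan")
    p_cell = n_cell / n_total
    p_stay_given = stay[cell].mean()
    probs = np.array([p_stay_given, 1.0 - p_stay_given])
    return float(p_cell * -_plogp(probs).sum())


def conditional_entropy(events: pd.DataFrame, conditioners=()) -> float:
    """Conditional entropy ``H(str | conditioners)`` of stay/switch, in bits.

    ``conditioners`` is a subset of ``{"reward", "option_role", "side"}``;
    empty gives the marginal stay/switch entropy.  Terms of empty conditioner
    cells are omitted; the result is undefined only when there are no events.
    """
    n = len(events)
    if n == 0:
        return float("nan")
    stay = events["stay"].to_numpy()
    key = np.zeros(n, dtype=int)
    for cond in conditioners:
        col = {"reward": "prev_win", "option_role": "prev_better", "side": None}[cond]
        bit = (
            (events["prev_choice"] == "A").to_numpy()
            if cond == "side"
            else events[col].to_numpy()
        )
        key = 2 * key + bit.astype(int)
    total = 0.0
    for k in np.unique(key):
        total += _cell_component(stay, key == k, n)
    return total


def erds_family(events: pd.DataFrame):
    """ERDS and its win/lose decomposition ``(ERDS, ERDS_plus, ERDS_minus)``.

    ``ERDS = H(str | rew)``; the components are the joint-weighted entropies
    after wins and after losses, so ``ERDS = ERDS_plus + ERDS_minus`` whenever
    both are defined.  A component over an empty cell (e.g. a block with no
    wins) is undefined while the parent remains defined from the nonempty
    cells.
    """
    n = len(events)
    if n == 0:
        return (float("nan"),) * 3
    stay = events["stay"].to_numpy()
    win = events["prev_win"].to_numpy()
    plus = _cell_component(stay, win, n)
    minus = _cell_component(stay, ~win, n)
    parent = np.nansum([plus, minus]) if not (np.isnan(plus) and np.isnan(minus)) else float("nan")
    return float(parent), plus, minus


def erds_closed_form(ws: float, ls: float, p_win: float) -> float:
    """ERDS from win-stay, lose-switch, and p(win).

    Algebraically identical to the joint-frequency form of
    :func:`erds_family`:
    ``ERDS = p(win)·Hb(WS) + (1−p(win))·Hb(LS)`` with ``Hb`` the binary
    entropy.  Undefined conditional probabilities contribute only when their
    branch has positive probability.
    """
    def hb(p):
        return float(-_plogp(np.array([p, 1.0 - p])).sum())

    total = 0.0
    if p_win > 0:
        if np.isnan(ws):
            return float("nan")
        total += p_win * hb(ws)
    if p_win < 1:
        if np.isnan(ls):
            return float("nan")
        total += (1.0 - p_win) * hb(ls)
    return total


def eods_family(events: pd.DataFrame, attribute: str = "better_worse"):
    """EODS and its decomposition.

    ``attribute="better_worse"`` returns ``(EODS, EODS_B, EODS_W)`` where the
    conditioner is whether the *previous* choice was the block's better
    option; ``attribute="left_right"`` returns the scalar ``EODS_LR``
    conditioned on the previous side.
    """
    n = len(events)
    if attribute == "left_right":
        if n == 0:
            return float("nan")
        return conditional_entropy(events, ("side",))
    if attribute != "better_worse":
        raise ValueError(f"unknown attribute {attribute!r}")
    if n == 0:
        return (float("nan"),) * 3
    stay = events["stay"].to_numpy()
    prev_b = events["prev_better"].to_numpy()
    comp_b = _cell_component(stay, prev_b, n)
    comp_w = _cell_component(stay, ~prev_b, n)
    parent = np.nansum([comp_b, comp_w]) if not (np.isnan(comp_b) and np.isnan(comp_w)) else float("nan")
    return float(parent), comp_b, comp_w


def erods_family(events: pd.DataFrame) -> dict:
    """ERODS and its eight decompositions.

    Returns a dict with keys ``ERODS``, ``ERODS_B``, ``ERODS_W``,
    ``ERODS_plus``, ``ERODS_minus``, ``ERODS_Bplus``, ``ERODS_Bminus``,
    ``ERODS_Wplus``, ``ERODS_Wminus``.  Cell components (e.g. ``ERODS_Wplus``,
    strategy after a win on the worse option) are undefined when their cell is
    empty — e.g. when the animal never won on the worse option in the block —
    and the pairwise sums (``ERODS_B = ERODS_Bplus + ERODS_Bminus`` etc.) are
    then undefined too, while ``ERODS`` itself remains defined from the
    nonempty cells.
    """
    n = len(events)
    keys = ("Bplus", "Bminus", "Wplus", "Wminus")
    if n == 0:
        out = {f"ERODS_{k}": float("nan") for k in keys}
        out.update(
            ERODS=float("nan"),
            ERODS_B=float("nan"),
            ERODS_W=float("nan"),
            ERODS_plus=float("nan"),
            ERODS_minus=float("nan"),
        )
        return out
    stay = events["stay"].to_numpy()
    win = events["prev_win"].to_numpy()
    prev_b = events["prev_better"].to_numpy()
    cells = {
        "Bplus": prev_b & win,
        "Bminus": prev_b & ~win,
        "Wplus": ~prev_b & win,
        "Wminus": ~prev_b & ~win,
    }
    comp = {k: _cell_component(stay, m, n) for k, m in cells.items()}
    vals = np.array(list(comp.values()))
    parent = float(np.nansum(vals)) if not np.all(np.isnan(vals)) else float("nan")
    out = {f"ERODS_{k}": v for k, v in comp.items()}
    out["ERODS"] = parent
    out["ERODS_B"] = comp["Bplus"] + comp["Bminus"]
    out["ERODS_W"] = comp["Wplus"] + comp["Wminus"]
    out["ERODS_plus"] = comp["Bplus"] + comp["Wplus"]
    out["ERODS_minus"] = comp["Bminus"] + comp["Wminus"]
    return out


# ---------------------------------------------------------------------------
# per-block aggregation
# ---------------------------------------------------------------------------

def block_metrics(block: Block, events: pd.DataFrame) -> dict:
    """All metrics of one block, given the events assigned to it."""
    cf, rf = matching_fractions(block)
    ws, ls, p_win, p_stay = win_stay_lose_switch(events)
    ri_lr = repetition_index(events, "left_right")
    _, ri_b, ri_w = repetition_index(events, "better_worse")
    erds, erds_p, erds_m = erds_family(events)
    eods, eods_b, eods_w = eods_family(events, "better_worse")
    eods_lr = eods_family(events, "left_right")
    row = {
        "session_id": block.session_id,
        "block_id": block.block_id,
        "schedule_label": block.schedule_label,
        "n_trials": int(len(retained(block.trials))),
        "n_events": int(len(events)),
        "choice_fraction": cf,
        "reward_fraction": rf,
        "UM": deviation_from_matching(cf, rf),
        "p_win": p_win,
        "p_stay": p_stay,
        "WS": ws,
        "LS": ls,
        "RI_LR": ri_lr,
        "RI_B": ri_b,
        "RI_W": ri_w,
        "ERDS": erds,
        "ERDS_plus": erds_p,
        "ERDS_minus": erds_m,
        "EODS": eods,
        "EODS_B": eods_b,
        "EODS_W": eods_w,
        "EODS_LR": eods_lr,
    }
    row.update(erods_family(events))
    return row


def metric_table(
    trials: pd.DataFrame, within_block_only: bool = False
) -> pd.DataFrame:
    """One row of metrics per block of a validated trial table.

    Blocks whose metrics are all undefined are kept (flagged by NaN and
    ``n_events``), not dropped, so downstream exclusion is explicit.
    Undefined values serialize as empty fields when written with
    :func:`write_metric_table`.
    """
    rows = []
    events_by_block: dict = {}
    for _, sess in trials.groupby("session_id", sort=False):
        ev = derive_strategy_events(sess, within_block_only=within_block_only)
        sid = sess["session_id"].iloc[0]
        for bid, grp in ev.groupby("block_id", sort=False):
            events_by_block[(sid, bid)] = grp
    empty = pd.DataFrame(
        columns=["stay", "prev_win", "prev_better", "cur_better", "prev_choice", "choice"]
    )
    for block in iter_blocks(trials):
        ev = events_by_block.get((block.session_id, block.block_id), empty)
        rows.append(block_metrics(block, ev))
    return pd.DataFrame(rows)


def write_metric_table(table: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a metric table as delimited text, NaN (undefined) as empty."""
    table.to_csv(path, sep=sep, index=False, na_rep="")
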