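"""Trial-table data model, readers/writers, and strategy-event derivation.

The package's unit of raw data is the *trial table*: a long-format table with
one row per behavioral trial.  Option labels are ``"A"`` and ``"B"`` and map
onto the ``p_reward_A`` / ``p_reward_B`` columns (for mice A/B are the left and
right lick ports; for monkeys they are the two stimuli).  A trial on which the
animal made no response carries the literal choice ``"MISS"`` and status
``miss``; no-go trials keep whatever response the animal made but are marked
``no_go`` and are never rewarded.

Trial tables are plain :class:`pandas.DataFrame` objects with the column
contract in :data:`TRIAL_COLUMNS`; :func:`read_trials` validates the contract
so downstream code can rely on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Option labels used throughout the package.
OPTIONS = ("A", "B")
#: Literal encoding of a missed (no-response) trial in the ``choice`` column.
MISS = "MISS"
#: Allowed trial statuses.
STATUSES = ("go", "no_go", "miss")

#: Required trial-table columns, in canonical order.
TRIAL_COLUMNS = (
    "session_id",
    "block_id",
    "trial_index",
    "choice",
    "status",
    "reward",
    "p_reward_A",
    "p_reward_B",
)

#: Columns of a strategy-event table (see :func:`derive_strategy_events`).
EVENT_COLUMNS = (
    "session_id",
    "block_id",
    "trial_index",
    "stay",
    "prev_win",
    "prev_better",
    "cur_better",
    "prev_choice",
    "choice",
)


class SchemaError(ValueError):
    """A trial table is missing required columns."""


class ValidationError(ValueError):
    """A trial table violates a row- or block-level invariant."""


@dataclass(frozen=True)
class Block:
    """A maximal run of trials sharing one reward-probability assignment.

    The block is the unit over which all behavioral metrics are computed.
    ``better_option`` is the option with the larger base reward probability.
    """

    session_id: object
    block_id: object
    trials: pd.DataFrame
    better_option: str
    worse_option: str
    schedule_label: str

    @property
    def p_better(self) -> float:
        return float(self.trials[f"p_reward_{self.better_option}"].iloc[0])

    @property
    def p_worse(self) -> float:
        return float(self.trials[f"p_reward_{self.worse_option}"].iloc[0])


def schedule_label(p_better: float, p_worse: float) -> str:
    """Conventional name of a schedule, e.g. ``"40/10"`` for (0.4, 0.1)."""
    return f"{round(p_better * 100):g}/{round(p_worse * 100):g}"


def validate_trials(trials: pd.DataFrame) -> None:
    """Validate a trial table against the data-model invariants.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValidationError
        If any row or block violates an invariant; the message names the
        offending (0-based) row of the table.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table missing required columns: {missing}")

    def _bad(mask: pd.Series, what: str) -> None:
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0])
            raise ValidationError(f"{what} (first offending row {row})")

    _bad(~trials["reward"].isin([0, 1]), "reward must be 0 or 1")
    _bad(~trials["status"].isin(STATUSES), f"status must be one of {STATUSES}")
    _bad(
        ~trials["choice"].isin(list(OPTIONS) + [MISS]),
        f"choice must be one of {OPTIONS} or '{MISS}'",
    )
    _bad(
        (trials["status"] == "miss") != (trials["choice"] == MISS),
        "status 'miss' must coincide exactly with choice 'MISS'",
    )
    _bad(
        (trials["status"] != "go") & (trials["reward"] != 0),
        "miss/no-go trials cannot be rewarded",
    )
    for col in ("p_reward_A", "p_reward_B"):
        _bad(
            (trials[col] < 0) | (trials[col] > 1) | trials[col].isna(),
            f"{col} must lie in [0, 1]",
        )
    _bad(
        trials["p_reward_A"] == trials["p_reward_B"],
        "p_reward_A must differ from p_reward_B (better/worse undefined)",
    )

    for sid, sess in trials.groupby("session_id", sort=False):
        idx = sess["trial_index"].to_numpy()
        if np.any(np.diff(idx) <= 0):
            raise ValidationError(
                f"trial_index not strictly increasing in session {sid!r}"
            )
        for bid, blk in sess.groupby("block_id", sort=False):
            if blk["p_reward_A"].nunique() > 1 or blk["p_reward_B"].nunique() > 1:
                raise ValidationError(
                    f"block {bid!r} of session {sid!r} mixes reward probabilities"
                )


def read_trials(path, sep: str | None = None) -> pd.DataFrame:
    """Read and validate a delimited trial table.

    Parameters
    ----------
    path
        File path of a UTF-8 delimited text file with a header row naming the
        columns in :data:`TRIAL_COLUMNS`.
    sep
        Field delimiter.  ``None`` (default) accepts comma or tab, sniffing
        from the header line.

    Returns
    -------
    pandas.DataFrame
        Validated trial table, sessions in file order and trials sorted by
        ``trial_index`` within each session.
    """
    if sep is None:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    trials = pd.read_csv(path, sep=sep, dtype={"choice": str, "status": str})
    validate_trials(trials)
    order = {s: i for i, s in enumerate(trials["session_id"].drop_duplicates())}
    trials = trials.sort_values(
        ["session_id", "trial_index"],
        key=lambda c: c.map(order) if c.name == "session_id" else c,
        kind="stable",
    ).reset_index(drop=True)
    return trials


def write_trials(trials: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a trial table as delimited text readable by :func:`read_trials`.

    An empty table produces a header-only file; ``MISS`` choices are written
    as the literal string ``MISS``.
    """
    if len(trials):
        validate_trials(trials)
        out = trials.loc[:, list(TRIAL_COLUMNS)]
    else:
        out = pd.DataFrame(columns=list(TRIAL_COLUMNS))
    out.to_csv(path, sep=sep, index=False)


def retained(trials: pd.DataFrame) -> pd.DataFrame:
    """Trials kept for analysis: go trials only (miss and no-go removed)."""
    return trials[trials["status"] == "go"]


def iter_blocks(trials: pd.DataFrame):
    """Yield :class:`Block` objects in session/trial order."""
    for sid, sess in trials.groupby("session_id", sort=False):
        for bid, blk in sess.groupby("block_id", sort=False):
            p_a = float(blk["p_reward_A"].iloc[0])
            p_b = float(blk["p_reward_B"].iloc[0])
            better, worse = ("A", "B") if p_a > p_b else ("B", "A")
            yield Block(
                session_id=sid,
                block_id=bid,
                trials=blk,
                better_option=better,
                worse_option=worse,
                schedule_label=schedule_label(max(p_a, p_b), min(p_a, p_b)),
            )


def derive_strategy_events(
    session: pd.DataFrame, within_block_only: bool = False
) -> pd.DataFrame:
    """Label consecutive retained trials of one session as stay/switch events.

    Miss and no-go trials are first deleted, treating them as though they had
    not occurred, so an event may span such trials.  Each event pairs a
    *previous* and a *current* retained trial: ``stay`` means the same option
    was chosen on both; ``prev_win`` is the previous trial's reward;
    ``prev_better`` / ``cur_better`` record whether the previous / current
    choice was the better option *of its own block* (block switches are
    unsignalled, so events cross block boundaries by default and the event is
    assigned to the current trial's block).

    Parameters
    ----------
    session
        Trial table of a single session, sorted by ``trial_index``.
    within_block_only
        If True, drop events whose two trials lie in different blocks
        (sensitivity analysis).

    Returns
    -------
    pandas.DataFrame
        Event table with columns :data:`EVENT_COLUMNS`; empty if fewer than
        two retained trials.
    """
    if session["session_id"].nunique() > 1:
        raise ValueError("derive_strategy_events expects a single session")
    kept = retained(session)
    empty = pd.DataFrame(columns=list(EVENT_COLUMNS))
    if len(kept) < 2:
        return empty

    choice = kept["choice"].to_numpy()
    reward = kept["reward"].to_numpy()
    block = kept["block_id"].to_numpy()
    better = np.where(
        kept["p_reward_A"].to_numpy() > kept["p_reward_B"].to_numpy(), "A", "B"
    )
    chose_better = choice == better

    events = pd.DataFrame(
        {
            "session_id": kept["session_id"].to_numpy()[1:],
            "block_id": block[1:],
            "trial_index": kept["trial_index"].to_numpy()[1:],
            "stay": choice[1:] == choice[:-1],
            "prev_win": reward[:-1] == 1,
            "prev_better": chose_better[:-1],
            "cur_better": chose_better[1:],
            "prev_choice": choice[:-1],
            "choice": choice[1:],
        }
    )
    if within_block_only:
        events = events[(block[1:] == block[:-1])].reset_index(drop=True)
    return events


def derive_all_events(
    trials: pd.DataFrame, within_block_only: bool = False
) -> pd.DataFrame:
    """Concatenate :func:`derive_strategy_events` over every session."""
    parts = [
        derive_strategy_events(sess, within_block_only=within_block_only)
        for _, sess in trials.groupby("session_id", sort=False)
    ]
    parts = [p for p in parts if len(p)]
    if not parts:
        return pd.DataFrame(columns=list(EVENT_COLUMNS))
    return pd.concat(parts, ignore_index=True)
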