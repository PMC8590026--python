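"""Shared fixtures: toy trial tables, random event blocks, and the
brute-force conditional-entropy oracle used to cross-check the closed-form
metric implementations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from entromatch.io import TRIAL_COLUMNS


def make_session(
    choices,
    rewards,
    session_id="s1",
    block_ids=None,
    statuses=None,
    p_a=0.4,
    p_b=0.1,
    per_trial_probs=None,
):
    """Build a small trial table from parallel per-trial sequences.

    ``choices`` uses "A"/"B"/"MISS"; a MISS choice implies status "miss".
    ``per_trial_probs`` optionally gives (p_reward_A, p_reward_B) per trial.
    """
    n = len(choices)
    block_ids = block_ids if block_ids is not None else [1] * n
    if statuses is None:
        statuses = ["miss" if c == "MISS" else "go" for c in choices]
    if per_trial_probs is None:
        per_trial_probs = [(p_a, p_b)] * n
    rows = [
        (
            session_id,
            block_ids[t],
            t + 1,
            choices[t],
            statuses[t],
            int(rewards[t]),
            per_trial_probs[t][0],
            per_trial_probs[t][1],
        )
        for t in range(n)
    ]
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))


def random_event_block(rng, n):
    """Random strategy-event table with random per-cell stay biases.

    Reward, option role and side of the previous trial are drawn i.i.d. with
    random marginals; the stay probability differs by (reward, role) cell so
    the conditional entropies take nontrivial values.
    """
    p_win = rng.uniform(0.05, 0.95)
    p_better = rng.uniform(0.05, 0.95)
    p_stay = rng.uniform(0.0, 1.0, size=4)  # per (win, better) cell
    win = rng.random(n) < p_win
    better = rng.random(n) < p_better
    cell = 2 * win.astype(int) + better.astype(int)
    stay = rng.random(n) < p_stay[cell]
    prev_choice = np.where(rng.random(n) < 0.5, "A", "B")
    choice = np.where(stay, prev_choice, np.where(prev_choice == "A", "B", "A"))
    return pd.DataFrame(
        {
            "session_id": "s1",
            "block_id": 1,
            "trial_index": np.arange(2, n + 2),
            "stay": stay,
            "prev_win": win,
            "prev_better": better,
            "cur_better": rng.random(n) < p_better,
            "prev_choice": prev_choice,
            "choice": choice,
        }
    )


def entropy_oracle(events, conditioners=()):
    """Brute-force H(str | conditioners) in bits from joint count tables.

    Tabulates the joint counts of (strategy, conditioner cell) and returns
    H(joint) − H(conditioner), entirely independent of the closed-form
    per-cell implementation.  NaN on an empty event table.
    """
    from collections import Counter

    if len(events) == 0:
        return float("nan")
    cols = {
        "reward": events["prev_win"],
        "option_role": events["prev_better"],
        "side": events["prev_choice"] == "A",
    }
    keys = list(zip(*[cols[c] for c in conditioners])) if conditioners else [()] * len(events)
    joint = Counter(zip(events["stay"], map(tuple, map(list, keys))))
    marg = Counter(map(tuple, map(list, keys)))
    n = len(events)

    def h(counter):
        p = np.array(list(counter.values()), dtype=float) / n
        return float(-(p * np.log2(p)).sum())

    return h(joint) - h(marg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
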