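"""Task environments and synthetic behavioral cohorts.

Two paradigms are generated:

``mouse_foraging``
    A dynamic foraging task: blocks of uniformly distributed length (40–80
    trials by default) with unsignalled switches between reward schedules
    drawn from {40/10, 40/5}.  Rewards are *baited*: a reward assigned to a
    side stays available until that side is next chosen, so the effective
    reward probability of a neglected side grows as ``1 − (1 − p)^k`` over
    ``k`` unvisited trials.  5% of trials carry a no-go cue (response is
    unrewarded) and a small fraction are misses (no response).

``monkey_reversal``
    A probabilistic reversal task in 80-trial superblocks: the reward
    probabilities of the two stimuli (80/20 or 70/30) reverse once, at a
    trial drawn uniformly from 30–50.  No baiting; each superblock starts
    with fresh stimuli, so it is treated as its own session (the agent's
    latent state resets).

Environment randomness and agent randomness use separate generator streams
spawned from a master seed, so cohorts are reproducible end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .io import schedule_label
from .models import ModelSpec, generate_session

MOUSE_SCHEDULES = ((0.4, 0.1), (0.4, 0.05))
MONKEY_SCHEDULES = ((0.8, 0.2), (0.7, 0.3))


@dataclass(frozen=True)
class EnvironmentConfig:
    """Generative definition of a task environment.

    ``schedules`` are (p_better, p_worse) pairs; ``block_length`` the
    inclusive uniform range of mouse block lengths; ``reversal_window`` the
    inclusive range of the monkey reversal trial within an 80-trial
    superblock.  ``miss_rate`` defaults to the observed ~0.9% of mouse trials
    (about 3.6 per 400-trial session); ``no_go_rate`` to 5%.
    """

    paradigm: str  # "mouse_foraging" | "monkey_reversal"
    schedules: tuple = ()
    baited: bool | None = None
    block_length: tuple[int, int] = (40, 80)
    superblock_length: int = 80
    reversal_window: tuple[int, int] = (30, 50)
    no_go_rate: float = 0.05
    miss_rate: float = 0.009
    n_blocks: int = 8
    n_superblocks: int = 1

    def __post_init__(self):
        if self.paradigm not in ("mouse_foraging", "monkey_reversal"):
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        schedules = self.schedules or (
            MOUSE_SCHEDULES if self.paradigm == "mouse_foraging" else MONKEY_SCHEDULES
        )
        object.__setattr__(self, "schedules", tuple(schedules))
        for p_hi, p_lo in self.schedules:
            if not (0 <= p_lo <= 1 and 0 <= p_hi <= 1):
                raise ValueError(f"reward probabilities must lie in [0,1]: {(p_hi, p_lo)}")
            if p_hi == p_lo:
                raise ValueError("schedule probabilities must differ")
        if self.baited is None:
            object.__setattr__(self, "baited", self.paradigm == "mouse_foraging")
        lo, hi = self.reversal_window
        if not (1 <= lo <= hi <= self.superblock_length):
            raise ValueError("reversal window must lie within the superblock")
        for rate in (self.no_go_rate, self.miss_rate):
            if not (0 <= rate < 1):
                raise ValueError("trial-status rates must lie in [0, 1)")


def step_environment(armed, p_a, p_b, choice, rng, baited):
    """Advance the reward process by one trial.

    Baited: each unarmed side arms with its base probability at trial start;
    choosing an armed side harvests (reward 1) and disarms it.  Non-baited:
    the chosen option is rewarded with its base probability.  ``choice`` is
    0/1 or None (no harvest this trial).  Returns ``(reward, armed')``.
    """
    if not baited:
        if choice is None:
            return 0, armed
        p = p_a if choice == 0 else p_b
        return int(rng.random() < p), armed
    a0, a1 = armed
    if not a0:
        a0 = rng.random() < p_a
    if not a1:
        a1 = rng.random() < p_b
    reward = 0
    if choice == 0 and a0:
        reward, a0 = 1, False
    elif choice == 1 and a1:
        reward, a1 = 1, False
    return reward, (a0, a1)


class TaskEnvironment:
    """Reward process over a fixed trial plan.

    ``trial_plan`` has one row per trial with columns ``block_id``,
    ``p_reward_A``, ``p_reward_B``, ``status``; :meth:`advance` consumes one
    trial per call and returns the harvested reward.
    """

    def __init__(self, trial_plan: pd.DataFrame, baited: bool, rng: np.random.Generator):
        self.trial_plan = trial_plan
        self.baited = baited
        self.rng = rng
        self._t = 0
        self._armed = (False, False)
        self._p_a = trial_plan["p_reward_A"].to_numpy()
        self._p_b = trial_plan["p_reward_B"].to_numpy()

    def advance(self, choice: str | None) -> int:
        idx = {"A": 0, "B": 1, None: None}[choice]
        reward, self._armed = step_environment(
            self._armed, self._p_a[self._t], self._p_b[self._t], idx, self.rng, self.baited
        )
        self._t += 1
        return reward


def _mouse_plan(config: EnvironmentConfig, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = config.block_length
    rows = []
    prev = None
    for b in range(config.n_blocks):
        length = int(rng.integers(lo, hi + 1))
        # redraw until the (p_A, p_B) assignment actually changes at the switch
        while True:
            p_hi, p_lo = config.schedules[rng.integers(len(config.schedules))]
            assign = (p_hi, p_lo) if rng.random() < 0.5 else (p_lo, p_hi)
            if assign != prev:
                break
        prev = assign
        rows.extend((b + 1, assign[0], assign[1]) for _ in range(length))
    plan = pd.DataFrame(rows, columns=["block_id", "p_reward_A", "p_reward_B"])
    u = rng.random(len(plan))
    status = np.where(
        u < config.miss_rate,
        "miss",
        np.where(u < config.miss_rate + config.no_go_rate, "no_go", "go"),
    )
    plan["status"] = status
    return plan


def _monkey_plan(config: EnvironmentConfig, rng: np.random.Generator) -> pd.DataFrame:
    p_hi, p_lo = config.schedules[rng.integers(len(config.schedules))]
    first = (p_hi, p_lo) if rng.random() < 0.5 else (p_lo, p_hi)
    lo, hi = config.reversal_window
    reversal = int(rng.integers(lo, hi + 1))  # first trial with reversed probs
    rows = []
    for t in range(1, config.superblock_length + 1):
        if t < reversal:
            rows.append((1, first[0], first[1], "go"))
        else:
            rows.append((2, first[1], first[0], "go"))
    return pd.DataFrame(rows, columns=["block_id", "p_reward_A", "p_reward_B", "status"])


def build_environment(config: EnvironmentConfig, rng: np.random.Generator) -> TaskEnvironment:
    """Draw a block/superblock schedule and wrap it in a reward process.

    A mouse environment covers one session of ``n_blocks`` blocks; a monkey
    environment covers a single 80-trial superblock.
    """
    if config.paradigm == "mouse_foraging":
        plan = _mouse_plan(config, rng)
    else:
        plan = _monkey_plan(config, rng)
    return TaskEnvironment(plan, config.baited, rng)


def _unit_sessions(spec, params, config, seedseq, unit_tag):
    """All sessions of one simulated unit (monkey reps emit one session per superblock)."""
    frames = []
    n_sess = 1 if config.paradigm == "mouse_foraging" else config.n_superblocks
    children = seedseq.spawn(2 * n_sess)
    for s in range(n_sess):
        env_rng = np.random.default_rng(children[2 * s])
        agent_rng = np.random.default_rng(children[2 * s + 1])
        env = build_environment(config, env_rng)
        sid = unit_tag if n_sess == 1 else f"{unit_tag}_sb{s:03d}"
        frames.append(generate_session(spec, params, env, agent_rng, session_id=sid))
    return frames


def simulate_cohort(
    model_spec: ModelSpec,
    params_per_unit,
    env_config: EnvironmentConfig,
    n_reps: int = 1,
    master_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Roll out ``n_reps`` sessions per unit and compute block metrics.

    ``params_per_unit`` is a sequence of parameter dicts, one per simulated
    animal/unit.  Returns ``(trials, metric_table)``; session ids encode unit
    and repetition.  Deterministic given ``master_seed``.
    """
    ss = np.random.SeedSequence(master_seed)
    unit_seeds = ss.spawn(len(params_per_unit) * n_reps)
    frames = []
    k = 0
    for i, params in enumerate(params_per_unit):
        for j in range(n_reps):
            tag = f"unit{i:03d}_rep{j:03d}"
            frames.extend(_unit_sessions(model_spec, params, env_config, unit_seeds[k], tag))
            k += 1
    trials = pd.concat(frames, ignore_index=True)
    return trials, _metrics.metric_table(trials)


def sample_rl2_params(rng: np.random.Generator) -> dict:
    """Random RL2 parameters for heterogeneous cohorts.

    Learning rates uniform on (0.02, 0.98), β log-uniform on [0.25, 40],
    decay fixed at 0.1 — a population spanning near-random to near-greedy
    agents.
    """
    return {
        "alpha_rew": float(rng.uniform(0.02, 0.98)),
        "alpha_unrew": float(rng.uniform(0.02, 0.98)),
        "decay_rate": 0.1,
        "beta": float(np.exp(rng.uniform(np.log(0.25), np.log(40.0)))),
    }


def heterogeneous_cohort(
    env_config: EnvironmentConfig,
    n_units: int,
    seed: int = 0,
    param_sampler=sample_rl2_params,
    model_name: str = "RL2",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort with unit-level parameters drawn from a population distribution.

    One session (or superblock set) per unit; used to probe metric→matching
    relationships without real data.  Returns ``(trials, metric_table)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    spec = ModelSpec.from_name(model_name)
    params = [param_sampler(rng) for _ in range(n_units)]
    return simulate_cohort(spec, params, env_config, n_reps=1, master_seed=seed + 1)
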