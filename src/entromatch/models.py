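"""Trial-wise generative models of two-option choice.

Nine models are available by name, all sharing one interface for likelihood
evaluation and simulation:

``RL1``
    Learns the value of the chosen option only
    (``Q_C ← Q_C + α(R − Q_C)``, with ``α = α_rew`` after reward and
    ``α_unrew`` otherwise); the unchosen value is untouched.
``RL2``
    As RL1, plus the unchosen value decays toward zero
    (``Q_U ← Q_U − decay_rate·Q_U``).
``RL1+CM``, ``RL2+CM``
    Add a choice-memory (CM) trace: ``C_C ← C_C + γ(1 − C_C)``,
    ``C_U ← C_U − γ·C_U``, weighted into the decision values by ``w_cm``
    (positive = perseverate on recent choices, negative = switch away).
``RL2+LM``
    Adds a loss-memory (LM) term: after an unrewarded trial the previously
    chosen option carries ``L = −E_rpe``, where ``E_rpe`` is the expected
    unsigned reward-prediction error (expected uncertainty), updated every
    trial as ``E_rpe ← E_rpe + γ(|R − Q_C| − E_rpe)`` using the pre-update
    ``Q_C``.  The term enters the decision value weighted by ``w_lm``.
``RL2+CM+LM``
    Both components, sharing a single ``γ``.
``RL2+CM+``, ``RL2+LM+``
    Sign-restricted variants with ``w_cm`` (resp. ``w_lm``) bounded to [0, 1].
``timescales``
    Values learned in parallel on three fixed timescales τ = (2, 20, 100)
    trials, each equivalent to RL2 with ``α_rew = α_unrew = decay_rate =
    1/τ``; the decision value is a normalized weighted sum of the three and
    choice follows the ratio rule ``P(A) = DV_A / (DV_A + DV_B)``.

All other models choose through a logistic:
``P(A) = 1 / (1 + exp(−β (DV_A − DV_B)))`` with inverse temperature
``β ∈ [0, 100]``.

Per-trial update order: the choice probability for trial *t* is computed from
the state entering the trial; after the choice and reward are observed, the
LM update runs first (it needs the pre-update value), then the value update,
then the CM update.  Values start at 0.5 (midpoint of the reward range),
traces at 0, at the start of each session (or monkey superblock, where new
stimuli appear).  Miss and no-go trials are treated as though they had not
occurred: no likelihood term and no state update.

Likelihood evaluation over a session runs through numba-compiled kernels;
the pure-Python per-trial operations below define the same computation and
are used for simulation and as an independently steppable reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .io import MISS, OPTIONS, retained

TIMESCALES = (2.0, 20.0, 100.0)

MODEL_NAMES = (
    "RL1",
    "RL2",
    "RL1+CM",
    "RL2+CM",
    "RL2+LM",
    "RL2+CM+LM",
    "RL2+CM+",
    "RL2+LM+",
    "timescales",
)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model structure: value rule, memory components, bounds."""

    name: str
    value_rule: str  # "RL1" | "RL2" | "timescales"
    use_cm: bool = False
    use_lm: bool = False
    cm_sign: str = "free"  # "free" -> w_cm in [-1,1]; "nonnegative" -> [0,1]
    lm_sign: str = "free"
    gamma_mode: str = "fitted"  # "fitted" | "tied_to_alpha_mean"

    def __post_init__(self):
        if self.use_lm and self.value_rule != "RL2":
            raise ValueError("the loss-memory component requires the RL2 value rule")
        if self.value_rule == "timescales" and (self.use_cm or self.use_lm):
            raise ValueError("the timescales model takes no memory components")

    @classmethod
    def from_name(cls, name: str, gamma_mode: str = "fitted") -> "ModelSpec":
        """Build a spec from a model name such as ``"RL2+CM+LM"``."""
        if name == "timescales":
            return cls(name=name, value_rule="timescales")
        parts = name.split("+")
        rule = parts[0]
        if rule not in ("RL1", "RL2"):
            raise ValueError(
                f"unknown model {name!r}; valid names: {', '.join(MODEL_NAMES)}"
            )
        use_cm = use_lm = False
        cm_sign = lm_sign = "free"
        comps = parts[1:]
        # a trailing '+' in e.g. "RL2+CM+" splits into ['CM', '']
        for i, comp in enumerate(comps):
            if comp == "CM":
                use_cm = True
                if i + 1 < len(comps) and comps[i + 1] == "":
                    cm_sign = "nonnegative"
            elif comp == "LM":
                use_lm = True
                if i + 1 < len(comps) and comps[i + 1] == "":
                    lm_sign = "nonnegative"
            elif comp != "":
                raise ValueError(
                    f"unknown model {name!r}; valid names: {', '.join(MODEL_NAMES)}"
                )
        spec = cls(
            name=name,
            value_rule=rule,
            use_cm=use_cm,
            use_lm=use_lm,
            cm_sign=cm_sign,
            lm_sign=lm_sign,
            gamma_mode=gamma_mode,
        )
        return spec

    # -- parameter vector ---------------------------------------------------

    @property
    def uses_gamma(self) -> bool:
        return self.use_cm or self.use_lm

    def param_names(self) -> tuple[str, ...]:
        """Fitted parameters, in canonical order."""
        if self.value_rule == "timescales":
            return ("w_fast1", "w_fast2", "w_slow")
        names = ["alpha_rew", "alpha_unrew"]
        if self.value_rule == "RL2":
            names.append("decay_rate")
        names.append("beta")
        if self.uses_gamma and self.gamma_mode == "fitted":
            names.append("gamma")
        if self.use_cm:
            names.append("w_cm")
        if self.use_lm:
            names.append("w_lm")
        return tuple(names)

    def bounds(self) -> tuple[tuple[float, float], ...]:
        """Box bounds matching :meth:`param_names`."""
        table = {
            "alpha_rew": (0.0, 1.0),
            "alpha_unrew": (0.0, 1.0),
            "decay_rate": (0.0, 1.0),
            "beta": (0.0, 100.0),
            "gamma": (0.0, 1.0),
            "w_cm": (0.0, 1.0) if self.cm_sign == "nonnegative" else (-1.0, 1.0),
            "w_lm": (0.0, 1.0) if self.lm_sign == "nonnegative" else (-1.0, 1.0),
            "w_fast1": (0.0, 1.0),
            "w_fast2": (0.0, 1.0),
            "w_slow": (0.0, 1.0),
        }
        return tuple(table[n] for n in self.param_names())

    @property
    def n_fitted(self) -> int:
        """Free-parameter count for AIC.

        The normalized timescale weight triple counts as two; a γ tied to
        mean(α_rew, α_unrew) is not counted.
        """
        if self.value_rule == "timescales":
            return 2
        return len(self.param_names())

    def validate_params(self, params: dict) -> None:
        for name, (lo, hi) in zip(self.param_names(), self.bounds()):
            if name not in params:
                raise ValueError(f"missing parameter {name!r} for model {self.name}")
            v = params[name]
            if not (lo - 1e-12 <= v <= hi + 1e-12):
                raise ValueError(
                    f"parameter {name}={v} outside bounds [{lo}, {hi}] for {self.name}"
                )

    def gamma_value(self, params: dict) -> float:
        if not self.uses_gamma:
            return 0.0
        if self.gamma_mode == "tied_to_alpha_mean":
            return 0.5 * (params["alpha_rew"] + params["alpha_unrew"])
        return params["gamma"]


@dataclass
class LatentState:
    """Per-trial latent variables of every model family.

    ``q`` are option values (A, B); ``c`` choice-memory traces; ``e_rpe`` the
    expected unsigned reward-prediction error; ``lm`` the loss-memory value of
    the previously chosen option (0 after a win, −e_rpe after a loss);
    ``last_choice`` indexes which option that was (−1 before the first
    update); ``q_ts`` the per-timescale values (3 × 2).
    """

    q: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))
    c: np.ndarray = field(default_factory=lambda: np.zeros(2))
    e_rpe: float = 0.0
    lm: float = 0.0
    last_choice: int = -1
    q_ts: np.ndarray = field(default_factory=lambda: np.full((3, 2), 0.5))

    def copy(self) -> "LatentState":
        return LatentState(
            q=self.q.copy(),
            c=self.c.copy(),
            e_rpe=self.e_rpe,
            lm=self.lm,
            last_choice=self.last_choice,
            q_ts=self.q_ts.copy(),
        )


def initial_state() -> LatentState:
    return LatentState()


def _choice_index(choice: str) -> int:
    return OPTIONS.index(choice)


# ---------------------------------------------------------------------------
# per-trial operations (pure-Python reference path)
# ---------------------------------------------------------------------------

def value_update(
    state: LatentState, choice: str, reward: int, params: dict, value_rule: str
) -> LatentState:
    """Update option values after one observed (choice, reward).

    Chosen value moves toward the reward by ``α_rew`` or ``α_unrew``; the
    unchosen value is unchanged (RL1) or decays by ``decay_rate`` (RL2).  The
    timescales rule applies the RL2 form at rate 1/τ on each timescale.
    """
    new = state.copy()
    ch = _choice_index(choice)
    un = 1 - ch
    if value_rule == "timescales":
        for k, tau in enumerate(TIMESCALES):
            rate = 1.0 / tau
            new.q_ts[k, ch] += rate * (reward - new.q_ts[k, ch])
            new.q_ts[k, un] -= rate * new.q_ts[k, un]
        return new
    alpha = params["alpha_rew"] if reward == 1 else params["alpha_unrew"]
    new.q[ch] += alpha * (reward - new.q[ch])
    if value_rule == "RL2":
        new.q[un] -= params["decay_rate"] * new.q[un]
    return new


def lm_update(state: LatentState, choice: str, reward: int, params: dict, gamma: float) -> LatentState:
    """Update expected uncertainty and the loss-memory value.

    Must run *before* :func:`value_update` on the trial: the unsigned
    prediction error ``|R − Q_C|`` uses the chosen option's value as it stood
    when the prediction was made.
    """
    new = state.copy()
    ch = _choice_index(choice)
    new.e_rpe += gamma * (abs(reward - state.q[ch]) - new.e_rpe)
    new.lm = 0.0 if reward == 1 else -new.e_rpe
    return new


def cm_update(state: LatentState, choice: str, gamma: float) -> LatentState:
    """Decay choice-memory traces toward the indicator of the current choice."""
    new = state.copy()
    ch = _choice_index(choice)
    un = 1 - ch
    new.c[ch] += gamma * (1.0 - new.c[ch])
    new.c[un] -= gamma * new.c[un]
    return new


def step_state(
    state: LatentState, spec: ModelSpec, params: dict, choice: str, reward: int
) -> LatentState:
    """Full per-trial state transition in the canonical order LM→value→CM."""
    gamma = spec.gamma_value(params)
    new = state
    if spec.use_lm:
        new = lm_update(new, choice, reward, params, gamma)
    new = value_update(new, choice, reward, params, spec.value_rule)
    if spec.use_cm:
        new = cm_update(new, choice, gamma)
    new.last_choice = _choice_index(choice)
    return new


def decision_values(state: LatentState, spec: ModelSpec, params: dict) -> tuple[float, float]:
    """Decision values (DV_A, DV_B) entering the next trial's choice rule.

    The CM trace is weighted into both options; the LM term applies only to
    the option chosen on the previous trial.
    """
    if spec.value_rule == "timescales":
        w = np.array([params["w_fast1"], params["w_fast2"], params["w_slow"]], float)
        s = w.sum()
        w = w / s if s > 0 else np.full(3, 1.0 / 3.0)
        dv = w @ state.q_ts
        return float(dv[0]), float(dv[1])
    dv = state.q.copy()
    if spec.use_cm:
        dv = dv + params["w_cm"] * state.c
    if spec.use_lm and state.last_choice >= 0:
        dv[state.last_choice] += params["w_lm"] * state.lm
    return float(dv[0]), float(dv[1])


def choice_probability(
    dv_a: float, dv_b: float, params: dict, value_rule: str
) -> float:
    """Probability of choosing option A from the decision values.

    Logistic of ``β(DV_A − DV_B)`` for the sigmoid families; the ratio rule
    ``DV_A / (DV_A + DV_B)`` for the timescales model, with the degenerate
    0/0 case returning 0.5.
    """
    if value_rule == "timescales":
        total = dv_a + dv_b
        return 0.5 if total == 0 else dv_a / total
    x = params["beta"] * (dv_a - dv_b)
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    ex = math.exp(x)
    return ex / (1.0 + ex)


# ---------------------------------------------------------------------------
# compiled session kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _loglik_sigmoid(
    choices,
    rewards,
    alpha_rew,
    alpha_unrew,
    decay,
    beta,
    gamma,
    w_cm,
    w_lm,
    use_decay,
    use_cm,
    use_lm,
    p_a,
):  # pragma: no cover - exercised via session_log_likelihood
    q0 = 0.5
    q1 = 0.5
    c0 = 0.0
    c1 = 0.0
    e = 0.0
    lm = 0.0
    last = -1
    ll = 0.0
    for t in range(choices.shape[0]):
        dv0 = q0
        dv1 = q1
        if use_cm:
            dv0 += w_cm * c0
            dv1 += w_cm * c1
        if use_lm and last >= 0:
            if last == 0:
                dv0 += w_lm * lm
            else:
                dv1 += w_lm * lm
        x = beta * (dv0 - dv1)
        if x >= 0:
            p0 = 1.0 / (1.0 + math.exp(-x))
        else:
            ex = math.exp(x)
            p0 = ex / (1.0 + ex)
        p_a[t] = p0
        ch = choices[t]
        r = rewards[t]
        z = x if ch == 0 else -x
        if z >= 0:
            ll -= math.log1p(math.exp(-z))
        else:
            ll += z - math.log1p(math.exp(z))
        if use_lm:
            qc = q0 if ch == 0 else q1
            e += gamma * (abs(r - qc) - e)
            lm = 0.0 if r == 1 else -e
        a = alpha_rew if r == 1 else alpha_unrew
        if ch == 0:
            q0 += a * (r - q0)
            if use_decay:
                q1 -= decay * q1
        else:
            q1 += a * (r - q1)
            if use_decay:
                q0 -= decay * q0
        if use_cm:
            if ch == 0:
                c0 += gamma * (1.0 - c0)
                c1 -= gamma * c1
            else:
                c1 += gamma * (1.0 - c1)
                c0 -= gamma * c0
        last = ch
    return ll


@njit(cache=True)
def _loglik_timescales(choices, rewards, w0, w1, w2, p_a):  # pragma: no cover
    n_ts = 3
    taus = (2.0, 20.0, 100.0)
    q = np.full((n_ts, 2), 0.5)
    ws = w0 + w1 + w2
    if ws > 0:
        v0 = w0 / ws
        v1 = w1 / ws
        v2 = w2 / ws
    else:
        v0 = v1 = v2 = 1.0 / 3.0
    ll = 0.0
    for t in range(choices.shape[0]):
        dva = v0 * q[0, 0] + v1 * q[1, 0] + v2 * q[2, 0]
        dvb = v0 * q[0, 1] + v1 * q[1, 1] + v2 * q[2, 1]
        total = dva + dvb
        p0 = 0.5 if total == 0.0 else dva / total
        p_a[t] = p0
        ch = choices[t]
        r = rewards[t]
        p = p0 if ch == 0 else 1.0 - p0
        if p < 1e-12:
            p = 1e-12
        ll += math.log(p)
        for k in range(n_ts):
            rate = 1.0 / taus[k]
            q[k, ch] += rate * (r - q[k, ch])
            q[k, 1 - ch] -= rate * q[k, 1 - ch]
    return ll


def _encode_session(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    kept = retained(trials)
    choices = (kept["choice"] == OPTIONS[1]).to_numpy(dtype=np.int64)
    rewards = kept["reward"].to_numpy(dtype=np.float64)
    return choices, rewards


def session_log_likelihood(
    spec: ModelSpec, params: dict, trials: pd.DataFrame
) -> tuple[float, np.ndarray]:
    """Log-likelihood of one session's retained choices under a model.

    Miss and no-go trials are removed before stepping; the latent state
    evolves in trial order from the initial state.  Returns ``(logL, p_A)``
    where ``p_A[t]`` is the model's probability of choosing option A on the
    t-th retained trial.

    Raises ``ValueError`` on a session with no retained trials.
    """
    spec.validate_params(params)
    choices, rewards = _encode_session(trials)
    if choices.size == 0:
        raise ValueError("session has no retained trials")
    p_a = np.empty(choices.size)
    if spec.value_rule == "timescales":
        ll = _loglik_timescales(
            choices, rewards, params["w_fast1"], params["w_fast2"], params["w_slow"], p_a
        )
        return float(ll), p_a
    ll = _loglik_sigmoid(
        choices,
        rewards,
        params["alpha_rew"],
        params["alpha_unrew"],
        params.get("decay_rate", 0.0),
        params["beta"],
        spec.gamma_value(params),
        params.get("w_cm", 0.0),
        params.get("w_lm", 0.0),
        spec.value_rule == "RL2",
        spec.use_cm,
        spec.use_lm,
        p_a,
    )
    return float(ll), p_a


def session_log_likelihood_stepped(
    spec: ModelSpec, params: dict, trials: pd.DataFrame
) -> tuple[float, np.ndarray]:
    """Reference likelihood composed from the public per-trial operations.

    Same contract as :func:`session_log_likelihood`; kept as an independently
    steppable path (and used to cross-check the compiled kernels).
    """
    spec.validate_params(params)
    kept = retained(trials)
    if len(kept) == 0:
        raise ValueError("session has no retained trials")
    state = initial_state()
    ll = 0.0
    p_a = np.empty(len(kept))
    for t, (choice, reward) in enumerate(
        zip(kept["choice"].to_numpy(), kept["reward"].to_numpy())
    ):
        dv_a, dv_b = decision_values(state, spec, params)
        p = choice_probability(dv_a, dv_b, params, spec.value_rule)
        p_a[t] = p
        p_obs = p if choice == OPTIONS[0] else 1.0 - p
        ll += math.log(max(p_obs, 1e-300))
        state = step_state(state, spec, params, choice, int(reward))
    return ll, p_a


def generate_session(
    spec: ModelSpec,
    params: dict,
    environment,
    rng: np.random.Generator,
    session_id: str = "sim",
) -> pd.DataFrame:
    """Roll out one session of an agent interacting with a task environment.

    ``environment`` provides a ``trial_plan`` DataFrame (columns
    ``block_id``, ``p_reward_A``, ``p_reward_B``, ``status``) and an
    ``advance(choice)`` method returning the reward (``choice=None`` when no
    option is harvested).  Choices are sampled from the model's choice
    probability using ``rng``; on no-go trials the sampled response goes
    unrewarded, on miss trials there is no response, and neither updates the
    agent's state.

    Returns a validated trial table, reproducible given the generators.
    """
    spec.validate_params(params)
    state = initial_state()
    plan = environment.trial_plan
    rows = []
    statuses = plan["status"].to_numpy()
    block_ids = plan["block_id"].to_numpy()
    p_as = plan["p_reward_A"].to_numpy()
    p_bs = plan["p_reward_B"].to_numpy()
    for t in range(len(plan)):
        status = statuses[t]
        dv_a, dv_b = decision_values(state, spec, params)
        p = choice_probability(dv_a, dv_b, params, spec.value_rule)
        if status == "miss":
            environment.advance(None)
            choice, reward = MISS, 0
        else:
            choice = OPTIONS[0] if rng.random() < p else OPTIONS[1]
            if status == "no_go":
                environment.advance(None)
                reward = 0
            else:
                reward = environment.advance(choice)
                state = step_state(state, spec, params, choice, reward)
        rows.append(
            (session_id, block_ids[t], t + 1, choice, status, reward, p_as[t], p_bs[t])
        )
    return pd.DataFrame(
        rows,
        columns=[
            "session_id",
            "block_id",
            "trial_index",
            "choice",
            "status",
            "reward",
            "p_reward_A",
            "p_reward_B",
        ],
    )
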