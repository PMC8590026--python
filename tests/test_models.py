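"""RL model update rules, choice rules, likelihood, and generation."""

import math

import numpy as np
import pandas as pd
import pytest

import entromatch as em
from entromatch.models import (
    initial_state,
    session_log_likelihood_stepped,
)

from conftest import make_session


def _flat_env(n, p_a=0.4, p_b=0.1, baited=True, seed=0):
    plan = pd.DataFrame(
        {"block_id": 1, "p_reward_A": p_a, "p_reward_B": p_b, "status": "go"},
        index=range(n),
    )
    return em.TaskEnvironment(plan, baited, np.random.default_rng(seed))


RL2_PARAMS = dict(alpha_rew=0.5, alpha_unrew=0.3, decay_rate=0.1, beta=5.0)
FULL_PARAMS = dict(
    alpha_rew=0.5, alpha_unrew=0.3, decay_rate=0.1, beta=5.0, gamma=0.4,
    w_cm=0.3, w_lm=0.4,
)


class TestSpecs:
    @pytest.mark.parametrize("name", em.MODEL_NAMES)
    def test_every_model_buildable(self, name):
        spec = em.ModelSpec.from_name(name)
        assert spec.name == name
        assert spec.n_fitted >= 2

    def test_sign_restricted_bounds(self):
        spec = em.ModelSpec.from_name("RL2+CM+")
        names, bounds = spec.param_names(), spec.bounds()
        assert bounds[names.index("w_cm")] == (0.0, 1.0)
        spec = em.ModelSpec.from_name("RL2+CM+LM")
        names, bounds = spec.param_names(), spec.bounds()
        assert bounds[names.index("w_cm")] == (-1.0, 1.0)
        assert bounds[names.index("beta")] == (0.0, 100.0)

    def test_tied_gamma_not_a_parameter(self):
        spec = em.ModelSpec.from_name("RL2+CM", gamma_mode="tied_to_alpha_mean")
        assert "gamma" not in spec.param_names()
        assert spec.gamma_value({"alpha_rew": 0.5, "alpha_unrew": 0.3}) == pytest.approx(0.4)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="RL2\\+CM\\+LM"):
            em.ModelSpec.from_name("RL3")

    def test_timescales_counts_two_parameters(self):
        assert em.ModelSpec.from_name("timescales").n_fitted == 2


class TestUpdates:
    def test_chosen_value_update(self):
        state = initial_state()
        new = em.value_update(state, "A", 1, RL2_PARAMS, "RL2")
        assert new.q[0] == pytest.approx(0.75)  # 0.5 + 0.5*(1-0.5)

    def test_rl2_unchosen_decay(self):
        state = initial_state()
        state.q[:] = [0.5, 0.8]
        new = em.value_update(state, "A", 1, RL2_PARAMS, "RL2")
        assert new.q[1] == pytest.approx(0.72)

    def test_rl1_unchosen_untouched(self):
        state = initial_state()
        state.q[:] = [0.5, 0.8]
        new = em.value_update(state, "A", 0, RL2_PARAMS, "RL1")
        assert new.q[1] == 0.8
        assert new.q[0] == pytest.approx(0.5 + 0.3 * (0 - 0.5))

    def test_lm_update_examples(self):
        state = initial_state()
        state.q[:] = [0.6, 0.5]
        state.e_rpe = 0.2
        new = em.lm_update(state, "A", 1, {}, gamma=0.5)
        assert new.e_rpe == pytest.approx(0.3)
        assert new.lm == 0.0
        new = em.lm_update(state, "A", 0, {}, gamma=0.5)
        assert new.e_rpe == pytest.approx(0.4)
        assert new.lm == pytest.approx(-0.4)

    def test_lm_uses_pre_update_value(self):
        """E_rpe is driven by |R − Q| with Q as it stood before the value update."""
        spec = em.ModelSpec.from_name("RL2+LM")
        params = dict(alpha_rew=0.5, alpha_unrew=0.3, decay_rate=0.0, beta=1.0, gamma=1.0)
        state = em.step_state(initial_state(), spec, params, "A", 1)
        # pre-update Q_A = 0.5, so E_rpe = |1 − 0.5| = 0.5 (not |1 − 0.75|)
        assert state.e_rpe == pytest.approx(0.5)

    def test_cm_update_examples(self):
        state = initial_state()
        new = em.cm_update(state, "A", gamma=0.2)
        assert new.c[0] == pytest.approx(0.2)
        state.c[:] = [0.0, 0.5]
        new = em.cm_update(state, "A", gamma=0.2)
        assert new.c[1] == pytest.approx(0.4)

    def test_cm_geometric_limit(self):
        state = initial_state()
        state.c[:] = [0.0, 1.0]
        for t in range(1, 51):
            state = em.cm_update(state, "A", gamma=0.3)
            assert state.c[0] == pytest.approx(1 - 0.7**t)
            assert state.c[1] == pytest.approx(0.7**t)

    def test_e_rpe_converges_to_mean_absolute_error(self, rng):
        """In a constant environment E_rpe approaches E|R − Q|."""
        spec = em.ModelSpec.from_name("RL2+LM")
        params = dict(alpha_rew=0.1, alpha_unrew=0.1, decay_rate=0.0, beta=1.0,
                      gamma=0.02, w_lm=0.0)
        state = initial_state()
        p = 0.7
        errs = []
        for t in range(20_000):
            r = int(rng.random() < p)
            errs.append(abs(r - state.q[0]))
            state = em.step_state(state, spec, params, "A", r)
        tail = np.mean(errs[5000:])
        assert state.e_rpe == pytest.approx(tail, abs=0.05)


class TestDecisionValues:
    def test_full_model_example(self):
        spec = em.ModelSpec.from_name("RL2+CM+LM")
        state = initial_state()
        state.q[:] = [0.6, 0.5]
        state.c[:] = [0.8, 0.0]
        state.lm = -0.4
        state.last_choice = 0
        dv_a, _ = em.decision_values(state, spec, dict(w_lm=0.5, w_cm=0.25, beta=1.0,
                                                       alpha_rew=0.5, alpha_unrew=0.5,
                                                       decay_rate=0.1, gamma=0.5))
        assert dv_a == pytest.approx(0.6 - 0.2 + 0.2)

    def test_zero_weights_reduce_to_rl_core(self):
        full = em.ModelSpec.from_name("RL2+CM+LM")
        core = em.ModelSpec.from_name("RL2")
        state = initial_state()
        state.q[:] = [0.63, 0.41]
        state.c[:] = [0.9, 0.1]
        state.lm = -0.5
        state.last_choice = 1
        p_full = dict(FULL_PARAMS, w_cm=0.0, w_lm=0.0)
        assert em.decision_values(state, full, p_full) == em.decision_values(
            state, core, RL2_PARAMS
        )

    def test_timescales_weighted_sum(self):
        spec = em.ModelSpec.from_name("timescales")
        state = initial_state()
        state.q_ts[:, 0] = [1.0, 0.5, 0.25]
        state.q_ts[:, 1] = 0.0
        dv_a, dv_b = em.decision_values(
            state, spec, dict(w_fast1=0.2, w_fast2=0.2, w_slow=0.6)
        )
        assert dv_a == pytest.approx(0.45)
        assert dv_b == 0.0


class TestChoiceRule:
    def test_symmetry(self):
        for beta in (0.0, 1.0, 50.0):
            assert em.choice_probability(0.4, 0.4, {"beta": beta}, "RL2") == 0.5

    def test_logistic_value(self):
        p = em.choice_probability(0.6, 0.5, {"beta": 10.0}, "RL2")
        assert p == pytest.approx(1 / (1 + math.exp(-1)), abs=1e-12)

    def test_ratio_rule(self):
        assert em.choice_probability(0.3, 0.1, {}, "timescales") == pytest.approx(0.75)
        assert em.choice_probability(0.0, 0.0, {}, "timescales") == 0.5


class TestEquivalences:
    def test_rl2_zero_decay_reproduces_rl1(self, rng):
        trials = make_session(
            list(np.where(rng.random(200) < 0.5, "A", "B")),
            list((rng.random(200) < 0.3).astype(int)),
        )
        p1 = dict(alpha_rew=0.4, alpha_unrew=0.2, beta=3.0)
        p2 = dict(p1, decay_rate=0.0)
        ll1, pa1 = em.session_log_likelihood(em.ModelSpec.from_name("RL1"), p1, trials)
        ll2, pa2 = em.session_log_likelihood(em.ModelSpec.from_name("RL2"), p2, trials)
        assert ll1 == pytest.approx(ll2, abs=1e-12)
        np.testing.assert_allclose(pa1, pa2, atol=1e-14)

    def test_fast_timescale_matches_rl2_half(self, rng):
        """τ=2 learning equals the RL2 rule with α_rew=α_unrew=decay=0.5."""
        spec_ts = em.ModelSpec.from_name("timescales")
        spec_rl2 = em.ModelSpec.from_name("RL2")
        p_rl2 = dict(alpha_rew=0.5, alpha_unrew=0.5, decay_rate=0.5, beta=1.0)
        state_ts, state_rl2 = initial_state(), initial_state()
        for _ in range(100):
            ch = "A" if rng.random() < 0.5 else "B"
            r = int(rng.random() < 0.4)
            state_ts = em.step_state(state_ts, spec_ts, dict(w_fast1=1.0, w_fast2=0.0, w_slow=0.0), ch, r)
            state_rl2 = em.step_state(state_rl2, spec_rl2, p_rl2, ch, r)
            np.testing.assert_allclose(state_ts.q_ts[0], state_rl2.q, atol=1e-14)

    def test_kernel_matches_stepped_reference(self, rng):
        """Compiled likelihood equals the composition of the public ops."""
        env = em.EnvironmentConfig(paradigm="mouse_foraging", n_blocks=2)
        trials, _ = em.heterogeneous_cohort(env, 1, seed=11)
        param_sets = {
            "RL1": dict(alpha_rew=0.4, alpha_unrew=0.2, beta=3.0),
            "RL2": RL2_PARAMS,
            "RL1+CM": dict(alpha_rew=0.4, alpha_unrew=0.2, beta=3.0, gamma=0.3, w_cm=-0.4),
            "RL2+CM": dict(RL2_PARAMS, gamma=0.3, w_cm=-0.4),
            "RL2+LM": dict(RL2_PARAMS, gamma=0.3, w_lm=0.6),
            "RL2+CM+LM": FULL_PARAMS,
            "RL2+CM+": dict(RL2_PARAMS, gamma=0.3, w_cm=0.4),
            "RL2+LM+": dict(RL2_PARAMS, gamma=0.3, w_lm=0.6),
            "timescales": dict(w_fast1=0.3, w_fast2=0.3, w_slow=0.4),
        }
        for name, params in param_sets.items():
            spec = em.ModelSpec.from_name(name)
            ll_k, p_k = em.session_log_likelihood(spec, params, trials)
            ll_s, p_s = session_log_likelihood_stepped(spec, params, trials)
            assert ll_k == pytest.approx(ll_s, abs=1e-10), name
            np.testing.assert_allclose(p_k, p_s, atol=1e-12)


class TestLikelihood:
    def test_beta_zero_is_coin_flip(self, rng):
        trials = make_session(list("ABABABAB"), [1, 0, 1, 0, 0, 1, 1, 0])
        spec = em.ModelSpec.from_name("RL2")
        ll, p = em.session_log_likelihood(spec, dict(RL2_PARAMS, beta=0.0), trials)
        assert ll == pytest.approx(8 * math.log(0.5))
        assert np.all(p == 0.5)

    def test_out_of_bounds_params_rejected(self):
        trials = make_session(["A", "B"], [1, 0])
        spec = em.ModelSpec.from_name("RL2")
        with pytest.raises(ValueError, match="beta"):
            em.session_log_likelihood(spec, dict(RL2_PARAMS, beta=200.0), trials)

    def test_no_retained_trials_is_error(self):
        trials = make_session(["MISS", "MISS"], [0, 0])
        with pytest.raises(ValueError, match="retained"):
            em.session_log_likelihood(em.ModelSpec.from_name("RL2"), RL2_PARAMS, trials)

    def test_generating_params_beat_perturbed(self):
        """Average likelihood is higher under the generating parameters."""
        spec = em.ModelSpec.from_name("RL2")
        perturbed = dict(alpha_rew=0.1, alpha_unrew=0.8, decay_rate=0.5, beta=1.0)
        wins = 0
        diffs = []
        for rep in range(20):
            env = _flat_env(500, seed=100 + rep)
            trials = em.generate_session(
                spec, RL2_PARAMS, env, np.random.default_rng(200 + rep)
            )
            ll_true, _ = em.session_log_likelihood(spec, RL2_PARAMS, trials)
            ll_pert, _ = em.session_log_likelihood(spec, perturbed, trials)
            diffs.append(ll_true - ll_pert)
            wins += ll_true > ll_pert
        assert np.mean(diffs) > 0
        assert wins >= 15


class TestStateClosure:
    def test_latents_stay_in_range(self, rng):
        """Q, C ∈ [0,1] and E_rpe ∈ [0,1] under any admissible parameters."""
        for _ in range(20):
            spec = em.ModelSpec.from_name("RL2+CM+LM")
            params = dict(
                alpha_rew=rng.uniform(0, 1), alpha_unrew=rng.uniform(0, 1),
                decay_rate=rng.uniform(0, 1), beta=rng.uniform(0, 100),
                gamma=rng.uniform(0, 1), w_cm=rng.uniform(-1, 1), w_lm=rng.uniform(-1, 1),
            )
            state = initial_state()
            for _ in range(200):
                ch = "A" if rng.random() < 0.5 else "B"
                state = em.step_state(state, spec, params, ch, int(rng.random() < 0.5))
                assert np.all((state.q >= 0) & (state.q <= 1))
                assert np.all((state.c >= 0) & (state.c <= 1))
                assert 0 <= state.e_rpe <= 1


class TestGeneration:
    def test_fixed_seed_bit_identical(self):
        spec = em.ModelSpec.from_name("RL2")
        a = em.generate_session(spec, RL2_PARAMS, _flat_env(300, seed=5),
                                np.random.default_rng(9))
        b = em.generate_session(spec, RL2_PARAMS, _flat_env(300, seed=5),
                                np.random.default_rng(9))
        pd.testing.assert_frame_equal(a, b)

    def test_beta_zero_choices_are_fair(self):
        spec = em.ModelSpec.from_name("RL2")
        trials = em.generate_session(
            spec, dict(RL2_PARAMS, beta=0.0), _flat_env(4000, seed=1),
            np.random.default_rng(2),
        )
        frac = (trials["choice"] == "A").mean()
        assert abs(frac - 0.5) < 3 * 0.5 / math.sqrt(4000)  # 3σ binomial band

    def test_near_greedy_agent_exploits_certain_reward(self):
        spec = em.ModelSpec.from_name("RL1")
        env = _flat_env(400, p_a=1.0, p_b=0.0, baited=False, seed=3)
        trials = em.generate_session(
            spec, dict(alpha_rew=0.5, alpha_unrew=0.5, beta=100.0), env,
            np.random.default_rng(4),
        )
        late = trials.iloc[100:]
        assert (late["choice"] == "A").mean() > 0.99

    def test_positive_lm_weight_promotes_lose_switch(self):
        """ω_LM > 0 raises P(switch) after losses relative to ω_LM = 0."""
        base = dict(alpha_rew=0.3, alpha_unrew=0.3, decay_rate=0.1, beta=5.0, gamma=0.5)
        spec = em.ModelSpec.from_name("RL2+LM")
        rates = {}
        for w in (-0.8, 0.0, 0.8):
            params = dict(base, w_lm=w)
            ls = []
            for rep in range(10):
                env = _flat_env(500, p_a=0.4, p_b=0.4 - 1e-9, baited=True, seed=rep)
                trials = em.generate_session(spec, params, env,
                                             np.random.default_rng(50 + rep))
                ev = em.derive_strategy_events(trials)
                _, ls_v, _, _ = em.win_stay_lose_switch(ev)
                ls.append(ls_v)
            rates[w] = np.nanmean(ls)
        assert rates[0.8] > rates[0.0] > rates[-0.8]
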