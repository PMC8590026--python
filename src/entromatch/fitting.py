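"""Maximum-likelihood fitting of choice models and model comparison.

One parameter set is fitted per unit (a mouse session or a monkey
superblock) by bounded multi-start local optimization of the negative log
likelihood (L-BFGS-B over the model's box constraints, start points Latin
hypercube within bounds, β started log-uniformly).  Model comparison uses
AIC = −2·logL + 2p, Akaike weights over mean AICs, McFadden's pseudo-R²
against the coin-flip null, and paired t tests of per-unit AICs against the
best model.

When several nested models are compared, each larger model is additionally
warm-started from the embedded optimum of its fitted submodels (extra
parameters at neutral values), so the nested-dominance property
logL(super) ≥ logL(sub) holds up to optimizer tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import qmc

from .io import retained
from .models import ModelSpec, session_log_likelihood


@dataclass(frozen=True)
class FitResult:
    """Best-of-starts maximum-likelihood fit of one model to one unit."""

    model: str
    params: dict
    logl: float
    aic: float
    n_trials: int
    n_params: int
    n_starts: int
    converged: bool
    seed: int


def aic(logl: float, p: int) -> float:
    """Akaike Information Criterion, ``−2·logL + 2p``."""
    if p < 0:
        raise ValueError("parameter count must be non-negative")
    return -2.0 * logl + 2.0 * p


def akaike_weights(mean_aics) -> np.ndarray:
    """Akaike weights from per-model mean AICs.

    ``w_i ∝ exp(−ΔAIC_i / 2)`` with ΔAIC relative to the smallest mean AIC;
    weights sum to one.
    """
    a = np.asarray(list(mean_aics), dtype=float)
    if a.size == 0:
        raise ValueError("need at least one model")
    delta = a - a.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def mcfadden_r2(logls, n_trials) -> float:
    """McFadden pseudo-R²: 1 − Σ logL / Σ n·ln(0.5)."""
    logls = np.asarray(list(logls), dtype=float)
    ns = np.asarray(list(n_trials), dtype=float)
    if np.any(ns <= 0):
        raise ValueError("trial counts must be positive")
    return 1.0 - logls.sum() / (ns.sum() * math.log(0.5))


def _start_points(spec: ModelSpec, n_starts: int, seed: int) -> np.ndarray:
    names = spec.param_names()
    bounds = np.asarray(spec.bounds(), dtype=float)
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    u = sampler.random(n_starts)
    pts = bounds[:, 0] + u * (bounds[:, 1] - bounds[:, 0])
    # start β log-uniformly in [0.1, 10]: the likelihood is nearly flat in β
    # at large values, so uniform starts over [0, 100] waste most starts
    for j, name in enumerate(names):
        if name == "beta":
            pts[:, j] = 10.0 ** (2.0 * u[:, j] - 1.0)
    return pts


def fit_unit(
    spec: ModelSpec,
    trials: pd.DataFrame,
    n_starts: int = 10,
    seed: int = 0,
    extra_starts=(),
) -> FitResult:
    """Fit one model to one unit (session/superblock) by multi-start MLE.

    ``extra_starts`` is an optional sequence of parameter dicts used as
    additional start points (each is also evaluated as-is, so the returned
    log likelihood can never fall below the likelihood at any of them).
    Deterministic given ``seed``.  A unit on which every start fails returns
    a flagged (``converged=False``) result rather than raising.
    """
    names = spec.param_names()
    bounds = spec.bounds()
    n_kept = int(len(retained(trials)))
    if n_kept == 0:
        raise ValueError("unit has no retained trials")

    def unpack(x: np.ndarray) -> dict:
        return {name: float(v) for name, v in zip(names, x)}

    def nll(x: np.ndarray) -> float:
        x = np.clip(x, [b[0] for b in bounds], [b[1] for b in bounds])
        ll, _ = session_log_likelihood(spec, unpack(x), trials)
        return -ll if np.isfinite(ll) else 1e12

    starts = [row for row in _start_points(spec, n_starts, seed)]
    for extra in extra_starts:
        x0 = np.array([np.clip(extra.get(n, 0.0), lo, hi) for n, (lo, hi) in zip(names, bounds)])
        starts.append(x0)

    best_x, best_f, converged = None, np.inf, False
    for i, x0 in enumerate(starts):
        if i >= n_starts:  # warm starts: keep the raw point as a candidate
            f0 = nll(x0)
            if f0 < best_f:
                best_x, best_f = x0, f0
        try:
            res = optimize.minimize(
                nll,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-10, "maxiter": 500},
            )
        except FloatingPointError:  # pragma: no cover - defensive
            continue
        if np.isfinite(res.fun) and res.fun < best_f:
            best_x, best_f = res.x, res.fun
        converged = converged or bool(res.success)

    if best_x is None:  # pragma: no cover - all starts failed
        best_x = starts[0]
        best_f = nll(best_x)
        converged = False
    params = unpack(np.clip(best_x, [b[0] for b in bounds], [b[1] for b in bounds]))
    logl = -best_f
    return FitResult(
        model=spec.name,
        params=params,
        logl=float(logl),
        aic=aic(logl, spec.n_fitted),
        n_trials=n_kept,
        n_params=spec.n_fitted,
        n_starts=len(starts),
        converged=converged,
        seed=seed,
    )


def embed_params(src: ModelSpec, dst: ModelSpec, params: dict) -> dict | None:
    """Map a fitted submodel's parameters into a supermodel's space.

    Missing components take neutral values (decay 0, memory weights 0,
    γ = 0.5 when newly fitted), so the embedded point reproduces the
    submodel's likelihood exactly.  Returns None when ``dst`` does not nest
    ``src``.
    """
    if src.value_rule == "timescales" or dst.value_rule == "timescales":
        return None
    if src.value_rule == "RL2" and dst.value_rule == "RL1":
        return None
    if (src.use_cm and not dst.use_cm) or (src.use_lm and not dst.use_lm):
        return None
    defaults = {"decay_rate": 0.0, "w_cm": 0.0, "w_lm": 0.0, "gamma": 0.5}
    out = {}
    for name, (lo, hi) in zip(dst.param_names(), dst.bounds()):
        v = params.get(name, defaults.get(name, 0.0))
        out[name] = float(np.clip(v, lo, hi))
    return out


def fit_models(
    units: dict,
    model_names,
    n_starts: int = 10,
    seed: int = 0,
    gamma_mode: str = "fitted",
) -> dict:
    """Fit several models to every unit, warm-starting nested supermodels.

    ``units`` maps unit id → trial table.  Models are fitted in order of
    increasing parameter count; each model's starts include the embedded
    optima of all already-fitted models it nests.  Returns
    ``{model_name: {unit_id: FitResult}}``.
    """
    specs = [ModelSpec.from_name(m, gamma_mode=gamma_mode) for m in model_names]
    specs.sort(key=lambda s: s.n_fitted)
    results: dict = {}
    ss = np.random.SeedSequence(seed)
    unit_seeds = {
        uid: int(child.generate_state(1)[0] % (2**31))
        for uid, child in zip(units, ss.spawn(len(units)))
    }
    for spec in specs:
        results[spec.name] = {}
        for uid, trials in units.items():
            extra = []
            for prev_name, prev_fits in results.items():
                if prev_name == spec.name or uid not in prev_fits:
                    continue
                prev_spec = next(s for s in specs if s.name == prev_name)
                emb = embed_params(prev_spec, spec, prev_fits[uid].params)
                if emb is not None:
                    extra.append(emb)
            results[spec.name][uid] = fit_unit(
                spec, trials, n_starts=n_starts, seed=unit_seeds[uid], extra_starts=extra
            )
    return results


def compare_models(results: dict) -> pd.DataFrame:
    """Comparison table across models fitted to the same units.

    One row per model: mean AIC, Akaike weight (from mean AICs), pooled
    McFadden R², and the paired-t p value of per-unit AICs against the model
    with the lowest mean AIC (NaN, flagged ``degenerate``, when the paired
    differences are identically zero).  Raises on mismatched unit sets.
    """
    models = list(results)
    unit_sets = [frozenset(results[m]) for m in models]
    if len(set(unit_sets)) != 1:
        raise ValueError("all models must be fitted to the same units")
    units = sorted(unit_sets[0], key=str)
    aics = {m: np.array([results[m][u].aic for u in units]) for m in models}
    mean_aics = {m: a.mean() for m, a in aics.items()}
    weights = akaike_weights(mean_aics.values())
    best = min(mean_aics, key=mean_aics.get)
    rows = []
    for m, w in zip(models, weights):
        fits = results[m]
        r2 = mcfadden_r2(
            (fits[u].logl for u in units), (fits[u].n_trials for u in units)
        )
        diffs = aics[m] - aics[best]
        degenerate = m == best or len(units) < 2 or np.allclose(diffs, 0.0)
        if degenerate:
            p = float("nan")
        else:
            p = float(stats.ttest_rel(aics[m], aics[best]).pvalue)
        rows.append(
            {
                "model": m,
                "n_units": len(units),
                "mean_aic": float(mean_aics[m]),
                "akaike_weight": float(w),
                "mcfadden_r2": float(r2),
                "p_vs_best": p,
                "degenerate_test": bool(degenerate),
            }
        )
    return pd.DataFrame(rows).sort_values("mean_aic").reset_index(drop=True)


def fit_results_table(results: dict) -> pd.DataFrame:
    """Flatten ``{model: {unit: FitResult}}`` to one row per unit × model."""
    rows = []
    for model, fits in results.items():
        for uid, fr in fits.items():
            row = {
                "model": model,
                "unit": uid,
                "logl": fr.logl,
                "aic": fr.aic,
                "n_trials": fr.n_trials,
                "n_params": fr.n_params,
                "n_starts": fr.n_starts,
                "converged": fr.converged,
                "seed": fr.seed,
            }
            row.update({f"param_{k}": v for k, v in fr.params.items()})
            rows.append(row)
    return pd.DataFrame(rows)
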