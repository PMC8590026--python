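"""Block-level statistical analyses: stepwise regression of deviation from
matching on behavioral metrics, cross-validated prediction, correlation
matrices, and KS comparison of observed vs model-predicted metric
distributions.

Blocks with an undefined (NaN) value in the response or any candidate
predictor are excluded listwise before regression, mirroring the exclusion of
blocks on which a conditional metric (e.g. ERODS_W+ in a block with no win on
the worse option) is undefined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold

#: Predictor sets used in the matching-law regressions.
CLASSIC_PREDICTORS = ("p_win", "p_stay", "WS", "LS")
RI_PREDICTORS = CLASSIC_PREDICTORS + ("RI_B", "RI_W")
FULL_PREDICTORS = RI_PREDICTORS + (
    "ERDS_plus",
    "ERDS_minus",
    "EODS_B",
    "EODS_W",
    "ERODS_Bplus",
    "ERODS_Bminus",
    "ERODS_Wplus",
    "ERODS_Wminus",
)


@dataclass
class RegressionReport:
    """Result of a stepwise regression.

    ``steps`` lists predictors in order of entry with the R² increment at
    the step they were added; ``coef_table`` is the final OLS coefficient
    table; ``n_excluded`` counts blocks dropped for undefined values.
    """

    steps: list
    selected: list
    coef_table: pd.DataFrame
    adj_r2: float
    r2: float
    n_blocks: int
    n_excluded: int


def _sse(y: np.ndarray, X: np.ndarray) -> float:
    # OLS residual sum of squares with intercept
    Z = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    return float(resid @ resid)


def _partial_f_pvalue(sse_small, sse_big, df_big, n):
    # F test of one added/removed term: df numerator 1
    df_resid = n - df_big - 1  # intercept included in df_big count
    if df_resid <= 0 or sse_big <= 0:
        return float("nan")
    f = (sse_small - sse_big) / (sse_big / df_resid)
    return float(stats.f.sf(max(f, 0.0), 1, df_resid))


def stepwise_regression(
    y: pd.Series,
    X: pd.DataFrame,
    p_add: float = 1e-4,
    p_remove: float = 1.1e-4,
    max_iter: int = 100,
) -> RegressionReport:
    """Forward/backward stepwise OLS by partial F tests.

    A candidate enters the model when the F test of its added explained sum
    of squares has p < ``p_add`` (smallest p first, ties broken by order);
    an included term leaves when its F-test p exceeds ``p_remove`` (largest
    p first).  Iterates until stable or ``max_iter`` sweeps.

    Blocks with any undefined value are dropped listwise; raises if no
    complete cases remain.
    """
    frame = pd.concat([y.rename("__y__"), X], axis=1)
    complete = frame.dropna()
    n_excluded = len(frame) - len(complete)
    if len(complete) == 0:
        raise ValueError("no complete-case blocks for regression")
    yv = complete["__y__"].to_numpy(dtype=float)
    cols = list(X.columns)
    Xv = {c: complete[c].to_numpy(dtype=float) for c in cols}
    n = len(yv)
    sst = float(((yv - yv.mean()) ** 2).sum())

    selected: list[str] = []
    steps: list[tuple[str, float]] = []
    sse_cur = _sse(yv, np.empty((n, 0)))
    for _ in range(max_iter):
        changed = False
        # entry
        candidates = []
        for c in cols:
            if c in selected:
                continue
            sse_new = _sse(yv, np.column_stack([Xv[s] for s in selected + [c]]))
            p = _partial_f_pvalue(sse_cur, sse_new, len(selected) + 1, n)
            if np.isfinite(p) and p < p_add:
                candidates.append((p, c, sse_new))
        if candidates:
            _, best, sse_new = min(candidates, key=lambda t: (t[0], cols.index(t[1])))
            selected.append(best)
            steps.append((best, (sse_cur - sse_new) / sst if sst > 0 else 0.0))
            sse_cur = sse_new
            changed = True
        # removal
        while selected:
            worst = None
            for c in selected:
                rest = [s for s in selected if s != c]
                X_rest = (
                    np.column_stack([Xv[s] for s in rest]) if rest else np.empty((n, 0))
                )
                sse_small = _sse(yv, X_rest)
                p = _partial_f_pvalue(sse_small, sse_cur, len(selected), n)
                if np.isfinite(p) and p > p_remove and (worst is None or p > worst[0]):
                    worst = (p, c, sse_small)
            if worst is None:
                break
            _, gone, sse_small = worst
            selected.remove(gone)
            sse_cur = sse_small
            changed = True
        if not changed:
            break

    if selected:
        design = sm.add_constant(complete[selected].astype(float))
    else:
        design = pd.DataFrame({"const": np.ones(n)}, index=complete.index)
    fit = sm.OLS(yv, design).fit()
    coef = pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    return RegressionReport(
        steps=steps,
        selected=list(selected),
        coef_table=coef,
        adj_r2=float(fit.rsquared_adj) if selected else 0.0,
        r2=float(fit.rsquared) if selected else 0.0,
        n_blocks=n,
        n_excluded=n_excluded,
    )


def cv_predict(
    y: pd.Series, X: pd.DataFrame, k: int = 10, seed: int = 0
) -> tuple[pd.Series, float]:
    """k-fold cross-validated linear prediction of the response.

    Folds are shuffled with ``seed``; a plain linear model is fitted on each
    training split and evaluated on the held-out blocks.  Returns the
    out-of-fold predictions (indexed like the complete cases) and the pooled
    out-of-fold R² (can be negative when the predictors are uninformative).
    Raises when fewer complete cases than folds.
    """
    frame = pd.concat([y.rename("__y__"), X], axis=1).dropna()
    if len(frame) < k:
        raise ValueError(f"need at least k={k} complete cases, got {len(frame)}")
    yv = frame["__y__"].to_numpy(dtype=float)
    Xv = frame[list(X.columns)].to_numpy(dtype=float)
    preds = np.empty(len(frame))
    for train, test in KFold(n_splits=k, shuffle=True, random_state=seed).split(Xv):
        model = LinearRegression().fit(Xv[train], yv[train])
        preds[test] = model.predict(Xv[test])
    sst = float(((yv - yv.mean()) ** 2).sum())
    ssr = float(((yv - preds) ** 2).sum())
    r2 = 1.0 - ssr / sst if sst > 0 else float("nan")
    return pd.Series(preds, index=frame.index, name="cv_prediction"), r2


def correlation_matrix(
    table: pd.DataFrame,
    columns=None,
    methods=("pearson", "spearman"),
    alpha: float = 1e-4,
) -> dict:
    """Pairwise correlations (with p values) between metric columns.

    Uses pairwise-complete observations.  Returns, per method, a dict with
    ``r``, ``p`` and boolean ``significant`` (p below ``alpha``) DataFrames;
    entries involving a constant column are undefined.
    """
    cols = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    funcs = {"pearson": stats.pearsonr, "spearman": stats.spearmanr}
    out = {}
    for method in methods:
        func = funcs[method]
        r = pd.DataFrame(np.nan, index=cols, columns=cols)
        p = pd.DataFrame(np.nan, index=cols, columns=cols)
        for i, a in enumerate(cols):
            for b in cols[i:]:
                pair = table[[a, b]].dropna() if a != b else table[[a]].dropna()
                if a == b:
                    if pair[a].nunique() > 1:
                        r.loc[a, a], p.loc[a, a] = 1.0, 0.0
                    continue
                if len(pair) < 3 or pair[a].nunique() < 2 or pair[b].nunique() < 2:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rv, pv = func(pair[a], pair[b])
                r.loc[a, b] = r.loc[b, a] = float(rv)
                p.loc[a, b] = p.loc[b, a] = float(pv)
        out[method] = {"r": r, "p": p, "significant": p < alpha}
    return out


def ks_compare(sample_a, sample_b, method: str = "asymp") -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov–Smirnov test.

    ``D`` is the maximum gap between the two empirical CDFs; the p value uses
    the asymptotic formula by default (``method="exact"`` for small samples).
    Raises on an empty sample.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("KS comparison requires two nonempty samples")
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def observed_vs_predicted_report(
    observed: pd.DataFrame, simulated: pd.DataFrame, metrics=("ERODS_Wminus", "UM")
) -> pd.DataFrame:
    """Per-metric distributional comparison of observed vs simulated blocks.

    For each metric present in both tables: KS D and p, the two medians and
    their gap, and the block counts after dropping undefined values.  Metrics
    absent from either table are skipped with a warning.
    """
    rows = []
    for m in metrics:
        if m not in observed.columns or m not in simulated.columns:
            warnings.warn(f"metric {m!r} missing from a table; skipped", stacklevel=2)
            continue
        obs = observed[m].dropna().to_numpy()
        simv = simulated[m].dropna().to_numpy()
        if obs.size == 0 or simv.size == 0:
            warnings.warn(f"metric {m!r} has no defined blocks; skipped", stacklevel=2)
            continue
        d, p = ks_compare(obs, simv)
        rows.append(
            {
                "metric": m,
                "D": d,
                "p": p,
                "median_observed": float(np.median(obs)),
                "median_predicted": float(np.median(simv)),
                "median_gap": float(np.median(simv) - np.median(obs)),
                "n_observed": int(obs.size),
                "n_predicted": int(simv.size),
            }
        )
    return pd.DataFrame(rows)


def plot_ecdf_overlay(observed, simulated, label_a="observed", label_b="predicted", ax=None):
    """ECDF overlay of two samples (optional; requires matplotlib)."""
    import matplotlib.pyplot as plt  # deferred: plotting is optional

    if ax is None:
        _, ax = plt.subplots()
    for sample, label in ((observed, label_a), (simulated, label_b)):
        x = np.sort(np.asarray(sample, dtype=float))
        x = x[~np.isnan(x)]
        ax.step(x, np.arange(1, x.size + 1) / x.size, where="post", label=label)
    ax.set_ylabel("cumulative fraction of blocks")
    ax.legend()
    return ax
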