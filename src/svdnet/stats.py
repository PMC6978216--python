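"""Longitudinal and cross-sectional inference for the cohort analyses.

Implements the statistical layer of the pipeline: paired change tests
over the two imaging waves (for two time points the repeated-measures
ANOVA F is exactly the squared paired t, so t-based estimates, CIs and
p-values are reported), group-by-time interaction tests, covariate-
adjusted group differences (ANCOVA), standardized-beta linear
regressions, WMH median split and log transform, and a single-mediator
path model with percentile-bootstrap inference for the indirect effect.

All analyses are complete-case; every result records the n actually
used.  No multiple-testing correction is applied; raw p-values are
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "ChangeTestResult",
    "RegressionResult",
    "MediationResult",
    "paired_change_test",
    "group_time_interaction",
    "adjusted_group_difference",
    "standardized_regression",
    "median_split",
    "log_transform_wmh",
    "fit_mediation",
]


@dataclass(frozen=True)
class ChangeTestResult:
    mean_difference: float
    ci95: tuple[float, float]
    p_value: float
    n: int


@dataclass(frozen=True)
class RegressionResult:
    """Standardized-beta OLS fit: one row per model term."""

    table: pd.DataFrame  # index: term; columns: beta, ci_low, ci_high, p
    outcome: str
    covariates: tuple[str, ...]
    n: int

    def beta(self, term: str) -> float:
        return float(self.table.loc[term, "beta"])


@dataclass(frozen=True)
class MediationResult:
    a: float
    b: float
    c_prime: float
    indirect: float
    a_p: float
    b_p: float
    c_prime_p: float
    sobel_z: float
    sobel_p: float
    indirect_ci95: tuple[float, float]
    indirect_boot_p: float
    direct_ci95: tuple[float, float]
    direct_boot_p: float
    n: int
    n_boot: int
    seed: int


def _complete_rows(*cols: np.ndarray) -> np.ndarray:
    mask = np.ones(len(cols[0]), dtype=bool)
    for c in cols:
        mask &= np.isfinite(np.asarray(c, dtype=float))
    return mask


def paired_change_test(
    values_baseline: np.ndarray, values_followup: np.ndarray
) -> ChangeTestResult:
    """Mean within-subject change (follow-up minus baseline) with t-based
    95% CI and p-value.

    With two time points this is identical to the one-way repeated-
    measures ANOVA (F = t^2).  Pairs with a missing value at either wave
    are dropped.
    """
    b = np.asarray(values_baseline, dtype=float)
    f = np.asarray(values_followup, dtype=float)
    if b.shape != f.shape:
        raise ValueError("baseline and follow-up must be paired (same length)")
    mask = _complete_rows(b, f)
    d = f[mask] - b[mask]
    n = d.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    mean = float(d.mean())
    se = float(d.std(ddof=1) / np.sqrt(n))
    df = n - 1
    if se == 0.0:
        return ChangeTestResult(mean, (mean, mean), 1.0 if mean == 0 else 0.0, n)
    t = mean / se
    p = float(2 * sps.t.sf(abs(t), df))
    tcrit = float(sps.t.ppf(0.975, df))
    return ChangeTestResult(mean, (mean - tcrit * se, mean + tcrit * se), p, n)


def group_time_interaction(
    values_baseline: np.ndarray,
    values_followup: np.ndarray,
    group: np.ndarray,
) -> float:
    """P-value of the group-by-time interaction in a two-wave design.

    Fits the within-subject model with subject fixed effects and a
    wave-by-group interaction; for two waves its interaction test is
    equivalent to a two-sample t-test on per-subject change scores.
    Returns the interaction p-value.
    """
    b = np.asarray(values_baseline, dtype=float)
    f = np.asarray(values_followup, dtype=float)
    g = np.asarray(group)
    if not (b.shape == f.shape == g.shape):
        raise ValueError("baseline, follow-up and group must be aligned")
    levels = pd.unique(g[pd.notna(g)])
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {list(levels)}")
    mask = _complete_rows(b, f) & pd.notna(g)
    b, f, g = b[mask], f[mask], g[mask]
    for lev in levels:
        if (g == lev).sum() < 3:
            raise ValueError(f"group {lev!r} has fewer than 3 subjects")
    n = b.size
    # Subject fixed effects + wave + wave:group; long format, 2n rows.
    y = np.concatenate([b, f])
    subj = np.tile(np.arange(n), 2)
    wave = np.repeat([0.0, 1.0], n)
    gnum = np.concatenate([(g == levels[1]).astype(float)] * 2)
    X = np.column_stack(
        [
            wave,
            wave * gnum,
            (subj[:, None] == np.arange(n)[None, :]).astype(float),
        ]
    )
    fit = sm.OLS(y, X).fit()
    return float(fit.pvalues[1])


def adjusted_group_difference(
    y: np.ndarray,
    group: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> ChangeTestResult:
    """Covariate-adjusted group difference (ANCOVA).

    Fits ``y ~ group + covariates`` by OLS and reports the group
    coefficient — the adjusted mean difference (second group level minus
    first, levels in order of appearance) — with its 95% CI and p-value.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(group)
    levels = pd.unique(g[pd.notna(g)])
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {list(levels)}")
    cov = None
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
    mask = _complete_rows(y) & pd.notna(g)
    if cov is not None:
        mask &= cov.notna().all(axis=1).to_numpy()
    y, g = y[mask], g[mask]
    gnum = (g == levels[1]).astype(float)
    X = np.column_stack([np.ones(y.size), gnum])
    if cov is not None:
        X = np.column_stack([X, cov.loc[mask].to_numpy(dtype=float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int()[1]
    return ChangeTestResult(
        float(fit.params[1]), (float(ci[0]), float(ci[1])), float(fit.pvalues[1]), int(y.size)
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def standardized_regression(
    y: np.ndarray | pd.Series,
    predictors: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    categorical_covariates: tuple[str, ...] = (),
    outcome_name: str = "y",
) -> RegressionResult:
    """OLS with standardized betas.

    The outcome and every predictor (and every covariate not listed in
    ``categorical_covariates``) are z-scored on the complete-case sample
    before fitting, so coefficients are standardized betas with 95% CIs
    and p-values.  Categorical covariates (e.g. a 0/1 sex indicator)
    enter unscaled.
    """
    pred = pd.DataFrame(predictors).reset_index(drop=True)
    cov = pd.DataFrame(covariates).reset_index(drop=True) if covariates is not None else None
    yv = pd.Series(np.asarray(y, dtype=float), name=outcome_name).reset_index(drop=True)
    frame = pd.concat([yv, pred] + ([cov] if cov is not None else []), axis=1)
    frame = frame.dropna()
    n = len(frame)
    if n < frame.shape[1] + 1:
        raise ValueError(f"too few complete cases ({n}) for {frame.shape[1]} terms")
    cols = {}
    for name in frame.columns:
        col = frame[name].to_numpy(dtype=float)
        if name in categorical_covariates:
            cols[name] = col
            continue
        if col.std(ddof=1) == 0:
            raise ValueError(f"zero-variance column: {name!r}")
        cols[name] = _standardize(col)
    yz = cols.pop(outcome_name)
    X = sm.add_constant(pd.DataFrame(cols))
    fit = sm.OLS(yz, X).fit()
    ci = fit.conf_int()
    table = pd.DataFrame(
        {
            "beta": fit.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": fit.pvalues,
        }
    ).drop(index="const")
    cov_names = tuple(cov.columns) if cov is not None else ()
    return RegressionResult(table, outcome_name, cov_names, n)


def median_split(values: np.ndarray) -> np.ndarray:
    """Dichotomize at the median: values <= median -> ``mild``, values
    above -> ``severe``.  Ties with the median go to the mild stratum.
    Missing values propagate as missing labels (NaN).
    """
    v = np.asarray(values, dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size < 2:
        raise ValueError("need at least 2 non-missing values")
    med = np.median(finite)
    if np.all(finite == finite[0]):
        raise ValueError("median split undefined: all values identical")
    out = np.where(v <= med, "mild", "severe").astype(object)
    out[~np.isfinite(v)] = np.nan
    return out


def log_transform_wmh(volume_ml: np.ndarray | float) -> np.ndarray | float:
    """Natural log of WMH volume (skew correction); requires volume > 0."""
    v = np.asarray(volume_ml, dtype=float)
    if np.any(v[np.isfinite(v)] <= 0):
        raise ValueError("WMH volume must be strictly positive for log transform")
    out = np.log(v)
    return float(out) if np.isscalar(volume_ml) else out


def _batched_ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Solve OLS for a stack of design matrices.  X: (B, n, k), y: (B, n)."""
    G = np.einsum("bni,bnj->bij", X, X)
    h = np.einsum("bni,bn->bi", X, y)
    return np.linalg.solve(G, h[..., None])[..., 0]


def fit_mediation(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    y_binary: bool = False,
    n_boot: int = 2000,
    seed: int = 0,
    y_model: str = "lpm",
) -> MediationResult:
    """Single-mediator path model X -> M -> Y with bootstrap inference.

    Fits ``m ~ x + covariates`` (path a) and ``y ~ m + x + covariates``
    (paths b and c') by OLS on standardized continuous variables; the
    indirect effect is the product a*b.  A binary outcome is kept on its
    0/1 scale and modelled by a linear probability model, which preserves
    the exact decomposition (total effect = c' + a*b); set
    ``y_model="probit"`` to fit the outcome equation by probit instead
    (paths b and c' are then latent-scale coefficients and the product
    identity is approximate).  Inference for the indirect and direct
    effects uses a nonparametric percentile bootstrap over subjects
    (two-sided p from the bootstrap distribution's position relative to
    zero); the Sobel normal-theory test is reported as well.
    """
    if y_model not in ("lpm", "probit"):
        raise ValueError(f"y_model must be 'lpm' or 'probit', got {y_model!r}")
    if y_model == "probit" and not y_binary:
        raise ValueError("y_model='probit' requires y_binary=True")
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = None
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True).to_numpy(dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    mask = _complete_rows(x, m, y)
    if cov is not None:
        mask &= np.isfinite(cov).all(axis=1)
    x, m, y = x[mask], m[mask], y[mask]
    cov_c = cov[mask] if cov is not None else None
    n = x.size
    if n < 30:
        raise ValueError(f"need at least 30 complete cases, got {n}")
    if n_boot < 500:
        raise ValueError(f"need at least 500 bootstrap draws for CIs, got {n_boot}")

    xz = _standardize(x)
    mz = _standardize(m)
    yz = y if y_binary else _standardize(y)

    ones = np.ones(n)
    cov_cols = [] if cov_c is None else [cov_c]
    Xa = np.column_stack([ones, xz] + cov_cols)               # m ~ x (+cov)
    Xb = np.column_stack([ones, mz, xz] + cov_cols)           # y ~ m + x (+cov)

    fit_a = sm.OLS(mz, Xa).fit()
    if y_model == "probit":
        fit_b = sm.Probit(yz, Xb).fit(disp=0)
    else:
        fit_b = sm.OLS(yz, Xb).fit()
    a, a_p = float(fit_a.params[1]), float(fit_a.pvalues[1])
    b, b_p = float(fit_b.params[1]), float(fit_b.pvalues[1])
    c_prime, cp_p = float(fit_b.params[2]), float(fit_b.pvalues[2])
    indirect = a * b

    # Sobel first-order normal-theory test
    se_a, se_b = float(fit_a.bse[1]), float(fit_b.bse[1])
    sobel_se = np.sqrt(a * a * se_b * se_b + b * b * se_a * se_a)
    sobel_z = indirect / sobel_se if sobel_se > 0 else 0.0
    sobel_p = float(2 * sps.norm.sf(abs(sobel_z)))

    # Percentile bootstrap, resampling subjects; same resample feeds both paths.
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    Xa_b, Xb_b = Xa[idx], Xb[idx]
    beta_a = _batched_ols(Xa_b, mz[idx])
    if y_model == "probit":
        bs, cps = [], []
        for r in range(n_boot):
            try:
                prm = sm.Probit(yz[idx[r]], Xb_b[r]).fit(disp=0, maxiter=50).params
            except Exception:  # perfect separation in a resample: drop it
                continue
            bs.append(prm[1])
            cps.append(prm[2])
        beta_b_1 = np.array(bs)
        dir_boot = np.array(cps)
        ind_boot = beta_a[: len(bs), 1] * beta_b_1
    else:
        beta_b = _batched_ols(Xb_b, yz[idx])
        ind_boot = beta_a[:, 1] * beta_b[:, 1]
        dir_boot = beta_b[:, 2]

    def _pct_ci(dist: np.ndarray) -> tuple[float, float]:
        lo, hi = np.percentile(dist, [2.5, 97.5])
        return float(lo), float(hi)

    def _boot_p(dist: np.ndarray) -> float:
        # Two-sided p: twice the smaller tail of the bootstrap
        # distribution relative to zero.
        p_lo = np.mean(dist <= 0)
        p_hi = np.mean(dist >= 0)
        return float(min(1.0, 2 * min(p_lo, p_hi)))

    return MediationResult(
        a=a, b=b, c_prime=c_prime, indirect=indirect,
        a_p=a_p, b_p=b_p, c_prime_p=cp_p,
        sobel_z=float(sobel_z), sobel_p=sobel_p,
        indirect_ci95=_pct_ci(ind_boot), indirect_boot_p=_boot_p(ind_boot),
        direct_ci95=_pct_ci(dir_boot), direct_boot_p=_boot_p(dir_boot),
        n=n, n_boot=n_boot, seed=seed,
    )
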