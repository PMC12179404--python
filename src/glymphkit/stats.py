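"""Univariate group statistics.

Group comparisons (one-way ANOVA, chi-squared), Tukey post hoc tests,
covariate-adjusted comparisons (ANCOVA and rank ANCOVA with age, sex
and education as covariates, Bonferroni-corrected pairwise contrasts),
pooled-SD Cohen's d with the r = d / sqrt(d^2 + 4) conversion,
Pearson/Spearman correlation, and RANSAC robust regression with
control variables residualized out.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.linear_model import LinearRegression, RANSACRegressor
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class ComparisonResult:
    statistic: float
    p_raw: float
    p_adjusted: float
    adjustment: str  # bonferroni | tukey | none
    effect_d: float | None = None
    effect_r: float | None = None
    label: str = ""
    extra: dict = field(default_factory=dict)


@dataclass
class RobustFit:
    coefficients: np.ndarray
    intercept: float
    inlier_mask: np.ndarray
    n_inliers: int
    controls: tuple
    predictors: tuple


# ---------------------------------------------------------------------------
# effect sizes


def cohens_d(x, y) -> float:
    """Pooled-SD Cohen's d, (mean(x) - mean(y)) / s_pooled.

    The pooled SD weights the two sample variances by their degrees of
    freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs n >= 2")
    pooled = np.sqrt(
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled SD: d undefined")
    return float((x.mean() - y.mean()) / pooled)


def d_to_r(d: float) -> float:
    """Effect-size r from pooled Cohen's d: r = d / sqrt(d^2 + 4)."""
    return float(d / np.sqrt(d**2 + 4.0))


def bonferroni(p_raw: float, m: int) -> float:
    """min(1, m * p); never below the raw p."""
    return float(min(1.0, m * p_raw))


# ---------------------------------------------------------------------------
# omnibus group tests


def group_compare(
    df: pd.DataFrame,
    outcome: str,
    group: str = "group",
    kind: str = "anova",
    continuity_correction: bool = False,
) -> ComparisonResult:
    """One-way ANOVA or chi-squared across groups.

    The ANOVA path also runs Tukey HSD post hoc pairwise comparisons
    (stored under ``extra['pairwise']``).  ``kind='chi2'`` treats the
    outcome as categorical and tests the outcome-by-group contingency
    table; no continuity correction by default.
    """
    data = df[[outcome, group]].dropna()
    levels = sorted(data[group].astype(str).unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    if kind == "anova":
        samples = [
            data.loc[data[group].astype(str) == g, outcome].to_numpy(float) for g in levels
        ]
        flags = []
        for g, s in zip(levels, samples):
            if len(s) < 2:
                raise ValueError(f"group {g} has fewer than 2 observations")
            if s.var(ddof=1) == 0:
                flags.append(f"group {g} has zero variance")
        f, p = sps.f_oneway(*samples)
        tukey = pairwise_tukeyhsd(
            data[outcome].to_numpy(float), data[group].astype(str).to_numpy(), alpha=0.05
        )
        uniq = [str(g) for g in tukey.groupsunique]
        pairs = [
            {
                "group1": uniq[i],
                "group2": uniq[j],
                "meandiff": float(md),
                "p_adjusted": float(pv),
            }
            for (i, j), md, pv in zip(
                itertools.combinations(range(len(uniq)), 2), tukey.meandiffs, tukey.pvalues
            )
        ]
        return ComparisonResult(
            statistic=float(f),
            p_raw=float(p),
            p_adjusted=float(p),
            adjustment="tukey",
            label=f"anova:{outcome}",
            extra={"pairwise": pairs, "flags": flags},
        )
    if kind == "chi2":
        table = pd.crosstab(data[outcome], data[group]).to_numpy()
        chi2, p, dof, expected = sps.chi2_contingency(table, correction=continuity_correction)
        flags = ["expected cell count < 1"] if (expected < 1).any() else []
        return ComparisonResult(
            statistic=float(chi2),
            p_raw=float(p),
            p_adjusted=float(p),
            adjustment="none",
            label=f"chi2:{outcome}",
            extra={"dof": int(dof), "flags": flags},
        )
    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# covariate-adjusted comparisons


def _design(
    data: pd.DataFrame, group: str, covariates: tuple, levels: list, second_factor: str | None
):
    """Treatment-coded design matrix: intercept, group dummies,
    optional second-factor dummies, covariates (sex dummy-coded)."""
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for lev in levels[1:]:
        cols.append((data[group].astype(str) == lev).to_numpy(float))
        names.append(f"{group}[{lev}]")
    if second_factor is not None:
        flevels = sorted(data[second_factor].astype(str).unique())
        for lev in flevels[1:]:
            cols.append((data[second_factor].astype(str) == lev).to_numpy(float))
            names.append(f"{second_factor}[{lev}]")
    for cov in covariates:
        v = data[cov]
        if v.dtype == object or str(v.dtype) in ("category", "bool"):
            clevels = sorted(v.astype(str).unique())
            for lev in clevels[1:]:
                cols.append((v.astype(str) == lev).to_numpy(float))
                names.append(f"{cov}[{lev}]")
        else:
            cols.append(v.to_numpy(float))
            names.append(cov)
    X = np.column_stack(cols)
    if np.linalg.cond(X) > 1e10:
        raise ValueError("collinear covariates: design matrix ill-conditioned")
    return X, names


def ancova(
    df: pd.DataFrame,
    outcome: str,
    group: str = "group",
    covariates: tuple = ("age", "sex", "education"),
    ranked: bool = False,
    second_factor: str | None = None,
) -> ComparisonResult:
    """ANCOVA: outcome ~ group + covariates, group F-test, Bonferroni-
    adjusted pairwise adjusted-mean contrasts.

    ``ranked=True`` rank-transforms the outcome first (rank ANCOVA),
    making the test invariant to monotone transforms of the outcome.
    ``second_factor`` adds a second categorical main effect (two-way
    ANCOVA); its F-test is reported under ``extra``.
    """
    use = [outcome, group, *covariates] + ([second_factor] if second_factor else [])
    data = df[use].dropna().reset_index(drop=True)
    y = data[outcome].to_numpy(float)
    if ranked:
        y = sps.rankdata(y)
    levels = sorted(data[group].astype(str).unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")

    X, names = _design(data, group, covariates, levels, second_factor)
    model = sm.OLS(y, X).fit()

    k = len(levels) - 1
    contrast = np.zeros((k, X.shape[1]))
    for i in range(k):
        contrast[i, 1 + i] = 1.0
    ftest = model.f_test(contrast)
    f_group = float(ftest.fvalue)
    p_group = float(ftest.pvalue)

    pairs = []
    m = len(levels) * (len(levels) - 1) // 2
    for a, b in itertools.combinations(range(len(levels)), 2):
        # dummy for levels[i] sits at column i (i >= 1); level 0 is reference
        vec = np.zeros(X.shape[1])
        if a > 0:
            vec[a] = 1.0
        if b > 0:
            vec[b] -= 1.0
        tt = model.t_test(vec)
        p_raw = float(tt.pvalue)
        pairs.append(
            {
                "group1": levels[a],
                "group2": levels[b],
                "adj_mean_diff": float(np.squeeze(tt.effect)),
                "p_raw": p_raw,
                "p_bonferroni": bonferroni(p_raw, m),
            }
        )

    extra = {"pairwise": pairs, "terms": names, "ranked": ranked}
    if second_factor is not None:
        fcols = [i for i, nm in enumerate(names) if nm.startswith(f"{second_factor}[")]
        c2 = np.zeros((len(fcols), X.shape[1]))
        for r, c in enumerate(fcols):
            c2[r, c] = 1.0
        ft2 = model.f_test(c2)
        extra["second_factor"] = {
            "name": second_factor,
            "F": float(ft2.fvalue),
            "p": float(ft2.pvalue),
        }
    return ComparisonResult(
        statistic=f_group,
        p_raw=p_group,
        p_adjusted=p_group,
        adjustment="bonferroni",
        label=f"{'rank-' if ranked else ''}ancova:{outcome}",
        extra=extra,
    )


# ---------------------------------------------------------------------------
# correlations


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with two-sided p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: correlation undefined")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


# ---------------------------------------------------------------------------
# robust regression


def _residualize(z: np.ndarray, controls: np.ndarray) -> np.ndarray:
    """Residuals of z after OLS on controls (with intercept)."""
    C = np.column_stack([np.ones(len(z)), controls]) if controls.size else np.ones((len(z), 1))
    beta, *_ = np.linalg.lstsq(C, z, rcond=None)
    return z - C @ beta


def ransac_fit(
    X: np.ndarray,
    y: np.ndarray,
    controls: np.ndarray | None = None,
    residual_threshold: float | None = None,
    max_trials: int = 1000,
    seed: int = 0,
    control_names: tuple = (),
    predictor_names: tuple = (),
) -> RobustFit:
    """RANSAC regression of y on X with controls partialled out first.

    Controls (e.g. age, sex, education) are residualized out of both X
    and y by OLS.  RANSAC then repeatedly fits minimal samples
    (p + 1 points), marks inliers by absolute residual below the
    threshold (default 1.5 x the MAD-based robust SD of the OLS
    residuals), and refits the best consensus set by least squares.
    Seed-reproducible.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(y):
        X = X.T
    y = np.asarray(y, float)
    n, p = X.shape
    if n <= p + 2:
        raise ValueError("too few observations for RANSAC")
    if controls is not None and np.asarray(controls).size:
        controls = np.atleast_2d(np.asarray(controls, float))
        if controls.shape[0] != n:
            controls = controls.T
        Xr = np.column_stack([_residualize(X[:, j], controls) for j in range(p)])
        yr = _residualize(y, controls)
    else:
        Xr, yr = X, y

    if residual_threshold is None:
        ols_resid = _residualize(yr, Xr)
        mad = np.median(np.abs(ols_resid - np.median(ols_resid)))
        residual_threshold = 1.5 * 1.4826 * mad
        if residual_threshold == 0:
            residual_threshold = 1e-12

    est = RANSACRegressor(
        estimator=LinearRegression(),
        min_samples=p + 1,
        residual_threshold=residual_threshold,
        max_trials=max_trials,
        random_state=seed,
    )
    est.fit(Xr, yr)
    if not est.inlier_mask_.sum() >= p + 1:
        raise RuntimeError("no consensus set of at least p + 1 points")
    return RobustFit(
        coefficients=np.asarray(est.estimator_.coef_, float),
        intercept=float(est.estimator_.intercept_),
        inlier_mask=est.inlier_mask_.copy(),
        n_inliers=int(est.inlier_mask_.sum()),
        controls=tuple(control_names),
        predictors=tuple(predictor_names),
    )


def results_table(results: list[ComparisonResult]) -> pd.DataFrame:
    """Tidy CSV-ready table of comparison results."""
    rows = []
    for r in results:
        rows.append(
            {
                "label": r.label,
                "statistic": r.statistic,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "adjustment": r.adjustment,
                "effect_d": r.effect_d,
                "effect_r": r.effect_r,
            }
        )
    return pd.DataFrame(rows)
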