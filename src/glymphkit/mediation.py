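"""Bootstrap mediation analysis.

Decomposes the effect of an exposure x on an outcome y into an
indirect path through a mediator m (a * b) and a remaining direct path
c'.  Three OLS fits on standardized variables:

    m ~ x + covariates            -> a
    y ~ x + m + covariates        -> b (and c', the direct effect)
    y ~ x + covariates            -> c (total effect)

In OLS algebra c = c' + a * b exactly.  The indirect effect gets a
seeded percentile bootstrap CI (row resampling); partial mediation is
declared when the indirect CI excludes 0 while the direct effect
remains nonzero at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MediationResult:
    a: float
    b: float
    c_total: float
    c_prime: float
    indirect: float
    boot_ci: tuple[float, float]
    p_indirect: float
    partial_mediation: bool
    covariates: tuple
    n: int
    n_boot: int
    n_degenerate: int
    seed: int


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("constant variable in mediation model")
    return (v - v.mean()) / sd


def _ols_coef(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def _paths(x, m, y, C):
    """(a, b, c_total, c_prime) from the three OLS fits."""
    ones = np.ones((len(x), 1))
    Xa = np.column_stack([ones, x, C])
    a = _ols_coef(Xa, m)[1]
    Xb = np.column_stack([ones, x, m, C])
    beta_b = _ols_coef(Xb, y)
    c_prime, b = beta_b[1], beta_b[2]
    c_total = _ols_coef(Xa, y)[1]
    return a, b, c_total, c_prime


def mediate(
    data: pd.DataFrame,
    x: str,
    m: str,
    y: str,
    covariates: tuple = (),
    n_boot: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
) -> MediationResult:
    """Percentile-bootstrap mediation of x -> m -> y.

    Variables are standardized internally so all coefficients are
    scale-free betas.  Complete cases only; requires n >= 30.
    Degenerate bootstrap resamples (a constant variable after
    resampling) are skipped and counted.
    """
    if m == x or m == y or x == y:
        raise ValueError("x, m, y must be distinct variables")
    cols = [x, m, y, *covariates]
    dd = data[cols].dropna()
    n = len(dd)
    if n < 30:
        raise ValueError(f"need >= 30 complete cases, got {n}")

    xv = _zscore(dd[x].to_numpy(float))
    mv = _zscore(dd[m].to_numpy(float))
    yv = _zscore(dd[y].to_numpy(float))
    C = np.column_stack(
        [
            _zscore(pd.get_dummies(dd[c], drop_first=True).to_numpy(float).ravel())
            if dd[c].dtype == object
            else _zscore(dd[c].to_numpy(float))
            for c in covariates
        ]
    ) if covariates else np.empty((n, 0))

    a, b, c_total, c_prime = _paths(xv, mv, yv, C)
    indirect = a * b

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n_degenerate = 0
    k = 0
    while k < n_boot:
        idx = rng.integers(0, n, n)
        xb, mb, yb = xv[idx], mv[idx], yv[idx]
        if xb.std() == 0 or mb.std() == 0 or yb.std() == 0:
            n_degenerate += 1
            continue
        ab, bb, *_ = _paths(xb, mb, yb, C[idx])
        boots[k] = ab * bb
        k += 1
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    # two-sided bootstrap p: twice the smaller tail fraction
    p_ind = 2 * min((boots <= 0).mean(), (boots >= 0).mean())
    p_ind = float(min(1.0, max(p_ind, 1.0 / n_boot)))

    excludes_zero = not (lo <= 0 <= hi)
    # direct effect nonzero at alpha via its OLS t-test
    ones = np.ones((n, 1))
    Xb = np.column_stack([ones, xv, mv, C])
    beta = _ols_coef(Xb, yv)
    resid = yv - Xb @ beta
    dof = n - Xb.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(Xb.T @ Xb)
    from scipy import stats as sps

    t_direct = beta[1] / np.sqrt(cov[1, 1])
    p_direct = 2 * sps.t.sf(abs(t_direct), dof)

    return MediationResult(
        a=float(a),
        b=float(b),
        c_total=float(c_total),
        c_prime=float(c_prime),
        indirect=float(indirect),
        boot_ci=(float(lo), float(hi)),
        p_indirect=p_ind,
        partial_mediation=bool(excludes_zero and p_direct < alpha),
        covariates=tuple(covariates),
        n=n,
        n_boot=n_boot,
        n_degenerate=n_degenerate,
        seed=seed,
    )
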