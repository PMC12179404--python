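"""Latent-variable structural equation modelling (ML estimation).

Model: observed indicators x = Lambda eta + eps load each on exactly
one latent; latents obey eta = B eta + zeta where B holds the
structural paths, exogenous latents have free (co)variances and
endogenous latents free disturbance variances.  Identification by the
marker-variable method: the first loading per latent is fixed to 1.

Implied covariance: Sigma(theta) = Lambda (I-B)^-1 Psi (I-B)^-T
Lambda^T + Theta with diagonal Theta.  Estimation minimises the ML
discrepancy F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p over the free
parameters; chi^2 = (n - 1) F, df = p(p+1)/2 - n_free.

Fit indices: CFI = 1 - max(chi2 - df, 0) / max(chi2_b - df_b,
chi2 - df, 0) against the uncorrelated-indicators baseline;
RMSEA = sqrt(max(chi2 - df, 0) / (df (n - 1)));
GFI = 1 - tr[(Sigma^-1 S - I)^2] / tr[(Sigma^-1 S)^2].

The default model is the glymphatic four-latent structure: Inflow
(ChP/LatVent, BOLD-CSF coupling max) and Outflow (ALPS average, dorsal
TTP/AUC/k_ep) as correlated exogenous latents, WMH (PWMH, DWMH,
Fazekas total) regressed on both, Cognition (MMSE, MoCA) regressed on
WMH.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize


@dataclass(frozen=True)
class SemModelSpec:
    """Measurement and structural specification.

    ``latents`` maps latent name -> ordered indicator columns (the
    first is the marker whose loading is fixed to 1); ``paths`` are
    directed (source, destination) latent pairs; ``covariances`` are
    undirected exogenous latent pairs allowed to covary.
    """

    latents: tuple  # ((name, (indicators...)), ...)
    paths: tuple  # ((src, dst), ...)
    covariances: tuple = ()

    def __post_init__(self) -> None:
        names = [n for n, _ in self.latents]
        if len(set(names)) != len(names):
            raise ValueError("duplicate latent names")
        seen: set = set()
        for _, inds in self.latents:
            if set(inds) & seen:
                raise ValueError("each indicator must load on exactly one latent")
            seen |= set(inds)
        for s, d in self.paths:
            if s not in names or d not in names:
                raise ValueError(f"path {s}->{d} references unknown latent")
        dsts = {d for _, d in self.paths}
        for a, b in self.covariances:
            if a in dsts or b in dsts:
                raise ValueError("covariances are only allowed between exogenous latents")

    @property
    def latent_names(self) -> list:
        return [n for n, _ in self.latents]

    @property
    def indicator_names(self) -> list:
        return [i for _, inds in self.latents for i in inds]

    @property
    def endogenous(self) -> list:
        dsts = {d for _, d in self.paths}
        return [n for n in self.latent_names if n in dsts]

    @property
    def exogenous(self) -> list:
        dsts = {d for _, d in self.paths}
        return [n for n in self.latent_names if n not in dsts]

    def n_free(self) -> int:
        free_load = sum(len(inds) - 1 for _, inds in self.latents)
        return (
            free_load
            + len(self.paths)
            + len(self.exogenous)  # exogenous variances
            + len(self.covariances)
            + len(self.endogenous)  # disturbance variances
            + len(self.indicator_names)  # Theta diagonal
        )

    def df(self) -> int:
        p = len(self.indicator_names)
        return p * (p + 1) // 2 - self.n_free()


def default_sem_spec(include_inflow_path: bool = True) -> SemModelSpec:
    """The glymphatic inflow/outflow -> WMH -> cognition model."""
    paths = [("outflow", "wmh"), ("wmh", "cognition")]
    if include_inflow_path:
        paths.insert(0, ("inflow", "wmh"))
    return SemModelSpec(
        latents=(
            ("inflow", ("chp_latvent", "coupling_max")),
            ("outflow", ("alps_avg", "dorsal_ttp", "dorsal_auc", "dorsal_kep")),
            ("wmh", ("pwmh_volume", "dwmh_volume", "fazekas_total")),
            ("cognition", ("mmse", "moca")),
        ),
        paths=tuple(paths),
        covariances=(("inflow", "outflow"),),
    )


@dataclass
class SemFit:
    loadings: dict  # indicator -> standardized loading
    paths: dict  # (src, dst) -> standardized coefficient
    exo_correlations: dict  # (a, b) -> correlation
    chi2: float
    df: int
    cfi: float
    gfi: float
    rmsea: float
    n: int
    converged: bool
    heywood: list = field(default_factory=list)
    theta_hat: np.ndarray = field(default=None, repr=False)
    spec: SemModelSpec = field(default=None, repr=False)

    @property
    def chi2_df_ratio(self) -> float:
        """chi^2 / df; NaN (flagged by df == 0) for a saturated model."""
        return self.chi2 / self.df if self.df > 0 else float("nan")


class _Model:
    """Index bookkeeping between the free-parameter vector and the
    (Lambda, B, Psi, Theta) matrices."""

    def __init__(self, spec: SemModelSpec):
        self.spec = spec
        self.lat = spec.latent_names
        self.ind = spec.indicator_names
        self.p = len(self.ind)
        self.L = len(self.lat)
        self.lat_of = {}
        self.marker = {}
        for name, inds in spec.latents:
            for j, i in enumerate(inds):
                self.lat_of[i] = name
                if j == 0:
                    self.marker[name] = i
        self.free_load = [i for i in self.ind if self.marker[self.lat_of[i]] != i]
        self.exo = spec.exogenous
        self.endo = spec.endogenous
        # slices into theta vector
        k = 0
        self.sl_load = slice(k, k + len(self.free_load)); k += len(self.free_load)
        self.sl_path = slice(k, k + len(spec.paths)); k += len(spec.paths)
        self.sl_exov = slice(k, k + len(self.exo)); k += len(self.exo)
        self.sl_exoc = slice(k, k + len(spec.covariances)); k += len(spec.covariances)
        self.sl_dist = slice(k, k + len(self.endo)); k += len(self.endo)
        self.sl_theta = slice(k, k + self.p); k += self.p
        self.n_free = k
        assert k == spec.n_free()

    def matrices(self, theta: np.ndarray):
        lam = np.zeros((self.p, self.L))
        li = {n: k for k, n in enumerate(self.lat)}
        for name in self.lat:
            lam[self.ind.index(self.marker[name]), li[name]] = 1.0
        for v, i in zip(theta[self.sl_load], self.free_load):
            lam[self.ind.index(i), li[self.lat_of[i]]] = v
        B = np.zeros((self.L, self.L))
        for v, (s, d) in zip(theta[self.sl_path], self.spec.paths):
            B[li[d], li[s]] = v
        psi = np.zeros((self.L, self.L))
        for v, n in zip(theta[self.sl_exov], self.exo):
            psi[li[n], li[n]] = v
        for v, (a, b) in zip(theta[self.sl_exoc], self.spec.covariances):
            psi[li[a], li[b]] = psi[li[b], li[a]] = v
        for v, n in zip(theta[self.sl_dist], self.endo):
            psi[li[n], li[n]] = v
        th = np.diag(theta[self.sl_theta])
        return lam, B, psi, th

    def implied(self, theta: np.ndarray) -> np.ndarray:
        lam, B, psi, th = self.matrices(theta)
        inv = np.linalg.inv(np.eye(self.L) - B)
        C = inv @ psi @ inv.T
        return lam @ C @ lam.T + th

    def value_and_grad(self, theta: np.ndarray, S: np.ndarray, logdet_S: float):
        """F_ML and its analytic gradient.

        dF/dt = tr[(Sigma^-1 - Sigma^-1 S Sigma^-1) dSigma/dt]; the
        per-parameter dSigma terms reduce to single matrix entries of
        precomputed products (A = the bracketed matrix, G = (I-B)^-1,
        C = G Psi G^T).
        """
        lam, B, psi, th = self.matrices(theta)
        G = np.linalg.inv(np.eye(self.L) - B)
        C = G @ psi @ G.T
        sigma = lam @ C @ lam.T + th
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(theta)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        inv_sigma = np.linalg.inv(sigma)
        f = logdet + np.trace(S @ inv_sigma) - logdet_S - self.p
        A = inv_sigma - inv_sigma @ S @ inv_sigma

        grad = np.zeros_like(theta)
        li = {n: k for k, n in enumerate(self.lat)}
        ALC = A @ lam @ C  # p x L
        # free loadings: dSigma = e_j (Lam C)_k^T + sym -> 2 (A Lam C)_{jk}
        grad[self.sl_load] = [
            2.0 * ALC[self.ind.index(i), li[self.lat_of[i]]] for i in self.free_load
        ]
        # paths B_{d,s}: 2 (C Lam^T A Lam G)_{s,d}
        M = C @ lam.T @ A @ lam @ G  # L x L
        grad[self.sl_path] = [2.0 * M[li[s], li[d]] for s, d in self.spec.paths]
        # psi entries: H = G^T Lam^T A Lam G
        H = G.T @ lam.T @ A @ lam @ G
        grad[self.sl_exov] = [H[li[n], li[n]] for n in self.exo]
        grad[self.sl_exoc] = [2.0 * H[li[a], li[b]] for a, b in self.spec.covariances]
        grad[self.sl_dist] = [H[li[n], li[n]] for n in self.endo]
        # Theta diagonal: A_jj
        grad[self.sl_theta] = np.diag(A)
        return float(f), grad

    def start(self, S: np.ndarray) -> np.ndarray:
        """Data-driven starting values from marker correlations."""
        sd = np.sqrt(np.diag(S))
        R = S / np.outer(sd, sd)
        theta = np.zeros(self.n_free)
        mk = {n: self.ind.index(self.marker[n]) for n in self.lat}
        loads = []
        for i in self.free_load:
            j = self.ind.index(i)
            m = mk[self.lat_of[i]]
            loads.append(np.clip(R[j, m], -0.9, 0.9) / 0.7)
        theta[self.sl_load] = loads
        theta[self.sl_path] = 0.0
        theta[self.sl_exov] = [0.5 * S[mk[n], mk[n]] for n in self.exo]
        theta[self.sl_exoc] = [0.5 * S[mk[a], mk[b]] for a, b in self.spec.covariances]
        theta[self.sl_dist] = [0.5 * S[mk[n], mk[n]] for n in self.endo]
        theta[self.sl_theta] = 0.5 * np.diag(S)
        return theta


def fit_sem(
    data: pd.DataFrame,
    spec: SemModelSpec | None = None,
    n: int | None = None,
    start: np.ndarray | None = None,
) -> SemFit:
    """Maximum-likelihood SEM fit on the sample covariance matrix.

    ``data`` holds the indicator columns (complete cases are used);
    ``n`` overrides the sample size entering chi^2 (for
    covariance-input workflows).  Columns are standardized internally;
    the standardized solution is reported.  A Heywood case (negative
    residual or disturbance variance) is flagged, not truncated.
    """
    spec = spec or default_sem_spec()
    model = _Model(spec)
    cols = spec.indicator_names
    dd = data[cols].dropna()
    n = n or len(dd)
    if spec.df() < 0:
        raise ValueError("model has negative degrees of freedom")
    if n <= model.n_free:
        raise ValueError("sample size must exceed the number of free parameters")
    X = dd.to_numpy(float)
    X = (X - X.mean(0)) / X.std(0)
    S = np.cov(X, rowvar=False, ddof=1)
    return _fit_from_cov(S, n, model, start=start)


def _fit_from_cov(
    S: np.ndarray,
    n: int,
    model: _Model,
    start: np.ndarray | None = None,
    opts: dict | None = None,
) -> SemFit:
    spec = model.spec
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance not positive definite")

    theta0 = model.start(S) if start is None else np.asarray(start, float)

    def objective(theta):
        return model.value_and_grad(theta, S, logdet_S)

    opts = opts or {"maxiter": 2000, "ftol": 1e-11, "gtol": 1e-6}
    sol = minimize(objective, theta0, jac=True, method="L-BFGS-B", options=opts)
    if start is None:
        # one polishing pass helps when the cold run stops on ftol
        sol2 = minimize(objective, sol.x, jac=True, method="L-BFGS-B", options=opts)
        if sol2.fun < sol.fun:
            sol = sol2
    theta = sol.x
    converged = bool(sol.success and np.isfinite(sol.fun) and sol.fun < 1e9)

    lam, B, psi, th = model.matrices(theta)
    heywood = []
    for v, name in zip(theta[model.sl_theta], model.ind):
        if v < 0:
            heywood.append(f"residual variance of {name} negative ({v:.4g})")
    for v, name in zip(theta[model.sl_dist], model.endo):
        if v < 0:
            heywood.append(f"disturbance variance of {name} negative ({v:.4g})")

    inv = np.linalg.inv(np.eye(model.L) - B)
    C = inv @ psi @ inv.T
    sigma = lam @ C @ lam.T + th
    sd_lat = np.sqrt(np.clip(np.diag(C), 1e-12, None))
    sd_ind = np.sqrt(np.clip(np.diag(sigma), 1e-12, None))
    li = {name: k for k, name in enumerate(model.lat)}

    loadings = {}
    for i in model.ind:
        j = model.ind.index(i)
        k = li[model.lat_of[i]]
        loadings[i] = float(lam[j, k] * sd_lat[k] / sd_ind[j])
    paths = {
        (s, d): float(B[li[d], li[s]] * sd_lat[li[s]] / sd_lat[li[d]])
        for s, d in spec.paths
    }
    exo_corr = {
        (a, b): float(psi[li[a], li[b]] / (sd_lat[li[a]] * sd_lat[li[b]]))
        for a, b in spec.covariances
    }

    f_min = float(sol.fun)
    chi2 = (n - 1) * f_min
    df = spec.df()
    p = model.p
    # baseline: uncorrelated indicators
    R = S / np.outer(np.sqrt(np.diag(S)), np.sqrt(np.diag(S)))
    chi2_b = -(n - 1) * np.linalg.slogdet(R)[1]
    df_b = p * (p - 1) // 2
    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 - max(chi2 - df, 0.0) / denom if denom > 0 else 1.0
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))) if df > 0 else 0.0
    inv_sigma = np.linalg.inv(sigma)
    M = inv_sigma @ S - np.eye(p)
    gfi = 1.0 - np.trace(M @ M) / np.trace((inv_sigma @ S) @ (inv_sigma @ S))

    return SemFit(
        loadings=loadings,
        paths=paths,
        exo_correlations=exo_corr,
        chi2=float(chi2),
        df=int(df),
        cfi=float(np.clip(cfi, 0.0, 1.0)),
        gfi=float(gfi),
        rmsea=rmsea,
        n=int(n),
        converged=converged,
        heywood=heywood,
        theta_hat=theta,
        spec=spec,
    )


def boot_sem(
    data: pd.DataFrame,
    spec: SemModelSpec | None = None,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    min_convergence: float = 0.95,
) -> dict:
    """Percentile bootstrap CIs for the standardized structural paths.

    Rows are resampled with replacement (seeded); each resample is
    refit warm-started at the full-sample solution.  Aborts with
    diagnostics when fewer than ``min_convergence`` of the resamples
    converge.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    spec = spec or default_sem_spec()
    full = fit_sem(data, spec)
    model = _Model(spec)
    cols = spec.indicator_names
    X = data[cols].dropna().to_numpy(float)
    X = (X - X.mean(0)) / X.std(0)
    n = len(X)

    rng = np.random.default_rng(seed)
    draws = {key: [] for key in full.paths}
    n_fail = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        Xb = X[idx]
        sd = Xb.std(0)
        if (sd == 0).any():
            n_fail += 1
            continue
        Xb = (Xb - Xb.mean(0)) / sd
        S = np.cov(Xb, rowvar=False, ddof=1)
        try:
            # warm-started resample refits tolerate a looser gradient stop
            fit = _fit_from_cov(
                S, n, model, start=full.theta_hat,
                opts={"maxiter": 800, "ftol": 1e-10, "gtol": 1e-5},
            )
        except (np.linalg.LinAlgError, ValueError):
            n_fail += 1
            continue
        if not fit.converged:
            n_fail += 1
            continue
        for key in draws:
            draws[key].append(fit.paths[key])
    rate = 1.0 - n_fail / n_boot
    if rate < min_convergence:
        raise RuntimeError(
            f"bootstrap convergence rate {rate:.2%} below {min_convergence:.0%} "
            f"({n_fail}/{n_boot} resamples failed)"
        )
    qs = (100 * alpha / 2, 100 * (1 - alpha / 2))
    cis = {
        key: tuple(np.percentile(np.array(vals), qs)) for key, vals in draws.items()
    }
    return {
        "paths": {f"{s}->{d}": full.paths[(s, d)] for s, d in full.paths},
        "ci": {f"{s}->{d}": cis[(s, d)] for s, d in cis},
        "n_boot": n_boot,
        "n_failed": n_fail,
        "convergence_rate": rate,
        "seed": seed,
    }
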