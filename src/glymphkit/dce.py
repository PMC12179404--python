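"""DCE-MRI time-intensity curve analysis for meningeal lymphatic vessels
(MLVs) and choroid plexus.

Semiquantitative descriptors (wash-in rate, time to peak, area under
the curve) are read off the normalised enhancement curve; quantitative
parameters come from the extended Tofts two-compartment model

    e(t) = v_p * C_a(t) + K_trans * (C_a * exp(-k_ep t))(t)

with C_a a bi-exponential population arterial input function.  K_trans
(1/min) is the contrast transfer constant, k_ep (1/min) the reflux
rate, V_e = K_trans / k_ep the extravascular extracellular volume
fraction, and v_p the plasma fraction.  Fits with normalised deviation
>= 0.05 are excluded by the quality filter.

Unit conventions (the vendor's are unpublished): wash-in in 1/s on the
normalised enhancement, TTP in minutes from injection, AUC the
trapezoidal integral of enhancement over a fixed 120-s post-injection
window divided by the window length (dimensionless).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

_SECONDS_PER_MINUTE = 60.0


@dataclass
class TimeIntensityCurve:
    """A DCE enhancement curve: times (s), raw signal, baseline window."""

    t: np.ndarray  # seconds
    s: np.ndarray  # a.u.
    baseline_window: tuple[int, ...] = (0, 1)  # pre-injection sample indices
    injection_index: int = 1  # last pre-injection sample
    region: str = "dorsal_mlv"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.t.shape != self.s.shape or self.t.ndim != 1:
            raise ValueError("t and s must be 1-D arrays of equal length")
        if not (np.diff(self.t) > 0).all():
            raise ValueError("t must be strictly increasing")
        if max(self.baseline_window, default=-1) > self.injection_index:
            raise ValueError("baseline window must precede the injection sample")


@dataclass
class SemiQuantParams:
    wash_in: float  # 1/s
    ttp: float  # minutes from injection
    auc: float  # dimensionless (mean enhancement over the window)
    degenerate: bool = False


@dataclass
class ToftsParams:
    ktrans: float  # 1/min
    kep: float  # 1/min
    vp: float  # fraction

    @property
    def ve(self) -> float:
        """Extravascular extracellular fraction, K_trans / k_ep."""
        return self.ktrans / self.kep if self.kep > 0 else 0.0

    def __post_init__(self) -> None:
        if self.ktrans < 0 or self.kep < 0 or self.vp < 0:
            raise ValueError("kinetic parameters must be non-negative")


@dataclass
class ToftsFit:
    ktrans: float
    kep: float
    ve: float
    vp: float
    fit_deviation: float  # RMS residual / max |e|
    converged: bool
    flags: list = field(default_factory=list)
    region: str = ""
    subject_id: str = ""


@dataclass(frozen=True)
class BiexpAif:
    """Population arterial input function, zero before the injection delay.

    C_a(t) = A1 exp(-m1 t') + A2 exp(-m2 t'), t' = t - t0 in minutes.
    Defaults give a bolus-plus-tail shape whose Tofts response with
    MLV-like parameters peaks around 1-2 min after injection.
    """

    a1: float = 5.0
    m1: float = 3.0  # 1/min, fast bolus decay
    a2: float = 1.0
    m2: float = 0.1  # 1/min, slow tail
    t0: float = 0.0  # injection delay, minutes

    def __call__(self, t_min: np.ndarray) -> np.ndarray:
        tp = np.asarray(t_min, dtype=float) - self.t0
        out = self.a1 * np.exp(-self.m1 * tp) + self.a2 * np.exp(-self.m2 * tp)
        return np.where(tp > 0, out, 0.0)

    def convolve_exp(self, t_min: np.ndarray, kep: float) -> np.ndarray:
        """(C_a * exp(-kep t))(t), analytic for the bi-exponential form.

        Integral of exp(-m tau) against exp(-kep (t - tau)) is
        (exp(-m t) - exp(-kep t)) / (kep - m); the m == kep limit is
        t exp(-kep t).
        """
        tp = np.asarray(t_min, dtype=float) - self.t0
        tpos = np.clip(tp, 0.0, None)
        out = np.zeros_like(tpos)
        for a, m in ((self.a1, self.m1), (self.a2, self.m2)):
            if abs(kep - m) < 1e-10:
                out += a * tpos * np.exp(-kep * tpos)
            else:
                out += a * (np.exp(-m * tpos) - np.exp(-kep * tpos)) / (kep - m)
        return np.where(tp > 0, out, 0.0)


def tofts_model(t_s: np.ndarray, params: ToftsParams, aif: BiexpAif, t_inj_s: float) -> np.ndarray:
    """Extended Tofts enhancement on a grid of seconds."""
    t_min = (np.asarray(t_s, dtype=float) - t_inj_s) / _SECONDS_PER_MINUTE
    return params.vp * aif(t_min) + params.ktrans * aif.convolve_exp(t_min, params.kep)


def enhancement(curve: TimeIntensityCurve) -> np.ndarray:
    """Normalised enhancement e(t) = (S(t) - S0) / S0.

    S0 is the mean signal over the pre-injection baseline window.
    """
    if len(curve.baseline_window) == 0:
        raise ValueError("baseline window empty")
    s0 = float(curve.s[list(curve.baseline_window)].mean())
    if s0 <= 0:
        raise ValueError(f"baseline signal S0 = {s0} <= 0: enhancement undefined")
    return (curve.s - s0) / s0


def semiquant(curve: TimeIntensityCurve, auc_window_s: float = 120.0) -> SemiQuantParams:
    """Wash-in rate, time to peak, and area under the enhancement curve.

    wash-in: maximum forward-difference slope of e between injection
    and peak (1/s).  TTP: time of peak enhancement minus injection
    time, minutes.  AUC: trapezoidal integral of e over
    ``auc_window_s`` seconds post injection, divided by the window
    length.  A flat curve is flagged degenerate with all-zero metrics.
    """
    e = enhancement(curve)
    i0 = curve.injection_index
    if len(curve.t) - i0 < 3:
        raise ValueError("need at least 3 post-injection samples")
    t_inj = curve.t[i0]
    if t_inj + auc_window_s > curve.t[-1] + 1e-9:
        raise ValueError("AUC window exceeds the acquisition")

    post = e[i0:]
    peak_rel = int(np.argmax(post))
    peak = i0 + peak_rel
    if peak_rel == 0 or np.allclose(post, post[0]):
        return SemiQuantParams(wash_in=0.0, ttp=0.0, auc=0.0, degenerate=True)

    slopes = np.diff(e[i0 : peak + 1]) / np.diff(curve.t[i0 : peak + 1])
    wash_in = float(slopes.max())
    ttp = float((curve.t[peak] - t_inj) / _SECONDS_PER_MINUTE)

    t_end = t_inj + auc_window_s
    grid = np.linspace(t_inj, t_end, 241)
    e_grid = np.interp(grid, curve.t, e)
    auc = float(np.trapezoid(e_grid, grid) / auc_window_s)
    return SemiQuantParams(wash_in=wash_in, ttp=ttp, auc=auc)


def fit_extended_tofts(
    curve: TimeIntensityCurve,
    aif: BiexpAif | None = None,
    n_starts: int = 5,
    seed: int = 0,
    max_ktrans: float = 5.0,
    max_kep: float = 20.0,
    max_vp: float = 1.0,
) -> ToftsFit:
    """Nonlinear least-squares extended Tofts fit with multi-start.

    Starting points are drawn log-uniformly (seeded); the best of
    ``n_starts`` trust-region fits is kept.  fit_deviation is the RMS
    residual normalised by the peak |enhancement|; V_e is reported as
    K_trans / k_ep (0, flagged, when K_trans ~ 0).
    """
    aif = aif or BiexpAif()
    e = enhancement(curve)
    t_inj = curve.t[curve.injection_index]

    def residuals(theta):
        kt, kep, vp = theta
        model = tofts_model(curve.t, ToftsParams(max(kt, 0), max(kep, 0), max(vp, 0)), aif, t_inj)
        return model - e

    rng = np.random.default_rng(seed)
    lo = np.array([0.0, 1e-6, 0.0])
    hi = np.array([max_ktrans, max_kep, max_vp])
    starts = [np.array([0.05, 0.5, 0.01])]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(
            np.array(
                [
                    10 ** rng.uniform(-3, 0),  # ktrans
                    10 ** rng.uniform(-2, 1),  # kep
                    10 ** rng.uniform(-4, -0.5),  # vp
                ]
            )
        )

    best = None
    any_converged = False
    for x0 in starts:
        try:
            sol = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        any_converged = any_converged or sol.success
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("extended Tofts fit failed from every start")

    kt, kep, vp = best.x
    flags = []
    scale = float(np.abs(e).max())
    rms = float(np.sqrt(np.mean(best.fun**2)))
    deviation = rms / scale if scale > 0 else 0.0
    if kt <= 1e-4:
        flags.append("ktrans ~ 0: ve reported as 0")
        ve = 0.0
    else:
        ve = kt / kep
    for name, val, top in (("ktrans", kt, max_ktrans), ("kep", kep, max_kep), ("vp", vp, max_vp)):
        if val >= top * (1 - 1e-6):
            flags.append(f"{name} at upper bound")
    return ToftsFit(
        ktrans=float(kt),
        kep=float(kep),
        ve=float(ve),
        vp=float(vp),
        fit_deviation=deviation,
        converged=bool(any_converged),
        flags=flags,
        region=curve.region,
    )


def qc_filter(fits: list[ToftsFit], threshold: float = 0.05):
    """Retain fits with deviation strictly below ``threshold``.

    Returns (retained, exclusion_log); the log carries one entry per
    excluded fit with its deviation.  An empty retained list is allowed.
    """
    retained, log = [], []
    for fit in fits:
        if fit.fit_deviation < threshold:
            retained.append(fit)
        else:
            log.append(
                {
                    "region": fit.region,
                    "subject_id": fit.subject_id,
                    "fit_deviation": fit.fit_deviation,
                    "reason": f"fit_deviation {fit.fit_deviation:.4g} >= {threshold}",
                }
            )
    return retained, log


def roi_mean_curve(series_4d: np.ndarray, mask: np.ndarray, t: np.ndarray, **kw) -> TimeIntensityCurve:
    """Voxel-mean signal per time point within an ROI mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    s = np.array([series_4d[..., k][mask].mean() for k in range(series_4d.shape[-1])])
    return TimeIntensityCurve(t=t, s=s, **kw)
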