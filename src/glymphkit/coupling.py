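"""Global BOLD-CSF coupling.

Low-frequency (< 0.1 Hz) oscillations of the global gray-matter BOLD
signal reflect slow vasomotor pulsations that drive CSF flow.  Coupling
is quantified by the lagged Pearson cross-correlation between the
global BOLD signal (or the negative of its first temporal derivative)
and the CSF inflow signal.

Sign convention: a positive lag means BOLD leads CSF, i.e. the
correlation at lag +L pairs BOLD(t - L) with CSF(t).  With that
orientation the BOLD-vs-CSF profile shows a positive peak near -6 s and
a negative peak near +2 s, and the negative-derivative profile a large
positive peak at lag 0 when coupling is intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats


@dataclass
class TimeSeriesPair:
    """Paired global BOLD and CSF signals on a shared TR grid."""

    bold: np.ndarray
    csf: np.ndarray
    tr: float
    discarded_volumes: int = 0

    def __post_init__(self) -> None:
        self.bold = np.asarray(self.bold, dtype=float)
        self.csf = np.asarray(self.csf, dtype=float)
        if self.bold.shape != self.csf.shape or self.bold.ndim != 1:
            raise ValueError("bold and csf must be 1-D series of equal length")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    def __len__(self) -> int:
        return len(self.bold)


@dataclass
class CouplingProfile:
    lags: np.ndarray  # seconds, symmetric about 0
    r: np.ndarray
    which: str  # bold_vs_csf | negderiv_vs_csf

    def r_at(self, lag_s: float) -> float:
        hit = np.isclose(self.lags, lag_s)
        if not hit.any():
            raise ValueError(
                f"lag {lag_s} s not on the profile grid (TR must divide it); "
                "no interpolation is performed"
            )
        return float(self.r[hit][0])


@dataclass
class CouplingMetrics:
    max_strength: float
    max_strength_lag: float
    r_at_plus2s: float
    r_at_minus6s: float
    deriv_coupling_at_0: float


def percent_change(x: np.ndarray) -> np.ndarray:
    """100 * (s - mean) / mean; undefined when the temporal mean ~ 0."""
    x = np.asarray(x, dtype=float)
    mu = x.mean()
    scale = np.abs(x).max()
    if scale == 0 or abs(mu) < 1e-9 * max(scale, 1.0):
        raise ValueError("temporal mean ~ 0: percent change undefined")
    return 100.0 * (x - mu) / mu


def bandpass(x: np.ndarray, tr: float, band=(0.01, 0.1), order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-pass (filtfilt)."""
    fs = 1.0 / tr
    lo, hi = band
    nyq = fs / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band} Hz invalid for fs = {fs} Hz")
    b, a = signal.butter(order, [lo / nyq, hi / nyq], btype="band")
    padlen = 3 * (max(len(a), len(b)) - 1)
    if len(x) <= padlen + 1:
        raise ValueError(f"series too short ({len(x)}) for zero-phase filtering")
    return signal.filtfilt(b, a, x)


def preprocess(
    pair_raw: TimeSeriesPair,
    discard: int = 10,
    band=(0.01, 0.1),
) -> TimeSeriesPair:
    """Discard leading volumes, convert to percent change, band-pass.

    The first ``discard`` volumes (default 10) are dropped, each series
    is normalised to percentage change about its temporal mean, and a
    zero-phase band-pass (default 0.01-0.1 Hz) is applied.
    """
    if len(pair_raw) <= discard:
        raise ValueError("series shorter than the discard window")
    bold = pair_raw.bold[discard:]
    csf = pair_raw.csf[discard:]
    bold = bandpass(percent_change(bold), pair_raw.tr, band)
    csf = bandpass(percent_change(csf), pair_raw.tr, band)
    return TimeSeriesPair(bold, csf, pair_raw.tr, discarded_volumes=discard)


def neg_derivative(x: np.ndarray, tr: float) -> np.ndarray:
    """-ds/dt by central differences (one-sided at the ends)."""
    return -np.gradient(np.asarray(x, dtype=float), tr)


def _lagged_r(ref: np.ndarray, csf: np.ndarray, m: int) -> float:
    """Pearson r between csf(t) and ref(t - m*TR) over the overlap."""
    n = len(ref)
    if m >= 0:
        a, b = csf[m:], ref[: n - m]
    else:
        a, b = csf[: n + m], ref[-m:]
    if len(a) < 3:
        raise ValueError("lag window leaves fewer than 3 overlapping samples")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance segment in lagged correlation")
    return float(stats.pearsonr(a, b)[0])


def xcorr_profile(
    pair: TimeSeriesPair,
    mode: str = "bold_vs_csf",
    lag_window: float = 20.0,
) -> CouplingProfile:
    """Lagged Pearson correlation profile over +/- ``lag_window`` seconds.

    ``mode``: ``bold_vs_csf`` correlates CSF with the BOLD signal;
    ``negderiv_vs_csf`` with the negative first derivative of BOLD.
    Lags run over integer multiples of TR; correlations use only the
    overlapping support (no padding).
    """
    if mode not in ("bold_vs_csf", "negderiv_vs_csf"):
        raise ValueError(f"unknown mode {mode!r}")
    tr = pair.tr
    max_m = int(np.floor(lag_window / tr + 1e-9))
    if max_m < 1:
        raise ValueError("lag window shorter than one TR")
    if max_m * 1 >= len(pair) - 3:
        raise ValueError("lag window too wide for the series span")
    ref = pair.bold if mode == "bold_vs_csf" else neg_derivative(pair.bold, tr)
    ms = np.arange(-max_m, max_m + 1)
    r = np.array([_lagged_r(ref, pair.csf, int(m)) for m in ms])
    return CouplingProfile(lags=ms * tr, r=r, which=mode)


def coupling_metrics(
    profile_bold: CouplingProfile,
    profile_deriv: CouplingProfile,
) -> CouplingMetrics:
    """Per-subject coupling summary.

    max_strength is the signed correlation with the largest magnitude
    in the BOLD-vs-CSF profile (ties broken toward the lag nearest 0);
    the +2 s and -6 s strengths are read directly off the grid, and the
    derivative coupling at lag 0.
    """
    if profile_bold.which != "bold_vs_csf" or profile_deriv.which != "negderiv_vs_csf":
        raise ValueError("profiles passed in the wrong order")
    absr = np.abs(profile_bold.r)
    best = absr.max()
    candidates = np.flatnonzero(np.isclose(absr, best))
    idx = candidates[np.argmin(np.abs(profile_bold.lags[candidates]))]
    return CouplingMetrics(
        max_strength=float(profile_bold.r[idx]),
        max_strength_lag=float(profile_bold.lags[idx]),
        r_at_plus2s=profile_bold.r_at(2.0),
        r_at_minus6s=profile_bold.r_at(-6.0),
        deriv_coupling_at_0=profile_deriv.r_at(0.0),
    )


def analyze_pair(
    pair_raw: TimeSeriesPair,
    discard: int = 10,
    band=(0.01, 0.1),
    lag_window: float = 20.0,
) -> tuple[CouplingMetrics, CouplingProfile, CouplingProfile]:
    """preprocess -> both profiles -> metrics, in one call."""
    pair = preprocess(pair_raw, discard=discard, band=band)
    prof_b = xcorr_profile(pair, "bold_vs_csf", lag_window)
    prof_d = xcorr_profile(pair, "negderiv_vs_csf", lag_window)
    return coupling_metrics(prof_b, prof_d), prof_b, prof_d
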