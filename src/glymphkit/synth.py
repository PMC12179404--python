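"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be simulated here: directional
diffusivity fields with planted ALPS ROI means, coupled BOLD/CSF series
with a planted (strength, lag), forward extended-Tofts DCE curves on
the 23 x 16.78-s grid, lesion scenes of axis-aligned ellipsoids against
a ventricle slab, and cohort tables drawn from the four-latent
structural model (Inflow, Outflow -> WMH -> Cognition) that the SEM
stage estimates.  Generators are pure functions of (truth, seed).

The cohort generator works in a standardized metric (all latents and
indicators unit variance), then rescales indicators affinely to
plausible observed units; correlations are unaffected by the rescale,
so the analytic implied covariance of the truth doubles as the implied
correlation of the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .alps import DiffusivityVolumes, RoiSpec
from .config import RunConfig
from .coupling import TimeSeriesPair, bandpass, neg_derivative
from .dce import BiexpAif, TimeIntensityCurve, ToftsParams, tofts_model
from .io import VoxelGrid
from .lesions import LesionScene

# ---------------------------------------------------------------------------
# diffusivity fields


def gen_diffusivity_field(
    values: dict,
    shape: tuple[int, int, int] = (40, 40, 12),
    spacing: tuple[float, float, float] = (1.8, 1.8, 1.8),
    background: float = 0.7e-3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DiffusivityVolumes:
    """Directional diffusivity maps with planted ROI means.

    ``values`` maps side -> fiber -> (dx, dy, dz) in mm^2/s, e.g.
    ``{"left": {"proj": (1.2e-3, 0.8e-3, 0.9e-3), "assoc": ...}, ...}``.
    ROI means equal the planted values exactly before noise; additive
    Gaussian noise with ``noise_sd`` is applied to the whole maps.
    """
    nx, ny, nz = shape
    if nx < 12 or ny < 12 or nz < 1:
        raise ValueError("shape too small to hold two 3x3 ROIs per hemisphere")
    rng = np.random.default_rng(seed)
    dx = np.full(shape, background)
    dy = np.full(shape, background)
    dz = np.full(shape, background)
    k = nz // 2
    centers = {
        ("left", "proj"): (nx // 4, ny // 3, k),
        ("left", "assoc"): (nx // 4, 2 * ny // 3, k),
        ("right", "proj"): (3 * nx // 4, ny // 3, k),
        ("right", "assoc"): (3 * nx // 4, 2 * ny // 3, k),
    }
    rois = {}
    for (side, fiber), center in centers.items():
        triple = values[side][fiber]
        if any(v < 0 for v in triple):
            raise ValueError("requested diffusivities must be non-negative")
        roi = RoiSpec(center)
        for vol, v in zip((dx, dy, dz), triple):
            for i, j, kk in roi.voxels():
                vol[i, j, kk] = v
        rois[(side, fiber)] = roi
    if noise_sd > 0:
        dx = np.clip(dx + rng.normal(0, noise_sd, shape), 0, None)
        dy = np.clip(dy + rng.normal(0, noise_sd, shape), 0, None)
        dz = np.clip(dz + rng.normal(0, noise_sd, shape), 0, None)
    return DiffusivityVolumes(dx=dx, dy=dy, dz=dz, spacing=spacing, rois=rois)


def alps_field_values(
    dxproj: float, dyproj: float, dxassoc: float, dzassoc: float, other: float = 0.8e-3
) -> dict:
    """Convenience: identical planted means for both hemispheres."""
    per_side = {
        "proj": (dxproj, dyproj, other),
        "assoc": (dxassoc, other, dzassoc),
    }
    return {"left": per_side, "right": per_side}


# ---------------------------------------------------------------------------
# BOLD / CSF series


def gen_bold_csf(
    strength: float | None = None,
    lag_s: float = 0.0,
    n_volumes: int = 240,
    tr: float = 2.0,
    snr: float | None = None,
    band: tuple[float, float] = (0.01, 0.1),
    seed: int = 0,
    bold_mean: float = 1000.0,
    csf_mean: float = 500.0,
) -> tuple[TimeSeriesPair, dict]:
    """Coupled BOLD/CSF series with a planted (strength, lag).

    BOLD is a band-limited (default 0.01-0.1 Hz) stochastic
    oscillation; CSF is the lag-shifted negative temporal derivative of
    BOLD plus white noise, scaled so the expected peak of the
    negative-derivative-vs-CSF correlation profile equals ``strength``
    at lag ``lag_s``.  Alternatively give ``snr`` (signal sd / noise
    sd); the implied strength is then recorded in the returned truth.
    Series are returned raw (positive means, pre-normalization).
    """
    if (strength is None) == (snr is None):
        raise ValueError("give exactly one of strength or snr")
    if strength is not None and abs(strength) > 1:
        raise ValueError("|coupling strength| must be <= 1")
    if snr is not None and snr <= 0:
        raise ValueError("snr must be positive")
    m_float = lag_s / tr
    m = int(round(m_float))
    if abs(m_float - m) > 1e-9:
        import warnings

        warnings.warn(f"lag {lag_s}s is not a multiple of TR={tr}s; rounding to {m * tr}s")
    if n_volumes <= 10 + abs(m) + 20:
        raise ValueError("n_volumes too small for the discard and lag window")

    rng = np.random.default_rng(seed)
    pad = 50
    white = rng.normal(size=n_volumes + 2 * pad)
    ext = bandpass(white, tr, band)
    b = ext[pad : pad + n_volumes]
    b = (b - b.mean()) / b.std()

    d = neg_derivative(b, tr)
    shifted = np.empty_like(d)
    if m >= 0:
        shifted[m:] = d[: n_volumes - m]
        shifted[:m] = d[0]
    else:
        shifted[:m] = d[-m:]
        shifted[m:] = d[-1]
    core = shifted / shifted.std()

    if strength is not None:
        rho = strength
    else:
        sigma = 1.0 / snr
        rho = 1.0 / np.sqrt(1.0 + sigma**2)
    if rho == 0:
        csf_unit = rng.normal(size=n_volumes)
    else:
        sigma = np.sqrt(1.0 / rho**2 - 1.0) if abs(rho) < 1 else 0.0
        csf_unit = np.sign(rho) * core + sigma * rng.normal(size=n_volumes)

    bold_raw = bold_mean * (1.0 + 0.01 * b)
    csf_raw = csf_mean * (1.0 + 0.02 * csf_unit)
    truth = {"coupling_strength": float(rho), "coupling_lag": m * tr, "seed": seed}
    return TimeSeriesPair(bold_raw, csf_raw, tr), truth


# ---------------------------------------------------------------------------
# DCE curves


def gen_dce_curve(
    params: ToftsParams,
    config: RunConfig | None = None,
    aif: BiexpAif | None = None,
    noise_sd: float = 0.0,
    noise: str = "gaussian",
    s0: float = 100.0,
    region: str = "dorsal_mlv",
    seed: int = 0,
) -> tuple[TimeIntensityCurve, dict]:
    """Forward extended-Tofts curve on the DCE acquisition grid.

    ``noise_sd`` is additive on the enhancement scale; ``noise`` is
    ``gaussian`` or ``rician``.  The returned truth records the planted
    parameters including V_e = K_trans / k_ep.
    """
    config = config or RunConfig()
    aif = aif or BiexpAif()
    t = config.dce_time_grid()
    t_inj = config.injection_time
    e = tofts_model(t, params, aif, t_inj)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        if noise == "gaussian":
            e = e + rng.normal(0, noise_sd, e.shape)
        elif noise == "rician":
            re = e + rng.normal(0, noise_sd, e.shape)
            im = rng.normal(0, noise_sd, e.shape)
            e = np.sqrt(re**2 + im**2)
        else:
            raise ValueError(f"unknown noise model {noise!r}")
    s = s0 * (1.0 + e)
    baseline = tuple(range(config.injection_series_index))
    curve = TimeIntensityCurve(
        t=t,
        s=s,
        baseline_window=baseline,
        injection_index=config.injection_series_index - 1,
        region=region,
    )
    truth = {
        "ktrans": params.ktrans,
        "kep": params.kep,
        "ve": params.ve,
        "vp": params.vp,
        "seed": seed,
    }
    return curve, truth


def dce_oracle_curve(
    params: ToftsParams,
    config: RunConfig | None = None,
    aif: BiexpAif | None = None,
    refine: int = 200,
) -> np.ndarray:
    """Independent check of the forward model: fine-grid trapezoidal
    convolution of the AIF with the exponential impulse response,
    sampled at the coarse acquisition grid."""
    config = config or RunConfig()
    aif = aif or BiexpAif()
    t = config.dce_time_grid()
    t_inj = config.injection_time
    t_min = (t - t_inj) / 60.0
    out = np.zeros_like(t_min)
    for i, tm in enumerate(t_min):
        if tm <= aif.t0:
            continue
        tau = np.linspace(aif.t0, tm, refine)
        integrand = aif(tau) * np.exp(-params.kep * (tm - tau))
        out[i] = params.vp * aif(np.array([tm]))[0] + params.ktrans * np.trapezoid(
            integrand, tau
        )
    return out


# ---------------------------------------------------------------------------
# lesion scenes


@dataclass(frozen=True)
class LesionSpec:
    """One planted ellipsoidal lesion: centre (voxels), full axis
    lengths (mm), and the intended periventricular/deep class."""

    center: tuple[int, int, int]
    axes_mm: tuple[float, float, float]
    intended_class: str  # periventricular | deep


def gen_lesion_scene(
    specs: list[LesionSpec],
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    ventricle_slab: tuple[int, int] = (0, 4),
) -> tuple[LesionScene, list[dict]]:
    """Ventricle slab + non-overlapping ellipsoidal lesions.

    The ventricle occupies the x-index slab ``[lo, hi]`` across the
    full volume.  Each lesion is voxelized from its ellipsoid; lesions
    touching the volume boundary or each other raise.  The realized
    minimum surface distance of each lesion to the ventricle is
    recorded (anisotropic EDT).
    """
    vent = np.zeros(shape, dtype=np.uint8)
    lo, hi = ventricle_slab
    vent[lo : hi + 1, :, :] = 1
    lesions = np.zeros(shape, dtype=np.uint8)
    grid = np.indices(shape).astype(float)

    for spec in specs:
        if any(a <= 0 for a in spec.axes_mm):
            raise ValueError("ellipsoid axes must be positive")
        if any(not (0 <= c < s) for c, s in zip(spec.center, shape)):
            raise ValueError(f"centroid {spec.center} outside the volume")
        semi_vox = [a / 2.0 / sp for a, sp in zip(spec.axes_mm, spacing)]
        dist2 = sum(
            ((grid[d] - spec.center[d]) / semi_vox[d]) ** 2 for d in range(3)
        )
        ell = dist2 <= 1.0
        idx = np.argwhere(ell)
        if len(idx) == 0:
            raise ValueError(f"lesion at {spec.center} voxelizes to nothing")
        if (idx == 0).any() or (idx == np.array(shape) - 1).any():
            raise ValueError(f"lesion at {spec.center} intersects the volume boundary")
        if (lesions[ell] > 0).any():
            raise ValueError(f"lesion at {spec.center} overlaps another lesion")
        lesions[ell] = 1

    edt = ndimage.distance_transform_edt(~vent.astype(bool), sampling=spacing)
    realized = []
    for spec in specs:
        semi_vox = [a / 2.0 / sp for a, sp in zip(spec.axes_mm, spacing)]
        dist2 = sum(
            ((grid[d] - spec.center[d]) / semi_vox[d]) ** 2 for d in range(3)
        )
        vox = np.argwhere(dist2 <= 1.0)
        realized.append(
            {
                "center": spec.center,
                "intended_class": spec.intended_class,
                "min_surface_distance": float(edt[tuple(vox.T)].min()),
            }
        )
    scene = LesionScene(
        lesion_mask=VoxelGrid.from_array(lesions, spacing),
        ventricle_mask=VoxelGrid.from_array(vent, spacing),
    )
    return scene, realized


def random_lesion_specs(
    n_lesions: int,
    seed: int = 0,
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    threshold: float = 8.0,
    margin_mm: float = 2.0,
    ventricle_slab: tuple[int, int] = (0, 4),
) -> list[LesionSpec]:
    """Draw lesion specs whose realized distances sit clear of the
    periventricular boundary by at least ``margin_mm``.

    Lesions are laid out on a (j, k) grid so they cannot overlap; the
    x-centre is chosen so the lesion's nearest voxel lands at the
    target distance from the ventricle slab.
    """
    rng = np.random.default_rng(seed)
    sx, sy, sz = spacing
    _, hi = ventricle_slab
    cells = int(np.ceil(np.sqrt(n_lesions)))
    cell_j = (shape[1] - 4) // cells
    cell_k = (shape[2] - 4) // cells
    max_axis = min(cell_j * sy, cell_k * sz, 10.0) * 0.8
    specs = []
    for i in range(n_lesions):
        intended = "periventricular" if rng.random() < 0.5 else "deep"
        if intended == "periventricular":
            d_mm = rng.uniform(sx, max(threshold - margin_mm, sx))
        else:
            d_mm = rng.uniform(threshold + margin_mm, threshold + margin_mm + 12.0)
        d_vox = max(int(round(d_mm / sx)), 1)
        if intended == "periventricular":
            d_vox = min(d_vox, int((threshold - margin_mm) / sx))
            d_vox = max(d_vox, 1)
        else:
            d_vox = max(d_vox, int(np.ceil((threshold + margin_mm) / sx)))
        axes = tuple(sorted(rng.uniform(3.0, max_axis, size=3), reverse=True))
        ax_vox = axes[0] / 2.0 / sx
        ci = hi + d_vox + int(np.floor(ax_vox))
        cj = 2 + (i % cells) * cell_j + cell_j // 2
        ck = 2 + (i // cells) * cell_k + cell_k // 2
        if ci + int(np.ceil(ax_vox)) >= shape[0] - 1:
            raise ValueError("volume too small for requested deep lesions")
        specs.append(LesionSpec(center=(ci, cj, ck), axes_mm=axes, intended_class=intended))
    return specs


# ---------------------------------------------------------------------------
# cohort tables from the latent structural model

LATENTS = ("inflow", "outflow", "wmh", "cognition")

#: indicator -> (latent, default standardized loading)
DEFAULT_LOADINGS = {
    "chp_latvent": ("inflow", 0.646),
    "coupling_max": ("inflow", -0.50),
    "alps_avg": ("outflow", 0.712),
    "dorsal_ttp": ("outflow", -0.55),
    "dorsal_auc": ("outflow", 0.60),
    "dorsal_kep": ("outflow", 0.55),
    "pwmh_volume": ("wmh", 0.85),
    "dwmh_volume": ("wmh", 0.80),
    "fazekas_total": ("wmh", 0.90),
    "mmse": ("cognition", 0.80),
    "moca": ("cognition", 0.85),
}

#: observed-unit rescaling: indicator -> (mean, sd), pooled across groups
DEFAULT_SCALES = {
    "chp_latvent": (0.065, 0.032),
    "coupling_max": (-0.207, 0.125),
    "alps_avg": (1.497, 0.20),
    "dorsal_ttp": (1.124, 0.31),
    "dorsal_auc": (0.065, 0.023),
    "dorsal_kep": (0.449, 0.162),
    "pwmh_volume": (2795.0, 5600.0),
    "dwmh_volume": (3334.0, 6700.0),
    "fazekas_total": (2.2, 1.9),
    "mmse": (26.1, 2.7),
    "moca": (24.0, 5.2),
}


@dataclass
class SemTruth:
    """Ground truth of the four-latent structural model.

    Standardized metric: all latents and indicators have unit variance;
    residual variances are derived, not free.  Paths: Inflow -> WMH,
    Outflow -> WMH, WMH -> Cognition; Inflow and Outflow are correlated
    exogenous latents.
    """

    loadings: dict = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    path_inflow_wmh: float = -0.30
    path_outflow_wmh: float = -0.572
    path_wmh_cognition: float = -0.705
    inflow_outflow_corr: float = 0.40
    scales: dict = field(default_factory=lambda: dict(DEFAULT_SCALES))
    confounding: dict = field(default_factory=dict)  # indicator -> {age, sex, education}

    def __post_init__(self) -> None:
        for name, (latent, lam) in self.loadings.items():
            if latent not in LATENTS:
                raise ValueError(f"unknown latent {latent!r} for {name}")
            if abs(lam) > 1:
                raise ValueError(f"standardized loading |{lam}| > 1 for {name}")
        if abs(self.inflow_outflow_corr) >= 1:
            raise ValueError("|inflow-outflow correlation| must be < 1")
        if self.wmh_residual_var < 0 or self.cognition_residual_var < 0:
            raise ValueError("structural paths imply negative disturbance variance")

    @property
    def indicator_names(self) -> list[str]:
        return list(self.loadings)

    @property
    def wmh_residual_var(self) -> float:
        g1, g2, phi = self.path_inflow_wmh, self.path_outflow_wmh, self.inflow_outflow_corr
        return 1.0 - (g1**2 + g2**2 + 2 * g1 * g2 * phi)

    @property
    def cognition_residual_var(self) -> float:
        return 1.0 - self.path_wmh_cognition**2

    def latent_cov(self) -> np.ndarray:
        """Analytic covariance of (inflow, outflow, wmh, cognition)."""
        B = np.zeros((4, 4))
        B[2, 0] = self.path_inflow_wmh
        B[2, 1] = self.path_outflow_wmh
        B[3, 2] = self.path_wmh_cognition
        psi = np.zeros((4, 4))
        psi[0, 0] = psi[1, 1] = 1.0
        psi[0, 1] = psi[1, 0] = self.inflow_outflow_corr
        psi[2, 2] = self.wmh_residual_var
        psi[3, 3] = self.cognition_residual_var
        inv = np.linalg.inv(np.eye(4) - B)
        return inv @ psi @ inv.T

    def lambda_matrix(self) -> np.ndarray:
        lam = np.zeros((len(self.loadings), 4))
        for i, (name, (latent, val)) in enumerate(self.loadings.items()):
            lam[i, LATENTS.index(latent)] = val
        return lam

    def implied_cov(self) -> np.ndarray:
        """Analytic implied covariance (= correlation) of the 11
        standardized indicators.  Raises when not positive definite."""
        lam = self.lambda_matrix()
        C = self.latent_cov()
        theta = np.diag(1.0 - np.einsum("ij,jk,ik->i", lam, C, lam))
        if (np.diag(theta) < 0).any():
            raise ValueError("loadings imply negative indicator residual variance")
        sigma = lam @ C @ lam.T + theta
        if np.linalg.eigvalsh(sigma).min() <= 0:
            raise ValueError("implied covariance not positive definite")
        return sigma


def gen_cohort(
    truth: SemTruth | None = None,
    n: int = 117,
    seed: int = 0,
    rescale: bool = True,
) -> pd.DataFrame:
    """Cohort table drawn from the latent structural model.

    Draws standardized latents (Inflow/Outflow correlated, WMH and
    Cognition structural), maps them to the 11 indicators through the
    loadings, adds unit-variance-preserving residuals, then rescales to
    observed units (``rescale=False`` keeps the standardized metric).
    Demographics (age, sex, education) are generated alongside and
    enter indicators linearly per ``truth.confounding`` (default: no
    confounding).
    """
    truth = truth or SemTruth()
    rng = np.random.default_rng(seed)
    phi = truth.inflow_outflow_corr
    L = np.linalg.cholesky(np.array([[1.0, phi], [phi, 1.0]]))
    exo = rng.standard_normal((n, 2)) @ L.T
    inflow, outflow = exo[:, 0], exo[:, 1]
    wmh = (
        truth.path_inflow_wmh * inflow
        + truth.path_outflow_wmh * outflow
        + rng.normal(0, np.sqrt(truth.wmh_residual_var), n)
    )
    cog = truth.path_wmh_cognition * wmh + rng.normal(
        0, np.sqrt(truth.cognition_residual_var), n
    )
    latents = {"inflow": inflow, "outflow": outflow, "wmh": wmh, "cognition": cog}

    age = np.clip(rng.normal(48.0, 14.0, n), 23, 80)
    sex = rng.choice(["M", "F"], size=n, p=(0.46, 0.54))
    education = np.clip(rng.normal(8.9, 3.6, n), 0, 20).round(0)
    age_std = (age - age.mean()) / age.std()
    sex_num = (sex == "M").astype(float)
    edu_std = (education - education.mean()) / max(education.std(), 1e-9)

    df = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:04d}" for i in range(n)],
            "age": age.round(1),
            "sex": sex,
            "education": education,
        }
    )
    for name, (latent, lam) in truth.loadings.items():
        resid_var = 1.0 - lam**2
        x = lam * latents[latent] + rng.normal(0, np.sqrt(resid_var), n)
        conf = truth.confounding.get(name, {})
        x = (
            x
            + conf.get("age", 0.0) * age_std
            + conf.get("sex", 0.0) * sex_num
            + conf.get("education", 0.0) * edu_std
        )
        if rescale:
            mu, sd = truth.scales[name]
            x = mu + sd * x
        df[name] = x
    return df


def to_cohort_table(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce a generated indicator table to the cohort schema.

    Volumes are clipped at zero, cognitive scores clipped to 0-30 and
    the continuous Fazekas indicator discretized into integer
    periventricular/deep scores (0-3 each) whose sum defines the
    severity group.
    """
    from .cohort import derive_columns, validate_cohort

    out = df.copy()
    for col in ("pwmh_volume", "dwmh_volume"):
        if col in out:
            out[col] = out[col].clip(lower=0.0)
    for col in ("mmse", "moca"):
        if col in out:
            out[col] = out[col].clip(0, 30).round(0)
    if "fazekas_total" in out:
        total = out["fazekas_total"].clip(0, 6).round(0).astype(int)
        out["fazekas_pwmh"] = (total // 2).clip(0, 3)
        out["fazekas_dwmh"] = (total - out["fazekas_pwmh"]).clip(0, 3)
        out["fazekas_total"] = out["fazekas_pwmh"] + out["fazekas_dwmh"]
        out = out.drop(columns=["group"], errors="ignore")
    out = derive_columns(out)
    return validate_cohort(out)
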