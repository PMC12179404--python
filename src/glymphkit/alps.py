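"""DTI-ALPS: diffusion analysis along the perivascular space.

At the level of the lateral-ventricle body, the deep medullary veins
(and their perivascular spaces) run left-right (x), perpendicular to
both the projection fibers (mainly z) and the association fibers
(mainly y).  Diffusivity along x in those two fiber regions therefore
isolates the perivascular contribution, and the index

    ALPS = (Dx_proj + Dx_assoc) / (Dy_proj + Dz_assoc)

is ~1 when there is no preferential perivascular diffusion and rises
above 1 with intact glymphatic transport.  A low index indicates
impaired glymphatic circulation (reporting annotation; no clinical
decision is made here).

ROIs are operator-supplied voxel coordinates: one 3x3 in-plane square
per fiber region per hemisphere (about 5.4 mm per side at 1.8-mm
voxels), on a designated slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ROI_KEYS = ("proj", "assoc")
SIDES = ("left", "right")


@dataclass(frozen=True)
class RoiSpec:
    """A 3x3 in-plane square ROI centred on ``center`` (voxel indices).

    ``center`` is 0-based (i, j, k); the ROI spans i+/-1, j+/-1 on
    slice k.  Other geometries can be given explicitly via ``offsets``.
    """

    center: tuple[int, int, int]
    offsets: tuple[tuple[int, int, int], ...] = tuple(
        (di, dj, 0) for di in (-1, 0, 1) for dj in (-1, 0, 1)
    )

    def voxels(self) -> list[tuple[int, int, int]]:
        ci, cj, ck = self.center
        return [(ci + di, cj + dj, ck + dk) for di, dj, dk in self.offsets]


@dataclass
class DiffusivityVolumes:
    """Co-registered directional diffusivity maps with per-hemisphere ROIs.

    ``rois`` maps (side, fiber) -> :class:`RoiSpec`, e.g.
    ``("left", "proj")``.  Diffusivities are in mm^2/s.
    """

    dx: np.ndarray
    dy: np.ndarray
    dz: np.ndarray
    spacing: tuple[float, float, float]
    rois: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dx, self.dy, self.dz = (np.asarray(a, float) for a in (self.dx, self.dy, self.dz))
        if not (self.dx.shape == self.dy.shape == self.dz.shape):
            raise ValueError("dx/dy/dz maps must share shape")
        for a in (self.dx, self.dy, self.dz):
            if (a < 0).any():
                raise ValueError("diffusivities must be non-negative")
        seen: set = set()
        for key, roi in self.rois.items():
            vox = set(roi.voxels())
            if vox & seen:
                raise ValueError(f"ROI {key} overlaps another ROI")
            seen |= vox

    @property
    def shape(self):
        return self.dx.shape


@dataclass
class AlpsResult:
    left: float
    right: float
    bilateral_avg: float
    roi_means: dict
    flags: list = field(default_factory=list)


def _roi_mean(volume: np.ndarray, roi: RoiSpec) -> tuple[float, int]:
    vox = roi.voxels()
    shape = volume.shape
    for v in vox:
        if any(c < 0 or c >= s for c, s in zip(v, shape)):
            raise ValueError(f"ROI voxel {v} outside volume of shape {shape}")
    idx = tuple(np.array([v[d] for v in vox]) for d in range(3))
    return float(volume[idx].mean()), len(vox)


def extract_roi_diffusivities(vols: DiffusivityVolumes, side: str) -> dict:
    """Mean Dx/Dy over the projection ROI and Dx/Dz over the association ROI.

    Returns a dict with keys dxproj, dyproj, dxassoc, dzassoc plus a
    voxel count ``n`` per ROI.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    for fiber in ROI_KEYS:
        if (side, fiber) not in vols.rois:
            raise ValueError(f"no ROI specified for ({side}, {fiber})")
    proj = vols.rois[(side, "proj")]
    assoc = vols.rois[(side, "assoc")]
    dxproj, n_proj = _roi_mean(vols.dx, proj)
    dyproj, _ = _roi_mean(vols.dy, proj)
    dxassoc, n_assoc = _roi_mean(vols.dx, assoc)
    dzassoc, _ = _roi_mean(vols.dz, assoc)
    return {
        "dxproj": dxproj,
        "dyproj": dyproj,
        "dxassoc": dxassoc,
        "dzassoc": dzassoc,
        "n": {"proj": n_proj, "assoc": n_assoc},
    }


def alps_from_means(dxproj: float, dyproj: float, dxassoc: float, dzassoc: float) -> float:
    """ALPS = (Dxproj + Dxassoc) / (Dyproj + Dzassoc)."""
    denom = dyproj + dzassoc
    if denom == 0:
        return float("nan")
    return (dxproj + dxassoc) / denom


def alps(vols: DiffusivityVolumes) -> AlpsResult:
    """Per-hemisphere ALPS index and the bilateral average.

    A zero denominator yields NaN for that hemisphere and a flag; it is
    never silently dropped.
    """
    means = {}
    per_side = {}
    flags: list[str] = []
    for side in SIDES:
        m = extract_roi_diffusivities(vols, side)
        means[side] = m
        idx = alps_from_means(m["dxproj"], m["dyproj"], m["dxassoc"], m["dzassoc"])
        if np.isnan(idx):
            flags.append(f"{side}: zero denominator, index undefined")
        per_side[side] = idx
    bilateral = (per_side["left"] + per_side["right"]) / 2.0
    return AlpsResult(
        left=per_side["left"],
        right=per_side["right"],
        bilateral_avg=bilateral,
        roi_means=means,
        flags=flags,
    )
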