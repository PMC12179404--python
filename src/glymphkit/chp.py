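"""Choroid plexus (ChP) volumetrics and inter-method reliability.

The ChP secretes CSF; its volume normalised by the lateral-ventricle
volume (ChP/LatVent) and by intracranial volume (ChP/ICV) serve as
inflow-side glymphatic markers.  Reliability between segmentation
methods is quantified with the intraclass correlation ICC(A,1):
two-way model, single measure, absolute agreement (McGraw & Wong).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import VoxelGrid


@dataclass
class ChpSummary:
    chp_volume: float  # mm^3
    latvent_volume: float  # mm^3
    icv: float  # mm^3
    chp_latvent: float
    chp_icv: float


def mask_volume(mask: VoxelGrid) -> float:
    """Voxel count x voxel volume, in mm^3."""
    if not mask.is_binary():
        raise ValueError("volume extraction requires a binary mask")
    return float(mask.data.sum()) * mask.voxel_volume


def chp_ratios(
    chp_mask: VoxelGrid,
    latvent_mask: VoxelGrid,
    icv: float,
    subtract_chp_from_latvent: bool = False,
) -> ChpSummary:
    """ChP volume and its ratios to lateral-ventricle volume and ICV.

    ``subtract_chp_from_latvent`` removes ChP voxels from the
    lateral-ventricle volume before forming the ratio (off by default:
    the ventricle mask is taken as delivered).
    """
    if chp_mask.spacing != latvent_mask.spacing:
        raise ValueError("masks must share voxel spacing")
    if icv <= 0:
        raise ValueError("icv must be positive")
    chp_vol = mask_volume(chp_mask)
    latvent_vol = mask_volume(latvent_mask)
    if subtract_chp_from_latvent:
        overlap = float(
            np.logical_and(chp_mask.data > 0, latvent_mask.data > 0).sum()
        ) * latvent_mask.voxel_volume
        latvent_vol -= overlap
    if latvent_vol == 0:
        raise ValueError("zero lateral-ventricle volume: ratio undefined")
    return ChpSummary(
        chp_volume=chp_vol,
        latvent_volume=latvent_vol,
        icv=float(icv),
        chp_latvent=chp_vol / latvent_vol,
        chp_icv=chp_vol / icv,
    )


def bilateral_permeability(left: dict, right: dict) -> dict:
    """Arithmetic mean of left/right ChP permeability indices.

    Input dicts carry per-side DCE summaries (e.g. wash_in, auc,
    ktrans); keys present on both sides are averaged.
    """
    return {k: 0.5 * (left[k] + right[k]) for k in left.keys() & right.keys()}


def icc_a1(ratings: np.ndarray) -> float:
    """ICC(A,1): two-way model, single measure, absolute agreement.

    Parameters
    ----------
    ratings:
        (n targets) x (k raters) complete matrix.

    Returns
    -------
    float
        (MS_rows - MS_err) / (MS_rows + (k-1) MS_err
        + (k/n)(MS_cols - MS_err)) from the two-way ANOVA
        decomposition.  NaN when the between-target variance is zero
        (agreement undefined on a constant panel).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D (targets x raters) matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >=2 targets and >=2 raters")
    if np.isnan(x).any():
        raise ValueError("ratings matrix must be complete")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols

    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))

    denom = ms_rows + (k - 1) * ms_err + (k / n) * (ms_cols - ms_err)
    if denom <= 0 or ms_rows == 0:
        return float("nan")
    return float((ms_rows - ms_err) / denom)
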