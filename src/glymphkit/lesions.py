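"""White-matter-hyperintensity lesion morphometry and classification.

Individual lesions are 26-connected components of a binary lesion mask.
Per lesion we compute the centre of mass (mm), the minimum Euclidean
distance from any lesion voxel to the ventricular system (via an
anisotropic distance transform of the ventricle mask), and principal
axis lengths from the moment ellipsoid of the voxel coordinates.
Lesions within 8 mm of the ventricles are periventricular (PWMH), those
farther away deep (DWMH); per-class volumes are voxel count x voxel
volume.  Summed periventricular + deep Fazekas scores (each 0-3) define
the severity groups HC (0), mild (1-3) and severe (4-6).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cohort import group_from_fazekas_total
from .io import VoxelGrid

#: 26-connectivity in 3-D
_STRUCTURE = np.ones((3, 3, 3), dtype=bool)


@dataclass
class LesionScene:
    lesion_mask: VoxelGrid
    ventricle_mask: VoxelGrid

    def __post_init__(self) -> None:
        lm, vm = self.lesion_mask, self.ventricle_mask
        if lm.data.shape != vm.data.shape:
            raise ValueError("lesion and ventricle masks must share shape")
        if lm.spacing != vm.spacing:
            raise ValueError("lesion and ventricle masks must share spacing")
        for name, g in (("lesion", lm), ("ventricle", vm)):
            if not g.is_binary():
                raise ValueError(f"{name} mask is not binary")

    @property
    def spacing(self):
        return self.lesion_mask.spacing


@dataclass
class Lesion:
    label: int
    voxels: int
    volume: float  # mm^3
    centroid: tuple | None = None  # mm
    min_distance_to_ventricle: float | None = None  # mm
    principal_axes: tuple | None = None  # mm, descending
    lesion_class: str | None = None  # periventricular | deep
    voxel_indices: np.ndarray = field(default=None, repr=False)


def label_components(scene: LesionScene) -> list[Lesion]:
    """Individuate lesions as 26-connected components.

    Labels are assigned by descending voxel count; ties broken by
    lexicographic centroid.  An empty mask yields an empty list.
    """
    mask = scene.lesion_mask.data.astype(bool)
    labelled, n = ndimage.label(mask, structure=_STRUCTURE)
    if n == 0:
        return []
    voxvol = scene.lesion_mask.voxel_volume
    comps = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labelled == lab)
        centroid = idx.mean(axis=0)
        comps.append((len(idx), tuple(centroid), idx))
    comps.sort(key=lambda c: (-c[0], c[1]))
    return [
        Lesion(label=i + 1, voxels=cnt, volume=cnt * voxvol, voxel_indices=idx)
        for i, (cnt, _, idx) in enumerate(comps)
    ]


def morphometry(lesion: Lesion, scene: LesionScene) -> Lesion:
    """Fill centroid, ventricle distance, and principal axis lengths.

    Distance is surface-to-surface: the Euclidean distance transform of
    the ventricle mask (anisotropic spacing honoured) evaluated at every
    lesion voxel, minimised.  Principal axes are the full lengths of the
    uniform ellipsoid with matching second moments, 2*sqrt(5 * lambda)
    for each covariance eigenvalue lambda, sorted descending.
    """
    if not scene.ventricle_mask.data.any():
        raise ValueError("empty ventricle mask: distances undefined")
    spacing = np.asarray(scene.spacing)
    idx = lesion.voxel_indices
    if idx is None or len(idx) == 0:
        raise ValueError("lesion has no voxels; run label_components first")
    coords = idx * spacing  # voxel-centre coordinates in mm
    lesion.centroid = tuple(coords.mean(axis=0))

    dist = ndimage.distance_transform_edt(
        ~scene.ventricle_mask.data.astype(bool), sampling=scene.spacing
    )
    lesion.min_distance_to_ventricle = float(dist[tuple(idx.T)].min())

    if len(coords) == 1:
        lesion.principal_axes = tuple(sorted(spacing, reverse=True))
    else:
        cov = np.cov(coords, rowvar=False)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eigvals = np.clip(eigvals, 0.0, None)
        lesion.principal_axes = tuple(2.0 * np.sqrt(5.0 * eigvals))
    return lesion


def classify_lesions(
    lesions: list[Lesion], threshold: float = 8.0
) -> tuple[list[Lesion], dict]:
    """Partition lesions into periventricular vs deep by the distance rule.

    A lesion within ``threshold`` mm of the ventricular system
    (inclusive at the boundary) is periventricular; farther lesions are
    deep.  Returns the labelled lesions and per-class volume totals.
    """
    pwmh = dwmh = 0.0
    for les in lesions:
        if les.min_distance_to_ventricle is None:
            raise ValueError(f"lesion {les.label}: morphometry not computed")
        if les.min_distance_to_ventricle <= threshold:
            les.lesion_class = "periventricular"
            pwmh += les.volume
        else:
            les.lesion_class = "deep"
            dwmh += les.volume
    summary = {
        "pwmh_volume": pwmh,
        "dwmh_volume": dwmh,
        "total_wmh_volume": pwmh + dwmh,
        "n_periventricular": sum(l.lesion_class == "periventricular" for l in lesions),
        "n_deep": sum(l.lesion_class == "deep" for l in lesions),
    }
    return lesions, summary


def analyze_scene(scene: LesionScene, threshold: float = 8.0):
    """label -> morphometry -> classify, in one call."""
    lesions = label_components(scene)
    for les in lesions:
        morphometry(les, scene)
    return classify_lesions(lesions, threshold=threshold)


def fazekas_group(pwmh_score: int, dwmh_score: int) -> str:
    """Severity group from periventricular + deep Fazekas scores."""
    for name, s in (("pwmh", pwmh_score), ("dwmh", dwmh_score)):
        if not 0 <= s <= 3:
            raise ValueError(f"fazekas_{name} score {s} outside 0-3")
    return group_from_fazekas_total(pwmh_score + dwmh_score)
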