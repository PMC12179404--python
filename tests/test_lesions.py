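"""Lesion labelling, morphometry, and the periventricular/deep rule."""

import numpy as np
import pytest

from glymphkit import synth
from glymphkit.io import VoxelGrid
from glymphkit.lesions import (
    Lesion,
    LesionScene,
    analyze_scene,
    classify_lesions,
    fazekas_group,
    label_components,
    morphometry,
)


def _scene(lesions, ventricle=None, spacing=(1.0, 1.0, 1.0)):
    shape = lesions.shape
    if ventricle is None:
        ventricle = np.zeros(shape, np.uint8)
        ventricle[0:2, :, :] = 1
    return LesionScene(
        VoxelGrid.from_array(lesions.astype(np.uint8), spacing),
        VoxelGrid.from_array(ventricle.astype(np.uint8), spacing),
    )


class TestLabelComponents:
    def test_two_disjoint_cubes(self):
        mask = np.zeros((30, 30, 30))
        mask[5:8, 5:8, 5:8] = 1  # 27 voxels
        mask[20:22, 20:22, 20:22] = 1  # 8 voxels
        lesions = label_components(_scene(mask))
        assert [l.voxels for l in lesions] == [27, 8]
        assert [l.label for l in lesions] == [1, 2]

    def test_diagonal_touch_is_one_component(self):
        mask = np.zeros((10, 10, 10))
        mask[4, 4, 4] = 1
        mask[5, 5, 5] = 1  # corner contact: connected under 26-connectivity
        assert len(label_components(_scene(mask))) == 1

    def test_empty_mask_yields_empty_list(self):
        assert label_components(_scene(np.zeros((8, 8, 8)))) == []

    def test_generator_scene_component_count(self):
        specs = synth.random_lesion_specs(6, seed=4)
        scene, _ = synth.gen_lesion_scene(specs)
        assert len(label_components(scene)) == 6


class TestMorphometry:
    def test_adjacent_voxel_unit_distance(self):
        mask = np.zeros((10, 10, 10))
        mask[2, 5, 5] = 1  # ventricle slab is x in [0, 1]
        scene = _scene(mask)
        les = morphometry(label_components(scene)[0], scene)
        assert np.isclose(les.min_distance_to_ventricle, 1.0)

    def test_overlap_gives_zero_distance(self):
        mask = np.zeros((10, 10, 10))
        mask[1:4, 5, 5] = 1
        scene = _scene(mask)
        les = morphometry(label_components(scene)[0], scene)
        assert les.min_distance_to_ventricle == 0.0

    def test_empty_ventricle_mask_is_hard_error(self):
        mask = np.zeros((8, 8, 8))
        mask[4, 4, 4] = 1
        scene = _scene(mask, ventricle=np.zeros((8, 8, 8)))
        with pytest.raises(ValueError, match="ventricle"):
            morphometry(label_components(scene)[0], scene)

    def test_planted_ellipsoid_axes_recovered(self):
        spec = synth.LesionSpec(center=(30, 30, 30), axes_mm=(12.0, 6.0, 4.0), intended_class="deep")
        scene, _ = synth.gen_lesion_scene([spec])
        les = morphometry(label_components(scene)[0], scene)
        for got, want in zip(les.principal_axes, (12.0, 6.0, 4.0)):
            assert abs(got - want) <= 1.0  # within one voxel

    def test_volume_is_count_times_voxel_volume(self):
        mask = np.zeros((10, 10, 10))
        mask[4:6, 4:6, 4:6] = 1
        scene = _scene(mask, spacing=(2.0, 1.0, 0.5))
        les = label_components(scene)[0]
        assert np.isclose(les.volume, 8 * 1.0)

    def test_distance_scales_with_spacing(self):
        mask = np.zeros((12, 12, 12))
        mask[5, 6, 6] = 1
        d1 = morphometry(label_components(_scene(mask))[0], _scene(mask)).min_distance_to_ventricle
        scene3 = _scene(mask, spacing=(3.0, 3.0, 3.0))
        d3 = morphometry(label_components(scene3)[0], scene3).min_distance_to_ventricle
        assert np.isclose(d3, 3.0 * d1)


class TestClassification:
    def _lesion(self, dist, vol=10.0):
        return Lesion(label=1, voxels=10, volume=vol, min_distance_to_ventricle=dist)

    def test_eight_mm_boundary_inclusive(self):
        lesions = [self._lesion(d) for d in (0.0, 7.9, 8.0, 8.1)]
        labelled, _ = classify_lesions(lesions, threshold=8.0)
        assert [l.lesion_class for l in labelled] == [
            "periventricular", "periventricular", "periventricular", "deep",
        ]

    def test_all_deep_gives_zero_pwmh(self):
        lesions = [self._lesion(d, vol=5.0) for d in (9.0, 12.0)]
        _, summary = classify_lesions(lesions)
        assert summary["pwmh_volume"] == 0.0 and summary["dwmh_volume"] == 10.0

    def test_partition_conserves_volume(self):
        specs = synth.random_lesion_specs(12, seed=9)
        scene, _ = synth.gen_lesion_scene(specs)
        lesions, summary = analyze_scene(scene)
        total = sum(l.volume for l in lesions)
        assert summary["pwmh_volume"] + summary["dwmh_volume"] == summary["total_wmh_volume"]
        assert np.isclose(summary["total_wmh_volume"], total)
        assert all(l.lesion_class in ("periventricular", "deep") for l in lesions)

    def test_threshold_monotonicity(self):
        specs = synth.random_lesion_specs(10, seed=2)
        scene, _ = synth.gen_lesion_scene(specs)
        lesions, _ = analyze_scene(scene)
        volumes = []
        for thr in (4.0, 8.0, 16.0, 40.0):
            _, s = classify_lesions(lesions, threshold=thr)
            volumes.append(s["pwmh_volume"])
        assert all(a <= b for a, b in zip(volumes, volumes[1:]))

    def test_intended_classes_reproduced(self):
        for seed in range(10):
            specs = synth.random_lesion_specs(8, seed=seed)
            scene, realized = synth.gen_lesion_scene(specs)
            lesions, _ = analyze_scene(scene)
            # match lesions to specs via centroids
            got = {}
            for l in lesions:
                centre_vox = tuple(int(round(c / s)) for c, s in zip(l.centroid, scene.spacing))
                got[centre_vox] = l.lesion_class
            for spec in specs:
                assert got[spec.center] == spec.intended_class


class TestSceneGeneration:
    def test_boundary_intersection_rejected(self):
        spec = synth.LesionSpec(center=(62, 30, 30), axes_mm=(8.0, 4.0, 4.0), intended_class="deep")
        with pytest.raises(ValueError, match="boundary"):
            synth.gen_lesion_scene([spec])

    def test_overlapping_lesions_rejected(self):
        a = synth.LesionSpec(center=(30, 30, 30), axes_mm=(8.0, 8.0, 8.0), intended_class="deep")
        b = synth.LesionSpec(center=(32, 30, 30), axes_mm=(8.0, 8.0, 8.0), intended_class="deep")
        with pytest.raises(ValueError, match="overlap"):
            synth.gen_lesion_scene([a, b])

    def test_realized_distances_recorded(self):
        specs = synth.random_lesion_specs(5, seed=1)
        _, realized = synth.gen_lesion_scene(specs)
        for spec, r in zip(specs, realized):
            if spec.intended_class == "periventricular":
                assert r["min_surface_distance"] <= 8.0
            else:
                assert r["min_surface_distance"] > 8.0


class TestFazekasGroup:
    @pytest.mark.parametrize(
        "p,d,expect", [(0, 0, "HC"), (1, 2, "mild"), (3, 0, "mild"), (2, 2, "severe"), (3, 3, "severe")]
    )
    def test_grouping(self, p, d, expect):
        assert fazekas_group(p, d) == expect

    @pytest.mark.parametrize("p,d", [(-1, 0), (0, 4)])
    def test_out_of_range_rejected(self, p, d):
        with pytest.raises(ValueError):
            fazekas_group(p, d)
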