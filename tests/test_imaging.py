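import math

import numpy as np
import pytest

from vffr.graph import prune_nonarterial
from vffr.imaging import (
    BinaryMask,
    GraphBuildConfig,
    ImagingError,
    PreprocessConfig,
    SegmentationConfig,
    VoxelVolume,
    build_artery_graph,
    extract_graph,
    match_rooted_trees,
    preprocess_volume,
    segment_vessels,
    skeletonize_and_measure,
)
from vffr.synthetic import PhantomSpec, make_coronary_tree, make_voxel_phantom


def cylinder_volume(radius_vox=4, length_vox=60, spacing=0.5, lumen=400.0, axis=0):
    """Straight tube along a grid axis; returns (volume, analytic voxel count)."""
    pad = radius_vox + 3
    shape = [2 * pad + 1] * 3
    shape[axis] = length_vox
    data = np.zeros(shape)
    coords = np.indices(shape, dtype=float)
    trans = [coords[i] - pad for i in range(3) if i != axis]
    rad = np.sqrt(trans[0] ** 2 + trans[1] ** 2)
    data[rad <= radius_vox] = lumen
    return VoxelVolume(data, (spacing,) * 3), float((rad <= radius_vox).sum())


class TestVoxelVolume:
    def test_spacing_positive(self):
        with pytest.raises(ImagingError):
            VoxelVolume(np.zeros((2, 2, 2)), (0.5, 0.0, 0.5))

    def test_nifti_roundtrip(self, tmp_path):
        vol, _ = cylinder_volume(length_vox=12)
        path = tmp_path / "v.nii.gz"
        vol.to_nifti(path)
        back = VoxelVolume.from_nifti(path)
        assert back.shape == vol.shape
        assert np.allclose(back.intensities, vol.intensities)
        assert back.spacing == vol.spacing

    def test_raw_roundtrip(self, tmp_path):
        vol, _ = cylinder_volume(length_vox=10)
        vol.to_raw(tmp_path / "v")
        back = VoxelVolume.from_raw(tmp_path / "v")
        assert np.allclose(back.intensities, vol.intensities)
        assert back.spacing == vol.spacing


class TestPreprocess:
    def test_slice_dropping_arithmetic(self):
        vol = VoxelVolume(np.zeros((200, 4, 4)), (0.5, 0.5, 0.5))
        out = preprocess_volume(vol, PreprocessConfig(drop_slices=10, opening_radius_mm=0))
        assert out.shape[0] == 190
        assert out.origin[0] == pytest.approx(5.0)

    def test_drop_too_many_slices(self):
        vol = VoxelVolume(np.zeros((5, 4, 4)), (0.5, 0.5, 0.5))
        with pytest.raises(ImagingError):
            preprocess_volume(vol, PreprocessConfig(drop_slices=5))

    def test_distractor_suppressed_arteries_kept(self):
        tree = make_coronary_tree(3, 3)
        ph = make_voxel_phantom(tree, PhantomSpec())
        data = ph.volume.intensities.copy()
        data[2:4, 2:4, 2:4] = 400.0  # ~1 mm bright blob far from the vessels
        noisy = VoxelVolume(data, ph.volume.spacing, ph.volume.origin)
        out = preprocess_volume(noisy, PreprocessConfig(opening_radius_mm=0.6))
        assert np.all(out.intensities[2:4, 2:4, 2:4] == 0.0)
        kept = int((out.intensities >= 200).sum())
        original = int((ph.volume.intensities >= 200).sum())
        # opening may shave isolated sub-element surface voxels, nothing more
        assert kept >= 0.995 * original

    def test_near_identity_when_nothing_to_do(self):
        tree = make_coronary_tree(3, 3)
        ph = make_voxel_phantom(tree, PhantomSpec())
        out = preprocess_volume(ph.volume, PreprocessConfig(drop_slices=0, opening_radius_mm=0.6))
        changed = int((out.intensities != ph.volume.intensities).sum())
        bright = int((ph.volume.intensities >= 200).sum())
        assert changed <= 0.005 * bright

    def test_exact_identity_with_opening_disabled(self):
        tree = make_coronary_tree(3, 2)
        ph = make_voxel_phantom(tree, PhantomSpec())
        out = preprocess_volume(ph.volume, PreprocessConfig(drop_slices=0, opening_radius_mm=0.0))
        assert np.array_equal(out.intensities, ph.volume.intensities)


class TestSegmentation:
    def test_cylinder_mask_volume(self):
        vol, analytic = cylinder_volume()
        seed = (30, vol.shape[1] // 2, vol.shape[2] // 2)
        _, artery, _ = segment_vessels(vol, [seed])
        assert abs(artery.count - analytic) <= 0.10 * analytic

    def test_two_branch_ostia(self):
        tree = make_coronary_tree(4, 2)  # trunk + 2 daughters, single ostium contact
        ph = make_voxel_phantom(tree, PhantomSpec())
        _, _, ostia = segment_vessels(ph.volume, ph.seeds)
        assert len(ostia) == 1  # one artery component touching the aorta

    def test_seed_below_threshold_errors(self):
        vol, _ = cylinder_volume()
        with pytest.raises(ImagingError, match="bright"):
            segment_vessels(vol, [(0, 0, 0)])

    def test_threshold_above_lumen_errors(self):
        vol, _ = cylinder_volume()
        seed = (30, vol.shape[1] // 2, vol.shape[2] // 2)
        with pytest.raises(ImagingError):
            segment_vessels(vol, [seed], SegmentationConfig(hu_threshold=500.0))

    def test_calcification_excluded_by_band(self):
        tree = make_coronary_tree(2, 3)
        ph = make_voxel_phantom(tree, PhantomSpec(calcification=True, seed=7))
        assert (ph.volume.intensities >= 800).any()
        _, artery, _ = segment_vessels(ph.volume, ph.seeds)
        calc = ph.volume.intensities >= 700
        assert not (artery.voxels & calc).any()


class TestSkeleton:
    def test_cylinder_centerline_and_radius(self):
        vol, _ = cylinder_volume(radius_vox=4, length_vox=60, spacing=0.5)
        mask = BinaryMask(vol.intensities >= 200, vol.spacing)
        sk = skeletonize_and_measure(mask)
        center = (vol.shape[1] - 1) / 2
        # all centerline voxels within 1 voxel of the true axis
        off_axis = np.sqrt(
            (sk.voxels[:, 1] - center) ** 2 + (sk.voxels[:, 2] - center) ** 2
        )
        interior = (sk.voxels[:, 0] > 5) & (sk.voxels[:, 0] < 55)
        assert np.all(off_axis[interior] <= 1.0 + 1e-9)
        median_r = float(np.median(sk.radius_mm[interior]))
        assert median_r == pytest.approx(2.0, abs=0.25)

    def test_y_phantom_single_branch_point(self):
        tree = make_coronary_tree(4, 2)
        ph = make_voxel_phantom(tree, PhantomSpec(with_aorta=False))
        mask = BinaryMask(ph.volume.intensities >= 200, ph.volume.spacing, ph.volume.origin)
        sk = skeletonize_and_measure(mask)
        from vffr.imaging import _trace_branches

        clusters, branches = _trace_branches(sk)
        degree = {i: 0 for i in range(len(clusters))}
        for br in branches:
            degree[br.a] += 1
            degree[br.b] += 1
        branch_clusters = [c for c, d in degree.items() if d >= 3]
        assert len(branch_clusters) == 1
        assert degree[branch_clusters[0]] == 3

    def test_tiny_mask_errors(self):
        mask = BinaryMask(np.zeros((5, 5, 5), bool), (0.5, 0.5, 0.5))
        mask.voxels[2, 2, 2] = True
        with pytest.raises(ImagingError):
            skeletonize_and_measure(mask)

    def test_skeleton_minimality(self):
        """Chain voxels have <= 2 neighbors; higher degrees only at branch points."""
        tree = make_coronary_tree(5, 3)
        ph = make_voxel_phantom(tree, PhantomSpec())
        _, artery, _ = segment_vessels(ph.volume, ph.seeds)
        sk = skeletonize_and_measure(artery)
        from vffr.imaging import _neighbor_map

        nbrs = _neighbor_map(sk.voxels)
        over = [v for v, lst in nbrs.items() if len(lst) > 3]
        # any voxel with >3 neighbors must be part of a branch-point cluster
        node_voxels = {v for v, lst in nbrs.items() if len(lst) != 2}
        assert all(v in node_voxels for v in over)


class TestBuildGraph:
    def test_cylinder_single_segment(self):
        vol, _ = cylinder_volume(radius_vox=4, length_vox=60, spacing=0.5)
        mask = BinaryMask(vol.intensities >= 200, vol.spacing)
        sk = skeletonize_and_measure(mask)
        center = (vol.shape[1] - 1) * 0.5 * 0.5
        ostia = [{"position_mm": (0.0, center, center), "index": (0, 0, 0), "component": 1}]
        g = build_artery_graph(sk, ostia)
        assert len(g.segments) == 1
        assert len(g.nodes) == 2
        seg = next(iter(g.segments.values()))
        true_length = 60 * 0.5  # mm (through-voxel extent)
        assert abs(seg.length - true_length) / true_length <= 0.05

    def test_no_ostium_errors(self):
        vol, _ = cylinder_volume()
        mask = BinaryMask(vol.intensities >= 200, vol.spacing)
        sk = skeletonize_and_measure(mask)
        with pytest.raises(ImagingError, match="ostium"):
            build_artery_graph(sk, [])

    def test_touching_vein_creates_cycle_error(self):
        tree = make_coronary_tree(1, 3)
        ph = make_voxel_phantom(tree, PhantomSpec(vein=True, vein_touching=True))
        with pytest.raises(ImagingError, match="cycle"):
            extract_graph(ph.volume, ph.seeds)


class TestRecovery:
    @pytest.mark.parametrize("seed", [2, 5])
    def test_noise_free_recovery(self, seed):
        tree = make_coronary_tree(seed, 3)
        ph = make_voxel_phantom(tree, PhantomSpec())
        g = extract_graph(ph.volume, ph.seeds)
        res = match_rooted_trees(g, tree)
        assert res["topology_equal"]
        assert res["max_length_rel_err"] <= 0.05
        half_voxel = 0.25
        assert (
            res["max_diameter_abs_err_mm"] <= half_voxel
            or res["max_diameter_rel_err"] <= 0.05
        )

    def test_noise_robust_topology(self):
        tree = make_coronary_tree(6, 3)
        clean = extract_graph(make_voxel_phantom(tree, PhantomSpec()).volume,
                              make_voxel_phantom(tree, PhantomSpec()).seeds)
        noisy_ph = make_voxel_phantom(tree, PhantomSpec(noise_sd=40.0, seed=99))
        noisy = extract_graph(noisy_ph.volume, noisy_ph.seeds)
        assert match_rooted_trees(noisy, tree)["topology_equal"]
        assert len(noisy.segments) == len(clean.segments)

    def test_vein_component_removed(self):
        tree = make_coronary_tree(7, 3)
        ph = make_voxel_phantom(tree, PhantomSpec(vein=True, seed=7))
        g = extract_graph(ph.volume, ph.seeds)
        assert all(s.label != "vein" for s in g.segments.values())
        arterial = prune_nonarterial(ph.truth)
        assert match_rooted_trees(g, arterial)["topology_equal"]
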