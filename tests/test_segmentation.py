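import numpy as np
import pytest

from fidseg import (
    SegmentationConfig,
    SegmentationError,
    build_template,
    compute_noise_threshold,
    connected_sets,
    iterative_signal_size,
    match_device,
    reference_threshold,
    segment_fiducial,
    shape_filter,
)
from fidseg.segmentation import CandidateSet

from conftest import make_volume
from oracles import bfs_label_26, brute_force_match, noise_threshold_scan


def volume_from_histogram(counts, shape=None):
    """A volume whose intensity histogram equals ``counts`` exactly."""
    vals = np.repeat(np.arange(len(counts)), counts)
    n = len(vals)
    side = int(np.ceil(n ** (1 / 3)))
    data = np.zeros(side**3, dtype=np.int32)
    data[:n] = vals
    rng = np.random.default_rng(1)
    rng.shuffle(data)
    return make_volume(data.reshape(side, side, side))


class TestNoiseThreshold:
    def test_worked_histogram(self):
        """Peak at I=2; forward differences -20, -8, -1, 0 after it, so the
        first non-negative change is entered at I=5."""
        counts = [0, 10, 30, 10, 2, 1, 1, 5, 9, 4]
        v = volume_from_histogram(counts)
        assert compute_noise_threshold(v) == 5

    def test_two_valued_volume(self):
        data = np.full((10, 10, 10), 10, dtype=np.int32)
        data.ravel()[:100] = 100
        v = make_volume(data)
        nt = compute_noise_threshold(v)
        assert 10 < nt <= 100
        assert (v.data >= nt).sum() == 100  # every signal voxel survives

    def test_constant_volume_fails(self):
        with pytest.raises(SegmentationError, match="noise_threshold"):
            compute_noise_threshold(make_volume(np.full((4, 4, 4), 7)))

    def test_monotone_histogram_fails(self):
        counts = [0, 100, 50, 20, 8, 3, 1]
        with pytest.raises(SegmentationError, match="no noise/signal separation"):
            compute_noise_threshold(volume_from_histogram(counts))

    def test_matches_exhaustive_scan_on_random_histograms(self, rng):
        """The implementation agrees with an independent exhaustive scan of
        the histogram rule across many random histograms."""
        for _ in range(60):
            n_bins = int(rng.integers(6, 40))
            counts = rng.integers(0, 50, n_bins)
            peak_pos = int(rng.integers(1, max(2, n_bins // 3)))
            counts[peak_pos] = 200  # background peak in the low range
            counts[0] = int(rng.integers(0, 500))
            if counts[1:].sum() == 0:
                continue
            expected = noise_threshold_scan(list(counts))
            v = volume_from_histogram(list(counts))
            if expected is None:
                with pytest.raises(SegmentationError):
                    compute_noise_threshold(v)
            else:
                assert compute_noise_threshold(v) == expected


class TestConnectedSets:
    def test_single_block(self):
        data = np.zeros((7, 7, 7), dtype=np.int32)
        data[2:5, 2:5, 2:5] = 50
        sets = connected_sets(make_volume(data), threshold=1)
        assert len(sets) == 1
        assert sets[0].n_voxels == 27

    def test_corner_adjacency_joins(self):
        data = np.zeros((4, 4, 4), dtype=np.int32)
        data[0, 0, 0] = 9
        data[1, 1, 1] = 9
        sets = connected_sets(make_volume(data), threshold=1)
        assert len(sets) == 1

    def test_matches_bfs_oracle_on_random_volume(self, rng):
        data = (rng.random((20, 20, 20)) < 0.1).astype(np.int32) * 7
        v = make_volume(data)
        sets = connected_sets(v, threshold=1)
        oracle = bfs_label_26(data > 0)
        assert len(sets) == oracle.max()
        # identical partitions: every returned set is exactly one oracle label
        for s in sets:
            labs = oracle[s.voxels[:, 0], s.voxels[:, 1], s.voxels[:, 2]]
            assert len(np.unique(labs)) == 1
            assert (oracle == labs[0]).sum() == s.n_voxels

    def test_com_inside_bbox_and_extent_floor(self, rng):
        data = np.zeros((12, 10, 8), dtype=np.int32)
        data[3:6, 2:7, 4:6] = rng.integers(10, 99, (3, 5, 2))
        v = make_volume(data, spacing=(0.7, 1.1, 2.0))
        (s,) = connected_sets(v, threshold=1)
        lo = s.voxels.min(axis=0) * v.spacing - v.spacing / 2
        hi = s.voxels.max(axis=0) * v.spacing + v.spacing / 2
        assert np.all(s.com_world >= lo) and np.all(s.com_world <= hi)
        assert np.all(s.extents_mm >= v.spacing - 1e-12)

    def test_volume_uses_physical_units(self):
        data = np.zeros((5, 5, 5), dtype=np.int32)
        data[1:3, 1:3, 1:3] = 10
        v = make_volume(data, spacing=(0.7, 0.7, 8.0))
        (s,) = connected_sets(v, threshold=1)
        assert s.volume_mm3 == pytest.approx(8 * 0.7 * 0.7 * 8.0)


def _fake_set(n_vox, intensity, vv=1.0):
    vox = np.column_stack([np.arange(n_vox), np.zeros(n_vox), np.zeros(n_vox)]).astype(int)
    inten = np.full(n_vox, intensity, dtype=np.int64)
    return CandidateSet(
        voxels=vox,
        intensities=inten,
        volume_mm3=n_vox * vv,
        com_world=vox.mean(axis=0),
        extents_mm=np.array([n_vox * vv, 1.0, 1.0]),
    )


class TestReferenceThreshold:
    def cfg(self, v_marker):
        return SegmentationConfig(v_marker=v_marker, shape_max_mm=26.9)

    def test_single_passing_set(self):
        vm = 100.0
        sets = [_fake_set(40, 10), _fake_set(100, 200), _fake_set(350, 10)]
        assert reference_threshold(sets, self.cfg(vm)) == 200

    def test_boundary_volume_excluded(self):
        vm = 100.0
        sets = [_fake_set(50, 500), _fake_set(80, 100)]  # 50 = exactly 0.5 Vm
        assert reference_threshold(sets, self.cfg(vm)) == 100

    def test_weighted_mean_over_passing_sets(self):
        vm = 150.0  # window (75, 450): both sets pass
        sets = [_fake_set(100, 100), _fake_set(300, 200)]
        expected = (100 * 100 + 300 * 200) / 400  # = 175
        assert reference_threshold(sets, self.cfg(vm)) == pytest.approx(expected)

    def test_no_marker_sized_object(self):
        with pytest.raises(SegmentationError, match="no marker-sized object"):
            reference_threshold([_fake_set(10, 50)], self.cfg(100.0))


class TestIterativeSignalSize:
    def make_cfg(self, vm):
        return SegmentationConfig(v_marker=vm, shape_max_mm=1e9)

    def test_faint_object_appears_only_at_lowest_threshold(self):
        """A uniform object at 0.6 R_T passes only ST_2 = 0.5 R_T."""
        data = np.zeros((12, 12, 12), dtype=np.int32)
        data[3:8, 3:8, 3:8] = 60  # 125 voxels
        v = make_volume(data)
        vm = 125.0  # object volume exactly 1.0 Vm
        sets = iterative_signal_size(v, r_t=100.0, cfg=self.make_cfg(vm))
        assert len(sets) == 1
        assert sets[0].n_voxels == 125
        assert sets[0].provenance == (2,)

    def test_growth_past_cap_is_rejected(self):
        """An object captured whole at a high threshold must keep that
        extent; a later thresholding that would grow it past 1.3 Vm is
        discarded."""
        data = np.zeros((20, 12, 12), dtype=np.int32)
        data[3:8, 3:8, 3:8] = 200  # bright core: 125 voxels at 2.0 R_T
        data[8:15, 3:8, 3:8] = 60  # faint extension: 175 voxels at 0.6 R_T
        v = make_volume(data)
        vm = 125.0
        sets = iterative_signal_size(v, r_t=100.0, cfg=self.make_cfg(vm))
        assert len(sets) == 1
        assert sets[0].n_voxels == 125  # core only; union (300) > 1.3 Vm rejected

    def test_radial_profile_keeps_mid_threshold_extent(self):
        """When the lowest superlevel set is too big (1.4 Vm) but a higher
        one fits (0.9 Vm), the candidate keeps the smaller extent."""
        vm = 125.0
        data = np.zeros((16, 16, 16), dtype=np.int32)
        # inner block 4x4x7 = 112 voxels (0.896 Vm) at 100 (= R_T)
        data[4:8, 4:8, 4:11] = 100
        # shell of 63 voxels at 55 (>= 0.5 R_T only), attached to the block
        data[8, 4:8, 4:11] = 55  # 28 voxels
        data[9, 4:8, 4:11] = 55  # 28 voxels
        data[10, 4:5, 4:11] = 55  # 7 voxels -> total 112 + 63 = 175 = 1.4 Vm
        v = make_volume(data)
        sets = iterative_signal_size(v, r_t=100.0, cfg=self.make_cfg(vm))
        assert len(sets) == 1
        assert sets[0].n_voxels == 112
        assert 4 in sets[0].provenance
        assert 2 not in sets[0].provenance

    def test_strict_candidate_window_edges(self):
        """Objects at exactly 0.35 Vm or 1.3 Vm are excluded (strict)."""
        data = np.zeros((30, 20, 10), dtype=np.int32)
        data[0:7, 0:5, 0:1] = 100  # 35 voxels
        data[10:23, 5:15, 2:3] = 100  # 130 voxels
        v = make_volume(data)
        with pytest.raises(SegmentationError, match="no candidates"):
            iterative_signal_size(v, r_t=100.0, cfg=self.make_cfg(100.0))

    def test_empty_composite_fails(self):
        v = make_volume(np.zeros((5, 5, 5), dtype=np.int32))
        with pytest.raises(SegmentationError, match="no candidates"):
            iterative_signal_size(v, r_t=100.0, cfg=self.make_cfg(100.0))


class TestShapeFilter:
    def cfg(self):
        return SegmentationConfig(v_marker=1608.8, shape_max_mm=26.9408)

    def _set_with_extents(self, extents):
        s = _fake_set(10, 100)
        s.extents_mm = np.asarray(extents, float)
        return s

    def test_oversized_axis_removed(self):
        kept = shape_filter([self._set_with_extents((27.5, 10, 10))], self.cfg())
        assert kept == []

    def test_not_exceeding_is_inclusive(self):
        s = self._set_with_extents((26.9408, 12.7, 12.7))
        assert shape_filter([s], self.cfg()) == [s]

    def test_rasterized_default_cylinder_retained(self, template, rng):
        """A marker cylinder rasterized at any orientation fits within the
        26.9 mm gate (space diagonal 17.96 mm)."""
        from fidseg import AcquisitionSpec, ScenePose, rasterize_scene
        from oracles import random_rotation

        cfg = SegmentationConfig.from_template(template)
        for _ in range(3):
            pose = ScenePose(
                device_orientation=random_rotation(rng), body_center=None, blobs=[]
            )
            spec = AcquisitionSpec(
                in_plane_mm=(1.5, 1.5), slice_thickness_mm=1.5,
                fov_mm=(124, 124, 124), fov_center_mm=(0, 0, 0), noise_sigma=0.0,
            )
            vol = rasterize_scene(template, pose, spec)
            sets = connected_sets(vol, threshold=100)
            assert len(sets) == 4
            assert len(shape_filter(sets, cfg)) == 4


class TestMatchDevice:
    def coms_with_decoys(self, template, rng, n_decoys=3):
        pts = template.points.copy()
        decoys = rng.uniform(-60, 150, (n_decoys, 3))
        decoys[:, 2] += 120  # keep decoys >= 5 mm away from any valid geometry
        return np.vstack([pts, decoys])

    def _sets_from_coms(self, coms):
        out = []
        for c in coms:
            s = _fake_set(10, 100)
            s.com_world = np.asarray(c, float)
            out.append(s)
        return out

    def test_exact_points_with_decoys_match_brute_force(self, template, seg_cfg, rng):
        coms = self.coms_with_decoys(template, rng)
        det = match_device(self._sets_from_coms(coms), template, seg_cfg)
        assert det.match_tolerance == 1.0
        for lab, pt in zip("ABCD", template.points):
            assert np.allclose(det.marker_coms[lab], pt, atol=1e-9)
        hits = brute_force_match(coms, template.points, tau=1.0)
        assert len(hits) == 1 and hits[0][0] == (0, 1, 2, 3)

    def test_perturbed_points_match_at_1mm(self, template, seg_cfg, rng):
        """Each point offset by <= 0.4 mm changes each pairwise distance by
        <= 0.8 mm, so the match succeeds at tau = 1."""
        pts = template.points + 0.4 * _unit_rows(rng.standard_normal((4, 3)))
        det = match_device(self._sets_from_coms(pts), template, seg_cfg)
        assert det.match_tolerance == 1.0

    def test_three_points_fail(self, template, seg_cfg):
        sets = self._sets_from_coms(template.points[:3])
        with pytest.raises(SegmentationError, match="device not found"):
            match_device(sets, template, seg_cfg)

    def test_no_geometry_fails_after_tau_max(self, template, seg_cfg, rng):
        coms = rng.uniform(0, 30, (6, 3))  # cluster far too small
        with pytest.raises(SegmentationError, match="device not found"):
            match_device(self._sets_from_coms(coms), template, seg_cfg)

    def test_distant_decoys_do_not_change_match(self, template, seg_cfg, rng):
        base = self._sets_from_coms(template.points)
        det0 = match_device(base, template, seg_cfg)
        far = self._sets_from_coms(template.points + np.array([200.0, 150.0, 90.0]))
        det1 = match_device(base + far[:3], template, seg_cfg)
        for lab in "ABCD":
            assert np.allclose(det0.marker_coms[lab], det1.marker_coms[lab])


def _unit_rows(x):
    return x / np.linalg.norm(x, axis=1, keepdims=True)


class TestFullPipeline:
    def test_noiseless_round_trip(self, template, small_marker_volume):
        vol, pose, spec = small_marker_volume
        det = segment_fiducial(vol, template)
        truth = pose.posed_points(template)
        half_voxel = max(vol.spacing) / 2
        err = np.linalg.norm(det.points - truth, axis=1)
        assert np.all(err <= half_voxel)
        assert det.diagnostics["n_candidates_shape"] >= 4

    def test_device_outside_fov_rejected(self, template):
        from fidseg import AcquisitionSpec, ScenePose, rasterize_scene

        pose = ScenePose.default(seed=5, v_marker=template.v_marker)
        pose.device_position = np.array([0.0, 500.0, 0.0])  # device far outside
        spec = AcquisitionSpec(in_plane_mm=(1.9, 1.9), slice_thickness_mm=6.0, seed=5)
        with pytest.raises(ValueError):
            rasterize_scene(template, pose, spec)

    def test_background_only_never_false_positive(self, template):
        from fidseg import AcquisitionSpec, ScenePose

        pose = ScenePose.default(seed=5, v_marker=template.v_marker)
        spec = AcquisitionSpec(in_plane_mm=(1.9, 1.9), slice_thickness_mm=6.0, seed=5)
        vol = _rasterize_background_only(template, pose, spec)
        with pytest.raises(SegmentationError):
            segment_fiducial(vol, template)

    def test_intensity_scale_invariance(self, template, small_marker_volume):
        """Multiplying all intensities by an integer constant leaves the
        detected marker voxel sets unchanged and COMs within 0.1 mm."""
        vol, pose, spec = small_marker_volume
        det1 = segment_fiducial(vol, template, keep_voxels=True)
        from fidseg import Volume3D

        v3 = Volume3D(vol.data * 3, vol.affine, dict(vol.meta))
        det3 = segment_fiducial(v3, template, keep_voxels=True)
        for lab in "ABCD":
            a = det1.diagnostics["marker_voxels"][lab]
            b = det3.diagnostics["marker_voxels"][lab]
            assert sorted(map(tuple, a)) == sorted(map(tuple, b))
            assert np.linalg.norm(det1.marker_coms[lab] - det3.marker_coms[lab]) < 0.1

    def test_pipeline_composite_equals_naive_reference_on_small_volume(self, rng):
        """On a <= 30^3 volume the composite candidate mask equals that of a
        naive reference implementation (BFS labeling, python loops)."""
        vm = 60.0
        cfg = SegmentationConfig(v_marker=vm, shape_max_mm=1e9)
        data = np.zeros((28, 28, 28), dtype=np.int32)
        # three blobs of different brightness and size plus noise floor
        data[2:6, 2:6, 2:6] = 180  # 64 vox: too big (> 1.3 Vm = 78)
        data[10:14, 10:14, 10:13] = 200  # 48 vox: candidate
        data[20:24, 20:24, 20:22] = 90  # 32 vox: candidate at lower thresholds
        noise = (rng.random(data.shape) < 0.3).astype(np.int32) * rng.integers(1, 12, data.shape)
        data = data + noise.astype(np.int32)
        v = make_volume(data)
        r_t = 150.0
        sets = iterative_signal_size(v, r_t=r_t, cfg=cfg, noise_threshold=20)
        got = np.zeros(data.shape, dtype=bool)
        for s in sets:
            got[s.voxels[:, 0], s.voxels[:, 1], s.voxels[:, 2]] = True
        expected = _naive_composite(data, r_t, vm, noise_threshold=20)
        assert np.array_equal(got, expected)


def _naive_composite(data, r_t, vm, noise_threshold):
    """Reference implementation of the iterative size/signal stage using
    the BFS labeling oracle and explicit python logic."""
    composite = np.zeros(data.shape, dtype=bool)
    cap = 1.3 * vm
    for n in (7, 6, 5, 4, 3, 2):
        st = n / 4.0 * r_t
        mask = (data >= st) & (data >= noise_threshold)
        labels = bfs_label_26(mask)
        sets = []
        for lab in range(1, labels.max() + 1):
            vox = np.argwhere(labels == lab)
            volume = len(vox)  # unit spacing
            if 0.35 * vm < volume < 1.3 * vm:
                sets.append(vox)
        sets.sort(key=lambda vx: (len(vx), tuple(vx[np.lexsort(vx.T[::-1])][0])))
        for vox in sets:
            trial = composite.copy()
            trial[vox[:, 0], vox[:, 1], vox[:, 2]] = True
            tl = bfs_label_26(trial)
            lab_of_set = np.unique(tl[vox[:, 0], vox[:, 1], vox[:, 2]])
            assert len(lab_of_set) == 1
            union_size = (tl == lab_of_set[0]).sum()
            if union_size <= cap:
                composite = trial
    return composite


def _rasterize_background_only(template, pose, spec):
    """A body+blobs scene with no device: rasterize, then blank the boxes
    around the marker sites (they sit in air, clear of the body)."""
    from fidseg import Volume3D, rasterize_scene, world_to_voxel

    vol = rasterize_scene(template, pose, spec)
    data = vol.data.copy()
    idx = np.rint(world_to_voxel(vol, pose.posed_points(template))).astype(int)
    half = np.ceil(14.0 / vol.spacing).astype(int)
    for c in idx:
        lo = np.maximum(c - half, 0)
        hi = np.minimum(c + half + 1, vol.shape)
        data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = 0
    return Volume3D(data, vol.affine, dict(vol.meta))
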