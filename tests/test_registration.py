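"""Landmark registration: Procrustes-oracle equivalence, exact recovery,
jitter propagation, ROI mapping arithmetic, and slice pairing."""

import math
import warnings

import numpy as np
import pytest

from trabec_bvtv import (
    LandmarkSet,
    PairedMeasurement,
    ROISpec,
    SliceCorrespondence,
    Transform2D,
    fit_similarity,
    map_roi,
    pair_measurements,
)
from conftest import procrustes_similarity


def apply_true(points, theta, scale, t):
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    return points @ (scale * rot).T + np.asarray(t)


CORNERS = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0], [5.0, 5.0]])


class TestFitSimilarity:
    def test_identity_pairs(self):
        t = fit_similarity(LandmarkSet(CORNERS, CORNERS.copy()))
        assert t.rotation == pytest.approx(0.0, abs=1e-12)
        assert t.scale == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(t.translation, 0.0, atol=1e-12)
        assert t.rmse == pytest.approx(0.0, abs=1e-12)

    def test_known_transform_recovered_exactly(self):
        theta, scale, trans = 0.1, 1.02, (1.5, -0.7)
        dst = apply_true(CORNERS, theta, scale, trans)
        t = fit_similarity(LandmarkSet(CORNERS, dst))
        assert t.rotation == pytest.approx(theta, abs=1e-9)
        assert t.scale == pytest.approx(scale, abs=1e-9)
        assert np.allclose(t.translation, trans, atol=1e-9)
        assert t.rmse < 1e-9

    def test_two_point_fit_is_exact(self):
        src = np.array([[0.0, 0.0], [3.0, 1.0]])
        dst = apply_true(src, -0.3, 0.9, (0.2, 2.0))
        t = fit_similarity(LandmarkSet(src, dst))
        assert t.rmse < 1e-9
        assert np.allclose(t.apply(src), dst, atol=1e-9)

    def test_matches_procrustes_oracle_on_random_instances(self):
        """The linear least-squares solution equals the closed-form
        SVD (Umeyama) Procrustes fit."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(3, 8)
            src = rng.uniform(-10, 10, (n, 2))
            dst = rng.uniform(-10, 10, (n, 2))
            t = fit_similarity(LandmarkSet(src, dst))
            rot, scale, trans = procrustes_similarity(src, dst)
            assert np.allclose(t.matrix, scale * rot, atol=1e-9)
            assert np.allclose(t.translation, trans, atol=1e-9)

    def test_jitter_propagation(self):
        """0.05 mm landmark jitter: fit RMSE concentrates near the jitter SD
        and parameter errors stay within 3x their propagation bounds."""
        rng = np.random.default_rng(7)
        sigma, n_rep = 0.05, 1000
        rmses, rot_errs, trans_errs = [], [], []
        for _ in range(n_rep):
            dst = CORNERS + rng.normal(0, sigma, CORNERS.shape)
            t = fit_similarity(LandmarkSet(CORNERS, dst))
            rmses.append(t.rmse)
            rot_errs.append(abs(t.rotation))
            trans_errs.append(np.hypot(*t.translation))
        # residual dof: 2n - 4 of 2n coordinates -> E[rmse^2] = sigma^2 (2n-4)/(2n) * 2
        assert np.mean(rmses) == pytest.approx(sigma, rel=0.15)
        r2 = np.sqrt(((CORNERS - CORNERS.mean(0)) ** 2).sum())
        assert np.quantile(rot_errs, 0.95) < 3 * 2 * sigma / r2
        assert np.quantile(trans_errs, 0.95) < 3 * 2 * sigma / math.sqrt(CORNERS.shape[0])

    def test_collinear_landmarks_warn(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.warns(UserWarning, match="collinear"):
            LandmarkSet(pts, pts + 0.1)

    def test_coincident_landmarks_rejected(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="coincident"):
            LandmarkSet(pts, pts)


class TestTransform2D:
    def test_inverse_roundtrip(self):
        t = Transform2D(rotation=0.25, scale=1.1, translation=(2.0, -1.0))
        pts = np.array([[0.3, 0.7], [4.0, 2.0], [-1.0, 5.0]])
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-10)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            Transform2D(rotation=0.0, scale=0.0, translation=(0.0, 0.0))


class TestMapRoi:
    roi = ROISpec("s", 3, ((2, 8), (2, 8)), 0.5)
    corr = SliceCorrespondence(k=10)

    def test_identity_gives_k_copies(self):
        t = Transform2D(0.0, 1.0, (0.0, 0.0))
        mapped = map_roi(self.roi, t, self.corr, uct_voxel=0.05)
        assert len(mapped) == 10
        assert [m.slice_index for m in mapped] == list(range(30, 40))
        assert all(m.bounds == ((20, 80), (20, 80)) for m in mapped)

    def test_pure_translation_shifts_by_exact_voxels(self):
        t = Transform2D(0.0, 1.0, (1.0, 2.0))  # x += 1 mm, y += 2 mm
        mapped = map_roi(self.roi, t, self.corr, uct_voxel=0.05)
        # rows follow y (+2 mm = 40 voxels), cols follow x (+1 mm = 20 voxels)
        assert mapped[0].bounds == ((60, 120), (40, 100))

    def test_rotation_grows_bounding_box(self):
        t = Transform2D(0.1, 1.0, (0.0, 0.0))
        mapped = map_roi(self.roi, t, self.corr, uct_voxel=0.05)
        (r0, r1), (c0, c1) = mapped[0].bounds
        area_mapped = (r1 - r0) * (c1 - c0)
        # axis-aligned box of a rotated square is at least as large
        assert area_mapped >= 60 * 60

    def test_rmse_gate_enforced(self):
        t = Transform2D(0.0, 1.0, (0.0, 0.0), rmse=0.4)
        with pytest.raises(ValueError, match="RMSE"):
            map_roi(self.roi, t, self.corr, uct_voxel=0.05)

    def test_out_of_bounds_rejected(self):
        t = Transform2D(0.0, 1.0, (50.0, 0.0))
        with pytest.raises(ValueError, match="exceed"):
            map_roi(self.roi, t, self.corr, uct_voxel=0.05, uct_shape=(40, 100, 100))


class TestPairing:
    def test_constant_block_mean(self):
        corr = SliceCorrespondence(k=10)
        mr = {("a", 2): 0.22}
        uct = {("a", z): 0.31 for z in range(20, 30)}
        pairs = pair_measurements(mr, uct, corr)
        assert len(pairs) == 1
        assert pairs[0].bvtv_uct == pytest.approx(0.31)

    def test_mixed_block_mean(self):
        corr = SliceCorrespondence(k=10)
        mr = {("a", 0): 0.2}
        uct = {("a", z): (0.30 if z < 5 else 0.32) for z in range(10)}
        pairs = pair_measurements(mr, uct, corr)
        assert pairs[0].bvtv_uct == pytest.approx(0.31)

    def test_pair_count_is_specimens_times_slices(self):
        corr = SliceCorrespondence(k=2)
        mr = {(f"s{i}", z): 0.2 for i in range(6) for z in range(10)}
        uct = {(f"s{i}", z): 0.3 for i in range(6) for z in range(20)}
        assert len(pair_measurements(mr, uct, corr)) == 60

    def test_missing_slice_names_gap(self):
        corr = SliceCorrespondence(k=10)
        mr = {("a", 0): 0.2}
        uct = {("a", z): 0.3 for z in range(9)}  # slice 9 missing
        with pytest.raises(KeyError, match="slice 9"):
            pair_measurements(mr, uct, corr)

    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            PairedMeasurement("a", 0, bvtv_mr=1.2, bvtv_uct=0.3)


def test_slice_correspondence_from_voxel_sizes():
    corr = SliceCorrespondence.from_voxel_sizes(0.5, 0.05)
    assert corr.k == 10
    assert list(corr.uct_slices(3)) == list(range(30, 40))
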