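"""RANSAC registration: residuals, inlier fitness, estimation, warping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fruitsense.frames import TofFrame, unproject_depth
from fruitsense.register import (
    MatchSet,
    PlanarTransform,
    apply_transform,
    count_inliers,
    fit_transform,
    ransac_register,
    residual,
    residuals,
)
from fruitsense.scene_sim import default_transform, generate_scene, sample_control_points
from tests.conftest import noiseless_config


def _similarity(scale, deg, tx, ty):
    th = math.radians(deg)
    R = scale * np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    return PlanarTransform(R, np.array([tx, ty]))


def test_residual_identity_and_345():
    ident = PlanarTransform.identity()
    assert residual((np.array([3.0, 7.0]), np.array([3.0, 7.0])), ident) == 0.0
    shifted = PlanarTransform(np.eye(2), np.array([3.0, 4.0]))
    assert residual((np.zeros(2), np.zeros(2)), shifted) == pytest.approx(5.0)


def test_residual_matches_hand_expansion():
    """‖R·X1 + T − X2‖ expanded scalar by scalar."""
    R = np.array([[1.3, -0.4], [0.4, 1.3]])
    T = np.array([5.0, -2.0])
    x1 = np.array([2.0, 3.0])
    x2 = np.array([1.0, 1.0])
    ex = R[0, 0] * x1[0] + R[0, 1] * x1[1] + T[0] - x2[0]
    ey = R[1, 0] * x1[0] + R[1, 1] * x1[1] + T[1] - x2[1]
    expected = math.sqrt(ex * ex + ey * ey)
    tr = PlanarTransform(R, T)
    assert residual((x1, x2), tr) == pytest.approx(expected, rel=1e-14)


def test_count_inliers_noiseless_and_strictness(rng):
    tr = _similarity(2.0, 10.0, 5.0, -3.0)
    x1 = rng.uniform(0, 100, size=(40, 2))
    ms = MatchSet(x1, tr.apply(x1))
    assert count_inliers(ms, tr, epsilon=1e-9) == 40
    # epsilon = 0 with strictly positive residuals gives zero inliers
    ms2 = MatchSet(x1, tr.apply(x1) + 0.001)
    assert count_inliers(ms2, tr, epsilon=0.0) == 0
    # exact boundary: residual == epsilon is NOT an inlier
    ms3 = MatchSet(np.zeros((1, 2)), np.array([[3.0, 4.0]]))
    assert count_inliers(ms3, PlanarTransform.identity(), epsilon=5.0) == 0
    assert count_inliers(ms3, PlanarTransform.identity(), epsilon=5.0 + 1e-9) == 1


def test_count_inliers_equals_bruteforce_loop(rng):
    for _ in range(50):
        tr = _similarity(rng.uniform(0.5, 3), rng.uniform(-40, 40), *rng.uniform(-20, 20, 2))
        x1 = rng.uniform(0, 50, size=(30, 2))
        x2 = tr.apply(x1) + rng.normal(0, 2.0, size=(30, 2))
        eps = rng.uniform(0.5, 5.0)
        ms = MatchSet(x1, x2)
        brute = sum(
            1 for i in range(30) if residual((x1[i], x2[i]), tr) < eps
        )
        assert count_inliers(ms, tr, eps) == brute


def test_empty_matchset_warns():
    ms = MatchSet(np.empty((0, 2)), np.empty((0, 2)))
    with pytest.warns(UserWarning, match="empty"):
        assert count_inliers(ms, PlanarTransform.identity(), 1.0) == 0


@settings(derandomize=True, max_examples=30)
@given(
    eps1=st.floats(0, 10),
    eps2=st.floats(0, 10),
    seed=st.integers(0, 1000),
)
def test_f0_monotone_in_epsilon(eps1, eps2, seed):
    """Inlier fitness is monotone non-decreasing in the threshold."""
    r = np.random.default_rng(seed)
    tr = _similarity(1.5, 5.0, 1.0, 2.0)
    x1 = r.uniform(0, 50, size=(25, 2))
    ms = MatchSet(x1, tr.apply(x1) + r.normal(0, 3, size=(25, 2)))
    lo, hi = sorted((eps1, eps2))
    assert count_inliers(ms, tr, lo) <= count_inliers(ms, tr, hi)


def test_ransac_identity_recovery(rng):
    x1 = rng.uniform(0, 100, size=(30, 2))
    ms = MatchSet(x1, x1.copy())
    res = ransac_register(ms, epsilon=1.0, max_iter=100, seed=0)
    np.testing.assert_allclose(res.transform.R, np.eye(2), atol=1e-6)
    np.testing.assert_allclose(res.transform.T, np.zeros(2), atol=1e-6)
    assert res.inlier_count == 30


def test_ransac_with_outliers_recovers_generating_transform(tiny_noiseless_scene):
    """30% outliers, 0.5 px noise: consensus covers the true inliers and
    every true inlier's residual stays below epsilon."""
    _, _, _, truth = tiny_noiseless_scene
    ms = sample_control_points(truth, 100, outlier_fraction=0.3, noise_sd=0.5, seed=21)
    res = ransac_register(ms, epsilon=2.0, max_iter=1000, seed=22)
    assert res.inlier_count >= 70
    true_inlier_res = residuals(ms, res.transform)[~ms.outlier_mask]
    assert true_inlier_res.max() < 2.0


def test_ransac_self_consistency(tiny_noiseless_scene):
    _, _, _, truth = tiny_noiseless_scene
    ms = sample_control_points(truth, 60, outlier_fraction=0.2, noise_sd=0.5, seed=5)
    res = ransac_register(ms, epsilon=2.0, seed=6)
    assert res.inlier_count == count_inliers(ms, res.transform, res.epsilon)
    assert res.inlier_count == int(res.inlier_flags.sum())


def test_ransac_agrees_with_skimage_oracle(tiny_noiseless_scene):
    """Independent estimator check: scikit-image's RANSAC similarity fit
    lands on the same transform (sub-pixel) for the same match set."""
    from skimage.measure import ransac as sk_ransac
    from skimage.transform import SimilarityTransform

    _, _, _, truth = tiny_noiseless_scene
    ms = sample_control_points(truth, 100, outlier_fraction=0.3, noise_sd=0.5, seed=31)
    ours = ransac_register(ms, epsilon=2.0, max_iter=1000, seed=32)
    model, _ = sk_ransac(
        (ms.x1, ms.x2),
        SimilarityTransform,
        min_samples=2,
        residual_threshold=2.0,
        max_trials=1000,
        rng=0,
    )
    np.testing.assert_allclose(ours.transform.R, model.params[:2, :2], atol=0.02)
    np.testing.assert_allclose(ours.transform.T, model.params[:2, 2], atol=1.0)


def test_ransac_preconditions():
    ms = MatchSet(np.zeros((1, 2)), np.zeros((1, 2)))
    with pytest.raises(ValueError, match="need >="):
        ransac_register(ms, model_kind="similarity")
    with pytest.raises(ValueError):
        fit_transform(np.zeros((2, 2)), np.zeros((2, 2)), model_kind="affine")


def test_rigid_invariants():
    tr = fit_transform(
        np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
        np.array([[1.0, 1.0], [1.0, 2.0], [0.0, 1.0]]),  # 90 deg rotation + shift
        model_kind="rigid",
    )
    assert np.allclose(tr.R.T @ tr.R, np.eye(2), atol=1e-9)
    assert np.isclose(np.linalg.det(tr.R), 1.0, atol=1e-9)


def _flat_tof(shape=(20, 30), depth=1.0):
    d = np.full(shape, depth)
    return TofFrame(
        amplitude=np.arange(shape[0] * shape[1], dtype=float).reshape(shape),
        depth=d,
        confidence=np.ones(shape),
        xyz=unproject_depth(d),
    )


def test_apply_identity_equal_shapes_roundtrips():
    tof = _flat_tof()
    reg = apply_transform(tof, PlanarTransform.identity(), tof.shape)
    np.testing.assert_array_equal(reg.amplitude, tof.amplitude)
    np.testing.assert_array_equal(reg.depth, tof.depth)
    assert not reg.nodata.any()


def test_apply_upsamples_to_full_sensor_shape():
    """A 144x176 TOF frame registered onto the full 2050x2448 colour grid."""
    tof = _flat_tof(shape=(144, 176))
    tr = default_transform((2050, 2448), (144, 176))
    reg = apply_transform(tof, tr, (2050, 2448))
    assert reg.depth.shape == (2050, 2448)
    assert reg.xyz.shape == (3, 2050, 2448)
    covered = ~reg.nodata
    assert covered.any() and reg.nodata.any()


def test_nearest_neighbour_depth_values_subset_of_input(rng):
    tof = _flat_tof(shape=(15, 20))
    tof.depth[:] = rng.uniform(0.5, 2.0, size=tof.depth.shape)
    tr = _similarity(3.1, 4.0, 5.0, 7.0)
    reg = apply_transform(tof, tr, (80, 90))
    vals = reg.depth[~reg.nodata]
    assert np.isin(vals, tof.depth.ravel()).all()
    assert np.isnan(reg.depth[reg.nodata]).all()


def test_nodata_area_matches_uncovered_footprint():
    """No-data pixel count equals the target area outside the transformed
    TOF footprint, to within a boundary-pixel band."""
    tof = _flat_tof(shape=(40, 50))
    tr = _similarity(2.0, 8.0, 30.0, 20.0)
    target = (200, 220)
    reg = apply_transform(tof, tr, target)
    # footprint polygon = transformed sampling extent (±0.5 px around grid)
    corners = np.array([[-0.5, -0.5], [49.5, -0.5], [49.5, 39.5], [-0.5, 39.5]])
    mapped = tr.apply(corners)
    x, y = mapped[:, 0], mapped[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    covered = float((~reg.nodata).sum())
    perimeter = 2 * (np.ptp(x) + np.ptp(y))
    assert abs(covered - min(area, reg.depth.size)) <= perimeter


def test_singular_transform_rejected():
    tof = _flat_tof()
    sing = PlanarTransform(np.array([[1.0, 0.0], [0.0, 0.0]]), np.zeros(2), model_kind="affine")
    with pytest.raises(np.linalg.LinAlgError):
        apply_transform(tof, sing, (10, 10))
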