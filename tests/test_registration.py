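"""NOA metric, residuals, Jacobians and the Levenberg-Marquardt stages."""

import numpy as np
import pytest

from noarsa.geometry import Pose6
from noarsa.imaging import DropoutMask, ImagingError, Radiograph
from noarsa.registration import (
    DEFAULT_SCHEDULE,
    NOAProblem,
    View,
    lm_stage,
    noa,
    pixel_differences,
    register,
    relative_noa,
    validate_schedule,
)
from noarsa.renderer import render_silhouette


def binary_rad(arr, spacing=1.0):
    return Radiograph(np.asarray(arr, dtype=float), spacing, is_binary=True)


def bruteforce_noa(dr, drr):
    """Independent oracle: double loop over every pixel."""
    total = 0.0
    for y in range(dr.shape[0]):
        for x in range(dr.shape[1]):
            total += (dr[y, x] - drr[y, x]) ** 2
    return total


# --------------------------------------------------------------------------- #
# pixel differences and the NOA metric


def test_identical_images_zero_residual():
    img = np.eye(4)
    assert np.all(pixel_differences(binary_rad(img), img) == 0)


def test_binary_difference_counts_discordant_pixels():
    a = np.zeros((4, 4))
    b = np.zeros((4, 4))
    a[0, 0] = a[1, 2] = 1.0
    b[3, 3] = 1.0
    res = pixel_differences(binary_rad(a), b)
    assert np.sum(res != 0) == 3
    assert set(np.abs(res[res != 0])) == {1.0}


def test_grayscale_residual_is_signed_difference():
    dr = Radiograph(np.array([[0.8]]), 1.0)
    res = pixel_differences(dr, np.array([[1.0]]))
    assert res[0] == pytest.approx(-0.2)


def test_dimension_mismatch_rejected():
    with pytest.raises(ImagingError):
        pixel_differences(binary_rad(np.zeros((4, 4))), np.zeros((5, 5)))


def test_relative_noa_enumerated_example():
    """3 discordant pixels against 5 doubly-lit pixels -> 3/8 = 0.375."""
    dr = np.zeros((4, 4))
    drr = np.zeros((4, 4))
    dr[0, :3] = 1.0  # 3 discordant (DR only)
    dr[1, :3] = drr[1, :3] = 1.0  # 3 overlapping
    dr[2, :2] = drr[2, :2] = 1.0  # 2 overlapping
    assert relative_noa(binary_rad(dr), drr) == pytest.approx(0.375)


def test_relative_noa_extremes():
    ones = np.ones((3, 3))
    zeros = np.zeros((3, 3))
    assert relative_noa(binary_rad(ones), ones) == 0.0
    assert relative_noa(binary_rad(ones), zeros) == 1.0


def test_relative_noa_undefined_for_grayscale():
    gray = Radiograph(np.full((3, 3), 0.4), 1.0)
    with pytest.raises(ImagingError):
        relative_noa(gray, np.zeros((3, 3)))


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_noa_matches_bruteforce_double_loop(seed):
    gen = np.random.default_rng(seed)
    shape = (gen.integers(4, 32), gen.integers(4, 32))
    dr = (gen.uniform(0, 1, shape) > 0.5).astype(float)
    drr = (gen.uniform(0, 1, shape) > 0.5).astype(float)
    ours = noa(pixel_differences(binary_rad(dr), drr))
    assert ours == bruteforce_noa(dr, drr)


def test_noa_symmetric_in_binary_mode(rng):
    a = (rng.uniform(0, 1, (16, 16)) > 0.5).astype(float)
    b = (rng.uniform(0, 1, (16, 16)) > 0.5).astype(float)
    assert noa(pixel_differences(binary_rad(a), b)) == noa(
        pixel_differences(binary_rad(b), a)
    )


def test_enlarging_mask_never_increases_noa(rng):
    a = (rng.uniform(0, 1, (20, 20)) > 0.5).astype(float)
    b = (rng.uniform(0, 1, (20, 20)) > 0.5).astype(float)
    small = rng.uniform(0, 1, (20, 20)) > 0.8
    big = small | (rng.uniform(0, 1, (20, 20)) > 0.8)
    n_none = noa(pixel_differences(binary_rad(a), b))
    n_small = noa(pixel_differences(binary_rad(a), b, mask=DropoutMask(small)))
    n_big = noa(pixel_differences(binary_rad(a), b, mask=DropoutMask(big)))
    assert n_big <= n_small <= n_none


# --------------------------------------------------------------------------- #
# schedule


def test_schedule_validation():
    assert validate_schedule([10, 1, 0.1]) == (10.0, 1.0, 0.1)
    with pytest.raises(ValueError):
        validate_schedule([1, 10])
    with pytest.raises(ValueError):
        validate_schedule([1, -2])
    with pytest.raises(ValueError):
        validate_schedule([])
    assert DEFAULT_SCHEDULE == (10.0, 1.0, 0.1, 0.01, 0.001)


# --------------------------------------------------------------------------- #
# Jacobian structure


def test_jacobian_row_count_respects_masks(scene05, binary_pair05):
    masks = []
    k_total = 0
    gen = np.random.default_rng(0)
    for dr in binary_pair05:
        m = gen.uniform(0, 1, dr.shape) > 0.999
        masks.append(DropoutMask(m))
    views = [
        View(dr, cam, mask)
        for dr, cam, mask in zip(binary_pair05, scene05.cameras, masks)
    ]
    problem = NOAProblem(scene05.mesh, views, margin_px=30)
    for roi, mask in zip(problem.rois, masks):
        ys, xs = roi.slices
        k_total += int(mask.pixels[ys, xs].sum())
    full = sum(r.width * r.height for r in problem.rois)
    assert problem.n_residuals == full - k_total
    jac = problem.jacobian(scene05.ground_truth_pose, 1.0)
    assert jac.shape == (problem.n_residuals, 6)


def test_jacobian_zero_when_no_pixels_flip(problem05, scene05):
    """A perturbation far below the pixel scale flips nothing: zero columns."""
    jac = problem05.jacobian(scene05.ground_truth_pose, 1e-9)
    assert np.all(jac == 0)


def test_jacobian_column_equals_independent_two_render_difference(
    problem05, scene05
):
    """The tx column equals the negative central difference of two
    independently rendered full-frame silhouettes."""
    pose = scene05.ground_truth_pose
    eps = 1.0
    jac = problem05.jacobian(pose, eps)
    col = []
    for cam, roi, keep in zip(scene05.cameras, problem05.rois, problem05._keep):
        plus = render_silhouette(scene05.mesh, cam, pose.perturbed(3, +eps))
        minus = render_silhouette(scene05.mesh, cam, pose.perturbed(3, -eps))
        ys, xs = roi.slices
        diff = (
            minus.pixels[ys, xs].astype(float) - plus.pixels[ys, xs]
        ) / (2 * eps)
        col.append(diff[keep])
    assert np.allclose(jac[:, 3], np.concatenate(col))


# --------------------------------------------------------------------------- #
# optimization


def test_lm_stage_terminates_immediately_at_truth(problem05, scene05):
    pose, iters, ssr, converged = lm_stage(problem05, scene05.ground_truth_pose, 1.0)
    assert iters == 0
    assert ssr == 0.0
    assert converged
    assert np.array_equal(pose.as_vector(), scene05.ground_truth_pose.as_vector())


def test_lm_stage_recovers_single_axis_offset(problem05, scene05):
    truth = scene05.ground_truth_pose
    start = truth.perturbed(3, 2.0)  # 2 mm in-plane translation offset
    pose, iters, ssr, _ = lm_stage(problem05, start, 1.0)
    assert iters >= 1
    assert abs(pose.tx - truth.tx) < 1.0


def test_lm_stage_never_increases_residual(problem05, scene05):
    truth = scene05.ground_truth_pose
    start = Pose6.from_vector(
        truth.as_vector() + np.array([1.0, -2.0, 0.5, 2.0, -1.0, 1.5]),
        truth.rotation_center,
    )
    ssr0 = problem05.noa(start)
    pose, _, ssr, _ = lm_stage(problem05, start, 1.0)
    assert ssr <= ssr0


def test_register_from_truth_is_exact(scene05, binary_pair05):
    views = [View(dr, cam) for dr, cam in zip(binary_pair05, scene05.cameras)]
    result = register(views, scene05.mesh, scene05.ground_truth_pose, margin_px=20)
    assert result.relative_noa == 0.0
    assert result.noa == 0.0
    assert result.converged
    assert all(it <= 1 for it in result.stage_iterations)
    assert np.array_equal(
        result.pose.as_vector(), scene05.ground_truth_pose.as_vector()
    )


def test_register_requires_binary_images_in_binary_mode(scene05):
    gray = Radiograph(
        np.full(
            (scene05.cameras[0].image_height, scene05.cameras[0].image_width), 0.4
        ),
        scene05.pixel_spacing,
    )
    views = [View(gray, cam) for cam in scene05.cameras]
    with pytest.raises(ImagingError, match="binary"):
        register(views, scene05.mesh, scene05.ground_truth_pose)
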