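"""Synthetic phantom, simulated observers, rater flips and synthetic dose."""

import numpy as np
import pytest
from scipy import ndimage

from caaseg.errors import DegenerateInputError, ParameterError, ValidationError
from caaseg.geometry import dice
from caaseg.phantom import (
    ObserverModel,
    PhantomSpec,
    generate_dose_grid,
    generate_thorax_phantom,
    simulate_observer_contour,
    simulate_rater_flip,
)


@pytest.fixture(scope="module")
def fine_phantom():
    return generate_thorax_phantom(PhantomSpec(seed=7))


def test_generation_is_deterministic():
    v1, t1 = generate_thorax_phantom(PhantomSpec.desk(seed=7))
    v2, t2 = generate_thorax_phantom(PhantomSpec.desk(seed=7))
    assert np.array_equal(v1.voxels, v2.voxels)
    for name in t1.names:
        assert np.array_equal(t1[name], t2[name])


def test_coronary_tube_dimensions(fine_phantom):
    """Coronaries are 7 mm wide and run 2 cm from the ostium (within a voxel)."""
    vol, truth = fine_phantom
    spacing = np.asarray(vol.spacing)
    for name, direction in (("LCA", (0.75, 0.45, -0.55)), ("RCA", (-0.35, -0.8, -0.48))):
        pts = np.argwhere(truth[name]) * spacing
        d = np.asarray(direction, float)
        d /= np.linalg.norm(d)
        along = (pts - pts.mean(axis=0)) @ d
        assert abs((along.max() - along.min()) - 20.0) <= spacing.max()
        perp = pts - np.outer(pts @ d, d)
        mid = np.abs(along - along.mean()) < 4.0
        from scipy.spatial.distance import pdist

        cross = pdist(perp[mid]).max()
        assert abs(cross - 7.0) <= spacing.max()


def test_labels_mutually_exclusive_and_inside_heart(fine_phantom):
    vol, truth = fine_phantom
    total = sum(truth[n].astype(int) for n in ("RightAtrium", "AorticValveRoot", "LCA", "RCA"))
    assert total.max() <= 1
    heart = truth["WholeHeart"].astype(bool)
    assert ((total > 0) & ~heart).sum() == 0
    lungs = truth["Lungs"].astype(bool)
    assert vol.voxels[lungs].mean() < -600  # lungs at low HU flank the mediastinum


def test_contrast_off_blood_equals_myocardium():
    spec = PhantomSpec.desk(seed=1, contrast=False, noise_hu=0.0)
    vol, truth = generate_thorax_phantom(spec)
    caa = truth["CAA"].astype(bool)
    heart_wall = truth["WholeHeart"].astype(bool) & ~caa
    assert np.unique(vol.voxels[caa]).tolist() == [spec.hu["myocardium"]]
    assert set(np.unique(vol.voxels[heart_wall])) <= {spec.hu["myocardium"]}


def test_grid_too_small_raises():
    with pytest.raises(ValidationError):
        generate_thorax_phantom(PhantomSpec(shape=(16, 16, 8), spacing=(1.5, 1.5, 3.0)))


def test_metal_flag_adds_high_density():
    vol, _ = generate_thorax_phantom(PhantomSpec.desk(seed=2, metal=True))
    assert (vol.voxels > 2500).sum() > 0


# --- simulated observers -----------------------------------------------------


def test_zero_noise_observer_is_identity(fine_phantom):
    _, truth = fine_phantom
    obs = ObserverModel(bias_mm=0.0, sd_mm=0.0)
    out = simulate_observer_contour(truth["RightAtrium"], obs, (1.5, 1.5, 3.0))
    assert np.array_equal(out, truth["RightAtrium"])


def test_positive_bias_dilates(fine_phantom):
    _, truth = fine_phantom
    obs = ObserverModel(bias_mm=2.0, sd_mm=0.0)
    out = simulate_observer_contour(truth["RightAtrium"], obs, (1.5, 1.5, 3.0))
    assert out.sum() > truth["RightAtrium"].sum()
    assert (out.astype(bool) & ~truth["RightAtrium"].astype(bool)).sum() > 0


def test_observer_pairwise_dsc_in_realistic_band(fine_phantom):
    """Three 1-mm observers of the CAA disagree, but only moderately."""
    _, truth = fine_phantom
    masks = [
        simulate_observer_contour(
            truth["CAA"],
            ObserverModel(bias_mm=0.0, sd_mm=1.0, corr_mm=6.0, seed=s),
            (1.5, 1.5, 3.0),
        )
        for s in (1, 2, 3)
    ]
    for i in range(3):
        for j in range(i + 1, 3):
            d = dice(masks[i], masks[j])
            assert 0.7 < d < 1.0


def test_observer_preserves_topology(fine_phantom):
    _, truth = fine_phantom
    obs = ObserverModel(bias_mm=1.0, sd_mm=1.5, seed=4)
    out = simulate_observer_contour(truth["RightAtrium"], obs, (1.5, 1.5, 3.0))
    _, n = ndimage.label(out)
    assert n == 1


def test_empty_truth_rejected():
    with pytest.raises(DegenerateInputError):
        simulate_observer_contour(np.zeros((8, 8, 8), np.uint8), ObserverModel(), (1, 1, 1))


# --- Bernoulli raters ---------------------------------------------------------


def test_perfect_rater_is_identity(rng):
    truth = (rng.random((20, 20, 20)) < 0.3).astype(np.uint8)
    assert np.array_equal(simulate_rater_flip(truth, 1.0, 1.0, seed=0), truth)


def test_rater_flip_matches_binomial_oracle():
    truth = np.zeros((100, 100, 20), np.uint8)
    truth[:50] = 1  # 1e5 foreground voxels
    out = simulate_rater_flip(truth, 0.9, 0.99, seed=42)
    kept = out[truth.astype(bool)].mean()
    fp = out[~truth.astype(bool)].mean()
    assert abs(kept - 0.9) < 0.01  # binomial sd ~ 9.5e-4
    assert abs(fp - 0.01) < 0.001


def test_nonidentifiable_rater_rejected():
    truth = np.ones((4, 4, 4), np.uint8)
    with pytest.raises(ParameterError):
        simulate_rater_flip(truth, 0.5, 0.99)
    with pytest.raises(ParameterError):
        simulate_rater_flip(truth, 0.9, 0.3)


# --- synthetic dose -----------------------------------------------------------


@pytest.fixture(scope="module")
def desk_truth():
    return generate_thorax_phantom(PhantomSpec.desk(seed=3))[1]


def test_ptv_mean_at_prescription(desk_truth):
    dose = generate_dose_grid(desk_truth, prescription_gy=55.0, seed=1)
    ptv_mean = dose.voxels[desk_truth["PTV"].astype(bool)].mean()
    assert 54.0 <= ptv_mean <= 56.0


def test_caa_suppression_respects_limit(desk_truth):
    dose = generate_dose_grid(desk_truth, caa_limit_gy=19.5, seed=1, suppress_caa=True)
    assert dose.voxels[desk_truth["CAA"].astype(bool)].max() <= 19.5 + 1e-5


def test_dose_nonnegative_and_deterministic(desk_truth):
    d1 = generate_dose_grid(desk_truth, seed=5)
    d2 = generate_dose_grid(desk_truth, seed=5)
    assert (d1.voxels >= 0).all()
    assert np.array_equal(d1.voxels, d2.voxels)


def test_dose_falls_off_with_distance(desk_truth):
    dose = generate_dose_grid(desk_truth, seed=1, noise_gy=0.0, suppress_caa=False)
    dist = ndimage.distance_transform_edt(
        ~desk_truth["PTV"].astype(bool), sampling=desk_truth.grid.spacing
    )
    near = dose.voxels[(dist > 0) & (dist < 20)].mean()
    far = dose.voxels[dist > 80].mean()
    assert near > far
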