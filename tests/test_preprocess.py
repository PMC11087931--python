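"""Heart localisation, cropping, metal removal, window normalisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from caaseg.errors import LocalizationError, ParameterError
from caaseg.phantom import PhantomSpec, generate_thorax_phantom
from caaseg.postprocess import pad_to_original
from caaseg.preprocess import (
    DEFAULT_WINDOWS,
    WindowSpec,
    crop_volume,
    localize_heart,
    normalize_channels,
    remove_metal_artifacts,
)
from caaseg.volume_io import ImageVolume


@pytest.fixture(scope="module")
def phantom():
    return generate_thorax_phantom(PhantomSpec(seed=5))


def test_heart_centre_near_label_centroid(phantom):
    ct, truth = phantom
    centre = localize_heart(ct)
    centroid = ndimage.center_of_mass(truth["WholeHeart"])
    err_mm = np.linalg.norm((np.asarray(centre) - np.asarray(centroid)) * np.asarray(ct.spacing))
    assert err_mm < 15.0


def test_mirrored_phantom_mirrors_centre(phantom):
    ct, _ = phantom
    centre = localize_heart(ct)
    mirrored = ImageVolume(ct.voxels[::-1].copy(), ct.spacing, ct.origin, ct.modality)
    centre_m = localize_heart(mirrored)
    assert abs((ct.shape[0] - 1 - centre[0]) - centre_m[0]) <= 2


def test_uniform_air_fails_localisation():
    ct = ImageVolume(np.full((32, 32, 16), -1000, np.int16), (3, 3, 6))
    with pytest.raises(LocalizationError):
        localize_heart(ct)


def test_single_lung_fails_localisation():
    vox = np.full((48, 48, 24), 40, np.int16)
    vox[10:20, 10:20, 5:15] = -800  # one lung only
    with pytest.raises(LocalizationError):
        localize_heart(ImageVolume(vox, (3, 3, 6)))


def test_crop_emits_requested_shape(phantom):
    ct, _ = phantom
    cropped, region = crop_volume(ct, (64, 64, 32), (128, 128, 64))
    assert cropped.shape == (128, 128, 64)
    assert region.original_shape == ct.shape


def test_corner_crop_pads_with_air(phantom):
    ct, _ = phantom
    cropped, _ = crop_volume(ct, (0, 0, 0), (32, 32, 16))
    assert cropped.voxels[0, 0, 0] == -1000
    # in-bounds corner content is preserved
    assert np.array_equal(cropped.voxels[16:, 16:, 8:], np.asarray(ct.voxels)[:16, :16, :8])


def test_crop_then_pad_restores_interior_mask(phantom):
    ct, truth = phantom
    mask = truth["RightAtrium"]
    vol = ImageVolume(mask, ct.spacing, modality="MASK")
    cropped, region = crop_volume(vol, (64, 64, 32), (64, 64, 32), fill_hu=0)
    restored = pad_to_original(cropped.voxels, region)
    assert np.array_equal(restored, mask)


def test_metal_removal_noop_without_metal(phantom):
    ct, _ = phantom
    out = remove_metal_artifacts(ct)
    assert np.array_equal(out.voxels, ct.voxels)


def test_metal_removal_replaces_neighbourhood_and_is_idempotent():
    vox = np.zeros((9, 9, 9), np.float32)
    vox[4, 4, 4] = 3000.0
    ct = ImageVolume(vox, (1.0, 1.0, 1.0))
    out = remove_metal_artifacts(ct, threshold_hu=2000, dilation_mm=3.0, replacement_hu=50)
    assert out.voxels[4, 4, 4] == 50
    for off in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
        assert out.voxels[4 + off[0], 4 + off[1], 4 + off[2]] == 50
    assert out.voxels[0, 0, 0] == 0.0  # beyond the dilation radius: untouched
    again = remove_metal_artifacts(out, threshold_hu=2000, dilation_mm=3.0, replacement_hu=50)
    assert np.array_equal(again.voxels, out.voxels)


def test_two_metal_blobs_replaced_independently():
    vox = np.zeros((24, 12, 12), np.float32)
    vox[4, 6, 6] = 2500.0
    vox[19, 6, 6] = 2600.0
    ct = ImageVolume(vox, (1.0, 1.0, 1.0))
    out = remove_metal_artifacts(ct, threshold_hu=2000, dilation_mm=2.0, replacement_hu=50)
    replaced = np.argwhere(out.voxels == 50)
    lab, n = ndimage.label(out.voxels == 50)
    assert n == 2
    assert {4, 19} <= set(replaced[:, 0])


def test_window_midpoint_and_edges():
    for window in DEFAULT_WINDOWS:
        lo = window.level - window.width / 2
        hi = window.level + window.width / 2
        assert window.apply(np.array(window.level)) == pytest.approx(0.5)
        assert window.apply(np.array(lo)) == 0.0
        assert window.apply(np.array(hi)) == 1.0
    # the wide thorax window's lower edge sits at air density
    assert DEFAULT_WINDOWS[0].level - DEFAULT_WINDOWS[0].width / 2 == -1000
    # the narrow cardiac window saturates at 165 HU
    assert DEFAULT_WINDOWS[1].apply(np.array(165.0)) == 1.0


def test_two_channels_stacked(phantom):
    ct, _ = phantom
    x = normalize_channels(ct)
    assert x.shape == (2,) + ct.shape
    assert x.dtype == np.float32
    assert 0.0 <= x.min() and x.max() <= 1.0


def test_nonpositive_width_rejected():
    with pytest.raises(ParameterError):
        WindowSpec(0, 50)


@settings(max_examples=50, deadline=None)
@given(
    hu=st.lists(st.floats(-1200, 3200), min_size=2, max_size=20),
    width=st.floats(1.0, 4000.0),
    level=st.floats(-1000.0, 1000.0),
)
def test_normalisation_monotone_in_hu(hu, width, level):
    window = WindowSpec(width, level)
    values = np.sort(np.asarray(hu))
    out = window.apply(values)
    assert (np.diff(out) >= -1e-7).all()
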