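"""Preprocessing for auto-contouring: heart localisation, cropping, metal
artefact removal and two-channel window/level normalisation.

The inference pipeline mirrors the clinical workflow: find the heart, crop a
fixed-size block around it (128 x 128 x 64 voxels by default), replace metal
artefacts with soft tissue, then map the HU into two display windows — a wide
thorax window (W1600, L-200) and a narrow soft-tissue window (W200, L65) — each
scaled to [0, 1], stacked as the network's two input channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import LocalizationError, ParameterError
from .volume_io import ImageVolume

AIR_FILL_HU = -1000.0


@dataclass(frozen=True)
class WindowSpec:
    """Display window: width W and level L in HU; maps [L-W/2, L+W/2] -> [0, 1]."""

    width: float
    level: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ParameterError(f"window width must be > 0, got {self.width}")

    def apply(self, hu: np.ndarray) -> np.ndarray:
        lo = self.level - self.width / 2.0
        return np.clip((np.asarray(hu, dtype=np.float32) - lo) / self.width, 0.0, 1.0)


#: Channel 1: wide thorax window. Channel 2: narrow cardiac soft-tissue window.
DEFAULT_WINDOWS: tuple[WindowSpec, WindowSpec] = (WindowSpec(1600, -200), WindowSpec(200, 65))

DEFAULT_CROP_SIZE = (128, 128, 64)


@dataclass(frozen=True)
class CropRegion:
    """Record of a crop so masks can be padded back to the original grid.

    ``start`` may be negative or extend past the volume: out-of-bounds voxels
    were filled with ``fill_hu`` during cropping.
    """

    start: tuple[int, int, int]
    size: tuple[int, int, int]
    original_shape: tuple[int, int, int]
    fill_hu: float = AIR_FILL_HU

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.size):
            raise ParameterError(f"crop size must be positive per axis, got {self.size}")


def localize_heart(ct: ImageVolume) -> tuple[int, int, int]:
    """Estimate the heart centre (voxel index) on a thorax CT.

    Heuristic: body = largest connected component above -300 HU; lungs = the two
    largest sub- -400 HU components inside the (hole-filled) body; the heart
    centre is the centroid of mediastinal soft tissue lying between the lungs
    over the mid-lung axial range.
    """
    hu = np.asarray(ct.voxels)
    body = hu > -300
    lab, n = ndimage.label(body)
    if n == 0:
        raise LocalizationError("no body found (no voxels above -300 HU)")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    body = lab == (1 + int(np.argmax(sizes)))
    body_filled = ndimage.binary_fill_holes(body)

    lung_cand = (hu < -400) & body_filled
    lab, n = ndimage.label(lung_cand)
    if n < 2:
        raise LocalizationError("fewer than two lung candidates found")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    if sizes[order[1]] < max(50.0, 0.05 * sizes[order[0]]):
        raise LocalizationError("second lung component too small — fewer than two lungs")
    lung_a = lab == (1 + int(order[0]))
    lung_b = lab == (1 + int(order[1]))

    ca = np.asarray(ndimage.center_of_mass(lung_a))
    cb = np.asarray(ndimage.center_of_mass(lung_b))
    if ca[0] > cb[0]:
        ca, cb = cb, ca
        lung_a, lung_b = lung_b, lung_a
    lungs = lung_a | lung_b

    zs = np.flatnonzero(lung_a.any(axis=(0, 1)) & lung_b.any(axis=(0, 1)))
    if zs.size == 0:
        raise LocalizationError("lungs share no axial slices")
    z_lo = zs[0] + zs.size // 4
    z_hi = zs[-1] - zs.size // 4

    idx = np.indices(hu.shape)
    ys = np.flatnonzero(lungs.any(axis=(0, 2)))
    band = (
        (hu > -300)
        & (idx[0] > ca[0])
        & (idx[0] < cb[0])
        & (idx[1] >= ys[0])
        & (idx[1] <= ys[-1])
        & (idx[2] >= z_lo)
        & (idx[2] <= z_hi)
    )
    if not band.any():
        raise LocalizationError("no mediastinal soft tissue found between the lungs")
    centre = ndimage.center_of_mass(band)
    return tuple(int(round(c)) for c in centre)


def crop_volume(
    ct: ImageVolume,
    centre: tuple[int, int, int],
    crop_size: tuple[int, int, int] = DEFAULT_CROP_SIZE,
    fill_hu: float = AIR_FILL_HU,
) -> tuple[ImageVolume, CropRegion]:
    """Crop a fixed-size block centred on ``centre``; out-of-bounds voxels get
    ``fill_hu``. Total function — any centre is valid."""
    region = CropRegion(
        start=tuple(int(c) - s // 2 for c, s in zip(centre, crop_size)),
        size=tuple(int(s) for s in crop_size),
        original_shape=ct.shape,
        fill_hu=fill_hu,
    )
    arr = np.asarray(ct.voxels)
    if np.issubdtype(arr.dtype, np.floating):
        dtype = arr.dtype
    elif (
        np.issubdtype(arr.dtype, np.integer)
        and float(fill_hu).is_integer()
        and np.iinfo(arr.dtype).min <= fill_hu <= np.iinfo(arr.dtype).max
    ):
        dtype = arr.dtype
    else:
        dtype = np.float32
    out = np.full(region.size, fill_hu, dtype=dtype)
    src, dst = _overlap_slices(region)
    out[dst] = arr[src]
    origin = tuple(
        ct.origin[a] + region.start[a] * ct.spacing[a] for a in range(3)
    )
    return ImageVolume(out, ct.spacing, origin, modality=ct.modality), region


def _overlap_slices(region: CropRegion) -> tuple[tuple[slice, ...], tuple[slice, ...]]:
    """Source (original-grid) and destination (crop-grid) slices of the overlap."""
    src, dst = [], []
    for a in range(3):
        s0 = region.start[a]
        lo = max(0, s0)
        hi = min(region.original_shape[a], s0 + region.size[a])
        if hi <= lo:  # crop entirely outside
            src.append(slice(0, 0))
            dst.append(slice(0, 0))
        else:
            src.append(slice(lo, hi))
            dst.append(slice(lo - s0, hi - s0))
    return tuple(src), tuple(dst)


def remove_metal_artifacts(
    ct: ImageVolume,
    threshold_hu: float = 2000.0,
    dilation_mm: float = 3.0,
    replacement_hu: float = 50.0,
) -> ImageVolume:
    """Replace high-density (metal) voxels with soft tissue.

    The above-threshold mask is dilated by ``dilation_mm`` (spacing-aware
    spherical dilation), smoothed with a 1-voxel Gaussian and re-thresholded at
    0.5, then every voxel in the resulting mask (always including the original
    metal voxels) is set to ``replacement_hu``. Idempotent as long as
    ``replacement_hu`` is below the threshold.
    """
    hu = np.asarray(ct.voxels)
    metal = hu > threshold_hu
    if not metal.any():
        return ImageVolume(hu.copy(), ct.spacing, ct.origin, ct.modality)
    dilated = ndimage.distance_transform_edt(~metal, sampling=ct.spacing) <= dilation_mm
    smoothed = ndimage.gaussian_filter(dilated.astype(np.float32), sigma=1.0) >= 0.5
    mask = smoothed | metal
    out = hu.astype(np.float32, copy=True)
    out[mask] = replacement_hu
    if np.issubdtype(hu.dtype, np.integer):
        out = np.rint(out).astype(hu.dtype)
    return ImageVolume(out, ct.spacing, ct.origin, ct.modality)


def normalize_channels(
    ct: ImageVolume,
    windows: tuple[WindowSpec, ...] = DEFAULT_WINDOWS,
) -> np.ndarray:
    """Stack per-window normalised copies of the CT as channels.

    Returns a float32 array of shape ``(len(windows), *ct.shape)`` with values
    in [0, 1]; per channel, HU at the window's lower edge maps to 0, the level
    to 0.5, and the upper edge to 1 (clipped outside).
    """
    return np.stack([w.apply(ct.voxels) for w in windows]).astype(np.float32)
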