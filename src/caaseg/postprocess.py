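"""Mask postprocessing: morphological cleaning, CAA assembly, grid restoration.

Inferred substructure masks are cleaned individually (binary opening with a
spherical element, then removal of small connected components) *before* being
united into the cardiac avoidance area — opening the thin coronary tubes after
the union would behave differently. The cleaned masks are finally padded back
from the crop to the original image matrix.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import GridMismatchError, MissingStructureError
from .preprocess import CropRegion, _overlap_slices
from .volume_io import CAA_MEMBERS, StructureSet, as_mask

_CONN = {6: ndimage.generate_binary_structure(3, 1), 26: ndimage.generate_binary_structure(3, 3)}


def _spherical_element(radius_mm: float, spacing) -> np.ndarray:
    """Spacing-aware ellipsoidal structuring element of physical radius ``radius_mm``."""
    spacing = np.asarray(spacing, dtype=float)
    half = np.maximum(np.floor(radius_mm / spacing).astype(int), 0)
    axes = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    return (X**2 + Y**2 + Z**2) <= radius_mm**2 + 1e-9


def clean_structure(
    mask: np.ndarray,
    spacing,
    opening_mm: float | None = None,
    min_component_cc: float = 0.05,
    connectivity: int = 26,
) -> np.ndarray:
    """Binary opening followed by small-component removal.

    ``opening_mm`` defaults to the smallest voxel spacing (a one-voxel-equivalent
    element); components below ``min_component_cc`` cm^3 under the given
    connectivity (26 by default) are dropped. Anti-extensive and idempotent;
    an empty mask passes through untouched.
    """
    mask = as_mask(mask).astype(bool)
    if not mask.any():
        return mask.astype(np.uint8)
    spacing = tuple(float(s) for s in spacing)
    if opening_mm is None:
        opening_mm = min(spacing)
    if opening_mm > 0:
        elem = _spherical_element(opening_mm, spacing)
        if elem.sum() > 1:
            mask = ndimage.binary_opening(mask, structure=elem)
    if min_component_cc > 0 and mask.any():
        voxel_cc = float(np.prod(spacing)) / 1000.0
        min_vox = min_component_cc / voxel_cc
        lab, n = ndimage.label(mask, structure=_CONN[connectivity])
        if n:
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
            keep = np.flatnonzero(sizes >= min_vox) + 1
            mask = np.isin(lab, keep)
    return mask.astype(np.uint8)


def assemble_caa(structures: StructureSet | dict) -> np.ndarray:
    """Voxelwise union of the four CAA substructures.

    Requires RightAtrium, AorticValveRoot, LCA and RCA; raises naming the first
    missing one. The union is a superset of each constituent by construction.
    """
    get = structures.structures if isinstance(structures, StructureSet) else structures
    caa = None
    for name in CAA_MEMBERS:
        if name not in get:
            raise MissingStructureError(f"cannot assemble CAA: missing substructure {name!r}")
        m = as_mask(get[name]).astype(bool)
        caa = m if caa is None else (caa | m)
    return caa.astype(np.uint8)


def pad_to_original(mask: np.ndarray, region: CropRegion) -> np.ndarray:
    """Place a crop-grid mask back on the original grid (zeros elsewhere).

    Content that was clipped at the crop edge stays clipped — the crop is lossy
    for structures extending beyond it.
    """
    mask = np.asarray(mask)
    if tuple(mask.shape) != tuple(region.size):
        raise GridMismatchError(
            f"mask shape {mask.shape} does not match crop size {region.size}"
        )
    out = np.zeros(region.original_shape, dtype=mask.dtype)
    src, dst = _overlap_slices(region)
    out[src] = mask[dst]
    return out
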