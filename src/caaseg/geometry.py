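"""Spacing-aware contour comparison metrics: MSD, HD, HD95 and DSC.

The mean surface distance between two surfaces S and S' is the symmetric pooled
mean

    MSD = ( sum_{p in S} d(p, S') + sum_{p' in S'} d(p', S) ) / (n_S + n_S'),

where d(p, S') is the minimum Euclidean distance (mm) from a point of one
surface to the other surface. HD is the maximum over both directed point sets;
HD95 the 95th percentile (linear interpolation) of the same pooled set —
excluding the 5% of points that are furthest apart makes it robust to outliers.

A surface is the set of centres of foreground voxels with at least one
background 6-neighbour; the grid boundary counts as background. Distances are
evaluated with an exact Euclidean distance transform honouring anisotropic
spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, GridMismatchError

_CROSS = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass(frozen=True)
class SurfaceDistanceResult:
    """MSD/HD/HD95 (mm) plus the directed distance multisets behind them."""

    msd: float
    hd: float
    hd95: float
    n_s: int
    n_s_prime: int
    distances_ab: np.ndarray  # d(p, S') for p in S
    distances_ba: np.ndarray  # d(p', S) for p' in S'


def _surface_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    # border_value=0: voxels outside the grid are background, so foreground
    # voxels on the grid boundary are surface voxels.
    interior = ndimage.binary_erosion(mask, structure=_CROSS, border_value=0)
    return mask & ~interior


def extract_surface_points(mask: np.ndarray, spacing) -> np.ndarray:
    """Physical (mm) coordinates of the surface voxel centres, shape (n, 3)."""
    mask = np.asarray(mask)
    if not mask.any():
        raise DegenerateInputError("cannot extract a surface from an empty mask")
    pts = np.argwhere(_surface_mask(mask)).astype(float)
    return pts * np.asarray(spacing, dtype=float)


def surface_distances(mask_a: np.ndarray, mask_b: np.ndarray, spacing) -> SurfaceDistanceResult:
    """Symmetric surface-distance metrics between two masks on one grid."""
    mask_a, mask_b = np.asarray(mask_a), np.asarray(mask_b)
    if mask_a.shape != mask_b.shape:
        raise GridMismatchError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    if not mask_a.any() or not mask_b.any():
        raise DegenerateInputError("surface distances are undefined for empty masks")
    surf_a = _surface_mask(mask_a)
    surf_b = _surface_mask(mask_b)
    spacing = tuple(float(s) for s in spacing)
    # distance from every voxel centre to the nearest surface voxel centre of the other mask
    dt_b = ndimage.distance_transform_edt(~surf_b, sampling=spacing)
    dt_a = ndimage.distance_transform_edt(~surf_a, sampling=spacing)
    d_ab = dt_b[surf_a]
    d_ba = dt_a[surf_b]
    pooled = np.concatenate([d_ab, d_ba])
    return SurfaceDistanceResult(
        msd=float(pooled.mean()),
        hd=float(pooled.max()),
        hd95=float(np.percentile(pooled, 95.0)),
        n_s=int(d_ab.size),
        n_s_prime=int(d_ba.size),
        distances_ab=d_ab,
        distances_ba=d_ba,
    )


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|).

    Two empty masks agree perfectly (1.0); empty vs non-empty is 0.0.
    """
    mask_a, mask_b = np.asarray(mask_a).astype(bool), np.asarray(mask_b).astype(bool)
    if mask_a.shape != mask_b.shape:
        raise GridMismatchError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    total = int(mask_a.sum()) + int(mask_b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((mask_a & mask_b).sum()) / total


def contour_metrics(mask_a: np.ndarray, mask_b: np.ndarray, spacing) -> dict[str, float]:
    """Convenience: {'msd_mm', 'dsc', 'hd95_mm', 'hd_mm'} in one call."""
    sd = surface_distances(mask_a, mask_b, spacing)
    return {
        "msd_mm": sd.msd,
        "dsc": dice(mask_a, mask_b),
        "hd95_mm": sd.hd95,
        "hd_mm": sd.hd,
    }
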