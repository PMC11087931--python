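"""Synthetic thorax phantoms with cardiac-substructure ground truth.

The phantom stands in for planning CT data: an elliptical soft-tissue body with
two low-density lungs, a vertebral column, an oesophagus, a heart between the
lungs, and — inside the heart — the four constituents of the cardiac avoidance
area (CAA): the right atrium, the aortic valve root, and the proximal left and
right coronary arteries contoured 7 mm wide over their first 2 cm. A tumour
(PTV/ITV) sits in one lung so that synthetic plans have a target. Optional
extras: IV-contrast enhancement of the blood pool (on by default, as it is for
the vast majority of clinical thorax planning scans), and a metal artefact.

Also provided: simulated manual observers (smooth boundary perturbations of the
truth), Bernoulli rater corruptions for consensus-recovery experiments, and a
synthetic dose grid emulating a CAA-sparing plan.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, ParameterError, ValidationError
from .volume_io import CAA_MEMBERS, Grid, ImageVolume, StructureSet

#: Default tissue palette (HU). Typical diagnostic-CT values.
DEFAULT_HU = {
    "air": -1000,
    "lung": -800,
    "soft": 40,
    "myocardium": 40,
    "blood": 200,
    "fat": -80,
    "bone": 700,
    "metal": 3000,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry + tissue recipe for one synthetic thorax.

    All physical sizes are mm. The default grid (128x128x64 at 1.5x1.5x3.0 mm)
    matches the auto-contouring crop size so the cropping stage is exercised
    without rescaling; :meth:`desk` gives a coarser grid of the same physical
    extent for fast tests.
    """

    shape: tuple[int, int, int] = (128, 128, 64)
    spacing: tuple[float, float, float] = (1.5, 1.5, 3.0)
    hu: dict = field(default_factory=lambda: dict(DEFAULT_HU))
    ra_axes_mm: tuple[float, float, float] = (17.0, 19.0, 15.0)
    avr_radius_mm: float = 11.0
    avr_height_mm: float = 22.0
    coronary_width_mm: float = 7.0
    coronary_length_mm: float = 20.0
    contrast: bool = True
    metal: bool = False
    noise_hu: float = 12.0
    jitter_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in self.hu.items():
            if not -1024 <= value <= 3071:
                raise ValidationError(f"HU for {name!r} outside [-1024, 3071]: {value}")
        if self.coronary_width_mm <= 0 or self.coronary_length_mm <= 0:
            raise ValidationError("coronary width/length must be positive")
        if self.noise_hu < 0 or self.jitter_mm < 0:
            raise ValidationError("noise_hu and jitter_mm must be >= 0")

    @classmethod
    def desk(cls, seed: int = 0, **kwargs) -> "PhantomSpec":
        """Desk-scale profile: 64x64x32 voxels at (3, 3, 6) mm — same physical extent."""
        return cls(shape=(64, 64, 32), spacing=(3.0, 3.0, 6.0), seed=seed, **kwargs)


@dataclass(frozen=True)
class ObserverModel:
    """Simulated manual observer: smooth signed perturbation of the true boundary.

    ``bias_mm`` shifts the contour surface outward (>0, systematic over-contouring)
    or inward (<0); ``sd_mm`` is the standard deviation of a zero-mean Gaussian
    random field with correlation length ``corr_mm`` added on top, mimicking the
    smooth, spatially correlated disagreement of human raters.
    """

    bias_mm: float = 0.0
    sd_mm: float = 1.5
    corr_mm: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_mm < 0:
            raise ParameterError("observer noise sd must be >= 0")
        if self.corr_mm <= 0:
            raise ParameterError("noise correlation length must be > 0")


# ---------------------------------------------------------------------------
# geometric primitives (all take physical-coordinate grids X, Y, Z in mm)
# ---------------------------------------------------------------------------


def _coords(grid: Grid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [
        grid.origin[a] + np.arange(grid.shape[a]) * grid.spacing[a] for a in range(3)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(X, Y, Z, centre, axes) -> np.ndarray:
    return (
        ((X - centre[0]) / axes[0]) ** 2
        + ((Y - centre[1]) / axes[1]) ** 2
        + ((Z - centre[2]) / axes[2]) ** 2
    ) <= 1.0


def _cylinder_z(X, Y, Z, centre, radius, height) -> np.ndarray:
    return (((X - centre[0]) ** 2 + (Y - centre[1]) ** 2) <= radius**2) & (
        np.abs(Z - centre[2]) <= height / 2.0
    )


def _tube(X, Y, Z, start, direction, length, radius) -> np.ndarray:
    """Capsule-free tube: distance to the segment [start, start+length*direction] <= radius,
    with the axial coordinate clamped to [0, length] (flat ends)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    px, py, pz = X - start[0], Y - start[1], Z - start[2]
    t = px * d[0] + py * d[1] + pz * d[2]
    within = (t >= 0) & (t <= length)
    cx, cy, cz = px - t * d[0], py - t * d[1], pz - t * d[2]
    return within & (cx**2 + cy**2 + cz**2 <= radius**2)


# ---------------------------------------------------------------------------
# thorax generation
# ---------------------------------------------------------------------------


def generate_thorax_phantom(spec: PhantomSpec) -> tuple[ImageVolume, StructureSet]:
    """Build one thorax CT plus its ground-truth structure set (observer ``"truth"``).

    The structure set contains the four CAA substructures (mutually exclusive),
    the derived CAA union, and the auxiliary planning structures WholeHeart,
    Lungs, PTV, ITV, SpinalCord and Oesophagus.
    """
    grid = Grid(spec.shape, spec.spacing)
    X, Y, Z = _coords(grid)
    extent = np.asarray(spec.shape) * np.asarray(spec.spacing)  # physical size, mm
    centre = (np.asarray(spec.shape) - 1) * np.asarray(spec.spacing) / 2.0
    rng = np.random.default_rng(spec.seed)
    hu = spec.hu

    heart_c = centre + np.array([6.0, -8.0, 0.0])
    heart_c = heart_c + rng.uniform(-spec.jitter_mm, spec.jitter_mm, size=3)
    heart_axes = np.array([38.0, 35.0, 45.0])

    # the heart template must fit inside the grid
    if np.any(heart_c - heart_axes < -1e-6) or np.any(heart_c + heart_axes > extent + 1e-6):
        raise ValidationError(
            f"grid {spec.shape}@{spec.spacing} too small to contain the heart template"
        )

    body = _ellipsoid(X, Y, Z, centre, (0.46 * extent[0], 0.40 * extent[1], 10 * extent[2]))
    fat = body & ~_ellipsoid(
        X, Y, Z, centre, (0.46 * extent[0] - 6.0, 0.40 * extent[1] - 6.0, 10 * extent[2])
    )
    lung_dx = 0.23 * extent[0]
    lung_axes = (0.15 * extent[0], 0.27 * extent[1], 0.42 * extent[2])
    lung_jit = rng.uniform(-spec.jitter_mm, spec.jitter_mm, size=(2, 3))
    lung_l = _ellipsoid(X, Y, Z, centre + np.array([+lung_dx, -4.0, 0]) + lung_jit[0], lung_axes)
    lung_r = _ellipsoid(X, Y, Z, centre + np.array([-lung_dx, -4.0, 0]) + lung_jit[1], lung_axes)

    heart = _ellipsoid(X, Y, Z, heart_c, heart_axes)
    lung_l &= ~heart
    lung_r &= ~heart
    lungs = lung_l | lung_r

    spine_c = centre + np.array([0.0, 0.30 * extent[1], 0.0])
    spine = _cylinder_z(X, Y, Z, spine_c, 14.0, 10 * extent[2]) & body
    cord = _cylinder_z(X, Y, Z, spine_c, 4.5, 10 * extent[2])
    oeso_c = centre + np.array([2.0, 0.17 * extent[1], 0.0])
    oesophagus = _cylinder_z(X, Y, Z, oeso_c, 5.0, 10 * extent[2]) & body & ~spine

    # tumour in the right (patient) lung = low-x lung
    ptv_c = centre + np.array([-lung_dx, -4.0, 6.0]) + lung_jit[1] + rng.uniform(
        -spec.jitter_mm, spec.jitter_mm, size=3
    )
    itv = _ellipsoid(X, Y, Z, ptv_c, (9.0, 9.0, 11.0))
    ptv = _ellipsoid(X, Y, Z, ptv_c, (14.0, 14.0, 16.0))

    # --- CAA substructures (heart-local frame) -------------------------------
    ra = _ellipsoid(X, Y, Z, heart_c + np.array([-14.0, 6.0, -8.0]), spec.ra_axes_mm)
    avr_c = heart_c + np.array([4.0, -2.0, 12.0])
    avr = _cylinder_z(X, Y, Z, avr_c, spec.avr_radius_mm, spec.avr_height_mm)
    r_cor = spec.coronary_width_mm / 2.0
    lca_start = avr_c + np.array([spec.avr_radius_mm + 1.5, 2.0, -2.0])
    lca = _tube(X, Y, Z, lca_start, (0.75, 0.45, -0.55), spec.coronary_length_mm, r_cor)
    rca_start = avr_c + np.array([-(spec.avr_radius_mm + 2.5), 2.0, -2.0])
    rca = _tube(X, Y, Z, rca_start, (-0.35, -0.8, -0.48), spec.coronary_length_mm, r_cor)

    # mutual exclusivity: registry order wins
    labels = np.zeros(spec.shape, dtype=np.uint8)
    for value, mask in enumerate((ra, avr, lca, rca), start=1):
        labels[mask & (labels == 0)] = value

    # --- CT assembly ----------------------------------------------------------
    ct = np.full(spec.shape, hu["air"], dtype=np.float32)
    ct[body] = hu["soft"]
    ct[fat] = hu["fat"]
    ct[lungs] = hu["lung"]
    ct[itv | ptv] = hu["soft"]  # tumour is soft-tissue density inside lung (PTV margin kept soft)
    ct[spine] = hu["bone"]
    ct[cord & spine] = hu["soft"]
    ct[oesophagus] = hu["soft"] - 10
    ct[heart] = hu["myocardium"]
    blood_hu = hu["blood"] if spec.contrast else hu["myocardium"]
    ct[labels > 0] = blood_hu
    if spec.metal:
        metal_c = centre + np.array([0.0, -0.36 * extent[1], 0.0])
        ct[_ellipsoid(X, Y, Z, metal_c, (4.0, 4.0, 6.0))] = hu["metal"]
    if spec.noise_hu > 0:
        noise = rng.standard_normal(spec.shape).astype(np.float32)
        noise = ndimage.gaussian_filter(noise, sigma=0.6)
        noise *= spec.noise_hu / max(noise.std(), 1e-9)
        ct = ct + noise
    ct = np.clip(ct, -1024, 3071).astype(np.int16)

    truth = StructureSet(grid=grid, structures={}, observer="truth")
    for name, value in zip(CAA_MEMBERS, range(1, 5)):
        truth.add(name, (labels == value).astype(np.uint8))
    truth.add("CAA", (labels > 0).astype(np.uint8))
    truth.add("WholeHeart", heart.astype(np.uint8))
    truth.add("Lungs", lungs.astype(np.uint8))
    truth.add("PTV", ptv.astype(np.uint8))
    truth.add("ITV", itv.astype(np.uint8))
    truth.add("SpinalCord", (cord & spine).astype(np.uint8))
    truth.add("Oesophagus", oesophagus.astype(np.uint8))
    volume = ImageVolume(ct, spec.spacing, modality="CT")
    return volume, truth


# ---------------------------------------------------------------------------
# simulated observers
# ---------------------------------------------------------------------------


def _signed_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """Signed Euclidean distance (mm): negative inside, positive outside."""
    mask = mask.astype(bool)
    d_out = ndimage.distance_transform_edt(~mask, sampling=spacing)
    d_in = ndimage.distance_transform_edt(mask, sampling=spacing)
    return (d_out - d_in).astype(np.float64)


def simulate_observer_contour(
    truth_mask: np.ndarray,
    observer: ObserverModel,
    spacing: tuple[float, float, float],
) -> np.ndarray:
    """Perturb a truth mask the way a human observer would re-draw it.

    The true boundary (zero level set of the signed distance) is shifted by
    ``bias_mm`` plus a smooth correlated Gaussian field of sd ``sd_mm``. With
    bias 0 and sd 0 the truth is returned unchanged.
    """
    truth_mask = np.asarray(truth_mask)
    if not truth_mask.any():
        raise DegenerateInputError("cannot simulate an observer on an empty truth mask")
    if observer.bias_mm == 0.0 and observer.sd_mm == 0.0:
        return truth_mask.astype(np.uint8)
    sdf = _signed_distance(truth_mask, spacing)
    shift = float(observer.bias_mm)
    if observer.sd_mm > 0:
        rng = np.random.default_rng(observer.seed)
        white = rng.standard_normal(truth_mask.shape)
        sigma_vox = [observer.corr_mm / s for s in spacing]
        smooth = ndimage.gaussian_filter(white, sigma=sigma_vox)
        smooth /= max(smooth.std(), 1e-12)
        shift = shift + observer.sd_mm * smooth
    return (sdf <= shift).astype(np.uint8)


def simulate_rater_flip(
    truth_mask: np.ndarray,
    sensitivity: float,
    specificity: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Independent Bernoulli rater: keep foreground w.p. ``sensitivity``, flip
    background on w.p. ``1 - specificity``. Requires both parameters in (0.5, 1]
    (at or below 0.5 the rater is non-identifiable)."""
    if not (0.5 < sensitivity <= 1.0) or not (0.5 < specificity <= 1.0):
        raise ParameterError("sensitivity and specificity must lie in (0.5, 1]")
    truth_mask = np.asarray(truth_mask).astype(bool)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(truth_mask.shape)
    out = np.where(truth_mask, u < sensitivity, u < (1.0 - specificity))
    return out.astype(np.uint8)


# ---------------------------------------------------------------------------
# synthetic dose
# ---------------------------------------------------------------------------


def generate_dose_grid(
    structures: StructureSet,
    prescription_gy: float = 55.0,
    caa_limit_gy: float = 19.5,
    seed: int = 0,
    suppress_caa: bool = True,
    caa_name: str = "CAA",
    falloff_mm: float = 22.0,
    noise_gy: float = 0.4,
) -> ImageVolume:
    """Smooth synthetic dose field emulating a CAA-sparing plan.

    Prescription dose (default 55 Gy, the 20-fraction schedule the panel
    assumes) covers the PTV; dose falls off exponentially with distance from
    the PTV surface; with ``suppress_caa`` the field is additionally capped at
    ``caa_limit_gy`` (default 19.5 Gy maximum-dose objective) inside the CAA,
    with a smooth shoulder outside it. Deterministic given the seed.
    """
    if "PTV" not in structures:
        raise ValidationError("dose generation requires a PTV structure")
    if caa_name not in structures:
        raise ValidationError(f"dose generation requires a {caa_name!r} structure")
    grid = structures.grid
    spacing = grid.spacing
    ptv = structures["PTV"].astype(bool)
    caa = structures[caa_name].astype(bool)
    rng = np.random.default_rng(seed)

    dist = ndimage.distance_transform_edt(~ptv, sampling=spacing)
    dose = prescription_gy * np.exp(-dist / falloff_mm)
    if noise_gy > 0:
        noise = ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma=2.0)
        noise *= noise_gy / max(noise.std(), 1e-12)
        dose = dose + noise
        # keep the target tightly at prescription despite noise
        dose[ptv] = prescription_gy + 0.2 * noise[ptv]

    if suppress_caa:
        caa_eff = caa
        if (caa & ptv).any():
            warnings.warn(
                "PTV and CAA overlap: PTV coverage takes priority over the CAA limit",
                stacklevel=2,
            )
            caa_eff = caa & ~ptv
        ramp = ndimage.gaussian_filter(caa_eff.astype(np.float64), sigma=2.0)
        ramp = np.clip(1.6 * ramp / max(ramp.max(), 1e-12), 0.0, 1.0)
        w = np.maximum(ramp, caa_eff)  # exactly 1 inside the CAA, smooth shoulder outside
        dose = dose - w * np.maximum(dose - caa_limit_gy, 0.0)

    dose = np.maximum(dose, 0.0).astype(np.float32)
    return ImageVolume(dose, spacing, grid.origin, modality="DOSE")
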