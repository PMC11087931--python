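"""DVH curves and dose metrics vs sorted-voxel oracles."""

import numpy as np
import pytest

from caaseg.dosimetry import (
    DEFAULT_PANEL,
    cumulative_dvh,
    dvh_metric,
    gy_to_cgy,
    plan_metric_panel,
)
from caaseg.errors import DegenerateInputError, MissingStructureError, UndefinedMetricError
from caaseg.volume_io import Grid, ImageVolume, StructureSet

SPACING = (2.0, 2.0, 2.5)  # voxel volume 0.01 cm^3


def _dose(voxels):
    return ImageVolume(np.asarray(voxels, np.float64), SPACING, modality="DOSE")


def test_uniform_dose_closed_forms():
    shape = (10, 10, 10)
    dose = _dose(np.full(shape, 10.0))
    mask = np.ones(shape, np.uint8)
    assert dvh_metric(dose, mask, "D95") == 10.0
    assert dvh_metric(dose, mask, "mean") == 10.0
    assert dvh_metric(dose, mask, "max") == 10.0
    assert dvh_metric(dose, mask, "min") == 10.0
    assert dvh_metric(dose, mask, "V5Gy") == 100.0
    assert dvh_metric(dose, mask, "V10Gy") == 100.0
    assert dvh_metric(dose, mask, "V11Gy") == 0.0
    curve = cumulative_dvh(dose, mask)
    assert curve.relative_volume_pct[0] == 100.0
    assert curve.relative_volume_pct[curve.bin_edges_gy > 10.0].max() == 0.0


def test_two_level_field_matches_sorted_oracle(rng):
    shape = (20, 20, 10)
    vox = np.zeros(shape)
    vox[:10] = 20.0  # half at 20 Gy, half at 0
    dose = _dose(vox)
    mask = np.ones(shape, np.uint8)
    assert dvh_metric(dose, mask, "V10Gy") == 50.0
    assert dvh_metric(dose, mask, "D95") == 0.0
    assert dvh_metric(dose, mask, "D50") == 20.0
    sorted_doses = np.sort(vox.reshape(-1))
    n = sorted_doses.size
    k = int(np.ceil(1.0 / dose.voxel_volume_cm3))
    assert dvh_metric(dose, mask, "1cc_max") == sorted_doses[n - k]
    assert dvh_metric(dose, mask, "1cc_min") == sorted_doses[k - 1]


def test_hot_spot_smaller_than_1cc_is_excluded():
    """0.5 cm^3 at 30 Gy inside a 10 Gy structure: the 1-cc max stays at 10 Gy."""
    shape = (10, 10, 10)  # 10 cm^3 structure
    vox = np.full(shape, 10.0)
    vox[:5, :5, :2] = 30.0  # 50 voxels = 0.5 cm^3
    dose = _dose(vox)
    mask = np.ones(shape, np.uint8)
    assert dvh_metric(dose, mask, "max") == 30.0
    assert dvh_metric(dose, mask, "1cc_max") == 10.0


def test_small_structure_1cc_undefined():
    shape = (4, 4, 5)  # 0.8 cm^3
    dose = _dose(np.full(shape, 10.0))
    with pytest.raises(UndefinedMetricError):
        dvh_metric(dose, np.ones(shape, np.uint8), "1cc_max")


def test_dvh_curve_nonincreasing_and_mean_consistent(rng):
    shape = (12, 12, 8)
    dose = _dose(rng.random(shape) * 60.0)
    mask = (rng.random(shape) < 0.5).astype(np.uint8)
    curve = cumulative_dvh(dose, mask)
    assert (np.diff(curve.relative_volume_pct) <= 0).all()
    assert curve.relative_volume_pct[0] == 100.0
    direct_mean = dose.voxels[mask.astype(bool)].mean()
    assert dvh_metric(dose, mask, "mean") == pytest.approx(direct_mean, abs=1e-12)


def test_dx_and_vx_monotone(rng):
    shape = (12, 12, 8)
    dose = _dose(rng.random(shape) * 60.0)
    mask = np.ones(shape, np.uint8)
    ds = [dvh_metric(dose, mask, f"D{x}") for x in (5, 25, 50, 75, 95)]
    assert all(a >= b for a, b in zip(ds, ds[1:]))
    vs = [dvh_metric(dose, mask, f"V{x}Gy") for x in (5, 15, 30, 45)]
    assert all(a >= b for a, b in zip(vs, vs[1:]))
    assert dvh_metric(dose, mask, "1cc_max") <= dvh_metric(dose, mask, "max")
    assert dvh_metric(dose, mask, "1cc_min") >= dvh_metric(dose, mask, "min")


def test_empty_mask_rejected():
    dose = _dose(np.zeros((4, 4, 4)))
    with pytest.raises(DegenerateInputError):
        cumulative_dvh(dose, np.zeros((4, 4, 4), np.uint8))


def test_panel_with_derived_structures(rng):
    shape = (16, 16, 12)
    grid = Grid(shape, SPACING)
    ss = StructureSet(grid=grid, structures={}, observer="truth")
    lungs = np.zeros(shape, np.uint8)
    lungs[:8] = 1
    ptv = np.zeros(shape, np.uint8)
    ptv[2:6, 2:6, 2:6] = 1
    ss.add("Lungs", lungs)
    ss.add("PTV", ptv)
    dose = _dose(np.full(shape, 10.0))
    panel = (("Lungs-PTV", "mean"), ("PTV", "mean"))
    table = plan_metric_panel(dose, ss, panel=panel, patient="p0")
    assert len(table) == 2
    assert set(table["metric"]) == {"Lungs-PTV mean", "PTV mean"}
    # set identity: |Lungs-PTV| = |Lungs| - |Lungs ∩ PTV|
    lp = lungs.astype(bool) & ~ptv.astype(bool)
    assert lp.sum() == lungs.sum() - (lungs.astype(bool) & ptv.astype(bool)).sum()


def test_missing_structure_names_metric():
    grid = Grid((4, 4, 4), SPACING)
    ss = StructureSet(grid=grid, structures={"PTV": np.ones((4, 4, 4), np.uint8)})
    dose = _dose(np.zeros((4, 4, 4)))
    with pytest.raises(MissingStructureError, match="CAA max"):
        plan_metric_panel(dose, ss, panel=(("CAA", "max"),))


def test_default_panel_membership():
    metrics = {f"{s} {m}" for s, m in DEFAULT_PANEL}
    assert "CAA max" in metrics and "CAA 1cc_max" in metrics
    assert "Oesophagus V55Gy" in metrics and "Lungs-PTV V20Gy" in metrics


def test_unit_converters():
    assert gy_to_cgy(19.5) == 1950.0
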