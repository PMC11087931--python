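"""Dose-volume histograms and the plan dose-metric panel.

Volume-referenced metrics (Dx%, VxGy, 1-cc max/min) are computed from the
exact sorted in-structure voxel doses — binned DVH curves are for plotting
only, which removes any bin-width ambiguity:

* ``Dx%``     — the largest dose d such that at least x% of the structure
                receives >= d (the x%-coverage dose).
* ``VxGy``    — the percentage of the structure receiving >= x Gy.
* ``1-cc max``— near-maximum dose: the largest d covering >= 1 cm^3.
* ``1-cc min``— near-minimum dose: the smallest d such that >= 1 cm^3
                receives <= d (i.e. the minimum after excluding the coldest
                volume beyond 1 cm^3).

Internal dose unit is Gy throughout; a cGy converter is provided for tables
printed in centigray. Masks are binary — partial-voxel overlap is ignored and
no dose interpolation is performed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    GridMismatchError,
    MissingStructureError,
    ParameterError,
    UndefinedMetricError,
)
from .volume_io import ImageVolume, StructureSet

#: The default commissioning dose-metric panel: (structure, metric) pairs over
#: target, cord, lungs, heart, CAA and oesophagus. Derived structures
#: ("Lungs-PTV", "Lungs-ITV") are set differences computed on the fly.
DEFAULT_PANEL: tuple[tuple[str, str], ...] = (
    ("PTV", "1cc_min"),
    ("PTV", "D95"),
    ("PTV", "1cc_max"),
    ("PTV", "mean"),
    ("SpinalCord", "max"),
    ("SpinalCord", "1cc_max"),
    ("Lungs-PTV", "V5Gy"),
    ("Lungs-PTV", "V10Gy"),
    ("Lungs-PTV", "V20Gy"),
    ("Lungs-ITV", "mean"),
    ("WholeHeart", "V30Gy"),
    ("WholeHeart", "V40Gy"),
    ("CAA", "max"),
    ("CAA", "1cc_max"),
    ("Oesophagus", "mean"),
    ("Oesophagus", "V55Gy"),
)


def gy_to_cgy(value_gy: float) -> float:
    return 100.0 * value_gy


def cgy_to_gy(value_cgy: float) -> float:
    return value_cgy / 100.0


@dataclass(frozen=True)
class DvhCurve:
    """Cumulative DVH: volume receiving at least each dose level."""

    structure: str
    bin_edges_gy: np.ndarray  # length nbins+1
    relative_volume_pct: np.ndarray  # volume(>= edge), %
    absolute_volume_cc: np.ndarray
    voxel_volume_cc: float

    @property
    def total_volume_cc(self) -> float:
        return float(self.absolute_volume_cc[0])


def _in_structure_doses(dose: ImageVolume, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if mask.shape != dose.shape:
        raise GridMismatchError("dose grid and mask must share one grid")
    if not mask.any():
        raise DegenerateInputError("DVH is undefined for an empty structure")
    return np.asarray(dose.voxels, dtype=np.float64)[mask]


def cumulative_dvh(
    dose: ImageVolume, mask: np.ndarray, bin_width_gy: float = 0.1, structure: str = ""
) -> DvhCurve:
    """Exact voxel-counting cumulative DVH; starts at 100% at 0 Gy."""
    if bin_width_gy <= 0:
        raise ParameterError("bin width must be > 0")
    doses = np.sort(_in_structure_doses(dose, mask))
    n = doses.size
    top = max(float(doses[-1]), 0.0) + bin_width_gy
    edges = np.arange(0.0, top + bin_width_gy, bin_width_gy)
    # volume with dose >= edge; searchsorted('left') counts doses < edge
    counts = n - np.searchsorted(doses, edges, side="left")
    vox_cc = dose.voxel_volume_cm3
    return DvhCurve(
        structure=structure,
        bin_edges_gy=edges,
        relative_volume_pct=100.0 * counts / n,
        absolute_volume_cc=counts * vox_cc,
        voxel_volume_cc=vox_cc,
    )


_D_RE = re.compile(r"^D(\d+(?:\.\d+)?)%?$")
_V_RE = re.compile(r"^V(\d+(?:\.\d+)?)Gy$", re.IGNORECASE)


def dvh_metric(dose: ImageVolume, mask: np.ndarray, metric: str) -> float:
    """Evaluate one dose metric from the sorted voxel doses (not binned).

    ``metric``: ``max``, ``min``, ``mean``, ``Dx`` / ``Dx%`` (Gy), ``VxGy``
    (%), ``1cc_max``, ``1cc_min`` (Gy).
    """
    doses = np.sort(_in_structure_doses(dose, mask))
    n = doses.size
    vox_cc = dose.voxel_volume_cm3
    if metric == "max":
        return float(doses[-1])
    if metric == "min":
        return float(doses[0])
    if metric == "mean":
        return float(doses.mean())
    m = _D_RE.match(metric)
    if m:
        x = float(m.group(1))
        if not 0 < x <= 100:
            raise ParameterError(f"Dx percentage out of range in {metric!r}")
        # largest d with >= x% of voxels at dose >= d: the ceil(x*n/100)-th largest
        k = int(np.ceil(x * n / 100.0))
        return float(doses[n - k])
    m = _V_RE.match(metric)
    if m:
        x = float(m.group(1))
        return float(100.0 * (doses >= x).sum() / n)
    if metric in ("1cc_max", "1cc_min"):
        k = int(np.ceil(1.0 / vox_cc))
        if n * vox_cc < 1.0:
            raise UndefinedMetricError(
                f"{metric}: structure volume {n * vox_cc:.2f} cm^3 is below 1 cm^3"
            )
        return float(doses[n - k]) if metric == "1cc_max" else float(doses[k - 1])
    raise ParameterError(f"unrecognised dose metric {metric!r}")


def _resolve_structure(structures: StructureSet, name: str) -> np.ndarray:
    """Fetch a mask, computing 'A-B' set differences on the fly."""
    if name in structures:
        return structures[name].astype(bool)
    if "-" in name:
        base, minus = name.split("-", 1)
        if base in structures and minus in structures:
            return structures[base].astype(bool) & ~structures[minus].astype(bool)
    raise MissingStructureError(f"structure {name!r} not found in set {structures.observer!r}")


def plan_metric_panel(
    dose: ImageVolume,
    structures: StructureSet,
    panel: tuple[tuple[str, str], ...] = DEFAULT_PANEL,
    patient: str = "",
    observer: str | None = None,
) -> pd.DataFrame:
    """Evaluate a (structure, metric) panel on one dose grid.

    Returns a long-format table (patient, observer, structure, metric, value,
    unit). A missing structure raises naming both the structure and metric.
    """
    records = []
    for struct_name, metric in panel:
        try:
            mask = _resolve_structure(structures, struct_name)
        except MissingStructureError as exc:
            raise MissingStructureError(
                f"panel metric {struct_name} {metric}: {exc.args[0]}"
            ) from exc
        value = dvh_metric(dose, mask, metric)
        unit = "%" if _V_RE.match(metric) else "Gy"
        records.append(
            {
                "patient": patient,
                "observer": observer if observer is not None else structures.observer,
                "structure": struct_name,
                "metric": f"{struct_name} {metric}",
                "value": value,
                "unit": unit,
            }
        )
    return pd.DataFrame.from_records(records)
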