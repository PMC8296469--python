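"""Dose-volume-histogram metrics and clinical constraint checks.

Conventions (fixed and documented rather than left to the caller):

* ``d_max`` is the single-voxel maximum.  Near-max statistics such as D(1%)
  are available through ``d_levels`` for serial organs where a robust
  near-maximum is preferable.
* ``V(x)`` counts voxels with dose **>= x** (closed at the dose level), so
  V(prescription) includes voxels at exactly the prescription dose.
* ``D(p%)`` follows the order-statistic rule: the dose of the k-th hottest
  voxel with k = ceil(p/100 * n) (clamped to at least 1 voxel).
* Constraint comparisons are strict: value < bound passes, equality fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import EmptyROIError, GeometryError, GridDomainError, SpecificationError
from .grid_io import DoseGrid, VoxelMask

__all__ = [
    "DVHSummary",
    "Constraint",
    "dvh_summary",
    "relative_dmean_diff",
    "check_constraint",
    "DEFAULT_OAR_CONSTRAINTS",
    "summaries_to_frame",
]


@dataclass
class DVHSummary:
    structure: str
    d_max: float
    d_mean: float
    volume_cc: float
    n_voxels: int
    v_at: dict[float, tuple[float, float]] = field(default_factory=dict)  # Gy -> (cc, %)
    d_at: dict[float, float] = field(default_factory=dict)  # % volume -> Gy


@dataclass(frozen=True)
class Constraint:
    """One clinical dose constraint, e.g. Dmax < 54 Gy or V60 < 2 cc.

    metric: 'Dmax' | 'Dmean' | 'V_at_dose_abs' (bound in cc) |
            'V_at_dose_rel' (bound in % of structure volume).
    dose_gy: dose level for V-type metrics (ignored otherwise).
    bound: upper bound; the comparison is strict less-than.
    """

    name: str
    metric: str
    bound: float
    dose_gy: Optional[float] = None

    def __post_init__(self) -> None:
        if self.metric not in ("Dmax", "Dmean", "V_at_dose_abs", "V_at_dose_rel"):
            raise SpecificationError(f"unknown metric {self.metric!r}")
        if self.bound <= 0:
            raise GridDomainError("constraint bound must be > 0")
        if self.metric.startswith("V_at") and self.dose_gy is None:
            raise SpecificationError(f"{self.name}: V-type constraint needs dose_gy")


#: Standard head-and-neck OAR constraint set used by the cohort reports.
DEFAULT_OAR_CONSTRAINTS: tuple[Constraint, ...] = (
    Constraint("Brainstem", "Dmax", 54.0),
    Constraint("Spinal cord", "Dmax", 40.0),
    Constraint("Optic chiasm", "Dmax", 54.0),
    Constraint("Optic nerves", "Dmax", 54.0),
    Constraint("Pituitary", "Dmax", 54.0),
    Constraint("Eyes", "Dmean", 25.0),
    Constraint("Temporal lobes", "V_at_dose_abs", 2.0, dose_gy=60.0),
    Constraint("Parotid glands", "Dmean", 30.0),
    Constraint("Lens", "Dmax", 12.0),
    Constraint("Inner ears", "Dmean", 35.0),
    Constraint("Oral cavity", "Dmean", 38.0),
    Constraint("Mandible", "V_at_dose_rel", 10.0, dose_gy=55.0),
)


def dvh_summary(
    grid: DoseGrid,
    mask: VoxelMask,
    v_levels: Iterable[float] = (),
    d_levels: Iterable[float] = (),
    structure: str = "",
) -> DVHSummary:
    """DVH metrics of ``grid`` restricted to ``mask``.

    v_levels are absolute doses (Gy) for V(x); d_levels are relative volumes
    (%) for D(p%).
    """
    if grid.header != mask.header:
        raise GeometryError("dvh_summary: grid and mask headers differ")
    if mask.count == 0:
        raise EmptyROIError(f"dvh_summary: structure {structure!r} has an empty mask")
    doses = grid.values[mask.flags]
    n = doses.size
    vol_cc = n * grid.header.voxel_volume_cc
    out = DVHSummary(
        structure=structure,
        d_max=float(doses.max()),
        d_mean=float(doses.mean()),
        volume_cc=vol_cc,
        n_voxels=n,
    )
    for x in v_levels:
        cnt = int(np.count_nonzero(doses >= x))
        out.v_at[float(x)] = (cnt * grid.header.voxel_volume_cc, 100.0 * cnt / n)
    d_levels = list(d_levels)
    if d_levels:
        desc = np.sort(doses)[::-1]
        for p in d_levels:
            if not 0 <= p <= 100:
                raise GridDomainError(f"D(p%) needs p in [0, 100], got {p}")
            k = max(1, int(np.ceil(p / 100.0 * n)))
            out.d_at[float(p)] = float(desc[k - 1])
    return out


def relative_dmean_diff(d_mean_tps: float, d_mean_mc: float) -> float:
    """Signed relative mean-dose difference in percent.

    Diff = (Dmean(TPS) - Dmean(MC)) / Dmean(MC) x 100%, negative when the
    evaluated engine underestimates the reference mean dose.
    """
    if d_mean_mc <= 0:
        raise GridDomainError("relative_dmean_diff: reference Dmean must be > 0")
    return 100.0 * (d_mean_tps - d_mean_mc) / d_mean_mc


def check_constraint(summary: DVHSummary, constraint: Constraint) -> bool:
    """Strict comparison of a DVH summary against one constraint."""
    if constraint.metric == "Dmax":
        value = summary.d_max
    elif constraint.metric == "Dmean":
        value = summary.d_mean
    else:
        entry = None
        for level, pair in summary.v_at.items():
            if abs(level - constraint.dose_gy) <= 1e-9:
                entry = pair
                break
        if entry is None:
            raise SpecificationError(
                f"{constraint.name}: summary lacks V({constraint.dose_gy:g} Gy)"
            )
        value = entry[0] if constraint.metric == "V_at_dose_abs" else entry[1]
    return value < constraint.bound


def summaries_to_frame(summaries: Iterable[DVHSummary]) -> pd.DataFrame:
    """Flatten DVH summaries into one row per structure x metric (CSV-ready)."""
    rows = []
    for s in summaries:
        rows.append({"structure": s.structure, "metric": "Dmax_Gy", "value": s.d_max})
        rows.append({"structure": s.structure, "metric": "Dmean_Gy", "value": s.d_mean})
        rows.append({"structure": s.structure, "metric": "volume_cc", "value": s.volume_cc})
        for x, (cc, pct) in s.v_at.items():
            rows.append({"structure": s.structure, "metric": f"V{x:g}Gy_cc", "value": cc})
            rows.append({"structure": s.structure, "metric": f"V{x:g}Gy_pct", "value": pct})
        for p, d in s.d_at.items():
            rows.append({"structure": s.structure, "metric": f"D{p:g}pct_Gy", "value": d})
    return pd.DataFrame(rows, columns=["structure", "metric", "value"])
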