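"""Global 3D gamma-index evaluation.

The gamma index combines a dose-difference criterion (percent of the global
reference maximum) with a distance-to-agreement (DTA) criterion: for each
scored reference voxel the quantity

    gamma(r) = min_{r_e} sqrt( |r_e - r|^2 / dta^2
                               + (D_e(r_e) - D_r(r))^2 / dDelta^2 )

is minimized over evaluated-dose positions, and the voxel passes when
gamma <= 1.  Evaluation here is *global*: dDelta = dose_diff_pct/100 x
max(reference over the whole grid).  Voxels whose reference dose falls below
the suppression level (default 10% of the reference maximum) are excluded
from the analysis entirely (denominator and numerator).

The minimization searches a cubic lattice of candidate offsets with step
dta_mm/10, trilinear interpolation of the evaluated dose, and a search radius
capped at ``search_cap_mm`` (default 3 x DTA); if the true minimum lies beyond
the cap the reported gamma is the lattice minimum within the cap, hence
>= search_cap_mm/dta_mm.  Passing uses gamma <= 1 with a 1e-9 guard that
absorbs floating-point round-off on exact-boundary constructions.

``gamma_bruteforce`` runs an exhaustive, unpruned minimization over the
identical lattice and exists purely as an equivalence oracle (guarded to
grids of at most 32^3 voxels).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._gamma_kernels import gamma_search, gamma_search_exhaustive
from .errors import EmptyROIError, GeometryError, GridDomainError, GridSizeError
from .grid_io import DoseGrid, GridHeader, VoxelMask

__all__ = ["GammaCriteria", "GammaResult", "compute_gamma", "gamma_bruteforce"]

_PASS_GUARD = 1e-9


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma-evaluation parameters.

    dose_diff_pct: dose tolerance as % of the global reference maximum.
    dta_mm: distance-to-agreement tolerance in mm.
    suppression_pct: reference voxels below this % of the reference maximum
        are excluded from scoring.
    search_cap_mm: maximum DTA search radius (defaults to 3 x dta_mm).
    local_normalization: per-ROI-maximum normalization (non-default variant).
    """

    dose_diff_pct: float = 3.0
    dta_mm: float = 2.0
    suppression_pct: float = 10.0
    search_cap_mm: Optional[float] = None
    local_normalization: bool = False

    def __post_init__(self) -> None:
        if self.search_cap_mm is None:
            object.__setattr__(self, "search_cap_mm", 3.0 * self.dta_mm)
        for name in ("dose_diff_pct", "dta_mm", "suppression_pct", "search_cap_mm"):
            if getattr(self, name) <= 0:
                raise GridDomainError(f"GammaCriteria.{name} must be > 0")
        if self.search_cap_mm < self.dta_mm:
            raise GridDomainError("search_cap_mm must be >= dta_mm")


@dataclass
class GammaResult:
    """Per-voxel gamma map (NaN where unscored) plus the passing-rate summary."""

    gamma_map: np.ndarray
    analyzed_count: int
    passing_rate_pct: float
    criteria: GammaCriteria
    normalization_gy: float

    def passing(self) -> np.ndarray:
        """Boolean map of scored voxels with gamma <= 1."""
        return np.isfinite(self.gamma_map) & (self.gamma_map <= 1.0 + _PASS_GUARD)


def _build_lattice(criteria: GammaCriteria, spacing: tuple[float, float, float]):
    """Distance-sorted candidate offsets (fractional-index units) and distance terms."""
    step = criteria.dta_mm / 10.0
    n = int(np.floor(criteria.search_cap_mm / step + 1e-12))
    ax = np.arange(-n, n + 1, dtype=np.float64)
    ii, jj, kk = np.meshgrid(ax, ax, ax, indexing="ij")
    d2 = (ii ** 2 + jj ** 2 + kk ** 2) * step * step
    keep = d2 <= criteria.search_cap_mm ** 2 * (1 + 1e-12)
    off_mm = np.column_stack([ii[keep], jj[keep], kk[keep]]) * step
    d2 = d2[keep]
    order = np.argsort(d2, kind="stable")
    off_mm = off_mm[order]
    d2 = d2[order]
    off_frac = off_mm / np.asarray(spacing, dtype=np.float64)
    dist_term = d2 / (criteria.dta_mm ** 2)
    return np.ascontiguousarray(off_frac), np.ascontiguousarray(dist_term)


def _scored_voxels(
    reference: DoseGrid,
    evaluated: DoseGrid,
    criteria: GammaCriteria,
    roi: Optional[VoxelMask],
):
    if reference.header != evaluated.header:
        raise GeometryError("gamma: reference and evaluated grids must share an identical header")
    if roi is not None and roi.header != reference.header:
        raise GeometryError("gamma: ROI header differs from the dose grids")
    ref_max = float(reference.values.max())
    if ref_max <= 0:
        raise GridDomainError("gamma: max(reference) must be > 0")
    scored = reference.values >= criteria.suppression_pct / 100.0 * ref_max
    if roi is not None:
        scored &= roi.flags
        if criteria.local_normalization:
            if not roi.flags.any():
                raise EmptyROIError("gamma: ROI is empty")
            ref_max = float(reference.values[roi.flags].max())
    if not scored.any():
        raise EmptyROIError(
            f"gamma: no voxels left to score after {criteria.suppression_pct:g}% suppression"
        )
    norm = criteria.dose_diff_pct / 100.0 * ref_max
    return scored, norm


def _finish(
    header: GridHeader,
    scored: np.ndarray,
    gamma_vals: np.ndarray,
    criteria: GammaCriteria,
    norm: float,
) -> GammaResult:
    gamma_map = np.full(header.dims, np.nan)
    gamma_map[scored] = gamma_vals
    analyzed = int(scored.sum())
    passing = int(np.count_nonzero(gamma_vals <= 1.0 + _PASS_GUARD))
    return GammaResult(
        gamma_map=gamma_map,
        analyzed_count=analyzed,
        passing_rate_pct=100.0 * passing / analyzed,
        criteria=criteria,
        normalization_gy=norm,
    )


def compute_gamma(
    reference: DoseGrid,
    evaluated: DoseGrid,
    criteria: GammaCriteria = GammaCriteria(),
    roi: Optional[VoxelMask] = None,
) -> GammaResult:
    """Gamma evaluation with a distance-sorted, exactly pruned lattice search."""
    scored, norm = _scored_voxels(reference, evaluated, criteria, roi)
    off_frac, dist_term = _build_lattice(criteria, reference.header.spacing)
    idx = np.ascontiguousarray(np.argwhere(scored).astype(np.int64))
    gamma_vals = gamma_search(
        reference.values, evaluated.values, idx, off_frac, dist_term, 1.0 / norm
    )
    return _finish(reference.header, scored, gamma_vals, criteria, norm)


def gamma_bruteforce(
    reference: DoseGrid,
    evaluated: DoseGrid,
    criteria: GammaCriteria = GammaCriteria(),
    roi: Optional[VoxelMask] = None,
) -> GammaResult:
    """Exhaustive-lattice gamma (testing oracle); grids capped at 32^3 voxels."""
    if reference.header.n_voxels > 32 ** 3:
        raise GridSizeError("gamma_bruteforce: grid larger than 32^3 voxels")
    scored, norm = _scored_voxels(reference, evaluated, criteria, roi)
    off_frac, dist_term = _build_lattice(criteria, reference.header.spacing)
    idx = np.ascontiguousarray(np.argwhere(scored).astype(np.int64))
    gamma_vals = gamma_search_exhaustive(
        reference.values, evaluated.values, idx, off_frac, dist_term, 1.0 / norm
    )
    return _finish(reference.header, scored, gamma_vals, criteria, norm)


def write_gamma_map(result: GammaResult, header: GridHeader, path) -> None:
    """Export a gamma map as DGRID v1 (undefined voxels written as -1).

    The DGRID unit line remains "Gy"; by documented convention the payload of
    a gamma export means "gamma value", with -1 marking unscored voxels.
    """
    from .grid_io import _write_dgrid_raw

    vals = np.where(np.isfinite(result.gamma_map), result.gamma_map, -1.0)
    _write_dgrid_raw(header, "Gy", vals.ravel(order="F"), "%.17g", path)
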