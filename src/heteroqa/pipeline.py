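"""Per-case and cohort-level QA orchestration.

``run_case`` is a thin composition of the gamma, DVH and mask modules — it
performs no hidden transformations, so its output equals hand-composed module
calls.  ``run_cohort`` maps ``run_case`` over a cohort manifest and produces
the report bundle: per-case records CSV, per-structure summary tables with
paired tests, the gamma-vs-ln(V) fits with their 95%-crossing volumes,
scatter CSVs for plotting, and a plain-text run log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .cohort_stats import CaseRecord, CohortSummary, summarize_cohort
from .dvh import dvh_summary, relative_dmean_diff
from .errors import ConfigurationError, GeometryError, HeteroQAError, SampleSizeError
from .gamma import GammaCriteria, compute_gamma
from .grid_io import DoseGrid, VoxelMask, read_dgrid
from .masks import volume_cc

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_case", "run_cohort", "CohortReport"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one QA run.

    ``roles`` maps the semantic roles the analysis needs (target/air/bone) to
    structure names present in each case's mask set; additional named masks
    are scored as OARs.
    """

    criteria: GammaCriteria = GammaCriteria()
    roles: Mapping[str, str] = field(
        default_factory=lambda: {"target": "target", "air": "air", "bone": "bone"}
    )
    v_levels: Sequence[float] = ()
    d_levels: Sequence[float] = ()
    gamma_star: float = 95.0

    def __post_init__(self) -> None:
        for role in ("target", "air", "bone"):
            if role not in self.roles:
                raise ConfigurationError(f"RunConfig.roles is missing the {role!r} role")


def run_case(
    reference: DoseGrid,
    evaluated: DoseGrid,
    masks: Mapping[str, VoxelMask],
    config: RunConfig = RunConfig(),
    case_id: str = "case",
    algorithm: str = "evaluated",
    cohort: str = "",
) -> CaseRecord:
    """Score one dose pair: entire-plan and per-structure gamma, Dmean diffs.

    The entire-plan gamma uses no ROI (all non-suppressed voxels).  Every mask
    in ``masks`` is scored; the air/bone role masks additionally provide
    V_air and V_bone.
    """
    if reference.header != evaluated.header:
        raise GeometryError("run_case: reference and evaluated headers differ")
    for role, name in config.roles.items():
        if name not in masks:
            raise ConfigurationError(
                f"run_case: role {role!r} references structure {name!r} which is absent"
            )
    gamma_pct: dict[str, float] = {}
    diff_pct: dict[str, float] = {}
    entire = compute_gamma(reference, evaluated, config.criteria, roi=None)
    gamma_pct["entire_plan"] = entire.passing_rate_pct
    for name, mask in masks.items():
        if name == "body":
            continue  # body duplicates the entire-plan score
        res = compute_gamma(reference, evaluated, config.criteria, roi=mask)
        gamma_pct[name] = res.passing_rate_pct
        ref_sum = dvh_summary(reference, mask, config.v_levels, config.d_levels, name)
        ev_sum = dvh_summary(evaluated, mask, config.v_levels, config.d_levels, name)
        diff_pct[name] = relative_dmean_diff(ev_sum.d_mean, ref_sum.d_mean)
    return CaseRecord(
        case_id=case_id,
        algorithm=algorithm,
        gamma_pct=gamma_pct,
        dmean_diff_pct=diff_pct,
        v_air_cc=volume_cc(masks[config.roles["air"]]),
        v_bone_cc=volume_cc(masks[config.roles["bone"]]),
        cohort=cohort,
    )


@dataclass
class CohortReport:
    records: list[CaseRecord]
    summary: CohortSummary
    skipped: list[str]
    out_dir: Optional[Path] = None


def _records_frame(records: Sequence[CaseRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "case_id": r.case_id,
            "algorithm": r.algorithm,
            "v_air_cc": r.v_air_cc,
            "v_bone_cc": r.v_bone_cc,
        }
        for s, v in r.gamma_pct.items():
            row[f"gamma_{s}_pct"] = v
        for s, v in r.dmean_diff_pct.items():
            row[f"diff_{s}_pct"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def run_cohort(
    manifest: pd.DataFrame | str | Path,
    config: RunConfig = RunConfig(),
    out: Optional[str | Path] = None,
) -> CohortReport:
    """Run per-case QA over a cohort manifest and aggregate the statistics.

    Unreadable cases are skipped with a logged warning (and recorded in the
    report); fewer than 3 usable cases aborts.  With ``out`` set, the report
    bundle is written as CSV/JSON plus a run log.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    eval_cols = [c for c in manifest.columns if c.startswith("evaluated_")]
    mask_cols = [c for c in manifest.columns if c.startswith("mask_")]
    records: list[CaseRecord] = []
    skipped: list[str] = []
    for _, row in manifest.iterrows():
        case_id = str(row["case_id"])
        try:
            reference = read_dgrid(row["reference"])
            masks = {c[len("mask_") :]: read_dgrid(row[c]) for c in mask_cols}
            for col in eval_cols:
                label = col[len("evaluated_") :]
                evaluated = read_dgrid(row[col])
                records.append(
                    run_case(reference, evaluated, masks, config, case_id, label)
                )
        except (OSError, HeteroQAError) as exc:
            logger.warning("skipping case %s: %s", case_id, exc)
            skipped.append(case_id)
    n_usable = len({r.case_id for r in records})
    if n_usable < 3:
        raise SampleSizeError(f"run_cohort: only {n_usable} usable cases (need >= 3)")
    summary = summarize_cohort(
        records,
        gamma_star=config.gamma_star,
        air_structure=config.roles["air"],
        bone_structure=config.roles["bone"],
    )
    report = CohortReport(records=records, summary=summary, skipped=skipped)
    if out is not None:
        report.out_dir = Path(out)
        _write_bundle(report, config)
    return report


def _write_bundle(report: CohortReport, config: RunConfig) -> None:
    out = report.out_dir
    out.mkdir(parents=True, exist_ok=True)
    _records_frame(report.records).to_csv(out / "case_records.csv", index=False)
    report.summary.structure_stats.to_csv(out / "summary.csv", index=False)
    fits = {
        f"{label}|{struct}": {
            "intercept_pct": fit.intercept,
            "slope_pct_per_ln_cc": fit.slope,
            "r_squared": fit.r_squared,
            "n": fit.n,
            "crossing_cc": report.summary.thresholds.get((label, struct)),
        }
        for (label, struct), fit in report.summary.fits.items()
    }
    with open(out / "fits.json", "w") as fh:
        json.dump(fits, fh, indent=2, sort_keys=True)
    air_s, bone_s = config.roles["air"], config.roles["bone"]
    for struct, vol_key, fname in (
        (air_s, "v_air_cc", "scatter_air.csv"),
        (bone_s, "v_bone_cc", "scatter_bone.csv"),
    ):
        rows = [
            {
                "case_id": r.case_id,
                "algorithm": r.algorithm,
                "volume_cc": getattr(r, vol_key),
                "gamma_pct": r.gamma_pct.get(struct),
            }
            for r in report.records
            if struct in r.gamma_pct
        ]
        pd.DataFrame(rows).to_csv(out / fname, index=False)
    with open(out / "run.log", "w") as fh:
        fh.write(f"heteroqa {__version__}\n")
        c = config.criteria
        fh.write(
            f"criteria: {c.dose_diff_pct:g}%/{c.dta_mm:g}mm, "
            f"suppression {c.suppression_pct:g}%, cap {c.search_cap_mm:g}mm\n"
        )
        fh.write(f"cases: {len({r.case_id for r in report.records})}\n")
        fh.write(f"skipped: {', '.join(report.skipped) if report.skipped else 'none'}\n")
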