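"""Cohort-level statistics: paired tests, log-linear fits, threshold volumes.

The central empirical relationship is a log-linear model between a structure's
gamma passing rate and its volume,

    gamma(%) = a + b * ln(V / cc),

fitted by unweighted ordinary least squares.  For targets containing air
cavities the slope is expected positive (small cavities concentrate interface
dose errors); for bony structures it is expected negative (larger bone volume
means a larger perturbed fraction).  The volume at which the fitted line
crosses a passing-rate level (95% by convention) is ``exp((level - a) / b)``;
the side on which plans fail depends on the slope sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDesignError,
    GridDomainError,
    NoCrossingError,
    PairingError,
    SampleSizeError,
)

__all__ = [
    "CaseRecord",
    "LogLinearFit",
    "PairedTResult",
    "fit_log_linear",
    "threshold_volume",
    "paired_t_test",
    "summarize_cohort",
    "CohortSummary",
]


@dataclass
class CaseRecord:
    """Per-case QA outcome for one algorithm label."""

    case_id: str
    algorithm: str
    gamma_pct: dict[str, float]  # structure -> gamma passing rate (%)
    dmean_diff_pct: dict[str, float]  # structure -> relative Dmean difference (%)
    v_air_cc: float
    v_bone_cc: float
    cohort: str = ""

    def __post_init__(self) -> None:
        for name, rate in self.gamma_pct.items():
            if not 0 <= rate <= 100:
                raise GridDomainError(f"{self.case_id}/{name}: gamma rate {rate} outside [0, 100]")


@dataclass(frozen=True)
class LogLinearFit:
    """OLS fit of gamma = a + b ln(V) with coefficient of determination."""

    intercept: float  # a, %
    slope: float  # b, % per ln(cc)
    r_squared: float
    n: int

    def predict(self, volume_cc) -> np.ndarray:
        return self.intercept + self.slope * np.log(np.asarray(volume_cc, dtype=float))

    def summary(self) -> str:
        return (
            f"gamma = {self.intercept:.2f} + {self.slope:.2f} ln(V)   "
            f"R^2 = {self.r_squared:.3f}   n = {self.n}"
        )


class PairedTResult(NamedTuple):
    t: float
    p: float


def fit_log_linear(pairs: Sequence[tuple[float, float]]) -> LogLinearFit:
    """Least-squares fit of gamma = a + b ln(V) to (volume cc, gamma %) pairs.

    Degenerate cases: fewer than 3 pairs or any non-positive volume raise;
    zero variance in ln V raises DegenerateDesignError.  When the response has
    zero variance the fit is the flat line b = 0 with R^2 = 0 (no variance to
    explain).
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise SampleSizeError("fit_log_linear needs at least 3 (volume, gamma) pairs")
    v, g = arr[:, 0], arr[:, 1]
    if np.any(v <= 0):
        raise GridDomainError("fit_log_linear: all volumes must be > 0 cc")
    x = np.log(v)
    if np.ptp(x) == 0:
        raise DegenerateDesignError("fit_log_linear: zero variance in ln(V)")
    if np.ptp(g) == 0:
        # flat response: the flat line fits perfectly but explains no variance
        return LogLinearFit(intercept=float(g[0]), slope=0.0, r_squared=0.0, n=arr.shape[0])
    res = stats.linregress(x, g)
    return LogLinearFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue ** 2),
        n=arr.shape[0],
    )


def threshold_volume(fit: LogLinearFit, gamma_star: float = 95.0) -> float:
    """Volume (cc) at which the fitted line crosses ``gamma_star``.

    For b > 0 the passing rate is below gamma_star for V < V*; for b < 0,
    for V > V*.
    """
    if fit.slope == 0:
        raise NoCrossingError("threshold_volume: slope is 0; the line never crosses")
    exponent = (gamma_star - fit.intercept) / fit.slope
    if exponent > 700.0:  # beyond double range: effectively no finite crossing
        return float("inf")
    return float(np.exp(exponent))


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> PairedTResult:
    """Two-sided paired Student t-test on matched samples.

    t = mean(d) / (sd(d)/sqrt(n)) with d = x - y and the n-1 sample SD; p from
    the Student t distribution with n-1 degrees of freedom.  Zero-variance
    differences are handled explicitly: nonzero mean reports (+/-inf, p=0),
    zero mean reports (0, p=1).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise SampleSizeError("paired_t_test: samples must be equal-length 1-D arrays")
    n = x.size
    if n < 2:
        raise SampleSizeError(f"paired_t_test needs n >= 2, got {n}")
    d = x - y
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0:
        if mean == 0:
            return PairedTResult(0.0, 1.0)
        return PairedTResult(float(np.copysign(np.inf, mean)), 0.0)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTResult(float(t), float(p))


@dataclass
class CohortSummary:
    """Aggregated cohort report: per-structure tables plus the volume fits."""

    structure_stats: pd.DataFrame
    fits: dict[tuple[str, str], LogLinearFit] = field(default_factory=dict)
    thresholds: dict[tuple[str, str], float] = field(default_factory=dict)


def _paired_frame(records: Iterable[CaseRecord]) -> tuple[list[str], dict[str, dict[str, CaseRecord]]]:
    by_label: dict[str, dict[str, CaseRecord]] = {}
    for rec in records:
        by_label.setdefault(rec.algorithm, {})
        if rec.case_id in by_label[rec.algorithm]:
            raise PairingError(f"duplicate case {rec.case_id!r} under label {rec.algorithm!r}")
        by_label[rec.algorithm][rec.case_id] = rec
    labels = sorted(by_label)
    ids = [set(v) for v in by_label.values()]
    common = set.intersection(*ids) if ids else set()
    offenders = sorted(set.union(*ids) - common) if ids else []
    if offenders:
        raise PairingError(f"cases not present under every label: {offenders}")
    return labels, by_label


def summarize_cohort(
    records: Sequence[CaseRecord],
    gamma_star: float = 95.0,
    air_structure: str = "air",
    bone_structure: str = "bone",
) -> CohortSummary:
    """Mean +/- SD tables with paired-t p-values, plus gamma-vs-ln(V) fits.

    One row per structure x metric (gamma passing rate, Dmean Diff); one
    log-linear fit per (algorithm label, air/bone structure), with the
    95%-crossing volume where the slope is nonzero.  Aggregation is
    order-independent (cases are sorted by id).
    """
    if len(records) < 2:
        raise SampleSizeError("summarize_cohort needs at least 2 records")
    labels, by_label = _paired_frame(records)
    if len(labels) < 2:
        raise PairingError("summarize_cohort needs at least 2 algorithm labels")
    ids = sorted(by_label[labels[0]])
    structures = sorted({s for rec in records for s in rec.gamma_pct})
    rows = []
    for metric, getter in (
        ("gamma_pct", lambda r, s: r.gamma_pct.get(s)),
        ("dmean_diff_pct", lambda r, s: r.dmean_diff_pct.get(s)),
    ):
        for struct in structures:
            values = {
                lab: np.array(
                    [getter(by_label[lab][i], struct) for i in ids], dtype=np.float64
                )
                for lab in labels
            }
            if any(np.any(np.isnan(v)) for v in values.values()):
                continue
            row: dict = {"structure": struct, "metric": metric, "n": len(ids)}
            for lab in labels:
                row[f"mean_{lab}"] = values[lab].mean()
                row[f"sd_{lab}"] = values[lab].std(ddof=1)
            tt = paired_t_test(values[labels[0]], values[labels[1]])
            row["t"] = tt.t
            row["p"] = tt.p
            row["significant"] = tt.p < 0.05
            rows.append(row)
    summary = CohortSummary(structure_stats=pd.DataFrame(rows))
    for lab in labels:
        recs = [by_label[lab][i] for i in ids]
        for struct, vol_attr in ((air_structure, "v_air_cc"), (bone_structure, "v_bone_cc")):
            pairs = [
                (getattr(r, vol_attr), r.gamma_pct[struct])
                for r in recs
                if struct in r.gamma_pct
            ]
            if len(pairs) < 3:
                continue
            fit = fit_log_linear(pairs)
            summary.fits[(lab, struct)] = fit
            if fit.slope != 0:
                summary.thresholds[(lab, struct)] = threshold_volume(fit, gamma_star)
    return summary
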