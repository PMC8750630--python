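"""Kaplan-Meier estimation, log-rank testing, and best-expression-cutoff scans.

Prognostic prioritization dichotomizes a cohort at a series of candidate
expression cutoffs (quantiles of the expression distribution), runs a
two-group log-rank test at each, and reports the cutoff minimizing the p
value ("best expression cutoff"). This minimum-p selection is deliberately
uncorrected for multiplicity and therefore anti-conservative under the null;
the behaviour is quantified in the test suite rather than corrected away,
because the readout mirrors how protein-atlas-style prognostic p-scores are
produced.

Estimation and testing are delegated to :mod:`lifelines`. Times are in years;
the 5-year readout is a reporting convention, configurable per call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

logger = logging.getLogger(__name__)


class ScanError(ValueError):
    """The cutoff scan cannot run (constant expression, too few subjects)."""


@dataclass
class SurvivalCohort:
    """Follow-up times (years), event indicators, and per-gene expression."""

    time: np.ndarray
    event: np.ndarray
    expression: pd.DataFrame  # one column per gene, rows aligned with time/event
    subject_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        if np.any(self.time < 0):
            raise ValueError("follow-up times must be non-negative")
        if not np.all(np.isfinite(self.expression.to_numpy())):
            raise ValueError("expression values must be finite")
        if len(self.time) != len(self.event) or len(self.time) != len(self.expression):
            raise ValueError("time, event and expression must have equal length")

    def __len__(self) -> int:
        return len(self.time)

    def subset(self, mask: np.ndarray) -> "SurvivalCohort":
        return SurvivalCohort(
            time=self.time[mask],
            event=self.event[mask],
            expression=self.expression.loc[mask].reset_index(drop=True),
            subject_id=None if self.subject_id is None else self.subject_id[mask],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalCohort":
        """Build from a cohort table with ``subject``, ``time_years``,
        ``event`` and ``expression_<gene>`` columns."""
        expr_cols = [c for c in df.columns if c.startswith("expression_")]
        expression = df[expr_cols].rename(
            columns={c: c[len("expression_") :] for c in expr_cols}
        )
        return cls(
            time=df["time_years"].to_numpy(dtype=float),
            event=df["event"].to_numpy(dtype=bool),
            expression=expression.reset_index(drop=True),
            subject_id=df["subject"].to_numpy() if "subject" in df else None,
        )


@dataclass
class CutoffScanResult:
    gene_id: str
    best_cutoff: float
    p_score: float
    direction: str  # "unfavorable" iff the high group has worse 5-year survival
    surv5_high: float
    surv5_low: float
    scanned: pd.DataFrame | None = None  # cutoff, p per scanned quantile


def km_survival(cohort: SurvivalCohort, t: float) -> float:
    """Product-limit survival estimate at time ``t``.

    Without censoring this equals the empirical fraction surviving past ``t``.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    kmf = KaplanMeierFitter()
    kmf.fit(cohort.time, cohort.event)
    return float(kmf.predict(t))


def logrank_test(group_a: SurvivalCohort, group_b: SurvivalCohort) -> float:
    """Two-group log-rank chi-square p value (symmetric in group order)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    if group_a.event.sum() == 0 or group_b.event.sum() == 0:
        logger.warning("a group has zero observed events; log-rank power is limited")
    res = _lifelines_logrank(
        group_a.time, group_b.time, event_observed_A=group_a.event, event_observed_B=group_b.event
    )
    return float(res.p_value)


def five_year_delta(
    cohort: SurvivalCohort, gene: str, cutoff: float, horizon: float = 5.0
) -> float:
    """Percentage-point difference in survival at ``horizon`` years,
    low-expression group minus high-expression group."""
    expr = cohort.expression[gene].to_numpy()
    high = expr > cutoff
    if high.all() or not high.any():
        name = "low" if high.all() else "high"
        raise ValueError(f"{name}-expression group is empty at cutoff {cutoff}")
    s_high = km_survival(cohort.subset(high), horizon)
    s_low = km_survival(cohort.subset(~high), horizon)
    return 100.0 * (s_low - s_high)


DEFAULT_QUANTILES = np.round(np.arange(0.20, 0.8001, 0.05), 2)


def best_cutoff_scan(
    cohort: SurvivalCohort,
    gene: str,
    quantiles: np.ndarray = DEFAULT_QUANTILES,
    horizon: float = 5.0,
    min_subjects: int = 20,
) -> CutoffScanResult:
    """Scan expression quantiles, log-rank at each dichotomization, keep the
    cutoff minimizing p.

    Direction is ``unfavorable`` iff the high-expression group has lower
    survival at the horizon than the low-expression group.
    """
    if len(cohort) < min_subjects:
        raise ScanError(f"need >= {min_subjects} subjects, have {len(cohort)}")
    expr = cohort.expression[gene].to_numpy()
    if np.all(expr == expr[0]):
        raise ScanError(f"expression of {gene} is constant; no cutoff splits the cohort")

    cutoffs = np.unique(np.quantile(expr, quantiles))
    rows = []
    seen_partitions: set[bytes] = set()
    for cutoff in cutoffs:
        high = expr > cutoff
        if not high.any() or high.all():
            continue
        key = np.packbits(high).tobytes()  # distinct cutoffs, same split -> one test
        if key in seen_partitions:
            continue
        seen_partitions.add(key)
        p = logrank_test(cohort.subset(high), cohort.subset(~high))
        rows.append((float(cutoff), p))
    if not rows:
        raise ScanError(f"no candidate cutoff splits the cohort for {gene}")
    scanned = pd.DataFrame(rows, columns=["cutoff", "p"])
    best = scanned.loc[scanned["p"].idxmin()]
    best_cutoff = float(best["cutoff"])

    high = expr > best_cutoff
    surv5_high = km_survival(cohort.subset(high), horizon)
    surv5_low = km_survival(cohort.subset(~high), horizon)
    direction = "unfavorable" if surv5_high < surv5_low else "favorable"
    return CutoffScanResult(
        gene_id=gene,
        best_cutoff=best_cutoff,
        p_score=float(best["p"]),
        direction=direction,
        surv5_high=surv5_high,
        surv5_low=surv5_low,
        scanned=scanned,
    )
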