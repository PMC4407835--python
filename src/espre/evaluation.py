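"""Retrospective screening-efficiency evaluation.

The central metric is the *workload*: how far down a ranked candidate list
a reviewer must read, top-down, to capture every reference-standard match
for the anchor. Because the cutoff is defined by the deepest positive,
false negatives are zero by construction, so recall and NPV are always 1;
precision and specificity at the cutoff measure how much of the review
effort is wasted:

    precision   = k / WL
    specificity = (N − WL) / (N − k)        (1 when N = k)

with k positives, workload WL, and a candidate universe of size N. Two
boundary rules keep the evaluation honest: an anchor with no positives
costs a full review of its ranked list, and a positive removed by the
demographic pre-filter (a filter error) forces an exhaustive review of the
whole universe.

The random-screening baseline has closed-form expected workload
E[WL] = k(N+1)/(k+1), the expectation of the maximum of k positive
positions in a uniform permutation of N candidates.

Also here: the chart-review precision adjustment (pooled hits over pooled
algorithm outputs, before and after a clinician verifies additional
eligible candidates) and the false-positive error-category breakdown, each
with the rounding conventions of the published worked examples; the row
counts of those examples ship as small CSV data files.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import stats

from .matching import RankedList

__all__ = [
    "ReferenceStandard",
    "ScreeningMetrics",
    "ChartReviewRow",
    "ChartReviewTable",
    "AggregateSummary",
    "load_reference",
    "workload",
    "metrics_at_workload",
    "expected_random_workload",
    "aggregate",
    "paired_workload_test",
    "chart_review_precision",
    "project_adjusted_precision",
    "error_category_fractions",
    "load_chart_review_table",
    "load_error_counts",
]


@dataclass
class ReferenceStandard:
    """Historical enrollment decisions: the positive (trial, patient) pairs."""

    matches: frozenset[tuple[str, str]]

    def positives_for_trial(self, nct_id: str) -> frozenset[str]:
        return frozenset(p for t, p in self.matches if t == nct_id)

    def positives_for_patient(self, patient_id: str) -> frozenset[str]:
        return frozenset(t for t, p in self.matches if p == patient_id)

    def __len__(self) -> int:
        return len(self.matches)


def load_reference(path: str | Path) -> ReferenceStandard:
    """Read a reference CSV with header ``patient_id,nct_id,enrollment_date``."""
    matches = set()
    with Path(path).open(encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            matches.add((row["nct_id"].strip(), row["patient_id"].strip()))
    return ReferenceStandard(matches=frozenset(matches))


@dataclass(frozen=True)
class ScreeningMetrics:
    anchor_id: str
    workload: int
    n_candidates: int
    n_positives: int
    precision: float
    specificity: float
    recall: float = 1.0
    npv: float = 1.0


def workload(
    ranked: RankedList, positives: frozenset[str] | set[str], n_universe: int
) -> int:
    """Review depth needed to capture every positive for this anchor.

    * no positives → the whole ranked (post-filter) list must be reviewed;
    * a positive missing from the ranked list was removed by the pre-filter:
      the filter erred, and confirming that requires reviewing the entire
      universe of ``n_universe`` candidates;
    * otherwise → the 1-based rank of the deepest positive.
    """
    if not positives:
        return len(ranked)
    ranks = []
    for pid in positives:
        r = ranked.rank_of(pid)
        if r is None:
            return n_universe
        ranks.append(r)
    return max(ranks)


def metrics_at_workload(
    wl: int, n_positives: int, n_candidates: int, anchor_id: str = ""
) -> ScreeningMetrics:
    """Confusion-matrix metrics at the workload cutoff.

    Reviewing the top ``wl`` candidates captures all ``n_positives``
    (FN = 0), so TP = k, FP = wl − k, TN = N − wl, and recall = NPV = 1.
    """
    if not 0 <= n_positives <= wl <= n_candidates:
        raise ValueError(
            f"need 0 <= k <= wl <= N, got k={n_positives}, wl={wl}, "
            f"N={n_candidates}"
        )
    precision = n_positives / wl if wl > 0 else 0.0
    if n_candidates > n_positives:
        specificity = (n_candidates - wl) / (n_candidates - n_positives)
    else:
        specificity = 1.0  # no true negatives exist
    return ScreeningMetrics(
        anchor_id=anchor_id,
        workload=wl,
        n_candidates=n_candidates,
        n_positives=n_positives,
        precision=precision,
        specificity=specificity,
    )


def expected_random_workload(n_candidates: int, n_positives: int) -> float:
    """Expected workload of the random-shuffle baseline.

    For k ≥ 1 positives among N candidates in uniform random order, the
    review depth is the maximum of the k positive positions, with
    expectation k(N+1)/(k+1); with no positives the whole pool of N is
    reviewed.
    """
    if not 0 <= n_positives <= n_candidates:
        raise ValueError("need 0 <= k <= N")
    if n_positives == 0:
        return float(n_candidates)
    return n_positives * (n_candidates + 1) / (n_positives + 1)


@dataclass(frozen=True)
class AggregateSummary:
    n_anchors: int
    mean_workload: float
    ci95: tuple[float, float]
    micro_precision: float
    macro_precision: float
    micro_specificity: float
    macro_specificity: float
    recall: float = 1.0
    npv: float = 1.0

    def as_dict(self) -> dict:
        return {
            "n_anchors": self.n_anchors,
            "mean_workload": self.mean_workload,
            "ci95": list(self.ci95),
            "micro_precision": self.micro_precision,
            "macro_precision": self.macro_precision,
            "micro_specificity": self.micro_specificity,
            "macro_specificity": self.macro_specificity,
            "recall": self.recall,
            "npv": self.npv,
        }


def aggregate(metrics: list[ScreeningMetrics]) -> AggregateSummary:
    """Pool per-anchor metrics: mean workload with a 95% t-interval, plus
    micro (pooled counts) and macro (mean of ratios) precision/specificity.

    A single anchor yields a degenerate interval at the point estimate.
    """
    if not metrics:
        raise ValueError("no metrics to aggregate")
    wl = np.array([m.workload for m in metrics], dtype=float)
    mean_wl = float(wl.mean())
    if len(wl) > 1 and wl.std(ddof=1) > 0:
        half = float(
            stats.t.ppf(0.975, len(wl) - 1)
            * wl.std(ddof=1)
            / math.sqrt(len(wl))
        )
        ci = (mean_wl - half, mean_wl + half)
    else:
        ci = (mean_wl, mean_wl)
    sum_wl = int(wl.sum())
    sum_k = sum(m.n_positives for m in metrics)
    sum_n = sum(m.n_candidates for m in metrics)
    micro_p = sum_k / sum_wl if sum_wl > 0 else 0.0
    macro_p = float(np.mean([m.precision for m in metrics]))
    micro_sp = (
        (sum_n - sum_wl) / (sum_n - sum_k) if sum_n > sum_k else 1.0
    )
    macro_sp = float(np.mean([m.specificity for m in metrics]))
    return AggregateSummary(
        n_anchors=len(metrics),
        mean_workload=mean_wl,
        ci95=ci,
        micro_precision=micro_p,
        macro_precision=macro_p,
        micro_specificity=micro_sp,
        macro_specificity=macro_sp,
    )


def paired_workload_test(
    wl_a: list[float] | list[int], wl_b: list[float] | list[int]
) -> float:
    """Two-sided paired t-test p-value on per-anchor workloads.

    Degenerate variance of the differences is handled explicitly: all-zero
    differences give p = 1 (the algorithms are identical), a constant
    non-zero difference gives p = 0 (the shift is certain under the model).
    """
    if len(wl_a) != len(wl_b):
        raise ValueError("paired samples must have equal length")
    if len(wl_a) < 2:
        raise ValueError("need at least 2 pairs")
    diff = np.asarray(wl_a, dtype=float) - np.asarray(wl_b, dtype=float)
    if float(diff.std(ddof=1)) == 0.0:
        return 1.0 if float(diff.mean()) == 0.0 else 0.0
    return float(stats.ttest_rel(wl_a, wl_b).pvalue)


# ---------------------------------------------------------------------------
# Chart-review adjustment and error-category arithmetic


@dataclass(frozen=True)
class ChartReviewRow:
    """One trial's chart-review bookkeeping.

    ``n_output`` is fixed at twice the historical enrollment count (the
    reviewer inspects the top 2N algorithm candidates); ``n_hits`` of those
    were historical enrollees, and the reviewing clinician found
    ``n_additional`` further truly-eligible patients among the outputs.
    """

    nct_id: str
    n_enrolled: int
    n_output: int
    n_hits: int
    n_additional: int

    def __post_init__(self) -> None:
        if self.n_output != 2 * self.n_enrolled:
            raise ValueError(
                f"{self.nct_id}: n_output must equal 2×n_enrolled"
            )
        if self.n_hits > min(self.n_enrolled, self.n_output):
            raise ValueError(f"{self.nct_id}: n_hits exceeds enrollments")
        if self.n_additional < 0:
            raise ValueError(f"{self.nct_id}: negative n_additional")


@dataclass(frozen=True)
class ChartReviewTable:
    rows: tuple[ChartReviewRow, ...]

    @property
    def total_enrolled(self) -> int:
        return sum(r.n_enrolled for r in self.rows)

    @property
    def total_output(self) -> int:
        return sum(r.n_output for r in self.rows)

    @property
    def total_hits(self) -> int:
        return sum(r.n_hits for r in self.rows)

    @property
    def total_additional(self) -> int:
        return sum(r.n_additional for r in self.rows)

    @property
    def total_eligible(self) -> int:
        """Patients the reviewing clinician judged truly eligible."""
        return self.total_hits + self.total_additional


def chart_review_precision(
    table: ChartReviewTable,
) -> tuple[float, float, float]:
    """Pooled precision before/after clinician verification.

    Returns (historical, adjusted, relative_improvement_percent):
    historical = Σhits/Σoutput and adjusted = Σ(hits+additional)/Σoutput,
    each rounded to 2 decimals as printed; the relative improvement is
    computed on the rounded values and given as a percentage to 1 decimal.
    """
    if table.total_output == 0:
        raise ValueError("chart-review table has no algorithm outputs")
    historical = round(table.total_hits / table.total_output, 2)
    adjusted = round(table.total_eligible / table.total_output, 2)
    improvement = round((adjusted - historical) / historical * 100, 1)
    return historical, adjusted, improvement


def project_adjusted_precision(
    base_precision: float, relative_improvement_pct: float
) -> float:
    """Project a chart-review relative improvement onto a base precision,
    capped at 1 and rounded to 3 decimals."""
    if not 0 <= base_precision <= 1:
        raise ValueError("base precision must be in [0, 1]")
    return min(
        round(base_precision * (1 + relative_improvement_pct / 100), 3), 1.0
    )


def error_category_fractions(counts: list[int]) -> dict:
    """Break six false-positive error-category counts into shares.

    Categories (as used in the bundled worked example): 1 prior enrollment
    elsewhere, 2 new diagnosis on standard-of-care, 3 wrong disease stage,
    4 wrong relapse status, 5 confusion between disease sub-categories,
    6 other wrong diagnosis. Returns the total, each category's share
    rounded to the nearest integer percent, and the grouped share of
    categories 3–5 truncated to 1 decimal (matching the printed figure).
    """
    if len(counts) != 6:
        raise ValueError("expected exactly 6 category counts")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("all category counts are zero")
    per_category = [math.floor(100 * c / total + 0.5) for c in counts]
    grouped_3_5 = math.floor(100 * sum(counts[2:5]) / total * 10) / 10
    return {
        "total": total,
        "per_category_pct": per_category,
        "grouped_3_5_pct": grouped_3_5,
    }


def _data_path(name: str) -> Path:
    return Path(str(resources.files("espre").joinpath("data", name)))


def load_chart_review_table(path: str | Path | None = None) -> ChartReviewTable:
    """Load a chart-review CSV (defaults to the bundled worked example)."""
    if path is None:
        path = _data_path("chart_review.csv")
    rows = []
    with Path(path).open(encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append(
                ChartReviewRow(
                    nct_id=row["nct_id"],
                    n_enrolled=int(row["n_enrolled"]),
                    n_output=int(row["n_output"]),
                    n_hits=int(row["n_hits"]),
                    n_additional=int(row["n_additional"]),
                )
            )
    return ChartReviewTable(rows=tuple(rows))


def load_error_counts(path: str | Path | None = None) -> list[int]:
    """Load the six error-category counts (bundled worked example by default)."""
    if path is None:
        path = _data_path("error_categories.csv")
    counts = []
    with Path(path).open(encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            counts.append(int(row["n_errors"]))
    return counts
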