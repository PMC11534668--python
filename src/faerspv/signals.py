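"""Reporting odds ratio (ROR) disproportionality analysis.

The 2x2 four-grid table counts cases, not reaction rows::

                      term reported    term not reported
    target cohort           a                 b
    comparator cohort       c                 d

ROR = (a/c) / (b/d), with the Woolf (log-normal) 95% confidence interval

    exp( ln ROR ± 1.96 * sqrt(1/a + 1/b + 1/c + 1/d) ).

A term is a signal when the lower 95% bound exceeds 1.0. Tables with a
zero cell, or with fewer target reports than the minimum report count, are
marked non-evaluable by default; an optional Haldane–Anscombe +0.5
correction is available behind a flag but deliberately off, so the engine
never manufactures a signal the formula itself cannot produce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .meddra import AdeEvent

DEFAULT_MIN_COUNT = 3
_Z95 = 1.96


@dataclass(frozen=True)
class ContingencyTable:
    """The 2x2 four-grid table of case counts."""

    a: int  # target cohort, term reported
    b: int  # target cohort, term not reported
    c: int  # comparator cohort, term reported
    d: int  # comparator cohort, term not reported

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n_target(self) -> int:
        return self.a + self.b

    @property
    def n_comparator(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class SignalResult:
    """ROR, 95% CI and signal flag for one term in one cohort pairing."""

    term: str
    level: str  # "PT" or "SOC"
    table: ContingencyTable
    ror: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    evaluable: bool
    is_signal: bool

    @property
    def n_reports(self) -> int:
        return self.table.a


def build_contingency(
    term: str,
    level: str,
    target_cases: set[str],
    comparator_cases: set[str],
    events: Iterable[AdeEvent],
) -> ContingencyTable:
    """Count cases with >=1 event for ``term`` in each cohort.

    ``level`` selects whether ``term`` is matched against the PT or the SOC
    of each event. Cohorts are caseid sets and must be disjoint.
    """
    overlap = target_cases & comparator_cases
    if overlap:
        raise ValueError(
            f"cohorts overlap on {len(overlap)} caseids (e.g. "
            f"{sorted(overlap)[:3]})"
        )
    key = (lambda e: e.pt) if level == "PT" else (lambda e: e.soc)
    with_term = {e.caseid for e in events if key(e) == term}
    a = len(with_term & target_cases)
    c = len(with_term & comparator_cases)
    return ContingencyTable(
        a=a, b=len(target_cases) - a,
        c=c, d=len(comparator_cases) - c,
    )


def compute_ror(
    table: ContingencyTable,
    term: str = "",
    level: str = "PT",
    min_count: int = DEFAULT_MIN_COUNT,
    continuity_correction: bool = False,
) -> SignalResult:
    """ROR with Woolf 95% CI for one table; flags `is_signal` when the
    lower bound exceeds 1. Any zero cell (unless the continuity correction
    is enabled) or a < min_count makes the result non-evaluable."""
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    if continuity_correction and min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) == 0.0 or table.a < min_count:
        return SignalResult(term, level, table, None, None, None,
                            evaluable=False, is_signal=False)
    ror = (a / c) / (b / d)
    half_width = _Z95 * math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_ror = math.log(ror)
    ci_low = math.exp(log_ror - half_width)
    ci_high = math.exp(log_ror + half_width)
    return SignalResult(
        term, level, table, ror, ci_low, ci_high,
        evaluable=True, is_signal=ci_low > 1.0,
    )


def detect_signals(
    target_cases: set[str],
    comparator_cases: set[str],
    events: Iterable[AdeEvent],
    level: str = "PT",
    min_count: int = DEFAULT_MIN_COUNT,
    continuity_correction: bool = False,
) -> list[SignalResult]:
    """One SignalResult per term observed in the target cohort.

    Evaluable results come first, sorted by descending ROR with ties broken
    lexicographically by term; non-evaluable results follow, sorted by term.
    """
    overlap = target_cases & comparator_cases
    if overlap:
        raise ValueError(f"cohorts overlap on {len(overlap)} caseids")
    key = (lambda e: e.pt) if level == "PT" else (lambda e: e.soc)
    # one grouping pass instead of one events scan per term
    by_term: dict[str, set[str]] = {}
    for e in events:
        by_term.setdefault(key(e), set()).add(e.caseid)
    n_t, n_c = len(target_cases), len(comparator_cases)
    results = []
    for term in sorted(by_term):
        with_term = by_term[term]
        a = len(with_term & target_cases)
        if a == 0:
            continue  # term not observed in the target cohort
        c = len(with_term & comparator_cases)
        table = ContingencyTable(a=a, b=n_t - a, c=c, d=n_c - c)
        results.append(compute_ror(
            table, term=term, level=level, min_count=min_count,
            continuity_correction=continuity_correction,
        ))
    return sorted(
        results,
        key=lambda r: ((0, -r.ror, r.term) if r.evaluable else (1, 0.0, r.term)),
    )


@dataclass(frozen=True)
class VennPartition:
    """PT overlap between two cohorts: left-only, shared, right-only."""

    unique_left: frozenset[str]
    shared: frozenset[str]
    unique_right: frozenset[str]


def venn_partition(left_pts: set[str], right_pts: set[str]) -> VennPartition:
    return VennPartition(
        unique_left=frozenset(left_pts - right_pts),
        shared=frozenset(left_pts & right_pts),
        unique_right=frozenset(right_pts - left_pts),
    )


def unique_pt_signals(
    partition: VennPartition,
    left_cases: set[str],
    right_cases: set[str],
    background_cases: set[str],
    events: Iterable[AdeEvent],
    min_count: int = DEFAULT_MIN_COUNT,
) -> tuple[list[SignalResult], list[SignalResult]]:
    """Disproportionality for the formulation-unique PTs only.

    Each cohort's unique PTs are tested for that cohort against the shared
    background comparator (all cases where the target drug is not primary
    suspect). Shared PTs appear in neither list.
    """
    events = list(events)
    left = [
        compute_ror(
            build_contingency(t, "PT", left_cases, background_cases, events),
            term=t, level="PT", min_count=min_count,
        )
        for t in sorted(partition.unique_left)
    ]
    right = [
        compute_ror(
            build_contingency(t, "PT", right_cases, background_cases, events),
            term=t, level="PT", min_count=min_count,
        )
        for t in sorted(partition.unique_right)
    ]
    order = lambda r: ((0, -r.ror, r.term) if r.evaluable else (1, 0.0, r.term))
    return sorted(left, key=order), sorted(right, key=order)


def route_vs_route_ror(
    term: str,
    level: str,
    oral_cases: set[str],
    subcut_cases: set[str],
    events: Iterable[AdeEvent],
    min_count: int = DEFAULT_MIN_COUNT,
) -> SignalResult:
    """Head-to-head ROR of one term, oral cohort versus subcutaneous.

    The lower CI bound is the ROR_025 statistic: ROR_025 > 1 would mean the
    term is disproportionately reported with the oral formulation.
    """
    table = build_contingency(term, level, oral_cases, subcut_cases, events)
    return compute_ror(table, term=term, level=level, min_count=min_count)


def signal_table_rows(results: Sequence[SignalResult]) -> list[dict]:
    """Flatten results for TSV / forest-plot export."""
    rows = []
    for r in results:
        rows.append({
            "term": r.term,
            "level": r.level,
            "a": r.table.a, "b": r.table.b,
            "c": r.table.c, "d": r.table.d,
            "ror": f"{r.ror:.4f}" if r.evaluable else "",
            "ci_low": f"{r.ci_low:.4f}" if r.evaluable else "",
            "ci_high": f"{r.ci_high:.4f}" if r.evaluable else "",
            "is_signal": str(r.is_signal).lower(),
        })
    return rows
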