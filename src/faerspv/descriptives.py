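"""Descriptive tables: demographics, SOC/PT frequencies, serious outcomes,
time-to-onset summaries, and the FAERS-vs-social-media comparison.

Percentage convention: round-half-up to two decimals, computed as an exact
rational before quantizing so 0.005-boundary cases never fall to banker's
rounding. Frequency tables carry their own denominator and counting unit
(cases, events, reviews or review-events) and always recompute their
percentages from their own counts, so every emitted table is
self-consistent.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional, Sequence

import numpy as np

from .cases import CaseReport, onset_days
from .meddra import AdeEvent
from .records import CodedReview

SERIOUS_OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI"})
DEATH_LIFE_THREAT_CODES = frozenset({"DE", "LT"})

AGE_BANDS = ("<35", "35-65", ">65", "unknown")


def percent(count: int, denominator: int) -> float:
    """100*count/denominator, round-half-up to 2 decimals; 0 when empty."""
    if denominator == 0:
        return 0.0
    exact = Decimal(100 * count) / Decimal(denominator)
    return float(exact.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FrequencyRow:
    label: str
    count: int
    percent: float


@dataclass
class FrequencyTable:
    """Labelled counts with percentages of a stated denominator."""

    rows: list[FrequencyRow]
    denominator: int
    unit: str  # cases | events | reviews | review-events
    title: str = ""

    @classmethod
    def from_counts(
        cls,
        counts: Iterable[tuple[str, int]],
        denominator: int,
        unit: str,
        title: str = "",
    ) -> "FrequencyTable":
        rows = [
            FrequencyRow(label, n, percent(n, denominator))
            for label, n in counts
        ]
        return cls(rows=rows, denominator=denominator, unit=unit, title=title)

    def get(self, label: str) -> Optional[FrequencyRow]:
        for row in self.rows:
            if row.label == label:
                return row
        return None

    def to_tsv(self) -> str:
        lines = ["label\tcount\tpercent"]
        lines += [f"{r.label}\t{r.count}\t{r.percent:.2f}" for r in self.rows]
        return "\n".join(lines) + "\n"

    def to_markdown(self) -> str:
        head = self.title or "table"
        lines = [
            f"| {head} | n | % of {self.denominator} {self.unit} |",
            "| --- | ---: | ---: |",
        ]
        lines += [
            f"| {r.label} | {r.count} | {r.percent:.2f} |" for r in self.rows
        ]
        return "\n".join(lines) + "\n"


def _sorted_desc(counter: Counter) -> list[tuple[str, int]]:
    # descending count, ties alphabetical
    return sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))


def age_band(age_years: Optional[float]) -> str:
    if age_years is None:
        return "unknown"
    if age_years < 35:
        return "<35"
    if age_years <= 65:
        return "35-65"
    return ">65"


def demographics_table(
    cases: Sequence[CaseReport], top_countries: int = 10
) -> dict[str, FrequencyTable]:
    """Case-unit demographic tables: report year, age band, sex, country,
    reporter occupation. Percentages use the full case count, so bands plus
    their 'unknown' row account for every case."""
    n = len(cases)
    years = Counter(
        str(c.fda_dt.year) if c.fda_dt is not None else "unknown"
        for c in cases
    )
    ages = Counter(age_band(c.age_years) for c in cases)
    sexes = Counter(
        {"M": "male", "F": "female"}.get(c.sex or "", "unknown") for c in cases
    )
    countries = Counter(c.country for c in cases if c.country is not None)
    occupations = Counter(
        c.occupation for c in cases if c.occupation is not None
    )
    return {
        "year": FrequencyTable.from_counts(
            sorted(years.items()), n, "cases", "Report year"),
        "age_band": FrequencyTable.from_counts(
            [(b, ages.get(b, 0)) for b in AGE_BANDS], n, "cases", "Age"),
        "sex": FrequencyTable.from_counts(
            [(s, sexes.get(s, 0)) for s in ("male", "female", "unknown")],
            n, "cases", "Sex"),
        "country": FrequencyTable.from_counts(
            _sorted_desc(countries)[:top_countries], n, "cases", "Country"),
        "occupation": FrequencyTable.from_counts(
            _sorted_desc(occupations), n, "cases", "Reporter occupation"),
    }


def review_demographics_table(
    reviews: Sequence[CodedReview],
) -> dict[str, FrequencyTable]:
    """Demographics of coded reviews, on the review counting unit."""
    pseudo = [
        CaseReport(
            caseid=r.review_id, primaryid=r.review_id, fda_dt=r.date,
            event_dt=None, age_years=r.age, sex=r.sex, country=None,
            occupation=None, reactions=set(r.pts) or {"-"},
        )
        for r in reviews
    ]
    tables = demographics_table(pseudo)
    out = {}
    for name, table in tables.items():
        if name in ("country", "occupation"):
            continue
        out[name] = FrequencyTable(
            rows=table.rows, denominator=table.denominator,
            unit="reviews", title=table.title,
        )
    return out


def soc_frequency_table(
    events: Sequence[AdeEvent],
    denominator: Optional[int] = None,
    unit: str = "events",
) -> FrequencyTable:
    """SOC frequencies on the event counting unit (one per case-PT pair)."""
    counts = Counter(e.soc for e in events)
    return FrequencyTable.from_counts(
        _sorted_desc(counts),
        len(events) if denominator is None else denominator,
        unit,
        "System organ class",
    )


def pt_frequency_table(
    events: Sequence[AdeEvent],
    top_k: Optional[int] = 30,
    denominator: Optional[int] = None,
    unit: str = "events",
) -> FrequencyTable:
    """Top-k PT frequencies (event unit); ties broken alphabetically."""
    counts = _sorted_desc(Counter(e.pt for e in events))
    if top_k is not None:
        counts = counts[:top_k]
    return FrequencyTable.from_counts(
        counts,
        len(events) if denominator is None else denominator,
        unit,
        "Preferred term",
    )


def serious_outcome_rate(
    cases: Sequence[CaseReport],
    serious_codes: frozenset[str] = SERIOUS_OUTCOME_CODES,
) -> FrequencyTable:
    """Share of cases carrying at least one serious outcome code."""
    n_serious = sum(1 for c in cases if c.outcomes & serious_codes)
    return FrequencyTable.from_counts(
        [("serious", n_serious)], len(cases), "cases", "Serious outcomes",
    )


@dataclass
class OnsetSummary:
    """Median and quartiles of per-case days to onset."""

    n_usable: int
    median: Optional[float]
    q1: Optional[float]
    q3: Optional[float]
    n_negative_excluded: int = 0
    defined: bool = True


def onset_summary(cases: Sequence[CaseReport]) -> OnsetSummary:
    """Quantiles (linear interpolation) of usable onsets; negative onsets
    are excluded and counted, not clipped."""
    counters: Counter = Counter()
    onsets = [
        d for d in (onset_days(c, counters) for c in cases) if d is not None
    ]
    if not onsets:
        return OnsetSummary(
            n_usable=0, median=None, q1=None, q3=None,
            n_negative_excluded=counters["negative_onset"], defined=False,
        )
    q1, med, q3 = np.percentile(onsets, [25, 50, 75], method="linear")
    return OnsetSummary(
        n_usable=len(onsets), median=float(med), q1=float(q1), q3=float(q3),
        n_negative_excluded=counters["negative_onset"],
    )


@dataclass(frozen=True)
class ComparisonRow:
    label: str
    left_count: Optional[int]
    left_percent: Optional[float]
    right_count: Optional[int]
    right_percent: Optional[float]
    abs_difference: Optional[float]
    one_sided: Optional[str]  # "left" / "right" when absent from one source


def compare_sources(
    left: FrequencyTable, right: FrequencyTable
) -> list[ComparisonRow]:
    """Merge two frequency tables (e.g. FAERS vs social media) row-wise.

    Rows present in only one source are flagged rather than zero-filled,
    because absence of a SOC from a source is itself a finding. Order:
    descending combined percentage, then label.
    """
    left_rows = {r.label: r for r in left.rows}
    right_rows = {r.label: r for r in right.rows}
    merged: list[ComparisonRow] = []
    for label in set(left_rows) | set(right_rows):
        lr, rr = left_rows.get(label), right_rows.get(label)
        merged.append(ComparisonRow(
            label=label,
            left_count=lr.count if lr else None,
            left_percent=lr.percent if lr else None,
            right_count=rr.count if rr else None,
            right_percent=rr.percent if rr else None,
            abs_difference=(
                round(abs(lr.percent - rr.percent), 2) if lr and rr else None
            ),
            one_sided=None if lr and rr else ("left" if lr else "right"),
        ))
    merged.sort(
        key=lambda r: (
            -((r.left_percent or 0.0) + (r.right_percent or 0.0)), r.label,
        )
    )
    return merged


def comparison_to_csv(rows: Sequence[ComparisonRow]) -> str:
    lines = ["label,left_count,left_percent,right_count,right_percent,"
             "abs_difference,one_sided"]
    for r in rows:
        fmt = lambda v: "" if v is None else (
            f"{v:.2f}" if isinstance(v, float) else str(v)
        )
        lines.append(",".join([
            r.label.replace(",", ";"),
            fmt(r.left_count), fmt(r.left_percent),
            fmt(r.right_count), fmt(r.right_percent),
            fmt(r.abs_difference), r.one_sided or "",
        ]))
    return "\n".join(lines) + "\n"
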