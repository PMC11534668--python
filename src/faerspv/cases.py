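"""Deduplication and case assembly.

A FAERS case accumulates report versions over time; analyses must count
each case once. Deduplication keeps, per ``caseid``, the version with the
latest received date, breaking ties by the numerically largest
``primaryid`` — received date first because ``primaryid`` is the case id
plus a version suffix, so the latest received report is the current
version of the case. Selected versions are then joined across the five
tables into :class:`CaseReport` objects restricted to cases where the
target drug is a primary suspect.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .faers_io import QuarterTables
from .records import DatePrecision, DemoRecord, DrugRecord, PartialDate

logger = logging.getLogger(__name__)

DEFAULT_TARGET_PATTERNS = ("semaglutide", "ozempic", "wegovy", "rybelsus")

# FAERS age-unit factors converting to years
_AGE_FACTORS = {
    "DEC": 10.0, "YR": 1.0, "MON": 1.0 / 12.0, "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25, "HR": 1.0 / 8766.0,
}


@dataclass
class CaseReport:
    """One deduplicated spontaneous report with all tables joined."""

    caseid: str
    primaryid: str
    fda_dt: Optional[PartialDate]
    event_dt: Optional[PartialDate]
    age_years: Optional[float]
    sex: Optional[str]
    country: Optional[str]
    occupation: Optional[str]
    drugs: list[DrugRecord] = field(default_factory=list)
    reactions: set[str] = field(default_factory=set)
    outcomes: set[str] = field(default_factory=set)
    therapy_start: Optional[PartialDate] = None


def _dedup_key(record: DemoRecord) -> tuple[int, int]:
    # absent received date sorts before any real date
    fda = record.fda_dt.value if record.fda_dt is not None else -1
    return (fda, int(record.primaryid))


def deduplicate(demo: Iterable[DemoRecord]) -> dict[str, str]:
    """Map each caseid to its selected primaryid (latest received date,
    ties broken by largest numeric primaryid). Idempotent and independent
    of input order, since selection is a max under a total key."""
    best: dict[str, DemoRecord] = {}
    for record in demo:
        current = best.get(record.caseid)
        if current is None or _dedup_key(record) > _dedup_key(current):
            best[record.caseid] = record
    return {caseid: rec.primaryid for caseid, rec in best.items()}


def matches_target(drugname: str, patterns: Sequence[str]) -> bool:
    name = drugname.casefold()
    return any(p.casefold() in name for p in patterns)


def select_target_cases(
    drug: Iterable[DrugRecord],
    kept: dict[str, str],
    target_patterns: Sequence[str] = DEFAULT_TARGET_PATTERNS,
) -> set[str]:
    """Caseids whose selected report lists a target drug as primary suspect.

    Matching is case-insensitive substring over the free-text drugname, so
    trade names with salt qualifiers ("OZEMPIC (SEMAGLUTIDE)") match.
    """
    if not target_patterns:
        raise ValueError("target_patterns must be non-empty")
    selected_primaryids = {pid: cid for cid, pid in kept.items()}
    out: set[str] = set()
    for record in drug:
        if record.role_cod != "PS":
            continue
        caseid = selected_primaryids.get(record.primaryid)
        if caseid is None:
            continue
        if matches_target(record.drugname, target_patterns):
            out.add(caseid)
    return out


def normalize_age_years(age: Optional[float],
                        age_cod: Optional[str]) -> Optional[float]:
    """FAERS age in its reported unit -> years; unknown unit -> absent."""
    if age is None:
        return None
    factor = _AGE_FACTORS.get(age_cod or "YR")
    if factor is None:
        return None
    years = age * factor
    return years if years >= 0 else None


def assemble_cases(
    tables: QuarterTables,
    kept: dict[str, str],
    caseids: set[str],
    target_patterns: Sequence[str] = DEFAULT_TARGET_PATTERNS,
) -> list[CaseReport]:
    """Join the five tables into CaseReports for the given caseids.

    Joins are restricted to each case's selected primaryid. The therapy
    start is the earliest day-precision start date among therapy rows whose
    drug ordinal points at a target-drug row. Cases with no reactions are
    dropped with a warning: a spontaneous report without an adverse event
    is not analyzable.
    """
    wanted_pids = {kept[cid]: cid for cid in caseids if cid in kept}

    drugs_by_pid: dict[str, list[DrugRecord]] = {}
    for d in tables.drug:
        if d.primaryid in wanted_pids:
            drugs_by_pid.setdefault(d.primaryid, []).append(d)
    reac_by_pid: dict[str, set[str]] = {}
    for r in tables.reac:
        if r.primaryid in wanted_pids:
            reac_by_pid.setdefault(r.primaryid, set()).add(r.pt)
    outc_by_pid: dict[str, set[str]] = {}
    for o in tables.outc:
        if o.primaryid in wanted_pids:
            outc_by_pid.setdefault(o.primaryid, set()).add(o.outc_cod)
    ther_by_pid: dict[str, list] = {}
    for t in tables.ther:
        if t.primaryid in wanted_pids:
            ther_by_pid.setdefault(t.primaryid, []).append(t)

    cases: list[CaseReport] = []
    for demo in tables.demo:
        caseid = wanted_pids.get(demo.primaryid)
        if caseid is None:
            continue
        pid = demo.primaryid
        reactions = reac_by_pid.get(pid, set())
        if not reactions:
            logger.warning("case %s dropped: no reactions", caseid)
            continue
        drugs = sorted(drugs_by_pid.get(pid, []), key=lambda d: d.drug_seq)
        target_seqs = {
            d.drug_seq for d in drugs
            if d.role_cod == "PS" and matches_target(d.drugname, target_patterns)
        }
        starts = [
            t.start_dt for t in ther_by_pid.get(pid, [])
            if t.dsg_drug_seq in target_seqs
            and t.start_dt is not None
            and t.start_dt.precision is DatePrecision.DAY
        ]
        cases.append(CaseReport(
            caseid=caseid,
            primaryid=pid,
            fda_dt=demo.fda_dt,
            event_dt=demo.event_dt,
            age_years=normalize_age_years(demo.age, demo.age_cod),
            sex=demo.sex,
            country=demo.reporter_country,
            occupation=demo.occp_cod,
            drugs=drugs,
            reactions=reactions,
            outcomes=outc_by_pid.get(pid, set()),
            therapy_start=min(starts, default=None),
        ))
    return cases


def onset_days(case: CaseReport,
               counters: Optional[Counter] = None) -> Optional[int]:
    """Days from target-drug therapy start to event onset.

    Requires day precision on both sides; anything coarser is unusable.
    Negative intervals (event dated before therapy start) are excluded
    rather than clipped, and tallied in ``counters['negative_onset']``
    when a counter is supplied.
    """
    if case.therapy_start is None or case.event_dt is None:
        return None
    start = case.therapy_start.to_date()
    event = case.event_dt.to_date()
    if start is None or event is None:
        return None
    delta = (event - start).days
    if delta < 0:
        if counters is not None:
            counters["negative_onset"] += 1
        return None
    return delta
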