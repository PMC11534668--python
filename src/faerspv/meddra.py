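"""PT -> SOC mapping and event aggregation.

The counting unit for frequency tables is the adverse-event *event*: one
distinct (case, PT) pair, so a case reporting three terms contributes
three events but a term listed twice in one case counts once. SOC comes
from a single-SOC dictionary (primary-SOC style); terms missing from the
dictionary are returned, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .cases import CaseReport
from .faers_io import PtSocDictionary
from .records import CodedReview, normalize_pt


@dataclass(frozen=True)
class AdeEvent:
    """One adverse-event observation: a distinct (case, PT) pair."""

    caseid: str
    pt: str
    soc: str


def map_events(
    cases: Sequence[CaseReport], dictionary: PtSocDictionary
) -> tuple[list[AdeEvent], list[str]]:
    """Map each case's reactions to (case, PT, SOC) events.

    Returns the events and the sorted list of distinct unmapped PTs.
    Duplicate PTs within a case collapse via the case's reaction set;
    PT display casing comes from the dictionary.
    """
    events: list[AdeEvent] = []
    unmapped: set[str] = set()
    for case in cases:
        seen: set[str] = set()
        for pt in sorted(case.reactions):
            key = normalize_pt(pt)
            if key in seen:
                continue
            seen.add(key)
            soc = dictionary.get(pt)
            if soc is None:
                unmapped.add(pt)
            else:
                events.append(AdeEvent(case.caseid, dictionary.display(pt), soc))
    return events, sorted(unmapped)


def map_review_events(
    reviews: Sequence[CodedReview], dictionary: PtSocDictionary
) -> tuple[list[AdeEvent], list[str]]:
    """Same mapping for coded social-media reviews (review id as case id)."""
    pseudo_cases = [
        CaseReport(
            caseid=r.review_id, primaryid=r.review_id, fda_dt=r.date,
            event_dt=None, age_years=r.age, sex=r.sex, country=None,
            occupation=None, reactions=set(r.pts),
        )
        for r in reviews if r.pts
    ]
    return map_events(pseudo_cases, dictionary)


def observed_pts(events: Iterable[AdeEvent]) -> set[str]:
    """Distinct PTs among events."""
    return {e.pt for e in events}


def events_for_cases(events: Iterable[AdeEvent],
                     caseids: set[str]) -> list[AdeEvent]:
    return [e for e in events if e.caseid in caseids]
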