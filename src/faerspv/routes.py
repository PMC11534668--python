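"""Formulation (route) classification of target-drug cases.

Semaglutide ships as a once-daily oral tablet (Rybelsus) and once-weekly
subcutaneous injections (Ozempic, Wegovy), but FAERS drug rows identify the
formulation inconsistently: sometimes an explicit route, sometimes only a
dose form, trade name or dosing frequency. Classification applies keyword
rules field by field in a fixed precedence — route, then dose form, then
trade name, then dose frequency — chosen so the least ambiguous evidence
wins. The first field whose keywords fire decides; if keywords for *both*
formulations fire within that same field level across the case's
target-drug rows, the case is flagged as a conflict and excluded. Cases
where no rule fires at all are excluded from the route comparison.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

from .cases import CaseReport, DEFAULT_TARGET_PATTERNS, matches_target


class Route(enum.Enum):
    ORAL = "oral"
    SUBCUTANEOUS = "subcutaneous"
    UNCLASSIFIED = "unclassified"


# precedence order of the identifying fields
RULE_FIELDS = ("route", "dose_form", "drugname", "dose_freq")


@dataclass(frozen=True)
class RouteLabel:
    value: Route
    evidence: Optional[str] = None  # which field decided
    conflict: bool = False


class RouteRulebook:
    """Per-field keyword sets compiled to word-boundary regexes."""

    def __init__(self, rules: dict[str, dict[str, list[str]]]):
        unknown = set(rules) - set(RULE_FIELDS)
        if unknown:
            raise ValueError(f"unknown rulebook fields: {sorted(unknown)}")
        self._patterns: dict[str, list[tuple[Route, re.Pattern]]] = {}
        for fld in RULE_FIELDS:
            compiled = []
            for label, keywords in rules.get(fld, {}).items():
                route = Route(label)
                for kw in keywords:
                    compiled.append(
                        (route, re.compile(rf"\b{re.escape(kw)}\b", re.I))
                    )
            self._patterns[fld] = compiled

    def labels_for(self, fld: str, text: str) -> set[Route]:
        return {route for route, pat in self._patterns[fld]
                if pat.search(text)}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RouteRulebook":
        with Path(path).open("r", encoding="utf-8") as fh:
            return cls(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "RouteRulebook":
        return cls.from_yaml(Path(__file__).parent / "data" / "route_rules.yaml")


def classify_route(
    case: CaseReport,
    rulebook: Optional[RouteRulebook] = None,
    target_patterns: Sequence[str] = DEFAULT_TARGET_PATTERNS,
) -> RouteLabel:
    """Classify one case's target-drug formulation.

    Only the case's own primary-suspect target-drug rows are consulted, so
    classification is deterministic and local. Returns UNCLASSIFIED either
    when no field carries a recognized keyword or when one field level
    carries keywords for both formulations (``conflict=True``).
    """
    rulebook = rulebook or RouteRulebook.default()
    rows = [
        d for d in case.drugs
        if d.role_cod == "PS" and matches_target(d.drugname, target_patterns)
    ]
    for fld in RULE_FIELDS:
        hits: set[Route] = set()
        for row in rows:
            text = getattr(row, fld)
            if text:
                hits |= rulebook.labels_for(fld, text)
        if len(hits) == 1:
            return RouteLabel(hits.pop(), evidence=fld)
        if len(hits) > 1:
            return RouteLabel(Route.UNCLASSIFIED, evidence=fld, conflict=True)
    return RouteLabel(Route.UNCLASSIFIED)


def split_cohorts(
    cases: Sequence[CaseReport], labels: Iterable[RouteLabel]
) -> tuple[list[CaseReport], list[CaseReport], int]:
    """Partition cases by label into (oral, subcutaneous, n_excluded)."""
    oral: list[CaseReport] = []
    subcut: list[CaseReport] = []
    excluded = 0
    for case, label in zip(cases, labels, strict=True):
        if label.value is Route.ORAL:
            oral.append(case)
        elif label.value is Route.SUBCUTANEOUS:
            subcut.append(case)
        else:
            excluded += 1
    return oral, subcut, excluded
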