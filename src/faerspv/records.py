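"""Record types for FAERS-style spontaneous-report tables.

FAERS quarterly extracts split one case over five analytic tables (DEMO,
DRUG, REAC, OUTC, THER) keyed by ``primaryid``, the per-version report
identifier. Dates in these tables are frequently partial (YYYYMM or YYYY),
so they are kept as integers with an explicit precision tag rather than
coerced to calendar dates; downstream code decides what precision it needs.
"""

from __future__ import annotations

import datetime
import enum
import re
from dataclasses import dataclass, field
from typing import Optional

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
AGE_CODES = frozenset({"DEC", "YR", "MON", "WK", "DY", "HR"})
SEX_CODES = frozenset({"M", "F"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})
OCCUPATION_CODES = frozenset({"MD", "PH", "OT", "CN", "LW", "HP"})

_WS = re.compile(r"\s+")


def normalize_pt(pt: str) -> str:
    """Normalize a MedDRA Preferred Term for matching.

    Trims, collapses internal whitespace and case-folds. Original casing is
    preserved elsewhere for display; this form is only a dictionary key.
    """
    return _WS.sub(" ", pt.strip()).casefold()


class DatePrecision(enum.Enum):
    DAY = "day"
    MONTH = "month"
    YEAR = "year"


@dataclass(frozen=True, order=True)
class PartialDate:
    """A FAERS date: YYYYMMDD, YYYYMM or YYYY, tagged with its precision.

    Ordering compares the raw integers, which sorts coarser dates before any
    finer date (4-digit < 6-digit < 8-digit); deduplication relies only on
    comparisons within day-precision received dates, where integer order is
    calendar order.
    """

    value: int
    precision: DatePrecision = field(compare=False)

    @classmethod
    def parse(cls, text: str) -> Optional["PartialDate"]:
        """Parse a FAERS date field; empty -> None; malformed -> ValueError."""
        text = text.strip()
        if not text:
            return None
        if not text.isdigit():
            raise ValueError(f"not a numeric date: {text!r}")
        n = len(text)
        value = int(text)
        if n == 8:
            y, m, d = value // 10000, (value // 100) % 100, value % 100
            datetime.date(y, m, d)  # raises on invalid calendar dates
            return cls(value, DatePrecision.DAY)
        if n == 6:
            y, m = value // 100, value % 100
            if not (1 <= m <= 12 and 1900 <= y <= 2200):
                raise ValueError(f"invalid month date: {text}")
            return cls(value, DatePrecision.MONTH)
        if n == 4:
            if not 1900 <= value <= 2200:
                raise ValueError(f"implausible year: {text}")
            return cls(value, DatePrecision.YEAR)
        raise ValueError(f"date must be 4, 6 or 8 digits: {text!r}")

    def to_date(self) -> Optional[datetime.date]:
        """Calendar date if day-precision, else None."""
        if self.precision is not DatePrecision.DAY:
            return None
        v = self.value
        return datetime.date(v // 10000, (v // 100) % 100, v % 100)

    @property
    def year(self) -> int:
        v = self.value
        while v > 9999:
            v //= 100
        return v

    def __str__(self) -> str:
        return str(self.value)


@dataclass(frozen=True)
class DemoRecord:
    """One row of the DEMO table: one report version's demographics."""

    primaryid: str
    caseid: str
    fda_dt: Optional[PartialDate] = None
    event_dt: Optional[PartialDate] = None
    age: Optional[float] = None
    age_cod: Optional[str] = None
    sex: Optional[str] = None
    reporter_country: Optional[str] = None
    occp_cod: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.primaryid:
            raise ValueError("primaryid must be non-empty")
        if not self.caseid:
            raise ValueError("caseid must be non-empty")
        if self.age_cod is not None and self.age_cod not in AGE_CODES:
            raise ValueError(f"unknown age unit code: {self.age_cod!r}")
        if self.sex is not None and self.sex not in SEX_CODES:
            raise ValueError(f"unknown sex code: {self.sex!r}")
        if self.occp_cod is not None and self.occp_cod not in OCCUPATION_CODES:
            raise ValueError(f"unknown occupation code: {self.occp_cod!r}")


@dataclass(frozen=True)
class DrugRecord:
    """One row of the DRUG table: one drug within one report version."""

    primaryid: str
    drug_seq: int
    role_cod: str
    drugname: str
    route: Optional[str] = None
    dose_form: Optional[str] = None
    dose_freq: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.primaryid:
            raise ValueError("primaryid must be non-empty")
        if self.role_cod not in ROLE_CODES:
            raise ValueError(f"unknown drug role code: {self.role_cod!r}")
        if self.drug_seq < 1:
            raise ValueError("drug_seq must be >= 1")
        if not self.drugname:
            raise ValueError("drugname must be non-empty")


@dataclass(frozen=True)
class ReacRecord:
    """One row of the REAC table: one reported Preferred Term."""

    primaryid: str
    pt: str

    def __post_init__(self) -> None:
        if not self.primaryid:
            raise ValueError("primaryid must be non-empty")
        if not normalize_pt(self.pt):
            raise ValueError("pt must be non-empty")


@dataclass(frozen=True)
class OutcRecord:
    """One row of the OUTC table: one outcome flag for one report version."""

    primaryid: str
    outc_cod: str

    def __post_init__(self) -> None:
        if not self.primaryid:
            raise ValueError("primaryid must be non-empty")
        if self.outc_cod not in OUTCOME_CODES:
            raise ValueError(f"unknown outcome code: {self.outc_cod!r}")


@dataclass(frozen=True)
class TherRecord:
    """One row of the THER table: therapy dates for one drug of one report."""

    primaryid: str
    dsg_drug_seq: int
    start_dt: Optional[PartialDate] = None
    end_dt: Optional[PartialDate] = None

    def __post_init__(self) -> None:
        if not self.primaryid:
            raise ValueError("primaryid must be non-empty")
        if self.dsg_drug_seq < 1:
            raise ValueError("dsg_drug_seq must be >= 1")
        if (
            self.start_dt is not None
            and self.end_dt is not None
            and self.start_dt.precision is DatePrecision.DAY
            and self.end_dt.precision is DatePrecision.DAY
            and self.start_dt.value > self.end_dt.value
        ):
            raise ValueError("therapy start_dt after end_dt")


@dataclass(frozen=True)
class CodedReview:
    """One manually MedDRA-coded social-media drug review."""

    review_id: str
    date: Optional[PartialDate] = None
    age: Optional[float] = None
    sex: Optional[str] = None
    pts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.review_id:
            raise ValueError("review_id must be non-empty")
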