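"""Reading and writing FAERS-style quarterly ASCII tables.

The FDA distributes FAERS quarterly extracts as ``$``-delimited text files
with a single header row and no quoting. This module reads and writes that
dialect for the five tables the pipeline uses (DEMO, DRUG, REAC, OUTC,
THER), plus the two auxiliary inputs: a PT->SOC dictionary (2-column TSV)
and a pre-coded social-media review table (CSV).

Parsing is line-by-line: a malformed line (wrong field count, or a field
that fails its record invariant) is skipped and counted, never silently
dropped. Because the dialect has no quoting, free text containing ``$``
cannot be represented; such lines show up as field-count mismatches.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional

import pandas as pd

from .records import (
    CodedReview,
    DemoRecord,
    DrugRecord,
    OutcRecord,
    PartialDate,
    ReacRecord,
    TherRecord,
    normalize_pt,
)

logger = logging.getLogger(__name__)

DELIMITER = "$"

TABLE_COLUMNS: dict[str, tuple[str, ...]] = {
    "DEMO": (
        "primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
        "sex", "reporter_country", "occp_cod",
    ),
    "DRUG": (
        "primaryid", "drug_seq", "role_cod", "drugname", "route",
        "dose_form", "dose_freq",
    ),
    "REAC": ("primaryid", "pt"),
    "OUTC": ("primaryid", "outc_cod"),
    "THER": ("primaryid", "dsg_drug_seq", "start_dt", "end_dt"),
}


def table_filename(table: str, quarter_tag: str) -> str:
    return f"{table}{quarter_tag}.txt"


@dataclass
class ParseReport:
    """Per-table record and skip counts for one quarter read."""

    records_read: dict[str, int] = field(default_factory=dict)
    lines_skipped: dict[str, int] = field(default_factory=dict)

    @property
    def total_skipped(self) -> int:
        return sum(self.lines_skipped.values())


@dataclass
class QuarterTables:
    """In-memory contents of one quarter: five record lists."""

    demo: list[DemoRecord] = field(default_factory=list)
    drug: list[DrugRecord] = field(default_factory=list)
    reac: list[ReacRecord] = field(default_factory=list)
    outc: list[OutcRecord] = field(default_factory=list)
    ther: list[TherRecord] = field(default_factory=list)
    parse_report: ParseReport = field(default_factory=ParseReport)

    def counts(self) -> dict[str, int]:
        return {
            "DEMO": len(self.demo),
            "DRUG": len(self.drug),
            "REAC": len(self.reac),
            "OUTC": len(self.outc),
            "THER": len(self.ther),
        }


def _opt(value: str) -> Optional[str]:
    value = value.strip()
    return value or None


def _opt_float(value: str) -> Optional[float]:
    value = value.strip()
    return float(value) if value else None


def _opt_date(value: str) -> Optional[PartialDate]:
    return PartialDate.parse(value)


def _parse_demo(fields: list[str]) -> DemoRecord:
    return DemoRecord(
        primaryid=fields[0].strip(),
        caseid=fields[1].strip(),
        fda_dt=_opt_date(fields[2]),
        event_dt=_opt_date(fields[3]),
        age=_opt_float(fields[4]),
        age_cod=_opt(fields[5]),
        sex=_opt(fields[6]),
        reporter_country=_opt(fields[7]),
        occp_cod=_opt(fields[8]),
    )


def _parse_drug(fields: list[str]) -> DrugRecord:
    return DrugRecord(
        primaryid=fields[0].strip(),
        drug_seq=int(fields[1]),
        role_cod=fields[2].strip(),
        drugname=fields[3].strip(),
        route=_opt(fields[4]),
        dose_form=_opt(fields[5]),
        dose_freq=_opt(fields[6]),
    )


def _parse_reac(fields: list[str]) -> ReacRecord:
    return ReacRecord(primaryid=fields[0].strip(), pt=fields[1].strip())


def _parse_outc(fields: list[str]) -> OutcRecord:
    return OutcRecord(primaryid=fields[0].strip(), outc_cod=fields[1].strip())


def _parse_ther(fields: list[str]) -> TherRecord:
    return TherRecord(
        primaryid=fields[0].strip(),
        dsg_drug_seq=int(fields[1]),
        start_dt=_opt_date(fields[2]),
        end_dt=_opt_date(fields[3]),
    )


_PARSERS: dict[str, Callable[[list[str]], object]] = {
    "DEMO": _parse_demo,
    "DRUG": _parse_drug,
    "REAC": _parse_reac,
    "OUTC": _parse_outc,
    "THER": _parse_ther,
}


def _read_table(path: Path, table: str, report: ParseReport) -> list:
    columns = TABLE_COLUMNS[table]
    parser = _PARSERS[table]
    records: list = []
    skipped = 0
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        got = tuple(h.strip().lower() for h in header.split(DELIMITER))
        if got != columns:
            raise ValueError(
                f"{path.name}: unparseable header {header!r}; "
                f"expected columns {DELIMITER.join(columns)}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(DELIMITER)
            if len(fields) != len(columns):
                skipped += 1
                logger.warning(
                    "%s:%d skipped: %d fields, expected %d",
                    path.name, lineno, len(fields), len(columns),
                )
                continue
            try:
                records.append(parser(fields))
            except (ValueError, TypeError) as exc:
                skipped += 1
                logger.warning("%s:%d skipped: %s", path.name, lineno, exc)
    report.records_read[table] = len(records)
    report.lines_skipped[table] = skipped
    return records


def read_quarter(directory: str | Path, quarter_tag: str) -> QuarterTables:
    """Read the five quarterly tables from ``directory``.

    Raises FileNotFoundError naming the first missing table file, and
    ValueError on an unparseable header. Malformed data lines are skipped
    and tallied in the returned ``parse_report``.
    """
    directory = Path(directory)
    report = ParseReport()
    tables: dict[str, list] = {}
    for table in TABLE_COLUMNS:
        path = directory / table_filename(table, quarter_tag)
        if not path.exists():
            raise FileNotFoundError(f"missing FAERS table file: {path}")
        tables[table] = _read_table(path, table, report)
    result = QuarterTables(
        demo=tables["DEMO"],
        drug=tables["DRUG"],
        reac=tables["REAC"],
        outc=tables["OUTC"],
        ther=tables["THER"],
        parse_report=report,
    )
    for table, n in result.counts().items():
        logger.info(
            "%s%s: %d records, %d lines skipped",
            table, quarter_tag, n, report.lines_skipped[table],
        )
    return result


def _fmt(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


def _record_fields(record: object, columns: tuple[str, ...]) -> list[str]:
    out = []
    for col in columns:
        raw = getattr(record, col)
        text = _fmt(raw)
        if DELIMITER in text:
            raise ValueError(
                f"field {col!r} contains the delimiter {DELIMITER!r}: {text!r}"
            )
        out.append(text)
    return out


def write_quarter(
    tables: QuarterTables, directory: str | Path, quarter_tag: str
) -> list[Path]:
    """Write the five tables in the quarterly dialect; returns paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    by_table = {
        "DEMO": tables.demo,
        "DRUG": tables.drug,
        "REAC": tables.reac,
        "OUTC": tables.outc,
        "THER": tables.ther,
    }
    for table, columns in TABLE_COLUMNS.items():
        path = directory / table_filename(table, quarter_tag)
        with path.open("w", encoding="utf-8") as fh:
            fh.write(DELIMITER.join(columns) + "\n")
            for record in by_table[table]:
                fh.write(DELIMITER.join(_record_fields(record, columns)) + "\n")
        written.append(path)
    return written


class PtSocDictionary:
    """PT -> SOC mapping with case-insensitive, whitespace-normalized keys.

    Lookup is total over loaded terms and raises KeyError otherwise; use
    ``get`` for a tolerant probe. Display casing of the PT as loaded is kept
    alongside the mapping.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self._soc: dict[str, str] = {}
        self._display: dict[str, str] = {}
        for pt, soc in pairs:
            self.add(pt, soc)

    def add(self, pt: str, soc: str) -> None:
        key = normalize_pt(pt)
        soc = soc.strip()
        if key in self._soc and self._soc[key] != soc:
            raise ValueError(
                f"conflicting SOC for PT {pt!r}: "
                f"{self._soc[key]!r} vs {soc!r}"
            )
        self._soc[key] = soc
        self._display.setdefault(key, pt.strip())

    def __len__(self) -> int:
        return len(self._soc)

    def __contains__(self, pt: str) -> bool:
        return normalize_pt(pt) in self._soc

    def __getitem__(self, pt: str) -> str:
        return self._soc[normalize_pt(pt)]

    def get(self, pt: str, default: Optional[str] = None) -> Optional[str]:
        return self._soc.get(normalize_pt(pt), default)

    def display(self, pt: str) -> str:
        return self._display[normalize_pt(pt)]

    def items(self) -> Iterable[tuple[str, str]]:
        for key, soc in self._soc.items():
            yield self._display[key], soc


def read_pt_soc_dictionary(path: str | Path) -> PtSocDictionary:
    """Load a 2-column (pt, soc) TSV; conflicting duplicate PT rows error."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected a 2-column PT/SOC TSV")
    dictionary = PtSocDictionary()
    pt_col, soc_col = frame.columns[:2]
    for pt, soc in zip(frame[pt_col], frame[soc_col]):
        if pd.isna(pt) or not str(pt).strip():
            continue
        if pd.isna(soc) or not str(soc).strip():
            raise ValueError(f"{path}: PT {pt!r} has no SOC")
        dictionary.add(str(pt), str(soc))
    return dictionary


def default_dictionary() -> PtSocDictionary:
    """The packaged mini PT->SOC dictionary (a licensed MedDRA drop-in)."""
    path = Path(__file__).parent / "data" / "pt_soc_dictionary.tsv"
    return read_pt_soc_dictionary(path)


def read_coded_reviews(path: str | Path) -> list[CodedReview]:
    """Read a coded social-media review CSV.

    Columns: ``review_id`` (mandatory), ``date``, ``age``, ``sex``, ``pts``
    (semicolon-joined Preferred Terms). Reviews with an empty PT list are
    kept but logged, since they contribute demographics without events.
    """
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "review_id" not in reader.fieldnames:
            raise ValueError(f"{path}: missing mandatory 'review_id' column")
        reviews: list[CodedReview] = []
        for row in reader:
            pts = tuple(
                p.strip() for p in (row.get("pts") or "").split(";") if p.strip()
            )
            if not pts:
                logger.warning(
                    "review %s has no coded PTs", row["review_id"]
                )
            reviews.append(
                CodedReview(
                    review_id=row["review_id"].strip(),
                    date=PartialDate.parse(row.get("date") or ""),
                    age=_opt_float(row.get("age") or ""),
                    sex=_opt(row.get("sex") or ""),
                    pts=pts,
                )
            )
    return reviews


def write_coded_reviews(reviews: Iterable[CodedReview], path: str | Path) -> Path:
    """Write coded reviews in the CSV dialect ``read_coded_reviews`` expects."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["review_id", "date", "age", "sex", "pts"])
        for r in reviews:
            writer.writerow([
                r.review_id,
                _fmt(r.date),
                _fmt(r.age),
                _fmt(r.sex),
                ";".join(r.pts),
            ])
    return path
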