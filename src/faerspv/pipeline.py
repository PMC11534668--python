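"""End-to-end pipeline: ingest -> dedup -> assemble -> map -> classify ->
signals -> compare -> describe, with a machine-readable run manifest.

Every intermediate artifact is a plain TSV/CSV with a header so each stage
of a pharmacovigilance claim can be audited independently; the manifest
(YAML) records stage-by-stage counts and a SHA-256 checksum per output.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import cases as case_processing
from . import descriptives, meddra, signals, synthetic
from .cases import CaseReport, DEFAULT_TARGET_PATTERNS
from .descriptives import SERIOUS_OUTCOME_CODES
from .faers_io import (
    PtSocDictionary,
    QuarterTables,
    default_dictionary,
    read_coded_reviews,
    read_pt_soc_dictionary,
    read_quarter,
    write_coded_reviews,
)
from .records import CodedReview
from .routes import Route, RouteRulebook, classify_route, split_cohorts
from .signals import DEFAULT_MIN_COUNT, signal_table_rows

logger = logging.getLogger(__name__)

GI_SOC = "Gastrointestinal disorders"


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    output_dir: Path
    input_dir: Optional[Path] = None
    quarter_tag: str = "SIM"
    simulate: bool = False
    sim_config: Optional[synthetic.SimConfig] = None
    dictionary_path: Optional[Path] = None
    rulebook_path: Optional[Path] = None
    reviews_path: Optional[Path] = None
    target_patterns: Sequence[str] = DEFAULT_TARGET_PATTERNS
    min_count: int = DEFAULT_MIN_COUNT
    serious_codes: frozenset[str] = SERIOUS_OUTCOME_CODES
    top_k_pts: int = 30
    seed: int = 0

    def validate(self) -> None:
        if not self.simulate and self.input_dir is None:
            raise ValueError("either simulate=True or an input_dir is required")
        for path in (self.input_dir, self.dictionary_path,
                     self.rulebook_path, self.reviews_path):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configured path does not exist: {path}")
        if not self.target_patterns:
            raise ValueError("target_patterns must be non-empty")
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


@dataclass
class RunResult:
    """Everything a run computed, plus the manifest written to disk."""

    config: RunConfig
    manifest: dict
    target_cases: list[CaseReport]
    background_cases: list[CaseReport]
    oral_cases: list[CaseReport]
    subcut_cases: list[CaseReport]
    events: list[meddra.AdeEvent]
    pt_signals: list[signals.SignalResult]
    soc_signals: list[signals.SignalResult]
    venn: signals.VennPartition
    oral_unique: list[signals.SignalResult]
    subcut_unique: list[signals.SignalResult]
    gi_route_ror: Optional[signals.SignalResult]


def _write(path: Path, text: str, checksums: dict[str, str]) -> None:
    path.write_text(text, encoding="utf-8")
    checksums[path.name] = _sha256(path)


def _signals_tsv(results: Sequence[signals.SignalResult]) -> str:
    cols = ("term", "level", "a", "b", "c", "d",
            "ror", "ci_low", "ci_high", "is_signal")
    lines = ["\t".join(cols)]
    for row in signal_table_rows(results):
        lines.append("\t".join(str(row[c]) for c in cols))
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> RunResult:
    """Run every stage and write the output bundle under ``output_dir``."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}
    stages: dict[str, dict] = {}

    # --- ingest ---------------------------------------------------------
    reviews: list[CodedReview] = []
    if config.simulate:
        sim = config.sim_config or synthetic.SimConfig(seed=config.seed)
        tables, _truth = synthetic.write_simulation(sim, out / "simulated")
        dictionary = synthetic.catalog_dictionary(sim)
        reviews = synthetic.simulate_coded_reviews(sim, seed=sim.seed + 1)
        write_coded_reviews(reviews, out / "simulated" / "coded_reviews.csv")
        quarter_tag = sim.quarter_tag
    else:
        tables = read_quarter(config.input_dir, config.quarter_tag)
        dictionary = (
            read_pt_soc_dictionary(config.dictionary_path)
            if config.dictionary_path is not None else default_dictionary()
        )
        if config.reviews_path is not None:
            reviews = read_coded_reviews(config.reviews_path)
        quarter_tag = config.quarter_tag
    stages["ingest"] = {
        "quarter_tag": quarter_tag,
        "records": tables.counts(),
        "lines_skipped": dict(tables.parse_report.lines_skipped),
        "dictionary_terms": len(dictionary),
        "reviews": len(reviews),
    }

    # --- dedup ----------------------------------------------------------
    kept = case_processing.deduplicate(tables.demo)
    stages["dedup"] = {
        "report_versions": len(tables.demo),
        "unique_cases": len(kept),
        "duplicates_removed": len(tables.demo) - len(kept),
    }

    # --- assemble -------------------------------------------------------
    target_ids = case_processing.select_target_cases(
        tables.drug, kept, config.target_patterns
    )
    background_ids = set(kept) - target_ids
    target_cases = case_processing.assemble_cases(
        tables, kept, target_ids, config.target_patterns
    )
    background_cases = case_processing.assemble_cases(
        tables, kept, background_ids, config.target_patterns
    )
    stages["assemble"] = {
        "target_cases": len(target_cases),
        "background_cases": len(background_cases),
        "dropped_no_reaction": (
            len(target_ids) - len(target_cases)
            + len(background_ids) - len(background_cases)
        ),
    }
    # audit table: one row per target case
    case_lines = ["caseid\tprimaryid\tfda_dt\tage_years\tsex\tcountry\t"
                  "n_drugs\tn_reactions\tonset_days"]
    for c in target_cases:
        onset = case_processing.onset_days(c)
        case_lines.append("\t".join(str(v) if v is not None else "" for v in (
            c.caseid, c.primaryid, c.fda_dt, c.age_years, c.sex, c.country,
            len(c.drugs), len(c.reactions), onset,
        )))
    _write(out / "cases.tsv", "\n".join(case_lines) + "\n", checksums)

    # --- map ------------------------------------------------------------
    all_cases = target_cases + background_cases
    events, unmapped = meddra.map_events(all_cases, dictionary)
    stages["map"] = {"events": len(events), "unmapped_pts": len(unmapped)}
    event_lines = ["caseid\tpt\tsoc"]
    event_lines += [f"{e.caseid}\t{e.pt}\t{e.soc}" for e in events]
    _write(out / "events.tsv", "\n".join(event_lines) + "\n", checksums)
    if unmapped:
        logger.warning("%d PTs missing from the dictionary: %s",
                       len(unmapped), ", ".join(unmapped[:10]))

    # --- classify -------------------------------------------------------
    rulebook = (
        RouteRulebook.from_yaml(config.rulebook_path)
        if config.rulebook_path is not None else RouteRulebook.default()
    )
    labels = [
        classify_route(c, rulebook, config.target_patterns)
        for c in target_cases
    ]
    oral_cases, subcut_cases, excluded = split_cohorts(target_cases, labels)
    stages["classify"] = {
        "oral": len(oral_cases),
        "subcutaneous": len(subcut_cases),
        "excluded_unclassified": excluded,
        "conflicts": sum(1 for l in labels if l.conflict),
    }
    label_lines = ["caseid\tlabel\tevidence"]
    label_lines += [
        f"{c.caseid}\t{l.value.value}\t{l.evidence or ''}"
        for c, l in zip(target_cases, labels)
    ]
    _write(out / "route_labels.tsv", "\n".join(label_lines) + "\n", checksums)

    # --- signals --------------------------------------------------------
    target_id_set = {c.caseid for c in target_cases}
    background_id_set = {c.caseid for c in background_cases}
    oral_id_set = {c.caseid for c in oral_cases}
    subcut_id_set = {c.caseid for c in subcut_cases}
    pt_signals = signals.detect_signals(
        target_id_set, background_id_set, events, "PT", config.min_count
    )
    soc_signals = signals.detect_signals(
        target_id_set, background_id_set, events, "SOC", config.min_count
    )
    oral_events = meddra.events_for_cases(events, oral_id_set)
    subcut_events = meddra.events_for_cases(events, subcut_id_set)
    venn = signals.venn_partition(
        meddra.observed_pts(oral_events), meddra.observed_pts(subcut_events)
    )
    oral_unique, subcut_unique = signals.unique_pt_signals(
        venn, oral_id_set, subcut_id_set, background_id_set,
        events, config.min_count,
    )
    gi_route = (
        signals.route_vs_route_ror(
            GI_SOC, "SOC", oral_id_set, subcut_id_set, events,
            config.min_count,
        )
        if oral_cases and subcut_cases else None
    )
    stages["signals"] = {
        "terms_tested_pt": len(pt_signals),
        "terms_tested_soc": len(soc_signals),
        "signals_pt": sum(1 for r in pt_signals if r.is_signal),
        "signals_soc": sum(1 for r in soc_signals if r.is_signal),
        "venn": {
            "oral_unique": len(venn.unique_left),
            "shared": len(venn.shared),
            "subcutaneous_unique": len(venn.unique_right),
        },
        "gi_ror_025": (
            round(gi_route.ci_low, 4)
            if gi_route is not None and gi_route.evaluable else None
        ),
    }
    _write(out / "signals_pt.tsv", _signals_tsv(pt_signals), checksums)
    _write(out / "signals_soc.tsv", _signals_tsv(soc_signals), checksums)
    _write(out / "signals_oral_unique.tsv", _signals_tsv(oral_unique), checksums)
    _write(out / "signals_subcut_unique.tsv", _signals_tsv(subcut_unique),
           checksums)
    # forest-plot export: evaluable PT signals only, ror + CI per term
    forest = [r for r in pt_signals if r.evaluable]
    _write(out / "forest_plot.tsv", _signals_tsv(forest), checksums)

    # --- compare (FAERS vs coded reviews) -------------------------------
    faers_soc = descriptives.soc_frequency_table(
        meddra.events_for_cases(events, target_id_set)
    )
    if reviews:
        review_events, _ = meddra.map_review_events(reviews, dictionary)
        review_soc = descriptives.soc_frequency_table(
            review_events, unit="review-events"
        )
        comparison = descriptives.compare_sources(faers_soc, review_soc)
        _write(out / "source_comparison.csv",
               descriptives.comparison_to_csv(comparison), checksums)
        stages["compare"] = {
            "review_events": len(review_events),
            "rows": len(comparison),
            "one_sided": sum(1 for r in comparison if r.one_sided),
        }
    else:
        stages["compare"] = {"review_events": 0, "rows": 0, "one_sided": 0}

    # --- describe -------------------------------------------------------
    demo_tables = descriptives.demographics_table(target_cases)
    target_events = meddra.events_for_cases(events, target_id_set)
    pt_table = descriptives.pt_frequency_table(target_events, config.top_k_pts)
    onset_all = descriptives.onset_summary(target_cases)
    onset_oral = descriptives.onset_summary(oral_cases)
    onset_subcut = descriptives.onset_summary(subcut_cases)
    serious_oral = descriptives.serious_outcome_rate(
        oral_cases, config.serious_codes
    )
    serious_subcut = descriptives.serious_outcome_rate(
        subcut_cases, config.serious_codes
    )
    for name, table in demo_tables.items():
        _write(out / f"table_demographics_{name}.tsv", table.to_tsv(), checksums)
    _write(out / "table_soc.tsv", faers_soc.to_tsv(), checksums)
    _write(out / "table_pt_top.tsv", pt_table.to_tsv(), checksums)
    markdown = "\n".join(
        [t.to_markdown() for t in demo_tables.values()]
        + [faers_soc.to_markdown(), pt_table.to_markdown()]
    )
    _write(out / "tables.md", markdown, checksums)
    stages["describe"] = {
        "onset": {
            "all": _onset_dict(onset_all),
            "oral": _onset_dict(onset_oral),
            "subcutaneous": _onset_dict(onset_subcut),
        },
        "serious_percent": {
            "oral": serious_oral.rows[0].percent if oral_cases else None,
            "subcutaneous": (
                serious_subcut.rows[0].percent if subcut_cases else None
            ),
        },
    }

    manifest = {
        "config": {
            "quarter_tag": quarter_tag,
            "simulate": config.simulate,
            "target_patterns": list(config.target_patterns),
            "min_count": config.min_count,
            "serious_codes": sorted(config.serious_codes),
            "top_k_pts": config.top_k_pts,
            "seed": config.seed,
        },
        "stages": stages,
        "checksums": checksums,
    }
    with (out / "manifest.yaml").open("w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)

    return RunResult(
        config=config, manifest=manifest,
        target_cases=target_cases, background_cases=background_cases,
        oral_cases=oral_cases, subcut_cases=subcut_cases,
        events=events, pt_signals=pt_signals, soc_signals=soc_signals,
        venn=venn, oral_unique=oral_unique, subcut_unique=subcut_unique,
        gi_route_ror=gi_route,
    )


def _onset_dict(summary: descriptives.OnsetSummary) -> dict:
    return {
        "n_usable": summary.n_usable,
        "median": summary.median,
        "q1": summary.q1,
        "q3": summary.q3,
        "n_negative_excluded": summary.n_negative_excluded,
    }
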