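"""Self-validation studies: calibration, recovery, dedup bookkeeping.

Each study generates a synthetic extract with known ground truth, pushes
it through the same stages a real analysis uses (deduplicate, select,
assemble, map, detect), and measures how well the pipeline recovers what
was embedded. Study sizes default to the conditions the package treats as
its reference validation scale: 2,000 null term-arms at 2,500 cases/arm
for calibration, and 5,000 cases/arm for parameter recovery.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Sequence

from .cases import assemble_cases, deduplicate, select_target_cases
from .meddra import map_events
from .signals import SignalResult, detect_signals
from .synthetic import PtSpec, SimConfig, catalog_dictionary, simulate_reports


def _run_detection(config: SimConfig, min_count: int = 3
                   ) -> tuple[list[SignalResult], dict[str, float], "SimConfig"]:
    """simulate -> dedup -> select -> assemble -> map -> detect."""
    tables, truth = simulate_reports(config)
    kept = deduplicate(tables.demo)
    target_ids = select_target_cases(tables.drug, kept)
    target = assemble_cases(tables, kept, target_ids)
    background = assemble_cases(tables, kept, set(kept) - target_ids)
    events, _ = map_events(target + background, catalog_dictionary(config))
    results = detect_signals(
        {c.caseid for c in target}, {c.caseid for c in background},
        events, "PT", min_count,
    )
    embedded = {pt: ror for pt, (ror, _, _) in truth.pt_params.items()}
    return results, embedded, config


@dataclass
class CalibrationResult:
    n_arms: int
    n_evaluable: int
    n_signals: int

    @property
    def signal_rate(self) -> float:
        return self.n_signals / self.n_evaluable if self.n_evaluable else 0.0


def null_calibration_study(
    seed: int,
    n_arms: int = 2000,
    n_per_arm: int = 2500,
    baseline: float = 0.02,
) -> CalibrationResult:
    """All embedded RORs = 1: the fraction of term-arms flagged as signals
    estimates the one-sided false-positive rate of the 95% interval
    criterion, which should sit near 2.5%."""
    catalog = [PtSpec(f"Null term {i:04d}", "Null SOC") for i in range(n_arms)]
    config = SimConfig(
        n_cases_target=n_per_arm, n_cases_background=n_per_arm,
        pt_catalog=catalog, baseline_prob=baseline,
        duplicate_fraction=0.0, seed=seed,
    )
    results, _, _ = _run_detection(config)
    arms = [r for r in results if r.term.startswith("Null term")]
    evaluable = [r for r in arms if r.evaluable]
    return CalibrationResult(
        n_arms=len(arms),
        n_evaluable=len(evaluable),
        n_signals=sum(1 for r in evaluable if r.is_signal),
    )


@dataclass
class RecoveryResult:
    n_terms: int
    n_covered: int                      # embedded ROR inside estimated 95% CI
    flagged_by_ror: dict[float, float]  # embedded ROR -> fraction flagged
    estimates: dict[str, tuple[float, float]]  # term -> (embedded, estimated)

    @property
    def coverage(self) -> float:
        return self.n_covered / self.n_terms if self.n_terms else 0.0


def recovery_study(
    seed: int,
    rors: Sequence[float] = (0.5, 1.0, 2.0, 5.0, 36.0),
    terms_per_level: int = 40,
    n_per_arm: int = 5000,
    baseline: float = 0.01,
) -> RecoveryResult:
    """Embedded RORs across the signal range: measures how often the
    estimated 95% CI covers the embedded value and how reliably strong
    signals are flagged."""
    catalog = [
        PtSpec(f"Term r{ror:g} {i:02d}", "Recovery SOC", ror)
        for ror in rors for i in range(terms_per_level)
    ]
    config = SimConfig(
        n_cases_target=n_per_arm, n_cases_background=n_per_arm,
        pt_catalog=catalog, baseline_prob=baseline,
        duplicate_fraction=0.0, seed=seed,
    )
    results, embedded, _ = _run_detection(config)
    by_term = {r.term: r for r in results}
    n_covered = 0
    n_terms = 0
    flagged: dict[float, list[bool]] = {ror: [] for ror in rors}
    estimates: dict[str, tuple[float, float]] = {}
    for spec in catalog:
        r = by_term.get(spec.pt)
        if r is None or not r.evaluable:
            continue
        n_terms += 1
        if r.ci_low <= embedded[spec.pt] <= r.ci_high:
            n_covered += 1
        flagged[spec.ror].append(r.is_signal)
        estimates[spec.pt] = (embedded[spec.pt], r.ror)
    return RecoveryResult(
        n_terms=n_terms,
        n_covered=n_covered,
        flagged_by_ror={
            ror: (sum(v) / len(v) if v else 0.0) for ror, v in flagged.items()
        },
        estimates=estimates,
    )


@dataclass
class DedupResult:
    true_cases: int
    report_versions: int
    recovered_cases: int
    idempotent: bool
    order_invariant: bool


def dedup_study(
    seed: int,
    n_cases: int = 1000,
    duplicate_fraction: float = 0.2,
) -> DedupResult:
    """Duplicated report versions: the recovered unique-case count must
    equal ground truth exactly, and selection must not depend on input
    order or repeated application."""
    config = SimConfig(
        n_cases_target=n_cases // 2,
        n_cases_background=n_cases - n_cases // 2,
        duplicate_fraction=duplicate_fraction, seed=seed,
    )
    tables, truth = simulate_reports(config)
    selected = deduplicate(tables.demo)
    shuffled = list(tables.demo)
    random.Random(seed).shuffle(shuffled)
    order_invariant = deduplicate(shuffled) == selected
    kept_records = [r for r in tables.demo if r.primaryid in set(selected.values())]
    idempotent = deduplicate(kept_records) == selected
    return DedupResult(
        true_cases=truth.n_cases,
        report_versions=truth.n_report_versions,
        recovered_cases=len(selected),
        idempotent=idempotent,
        order_invariant=order_invariant,
    )
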