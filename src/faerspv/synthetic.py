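"""Synthetic FAERS-like report generator with known embedded signals.

Spontaneous-report databases have no ground truth: nobody knows the real
reporting odds ratio behind an observed 2x2 table. This module manufactures
that ground truth. It emits quarterly tables in the exact dialect
:mod:`faerspv.faers_io` reads, built from two arms of cases — target-drug
cases (the drug under surveillance as primary suspect) and background cases
(all other drugs) — where every Preferred Term in the catalog occurs with
per-arm probabilities chosen so the *population* reporting odds ratio equals
a configured value exactly.

The embedding holds the background occurrence probability ``p_b`` fixed and
solves the odds equation for the target-arm probability::

    odds_t / odds_b = r   =>   p_t = r * odds_b / (1 + r * odds_b)

so the population odds ratio is exact, not approximate. Duplicated report
versions, demographic missingness, partial dates, route-revealing drug
fields and serious-outcome flags are layered on top with configurable
rates, giving each downstream stage (deduplication, route classification,
disproportionality, onset analysis) a recoverable truth to be checked
against.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .faers_io import PtSocDictionary, QuarterTables, write_quarter
from .records import (
    CodedReview,
    DatePrecision,
    DemoRecord,
    DrugRecord,
    OutcRecord,
    PartialDate,
    ReacRecord,
    TherRecord,
)

TARGET_DRUG = "SEMAGLUTIDE"
ORAL, SUBCUTANEOUS, UNCLASSIFIABLE = "oral", "subcutaneous", "unclassifiable"

_BACKGROUND_DRUGS = (
    "METFORMIN", "LIRAGLUTIDE", "DULAGLUTIDE", "INSULIN GLARGINE",
    "ATORVASTATIN", "EMPAGLIFLOZIN", "LISINOPRIL", "LEVOTHYROXINE",
)
_COUNTRIES = ("US", "GB", "CA", "JP", "FR", "BR", "DK", "AU")
_COUNTRY_P = (0.86, 0.028, 0.028, 0.024, 0.015, 0.015, 0.015, 0.015)
_OCCUPATIONS = ("MD", "PH", "HP", "CN", "OT")
_OCCUPATION_P = (0.35, 0.20, 0.22, 0.20, 0.03)

_EPOCH = datetime.date(2018, 1, 1).toordinal()
_SPAN = datetime.date(2023, 6, 30).toordinal() - _EPOCH


@dataclass(frozen=True)
class PtSpec:
    """One catalog term: its SOC, embedded reporting odds ratio, and an
    optional route restriction (the PT then occurs only in target cases of
    that formulation, which makes it a formulation-unique signal)."""

    pt: str
    soc: str
    ror: float = 1.0
    route: Optional[str] = None
    baseline: Optional[float] = None  # overrides SimConfig.baseline_prob

    def __post_init__(self) -> None:
        if self.ror < 0:
            raise ValueError(f"embedded ROR must be >= 0 for {self.pt!r}")
        if self.route not in (None, ORAL, SUBCUTANEOUS):
            raise ValueError(f"unknown route restriction {self.route!r}")
        if self.baseline is not None and not 0.0 < self.baseline < 1.0:
            raise ValueError(f"baseline must be in (0, 1) for {self.pt!r}")


def default_pt_catalog() -> list[PtSpec]:
    """A compact surveillance catalog: common GI terms with elevated odds,
    a spread of null terms across organ classes, and one formulation-unique
    strong signal per route."""
    gi = "Gastrointestinal disorders"
    elevated = [
        PtSpec("Nausea", gi, 8.0),
        PtSpec("Vomiting", gi, 6.0),
        PtSpec("Diarrhoea", gi, 5.0),
        PtSpec("Constipation", gi, 3.0),
        PtSpec("Eructation", gi, 12.0),
        PtSpec("Decreased appetite", "Metabolism and nutrition disorders", 10.0),
        PtSpec("Weight decreased", "Investigations", 6.0),
        PtSpec("Pancreatitis", gi, 4.0),
    ]
    # formulation-unique terms are rare in the background (device issues,
    # contractures), so their strong odds ratios rest on few reports and
    # carry wide confidence intervals
    unique = [
        PtSpec("Dupuytren's contracture",
               "Musculoskeletal and connective tissue disorders",
               40.0, route=ORAL, baseline=0.0008),
        PtSpec("Pancreatic failure", gi, 36.0, route=SUBCUTANEOUS,
               baseline=0.0008),
        PtSpec("Device leakage", "Product issues", 20.0, route=SUBCUTANEOUS,
               baseline=0.002),
        PtSpec("Injection phobia", "Psychiatric disorders", 15.0,
               route=SUBCUTANEOUS, baseline=0.002),
    ]
    null = [
        PtSpec("Headache", "Nervous system disorders"),
        PtSpec("Dizziness", "Nervous system disorders"),
        PtSpec("Fatigue", "General disorders and administration site conditions"),
        PtSpec("Rash", "Skin and subcutaneous tissue disorders"),
        PtSpec("Back pain", "Musculoskeletal and connective tissue disorders"),
        PtSpec("Insomnia", "Psychiatric disorders"),
        PtSpec("Cough", "Respiratory, thoracic and mediastinal disorders"),
        PtSpec("Nasopharyngitis", "Infections and infestations"),
        PtSpec("Hypertension", "Vascular disorders"),
        PtSpec("Vision blurred", "Eye disorders"),
        PtSpec("Palpitations", "Cardiac disorders"),
        PtSpec("Anaemia", "Blood and lymphatic system disorders"),
    ]
    return elevated + unique + null


@dataclass
class SimConfig:
    """Study conditions for one simulated surveillance extract.

    Defaults emulate the scale and mix of a single-drug FAERS cohort study:
    two arms of 5,000 cases, 20% of cases filed as two report versions,
    an oral/subcutaneous/unidentifiable formulation mix of 13%/85%/2%,
    log-normal days-to-onset with median 4, and FAERS-like missingness
    (age absent in ~45% of reports, many partial event dates).
    """

    n_cases_target: int = 5000
    n_cases_background: int = 5000
    duplicate_fraction: float = 0.2
    pt_catalog: list[PtSpec] = field(default_factory=default_pt_catalog)
    baseline_prob: float = 0.01
    route_mix: dict[str, float] = field(default_factory=lambda: {
        ORAL: 0.13, SUBCUTANEOUS: 0.85, UNCLASSIFIABLE: 0.02,
    })
    onset_distribution: dict[str, float] = field(default_factory=lambda: {
        "median_days": 4.0, "sigma": 2.0,
    })
    missingness: dict[str, float] = field(default_factory=lambda: {
        "age": 0.45, "sex": 0.04, "reporter_country": 0.02,
        "occp_cod": 0.10, "event_dt": 0.25, "start_dt": 0.25,
        "event_dt_partial": 0.10,
    })
    serious_outcome_prob: dict[str, float] = field(default_factory=lambda: {
        "DE": 0.008, "LT": 0.005, "HO": 0.02, "DS": 0.003,
        "CA": 0.0005, "RI": 0.002, "OT": 0.05,
    })
    duplicate_field_noise: bool = False
    # catch-all terms for cases with no catalog reaction, spread over SOCs
    # the way FAERS miscellaneous reporting is; must not collide with the
    # catalog, so embedded per-term probabilities stay exact
    filler_terms: list[tuple[str, str]] = field(default_factory=lambda: [
        ("Drug ineffective",
         "General disorders and administration site conditions"),
        ("Off label use", "Injury, poisoning and procedural complications"),
        ("Malaise", "General disorders and administration site conditions"),
        ("Dysgeusia", "Nervous system disorders"),
        ("Pruritus", "Skin and subcutaneous tissue disorders"),
        ("Vertigo", "Ear and labyrinth disorders"),
    ])
    quarter_tag: str = "SIM"
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases_target < 0 or self.n_cases_background < 0:
            raise ValueError("case counts must be non-negative")
        if not 0.0 <= self.duplicate_fraction <= 1.0:
            raise ValueError("duplicate_fraction must be in [0, 1]")
        if not 0.0 < self.baseline_prob < 1.0:
            raise ValueError("baseline_prob must be in (0, 1)")
        mix = self.route_mix
        if set(mix) != {ORAL, SUBCUTANEOUS, UNCLASSIFIABLE}:
            raise ValueError("route_mix must cover oral/subcutaneous/unclassifiable")
        if any(not 0.0 <= p <= 1.0 for p in mix.values()):
            raise ValueError("route_mix proportions must be in [0, 1]")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("route_mix must sum to 1")
        for prob in self.missingness.values():
            if not 0.0 <= prob <= 1.0:
                raise ValueError("missingness probabilities must be in [0, 1]")
        for prob in self.serious_outcome_prob.values():
            if not 0.0 <= prob <= 1.0:
                raise ValueError("outcome probabilities must be in [0, 1]")
        for spec in self.pt_catalog:
            target_occurrence_prob(
                spec.ror, spec.baseline or self.baseline_prob, spec.pt
            )
        if not self.filler_terms:
            raise ValueError("filler_terms must be non-empty")
        catalog_pts = {s.pt for s in self.pt_catalog}
        colliding = catalog_pts & {pt for pt, _ in self.filler_terms}
        if colliding:
            raise ValueError(
                f"filler terms collide with catalog PTs: {sorted(colliding)}"
            )

    def to_dict(self) -> dict:
        return {
            "n_cases_target": self.n_cases_target,
            "n_cases_background": self.n_cases_background,
            "duplicate_fraction": self.duplicate_fraction,
            "baseline_prob": self.baseline_prob,
            "pt_catalog": [
                {"pt": s.pt, "soc": s.soc, "ror": s.ror, "route": s.route,
                 "baseline": s.baseline}
                for s in self.pt_catalog
            ],
            "route_mix": dict(self.route_mix),
            "onset_distribution": dict(self.onset_distribution),
            "missingness": dict(self.missingness),
            "serious_outcome_prob": dict(self.serious_outcome_prob),
            "duplicate_field_noise": self.duplicate_field_noise,
            "filler_terms": [list(t) for t in self.filler_terms],
            "quarter_tag": self.quarter_tag,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data)
        catalog = data.pop("pt_catalog", None)
        fillers = data.pop("filler_terms", None)
        config = cls(**data)
        if catalog is not None:
            config.pt_catalog = [PtSpec(**entry) for entry in catalog]
        if fillers is not None:
            config.filler_terms = [tuple(t) for t in fillers]
        return config


def target_occurrence_prob(ror: float, baseline_prob: float,
                           pt: str = "?") -> float:
    """Per-case occurrence probability in the target arm that embeds ``ror``
    against a background probability ``baseline_prob`` (exact on the odds
    scale). Raises if the implied probability is not a probability."""
    odds_b = baseline_prob / (1.0 - baseline_prob)
    odds_t = ror * odds_b
    p_t = odds_t / (1.0 + odds_t)
    if not np.isfinite(p_t) or p_t >= 1.0 or p_t < 0.0:
        raise ValueError(
            f"infeasible occurrence probability for PT {pt!r}: "
            f"ror={ror}, baseline={baseline_prob}"
        )
    return p_t


@dataclass
class GroundTruth:
    """What the generator actually did, for oracle checks downstream."""

    target_caseids: list[str]
    background_caseids: list[str]
    case_route: dict[str, str]
    pt_params: dict[str, tuple[float, float, float]]  # pt -> (ror, p_t, p_b)
    pt_counts: dict[str, tuple[int, int]]  # pt -> (target cases, background cases)
    n_report_versions: int

    @property
    def n_cases(self) -> int:
        return len(self.target_caseids) + len(self.background_caseids)


def _date_of(ordinal: int) -> PartialDate:
    d = datetime.date.fromordinal(int(ordinal))
    return PartialDate(d.year * 10000 + d.month * 100 + d.day,
                       precision=DatePrecision.DAY)


def _month_of(ordinal: int) -> PartialDate:
    d = datetime.date.fromordinal(int(ordinal))
    return PartialDate.parse(f"{d.year * 100 + d.month:06d}")


def simulate_reports(config: SimConfig) -> tuple[QuarterTables, GroundTruth]:
    """Generate one synthetic quarterly extract plus its ground truth.

    Every case has at least one drug (target cases carry the target drug as
    primary suspect) and at least one reaction (a neutral filler PT outside
    the catalog is used when no catalog term fires, so catalog occurrence
    probabilities stay exactly as configured). Duplicated cases are emitted
    as two report versions sharing a caseid, with increasing primaryid and
    non-decreasing received date; by default only primaryid and fda_dt
    differ between versions.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_t, n_b = config.n_cases_target, config.n_cases_background
    n = n_t + n_b

    caseids = [str(1_000_000 + i) for i in range(n_t)]
    caseids += [str(2_000_000 + i) for i in range(n_b)]
    is_target = np.arange(n) < n_t

    # formulation label per target case
    route_names = (ORAL, SUBCUTANEOUS, UNCLASSIFIABLE)
    route_p = [config.route_mix[r] for r in route_names]
    route_idx = rng.choice(3, size=n, p=route_p)
    case_route = {
        cid: route_names[route_idx[i]]
        for i, cid in enumerate(caseids) if is_target[i]
    }

    # reactions: per-catalog-PT Bernoulli occurrence, exact odds embedding
    reactions: list[list[str]] = [[] for _ in range(n)]
    pt_params: dict[str, tuple[float, float, float]] = {}
    pt_counts: dict[str, tuple[int, int]] = {}
    for spec in config.pt_catalog:
        p_b = spec.baseline or config.baseline_prob
        p_t = target_occurrence_prob(spec.ror, p_b, spec.pt)
        draws = rng.random(n)
        occurs = np.where(is_target, draws < p_t, draws < p_b)
        if spec.route is not None:
            allowed = np.array(
                [route_names[route_idx[i]] == spec.route for i in range(n)]
            )
            occurs &= ~is_target | allowed
        for i in np.nonzero(occurs)[0]:
            reactions[i].append(spec.pt)
        pt_params[spec.pt] = (spec.ror, p_t, p_b)
        pt_counts[spec.pt] = (
            int(np.count_nonzero(occurs & is_target)),
            int(np.count_nonzero(occurs & ~is_target)),
        )
    filler_draws = rng.integers(0, len(config.filler_terms), size=n)
    for i in range(n):
        if not reactions[i]:
            reactions[i].append(config.filler_terms[filler_draws[i]][0])

    # dates: therapy start -> onset -> event -> received
    onset_cfg = config.onset_distribution
    mu = np.log(onset_cfg["median_days"])
    onset_days = np.rint(
        rng.lognormal(mean=mu, sigma=onset_cfg["sigma"], size=n)
    ).astype(int)
    onset_days = np.clip(onset_days, 0, 3650)
    start_ord = _EPOCH + rng.integers(0, _SPAN - 60, size=n)
    event_ord = start_ord + onset_days
    fda_ord = np.minimum(event_ord + rng.integers(1, 61, size=n),
                         _EPOCH + _SPAN)
    event_ord = np.minimum(event_ord, _EPOCH + _SPAN)

    miss = config.missingness
    u_age = rng.random(n)
    u_sex = rng.random(n)
    u_country = rng.random(n)
    u_occp = rng.random(n)
    u_event = rng.random(n)
    u_event_partial = rng.random(n)
    u_start = rng.random(n)
    ages = np.clip(rng.normal(62.0, 15.0, size=n), 18.0, 95.0)
    age_dec = rng.random(n) < 0.05  # a few reports use decades
    sexes = np.where(rng.random(n) < 0.61, "F", "M")
    countries = rng.choice(_COUNTRIES, size=n, p=_COUNTRY_P)
    occps = rng.choice(_OCCUPATIONS, size=n, p=_OCCUPATION_P)

    # drug rows and their route-revealing fields
    tradename = rng.random(n) < 0.8
    keep_route = rng.random(n) < 0.6
    keep_form = rng.random(n) < 0.5
    keep_freq = rng.random(n) < 0.5
    # an oral/subcutaneous case always keeps at least one identifying field,
    # so only the configured unclassifiable share is excluded downstream
    keep_route |= ~(tradename | keep_form | keep_freq)
    n_concomitant = rng.poisson(1.0, size=n)
    background_ps = rng.choice(_BACKGROUND_DRUGS, size=n)
    target_as_concomitant = rng.random(n) < 0.02

    # duplicated report versions
    n_dup = int(round(config.duplicate_fraction * n))
    dup_cases = set(rng.choice(n, size=n_dup, replace=False)) if n_dup else set()
    dup_gap = rng.integers(1, 91, size=n)

    tables = QuarterTables()
    gt = GroundTruth(
        target_caseids=[cid for i, cid in enumerate(caseids) if is_target[i]],
        background_caseids=[cid for i, cid in enumerate(caseids)
                            if not is_target[i]],
        case_route=case_route,
        pt_params=pt_params,
        pt_counts=pt_counts,
        n_report_versions=0,
    )

    for i, caseid in enumerate(caseids):
        versions = (1, 2) if i in dup_cases else (1,)
        final_fda = int(fda_ord[i])
        drugs = _case_drugs(
            i, caseid, is_target[i], route_names[route_idx[i]],
            background_ps[i], tradename[i], keep_route[i], keep_form[i],
            keep_freq[i], n_concomitant[i], target_as_concomitant[i], rng,
        )
        event: Optional[PartialDate]
        if u_event[i] < miss["event_dt"]:
            event = None
        elif u_event_partial[i] < miss["event_dt_partial"]:
            event = _month_of(event_ord[i])
        else:
            event = _date_of(event_ord[i])
        start = (None if u_start[i] < miss["start_dt"]
                 else _date_of(start_ord[i]))
        outc_codes = [
            code for code, prob in config.serious_outcome_prob.items()
            if rng.random() < prob
        ]
        for version in versions:
            primaryid = f"{caseid}{version}"
            fda = final_fda if version == versions[-1] else final_fda - int(dup_gap[i])
            age: Optional[float] = None if u_age[i] < miss["age"] else (
                round(ages[i] / 10.0, 1) if age_dec[i] else round(ages[i])
            )
            sex = None if u_sex[i] < miss["sex"] else str(sexes[i])
            if (config.duplicate_field_noise and version != versions[-1]):
                age = None
                sex = None
            tables.demo.append(DemoRecord(
                primaryid=primaryid,
                caseid=caseid,
                fda_dt=_date_of(fda),
                event_dt=event,
                age=age,
                age_cod=None if age is None else ("DEC" if age_dec[i] else "YR"),
                sex=sex,
                reporter_country=(None if u_country[i] < miss["reporter_country"]
                                  else str(countries[i])),
                occp_cod=(None if u_occp[i] < miss["occp_cod"]
                          else str(occps[i])),
            ))
            for drug in drugs:
                tables.drug.append(replace(drug, primaryid=primaryid))
            for pt in reactions[i]:
                tables.reac.append(ReacRecord(primaryid=primaryid, pt=pt))
            for code in outc_codes:
                tables.outc.append(OutcRecord(primaryid=primaryid,
                                              outc_cod=code))
            if start is not None:
                tables.ther.append(TherRecord(
                    primaryid=primaryid, dsg_drug_seq=1, start_dt=start,
                ))
            gt.n_report_versions += 1
    return tables, gt


def _case_drugs(
    i: int, caseid: str, target: bool, route: str, background_drug: str,
    tradename: bool, keep_route: bool, keep_form: bool, keep_freq: bool,
    n_concomitant: int, target_concomitant: bool, rng: np.random.Generator,
) -> list[DrugRecord]:
    """Drug rows for one case (primaryid filled in per version later)."""
    drugs: list[DrugRecord] = []
    if target:
        if route == ORAL:
            name = "RYBELSUS (SEMAGLUTIDE)" if tradename else TARGET_DRUG
            row = DrugRecord(
                primaryid="x", drug_seq=1, role_cod="PS", drugname=name,
                route="ORAL" if keep_route else None,
                dose_form="TABLET" if keep_form else None,
                dose_freq="QD" if keep_freq else None,
            )
        elif route == SUBCUTANEOUS:
            brand = "OZEMPIC (SEMAGLUTIDE)" if rng.random() < 0.7 else "WEGOVY"
            name = brand if tradename else TARGET_DRUG
            row = DrugRecord(
                primaryid="x", drug_seq=1, role_cod="PS", drugname=name,
                route="SUBCUTANEOUS" if keep_route else None,
                dose_form="SOLUTION FOR INJECTION" if keep_form else None,
                dose_freq="QW" if keep_freq else None,
            )
        else:  # unclassifiable: plain name, nothing identifying
            row = DrugRecord(primaryid="x", drug_seq=1, role_cod="PS",
                             drugname=TARGET_DRUG)
        drugs.append(row)
    else:
        drugs.append(DrugRecord(
            primaryid="x", drug_seq=1, role_cod="PS",
            drugname=background_drug,
            route="ORAL" if rng.random() < 0.7 else "SUBCUTANEOUS",
        ))
        if target_concomitant:
            drugs.append(DrugRecord(
                primaryid="x", drug_seq=len(drugs) + 1, role_cod="C",
                drugname=TARGET_DRUG,
            ))
    for _ in range(int(n_concomitant)):
        drugs.append(DrugRecord(
            primaryid="x", drug_seq=len(drugs) + 1, role_cod="C",
            drugname=str(rng.choice(_BACKGROUND_DRUGS)),
        ))
    return drugs


def catalog_dictionary(config: SimConfig) -> PtSocDictionary:
    """PT->SOC dictionary covering everything the generator can emit."""
    dictionary = PtSocDictionary()
    for spec in config.pt_catalog:
        dictionary.add(spec.pt, spec.soc)
    for pt, soc in config.filler_terms:
        dictionary.add(pt, soc)
    return dictionary


def simulate_coded_reviews(
    config: SimConfig,
    n_reviews: int = 422,
    female_prob: float = 0.75,
    seed: Optional[int] = None,
) -> list[CodedReview]:
    """Generate coded social-media reviews from the catalog's target-arm
    occurrence profile: each review carries 1-5 PTs drawn (without
    replacement) with probability proportional to the PT's target-arm
    occurrence probability."""
    if not config.pt_catalog:
        raise ValueError("pt_catalog must be non-empty")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pts = [s.pt for s in config.pt_catalog]
    weights = np.array([
        target_occurrence_prob(s.ror, s.baseline or config.baseline_prob, s.pt)
        for s in config.pt_catalog
    ])
    weights = weights / weights.sum()
    reviews = []
    for i in range(n_reviews):
        k = min(int(rng.integers(1, 6)), len(pts))
        chosen = rng.choice(len(pts), size=k, replace=False, p=weights)
        date_ord = _EPOCH + int(rng.integers(0, _SPAN))
        reviews.append(CodedReview(
            review_id=f"R{i + 1:05d}",
            date=_date_of(date_ord),
            age=float(np.clip(round(rng.normal(48.0, 12.0)), 18, 90)),
            sex="F" if rng.random() < female_prob else "M",
            pts=tuple(pts[j] for j in sorted(chosen)),
        ))
    return reviews


def write_simulation(
    config: SimConfig, directory: str | Path
) -> tuple[QuarterTables, GroundTruth]:
    """Run the generator and write the full bundle: quarterly tables, the
    PT->SOC dictionary, the resolved config as YAML, and a ground-truth TSV
    (pt, embedded_ror, p_t, p_b, target/background case counts)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tables, truth = simulate_reports(config)
    write_quarter(tables, directory, config.quarter_tag)
    dictionary = catalog_dictionary(config)
    with (directory / "pt_soc_dictionary.tsv").open("w", encoding="utf-8") as fh:
        fh.write("pt\tsoc\n")
        for pt, soc in dictionary.items():
            fh.write(f"{pt}\t{soc}\n")
    with (directory / "sim_config.yaml").open("w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    with (directory / "ground_truth.tsv").open("w", encoding="utf-8") as fh:
        fh.write("pt\tembedded_ror\tp_target\tp_background\t"
                 "n_target_cases\tn_background_cases\n")
        for pt, (ror, p_t, p_b) in truth.pt_params.items():
            a, c = truth.pt_counts[pt]
            fh.write(f"{pt}\t{ror}\t{p_t:.8g}\t{p_b:.8g}\t{a}\t{c}\n")
    return tables, truth
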