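# faerspv

Pharmacovigilance signal detection on FAERS-style spontaneous adverse-event
reports, built around the semaglutide oral-vs-subcutaneous safety question:
ingest quarterly report tables, deduplicate case versions, classify each
case's formulation, detect adverse-drug-reaction signals by reporting odds
ratio, and produce the descriptive tables of a drug-safety study — with a
synthetic report generator that embeds known signal strengths so every
stage can be validated against ground truth.

## Who this is for

Drug-safety researchers and biostatisticians who work with spontaneous
reporting systems (FDA FAERS quarterly ASCII extracts or data shaped like
them) and want a tested, auditable implementation of the standard
disproportionality workflow rather than a one-off script.

## The statistic

For one adverse-event term, cases are cross-classified into the 2×2
four-grid table

|                  | term reported | term not reported |
| ---------------- | ------------- | ----------------- |
| target drug      | a             | b                 |
| all other drugs  | c             | d                 |

and the reporting odds ratio with its Woolf 95% confidence interval is

    ROR = (a/c) / (b/d)
    95% CI = exp( ln ROR ± 1.96 · sqrt(1/a + 1/b + 1/c + 1/d) )

A term is a **signal** when the lower bound exceeds 1.0 (that bound is the
ROR_025 statistic). Counting is case-level: a term reported twice in one
case counts once. Tables with a zero cell or fewer than `min_count`
(default 3) target reports are non-evaluable by default.

Around the statistic the package implements the full study pipeline:
version deduplication (latest received date, then largest primary id),
primary-suspect cohort selection, PT→SOC mapping on the event counting
unit, rule-based oral/subcutaneous classification, Venn partition of
formulation-unique terms, serious-outcome rates, and time-to-onset
quartiles. See `docs/methods.md` for every convention and its rationale.

## Worked example

```python
from faerspv import (SimConfig, simulate_reports, deduplicate,
                     select_target_cases, assemble_cases, map_events,
                     detect_signals)
from faerspv.synthetic import catalog_dictionary

config = SimConfig(n_cases_target=3000, n_cases_background=3000, seed=7)
tables, truth = simulate_reports(config)        # 7200 report versions
kept = deduplicate(tables.demo)                 # 6000 unique cases
target_ids = select_target_cases(tables.drug, kept)
target = assemble_cases(tables, kept, target_ids)
background = assemble_cases(tables, kept, set(kept) - target_ids)
events, _ = map_events(target + background, catalog_dictionary(config))
results = detect_signals({c.caseid for c in target},
                         {c.caseid for c in background}, events)
```

Running `python examples/01_simulate_and_detect_signals.py` (which adds
the embedded truth column) prints:

```
term                         embedded estimate  95% CI          signal
Pancreatic failure               36.0    26.67  (  8.41,   84.58)  True
Device leakage                   20.0    16.67  (  7.30,   38.09)  True
Nausea                            8.0    11.73  (  7.40,   18.60)  True
Eructation                       12.0    11.04  (  7.69,   15.85)  True
Injection phobia                 15.0     9.47  (  4.33,   20.68)  True
```

Each estimate is the reporting odds ratio of the target drug against the
background arm; the generator embedded the `embedded` column, and every
estimate's 95% interval covers it. Rare formulation-specific terms
(pancreatic failure occurs only in subcutaneous cases, with a tiny
background rate) show the characteristic extreme-signal pattern: a large
ROR resting on few reports, with a wide interval. The other scripts in
`examples/` walk through the route comparison (Venn partition,
formulation-unique signals, the GI ROR_025 statistic), the descriptive
tables, and the FAERS-vs-social-media comparison.

A command-line interface wraps the same pipeline:

```
faerspv simulate --out sim/ --cases 3000 --seed 7
faerspv run-all --input-dir sim/ --quarter-tag SIM \
    --dictionary sim/pt_soc_dictionary.tsv --out run/
```

writing per-stage TSV artifacts and a YAML manifest with stage counts and
checksums under `run/`.

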