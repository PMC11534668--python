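"""Compare oral and subcutaneous formulation cohorts of the target drug.

Classifies each target case's formulation from its drug rows, partitions
the Preferred Terms reported by each cohort (Venn), and tests the
formulation-unique terms for disproportionality against the background.
"""

from faerspv import (
    SimConfig,
    assemble_cases,
    classify_route,
    deduplicate,
    map_events,
    observed_pts,
    route_vs_route_ror,
    select_target_cases,
    simulate_reports,
    split_cohorts,
    unique_pt_signals,
    venn_partition,
)
from faerspv.meddra import events_for_cases
from faerspv.synthetic import catalog_dictionary

config = SimConfig(n_cases_target=4000, n_cases_background=4000, seed=11)
tables, truth = simulate_reports(config)
kept = deduplicate(tables.demo)
target_ids = select_target_cases(tables.drug, kept)
target = assemble_cases(tables, kept, target_ids)
background = assemble_cases(tables, kept, set(kept) - target_ids)
events, _ = map_events(target + background, catalog_dictionary(config))

labels = [classify_route(c) for c in target]
oral, subcut, excluded = split_cohorts(target, labels)
print(f"oral: {len(oral)}  subcutaneous: {len(subcut)}  excluded: {excluded}")

oral_ids = {c.caseid for c in oral}
subcut_ids = {c.caseid for c in subcut}
background_ids = {c.caseid for c in background}
venn = venn_partition(
    observed_pts(events_for_cases(events, oral_ids)),
    observed_pts(events_for_cases(events, subcut_ids)),
)
print(
    f"PTs: {len(venn.unique_left)} oral-only, {len(venn.shared)} shared, "
    f"{len(venn.unique_right)} subcutaneous-only"
)

oral_unique, subcut_unique = unique_pt_signals(
    venn, oral_ids, subcut_ids, background_ids, events
)
for name, rows in (("oral-only", oral_unique),
                   ("subcutaneous-only", subcut_unique)):
    for r in rows:
        if r.evaluable:
            print(f"{name:>18}: {r.term:<26} ROR {r.ror:6.1f} "
                  f"({r.ci_low:.1f}, {r.ci_high:.1f}) signal={r.is_signal}")

gi = route_vs_route_ror(
    "Gastrointestinal disorders", "SOC", oral_ids, subcut_ids, events
)
print(
    f"\nGI disorders, oral vs subcutaneous: ROR {gi.ror:.2f}, "
    f"ROR_025 = {gi.ci_low:.2f}"
)
print(
    "\nFormulation-unique terms appear only on their own side of the Venn"
    "\npartition; rare ones show large odds ratios with wide intervals. A"
    "\nGI ROR_025 below 1 means the oral form shows no disproportionate"
    "\nexcess of gastrointestinal reporting over the subcutaneous form."
)
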