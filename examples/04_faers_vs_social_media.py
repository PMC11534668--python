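"""Compare organ-class profiles between FAERS-style reports and coded
social-media reviews generated from the same term catalog."""

from faerspv import (
    SimConfig,
    assemble_cases,
    compare_sources,
    deduplicate,
    map_events,
    map_review_events,
    select_target_cases,
    simulate_coded_reviews,
    simulate_reports,
    soc_frequency_table,
)
from faerspv.synthetic import catalog_dictionary

config = SimConfig(n_cases_target=3000, n_cases_background=3000, seed=23)
tables, _ = simulate_reports(config)
reviews = simulate_coded_reviews(config, n_reviews=422, seed=24)
dictionary = catalog_dictionary(config)

kept = deduplicate(tables.demo)
target_ids = select_target_cases(tables.drug, kept)
target = assemble_cases(tables, kept, target_ids)
faers_events, _ = map_events(target, dictionary)
review_events, _ = map_review_events(reviews, dictionary)

faers_soc = soc_frequency_table(faers_events)
review_soc = soc_frequency_table(review_events, unit="review-events")
rows = compare_sources(faers_soc, review_soc)

print(f"{'SOC':<55}{'FAERS %':>9}{'social %':>10}  |diff|")
for r in rows[:8]:
    left = f"{r.left_percent:.2f}" if r.left_percent is not None else "-"
    right = f"{r.right_percent:.2f}" if r.right_percent is not None else "-"
    diff = f"{r.abs_difference:.2f}" if r.abs_difference is not None else ""
    flag = f"  (only in {r.one_sided})" if r.one_sided else ""
    print(f"{r.label:<55}{left:>9}{right:>10}  {diff}{flag}")
print(
    "\nEach row compares one organ class's share of adverse-event terms"
    "\nbetween the two sources (event counting unit on each side); rows"
    "\npresent in only one source are flagged rather than zero-filled."
)
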