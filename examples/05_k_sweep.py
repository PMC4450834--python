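"""Optimizing the regularization exponent k.

With delta = 10^-k appended to every vector, k = 0 (delta = 1) swamps the
content of the vectors — every pair looks alike — while very large k only
matters for nearly-empty reports.  The sweep traces AUROC against k and
picks the smallest k on the plateau of the maximum.
"""

from ontosim import equal_weights, feature_space, label_pairs, sweep_k, synthetic

graph = synthetic.generate_ontology(synthetic.OntologySpec(depth=7, seed=5))
panels = synthetic.label_panels(graph, ["HCC", "NAD"], overlap=0.0, seed=6)
cohort = synthetic.generate_cohort(
    synthetic.CohortSpec(
        n_reports={"HCC": 15, "NAD": 15}, panels=panels,
        empty_report_prob=0.1, seed=7,
    ),
    graph,
)
space = feature_space(graph, 4)

result = sweep_k(cohort, space, graph, equal_weights(space), list(range(13)))
print("  k   AUROC")
for row in result.rows.itertuples(index=False):
    marker = "  <- chosen" if row.k == result.chosen_k else ""
    print(f"  {row.k:2d}  {row.auroc:.4f}{marker}")

print(
    f"\nAccuracy climbs away from k = 0 (delta domination) and saturates;"
    f"\nthe smallest k within 1e-3 of the maximum is k = {result.chosen_k}."
)
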