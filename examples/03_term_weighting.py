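"""Literature co-occurrence weighting: equal, generic, and specific.

Counts on the bundled 12-abstract corpus are small enough to verify by
hand: 8 abstracts mention hepatocellular carcinoma; 4 of them also mention
cirrhosis, so P(cirrhosis | HCC) = 4/8 = 0.5.
"""

from ontosim import (
    CorpusCountProvider,
    QueryGroup,
    equal_weights,
    feature_space,
    generic_weights,
    rank_terms,
    specific_term_probability,
    specific_weights,
    toy,
)
from ontosim.vectors import Report

graph = toy.liver_hierarchy()
space = feature_space(graph, 4)
provider = CorpusCountProvider(toy.liver_corpus())
disease = QueryGroup(toy.DISEASE_NAMES)

print(f"Corpus: {provider.n_abstracts} abstracts, "
      f"{provider.count(disease)} mention the disease\n")

print("Equal weights (baseline, p_i = 1):")
print(" ", equal_weights(space).weights)

print("\nGeneric weights, P(feature concept | disease) from direct counts:")
for fid, p in generic_weights(space, disease, provider, graph).weights.items():
    print(f"  {fid:24s} {p:.3f}")

report = Report("r1", "HCC", frozenset({"cirrhosis", "fatty-liver"}))
print(f"\nSpecific weights for report {report.report_id} "
      f"(terms: {sorted(report.term_ids)}):")
for fid, p in specific_weights(report, space, graph, disease, provider).weights.items():
    print(f"  {fid:24s} {p:.3f}")

terms = ["cirrhosis", "hepatic-fibrosis", "splenomegaly", "fatty-liver"]
ranked = rank_terms(
    [specific_term_probability(graph.concept(t), disease, provider) for t in terms]
)
print("\nExtracted terms ranked by conditional probability given the disease:")
for rank, tw in enumerate(ranked, 1):
    print(f"  {rank}. {graph.concept(tw.term_id).preferred_name:18s} {tw.q:.3f}")

print(
    "\nGeneric weights are shared by every report; specific weights average"
    "\nthe ranked per-term probabilities of each report's own terms, so they"
    "\nchange from patient to patient."
)
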