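"""ROC evaluation of diagnosis co-occurrence prediction on synthetic data.

Generates an ontology, an 80-report two-label cohort whose labels draw
terms from disjoint feature subtrees, and a 5000-abstract corpus with
planted co-mention probabilities; then scores all pairs under the three
weighting schemes and compares the resulting AUROCs.
"""

from ontosim import (
    CorpusCountProvider,
    QueryGroup,
    VectorConfig,
    compare_auroc,
    equal_weights,
    feature_space,
    generic_weights,
    label_pairs,
    pairwise_similarities,
    roc_auroc,
    specific_weights,
    synthetic,
)

graph = synthetic.generate_ontology(synthetic.OntologySpec(depth=7, branching=2.0, seed=2))
space = feature_space(graph, 4)
panels = synthetic.label_panels(graph, ["HCC", "NAD"], overlap=0.0, seed=3)
cohort = synthetic.generate_cohort(
    synthetic.CohortSpec(n_reports={"HCC": 40, "NAD": 40}, panels=panels, seed=4), graph
)
corpus = synthetic.generate_corpus(
    synthetic.CorpusSpec(
        n_abstracts=5000,
        p_term_given_disease=synthetic.disease_comention_probs(graph, panels["HCC"]),
        seed=5,
    ),
    graph,
)
provider = CorpusCountProvider(corpus)
disease = QueryGroup(("hepatocellular carcinoma", "HCC"))
labels = label_pairs(cohort)
config = VectorConfig(k=10)

print(f"{len(graph)} concepts, {len(space)} feature concepts, "
      f"{len(cohort)} reports -> {len(labels)} pairs "
      f"({labels.n_match} matches, {labels.n_mismatch} mismatches)\n")

tables = {}
for scheme, w in [
    ("equal", equal_weights(space)),
    ("generic", generic_weights(space, disease, provider, graph)),
    ("specific", lambda r: specific_weights(r, space, graph, disease, provider)),
]:
    tables[scheme] = pairwise_similarities(cohort, space, graph, w, config)
    res = roc_auroc(tables[scheme], labels)
    print(f"  {scheme:9s} AUROC = {res.auroc:.3f}  "
          f"(95% CI {res.ci_low:.3f}-{res.ci_high:.3f})")

a, b, diff, p = compare_auroc(tables["specific"], tables["equal"], labels)
print(f"\nDeLong test specific vs equal: difference = {diff:+.4f}, p = {p:.3f}")
print(
    "\nAUROC is the probability that a randomly drawn same-diagnosis pair"
    "\nscores above a different-diagnosis pair; 0.5 is chance.  With"
    "\ndisjoint label panels all schemes discriminate nearly perfectly."
)
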