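"""Edge-count semantic distance on a small is-a hierarchy.

Builds the bundled liver-finding fragment and walks through the three
distance rules: an extracted term that descends from a feature concept is
scored by the minimum number of is-a links between them; a term that is not
a descendant is unreachable (infinitely distant); a term that *is* a feature
concept has distance zero to itself.
"""

from ontosim import concept_level, feature_space, semantic_distance, toy

graph = toy.liver_hierarchy()

print("Concept levels (is-a edges below the root):")
for cid in ("root", "liver-finding", "hepatic-fibrosis", "cirrhosis"):
    print(f"  {graph.concept(cid).preferred_name:24s} level {concept_level(graph, cid)}")

space = feature_space(graph, 4)
print(f"\nFeature concepts at level 4: {', '.join(space.feature_ids)}")

print("\nSemantic distances from extracted terms up to feature concepts:")
for term, feat in [
    ("cirrhosis", "liver-finding"),
    ("hepatic-fibrosis", "liver-finding"),
    ("splenomegaly", "liver-finding"),
    ("splenomegaly", "abdominal-organ-finding"),
    ("fatty-liver", "fatty-liver"),
]:
    d = semantic_distance(graph, term, feat)
    print(f"  {term:18s} -> {feat:24s} {d}")

print(
    "\nA finite distance d contributes a vector element 1/(1+d) under equal"
    "\nweighting; UNREACHABLE contributes 0 — the term carries no evidence"
    "\nfor that feature concept."
)
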