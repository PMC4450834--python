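"""Synthetic ontologies, report cohorts, and abstract corpora.

Real inputs to the pipeline — a clinical terminology such as SNOMED CT,
hospital imaging reports, and a literature index — cannot be redistributed,
so this module generates structurally faithful stand-ins with *known ground
truth*:

* :func:`generate_ontology` builds a rooted is-a DAG level by level with a
  configurable mean branching factor and an optional probability of second
  parents, plus synthetic synonym lists;
* :func:`generate_cohort` samples reports whose extracted terms come from
  label-specific concept panels, so the amount of overlap between panels
  controls how much true inter-patient signal exists;
* :func:`generate_corpus` emits abstracts under an abstract-level Bernoulli
  co-mention model: each abstract mentions the disease with a fixed
  probability, and each term independently with a conditional probability
  that depends on the disease status.  Under this model the co-occurrence
  ratio estimators of the weighting module are consistent for the planted
  conditionals.

All generators are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ontosim.errors import ValidationError
from ontosim.ontology import Concept, OntologyGraph
from ontosim.vectors import Report

__all__ = [
    "OntologySpec",
    "CohortSpec",
    "CorpusSpec",
    "generate_ontology",
    "generate_cohort",
    "generate_corpus",
    "label_panels",
    "disease_comention_probs",
    "write_corpus",
    "write_reports",
    "write_hierarchy",
]


@dataclass(frozen=True)
class OntologySpec:
    """Shape of a synthetic is-a hierarchy.

    ``depth`` is the number of levels below the root; ``branching`` the mean
    number of children per node (Poisson); ``multi_parent_prob`` the chance a
    node gains a second parent at its own parent level, emulating SNOMED's
    multiple inheritance without disturbing node levels.
    """

    depth: int = 7
    branching: float = 2.0
    multi_parent_prob: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValidationError("ontology depth must be >= 1")
        if self.branching < 1:
            raise ValidationError("mean branching must be >= 1")
        if not (0 <= self.multi_parent_prob <= 1):
            raise ValidationError("multi_parent_prob must be in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort of labeled reports drawing terms from per-label panels.

    ``panels`` maps each diagnosis label to the concept ids its reports
    sample from; ``n_reports`` gives the cohort size per label.  Reports are
    empty with probability ``empty_report_prob``; otherwise their term count
    is 1 + Poisson(``terms_per_report`` - 1), capped at the panel size.
    """

    n_reports: dict[str, int]
    panels: dict[str, tuple[str, ...]]
    terms_per_report: float = 4.0
    empty_report_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.n_reports) < 2:
            raise ValidationError("cohort needs at least two diagnosis labels")
        if set(self.n_reports) != set(self.panels):
            raise ValidationError("n_reports and panels must cover the same labels")
        if any(len(p) == 0 for p in self.panels.values()):
            raise ValidationError("every label needs a non-empty term panel")
        if not (0 <= self.empty_report_prob <= 1):
            raise ValidationError("empty_report_prob must be in [0, 1]")
        if self.terms_per_report < 1:
            raise ValidationError("terms_per_report must be >= 1")


@dataclass(frozen=True)
class CorpusSpec:
    """Bernoulli co-mention model for a synthetic abstract corpus.

    Each abstract mentions the disease with probability
    ``disease_mention_prob``; a term listed in ``p_term_given_disease`` is
    then mentioned with that probability in disease abstracts and with
    ``p_term_given_background`` (a default, overridable per term via
    ``p_term_given_no_disease``) otherwise.  Mentions are independent across
    terms given the disease status.
    """

    n_abstracts: int = 5000
    disease_names: tuple[str, ...] = ("hepatocellular carcinoma", "HCC")
    disease_mention_prob: float = 0.3
    p_term_given_disease: dict[str, float] = field(default_factory=dict)
    p_term_given_no_disease: dict[str, float] = field(default_factory=dict)
    p_term_given_background: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_abstracts < 1:
            raise ValidationError("n_abstracts must be >= 1")
        probs = [self.disease_mention_prob, self.p_term_given_background]
        probs += list(self.p_term_given_disease.values())
        probs += list(self.p_term_given_no_disease.values())
        if any(not (0 <= p <= 1) for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------


def generate_ontology(spec: OntologySpec) -> OntologyGraph:
    """Grow a rooted is-a DAG level by level.

    Every level up to ``spec.depth`` is guaranteed non-empty (a parent is
    forced to spawn one child if the Poisson draws leave a level bare), so a
    feature space at any level <= depth exists.  Concepts get 0-3 synthetic
    synonyms.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    counter = 0

    def new_id() -> str:
        nonlocal counter
        cid = f"C{counter:05d}"
        counter += 1
        return cid

    root = new_id()
    levels: list[list[str]] = [[root]]
    edges: list[tuple[str, str]] = []
    for _depth in range(1, spec.depth + 1):
        parents = levels[-1]
        children: list[str] = []
        for parent in parents:
            # 1 + Poisson keeps the stated mean while preventing extinct
            # lineages, so every level is populated down to `depth`
            for _ in range(1 + rng.poisson(spec.branching - 1)):
                cid = new_id()
                children.append(cid)
                edges.append((cid, parent))
        if len(parents) > 1 and spec.multi_parent_prob > 0:
            for cid, parent in [(c, p) for c, p in edges if c in set(children)]:
                if rng.random() < spec.multi_parent_prob:
                    others = [p2 for p2 in parents if p2 != parent]
                    if others:
                        edges.append((cid, others[rng.integers(len(others))]))
        levels.append(children)

    concepts = []
    for cid in (c for lvl in levels for c in lvl):
        n_syn = int(rng.integers(0, 4))
        syns = tuple(f"synonym {cid.lower()} v{j}" for j in range(n_syn))
        concepts.append(Concept(cid, f"finding {cid.lower()}", syns))
    return OntologyGraph(concepts, edges)


def generate_cohort(spec: CohortSpec, graph: OntologyGraph) -> list[Report]:
    """Sample a labeled report cohort from per-label term panels."""
    for label, panel in spec.panels.items():
        unknown = [t for t in panel if t not in graph]
        if unknown:
            raise ValidationError(f"panel for {label!r} references unknown concepts {unknown[:3]}")
    rng = np.random.default_rng(spec.seed)
    reports: list[Report] = []
    for label in sorted(spec.n_reports):
        panel = list(spec.panels[label])
        for i in range(spec.n_reports[label]):
            rid = f"{label}_{i:04d}"
            if rng.random() < spec.empty_report_prob:
                reports.append(Report(rid, label, frozenset()))
                continue
            n_terms = min(1 + rng.poisson(spec.terms_per_report - 1), len(panel))
            terms = rng.choice(panel, size=n_terms, replace=False)
            reports.append(Report(rid, label, frozenset(terms.tolist())))
    return reports


_FILLER = (
    "imaging of the abdomen was reviewed",
    "the cohort was followed prospectively",
    "contrast enhanced scans were obtained",
    "histology confirmed the assessment",
    "no further lesion was identified",
)


def generate_corpus(spec: CorpusSpec, graph: OntologyGraph) -> dict[str, str]:
    """Emit synthetic abstracts under the planted Bernoulli co-mention model.

    Term mentions use the concept's preferred name or, at random, one of its
    synonyms — both must be recognized by phrase matching downstream.
    Returns ``{abstract_id: text}``; deterministic per seed.
    """
    for tid in list(spec.p_term_given_disease) + list(spec.p_term_given_no_disease):
        if tid not in graph:
            raise ValidationError(f"corpus spec references unknown concept {tid!r}")
    rng = np.random.default_rng(spec.seed)
    term_ids = sorted(set(spec.p_term_given_disease) | set(spec.p_term_given_no_disease))
    abstracts: dict[str, str] = {}
    for i in range(spec.n_abstracts):
        has_disease = rng.random() < spec.disease_mention_prob
        phrases = []
        if has_disease:
            phrases.append(str(rng.choice(spec.disease_names)))
        for tid in term_ids:
            p = (
                spec.p_term_given_disease.get(tid, spec.p_term_given_background)
                if has_disease
                else spec.p_term_given_no_disease.get(tid, spec.p_term_given_background)
            )
            if rng.random() < p:
                c = graph.concept(tid)
                names = (c.preferred_name, *c.synonyms)
                phrases.append(str(names[rng.integers(len(names))]))
        body = ". ".join(
            s.capitalize()
            for s in ([str(rng.choice(_FILLER))] + phrases)
        )
        abstracts[f"PM{i:06d}"] = body + "."
    return abstracts


def disease_comention_probs(
    graph: OntologyGraph,
    panel: tuple[str, ...],
    *,
    feature_level: int = 4,
    p_term: float = 0.6,
    p_feature: float = 0.45,
) -> dict[str, float]:
    """Planted P(mention | disease) for a disease panel and its broader terms.

    Abstracts about a disease mention its characteristic specific terms, but
    authors also write the broader (feature-level) terms those specialize —
    the reason feature-concept literature counts are non-zero at all.  This
    returns ``p_term`` for every panel term and ``p_feature`` for each
    feature-level ancestor of a panel term.
    """
    from ontosim.ontology import concept_level

    probs = {t: p_term for t in panel}
    for t in panel:
        for anc in graph.ancestors(t):
            if concept_level(graph, anc) == feature_level:
                probs.setdefault(anc, p_feature)
    return probs


def label_panels(
    graph: OntologyGraph,
    labels: list[str],
    *,
    panel_size: int = 12,
    overlap: float = 0.5,
    feature_level: int = 4,
    min_level: int = 5,
    seed: int = 0,
) -> dict[str, tuple[str, ...]]:
    """Build per-label term panels from deep concepts of a hierarchy.

    Panels draw from concepts at level >= ``min_level`` — strictly below the
    feature level, the way extracted clinical terms sit below the feature
    concepts they project to.  Overlap is controlled *at the feature level*:
    a fraction ``overlap`` of the feature-concept subtrees is shared across
    all labels, the rest are partitioned label-exclusively, and each label's
    panel samples from its own subtrees (terms descending from another
    label's exclusive subtree are excluded).  ``overlap=0`` therefore gives
    panels whose feature-concept projections are disjoint (strong
    inter-patient signal); ``overlap=1`` gives identical panels (no signal).
    """
    if not (0 <= overlap <= 1):
        raise ValidationError("overlap must be in [0, 1]")
    labels = sorted(labels)
    levels = graph._levels
    features = sorted(cid for cid, lv in levels.items() if lv == feature_level)
    pool = sorted(cid for cid, lv in levels.items() if lv >= min_level)
    # map each deep concept to the feature concepts it descends from
    feats_of = {
        t: frozenset(f for f in features if f in graph._up_lengths[t]) for t in pool
    }
    pool = [t for t in pool if feats_of[t]]

    rng = np.random.default_rng(seed)
    n_shared_f = round(overlap * len(features))
    perm = rng.permutation(features).tolist()
    shared_f = set(perm[:n_shared_f])
    own_f: dict[str, set] = {lab: set() for lab in labels}
    for i, f in enumerate(perm[n_shared_f:]):
        own_f[labels[i % len(labels)]].add(f)

    n_shared_terms = round(overlap * panel_size)
    shared_pool = [t for t in pool if feats_of[t] <= shared_f]
    if len(shared_pool) < n_shared_terms:
        raise ValidationError("not enough terms under the shared feature subtrees")
    shared_terms = rng.choice(shared_pool, size=n_shared_terms, replace=False).tolist() \
        if n_shared_terms else []

    panels = {}
    for lab in labels:
        allowed = shared_f | own_f[lab]
        own_pool = [
            t for t in pool
            if feats_of[t] <= allowed and feats_of[t] & own_f[lab]
        ]
        n_own = panel_size - n_shared_terms
        if len(own_pool) < n_own:
            raise ValidationError(
                f"not enough exclusive terms for label {lab!r} "
                f"({len(own_pool)} available, {n_own} needed)"
            )
        own_terms = rng.choice(own_pool, size=n_own, replace=False).tolist() if n_own else []
        panels[lab] = tuple(sorted(shared_terms + own_terms))
    return panels


# ---------------------------------------------------------------------------
# writers for the on-disk formats the other modules consume


def write_corpus(abstracts: dict[str, str], path: str | Path) -> None:
    """Write ``abstract_id<TAB>text`` TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        for aid, text in abstracts.items():
            fh.write(f"{aid}\t{text}\n")


def write_reports(reports: list[Report], path: str | Path) -> None:
    """Write ``report_id<TAB>diagnosis<TAB>term;term;...`` TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in reports:
            fh.write(f"{r.report_id}\t{r.diagnosis}\t{';'.join(sorted(r.term_ids))}\n")


def write_hierarchy(graph: OntologyGraph, edge_path: str | Path, synonym_path: str | Path | None = None) -> None:
    """Write the edge-list TSV (and optionally the synonym table)."""
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("child_id\tparent_id\n")
        for child, parent in graph.isa_edges():
            fh.write(f"{child}\t{parent}\n")
    if synonym_path is not None:
        # the edge-list format has no name column, so a reloaded graph names
        # concepts by their ids; emitting the preferred name as a leading
        # synonym keeps query groups matchable against corpus text
        with open(synonym_path, "w", encoding="utf-8") as fh:
            for cid in graph.concept_ids:
                c = graph.concept(cid)
                names = list(c.synonyms)
                if c.preferred_name != cid:
                    names.insert(0, c.preferred_name)
                for syn in names:
                    fh.write(f"{cid}\t{syn}\n")
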