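"""Literature co-occurrence term weighting.

Feature-concept weights ``p_i`` are conditional probabilities of observing a
concept in an abstract given that the abstract mentions the disease of
interest, estimated from co-occurrence counts:

* *equal* weighting — the unweighted baseline, ``p_i = 1`` for every feature;
* *generic* weighting — ``p_i = #(feature AND disease) / #(disease)`` counted
  directly on the feature concepts; identical for all reports;
* *specific* weighting — each extracted term ``d_m`` gets its own conditional
  probability ``q_m = #(term AND disease) / #(disease)``, and a feature
  concept's weight is the plain average of the ``q`` values of the report's
  extracted terms that descend from it.  Weights then vary report by report.

Each term or disease is matched as a *query group*: its name together with
its synonyms, any of which counts as a mention.  Counts come from a
:class:`CountProvider` — either a local abstract corpus scanned with
case-insensitive whole-phrase matching, or a replayed table of counts
recorded from any literature index.
"""

from __future__ import annotations

import abc
import re
from dataclasses import dataclass, field
from pathlib import Path

from ontosim.errors import (
    FormatError,
    LookupError_,
    UndefinedDenominatorError,
    ValidationError,
)
from ontosim.ontology import Concept, FeatureSpace, OntologyGraph, semantic_distance, UNREACHABLE

__all__ = [
    "QueryGroup",
    "CountProvider",
    "CorpusCountProvider",
    "TableCountProvider",
    "WeightVector",
    "TermWeight",
    "concept_query_group",
    "corpus_count_provider",
    "table_count_provider",
    "equal_weights",
    "generic_weights",
    "specific_term_probability",
    "specific_weights",
    "rank_terms",
]


@dataclass(frozen=True)
class QueryGroup:
    """A disjunctive query: a name plus its synonyms, duplicates removed."""

    names: tuple[str, ...]

    def __init__(self, names):
        seen, kept = set(), []
        for n in names:
            if not n:
                raise ValidationError("query group contains an empty string")
            key = n.casefold()
            if key not in seen:
                seen.add(key)
                kept.append(n)
        if not kept:
            raise ValidationError("query group must contain at least one name")
        object.__setattr__(self, "names", tuple(kept))

    @property
    def key(self) -> str:
        """Canonical key: the primary (first) name, case-folded."""
        return self.names[0].casefold()


def concept_query_group(graph: OntologyGraph, concept_id: str) -> QueryGroup:
    """Query group for a concept: preferred name plus synonyms."""
    c = graph.concept(concept_id)
    return QueryGroup((c.preferred_name, *c.synonyms))


class CountProvider(abc.ABC):
    """Source of abstract counts for query groups.

    Implementations guarantee ``count_joint(g1, g2) <= min(count(g1),
    count(g2))``, symmetry of ``count_joint``, and determinism for a fixed
    snapshot.
    """

    @abc.abstractmethod
    def count(self, group: QueryGroup) -> int: ...

    @abc.abstractmethod
    def count_joint(self, group1: QueryGroup, group2: QueryGroup) -> int: ...


class CorpusCountProvider(CountProvider):
    """Counts derived by scanning a local corpus of abstracts.

    A group matches an abstract when at least one of its names occurs as a
    case-insensitive whole phrase (word-boundary anchored); each abstract is
    counted at most once per group.
    """

    def __init__(self, abstracts: dict[str, str]):
        if not abstracts:
            raise ValidationError("corpus is empty")
        self._texts = list(abstracts.values())
        self._cache: dict[tuple[str, ...], frozenset[int]] = {}

    @property
    def n_abstracts(self) -> int:
        return len(self._texts)

    def _matching(self, group: QueryGroup) -> frozenset[int]:
        key = group.names
        if key not in self._cache:
            pattern = re.compile(
                "|".join(r"\b" + re.escape(n) + r"\b" for n in group.names),
                re.IGNORECASE,
            )
            self._cache[key] = frozenset(
                i for i, text in enumerate(self._texts) if pattern.search(text)
            )
        return self._cache[key]

    def count(self, group: QueryGroup) -> int:
        return len(self._matching(group))

    def count_joint(self, group1: QueryGroup, group2: QueryGroup) -> int:
        return len(self._matching(group1) & self._matching(group2))


def corpus_count_provider(corpus_source: str | Path) -> CorpusCountProvider:
    """Load a TSV corpus (``abstract_id<TAB>text``) into a count provider."""
    path = Path(corpus_source)
    abstracts: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t", 1)
            if len(parts) != 2 or not parts[0]:
                raise FormatError(f"{path}:{lineno}: expected 'abstract_id<TAB>text'")
            abstracts[parts[0]] = parts[1]
    if not abstracts:
        raise ValidationError(f"corpus {path} contains no abstracts")
    return CorpusCountProvider(abstracts)


MARGINAL_KEY = "*"


class TableCountProvider(CountProvider):
    """Replays precomputed counts keyed by query-group primary names.

    The table stores joint counts as ``(key_a, key_b)`` rows (order-free) and
    marginal counts as ``(key, '*')`` rows.  Useful for replaying counts
    recorded from an external literature index such as a manual PubMed
    session.
    """

    def __init__(self, joints: dict[frozenset, int], marginals: dict[str, int]):
        for pair, joint in joints.items():
            for k in pair:
                if k in marginals and joint > marginals[k]:
                    raise ValidationError(
                        f"joint count {joint} for {sorted(pair)} exceeds marginal "
                        f"{marginals[k]} of {k!r}"
                    )
        self._joints = joints
        self._marginals = marginals

    def count(self, group: QueryGroup) -> int:
        try:
            return self._marginals[group.key]
        except KeyError:
            raise LookupError_(f"no marginal count stored for key {group.key!r}") from None

    def count_joint(self, group1: QueryGroup, group2: QueryGroup) -> int:
        pair = frozenset((group1.key, group2.key))
        try:
            return self._joints[pair]
        except KeyError:
            raise LookupError_(f"no joint count stored for keys {sorted(pair)}") from None

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for key, n in sorted(self._marginals.items()):
                fh.write(f"{key}\t{MARGINAL_KEY}\t{n}\n")
            for pair, n in sorted(self._joints.items(), key=lambda kv: sorted(kv[0])):
                a, b = sorted(pair)
                fh.write(f"{a}\t{b}\t{n}\n")


def table_count_provider(table_source: str | Path) -> TableCountProvider:
    """Load a count table TSV ``key_a<TAB>key_b<TAB>count`` ('*' = marginal)."""
    path = Path(table_source)
    joints: dict[frozenset, int] = {}
    marginals: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 'key_a<TAB>key_b<TAB>count'")
            a, b, raw = parts
            try:
                n = int(raw)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: count {raw!r} is not an integer") from None
            if n < 0:
                raise ValidationError(f"{path}:{lineno}: negative count")
            a, b = a.casefold(), b.casefold()
            if MARGINAL_KEY in (a, b):
                key = b if a == MARGINAL_KEY else a
                marginals[key] = n
            else:
                joints[frozenset((a, b))] = n
    return TableCountProvider(joints, marginals)


# ---------------------------------------------------------------------------
# weight vectors


@dataclass(frozen=True)
class WeightVector:
    """Per-feature conditional probabilities ``p_i`` under one scheme."""

    weights: dict[str, float]
    scheme: str  # 'equal' | 'generic' | 'specific'
    report_id: str | None = None

    def __post_init__(self):
        if self.scheme not in ("equal", "generic", "specific"):
            raise ValidationError(f"unknown weighting scheme {self.scheme!r}")
        if (self.scheme == "specific") != (self.report_id is not None):
            raise ValidationError("report_id must be set iff scheme is 'specific'")
        for fid, p in self.weights.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"weight {p} for {fid!r} outside [0, 1]")

    def __getitem__(self, feature_id: str) -> float:
        return self.weights[feature_id]


@dataclass(frozen=True)
class TermWeight:
    """Conditional probability ``q`` of one extracted term given the disease."""

    term_id: str
    q: float

    def __post_init__(self):
        if not (0.0 <= self.q <= 1.0):
            raise ValidationError(f"term probability {self.q} outside [0, 1]")


def equal_weights(space: FeatureSpace) -> WeightVector:
    """Baseline: every feature weight is 1 (unweighted vector model)."""
    if len(space) == 0:
        raise ValidationError("feature space is empty")
    return WeightVector({fid: 1.0 for fid in space.feature_ids}, scheme="equal")


def _conditional(joint: int, marginal: int) -> float:
    if marginal <= 0:
        raise UndefinedDenominatorError(
            "disease query group has zero abstract count; conditional probability undefined"
        )
    p = joint / marginal
    if p > 1.0:
        raise ValidationError(f"joint count {joint} exceeds marginal {marginal}")
    return p


def generic_weights(
    space: FeatureSpace,
    disease: QueryGroup,
    provider: CountProvider,
    graph: OntologyGraph,
) -> WeightVector:
    """Report-independent weights counted directly on the feature concepts.

    ``p_i = #(feature_i AND disease) / #(disease)`` where each side of the
    query is the concept's full synonym group.
    """
    denom = provider.count(disease)
    weights = {}
    for fid in space.feature_ids:
        group = concept_query_group(graph, fid)
        weights[fid] = _conditional(provider.count_joint(group, disease), denom)
    return WeightVector(weights, scheme="generic")


def specific_term_probability(
    term: Concept, disease: QueryGroup, provider: CountProvider
) -> TermWeight:
    """``q_m`` for one extracted term: joint count over the disease marginal."""
    group = QueryGroup((term.preferred_name, *term.synonyms))
    q = _conditional(provider.count_joint(group, disease), provider.count(disease))
    return TermWeight(term_id=term.concept_id, q=q)


def specific_weights(
    report,
    space: FeatureSpace,
    graph: OntologyGraph,
    disease: QueryGroup,
    provider: CountProvider,
) -> WeightVector:
    """Per-report weights: mean ``q`` of the report's terms under each feature.

    For each feature concept the report's extracted terms that are descendants
    of (or equal to) it are collected; the weight is the plain average of
    their conditional probabilities, or 0 when no extracted term falls under
    the feature (the corresponding vector element is already 0 in that case).
    """
    qs = {
        tid: specific_term_probability(graph.concept(tid), disease, provider).q
        for tid in sorted(report.term_ids)
    }
    weights = {}
    for fid in space.feature_ids:
        under = [
            qs[tid]
            for tid in sorted(report.term_ids)
            if semantic_distance(graph, tid, fid) is not UNREACHABLE
        ]
        weights[fid] = sum(under) / len(under) if under else 0.0
    return WeightVector(weights, scheme="specific", report_id=report.report_id)


def rank_terms(terms: list[TermWeight]) -> list[TermWeight]:
    """Sort term weights by descending probability, ties broken by term id."""
    return sorted(terms, key=lambda t: (-t.q, t.term_id))
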