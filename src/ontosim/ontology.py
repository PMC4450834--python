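"""The "is-a" concept hierarchy: loading, levels, and semantic distance.

Concepts form a rooted directed acyclic graph whose edges ``child -> parent``
assert specialization.  A concept's *level* is the minimum number of is-a
edges separating it from the root (root = level 0 by default).  The *semantic
distance* from an extracted term ``d`` to a feature concept ``f`` follows
three rules: if ``d`` is ``f`` the distance is 0; if ``d`` is a descendant of
``f`` it is the minimum number of is-a links on an upward path from ``d`` to
``f``; otherwise it is unreachable (conceptually infinite).  Distance is
deliberately asymmetric — it is defined along upward paths only.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from ontosim.errors import FormatError, LookupError_, ValidationError

__all__ = [
    "Concept",
    "OntologyGraph",
    "FeatureSpace",
    "UNREACHABLE",
    "Unreachable",
    "load_ontology",
    "concept_level",
    "semantic_distance",
    "feature_space",
]


class Unreachable:
    """Sentinel for an undefined (infinite) semantic distance.

    A typed singleton rather than a large integer so that accidental
    arithmetic fails loudly.  It compares greater than every int, which is
    the only ordering the vector model needs (taking a min over distances).
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNREACHABLE"

    def __gt__(self, other):
        if isinstance(other, (int, Unreachable)):
            return not isinstance(other, Unreachable)
        return NotImplemented

    def __lt__(self, other):
        if isinstance(other, (int, Unreachable)):
            return False
        return NotImplemented

    def __ge__(self, other):
        if isinstance(other, (int, Unreachable)):
            return True
        return NotImplemented

    def __le__(self, other):
        return isinstance(other, Unreachable)

    def __hash__(self):
        return hash("ontosim.UNREACHABLE")


UNREACHABLE = Unreachable()


@dataclass(frozen=True)
class Concept:
    """A node of the hierarchy: id, preferred name, optional synonyms."""

    concept_id: str
    preferred_name: str
    synonyms: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.preferred_name:
            raise ValidationError(f"concept {self.concept_id!r} has an empty preferred name")


class OntologyGraph:
    """Rooted DAG of concepts connected by is-a edges.

    Parameters
    ----------
    concepts
        The concept set; ids must be unique.
    isa_edges
        ``(child_id, parent_id)`` pairs.  The graph must be acyclic, free of
        self-edges, contain exactly one root (a concept with no parent), and
        every other concept must reach the root along is-a edges.
    """

    def __init__(self, concepts: list[Concept], isa_edges: list[tuple[str, str]]):
        self._concepts: dict[str, Concept] = {}
        for c in concepts:
            if c.concept_id in self._concepts:
                raise ValidationError(f"duplicate concept id {c.concept_id!r}")
            self._concepts[c.concept_id] = c

        g = nx.DiGraph()
        g.add_nodes_from(self._concepts)
        for child, parent in isa_edges:
            if child == parent:
                raise ValidationError(f"self-edge on {child!r}")
            for cid in (child, parent):
                if cid not in self._concepts:
                    raise ValidationError(f"edge references unknown concept {cid!r}")
            g.add_edge(child, parent)

        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
            raise ValidationError(f"is-a hierarchy contains a cycle: {path}")

        roots = [n for n in g.nodes if g.out_degree(n) == 0]
        if len(roots) != 1:
            raise ValidationError(
                f"hierarchy must have exactly one root; found {len(roots)}: {sorted(roots)[:5]}"
            )
        self.root_id: str = roots[0]
        # nodes with an upward path to root (edges run child -> parent)
        reach = set(nx.ancestors(g, self.root_id))
        missing = set(g.nodes) - reach - {self.root_id}
        if missing:
            raise ValidationError(
                f"{len(missing)} concept(s) cannot reach the root, e.g. {sorted(missing)[:5]}"
            )
        self._g = g

    # -- basic introspection -------------------------------------------------
    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._concepts

    def __len__(self) -> int:
        return len(self._concepts)

    @property
    def concept_ids(self) -> list[str]:
        return sorted(self._concepts)

    def concept(self, concept_id: str) -> Concept:
        try:
            return self._concepts[concept_id]
        except KeyError:
            raise LookupError_(f"unknown concept id {concept_id!r}") from None

    def parents(self, concept_id: str) -> list[str]:
        self.concept(concept_id)
        return sorted(self._g.successors(concept_id))

    def children(self, concept_id: str) -> list[str]:
        self.concept(concept_id)
        return sorted(self._g.predecessors(concept_id))

    def isa_edges(self) -> list[tuple[str, str]]:
        return sorted(self._g.edges)

    def ancestors(self, concept_id: str) -> set[str]:
        """All concepts reachable from *concept_id* along upward is-a paths."""
        self.concept(concept_id)
        return set(self._up_lengths[concept_id]) - {concept_id}

    # -- levels and distances (cached per graph) -----------------------------
    @functools.cached_property
    def _levels(self) -> dict[str, int]:
        # min #edges from each node up to root == shortest path on upward edges
        return nx.shortest_path_length(self._g.reverse(copy=False), source=self.root_id)

    @functools.cached_property
    def _up_lengths(self) -> dict[str, dict[str, int]]:
        # shortest upward distances from every node to all its ancestors
        return {n: nx.shortest_path_length(self._g, source=n) for n in self._g.nodes}


@dataclass(frozen=True)
class FeatureSpace:
    """Ordered feature concepts at one hierarchy level; defines vector axes."""

    feature_ids: tuple[str, ...]
    level: int

    def __len__(self) -> int:
        return len(self.feature_ids)

    def index(self, feature_id: str) -> int:
        return self.feature_ids.index(feature_id)


# ---------------------------------------------------------------------------
# loading


def _parse_obo(path: Path) -> tuple[list[Concept], list[tuple[str, str]]]:
    import obonet

    g = obonet.read_obo(path, ignore_obsolete=True)
    concepts, edges = [], []
    for node, data in g.nodes(data=True):
        name = data.get("name") or node
        syns = []
        for raw in data.get("synonym", []):
            # OBO synonym line: "text" SCOPE [xrefs]
            if raw.startswith('"'):
                end = raw.find('"', 1)
                if end > 0:
                    syns.append(raw[1:end])
        concepts.append(Concept(node, name, tuple(syns)))
    for child, parent, key in g.edges(keys=True):
        if key == "is_a":
            edges.append((child, parent))
    return concepts, edges


def _parse_edge_tsv(path: Path) -> tuple[list[Concept], list[tuple[str, str]]]:
    edges: list[tuple[str, str]] = []
    ids: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip().split("\t")[:2] != ["child_id", "parent_id"]:
            raise FormatError(f"{path}:1: expected header 'child_id<TAB>parent_id'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or not all(parts):
                raise FormatError(f"{path}:{lineno}: expected two tab-separated ids")
            child, parent = parts
            edges.append((child, parent))
            ids.update((child, parent))
    concepts = [Concept(cid, cid) for cid in sorted(ids)]
    return concepts, edges


def _parse_synonym_tsv(path: Path) -> dict[str, list[str]]:
    table: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or not all(parts):
                raise FormatError(f"{path}:{lineno}: expected 'concept_id<TAB>synonym'")
            table.setdefault(parts[0], []).append(parts[1])
    return table


def load_ontology(hierarchy_source: str | Path, synonym_source: str | Path | None = None) -> OntologyGraph:
    """Load an is-a hierarchy from an OBO file or a two-column edge-list TSV.

    The format is chosen by suffix (``.obo`` vs anything else).  An optional
    synonym table (TSV ``concept_id<TAB>synonym``, one row per synonym)
    attaches synonyms; for OBO input it overrides in-file synonyms for the
    concepts it mentions.
    """
    path = Path(hierarchy_source)
    if not path.exists():
        raise FormatError(f"hierarchy file not found: {path}")
    if path.suffix.lower() == ".obo":
        concepts, edges = _parse_obo(path)
    else:
        concepts, edges = _parse_edge_tsv(path)

    if synonym_source is not None:
        syn = _parse_synonym_tsv(Path(synonym_source))
        concepts = [
            Concept(c.concept_id, c.preferred_name, tuple(syn.get(c.concept_id, c.synonyms)))
            for c in concepts
        ]
    return OntologyGraph(concepts, edges)


# ---------------------------------------------------------------------------
# levels, distances, feature spaces


def concept_level(graph: OntologyGraph, concept_id: str) -> int:
    """Minimum number of is-a edges from *concept_id* up to the root."""
    graph.concept(concept_id)
    return graph._levels[concept_id]


def semantic_distance(graph: OntologyGraph, extracted_id: str, feature_id: str) -> int | Unreachable:
    """Edge-count distance from an extracted term up to a feature concept.

    Returns 0 when the two ids coincide, the minimum number of is-a links on
    any upward path when the extracted term is a descendant of the feature
    concept, and :data:`UNREACHABLE` otherwise.  Not symmetric: only upward
    paths (child to ancestor) count.
    """
    graph.concept(extracted_id)
    graph.concept(feature_id)
    if extracted_id == feature_id:
        return 0
    dist = graph._up_lengths[extracted_id].get(feature_id)
    return UNREACHABLE if dist is None else dist


def feature_space(graph: OntologyGraph, level: int, *, root_level: int = 0) -> FeatureSpace:
    """All concepts at the given level, ordered lexicographically by id.

    ``root_level`` shifts the level convention: the default 0 places the root
    at level 0, so "level 4" means four is-a edges below the root.  With
    ``root_level=1`` the same slice is addressed as level 5.
    """
    depth = level - root_level
    if depth < 0:
        raise ValidationError(f"level {level} lies above the root (root_level={root_level})")
    ids = tuple(sorted(cid for cid, lv in graph._levels.items() if lv == depth))
    if not ids:
        raise ValidationError(f"no concept at level {level} (depth {depth} below root)")
    return FeatureSpace(feature_ids=ids, level=level)
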