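"""Weighted, regularized ontological feature vectors and their similarity.

A report with extracted concepts ``d_1..d_n`` maps to the vector
``[a_1, ..., a_m, delta]`` over the feature concepts ``f_1..f_m``:

    a_i = sqrt(p_i) / (1 + min_j s_ij)

where ``s_ij`` is the edge-count semantic distance from ``d_j`` up to
``f_i`` and ``p_i`` the feature's conditional-probability weight.  When no
extracted term descends from ``f_i`` (all distances unreachable, or the
report is empty) the element is 0.  The regularization constant
``delta = 10^-k`` is appended as an extra element so vector norms stay
bounded away from zero; the cosine of two augmented vectors (the modified
direction cosine) is therefore defined — and strictly positive — even for
reports with few or no extracted terms.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from ontosim.errors import ContractError, ValidationError
from ontosim.ontology import FeatureSpace, OntologyGraph, UNREACHABLE, semantic_distance
from ontosim.weighting import WeightVector, equal_weights

__all__ = [
    "Report",
    "VectorConfig",
    "OntoFeatureVector",
    "build_feature_vector",
    "mdc_similarity",
    "pairwise_similarities",
    "read_reports",
]


@dataclass(frozen=True)
class Report:
    """One patient record: id, diagnosis label, extracted concept ids."""

    report_id: str
    diagnosis: str
    term_ids: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.report_id:
            raise ValidationError("report_id must be non-empty")
        if not self.diagnosis:
            raise ValidationError(f"report {self.report_id!r} has an empty diagnosis")
        object.__setattr__(self, "term_ids", frozenset(self.term_ids))


def read_reports(path) -> list[Report]:
    """Read a report table TSV: ``report_id<TAB>diagnosis<TAB>a;b;c``.

    The third column is a semicolon-joined (possibly empty) list of concept
    ids.
    """
    from ontosim.errors import FormatError

    reports = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) not in (2, 3):
                raise FormatError(f"{path}:{lineno}: expected 2-3 tab-separated fields")
            rid, diag = parts[0], parts[1]
            terms = [t for t in (parts[2].split(";") if len(parts) == 3 else []) if t]
            reports.append(Report(rid, diag, frozenset(terms)))
    return reports


@dataclass(frozen=True)
class VectorConfig:
    """Vector-model settings: regularization exponent k and feature level."""

    k: int = 10
    level: int = 4

    def __post_init__(self):
        if self.k < 0:
            raise ValidationError("k must be a non-negative integer")
        if self.level < 1:
            raise ValidationError("feature level must be >= 1")

    @property
    def delta(self) -> float:
        return 10.0 ** (-self.k)


@dataclass(frozen=True)
class OntoFeatureVector:
    """The augmented vector ``[a_1..a_m, delta]`` tied to its feature space."""

    elements: np.ndarray  # the a_i only; delta kept separately
    delta: float
    space: FeatureSpace

    def __post_init__(self):
        arr = np.asarray(self.elements, dtype=float)
        object.__setattr__(self, "elements", arr)
        if arr.ndim != 1 or len(arr) != len(self.space):
            raise ContractError("element count does not match the feature space")
        if np.any((arr < 0) | (arr > 1)):
            raise ValidationError("vector elements must lie in [0, 1]")
        if not (0 < self.delta <= 1):
            raise ValidationError("delta must lie in (0, 1]")

    @property
    def augmented(self) -> np.ndarray:
        return np.concatenate([self.elements, [self.delta]])


def build_feature_vector(
    report: Report,
    space: FeatureSpace,
    graph: OntologyGraph,
    weights: WeightVector,
    config: VectorConfig,
) -> OntoFeatureVector:
    """Map a report to its weighted, regularized ontological feature vector."""
    if weights.scheme == "specific" and weights.report_id != report.report_id:
        raise ContractError(
            f"specific weights for report {weights.report_id!r} used with "
            f"report {report.report_id!r}"
        )
    missing = [fid for fid in space.feature_ids if fid not in weights.weights]
    if missing:
        raise ContractError(f"weights missing for features {missing[:5]}")

    elems = np.zeros(len(space))
    for i, fid in enumerate(space.feature_ids):
        best: int | None = None
        for tid in report.term_ids:
            s = semantic_distance(graph, tid, fid)
            if s is not UNREACHABLE and (best is None or s < best):
                best = s
        if best is not None:
            elems[i] = math.sqrt(weights[fid]) / (1 + best)
    return OntoFeatureVector(elements=elems, delta=config.delta, space=space)


def mdc_similarity(q: OntoFeatureVector, d: OntoFeatureVector) -> float:
    """Modified direction cosine: cosine of the two delta-augmented vectors.

    Symmetric, equal to 1 for identical vectors (to floating-point
    tolerance), and strictly positive because both vectors share the same
    positive delta element.
    """
    if q.space != d.space:
        raise ContractError("vectors built over different feature spaces")
    if q.delta != d.delta:
        raise ContractError(f"delta mismatch: {q.delta} vs {d.delta}")
    a, b = q.augmented, d.augmented
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def pairwise_similarities(
    cohort: list[Report],
    space: FeatureSpace,
    graph: OntologyGraph,
    weights: WeightVector | Callable[[Report], WeightVector],
    config: VectorConfig,
) -> pd.DataFrame:
    """Similarity scores for every unordered pair of distinct reports.

    ``weights`` is either a single shared :class:`WeightVector` (equal or
    generic schemes) or a factory ``report -> WeightVector`` producing the
    per-report weights of the specific scheme.  Returns a DataFrame with
    columns ``id_a``, ``id_b``, ``score`` and C(R, 2) rows, ordered by the
    sorted pair of ids so the output is independent of cohort input order.
    """
    if len(cohort) < 2:
        raise ValidationError("need at least two reports to form pairs")
    ids = [r.report_id for r in cohort]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate report ids: {dupes[:5]}")

    factory = weights if callable(weights) else (lambda _report: weights)
    vectors = {r.report_id: build_feature_vector(r, space, graph, factory(r), config) for r in cohort}

    rows = []
    for id_a, id_b in itertools.combinations(sorted(vectors), 2):
        rows.append((id_a, id_b, mdc_similarity(vectors[id_a], vectors[id_b])))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "score"])
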