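"""ROC evaluation of diagnosis co-occurrence prediction.

Every unordered pair of reports is labeled *match* (same diagnosis) or
*mismatch* (different diagnosis); the similarity score is scored as a
classifier of that label.  The AUROC — the probability that a randomly
chosen match pair scores above a randomly chosen mismatch pair — is
computed by the rank (Mann–Whitney) formulation with midranks for ties,
with a 95% confidence interval from the Hanley–McNeil standard error.
Correlated AUROCs from different weighting schemes on the same pairs are
compared with DeLong's covariance method.  ``sweep_k`` traces AUROC against
the regularization exponent k and picks the smallest k on the plateau of
the maximum.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from ontosim.errors import ContractError, DegenerateRocError, ValidationError
from ontosim.vectors import Report, VectorConfig, pairwise_similarities

__all__ = [
    "PairLabelSet",
    "RocResult",
    "KSweepResult",
    "label_pairs",
    "roc_auroc",
    "compare_auroc",
    "sweep_k",
    "cluster_bootstrap_auroc_ci",
]

MATCH, MISMATCH = "match", "mismatch"


@dataclass(frozen=True)
class PairLabelSet:
    """Match/mismatch labels for all C(R,2) unordered report pairs."""

    rows: pd.DataFrame  # columns: id_a, id_b, label

    @property
    def n_match(self) -> int:
        return int((self.rows["label"] == MATCH).sum())

    @property
    def n_mismatch(self) -> int:
        return int((self.rows["label"] == MISMATCH).sum())

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class RocResult:
    auroc: float
    ci_low: float
    ci_high: float
    curve: pd.DataFrame  # columns: fpr, tpr
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class KSweepResult:
    rows: pd.DataFrame  # columns: k, auroc
    chosen_k: int


def label_pairs(cohort: list[Report]) -> PairLabelSet:
    """Label every unordered pair of distinct reports by diagnosis identity."""
    if len(cohort) < 2:
        raise ValidationError("need at least two reports to form pairs")
    ids = [r.report_id for r in cohort]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate report ids in cohort")
    diag = {r.report_id: r.diagnosis for r in cohort}
    rows = [
        (a, b, MATCH if diag[a] == diag[b] else MISMATCH)
        for a, b in itertools.combinations(sorted(ids), 2)
    ]
    return PairLabelSet(pd.DataFrame(rows, columns=["id_a", "id_b", "label"]))


def _align(scores: pd.DataFrame, labels: PairLabelSet) -> tuple[np.ndarray, np.ndarray]:
    """Return (score array, boolean positive array) aligned over the pair set."""
    key = lambda df: df.apply(
        lambda r: (min(r["id_a"], r["id_b"]), max(r["id_a"], r["id_b"])), axis=1
    )
    s = scores.set_axis(key(scores), axis=0)["score"]
    lab = labels.rows.set_axis(key(labels.rows), axis=0)["label"]
    missing = lab.index.difference(s.index)
    if len(missing) > 0:
        raise ContractError(f"missing scores for {len(missing)} labeled pair(s), e.g. {missing[0]}")
    s = s.loc[lab.index]
    pos = (lab == MATCH).to_numpy()
    if pos.all() or not pos.any():
        raise DegenerateRocError("ROC needs both match and mismatch pairs")
    return s.to_numpy(dtype=float), pos


def _rank_auroc(scores: np.ndarray, pos: np.ndarray) -> float:
    """Mann–Whitney AUROC with midranks for ties."""
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)  # midranks
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def roc_auroc(scores: pd.DataFrame, labels: PairLabelSet) -> RocResult:
    """ROC curve and AUROC (with 95% CI) of pair scores against match labels.

    ``scores`` must cover every labeled pair (columns ``id_a, id_b, score``).
    Matches are the positive class.
    """
    s, pos = _align(scores, labels)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    auc = _rank_auroc(s, pos)
    se = _hanley_mcneil_se(auc, n_pos, n_neg)
    half = norm.ppf(0.975) * se
    fpr, tpr, _ = _sk_roc_curve(pos.astype(int), s, drop_intermediate=False)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return RocResult(
        auroc=auc,
        ci_low=max(0.0, auc - half),
        ci_high=min(1.0, auc + half),
        curve=curve,
        n_pos=n_pos,
        n_neg=n_neg,
    )


# ---------------------------------------------------------------------------
# DeLong comparison of correlated AUROCs


def _delong_components(scores: np.ndarray, pos: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUROC plus the V10 (per-positive) and V01 (per-negative) placements."""
    x, y = scores[pos], scores[~pos]  # positives, negatives
    m, n = len(x), len(y)
    # midrank placements via global/midrank trick (DeLong via Sun & Xu)
    rx = rankdata(x)
    ry = rankdata(y)
    rall = rankdata(np.concatenate([x, y]))
    v10 = (rall[:m] - rx) / n
    v01 = 1.0 - (rall[m:] - ry) / m
    auc = float(v10.mean())
    return auc, v10, v01


def compare_auroc(
    scores_a: pd.DataFrame, scores_b: pd.DataFrame, labels: PairLabelSet
) -> tuple[float, float, float, float]:
    """DeLong test for two correlated AUROCs computed on the same pairs.

    Returns ``(auroc_a, auroc_b, difference, p_value)`` with a two-sided
    p-value for ``auroc_a - auroc_b``.  Both score tables must cover the
    identical labeled pair set; rank-preserving transformations of the
    scores leave the result unchanged.
    """
    sa, pos_a = _align(scores_a, labels)
    sb, pos_b = _align(scores_b, labels)
    if not np.array_equal(pos_a, pos_b):
        raise ContractError("score tables disagree on the labeled pair set")

    auc_a, v10_a, v01_a = _delong_components(sa, pos_a)
    auc_b, v10_b, v01_b = _delong_components(sb, pos_a)
    m, n = len(v10_a), len(v01_a)

    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    var_diff = (
        s10[0, 0] / m + s10[1, 1] / m - 2 * s10[0, 1] / m
        + s01[0, 0] / n + s01[1, 1] / n - 2 * s01[0, 1] / n
    )
    diff = auc_a - auc_b
    if var_diff <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2 * norm.sf(abs(z)))
    return auc_a, auc_b, diff, p


def cluster_bootstrap_auroc_ci(
    scores: pd.DataFrame,
    cohort: list[Report],
    *,
    n_boot: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Report-level bootstrap CI for the AUROC (sensitivity analysis).

    Pairs sharing a report are statistically dependent, which the standard
    analysis (and the Hanley–McNeil CI) ignores by treating pairs as
    independent observations.  This resamples *reports* with replacement and
    recomputes the AUROC over pairs of distinct resampled reports, giving a
    dependence-aware percentile interval.  Offered as a sensitivity check;
    the default analysis keeps the pair-independence convention.
    """
    rng = np.random.default_rng(seed)
    diag = {r.report_id: r.diagnosis for r in cohort}
    lookup: dict[tuple[str, str], float] = {}
    for row in scores.itertuples(index=False):
        a, b = sorted((row.id_a, row.id_b))
        lookup[(a, b)] = row.score
    ids = sorted(diag)
    aucs = []
    while len(aucs) < n_boot:
        sample = rng.choice(ids, size=len(ids), replace=True)
        vals, pos = [], []
        for i, j in itertools.combinations(range(len(sample)), 2):
            a, b = sample[i], sample[j]
            if a == b:
                continue
            vals.append(lookup[tuple(sorted((a, b)))])
            pos.append(diag[a] == diag[b])
        pos_arr = np.asarray(pos)
        if pos_arr.all() or not pos_arr.any():
            continue  # degenerate resample; redraw
        aucs.append(_rank_auroc(np.asarray(vals), pos_arr))
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# regularization sweep


def sweep_k(
    cohort: list[Report],
    space,
    graph,
    weights,
    k_values: list[int],
    *,
    plateau_tol: float = 1e-3,
) -> KSweepResult:
    """AUROC as a function of the regularization exponent k.

    ``chosen_k`` is the smallest swept k whose AUROC lies within
    ``plateau_tol`` of the maximum — the smallest k safely on the plateau
    where accuracy has saturated.
    """
    if not k_values:
        raise ValidationError("k_values must be non-empty")
    if any((not isinstance(k, (int, np.integer))) or k < 0 for k in k_values):
        raise ValidationError("k values must be non-negative integers")
    labels = label_pairs(cohort)
    rows = []
    for k in k_values:
        cfg = VectorConfig(k=int(k), level=space.level)
        scores = pairwise_similarities(cohort, space, graph, weights, cfg)
        rows.append((int(k), roc_auroc(scores, labels).auroc))
    df = pd.DataFrame(rows, columns=["k", "auroc"])
    best = df["auroc"].max()
    chosen = int(df.loc[df["auroc"] >= best - plateau_tol, "k"].min())
    return KSweepResult(rows=df, chosen_k=chosen)
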