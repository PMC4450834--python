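# Methods

## Model

A patient report is a set of extracted concept ids from a rooted is-a
hierarchy (a DAG; multiple parents allowed).  Fix a feature level *L*
(default 4, root at level 0) and let *f₁..f_m* be the concepts whose
minimum edge distance to the root equals *L*, ordered lexicographically by
id so vector axes are reproducible.

**Semantic distance.** For an extracted term *d* and feature concept *f*,
*s(d, f)* is 0 when *d = f*, the minimum number of is-a edges over all
upward paths from *d* to *f* when *d* is a descendant, and an UNREACHABLE
sentinel otherwise.  Distance is deliberately asymmetric (upward paths
only), and both levels and distances take the minimum over paths when a
concept has several parents — the same convention as the minimum over terms
inside the vector element.  UNREACHABLE is a typed singleton, not a large
integer; arithmetic with it is an error, and its only sanctioned use is
"contributes a zero element".

**Feature vector.** Report → [a₁..a_m, δ] with aᵢ = √pᵢ / (1 + min_j sᵢⱼ),
the minimum running over the report's terms with finite distance; an empty
term set, or one with no descendant of *fᵢ*, gives aᵢ = 0 exactly (√0 = 0;
no epsilon flooring).  δ = 10⁻ᵏ, k a non-negative integer (default 10), is
appended once per vector.  Similarity is the cosine of the two augmented
vectors, which is symmetric, 1 on identical vectors to 1e-12 relative
tolerance, and strictly positive since both vectors share δ > 0.  Scores
are emitted at full precision; two vectors built over different feature
spaces or with different δ are a contract error rather than silently
reconciled.  At k = 0 the δ element dominates every score (all pairs look
alike); as k grows the augmented cosine converges monotonically to the
plain cosine of the raw vectors.  The sweep utility picks the smallest k
whose AUROC is within 1e-3 of the sweep maximum, over a default range
0..12.

## Term weighting

Weights are conditional probabilities of concept mention given a disease
mention, estimated as ratios of abstract counts.  A concept is queried as a
*group* — preferred name plus synonyms, deduplicated case-insensitively —
and an abstract counts when any group name occurs as a case-insensitive
whole-phrase (word-boundary) match, at most once per group.  This
approximates the phrase search of a literature index without reproducing
any specific engine's tokenizer; the `CountProvider` interface is the seam
where a live index client could be plugged in, but only the local-corpus
scanner and the replayed count table are part of the tested surface, since
counts from a live service drift over time.  The count table keys groups by
their case-folded primary name, with `*` as the marginal key, and validates
joint ≤ marginal on load.

Specific weighting averages the per-term conditionals *q* of the report's
terms descending from (or equal to) each feature concept.  A feature with
no such term gets weight 0: the choice is inert because the corresponding
vector element is already 0, but it keeps the weight vector total.  The
plain (unweighted) mean is used; weighting by within-report term frequency
would require counts the report representation does not carry.  A zero
disease marginal raises an undefined-denominator error rather than
returning 0/0.

## Evaluation

Pairs of reports are labeled match/mismatch by diagnosis identity; for R
reports all C(R, 2) unordered pairs are formed (a 59 + 53 cohort yields
6216 pairs: 3089 matches, 3127 mismatches).  AUROC uses the midrank
Mann–Whitney formulation — ties everywhere get midranks — with a
Hanley–McNeil 95% CI for single curves, and the ROC curve itself comes
from a threshold sweep so that its trapezoidal area matches the rank AUROC
to 1e-9.  Correlated AUROCs over the same pair set are compared with
DeLong's covariance method (two-sided; monotone score transforms leave the
statistic unchanged; a zero-variance difference of zero reports p = 1).
Hand-written because no installed package exposes DeLong or Hanley–McNeil;
the AUROC is cross-checked in tests against an O(n²) counting oracle and
an independent curve integration.

Pairs sharing a report are dependent, but the default analysis follows the
field convention of treating pairs as independent.  A report-level
(cluster) bootstrap CI is available as a clearly separated sensitivity
option (`--cluster-bootstrap`); it resamples reports with replacement,
redraws degenerate one-class resamples, and reports a percentile interval.

## Synthetic data

The generator emulates the structure of the real inputs, not their
content:

- **Ontology** — grown level by level to a fixed depth (default 7);
  children per node are 1 + Poisson(branching − 1), keeping the stated mean
  branching while preventing extinct lineages so every level down to the
  target depth is populated; an optional probability adds second parents at
  the same parent level, emulating multiple inheritance without disturbing
  levels.  Concepts get 0–3 synthetic synonyms.
- **Cohort** — each diagnosis label owns a panel of deep concepts (level ≥
  5, strictly below the feature level, as extracted clinical terms are).
  Panel overlap is controlled at the feature level: shared feature subtrees
  supply the common terms, label-exclusive subtrees the discriminative
  ones.  Overlap 0 therefore yields disjoint feature projections (near-
  perfect signal by construction), overlap 1 identical panels (no signal);
  AUROC responds monotonically in between.  Term counts per report are 1 +
  Poisson(mean − 1) (default mean 4), with an optional empty-report
  probability.
- **Corpus** — abstract-level Bernoulli co-mention model: an abstract
  mentions the disease with fixed probability, and each term independently
  with a probability conditional on disease status.  This is the simplest
  model under which the ratio estimators are consistent for the planted
  conditionals (binomial error ~ 1/√n of disease abstracts).  Mentions use
  the preferred name or a random synonym.  Because generic weighting
  queries the feature-level names themselves, the default profiles also
  plant mentions of the panel terms' feature-level ancestors at a slightly
  lower rate — mirroring how authors use both specific and broader terms —
  otherwise feature-level counts would all be zero and generic weighting
  degenerate.

All generators are deterministic per seed.  What passing tests show is
that the implementation recovers planted parameters and orderings under
this model; real report corpora have correlated term usage, non-Bernoulli
literature counts, and terminology-mapping noise that the generators do
not emulate, so synthetic AUROCs say nothing about absolute performance on
real data.

## Scale of the shipped analyses

The test suite and the acceptance script run end-to-end analyses at 80
reports (3160 pairs), ontologies of a few hundred concepts, 5000-abstract
corpora, and 1000 Monte-Carlo replicates for the type-I-error check of the
correlated-AUROC test — sizes chosen to exercise every code path at the
cohort scale the method targets while keeping a full run in seconds.  The
acceptance script redraws the ontology seed until the concept count lands
in the few-hundred range, since the branching process has heavy size
variance.

## Known limitations

- Only is-a relations are used; other relationship types are out of scope,
  as is parsing full terminology releases (RF2) — inputs are OBO or
  edge-list TSV.
- The edge-list format carries no preferred-name column; round-tripping a
  graph through it stores preferred names as leading synonyms so query
  groups survive.
- Phrase matching is whole-word substring, not a tokenizer-faithful
  reproduction of any specific literature index; field restrictions and
  index dates of a live search are inherently unreproducible and are not
  modeled.
- The level convention (root = 0) is configurable (`root_level`) because
  terminologies differ on whether the root counts as level 0 or 1.
- A term descending from several feature concepts contributes to every one
  of them independently, consistent with scoring each feature axis in
  isolation.
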