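# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and
the numerical conventions a maintainer needs.

## Differential expression

Input is log2-scale expression already summarized to gene/probe-set level,
as paired treated/control replicate matrices. Quantile normalization maps
every sample column onto the row-wise mean of the column-sorted matrix;
ties receive average ranks, with half-ranks interpolating the two flanking
reference values. Background subtraction and probe-level summarization are
out of scope — the package consumes summarized matrices.

The per-gene test is the two-sided Wilcoxon signed-rank test on paired
differences. Zero differences are excluded before ranking (the classical
rule) and tied |differences| get average ranks. For up to 25 non-zero pairs
the p-value is exact: the null distribution of the rank sum is built by
dynamic programming over the doubled ranks (doubling makes tied half-ranks
integral), and the two-sided p is min(1, 2·min(P(W ≤ w), P(W ≥ w))). Above
25 pairs a normal approximation with continuity correction and the standard
tie-correction of the variance is used. Scipy's implementation serves as an
independent cross-check in the test suite (exact mode for untied data,
approximate mode above the exact limit) but is not the implementation,
because the exact-with-average-ranks behavior under ties is part of this
package's contract.

Genes are selected at *p* strictly below 0.003, uncorrected — a fixed
profile-selection threshold, not an FDR procedure. Replicate probe IDs are
then collapsed to one row per gene: collapsed p is the arithmetic mean of
member p-values, fold change is the member mean and sets the direction, and
conflicting member directions are kept (direction from the mean) with a
warning. Select-then-collapse is the default ordering; `resignify=True`
gives collapse-then-select for users who prefer re-thresholding the
averaged p. Whether testing should be one- or two-sided is exposed only as
the two-sided choice: both regulation directions are retained and carried
downstream, which the directional compendium states require.

A test discreteness consequence worth knowing: the exact two-sided p can
never fall below 2/2ⁿ for n pairs, so at least 10 replicate pairs are
needed for any gene to pass 0.003. The synthetic default of 12 pairs (see
below) is chosen with this in mind.

## Knowledge bases

The compendium (extended GMT: pathway, stratum tag, member genes), the
signed regulator network (3-column TSV) and the interaction graph (SIF)
replace a proprietary commercial knowledge base with user-supplied files;
the package ships none of its own curated content. Validation enforces the
nine required pathway names (unicode spellings are canonicalized to ASCII),
disjoint upstream/downstream strata within a pathway, ±1 edge signs without
duplicate pairs, and a simple interaction graph. Gene identifiers are
upper-cased everywhere.

"Focus genes" are significant DE genes with degree ≥ 1 in the interaction
graph. Commercial eligibility rules are proprietary, so graph membership is
used as the closest observable proxy; the eligibility percentage is
100·|focus|/|significant| rounded to one decimal.

## Compendium scoring

Each significant gene contributes to every (pathway, stratum) that lists it
— pathway profiles are marginal summaries, so multi-pathway genes are
counted once per stratum but in every pathway. The stratum activation
percent is 100·(up+down)/|stratum members|; member-gene counting is used
for the denominator (an interaction-count denominator was considered and
rejected as unobservable from GMT-style inputs). Up and down counts are
reported separately in the long-format output, while the model features
use the combined percent: the predictor space is deliberately
18-dimensional (9 pathways × 2 strata), not 36, and feature order is fixed
(pathway case-insensitive alphabetical × upstream-then-downstream) so that
model coefficients are reproducible. Empty strata yield 0% with a warning
rather than an error.

## Upstream regulators

Enrichment of a regulator's targets among significant genes is the
hypergeometric upper tail P(X ≥ k) (one-tailed Fisher exact) against the
measured universe — all genes on the array after collapse, not the
knowledge-base genes, because the background must be the space in which
significance was assessed. The activation z-score is the unweighted
sign-consistency statistic z = Σsᵢ/√N over significant targets, sᵢ = +1
when the observed direction matches the edge-sign prediction under
activation. No literature-confidence weighting or bias correction is
applied (those schemes are proprietary); output metadata labels the
statistic accordingly. Defaults z = ±2.0 and p_max = 0.01 are the
conventional cutoffs and are flags; regulators failing either, or with no
significant targets, are "undetermined".

## Networks

Construction is deterministic greedy accretion: seed at the highest-degree
focus gene not covered by a previous network, then repeatedly add the
neighbor maximizing (focus-gene gain, graph degree, lexicographically
smallest ID) until the 35-node cap. The cap and the greedy rule replace a
proprietary algorithm; what matters downstream — connectivity-driven,
score-ranked, deterministic networks — is preserved, and every tie-break is
total so reruns are identical. Networks share no seeds but may share other
nodes. The score is −log10 of the hypergeometric tail for focus content
(score 3 ⇔ p = 10⁻³ ⇔ 99.9% confidence); p is floored at 1e-300 before the
log. Degree rankings count intra-network edges only. Merging
pathway-anchored networks takes the node/edge union and retains one
regulation state per source treatment. For percent overlap of two gene
sets, three denominator conventions (union, smaller set, mean size) are
implemented without endorsing one; reports should state which was used.

## PLSR

PLS1 by NIPALS: weight vectors are successive directions of maximal
covariance between the centered (and by default unit-variance scaled)
features and the centered response, with X deflated after each component.
Coefficients are returned on the original feature scale. The component
count defaults to min(n−1, p) — the maximum, equal to 4 for the 5-sample ×
18-feature problem the pipeline produces — at which the fit coincides with
least squares on the centered data; fewer components regularize. Requests
beyond the maximum are clamped with a warning, and extraction stops early
if the response residual is numerically exhausted. Scaling is on by default
because the percent features span very different ranges; `scale=False`
reproduces raw-covariance behavior.

Sensitivity pruning is a single pass, not an iterated greedy: each feature
is left out once, the model refit, and the training RSS compared with the
full model's. A feature is dropped when its removal does not increase the
RSS beyond tolerance (1e-8·(1+RSS)); the survivors are refit jointly. The
non-strict comparison is deliberate — a pure-noise column added to an
interpolating fit leaves the RSS unchanged rather than strictly lowering
it, and must still be flagged. Two consequences to be aware of: mutually
redundant features (duplicated columns) are all dropped together, and in
the p ≫ n regime every leave-one-out refit interpolates, so all features
become removable and the fallback keeps only the single feature whose
removal is most damaging, with a warning. Removal of a pathway's influence
can be tested two ways — dropping its feature columns or dropping a
treatment row — and the CLI exposes both (`--drop-feature`,
`--drop-sample`) so they can be reported side by side.

Percent error is 100·|ŷ−y|/|y| per sample (NaN with a warning when y = 0)
and the total error is the residual sum of squares.

## Synthetic data

The generator's defaults are the study conditions of the pipeline:
10,000 genes, 12 replicate pairs, six treatments (PNF-1, SC-3-141,
SC-3-143, SC-3-263, VEGF, endostatin), nine pathways of 15 upstream + 30
downstream members drawn disjointly from the universe, Gaussian noise of
0.25 on the log2 scale (Gaussian noise on log2 expression matches
RMA-style summarized data conventions), and planted per-treatment pathway
effects of 1.2–2.5 log2 units echoing the modeled biology (TNF-α/TGF-β/
NR3C1 signatures for the phthalimides, VEGF-axis effects for the
controls). Off-pathway background DE hits an 8% fraction of non-member
genes with effects of ±Uniform(1, 2) log2 units; at these settings each
treatment yields several hundred to ~1,000 significant genes, matching the
600–1,400 per-treatment range the analysis is designed for. Twelve
replicate pairs make the exact signed-rank null rate at p < 0.003 equal
10/4096 ≈ 0.0024, within the binomial calibration band tested at 10⁴
genes. Growth rates are a sparse linear map of the 18 percent features
(weights on the VEGF, TGF-β, TNF-α and NR3C1 downstream strata) plus
Gaussian noise of 0.05.

All randomness flows through per-purpose `SeedSequence` streams derived
from the config seed (never global state), so knowledge base, expression,
and growth draws are independent and each is bit-reproducible.

What the generator does **not** emulate: probe-level intensities, array
batch effects, time-course autocorrelation, heavy-tailed or
intensity-dependent noise, and correlated co-expression outside the
planted pathway structure. Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes — planted effects, calibrated
nulls, linear growth maps — not that real microarray data satisfy those
assumptions.

## Problem sizes used in the shipped runs

The bundled demo and the reproducibility checks run a scaled-down study —
2,000 genes, 8+16-member strata, 12 replicate pairs, six treatments —
which preserves every structural property of the full-size defaults
(pathway disjointness, null calibration granularity, the 5 × 18 PLSR
shape with a held-out treatment) while keeping a full pipeline run around
a second. Unit tests use smaller universes still (100–1,500 genes) where
brute-force oracles (2ⁿ sign enumeration, hypergeometric pmf summation,
nested-loop recounts) are feasible.

## Known limitations

- Table-level reproduction of any specific published knowledge-base
  content is out of scope: compendium counts, regulator calls and network
  memberships depend entirely on the user-supplied knowledge files.
- The activation z-score is unweighted; calls for regulators with few
  significant targets are noisy and gated only by the enrichment p.
- The greedy network growth is a deterministic stand-in, not an inference
  procedure with optimality guarantees.
- With p ≫ n the PLSR training fit is an interpolation; held-out
  predictions are only meaningful when new samples share the training
  data's latent structure, and the sensitivity prune degenerates as
  described above.
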