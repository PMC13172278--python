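# Methods

This note documents the models and procedures implemented in `refugia`, the
assumptions behind them, the parameters that matter, and the choices made
where the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic study system

All validation runs on simulated landscapes with known ground truth.

**Environment.** Each layer is white noise convolved with an isotropic
Gaussian kernel (sigma = `correlation_length`, default 8 cells),
standardized to mean 0 / sd 1 over the analysis mask, plus a north–south
ramp scaled by `latitudinal_trend` (default 0.5). This reproduces the one
property of real climate rasters that distribution models exploit — smooth
spatial autocorrelation with a broad gradient — and nothing else: no
cross-layer covariance structure, no topography, no coastlines. Layers are
unitless (sd units). Future scenarios add a per-layer constant, an optional
extra ramp, and small seeded noise (sd 0.05); three ordered presets (mild /
moderate / severe: +1, +2.5, +4 on temperature-like layers; −0.2, −0.5,
−1.0 on precipitation-like layers) stand in for an ordered ladder of
emission pathways. These shifts are large relative to the niche breadths
below, so projected ranges move a lot; the synthetic "climate change" is
deliberately strong rather than calibrated to any real scenario.

**Phylogeny.** A Yule (pure-birth) process: waiting times between
speciations are Exponential(k·λ) over k extant lineages, a uniformly random
lineage splits at each event, and after the n-th tip appears the tree is
extended to the present by one further exponential draw so every branch
length is strictly positive. Trees are ultrametric; λ (`birth_rate`,
default 1) only sets the time scale.

**Traits.** Continuous traits evolve by Brownian motion along the tree
(variance `signal` per unit branch length); categorical traits threshold an
underlying Brownian trait at tip-value quantiles into ≥ 2 states. Exactly
`floor(missing_fraction · n_species · n_traits)` entries are masked
uniformly at random, redrawing (bounded retries) any mask that would blank
an entire species row. Traits are phylogenetically structured by
construction — there is no environmental or allometric component.

**Virtual species.** Each species' niche center is the environment vector
of a randomly drawn analysis cell, which guarantees a nonempty true range
for any presence cutoff < 1; per-layer niche breadths are uniform on
`breadth_range` (default 1–2 sd). Suitability is the product Gaussian
`exp(−Σ_k (e_k − μ_k)²/(2σ_k²))` and the true range is
`suitability ≥ presence_cutoff` (default 0.5). Occurrences are drawn from
true-range cells with probability proportional to suitability, with
replacement (so record counts can exceed distinct occupied cells, as in
real data), at cell centers unless `coordinate_noise` > 0.

**Protected areas and condition layer.** The PA mask is the union of disks
grown around `n_patches` seed cells and trimmed farthest-first to the
target coverage (default 10% of the analysis mask, ± 10% relative — met
exactly whenever the cell budget allows). The human-influence surface is
rank-normalized smoothed noise in [0, 1]; the prioritization condition
layer is 1 − influence, generated independently of the species, so any
PA–priority overlap in a synthetic run is geometric coincidence, not
ecology. Passing tests therefore validate the *machinery* (metrics,
ranking, Boolean logic), not any empirical claim about real protected-area
performance.

## Occurrence QC and variable filtering

Cleaning applies four rules in a fixed order, each tallied in the QC
report: non-finite coordinates; records outside the analysis mask; exact
duplicates of (species, x, y); and per-species grid-cell thinning keeping
the first record in stable input order. Gazetteer-based checks (country
centroids, institutions, urban areas) are out of scope — the report makes
the reduced rule set visible. Cleaning is idempotent.

Collinearity filtering scans layers in a caller-supplied priority order
(default: stack order) and keeps a layer iff its absolute Pearson
correlation with every already-kept layer, over analysis-mask cells, is
below the threshold (default 0.8). Constant layers are dropped with a
warning. No "model contribution" screen is implemented, because no defensible
definition exists without fixing a model class first; the priority order is
the hook for encoding one.

## Tiered distribution modeling

Species are routed by cleaned record count: ≥ 6 records → tier 1; 2–5 →
tier 2; 1 → tier 3.

**Evaluation primitives.** AUC is the Mann–Whitney rank statistic (ties
count one half). The binarization threshold is the observed score
maximizing sensitivity + specificity (maxSSS) under the rule
`score ≥ θ → presence`; the scan compares candidates by the exact integer
count `sens_count·n_b + spec_count·n_p`, because floating-point summation
order can otherwise make exact rational ties ill-defined, and takes the
smallest candidate on ties. TSS = sensitivity + specificity − 1 at θ.

**Tier 1.** Three built-in member families fit labeled presence/background
points in standardized environmental space: a logistic-linear model, a
percentile-envelope (per-variable presence percentile folded so the median
scores 1, combined by minimum), and a kernel-density ratio p/(p+b). The
KDE is a diagonal-bandwidth product Gaussian with per-dimension Silverman
bandwidths floored at 0.1 sd — the floor keeps the density finite for tiny
or degenerate samples. The family roster is a plugin point; the framework
around it is fixed: each family is scored by 5-fold cross-validation
repeated 5 times (folds are random partitions of presences and backgrounds
separately; 5 folds ≈ an 80/20 split, reduced toward leave-one-out with a
warning when records are scarce), families with mean held-out TSS ≥ 0.7
are retained, refit on all records, and averaged with TSS-proportional
weights; the ensemble is min–max rescaled to [0, 1] over the analysis mask
and binarized at its maxSSS threshold. If no family qualifies the best one
is kept and flagged. Future projection applies the stored scaler, weights,
rescale, and threshold to the future stack — nothing is re-estimated.
Background: 1000 cells drawn uniformly from the analysis mask excluding
presence cells.

**Tier 2.** Three presence-only plausibility models (presence/background
KDE ratio, presence-only KDE, exponential decay with distance to the
presence centroid, time constant floored at 0.5 sd). Each is thresholded
at the 5% linear-interpolation quantile of its scores at the presence
points — with n ≤ 5 points this sits just above the minimum score —
filtered at AUC ≥ 0.7 against background, and the range is the union of
the survivors (best single model, flagged, if none survive).

**Tier 3.** Cells whose centers lie within 5 km of the single record,
attached unchanged to every scenario.

## Diversity metrics

TD, PD and FD share one computational core: an edge × species incidence
matrix over the tree (or dendrogram), so the branch sum for every cell of a
raster is a single matrix product. An edge contributes its length when at
least one descendant species is present — exactly the root-inclusive
spanning-subtree convention, under which a single-species cell scores its
root-to-tip path. The same convention is applied to the functional
dendrogram for structural comparability of PD and FD; single-species FD is
therefore also positive. Species absent from the tree are excluded with a
one-time warning. Polytomies are handled naturally (every edge scored
independently).

Trait imputation fills each missing value from the k = 5 phylogenetically
nearest species with observed values: inverse-path-distance weighted mean
for continuous/ordinal traits (ordinal rounded), plurality for
categorical/binary with ties resolved by the single nearest donor. Imputed
entries are flagged. This is a deliberately simple, auditable stand-in for
heavier phylogenetic-comparative imputation ensembles; the test suite
verifies it beats grand-mean imputation on Brownian traits, which is the
property the pipeline actually needs.

Gower distances use pairwise deletion (a trait contributes to a pair only
when both values are observed), range-normalization by the observed range
for continuous/ordinal traits (zero-range traits skipped), and mismatch
indicators for categorical/binary. A pair with no comparable trait is an
error naming the pair. UPGMA merges the closest pair (size-weighted average
linkage), with node height half the merge distance; ties on the closest
pair break by the lexicographically smallest pair of cluster labels (a
cluster is labelled by its alphabetically first member), which fixes the
topology across platforms.

## Prioritization

Features are species ranges (weight 1) for TD, or tree/dendrogram edges
(weight = branch length, footprint = union of descendant-species ranges)
for PD/FD; empty features are dropped with a warning. A [0, 1] condition
layer multiplies feature values cell-wise. The greedy core-area rule
removes, at each step, the remaining cell minimizing
`δ_i = max_j (w_j · r_ij / Σ_remaining r_j) / c_i`, ties to the smallest
row-major index; cell cost c is 1 throughout. This is the classic
core-area marginal-loss rule — an auditable approximation of commercial
CAZ implementations, not a clone. Priority rank is removal position / N;
the top 30% of ranks per dimension are priority areas.

The implementation exploits a monotonicity: remaining totals only shrink,
so `w_j / total_j` only grows and each cell's δ can be maintained as a
running maximum, updated sparsely when one of its features loses mass.
This reproduces the exact per-step argmin (verified against a per-step
brute-force oracle) at far lower cost; batching is not used, so oracle
equivalence holds unconditionally. Scale invariance (uniform scaling of
weights or condition) and feature-relabeling equivariance follow from the
rule and are tested.

Future-scenario features are first multiplied by a connectivity factor:
the fraction of each cell's Euclidean disk neighborhood (radius 5 cells)
occupied by the species' *current* range, so projected habitat unreachable
from today's range contributes nothing. Radius 0 degenerates to the
intersection with the current range. One prioritization runs per scenario.

## Congruence, gaps, refugia

Kendall τ-b (tie-corrected) measures agreement between diversity maps and
between priority rank maps over analysis cells; constant maps are reported
missing. Hotspots use a value threshold: the smallest positive value v*
such that cells with value ≥ v* number at most ⌈p·N⌉ — with integer
richness the tie structure makes the achieved fraction undershoot (or, if
no value satisfies the bound, overshoot) the nominal percentage, which is
inherent to value-thresholded hotspots and is reported alongside v*.
Coverage is the cell fraction of a mask inside protected areas (cells, not
area-weighted; a hook exists for weighting). The per-scenario optimal
priority area is the TD∩PD∩FD intersection of top-30% masks; refugia are
the cells optimal under the current climate and every future scenario.
Connected regions (8-connectivity by default) below 5 cells are suppressed
as speckle; survivors are ranked by area.

## Problem sizes and determinism

The demo configuration — the default `PipelineConfig` — is a 100×100
landscape, 5 environmental layers, 30 species split 15/9/6 across tiers 1/2/3
(roughly the half/third/fifth mix typical of data-limited clades), the
current climate plus the three severity presets at one horizon, 10% PA
coverage in 6 patches. It runs end-to-end in well under a minute on one
CPU, which keeps the full test suite and the acceptance script fast while
leaving every mechanism (all three tiers, all three dimensions, four
scenarios) exercised. Every stage derives its own child seed from the
master seed via `SeedSequence`, so identical configs give bit-identical
results; warnings from any stage are collected into the provenance log.

## Known limitations

- Synthetic layers lack cross-variable covariance and realistic
  topographic structure; model-transfer pathologies (extrapolation beyond
  training ranges) are therefore milder than with real climate surfaces.
- The built-in tier-1 families are linear/envelope/density models; there is
  no boosting, random forest, or MaxEnt feature machinery. The ensemble
  framework, not the family roster, is the tested contribution.
- The greedy rule approximates core-area behavior with a max-over-features
  marginal loss; no warp/batching, corridor, or boundary penalties exist.
- Hotspot and coverage statistics count cells; on real unprojected rasters
  cell area varies with latitude and the area-weighting hook should be used.
- Refugia are overlap constructs across scenario priorities, not
  demographic persistence forecasts.
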