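# Methods

This note documents the statistical procedures, the synthetic study system,
and the numerical choices behind `phyllocore`, in the package's own terms.

## Preprocessing

Counts tables are samples × ASVs. Rare-ASV filtering removes every taxon
whose **dataset-wide** total is below 10 reads (this subsumes singleton and
doubleton removal); the threshold is applied to totals rather than per-sample
counts because singleton/doubleton language refers to whole-dataset tallies.
Rarefaction subsamples each sample without replacement to a common depth
(default: the minimum sample total) using a multivariate hypergeometric draw;
it is a single seeded draw, not an average over repeats — repeats are
available by iterating seeds. Relative abundances divide each row by its
total; all-zero rows are preserved and flagged.

## Synthetic study system

`simulate_stratified_system` emulates a vertically stratified design:
5 sites × 5 plots, each plot contributing one litter, one moss (host) and one
soil sample (75 samples). Taxa belong to planted classes: 20 SU (structurally
absent outside the host), 20 ES (expected abundance `enrichment_fold` = 5×
higher in the host), 20 EC (habitat-independent), 30 habitat specialists
(one habitat each, round-robin) and 60 low-abundance background generalists.

Counts are rounded log-normal intensities (per-class median reads, log-sd
0.6, per-taxon offset sd 0.35) with per-class structural zero-inflation
applied after the abundance draw, so the zero-inflated beta model fitted
downstream is correctly specified. Core-class zero-inflation is 0.05 —
core taxa are near-ubiquitous in their host by definition (the 80 %
prevalence threshold presupposes it); background taxa use 0.40. Covariate
effects act on the **log** of expected abundance (EC tracks pH at +0.4 per
SD; SU/ES track elevation at −0.3 per SD), so expected abundances are
positive by construction and no clipping branch can trigger. ES enrichment
is multiplicative on the log-normal median, matching fold-change language.
Elevation is a site-level gradient (1100–1500 m); pH has habitat baselines
(moss 4.0 < soil 4.4 < litter 4.8) with sd 0.25.

The generator also emits a per-sample "pathway abundance" proxy with known
negative dependence on the host-specific core share, pH and elevation, which
the path-model stage consumes as its function variable.

What the generator does **not** emulate: taxonomic structure, phylogenetic
signal in habitat preference (the tree is an independent Yule tree),
sequencing-depth artefacts beyond Poisson-like rounding noise, and spatial
autocorrelation between plots. Passing tests therefore demonstrate estimator
correctness under the model's assumptions, not robustness to those realities.

## Neutral community model

The fitted curve is the Sloan occurrence-frequency model: frequency =
Beta-survival at the detection limit *d* with shape (N·m·p, N·m·(1−p)).
Fitting minimises summed squared frequency residuals over m ∈ (1e−6, 1] via
a 50-point log-spaced grid followed by bounded local refinement; the returned
objective is verified in tests to beat every grid point. R² = 1 − SSE/SST is
reported as-is and may be negative.

**Detection limit.** Detection in rarefied counts is the discrete event
"≥ 1 read", while the model's tail is continuous. Matching the discrete
stationary distribution (beta-binomial) against the continuous Beta tail
shows that *d* = (smallest nonzero relative abundance) under-predicts
occurrence and inflates the fitted m by roughly 40 %; using **half** the
smallest nonzero relative abundance (a standard continuity correction)
removes most of the bias. The default `default_detection_limit` therefore
uses the half-count rule; *d* remains an explicit parameter and is logged.

The companion simulator implements the model's own assumptions: a
fixed-size community in which one random individual dies per event and is
replaced from the source pool with probability m, otherwise by a copy of a
random local individual. Communities are initialised from the pool and run
for ~10·N/m events so the stationary distribution is reached; the chain's
effective migration parameter is m/(1−m) (≈ +11 % at m = 0.1). Partitioning
uses a Wilson interval at 95 % around the predicted frequency with n = number
of communities.

## Core stratification

Core = mean host relative abundance ≥ 0.1 % **and** host prevalence ≥ 80 %,
both inclusive; the abundance criterion is the mean across host samples (a
per-sample-minimum variant is a flag). Core taxa are then labelled:

- **SU** — zero counts in every non-host sample;
- **ES** — both host-vs-litter and host-vs-soil contrasts significant at
  α = 0.05 with the higher beta mean in the host;
- **EC** — present in all three habitats and not enriched;
- **core-unresolved** — present in exactly two habitats and not enriched
  (the remaining logical cell; kept explicit rather than folded into EC).

The differential test is a two-part zero-inflated beta model. The likelihood
separates exactly: the zero mass gives π_g = (fraction of zeros in group g)
in closed form, and the beta part is ML on positive observations with
group-specific logit μ and a shared log φ (Nelder–Mead; covariance from a
central-difference Hessian). Groups with no positive values are flagged
degenerate, with π pinned at 1 and no μ contrast. Values equal to 1 are
squeezed to (n−0.5)/n. Site/plot random effects are deliberately omitted
from the default fit: a mixed zero-inflated beta ML is out of proportion to
the binary classification decision the p-values feed; a fixed site covariate
can be added upstream if needed. The two host contrasts are adjusted with the
single-step multivariate-normal method (Holm as fallback).

## Diversity and phylogenetic structure

Faith's PD includes the path to the root (this changes single-tip values and
is stated for that reason). NRI = −(MPD_obs − mean MPD_null)/sd(MPD_null)
with unweighted (presence-based) mean pairwise patristic distance; the null
shuffles tip labels across the whole tree, which is sampled as uniformly
random tip sets of the same richness (999 draws by default, seeded). A
community containing every tip has a zero-variance null and errors.
Habitat effects on per-sample metrics use Type II ANOVA on
value ~ habitat + site + habitat:site (interaction dropped when any cell is
empty), with pairwise habitat contrasts as differences of site-averaged
marginal means and familywise adjustment via the studentized range with
k = number of habitats. A zero-variance response short-circuits to F = 0,
p = 1.

## Cohesion, networks, robustness

Connectedness follows the taxa-shuffle variant of the Herren–McMahon
procedure on Pearson correlations of relative abundances: for each ordered
pair (i, j), the mean correlation of x_i with independently permuted x_j
(200 shuffles by default) is subtracted from the observed correlation, and
the positive / negative corrected values are averaged separately per taxon.
Cohesion is the per-sample abundance-weighted sum of connectedness by sign;
association strength is positive cohesion over |negative cohesion|, flagged
undefined (NaN, excluded from regressions) when negative cohesion is zero.
Cohesion uses the full corrected correlation set, not only thresholded
network edges (a network-restricted option exists).

Co-occurrence networks use Spearman correlations with inclusive thresholds
|ρ| ≥ 0.6 and t-approximation p ≤ 0.05 (defaults; configurable and recorded
with the network). No multiple-testing correction is applied to edge
p-values by default — the edge set is threshold-driven — with a
Benjamini–Hochberg switch available upstream. Robustness is the trapezoidal
area under the mean largest-connected-component fraction across seeded
uniform-random node-removal orders (100 orders, grid step 0.05 by default).
A complete graph loses only the removed nodes, giving the linear curve 1 − f
and AUC 0.5 — the attainable ceiling used as a calibration point. Note that
for 10-node toys the ring and the star have nearly identical expected AUCs
(≈ 0.374 vs ≈ 0.379), so their relative order under few Monte-Carlo orders
is seed-dependent.

## Distance statistics

Bray–Curtis uses the standard 1 − 2Σmin/Σtotal form. NMDS minimises Kruskal
stress-1 by alternating isotonic regression of configuration distances on
dissimilarities (ties pooled by averaging) with Guttman updates; a run stops
when a step would increase stress, so the recorded stress sequence is
non-increasing by construction. The first start is the principal-coordinate
configuration, followed by seeded random starts (20 by default). PERMANOVA
uses the Gower-centered inner-product decomposition; p = (#{F_perm ≥ F_obs}
+ 1)/(n_perms + 1) over seeded label permutations, with pairwise mode
Holm-adjusted. Beta-dispersion and centroid distances work in the dual
principal-coordinate embedding, subtracting imaginary-axis contributions
from squared distances (clipped at zero) to handle negative eigenvalues.
The Mantel statistic is the Pearson correlation of lower triangles with a
one-sided (greater) permutation p.

## Stability regressions

AVD is computed per sample within its habitat group; exactly constant taxa
are excluded from both the sum and the divisor (the constancy test uses the
exact range, not a floating-point sd, so compositional round-off cannot
inflate z-scores). Group-abundance vs stability regressions are OLS with
F-test p-values; samples with undefined association strength are dropped and
counted. Because network robustness is a per-network quantity, its
regression response is built from bootstrap replicates: samples are resampled
with replacement, the network is rebuilt and its robustness measured, and
the replicate's mean group abundance is the predictor (30 replicates by
default). A leave-one-sample-out jackknife variant is the alternative mode;
both are explicit config choices because no unique per-sample robustness
exists.

## Path models

Component models are ordinary linear regressions (all endogenous variables
are continuous). The basis set contains one claim per non-adjacent variable
pair, with the later variable in topological order as the response and the
union of both variables' parents as the conditioning set; each claim's p is
the partial regression t-test on the earlier variable. Fisher's C = −2Σln p
with df = 2k; a model is accepted when df = 0 (saturated) or C/df ≤ 2 and
p > 0.05. Model simplification by repeated pruning of non-significant paths
is intentionally not automated; the pipeline fits the declared spec and
reports. The default pipeline DAG: pH, elevation and the two
neighbouring-habitat NRI convergence variables point at core-group
abundance; core abundance points at community structure (NMDS axis 1);
structure, pH and elevation point at the pathway-abundance function proxy.

## Problem sizes and determinism

Default analysis sizes: 75 samples × 150 taxa, 999 permutations, 999 NRI
null draws, 200 cohesion shuffles, 100 removal orders. The test suite and
acceptance script use the same machinery at reduced Monte-Carlo sizes
(49–4999 permutations, 99 null draws, 5–30 bootstrap replicates) chosen so
each check retains the precision its tolerance needs — e.g. enumeration
comparisons use 4999 permutations so Monte-Carlo error is well inside the
0.02 agreement band. Every stochastic stage receives a seed derived from the
master seed and the stage name (SHA-256 truncated below 2³¹); identical
config and inputs reproduce byte-identical output manifests.

## Known limitations

- The ZIB fit omits random effects; with strong plot-level correlation its
  contrasts will be anti-conservative.
- The NCM's N is taken as the rarefaction depth; when samples are not
  rarefied the Beta parameterisation is only approximate.
- Cohesion's shuffle null preserves marginals but not compositional
  closure; on strongly compositional data corrected correlations retain a
  small negative offset of order −1/(k−1).
- NMDS returns the best of finitely many starts; stress is a local optimum.
- The synthetic generator's independent-taxon counts do not impose a
  fixed sequencing depth per sample; depth variation enters only through
  rarefaction.
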