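# Methods

`ploidyshift` implements a comparative-phylogenetics workflow for studying
the evolution of haplodiploid reproduction on time-calibrated trees: how
often it arose, whether it is ever lost, and whether lineages with few
chromosomes are the ones that make the transition.  This note documents the
models, the numerical choices, the synthetic-data regimes the test suite
relies on, and the known limitations.

## Data model

The analyses act on a rooted, ultrametric `TimeTree` (branch lengths in
time units) and a trait table with one record per taxon: a binary
reproductive system (`diplodiploid` / `haplodiploid`, where haplodiploidy
covers both arrhenotoky and paternal genome elimination), the diploid
chromosome count in females (2n), optional taxonomy
(infraorder/family/genus/species) and optional sex determination (XY/XO).
Ultrametricity is checked (relative tolerance 1e-6) and reported but not
enforced, because genus- and family-level matching deliberately places
collapsed tips at internal depths (below).  Missing branch lengths are a
fatal error, never defaulted: every model here is time-calibrated and a
default length would silently rescale every rate estimate.

### Tip matching

Overlap between a tree and a trait database is maximised iteratively:

1. exact species matches, comparing labels case-insensitively with
   underscores treated as spaces;
2. every genus on the tree with no species-level match is collapsed to one
   tip and matched against all records of that genus;
3. the same at family level, for tips identified only to family resolution
   (their first label token is a family name in the table).

Multiple records behind one tip contribute their mean 2n; they must agree
on the reproductive system — a conflict is an error, not a vote.  The
collapsed tip keeps the collapsed clade's stem branch, i.e. it ends at the
original crown-node depth.  This is a convention, flagged in the matching
metadata: it preserves the time scale of the stem lineage at the cost of a
slightly non-ultrametric tree.  Non-monophyletic genus groups (possible on
any single tree) degrade gracefully: one representative tip is kept.
Pruning always preserves patristic distances among retained tips exactly
(suppressed unifurcations sum their branch lengths), and the original root
is retained even when left with a single child, so root-to-tip depths never
change.

## Binary-trait (Mk) models

Two continuous-time Markov models of the reproductive system
(D = diplodiploid, H = haplodiploid):

* **two-rate**: independent gain rate `q_DH` and loss rate `q_HD`, root
  state drawn from the stationary frequencies
  `pi_D = q_HD / (q_DH + q_HD)` of the fitted chain;
* **one-rate** (irreversible): `q_HD = 0`, root fixed diplodiploid.

Likelihoods use the pruning algorithm with per-node rescaling and the
closed-form two-state transition probabilities
`P_DD(t) = pi_D + pi_H e^{-(q_DH+q_HD) t}`.  Impossible data yield `-inf`
(never NaN), which deliberately poisons the AICc of that fit.  ML fitting
is bounded quasi-Newton (L-BFGS-B) on log rates in `[1e-8, 1e3]` per unit
time, from five Latin-hypercube starting points; rare-transition likelihood
surfaces are flat and a single start can stall.  Model fit is summarised by
`AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1)` with `n` = number of tips (the
standard sample-size choice for a single character), and comparisons report
the per-tree and mean difference `AICc(two_rate) - AICc(one_rate)`, so
negative values favour reversibility.  A drop-one-tip re-analysis
(`drop_tip_sensitivity`) re-runs the comparison with a named taxon removed
from every tree; the constructed `nested_reversal_fixture` shows the
canonical situation where a single diplodiploid tip nested in a
haplodiploid clade carries all support for the reversible model.

## Stochastic character mapping

Maps are drawn by sampling node states root-to-tip from their joint
conditional distribution (computed from the pruning pass), then filling
each branch with a path bridge conditioned on its endpoint states:

* irreversible rates: closed form (a D->H branch carries exactly one event
  at a truncated-exponential time);
* otherwise rejection sampling of forward simulations, with the first event
  forced when the endpoints differ, capped at 10^4 attempts;
* uniformization as exact fallback beyond the cap.

An *origin* is a D->H event; a haplodiploid root state counts as one
additional origin (the transition happened on the unobserved stem) — a
reporting convention, since whether a haplodiploid root is "an origin" is
not well defined.  Counts are pooled over maps and trees with both
averaging levels reported, because the number of maps per tree and the
number of trees are distinct sources of uncertainty.

## Brownian-motion ancestral reconstruction

Chromosome number is reconstructed under BM, by default on the log scale
(counts are positive and multiplicative), with back-transformation by
`exp` — without bias correction, as a reporting convention — where counts
are quoted in 2n units; raw-scale reconstruction is available.  The
implementation is the linear-time two-pass algorithm (tipward conditional
means/variances, rootward outside-subtree distributions, per-node merge);
it is checked against a dense GLS solve with the full phylogenetic
covariance matrix to 1e-8 in the test suite.  `sigma2` is the ML estimator
(divide by n).  Zero-length terminal branches pin their node's estimate;
their degenerate contribution is excluded from the `sigma2` sum, and a tree
with zero total branch length is rejected.

## Directionality analyses

**Infraorder comparison.**  Each infraorder contributes the mean 2n of its
diplodiploid species; infraorders are split by whether they contain any
haplodiploid taxa and compared with a Welch two-sample t-test
(Welch-Satterthwaite df).  Positive t means infraorders without
haplodiploids have higher counts.  When both groups are constant the Welch
denominator is degenerate; equal means then report t = 0, p = 1.

**Origin-node Monte Carlo test.**  For each stochastic map: find the parent
node of every branch carrying a D->H event (duplicates kept), prune all
haplodiploid tips, reconstruct 2n on the pruned tree from diplodiploid tips
only, and compare the mean reconstructed count at the origin nodes (mapped
to their nearest surviving ancestor when pruning removed them) with R = 100
null means at equally many internal nodes drawn uniformly without
replacement.  The test is one-sided (low tail, the directional hypothesis)
with the add-one rule `p = (1 + #{null <= observed}) / (R + 1)`.  Pooling
over maps/trees cannot use Fisher's method (the maps share the data); the
combined p pushes every map's origin-node multiset through one shared
random permutation of internal nodes per null replicate, preserving
duplicate origins and between-map overlap so pooled null and pooled
observed variances match.

*Known power/calibration limits, measured in simulation*: the test is
mildly conservative (empirical size 1-7% at nominal 5% over independent-
trait simulations) and has limited power on 60-tip trees (median p around
0.1-0.3 even under strong state dependence).  Three causes: origin nodes
are typically parents of long branches and deeper than uniform null nodes,
so their BM estimates are shrunk toward the grand mean while the null
includes high-variance shallow nodes; strong state dependence converts
precisely the low-count diplodiploid lineages, censoring the signal
carriers out of the pruned reconstruction; and several origins inside one
converted clade collapse onto the same surviving ancestor.  These are
properties of the procedure itself, worth keeping in mind when interpreting
marginal p-values from it.

## Mixed models

All regressions use log 2n as the Gaussian response and ploidy
(diplodiploid = 0, haplodiploid = 1) as the fixed predictor, so the
hypothesis of interest is beta < 0.

**Phylogenetic animal model** (`phylo_lmm`):
`y = mu + beta z + u + e`, `u ~ N(0, sigma2_p C)`, `e ~ N(0, sigma2_e I)`,
with `C` the phylogenetic covariance scaled to unit tree height so variance
components are comparable across trees.  Gibbs sampling with flat priors on
fixed effects, an inverse-gamma(0.001, 0.001) prior on `sigma2_e`, and a
parameter-expanded prior on the phylogenetic component (`u = alpha v`,
`v ~ N(0, phi C)`, `alpha ~ N(0, 1000)`, `phi ~ IG(0.001, 0.001)`), giving
a heavy-tailed induced prior that mixes well when the component is near
zero.  Phylogenetic heritability `sigma2_p / (sigma2_p + sigma2_e)` plays
the role of Pagel's lambda.  A tree set is handled by one chain per tree
with pooled posteriors.  Fixed effects are summarised by `P_MCMC` = twice
the smaller posterior tail probability of the sign, floored at
`2/n_samples`.  Default chain lengths (50k iterations, 10k burn-in, thin
10) are a desk-scale choice; mixing is monitored with single-chain
split-R-hat on beta (warning above 1.1).

**Taxonomic mixed model** (`taxonomic_lmm`): the same machinery with nested
infraorder/family/genus random intercepts instead of the phylogeny;
"heritability" is the summed taxonomic variance fraction.  A level whose
groups are all singletons is confounded with the residual and dropped with
a warning.

**Threshold model** (`threshold_model`): ploidy is the sign of a latent
liability evolving jointly with log 2n as bivariate BM on the unit-height
tree with *no residual* (both heritabilities fixed at 1).  Data-augmentation
MCMC: single-site truncated-normal liability updates (inverse-CDF in the
bulk, exponential-rejection in the far tail), Gaussian updates of the two
ancestral means, inverse-Wishart (df 3 + n, scale 0.01 I + cross-products)
updates of the 2x2 covariance, and a parameter-expansion rescaling that
pins the liability variance at 1 after every sweep — the sign constraint is
scale-invariant, so this fixes the identifiable scale without touching the
reported correlation.

## Synthetic data

The generator defines the study conditions every calibration figure refers
to.  Defaults (`SimConfig`): 100-tip pure-birth trees (birth rate 1; a
birth-death option conditions on the extant tip count and prunes extinct
lineages — mean Yule root age `sum_{k=2..n} 1/k` is verified against theory);
log 2n Brownian with `sigma2 = 0.03` per unit time from a root at
`log 18`, giving tip counts roughly 8-32 (clamped at 4, the empirical floor
for the group being emulated); a baseline D->H rate `q_DH0 = 0.08` with
`q_HD = 0` (irreversible truth), yielding on the order of 5-13 origins on a
100-tip tree, matching the range the real analyses infer.

The *causal* regime (`SimConfig.causal`) makes the transition hazard
state-dependent, `q_DH0 exp(-beta x)` with `x = log 2n` — log-linear, a
form chosen to keep rates positive and the coefficient interpretable — with
the baseline rescaled so the hazard at the root value is unchanged, and
adds a post-transition drift that lowers log 2n by `ploidy_effect`
(default -0.3, about five chromosomes at 2n near 18) spread linearly over
half the tree height.  The joint simulation uses Euler steps of at most
1/1000 of tree height, subdivided so hazard*dt stays below 0.1, and returns
the complete true history (every transition time, every node's true log
2n), so downstream estimators are tested against ground truth rather than
against each other.

Separate Gaussian helpers (`simulate_phylo_gaussian`,
`simulate_threshold_traits`) generate data *exactly under the mixed-model
and threshold-model assumptions* for recovery tests, including a residual
component (the joint generator's counts are nearly residual-free, so
heritability-recovery tests use the Gaussian helper with
`sigma2_p/sigma2_e = 9`, i.e. true heritability 0.9).  A deterministic
taxonomy is cut from the tree at fixed depth fractions (0.25/0.55/0.80 of
height for infraorder/family/genus) so taxonomic analyses have nested
groups.

What the generator does **not** emulate: rate variation across clades,
chromosome-number jumps from fission/fusion bursts, correlated sampling
bias (real databases over-represent well-studied clades), measurement error
in published karyotypes, or posterior tree sets with genuine topological
uncertainty (tree sets in tests are replicate draws or copies).  Passing
calibration here shows the machinery is correct under its own assumptions,
not that real mite data satisfy them.

## Problem sizes in the test suite

The statistical tests run at sizes chosen to give stable verdicts on one
CPU: 200 small trees for the likelihood-vs-enumeration oracle; 50 + 50
datasets of 200 tips for model-selection calibration; 10^4 maps for
bridge/root-state consistency; 200 + 50 datasets of 60 tips (R = 100) for
origin-test calibration and power; 50 replicates of 100 tips with
shortened chains (2500 iterations) for mixed-model coverage and threshold
recovery.  The acceptance script analyses one 100-tip causal-regime dataset
end to end with 100 maps, 10-map origin testing and 10k-iteration chains.

## Known limitations

* The origin-node test's conservatism and power ceiling (above).
* Empirical-Bayes mapping only: rates are fixed at their ML estimates when
  sampling maps, understating rate uncertainty (matching common practice).
* The two-rate model with stationary root has a well-known saturating
  high-rate mode that can absorb scattered singleton states; multi-start
  optimisation finds it when it is the global optimum, which is a real
  feature of the likelihood, not an artefact.
* `P_MCMC` and credible intervals are Monte Carlo estimates; with the
  desk-scale default chains their resolution is limited by the floor
  `2/n_samples`.
* Genus/family collapsing assumes the collapsed group is monophyletic on
  the tree; non-monophyly falls back to a single representative tip.
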