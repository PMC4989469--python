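# ploidyshift

Comparative phylogenetics of haplodiploid reproduction.

In haplodiploid animals males are haploid and females diploid, either
through arrhenotoky (haploid sons from unfertilised eggs) or paternal
genome elimination.  Theory predicts that transitions from ordinary
diplodiploidy to haplodiploidy are easiest in male-heterogametic lineages
with *few chromosomes* — the fewer the chromosomes, the larger the share of
the genome that is X-linked and already purged of recessive lethals in
haploid males — and that reversals should be rare because mitotic
spermatogenesis is hard to unwind.  `ploidyshift` packages the analyses
needed to test these predictions on a time-calibrated phylogeny with
per-taxon reproductive-system and diploid chromosome-count (2n) data, as in
mites (Acari), the one clade where haplodiploidy has evolved many times.

## What it computes

With states D (diplodiploid) and H (haplodiploid), gain rate `q_DH`, loss
rate `q_HD`, and `x = log 2n`:

* **Irreversibility** — pruning-algorithm likelihoods of a two-rate Mk
  model (stationary root) versus a one-rate irreversible model
  (`q_HD = 0`, root fixed D), compared by mean AICc difference
  `AICc(two) − AICc(one)` over a tree set, with a drop-one-tip sensitivity
  re-analysis.
* **Number of origins** — stochastic character mapping (joint node-state
  sampling plus endpoint-conditioned branch bridges); each D→H event in a
  sampled history is one origin of haplodiploidy.
* **Ploidy–chromosome association** — a Bayesian phylogenetic animal model
  `log 2n = μ + β·ploidy + u + e` with `u ~ N(0, σ²_p C)` (phylogenetic
  heritability `σ²_p/(σ²_p+σ²_e)`, akin to Pagel's λ), its taxonomic
  analogue with nested infraorder/family/genus intercepts, and
  Felsenstein's threshold model (latent liability, both heritabilities
  fixed at 1) for the liability–log 2n correlation; effects summarised by
  `P_MCMC`.
* **Directionality** — (1) Welch t-test of infraorder mean 2n between
  infraorders with and without nested haplodiploids; (2) a Monte Carlo
  test of whether the nodes subtending haplodiploid origins have lower
  BM-reconstructed 2n than randomly chosen nodes, after pruning the
  haplodiploid tips.
* **Synthetic data** — birth–death trees plus a joint generator in which
  log 2n evolves by Brownian motion and the D→H hazard is
  `q_DH0·exp(−β·x)`, so "low chromosome number causes haplodiploidy" has a
  ground truth that every estimator above is tested against.

See `docs/methods.md` for models, priors, numerical choices and known
limitations.

## Worked example

Simulate a 100-tip dataset under the state-dependent (causal) regime and
run the core analyses from the shell:

```sh
$ ploidyshift simulate --out sim --seed 11 --causal
simulated 100 tips, 5 true origins -> sim

$ ploidyshift mkcompare --trees sim/tree.nwk --traits sim/traits.csv
{
  "mean_delta_aicc": 4.3692101321221415,
  "preferred": "one_rate",
  "n_trees": 1
}

$ ploidyshift simmap --trees sim/tree.nwk --traits sim/traits.csv \
      --model one_rate --nmaps 100 --seed 2
{
  "model": "one_rate",
  "mean_origins": 5.09,
  "sd": 0.2876234912646614,
  "per_tree_mean": [5.09]
}

$ ploidyshift origintest --trees sim/tree.nwk --traits sim/traits.csv \
      --nmaps 10 --seed 5
{
  "observed_mean_2n": 17.80296167225388,
  "expected_mean_2n": 19.37825148334144,
  "p_value": 0.07920792079207921,
  "n_map_results": 10
}
```

Reading the output: the positive AICc difference (+4.37) says the
irreversible one-rate model fits better than the reversible two-rate model
— reversals are not needed to explain the data.  Stochastic maps under
that model infer 5.09 origins of haplodiploidy on average, matching the
generator's 5 true origins.  The origin-node test finds a mean
reconstructed 2n of 17.8 at the nodes subtending those origins versus 19.4
expected at random nodes (one-sided P = 0.079): chromosome number at
origin points is lower than chance, weak evidence here because this
replicate carries only ~5 origins — the power analysis in
`docs/methods.md` explains why single-dataset p-values from this test are
usually marginal.

The same stages are available as library calls (`compare_models_over_trees`,
`summarize_origins`, `monte_carlo_origin_test`, `phylo_lmm`,
`threshold_model`, …), and `ploidyshift run --config run.yaml` executes the
whole pipeline (matching → model comparison → mapping → tests → mixed
models → report and figures) with one master seed and a reproducibility
manifest.

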