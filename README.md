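# trophicblocks

Bayesian stochastic block models for directed food webs.

Food webs — who eats whom in an ecosystem — carry structure beyond the
classical compartments (dense within, sparse between). `trophicblocks`
infers *trophic guilds*: groups of species with similar diets and similar
consumers, under a directed stochastic block model in which every ordered
group pair (k, l) has one link probability p_kl governing all possible
links from consumer group k to resource group l. It is aimed at ecologists
analyzing binary feeding networks with well-resolved species lists (for
example savanna plant–mammal webs), and more generally at anyone fitting
group structure to a directed graph with proper Bayesian model comparison.

## The model

For S species the data are the S² ordered pairs (self-pairs included),
A_ij ∈ {0, 1}. Conditional on a partition g into K groups,

    P(A | g, p) = ∏_{k,l} p_kl^{L_kl} (1 − p_kl)^{N_kl − L_kl},

with L_kl realized and N_kl = n_k n_l possible links per block. Partitions
carry either a uniform prior (1/Bell(S)) or a Dirichlet-process (Chinese
restaurant) prior with aggregation parameter α ~ Exp(1); link probabilities
carry either a Uniform(0,1) prior or Beta(a, b) with a, b ~ Exp(1). With a
beta prior, p integrates out analytically,

    ln P(A | g, a, b) = Σ_kl [ ln B(a+L_kl, b+N_kl−L_kl) − ln B(a, b) ],

and this collapsed form drives everything. The package provides:

- **Posterior sampling** over partitions and hyperparameters by
  Metropolis-coupled MCMC (collapsed Gibbs sweeps, tempered ladder with
  state swaps), plus a reversible-jump sampler for the
  compartment-constrained variant (p_kl < min(p_kk, p_ll));
- **Marginal likelihoods** by thermodynamic integration over power
  posteriors, with closed-form dispatch for the group-free null models,
  and Bayes-factor model comparison;
- **Consensus partitions** from the posterior co-grouping (affinity)
  matrix by average-linkage clustering, cut to minimize the mean
  pair-disagreement distance to the samples;
- **Habitat signatures**: size-weighted Shannon entropy of habitat labels
  within groups, a size-preserving randomization test across the
  posterior, and exact hypergeometric per-group enrichment;
- **A generative simulator**, including a 161-species savanna-scale
  fixture (129 plants / 23 herbivores / 9 carnivores, 592 links,
  connectance ≈ 0.023) so the whole pipeline runs without any downloads.

See `docs/methods.md` for the full model account, sampler details,
numerical choices, and limitations.

## Worked example

Simulate the savanna-scale fixture, compare the closed-form null models,
fit the flexible model, and summarize:

```sh
$ trophicblocks simulate --seed 1 --out web
wrote 161 species, 592 links to web

$ trophicblocks evidence --species web/species.csv --links web/links.csv \
      --variants one_group_uniform,full_uniform,full_beta --out ev
          variant  log_marginal_likelihood  ci95  log_bayes_factor
one_group_uniform             -2828.598113   0.0          0.000000
        full_beta             -2828.598113   0.0          0.000000
     full_uniform            -17967.068067   0.0     -15138.469954

$ trophicblocks fit --species web/species.csv --links web/links.csv \
      --iterations 2600 --burn-in 2000 --chains 2 --seed 1 --out fit
kept 600 posterior samples -> fit

$ trophicblocks consensus --samples fit/posterior_samples.csv --out cons
consensus: 16 groups; mean distance to samples 5.3%; sample-sample 7.5%

$ trophicblocks habitat --samples fit/posterior_samples.csv \
      --species web/species.csv --reps 5 --seed 0 --out hab
weighted entropy 1.026 vs randomized 1.414 (p = 0)
```

Reading the numbers: the one-group null (a directed random graph with a
single uniform link probability) scores ln B(593, 25330) = −2828.60; the
fully parameterized null with an independent uniform probability per pair
scores −161² ln 2 = −17967.07 — enormously worse, because 25,921 free
parameters are penalized by the evidence; and the per-pair Beta(a,b) null
with Exp(1) hyperpriors collapses exactly to the one-group value (given
the shapes, every pair shares the success probability a/(a+b), which is
uniformly distributed). The fitted flexible model finds 16 groups; the
consensus partition sits closer to the posterior samples (5.3% of species
pairs disagree on average) than the samples sit to one another (7.5%),
which is what makes it a useful single-partition summary. Plant habitat
labels cluster strongly within groups: weighted entropy 1.026 against a
size-matched randomized mean of 1.414 (lower entropy = stronger habitat
clustering), with none of the randomized replicates beating the observed
value.

The same operations are available as library calls
(`trophicblocks.run_mcmc`, `estimate_log_evidence`, `compare_models`,
`consensus_partition`, `randomization_test_overall`, ...), which is what
the test suite uses.

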