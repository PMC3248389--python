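# Methods

## The model

A directed food web over S species is recorded as the presence or absence
of each of the S² ordered consumer→resource pairs, self-pairs included, so
the data are exactly S² Bernoulli trials and the connectance is L/S². The
group model (a directed stochastic block model) assigns each species to one
of K groups through a partition g, and gives every ordered group pair
(k, l) a single link probability p_kl:

    P(A | g, p) = ∏_{kl} p_kl^{L_kl} (1 − p_kl)^{N_kl − L_kl},

where L_kl counts realized and N_kl = n_k n_l possible links in block
(k, l). Groups defined this way are trophic guilds — species with similar
diets and similar consumers — of which classical compartments
(dense-within, sparse-between) are the special case in which the diagonal
blocks dominate.

### Priors

Two partition priors and two link-probability priors combine into the model
variants:

- **Partition, uniform**: every set partition of S elements is equally
  likely, normalized by the Bell number, P(g) = 1/B(S). The
  normalization matters because evidences under different partition priors
  are compared on one scale; B(S) is computed exactly with the Bell
  triangle in arbitrary-precision integers and only then logged.
- **Partition, Dirichlet process (CRP)**: P(g | α) = α^K ∏_k (n_k−1)! ·
  Γ(α)/Γ(α+S), with aggregation parameter α ~ Exp(mean 1). Large α favors
  many small groups, small α few skewed groups.
- **Link probabilities, uniform**: p_kl ~ Uniform(0,1) iid, i.e. Beta(1,1)
  held fixed.
- **Link probabilities, beta**: p_kl ~ Beta(a, b) iid with a, b ~ Exp(mean
  1). Because most pairs of species do not interact, the posterior pushes
  a/(a+b) toward the connectance and the prior mass toward 0, which is what
  lets variants with this prior support many groups without paying the full
  parameter-count penalty.

For all variants except the compartment-constrained one, p integrates out
in closed form (beta–Bernoulli conjugacy):

    ln P(A | g, a, b) = Σ_kl [ ln B(a + L_kl, b + N_kl − L_kl) − ln B(a, b) ],

and this collapsed likelihood is the only likelihood the samplers touch.
Everything is evaluated in log space through log-gamma; nothing is ever
exponentiated at data scale.

### Null structures and the compartment constraint

Two group-free references bracket the flexible model: *one group* (a
directed Erdős–Rényi graph with one shared p, evidence
ln B(L+1, S²−L+1) under the uniform prior) and *fully parameterized*
(each species its own group). The fully parameterized model with uniform
per-pair priors has evidence −S² ln 2 regardless of the data; with
Beta(a, b) per-pair priors and iid Exp(1) shapes, each pair's marginal
link probability is the shared m = a/(a+b), which is exactly Uniform(0,1)
for iid Exp(1) shapes, so its evidence collapses to the one-group uniform
value. That identity is used directly; naive two-dimensional quadrature
over (a, b) under-resolves the sharply peaked integrand at realistic
connectance and is reserved for small-S cross-checks.

The compartment-constrained variant forces p_kl < min(p_kk, p_ll) for all
k ≠ l by the reparameterization p_kl = x_kl · min(p_kk, p_ll) with
x_kl ~ Uniform(0,1) and p_kk ~ Beta(a, b). The multiplicative-minimum form
is the simplest construction that enforces the constraint; because the
constraint breaks conjugacy, this variant alone carries explicit
probabilities in its sampler state.

## Posterior sampling

Each chain targets prior × likelihood^β for an inverse temperature
β ∈ (0, 1]; the cold chain (β = 1) is the posterior. Only the likelihood
is heated: every chain keeps the full proper prior, which (a) makes the
chain family coincide with the power-posterior path needed for evidence
estimation, and (b) makes the swap acceptance between chains i and j
exactly min{1, exp[(β_i − β_j)(ℓ_j − ℓ_i)]} with ℓ the untempered log
likelihood (the shared prior cancels).

**Partition moves** are collapsed Gibbs sweeps: each species in index order
is detached, and its conditional distribution over the existing groups plus
one fresh singleton group is sampled exactly, with weights
prior-weight × exp(β Δℓ). Under the CRP the prior weight is n_g for an
existing group and α for the fresh one; under the uniform partition prior
all options weigh equally. Δℓ touches only the row and column of the
candidate group, and empty blocks contribute exactly zero, so a sweep costs
O(S K²) log-gamma lookups. The inner loop runs over plain Python lists with
per-(a,b) cached log-gamma tables: at the group counts this model operates
at, that is several times faster than vectorized calls on length-K arrays.
Group labels are canonicalized (order of smallest member) after every
sweep so identical partitions always serialize identically, and the
incremental block counts are checked against a from-scratch recomputation
every 10³ sweeps.

For the compartment-constrained variant, single-species reassignment is a
Metropolis–Hastings move (a reversible-jump birth/death when groups appear
or vanish) with new-group parameters proposed from their priors, so the
proposal density cancels the prior factor and the acceptance reduces to the
tempered likelihood ratio × partition-prior ratio × option-count
correction. Probabilities are refreshed by MH: a logit-scale walk on each
p_kk (Beta(a, b) prior, with the logit Jacobian) and a reflected walk on
each x_kl; the reparameterization keeps the constraint satisfied after
every accepted move.

**Hyperparameters** α, a, b get log-scale random-walk MH updates (step 0.5)
with their Exp(1) priors; α sees only the CRP term (part of the prior,
never tempered), a and b see the tempered collapsed likelihood (or the
p_kk prior density in the constrained variant).

**Defaults**: ladder β = (1, 0.7, 0.5, 0.35) with one swap proposal per
sweep between a uniformly chosen adjacent pair; burn-in 10⁴ sweeps and
30,000 kept cold-chain samples; a single seeded generator per run, with the
seed echoed into all outputs. At S ≈ 160 a sweep costs ~4 ms, so full-scale
runs are minutes-to-hours depending on the sample count; tests and examples
use shorter, explicitly configured runs.

## Marginal likelihoods

The log evidence is computed by thermodynamic integration along the power
posterior path: ln Z = ∫₀¹ E_β[ln P(A | ·)] dβ, with rungs
β_i = (i/(n−1))^{1/0.3} (dense near the prior, where the integrand moves
fastest), per-rung expectations from MCMC, trapezoid quadrature, and a 95%
CI from batch-means standard errors propagated through the trapezoid
weights. Group-free structures never sample: their evidences dispatch to
the closed forms above (CI exactly 0), and the one-group beta variant uses
two-dimensional Gauss–Laguerre quadrature over the Exp(1) hyperpriors.

Two practical choices matter here. First, rungs are *annealed*: each rung's
chains warm-start from the previous (hotter) rung's final state. Second,
each rung is itself Metropolis-coupled to companion chains at 2β (capped at
1) and β/2. Both exist for the same reason: the prior→structure transition
is sharp (at planted 60-species webs the expected log likelihood jumps by
hundreds of units across β ≈ 0.1), and an independently cold-started,
uncoupled rung near the transition can lodge in the wrong mode for an
entire run, biasing the integral by several log units while reporting a
small within-run standard error. The colder companion feeds structured
states into the transition rung by swapping; the hotter one keeps breaking
modes. With these two devices the estimator is stable to a fraction of a
log unit across seeds at the problem sizes the tests use, with reported
CIs below one log unit. The stepping-stone estimator is a documented
alternative left unimplemented.

Bayes factors are differences of log evidences; the comparison table sorts
variants by evidence and reports log Bayes factors relative to the best.

## Consensus partitions

The affinity matrix holds the fraction of posterior partitions in which
each species pair co-groups. Species are clustered by average linkage on
1 − affinity; every dendrogram cut level K = 1..S is evaluated by its mean
pair-disagreement distance to the posterior samples — the fraction of
unordered pairs grouped together in one partition but apart in the other —
and the minimizing cut is returned, ties broken toward fewer groups.
Since the pair-disagreement distance is also the diagnostic reported for
the consensus, minimizing it is the self-consistent selection rule. Both
diagnostics (consensus-to-samples and
sample-to-sample mean distance) are computed exactly from co-grouping
counts rather than by looping over sample pairs: a pair co-grouped in c of
n samples is discordant in c(n−c) of the C(n,2) sample pairs.

## Habitat signature

A group's habitat signature is the Shannon entropy (natural log, matching
the log units used throughout) of its members' habitat labels; a
partition's overall signature is the group-size-weighted mean, with sizes
and totals counting only habitat-assigned species. Species with habitat
"unassigned" are excluded entirely — treating them as a pseudo-habitat
would manufacture entropy. Overall significance is a randomization test
across posterior samples: each sampled partition's weighted entropy is
compared against size-preserving random relabelings, and the p-value is
the fraction of (sample, replicate) pairs in which observed clustering
fails to exceed the randomized one (ties count against the alternative).
Per-group overrepresentation of a single habitat is the exact
hypergeometric upper tail for a uniformly random same-size subset of the
assigned universe — the same null as a Monte-Carlo randomization, but
exact and fast.

## The synthetic generator

`make_serengeti_like` emulates a well-resolved savanna plant–mammal web at
its documented scale: 161 species (129 plants in five habitat-correlated
blocks, 23 herbivores in three blocks, 9 carnivores in two), exactly 507
herbivorous and 85 predatory links (592 total, connectance 0.0228), drawn
by weighted sampling without replacement with weights concentrated on
designated herbivore→plant and carnivore→herbivore block pairs (plus a
little intraguild predation among the large carnivores). The structure is
therefore trophically layered — links concentrate in off-diagonal blocks —
rather than modular, which is the structure such webs actually show. Plant
habitat labels follow the plant block with 0.8 fidelity, a single choice
representing a strong but imperfect plant-community signal; herbivores and
carnivores carry no habitat.

What the generator does *not* emulate: the empirical web's specific
adjacency, degree heterogeneity within blocks beyond Bernoulli noise,
taxonomic or body-size structure, and the field-derived habitat
assignment pipeline. Tests that pass on this fixture therefore demonstrate
that the machinery is correct and that the inferential claims hold on
block-structured data of the right scale — not that the empirical web's
published evidence values or its particular 14-group consensus are
reproduced, which requires the original link table.

## Numerical choices and degenerate inputs

- All likelihood/prior arithmetic in log space; collapsed block terms via
  integer-indexed log-gamma tables; empty blocks contribute exactly 0.
- Explicit likelihood returns −∞ (never raises) for p_kl ∈ {0, 1}
  inconsistent with the data, and the compartment constraint violation is
  likewise probability zero, not an error.
- Tie-breaks: consensus cut levels toward fewer groups; group labels
  canonical by smallest member index.
- Degenerate inputs: S = 1 webs work throughout (CRP prior 0, entropy 0);
  empty link tables are valid; duplicate links and unknown species are
  hard errors (binary-link model — a repeated row signals corrupted data).
- Sampler determinism is a contract: one generator seeded per run; equal
  seeds give byte-identical outputs.

## Problem sizes used by the test suite

Exhaustive-oracle tests run at S ≤ 4 (enumeration over all 15 partitions,
2×10⁵ sweeps), CRP normalization at S ≤ 8 (Bell(8) = 4140 partitions),
planted-recovery at S = 60 (three blocks of 20, link densities 0.5 between
designated blocks and 0.01 elsewhere, 3000 sweeps per seed), and
full-pipeline checks at S = 161 on the synthetic web with runs of a few
thousand sweeps. These sizes were chosen so each check isolates one claim
at the smallest scale where it is meaningful.

## Known limitations

- No degree correction: hub species within a block are indistinguishable
  from the block average, and strong degree heterogeneity will be absorbed
  by extra groups.
- Single-species Gibbs moves only (no split–merge); at much larger S or
  with near-symmetric modes, mixing between high-K modes relies on the
  temperature ladder.
- Trapezoid discretization bias near the evidence transition is not
  included in the reported CI (standard for thermodynamic integration);
  rung counts should be increased when comparing models whose evidences
  differ by only a few log units.
- The consensus is a summary heuristic; all quantitative claims should be
  made across the posterior, and the habitat tests are therefore computed
  across samples, not on the consensus alone.
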