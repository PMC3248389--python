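"""MCMC correctness: exact posteriors on enumerable webs, prior recovery,
detailed balance of the tempering swaps, and determinism."""

import math
from collections import Counter

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import kstest

from trophicblocks import (FoodWeb, LadderConfig, LinkPriorSpec,
                           LinkProbMatrix, ModelVariant, Partition,
                           PartitionPriorSpec, SpeciesRecord, VARIANTS,
                           block_counts, collapsed_log_likelihood,
                           crp_log_prior, run_mcmc,
                           uniform_partition_log_prior)
from trophicblocks.group_model import all_partitions, explicit_log_likelihood
from trophicblocks.sampler import (_assert_cache, _initial_state,
                                   reassign_species_sweep, swap_chains,
                                   update_hyperparameters, update_link_probs)


def exact_collapsed_posterior(web, variant, alpha, a, b):
    """Brute-force posterior over all partitions at fixed hyperparameters."""
    parts = list(all_partitions(web.S))
    lp = []
    for p in parts:
        if variant.partition_prior.kind == "dirichlet_process":
            prior = crp_log_prior(p, alpha)
        else:
            prior = uniform_partition_log_prior(web.S)
        lp.append(prior + collapsed_log_likelihood(block_counts(web, p), a, b))
    lp = np.array(lp)
    return parts, np.exp(lp - logsumexp(lp))


def empirical_partition_freqs(web, variant, n_sweeps, seed, *, alpha=1.0, a=1.0, b=1.0,
                              hyper_updates=False):
    rng = np.random.default_rng(seed)
    st = _initial_state(web, variant, 1.0, rng)
    st.alpha, st.a, st.b = alpha, a, b
    A = web.adjacency()
    counts = Counter()
    for _ in range(n_sweeps):
        reassign_species_sweep(st, A, variant, rng)
        if hyper_updates:
            update_hyperparameters(st, variant, rng)
        counts[tuple(st.labels)] += 1
    _assert_cache(st, A)
    return counts


class TestGibbsAgainstEnumeration:
    def test_two_species_together_vs_apart(self):
        """Empirical frequency of the two partitions of a 2-species web
        matches the exact posterior within 3 Monte-Carlo standard errors."""
        web = FoodWeb(species=[SpeciesRecord("a"), SpeciesRecord("b")],
                      links={("a", "b")})
        variant = ModelVariant("flexible", LinkPriorSpec("uniform"),
                               PartitionPriorSpec("dirichlet_process"))
        parts, post = exact_collapsed_posterior(web, variant, 1.0, 1.0, 1.0)
        n = 40_000
        counts = empirical_partition_freqs(web, variant, n, seed=1)
        p_together = post[[p.K == 1 for p in parts].index(True)]
        emp = counts[(0, 0)] / n
        se = math.sqrt(p_together * (1 - p_together) / n)
        assert abs(emp - p_together) < 3 * se + 0.005  # allowance for autocorrelation

    @pytest.mark.parametrize("variant_name", ["flexible_dp_beta", "flexible_uniform_uniform"])
    def test_four_species_all_fifteen_partitions(self, toy4_web, variant_name):
        variant = VARIANTS[variant_name]
        parts, post = exact_collapsed_posterior(toy4_web, variant, 0.8, 1.5, 2.5)
        n = 50_000
        counts = empirical_partition_freqs(toy4_web, variant, n, seed=3,
                                           alpha=0.8, a=1.5, b=2.5)
        emp = np.array([counts.get(tuple(p.labels), 0) / n for p in parts])
        tv = 0.5 * np.abs(emp - post).sum()
        assert tv < 0.02

    def test_fixed_seed_reproduces_sample_sequence(self, toy4_web):
        kw = dict(iterations=300, burn_in=100, thin=2, seed=42,
                  ladder=LadderConfig(temperatures=(1.0, 0.6)))
        s1 = run_mcmc(toy4_web, VARIANTS["flexible_dp_beta"], **kw)
        s2 = run_mcmc(toy4_web, VARIANTS["flexible_dp_beta"], **kw)
        assert np.array_equal(s1.labels, s2.labels)
        assert np.array_equal(s1.alpha, s2.alpha)
        assert np.array_equal(s1.log_joint, s2.log_joint)


class TestCompartmentalSampler:
    def test_partition_posterior_matches_prior_average_oracle(self, toy3_web):
        """Partition frequencies from the reversible-jump sampler match the
        per-partition evidence estimated by averaging the explicit likelihood
        over prior draws of the constrained probabilities."""
        rng = np.random.default_rng(0)
        parts = list(all_partitions(3))
        logZ = []
        n_mc = 120_000
        for p in parts:
            c = block_counts(toy3_web, p)
            K = p.K
            pd = rng.beta(1, 1, size=(n_mc, K))
            x = rng.uniform(size=(n_mc, K, K))
            pmin = np.minimum(pd[:, :, None], pd[:, None, :])
            full = x * pmin
            idx = np.arange(K)
            full[:, idx, idx] = pd
            with np.errstate(divide="ignore"):
                ll = (c.L * np.log(full) + (c.N - c.L) * np.log1p(-full)).sum(axis=(1, 2))
            logZ.append(logsumexp(ll) - math.log(n_mc) + crp_log_prior(p, 1.0))
        post = np.exp(np.array(logZ) - logsumexp(logZ))

        variant = VARIANTS["compartmental_dp_beta"]
        rng2 = np.random.default_rng(11)
        st = _initial_state(toy3_web, variant, 1.0, rng2)
        A = toy3_web.adjacency()
        counts = Counter()
        n_sweeps = 30_000
        for _ in range(n_sweeps):
            reassign_species_sweep(st, A, variant, rng2)
            update_link_probs(st, None, rng2)
            counts[tuple(st.labels)] += 1
        emp = np.array([counts.get(tuple(p.labels), 0) / n_sweeps for p in parts])
        assert 0.5 * np.abs(emp - post).sum() < 0.03

    def test_fixed_partition_posterior_mean_matches_rejection_oracle(self):
        """Two-group toy with the partition held fixed: the posterior mean of
        p_00 from the probability moves matches rejection sampling from
        prior x likelihood within 3 standard errors."""
        species = [SpeciesRecord(s) for s in "abcd"]
        web = FoodWeb(species=species,
                      links={("a", "b"), ("b", "a"), ("a", "a"),
                             ("c", "d"), ("d", "c")})
        part = Partition([0, 0, 1, 1])
        c = block_counts(web, part)

        rng = np.random.default_rng(5)
        n_mc = 300_000
        pd = rng.uniform(size=(n_mc, 2))
        x = rng.uniform(size=(n_mc, 2, 2))
        pmin = np.minimum(pd[:, :, None], pd[:, None, :])
        full = x * pmin
        full[:, [0, 1], [0, 1]] = pd
        with np.errstate(divide="ignore"):
            ll = (c.L * np.log(full) + (c.N - c.L) * np.log1p(-full)).sum(axis=(1, 2))
        w = np.exp(ll - ll.max())
        oracle_mean = float((w * pd[:, 0]).sum() / w.sum())
        oracle_var = float((w * (pd[:, 0] - oracle_mean) ** 2).sum() / w.sum())

        variant = VARIANTS["compartmental_dp_beta"]
        rng2 = np.random.default_rng(9)
        st = _initial_state(web, variant, 1.0, rng2)
        st.labels = part.labels.copy()
        st.sizes = part.sizes.copy()
        st.L = c.L.copy()
        st.probs = LinkProbMatrix(p_diag=np.array([0.5, 0.5]),
                                  x=np.full((2, 2), 0.5))
        draws = []
        for it in range(20_000):
            update_link_probs(st, None, rng2)
            if it >= 2_000:
                draws.append(st.probs.p_diag[0])
        mcmc_mean = float(np.mean(draws))
        se = math.sqrt(oracle_var / 1_000)  # generous effective sample size
        assert abs(mcmc_mean - oracle_mean) < 3 * se + 0.01

    def test_constraint_always_satisfied(self, toy3_web):
        variant = VARIANTS["compartmental_dp_beta"]
        rng = np.random.default_rng(2)
        st = _initial_state(toy3_web, variant, 1.0, rng)
        A = toy3_web.adjacency()
        for _ in range(500):
            reassign_species_sweep(st, A, variant, rng)
            update_link_probs(st, None, rng)
            assert st.probs.satisfies_constraint()

    def test_single_group_updates_only_diagonal(self, toy3_web):
        variant = VARIANTS["compartmental_dp_beta"]
        rng = np.random.default_rng(3)
        st = _initial_state(toy3_web, variant, 1.0, rng)
        x_before = st.probs.x.copy()
        p_before = st.probs.p_diag.copy()
        for _ in range(50):
            update_link_probs(st, None, rng)
        assert st.probs.K == 1
        assert np.array_equal(st.probs.x, x_before)
        assert not np.array_equal(st.probs.p_diag, p_before)


class TestHyperparameterMoves:
    def test_alpha_prior_recovery(self, toy3_web):
        """With the likelihood switched off (inverse temperature 0) the
        sampled aggregation parameter must be Exp(1)-distributed."""
        variant = VARIANTS["flexible_dp_uniform"]
        rng = np.random.default_rng(3)
        st = _initial_state(toy3_web, variant, 0.0, rng)
        A = toy3_web.adjacency()
        draws = []
        for it in range(51_000):
            reassign_species_sweep(st, A, variant, rng)
            update_hyperparameters(st, variant, rng)
            if it >= 1_000 and it % 5 == 0:
                draws.append(st.alpha)
        stat = kstest(np.array(draws), "expon")
        assert stat.pvalue > 0.01

    def test_uniform_link_prior_leaves_shapes_untouched(self, toy4_web):
        variant = VARIANTS["flexible_dp_uniform"]
        rng = np.random.default_rng(4)
        st = _initial_state(toy4_web, variant, 1.0, rng)
        for _ in range(200):
            update_hyperparameters(st, variant, rng)
        assert st.a == 1.0 and st.b == 1.0


class TestSwapMoves:
    def _two_states(self, web, variant, betas, seed):
        rng = np.random.default_rng(seed)
        states = [_initial_state(web, variant, bt, rng) for bt in betas]
        return states, rng

    def test_equal_temperature_swap_always_accepted(self, toy3_web):
        variant = VARIANTS["flexible_dp_beta"]
        states, rng = self._two_states(toy3_web, variant, (1.0, 1.0), 0)
        states[1].labels = np.array([0, 1, 2])
        states[1].sizes = np.ones(3, dtype=np.int64)
        states[1].L = block_counts(toy3_web, Partition([0, 1, 2])).L
        before = [s.labels.copy() for s in states]
        swap_chains(states, variant, rng)
        assert np.array_equal(states[0].labels, before[1])
        assert np.array_equal(states[1].labels, before[0])
        assert states[0].beta_temp == states[1].beta_temp == 1.0

    def test_identical_states_swap_accepted(self, toy3_web):
        variant = VARIANTS["flexible_dp_beta"]
        states, rng = self._two_states(toy3_web, variant, (1.0, 0.5), 1)
        ll0 = states[0].log_likelihood(variant)
        ll1 = states[1].log_likelihood(variant)
        assert ll0 == ll1  # identical partitions and hyperparameters
        # acceptance exponent is exactly zero, so the swap must occur
        swap_chains(states, variant, rng)
        assert states[0].beta_temp == 1.0 and states[1].beta_temp == 0.5

    def test_cold_chain_distribution_preserved_under_coupling(self, toy3_web):
        """Two-chain coupled run on an enumerable web: the cold chain's
        partition frequencies still match the exact posterior."""
        variant = VARIANTS["flexible_uniform_uniform"]
        parts, post = exact_collapsed_posterior(toy3_web, variant, 1.0, 1.0, 1.0)
        rng = np.random.default_rng(6)
        states = [_initial_state(toy3_web, variant, bt, rng) for bt in (1.0, 0.4)]
        A = toy3_web.adjacency()
        counts = Counter()
        n = 40_000
        for _ in range(n):
            for st in states:
                reassign_species_sweep(st, A, variant, rng)
            swap_chains(states, variant, rng)
            counts[tuple(states[0].labels)] += 1
        emp = np.array([counts.get(tuple(p.labels), 0) / n for p in parts])
        assert 0.5 * np.abs(emp - post).sum() < 0.02


class TestRunMcmc:
    def test_keeps_configured_sample_count(self, toy4_web):
        s = run_mcmc(toy4_web, VARIANTS["flexible_dp_beta"], iterations=250,
                     burn_in=50, thin=2, seed=0,
                     ladder=LadderConfig(temperatures=(1.0,)))
        assert s.n_samples == 100
        assert s.labels.shape == (100, 4)

    def test_default_keep_count_is_thirty_thousand(self):
        # (iterations - burn_in) / thin at the documented defaults
        import inspect

        sig = inspect.signature(run_mcmc)
        it = sig.parameters["iterations"].default
        burn = sig.parameters["burn_in"].default
        thin = sig.parameters["thin"].default
        assert (it - burn) // thin == 30_000

    def test_zero_kept_samples_rejected(self, toy4_web):
        with pytest.raises(ValueError):
            run_mcmc(toy4_web, VARIANTS["flexible_dp_beta"], iterations=100,
                     burn_in=100, seed=0)

    def test_csv_round_trip(self, toy4_web, tmp_path):
        s = run_mcmc(toy4_web, VARIANTS["flexible_dp_beta"], iterations=60,
                     burn_in=10, seed=1, ladder=LadderConfig(temperatures=(1.0,)))
        s.to_csv(tmp_path / "post.csv")
        from trophicblocks import PosteriorSamples

        s2 = PosteriorSamples.from_csv(tmp_path / "post.csv")
        assert np.array_equal(s2.labels, s.labels)
        assert s2.species_ids == s.species_ids

    def test_cached_counts_never_drift(self, toy4_web):
        """The periodic internal consistency check (every 10^3 sweeps) runs
        inside run_mcmc; drive it past the checkpoint explicitly."""
        s = run_mcmc(toy4_web, VARIANTS["flexible_dp_beta"], iterations=1100,
                     burn_in=100, seed=5, ladder=LadderConfig(temperatures=(1.0,)))
        assert s.n_samples == 1000


class TestLadderConfig:
    def test_must_start_cold(self):
        with pytest.raises(ValueError):
            LadderConfig(temperatures=(0.9, 0.5))

    def test_must_decrease(self):
        with pytest.raises(ValueError):
            LadderConfig(temperatures=(1.0, 0.5, 0.7))
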