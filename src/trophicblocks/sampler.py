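"""Metropolis-coupled MCMC over partitions and hyperparameters.

Each chain targets prior x likelihood^beta for an inverse temperature
beta in (0, 1]; the cold chain (beta = 1) is the posterior. Heating only
the likelihood keeps every chain's prior proper, which is also exactly the
power-posterior family needed for marginal-likelihood estimation, so the
same machinery drives both posterior sampling and evidence rungs.

Partition moves are collapsed Gibbs sweeps: each species in turn is
reassigned among the existing groups plus one fresh singleton group, with
conditional weights prior_weight x exp(beta * delta log-likelihood)
computed incrementally from block sufficient statistics. Under the CRP
prior the prior weight is n_g for an existing group and alpha for a fresh
one; under the uniform-partition prior every option weighs equally. The
compartment-constrained variant, which carries explicit link
probabilities, uses Metropolis-Hastings reassignment with new-group
parameters proposed from their priors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .group_model import (
    BlockCounts,
    LinkProbMatrix,
    ModelVariant,
    Partition,
    block_counts_from_adjacency,
    collapsed_log_likelihood,
    crp_log_prior,
    explicit_log_likelihood,
    link_prob_log_prior,
    uniform_partition_log_prior,
)
from .network_data import FoodWeb

__all__ = ["ChainState", "LadderConfig", "PosteriorSamples", "run_mcmc",
           "reassign_species_sweep", "update_hyperparameters",
           "update_link_probs", "swap_chains"]

_CACHE_CHECK_INTERVAL = 1000
_HYPER_STEP = 0.5   # std of the log-scale random walk on alpha, a, b
_PROB_STEP = 0.6    # std of the logit/reflected walk on p_kk and x_kl


# ---------------------------------------------------------------------------
# chain state
# ---------------------------------------------------------------------------

@dataclass
class ChainState:
    """Mutable state of one tempered chain."""

    labels: np.ndarray            # (S,) group of each species
    sizes: np.ndarray             # (K,)
    L: np.ndarray                 # (K, K) realized links per block
    alpha: float = 1.0
    a: float = 1.0
    b: float = 1.0
    probs: LinkProbMatrix | None = None   # compartmental only
    beta_temp: float = 1.0

    @property
    def K(self) -> int:
        return self.sizes.size

    @property
    def S(self) -> int:
        return self.labels.size

    def counts(self) -> BlockCounts:
        return BlockCounts(L=self.L.copy(), N=np.outer(self.sizes, self.sizes))

    def log_likelihood(self, variant: ModelVariant) -> float:
        if variant.collapsed:
            return collapsed_log_likelihood(self.counts(), self.a, self.b)
        return explicit_log_likelihood(self.counts(), self.probs.full())

    def log_prior(self, variant: ModelVariant) -> float:
        lp = 0.0
        if not variant.fixed_partition:
            if variant.partition_prior.kind == "dirichlet_process":
                lp += crp_log_prior(Partition(self.labels), self.alpha) - self.alpha
            else:
                lp += uniform_partition_log_prior(self.S)
        if variant.link_prior.free:
            lp += -(self.a + self.b)
        if not variant.collapsed:
            lp += link_prob_log_prior(self.probs, self.a, self.b)
        return lp

    def log_target(self, variant: ModelVariant) -> float:
        """prior x likelihood^beta, in log."""
        return self.log_prior(variant) + self.beta_temp * self.log_likelihood(variant)


def _initial_state(web: FoodWeb, variant: ModelVariant, beta_temp: float,
                   rng: np.random.Generator) -> ChainState:
    S = web.S
    A = web.adjacency()
    if variant.structure == "full_independent":
        labels = np.arange(S, dtype=np.int64)
    elif variant.structure == "one_group":
        labels = np.zeros(S, dtype=np.int64)
    else:
        labels = np.zeros(S, dtype=np.int64)  # deterministic one-group start
    K = int(labels.max()) + 1
    counts = block_counts_from_adjacency(A, labels, K)
    state = ChainState(labels=labels, sizes=np.bincount(labels, minlength=K),
                       L=counts.L.astype(np.int64), beta_temp=beta_temp)
    if not variant.collapsed:
        state.probs = _prior_probs(K, state.a, state.b, rng)
    return state


def _prior_probs(K: int, a: float, b: float, rng: np.random.Generator) -> LinkProbMatrix:
    x = rng.uniform(size=(K, K))
    np.fill_diagonal(x, 1.0)
    return LinkProbMatrix(p_diag=rng.beta(a, b, size=K), x=x)


# ---------------------------------------------------------------------------
# collapsed Gibbs sweep
# ---------------------------------------------------------------------------

def _lgamma_tables(state: ChainState, max_n: int):
    """Log-gamma lookup tables at the chain's current (a, b), cached on the
    state; the collapsed block term becomes pure integer indexing."""
    key = (state.a, state.b, max_n)
    if getattr(state, "_tab_key", None) != key:
        n_idx = np.arange(max_n + 1, dtype=float)
        state._tab_key = key
        state._ga = gammaln(state.a + n_idx).tolist()
        state._gb = gammaln(state.b + n_idx).tolist()
        state._gab = gammaln(state.a + state.b + n_idx).tolist()
    return state._ga, state._gb, state._gab


def _gibbs_sweep_collapsed(state: ChainState, A: np.ndarray, variant: ModelVariant,
                           rng: np.random.Generator) -> None:
    """One full pass reassigning every species in index order (in place).

    Works on plain Python lists with sparse neighbor lists: at the group
    counts this model operates at (K of order 10), interpreter loops over
    scalars beat vectorized calls on length-K arrays by a wide margin.
    """
    S = state.S
    beta = state.beta_temp
    crp = variant.partition_prior.kind == "dirichlet_process"
    alpha = state.alpha
    ga, gb, gab = _lgamma_tables(state, S * S)
    c0 = ga[0] + gb[0] - gab[0]
    out_nbrs = [np.flatnonzero(A[i]).tolist() for i in range(S)]
    in_nbrs = [np.flatnonzero(A[:, i]).tolist() for i in range(S)]

    labels: list[int] = state.labels.tolist()
    sizes: list[int] = state.sizes.tolist()
    L: list[list[int]] = [row.tolist() for row in state.L]
    K = len(sizes)
    uniform = rng.random(S)  # one draw per species, consumed in order

    for i in range(S):
        c = labels[i]
        aii = 1 if i in out_nbrs[i] else 0
        out_i = [0] * K
        for j in out_nbrs[i]:
            out_i[labels[j]] += 1
        in_i = [0] * K
        for j in in_nbrs[i]:
            in_i[labels[j]] += 1
        # detach species i from group c
        Lc = L[c]
        for g in range(K):
            Lc[g] -= out_i[g]
            L[g][c] -= in_i[g]
        Lc[c] += aii
        sizes[c] -= 1
        out_i[c] -= aii
        in_i[c] -= aii
        if sizes[c] == 0:
            del sizes[c], out_i[c], in_i[c], L[c]
            for row in L:
                del row[c]
            for j in range(S):
                if labels[j] > c:
                    labels[j] -= 1
            labels[i] = -1
            K -= 1
        # conditional weights: existing groups + one fresh singleton group.
        # Only blocks in row g and column g change when i joins group g, and
        # empty blocks contribute exactly zero.
        logw = [0.0] * (K + 1)
        for g in range(K):
            ng = sizes[g]
            Lg = L[g]
            delta = 0.0
            for l in range(K):
                nl = sizes[l]
                if l == g:
                    Ln, Nn = Lg[g] + out_i[g] + in_i[g] + aii, (ng + 1) * (ng + 1)
                    Lo, No = Lg[g], ng * ng
                    delta += ga[Ln] + gb[Nn - Ln] - gab[Nn] \
                        - (ga[Lo] + gb[No - Lo] - gab[No])
                else:
                    Ln, Nn = Lg[l] + out_i[l], (ng + 1) * nl
                    Lo, No = Lg[l], ng * nl
                    delta += ga[Ln] + gb[Nn - Ln] - gab[Nn] \
                        - (ga[Lo] + gb[No - Lo] - gab[No])
                    Ln, Nn = L[l][g] + in_i[l], nl * (ng + 1)
                    Lo, No = L[l][g], nl * ng
                    delta += ga[Ln] + gb[Nn - Ln] - gab[Nn] \
                        - (ga[Lo] + gb[No - Lo] - gab[No])
            logw[g] = beta * delta + (math.log(ng) if crp else 0.0)
        delta = ga[aii] + gb[1 - aii] - gab[1] - c0
        for l in range(K):
            nl = sizes[l]
            delta += ga[out_i[l]] + gb[nl - out_i[l]] - gab[nl] - c0
            delta += ga[in_i[l]] + gb[nl - in_i[l]] - gab[nl] - c0
        logw[K] = beta * delta + (math.log(alpha) if crp else 0.0)
        top = max(logw)
        w = [math.exp(x - top) for x in logw]
        total = 0.0
        for g in range(K + 1):
            total += w[g]
            w[g] = total
        u = uniform[i] * total
        g_new = 0
        while w[g_new] < u and g_new < K:
            g_new += 1
        # attach species i to the chosen group
        if g_new == K:
            sizes.append(0)
            out_i.append(0)
            in_i.append(0)
            for row in L:
                row.append(0)
            L.append([0] * (K + 1))
            K += 1
        Lg = L[g_new]
        for g in range(K):
            Lg[g] += out_i[g]
            L[g][g_new] += in_i[g]
        Lg[g_new] += aii
        sizes[g_new] += 1
        labels[i] = g_new

    state.labels = np.asarray(labels, dtype=np.int64)
    state.sizes = np.asarray(sizes, dtype=np.int64)
    state.L = np.asarray(L, dtype=np.int64)
    # canonical labels keep serialization and equality stable
    _recanonicalize(state)


def _recanonicalize(state: ChainState) -> None:
    part = Partition(state.labels)
    if not np.array_equal(part.labels, state.labels):
        perm = np.full(state.K, -1, dtype=np.int64)
        for old, new in zip(state.labels, part.labels):
            perm[old] = new
        state.labels = part.labels
        state.sizes = part.sizes
        Lnew = np.zeros_like(state.L)
        Lnew[np.ix_(perm, perm)] = state.L
        state.L = Lnew
        if state.probs is not None:
            p = state.probs
            pd_new = np.empty_like(p.p_diag)
            pd_new[perm] = p.p_diag
            x_new = np.zeros_like(p.x)
            x_new[np.ix_(perm, perm)] = p.x
            state.probs = LinkProbMatrix(p_diag=pd_new, x=x_new)


def reassign_species_sweep(state: ChainState, web_or_A, variant: ModelVariant,
                           rng: np.random.Generator) -> ChainState:
    """Reassign every species once (in place; also returned for convenience)."""
    A = web_or_A.adjacency() if isinstance(web_or_A, FoodWeb) else np.asarray(web_or_A)
    if variant.fixed_partition:
        return state
    if variant.collapsed:
        _gibbs_sweep_collapsed(state, A, variant, rng)
    else:
        _mh_sweep_compartmental(state, A, variant, rng)
    return state


# ---------------------------------------------------------------------------
# compartmental moves (explicit probabilities, Metropolis-Hastings)
# ---------------------------------------------------------------------------

def _mh_sweep_compartmental(state: ChainState, A: np.ndarray, variant: ModelVariant,
                            rng: np.random.Generator) -> None:
    """Single-species reassignment with new-group parameters drawn from
    their priors; prior proposal densities cancel in the acceptance ratio,
    leaving the tempered likelihood ratio, the partition-prior ratio and
    the option-count correction."""
    crp = variant.partition_prior.kind == "dirichlet_process"
    for i in range(state.S):
        K = state.K
        c = int(state.labels[i])
        singleton = state.sizes[c] == 1
        n_opt_fwd = K if not singleton else K  # (K-1 others) + fresh
        choice = int(rng.integers(n_opt_fwd))
        others = [g for g in range(K) if g != c]
        target_g = others[choice] if choice < K - 1 else None  # None = fresh
        if singleton and target_g is None:
            continue  # fresh group from a singleton is the identity move
        old_ll = state.log_likelihood(variant)
        lab_new = state.labels.copy()
        if target_g is None:
            # birth: move i to a fresh group with prior-drawn parameters
            lab_new[i] = K
            probs_new = _extend_probs(state.probs, state.a, state.b, rng)
            log_ratio_prior = (math.log(state.alpha) - math.log(state.sizes[c] - 1)) if crp else 0.0
            log_opt = math.log(n_opt_fwd) - math.log(K + 1)
        elif singleton:
            # death: singleton c dissolves into target_g
            lab_new[i] = target_g
            probs_new = _drop_group(state.probs, c)
            lab_new[lab_new > c] -= 1
            log_ratio_prior = (math.log(state.sizes[target_g]) - math.log(state.alpha)) if crp else 0.0
            log_opt = math.log(n_opt_fwd) - math.log(K - 1)
        else:
            lab_new[i] = target_g
            probs_new = state.probs
            log_ratio_prior = (math.log(state.sizes[target_g]) - math.log(state.sizes[c] - 1)) if crp else 0.0
            log_opt = 0.0
        K_new = int(lab_new.max()) + 1
        counts_new = block_counts_from_adjacency(A, lab_new, K_new)
        new_ll = explicit_log_likelihood(counts_new, probs_new.full())
        log_acc = state.beta_temp * (new_ll - old_ll) + log_ratio_prior + log_opt
        if math.log(rng.uniform()) < log_acc:
            state.labels = lab_new
            state.sizes = np.bincount(lab_new, minlength=K_new)
            state.L = counts_new.L
            state.probs = probs_new
    _recanonicalize(state)


def _extend_probs(probs: LinkProbMatrix, a: float, b: float,
                  rng: np.random.Generator) -> LinkProbMatrix:
    K = probs.K
    p_diag = np.append(probs.p_diag, rng.beta(a, b))
    x = np.ones((K + 1, K + 1))
    x[:K, :K] = probs.x
    x[K, :K] = rng.uniform(size=K)
    x[:K, K] = rng.uniform(size=K)
    return LinkProbMatrix(p_diag=p_diag, x=x)


def _drop_group(probs: LinkProbMatrix, g: int) -> LinkProbMatrix:
    keep = [k for k in range(probs.K) if k != g]
    return LinkProbMatrix(p_diag=probs.p_diag[keep], x=probs.x[np.ix_(keep, keep)])


def update_link_probs(state: ChainState, counts: BlockCounts | None,
                      rng: np.random.Generator) -> ChainState:
    """MH updates of the diagonal probabilities p_kk (logit walk, Beta(a, b)
    prior) and the between-group fractions x_kl (reflected walk in (0, 1)).

    The parameterization p_kl = x_kl * min(p_kk, p_ll) keeps the
    compartment constraint satisfied after every accepted move.
    """
    if state.probs is None:
        raise ValueError("link-probability updates apply to the compartmental variant only")
    if counts is None:
        counts = state.counts()
    beta = state.beta_temp
    p = state.probs
    for k in range(state.K):
        old = p.p_diag[k]
        logit = math.log(old / (1 - old)) + _PROB_STEP * rng.normal()
        new = 1.0 / (1.0 + math.exp(-logit))
        old_ll = explicit_log_likelihood(counts, p.full())
        cand = LinkProbMatrix(p_diag=p.p_diag.copy(), x=p.x)
        cand.p_diag[k] = new
        new_ll = explicit_log_likelihood(counts, cand.full())
        # Beta(a,b) prior with the logit-walk Jacobian p(1-p)
        log_acc = beta * (new_ll - old_ll) \
            + (state.a - 1) * (math.log(new) - math.log(old)) \
            + (state.b - 1) * (math.log1p(-new) - math.log1p(-old)) \
            + math.log(new * (1 - new)) - math.log(old * (1 - old))
        if math.log(rng.uniform()) < log_acc:
            p = cand
    for k in range(state.K):
        for l in range(state.K):
            if k == l:
                continue
            prop = p.x[k, l] + _PROB_STEP * rng.normal()
            prop = prop % 2.0
            if prop > 1.0:
                prop = 2.0 - prop  # reflection keeps the walk symmetric
            old_ll = explicit_log_likelihood(counts, p.full())
            cand = LinkProbMatrix(p_diag=p.p_diag, x=p.x.copy())
            cand.x[k, l] = prop
            new_ll = explicit_log_likelihood(counts, cand.full())
            if math.log(rng.uniform()) < beta * (new_ll - old_ll):
                p = cand
    state.probs = p
    return state


# ---------------------------------------------------------------------------
# hyperparameter moves
# ---------------------------------------------------------------------------

def update_hyperparameters(state: ChainState, variant: ModelVariant,
                           rng: np.random.Generator) -> ChainState:
    """Metropolis-Hastings log-scale random-walk updates of alpha, a, b.

    alpha's conditional is Exp(1) x CRP(partition | alpha) (part of the
    prior, never tempered); a and b see the Exp(1) hyperprior plus the
    tempered collapsed likelihood (collapsed variants) or the diagonal
    link-probability prior (compartmental).
    """
    part = None
    if variant.partition_prior.free and not variant.fixed_partition:
        part = Partition(state.labels)
        cur = -state.alpha + crp_log_prior(part, state.alpha)
        prop = state.alpha * math.exp(_HYPER_STEP * rng.normal())
        cand = -prop + crp_log_prior(part, prop)
        # log-scale walk: Hastings factor prop/alpha
        if math.log(rng.uniform()) < cand - cur + math.log(prop / state.alpha):
            state.alpha = prop
    if variant.link_prior.free:
        counts = state.counts() if variant.collapsed else None
        for name in ("a", "b"):
            cur_val = getattr(state, name)
            prop = cur_val * math.exp(_HYPER_STEP * rng.normal())
            if variant.collapsed:
                cur_t = -cur_val + state.beta_temp * collapsed_log_likelihood(
                    counts, state.a, state.b)
                a_new = prop if name == "a" else state.a
                b_new = prop if name == "b" else state.b
                cand_t = -prop + state.beta_temp * collapsed_log_likelihood(
                    counts, a_new, b_new)
            else:
                cur_t = -cur_val + link_prob_log_prior(state.probs, state.a, state.b)
                a_new = prop if name == "a" else state.a
                b_new = prop if name == "b" else state.b
                cand_t = -prop + link_prob_log_prior(state.probs, a_new, b_new)
            if math.log(rng.uniform()) < cand_t - cur_t + math.log(prop / cur_val):
                setattr(state, name, prop)
    return state


# ---------------------------------------------------------------------------
# tempering ladder
# ---------------------------------------------------------------------------

@dataclass
class LadderConfig:
    """Temperature ladder for Metropolis coupling.

    ``temperatures`` are inverse temperatures, strictly positive and
    decreasing with the first equal to 1 (the cold, untempered chain).
    """

    temperatures: tuple[float, ...] = (1.0, 0.7, 0.5, 0.35)
    swap_interval: int = 1

    def __post_init__(self) -> None:
        t = self.temperatures
        if len(t) < 1 or t[0] != 1.0:
            raise ValueError("ladder must start at inverse temperature 1.0")
        if any(x <= 0 for x in t):
            raise ValueError("temperatures must be positive")
        if list(t) != sorted(t, reverse=True) or len(set(t)) != len(t):
            raise ValueError("temperatures must be strictly decreasing")

    @property
    def n_chains(self) -> int:
        return len(self.temperatures)


def swap_chains(states: list[ChainState], variant: ModelVariant,
                rng: np.random.Generator) -> list[ChainState]:
    """Propose swapping the full states of one uniformly chosen adjacent
    temperature pair; accept with probability
    min(1, exp[(beta_i - beta_j)(loglik_j - loglik_i)]).

    Because every chain shares the same (untempered) prior, the prior terms
    cancel and only the untempered log likelihoods enter the ratio.
    """
    if len(states) < 2:
        return states
    i = int(rng.integers(len(states) - 1))
    j = i + 1
    ll_i = states[i].log_likelihood(variant)
    ll_j = states[j].log_likelihood(variant)
    log_acc = (states[i].beta_temp - states[j].beta_temp) * (ll_j - ll_i)
    if math.log(rng.uniform()) < log_acc:
        bi, bj = states[i].beta_temp, states[j].beta_temp
        states[i], states[j] = states[j], states[i]
        states[i].beta_temp, states[j].beta_temp = bi, bj
    return states


# ---------------------------------------------------------------------------
# posterior container and the main driver
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """Cold-chain draws after burn-in and thinning, plus run metadata."""

    species_ids: list[str]
    labels: np.ndarray        # (n_samples, S)
    alpha: np.ndarray
    a: np.ndarray
    b: np.ndarray
    log_likelihood: np.ndarray
    log_joint: np.ndarray
    config: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]

    @property
    def S(self) -> int:
        return self.labels.shape[1]

    def partitions(self):
        return [Partition(row) for row in self.labels]

    def group_counts(self) -> np.ndarray:
        return self.labels.max(axis=1) + 1

    def to_csv(self, path) -> None:
        cols = {
            "sample": np.arange(self.n_samples),
            "K": self.group_counts(),
            "alpha": self.alpha,
            "a": self.a,
            "b": self.b,
            "log_likelihood": self.log_likelihood,
            "log_joint": self.log_joint,
        }
        cols.update({f"g_{sid}": self.labels[:, j]
                     for j, sid in enumerate(self.species_ids)})
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PosteriorSamples":
        df = pd.read_csv(path)
        gcols = [c for c in df.columns if c.startswith("g_")]
        return cls(
            species_ids=[c[2:] for c in gcols],
            labels=df[gcols].to_numpy(dtype=np.int64),
            alpha=df["alpha"].to_numpy(),
            a=df["a"].to_numpy(),
            b=df["b"].to_numpy(),
            log_likelihood=df["log_likelihood"].to_numpy(),
            log_joint=df["log_joint"].to_numpy(),
        )


def run_mcmc(
    web: FoodWeb,
    variant: ModelVariant,
    *,
    ladder: LadderConfig | None = None,
    iterations: int = 40_000,
    burn_in: int = 10_000,
    thin: int = 1,
    seed: int = 0,
    check_cache: bool = True,
) -> PosteriorSamples:
    """Sample the posterior (or a tempered target) by Metropolis-coupled MCMC.

    ``iterations`` counts full sweeps; the cold chain is recorded every
    ``thin`` sweeps after ``burn_in``, giving (iterations - burn_in) / thin
    kept samples (30,000 at the defaults). Fully reproducible given ``seed``.
    """
    if iterations <= burn_in:
        raise ValueError("iterations must exceed burn_in")
    n_keep = (iterations - burn_in) // thin
    if n_keep < 1:
        raise ValueError("configuration keeps zero samples")
    ladder = ladder or LadderConfig()
    rng = np.random.default_rng(seed)
    A = web.adjacency()
    states = [_initial_state(web, variant, bt, rng) for bt in ladder.temperatures]

    kept_labels = np.empty((n_keep, web.S), dtype=np.int64)
    kept = {k: np.empty(n_keep) for k in ("alpha", "a", "b", "ll", "lj")}
    m = 0
    for it in range(iterations):
        for st in states:
            reassign_species_sweep(st, A, variant, rng)
            if variant.partition_prior.free or variant.link_prior.free:
                update_hyperparameters(st, variant, rng)
            if not variant.collapsed:
                update_link_probs(st, None, rng)
        if len(states) > 1 and (it + 1) % ladder.swap_interval == 0:
            swap_chains(states, variant, rng)
        if check_cache and (it + 1) % _CACHE_CHECK_INTERVAL == 0:
            _assert_cache(states[0], A)
        if it >= burn_in and (it - burn_in) % thin == 0 and m < n_keep:
            cold = states[0]
            kept_labels[m] = cold.labels
            kept["alpha"][m] = cold.alpha
            kept["a"][m] = cold.a
            kept["b"][m] = cold.b
            ll = cold.log_likelihood(variant)
            kept["ll"][m] = ll
            kept["lj"][m] = cold.log_prior(variant) + ll
            m += 1
    return PosteriorSamples(
        species_ids=web.species_ids,
        labels=kept_labels[:m],
        alpha=kept["alpha"][:m],
        a=kept["a"][:m],
        b=kept["b"][:m],
        log_likelihood=kept["ll"][:m],
        log_joint=kept["lj"][:m],
        config={
            "variant": variant.describe(),
            "iterations": iterations,
            "burn_in": burn_in,
            "thin": thin,
            "seed": seed,
            "temperatures": list(ladder.temperatures),
            "swap_interval": ladder.swap_interval,
        },
    )


def _assert_cache(state: ChainState, A: np.ndarray) -> None:
    """Incremental block counts must agree with a from-scratch recomputation."""
    fresh = block_counts_from_adjacency(A, state.labels, state.K)
    if not np.array_equal(fresh.L, state.L):
        raise RuntimeError("block-count cache drifted from recomputation")
    if not np.array_equal(np.bincount(state.labels, minlength=state.K), state.sizes):
        raise RuntimeError("group-size cache drifted from recomputation")
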