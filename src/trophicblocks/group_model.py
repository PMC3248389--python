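"""Partitions, block sufficient statistics, likelihoods, priors, null evidences.

The group model (a directed stochastic block model) assigns every species to
one of K groups; every ordered group pair (k, l) carries a single probability
p_kl that a species in consumer group k eats a species in resource group l.
Conditional on the partition, the adjacency data are S^2 independent Bernoulli
trials. With a Beta(a, b) prior on each p_kl the likelihood collapses
analytically:

    ln P(data | partition, a, b)
        = sum_kl [ ln B(a + L_kl, b + N_kl - L_kl) - ln B(a, b) ]

where L_kl counts realized and N_kl = n_k * n_l possible links in block
(k, l), and B is the Beta function. The collapsed form is the primary
computational path; only the compartment-constrained variant, whose
constraint breaks conjugacy, carries explicit link probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln

from .network_data import FoodWeb

__all__ = [
    "Partition",
    "BlockCounts",
    "LinkPriorSpec",
    "PartitionPriorSpec",
    "ModelVariant",
    "LinkProbMatrix",
    "block_counts",
    "collapsed_log_likelihood",
    "explicit_log_likelihood",
    "crp_log_prior",
    "uniform_partition_log_prior",
    "log_bell",
    "hyper_log_prior",
    "log_joint",
    "closed_form_null_evidence",
    "VARIANTS",
]


# ---------------------------------------------------------------------------
# partitions
# ---------------------------------------------------------------------------

class Partition:
    """Assignment of S species to K groups, labels contiguous 0..K-1.

    Group labels are canonical: groups are numbered in order of their
    smallest member index, so identical set partitions always compare and
    serialize identically.
    """

    __slots__ = ("labels", "K", "sizes")

    def __init__(self, labels) -> None:
        labels = np.asarray(labels, dtype=np.int64)
        if labels.ndim != 1 or labels.size == 0:
            raise ValueError("labels must be a non-empty 1-d sequence")
        self.labels = _canonicalize(labels)
        self.K = int(self.labels.max()) + 1
        self.sizes = np.bincount(self.labels, minlength=self.K)
        if (self.sizes == 0).any():
            raise ValueError("group labels must be contiguous with no empty group")

    @property
    def S(self) -> int:
        return self.labels.size

    def __eq__(self, other) -> bool:
        return isinstance(other, Partition) and np.array_equal(self.labels, other.labels)

    def __hash__(self) -> int:
        return hash(self.labels.tobytes())

    def __repr__(self) -> str:
        return f"Partition(S={self.S}, K={self.K})"

    def groups(self) -> list[np.ndarray]:
        """Member indices per group, in canonical label order."""
        return [np.flatnonzero(self.labels == k) for k in range(self.K)]

    def to_frame(self, species_ids: list[str]) -> pd.DataFrame:
        if len(species_ids) != self.S:
            raise ValueError("species id list length does not match partition size")
        return pd.DataFrame({"species_id": species_ids, "group_label": self.labels})

    def to_csv(self, path, species_ids: list[str]) -> None:
        self.to_frame(species_ids).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, species_ids: list[str]) -> "Partition":
        df = pd.read_csv(path).set_index("species_id")
        return cls(df.loc[species_ids, "group_label"].to_numpy())


def _canonicalize(labels: np.ndarray) -> np.ndarray:
    """Relabel groups by order of first appearance (smallest member index)."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        lab = int(lab)
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def all_partitions(S: int):
    """Yield every set partition of range(S) as a Partition (Bell(S) of them)."""
    def rec(i, labels, k):
        if i == S:
            yield Partition(labels.copy())
            return
        for g in range(k + 1):
            labels[i] = g
            yield from rec(i + 1, labels, max(k, g + 1))

    yield from rec(0, np.zeros(S, dtype=np.int64), 0)


# ---------------------------------------------------------------------------
# sufficient statistics
# ---------------------------------------------------------------------------

@dataclass
class BlockCounts:
    """Per ordered group pair (k, l): realized links L_kl, possible N_kl.

    Conservation: sum(N) == S^2 and sum(L) == L of the web.
    """

    L: np.ndarray  # (K, K) int
    N: np.ndarray  # (K, K) int

    @property
    def K(self) -> int:
        return self.L.shape[0]


def block_counts(web: FoodWeb, partition: Partition) -> BlockCounts:
    """Aggregate the adjacency matrix into block sufficient statistics."""
    if partition.S != web.S:
        raise ValueError("partition size does not match web species count")
    A = web.adjacency()
    return block_counts_from_adjacency(A, partition.labels, partition.K)


def block_counts_from_adjacency(A: np.ndarray, labels: np.ndarray, K: int) -> BlockCounts:
    sizes = np.bincount(labels, minlength=K)
    onehot = np.zeros((labels.size, K))
    onehot[np.arange(labels.size), labels] = 1.0
    L = onehot.T @ A @ onehot
    return BlockCounts(L=np.rint(L).astype(np.int64), N=np.outer(sizes, sizes))


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------

def collapsed_log_likelihood(counts: BlockCounts, a: float = 1.0, b: float = 1.0) -> float:
    """Log probability of the adjacency data with every p_kl integrated out
    under a shared Beta(a, b) prior."""
    if a <= 0 or b <= 0:
        raise ValueError("beta shape parameters must be positive")
    L, N = counts.L, counts.N
    return float(np.sum(betaln(a + L, b + (N - L)) - betaln(a, b)))


def explicit_log_likelihood(counts: BlockCounts, probs: np.ndarray) -> float:
    """Log probability of the adjacency data at explicit link probabilities.

    Returns -inf when a zero-probability block contains a link (or a
    probability-one block misses one).
    """
    probs = np.asarray(probs, dtype=float)
    if probs.shape != counts.L.shape:
        raise ValueError("link probability matrix shape does not match block counts")
    if (probs < 0).any() or (probs > 1).any():
        raise ValueError("link probabilities must lie in [0, 1]")
    L = counts.L
    M = counts.N - counts.L
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(L > 0, L * np.log(probs), 0.0) + np.where(
            M > 0, M * np.log1p(-probs), 0.0
        )
    if np.isnan(term).any():
        return -math.inf
    return float(term.sum())


# ---------------------------------------------------------------------------
# partition priors
# ---------------------------------------------------------------------------

def crp_log_prior(partition: Partition, alpha: float) -> float:
    """Log probability of a partition under the Chinese restaurant process.

    P(partition) = alpha^K * prod_k (n_k - 1)! * Gamma(alpha) / Gamma(alpha + S).
    Exchangeable: depends only on the multiset of group sizes.
    """
    if alpha <= 0:
        raise ValueError("aggregation parameter alpha must be positive")
    n = partition.sizes
    return float(
        partition.K * math.log(alpha)
        + gammaln(n).sum()
        + gammaln(alpha)
        - gammaln(alpha + partition.S)
    )


def log_bell(S: int) -> float:
    """Natural log of the Bell number B(S), exact via the Bell triangle."""
    if S < 0:
        raise ValueError("S must be non-negative")
    row = [1]
    for _ in range(S):
        new = [row[-1]]
        for v in row:
            new.append(new[-1] + v)
        row = new
    return math.log(row[0])


def uniform_partition_log_prior(S: int) -> float:
    """Log prior of any single partition under the uniform-over-partitions
    prior, -ln Bell(S)."""
    if S < 1:
        raise ValueError("S must be at least 1")
    return -log_bell(S)


# ---------------------------------------------------------------------------
# priors / variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkPriorSpec:
    """Prior on block link probabilities: uniform, or Beta(a, b) with
    Exp(mean 1) hyperpriors on a and b. Uniform is Beta(1, 1) held fixed."""

    kind: str = "beta"  # "uniform" | "beta"
    a: float = 1.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "beta"):
            raise ValueError(f"unknown link prior kind {self.kind!r}")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("beta shapes must be positive")
        if self.kind == "uniform" and (self.a != 1.0 or self.b != 1.0):
            raise ValueError("uniform link prior fixes a = b = 1")

    @property
    def free(self) -> bool:
        return self.kind == "beta"


@dataclass(frozen=True)
class PartitionPriorSpec:
    """Prior on partitions: uniform over set partitions, or Dirichlet-process
    (CRP) with Exp(mean 1) hyperprior on the aggregation parameter alpha."""

    kind: str = "dirichlet_process"  # "uniform" | "dirichlet_process"
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "dirichlet_process"):
            raise ValueError(f"unknown partition prior kind {self.kind!r}")
        if not (self.alpha > 0 and math.isfinite(self.alpha)):
            raise ValueError("alpha must be finite and positive")

    @property
    def free(self) -> bool:
        return self.kind == "dirichlet_process"


@dataclass(frozen=True)
class ModelVariant:
    """A full model specification: structure x link prior x partition prior.

    structure is one of "one_group", "full_independent", "flexible",
    "compartmental". The two null structures fix the partition (one group /
    all singletons), so their partition prior is ignored.
    """

    structure: str = "flexible"
    link_prior: LinkPriorSpec = field(default_factory=LinkPriorSpec)
    partition_prior: PartitionPriorSpec = field(default_factory=PartitionPriorSpec)

    def __post_init__(self) -> None:
        if self.structure not in ("one_group", "full_independent", "flexible", "compartmental"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.structure == "compartmental" and self.link_prior.kind != "beta":
            raise ValueError("compartmental variant requires the beta link prior")

    @property
    def fixed_partition(self) -> bool:
        return self.structure in ("one_group", "full_independent")

    @property
    def collapsed(self) -> bool:
        """True when the likelihood path integrates p_kl analytically."""
        return self.structure != "compartmental"

    def describe(self) -> str:
        return f"{self.structure}/{self.partition_prior.kind}/{self.link_prior.kind}"


def _named_variants() -> dict[str, ModelVariant]:
    u = LinkPriorSpec(kind="uniform")
    beta = LinkPriorSpec(kind="beta")
    up = PartitionPriorSpec(kind="uniform")
    dp = PartitionPriorSpec(kind="dirichlet_process")
    return {
        "one_group_uniform": ModelVariant("one_group", u, up),
        "full_uniform": ModelVariant("full_independent", u, up),
        "full_beta": ModelVariant("full_independent", beta, up),
        "flexible_uniform_uniform": ModelVariant("flexible", u, up),
        "flexible_uniform_beta": ModelVariant("flexible", beta, up),
        "flexible_dp_uniform": ModelVariant("flexible", u, dp),
        "flexible_dp_beta": ModelVariant("flexible", beta, dp),
        "compartmental_dp_beta": ModelVariant("compartmental", beta, dp),
    }


#: The eight model variants compared in the model-selection table.
VARIANTS: dict[str, ModelVariant] = _named_variants()


def hyper_log_prior(spec: LinkPriorSpec | PartitionPriorSpec) -> float:
    """Sum of Exp(mean 1) log densities over the spec's free hyperparameters."""
    if isinstance(spec, LinkPriorSpec):
        return -(spec.a + spec.b) if spec.free else 0.0
    if isinstance(spec, PartitionPriorSpec):
        return -spec.alpha if spec.free else 0.0
    raise TypeError(f"unsupported spec type {type(spec)!r}")


# ---------------------------------------------------------------------------
# compartmental parameterization
# ---------------------------------------------------------------------------

@dataclass
class LinkProbMatrix:
    """Explicit link probabilities for the compartment-constrained variant.

    Diagonal entries p_kk are free in (0, 1); each off-diagonal probability
    is p_kl = x_kl * min(p_kk, p_ll) with x_kl ~ Uniform(0, 1), which
    enforces p_kl < p_kk and p_kl < p_ll by construction.
    """

    p_diag: np.ndarray  # (K,)
    x: np.ndarray       # (K, K), diagonal ignored

    @property
    def K(self) -> int:
        return self.p_diag.size

    def full(self) -> np.ndarray:
        p = np.minimum.outer(self.p_diag, self.p_diag) * self.x
        np.fill_diagonal(p, self.p_diag)
        return p

    def satisfies_constraint(self) -> bool:
        p = self.full()
        d = self.p_diag
        off = ~np.eye(self.K, dtype=bool)
        return bool(
            np.all(p[off] < np.minimum.outer(d, d)[off]) if self.K > 1 else True
        )


def link_prob_log_prior(probs: LinkProbMatrix, a: float, b: float) -> float:
    """Log prior density of the compartmental parameters: p_kk ~ Beta(a, b)
    independently, x_kl ~ Uniform(0, 1) (zero log density)."""
    d = probs.p_diag
    if (d <= 0).any() or (d >= 1).any():
        return -math.inf
    off = ~np.eye(probs.K, dtype=bool)
    if probs.K > 1 and ((probs.x[off] < 0).any() or (probs.x[off] > 1).any()):
        return -math.inf
    return float(np.sum((a - 1) * np.log(d) + (b - 1) * np.log1p(-d) - betaln(a, b)))


# ---------------------------------------------------------------------------
# joint density and closed-form null evidences
# ---------------------------------------------------------------------------

def log_joint(
    web: FoodWeb,
    partition: Partition,
    variant: ModelVariant,
    *,
    alpha: float | None = None,
    a: float | None = None,
    b: float | None = None,
    probs: LinkProbMatrix | None = None,
    counts: BlockCounts | None = None,
) -> float:
    """Log joint density of (partition, hyperparameters[, probabilities], data).

    Collapsed variants take no explicit probabilities; the compartmental
    variant requires them and returns -inf (not an exception) when the
    between-group constraint is violated.
    """
    a = variant.link_prior.a if a is None else a
    b = variant.link_prior.b if b is None else b
    alpha = variant.partition_prior.alpha if alpha is None else alpha
    if counts is None:
        counts = block_counts(web, partition)

    lp = 0.0
    if not variant.fixed_partition:
        if variant.partition_prior.kind == "dirichlet_process":
            lp += crp_log_prior(partition, alpha)
            lp += -alpha  # Exp(1) hyperprior
        else:
            lp += uniform_partition_log_prior(web.S)
    if variant.link_prior.free:
        lp += -(a + b)  # Exp(1) hyperpriors on the beta shapes

    if variant.collapsed:
        if probs is not None:
            raise ValueError("collapsed variants take no explicit probabilities")
        return lp + collapsed_log_likelihood(counts, a, b)

    if probs is None:
        raise ValueError("compartmental variant requires explicit probabilities")
    prior_p = link_prob_log_prior(probs, a, b)
    if not math.isfinite(prior_p):
        return -math.inf
    return lp + prior_p + explicit_log_likelihood(counts, probs.full())


def closed_form_null_evidence(S: int, L: int, which: str) -> float:
    """Exact log marginal likelihood of the group-free null models.

    - ``one_group_uniform``: a single shared link probability with a uniform
      prior; evidence = ln B(L + 1, S^2 - L + 1).
    - ``full_uniform``: an independent Uniform(0,1) probability per ordered
      pair; every Bernoulli marginal is 1/2, so the evidence is -S^2 ln 2
      regardless of the data.
    - ``full_beta``: per-pair probabilities iid Beta(a, b) with a, b each
      Exp(1). Given (a, b) each link is present with probability
      m = a / (a + b), and for iid Exp(1) shapes m is Uniform(0, 1); all S^2
      trials share that single m, so the evidence collapses to the
      one-group uniform value ln B(L + 1, S^2 - L + 1).
    """
    if not 0 <= L <= S * S:
        raise ValueError("need 0 <= L <= S^2")
    if which in ("one_group_uniform", "full_beta"):
        return float(betaln(L + 1, S * S - L + 1))
    if which == "full_uniform":
        return -(S * S) * math.log(2.0)
    raise ValueError(f"unknown null model {which!r}")
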