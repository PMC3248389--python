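"""Habitat-signature statistics for inferred species groups.

A group's habitat signature is the Shannon entropy (natural log) of its
members' habitat labels: low entropy means the group is dominated by one
habitat. A partition's overall signature is the group-size-weighted mean of
the group entropies. Significance is assessed against size-preserving random
relabelings (overall clustering across posterior samples) and by the exact
hypergeometric tail (per-group overrepresentation of a single habitat).

Species whose habitat is "unassigned" are excluded from every statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .group_model import Partition
from .network_data import UNASSIGNED, SpeciesRecord
from .sampler import PosteriorSamples

__all__ = [
    "HabitatAssignment",
    "EntropyReport",
    "group_entropy",
    "weighted_entropy",
    "randomization_test_overall",
    "group_enrichment",
    "enrichment_table",
]

#: species_id -> habitat label (or "unassigned")
HabitatAssignment = dict


def habitats_from_species(species: list[SpeciesRecord]) -> HabitatAssignment:
    return {sp.species_id: sp.habitat_code for sp in species}


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n <= 1:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def group_entropy(members, habitats: HabitatAssignment) -> float:
    """Shannon entropy (nats) of habitat labels among a group's assigned
    members; 0 when at most one member carries a habitat."""
    if len(members) == 0:
        raise ValueError("group must be non-empty")
    labels = [habitats.get(m, UNASSIGNED) for m in members]
    labels = [h for h in labels if h != UNASSIGNED]
    if not labels:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    return _entropy(counts)


def weighted_entropy(partition: Partition, species_ids: list[str],
                     habitats: HabitatAssignment) -> float:
    """Group-size-weighted mean entropy, sum_g (n_g / n) H_g, where n_g and n
    count habitat-assigned species only."""
    total = 0.0
    n_assigned = 0
    for members_idx in partition.groups():
        members = [species_ids[i] for i in members_idx]
        labels = [habitats.get(m, UNASSIGNED) for m in members]
        labels = [h for h in labels if h != UNASSIGNED]
        if not labels:
            continue
        _, counts = np.unique(labels, return_counts=True)
        total += len(labels) * _entropy(counts)
        n_assigned += len(labels)
    return total / n_assigned if n_assigned else 0.0


@dataclass
class EntropyReport:
    """Observed vs randomized weighted entropy across posterior partitions."""

    mean_observed: float
    mean_randomized: float
    p_value: float
    per_sample_observed: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


def randomization_test_overall(
    samples: PosteriorSamples,
    habitats: HabitatAssignment,
    *,
    n_reps: int = 1,
    seed: int = 0,
) -> EntropyReport:
    """Randomization test of overall habitat clustering across the posterior.

    For every posterior partition the observed weighted entropy is compared
    with that of size-preserving random relabelings (species shuffled among
    groups of identical sizes). The p-value is the fraction of
    (sample, replicate) pairs in which the observed clustering fails to
    exceed the randomized one, i.e. observed entropy >= randomized entropy.
    """
    if n_reps < 1:
        raise ValueError("need at least one randomization replicate")
    rng = np.random.default_rng(seed)
    ids = samples.species_ids
    obs = np.empty(samples.n_samples)
    exceed_failures = 0
    rand_total = 0.0
    for s, part in enumerate(samples.partitions()):
        obs[s] = weighted_entropy(part, ids, habitats)
        for _ in range(n_reps):
            perm = rng.permutation(part.S)
            rand_part = Partition(part.labels[perm])
            h = weighted_entropy(rand_part, ids, habitats)
            rand_total += h
            if obs[s] >= h:
                exceed_failures += 1
    n_pairs = samples.n_samples * n_reps
    return EntropyReport(
        mean_observed=float(obs.mean()),
        mean_randomized=rand_total / n_pairs,
        p_value=exceed_failures / n_pairs,
        per_sample_observed=obs,
    )


def group_enrichment(members, habitat: str, habitats: HabitatAssignment,
                     universe) -> dict:
    """Exact hypergeometric overrepresentation of one habitat in one group.

    The null draws a uniformly random subset of the habitat-assigned
    universe with as many members as the group has assigned; the p-value is
    the upper tail P(X >= k) for the observed habitat count k. Reports the
    observed within-group fraction and the universe ("random expectation")
    fraction.
    """
    uni = [s for s in universe if habitats.get(s, UNASSIGNED) != UNASSIGNED]
    if habitat not in {habitats[s] for s in uni}:
        raise ValueError(f"habitat {habitat!r} absent from the universe")
    grp = [s for s in members if habitats.get(s, UNASSIGNED) != UNASSIGNED]
    M = len(uni)
    n_hab = sum(habitats[s] == habitat for s in uni)
    n_grp = len(grp)
    k = sum(habitats[s] == habitat for s in grp)
    p = float(hypergeom.sf(k - 1, M, n_hab, n_grp)) if n_grp else 1.0
    return {
        "observed": k / n_grp if n_grp else 0.0,
        "expected": n_hab / M,
        "count": k,
        "group_size": n_grp,
        "p_value": p,
    }


def enrichment_table(partition: Partition, species_ids: list[str],
                     habitats: HabitatAssignment) -> pd.DataFrame:
    """Per (group, habitat) overrepresentation report as a tidy table."""
    assigned = [s for s in species_ids if habitats.get(s, UNASSIGNED) != UNASSIGNED]
    habs = sorted({habitats[s] for s in assigned})
    rows = []
    for g, members_idx in enumerate(partition.groups()):
        members = [species_ids[i] for i in members_idx]
        if not any(habitats.get(m, UNASSIGNED) != UNASSIGNED for m in members):
            continue
        for h in habs:
            r = group_enrichment(members, h, habitats, species_ids)
            rows.append({"group": g, "habitat": h,
                         "observed_pct": 100 * r["observed"],
                         "expected_pct": 100 * r["expected"],
                         "p_value": r["p_value"]})
    return pd.DataFrame(rows)
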