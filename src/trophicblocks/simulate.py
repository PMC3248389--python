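"""Generative sampling from the group model.

Everything here runs the model forward: partitions from the Chinese
restaurant process, adjacency matrices from block link probabilities, and a
download-free synthetic food web at the scale of a well-resolved savanna
plant-mammal web (161 species, 592 links, connectance ~ 0.023) for fixtures
and end-to-end checks. The synthetic web is trophically layered - links run
herbivore -> plant and carnivore -> animal, concentrated in off-diagonal
blocks - rather than modular, matching the structure such webs actually
show.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .group_model import Partition
from .network_data import FoodWeb, SpeciesRecord

__all__ = [
    "PlantedWebSpec",
    "sample_partition_crp",
    "sample_web",
    "planted_web",
    "make_serengeti_like",
]


@dataclass(frozen=True)
class PlantedWebSpec:
    """Block sizes plus either a full p_kl matrix or (p_in, p_out)."""

    sizes: tuple[int, ...]
    p_in: float | None = None
    p_out: float | None = None
    P: tuple | None = None  # full K x K matrix overrides p_in/p_out

    def matrix(self) -> np.ndarray:
        K = len(self.sizes)
        if self.P is not None:
            P = np.asarray(self.P, dtype=float)
            if P.shape != (K, K):
                raise ValueError("P must be K x K")
        else:
            P = np.full((K, K), self.p_out, dtype=float)
            np.fill_diagonal(P, self.p_in)
        if (P < 0).any() or (P > 1).any():
            raise ValueError("link densities must lie in [0, 1]")
        return P


def sample_partition_crp(S: int, alpha: float, rng: np.random.Generator) -> Partition:
    """Sequential Chinese-restaurant draw of a partition of S species."""
    if S < 1 or alpha <= 0:
        raise ValueError("need S >= 1 and alpha > 0")
    labels = np.zeros(S, dtype=np.int64)
    sizes: list[int] = [1]
    u = rng.random(S)
    for i in range(1, S):
        # seat i at an occupied table w.p. n_k / (i + alpha), else a new one
        v = u[i] * (i + alpha)
        cum = 0.0
        g = len(sizes)
        for k, sz in enumerate(sizes):
            cum += sz
            if v < cum:
                g = k
                break
        if g == len(sizes):
            sizes.append(1)
        else:
            sizes[g] += 1
        labels[i] = g
    return Partition(labels)


def sample_web(
    partition: Partition,
    P: np.ndarray,
    rng: np.random.Generator,
    species: list[SpeciesRecord] | None = None,
) -> FoodWeb:
    """Draw each of the S^2 ordered pairs (self-pairs included)
    independently with its block probability p_{g(i) g(j)}."""
    P = np.asarray(P, dtype=float)
    if P.shape != (partition.K, partition.K):
        raise ValueError("probability matrix shape must match the group count")
    S = partition.S
    if species is None:
        species = [SpeciesRecord(species_id=f"sp{i:03d}") for i in range(S)]
    probs = P[np.ix_(partition.labels, partition.labels)]
    A = rng.uniform(size=(S, S)) < probs
    ids = [sp.species_id for sp in species]
    links = {(ids[i], ids[j]) for i, j in zip(*np.nonzero(A))}
    return FoodWeb(species=species, links=links)


def planted_web(spec: PlantedWebSpec, seed: int = 0) -> tuple[FoodWeb, Partition]:
    """A web with known block structure, plus the planted partition."""
    labels = np.repeat(np.arange(len(spec.sizes)), spec.sizes)
    partition = Partition(labels)
    rng = np.random.default_rng(seed)
    return sample_web(partition, spec.matrix(), rng), partition


# ---------------------------------------------------------------------------
# the savanna-scale synthetic fixture
# ---------------------------------------------------------------------------

_PLANT_BLOCKS = (40, 25, 20, 24, 20)          # 129 plants
_HERB_BLOCKS = (10, 8, 5)                     # 23 herbivores
_CARN_BLOCKS = (5, 4)                         # 9 carnivores
_PLANT_HABITATS = ("grassland", "woodland", "riparian", "kopje", "shrubland")
_N_HERBIVORY = 507
_N_PREDATION = 85
_HABITAT_FIDELITY = 0.8


def make_serengeti_like(seed: int = 0) -> tuple[FoodWeb, Partition, dict]:
    """Synthetic savanna food web: 161 species (129 plants, 23 herbivores,
    9 carnivores), exactly 507 herbivorous and 85 predatory links (592 in
    all, connectance 592/161^2 ~ 0.0228).

    Links are placed by weighted sampling without replacement over the
    allowed consumer -> resource pairs, with weights concentrated on
    designated herbivore-block -> plant-block and carnivore-block ->
    herbivore-block pairs, so the planted structure is off-diagonal
    (trophically layered). Plant habitat labels follow the plant block with
    80% fidelity. Returns (web, planted partition, habitat assignment).
    """
    rng = np.random.default_rng(seed)
    species: list[SpeciesRecord] = []
    labels: list[int] = []
    habitats: dict[str, str] = {}
    block = 0
    n_plant = n_herb = n_carn = 0
    for bsize, hab in zip(_PLANT_BLOCKS, _PLANT_HABITATS):
        for _ in range(bsize):
            n_plant += 1
            sid = f"p{n_plant:03d}"
            h = hab if rng.uniform() < _HABITAT_FIDELITY else \
                _PLANT_HABITATS[rng.integers(len(_PLANT_HABITATS))]
            species.append(SpeciesRecord(sid, name=f"Planta {sid}", trophic_role="plant",
                                         habitat_code=h))
            habitats[sid] = h
            labels.append(block)
        block += 1
    for bsize in _HERB_BLOCKS:
        for _ in range(bsize):
            n_herb += 1
            sid = f"h{n_herb:02d}"
            species.append(SpeciesRecord(sid, name=f"Herbivora {sid}", trophic_role="herbivore"))
            habitats[sid] = "unassigned"
            labels.append(block)
        block += 1
    for bsize in _CARN_BLOCKS:
        for _ in range(bsize):
            n_carn += 1
            sid = f"c{n_carn:02d}"
            species.append(SpeciesRecord(sid, name=f"Carnivora {sid}", trophic_role="carnivore"))
            habitats[sid] = "unassigned"
            labels.append(block)
        block += 1
    partition = Partition(np.asarray(labels))
    ids = [sp.species_id for sp in species]
    lab = partition.labels

    # block-pair weights: each herbivore block grazes two designated plant
    # blocks heavily, everything else lightly; carnivore block 8 hunts the
    # large-herbivore blocks, block 9 the smaller ones
    W = np.zeros((10, 10))
    heavy = 30.0
    light = 1.0
    herb_diet = {5: (0, 1), 6: (2, 3), 7: (3, 4)}
    for hb, plants in herb_diet.items():
        W[hb, 0:5] = light
        for pb in plants:
            W[hb, pb] = heavy
    carn_diet = {8: (5, 6), 9: (6, 7)}
    for cb, herbs in carn_diet.items():
        W[cb, 5:8] = light
        for hbb in herbs:
            W[cb, hbb] = heavy
    W[8, 8] = 0.5  # a little intraguild predation in the big-carnivore block

    pair_w = W[np.ix_(lab, lab)].astype(float)
    np.fill_diagonal(pair_w, 0.0)  # no self-links in the fixture
    idx = np.arange(len(ids))
    is_plant = idx < 129
    is_herb = (idx >= 129) & (idx < 152)
    is_carn = idx >= 152

    links: set[tuple[str, str]] = set()
    for mask_c, mask_r, n_links in (
        (is_herb, is_plant, _N_HERBIVORY),
        (is_carn, ~is_plant, _N_PREDATION),
    ):
        w = pair_w.copy()
        w[~mask_c, :] = 0.0
        w[:, ~mask_r] = 0.0
        flat = w.ravel()
        pos = np.flatnonzero(flat > 0)
        if pos.size < n_links:
            raise RuntimeError("not enough admissible pairs for the requested link count")
        chosen = rng.choice(pos, size=n_links, replace=False, p=flat[pos] / flat[pos].sum())
        for f in chosen:
            links.add((ids[f // len(ids)], ids[f % len(ids)]))
    return FoodWeb(species=species, links=links), partition, habitats
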