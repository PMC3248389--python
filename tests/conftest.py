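"""Shared fixtures: tiny hand-checkable webs and the synthetic savanna web."""

from __future__ import annotations

import numpy as np
import pytest

from trophicblocks import FoodWeb, SpeciesRecord, make_serengeti_like


@pytest.fixture
def toy4_web() -> FoodWeb:
    """Four species, five links (one a self-link); small enough to enumerate
    all 15 partitions."""
    species = [SpeciesRecord(f"s{i}") for i in range(4)]
    links = {("s0", "s1"), ("s2", "s1"), ("s3", "s0"), ("s1", "s1"), ("s2", "s3")}
    return FoodWeb(species=species, links=links)


@pytest.fixture
def toy3_web() -> FoodWeb:
    """Three species forming a feeding triangle."""
    species = [SpeciesRecord(f"s{i}") for i in range(3)]
    return FoodWeb(species=species, links={("s0", "s1"), ("s1", "s2"), ("s0", "s2")})


@pytest.fixture
def tiny_role_web() -> FoodWeb:
    """Two herbivores eating one plant, with roles attached."""
    species = [
        SpeciesRecord("grass", trophic_role="plant"),
        SpeciesRecord("gazelle", trophic_role="herbivore"),
        SpeciesRecord("zebra", trophic_role="herbivore"),
    ]
    return FoodWeb(species=species,
                   links={("gazelle", "grass"), ("zebra", "grass")})


@pytest.fixture(scope="session")
def savanna():
    """The 161-species synthetic savanna web (fixed seed), with its planted
    partition and habitat assignment."""
    return make_serengeti_like(seed=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
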