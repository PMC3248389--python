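"""Data model and I/O for directed food webs and species metadata.

A food web is a directed network of consumer -> resource feeding links.
The link universe is all S^2 ordered species pairs, self-pairs included,
so that every likelihood in the block model is a product of exactly S^2
Bernoulli terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

TROPHIC_ROLES = frozenset({"plant", "herbivore", "carnivore"})
HABITAT_CODES = frozenset(
    {"grassland", "woodland", "riparian", "kopje", "shrubland", "thicket", "disturbed"}
)
UNASSIGNED = "unassigned"


class FoodWebError(ValueError):
    """Raised on malformed species or link tables."""


@dataclass(frozen=True)
class SpeciesRecord:
    """One species: stable id, Latin binomial, trophic role, habitat label.

    ``trophic_role`` and ``habitat_code`` are drawn from closed vocabularies;
    anything else is normalised to ``"unassigned"`` at read time.
    """

    species_id: str
    name: str = ""
    trophic_role: str = UNASSIGNED
    habitat_code: str = UNASSIGNED


@dataclass
class FoodWeb:
    """Directed feeding network over an ordered species list.

    ``links`` holds ordered (consumer_id, resource_id) pairs. ``S`` and ``L``
    are the species and link counts that enter every likelihood.
    """

    species: list[SpeciesRecord]
    links: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [sp.species_id for sp in self.species]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FoodWebError(f"duplicate species_id values: {dup}")
        known = set(ids)
        for c, r in self.links:
            if c not in known or r not in known:
                raise FoodWebError(f"link ({c!r}, {r!r}) references unknown species")

    @property
    def S(self) -> int:
        return len(self.species)

    @property
    def L(self) -> int:
        return len(self.links)

    @property
    def species_ids(self) -> list[str]:
        return [sp.species_id for sp in self.species]

    def index_of(self) -> dict[str, int]:
        return {sp.species_id: i for i, sp in enumerate(self.species)}

    def adjacency(self):
        """S x S boolean matrix; entry (i, j) True when species i eats j."""
        import numpy as np

        idx = self.index_of()
        A = np.zeros((self.S, self.S), dtype=bool)
        for c, r in self.links:
            A[idx[c], idx[r]] = True
        return A


def _normalise_vocab(value: object, vocab: frozenset[str], what: str, sid: str) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return UNASSIGNED
    text = str(value).strip().lower()
    if text in ("", UNASSIGNED, "na", "nan", "none"):
        return UNASSIGNED
    if text not in vocab:
        warnings.warn(
            f"unknown {what} {text!r} for species {sid!r}; storing as 'unassigned'",
            stacklevel=3,
        )
        return UNASSIGNED
    return text


def read_species_table(
    path,
    *,
    id_col: str = "species_id",
    name_col: str = "name",
    role_col: str = "trophic_role",
    habitat_col: str = "habitat",
) -> list[SpeciesRecord]:
    """Read a delimited species table into :class:`SpeciesRecord` rows.

    The table must contain the id column; name, trophic role and habitat
    columns are optional and configurable to tolerate dialect differences.
    Unknown role/habitat values are warned about and stored as
    ``"unassigned"``. Duplicate ids are an error.
    """
    df = pd.read_csv(path)
    if id_col not in df.columns:
        raise FoodWebError(f"species table missing required column {id_col!r}")
    ids = df[id_col].astype(str).str.strip()
    if ids.duplicated().any():
        dup = sorted(ids[ids.duplicated()].unique())
        raise FoodWebError(f"duplicate species_id values: {dup}")
    records = []
    for _, row in df.iterrows():
        sid = str(row[id_col]).strip()
        records.append(
            SpeciesRecord(
                species_id=sid,
                name=str(row[name_col]).strip() if name_col in df.columns else "",
                trophic_role=_normalise_vocab(
                    row.get(role_col), TROPHIC_ROLES, "trophic role", sid
                ),
                habitat_code=_normalise_vocab(
                    row.get(habitat_col), HABITAT_CODES, "habitat", sid
                ),
            )
        )
    return records


def read_link_table(
    path,
    species: list[SpeciesRecord],
    *,
    consumer_col: str = "consumer_id",
    resource_col: str = "resource_id",
) -> FoodWeb:
    """Read a consumer -> resource link table against a loaded species list.

    Every row is one directed link. Links naming unknown species and
    duplicated rows are data-integrity errors (links are binary; a repeat
    indicates a corrupted table, so it is never silently merged).
    """
    df = pd.read_csv(path)
    for col in (consumer_col, resource_col):
        if col not in df.columns:
            raise FoodWebError(f"link table missing required column {col!r}")
    pairs = list(
        zip(df[consumer_col].astype(str).str.strip(), df[resource_col].astype(str).str.strip())
    )
    if len(set(pairs)) != len(pairs):
        seen: set[tuple[str, str]] = set()
        dup = [p for p in pairs if p in seen or seen.add(p)]
        raise FoodWebError(f"duplicated link rows: {sorted(set(dup))}")
    return FoodWeb(species=species, links=set(pairs))


def write_species_table(species: list[SpeciesRecord], path) -> None:
    pd.DataFrame(
        {
            "species_id": [s.species_id for s in species],
            "name": [s.name for s in species],
            "trophic_role": [s.trophic_role for s in species],
            "habitat": [s.habitat_code for s in species],
        }
    ).to_csv(path, index=False)


def write_link_table(web: FoodWeb, path) -> None:
    # deterministic order: by species position, consumer-major
    idx = web.index_of()
    links = sorted(web.links, key=lambda cr: (idx[cr[0]], idx[cr[1]]))
    pd.DataFrame(links, columns=["consumer_id", "resource_id"]).to_csv(path, index=False)


def connectance(web: FoodWeb) -> float:
    """Realized fraction of the S^2 ordered pairs (self-pairs included)."""
    if web.S < 1:
        raise FoodWebError("connectance undefined for an empty species list")
    return web.L / web.S**2


def links_by_consumer_role(web: FoodWeb, species: list[SpeciesRecord] | None = None) -> dict[str, int]:
    """Count links by the consumer's trophic role.

    Herbivore-consumer links are the web's herbivorous links; carnivore-consumer
    links its predatory links. A link whose consumer is a plant is flagged as a
    data inconsistency (warning) but still counted under "plant".
    """
    if species is None:
        species = web.species
    role = {sp.species_id: sp.trophic_role for sp in species}
    counts: dict[str, int] = {}
    for consumer, _ in web.links:
        r = role.get(consumer, UNASSIGNED)
        if r == "plant":
            warnings.warn(f"link with plant consumer {consumer!r}", stacklevel=2)
        counts[r] = counts.get(r, 0) + 1
    return counts
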