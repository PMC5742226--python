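"""Domain types, readers, and site-retention filters.

The central object is the :class:`IncidenceMatrix`, a binary site × species
presence/absence table built from collated floristic surveys.  Sites carry
metadata (substrate, vegetation physiognomy, disturbance) from which a
habitat class — forest/open crossed with canga/quartzite — is derived, and
the filters here reduce a raw compilation to the analysis matrix: sites with
unknown substrate or physiognomy, disturbed sites, and limestone sites are
excluded, after which species left with no occurrences are dropped.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Substrate",
    "Physiognomy",
    "HabitatClass",
    "TaxonName",
    "SiteRecord",
    "IncidenceMatrix",
    "DatasetSummary",
    "sanitize_label",
    "read_incidence",
    "read_metadata",
    "apply_site_filters",
    "drop_taxa",
    "summarize",
]


class Substrate(str, Enum):
    CANGA = "canga"
    QUARTZITE = "quartzite"
    LIMESTONE = "limestone"
    UNKNOWN = "unknown"


class Physiognomy(str, Enum):
    OPEN = "open"
    FOREST = "forest"
    UNKNOWN = "unknown"


class HabitatClass(str, Enum):
    """Substrate × physiognomy combination.

    FC = forest on canga, FQ = forest on quartzite, OC = open vegetation on
    canga, OQ = open vegetation on quartzite.
    """

    FC = "FC"
    FQ = "FQ"
    OC = "OC"
    OQ = "OQ"


_HABITAT_TABLE = {
    (Physiognomy.FOREST, Substrate.CANGA): HabitatClass.FC,
    (Physiognomy.FOREST, Substrate.QUARTZITE): HabitatClass.FQ,
    (Physiognomy.OPEN, Substrate.CANGA): HabitatClass.OC,
    (Physiognomy.OPEN, Substrate.QUARTZITE): HabitatClass.OQ,
}


def sanitize_label(name: str) -> str:
    """Sanitize a species name into a matrix/tree-safe label.

    Lowercase; whitespace → ``_``; ``-`` → ``.`` (composite epithets such as
    *Dolichandra unguis-cati* become ``dolichandra_unguis.cati``); tokens
    below the species epithet (infraspecific ranks, e.g. ``var. minor``) are
    stripped, so infraspecifics are treated at species level.
    """
    name = name.strip().lower()
    # cut at infraspecific rank markers
    name = re.split(r"\s+(?:var\.|subsp\.|ssp\.|f\.|forma)\s+", name)[0]
    tokens = name.split()
    if len(tokens) > 2:
        tokens = tokens[:2]
    label = "_".join(tokens)
    label = label.replace("-", ".")
    if not label:
        raise ValueError(f"species name {name!r} sanitizes to an empty label")
    return label


@dataclass(frozen=True)
class TaxonName:
    """Sanitized species identifier with its genus and family."""

    label: str
    genus: str
    family: str = ""

    def __post_init__(self):
        if not self.label or " " in self.label or "-" in self.label:
            raise ValueError(f"invalid taxon label {self.label!r}")

    @classmethod
    def from_raw(cls, name: str, family: str = "") -> "TaxonName":
        label = sanitize_label(name)
        return cls(label=label, genus=label.split("_")[0], family=family.strip().lower())


@dataclass(frozen=True)
class SiteRecord:
    site_id: str
    location_code: str = ""
    substrate: Substrate = Substrate.UNKNOWN
    physiognomy: Physiognomy = Physiognomy.UNKNOWN
    disturbed: bool = False

    @property
    def habitat(self) -> HabitatClass | None:
        """Habitat class, derivable only for canga/quartzite × open/forest."""
        return _HABITAT_TABLE.get((self.physiognomy, self.substrate))


@dataclass
class IncidenceMatrix:
    """Binary site × species occurrence table.

    ``values`` has shape (n_sites, n_species), entries in {0, 1}.  Species
    labels are sanitized.  After construction through the public readers and
    filters, no species column is all-zero.
    """

    sites: list[str]
    species: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.sites), len(self.species)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sites)} sites × {len(self.species)} species"
            )
        for axis, labels in (("site", self.sites), ("species", self.species)):
            dupes = pd.Index(labels)[pd.Index(labels).duplicated()].unique().tolist()
            if dupes:
                raise ValueError(f"duplicate {axis} labels: {dupes}")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary cell at site {self.sites[i]!r}, species "
                f"{self.species[j]!r}: {self.values[i, j]}"
            )

    # -- convenience ------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_records(self) -> int:
        return int(self.values.sum())

    def richness(self) -> pd.Series:
        """Species count per site."""
        return pd.Series(self.values.sum(axis=1), index=self.sites, name="richness")

    def site_community(self, site_id: str) -> list[str]:
        """Species present at one site."""
        i = self.sites.index(site_id)
        return [s for s, v in zip(self.species, self.values[i]) if v]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sites, columns=self.species)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IncidenceMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)),
                   df.to_numpy())

    def write(self, path: str | Path) -> None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        self.to_frame().rename_axis("site_id").to_csv(path, sep=sep)


@dataclass(frozen=True)
class DatasetSummary:
    n_sites: int
    n_species: int
    n_genera: int
    n_families: int
    n_records: int
    richness_min: int
    richness_max: int
    richness_mean: float

    @property
    def richness_mean_rounded(self) -> int:
        return round(self.richness_mean)


# ---------------------------------------------------------------------------
# Readers


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_incidence(path: str | Path, orientation: str = "sites_by_species") -> IncidenceMatrix:
    """Read a delimited presence/absence table.

    By default sites are rows and species columns, with the first column
    holding site ids; ``orientation="species_by_sites"`` accepts the
    transpose.  Species labels are sanitized.  Abundance-like values are
    binarized (any value > 0 → 1) with a warning.
    """
    if orientation not in ("sites_by_species", "species_by_sites"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if orientation == "species_by_sites":
        df = df.T
    sites = [str(s) for s in df.index]
    raw_species = [str(s) for s in df.columns]
    species = [sanitize_label(s) for s in raw_species]
    collisions = pd.Index(species)[pd.Index(species).duplicated()].unique().tolist()
    if collisions:
        raise ValueError(f"species labels collide after sanitization: {collisions}")
    vals = df.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        neg = vals < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValueError(
                f"negative cell at site {sites[i]!r}, species {raw_species[j]!r}"
            )
        warnings.warn("abundance-like values found; binarizing (value > 0 -> 1)")
        vals = (vals > 0).astype(np.int8)
    return IncidenceMatrix(sites, species, vals)


def read_metadata(path: str | Path) -> list[SiteRecord]:
    """Read site metadata (columns: site_id, location, substrate, physiognomy, disturbed)."""
    df = pd.read_csv(path, sep=_sep_for(path))
    records = []
    for _, row in df.iterrows():
        records.append(
            SiteRecord(
                site_id=str(row["site_id"]),
                location_code=str(row.get("location", "")),
                substrate=Substrate(str(row["substrate"]).strip().lower()),
                physiognomy=Physiognomy(str(row["physiognomy"]).strip().lower()),
                disturbed=str(row["disturbed"]).strip().lower() in ("1", "true", "yes"),
            )
        )
    return records


def write_metadata(records: Sequence[SiteRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "site_id": [r.site_id for r in records],
            "location": [r.location_code for r in records],
            "substrate": [r.substrate.value for r in records],
            "physiognomy": [r.physiognomy.value for r in records],
            "disturbed": [r.disturbed for r in records],
        }
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# Filters


def apply_site_filters(
    matrix: IncidenceMatrix, meta: Sequence[SiteRecord]
) -> tuple[IncidenceMatrix, list[SiteRecord]]:
    """Retain only analyzable sites.

    Removes sites with unknown substrate or physiognomy, disturbed sites, and
    limestone sites; then drops species left with zero occurrences.
    Idempotent.  Every matrix site must have a metadata record.
    """
    by_id = {r.site_id: r for r in meta}
    missing = [s for s in matrix.sites if s not in by_id]
    if missing:
        raise ValueError(f"sites without metadata: {missing}")

    def keep(r: SiteRecord) -> bool:
        return (
            r.substrate in (Substrate.CANGA, Substrate.QUARTZITE)
            and r.physiognomy in (Physiognomy.OPEN, Physiognomy.FOREST)
            and not r.disturbed
        )

    kept_sites = [s for s in matrix.sites if keep(by_id[s])]
    removed = sorted(set(matrix.sites) - set(kept_sites))
    if removed:
        logger.info("site filters removed %d sites: %s", len(removed), removed)
    row_idx = [matrix.sites.index(s) for s in kept_sites]
    vals = matrix.values[row_idx]
    col_keep = vals.sum(axis=0) > 0
    dropped = [sp for sp, k in zip(matrix.species, col_keep) if not k]
    if dropped:
        logger.info("dropped %d species with no remaining occurrences", len(dropped))
    out = IncidenceMatrix(
        kept_sites,
        [sp for sp, k in zip(matrix.species, col_keep) if k],
        vals[:, col_keep],
    )
    return out, [by_id[s] for s in kept_sites]


def drop_taxa(matrix: IncidenceMatrix, labels: Iterable[str]) -> IncidenceMatrix:
    """Remove named species from the matrix (absent labels are logged no-ops).

    A site emptied by the removal is retained with richness 0 and a warning,
    so downstream guards can act on it explicitly.
    """
    drop = {sanitize_label(l) for l in labels}
    absent = drop - set(matrix.species)
    for l in sorted(absent):
        logger.info("drop_taxa: label %r not in matrix (no-op)", l)
    keep = [i for i, sp in enumerate(matrix.species) if sp not in drop]
    out = IncidenceMatrix(
        list(matrix.sites), [matrix.species[i] for i in keep], matrix.values[:, keep]
    )
    empty = [s for s, r in zip(out.sites, out.values.sum(axis=1)) if r == 0]
    if empty:
        warnings.warn(f"sites emptied by drop_taxa: {empty}")
    return out


def summarize(
    matrix: IncidenceMatrix, taxonomy: Sequence[TaxonName] | Mapping[str, TaxonName] | None = None
) -> DatasetSummary:
    """Dataset-level counts: sites, species, genera, families, records, richness.

    Genus is the first token of the sanitized label when no taxonomy is given;
    families come from the taxonomy mapping (unmapped species are logged and
    excluded from the family tally, never fatal).
    """
    if taxonomy is None:
        tax_map: dict[str, TaxonName] = {}
    elif isinstance(taxonomy, Mapping):
        tax_map = dict(taxonomy)
    else:
        tax_map = {t.label: t for t in taxonomy}

    genera, families, unmapped = set(), set(), []
    for sp in matrix.species:
        t = tax_map.get(sp)
        genera.add(t.genus if t else sp.split("_")[0])
        if t and t.family:
            families.add(t.family)
        elif taxonomy is not None:
            unmapped.append(sp)
    if unmapped:
        logger.info("%d species without family mapping: %s", len(unmapped), unmapped[:10])

    rich = matrix.richness().to_numpy()
    return DatasetSummary(
        n_sites=matrix.n_sites,
        n_species=matrix.n_species,
        n_genera=len(genera),
        n_families=len(families),
        n_records=matrix.n_records,
        richness_min=int(rich.min()) if len(rich) else 0,
        richness_max=int(rich.max()) if len(rich) else 0,
        richness_mean=float(rich.mean()) if len(rich) else 0.0,
    )
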