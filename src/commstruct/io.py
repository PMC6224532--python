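"""Readers, writers and validated core data structures.

The analysis operates on four linked inputs: a rooted, branch-length-bearing
phylogeny; a binary site x species incidence matrix; a species trait table
(log10 body mass plus a 10-state lifestyle category); and per-site metadata
(coordinates, biome label, bioclim covariates).  This module loads each from
plain text, validates the invariants the downstream statistics rely on, and
defines the species-pool construction used by the null models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("commstruct")

#: The fixed lifestyle vocabulary.  Intermediate states (e.g.
#: "terrestrial/arboreal") are full categories of their own, at categorical
#: distance 1 from both parent states.
LIFESTYLES = (
    "fossorial",
    "terrestrial",
    "saxicolous",
    "arboreal",
    "generalist",
    "terrestrial/arboreal",
    "terrestrial/saxicolous",
    "terrestrial/fossorial",
    "saxicolous/arboreal",
    "terrestrial/aquatic",
)

#: Bioclim covariates carried in site metadata.
CLIMATE_VARS = ("Bio1", "Bio4", "Bio12", "Bio14", "Bio15")


class ValidationError(ValueError):
    """An input violates a structural invariant."""


@dataclass
class PhyloTree:
    """A rooted phylogeny with branch lengths in arbitrary time units.

    Wraps a :class:`dendropy.Tree`; tip labels must be unique, branch
    lengths nonnegative, and there must be at least two tips.  Polytomies
    are allowed (grafted clades commonly produce them).
    """

    tree: dendropy.Tree
    tip_labels: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(labels) < 2:
            raise ValidationError("tree must have at least 2 tips")
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise ValidationError(f"duplicate tip labels: {sorted(dupes)}")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError(
                    f"negative branch length {edge.length} on edge to "
                    f"{edge.head_node}"
                )
        self.tip_labels = tuple(labels)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def total_branch_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self.tree.preorder_edge_iter()
        )

    def pruned_to(self, species: list[str]) -> "PhyloTree":
        """Return a copy pruned to ``species`` (patristic distances among
        retained tips are unchanged by pruning)."""
        missing = sorted(set(species) - set(self.tip_labels))
        if missing:
            raise ValidationError(f"species not in tree: {missing}")
        clone = self.tree.clone(depth=1)
        keep = set(species)
        taxa = [t for t in clone.taxon_namespace if t.label in keep]
        clone.retain_taxa(taxa)
        return PhyloTree(clone)

    def write_newick(self, path) -> None:
        self.tree.write(path=str(path), schema="newick",
                        suppress_rooting=True)


def read_newick(path) -> PhyloTree:
    """Parse a newick file into a validated :class:`PhyloTree`.

    Malformed newick raises dendropy's parse error (which names the
    position); duplicate tip labels raise :class:`ValidationError`.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        if "DuplicateTaxon" in type(exc).__name__:
            raise ValidationError(f"duplicate tip label: {exc}") from exc
        raise
    return PhyloTree(tree)


def tree_from_string(newick: str) -> PhyloTree:
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        if "DuplicateTaxon" in type(exc).__name__:
            raise ValidationError(f"duplicate tip label: {exc}") from exc
        raise
    return PhyloTree(tree)


@dataclass
class CommunityMatrix:
    """Binary site x species incidence.

    Every species occurs in >= 1 site (all-zero columns are dropped at read
    time with a warning).  Sites with richness < 2 are retained — richness
    regressions still use them — but flagged in :attr:`low_richness_sites`
    and excluded from SES computation, where mean pairwise distance is
    undefined.
    """

    sites: list[str]
    species: list[str]
    incidence: np.ndarray  # (n_sites, n_species) of 0/1

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence)
        if self.incidence.shape != (len(self.sites), len(self.species)):
            raise ValidationError("incidence shape does not match labels")
        vals = np.unique(self.incidence)
        if not np.isin(vals, [0, 1]).all():
            bad = [v for v in vals if v not in (0, 1)]
            raise ValidationError(f"non-binary incidence values: {bad}")
        self.incidence = self.incidence.astype(np.int8)
        if len(set(self.sites)) != len(self.sites):
            raise ValidationError("duplicate site ids")
        if len(set(self.species)) != len(self.species):
            raise ValidationError("duplicate species ids")
        if self.n_species and (self.incidence.sum(axis=0) == 0).any():
            empty = [s for s, tot in zip(self.species,
                                         self.incidence.sum(axis=0))
                     if tot == 0]
            raise ValidationError(
                f"species occurring nowhere: {empty}; drop before construction"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def richness(self) -> pd.Series:
        return pd.Series(self.incidence.sum(axis=1), index=self.sites,
                         name="richness")

    @property
    def low_richness_sites(self) -> list[str]:
        r = self.incidence.sum(axis=1)
        return [s for s, k in zip(self.sites, r) if k < 2]

    def members(self, site: str) -> set[str]:
        i = self.sites.index(site)
        row = self.incidence[i]
        return {sp for sp, v in zip(self.species, row) if v}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.incidence, index=pd.Index(self.sites, name="site"),
                            columns=self.species)

    def subset_species(self, keep: list[str]) -> "CommunityMatrix":
        """Restrict to ``keep`` (e.g. lizards only), dropping species not
        listed and any species left with zero occurrences."""
        keep_set = set(keep)
        cols = [j for j, sp in enumerate(self.species) if sp in keep_set]
        inc = self.incidence[:, cols]
        spp = [self.species[j] for j in cols]
        occ = inc.sum(axis=0) > 0
        return CommunityMatrix(list(self.sites),
                               [s for s, o in zip(spp, occ) if o],
                               inc[:, occ])


def read_community(path) -> CommunityMatrix:
    """Read a site x species table (wide 0/1, or long ``site,species`` pairs).

    Delimiter (comma/tab) is autodetected.  All-zero species columns are
    dropped with a logged warning; non-binary cells are a validation error.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.shape[1] == 1 and not set(pd.unique(df.iloc[:, 0].values)) <= {0, 1}:
        # long format: first column site, second species
        long = pd.read_csv(path, sep=None, engine="python")
        long.columns = ["site", "species"]
        df = pd.crosstab(long["site"], long["species"]).clip(upper=1)
    vals = df.to_numpy()
    if not np.isin(np.unique(vals), [0, 1]).all():
        bad = sorted(set(np.unique(vals)) - {0, 1})
        raise ValidationError(f"non-binary incidence values: {bad}")
    empty = df.columns[(vals.sum(axis=0) == 0)]
    if len(empty):
        logger.warning("dropping %d species absent from every site: %s",
                       len(empty), list(empty))
        df = df.drop(columns=empty)
    cm = CommunityMatrix([str(s) for s in df.index],
                         [str(s) for s in df.columns], df.to_numpy())
    if cm.low_richness_sites:
        logger.warning("richness-1 sites flagged (excluded from SES): %s",
                       cm.low_richness_sites)
    return cm


def write_community(cm: CommunityMatrix, path) -> None:
    cm.to_frame().to_csv(path)


@dataclass
class TraitTable:
    """Species traits: log10 body mass (grams) and lifestyle category.

    ``body_size`` must be finite for all species; ``lifestyle`` may be
    missing (NaN) and is otherwise restricted to :data:`LIFESTYLES`.
    """

    data: pd.DataFrame  # index species; columns body_size, lifestyle

    def __post_init__(self) -> None:
        need = {"body_size", "lifestyle"}
        if not need <= set(self.data.columns):
            raise ValidationError(f"trait table needs columns {sorted(need)}")
        if not np.isfinite(self.data["body_size"].to_numpy(float)).all():
            raise ValidationError("body_size must be finite for every species")
        ls = self.data["lifestyle"]
        bad = set(ls.dropna()) - set(LIFESTYLES)
        if bad:
            raise ValidationError(f"unknown lifestyle categories: {sorted(bad)}")
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate species in trait table")

    @property
    def species(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def body_size(self, species: list[str]) -> np.ndarray:
        return self.data.loc[species, "body_size"].to_numpy(float)

    def lifestyle(self, species: list[str]) -> pd.Series:
        return self.data.loc[species, "lifestyle"]


def read_traits(path) -> TraitTable:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df["lifestyle"] = df["lifestyle"].replace({"": np.nan, "NA": np.nan})
    return TraitTable(df)


def write_traits(tt: TraitTable, path) -> None:
    tt.data.to_csv(path)


@dataclass
class SiteMetadata:
    """Per-site coordinates, biome label and bioclim covariates."""

    data: pd.DataFrame  # index site; lon, lat, biome, Bio1..Bio15

    def __post_init__(self) -> None:
        need = {"lon", "lat", "biome", *CLIMATE_VARS}
        missing = need - set(self.data.columns)
        if missing:
            raise ValidationError(f"metadata missing columns {sorted(missing)}")
        lon = self.data["lon"].to_numpy(float)
        lat = self.data["lat"].to_numpy(float)
        if ((lon < -180) | (lon > 180)).any():
            raise ValidationError("lon outside [-180, 180]")
        if ((lat < -90) | (lat > 90)).any():
            raise ValidationError("lat outside [-90, 90]")
        if self.data["biome"].isna().any() or (self.data["biome"] == "").any():
            raise ValidationError("every site needs a biome label")
        clim = self.data[list(CLIMATE_VARS)].to_numpy(float)
        if not np.isfinite(clim).all():
            raise ValidationError("climate values must be finite")

    @property
    def sites(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def biomes(self) -> pd.Series:
        return self.data["biome"]

    def coords(self) -> np.ndarray:
        return self.data[["lon", "lat"]].to_numpy(float)

    def climate(self) -> pd.DataFrame:
        return self.data[list(CLIMATE_VARS)].astype(float)


def read_metadata(path) -> SiteMetadata:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.map(str)
    return SiteMetadata(df)


def write_metadata(meta: SiteMetadata, path) -> None:
    meta.data.to_csv(path)


@dataclass(frozen=True)
class SpeciesPool:
    """A named species pool from which null assemblages are drawn."""

    label: str
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


def build_pools(cm: CommunityMatrix, meta: SiteMetadata,
                min_sites_per_biome: int = 3) -> list[SpeciesPool]:
    """Continental pool plus one pool per biome with enough localities.

    The continental pool is the union of all species; each biome pool is the
    union of that biome's site assemblages.  Biomes with fewer than
    ``min_sites_per_biome`` sites are excluded (and logged) — with one or
    two localities a biome pool is too thin to define a meaningful null.
    """
    pools = [SpeciesPool("continental", frozenset(cm.species))]
    biomes = meta.biomes
    counts = biomes.value_counts()
    excluded = []
    frame = cm.to_frame()
    for biome in counts.index:
        if counts[biome] < min_sites_per_biome:
            excluded.append((biome, int(counts[biome])))
            continue
        sites = [s for s in cm.sites if biomes.get(s) == biome]
        sub = frame.loc[sites]
        members = frozenset(sub.columns[(sub.to_numpy().sum(axis=0) > 0)])
        pools.append(SpeciesPool(str(biome), members))
    if excluded:
        logger.info("biomes excluded from biome-pool analysis (<%d sites): %s",
                    min_sites_per_biome, excluded)
    return pools
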