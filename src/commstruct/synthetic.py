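"""Synthetic worlds with known assembly processes.

Generates everything the pipeline consumes — a Yule phylogeny, Brownian
body sizes, Mk lifestyle states, an aridity-driven climate gradient with
biome bands, and site assemblages built under a known rule — so that every
stage of the analysis can be exercised and calibrated without any external
download.  The default scenario mirrors the scale of a continental squamate
survey: 92 sites, 904 species, six biomes with uneven site counts
(2/21/7/1/30/31), and five bioclim covariates that are monotone functions
of a latent aridity axis.

Assembly rules
--------------
``neutral``
    uniform draw of k species without replacement — the type-I calibration
    condition.
``filtering``
    environmental filtering: inclusion weight
    exp(-(z_i - mu_s)^2 / (2 sigma_f^2)) on log10 body mass, with the site
    optimum mu_s tracking the humidity gradient (larger bodies in humid
    sites).  Small sigma_f -> strong functional clustering; sigma_f -> inf
    recovers the neutral rule.
``limiting_similarity``
    a stylised competition model: a random first member, then greedily add
    the species maximising its minimum Gower distance to the current
    members — functional overdispersion.
``mixed``
    the stress-dominance layout: filtering in arid biomes, limiting
    similarity in humid biomes, with humid assemblages additionally drawn
    from a single large clade (so humid sites are phylogenetically
    clustered while functionally overdispersed).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath

from .io import (CommunityMatrix, PhyloTree, SiteMetadata, TraitTable,
                 LIFESTYLES)
from .distances import gower_matrix

#: humid -> arid ordering; counts as in the emulated survey
DEFAULT_BIOME_PLAN = (
    ("TMBF", 31),   # tropical moist broadleaf forests
    ("FGS", 1),     # flooded grasslands & savannahs
    ("TGSS", 30),   # tropical grasslands, savannahs & shrublands
    ("MGS", 7),     # montane grasslands & shrublands
    ("MFWS", 2),    # mediterranean forests, woodlands & scrubs
    ("DXS", 21),    # deserts & xeric shrublands
)

ARID_BIOMES = ("DXS", "MFWS")


@dataclass
class AssemblyScenario:
    """Generative parameters for one synthetic world."""

    n_species: int = 904
    n_sites: int = 92
    biome_plan: tuple[tuple[str, int], ...] = DEFAULT_BIOME_PLAN
    yule_rate: float = 1.0          # birth rate per lineage per unit time
    sigma2_bm: float = 0.2          # Brownian rate of log10 body mass
    mk_rate: float = 0.05           # per-state flow rate of the lifestyle Mk
    missing_lifestyle_frac: float = 20 / 904
    assembly: str = "neutral"       # | "filtering" | "limiting_similarity"
                                    # | "mixed"
    sigma_f: float = 0.35           # filter width on log10 mass
    richness_mean: float = 40.0     # truncated negative binomial
    richness_disp: float = 5.0
    climate_noise: float = 0.05     # relative noise on bioclim values
    clade_fraction: float = 0.4     # "mixed": clade size for humid pools
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species >= 2")
        if sum(c for _, c in self.biome_plan) != self.n_sites:
            raise ValueError("biome plan site counts must sum to n_sites")
        for name, val in (("yule_rate", self.yule_rate),
                          ("sigma2_bm", self.sigma2_bm),
                          ("mk_rate", self.mk_rate)):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_tree(n_species: int, yule_rate: float = 1.0,
                  seed: int = 0) -> PhyloTree:
    """Pure-birth (Yule) tree with ``n_species`` extant tips; ultrametric."""
    if n_species < 2:
        raise ValueError("n_species >= 2")
    tree = birthdeath.birth_death_tree(
        birth_rate=yule_rate, death_rate=0.0,
        num_extant_tips=n_species,
        rng=random.Random(seed))
    width = len(str(n_species))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"S{i + 1:0{width}d}"
    return PhyloTree(tree)


def simulate_traits(tree: PhyloTree, sigma2_bm: float = 0.2,
                    mk_rate: float = 0.05, seed: int = 0,
                    missing_lifestyle_frac: float = 0.0,
                    root_body_size: float = 1.3) -> TraitTable:
    """Brownian body size and symmetric-Mk lifestyle along the tree.

    Body size diffuses from the root value (log10 grams) with variance
    ``sigma2_bm`` per unit branch length.  Lifestyle evolves under a
    symmetric Mk process over the 10 categories: along a branch of length
    t the probability of remaining in the current state is
    ``1/k + (k-1)/k * exp(-k q t)`` with k = 10 and per-state flow q.
    """
    rng = np.random.default_rng(seed)
    k = len(LIFESTYLES)
    root = tree.tree.seed_node
    bm = {root: root_body_size}
    state = {root: int(rng.integers(k))}
    for node in tree.tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length or 0.0
        parent = node.parent_node
        bm[node] = bm[parent] + rng.normal(0.0, np.sqrt(sigma2_bm * t))
        p_same = 1.0 / k + (k - 1.0) / k * np.exp(-k * mk_rate * t)
        if rng.random() < p_same:
            state[node] = state[parent]
        else:
            others = [s for s in range(k) if s != state[parent]]
            state[node] = int(rng.choice(others))
    rows = {}
    for leaf in tree.tree.leaf_node_iter():
        rows[leaf.taxon.label] = (bm[leaf], LIFESTYLES[state[leaf]])
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["body_size", "lifestyle"])
    df.index.name = "species"
    if missing_lifestyle_frac > 0:
        n_miss = int(round(missing_lifestyle_frac * len(df)))
        miss = rng.choice(len(df), size=n_miss, replace=False)
        df.iloc[miss, df.columns.get_loc("lifestyle")] = np.nan
    return TraitTable(df)


def simulate_sites(scenario: AssemblyScenario) -> SiteMetadata:
    """Site coordinates, latent aridity, biome bands and bioclim values.

    A latent aridity axis a in [0, 1] orders the sites; biomes are
    contiguous aridity bands with the planned site counts (humid plan
    entries first).  Bio12 (annual precipitation) and Bio14 (precipitation
    of the driest month) decrease with aridity; Bio1 (mean annual
    temperature), Bio4 (temperature seasonality) and Bio15 (precipitation
    seasonality) increase.  Each variable mixes the aridity axis with its
    own independent latent driver (plus multiplicative noise) so that the
    generated set behaves like real post-collinearity-screen bioclim
    variables: pairwise |r| stays moderate while Bio12 remains the
    strongest single aridity proxy.  Latitude tracks aridity so the
    climate gradient is also a spatial gradient.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=scenario.seed, spawn_key=(1,)))
    n = scenario.n_sites
    aridity = np.sort(rng.random(n))
    biome = np.empty(n, dtype=object)
    start = 0
    for name, count in scenario.biome_plan:
        biome[start:start + count] = name
        start += count
    lon = rng.uniform(-17.0, 50.0, n)
    lat = np.clip(-34.0 + 68.0 * aridity + rng.normal(0, 3.0, n), -90, 90)

    def noisy(x):
        eps = 1.0 + scenario.climate_noise * rng.standard_normal(n)
        return x * eps

    # independent latent drivers (continentality, dry-season length, ...)
    u1, u2, u3, u4 = (rng.random(n) for _ in range(4))
    bio1 = noisy(10.0 + 18.0 * (0.45 * aridity + 0.55 * u1))   # deg C
    bio4 = np.maximum(
        noisy(1500.0 + 6500.0 * (0.45 * aridity + 0.55 * u2)), 1.0)
    bio12 = np.maximum(noisy(2400.0 * (1.0 - aridity)), 0.0)
    bio14 = np.maximum(
        noisy(80.0 * (1.0 - (0.5 * aridity + 0.5 * u3)) ** 3), 0.0)
    bio15 = np.maximum(
        noisy(30.0 + 90.0 * (0.45 * aridity + 0.55 * u4)), 0.0)
    width = len(str(n))
    sites = [f"L{i + 1:0{width}d}" for i in range(n)]
    df = pd.DataFrame({
        "lon": lon, "lat": lat, "biome": biome, "aridity": aridity,
        "Bio1": bio1, "Bio4": bio4, "Bio12": bio12, "Bio14": bio14,
        "Bio15": bio15,
    }, index=pd.Index(sites, name="site"))
    return SiteMetadata(df)


def _richness_draws(scenario: AssemblyScenario, rng, n: int,
                    k_max: int) -> np.ndarray:
    """Per-site richness: negative binomial truncated to [2, k_max]."""
    r = scenario.richness_disp
    p = r / (r + scenario.richness_mean)
    k = rng.negative_binomial(r, p, size=n)
    return np.clip(k, 2, k_max)


def _weighted_sample_without_replacement(rng, weights: np.ndarray,
                                         k: int) -> np.ndarray:
    # Efraimidis-Spirakis exponential-key trick
    keys = rng.exponential(1.0, len(weights)) / weights
    return np.argpartition(keys, k - 1)[:k]


def _pick_clade(tree: PhyloTree, fraction: float) -> set[str]:
    """Internal node whose tip count is closest to fraction * n_tips."""
    target = fraction * tree.n_tips
    counts = {}
    for node in tree.tree.postorder_node_iter():
        counts[node] = 1 if node.is_leaf() else sum(
            counts[c] for c in node.child_nodes())
    best = min((n for n in counts if not n.is_leaf()),
               key=lambda n: abs(counts[n] - target))
    return {l.taxon.label for l in best.leaf_iter()}


def assemble_communities(scenario: AssemblyScenario, tree: PhyloTree,
                         traits: TraitTable, meta: SiteMetadata
                         ) -> CommunityMatrix:
    """Build site assemblages under the scenario's assembly rule."""
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=scenario.seed, spawn_key=(2,)))
    species = list(tree.tip_labels)
    n_sp = len(species)
    z = traits.body_size(species)
    aridity = meta.data["aridity"].to_numpy(float) \
        if "aridity" in meta.data.columns else \
        1.0 - meta.data["Bio12"].to_numpy(float) / meta.data["Bio12"].max()
    ks = _richness_draws(scenario, rng, meta.data.shape[0], n_sp - 1)

    gower = None
    if scenario.assembly in ("limiting_similarity", "mixed"):
        gower = gower_matrix(traits, species).d
    clade = None
    if scenario.assembly == "mixed":
        clade = np.array([sp in _pick_clade(tree, scenario.clade_fraction)
                          for sp in species])

    biomes = meta.biomes.to_numpy()
    inc = np.zeros((meta.data.shape[0], n_sp), dtype=np.int8)
    for i in range(meta.data.shape[0]):
        k = int(ks[i])
        rule = scenario.assembly
        if rule == "mixed":
            rule = ("filtering" if biomes[i] in ARID_BIOMES
                    else "limiting_similarity")
        if rule == "neutral":
            chosen = rng.choice(n_sp, size=k, replace=False)
        elif rule == "filtering":
            mu_s = 0.6 + 1.4 * (1.0 - aridity[i])  # larger bodies when humid
            w = np.exp(-(z - mu_s) ** 2 / (2.0 * scenario.sigma_f ** 2))
            w = np.maximum(w, 1e-300)
            chosen = _weighted_sample_without_replacement(rng, w, k)
        elif rule == "limiting_similarity":
            candidates = np.arange(n_sp)
            if scenario.assembly == "mixed":
                pool = np.flatnonzero(clade)
                if len(pool) > k:
                    candidates = pool
            chosen = _greedy_maxmin(rng, gower, candidates, k)
        else:
            raise ValueError(f"unknown assembly rule {scenario.assembly!r}")
        inc[i, np.asarray(chosen)] = 1

    keep = inc.sum(axis=0) > 0
    return CommunityMatrix(list(meta.sites),
                           [s for s, kp in zip(species, keep) if kp],
                           inc[:, keep])


def _greedy_maxmin(rng, d: np.ndarray, candidates: np.ndarray,
                   k: int) -> list[int]:
    first = int(rng.choice(candidates))
    chosen = [first]
    mind = d[first, candidates].copy()
    for _ in range(k - 1):
        mind[np.isin(candidates, chosen)] = -np.inf
        nxt = int(candidates[int(np.argmax(mind))])
        chosen.append(nxt)
        mind = np.minimum(mind, d[nxt, candidates])
    return chosen


def generate_world(scenario: AssemblyScenario
                   ) -> tuple[PhyloTree, TraitTable, SiteMetadata,
                              CommunityMatrix]:
    """Tree + traits + sites + assemblages for one scenario."""
    tree = simulate_tree(scenario.n_species, scenario.yule_rate,
                         seed=scenario.seed)
    traits = simulate_traits(
        tree, scenario.sigma2_bm, scenario.mk_rate,
        seed=int(np.random.SeedSequence(
            entropy=scenario.seed, spawn_key=(3,)).generate_state(1)[0]
            % (2 ** 31)),
        missing_lifestyle_frac=scenario.missing_lifestyle_frac)
    meta = simulate_sites(scenario)
    cm = assemble_communities(scenario, tree, traits, meta)
    return tree, traits, meta, cm


def toy4() -> tuple[PhyloTree, TraitTable, SiteMetadata, CommunityMatrix]:
    """The tiny hand-checkable fixture used throughout the unit tests."""
    from .io import tree_from_string
    tree = tree_from_string("((A:1,B:1):1,(C:1,D:1):1);")
    traits = TraitTable(pd.DataFrame({
        "body_size": [0.5, 1.5, 1.0, 2.0],
        "lifestyle": ["terrestrial", "arboreal", "terrestrial", np.nan],
    }, index=pd.Index(["A", "B", "C", "D"], name="species")))
    meta = SiteMetadata(pd.DataFrame({
        "lon": [10.0, 20.0], "lat": [0.0, 10.0],
        "biome": ["X", "Y"],
        "Bio1": [20.0, 25.0], "Bio4": [1000.0, 2000.0],
        "Bio12": [800.0, 200.0], "Bio14": [30.0, 2.0],
        "Bio15": [40.0, 90.0],
    }, index=pd.Index(["s1", "s2"], name="site")))
    cm = CommunityMatrix(["s1", "s2"], ["A", "B", "C", "D"],
                         np.array([[1, 1, 0, 0], [1, 1, 1, 1]]))
    return tree, traits, meta, cm


def make_fixture(scenario: AssemblyScenario, outdir) -> dict:
    """Write a complete world (newick + three tables) to ``outdir``."""
    from pathlib import Path
    from .io import write_community, write_metadata, write_traits

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tree, traits, meta, cm = generate_world(scenario)
    paths = {"tree": out / "tree.nwk", "community": out / "community.csv",
             "traits": out / "traits.csv", "meta": out / "meta.csv"}
    tree.write_newick(paths["tree"])
    write_community(cm, paths["community"])
    write_traits(traits, paths["traits"])
    write_metadata(meta, paths["meta"])
    return {k: str(v) for k, v in paths.items()}
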