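"""End-to-end orchestration: config-driven run with logging and a manifest.

``run_all`` composes the whole analysis plan on any conforming dataset:
load and validate -> species pools -> phylogenetic and functional NRI/NTI
of every site against the continental and biome pools -> biome-level
assemblage tests -> NRI-vs-NTI Pearson correlations -> per-response
climate model selection (OLS vs SAR) -> richness post hoc across biomes ->
delimited summary tables plus a JSON manifest.  ``run_subsets`` reruns the
plan on species subsets (e.g. lizards vs snakes, or robustness subsets
dropping fossorial families) with the tree pruned accordingly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate as cl
from . import nullmodels as nm
from . import posthoc as ph
from .distances import DistanceMatrix, gower_matrix, patristic_matrix
from .io import (CommunityMatrix, PhyloTree, SiteMetadata, SpeciesPool,
                 TraitTable, build_pools, read_community, read_metadata,
                 read_newick, read_traits)

logger = logging.getLogger("commstruct")


@dataclass
class RunConfig:
    tree: str
    community: str
    traits: str
    meta: str
    out_dir: str = "run_out"
    n_null: int = 5000
    n_perm: int = 999
    seed: int = 0
    weight_scheme: str = "knn6"
    min_sites_per_biome: int = 3
    drop_species_files: dict[str, str] = field(default_factory=dict)
    drop_sites_files: dict[str, str] = field(default_factory=dict)
    subsets: dict[str, str] = field(default_factory=dict)  # name -> list file

    def __post_init__(self) -> None:
        for p in (self.tree, self.community, self.traits, self.meta):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.n_null < 100:
            raise ValueError("n_null >= 100 for reported runs")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{stage}:{seed}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def pool_distance_matrices(tree: PhyloTree, traits: TraitTable,
                           pools: list[SpeciesPool]
                           ) -> tuple[dict[str, DistanceMatrix],
                                      dict[str, DistanceMatrix]]:
    """Patristic and Gower matrices per pool.

    Gower ranges are computed within each pool (and held fixed across its
    null draws); the patristic matrices are submatrices of the continental
    cophenetic matrix, which pruning would not change.
    """
    cont = patristic_matrix(tree)
    d_phylo, d_func = {}, {}
    for pool in pools:
        members = sorted(pool.members)
        d_phylo[pool.label] = DistanceMatrix(
            members, cont.submatrix(members), "phylogenetic")
        d_func[pool.label] = gower_matrix(traits, members)
    return d_phylo, d_func


def structure_stage(cm: CommunityMatrix, meta: SiteMetadata,
                    tree: PhyloTree, traits: TraitTable,
                    n_null: int, seed: int,
                    min_sites_per_biome: int = 3) -> dict:
    pools = build_pools(cm, meta, min_sites_per_biome)
    d_phylo, d_func = pool_distance_matrices(tree, traits, pools)
    res = []
    for kind, dmats in (("phylogenetic", d_phylo), ("functional", d_func)):
        res.append(nm.site_structure(
            cm, dmats, pools, meta, n_null=n_null,
            seed=_stage_seed(seed, f"site-{kind}")))
        res.append(nm.biome_structure(
            cm, meta, dmats["continental"], n_null=n_null,
            seed=_stage_seed(seed, f"biome-{kind}")))
    sites = pd.concat([res[0], res[2]], ignore_index=True)
    biomes_tbl = pd.concat([res[1], res[3]], ignore_index=True)
    return {"sites": sites, "biomes": biomes_tbl, "pools": pools}


def index_vector(site_results: pd.DataFrame, meta: SiteMetadata,
                 kind: str, metric: str = "mpd",
                 pool: str = "continental") -> pd.Series:
    sel = site_results.query(
        "kind == @kind and metric == @metric and pool == @pool")
    s = sel.set_index("site")["index"].reindex(meta.sites)
    s.name = f"{'nri' if metric == 'mpd' else 'nti'}_{kind}"
    return s


def run_all(config: RunConfig) -> Path:
    """Execute the full analysis plan; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": {k: v for k, v in vars(config).items()},
                "stages": {}}
    t0 = time.time()

    def log_stage(name, **info):
        manifest["stages"][name] = {"wall_s": round(time.time() - t0, 2),
                                    **info}
        logger.info("stage %s done (%.1fs): %s", name, time.time() - t0, info)

    try:
        tree = read_newick(config.tree)
        cm = read_community(config.community)
        traits = read_traits(config.traits)
        meta = read_metadata(config.meta)
        cm = cm.subset_species([s for s in cm.species
                                if s in set(tree.tip_labels)])
        for name, path in config.drop_species_files.items():
            drop = set(Path(path).read_text().split())
            cm = cm.subset_species([s for s in cm.species if s not in drop])
        meta = SiteMetadata(meta.data.loc[[s for s in meta.sites
                                           if s in set(cm.sites)]])
        log_stage("load", n_sites=cm.n_sites, n_species=cm.n_species)

        st = structure_stage(cm, meta, tree, traits, config.n_null,
                             config.seed, config.min_sites_per_biome)
        st["sites"].to_csv(out / "site_structure.csv", index=False)
        st["biomes"].to_csv(out / "biome_structure.csv", index=False)
        nm.structure_summary(st["sites"], meta).to_csv(
            out / "biome_proportions.csv", index=False)
        log_stage("structure", n_rows=len(st["sites"]))

        # NRI vs NTI correlations per kind (continental pool)
        corr_rows = []
        for kind in ("phylogenetic", "functional"):
            nri = index_vector(st["sites"], meta, kind, "mpd")
            nti = index_vector(st["sites"], meta, kind, "mnnd")
            ok = nri.notna() & nti.notna()
            r, p = nm.correlate_indices(nri[ok], nti[ok])
            corr_rows.append({"kind": kind, "r": r, "p": p, "n": int(ok.sum())})
        pd.DataFrame(corr_rows).to_csv(out / "nri_nti_correlations.csv",
                                       index=False)
        log_stage("correlations")

        # climate models
        X_all = cl.transform_climate(meta)
        retained, dropped = cl.screen_collinear(X_all, 0.75)
        X = X_all[retained]
        richness = cm.richness.astype(float)
        mean_mass = pd.Series(
            [np.mean(traits.body_size(sorted(cm.members(s))))
             if len(cm.members(s)) else np.nan for s in cm.sites],
            index=cm.sites, name="mean_bodysize")
        responses = {
            "nri_phylo": index_vector(st["sites"], meta, "phylogenetic"),
            "nri_func": index_vector(st["sites"], meta, "functional"),
            "richness": richness,
            "mean_bodysize": mean_mass,
        }
        model_rows, importance_rows = [], []
        reports = {}
        for name, y in responses.items():
            ok = y.reindex(meta.sites).notna()
            meta_ok = SiteMetadata(meta.data.loc[ok[ok].index])
            rep = cl.select_and_report(
                y.reindex(meta.sites)[ok].to_numpy(float), X.loc[ok[ok].index],
                meta_ok, response=name, n_perm=config.n_perm,
                seed=_stage_seed(config.seed, f"climate-{name}"))
            reports[name] = rep
            chosen = rep["chosen"]
            model_rows.append({
                "response": name, "model": chosen.model_type,
                "predictors": "+".join(chosen.predictors) or "(intercept)",
                "aicc": chosen.aicc, "r2_adj": chosen.r2_adj,
                "pseudo_r2": chosen.pseudo_r2, "lambda": chosen.lam,
                "moran_I_ols": rep["moran_ols_knn6"]["I"],
                "moran_p_ols": rep["moran_ols_knn6"]["p_perm"],
                **{f"beta_{k}": v for k, v in chosen.coefficients.items()},
            })
            for pred, w in rep["importance"].items():
                importance_rows.append({"response": name, "predictor": pred,
                                        "importance": w})
        pd.DataFrame(model_rows).to_csv(out / "climate_models.csv",
                                        index=False)
        pd.DataFrame(importance_rows).to_csv(out / "aicc_importance.csv",
                                             index=False)
        log_stage("climate", dropped_covariates=[d[0] for d in dropped])

        # richness post hoc
        try:
            pt = ph.compare_biomes(richness, meta.biomes,
                                   min_sites=config.min_sites_per_biome)
            pt.table.assign(test=pt.test).to_csv(
                out / "richness_posthoc.csv", index=False)
            manifest["posthoc_gate"] = pt.gate
        except ValueError as exc:
            logger.warning("post hoc skipped: %s", exc)
            manifest["posthoc_gate"] = {"skipped": str(exc)}
        log_stage("posthoc")

    except Exception as exc:  # preserve partial outputs, name the stage
        manifest["error"] = {"stage": list(manifest["stages"])[-1:],
                             "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
        raise

    manifest["versions"] = _versions()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return out


def _versions() -> dict:
    import dendropy
    import scipy
    import statsmodels

    return {"numpy": np.__version__, "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
            "dendropy": dendropy.__version__}


def run_subsets(config: RunConfig) -> pd.DataFrame:
    """Rerun the full plan per species subset, pruning the tree each time.

    Subsets are named species-list files (whitespace-separated ids).
    Returns a side-by-side classification summary across subsets.
    """
    if not config.subsets:
        raise ValueError("no subsets configured")
    frames = []
    base_out = Path(config.out_dir)
    for name, listfile in config.subsets.items():
        keep = set(Path(listfile).read_text().split())
        if not keep:
            raise ValueError(f"subset {name!r} is empty")
        cm = read_community(config.community)
        keep &= set(cm.species)
        sub_dir = base_out / f"subset_{name}"
        tree = read_newick(config.tree)
        pruned = tree.pruned_to(sorted(keep & set(tree.tip_labels)))
        sub_tree = sub_dir / "pruned.nwk"
        sub_dir.mkdir(parents=True, exist_ok=True)
        pruned.write_newick(sub_tree)
        cm_sub = cm.subset_species(sorted(keep))
        sub_comm = sub_dir / "community.csv"
        cm_sub.to_frame().to_csv(sub_comm)
        sub_cfg = RunConfig(
            tree=str(sub_tree), community=str(sub_comm),
            traits=config.traits, meta=config.meta,
            out_dir=str(sub_dir), n_null=config.n_null,
            n_perm=config.n_perm, seed=config.seed,
            weight_scheme=config.weight_scheme,
            min_sites_per_biome=config.min_sites_per_biome)
        run_all(sub_cfg)
        tbl = pd.read_csv(sub_dir / "site_structure.csv")
        summ = (tbl.groupby(["pool", "metric", "kind", "classification"])
                .size().rename("count").reset_index())
        summ["subset"] = name
        frames.append(summ)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(base_out / "subset_comparison.csv", index=False)
    return out
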