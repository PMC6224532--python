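"""MPD/MNND, label-shuffle null models, NRI/NTI and classification.

The standardized effect size (SES) of an assemblage's mean pairwise
distance (MPD) or mean nearest-neighbour distance (MNND) is computed
against a null distribution obtained by shuffling taxon labels across the
pool's distance matrix.  For these metrics on a fixed pool matrix that is
equivalent to redrawing the assemblage's k members uniformly without
replacement from the pool, which is how the null is implemented (and the
equivalence is asserted in the test suite).

Sign convention: NRI = -1 * SES(MPD) and NTI = -1 * SES(MNND), so
positive index values mean clustering (observed distances smaller than
the null) and negative values overdispersion.  A site is called
significantly clustered when its lower-tail permutation p < 0.025 and
significantly overdispersed when p > 0.975.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import CommunityMatrix, SiteMetadata, SpeciesPool
from .distances import DistanceMatrix

logger = logging.getLogger("commstruct")

CLUSTER_P = 0.025
OVERDISP_P = 0.975


class MetricUndefinedError(ValueError):
    """MPD/MNND need at least two assemblage members."""


def mpd(d: DistanceMatrix | np.ndarray, members=None) -> float:
    """Mean pairwise distance over all unordered distinct pairs."""
    sub = _member_matrix(d, members)
    k = sub.shape[0]
    return float(sub[np.triu_indices(k, 1)].mean())


def mnnd(d: DistanceMatrix | np.ndarray, members=None) -> float:
    """Mean over members of the distance to their nearest other member."""
    sub = _member_matrix(d, members).copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _member_matrix(d, members) -> np.ndarray:
    if isinstance(d, DistanceMatrix):
        if members is None:
            sub = d.d
        else:
            sub = d.submatrix(sorted(members))
    else:
        sub = np.asarray(d, dtype=float)
    if sub.shape[0] < 2:
        raise MetricUndefinedError("metric needs >= 2 members")
    return sub


_METRICS = {"mpd": mpd, "mnnd": mnnd}


@dataclass
class SESResult:
    site: str
    pool: str
    metric: str          # "mpd" | "mnnd"
    kind: str            # "phylogenetic" | "functional"
    obs: float
    null_mean: float
    null_sd: float
    ses: float           # (obs - null_mean) / null_sd; NaN if degenerate
    index: float         # NRI or NTI = -ses
    p_low: float         # lower-tail permutation p (clustering tail)
    n_null: int
    classification: str  # "clustered" | "overdispersed" | "random"


def classify(p_low: float) -> str:
    if p_low < CLUSTER_P:
        return "clustered"
    if p_low > OVERDISP_P:
        return "overdispersed"
    return "random"


def _null_metric_draws(pool_d: np.ndarray, k: int, metric: str,
                       n_null: int, rng: np.random.Generator,
                       chunk: int = 1024) -> np.ndarray:
    """Metric values for n_null uniform k-subsets of the pool (vectorised)."""
    n = pool_d.shape[0]
    fn_is_mpd = metric == "mpd"
    out = np.empty(n_null)
    done = 0
    iu = np.triu_indices(k, 1)
    while done < n_null:
        m = min(chunk, n_null - done)
        idx = np.argpartition(rng.random((m, n)), k - 1, axis=1)[:, :k]
        sub = pool_d[idx[:, :, None], idx[:, None, :]]  # (m, k, k)
        if fn_is_mpd:
            out[done:done + m] = sub[:, iu[0], iu[1]].mean(axis=1)
        else:
            sub[:, np.arange(k), np.arange(k)] = np.inf
            out[done:done + m] = sub.min(axis=2).mean(axis=1)
        done += m
    return out


def _p_low(null: np.ndarray, obs: float, n: int) -> float:
    """Lower-tail permutation p: mid-rank for ties, add-one so p > 0,
    capped at n/(n+1) so the complementary tail also stays positive."""
    num = np.sum(null < obs) + 0.5 * np.sum(null == obs) + 1
    return float(min(num, n) / (n + 1))


def ses_index(d_pool: DistanceMatrix, members, metric: str = "mpd",
              n_null: int = 5000, rng_seed=0, site: str = "",
              pool_label: str = "") -> SESResult:
    """SES of a metric for one assemblage against a pool null.

    The null is ``n_null`` uniform redraws of ``len(members)`` labels from
    the pool.  ``p_low`` uses the mid-rank add-one convention
    ``(#{null < obs} + 0.5 #{null == obs} + 1) / (n_null + 1)``, which
    avoids p = 0.  When the null has zero spread (degenerate pool) the SES
    is undefined and the site is classified "random" with a warning.
    """
    members = sorted(members)
    k = len(members)
    if k < 2:
        raise MetricUndefinedError("assemblage needs >= 2 members")
    if k >= len(d_pool.labels):
        logger.warning("assemblage %r equals its pool; null is degenerate",
                       site or members)
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    fn = _METRICS[metric]
    obs = fn(d_pool, members)
    rng = np.random.default_rng(rng_seed)
    null = _null_metric_draws(d_pool.d, k, metric, n_null, rng)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_null > 1 else 0.0
    p_low = _p_low(null, obs, n_null)
    if null_sd > 0:
        ses = (obs - null_mean) / null_sd
        cls = classify(p_low)
    else:
        logger.warning("degenerate null (sd=0) for site %r", site or members)
        ses = float("nan")
        cls = "random"
    return SESResult(site=site, pool=pool_label, metric=metric,
                     kind=d_pool.kind, obs=obs, null_mean=null_mean,
                     null_sd=null_sd, ses=ses, index=-ses, p_low=p_low,
                     n_null=n_null, classification=cls)


def ses_exhaustive(d_pool: DistanceMatrix, members, metric: str = "mpd",
                   site: str = "", pool_label: str = "") -> SESResult:
    """Exact SES from complete enumeration of all C(n, k) subsets.

    Feasible for small pools only; serves as the exact oracle for the
    Monte-Carlo null.
    """
    members = sorted(members)
    k = len(members)
    fn = _METRICS[metric]
    obs = fn(d_pool, members)
    n = len(d_pool.labels)
    vals = np.array([fn(d_pool.d[np.ix_(c, c)])
                     for c in combinations(range(n), k)])
    null_mean = float(vals.mean())
    null_sd = float(vals.std(ddof=1))
    p_low = _p_low(vals, obs, len(vals))
    ses = (obs - null_mean) / null_sd if null_sd > 0 else float("nan")
    return SESResult(site=site, pool=pool_label, metric=metric,
                     kind=d_pool.kind, obs=obs, null_mean=null_mean,
                     null_sd=null_sd, ses=ses, index=-ses, p_low=p_low,
                     n_null=len(vals),
                     classification=classify(p_low) if null_sd > 0 else "random")


def _site_seed(seed, i: int) -> np.random.SeedSequence:
    # per-site substream: reproducible regardless of execution order
    return np.random.SeedSequence(entropy=seed, spawn_key=(i,))


def site_structure(cm: CommunityMatrix, d_pools: dict[str, DistanceMatrix],
                   pools: list[SpeciesPool], meta: SiteMetadata | None = None,
                   metrics: tuple[str, ...] = ("mpd", "mnnd"),
                   n_null: int = 5000, seed=0) -> pd.DataFrame:
    """One SES row per site x pool x metric.

    ``d_pools`` maps pool label -> pool distance matrix (the matrix defines
    the distance kind).  For biome pools only the sites of that biome are
    tested; the continental pool covers every site.  Sites with richness
    < 2 are skipped.
    """
    rows = []
    biomes = meta.biomes if meta is not None else None
    for p_idx, pool in enumerate(pools):
        d_pool = d_pools[pool.label]
        for i, s in enumerate(cm.sites):
            if pool.label != "continental":
                if biomes is None or biomes.get(s) != pool.label:
                    continue
            members = cm.members(s)
            if len(members) < 2:
                continue
            if not members <= pool.members:
                raise ValueError(f"site {s} not contained in pool {pool.label}")
            for m_idx, metric in enumerate(metrics):
                ss = _site_seed(seed, i * 1000 + p_idx * 10 + m_idx)
                rows.append(asdict(ses_index(
                    d_pool, members, metric=metric, n_null=n_null,
                    rng_seed=ss, site=s, pool_label=pool.label)))
    return pd.DataFrame(rows)


def biome_structure(cm: CommunityMatrix, meta: SiteMetadata,
                    d_continental: DistanceMatrix,
                    metrics: tuple[str, ...] = ("mpd", "mnnd"),
                    n_null: int = 5000, seed=0,
                    min_sites_per_biome: int = 1) -> pd.DataFrame:
    """Each biome's species union tested as one assemblage against the
    continental pool."""
    frame = cm.to_frame()
    biomes = meta.biomes
    rows = []
    for b_idx, biome in enumerate(sorted(biomes.unique())):
        sites = [s for s in cm.sites if biomes.get(s) == biome]
        if len(sites) < min_sites_per_biome:
            continue
        sub = frame.loc[sites]
        union = set(sub.columns[sub.to_numpy().sum(axis=0) > 0])
        if len(union) < 2:
            continue
        for m_idx, metric in enumerate(metrics):
            ss = _site_seed(seed, 10_000_000 + b_idx * 10 + m_idx)
            rows.append(asdict(ses_index(
                d_continental, union, metric=metric, n_null=n_null,
                rng_seed=ss, site=str(biome), pool_label="continental")))
    return pd.DataFrame(rows)


def structure_summary(results: pd.DataFrame, meta: SiteMetadata
                      ) -> pd.DataFrame:
    """Per-biome proportions of clustered/overdispersed/random sites with
    Wilson 95% binomial intervals."""
    from statsmodels.stats.proportion import proportion_confint

    res = results.copy()
    res["biome"] = res["site"].map(meta.biomes)
    rows = []
    for (biome, pool, metric, kind), grp in res.groupby(
            ["biome", "pool", "metric", "kind"]):
        n = len(grp)
        for cls in ("clustered", "overdispersed", "random"):
            c = int((grp["classification"] == cls).sum())
            lo, hi = proportion_confint(c, n, alpha=0.05, method="wilson")
            rows.append({"biome": biome, "pool": pool, "metric": metric,
                         "kind": kind, "classification": cls, "n_sites": n,
                         "count": c, "proportion": c / n,
                         "ci_low": float(lo), "ci_high": float(hi)})
    return pd.DataFrame(rows)


def correlate_indices(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided t-test p (e.g. NRI vs NTI)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
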