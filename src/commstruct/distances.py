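"""Pairwise species distance matrices: patristic and Gower.

Phylogenetic structure is measured on patristic distances (sum of branch
lengths along the tip-to-tip path); functional structure on a Gower
distance over one continuous trait (log10 body mass, range-normalised) and
one categorical trait (lifestyle, 0/1 mismatch with intermediate states as
distinct categories).  Missing lifestyle is handled by trait-wise deletion:
the pair's distance averages over the traits that are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PhyloTree, TraitTable, ValidationError


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative species distance matrix with zero diagonal."""

    labels: list[str]
    d: np.ndarray
    kind: str  # "phylogenetic" | "functional"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if not np.isfinite(self.d).all():
            raise ValidationError("non-finite distances")
        if (self.d < 0).any():
            raise ValidationError("negative distances")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValidationError("nonzero diagonal")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def indices(self, species) -> np.ndarray:
        missing = sorted(set(species) - self._index.keys())
        if missing:
            raise ValidationError(f"species not in matrix: {missing}")
        return np.array([self._index[s] for s in species], dtype=int)

    def submatrix(self, species: list[str]) -> np.ndarray:
        idx = self.indices(species)
        return self.d[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def write(self, path) -> None:
        self.to_frame().to_csv(path)


def read_distance_matrix(path, kind: str) -> DistanceMatrix:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return DistanceMatrix([str(c) for c in df.columns], df.to_numpy(), kind)


def patristic_matrix(tree: PhyloTree, species: list[str] | None = None
                     ) -> DistanceMatrix:
    """Tip-to-tip path-length distances, restricted to ``species``.

    Computed in a single postorder sweep: at each internal node the
    distances between tips in different child subtrees are
    ``depth_i + depth_j - 2 * depth(node)``.  Pruning the tree first gives
    identical values, since pruning never alters tip-to-tip paths.
    """
    if species is None:
        species = list(tree.tip_labels)
    missing = sorted(set(species) - set(tree.tip_labels))
    if missing:
        raise ValidationError(f"species not in tree: {missing}")

    t = tree.tree
    labels = list(tree.tip_labels)
    pos = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    d = np.zeros((n, n))

    depth = {}
    tips_below = {}
    root = t.seed_node
    for node in t.preorder_node_iter():
        depth[node] = (0.0 if node is root
                       else depth[node.parent_node] + (node.edge.length or 0.0))
    tip_depth = np.zeros(n)
    for node in t.postorder_node_iter():
        if node.is_leaf():
            i = pos[node.taxon.label]
            tip_depth[i] = depth[node]
            tips_below[node] = np.array([i])
            continue
        children = [tips_below.pop(c) for c in node.child_nodes()]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                ia, ib = children[a], children[b]
                block = (tip_depth[ia][:, None] + tip_depth[ib][None, :]
                         - 2.0 * depth[node])
                d[np.ix_(ia, ib)] = block
                d[np.ix_(ib, ia)] = block.T
        tips_below[node] = np.concatenate(children)

    full = DistanceMatrix(labels, d, "phylogenetic")
    if list(species) == labels:
        return full
    return DistanceMatrix(list(species), full.submatrix(list(species)),
                          "phylogenetic")


def gower_matrix(traits: TraitTable, species: list[str],
                 ranges: float | None = None,
                 partial_intermediate: bool = False) -> DistanceMatrix:
    """Gower distance over body size and lifestyle for a species pool.

    Per pair, the distance averages the available trait contributions:
    ``|x_i - x_j| / range`` for body size and a 0/1 lifestyle mismatch.
    ``ranges`` fixes the body-size normalisation range; it defaults to the
    range over the supplied pool and should be held fixed across null
    draws so observed and null values are comparable.

    ``partial_intermediate=True`` scores an intermediate state (e.g.
    "terrestrial/arboreal") at distance 0.5 from each of its parent
    states instead of 1; off by default — intermediates are ruled full
    categories.
    """
    missing = sorted(set(species) - set(traits.species))
    if missing:
        raise ValidationError(f"species without traits: {missing}")
    species = list(species)
    x = traits.body_size(species)
    if ranges is None:
        ranges = float(np.ptp(x))
    if ranges == 0 and len(np.unique(x)) > 1:
        raise ValidationError("zero range with distinct body sizes")
    cont = np.abs(x[:, None] - x[None, :])
    cont = cont / ranges if ranges > 0 else np.zeros_like(cont)

    ls = traits.lifestyle(species)
    known = ls.notna().to_numpy()
    codes = ls.fillna("").to_numpy()
    cat = (codes[:, None] != codes[None, :]).astype(float)
    if partial_intermediate:
        parts = [set(str(c).split("/")) if k else set()
                 for c, k in zip(codes, known)]
        for i in range(len(species)):
            for j in range(i + 1, len(species)):
                if parts[i] and parts[j] and parts[i] != parts[j] \
                        and (parts[i] & parts[j]):
                    cat[i, j] = cat[j, i] = 0.5
    avail = np.outer(known, known)  # lifestyle usable for the pair?

    n_traits = 1.0 + avail
    d = (cont + np.where(avail, cat, 0.0)) / n_traits
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(species, d, "functional")
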