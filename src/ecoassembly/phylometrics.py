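"""Distance primitives: cophenetic distances, Bray–Curtis, abundance-weighted
βMNTD, and (normalized) weighted UniFrac.

βMNTD is the abundance-weighted mean distance from each taxon in one
community to its nearest relative in the other community; it is the observed
statistic standardized by the null engines in :mod:`ecoassembly.nullmodels`.
Weighted UniFrac is implemented through an explicit branch-incidence table so
that the null loops can evaluate it as two matrix–vector products.
"""

from __future__ import annotations

import warnings

import numpy as np
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "cophenetic",
    "bray_curtis",
    "beta_mntd",
    "BranchTable",
    "weighted_unifrac",
]


def cophenetic(tree: TreeNode) -> DistanceMatrix:
    """Pairwise path-length (cophenetic) distances between all tips."""
    n_tips = sum(1 for _ in tree.tips())
    if n_tips < 2:
        raise ValueError("tree must have at least 2 tips")
    return tree.tip_tip_distances()


def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity Σ|x−y| / Σ(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(x - y).sum() / denom)


def beta_mntd(fx, fy, d) -> float:
    """Abundance-weighted β mean-nearest-taxon distance between two communities.

    Parameters
    ----------
    fx, fy : array-like
        Relative abundances of the two communities over the same taxon
        ordering as ``d``. Taxa with zero abundance are absent.
    d : skbio.DistanceMatrix or ndarray
        Pairwise phylogenetic distances between taxa.

    Notes
    -----
    βMNTD = ½[ Σ_{i∈X} fx_i · min_{j∈Y} d(i,j) + Σ_{j∈Y} fy_j · min_{i∈X} d(i,j) ].
    The nearest-taxon search runs over taxa present in the *opposite*
    community; a shared taxon matches itself at distance 0.
    """
    fx = np.asarray(fx, dtype=float)
    fy = np.asarray(fy, dtype=float)
    dm = d.data if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    if fx.shape[0] != dm.shape[0] or fy.shape[0] != dm.shape[0]:
        raise ValueError("abundance vectors must match the distance matrix")
    ix = np.flatnonzero(fx > 0)
    iy = np.flatnonzero(fy > 0)
    if ix.size == 0 or iy.size == 0:
        raise ValueError("each community must contain at least one taxon")
    sub = dm[np.ix_(ix, iy)]
    wx = fx[ix] / fx[ix].sum()
    wy = fy[iy] / fy[iy].sum()
    return float(0.5 * (wx @ sub.min(axis=1) + wy @ sub.min(axis=0)))


class BranchTable:
    """Branch-length / tip-incidence representation of a rooted tree.

    For a fixed taxon ordering, stores for every branch its length and the
    set of tips descending from it, as a dense 0/1 matrix. Weighted UniFrac
    between two relative-abundance vectors then reduces to matrix–vector
    products, which is what the β-null loops need.

    Taxa in ``taxon_ids`` that are not tips of the tree are dropped (their
    incidence column is zero) with a warning unless ``strict``.
    """

    def __init__(self, tree: TreeNode, taxon_ids, strict: bool = False):
        self.taxon_ids = list(taxon_ids)
        index = {t: i for i, t in enumerate(self.taxon_ids)}
        tip_names = {t.name for t in tree.tips()}
        missing = [t for t in self.taxon_ids if t not in tip_names]
        if missing:
            msg = f"{len(missing)} taxa absent from tree: {missing[:5]}..."
            if strict:
                raise ValueError(msg)
            warnings.warn(msg + " (dropped from phylogenetic metrics)")
        self.in_tree = np.array([t in tip_names for t in self.taxon_ids])

        lengths: list[float] = []
        rows: list[np.ndarray] = []
        # postorder: each internal node's tip set is the union of its children's
        tipsets: dict[int, np.ndarray] = {}
        for node in tree.postorder(include_self=True):
            if node.is_tip():
                vec = np.zeros(len(self.taxon_ids))
                if node.name in index:
                    vec[index[node.name]] = 1.0
                tipsets[id(node)] = vec
            else:
                vec = np.zeros(len(self.taxon_ids))
                for child in node.children:
                    vec += tipsets[id(child)]
                tipsets[id(node)] = vec
            if node is not tree:  # root branch carries no contrast
                lengths.append(float(node.length or 0.0))
                rows.append(tipsets[id(node)])
        self.lengths = np.asarray(lengths)
        self.incidence = np.asarray(rows)  # branches × taxa

    def branch_proportions(self, p: np.ndarray) -> np.ndarray:
        """Fraction of a sample's total descending from each branch."""
        p = np.asarray(p, dtype=float)
        p = np.where(self.in_tree, p, 0.0)
        total = p.sum()
        if total <= 0:
            raise ValueError("sample has no abundance on tree tips")
        return self.incidence @ (p / total)

    def unifrac(self, px, py, normalized: bool = True) -> float:
        a = self.branch_proportions(px)
        b = self.branch_proportions(py)
        raw = float(self.lengths @ np.abs(a - b))
        if not normalized:
            return raw
        denom = float(self.lengths @ (a + b))
        return raw / denom if denom > 0 else 0.0


def weighted_unifrac(x, y, tree: TreeNode, taxon_ids, normalized: bool = True,
                     strict: bool = False) -> float:
    """Weighted UniFrac between two count/abundance vectors.

    ``normalized=True`` (default) divides the branch-weighted difference by
    the branch-weighted sum, bounding the result in [0, 1]; ``False``
    returns the raw branch-length-weighted difference.
    """
    table = BranchTable(tree, taxon_ids, strict=strict)
    return table.unifrac(np.asarray(x, dtype=float), np.asarray(y, dtype=float),
                         normalized=normalized)
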