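"""Null models for community assembly inference.

Implements the two-stage null-model partitioning of pairwise community
turnover into five ecological processes:

1. βNTI — the observed βMNTD standardized against a null distribution
   obtained by shuffling taxon labels across the metacommunity species pool
   (phylogenetic turnover). |βNTI| > 2 indicates deterministic selection:
   positive = variable selection, negative = homogeneous selection.
2. RC_bray — the observed Bray–Curtis dissimilarity ranked within a null of
   probabilistically assembled community pairs that preserve each
   community's richness and total individual count, with taxon inclusion
   weighted by metacommunity occupancy and individual placement weighted by
   metacommunity relative abundance. Standardized to [−1, 1]; for pairs with
   |βNTI| ≤ 2, RC_bray > 0.95 indicates dispersal limitation and
   RC_bray < −0.95 homogenizing dispersal, the remainder being undominated.

Also provides abundance-based β-null deviations (observed β-diversity minus
the mean β-diversity of randomly assembled pairs) for Bray–Curtis and
weighted UniFrac.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .community_io import CommunityTable
from .phylometrics import BranchTable, bray_curtis, cophenetic

__all__ = [
    "PROCESSES",
    "NullDistribution",
    "classify_processes",
    "bnti_pair",
    "rc_bray_pair",
    "assembly_profile",
    "per_phylum_assembly",
    "beta_null_deviation",
]

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "homogenizing_dispersal",
    "dispersal_limitation",
    "undominated",
)

# spawn-key stage ids keep per-stage random streams independent
_STAGE_BNTI = 1
_STAGE_RC = 2
_STAGE_BETANULL = 3


@dataclass
class NullDistribution:
    """Draws of a null statistic with summary moments."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 100:
            warnings.warn(
                f"only {self.values.size} null draws; >=100 recommended for inference"
            )

    @property
    def reps(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1))


def classify_processes(bnti: float, rc_bray: float,
                       bnti_cut: float = 2.0, rc_cut: float = 0.95) -> str:
    """Assign one of the five assembly processes from (βNTI, RC_bray).

    Deterministic branches: βNTI > cut → variable selection, βNTI < −cut →
    homogeneous selection. Stochastic branches (|βNTI| ≤ cut): RC_bray >
    rc_cut → dispersal limitation, RC_bray < −rc_cut → homogenizing
    dispersal, otherwise undominated. Total: every finite input pair
    receives exactly one category.
    """
    if not (np.isfinite(bnti) and np.isfinite(rc_bray)):
        raise ValueError("bnti and rc_bray must be finite")
    if not -1.0 - 1e-9 <= rc_bray <= 1.0 + 1e-9:
        raise ValueError("rc_bray must lie in [-1, 1]")
    if bnti > bnti_cut:
        return "variable_selection"
    if bnti < -bnti_cut:
        return "homogeneous_selection"
    if rc_bray > rc_cut:
        return "dispersal_limitation"
    if rc_bray < -rc_cut:
        return "homogenizing_dispersal"
    return "undominated"


def _pair_rng(seed, stage: int, i: int, j: int) -> np.random.Generator:
    """Independent stream per (stage, pair) so results are order-independent."""
    ss = np.random.SeedSequence(entropy=0 if seed is None else int(seed),
                                spawn_key=(stage, int(i), int(j)))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# βNTI
# ---------------------------------------------------------------------------


def _beta_mntd_indexed(wx, ix, wy, iy, dmat) -> float:
    sub = dmat[np.ix_(ix, iy)]
    return float(0.5 * (wx @ sub.min(axis=1) + wy @ sub.min(axis=0)))


class _BntiEngine:
    """Precomputed cophenetic matrix over a fixed species pool."""

    def __init__(self, table: CommunityTable, tree: TreeNode, pool_taxa=None):
        counts = table.counts
        if pool_taxa is None:
            pool_taxa = counts.index[counts.sum(axis=1) > 0].tolist()
        tip_names = {t.name for t in tree.tips()}
        dropped = [t for t in pool_taxa if t not in tip_names]
        if dropped:
            warnings.warn(
                f"{len(dropped)} pool taxa absent from tree dropped for beta-MNTD"
            )
            pool_taxa = [t for t in pool_taxa if t in tip_names]
        if len(pool_taxa) < 3:
            raise ValueError("species pool too small for a beta-MNTD null")
        pruned = tree.shear(pool_taxa)
        dm = cophenetic(pruned)
        order = [dm.index(t) for t in pool_taxa]
        self.dmat = dm.data[np.ix_(order, order)]
        self.pool_taxa = pool_taxa
        self.counts = counts.loc[pool_taxa]

    def pair(self, x: str, y: str, reps: int, seed, i: int, j: int):
        cx = self.counts[x].to_numpy(dtype=float)
        cy = self.counts[y].to_numpy(dtype=float)
        ix = np.flatnonzero(cx > 0)
        iy = np.flatnonzero(cy > 0)
        if ix.size == 0 or iy.size == 0:
            raise ValueError(f"empty community in pair ({x}, {y})")
        wx = cx[ix] / cx[ix].sum()
        wy = cy[iy] / cy[iy].sum()
        obs = _beta_mntd_indexed(wx, ix, wy, iy, self.dmat)
        rng = _pair_rng(seed, _STAGE_BNTI, i, j)
        n_pool = self.dmat.shape[0]
        nulls = np.empty(reps)
        for r in range(reps):
            perm = rng.permutation(n_pool)
            nulls[r] = _beta_mntd_indexed(wx, perm[ix], wy, perm[iy], self.dmat)
        null = NullDistribution(nulls)
        if null.sd == 0:
            # identical taxon sets leave every draw equal to the observed
            # value: no deviation from the null, i.e. bNTI = 0
            if abs(obs - null.mean) < 1e-12:
                return obs, null, 0.0
            raise ValueError("degenerate null: zero variance in beta-MNTD draws")
        return obs, null, (obs - null.mean) / null.sd


def bnti_pair(x: str, y: str, table: CommunityTable, tree: TreeNode,
              reps: int = 999, seed=None, pool_taxa=None):
    """βMNTD, its taxa-shuffle null, and βNTI for one sample pair.

    The null shuffles taxon labels across the metacommunity species pool
    (all taxa with nonzero total count in ``table`` unless ``pool_taxa`` is
    given) and recomputes βMNTD each draw.
    """
    if reps < 100:
        warnings.warn("reps < 100 is below the recommended minimum for inference")
    engine = _BntiEngine(table, tree, pool_taxa)
    cols = list(table.counts.columns)
    return engine.pair(x, y, reps, seed, cols.index(x), cols.index(y))


# ---------------------------------------------------------------------------
# RC_bray
# ---------------------------------------------------------------------------


class _RcBrayEngine:
    """Occupancy/abundance-weighted probabilistic assembly null."""

    def __init__(self, table: CommunityTable, pool_samples=None):
        counts = table.counts if pool_samples is None else table.counts[list(pool_samples)]
        totals = counts.sum(axis=1)
        keep = totals > 0
        if keep.sum() < 2:
            raise ValueError("metacommunity must contain more than one taxon")
        self.taxa = counts.index[keep].tolist()
        sub = counts.loc[keep]
        self.occupancy = (sub > 0).sum(axis=1).to_numpy(dtype=float)
        self.abundance = totals[keep].to_numpy(dtype=float)
        self.occ_p = self.occupancy / self.occupancy.sum()
        self.counts = sub

    def _assemble(self, richness: int, n_ind: int, rng) -> np.ndarray:
        s = len(self.taxa)
        richness = min(richness, s)
        sel = rng.choice(s, size=richness, replace=False, p=self.occ_p)
        out = np.zeros(s)
        out[sel] = 1.0
        if n_ind > richness:
            ab = self.abundance[sel]
            out[sel] += rng.multinomial(n_ind - richness, ab / ab.sum())
        return out

    def pair(self, x: str, y: str, reps: int, seed, i: int, j: int):
        cx = self.counts[x].to_numpy(dtype=float)
        cy = self.counts[y].to_numpy(dtype=float)
        obs = bray_curtis(cx, cy)
        rx, nx = int((cx > 0).sum()), int(cx.sum())
        ry, ny = int((cy > 0).sum()), int(cy.sum())
        rng = _pair_rng(seed, _STAGE_RC, i, j)
        nulls = np.empty(reps)
        for r in range(reps):
            a = self._assemble(rx, nx, rng)
            b = self._assemble(ry, ny, rng)
            nulls[r] = bray_curtis(a, b)
        null = NullDistribution(nulls)
        below = int((nulls < obs - 1e-12).sum())
        ties = int((np.abs(nulls - obs) <= 1e-12).sum())
        rc = (below + 0.5 * ties) / reps
        return obs, null, 2.0 * (rc - 0.5)


def rc_bray_pair(x: str, y: str, table: CommunityTable,
                 reps: int = 999, seed=None, pool_samples=None):
    """Observed Bray–Curtis, its probabilistic-assembly null, and RC_bray.

    RC = ((#null < obs) + 0.5·(#null == obs)) / reps, standardized as
    2·(RC − 0.5) ∈ [−1, 1].
    """
    if reps < 100:
        warnings.warn("reps < 100 is below the recommended minimum for inference")
    engine = _RcBrayEngine(table, pool_samples)
    cols = list(table.counts.columns)
    return engine.pair(x, y, reps, seed, cols.index(x), cols.index(y))


# ---------------------------------------------------------------------------
# Per-group profiles
# ---------------------------------------------------------------------------


def _normalize_groups(groups, sample_ids) -> dict[str, list[str]]:
    if hasattr(groups, "groups") and callable(groups.groups):  # SampleTable
        groups = groups.groups()
    if isinstance(groups, pd.Series):
        out: dict[str, list[str]] = {}
        for sid, g in groups.items():
            out.setdefault(g, []).append(sid)
        groups = out
    unknown = {s for sids in groups.values() for s in sids} - set(sample_ids)
    if unknown:
        raise KeyError(f"group samples missing from table: {sorted(unknown)}")
    return {str(g): list(sids) for g, sids in groups.items()}


def assembly_profile(table: CommunityTable, tree: TreeNode, groups,
                     reps: int = 999, seed=None, pool: str = "metacommunity",
                     bnti_cut: float = 2.0, rc_cut: float = 0.95):
    """Score all within-group sample pairs and tally process fractions.

    Parameters
    ----------
    groups : SampleTable, pandas.Series, or dict
        Mapping of group label → sample ids (a Series maps sample → group).
    pool : {"metacommunity", "group"}
        Species pool and sample pool for the null models: either the full
        table (default) or each group separately. Recorded in the output.

    Returns
    -------
    pairs : pandas.DataFrame
        One row per pair: sample_a, sample_b, group, beta_mntd, bnti,
        bc_obs, rc_bray, process.
    fractions : pandas.DataFrame
        Per-group fraction of pairs in each of the five categories
        (rows sum to 1).
    """
    if pool not in {"metacommunity", "group"}:
        raise ValueError("pool must be 'metacommunity' or 'group'")
    groups = _normalize_groups(groups, table.sample_ids)
    cols = list(table.counts.columns)

    if pool == "metacommunity":
        bnti_engine = _BntiEngine(table, tree)
        rc_engine = _RcBrayEngine(table)

    rows = []
    for gname, sids in groups.items():
        if len(sids) < 2:
            warnings.warn(f"group {gname!r} has fewer than 2 samples; skipped")
            continue
        if pool == "group":
            gtab = table.subset_samples(sids)
            bnti_engine = _BntiEngine(gtab, tree)
            rc_engine = _RcBrayEngine(gtab)
        for a_idx in range(len(sids)):
            for b_idx in range(a_idx + 1, len(sids)):
                x, y = sids[a_idx], sids[b_idx]
                i, j = cols.index(x), cols.index(y)
                obs_mntd, _, bnti = bnti_engine.pair(x, y, reps, seed, i, j)
                bc_obs, _, rc = rc_engine.pair(x, y, reps, seed, i, j)
                rows.append({
                    "sample_a": x, "sample_b": y, "group": gname,
                    "beta_mntd": obs_mntd, "bnti": bnti,
                    "bc_obs": bc_obs, "rc_bray": rc,
                    "process": classify_processes(bnti, rc, bnti_cut, rc_cut),
                })
    pairs = pd.DataFrame(rows)
    if pairs.empty:
        raise ValueError("no scorable pairs (all groups too small)")
    frac = (
        pairs.groupby("group")["process"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=list(PROCESSES), fill_value=0.0)
    )
    frac.attrs["pool"] = pool
    pairs.attrs["pool"] = pool
    return pairs, frac


def per_phylum_assembly(table: CommunityTable, tree: TreeNode, phylum: str,
                        groups, reps: int = 999, seed=None,
                        min_taxa: int = 20, **kwargs):
    """Assembly profile restricted to one phylum's taxa.

    The count table is subset to the phylum, the tree pruned to its tips
    and abundances renormalized within the subset (implicitly, by the
    relative-abundance computations); then :func:`assembly_profile` runs
    unchanged.
    """
    if table.taxonomy is None:
        raise ValueError("table has no taxonomy labels")
    taxa = table.counts.index[table.taxonomy == phylum].tolist()
    if len(taxa) < min_taxa:
        raise ValueError(
            f"phylum {phylum!r} has {len(taxa)} taxa (< min_taxa={min_taxa}); "
            "null standard deviations are unstable for small pools"
        )
    sub = table.subset_taxa(taxa)
    return assembly_profile(sub, tree, groups, reps=reps, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# Abundance-based β-null deviation
# ---------------------------------------------------------------------------


def beta_null_deviation(table: CommunityTable, metric: str = "bray_curtis",
                        tree: TreeNode | None = None, groups=None,
                        reps: int = 999, seed=None,
                        normalized: bool = True) -> pd.DataFrame:
    """Observed β-diversity minus the mean of randomly assembled pairs.

    The null draws, for each sample, its observed number of individuals
    from the metacommunity relative-abundance distribution (richness free
    to vary). Deviations near 0 read as stochastic; near ±1 as
    deterministic. ``metric`` is ``"bray_curtis"`` or ``"weighted_unifrac"``
    (the latter requires ``tree``).
    """
    if metric not in {"bray_curtis", "weighted_unifrac"}:
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "weighted_unifrac" and tree is None:
        raise ValueError("weighted_unifrac requires a tree")
    counts = table.counts
    taxa_totals = counts.sum(axis=1)
    if (taxa_totals > 0).sum() < 2:
        raise ValueError("metacommunity must contain more than one taxon")
    meta_p = (taxa_totals / taxa_totals.sum()).to_numpy(dtype=float)
    cols = list(counts.columns)
    if groups is None:
        group_map = {"all": cols}
    else:
        group_map = _normalize_groups(groups, cols)

    branch = BranchTable(tree, list(counts.index)) if metric == "weighted_unifrac" else None

    def observed(cx, cy):
        if metric == "bray_curtis":
            return bray_curtis(cx, cy)
        return branch.unifrac(cx, cy, normalized=normalized)

    def null_metric(nx_mat, ny_mat):
        if metric == "bray_curtis":
            num = np.abs(nx_mat - ny_mat).sum(axis=1)
            den = (nx_mat + ny_mat).sum(axis=1)
            return num / den
        a = (nx_mat / nx_mat.sum(axis=1, keepdims=True)) @ branch.incidence.T
        b = (ny_mat / ny_mat.sum(axis=1, keepdims=True)) @ branch.incidence.T
        raw = np.abs(a - b) @ branch.lengths
        if not normalized:
            return raw
        return raw / ((a + b) @ branch.lengths)

    rows = []
    for gname, sids in group_map.items():
        for a_idx in range(len(sids)):
            for b_idx in range(a_idx + 1, len(sids)):
                x, y = sids[a_idx], sids[b_idx]
                i, j = cols.index(x), cols.index(y)
                cx = counts[x].to_numpy(dtype=float)
                cy = counts[y].to_numpy(dtype=float)
                obs = observed(cx, cy)
                rng = _pair_rng(seed, _STAGE_BETANULL, i, j)
                nx = rng.multinomial(int(cx.sum()), meta_p, size=reps).astype(float)
                ny = rng.multinomial(int(cy.sum()), meta_p, size=reps).astype(float)
                null_mean = float(null_metric(nx, ny).mean())
                rows.append({
                    "sample_a": x, "sample_b": y, "group": gname, "metric": metric,
                    "observed": obs, "null_mean": null_mean,
                    "deviation": obs - null_mean,
                })
    return pd.DataFrame(rows)
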