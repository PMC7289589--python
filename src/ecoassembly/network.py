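"""Ensemble co-occurrence network inference.

Association between two OTUs is scored with four measures — Pearson and
Spearman correlation on raw counts, and Bray–Curtis and symmetrized
Kullback–Leibler dissimilarity on the OTUs' across-sample relative-abundance
profiles. Each measure gets a permutation p-value (one OTU's vector permuted
across samples); the four p-values are merged with Brown's method, which
extends Fisher's combination to dependent tests using the covariance of the
−2·ln p transforms (Kost–McDermott polynomial approximation, with the
between-measure correlation estimated from the shared permutation draws).
Merged p-values are Benjamini–Hochberg corrected across all candidate pairs;
an edge is retained when both correlation coefficients exceed the magnitude
threshold and the adjusted p-value passes.

Topology metrics, the percentage of negative correlations (PNC), and the
observed/random (O/R) intra- and inter-phylum association statistic are
computed on the resulting graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .community_io import CommunityTable

__all__ = [
    "association_scores",
    "permutation_pvalues",
    "brown_merge",
    "build_network",
    "CooccurrenceNetwork",
    "topology",
    "or_ratio",
]

_KL_PSEUDOCOUNT = 1e-6
_STAGE_NET = 4

# Kost–McDermott cubic approximation to cov(−2 ln p_i, −2 ln p_j) as a
# function of the correlation rho between the underlying statistics.
def _kost_mcdermott_cov(rho):
    return 3.263 * rho + 0.710 * rho ** 2 + 0.027 * rho ** 3


def _profiles(x, y):
    """Across-sample relative-abundance profiles (each sums to 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("profile of an all-zero vector is undefined")
    return x / x.sum(), y / y.sum()


def _kl_prep(p):
    """Pseudocount then renormalize, so KL is defined on zero entries."""
    q = p + _KL_PSEUDOCOUNT
    return q / q.sum()


def _sym_kl(p, q):
    return float(np.sum((p - q) * (np.log(p) - np.log(q))))


def association_scores(x, y) -> dict[str, float]:
    """Pearson, Spearman, Bray–Curtis and symmetrized KL for one OTU pair.

    Correlations are computed on raw counts; the dissimilarities on each
    OTU's across-sample profile normalized to sum 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector; exclude upstream")
    px, py = _profiles(x, y)
    qx, qy = _kl_prep(px), _kl_prep(py)
    return {
        "pearson": float(stats.pearsonr(x, y).statistic),
        "spearman": float(stats.spearmanr(x, y).statistic),
        "bray_curtis": float(np.abs(px - py).sum() / (px + py).sum()),
        "kl": _sym_kl(qx, qy),
    }


def _null_scores(x, y, B: int, rng) -> dict[str, np.ndarray]:
    """Null score vectors for the four measures under sample permutation of y."""
    n = x.size
    perms = np.argsort(rng.random((B, n)), axis=1)
    zx = (x - x.mean()) / x.std(ddof=0)
    zy = (y - y.mean()) / y.std(ddof=0)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    zrx = (rx - rx.mean()) / rx.std(ddof=0)
    zry = (ry - ry.mean()) / ry.std(ddof=0)
    px, py = _profiles(x, y)
    qx, qy = _kl_prep(px), _kl_prep(py)
    lqx, lqy = np.log(qx), np.log(qy)

    py_p = py[perms]                       # B × n permuted profiles
    qy_p = qy[perms]
    lqy_p = lqy[perms]
    return {
        "pearson": (zy[perms] @ zx) / n,
        "spearman": (zry[perms] @ zrx) / n,
        "bray_curtis": np.abs(px - py_p).sum(axis=1) / 2.0,
        "kl": (
            float(qx @ lqx) - qy_p @ lqx - lqy_p @ qx + float(qy @ lqy)
        ),
    }


def permutation_pvalues(x, y, B: int = 1000, rng=None):
    """Permutation p-values per measure, plus the null score vectors.

    Correlations use the two-sided rule p = (#{|null| ≥ |obs|} + 1)/(B+1);
    dissimilarities use the left tail (low dissimilarity = association).
    The null scores are returned so the Brown covariance between measures
    can be estimated from the shared permutation draws.
    """
    if B < 100:
        warnings.warn("B < 100 permutations is too few for small p-values")
    rng = np.random.default_rng(rng)
    obs = association_scores(x, y)
    nulls = _null_scores(np.asarray(x, float), np.asarray(y, float), B, rng)
    pvals = {}
    for meas in ("pearson", "spearman"):
        pvals[meas] = (np.sum(np.abs(nulls[meas]) >= abs(obs[meas]) - 1e-12) + 1) / (B + 1)
    for meas in ("bray_curtis", "kl"):
        pvals[meas] = (np.sum(nulls[meas] <= obs[meas] + 1e-12) + 1) / (B + 1)
    return obs, pvals, nulls


def _null_rho(nulls: dict[str, np.ndarray]) -> np.ndarray:
    """Correlation of the −2 ln p transforms across the four null score sets."""
    measures = ("pearson", "spearman", "bray_curtis", "kl")
    B = nulls["pearson"].size
    transforms = []
    for meas in measures:
        s = nulls[meas]
        if meas in ("pearson", "spearman"):
            # pseudo p of each null draw within its own null distribution
            ptilde = stats.rankdata(-np.abs(s), method="max") / B
        else:
            ptilde = stats.rankdata(s, method="max") / B
        transforms.append(-2.0 * np.log(ptilde))
    rho = np.corrcoef(np.asarray(transforms))
    return np.nan_to_num(rho, nan=0.0)


def brown_merge(p_values, rho) -> float:
    """Brown's method: combine dependent p-values via a scaled chi-square.

    X = −2 Σ ln p has mean 2k and variance 4k + 2 Σ_{i<j} cov_ij with
    cov_ij approximated by the Kost–McDermott cubic in ρ_ij. The merged
    p-value is the upper tail of X/c on f degrees of freedom, with
    c = Var/(2E) and f = 2E²/Var. With ρ = I it reduces to Fisher's method.
    """
    p = np.asarray(p_values, dtype=float)
    rho = np.asarray(rho, dtype=float)
    k = p.size
    if k < 2:
        raise ValueError("need at least 2 p-values")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if rho.shape != (k, k) or not np.allclose(rho, rho.T) or not np.allclose(np.diag(rho), 1.0):
        raise ValueError("rho must be a symmetric correlation matrix with unit diagonal")
    X = -2.0 * np.log(p).sum()
    E = 2.0 * k
    iu = np.triu_indices(k, 1)
    var = 4.0 * k + 2.0 * _kost_mcdermott_cov(rho[iu]).sum()
    c = var / (2.0 * E)
    f = 2.0 * E ** 2 / var
    return float(stats.chi2.sf(X / c, f))


@dataclass
class CooccurrenceNetwork:
    """Retained signed edges plus the full candidate-edge table."""

    graph: nx.Graph
    edges: pd.DataFrame       # retained edges with all statistics
    candidates: pd.DataFrame  # every tested pair
    thresholds: dict = field(default_factory=dict)

    @property
    def pnc(self) -> float:
        """Percentage of negative edges among retained edges."""
        if len(self.edges) == 0:
            return float("nan")
        return 100.0 * float((self.edges["sign"] == "-").mean())


def build_network(table: CommunityTable, r_cut: float = 0.6,
                  p_cut: float = 0.01, B: int = 1000, seed=None,
                  taxonomy: pd.Series | None = None) -> CooccurrenceNetwork:
    """Infer a co-occurrence network from a (prevalence-filtered) table.

    All OTU pairs are candidates. A pair becomes an edge when
    |pearson| > r_cut and |spearman| > r_cut and the BH-adjusted Brown
    p-value < p_cut (BH across all candidate pairs). The edge sign follows
    the Pearson coefficient (Spearman breaks a zero tie). Nodes are the
    OTUs participating in at least one retained edge.
    """
    counts = table.counts
    if counts.shape[1] < 5:
        raise ValueError("need at least 5 samples")
    arr = counts.to_numpy(dtype=float)
    variable = np.ptp(arr, axis=1) > 0
    if not variable.all():
        warnings.warn(f"{int((~variable).sum())} constant OTU vectors excluded")
    otus = counts.index[variable].tolist()
    arr = arr[variable]
    tax = taxonomy if taxonomy is not None else table.taxonomy

    rows = []
    for i in range(len(otus)):
        for j in range(i + 1, len(otus)):
            ss = np.random.SeedSequence(entropy=0 if seed is None else int(seed),
                                        spawn_key=(_STAGE_NET, i, j))
            rng = np.random.default_rng(ss)
            obs, pvals, nulls = permutation_pvalues(arr[i], arr[j], B=B, rng=rng)
            rho = _null_rho(nulls)
            brown_p = brown_merge(
                [pvals[m] for m in ("pearson", "spearman", "bray_curtis", "kl")], rho
            )
            rows.append({
                "otu_a": otus[i], "otu_b": otus[j],
                "pearson": obs["pearson"], "spearman": obs["spearman"],
                "bray_curtis": obs["bray_curtis"], "kl": obs["kl"],
                "p_pearson": pvals["pearson"], "p_spearman": pvals["spearman"],
                "p_bray_curtis": pvals["bray_curtis"], "p_kl": pvals["kl"],
                "brown_p": brown_p,
            })
    cand = pd.DataFrame(rows)
    if cand.empty:
        warnings.warn("no candidate pairs; empty network")
        return CooccurrenceNetwork(nx.Graph(), cand, cand,
                                   {"r_cut": r_cut, "p_cut": p_cut, "B": B})
    cand["bh_q"] = multipletests(cand["brown_p"], method="fdr_bh")[1]
    strong = (cand["pearson"].abs() > r_cut) & (cand["spearman"].abs() > r_cut)
    cand["retained"] = strong & (cand["bh_q"] < p_cut)

    edges = cand[cand["retained"]].copy()
    sign = np.where(edges["pearson"] != 0,
                    np.sign(edges["pearson"]), np.sign(edges["spearman"]))
    edges["sign"] = np.where(sign >= 0, "+", "-")

    g = nx.Graph()
    for _, e in edges.iterrows():
        g.add_edge(e["otu_a"], e["otu_b"], weight=float(e["pearson"]),
                   sign=e["sign"], brown_p=float(e["brown_p"]))
    if tax is not None:
        nx.set_node_attributes(
            g, {n: str(tax.get(n, "unclassified")) for n in g.nodes}, "phylum")
    if len(edges) == 0:
        warnings.warn("zero retained edges; empty network")
    return CooccurrenceNetwork(g, edges, cand,
                               {"r_cut": r_cut, "p_cut": p_cut, "B": B})


def topology(net) -> dict[str, float]:
    """Topology metrics plus PNC.

    Path length and diameter are computed on the largest connected
    component; modularity uses deterministic greedy modularity
    maximization. An empty network yields NaN markers, not exceptions.
    """
    g = net.graph if isinstance(net, CooccurrenceNetwork) else net
    n, e = g.number_of_nodes(), g.number_of_edges()
    out: dict[str, float] = {"n_nodes": float(n), "n_edges": float(e)}
    if n == 0 or e == 0:
        for key in ("graph_density", "average_degree", "average_clustering",
                    "average_path_length", "diameter", "modularity", "pnc"):
            out[key] = float("nan")
        return out
    out["graph_density"] = 2.0 * e / (n * (n - 1)) if n > 1 else float("nan")
    out["average_degree"] = 2.0 * e / n
    out["average_clustering"] = float(np.mean(list(nx.clustering(g).values())))
    lcc = g.subgraph(max(nx.connected_components(g), key=len))
    if lcc.number_of_nodes() > 1:
        out["average_path_length"] = nx.average_shortest_path_length(lcc)
        out["diameter"] = float(nx.diameter(lcc))
    else:
        out["average_path_length"] = float("nan")
        out["diameter"] = float("nan")
    comms = nx.algorithms.community.greedy_modularity_communities(g)
    out["modularity"] = nx.algorithms.community.modularity(g, comms)
    if isinstance(net, CooccurrenceNetwork):
        out["pnc"] = net.pnc
    else:
        signs = nx.get_edge_attributes(g, "sign")
        out["pnc"] = 100.0 * np.mean([s == "-" for s in signs.values()]) if signs else float("nan")
    return out


def or_ratio(net, labels: pd.Series | dict | None = None) -> pd.DataFrame:
    """Observed vs random intra/inter-phylum edge percentages.

    O% = 100·Eo/E for each unordered phylum pair. R% is the exact
    without-replacement expectation from the node frequencies: for one
    phylum A, 100·n_A(n_A−1)/(n(n−1)); for distinct A,B,
    100·2·n_A·n_B/(n(n−1)). The with-replacement product approximation is
    emitted alongside. O/R > 1 reads as deterministic association, < 1 as
    stochastic. ΣO = ΣR = 100 over all pairs.
    """
    g = net.graph if isinstance(net, CooccurrenceNetwork) else net
    E = g.number_of_edges()
    if E < 1:
        raise ValueError("network has no edges")
    if labels is None:
        labels = nx.get_node_attributes(g, "phylum")
        if len(labels) != g.number_of_nodes():
            raise ValueError("every node needs a phylum label")
    lab = {n: labels[n] for n in g.nodes}
    n = g.number_of_nodes()
    phyla = sorted(set(lab.values()))
    counts = {p: sum(1 for v in lab.values() if v == p) for p in phyla}

    eo: dict[tuple[str, str], int] = {}
    for u, v in g.edges:
        key = tuple(sorted((lab[u], lab[v])))
        eo[key] = eo.get(key, 0) + 1

    rows = []
    for ai, a in enumerate(phyla):
        for b in phyla[ai:]:
            na, nb = counts[a], counts[b]
            obs = eo.get((a, b) if a <= b else (b, a), 0)
            o_pct = 100.0 * obs / E
            if a == b:
                r_pct = 100.0 * na * (na - 1) / (n * (n - 1))
                r_wr = 100.0 * (na / n) ** 2
            else:
                r_pct = 100.0 * 2 * na * nb / (n * (n - 1))
                r_wr = 100.0 * 2 * (na / n) * (nb / n)
            rows.append({
                "phylum_a": a, "phylum_b": b, "Eo": obs, "E": E,
                "F_a": na / n, "F_b": nb / n,
                "O_pct": o_pct, "R_pct": r_pct,
                "R_pct_with_replacement": r_wr,
                "ratio": o_pct / r_pct if r_pct > 0 else float("nan"),
            })
    return pd.DataFrame(rows)


def write_graphml(net: CooccurrenceNetwork, path) -> None:
    nx.write_graphml(net.graph, path)
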