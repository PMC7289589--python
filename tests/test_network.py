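import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ecoassembly import (CommunityTable, association_scores, brown_merge,
                         build_network, or_ratio, permutation_pvalues,
                         topology)


def brown_oracle(p_values, rho):
    """Independent re-implementation of the dependent-p-value combination."""
    k = len(p_values)
    X = -2.0 * sum(np.log(p) for p in p_values)
    var = 4.0 * k
    for i in range(k):
        for j in range(i + 1, k):
            r = rho[i][j]
            var += 2.0 * (3.263 * r + 0.710 * r ** 2 + 0.027 * r ** 3)
    E = 2.0 * k
    c = var / (2 * E)
    f = 2 * E ** 2 / var
    return stats.chi2.sf(X / c, f)


class TestAssociationScores:
    def test_proportional_profiles(self):
        x = np.array([1, 4, 2, 8, 5])
        scores = association_scores(x, 2 * x)
        assert scores["pearson"] == pytest.approx(1.0)
        assert scores["spearman"] == pytest.approx(1.0)
        assert scores["bray_curtis"] == pytest.approx(0.0, abs=1e-12)
        assert scores["kl"] == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_support_bc_one(self):
        x = np.array([3, 5, 0, 0, 0])
        y = np.array([0, 0, 2, 4, 1])
        assert association_scores(x, y)["bray_curtis"] == pytest.approx(1.0)

    def test_five_sample_toy_matches_oracle(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.0])
        scores = association_scores(x, y)
        assert scores["pearson"] == pytest.approx(stats.pearsonr(x, y)[0])
        assert scores["spearman"] == pytest.approx(stats.spearmanr(x, y)[0])
        px, py = x / x.sum(), y / y.sum()
        assert scores["bray_curtis"] == pytest.approx(
            np.abs(px - py).sum() / (px + py).sum())
        eps = 1e-6
        qx = (px + eps) / (px + eps).sum()
        qy = (py + eps) / (py + eps).sum()
        kl = np.sum(qx * np.log(qx / qy)) + np.sum(qy * np.log(qy / qx))
        assert scores["kl"] == pytest.approx(kl, rel=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            association_scores([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])


class TestPermutationPvalues:
    def test_extreme_observation_floor(self):
        x = np.arange(1.0, 13.0)
        y = 3 * x + 1  # perfectly correlated; no permutation can beat it
        _, pvals, _ = permutation_pvalues(x, y, B=200,
                                          rng=np.random.default_rng(0))
        assert pvals["pearson"] == pytest.approx(1 / 201)
        assert pvals["spearman"] == pytest.approx(1 / 201)

    def test_reproducible(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 30, 10).astype(float)
        y = rng.integers(0, 30, 10).astype(float)
        a = permutation_pvalues(x, y, B=150, rng=np.random.default_rng(1))[1]
        b = permutation_pvalues(x, y, B=150, rng=np.random.default_rng(1))[1]
        assert a == b

    def test_independent_pairs_uniform(self):
        # p-values for independent pairs should be ~Uniform(0,1)
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(120):
            x = rng.lognormal(0, 1, 12)
            y = rng.lognormal(0, 1, 12)
            _, p, _ = permutation_pvalues(x, y, B=120,
                                          rng=np.random.default_rng(rng.integers(2**31)))
            pvals.append(p["pearson"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestBrownMerge:
    def test_identity_rho_is_fisher(self):
        p = [0.02, 0.01, 0.03, 0.05]
        fisher = stats.combine_pvalues(p, method="fisher").pvalue
        assert brown_merge(p, np.eye(4)) == pytest.approx(fisher, abs=1e-12)

    def test_perfect_dependence_returns_common_p(self):
        for p in (0.001, 0.02, 0.5):
            merged = brown_merge([p] * 4, np.ones((4, 4)))
            assert merged == pytest.approx(p, rel=1e-9)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            k = rng.integers(2, 6)
            p = rng.uniform(1e-4, 1, k)
            a = rng.uniform(-0.5, 1, (k, k))
            rho = (a + a.T) / 2
            np.fill_diagonal(rho, 1.0)
            assert brown_merge(p, rho) == pytest.approx(
                brown_oracle(p.tolist(), rho.tolist()), abs=1e-9)

    def test_monotone_in_inputs(self):
        rho = np.eye(4) * 0.5 + 0.5
        base = brown_merge([0.01, 0.02, 0.03, 0.04], rho)
        worse = brown_merge([0.05, 0.02, 0.03, 0.04], rho)
        assert worse >= base

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            brown_merge([0.0, 0.5], np.eye(2))


def planted_block_table(n_samples=40, block=8, r_latent=0.95, seed=0):
    """Two blocks of co-varying OTUs, independent across blocks."""
    rng = np.random.default_rng(seed)
    cols = {}
    z = rng.standard_normal((2, n_samples))
    rows = []
    for b in range(2):
        for i in range(block):
            eps = rng.standard_normal(n_samples)
            latent = r_latent * z[b] + np.sqrt(1 - r_latent ** 2) * eps
            # mild skew: heavier tails would erode the linear correlation
            rows.append(np.floor(np.exp(0.5 * latent) * 30).astype(int))
    counts = pd.DataFrame(
        np.array(rows), index=[f"b{b}_o{i}" for b in range(2) for i in range(block)],
        columns=[f"s{j}" for j in range(n_samples)])
    return CommunityTable(counts)


class TestBuildNetwork:
    def test_weak_correlation_excluded(self):
        # r below the magnitude cut never becomes an edge, whatever its p
        rng = np.random.default_rng(5)
        x = rng.standard_normal(200)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(200)
        counts = pd.DataFrame({"a": np.floor(np.exp(x) * 10).astype(int),
                               "b": np.floor(np.exp(y) * 10).astype(int)}).T
        counts.columns = [f"s{i}" for i in range(200)]
        table = CommunityTable(counts)
        net = build_network(table, B=150, seed=0)
        r = net.candidates["pearson"].iloc[0]
        if abs(r) <= 0.6:
            assert len(net.edges) == 0

    def test_planted_blocks_recovered(self):
        table = planted_block_table(seed=1)
        net = build_network(table, B=300, seed=1)
        within = {frozenset((f"b{b}_o{i}", f"b{b}_o{j}"))
                  for b in range(2) for i in range(8) for j in range(i + 1, 8)}
        got = {frozenset((u, v)) for u, v in net.graph.edges}
        recall = len(got & within) / len(within)
        cross = len(got - within)
        assert recall >= 0.9
        assert cross <= 2

    def test_invariant_to_otu_order(self):
        table = planted_block_table(n_samples=20, block=3, seed=2)
        a = build_network(table, B=120, seed=3)
        shuffled = CommunityTable(table.counts.sample(frac=1, random_state=1))
        b = build_network(shuffled, B=120, seed=3)
        ea = {frozenset((u, v)) for u, v in a.graph.edges}
        eb = {frozenset((u, v)) for u, v in b.graph.edges}
        assert ea == eb


class TestTopology:
    def test_complete_graph(self):
        g = nx.complete_graph(5)
        t = topology(g)
        assert t["graph_density"] == 1.0
        assert t["average_degree"] == 4.0
        assert t["average_clustering"] == 1.0
        assert t["diameter"] == 1.0

    def test_path_graph(self):
        g = nx.path_graph(4)
        t = topology(g)
        assert t["average_path_length"] == pytest.approx(10 / 6)
        assert t["diameter"] == 3.0

    def test_empty_graph_nan_markers(self):
        t = topology(nx.Graph())
        assert np.isnan(t["graph_density"])
        assert np.isnan(t["modularity"])

    def test_pnc(self):
        g = nx.Graph()
        g.add_edge("a", "b", sign="+")
        g.add_edge("b", "c", sign="-")
        g.add_edge("c", "d", sign="-")
        assert topology(g)["pnc"] == pytest.approx(100 * 2 / 3)


class TestOrRatio:
    @staticmethod
    def ring_graph(labels):
        g = nx.Graph()
        nodes = list(labels)
        for i, n in enumerate(nodes):
            g.add_edge(n, nodes[(i + 1) % len(nodes)])
        return g

    def test_single_phylum_identity(self):
        g = self.ring_graph([f"n{i}" for i in range(6)])
        labels = pd.Series("OnePhylum", index=[f"n{i}" for i in range(6)])
        out = or_ratio(g, labels)
        assert out["O_pct"].iloc[0] == 100.0
        assert out["R_pct"].iloc[0] == 100.0
        assert out["ratio"].iloc[0] == pytest.approx(1.0)

    def test_partition_identities(self):
        rng = np.random.default_rng(4)
        g = nx.gnp_random_graph(20, 0.3, seed=2)
        labels = pd.Series(rng.choice(["P1", "P2", "P3"], size=20),
                           index=list(g.nodes))
        out = or_ratio(g, labels)
        assert out["O_pct"].sum() == pytest.approx(100.0, abs=1e-9)
        assert out["R_pct"].sum() == pytest.approx(100.0, abs=1e-9)
        assert out["R_pct_with_replacement"].sum() == pytest.approx(100.0, abs=1.0)

    def test_matches_random_reassignment_oracle(self):
        rng = np.random.default_rng(9)
        g = nx.gnp_random_graph(15, 0.4, seed=5)
        nodes = list(g.nodes)
        labels = pd.Series(rng.choice(["P1", "P2"], size=len(nodes)), index=nodes)
        out = or_ratio(g, labels).set_index(["phylum_a", "phylum_b"])
        E = g.number_of_edges()
        n = len(nodes)
        # oracle: rewire edges to uniformly random node pairs, tally O%
        n_rep = 4000
        tallies = {key: [] for key in out.index}
        lab = labels.to_numpy()
        for _ in range(n_rep):
            counts = {key: 0 for key in out.index}
            for _e in range(E):
                i, j = rng.choice(n, 2, replace=False)
                key = tuple(sorted((lab[i], lab[j])))
                counts[key] += 1
            for key in counts:
                tallies[key].append(100 * counts[key] / E)
        for key in out.index:
            mc = np.asarray(tallies[key])
            se = mc.std(ddof=1) / np.sqrt(n_rep)
            assert abs(mc.mean() - out.loc[key, "R_pct"]) < max(3 * se, 0.05)


def test_bh_matches_step_up_definition():
    # worked example: m=10 p-values, step-up thresholds i/m * q
    p = np.array([0.0001, 0.0004, 0.0019, 0.0095, 0.0201,
                  0.0278, 0.0298, 0.0344, 0.0459, 0.3240])
    q = 0.05
    order = np.argsort(p)
    m = len(p)
    passed = [i for i in range(m) if p[order[i]] <= (i + 1) / m * q]
    k = max(passed) + 1 if passed else 0
    reject_manual = np.zeros(m, bool)
    reject_manual[order[:k]] = True
    reject_sm = multipletests(p, alpha=q, method="fdr_bh")[0]
    assert (reject_manual == reject_sm).all()
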