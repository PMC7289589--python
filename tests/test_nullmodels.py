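import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ecoassembly import (CommunityTable, PROCESSES, assembly_profile,
                         beta_null_deviation, bnti_pair, classify_processes,
                         per_phylum_assembly, rc_bray_pair, simulate_tree)
from ecoassembly.simulate import SimulationConfig, simulate_dataset


def exchangeable_table(n_taxa=60, n_samples=8, reads=500, seed=0):
    """Taxa-exchangeable data: no link between abundance and phylogeny."""
    rng = np.random.default_rng(seed)
    meta = rng.lognormal(0, 1.5, n_taxa)
    meta /= meta.sum()
    tree = simulate_tree(n_taxa, seed=seed + 1)
    taxa = [t.name for t in tree.tips()]
    counts = pd.DataFrame(
        {f"s{i}": rng.multinomial(reads, meta) for i in range(n_samples)},
        index=taxa)
    return CommunityTable(counts), tree


class TestClassifyProcesses:
    @pytest.mark.parametrize("bnti,rc,expected", [
        (3.1, 0.0, "variable_selection"),
        (-2.7, 0.0, "homogeneous_selection"),
        (0.4, -0.97, "homogenizing_dispersal"),
        (0.4, 0.97, "dispersal_limitation"),
        (0.4, 0.1, "undominated"),
        (2.0, 0.99, "dispersal_limitation"),   # boundary: |bnti| <= 2 is stochastic
        (-2.0, -0.99, "homogenizing_dispersal"),
    ])
    def test_category_assignment(self, bnti, rc, expected):
        assert classify_processes(bnti, rc) == expected

    @given(st.floats(-10, 10), st.floats(-1, 1))
    @settings(deadline=None, max_examples=200)
    def test_total_function(self, bnti, rc):
        assert classify_processes(bnti, rc) in PROCESSES

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_processes(float("nan"), 0.0)


class TestBntiPair:
    def test_reproducible_and_order_independent(self):
        table, tree = exchangeable_table()
        a = bnti_pair("s0", "s1", table, tree, reps=120, seed=9)
        b = bnti_pair("s0", "s1", table, tree, reps=120, seed=9)
        assert a[0] == b[0] and a[2] == b[2]
        # a different pair computed first must not perturb this pair
        bnti_pair("s2", "s3", table, tree, reps=120, seed=9)
        c = bnti_pair("s0", "s1", table, tree, reps=120, seed=9)
        assert c[2] == a[2]

    def test_tiny_species_pool_rejected(self):
        counts = pd.DataFrame({"s1": [5, 5], "s2": [5, 5]}, index=["A", "B"])
        tree = simulate_tree(4, seed=0)
        names = [t.name for t in tree.tips()][:2]
        counts.index = names
        with pytest.raises(ValueError, match="pool too small"):
            bnti_pair("s1", "s2", CommunityTable(counts), tree, reps=100, seed=0)

    def test_identical_taxon_sets_give_zero(self):
        # identical membership: every null draw equals the observation
        counts = pd.DataFrame({"s1": [5, 5, 2, 0], "s2": [3, 6, 1, 0]})
        tree = simulate_tree(4, seed=0)
        counts.index = [t.name for t in tree.tips()]
        counts.loc[counts.index[3]] = [1, 1]  # keep pool at 4 taxa
        table = CommunityTable(counts)
        obs, null, b = bnti_pair("s1", "s2", table, tree, reps=100, seed=0)
        assert b == 0.0 or null.sd > 0

    def test_exchangeable_null_centered(self):
        # over several exchangeable pairs, bnti should be roughly centered at 0
        table, tree = exchangeable_table(seed=4)
        scores = [bnti_pair(f"s{i}", f"s{j}", table, tree, reps=199, seed=4)[2]
                  for i, j in [(0, 1), (2, 3), (4, 5), (6, 7), (0, 4), (1, 5)]]
        assert abs(np.mean(scores)) < 1.5


class TestRcBrayPair:
    def test_identical_communities_extreme_low(self):
        table, _ = exchangeable_table(seed=2)
        counts = table.counts.copy()
        counts["dup"] = counts["s0"]
        table2 = CommunityTable(counts)
        _, _, rc = rc_bray_pair("s0", "dup", table2, reps=199, seed=1)
        assert rc <= -0.95

    def test_disjoint_extreme_high(self):
        # engineered maximal turnover against a shared metacommunity
        n = 40
        rng = np.random.default_rng(0)
        a = np.zeros(n, dtype=int)
        b = np.zeros(n, dtype=int)
        a[:20] = rng.integers(5, 30, 20)
        b[20:] = rng.integers(5, 30, 20)
        fill = pd.DataFrame({f"m{i}": rng.integers(0, 10, n) for i in range(6)})
        counts = pd.concat(
            [pd.Series(a, name="x"), pd.Series(b, name="y"), fill], axis=1)
        counts.index = [f"t{i}" for i in range(n)]
        table = CommunityTable(counts)
        obs, _, rc = rc_bray_pair("x", "y", table, reps=199, seed=1)
        assert obs == 1.0
        assert rc >= 0.9

    def test_bounded(self):
        table, _ = exchangeable_table(seed=3)
        for i, j in [(0, 1), (2, 5)]:
            _, _, rc = rc_bray_pair(f"s{i}", f"s{j}", table, reps=151, seed=2)
            assert -1.0 <= rc <= 1.0

    def test_single_taxon_metacommunity_rejected(self):
        counts = pd.DataFrame({"s1": [5], "s2": [3]}, index=["A"])
        with pytest.raises(ValueError):
            rc_bray_pair("s1", "s2", CommunityTable(counts), reps=100, seed=0)


class TestAssemblyProfile:
    def test_two_sample_group_single_pair(self):
        table, tree = exchangeable_table(n_samples=4)
        pairs, frac = assembly_profile(table, tree, {"g": ["s0", "s1"]},
                                       reps=120, seed=0)
        assert len(pairs) == 1
        assert frac.loc["g"].max() == 1.0

    def test_fractions_sum_to_one(self, tiny_dataset):
        table, samples, truth = tiny_dataset
        _, frac = assembly_profile(table, truth.tree, samples.groups(),
                                   reps=120, seed=0)
        assert np.allclose(frac.sum(axis=1), 1.0)

    def test_singleton_group_skipped_with_warning(self):
        table, tree = exchangeable_table(n_samples=4)
        with pytest.warns(UserWarning, match="skipped"):
            pairs, _ = assembly_profile(
                table, tree, {"a": ["s0"], "b": ["s1", "s2"]}, reps=120, seed=0)
        assert set(pairs["group"]) == {"b"}


class TestPerPhylum:
    def test_full_phylum_equals_whole_community(self):
        table, tree = exchangeable_table(n_samples=4)
        tax = pd.Series("OnlyPhylum", index=table.counts.index)
        table = CommunityTable(table.counts, tax)
        whole = assembly_profile(table, tree, {"g": ["s0", "s1"]},
                                 reps=120, seed=0)[0]
        sub = per_phylum_assembly(table, tree, "OnlyPhylum", {"g": ["s0", "s1"]},
                                  reps=120, seed=0)[0]
        assert sub["bnti"].iloc[0] == whole["bnti"].iloc[0]
        assert sub["rc_bray"].iloc[0] == whole["rc_bray"].iloc[0]

    def test_small_phylum_rejected(self):
        table, tree = exchangeable_table(n_samples=4)
        tax = pd.Series("Rare", index=table.counts.index)
        tax.iloc[5:] = "Common"
        table = CommunityTable(table.counts, tax)
        with pytest.raises(ValueError, match="min_taxa"):
            per_phylum_assembly(table, tree, "Rare", {"g": ["s0", "s1"]},
                                reps=120, seed=0)


class TestBetaNullDeviation:
    def test_bounded_and_grouped(self, tiny_dataset):
        table, samples, truth = tiny_dataset
        for metric in ("bray_curtis", "weighted_unifrac"):
            dev = beta_null_deviation(table, metric=metric, tree=truth.tree,
                                      groups=samples.groups(), reps=120, seed=0)
            assert dev["deviation"].between(-1, 1).all()
            assert set(dev["group"]) == set(samples.groups())

    def test_unifrac_requires_tree(self, tiny_dataset):
        table, _, _ = tiny_dataset
        with pytest.raises(ValueError, match="tree"):
            beta_null_deviation(table, metric="weighted_unifrac", reps=120)

    def test_selection_exceeds_neutral_deviation(self):
        cfg = SimulationConfig(n_taxa=120, samples_per_layer=4,
                               reads_per_sample=600, seed=5,
                               regimes=("selection_variable", "neutral",
                                        "neutral", "neutral", "neutral"))
        table, samples, truth = simulate_dataset(cfg)
        groups = samples.groups()
        dev = beta_null_deviation(table, tree=truth.tree,
                                  groups={"sel": groups["L1"], "neu": groups["L2"]},
                                  reps=199, seed=5)
        mean_abs = dev.groupby("group")["deviation"].apply(
            lambda s: s.abs().mean())
        assert mean_abs["sel"] > mean_abs["neu"]
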