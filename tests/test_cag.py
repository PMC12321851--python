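"""Filtering, network construction, Ward CAG clustering, differential tests."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cagnet.cag import (FilterRules, build_network, cag_abundance,
                        cag_differential, cluster_cags, filter_genera,
                        filter_low_count_features, genus_venn, spearman_matrix)
from cagnet.simulate import SimConfig, simulate_genus_table

from conftest import make_table


class TestLowCountFilter:
    def _counts(self, presence, reads):
        """One feature with given presence (samples > 0) and total reads.

        Requires reads >= presence: every present sample carries >= 1 read.
        """
        n = 40
        col = np.zeros(n)
        col[:presence] = 1
        if presence:
            col[0] += reads - presence
        return col

    def test_high_presence_kept_regardless_of_reads(self):
        tbl = make_table(np.column_stack([self._counts(31, 31), self._counts(35, 1000)]))
        kept = filter_low_count_features(tbl, FilterRules())
        assert list(kept.columns) == list(tbl.columns)

    def test_fails_both_removed(self):
        tbl = make_table(np.column_stack([self._counts(2, 5), self._counts(35, 1000)]))
        kept = filter_low_count_features(tbl)
        assert list(kept.columns) == ["g1"]

    def test_hand_enumerated_toy_table(self):
        # presence / total-reads per feature: (31,31) (2,50) (2,5) (30,30) (0,0)
        cols = [self._counts(31, 31), self._counts(2, 50), self._counts(2, 5),
                self._counts(30, 30), np.zeros(40)]
        tbl = make_table(np.column_stack(cols))
        kept = filter_low_count_features(tbl)  # removed iff both thresholds fail
        assert list(kept.columns) == ["g0", "g1", "g3"]
        strict = filter_low_count_features(tbl, exclusion_rule="any")
        assert list(strict.columns) == ["g0", "g3"]

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError, match="count"):
            filter_low_count_features(make_table([[0.5, 1.0]]))

    def test_empty_table_passes_through(self):
        tbl = make_table(np.zeros((0, 0)))
        assert filter_low_count_features(tbl).shape == (0, 0)


class TestGenusFilter:
    def test_low_prevalence_removed(self):
        x = np.full((100, 2), 0.01)
        x[19:, 0] = 0.0  # prevalence 19%
        kept = filter_genera(make_table(x))
        assert list(kept.columns) == ["g1"]

    def test_low_mean_abundance_removed(self):
        x = np.column_stack([np.full(100, 0.0004), np.full(100, 0.01)])
        x[50:, 0] = 0.0004  # prevalence 100%, mean 0.0004 < 0.0005
        kept = filter_genera(make_table(x))
        assert list(kept.columns) == ["g1"]

    def test_hand_enumerated_survivors_keep_original_scale(self, rng):
        n = 50
        x = np.zeros((n, 4))
        x[:, 0] = 0.02                         # kept
        x[: n // 2, 1] = 0.001                 # prevalence 50%, mean 5e-4: kept
        x[: 5, 2] = 0.01                       # prevalence 10%: removed
        x[:, 3] = 0.0001                       # mean below cut: removed
        tbl = make_table(x)
        kept = filter_genera(tbl)
        assert list(kept.columns) == ["g0", "g1"]
        # no re-closure: survivors keep their original values
        assert np.allclose(kept["g0"], 0.02)


class TestBuildNetwork:
    def test_duplicated_genus_gives_single_perfect_edge(self, rng):
        x = rng.random(50)
        tbl = make_table(np.column_stack([x, x]))
        net = build_network(tbl)
        assert net.n_edges == 1
        assert net.edges.iloc[0]["rho"] == pytest.approx(1.0)

    def test_independent_genera_yield_no_edges(self):
        """20 independent genera, n=400: BH + 0.4 threshold keep nothing."""
        clean_runs = 0
        for seed in range(20):
            cfg = SimConfig(n_cases=200, n_controls=200, n_genera=20, n_blocks=0,
                            block_sizes=(), effect_blocks={}, seed=seed)
            table, _ = simulate_genus_table(cfg)
            clean_runs += build_network(table).n_edges == 0
        assert clean_runs >= 19

    def test_planted_block_recovers_all_six_edges(self):
        """One block of 4 at latent 0.9 gives exactly C(4,2)=6 edges."""
        hits = 0
        for seed in range(20):
            cfg = SimConfig(n_cases=200, n_controls=200, n_genera=30, n_blocks=1,
                            block_sizes=(4,), within_block_rho=0.9,
                            effect_blocks={}, seed=seed)
            table, truth = simulate_genus_table(cfg)
            net = build_network(table)
            members = set(truth.block_members(1))
            block_edges = net.edges[(net.edges["source"].isin(members)) &
                                    (net.edges["target"].isin(members))]
            hits += (net.n_edges == 6) and (len(block_edges) == 6)
        assert hits >= 18

    def test_constant_genus_excluded_and_logged(self, rng):
        x = np.column_stack([rng.random(30), rng.random(30), np.full(30, 0.5)])
        with pytest.warns(UserWarning, match="constant"):
            net = build_network(make_table(x))
        assert net.excluded == ["g2"]
        assert not net.edges[["source", "target"]].isin(["g2"]).any().any()

    def test_edge_set_invariant_to_sample_and_column_order(self, small_table):
        net1 = build_network(small_table, threshold=0.3)
        shuffled = small_table.iloc[::-1, ::-1]
        net2 = build_network(shuffled, threshold=0.3)
        e1 = {frozenset((r.source, r.target)) for r in net1.edges.itertuples()}
        e2 = {frozenset((r.source, r.target)) for r in net2.edges.itertuples()}
        assert e1 == e2

    def test_negative_edges_need_absolute_rule(self, rng):
        x = rng.standard_normal(200)
        tbl = make_table(np.column_stack([x, -x + 0.01 * rng.standard_normal(200)]))
        assert build_network(tbl, positive_only=True).n_edges == 0
        assert build_network(tbl, positive_only=False).n_edges == 1


class TestClusterCags:
    def test_exact_block_diagonal_recovery(self):
        """rho=1 within, 0 between, 8 blocks: zero within-block distance."""
        sizes = [3, 4, 5, 2, 6, 3, 4, 5]
        labels = np.repeat(np.arange(8), sizes)
        rho = (labels[:, None] == labels[None, :]).astype(float)
        names = [f"g{i}" for i in range(len(labels))]
        part = cluster_cags(pd.DataFrame(rho, index=names, columns=names), k=8)
        assert adjusted_rand_score(labels, part.assignment.to_numpy()) == 1.0

    def test_planted_blocks_high_ari(self, small_cohort, small_config):
        rho, _ = spearman_matrix(small_cohort["genus"])
        part = cluster_cags(rho, k=small_config.n_blocks)
        truth = small_cohort["truth"].block_assignment
        assert adjusted_rand_score(truth.to_numpy(), part.assignment.to_numpy()) >= 0.9

    def test_k_equals_genus_count_gives_flagged_singletons(self, small_table):
        rho, _ = spearman_matrix(small_table)
        part = cluster_cags(rho, k=rho.shape[0])
        report = part.size_bound_report()
        assert (part.sizes == 1).all() and (~report["within_bounds"]).all()

    def test_k_one_single_cag(self, small_table):
        rho, _ = spearman_matrix(small_table)
        part = cluster_cags(rho, k=1)
        assert part.sizes.tolist() == [rho.shape[0]]

    def test_k_above_genus_count_errors(self, small_table):
        rho, _ = spearman_matrix(small_table)
        with pytest.raises(ValueError, match="exceeds"):
            cluster_cags(rho, k=rho.shape[0] + 1)

    def test_deterministic_repeat_calls(self, small_table):
        rho, _ = spearman_matrix(small_table)
        p1 = cluster_cags(rho, k=4)
        p2 = cluster_cags(rho, k=4)
        assert p1.assignment.equals(p2.assignment)


class TestCagAbundance:
    def _partition(self, genera, groups):
        from cagnet.cag import CagPartition
        return CagPartition(assignment=pd.Series(groups, index=genera), k=len(set(groups)),
                            linkage_method="manual")

    def test_singleton_cag_equals_genus(self, rng):
        tbl = make_table(rng.random((10, 3)))
        part = self._partition(tbl.columns, [1, 2, 2])
        for summary in ("mean", "sum"):
            out = cag_abundance(tbl, part, summary)
            assert np.allclose(out["CAG1"], tbl["g0"])

    def test_mean_and_sum_on_known_values(self):
        tbl = make_table([[0.1, 0.2, 0.3]])
        part = self._partition(tbl.columns, [1, 1, 1])
        assert cag_abundance(tbl, part, "mean").iloc[0, 0] == pytest.approx(0.2)
        assert cag_abundance(tbl, part, "sum").iloc[0, 0] == pytest.approx(0.6)

    def test_sum_conserves_total_abundance(self, small_table, rng):
        part = self._partition(small_table.columns,
                               rng.integers(1, 4, size=small_table.shape[1]))
        out = cag_abundance(small_table, part, "sum")
        assert np.allclose(out.sum(axis=1), small_table.sum(axis=1), atol=1e-12)

    def test_unpartitioned_genus_errors(self, small_table):
        part = self._partition(small_table.columns[:-1],
                               [1] * (small_table.shape[1] - 1))
        with pytest.raises(ValueError, match="absent"):
            cag_abundance(small_table, part)


class TestCagDifferential:
    def test_identical_groups_give_p_one(self, rng):
        vals = rng.random((10, 2))
        tbl = make_table(np.vstack([vals, vals]))
        labels = pd.Series(["case"] * 10 + ["control"] * 10, index=tbl.index)
        res = cag_differential(tbl, labels)
        assert (res["p_value"] > 0.99).all()

    def test_null_rejection_rate_calibrated(self, rng):
        """Shuffled labels: ~5% of 1,000 null contrasts rejected at 0.05."""
        rejections = 0
        n_sims = 1000
        for _ in range(n_sims):
            vals = rng.random((40, 1))
            tbl = make_table(vals)
            labels = pd.Series(rng.permutation(["case"] * 20 + ["control"] * 20),
                               index=tbl.index)
            res = cag_differential(tbl, labels)
            rejections += int(res["p_value"].iloc[0] < 0.05)
        assert 0.03 <= rejections / n_sims <= 0.07

    def test_planted_effect_detected(self):
        """Log-fold 1.0 on one block, n=365/365: that CAG flagged at p<0.01."""
        hits = 0
        for seed in range(10):
            cfg = SimConfig(n_cases=365, n_controls=365, n_genera=20, n_blocks=2,
                            block_sizes=(4, 4), within_block_rho=0.7,
                            effect_blocks={1: 1.0}, seed=seed)
            table, truth = simulate_genus_table(cfg)
            from cagnet.cag import CagPartition
            part = CagPartition(assignment=truth.block_assignment.replace(0, 3),
                                k=3, linkage_method="truth")
            cag_tbl = cag_abundance(table, part, "mean")
            labels = pd.Series(["case"] * 365 + ["control"] * 365, index=table.index)
            res = cag_differential(cag_tbl, labels)
            hits += res.loc["CAG1", "p_value"] < 0.01
        assert hits >= 9


class TestGenusVenn:
    def test_identical_sets(self):
        s = set("abcdefghij")
        out = genus_venn({"A": s, "B": s, "C": s})
        assert out["A+B+C"] == 10
        assert all(v == 0 for k, v in out.items() if k != "A+B+C")

    def test_disjoint_sets(self):
        out = genus_venn({"A": {"a"}, "B": {"b"}, "C": {"c"}})
        assert out["A+B+C"] == 0 and out["A"] == out["B"] == out["C"] == 1

    def test_hand_enumerated_overlap(self):
        out = genus_venn({"A": {"a", "b", "c"}, "B": {"b", "c", "d"},
                          "C": {"c", "d", "e"}})
        assert out == {"A": 1, "B": 0, "C": 1, "A+B": 1, "B+C": 1,
                       "A+C": 0, "A+B+C": 1}
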