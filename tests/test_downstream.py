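"""Pattern clustering, enrichment, chord weights, regression, differential."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from bimoran import (
    LRDatabase,
    LRPair,
    celltype_regression,
    chord_celltype,
    chord_lr,
    cluster_patterns,
    differential_test,
    pathway_enrichment,
)
from bimoran.local_stats import LocalResult

from conftest import random_weights


def make_local(sender, receiver, pair_id="p"):
    sender = np.asarray(sender, dtype=float)
    receiver = np.asarray(receiver, dtype=float)
    return LocalResult(
        pair_id=pair_id,
        local_R=sender + receiver,
        sender_R=sender,
        receiver_R=receiver,
        p=np.ones_like(sender),
        hits=np.zeros_like(sender, dtype=bool),
        method="zscore",
        clip_bound=10.0,
        local_threshold=0.1,
    )


def grid_coords(side):
    xx, yy = np.meshgrid(np.arange(side), np.arange(side))
    return np.column_stack([xx.ravel(), yy.ravel()]).astype(float)


class TestClusterPatterns:
    def planted(self, n_per_block=4):
        """Three groups of pairs hitting three disjoint spatial blocks."""
        coords = grid_coords(12)
        blocks = [
            (coords[:, 0] < 6) & (coords[:, 1] < 6),
            (coords[:, 0] >= 6) & (coords[:, 1] < 6),
            (coords[:, 1] >= 6),
        ]
        rows, truth = [], []
        for b, mask in enumerate(blocks):
            for j in range(n_per_block):
                rows.append(mask.astype(int))
                truth.append(b)
        hits = pd.DataFrame(rows, index=[f"pair{b}_{j}" for b, j in
                                         itertools.product(range(3), range(n_per_block))])
        return hits, coords, np.array(truth)

    def test_recovers_planted_blocks(self):
        hits, coords, truth = self.planted()
        res = cluster_patterns(hits, coords, k=3, length_scale=1.5, seed=0)
        assert adjusted_rand_score(truth, res.labels.to_numpy()) == 1.0

    def test_identical_profiles_share_a_label(self):
        hits, coords, _ = self.planted()
        res = cluster_patterns(hits, coords, k=3, length_scale=1.5, seed=0)
        assert res.labels["pair0_0"] == res.labels["pair0_1"]

    def test_deterministic_under_seed(self):
        hits, coords, _ = self.planted()
        a = cluster_patterns(hits, coords, k=3, length_scale=1.5, seed=5)
        b = cluster_patterns(hits, coords, k=3, length_scale=1.5, seed=5)
        pd.testing.assert_series_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_intensity_rows_are_spatially_smooth(self):
        hits, coords, _ = self.planted()
        res = cluster_patterns(hits, coords, k=3, length_scale=1.5, seed=0)
        from bimoran import build_rbf_weights, moran_i

        w = build_rbf_weights(coords, l=1.5, cutoff=0.1)
        rng = np.random.default_rng(0)
        for row in res.intensity:
            assert moran_i(row, w) > moran_i(rng.permutation(row), w)

    def test_too_few_eligible_pairs_fatal(self):
        hits, coords, _ = self.planted(n_per_block=1)
        sparse = hits.copy()
        sparse.iloc[1:] = 0  # only one pair keeps >= 10 hits
        with pytest.raises(ValueError, match="exceeds"):
            cluster_patterns(sparse, coords, k=3, length_scale=1.5, seed=0)


class TestPathwayEnrichment:
    @staticmethod
    def hypergeom_tail(a, b, c, d):
        """P(X >= a) for X ~ Hypergeom(N=a+b+c+d, K=a+c, n=a+b), by summation."""
        from math import comb

        N, K, ndraw = a + b + c + d, a + c, a + b
        denom = comb(N, ndraw)
        return sum(
            comb(K, k) * comb(N - K, ndraw - k)
            for k in range(a, min(K, ndraw) + 1)
        ) / denom

    def test_matches_hypergeometric_summation(self):
        # 8 selected in pathway, 2 selected outside, 10/80 unselected
        db = LRDatabase(
            pairs=[LRPair(f"in{i}", [f"L{i}"], [f"R{i}"], pathway="A") for i in range(18)]
            + [LRPair(f"out{i}", [f"M{i}"], [f"S{i}"], pathway="B") for i in range(82)]
        )
        selected = [f"in{i}" for i in range(8)] + [f"out{i}" for i in range(2)]
        table = pathway_enrichment(selected, db).set_index("pathway")
        expected = self.hypergeom_tail(8, 2, 10, 80)
        assert table.loc["A", "fisher_p"] == pytest.approx(expected, rel=1e-10)
        assert table.loc["A", "n_selected"] == 8
        assert table.loc["A", "pct_of_pathway"] == pytest.approx(100 * 8 / 18)

    def test_exhaustive_small_tables(self):
        # every 2x2 table with margins <= 8: Fisher == direct hypergeometric tail
        for a, b, c, d in itertools.product(range(5), repeat=4):
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            assert p == pytest.approx(self.hypergeom_tail(a, b, c, d), rel=1e-9)

    def test_zero_selected_in_pathway_p_is_one_tail(self):
        db = LRDatabase(
            pairs=[LRPair("a", ["L1"], ["R1"], pathway="A"),
                   LRPair("b", ["L2"], ["R2"], pathway="B"),
                   LRPair("c", ["L3"], ["R3"], pathway="B")]
        )
        table = pathway_enrichment(["b", "c"], db).set_index("pathway")
        assert table.loc["A", "fisher_p"] == 1.0
        assert bool(table.loc["A", "flagged"])

    def test_all_selected_gives_p_one_everywhere(self):
        db = LRDatabase(
            pairs=[LRPair(f"p{i}", [f"L{i}"], [f"R{i}"], pathway=f"PW{i % 2}") for i in range(6)]
        )
        table = pathway_enrichment([f"p{i}" for i in range(6)], db)
        assert (table["fisher_p"] == 1.0).all()


class TestChord:
    def test_single_term_concentrated_types(self, rng):
        n = 4
        w = random_weights(n, rng)
        local = make_local(rng.normal(size=n), rng.normal(size=n))
        ct = pd.DataFrame(0.0, index=range(n), columns=["A", "B"])
        ct.loc[1, "A"] = 1.0  # sender mass only at spot 1
        ct.loc[3, "B"] = 1.0  # receiver mass only at spot 3
        expected = w.toarray()[1, 3] * local.sender_R[1] * local.receiver_R[3]
        assert chord_celltype(local, w, ct, "A", "B") == pytest.approx(expected)

    def test_matches_bruteforce_double_loop(self, rng):
        n = 5
        w = random_weights(n, rng)
        local = make_local(rng.normal(size=n), rng.normal(size=n))
        ct = pd.DataFrame(rng.dirichlet([1, 1], size=n), columns=["A", "B"])
        arr = w.toarray()
        expected = sum(
            arr[i, j] * local.sender_R[i] * ct.iloc[i, 0] * local.receiver_R[j] * ct.iloc[j, 1]
            for i in range(n)
            for j in range(n)
        )
        assert chord_celltype(local, w, ct, "A", "B") == pytest.approx(expected, rel=1e-10)

    def test_bilinearity_and_total_flow(self, rng):
        n = 6
        w = random_weights(n, rng)
        local = make_local(rng.normal(size=n), rng.normal(size=n))
        ct = pd.DataFrame(rng.dirichlet([1, 1, 1], size=n), columns=["A", "B", "C"])
        # n_{A+A',B} = n_{A,B} + n_{A',B}
        merged = ct.copy()
        merged["AC"] = ct["A"] + ct["C"]
        lhs = chord_celltype(local, w, merged, "AC", "B")
        rhs = chord_celltype(local, w, ct, "A", "B") + chord_celltype(local, w, ct, "C", "B")
        assert lhs == pytest.approx(rhs, rel=1e-10)
        # summing over all type pairs recovers the unweighted flow
        total = sum(
            chord_celltype(local, w, ct, a, b)
            for a in ["A", "B", "C"]
            for b in ["A", "B", "C"]
        )
        expected = (local.sender_R) @ w.toarray() @ (local.receiver_R)
        assert total == pytest.approx(expected, rel=1e-10)

    def test_unknown_type_fatal(self, rng):
        w = random_weights(4, rng)
        local = make_local(np.ones(4), np.ones(4))
        ct = pd.DataFrame(np.ones((4, 1)), columns=["A"])
        with pytest.raises(ValueError, match="unknown cell type"):
            chord_celltype(local, w, ct, "A", "Z")

    def test_chord_lr_orders_pairs_by_interaction(self, rng):
        n = 30
        w = random_weights(n, rng, symmetric=True)
        strong = make_local(np.abs(rng.normal(2, 0.2, n)), np.abs(rng.normal(2, 0.2, n)), "strong")
        weak = make_local(rng.normal(0, 0.05, n), rng.normal(0, 0.05, n), "weak")
        ct = pd.DataFrame(np.full((n, 2), 0.5), columns=["A", "B"])
        edges = chord_lr({"strong": strong, "weak": weak}, w, ct, "A", "B")
        assert abs(edges["strong"]) > abs(edges["weak"])
        assert edges["strong"] == pytest.approx(chord_celltype(strong, w, ct, "A", "B"))


class TestCelltypeRegression:
    def test_exact_linear_relationship_gives_r_one(self, rng):
        local_p = pd.DataFrame(rng.random((40, 3)))
        B = rng.normal(size=(3, 2))
        ct = pd.DataFrame(local_p.to_numpy() @ B + 0.3, columns=["A", "B"])
        fit = celltype_regression(local_p, ct)
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-9)

    def test_independent_responses_give_small_r(self, rng):
        local_p = pd.DataFrame(rng.random((400, 2)))
        ct = pd.DataFrame(rng.random((400, 2)), columns=["A", "B"])
        fit = celltype_regression(local_p, ct)
        assert abs(fit.pearson_r) < 0.2

    def test_joint_spot_permutation_invariance(self, rng):
        local_p = pd.DataFrame(rng.random((30, 3)))
        ct = pd.DataFrame(rng.random((30, 2)), columns=["A", "B"])
        r0 = celltype_regression(local_p, ct).pearson_r
        perm = rng.permutation(30)
        r1 = celltype_regression(
            local_p.iloc[perm].reset_index(drop=True),
            ct.iloc[perm].reset_index(drop=True),
        ).pearson_r
        assert r1 == pytest.approx(r0, rel=1e-9)


class TestDifferential:
    def test_identical_z_gives_zero_lrt_and_p_one(self):
        zm = pd.DataFrame(
            np.tile([[2.0, 2.0, 2.0, 2.0, 2.0, 2.0]], (3, 1)),
            index=["a", "b", "c"],
            columns=list("stuvwx"),
        )
        res = differential_test(zm, ["f", "f", "f", "ad", "ad", "ad"])
        assert (res.table["lrt_stat"] == 0).all()
        assert (res.table["p"] == 1.0).all()
        assert (res.table["label"] == "ns").all()

    def test_missing_pair_z_enters_as_zero(self):
        zm = pd.DataFrame(
            [[np.nan, 1.0, 1.0, 1.0, 1.0, 1.0]], index=["a"], columns=list("stuvwx")
        )
        res = differential_test(zm, ["f", "f", "f", "ad", "ad", "ad"])
        assert res.table.loc[0, "z_s"] == 0.0
        # z_diff = mean(f) - mean(ad) = (0+1+1)/3 - 1
        assert res.table.loc[0, "z_diff"] == pytest.approx(2 / 3 - 1)

    def test_single_condition_fatal(self):
        zm = pd.DataFrame(np.ones((2, 4)), columns=list("abcd"))
        with pytest.raises(ValueError):
            differential_test(zm, ["x", "x", "x", "x"])

    def test_recovery_of_planted_effects(self):
        # 500 pairs, 3+3 samples, effect delta = 3 sd on the first 50 pairs
        rng = np.random.default_rng(2024)
        n_pairs, n_true = 500, 50
        Z = rng.normal(size=(n_pairs, 6))
        Z[:n_true, 3:] += 3.0
        zm = pd.DataFrame(Z, index=[f"p{i}" for i in range(n_pairs)],
                          columns=[f"s{i}" for i in range(6)])
        res = differential_test(zm, ["f", "f", "f", "ad", "ad", "ad"], fdr_threshold=0.1)
        sig = res.table["fdr"] < 0.1
        power = sig[:n_true].mean()
        assert power >= 0.8
        # null pairs: uniform p-values
        ks = stats.kstest(res.table["p"][n_true:], "uniform")
        assert ks.pvalue > 0.01
        # direction labels point at the enriched condition
        labelled = res.table.loc[sig & (res.table.index < n_true), "label"]
        assert (labelled.isin(["ad_specific", "ns"])).all()
        assert (labelled == "ad_specific").mean() > 0.5

    def test_chi2_mode_is_anticonservative_at_small_n(self):
        # documents why the exact F tail is the default: same ranking,
        # inflated chi-squared p at 3+3 samples
        rng = np.random.default_rng(7)
        Z = rng.normal(size=(2000, 6))
        zm = pd.DataFrame(Z, columns=list("abcdef"))
        cond = ["f", "f", "f", "ad", "ad", "ad"]
        p_f = differential_test(zm, cond, var_method="per_pair", p_method="fstat").table["p"]
        p_c = differential_test(zm, cond, var_method="per_pair", p_method="chi2").table["p"]
        assert stats.spearmanr(p_f, p_c).statistic > 0.9999
        assert (p_c < 0.05).mean() > 0.09  # chi2 badly inflated
        assert abs((p_f < 0.05).mean() - 0.05) < 0.02  # F calibrated

    def test_continuous_covariate_path(self, rng):
        t = np.linspace(0, 1, 8)
        Z = np.vstack([5 * t + 0.1 * rng.normal(size=8),
                       rng.normal(size=8)])
        zm = pd.DataFrame(Z, index=["up", "flat"], columns=[f"s{i}" for i in range(8)])
        res = differential_test(zm, t, fdr_threshold=0.1, quantile_cut=0.4)
        table = res.table.set_index("pair_id")
        assert table.loc["up", "fdr"] < 0.1
        assert table.loc["up", "label"] == "positive"
        assert table.loc["flat", "label"] == "ns"
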