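"""Co-expression statistics against independent brute-force oracles."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thermoplast import coexpr as cx
from thermoplast import permstats as ps


def bicor_reference(x, y):
    """Direct transcription of the biweight midcorrelation definition."""
    out = []
    for v in (np.asarray(x, float), np.asarray(y, float)):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9 * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        out.append((v - med) * w)
    xt, yt = out
    return float(xt @ yt / (np.linalg.norm(xt) * np.linalg.norm(yt)))


class TestFilterTransform:
    def test_all_zero_gene_removed(self):
        counts = pd.DataFrame(
            {"s1": [0, 100, 50], "s2": [0, 90, 60]}, index=["gz", "ga", "gb"]
        )
        expr = cx.filter_and_transform(counts)
        assert "gz" not in expr.index

    def test_cpm_exactly_at_threshold_removed(self):
        # craft a gene sitting at CPM exactly 1 in every sample
        lib = 1_000_000
        counts = pd.DataFrame(
            {"s1": [1, lib - 1], "s2": [1, lib - 1]}, index=["edge", "big"]
        )
        expr = cx.filter_and_transform(counts, cpm_min=1.0)
        assert "edge" not in expr.index and "big" in expr.index

    def test_matches_brute_force_oracle(self, expr_bundle):
        _, counts, _, _ = expr_bundle
        expr = cx.filter_and_transform(counts, cpm_min=1.0, min_frac=0.2)
        lib = counts.sum(axis=0)
        need = math.ceil(0.2 * counts.shape[1])
        kept = [
            g
            for g in counts.index
            if sum(counts.loc[g, s] / lib[s] * 1e6 > 1.0 for s in counts.columns) >= need
        ]
        assert list(expr.index) == kept
        # transform oracle: median-of-ratios size factors on the kept genes
        kept_counts = counts.loc[kept].to_numpy(dtype=float)
        pos = (kept_counts > 0).all(axis=1)
        logk = np.log(kept_counts[pos])
        sf = np.exp(np.median(logk - logk.mean(axis=1, keepdims=True), axis=0))
        np.testing.assert_allclose(
            expr.to_numpy(), np.log2(kept_counts / sf[None, :] + 1), atol=1e-12
        )

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0], "s2": [5, 5]}, index=["a", "b"])
        with pytest.raises(ValueError, match="library"):
            cx.filter_and_transform(counts)


class TestOutlierRemoval:
    def test_tight_cluster_untouched(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(0, 1, (50, 8)), columns=[f"s{i}" for i in range(8)])
        out = cx.remove_outlier_samples(expr, height_cutoff=1e6)
        assert list(out.columns) == list(expr.columns)

    def test_extreme_sample_removed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (60, 9))
        X[:, 4] += 100  # one sample shifted far away
        expr = pd.DataFrame(X, columns=[f"s{i}" for i in range(9)])
        with pytest.warns(UserWarning, match="s4"):
            out = cx.remove_outlier_samples(expr, height_cutoff=200)
        assert "s4" not in out.columns and out.shape[1] == 8

    def test_zero_cutoff_degenerate(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(0, 1, (30, 6)))
        with pytest.raises(ValueError):
            cx.remove_outlier_samples(expr, height_cutoff=0.0)


class TestTopVariable:
    def test_identity_when_fewer_genes(self):
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 5)))
        assert cx.top_variable(expr, n=10).equals(expr)

    def test_constant_gene_ranked_last(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(20, 6)), index=[f"g{i}" for i in range(20)])
        expr.loc["g0"] = 1.0
        assert "g0" not in cx.top_variable(expr, n=19).index

    def test_matches_variance_sort_oracle(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(40, 7)), index=[f"g{i:02d}" for i in range(40)])
        got = list(cx.top_variable(expr, n=15).index)
        var = expr.var(axis=1, ddof=1)
        expected = sorted(expr.index, key=lambda g: (-var[g], g))[:15]
        assert got == expected


class TestBicor:
    def test_affine_invariance(self):
        x = np.random.default_rng(0).normal(size=50)
        assert cx.bicor(x, 2 * x + 3) == pytest.approx(1.0)
        assert cx.bicor(x, -x) == pytest.approx(-1.0)

    def test_close_to_pearson_on_gaussian(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=500)
        y = 0.6 * x + 0.8 * rng.normal(size=500)
        pear = np.corrcoef(x, y)[0, 1]
        assert abs(cx.bicor(x, y) - pear) < 0.05

    def test_matches_definition_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            x, y = rng.normal(size=(2, 31))
            assert cx.bicor(x, y) == pytest.approx(bicor_reference(x, y), abs=1e-12)

    def test_zero_mad_falls_back_to_pearson(self):
        x = np.array([1.0, 1, 1, 1, 1, 2, 1, 1, 1])  # MAD = 0
        y = np.linspace(0, 1, 9)
        with pytest.warns(UserWarning, match="MAD"):
            r = cx.bicor(x, y)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_matrix_agrees_with_pairwise(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(6, 25))
        M = cx.bicor_matrix(X)
        for i in range(6):
            for j in range(6):
                assert M[i, j] == pytest.approx(cx.bicor(X[i], X[j]), abs=1e-12)


class TestSoftPower:
    def test_zero_target_returns_lowest_passing_power(self, hub_expr):
        res = cx.pick_soft_power(hub_expr, r2_target=0.0)
        assert res.achieved_target
        expected = int(res.table[res.table["r2"] > 0]["power"].iloc[0])
        assert res.power == expected

    def test_scale_free_fixture_passes_target(self, hub_expr):
        res = cx.pick_soft_power(hub_expr, r2_target=0.80)
        assert res.achieved_target and res.r2 > 0.80

    def test_reported_r2_matches_independent_recomputation(self, hub_expr):
        res = cx.pick_soft_power(hub_expr)
        X = hub_expr.to_numpy()
        cor = np.corrcoef(X)
        for row in res.table.dropna().itertuples():
            a = ((1 + cor) / 2) ** row.power
            np.fill_diagonal(a, 0)
            k = a.sum(axis=1)
            edges = np.linspace(k.min(), k.max(), 11)
            idx = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
            freq = np.bincount(idx, minlength=10).astype(float)
            ok = freq > 0
            mean_k = np.bincount(idx, weights=k, minlength=10)[ok] / freq[ok]
            slope, _, r, _, _ = stats.linregress(np.log10(mean_k), np.log10(freq[ok] / freq.sum()))
            assert row.r2 == pytest.approx(-np.sign(slope) * r**2, abs=1e-12)

    def test_too_few_genes_rejected(self):
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 10)))
        with pytest.raises(ValueError):
            cx.pick_soft_power(expr)


class TestModules:
    def test_planted_modules_recovered(self, expr_bundle):
        from sklearn.metrics import adjusted_rand_score

        _, counts, _, truth = expr_bundle
        expr = cx.top_variable(cx.filter_and_transform(counts), n=500)
        assign = cx.detect_modules(expr, beta=9, min_size=30)
        truth_labels = np.array([truth.data["module_of"][g] for g in expr.index])
        assert adjusted_rand_score(truth_labels, assign.to_numpy()) > 0.8

    def test_min_size_above_gene_count_unassigns_all(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(20, 10)), index=[f"g{i}" for i in range(20)])
        with pytest.warns(UserWarning):
            assign = cx.detect_modules(expr, beta=3, min_size=100)
        assert (assign == cx.UNASSIGNED).all()

    def test_shared_factor_modules_merged(self):
        rng = np.random.default_rng(4)
        n = 20
        f = rng.standard_normal(n)
        rows = [0.95 * f + 0.3 * rng.standard_normal(n) for _ in range(80)]
        expr = pd.DataFrame(np.asarray(rows), index=[f"g{i}" for i in range(80)])
        assign = cx.detect_modules(expr, beta=6, min_size=20)
        mods = set(assign) - {cx.UNASSIGNED}
        assert len(mods) == 1  # one latent factor, one module


class TestEigengenes:
    def test_identical_gene_module_orientation(self):
        profile = np.linspace(-1, 1, 12)
        expr = pd.DataFrame(
            [profile + 5, profile + 5, profile + 5],
            index=["a", "b", "c"],
            columns=[f"s{i}" for i in range(12)],
        )
        assign = pd.Series("M1", index=expr.index)
        eig = cx.module_eigengenes(expr, assign)
        z = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(eig.loc["M1"].to_numpy(), z / np.linalg.norm(z), atol=1e-8)

    def test_matches_svd_oracle(self, expr_bundle):
        _, counts, _, truth = expr_bundle
        expr = cx.filter_and_transform(counts)
        assign = pd.Series(
            [truth.data["module_of"][g] for g in expr.index], index=expr.index
        )
        eig = cx.module_eigengenes(expr, assign)
        for m in eig.index:
            sub = expr.loc[assign[assign == m].index].to_numpy()
            Z = (sub - sub.mean(1, keepdims=True)) / sub.std(1, keepdims=True)
            _, _, vt = np.linalg.svd(Z, full_matrices=False)
            ref = vt[0]
            got = eig.loc[m].to_numpy()
            assert min(np.abs(got - ref).max(), np.abs(got + ref).max()) < 1e-8

    def test_constant_gene_module_rejected(self):
        expr = pd.DataFrame(np.ones((3, 8)), index=["a", "b", "c"])
        with pytest.raises(ValueError, match="M1"):
            cx.module_eigengenes(expr, pd.Series("M1", index=expr.index))


class TestKME:
    def test_gene_equal_to_eigengene(self):
        rng = np.random.default_rng(0)
        e = rng.normal(size=14)
        expr = pd.DataFrame([e, rng.normal(size=14)], index=["hub", "noise"],
                            columns=[f"s{i}" for i in range(14)])
        eig = pd.DataFrame([e], index=["M1"], columns=expr.columns)
        K = cx.kme(expr, eig)
        assert K.loc["hub", "M1"] == pytest.approx(1.0)
        K2 = cx.kme(expr, -eig)
        assert K2.loc["hub", "M1"] == pytest.approx(-K.loc["hub", "M1"])

    def test_matches_elementwise_bicor(self, expr_bundle):
        _, counts, _, truth = expr_bundle
        expr = cx.filter_and_transform(counts).iloc[:40]
        assign = pd.Series(
            [truth.data["module_of"][g] for g in expr.index], index=expr.index
        )
        full = cx.filter_and_transform(counts)
        full_assign = pd.Series(
            [truth.data["module_of"][g] for g in full.index], index=full.index
        )
        eig = cx.module_eigengenes(full, full_assign)
        K = cx.kme(expr, eig)
        for g in expr.index[:10]:
            for m in eig.index:
                assert K.loc[g, m] == pytest.approx(
                    cx.bicor(expr.loc[g].to_numpy(), eig.loc[m].to_numpy()), abs=1e-12
                )

    def test_own_module_membership_dominates(self, expr_bundle):
        _, counts, _, truth = expr_bundle
        expr = cx.filter_and_transform(counts)
        assign = pd.Series(
            [truth.data["module_of"][g] for g in expr.index], index=expr.index
        )
        eig = cx.module_eigengenes(expr, assign)
        K = cx.kme(expr, eig)
        members = assign[assign != cx.UNASSIGNED]
        wins = sum(K.loc[g].idxmax() == m for g, m in members.items())
        assert wins / len(members) >= 0.95


class TestModuleTrait:
    def test_perfect_indicator_association(self):
        ind = np.repeat([0.0, 1.0], 8)
        eig = pd.DataFrame([ind], index=["M1"], columns=[f"s{i}" for i in range(16)])
        g = pd.Series(np.repeat(["group1", "group2"], 8), index=eig.columns)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = cx.module_trait(eig, g)
        row = tab[(tab["module"] == "M1") & (tab["trait"] == "group2")].iloc[0]
        assert row["r"] == pytest.approx(1.0) and row["p"] < 1e-12

    def test_zero_correlation_gives_p_one(self):
        e = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        ind_groups = pd.Series(
            ["group1"] * 4 + ["group2"] * 4, index=[f"s{i}" for i in range(8)]
        )
        eig = pd.DataFrame([e], index=["M1"], columns=ind_groups.index)
        tab = cx.module_trait(eig, ind_groups)
        assert tab["p"].iloc[0] == pytest.approx(1.0)

    def test_q_values_match_bh_adjust(self, expr_bundle):
        _, counts, samples, truth = expr_bundle
        expr = cx.filter_and_transform(counts)
        assign = pd.Series(
            [truth.data["module_of"][g] for g in expr.index], index=expr.index
        )
        eig = cx.module_eigengenes(expr, assign)
        groups = samples.set_index("sample_id").loc[eig.columns, "group"]
        tab = cx.module_trait(eig, groups)
        np.testing.assert_allclose(tab["q"], ps.bh_adjust(tab["p"].to_numpy()), atol=1e-15)

    def test_planted_module_has_smallest_q(self, expr_bundle):
        _, counts, samples, truth = expr_bundle
        expr = cx.filter_and_transform(counts)
        assign = pd.Series(
            [truth.data["module_of"][g] for g in expr.index], index=expr.index
        )
        eig = cx.module_eigengenes(expr, assign)
        groups = samples.set_index("sample_id").loc[eig.columns, "group"]
        tab = cx.module_trait(eig, groups)
        best = tab.loc[tab["q"].idxmin()]
        assert best["module"] == truth.data["trait_linked_module"]


class TestHubGenes:
    def test_threshold_extremes(self, expr_bundle):
        _, counts, _, truth = expr_bundle
        expr = cx.filter_and_transform(counts)
        assign = pd.Series(
            [truth.data["module_of"][g] for g in expr.index], index=expr.index
        )
        eig = cx.module_eigengenes(expr, assign)
        K = cx.kme(expr, eig)
        assert all(not v for v in cx.hub_genes(K, assign, threshold=1.0).values())
        all_hubs = cx.hub_genes(K, assign, threshold=0.0)
        for m, genes in all_hubs.items():
            members = set(assign.index[assign == m])
            assert set(genes) == {g for g in members if abs(K.loc[g, m]) > 0}

    def test_matches_brute_force_filter(self, expr_bundle):
        _, counts, _, truth = expr_bundle
        expr = cx.filter_and_transform(counts)
        assign = pd.Series(
            [truth.data["module_of"][g] for g in expr.index], index=expr.index
        )
        eig = cx.module_eigengenes(expr, assign)
        K = cx.kme(expr, eig)
        hubs = cx.hub_genes(K, assign, threshold=0.8)
        for m in eig.index:
            expected = sorted(
                g for g in assign.index[assign == m] if abs(K.loc[g, m]) > 0.8
            )
            assert hubs[m] == expected


class TestStability:
    def test_identity_resample_equals_full_data_mean(self, expr_bundle):
        _, counts, _, truth = expr_bundle
        expr = cx.filter_and_transform(counts)
        assign = pd.Series(
            [truth.data["module_of"][g] for g in expr.index], index=expr.index
        )
        rep = cx.bootstrap_stability(
            expr, assign, n_boot=1, seed=0, resampler=lambda rng, n: np.arange(n)
        )
        eig = cx.module_eigengenes(expr, assign)
        K = cx.kme(expr, eig)
        members = assign[assign != cx.UNASSIGNED]
        expected = np.mean([K.loc[g, m] for g, m in members.items()])
        assert rep.score == pytest.approx(expected, abs=1e-12)

    def test_random_assignment_scores_near_zero(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.normal(size=(120, 16)),
            index=[f"g{i}" for i in range(120)],
            columns=[f"s{i}" for i in range(16)],
        )
        assign = pd.Series(
            rng.permutation(np.repeat(["M1", "M2", "M3"], 40)), index=expr.index
        )
        rep = cx.bootstrap_stability(expr, assign, n_boot=20, seed=1)
        assert abs(rep.score) <= 0.15


class TestFisherOverlap:
    def test_identical_sets_maximal_association(self):
        uni = set(range(50))
        res = cx.fisher_overlap(set(range(10)), set(range(10)), uni)
        assert res.odds_ratio == float("inf")
        assert res.p < 1e-9

    def test_independent_proportions_odds_ratio_one(self):
        uni = set(range(100))
        A = set(range(50))  # a=25, b=25, c=25, d=25
        B = set(range(25)) | set(range(50, 75))
        res = cx.fisher_overlap(A, B, uni)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            N = int(rng.integers(20, 60))
            uni = list(range(N))
            A = set(rng.choice(uni, size=rng.integers(3, N - 3), replace=False).tolist())
            B = set(rng.choice(uni, size=rng.integers(3, N - 3), replace=False).tolist())
            res = cx.fisher_overlap(A, B, uni)
            # enumerate all tables with the observed margins
            nA, nB = len(A), len(B)
            probs = [
                stats.hypergeom.pmf(a, N, nA, nB) for a in range(max(0, nA + nB - N), min(nA, nB) + 1)
            ]
            obs_p = stats.hypergeom.pmf(res.a, N, nA, nB)
            expected = sum(p for p in probs if p <= obs_p * (1 + 1e-12))
            assert res.p == pytest.approx(expected, rel=1e-8)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            cx.fisher_overlap(set(), set(), set())

    def test_shared_percentage(self):
        res = cx.fisher_overlap(set(range(428)), set(range(375, 428 + 375)), set(range(5000)))
        assert res.a == 53
        assert round(res.shared_pct("A"), 1) == 12.4
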