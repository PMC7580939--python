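import numpy as np
import pandas as pd
import pytest
from scipy import stats

from imhaseq import network as net


def brute_force_tom(A):
    """O(n^3) triple-loop oracle for the topological overlap matrix."""
    n = A.shape[0]
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    T = np.eye(n)
    k = A0.sum(axis=1)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(A0[i, u] * A0[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (l + A0[i, j]) / (min(k[i], k[j]) + 1 - A0[i, j])
    return T


def random_adjacency(rng, n):
    X = rng.standard_normal((n, 30))
    A = np.abs(np.corrcoef(X))
    np.fill_diagonal(A, 1.0)
    return A


class TestTOM:
    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(3):
            A = random_adjacency(rng, 10)
            T = net.tom(pd.DataFrame(A)).to_numpy()
            assert np.allclose(T, brute_force_tom(A), atol=1e-12)

    def test_hand_example(self):
        A = np.array([[1.0, 0.8, 0.4], [0.8, 1.0, 0.2], [0.4, 0.2, 1.0]])
        T = net.tom(pd.DataFrame(A)).to_numpy()
        # l_12 = a_13 * a_32 = 0.08; k = (1.2, 1.0, 0.6)
        assert T[0, 1] == pytest.approx((0.08 + 0.8) / (1.0 + 1 - 0.8))
        assert T[0, 2] == pytest.approx((0.8 * 0.2 + 0.4) / (0.6 + 1 - 0.4))

    def test_identity_adjacency(self):
        T = net.tom(pd.DataFrame(np.eye(4))).to_numpy()
        assert np.allclose(T, np.eye(4))

    def test_values_in_unit_interval(self, rng):
        for _ in range(3):
            T = net.tom(pd.DataFrame(random_adjacency(rng, 12))).to_numpy()
            assert (T >= -1e-12).all() and (T <= 1 + 1e-12).all()

    def test_asymmetric_rejected(self):
        A = np.array([[1.0, 0.5], [0.4, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            net.tom(pd.DataFrame(A))


class TestAdjacency:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        expr = pd.DataFrame([x, 2 * x + 1], index=["a", "b"])
        A = net.adjacency(expr, 6)
        assert A.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_series_near_zero(self, rng):
        expr = pd.DataFrame(rng.standard_normal((2, 2000)), index=["a", "b"])
        A = net.adjacency(expr, 6)
        assert A.loc["a", "b"] < 1e-6

    def test_symmetric_unit_diagonal(self, rng):
        expr = pd.DataFrame(rng.standard_normal((8, 15)))
        A = net.adjacency(expr, 3).to_numpy()
        assert np.allclose(A, A.T) and np.allclose(np.diag(A), 1.0)

    def test_zero_variance_gene_removed(self, rng):
        expr = pd.DataFrame(rng.standard_normal((4, 10)))
        expr.iloc[2] = 7.0
        A = net.adjacency(expr, 2)
        assert A.shape == (3, 3) and 2 not in A.index


class TestSoftPower:
    def test_forced_single_candidate(self, rng):
        expr = pd.DataFrame(rng.standard_normal((60, 12)))
        assert net.pick_soft_power(expr, candidates=(17,)) == 17

    def test_modular_structure_reaches_fit(self, rng):
        """Block-structured expression with hub-like modules yields a
        soft power whose connectivity distribution fits a power law."""
        n_per, n_mod, n_samp = 60, 5, 30
        cols = []
        for m in range(n_mod):
            latent = rng.standard_normal(n_samp)
            load = rng.uniform(0.3, 1.0, n_per)
            block = (
                load[:, None] * latent[None, :]
                + np.sqrt(1 - load[:, None] ** 2) * rng.standard_normal((n_per, n_samp))
            )
            cols.append(block)
        expr = pd.DataFrame(np.vstack(cols))
        beta = net.pick_soft_power(expr)
        absr = np.abs(np.corrcoef(expr.to_numpy()))
        np.fill_diagonal(absr, 0)
        k = (absr**beta).sum(axis=1)
        assert net._scale_free_fit(k, 10) >= 0.8

    def test_deterministic(self, rng):
        expr = pd.DataFrame(rng.standard_normal((40, 12)))
        assert net.pick_soft_power(expr) == net.pick_soft_power(expr)


class TestModules:
    def _block_tom(self, rng, sizes, within=0.8, between=0.002):
        n = sum(sizes)
        T = np.full((n, n), between)
        start = 0
        for s in sizes:
            T[start : start + s, start : start + s] = within + rng.uniform(
                0, 0.05, (s, s)
            )
            start += s
        T = (T + T.T) / 2
        np.fill_diagonal(T, 1.0)
        return pd.DataFrame(T)

    def test_two_planted_blocks_recovered(self, rng):
        T = self._block_tom(rng, [40, 35])
        labels = net.detect_modules(T, min_module_size=10)
        assert labels.nunique() == 2
        assert labels.iloc[:40].nunique() == 1 and labels.iloc[40:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_identical_genes_single_module(self):
        T = pd.DataFrame(np.ones((35, 35)))
        labels = net.detect_modules(T)
        assert labels.nunique() == 1 and (labels != 0).all()

    def test_small_clusters_unassigned(self, rng):
        T = self._block_tom(rng, [40, 5])
        labels = net.detect_modules(T, min_module_size=10)
        assert (labels.iloc[40:] == net.UNASSIGNED).all()

    def test_gene_order_invariance_up_to_renaming(self, rng):
        T = self._block_tom(rng, [30, 30])
        labels = net.detect_modules(T, min_module_size=10)
        perm = rng.permutation(60)
        Tp = T.iloc[perm, perm]
        labels_p = net.detect_modules(Tp, min_module_size=10).loc[labels.index]
        tab = pd.crosstab(labels, labels_p)
        assert (tab.gt(0).sum(axis=1) == 1).all()  # one-to-one mapping


class TestEigengenes:
    def test_identical_genes_give_shared_z_profile(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.0])
        expr = pd.DataFrame(np.tile(x, (4, 1)))
        labels = pd.Series(1, index=expr.index)
        eg = net.module_eigengene(expr, labels).loc[1].to_numpy()
        z = (x - x.mean()) / x.std(ddof=1)
        z = z / np.linalg.norm(z)
        assert np.allclose(np.abs(eg), np.abs(z), atol=1e-12)
        assert np.corrcoef(eg, x)[0, 1] > 0  # sign convention

    def test_matches_svd_oracle(self, rng):
        expr = pd.DataFrame(rng.standard_normal((5, 6)))
        labels = pd.Series(1, index=expr.index)
        eg = net.module_eigengene(expr, labels).loc[1].to_numpy()
        X = expr.to_numpy()
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
        _, _, Vt = np.linalg.svd(Z)
        v = Vt[0]
        assert np.allclose(np.abs(eg), np.abs(v), atol=1e-10)

    def test_variance_explained_optimality(self, rng):
        expr = pd.DataFrame(rng.standard_normal((8, 10)))
        labels = pd.Series(1, index=expr.index)
        eg = net.module_eigengene(expr, labels).loc[1].to_numpy()
        X = expr.to_numpy()
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
        best = ((Z @ eg) ** 2).sum()
        for _ in range(50):
            v = rng.standard_normal(10)
            v /= np.linalg.norm(v)
            assert ((Z @ v) ** 2).sum() <= best + 1e-9


class TestMerging:
    def _expr_two_modules(self, rng, r):
        latent = rng.standard_normal(20)
        other = r * latent + np.sqrt(max(0.0, 1 - r**2)) * rng.standard_normal(20)
        if r < 0:
            other = r * latent - np.sqrt(1 - r**2) * rng.standard_normal(20)
        rows = [latent + 0.05 * rng.standard_normal(20) for _ in range(10)]
        rows += [other + 0.05 * rng.standard_normal(20) for _ in range(10)]
        expr = pd.DataFrame(rows)
        labels = pd.Series([1] * 10 + [2] * 10, index=expr.index)
        return expr, labels

    def test_highly_correlated_modules_merge(self, rng):
        expr, labels = self._expr_two_modules(rng, 0.95)
        ms = net.merge_modules(expr, labels, merge_cor=0.30)
        assert ms.labels.nunique() == 1 and len(ms.merge_history) == 1

    def test_anticorrelated_modules_never_merge(self, rng):
        expr, labels = self._expr_two_modules(rng, -0.9)
        ms = net.merge_modules(expr, labels, merge_cor=0.30)
        assert ms.labels.nunique() == 2 and not ms.merge_history

    def test_literal_correlation_mode_is_more_aggressive(self, rng):
        expr, labels = self._expr_two_modules(rng, 0.5)
        keep = net.merge_modules(expr, labels, merge_cor=0.30)
        collapse = net.merge_modules(
            expr, labels, merge_cor=0.30, merge_on="correlation"
        )
        assert keep.labels.nunique() == 2
        assert collapse.labels.nunique() == 1


class TestTraitStats:
    def test_trait_equal_to_eigengene(self, rng):
        eg = pd.DataFrame(
            rng.standard_normal((2, 12)), index=[1, 2],
            columns=[f"s{j}" for j in range(12)],
        )
        traits = pd.DataFrame({"t": eg.loc[1]}, index=eg.columns)
        r, p = net.module_trait(eg, traits)
        assert r.loc[1, "t"] == pytest.approx(1.0)
        assert p.loc[1, "t"] < 1e-10

    def test_trait_negation_antisymmetry(self, rng):
        eg = pd.DataFrame(rng.standard_normal((2, 10)), index=[1, 2])
        traits = pd.DataFrame({"t": rng.standard_normal(10)}, index=eg.columns)
        r1, _ = net.module_trait(eg, traits)
        r2, _ = net.module_trait(eg, -traits)
        assert np.allclose(r1, -r2)

    def test_constant_trait_missing(self, rng):
        eg = pd.DataFrame(rng.standard_normal((1, 10)), index=[1])
        traits = pd.DataFrame({"t": np.ones(10)}, index=eg.columns)
        r, p = net.module_trait(eg, traits)
        assert r.isna().all().all() and p.isna().all().all()

    def test_null_trait_small_correlation(self, rng):
        eg = pd.DataFrame(rng.standard_normal((1, 500)), index=[1])
        traits = pd.DataFrame({"t": rng.standard_normal(500)}, index=eg.columns)
        r, _ = net.module_trait(eg, traits)
        assert abs(r.loc[1, "t"]) < 0.15

    def test_gene_stats_identities(self, rng):
        expr = pd.DataFrame(
            rng.standard_normal((5, 12)), index=[f"g{i}" for i in range(5)]
        )
        labels = pd.Series(1, index=expr.index)
        eg = net.module_eigengene(expr, labels)
        trait = pd.Series(expr.iloc[0].to_numpy(), index=expr.columns)
        stats_df = net.gene_stats(expr, eg, labels, trait)
        assert stats_df.loc["g0", "gs"] == pytest.approx(1.0)
        # genes identical to the eigengene profile have mm = 1
        shared = rng.standard_normal(12)
        expr3 = pd.DataFrame(
            np.tile(shared, (4, 1)), index=[f"h{i}" for i in range(4)]
        )
        labels3 = pd.Series(1, index=expr3.index)
        eg3 = net.module_eigengene(expr3, labels3)
        stats3 = net.gene_stats(
            expr3, eg3, labels3, pd.Series(shared, index=expr3.columns)
        )
        assert np.allclose(stats3["mm"], 1.0, atol=1e-9)

    def test_select_matches_filter_oracle(self, rng):
        df = pd.DataFrame(
            {
                "gs_p": rng.random(100),
                "mm_p": rng.random(100),
                "mm": rng.uniform(-1, 1, 100),
                "gs": rng.uniform(-1, 1, 100),
            },
            index=[f"g{i}" for i in range(100)],
        )
        got = net.select_module_genes(df)
        expected = df[(df.gs_p <= 0.05) & (df.mm_p <= 0.05) & (df.mm >= 0)]
        assert got == list(expected.index)

    def test_negative_mm_excluded_regardless_of_p(self):
        df = pd.DataFrame(
            {"gs_p": [0.001], "mm_p": [0.001], "mm": [-0.9], "gs": [0.5]},
            index=["g"],
        )
        assert net.select_module_genes(df) == []


class TestOverrepresentation:
    def test_exact_hypergeometric_value(self):
        universe = [f"u{i}" for i in range(20)]
        from imhaseq.io import GeneSetCollection

        coll = GeneSetCollection({"S": ("d", universe[:5])})
        selected = universe[1:5] + [universe[10]]  # overlap 4 of 5
        res = net.overrepresentation(selected, coll, universe)
        assert res.loc["S", "p"] == pytest.approx(76 / 15504)

    def test_zero_overlap_near_one(self):
        from imhaseq.io import GeneSetCollection

        universe = [f"u{i}" for i in range(20)]
        coll = GeneSetCollection({"S": ("d", universe[:5])})
        res = net.overrepresentation(universe[10:12], coll, universe)
        assert res.loc["S", "p"] > 0.4

    def test_selected_outside_universe_rejected(self):
        from imhaseq.io import GeneSetCollection

        coll = GeneSetCollection({"S": ("d", ["a"])})
        with pytest.raises(ValueError):
            net.overrepresentation(["zz"], coll, ["a", "b"])


class TestAnovaTukey:
    def test_two_groups_equals_t_test(self, rng):
        tpm = pd.DataFrame(
            rng.lognormal(3, 1, (5, 10)), columns=[f"s{j}" for j in range(10)]
        )
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=tpm.columns)
        anova, _ = net.group_anova_tukey(tpm, tpm.index, groups, alpha=1.0)
        for gene in tpm.index:
            t, p = stats.ttest_ind(
                tpm.loc[gene].iloc[:5], tpm.loc[gene].iloc[5:], equal_var=True
            )
            assert anova.loc[gene, "F"] == pytest.approx(t**2)
            assert anova.loc[gene, "p"] == pytest.approx(p)

    def test_planted_shift_flagged_for_right_pair(self, rng):
        base = rng.normal(10, 1, (1, 18))
        base[0, 12:] += 10.0  # third group shifted by 10 SD
        tpm = pd.DataFrame(base, index=["g"], columns=[f"s{j}" for j in range(18)])
        groups = pd.Series(["a"] * 6 + ["b"] * 6 + ["c"] * 6, index=tpm.columns)
        anova, tukey = net.group_anova_tukey(tpm, ["g"], groups)
        assert anova.loc["g", "p"] < 1e-6
        tk = tukey.set_index(["group_a", "group_b"])
        assert tk.loc[("a", "c"), "significant"].all()
        assert tk.loc[("b", "c"), "significant"].all()
        assert not tk.loc[("a", "b"), "significant"].any()

    def test_empty_group_rejected(self, rng):
        tpm = pd.DataFrame(rng.random((2, 4)), columns=list("wxyz"))
        groups = pd.Series(["a", "a", "a", "b"], index=tpm.columns)
        with pytest.raises(ValueError, match="< 2"):
            net.group_anova_tukey(tpm, tpm.index, groups)
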