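"""Signed adjacency, soft threshold, TOM, module detection and trait tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import linregress, pearsonr

from afcerna import (
    ModuleAssignment,
    cluster_modules,
    compute_eigengenes,
    compute_tom,
    merge_modules,
    module_eigengene,
    module_trait_correlation,
    pick_beta,
    scale_free_fit,
    signed_adjacency,
)

from conftest import toy_expression


def _expr_with_cor(r: float, n=50, seed=0) -> pd.DataFrame:
    """Two genes with exact sample correlation r (via orthogonalization)."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    a = (a - a.mean()) / a.std()
    b = b - b.mean()
    b -= a * (a @ b) / (a @ a)
    b /= b.std()
    y = r * a + np.sqrt(1 - r**2) * b
    return pd.DataFrame([a, y], index=["G0", "G1"], columns=[f"S{j}" for j in range(n)])


class TestSignedAdjacency:
    @pytest.mark.parametrize(
        "r,beta,expected",
        [(1.0, 7, 1.0), (-1.0, 3, 0.0), (0.0, 12, 2.0**-12)],
    )
    def test_closed_form_values(self, r, beta, expected):
        if r == 1.0:
            expr = pd.DataFrame(
                [np.arange(10.0), 2 * np.arange(10.0) + 5], index=["G0", "G1"]
            )
        elif r == -1.0:
            expr = pd.DataFrame(
                [np.arange(10.0), -np.arange(10.0)], index=["G0", "G1"]
            )
        else:
            expr = _expr_with_cor(0.0)
        a = signed_adjacency(expr, beta)
        assert a.iloc[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_bounds_and_symmetry(self, rng):
        expr = toy_expression(n_genes=15, seed=2)
        a = signed_adjacency(expr, 6).to_numpy()
        assert np.all((a >= 0) & (a <= 1))
        np.testing.assert_allclose(a, a.T, atol=1e-12)

    def test_zero_variance_gene_raises(self):
        expr = toy_expression(n_genes=4)
        expr.iloc[2] = 7.0
        with pytest.raises(ValueError, match="zero-variance"):
            signed_adjacency(expr, 6)


class TestPickBeta:
    def test_threshold_zero_returns_smallest_candidate(self):
        expr = toy_expression(n_genes=40, seed=3)
        assert pick_beta(expr, candidates=[2, 5, 9], fit_threshold=0.0) == 2

    def test_first_qualifying_beta_matches_independent_fit(self, small_dataset):
        """pick_beta must return the smallest beta whose scale-free fit
        (recomputed here with an independent log-log regression) reaches the
        threshold."""
        expr = np.log2(small_dataset.train_counts.iloc[:200] + 1.0)
        expr = expr[expr.std(axis=1) > 0]
        cands = list(range(1, 13))

        def oracle_fit(beta):
            c = np.corrcoef(expr.to_numpy())
            base = (1 + np.clip(c, -1, 1)) / 2
            a = base**beta
            k = a.sum(axis=0) - np.diag(a)
            k = k[k > 0]
            edges = np.linspace(k.min(), k.max() + 1e-12, 11)
            idx = np.clip(np.digitize(k, edges) - 1, 0, 9)
            xs, ys = [], []
            for b in range(10):
                if (idx == b).sum():
                    xs.append(np.log10(k[idx == b].mean()))
                    ys.append(np.log10((idx == b).sum()))
            res = linregress(xs, ys)
            return res.rvalue**2 if res.slope < 0 else 0.0

        fits = {b: oracle_fit(b) for b in cands}
        qualifying = [b for b in cands if fits[b] >= 0.5]
        if qualifying:
            assert pick_beta(expr, candidates=cands, fit_threshold=0.5) == qualifying[0]
        else:
            with pytest.raises(ValueError):
                pick_beta(expr, candidates=cands, fit_threshold=0.5)

    def test_unreachable_threshold_reports_best_fit(self):
        expr = toy_expression(n_genes=40, seed=3)
        with pytest.raises(ValueError, match="best was"):
            pick_beta(expr, candidates=[2, 3], fit_threshold=1.0)

    def test_constant_connectivity_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate|occupied"):
            scale_free_fit(np.full(30, 2.5))


class TestTOM:
    def test_two_node_closed_form(self):
        a = pd.DataFrame([[1.0, 0.3], [0.3, 1.0]], index=["G0", "G1"], columns=["G0", "G1"])
        tom = compute_tom(a)
        assert tom.iloc[0, 1] == pytest.approx(0.3, abs=1e-12)
        assert tom.iloc[0, 0] == 1.0

    def test_complete_graph_has_maximal_overlap(self):
        n = 6
        a = np.ones((n, n))
        tom = compute_tom(a)
        off = tom[~np.eye(n, dtype=bool)]
        np.testing.assert_allclose(off, 1.0, atol=1e-12)

    def test_empty_graph_has_zero_overlap(self):
        tom = compute_tom(np.zeros((5, 5)))
        assert tom.sum() == pytest.approx(5.0)  # identity pattern

    def test_bounds_symmetry_on_random_adjacency(self, rng):
        a = rng.uniform(0, 1, size=(30, 30))
        a = (a + a.T) / 2
        tom = compute_tom(a)
        assert np.all((tom >= 0) & (tom <= 1 + 1e-12))
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)

    def test_asymmetric_input_raises(self):
        a = np.zeros((3, 3))
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            compute_tom(a)


def _block_tom(sizes, within=0.9, between=0.01):
    n = sum(sizes)
    tom = np.full((n, n), between)
    start = 0
    for s in sizes:
        tom[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(tom, 1.0)
    genes = [f"G{i:03d}" for i in range(n)]
    return pd.DataFrame(tom, index=genes, columns=genes)


class TestClusterModules:
    def test_two_separated_blocks_recovered_exactly(self):
        tom = _block_tom([40, 50])
        assignment = cluster_modules(tom, min_module_size=30)
        labels = assignment.labels
        assert set(labels.unique()) == {1, 2}
        # module 1 is the larger block
        assert (labels.iloc[40:] == 1).all() and (labels.iloc[:40] == 2).all()

    def test_blocks_below_min_size_go_unassigned(self):
        tom = _block_tom([10, 15, 20])
        assignment = cluster_modules(tom, min_module_size=30)
        assert (assignment.labels == 0).all()

    def test_identical_profiles_form_one_module(self):
        n = 60
        tom = pd.DataFrame(np.ones((n, n)), index=[f"G{i}" for i in range(n)])
        tom.columns = tom.index
        assignment = cluster_modules(tom, min_module_size=30)
        assert set(assignment.labels.unique()) == {1}

    def test_fewer_genes_than_min_size_warns(self):
        tom = _block_tom([10])
        with pytest.warns(UserWarning, match="unassigned"):
            assignment = cluster_modules(tom, min_module_size=30)
        assert (assignment.labels == 0).all()


class TestEigengene:
    def test_identical_member_profiles_give_their_standardized_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.0])
        expr = pd.DataFrame([profile] * 4 + [profile * 2 + 1], index=list("abcde"))
        me = module_eigengene(expr, list("abcde"))
        z = (profile - profile.mean()) / profile.std(ddof=1)
        r = np.corrcoef(me, z)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)
        assert np.linalg.norm(me) == pytest.approx(1.0)

    def test_matches_full_svd_oracle_for_two_genes(self, rng):
        expr = toy_expression(n_genes=2, seed=9)
        me = module_eigengene(expr, list(expr.index))
        z = expr.to_numpy()
        z = (z - z.mean(1, keepdims=True)) / z.std(1, ddof=1, keepdims=True)
        _, _, vt = np.linalg.svd(z)
        assert abs(np.dot(me, vt[0])) == pytest.approx(1.0, abs=1e-10)

    def test_sign_convention_holds(self, rng):
        for seed in range(5):
            expr = toy_expression(n_genes=8, seed=seed)
            me = module_eigengene(expr, list(expr.index))
            z = expr.sub(expr.mean(1), axis=0).div(expr.std(1, ddof=1), axis=0)
            assert np.corrcoef(me, z.mean(0))[0, 1] >= 0

    def test_zero_variance_member_raises(self):
        expr = toy_expression(n_genes=3)
        expr.iloc[1] = 2.0
        with pytest.raises(ValueError, match="zero-variance"):
            module_eigengene(expr, list(expr.index))


class TestMergeModules:
    def _assignment(self, expr, groups):
        labels = pd.Series(0, index=expr.index)
        for m, genes in groups.items():
            labels.loc[genes] = m
        return ModuleAssignment(labels)

    def test_identical_eigengenes_are_merged(self, rng):
        profile = rng.normal(size=20)
        noise = 0.01 * rng.normal(size=(8, 20))
        expr = pd.DataFrame(
            np.vstack([profile + noise[:4], profile + noise[4:]]),
            index=[f"G{i}" for i in range(8)],
        )
        assignment = self._assignment(expr, {1: expr.index[:4], 2: expr.index[4:]})
        merged = merge_modules(assignment, expr)
        assert len(merged.modules()) == 1
        assert merged.merge_history

    def test_distant_modules_are_unchanged(self, rng):
        expr = toy_expression(n_genes=10, n_samples=40, seed=13)
        assignment = self._assignment(expr, {1: expr.index[:5], 2: expr.index[5:]})
        mes = compute_eigengenes(expr, assignment.labels)
        if 1 - np.corrcoef(mes[1], mes[2])[0, 1] >= 0.5:
            merged = merge_modules(assignment, expr, cut_height=0.25)
            assert len(merged.modules()) == 2

    def test_three_modules_merge_to_two(self, rng):
        base = rng.normal(size=30)
        other = rng.normal(size=30)
        other -= base * (base @ other) / (base @ base)  # orthogonal to base
        rowsA = base + 0.1 * rng.normal(size=(5, 30))
        rowsB = base + 0.1 * rng.normal(size=(5, 30))
        rowsC = other + 0.1 * rng.normal(size=(5, 30))
        expr = pd.DataFrame(
            np.vstack([rowsA, rowsB, rowsC]), index=[f"G{i}" for i in range(15)]
        )
        assignment = self._assignment(
            expr, {1: expr.index[:5], 2: expr.index[5:10], 3: expr.index[10:]}
        )
        merged = merge_modules(assignment, expr, cut_height=0.25)
        assert len(merged.modules()) == 2


class TestModuleTrait:
    def _phen(self, rhythm):
        return pd.DataFrame(
            {"rhythm": rhythm}, index=[f"S{j}" for j in range(len(rhythm))]
        )

    def test_eigengene_equal_to_code_gives_r_one(self):
        rhythm = ["SR/SR"] * 10 + ["AF/SR"] * 10
        me = np.array([0.0] * 10 + [1.0] * 10)
        out = module_trait_correlation({1: me}, self._phen(rhythm), "susceptibility")
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_orthogonal_eigengene_is_null(self, rng):
        """An eigengene orthogonal to the contrast code should look like the
        permutation null: tiny r, large p."""
        rhythm = ["SR/SR"] * 20 + ["AF/SR"] * 20
        code = np.array([0.0] * 20 + [1.0] * 20)
        me = rng.normal(size=40)
        me -= me.mean()
        c = code - code.mean()
        me -= c * (c @ me) / (c @ c)
        out = module_trait_correlation({1: me}, self._phen(rhythm), "susceptibility")
        assert abs(out.loc[0, "r"]) < 1e-10 and out.loc[0, "p"] > 0.5
        # permutation oracle agrees the observed |r| is unremarkable
        rperm = []
        prng = np.random.default_rng(0)
        for _ in range(200):
            rperm.append(abs(pearsonr(me, prng.permutation(code)).statistic))
        assert abs(out.loc[0, "r"]) <= np.quantile(rperm, 0.95)

    def test_contrast_uses_only_its_two_groups(self):
        rhythm = ["SR/SR"] * 5 + ["AF/SR"] * 5 + ["AF/AF"] * 5
        me = np.concatenate([np.zeros(5), np.ones(5), np.full(5, 100.0)])
        out = module_trait_correlation({1: me}, self._phen(rhythm), "susceptibility")
        assert out.loc[0, "n"] == 10
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_constant_trait_subset_raises(self):
        rhythm = ["SR/SR"] * 6
        with pytest.raises(ValueError, match="constant|empty"):
            module_trait_correlation(
                {1: np.arange(6.0)}, self._phen(rhythm), "susceptibility"
            )
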