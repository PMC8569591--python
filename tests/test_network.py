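"""Signed adjacency, TOM, module detection, eigenproteins, merging."""

import numpy as np
import pandas as pd
import pytest

from phosol.network import (
    AdjacencyMatrix,
    detect_modules,
    eigenproteins,
    merge_close_modules,
    module_summary,
    signed_adjacency,
    tom_similarity,
    variance_explained,
)
from phosol.quant import QuantMatrix, SampleDesign


def expr_matrix(values, design=None, ids=None):
    values = np.asarray(values, dtype=float)
    design = design or SampleDesign.full_factorial(values.shape[1] // 4)
    ids = ids or [f"P{i}" for i in range(values.shape[0])]
    data = pd.DataFrame(values, index=ids, columns=design.sample_ids)
    return QuantMatrix(data, pd.Series(3, index=data.index),
                       pd.DataFrame(False, index=data.index,
                                    columns=["reverse", "contaminant", "site_only"]),
                       design, scale="log2")


def block_expression(rng, n_per_block, n_samples, within_cor, n_noise=0,
                     noise_sd=1.0):
    """Factor-model expression with known block structure."""
    lam = np.sqrt(within_cor)
    rows = []
    for b in range(len(n_per_block)):
        factor = rng.normal(size=n_samples)
        for _ in range(n_per_block[b]):
            rows.append(lam * factor +
                        np.sqrt(1 - lam**2) * rng.normal(size=n_samples))
    for _ in range(n_noise):
        rows.append(noise_sd * rng.normal(size=n_samples))
    return np.array(rows)


def brute_force_tom(a):
    """Triple-loop oracle for the TOM formula."""
    n = a.shape[0]
    k = a.sum(axis=0) - 1.0
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestAdjacency:
    def test_closed_forms(self, rng):
        # perfectly correlated pair -> 1; anticorrelated -> 0; independent -> ~0.5^20
        x = rng.normal(size=16)
        vals = np.array([x, 2 * x + 3, -x + 1])
        adj = signed_adjacency(expr_matrix(vals), beta=20.0)
        a = adj.values
        assert a[0, 1] == pytest.approx(1.0, abs=1e-9)
        assert a[0, 2] == pytest.approx(0.0, abs=1e-9)
        assert np.all((a >= 0) & (a <= 1))
        assert np.allclose(np.diag(a), 1.0)

    def test_uncorrelated_closed_form(self):
        # build two exactly orthogonal, zero-mean profiles: cor = 0
        x = np.array([1.0, -1.0, 1.0, -1.0, 2.0, -2.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0, 2.0, 2.0, -2.0, -2.0])
        assert abs(np.corrcoef(x, y)[0, 1]) < 1e-12
        adj = signed_adjacency(expr_matrix(np.array([x, y]),
                                           design=SampleDesign.full_factorial(2)),
                               beta=20.0)
        assert adj.values[0, 1] == pytest.approx(0.5**20, rel=1e-9)

    def test_zero_variance_named(self, rng):
        vals = rng.normal(size=(3, 8))
        vals[1] = 5.0
        with pytest.raises(ValueError, match="P1"):
            signed_adjacency(expr_matrix(vals, SampleDesign.full_factorial(2)))

    def test_missing_rejected(self, rng):
        vals = rng.normal(size=(3, 8))
        qm = expr_matrix(vals, SampleDesign.full_factorial(2))
        qm.data.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            signed_adjacency(qm)


class TestTOM:
    def test_all_ones_adjacency(self):
        n = 12
        adj = AdjacencyMatrix(np.ones((n, n)), [f"P{i}" for i in range(n)], 20.0)
        tom = tom_similarity(adj).to_numpy()
        assert np.allclose(tom, 1.0)

    def test_three_node_hand_value(self):
        a = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.0], [0.5, 0.0, 1.0]])
        tom = tom_similarity(AdjacencyMatrix(a, ["a", "b", "c"], 20.0))
        assert tom.loc["b", "c"] == pytest.approx(1 / 6, abs=1e-12)
        assert np.allclose(np.diag(tom.to_numpy()), 1.0)

    def test_matches_triple_loop_oracle(self, rng):
        for n in (5, 20, 50):
            c = rng.uniform(-1, 1, size=(n, n))
            a = np.power((1 + (c + c.T) / 2) / 2, 6.0)
            np.fill_diagonal(a, 1.0)
            tom = tom_similarity(AdjacencyMatrix(a, [f"P{i}" for i in range(n)], 6.0))
            assert np.allclose(tom.to_numpy(), brute_force_tom(a), atol=1e-12)

    def test_symmetry_and_range(self, rng):
        vals = rng.normal(size=(30, 16))
        tom = tom_similarity(signed_adjacency(expr_matrix(vals))).to_numpy()
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0


class TestModuleDetection:
    def test_two_planted_blocks_recovered(self):
        rng = np.random.default_rng(42)
        vals = block_expression(rng, [30, 30], 30, within_cor=0.9)
        design = SampleDesign.full_factorial(7)
        qm = expr_matrix(vals[:, :28], design)
        tom = tom_similarity(signed_adjacency(qm))
        modules = detect_modules(tom, min_size=15)
        labels = modules.labels
        assert len(modules.module_labels()) == 2
        for block in (labels.iloc[:30], labels.iloc[30:]):
            top = block.value_counts().idxmax()
            assert top != 0
            assert (block == top).mean() >= 0.9

    def test_small_cluster_unassigned(self, rng):
        vals = block_expression(rng, [10], 16, within_cor=0.95)
        tom = tom_similarity(signed_adjacency(expr_matrix(vals)))
        with pytest.warns(UserWarning):
            modules = detect_modules(tom, min_size=15)
        assert (modules.labels == 0).all()

    def test_noise_mostly_unassigned(self):
        """i.i.d. noise proteins stay >= 95% unassigned across seeds."""
        frac_unassigned = []
        for seed in range(20):
            rng = np.random.default_rng(900 + seed)
            vals = rng.normal(size=(60, 16))
            tom = tom_similarity(signed_adjacency(expr_matrix(vals)))
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                modules = detect_modules(tom, min_size=15)
            frac_unassigned.append((modules.labels == 0).mean())
        assert np.mean(frac_unassigned) >= 0.95

    def test_deterministic(self, rng):
        vals = block_expression(rng, [20, 20], 16, within_cor=0.8)
        tom = tom_similarity(signed_adjacency(expr_matrix(vals)))
        a = detect_modules(tom, min_size=10).labels
        b = detect_modules(tom, min_size=10).labels
        assert a.equals(b)

    def test_cut_height_range(self, rng):
        vals = rng.normal(size=(10, 16))
        tom = tom_similarity(signed_adjacency(expr_matrix(vals)))
        with pytest.raises(ValueError):
            detect_modules(tom, cut_height=1.5)


class TestEigenproteins:
    def _fixture(self, seed=7):
        rng = np.random.default_rng(seed)
        vals = block_expression(rng, [25, 25], 16, within_cor=0.9)
        qm = expr_matrix(vals)
        labels = pd.Series([1] * 25 + [2] * 25, index=qm.data.index)
        from phosol.network import ModuleSet
        return qm, ModuleSet(labels)

    def test_identical_profiles(self):
        rng = np.random.default_rng(3)
        profile = rng.normal(size=16)
        vals = np.array([2 * profile + 1, 0.5 * profile - 2, profile])
        qm = expr_matrix(vals)
        from phosol.network import ModuleSet
        mods = eigenproteins(qm, ModuleSet(pd.Series([1, 1, 1],
                                                     index=qm.data.index)))
        e = mods.eigenproteins.loc[1].to_numpy()
        z = (profile - profile.mean()) / profile.std(ddof=1)
        assert np.allclose(e / np.linalg.norm(e), z / np.linalg.norm(z), atol=1e-9)
        assert np.allclose(mods.kme[1], 1.0, atol=1e-9)

    def test_unit_norm_and_orientation(self):
        qm, mods = self._fixture()
        out = eigenproteins(qm, mods)
        for label in (1, 2):
            e = out.eigenproteins.loc[label].to_numpy()
            assert np.linalg.norm(e) == pytest.approx(1.0, abs=1e-9)
            members = sorted(out.members(label))
            assert out.kme.loc[members, label].mean() > 0

    def test_variance_explained_above_members(self):
        """First-PC optimality: the eigenprotein explains at least as much
        standardized variance as any single member profile direction."""
        qm, mods = self._fixture()
        out = eigenproteins(qm, mods)
        from phosol.network import _standardize
        for label in (1, 2):
            ve = variance_explained(qm, out, label)
            assert ve > 0.8
            members = sorted(out.members(label))
            X = _standardize(qm.data.loc[members])
            for row in X:
                d = row / np.linalg.norm(row)
                assert ve >= ((X @ d) ** 2).sum() / (X**2).sum() - 1e-9

    def test_degenerate_module_errors(self):
        qm = expr_matrix(np.array([[1.0] * 16, [2.0] * 16]))
        from phosol.network import ModuleSet
        with pytest.raises(ValueError):
            eigenproteins(qm, ModuleSet(pd.Series([1, 1], index=qm.data.index)))


class TestMerging:
    def test_near_identical_modules_merge(self):
        rng = np.random.default_rng(11)
        factor = rng.normal(size=16)
        lam = np.sqrt(0.97)
        vals = np.array([lam * factor + np.sqrt(1 - lam**2) * rng.normal(size=16)
                         for _ in range(40)])
        qm = expr_matrix(vals)
        from phosol.network import ModuleSet
        labels = pd.Series([1] * 20 + [2] * 20, index=qm.data.index)
        merged = merge_close_modules(ModuleSet(labels), qm, merge_height=0.07)
        assert len(merged.module_labels()) == 1
        assert merged.sizes()[1] == 40

    def test_distinct_modules_stay(self):
        rng = np.random.default_rng(12)
        vals = block_expression(rng, [20, 20], 16, within_cor=0.9)
        qm = expr_matrix(vals)
        from phosol.network import ModuleSet
        labels = pd.Series([1] * 20 + [2] * 20, index=qm.data.index)
        merged = merge_close_modules(ModuleSet(labels), qm, merge_height=0.07)
        assert len(merged.module_labels()) == 2

    def test_chain_merge_to_fixpoint(self):
        rng = np.random.default_rng(13)
        factor = rng.normal(size=16)
        lam = np.sqrt(0.96)
        vals = np.array([lam * factor + np.sqrt(1 - lam**2) * rng.normal(size=16)
                         for _ in range(60)])
        qm = expr_matrix(vals)
        from phosol.network import ModuleSet
        labels = pd.Series([1] * 20 + [2] * 20 + [3] * 20, index=qm.data.index)
        merged = merge_close_modules(ModuleSet(labels), qm, merge_height=0.07)
        assert len(merged.module_labels()) == 1


class TestModuleSummary:
    def test_planted_rs_module_hottest(self, rng):
        """A module made of the planted RS-like class tops both the mean
        NCPR and the insolubility heat of all modules."""
        vals = block_expression(rng, [20, 20, 20], 16, within_cor=0.9)
        qm = expr_matrix(vals)
        ids = list(qm.data.index)
        from phosol.network import ModuleSet
        labels = pd.Series([1] * 20 + [2] * 20 + [3] * 20, index=ids)
        mods = eigenproteins(qm, ModuleSet(labels))
        soluble = pd.DataFrame(
            {"mean_delta": [2.0] * 20 + [0.0] * 20 + [-0.5] * 20}, index=ids)
        charge = pd.DataFrame({"id": ids,
                               "ncpr": [0.3] * 20 + [0.0] * 20 + [-0.3] * 20})
        out = module_summary(mods, soluble, charge)
        top = out.sort_values("mean_ncpr", ascending=False).iloc[0]
        assert top["module"] == "M1"
        assert out.sort_values("mean_delta", ascending=False).iloc[0]["module"] == "M1"
        assert top["mean_delta"] == pytest.approx(2.0)

    def test_hub_ordering_is_kme_sort(self, rng):
        vals = block_expression(rng, [20], 16, within_cor=0.9)
        qm = expr_matrix(vals)
        from phosol.network import ModuleSet
        mods = eigenproteins(qm, ModuleSet(pd.Series([1] * 20,
                                                     index=qm.data.index)))
        ids = list(qm.data.index)
        soluble = pd.DataFrame({"mean_delta": 1.0}, index=ids)
        charge = pd.DataFrame({"id": ids, "ncpr": 0.1})
        out = module_summary(mods, soluble, charge, n_hubs=5)
        hubs = out.iloc[0]["hubs"].split(";")
        kme = mods.kme[1]
        expected = list(kme.sort_values(ascending=False).index[:5])
        assert hubs == expected
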