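"""Network construction, module detection and trait statistics."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from floranet import coexpression as cx
from floranet import simulate as sim
from floranet.config import NetworkParams, SimulationConfig


def _expr(values: np.ndarray, trait=None) -> cx.ExpressionData:
    m, n = values.shape
    df = pd.DataFrame(
        values, index=[f"S{i}" for i in range(m)], columns=[f"g{j}" for j in range(n)]
    )
    if trait is None:
        trait = np.r_[np.zeros(m // 2), np.ones(m - m // 2)]
    return cx.ExpressionData(values=df, trait=pd.Series(trait, index=df.index))


class TestFilterGenes:
    def test_tau_zero_keeps_everything(self, rng):
        expr = _expr(rng.normal(size=(10, 8)))
        out = cx.filter_genes_by_pcc(expr, 0.0)
        assert out.gene_ids == expr.gene_ids

    def test_noise_gene_dropped(self, rng):
        base = rng.normal(size=10)
        values = np.column_stack([base, base * 2.0, rng.normal(size=10)])
        out = cx.filter_genes_by_pcc(_expr(values), 0.99)
        assert out.gene_ids == ["g0", "g1"]

    def test_matches_brute_force_scan(self, rng):
        values = rng.normal(size=(20, 60))
        values[:, :10] += 2.0 * rng.normal(size=(20, 1))  # correlated block
        expr = _expr(values)
        tau = 0.5
        corr = np.corrcoef(values, rowvar=False)
        keep = [
            j
            for j in range(60)
            if any(abs(corr[j, k]) >= tau for k in range(60) if k != j)
        ]
        out = cx.filter_genes_by_pcc(expr, tau)
        assert out.gene_ids == [f"g{j}" for j in keep]

    def test_too_strict_raises(self, rng):
        expr = _expr(rng.normal(size=(12, 6)))
        with pytest.raises(ValueError, match="filter too strict"):
            cx.filter_genes_by_pcc(expr, 1.0)


class TestAdjacency:
    def test_beta_one_is_absolute_correlation(self, rng):
        values = rng.normal(size=(15, 10))
        adj = cx.adjacency(_expr(values), 1.0)
        corr = np.abs(np.corrcoef(values, rowvar=False))
        np.fill_diagonal(corr, 0.0)
        assert np.allclose(adj.to_numpy(), corr, atol=1e-12)

    def test_identical_genes_have_unit_weight(self, rng):
        base = rng.normal(size=12)
        adj = cx.adjacency(_expr(np.column_stack([base, base])), 7.0)
        assert adj.iloc[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_per_pair_oracle(self, rng):
        values = rng.normal(size=(14, 20))
        beta = 5.0
        adj = cx.adjacency(_expr(values), beta).to_numpy()
        for i in range(20):
            for j in range(20):
                if i == j:
                    assert adj[i, j] == 0.0
                    continue
                r = np.corrcoef(values[:, i], values[:, j])[0, 1]
                assert adj[i, j] == pytest.approx(abs(r) ** beta, abs=1e-12)

    def test_zero_variance_gene_named(self, rng):
        values = rng.normal(size=(10, 3))
        values[:, 1] = 4.2
        with pytest.raises(ValueError, match="g1"):
            cx.adjacency(_expr(values), 2.0)


class TestTOM:
    def test_zero_adjacency_gives_identity(self):
        tom = cx.tom_similarity(np.zeros((5, 5)))
        assert np.allclose(tom, np.eye(5))

    def test_three_node_hand_case(self):
        adj = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        tom = cx.tom_similarity(adj)
        # TOM_12 = (sum_u a_1u a_u2 + a_12) / (min(k) + 1 - a_12) = 2 / 2
        assert tom[0, 1] == pytest.approx(1.0)

    def test_matches_triple_loop_oracle(self, rng):
        a = rng.uniform(0, 1, size=(15, 15))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = cx.tom_similarity(a)
        k = a.sum(axis=1)
        for i in range(15):
            for j in range(15):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(15) if u not in (i, j))
                expected = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-12)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            cx.tom_similarity(np.zeros((3, 4)))

    def test_symmetry_and_range_on_random_inputs(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 12))
            a = rng.uniform(0, 1, size=(n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            tom = cx.tom_similarity(a)
            assert np.allclose(tom, tom.T, atol=1e-12)
            assert tom.min() >= 0.0 and tom.max() <= 1.0


class TestSoftThreshold:
    @staticmethod
    def _scale_free_expression(rng, n_genes=120, m=60):
        """Hub-structured expression whose connectivity is power-law-like."""
        z = rng.normal(size=m)
        weights = rng.pareto(2.0, size=n_genes) + 0.05
        weights = np.clip(weights / weights.max(), 0.03, 1.0)
        values = weights[None, :] * z[:, None] + 0.4 * rng.normal(size=(m, n_genes))
        return _expr(values)

    def test_fit_table_covers_interval_inclusive(self, rng):
        expr = self._scale_free_expression(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, table = cx.pick_soft_threshold(expr)
        assert list(table["power"]) == list(range(1, 41))

    def test_chosen_power_fits_scale_free_topology(self, rng):
        expr = self._scale_free_expression(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta, table = cx.pick_soft_threshold(expr)
        row = table[table["power"] == beta].iloc[0]
        if row["signed_r2"] < 0.6:  # fallback power; fit must exist elsewhere
            assert table["signed_r2"].max() < 0.6
        else:
            assert row["signed_r2"] >= 0.6

    def test_r2_min_zero_returns_power_one(self, rng):
        expr = self._scale_free_expression(rng)
        params = NetworkParams(r2_min=0.0)
        beta, table = cx.pick_soft_threshold(expr, params)
        # power 1 already has a decreasing degree distribution here
        assert table.loc[table["power"] == 1, "slope"].iloc[0] < 0
        assert beta == 1


class TestDetectModules:
    def test_noise_free_planted_modules_recovered_exactly(self):
        cfg = SimulationConfig(
            seed=2, noise_sd=0.0, n_background_genes=0,
            module_sizes=(40, 35, 30), trait_assoc=(0.9, 0.1, 0.1),
        )
        expr, truth = sim.generate_expression(cfg)
        tom = cx.tom_similarity(cx.adjacency(expr, 6))
        part = cx.detect_modules(tom)
        assert len(part.modules()) == 3
        ari = adjusted_rand_score(
            [truth.gene_modules[g] for g in part.labels.index], list(part.labels)
        )
        assert ari == 1.0

    def test_small_cluster_goes_grey(self):
        cfg = SimulationConfig(
            seed=3, noise_sd=0.0, n_background_genes=0,
            module_sizes=(40, 10), trait_assoc=(0.5, 0.0),
        )
        expr, truth = sim.generate_expression(cfg)
        tom = cx.tom_similarity(cx.adjacency(expr, 6))
        part = cx.detect_modules(tom, NetworkParams(min_module_size=30))
        small = [g for g, m in truth.gene_modules.items() if m == "M2"]
        assert all(part.labels[g] == cx.GREY for g in small)

    def test_labels_deterministic(self, analyzed):
        expr, _, partition, _, _, _ = analyzed
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            again, _, _, _ = cx.analyze(expr)
        assert partition.labels.equals(again.labels)

    def test_min_module_size_validated(self):
        tom = pd.DataFrame(np.eye(4))
        with pytest.raises(ValueError):
            cx.detect_modules(tom, NetworkParams(min_module_size=1))


class TestEigengeneAndStats:
    def test_eigengene_matches_svd_oracle(self, rng):
        values = rng.normal(size=(20, 8))
        expr = _expr(values)
        e = cx.module_eigengene(expr, expr.gene_ids)
        std = (values - values.mean(0)) / values.std(0)
        cov = std @ std.T
        evals, evecs = np.linalg.eigh(cov)
        lead = evecs[:, -1]
        assert abs(abs(e.to_numpy() @ lead) - 1.0) < 1e-10
        assert np.linalg.norm(e) == pytest.approx(1.0)
        # variance explained along the eigengene equals the top eigenvalue
        assert (e.to_numpy() @ cov @ e.to_numpy()) == pytest.approx(evals[-1], rel=1e-10)

    def test_sign_convention_and_identical_gene_kme(self, rng):
        base = rng.normal(size=16)
        values = np.column_stack([base, base, base])
        expr = _expr(values)
        e = cx.module_eigengene(expr, expr.gene_ids)
        kme = cx.module_membership(expr, pd.DataFrame({"m": e}))
        assert np.allclose(kme["m"], 1.0, atol=1e-10)

    def test_gene_equal_to_trait_has_gs_one(self):
        trait = np.r_[np.zeros(8), np.ones(8)]
        expr = _expr(
            np.column_stack([trait, np.sin(np.arange(16))]), trait=trait
        )
        gs = cx.gene_significance(expr)
        assert gs["g0"] == pytest.approx(1.0)

    def test_single_class_trait_rejected(self, rng):
        expr = _expr(rng.normal(size=(10, 4)), trait=np.zeros(10))
        with pytest.raises(ValueError, match="no contrast"):
            cx.gene_significance(expr)

    def test_module_significance_is_mean_member_gs(self, analyzed):
        _, _, partition, _, _, _ = analyzed
        for module in partition.modules():
            expected = partition.gs[partition.members(module)].mean()
            assert partition.module_significance[module] == pytest.approx(expected)

    def test_kme_bounded_and_planted_hub_near_one(self, analyzed):
        _, _, partition, _, _, _ = analyzed
        assert (partition.kme.abs() <= 1.0 + 1e-12).all().all()
        top = partition.module_significance.index[0]
        hubs = cx.identify_hubs(partition, top_k=1)
        assert partition.kme.loc[hubs[top][0], top] > 0.9

    def test_hub_ranking_and_validation(self, analyzed):
        _, _, partition, _, _, _ = analyzed
        with pytest.raises(ValueError):
            cx.identify_hubs(partition, top_k=0)
        top = partition.module_significance.index[0]
        hubs = cx.identify_hubs(partition, top_k=5)[top]
        kmes = [partition.kme.loc[g, top] for g in hubs]
        assert kmes == sorted(kmes, reverse=True)


class TestEquivariance:
    def test_gene_permutation_permutes_outputs(self, rng):
        cfg = SimulationConfig(
            seed=6, module_sizes=(35, 30), trait_assoc=(0.8, 0.2),
            n_background_genes=10,
        )
        expr, _ = sim.generate_expression(cfg)
        perm = rng.permutation(expr.values.shape[1])
        shuffled = cx.ExpressionData(
            values=expr.values.iloc[:, perm], trait=expr.trait
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p1, b1, _, _ = cx.analyze(expr)
            p2, b2, _, _ = cx.analyze(shuffled)
        assert b1 == b2
        # same genes retained, same partition as sets, same GS per gene
        assert set(p1.labels.index) == set(p2.labels.index)
        for module in p1.modules():
            genes = set(p1.members(module))
            matches = [set(p2.members(m)) for m in p2.modules()]
            assert genes in matches
        common = list(p1.labels.index)
        assert np.allclose(p1.gs[common], p2.gs[common], atol=1e-10)
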