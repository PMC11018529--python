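"""Co-expression network: bicor, soft power, adjacency, TOM, modules, hubs."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import polybias as pb
from oracles import naive_bicor, naive_scale_free_choice, naive_tom


class TestBicor:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        assert pb.bicor(x, x) == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert pb.bicor(3.0 * x + 7.0, y) == pytest.approx(pb.bicor(x, y))
        assert pb.bicor(x, 0.5 * y - 2.0) == pytest.approx(pb.bicor(x, y))

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=25), rng.normal(size=25)
        assert pb.bicor(x, y) == pytest.approx(pb.bicor(y, x))

    def test_matches_naive_oracle_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.normal(size=50)
            y = 0.5 * x + rng.normal(size=50)
            assert pb.bicor(x, y) == pytest.approx(naive_bicor(x, y), abs=1e-10)

    def test_close_to_pearson_without_outliers(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=200)
        y = 0.7 * x + rng.normal(size=200) * 0.5
        assert abs(pb.bicor(x, y) - np.corrcoef(x, y)[0, 1]) < 0.05

    def test_constant_vector_errors_or_falls_back(self):
        x = np.ones(10)
        y = np.arange(10.0)
        with pytest.raises(pb.InputError):
            pb.bicor(x, y)

    def test_matrix_agrees_with_pairwise(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(8, 40))
        mat = pb.bicor_matrix(x)
        for i in range(8):
            for j in range(i + 1, 8):
                assert mat[i, j] == pytest.approx(pb.bicor(x[i], x[j]), abs=1e-12)


class TestAdjacencyTom:
    @pytest.mark.parametrize(
        "corr,power,expected", [(-0.9, 1, 0.0), (0.5, 1, 0.5), (0.9, 2, 0.81)]
    )
    def test_signed_hybrid_values(self, corr, power, expected):
        c = np.array([[1.0, corr], [corr, 1.0]])
        adj = pb.adjacency_signed_hybrid(c, power)
        assert adj[0, 1] == pytest.approx(expected)
        assert adj[0, 0] == 0.0

    def test_exclusive_pair_has_tom_one(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        tom = pb.tom_unsigned(a)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_zero_adjacency_gives_zero_overlap(self):
        tom = pb.tom_unsigned(np.zeros((5, 5)))
        assert np.all(tom[~np.eye(5, dtype=bool)] == 0.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            x = rng.normal(size=(20, 50))
            corr = np.corrcoef(x)
            adj = pb.adjacency_signed_hybrid(corr, 3)
            assert np.max(np.abs(pb.tom_unsigned(adj) - naive_tom(adj))) < 1e-10

    def test_range_and_symmetry_invariants(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(30, 25))
        adj = pb.adjacency_signed_hybrid(pb.bicor_matrix(x), 4)
        tom = pb.tom_unsigned(adj)
        assert adj.min() >= 0 and adj.max() <= 1
        assert tom.min() >= 0 and tom.max() <= 1
        assert np.allclose(tom, tom.T) and np.allclose(adj, adj.T)


def modular_expression(n_genes=150, n_modules=5, seed=8, noise=0.6):
    """Noisy modular data whose connectivity is heterogeneous enough to scan."""
    rng = np.random.default_rng(seed)
    sizes = rng.multinomial(n_genes - n_modules, np.ones(n_modules) / n_modules) + 1
    rows = []
    for m, sz in enumerate(sizes):
        latent = rng.normal(size=30)
        load = rng.uniform(0.2, 1.5, size=sz)
        rows.append(load[:, None] * latent[None, :] + rng.normal(0, noise, (sz, 30)))
    return np.vstack(rows)


class TestSoftPower:
    def test_matches_exhaustive_scan_oracle(self):
        x = modular_expression()
        corr = np.corrcoef(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            power, table = pb.pick_soft_power(corr, powers=range(1, 13), target_fit=0.8)
        oracle = naive_scale_free_choice(corr, range(1, 13), target_fit=0.8)
        assert power == oracle

    def test_deterministic(self):
        x = modular_expression(seed=9)
        corr = np.corrcoef(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p1, _ = pb.pick_soft_power(corr, powers=range(1, 8))
            p2, _ = pb.pick_soft_power(corr, powers=range(1, 8))
        assert p1 == p2

    def test_target_zero_boundary(self):
        x = modular_expression(seed=10)
        corr = np.corrcoef(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            power, table = pb.pick_soft_power(corr, powers=range(1, 8), target_fit=0.0)
        # first power with nonnegative fit (negative slope) must be chosen
        valid = table["fit"].dropna()
        qualifying = valid[valid >= 0.0]
        expected = int(qualifying.index.min()) if len(qualifying) else int(valid.idxmax())
        assert power == expected


class TestModules:
    def test_planted_modules_recovered_noise_free(self):
        expr, truth = pb.simulate_modules(120, 2, noise_sd=0.0, seed=11, min_module_size=30)
        x = expr.data.to_numpy()
        adj = pb.adjacency_signed_hybrid(pb.bicor_matrix(x), 6)
        labels = pb.detect_modules(pb.tom_unsigned(adj), expr=x, min_size=30)
        planted = np.array([truth.modules[g] for g in expr.genes])
        assert adjusted_rand_score(planted, labels) == 1.0

    def test_min_size_larger_than_clusters_unassigns_all(self):
        expr, _ = pb.simulate_modules(90, 3, noise_sd=0.0, seed=12)
        x = expr.data.to_numpy()
        adj = pb.adjacency_signed_hybrid(pb.bicor_matrix(x), 6)
        labels = pb.detect_modules(pb.tom_unsigned(adj), expr=x, min_size=91)
        assert np.all(labels == 0)

    def test_merge_is_idempotent(self):
        from polybias.network import _merge_modules

        expr, truth = pb.simulate_modules(120, 2, noise_sd=0.2, seed=13)
        x = expr.data.to_numpy()
        labels = np.array([truth.modules[g] for g in expr.genes])
        once = _merge_modules(x, labels, merge_height=0.15)
        twice = _merge_modules(x, once, merge_height=0.15)
        assert np.array_equal(once, twice)

    def test_pipeline_deterministic(self):
        expr, _ = pb.simulate_modules(100, 2, noise_sd=0.3, seed=14)
        x = expr.data.to_numpy()
        n1 = pb.build_network(x, power=6)
        n2 = pb.build_network(x, power=6)
        assert np.array_equal(n1.labels, n2.labels)
        assert np.array_equal(n1.hubs, n2.hubs)


class TestEigengeneHubs:
    def test_identical_genes_give_perfect_correlation(self):
        rng = np.random.default_rng(15)
        profile = rng.normal(size=20)
        x = np.tile(profile, (5, 1))
        e = pb.module_eigengene(x)
        assert abs(np.corrcoef(e, profile)[0, 1]) == pytest.approx(1.0)
        # sign convention: mean member correlation nonnegative
        assert np.corrcoef(e, profile)[0, 1] > 0

    def test_unit_variance(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=(10, 30))
        e = pb.module_eigengene(x)
        assert e.std() == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=(10, 25))
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        evals, evecs = np.linalg.eigh(z.T @ z)
        top = evecs[:, -1]
        e = pb.module_eigengene(x)
        assert abs(np.corrcoef(e, top)[0, 1]) == pytest.approx(1.0)

    def test_kme_one_for_member_equal_to_eigengene(self):
        rng = np.random.default_rng(18)
        profile = rng.normal(size=20)
        x = np.tile(profile, (40, 1))
        labels = np.ones(40, dtype=int)
        hubs, kme = pb.hub_genes(x, labels, kme_threshold=0.9)
        assert np.allclose(kme, 1.0) and hubs.all()

    def test_threshold_one_yields_no_hubs(self):
        expr, _ = pb.simulate_modules(80, 2, noise_sd=0.5, seed=19)
        x = expr.data.to_numpy()
        net = pb.build_network(x, power=6, kme_threshold=1.0)
        assert not net.hubs.any()

    def test_planted_hub_sensitivity(self):
        expr, truth = pb.simulate_modules(200, 2, noise_sd=0.1, seed=20)
        x = expr.data.to_numpy()
        net = pb.build_network(x, power=6)
        planted = np.array([truth.hub_flags[g] for g in expr.genes])
        assert net.hubs[planted].mean() >= 0.9


class TestNeighborComposition:
    def test_single_subgenome_all_intra(self):
        rng = np.random.default_rng(21)
        w = rng.random((12, 12))
        w = (w + w.T) / 2
        comp = pb.neighbor_composition(w, ["A"] * 12, k=5)
        assert (comp["intra"] == 5).all() and (comp["inter"] == 0).all()

    def test_total_tie_is_deterministic(self):
        w = np.ones((10, 10))
        subs = ["A"] * 5 + ["B"] * 5
        a = pb.neighbor_composition(w, subs, k=4)
        b = pb.neighbor_composition(w, subs, k=4)
        pd.testing.assert_frame_equal(a, b)
        # ties broken by ascending gene id: gene 0's top-4 are genes 1-4
        assert a.iloc[0]["intra"] == 4

    def test_k_exceeding_network_uses_all(self):
        w = np.ones((6, 6))
        comp = pb.neighbor_composition(w, ["A", "A", "B", "B", "B", "B"], k=100)
        assert (comp["k_used"] == 5).all()
        assert comp["intra"].iloc[0] == 1  # the other A gene

    def test_weighted_hub_labels_overrepresented(self):
        expr, truth = pb.simulate_modules(
            400, 2, hub_subgenome_weights={"A": 0.025, "B": 0.025, "C": 0.95},
            noise_sd=0.1, seed=22,
        )
        x = expr.data.to_numpy()
        subs = [truth.gene_subgenome[g] for g in expr.genes]
        net = pb.build_network(x, power=6)
        comp = pb.neighbor_composition(net.tom, subs, gene_ids=list(expr.genes), k=30)
        planted_hubs = [g for g in expr.genes if truth.hub_flags[g]]
        c_frac_hubs = np.mean([truth.gene_subgenome[g] == "C" for g in planted_hubs])
        base_rate = np.mean([s == "C" for s in subs])
        assert c_frac_hubs >= 0.8
        assert c_frac_hubs > base_rate
        assert set(comp.columns) >= {"intra", "inter", "pct_intra", "n_C"}
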