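"""Mapping objective, optimization and assignment extraction."""

import numpy as np
import pandas as pd
import pytest

import spotmap as sm
from spotmap.io import ExpressionMatrix, ValidationError
from spotmap.mapping import KL_EPS, CostMatrices, MappingConfig, MappingMatrix


def norm_mat(values, modality="sc") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    prefix = "c" if modality == "sc" else "s"
    return ExpressionMatrix(values, [f"{prefix}{i}" for i in range(values.shape[0])],
                            [f"g{j}" for j in range(values.shape[1])],
                            layer="cpm_log2", modality=modality)


def oracle_kl(C, S, eps=KL_EPS):
    """Naive double-loop KL between eps-smoothed renormalized profiles."""
    out = np.zeros((len(C), len(S)))
    for i, c in enumerate(C):
        p = (np.asarray(c, float) + eps)
        p = p / p.sum()
        for j, s in enumerate(S):
            q = (np.asarray(s, float) + eps)
            q = q / q.sum()
            out[i, j] = sum(pi * np.log(pi / qi) for pi, qi in zip(p, q))
    return out


def oracle_loss(M, kl, D, N, lam):
    m, w = M.shape
    total = 0.0
    for i in range(m):
        for j in range(w):
            total += (kl[i, j] + D[i, j]) * M[i, j]
    quantity = sum(abs(N[j] - sum(M[i, j] for i in range(m))) for j in range(w))
    return total + lam * quantity / w


class TestKLCost:
    def test_proportional_profiles_have_zero_kl(self):
        C = norm_mat([[2, 4, 6]])
        S = norm_mat([[1, 2, 3]], modality="st")
        assert sm.kl_cost_matrix(C, S)[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_opposed_one_hot_profiles(self):
        C = norm_mat([[1, 0]])
        S = norm_mat([[0, 1]], modality="st")
        got = sm.kl_cost_matrix(C, S)[0, 0]
        assert got == pytest.approx(oracle_kl([[1, 0]], [[0, 1]])[0, 0], rel=1e-9)
        assert got > 10

    def test_two_by_two_table_matches_oracle(self):
        C_rows = [[0.5, 0.5], [0.9, 0.1]]
        S_rows = [[0.5, 0.5], [0.8, 0.2]]
        got = sm.kl_cost_matrix(norm_mat(C_rows), norm_mat(S_rows, "st"))
        np.testing.assert_allclose(got, oracle_kl(C_rows, S_rows), rtol=1e-9, atol=1e-12)

    def test_gene_mismatch_rejected(self):
        C = norm_mat([[1, 2]])
        S = ExpressionMatrix([[1, 2]], ["s0"], ["gA", "gB"], layer="cpm_log2", modality="st")
        with pytest.raises(ValidationError):
            sm.kl_cost_matrix(C, S)


class TestPearsonDistance:
    def test_identical_and_antiproportional(self):
        z1 = sm.Embedding(np.array([[1.0, 2, 3], [3, 2, 1]]), "sc")
        z2 = sm.Embedding(np.array([[2.0, 4, 6], [-1, -2, -3]]), "st")
        D = sm.pearson_distance_matrix(z1, z2)
        assert D[0, 0] == pytest.approx(0.0, abs=1e-12)   # proportional
        assert D[0, 1] == pytest.approx(2.0, abs=1e-12)   # anti-proportional

    def test_closed_form_value(self):
        z1 = sm.Embedding(np.array([[1.0, 2, 3]]), "sc")
        z2 = sm.Embedding(np.array([[1.0, 2, 4]]), "st")
        pcc = np.corrcoef([1, 2, 3], [1, 2, 4])[0, 1]
        assert sm.pearson_distance_matrix(z1, z2)[0, 0] == pytest.approx(1 - pcc, rel=1e-9)
        assert 1 - pcc == pytest.approx(0.01802, abs=1e-5)

    def test_zero_variance_row_maps_to_one(self):
        z1 = sm.Embedding(np.array([[5.0, 5, 5]]), "sc")
        z2 = sm.Embedding(np.array([[1.0, 2, 4]]), "st")
        assert sm.pearson_distance_matrix(z1, z2)[0, 0] == 1.0


class TestInitMapping:
    def test_uniform_counts(self):
        N = sm.CellsPerSpot(["a", "b"], [1, 1], source="constant")
        M = sm.init_mapping(N, m=3, jitter_sd=0.0).M
        np.testing.assert_allclose(M, 0.5)

    def test_proportional_counts(self):
        N = sm.CellsPerSpot(["a", "b"], [1, 3], source="constant")
        M = sm.init_mapping(N, m=2, jitter_sd=0.0).M
        np.testing.assert_allclose(M, [[0.25, 0.75]] * 2, rtol=1e-12)

    def test_seeded_jitter_reproducible(self):
        N = sm.CellsPerSpot(["a", "b", "c"], [2, 1, 4], source="constant")
        a = sm.init_mapping(N, m=5, seed=9).logits
        b = sm.init_mapping(N, m=5, seed=9).logits
        np.testing.assert_array_equal(a, b)


class TestMappingLoss:
    def test_hand_evaluations(self):
        kl = np.array([[0.0, 1], [1, 0]])
        costs = CostMatrices(kl, np.zeros((2, 2)))
        N = sm.CellsPerSpot(["a", "b"], [1, 1], source="constant")
        assert sm.mapping_loss(np.eye(2), costs, N, lam=7.3) == pytest.approx(0.0)
        M = np.full((2, 2), 0.5)
        assert sm.mapping_loss(M, costs, N, lam=5.0) == pytest.approx(1.0)

    def test_lambda_zero_ignores_quantities(self, rng):
        costs = CostMatrices(rng.uniform(0, 2, (4, 3)), rng.uniform(0, 2, (4, 3)))
        M = rng.dirichlet(np.ones(3), size=4)
        n1 = sm.CellsPerSpot(list("abc"), [1, 1, 1], source="constant")
        n2 = sm.CellsPerSpot(list("abc"), [9, 1, 2], source="constant")
        assert sm.mapping_loss(M, costs, n1, 0.0) == sm.mapping_loss(M, costs, n2, 0.0)

    def test_matches_double_loop_oracle_on_random_instances(self, rng):
        for _ in range(100):
            kl = rng.uniform(0, 3, (5, 4))
            D = rng.uniform(0, 2, (5, 4))
            M = rng.dirichlet(np.ones(4), size=5)
            counts = rng.integers(1, 6, 4)
            lam = rng.uniform(0, 2)
            N = sm.CellsPerSpot(list("abcd"), counts, source="constant")
            got = sm.mapping_loss(M, CostMatrices(kl, D), N, lam)
            assert got == pytest.approx(oracle_loss(M, kl, D, counts, lam), abs=1e-9)


class TestOptimize:
    def test_block_diagonal_costs_reach_their_optimum(self):
        kl = np.array([[0.0, 5, 5], [5, 0, 5], [5, 5, 0]])
        costs = CostMatrices(kl, np.zeros_like(kl))
        N = sm.CellsPerSpot(list("abc"), [1, 1, 1], source="constant")
        mapping, history = sm.optimize_mapping(
            costs, N, MappingConfig(lam=0.0, epochs=2500, lr=0.05, seed=0))
        M = mapping.M
        assert history[-1] <= history[0]
        for i in range(3):
            assert M[i, i] > 0.99

    def test_symmetric_costs_stay_uniform(self):
        costs = CostMatrices(np.ones((4, 3)), np.zeros((4, 3)))
        N = sm.CellsPerSpot(list("abc"), [1, 1, 1], source="constant")
        mapping, _ = sm.optimize_mapping(costs, N,
                                         MappingConfig(lam=0.0, epochs=200, seed=0,
                                                       jitter_sd=0.0))
        np.testing.assert_allclose(mapping.M, 1 / 3, atol=1e-6)

    def test_strong_quantity_constraint_matches_counts(self):
        costs = CostMatrices(np.zeros((4, 2)), np.zeros((4, 2)))
        N = sm.CellsPerSpot(["a", "b"], [2, 2], source="constant")
        mapping, _ = sm.optimize_mapping(costs, N,
                                         MappingConfig(lam=100.0, epochs=1500, lr=0.05, seed=1))
        np.testing.assert_allclose(mapping.M.sum(axis=0), [2, 2], atol=0.05)

    def test_lambda_shrinks_quantity_gap(self, rng):
        kl = rng.uniform(0, 2, (8, 4))
        costs = CostMatrices(kl, rng.uniform(0, 2, (8, 4)))
        N = sm.CellsPerSpot(list("abcd"), [3, 1, 2, 2], source="constant")

        def gap(lam):
            mapping, _ = sm.optimize_mapping(
                costs, N, MappingConfig(lam=lam, epochs=800, lr=0.02, seed=5))
            return np.abs(N.counts - mapping.M.sum(axis=0)).mean()

        assert gap(1.0) < gap(0.0)

    def test_rows_remain_stochastic(self, rng):
        costs = CostMatrices(rng.uniform(0, 2, (6, 5)), rng.uniform(0, 2, (6, 5)))
        N = sm.CellsPerSpot(list("abcde"), [1] * 5, source="constant")
        mapping, _ = sm.optimize_mapping(costs, N, MappingConfig(epochs=300, seed=2))
        np.testing.assert_allclose(mapping.M.sum(axis=1), 1.0, atol=1e-6)


class TestExtraction:
    def test_regular_argmax_per_column(self):
        M = MappingMatrix(np.log(np.array([[0.9, 0.1], [0.2, 0.8]])))
        N = sm.CellsPerSpot(["s1", "s2"], [1, 1], source="constant")
        res = sm.extract_regular(M, N, ["c1", "c2"], ["s1", "s2"])
        pairs = set(zip(res.assignments.cell_id, res.assignments.spot_id))
        assert pairs == {("c1", "s1"), ("c2", "s2")}

    def test_regular_can_duplicate_cells(self):
        # row softmaxes: c1 -> (0.5, 0.5), c2 -> (0.73, 0.27); spot 2's top is c1
        M = MappingMatrix(np.array([[0.0, 0.0], [0.0, -1.0]]))
        N = sm.CellsPerSpot(["s1", "s2"], [2, 1], source="constant")
        res = sm.extract_regular(M, N, ["c1", "c2"], ["s1", "s2"])
        assert len(res) == 3
        # spot 1 takes both cells; spot 2 duplicates c1
        assert list(res.assignments.spot_id).count("s1") == 2
        assert ("c1", "s2") in set(zip(res.assignments.cell_id, res.assignments.spot_id))

    def test_regular_tie_prefers_lower_cell_index(self):
        M = MappingMatrix(np.zeros((3, 1)))
        N = sm.CellsPerSpot(["s1"], [2], source="constant")
        res = sm.extract_regular(M, N, ["c1", "c2", "c3"], ["s1"])
        assert list(res.assignments.cell_id) == ["c1", "c2"]

    def test_regular_requesting_too_many_cells_errors(self):
        M = MappingMatrix(np.zeros((2, 1)))
        N = sm.CellsPerSpot(["s1"], [3], source="constant")
        with pytest.raises(ValidationError):
            sm.extract_regular(M, N, ["c1", "c2"], ["s1"])

    def test_greedy_matches_brute_force_row_scan(self, rng):
        logits = rng.normal(size=(3, 3))
        M = MappingMatrix(logits)
        res = sm.extract_greedy(M, ["c1", "c2", "c3"], ["s1", "s2", "s3"])
        assert len(res) == 3
        for row, spot in zip(M.M, res.assignments.spot_id):
            best = max(range(3), key=lambda j: (row[j], -j))
            assert spot == f"s{best + 1}"

    def test_greedy_tie_prefers_lower_spot_index(self):
        M = MappingMatrix(np.zeros((1, 4)))
        res = sm.extract_greedy(M, ["c1"], ["s1", "s2", "s3", "s4"])
        assert res.assignments.spot_id[0] == "s1"


class TestProportions:
    def test_counting_oracle(self):
        df = pd.DataFrame({
            "cell_id": ["c1", "c2", "c3", "c4", "c5", "c6"],
            "spot_id": ["s1", "s1", "s1", "s2", "s3", "s3"],
            "score": [1.0] * 6,
        })
        res = sm.MappingResult(df, mode="regular")
        ann = sm.CellAnnotation([f"c{i}" for i in range(1, 7)],
                                ["A", "A", "B", "B", "A", "A"])
        table = sm.spot_celltype_proportions(res, ann, ["s1", "s2", "s3", "s4"])
        assert table.loc["s1", "A"] == pytest.approx(2 / 3)
        assert table.loc["s1", "B"] == pytest.approx(1 / 3)
        assert table.loc["s2", "B"] == 1.0
        assert table.loc["s3", "A"] == 1.0
        assert table.loc["s4"].sum() == 0.0  # empty spot flagged by all-zero row

    def test_unannotated_cell_rejected(self):
        df = pd.DataFrame({"cell_id": ["cX"], "spot_id": ["s1"], "score": [1.0]})
        res = sm.MappingResult(df, mode="greedy")
        ann = sm.CellAnnotation(["c1"], ["A"])
        with pytest.raises(ValidationError, match="cX"):
            sm.spot_celltype_proportions(res, ann, ["s1"])
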