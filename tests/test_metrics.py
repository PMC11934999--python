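"""Mapping metrics against independent counting oracles."""

import numpy as np
import pandas as pd
import pytest

import spotmap as sm
from spotmap.io import ValidationError
from spotmap.mapping import MappingResult


def result(pairs, mode):
    df = pd.DataFrame(pairs, columns=["cell_id", "spot_id"])
    df["score"] = 1.0
    return MappingResult(df, mode=mode)


def truth_table(mapping: dict) -> pd.DataFrame:
    return pd.DataFrame({"cell_id": list(mapping), "spot_id": list(mapping.values())})


class TestPmap:
    def test_perfect_assignments(self):
        truth = truth_table({"c1": "s1", "c2": "s2"})
        ann = sm.CellAnnotation(["c1", "c2"], ["A", "B"])
        res = result([("c1", "s1"), ("c2", "s2")], "regular")
        assert (sm.pmap(res, truth, ann) == 1.0).all()

    def test_three_of_four_correct(self):
        truth = truth_table({f"c{i}": f"s{i}" for i in range(4)})
        ann = sm.CellAnnotation([f"c{i}" for i in range(4)], ["A"] * 4)
        res = result([("c0", "s0"), ("c1", "s1"), ("c2", "s2"), ("c3", "s0")], "regular")
        assert sm.pmap(res, truth, ann)["A"] == pytest.approx(0.75)

    def test_two_type_counting_oracle(self):
        truth = truth_table({f"c{i}": f"s{i}" for i in range(5)})
        ann = sm.CellAnnotation([f"c{i}" for i in range(5)], ["A", "A", "A", "B", "B"])
        res = result([("c0", "s0"), ("c1", "s1"), ("c2", "sX"),
                      ("c3", "s3"), ("c4", "sX")], "regular")
        got = sm.pmap(res, truth, ann)
        assert got["A"] == pytest.approx(2 / 3)
        assert got["B"] == pytest.approx(1 / 2)

    def test_requires_regular_mode(self):
        res = result([("c1", "s1")], "greedy")
        with pytest.raises(ValidationError):
            sm.pmap(res, truth_table({"c1": "s1"}), sm.CellAnnotation(["c1"], ["A"]))

    def test_type_without_assignments_is_missing(self):
        truth = truth_table({"c1": "s1", "c2": "s2"})
        ann = sm.CellAnnotation(["c1", "c2"], ["A", "B"])
        res = result([("c1", "s1")], "regular")
        got = sm.pmap(res, truth, ann)
        assert got["A"] == 1.0 and np.isnan(got["B"])


class TestErrorRate:
    def make(self, truth_types, pred_types):
        """One spot per entry; types like {'s1': ['A','A','B']}."""
        truth_rows, pred_rows, ann_rows = [], [], {}
        i = 0
        for spot, types in truth_types.items():
            for t in types:
                cid = f"t{i}"
                truth_rows.append((cid, spot))
                ann_rows[cid] = t
                i += 1
        for spot, types in pred_types.items():
            for t in types:
                cid = f"p{i}"
                pred_rows.append((cid, spot))
                ann_rows[cid] = t
                i += 1
        ann = sm.CellAnnotation(list(ann_rows), list(ann_rows.values()))
        return result(pred_rows, "regular"), pd.DataFrame(truth_rows, columns=["cell_id", "spot_id"]), ann

    def test_perfect_prediction(self):
        res, truth, ann = self.make({"s1": ["A", "B"]}, {"s1": ["B", "A"]})
        assert sm.celltype_error_rate(res, truth, ann) == 0.0

    def test_single_mismatch_in_three_cells(self):
        res, truth, ann = self.make({"s1": ["A", "A", "B"]}, {"s1": ["A", "B", "B"]})
        assert sm.celltype_error_rate(res, truth, ann) == pytest.approx(1 / 3)

    def test_everything_wrong(self):
        res, truth, ann = self.make({"s1": ["A", "A"]}, {"s1": ["B", "B"]})
        assert sm.celltype_error_rate(res, truth, ann) == 1.0

    def test_order_invariance_within_spot(self):
        res1, truth, ann = self.make({"s1": ["A", "B", "C"]}, {"s1": ["C", "A", "B"]})
        assert sm.celltype_error_rate(res1, truth, ann) == 0.0

    def test_unfilled_cells_count_as_errors(self):
        res, truth, ann = self.make({"s1": ["A", "A", "B"]}, {"s1": ["A"]})
        assert sm.celltype_error_rate(res, truth, ann) == pytest.approx(2 / 3)


class TestPloc:
    def test_perfect_recovery(self):
        truth = truth_table({"c1": "s1", "c2": "s2"})
        ann = sm.CellAnnotation(["c1", "c2"], ["A", "A"])
        res = result([("c1", "s1"), ("c2", "s2")], "greedy")
        assert sm.ploc(res, truth, ann)["A"] == 1.0

    def test_six_of_ten_correct(self):
        cells = [f"c{i}" for i in range(10)]
        truth = truth_table({c: f"s{i}" for i, c in enumerate(cells)})
        ann = sm.CellAnnotation(cells, ["A"] * 10)
        pairs = [(c, f"s{i}" if i < 6 else "sX") for i, c in enumerate(cells)]
        assert sm.ploc(result(pairs, "greedy"), truth, ann)["A"] == pytest.approx(0.6)

    def test_three_type_counting_oracle(self, rng):
        cells = [f"c{i}" for i in range(30)]
        types = [["A", "B", "C"][i % 3] for i in range(30)]
        truth = truth_table({c: f"s{i}" for i, c in enumerate(cells)})
        ann = sm.CellAnnotation(cells, types)
        correct = rng.random(30) < 0.5
        pairs = [(c, f"s{i}" if correct[i] else "sWRONG") for i, c in enumerate(cells)]
        got = sm.ploc(result(pairs, "greedy"), truth, ann)
        for label in "ABC":
            members = [i for i in range(30) if types[i] == label]
            expected = sum(correct[i] for i in members) / len(members)
            assert got[label] == pytest.approx(expected, abs=1e-12)


class TestProportionPCC:
    def test_identical_tables(self):
        tab = pd.DataFrame([[0.2, 0.8], [0.6, 0.4]], index=["s1", "s2"], columns=["A", "B"])
        per_spot, mean = sm.proportion_pcc(tab, tab.copy())
        np.testing.assert_allclose(per_spot, 1.0, rtol=1e-12)
        assert mean == pytest.approx(1.0, rel=1e-12)

    def test_closed_form_three_types(self):
        pred = pd.DataFrame([[0.5, 0.3, 0.2]], index=["s1"], columns=list("ABC"))
        true = pd.DataFrame([[1.0, 0.0, 0.0]], index=["s1"], columns=list("ABC"))
        expected = np.corrcoef([0.5, 0.3, 0.2], [1, 0, 0])[0, 1]
        per_spot, _ = sm.proportion_pcc(pred, true)
        assert per_spot["s1"] == pytest.approx(expected, rel=1e-12)

    def test_anti_ordered_is_negative(self):
        pred = pd.DataFrame([[0.7, 0.2, 0.1]], index=["s1"], columns=list("ABC"))
        true = pd.DataFrame([[0.1, 0.2, 0.7]], index=["s1"], columns=list("ABC"))
        assert sm.proportion_pcc(pred, true)[0]["s1"] < 0

    def test_zero_variance_row_is_missing(self):
        pred = pd.DataFrame([[1 / 3, 1 / 3, 1 / 3]], index=["s1"], columns=list("ABC"))
        true = pd.DataFrame([[1.0, 0.0, 0.0]], index=["s1"], columns=list("ABC"))
        per_spot, _ = sm.proportion_pcc(pred, true)
        assert np.isnan(per_spot["s1"])

    def test_column_mismatch_rejected(self):
        pred = pd.DataFrame([[1.0]], index=["s1"], columns=["A"])
        true = pd.DataFrame([[1.0]], index=["s1"], columns=["B"])
        with pytest.raises(ValidationError):
            sm.proportion_pcc(pred, true)


class TestKDistance:
    def test_query_on_reference_is_zero(self):
        refs = np.array([[0.0, 0], [3, 4]])
        assert sm.k_distance(np.array([[3.0, 4]]), refs, k=1)[0] == 0.0

    def test_sorted_average(self):
        refs = np.array([[1.0, 0], [2, 0], [3, 0], [4, 0], [5, 0], [9, 0]])
        got = sm.k_distance(np.array([[0.0, 0]]), refs, k=5)
        assert got[0] == pytest.approx(3.0)

    def test_translation_invariance(self, rng):
        q = rng.uniform(0, 5, (10, 2))
        r = rng.uniform(0, 5, (20, 2))
        shift = np.array([100.0, -40.0])
        np.testing.assert_allclose(sm.k_distance(q, r, 3),
                                   sm.k_distance(q + shift, r + shift, 3), rtol=1e-9)

    def test_k_larger_than_reference_rejected(self):
        with pytest.raises(ValidationError):
            sm.k_distance(np.zeros((1, 2)), np.zeros((2, 2)), k=3)

    def test_matches_brute_force(self, rng):
        q = rng.uniform(0, 1, (15, 2))
        r = rng.uniform(0, 1, (25, 2))
        got = sm.k_distance(q, r, k=4)
        for i in range(15):
            d = np.sort(np.linalg.norm(r - q[i], axis=1))[:4].mean()
            assert got[i] == pytest.approx(d, abs=1e-12)
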