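"""TOPSIS ranking: normalization, ideals, separations, closeness, properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from eoscreen import topsis as tp
from eoscreen.errors import (
    DegenerateCriterionError,
    DegenerateIdealError,
    NegativeCriterionWarning,
    TieWarning,
)


def oracle_closeness(x: np.ndarray, directions=None) -> np.ndarray:
    """Independent single-expression evaluation of the whole TOPSIS chain."""
    r = x / np.sqrt((x**2).sum(axis=0))
    if directions is None:
        a_plus, a_minus = r.max(axis=0), r.min(axis=0)
    else:
        benefit = np.array([d == "benefit" for d in directions])
        a_plus = np.where(benefit, r.max(axis=0), r.min(axis=0))
        a_minus = np.where(benefit, r.min(axis=0), r.max(axis=0))
    dp = np.sqrt(((r - a_plus) ** 2).sum(axis=1))
    dm = np.sqrt(((r - a_minus) ** 2).sum(axis=1))
    return dm / (dp + dm)


class TestVectorNormalize:
    def test_three_four_five(self):
        out = tp.vector_normalize(np.array([[3.0], [4.0]]))
        assert np.allclose(out.ravel(), [0.6, 0.8])

    def test_equal_column(self):
        out = tp.vector_normalize(np.full((4, 1), 7.0))
        assert np.allclose(out, 0.5)

    def test_unit_column_norms(self):
        rng = np.random.default_rng(3)
        out = tp.vector_normalize(rng.uniform(0.1, 9, (6, 4)))
        assert np.allclose((out**2).sum(axis=0), 1.0)

    def test_zero_column_rejected(self):
        with pytest.raises(DegenerateCriterionError):
            tp.vector_normalize(np.array([[0.0, 1.0], [0.0, 2.0]]))


class TestIdealSolutions:
    def test_benefit_direction(self):
        ideals = tp.ideal_solutions(np.array([[0.6], [0.8]]), ["benefit"])
        assert ideals.a_plus[0] == 0.8 and ideals.a_minus[0] == 0.6

    def test_cost_direction(self):
        ideals = tp.ideal_solutions(np.array([[0.6], [0.8]]), ["cost"])
        assert ideals.a_plus[0] == 0.6 and ideals.a_minus[0] == 0.8

    def test_constant_column(self):
        ideals = tp.ideal_solutions(np.full((3, 1), 0.5), ["benefit"])
        assert ideals.a_plus[0] == ideals.a_minus[0]


class TestSeparations:
    def test_at_ideals(self):
        r = np.array([[0.2, 0.3], [0.8, 0.9]])
        ideals = tp.ideal_solutions(r, ["benefit", "benefit"])
        dp, dm = tp.separation_distances(r, ideals)
        assert dp[1] == pytest.approx(0.0)
        assert dm[0] == pytest.approx(0.0)

    def test_matches_element_oracle(self):
        rng = np.random.default_rng(11)
        r = tp.vector_normalize(rng.uniform(0.5, 5, (6, 4)))
        ideals = tp.ideal_solutions(r, ["benefit"] * 4)
        dp, dm = tp.separation_distances(r, ideals)
        for i in range(6):
            assert dp[i] == pytest.approx(
                np.sqrt(sum((r[i, j] - ideals.a_plus[j]) ** 2 for j in range(4)))
            )
            assert dm[i] == pytest.approx(
                np.sqrt(sum((r[i, j] - ideals.a_minus[j]) ** 2 for j in range(4)))
            )


class TestCloseness:
    def test_published_separation_pairs(self):
        ref = tp.reference_separations()
        ci = tp.closeness_coefficients(ref["d_plus"], ref["d_minus"])
        assert ci[list(ref.index).index("DM")] == pytest.approx(0.9416, abs=1e-3)
        assert ci[list(ref.index).index("MP")] == pytest.approx(0.0730, abs=1e-3)

    def test_boundary_values(self):
        ci = tp.closeness_coefficients([0.0, 0.5], [0.5, 0.0])
        assert np.allclose(ci, [1.0, 0.0])

    def test_degenerate_ideal(self):
        with pytest.raises(DegenerateIdealError):
            tp.closeness_coefficients([0.0], [0.0])


class TestRanking:
    def test_published_full_ranking(self):
        ref = tp.reference_separations()
        ci = tp.closeness_coefficients(ref["d_plus"], ref["d_minus"])
        ranks, ties = tp.rank_alternatives(ci)
        assert not ties
        assert dict(zip(ref.index, ranks)) == {
            "DM": 1, "MO": 2, "BL": 3, "AL": 4, "MJU": 5, "MP": 6,
        }
        assert list(ranks) == list(ref["rank_printed"])

    def test_ties_stable_in_input_order(self):
        with pytest.warns(TieWarning):
            ranks, ties = tp.rank_alternatives([0.4, 0.4, 0.4])
        assert ties and list(ranks) == [1, 2, 3]

    def test_two_alternatives(self):
        ranks, _ = tp.rank_alternatives([0.2, 0.8])
        assert list(ranks) == [2, 1]


class TestTopsisEndToEnd:
    def test_dominant_alternative_gets_ci_one(self, toy_matrix):
        result = tp.topsis(toy_matrix)
        assert result.closeness["best"] == pytest.approx(1.0)
        assert result.rank["best"] == 1

    def test_oracle_equivalence_seeded(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            m = rng.integers(2, 9)
            n = rng.integers(1, 7)
            x = rng.uniform(0.1, 10.0, (m, n))
            got = tp.topsis(pd.DataFrame(x)).closeness.to_numpy()
            assert np.allclose(got, oracle_closeness(x), atol=1e-12)

    def test_column_scale_invariance(self, toy_matrix):
        base = tp.topsis(toy_matrix).closeness
        scaled = toy_matrix.copy()
        scaled["c2"] = scaled["c2"] * 137.5
        assert np.allclose(tp.topsis(scaled).closeness, base, atol=1e-12)

    def test_permuting_alternatives_permutes_ci(self, toy_matrix):
        base = tp.topsis(toy_matrix).closeness
        perm = toy_matrix.iloc[[2, 0, 1]]
        got = tp.topsis(perm).closeness
        assert np.allclose(got.reindex(base.index), base, atol=1e-12)

    def test_permuting_criteria_leaves_ci_unchanged(self, toy_matrix):
        base = tp.topsis(toy_matrix).closeness
        got = tp.topsis(toy_matrix[["c3", "c1", "c2"]]).closeness
        assert np.allclose(got, base, atol=1e-12)

    def test_duplicate_alternative_same_ci(self, toy_matrix):
        dup = pd.concat([toy_matrix, toy_matrix.iloc[[0]].rename(index={"a": "a2"})])
        with pytest.warns(TieWarning):
            result = tp.topsis(dup)
        assert result.closeness["a"] == pytest.approx(result.closeness["a2"], abs=1e-12)

    def test_closeness_in_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ci = tp.topsis(pd.DataFrame(rng.uniform(0.1, 5, (5, 3)))).closeness
            assert ((ci >= 0) & (ci <= 1)).all()

    def test_cost_direction_reverses_preference(self):
        x = pd.DataFrame({"c": [1.0, 2.0, 4.0]})
        benefit = tp.topsis(tp.DecisionMatrix(values=x, directions=["benefit"]))
        cost = tp.topsis(tp.DecisionMatrix(values=x.copy(), directions=["cost"]))
        assert benefit.rank.iloc[2] == 1 and cost.rank.iloc[0] == 1

    def test_negative_entries_warn(self):
        x = pd.DataFrame({"c1": [-1.0, 2.0], "c2": [1.0, 2.0]})
        with pytest.warns(NegativeCriterionWarning):
            tp.topsis(x)

    def test_weights_change_tradeoff(self):
        x = pd.DataFrame({"c1": [5.0, 1.0], "c2": [1.0, 5.0]})
        w1 = tp.TopsisRanker(weights=[0.99, 0.01]).fit(x).rank_
        w2 = tp.TopsisRanker(weights=[0.01, 0.99]).fit(x).rank_
        assert w1.iloc[0] == 1 and w2.iloc[1] == 1


class TestEstimatorApi:
    def test_get_set_params_roundtrip(self):
        ranker = tp.TopsisRanker(directions="cost")
        params = ranker.get_params()
        clone = tp.TopsisRanker(**params)
        assert clone.get_params() == params

    def test_fit_predict_returns_ranks(self, toy_matrix):
        ranks = tp.TopsisRanker().fit_predict(toy_matrix)
        assert sorted(ranks) == [1, 2, 3]


class TestIO:
    def test_csv_round_trip(self, tmp_path, toy_matrix):
        path = tmp_path / "dm.csv"
        with open(path, "w") as fh:
            fh.write("alternative," + ",".join(toy_matrix.columns) + "\n")
            fh.write("direction,benefit,benefit,cost\n")
            fh.write("weight,0.5,0.3,0.2\n")
            for idx, row in toy_matrix.iterrows():
                fh.write(f"{idx}," + ",".join(map(str, row)) + "\n")
        dm = tp.read_decision_matrix(path)
        assert dm.directions == ["benefit", "benefit", "cost"]
        assert np.allclose(dm.weights, [0.5, 0.3, 0.2])
        assert np.allclose(dm.values, toy_matrix)

    def test_result_tsv(self, tmp_path, toy_matrix):
        out = tmp_path / "result.tsv"
        tp.write_result_tsv(tp.topsis(toy_matrix), out)
        back = pd.read_csv(out, sep="\t", index_col=0)
        assert list(back.columns) == ["d_plus", "d_minus", "closeness", "rank"]
        assert back.loc["best", "rank"] == 1
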