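"""Selection rates, probit scaling, pairwise tests, Grubbs replacement."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snakescomp.scoring import (
    ALGORITHMS,
    PairedComparisonMatrix,
    correct_zero_cells,
    grubbs_replace,
    pairwise_pvalues,
    probit_score,
    read_experiment_workbook,
    selection_rate,
    subject_scores,
    summarize,
)


class TestSelectionRate:
    @pytest.mark.parametrize("chosen,total,want", [(6, 10, 0.6), (0, 10, 0.0), (10, 10, 1.0)])
    def test_values(self, chosen, total, want):
        choices = [True] * chosen + [False] * (total - chosen)
        assert selection_rate(choices) == want

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            selection_rate([])


class TestZeroCellCorrection:
    def test_zero_selected(self):
        assert correct_zero_cells(0, 12) == (0.5, 11.5)

    def test_zero_not_selected(self):
        assert correct_zero_cells(12, 0) == (11.5, 0.5)

    def test_interior_unchanged(self):
        assert correct_zero_cells(6, 6) == (6, 6)
        assert correct_zero_cells(1, 11) == (1, 11)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            correct_zero_cells(-1, 13)


class TestProbitScore:
    def test_half_is_zero(self):
        assert probit_score(0.5) == 0.0

    @pytest.mark.parametrize("ratio,want", [(11.5 / 12, 1.7317), (0.6, 0.2533)])
    def test_reference_values(self, ratio, want):
        assert probit_score(ratio) == pytest.approx(want, abs=1e-4)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        for r in rng.uniform(0.01, 0.99, size=50):
            assert probit_score(1 - r) == pytest.approx(-probit_score(r), abs=1e-12)

    def test_extremes_instruct_correction(self):
        with pytest.raises(ValueError, match="correct_zero_cells"):
            probit_score(1.0)


def balanced_matrix(counts_for=None):
    """All cells (6,6) except optional overrides {(i_label, j_label): wins}."""
    m = PairedComparisonMatrix()
    k = len(m.algorithms)
    for i in range(k):
        for j in range(i + 1, k):
            m.counts[i, j] = m.counts[j, i] = 6
    if counts_for:
        for (wi, lj), n in counts_for.items():
            i, j = m.algorithms.index(wi), m.algorithms.index(lj)
            m.counts[i, j] = n
            m.counts[j, i] = m.trials_per_pair - n
    return m


class TestSubjectScores:
    def test_balanced_design_scores_zero(self):
        assert subject_scores(balanced_matrix()) == {a: 0.0 for a in ALGORITHMS}

    def test_single_dominant_algorithm(self):
        m = balanced_matrix({("B", o): 9 for o in ALGORITHMS if o != "B"})
        scores = subject_scores(m)
        assert scores["B"] == pytest.approx(stats.norm.ppf(0.75), abs=1e-9)

    def test_relabeling_swaps_scores(self):
        m = balanced_matrix({("A", "U"): 10, ("A", "O"): 8})
        base = subject_scores(m)
        # swap A and U rows/columns
        i, j = m.algorithms.index("A"), m.algorithms.index("U")
        perm = list(range(len(m.algorithms)))
        perm[i], perm[j] = perm[j], perm[i]
        swapped = PairedComparisonMatrix(counts=m.counts[np.ix_(perm, perm)])
        got = subject_scores(swapped)
        assert got["U"] == pytest.approx(base["A"])
        assert got["A"] == pytest.approx(base["U"])

    def test_complement_matrix_negates_scores(self):
        m = balanced_matrix({("A", "U"): 11, ("B", "C"): 2, ("O", "A"): 7})
        base = subject_scores(m)
        comp = subject_scores(m.complement())
        for a in ALGORITHMS:
            assert comp[a] == pytest.approx(-base[a], abs=1e-12)

    def test_extreme_cells_pass_through_correction(self):
        m = balanced_matrix({("A", "U"): 12})
        scores = subject_scores(m)
        assert np.isfinite(scores["A"]) and np.isfinite(scores["U"])

    def test_incomplete_matrix_rejected(self):
        m = balanced_matrix()
        m.counts[0, 1] = 5  # breaks the 12-trial pair total
        with pytest.raises(ValueError, match="incomplete"):
            subject_scores(m)


class TestPairwisePvalues:
    def test_identical_populations_p_one(self):
        df = pd.DataFrame({"A": [0.1, 0.2, 0.3], "B": [0.1, 0.2, 0.3]})
        assert pairwise_pvalues(df).loc["A", "B"] == 1.0

    def test_bonferroni_factor_is_ten_for_five_algorithms(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(0, 1, size=(7, 5)), columns=list(ALGORITHMS))
        p = pairwise_pvalues(df)
        a, b = df["O"].to_numpy(), df["A"].to_numpy()
        se = np.sqrt(a.var(ddof=1) / 7 + b.var(ddof=1) / 7)
        z = (a.mean() - b.mean()) / se
        want = min(1.0, 2 * stats.norm.sf(abs(z)) * 10)
        assert p.loc["O", "A"] == pytest.approx(want, abs=1e-12)

    def test_separated_populations_tiny_p(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "A": rng.normal(1.0, 0.1, 7),
                "B": rng.normal(-1.0, 0.1, 7),
            }
        )
        # uncorrected z ~ 37 -> p << 1e-10 even after correction
        assert pairwise_pvalues(df).loc["A", "B"] < 1e-10

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            pairwise_pvalues(pd.DataFrame({"A": [1.0], "B": [0.0]}))


class TestGrubbs:
    def test_constant_vector_unchanged(self):
        x = [1.0] * 5
        out, report = grubbs_replace(x)
        assert np.array_equal(out, x)
        assert report["replaced_index"] is None

    def test_gross_outlier_replaced_by_peer_mean(self):
        x = [1.0, 1.1, 0.9, 1.05, 0.95, 1.02, 10.0]
        out, report = grubbs_replace(x)
        assert report["replaced_index"] == 6
        assert out[6] == pytest.approx(np.mean(x[:6]), abs=1e-12)
        assert out[6] == pytest.approx(1.003, abs=1e-3)
        assert report["p"] < 0.001

    def test_idempotent_after_replacement(self):
        x = [1.0, 1.1, 0.9, 1.05, 0.95, 1.02, 10.0]
        out, _ = grubbs_replace(x)
        out2, report2 = grubbs_replace(out)
        assert report2["replaced_index"] is None
        assert np.array_equal(out, out2)

    def test_inlier_spread_not_flagged(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 10)
        _, report = grubbs_replace(x)
        # statistic below critical for this draw; nothing replaced
        assert report["statistic"] < report["critical"]

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            grubbs_replace([1.0, 2.0])


class TestSummarize:
    def test_all_zero_scores(self):
        df = pd.DataFrame(np.zeros((4, 5)), columns=list(ALGORITHMS))
        out = summarize(df)
        assert (out["median"] == 0).all()
        assert out.loc["A", "n_larger"] == 0

    def test_zero_constant_excluded_from_ratio(self):
        scores = pd.DataFrame(
            {"O": [0.0, 0.0, 0.0], "A": [0.5, 0.4, 0.3], "B": [0.2, -0.1, 0.3],
             "C": [0.1, 0.1, 0.1], "U": [-0.5, -0.4, -0.3]}
        )
        consts = pd.DataFrame(
            {"O": [0.0] * 3, "A": [-0.7, -0.7, 0.0], "B": [-0.3] * 3,
             "C": [-0.4] * 3, "U": [-0.1] * 3}
        )
        out = summarize(scores, consts)
        assert out.loc["A", "ratio_larger"] == "2/2"  # third subject dropped
        assert out.loc["B", "ratio_larger"] == "2/3"
        assert out.loc["U", "ratio_larger"] == "0/3"

    def test_quartiles_match_order_statistics_oracle(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(0, 1, size=(9, 5)), columns=list(ALGORITHMS))
        out = summarize(df)
        for a in ALGORITHMS:
            x = np.sort(df[a].to_numpy())
            # linear interpolation oracle at the quartile positions
            for col, q in (("q1", 0.25), ("median", 0.5), ("q3", 0.75)):
                pos = q * (len(x) - 1)
                lo, hi = int(np.floor(pos)), int(np.ceil(pos))
                want = x[lo] + (pos - lo) * (x[hi] - x[lo])
                assert out.loc[a, col] == pytest.approx(want, abs=1e-12)


class TestWorkbookReader:
    def test_round_trip_synthetic_workbook(self, tmp_path):
        pytest.importorskip("openpyxl")
        p = tmp_path / "book.xlsx"
        df1 = pd.DataFrame({"subject": [1, 2], "sr": [0.3, 0.5]})
        df2 = pd.DataFrame({"subject": [1, 2], "c_A": [-0.7, -0.8]})
        with pd.ExcelWriter(p) as xw:
            df1.to_excel(xw, sheet_name="Experiment 1", index=False)
            df2.to_excel(xw, sheet_name="Experiment 3-1", index=False)
        book = read_experiment_workbook(p, {"exp1": "Experiment 1", "exp31": "Experiment 3-1"})
        pd.testing.assert_frame_equal(book["exp1"], df1)
        with pytest.raises(ValueError, match="no sheet"):
            read_experiment_workbook(p, {"x": "missing"})
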