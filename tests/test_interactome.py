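import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nascentflow.errors import ConfigurationError, InputFormatError
from nascentflow.interactome import (
    analyze,
    bait_normalize,
    complex_summary,
    differential_interactome,
    dual_response_filter,
    intersection_sizes,
    pseudo_floor,
    selective_sets,
)

DESIGN = pd.DataFrame(
    {
        "sample": ["c1", "c2", "c3", "t1", "t2", "t3"],
        "condition": ["control"] * 3 + ["treated"] * 3,
        "replicate": [1, 2, 3, 1, 2, 3],
    }
)


def matrix_of(rows: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame(rows, index=DESIGN["sample"]).T.rename_axis("protein_id")


class TestPseudoFloor:
    def test_zero_becomes_one(self):
        m = matrix_of({"P": [0, 2, 3, 4, 5, 6]})
        assert pseudo_floor(m).loc["P", "c1"] == 1.0

    def test_nonzero_unchanged(self):
        m = matrix_of({"P": [57.3, 2, 3, 4, 5, 0.001]})
        out = pseudo_floor(m)
        assert out.loc["P", "c1"] == 57.3
        assert out.loc["P", "t3"] == 0.001

    def test_idempotent(self):
        m = matrix_of({"P": [0, 2, 0, 4, 5, 6], "Q": [1, 1, 1, 1, 1, 1]})
        once = pseudo_floor(m)
        pd.testing.assert_frame_equal(pseudo_floor(once), once)

    def test_negative_intensity_rejected(self):
        m = matrix_of({"P": [-1, 2, 3, 4, 5, 6]})
        with pytest.raises(InputFormatError):
            pseudo_floor(m)


class TestBaitNormalize:
    def test_bait_row_becomes_one(self):
        m = matrix_of({"BAIT": [400, 300, 500, 200, 250, 350], "P": [200, 30, 50, 20, 25, 35]})
        out = bait_normalize(m, "BAIT")
        assert (out.loc["BAIT"] == 1.0).all()

    def test_direct_arithmetic(self):
        m = matrix_of({"BAIT": [400, 1, 1, 1, 1, 1], "P": [200, 1, 1, 1, 1, 1]})
        assert bait_normalize(m, "BAIT").loc["P", "c1"] == 0.5

    def test_per_sample_scale_invariance(self):
        rng = np.random.default_rng(0)
        m = matrix_of(
            {"BAIT": rng.uniform(100, 200, 6), "P": rng.uniform(1, 50, 6), "Q": rng.uniform(1, 50, 6)}
        )
        scales = rng.uniform(0.1, 10, 6)
        scaled = m * scales
        pd.testing.assert_frame_equal(bait_normalize(m, "BAIT"), bait_normalize(scaled, "BAIT"))

    def test_missing_bait_rejected(self):
        m = matrix_of({"P": [1, 2, 3, 4, 5, 6]})
        with pytest.raises(InputFormatError):
            bait_normalize(m, "BAIT")

    def test_zero_bait_requires_floor_first(self):
        m = matrix_of({"BAIT": [0, 1, 1, 1, 1, 1], "P": [1, 2, 3, 4, 5, 6]})
        with pytest.raises(InputFormatError):
            bait_normalize(m, "BAIT")
        bait_normalize(pseudo_floor(m), "BAIT")  # floor first: fine

    def test_order_floor_then_normalize_differs_from_swap(self):
        m = matrix_of({"BAIT": [2, 2, 2, 2, 2, 2], "P": [0, 4, 4, 4, 4, 4]})
        fixed_order = bait_normalize(pseudo_floor(m), "BAIT")
        # floor-first turns the missing value into 1/2 = 0.5 after normalization;
        # normalizing first would keep 0 and then floor it to 1.0
        swapped = pseudo_floor(m.div(m.loc["BAIT"], axis=1))
        assert fixed_order.loc["P", "c1"] == 0.5
        assert swapped.loc["P", "c1"] == 1.0


class TestDifferentialInteractome:
    def test_identical_replicates_unchanged(self):
        m = matrix_of({"BAIT": [1] * 6, "P": [0.3] * 6})
        table = differential_interactome(m, DESIGN, "control", "treated").set_index("protein_id")
        assert table.loc["P", "fold_change"] == 1.0
        assert table.loc["P", "class"] == "unchanged"

    def test_worked_example_fourfold_gain(self):
        m = matrix_of(
            {"BAIT": [1] * 6, "P": [0.10, 0.11, 0.09, 0.40, 0.44, 0.36]}
        )
        table = differential_interactome(m, DESIGN, "control", "treated").set_index("protein_id")
        assert table.loc["P", "fold_change"] == pytest.approx(4.0)
        assert table.loc["P", "log2FC"] == pytest.approx(2.0)
        # independent t-test oracle
        p_oracle = stats.ttest_ind(
            [0.40, 0.44, 0.36], [0.10, 0.11, 0.09], equal_var=True
        ).pvalue
        assert table.loc["P", "p_value"] == pytest.approx(p_oracle)
        assert table.loc["P", "class"] == "gained"

    def test_two_replicates_minimum(self):
        design = DESIGN[DESIGN["replicate"] != 3]
        m = matrix_of({"BAIT": [1] * 6, "P": [1, 2, 3, 4, 5, 6]})[design["sample"]]
        differential_interactome(m, design, "control", "treated")
        with pytest.raises(ConfigurationError):
            single = DESIGN[DESIGN["sample"].isin(["c1", "t1", "t2"])]
            differential_interactome(m[single["sample"]], single, "control", "treated")

    def test_classification_recomputable_from_columns(self):
        from nascentflow.synthetic import InteractomeSpikeDesign, simulate_interactome

        d = InteractomeSpikeDesign(
            n_proteins=100, spiked={"P001": -2.5, "P002": 2.5}, seed=3, missing_fraction=0.05
        )
        matrix, design = simulate_interactome(d)
        table = analyze(matrix, design, "BAIT", "control", "treated")
        expected = np.where(
            (table["p_value"] < 0.05) & (table["log2FC"] > 0),
            "gained",
            np.where((table["p_value"] < 0.05) & (table["log2FC"] < 0), "lost", "unchanged"),
        )
        assert (table["class"] == expected).all()

    def test_fold_changes_invariant_under_sample_scaling(self):
        from nascentflow.synthetic import InteractomeSpikeDesign, simulate_interactome

        d = InteractomeSpikeDesign(n_proteins=30, spiked={"P01": 1.5}, seed=5)
        matrix, design = simulate_interactome(d)
        rng = np.random.default_rng(1)
        scaled = matrix * rng.uniform(0.2, 5.0, matrix.shape[1])
        a = analyze(matrix, design, "BAIT", "control", "treated")
        b = analyze(scaled, design, "BAIT", "control", "treated")
        assert np.allclose(a["fold_change"], b["fold_change"])
        assert np.allclose(a["p_value"], b["p_value"])

    def test_imputed_floor_flagged(self):
        m = matrix_of({"BAIT": [10] * 6, "P": [0, 0, 0, 5, 6, 7]})
        table = analyze(m, DESIGN, "BAIT", "control", "treated").set_index("protein_id")
        assert table.loc["P", "imputed_floor"]
        assert not table.loc["BAIT", "imputed_floor"]


class TestDualResponseFilter:
    def _table(self, entries):
        rows = []
        for pid, lfc, p in entries:
            cls = "unchanged"
            if p < 0.05:
                cls = "gained" if lfc > 0 else "lost"
            rows.append((pid, lfc, p, cls))
        return pd.DataFrame(rows, columns=["protein_id", "log2FC", "p_value", "class"])

    def test_empty_result(self):
        a = self._table([("P1", 0.1, 0.5)])
        b = self._table([("P1", 0.2, 0.6)])
        assert len(dual_response_filter(a, b)) == 0

    def test_concordant_gained(self):
        a = self._table([("P1", 2.5, 0.01), ("P2", 1.0, 0.01)])
        b = self._table([("P1", 2.2, 0.03), ("P2", 2.5, 0.01)])
        out = dual_response_filter(a, b, lfc_cutoff=2)
        assert list(out["protein_id"]) == ["P1"]
        assert out["concordance"].iloc[0] == "concordant-gained"

    def test_discordant_included_and_labeled(self):
        a = self._table([("P1", 2.5, 0.01)])
        b = self._table([("P1", -2.2, 0.02)])
        out = dual_response_filter(a, b)
        assert out["concordance"].iloc[0] == "discordant"

    def test_disjoint_universe_rejected(self):
        a = self._table([("P1", 2.5, 0.01)])
        b = self._table([("P2", 2.5, 0.01)])
        with pytest.raises(ConfigurationError):
            dual_response_filter(a, b)


class TestSelectiveSets:
    def _table(self, lost=(), gained=(), universe=()):
        ids = sorted(set(lost) | set(gained) | set(universe))
        rows = []
        for pid in ids:
            cls = "lost" if pid in lost else "gained" if pid in gained else "unchanged"
            rows.append((pid, 0.0, 1.0, cls))
        return pd.DataFrame(rows, columns=["protein_id", "log2FC", "p_value", "class"])

    def test_single_condition_selective_equals_significant(self):
        tables = {"A": self._table(lost={"p1", "p2"}, universe={"p3"})}
        exclusive, _ = selective_sets(tables, "lost")
        assert exclusive["A"] == {"p1", "p2"}

    def test_hand_built_three_conditions(self):
        tables = {
            "A": self._table(lost={"p1", "p2"}, universe={"p3"}),
            "B": self._table(lost={"p2"}, universe={"p1", "p3"}),
            "C": self._table(universe={"p1", "p2", "p3"}),
        }
        exclusive, patterns = selective_sets(tables, "lost")
        assert exclusive == {"A": {"p1"}, "B": set(), "C": set()}
        assert patterns[frozenset({"A", "B"})] == {"p2"}

    def test_universal_significance_empties_exclusives(self):
        tables = {
            "A": self._table(gained={"p1", "p2"}),
            "B": self._table(gained={"p1", "p2"}),
        }
        exclusive, _ = selective_sets(tables, "gained")
        assert exclusive == {"A": set(), "B": set()}

    def test_intersection_sizes_table(self):
        tables = {
            "A": self._table(lost={"p1", "p2"}),
            "B": self._table(lost={"p2"}, universe={"p1"}),
        }
        _, patterns = selective_sets(tables, "lost")
        sizes = intersection_sizes(patterns)
        assert set(sizes["pattern"]) == {"A", "A+B"}


class TestComplexSummary:
    def test_bait_alone_is_unity(self):
        m = matrix_of({"BAIT": [10, 20, 30, 5, 6, 7], "P": [1] * 6})
        normalized = bait_normalize(pseudo_floor(m), "BAIT")
        table, summary = complex_summary(normalized, DESIGN, "control", "treated", ["BAIT"])
        assert table["relative_binding"].iloc[0] == pytest.approx(1.0)

    def test_uniform_reduction_recovered(self):
        rng = np.random.default_rng(9)
        members = [f"M{i}" for i in range(15)]
        rows = {"BAIT": np.full(6, 100.0)}
        for m in members:
            base = rng.uniform(10, 50)
            ctrl = base * (1 + rng.normal(0, 0.01, 3))
            trt = base * 0.75 * (1 + rng.normal(0, 0.01, 3))
            rows[m] = np.concatenate([ctrl, trt])
        normalized = bait_normalize(pseudo_floor(matrix_of(rows)), "BAIT")
        table, summary = complex_summary(normalized, DESIGN, "control", "treated", members)
        assert np.allclose(table["relative_binding"], 0.75, atol=0.05)
        assert summary["fraction_below_1"] == 1.0
        assert summary["complex_mean_relative_binding"] == pytest.approx(0.75, abs=0.02)

    def test_absent_members_reported_excluded(self):
        m = matrix_of({"BAIT": [1] * 6, "M1": [2] * 6})
        normalized = bait_normalize(m, "BAIT")
        table, summary = complex_summary(
            normalized, DESIGN, "control", "treated", ["M1", "GHOST"]
        )
        assert summary["n_members_missing"] == 1
        assert list(table["protein_id"]) == ["M1"]

    def test_no_member_detected_is_error(self):
        m = matrix_of({"BAIT": [1] * 6})
        with pytest.raises(InputFormatError, match="GHOST"):
            complex_summary(bait_normalize(m, "BAIT"), DESIGN, "control", "treated", ["GHOST"])
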