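"""Differential-abundance testing, tallies and the ANOVA screen."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from lipidome.differential import (
    DifferentialTable,
    anova_screen,
    approx_percent,
    differential_table,
    log2_fc,
    percent,
    student_t,
    subclass_composition,
    summarize_counts,
)
from lipidome.preprocess import IntensityMatrix, log2_median_normalize
from lipidome.synthetic import simulate_two_group


def t_sf_by_integration(t_value, df):
    """Independent upper-tail t probability via numeric integration."""

    def pdf(x):
        c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
        return c * (1 + x * x / df) ** (-(df + 1) / 2)

    tail, _ = integrate.quad(pdf, abs(t_value), np.inf)
    return tail


class TestStudentT:
    def test_identical_groups(self):
        t, p = student_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_zero_variance_unequal_means_is_degenerate(self):
        with pytest.warns(UserWarning, match="zero pooled variance"):
            t, p = student_t([0, 0, 0, 0], [1, 1, 1, 1])
        assert p == 0.0 and np.isinf(t)

    def test_p_matches_numeric_integration_of_t_density(self):
        t, p = student_t([2.1, 2.5, 2.3], [3.9, 4.2, 4.0])
        assert p == pytest.approx(2 * t_sf_by_integration(t, df=4), rel=1e-8)

    def test_too_few_replicates_is_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            student_t([1.0], [1.0, 2.0])


class TestLog2FC:
    def test_mean_difference(self):
        assert log2_fc([1, 1], [3, 3]) == 2.0
        assert log2_fc([1, 2, 3], [1, 2, 3]) == 0.0

    def test_reversed_convention_negates(self):
        a, b = [1.0, 1.4], [3.0, 3.2]
        assert log2_fc(a, b, "A_over_B") == -log2_fc(a, b, "B_over_A")


@pytest.fixture(scope="module")
def planted_tables(catalog194):
    matrix, truth = simulate_two_group(
        n_lipids=194, n_per_group=3, planted_lipids=20,
        delta_log2=3.0, sigma=0.5, seed=42, catalog=catalog194,
    )
    logm = log2_median_normalize(matrix)
    table = differential_table(logm, {"group": "A"}, {"group": "B"})
    return logm, table, truth


class TestDifferentialTable:
    def test_recovers_planted_effects(self, planted_tables):
        _, table, truth = planted_tables
        planted = set(truth.planted_lipids)
        hits = planted & set(table.significant.index)
        assert len(hits) >= 18
        false_pos = set(table.significant.index) - planted
        # planted-null false positives bounded by binomial expectation
        n_null = 194 - 20
        bound = 0.05 * n_null + 3 * math.sqrt(n_null * 0.05 * 0.95)
        assert len(false_pos) <= bound

    def test_planted_direction_is_up_in_b(self, planted_tables):
        _, table, truth = planted_tables
        hits = set(truth.planted_lipids) & set(table.significant.index)
        assert (table.table.loc[sorted(hits), "direction"] == "up_in_B").all()

    def test_stricter_thresholds_select_subset(self, planted_tables):
        logm, table, _ = planted_tables
        strict = differential_table(
            logm, {"group": "A"}, {"group": "B"}, p_threshold=0.01, fc_threshold=2.5
        )
        assert set(strict.significant.index) <= set(table.significant.index)

    def test_invariant_to_sample_and_lipid_order(self, planted_tables):
        logm, table, _ = planted_tables
        shuffled = IntensityMatrix(
            logm.values.iloc[::-1, ::-1],
            logm.mode_of.iloc[::-1],
            sample_meta=logm.sample_meta.iloc[::-1],
            state="log2_median",
        )
        table2 = differential_table(shuffled, {"group": "A"}, {"group": "B"})
        merged = table2.table.loc[table.table.index]
        assert np.allclose(merged["p_value"], table.table["p_value"], equal_nan=True)
        assert np.allclose(merged["log2_fc"], table.table["log2_fc"], equal_nan=True)

    def test_overlapping_selectors_are_error(self, planted_tables):
        logm, _, _ = planted_tables
        with pytest.raises(ValueError, match="overlap"):
            differential_table(logm, {"group": "A"}, {"group": ["A", "B"]})

    def test_under_two_replicates_is_untestable(self, planted_tables):
        logm, _, _ = planted_tables
        vals = logm.values.copy()
        lipid = vals.index[0]
        vals.loc[lipid, ["A_r1", "A_r2"]] = np.nan
        m = IntensityMatrix(
            vals, logm.mode_of, sample_meta=logm.sample_meta, state="log2_median"
        )
        t = differential_table(m, {"group": "A"}, {"group": "B"})
        assert t.table.loc[lipid, "untestable"]
        assert not t.table.loc[lipid, "significant"]

    def test_requires_log2_median_state(self, planted_tables):
        logm, _, _ = planted_tables
        raw = IntensityMatrix(
            np.exp2(logm.values), logm.mode_of,
            sample_meta=logm.sample_meta, state="raw",
        )
        with pytest.raises(ValueError, match="log2_median"):
            differential_table(raw, {"group": "A"}, {"group": "B"})


def _tally_table(class_counts_up, class_counts_down=()):
    """Build a DifferentialTable carrying given significant class tallies."""
    rows = []
    i = 0
    charge = {"PG": "anionic", "CL": "anionic", "PA": "anionic",
              "PE": "zwitterionic", "PC": "zwitterionic",
              "DG": "neutral", "TG": "neutral"}
    for counts, direction in ((class_counts_up, "up_in_B"), (class_counts_down, "down_in_B")):
        for cls, n in counts:
            for _ in range(n):
                rows.append((f"{cls}_{i}", 0.01, 3.0, True, direction, cls, charge[cls]))
                i += 1
    df = pd.DataFrame(
        rows,
        columns=["lipid", "p_value", "log2_fc", "significant", "direction",
                 "lipid_class", "charge_class"],
    ).set_index("lipid")
    df = df.astype({"significant": bool, "p_value": float, "log2_fc": float})
    df["untestable"] = False
    df["n_a"] = df["n_b"] = 3
    return DifferentialTable(df, "A", "B", 0.05, 1.5)


class TestSubclassComposition:
    def test_salinity_elevated_tally_charge_percentages(self):
        # 15 elevated species: 4 PE, 4 PG, 3 CL, 4 DG
        table = _tally_table([("PE", 4), ("PG", 4), ("CL", 3), ("DG", 4)])
        comp = subclass_composition(table, direction="up")
        assert comp.total == 15
        assert approx_percent(comp.charge_counts["anionic"], comp.total) == 47
        assert approx_percent(comp.charge_counts["zwitterionic"], comp.total) == 27

    def test_direction_filter(self):
        table = _tally_table([("PG", 2)], [("TG", 1)])
        up = subclass_composition(table, direction="up")
        down = subclass_composition(table, direction="down")
        assert up.class_counts == {"PG": 2}
        assert down.class_counts == {"TG": 1}
        assert subclass_composition(table).total == 3

    def test_empty_selection_has_no_division_by_zero(self):
        table = _tally_table([])
        comp = subclass_composition(table)
        assert comp.total == 0 and comp.class_percent == {}


class TestSummarizeCounts:
    def test_headline_percentages(self):
        table = _tally_table([("PG", 74)], [("TG", 2)])
        summary = summarize_counts(table, detected_total=194)
        assert summary.n_significant == 76
        assert approx_percent(summary.n_significant, 194) == 39
        assert approx_percent(74, summary.n_significant) == 97

    def test_zero_significant(self):
        summary = summarize_counts(_tally_table([]), detected_total=194)
        assert summary.n_significant == 0 and summary.percent_up == 0.0

    def test_rounding_helpers(self):
        assert percent(16, 31) == 51.6
        assert percent(13, 194) == 6.7
        assert approx_percent(100, 194) == 52
        assert percent(16, 194) == 8.2


class TestAnovaScreen:
    def test_two_groups_equals_t_test(self, planted_tables):
        logm, table, _ = planted_tables
        labels = logm.sample_meta["group"]
        top = anova_screen(logm, labels, k=194)
        # ANOVA p for 2 groups equals the equal-variance t-test p (F = t^2)
        ranked_by_t = list(table.table["p_value"].sort_values().index[:10])
        assert top[:10] == sorted(
            ranked_by_t, key=lambda l: table.table.loc[l, "p_value"]
        )

    def test_planted_lipids_dominate_top_k(self, catalog194):
        matrix, truth = simulate_two_group(
            n_lipids=194, n_per_group=4, planted_lipids=10,
            delta_log2=4.0, sigma=0.5, seed=9, catalog=catalog194,
        )
        logm = log2_median_normalize(matrix)
        top50 = anova_screen(logm, logm.sample_meta["group"], k=50)
        assert set(truth.planted_lipids) <= set(top50)

    def test_k_zero_and_k_too_large(self, planted_tables):
        logm, _, _ = planted_tables
        labels = logm.sample_meta["group"]
        assert anova_screen(logm, labels, k=0) == []
        with pytest.warns(UserWarning, match="exceeds"):
            allofthem = anova_screen(logm, labels, k=500)
        assert len(allofthem) == 194
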