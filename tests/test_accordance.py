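import numpy as np
import pandas as pd
import pytest

from ironaccord.accordance import (
    PatientRecord,
    UndefinedRateError,
    annotate_bins,
    dar,
    double_standardize,
    sdar,
    stratify,
    stratum_table,
)


def cell(subgroup_rows, layer_value, n_cases, n_match, layer_col="layer", **extra):
    """Append records for one (subgroup, layer) cell with a given match count."""
    for i in range(n_cases):
        row = {
            layer_col: layer_value,
            "grade_hat": "mild" if i < n_match else "mild",
            "grade_ref": "mild" if i < n_match else "severe",
        }
        row.update(extra)
        subgroup_rows.append(row)


def build(rows):
    return pd.DataFrame(rows)


def sdar_oracle(subgroups, layer_col):
    """Independent nested-loop direct standardization (renormalizing rule)."""
    pooled = {}
    for frame in subgroups.values():
        for value in frame[layer_col]:
            pooled[value] = pooled.get(value, 0) + 1
    out = {}
    for name, frame in subgroups.items():
        num = den = 0.0
        for layer, n_i in pooled.items():
            cases = frame[frame[layer_col] == layer]
            if len(cases) == 0:
                continue
            p_i = (cases["grade_hat"] == cases["grade_ref"]).mean()
            num += n_i * p_i
            den += n_i
        out[name] = num / den if den else float("nan")
    return out


class TestDar:
    def test_identical(self):
        assert dar(["severe", "mild"], ["severe", "mild"]) == 1.0

    def test_hand_count(self):
        assert dar(
            ["severe", "mild", "normal"], ["severe", "moderate", "normal"]
        ) == pytest.approx(2 / 3)

    def test_disjoint(self):
        assert dar(["normal", "slight"], ["severe", "moderate"]) == 0.0

    def test_empty_undefined(self):
        with pytest.raises(UndefinedRateError):
            dar([], [])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            dar(["mild"], ["mild", "severe"])

    def test_no_adjacent_grade_credit(self):
        assert dar(["moderate"], ["severe"]) == 0.0


def record_frame(rows):
    frame = pd.DataFrame(
        rows,
        columns=["patient_id", "lic_ref", "grade_ref", "lic_hat", "grade_hat",
                 "r_squared", "n_echoes"],
    )
    return annotate_bins(frame)


class TestStratify:
    def _records(self, r2_values, n_echoes=6):
        rows = [
            (f"P{i}", 5.0, "mild", 5.0, "mild", r2, n_echoes)
            for i, r2 in enumerate(r2_values)
        ]
        return record_frame(rows)

    def test_high_r2_lands_in_top_bin(self):
        strat = stratify(self._records([0.9931]), "r2")
        assert len(strat.groups["[0.99,1.00]"]) == 1

    def test_perfect_r2_in_closed_top_bin(self):
        strat = stratify(self._records([1.0]), "r2")
        assert len(strat.groups["[0.99,1.00]"]) == 1

    def test_low_r2_excluded_with_count(self):
        # 1,080-record layout with 11 below threshold -> 1,069 stratified
        r2s = [0.97] * 1069 + [0.90] * 11
        strat = stratify(self._records(r2s), "r2")
        assert strat.n_input == 1080
        assert strat.n_excluded_low_r2 == 11
        assert strat.n_stratified == 1069

    def test_te_strata_are_singletons(self):
        rows = [(f"P{i}", 5.0, "mild", 5.0, "mild", 0.99, n)
                for i, n in enumerate([3, 3, 12, 7])]
        strat = stratify(record_frame(rows), "te")
        assert list(strat.groups) == list(range(3, 13))
        assert len(strat.groups[3]) == 2
        assert len(strat.groups[12]) == 1
        assert len(strat.groups[4]) == 0

    def test_lic_strata_use_reference_grade(self):
        rows = [("P0", 0.7, "normal", 20.0, "severe", 0.99, 6),
                ("P1", 20.0, "severe", 0.7, "normal", 0.99, 6)]
        strat = stratify(record_frame(rows), "lic")
        assert len(strat.groups["normal"]) == 1
        assert len(strat.groups["severe"]) == 1

    def test_unknown_variable(self):
        with pytest.raises(ValueError):
            stratify(self._records([0.99]), "age")


class TestSdar:
    def test_hand_example_two_layers(self):
        # pooled N1=10, N2=30; target subgroup has p1=0.5, p2=0.9
        g_rows, h_rows = [], []
        cell(g_rows, "L1", 4, 2)
        cell(g_rows, "L2", 10, 9)
        cell(h_rows, "L1", 6, 6)
        cell(h_rows, "L2", 20, 20)
        results = sdar({"G": build(g_rows), "H": build(h_rows)}, "layer")
        assert results["G"].sdar == pytest.approx((10 * 0.5 + 30 * 0.9) / 40)
        assert results["G"].sdar == pytest.approx(0.8)

    def test_identical_layer_dars_give_common_rate(self):
        g_rows, h_rows = [], []
        for layer, n in [("L1", 4), ("L2", 8)]:
            cell(g_rows, layer, n, n // 2)  # p = 0.5 everywhere
            cell(h_rows, layer, n * 2, n)
        results = sdar({"G": build(g_rows), "H": build(h_rows)}, "layer")
        assert results["G"].sdar == pytest.approx(0.5, abs=1e-12)
        assert results["H"].sdar == pytest.approx(0.5, abs=1e-12)

    def test_single_layer_degenerate_weights(self):
        g_rows = []
        cell(g_rows, "L1", 10, 7)
        results = sdar({"G": build(g_rows)}, "layer")
        assert results["G"].sdar == pytest.approx(0.7)

    def test_missing_layer_renormalize(self):
        g_rows, h_rows = [], []
        cell(g_rows, "L1", 5, 5)  # G has no L2 cases
        cell(h_rows, "L1", 5, 0)
        cell(h_rows, "L2", 10, 5)
        results = sdar({"G": build(g_rows), "H": build(h_rows)}, "layer")
        assert results["G"].sdar == pytest.approx(1.0)  # weight on L1 only
        assert results["G"].dropped_layers == ("L2",)

    def test_missing_layer_drop_keeps_full_denominator(self):
        g_rows, h_rows = [], []
        cell(g_rows, "L1", 5, 5)
        cell(h_rows, "L1", 5, 0)
        cell(h_rows, "L2", 10, 5)
        results = sdar(
            {"G": build(g_rows), "H": build(h_rows)}, "layer", missing_layer="drop"
        )
        assert results["G"].sdar == pytest.approx(10 / 20)  # N1=10 of N=20

    def test_empty_subgroup_missing_sdar(self):
        g_rows = []
        cell(g_rows, "L1", 3, 3)
        results = sdar({"G": build(g_rows), "H": build([])}, "layer")
        assert np.isnan(results["H"].sdar)

    def test_bounded_by_layer_dars(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            g_rows = []
            p_is = []
            for layer in range(rng.integers(2, 5)):
                n = int(rng.integers(1, 8))
                k = int(rng.integers(0, n + 1))
                cell(g_rows, f"L{layer}", n, k)
                p_is.append(k / n)
            results = sdar({"G": build(g_rows)}, "layer")
            assert min(p_is) - 1e-12 <= results["G"].sdar <= max(p_is) + 1e-12

    def test_layer_relabeling_invariance(self):
        g_rows, h_rows = [], []
        cell(g_rows, "L1", 4, 2)
        cell(g_rows, "L2", 6, 5)
        cell(h_rows, "L1", 3, 1)
        cell(h_rows, "L2", 5, 5)
        base = sdar({"G": build(g_rows), "H": build(h_rows)}, "layer")
        relabel = {"L1": "Z9", "L2": "A0"}
        g2 = build(g_rows).assign(layer=lambda d: d["layer"].map(relabel))
        h2 = build(h_rows).assign(layer=lambda d: d["layer"].map(relabel))
        swapped = sdar({"G": g2, "H": h2}, "layer")
        assert swapped["G"].sdar == pytest.approx(base["G"].sdar, abs=1e-15)

    def test_identical_compositions_reduce_to_crude(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            layout = [(f"L{j}", int(rng.integers(1, 6))) for j in range(3)]
            groups = {}
            for name in ("G", "H"):
                rows = []
                for layer, n in layout:
                    cell(rows, layer, n, int(rng.integers(0, n + 1)))
                groups[name] = build(rows)
            results = sdar(groups, "layer")
            for name, frame in groups.items():
                crude = (frame["grade_hat"] == frame["grade_ref"]).mean()
                assert results[name].sdar == pytest.approx(crude, abs=1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            n_layers = int(rng.integers(1, 6))
            n_groups = int(rng.integers(1, 5))
            groups = {}
            for g in range(n_groups):
                rows = []
                for layer in range(n_layers):
                    n = int(rng.integers(0, 7))
                    if n:
                        cell(rows, f"L{layer}", n, int(rng.integers(0, n + 1)))
                groups[f"G{g}"] = build(rows) if rows else build(
                    [{"layer": "x", "grade_hat": "a", "grade_ref": "a"}]
                ).iloc[:0]
            expected = sdar_oracle(groups, "layer")
            results = sdar(groups, "layer")
            for name in groups:
                if np.isnan(expected[name]):
                    assert np.isnan(results[name].sdar)
                else:
                    assert results[name].sdar == pytest.approx(
                        expected[name], abs=1e-12
                    )

    def test_unknown_missing_rule(self):
        with pytest.raises(ValueError):
            sdar({"G": build([])}, "layer", missing_layer="impute")


class TestDoubleStandardize:
    def test_hand_computed_2x2(self):
        g_rows, h_rows = [], []
        cell(g_rows, "a", 2, 2, v2="u")
        cell(g_rows, "b", 2, 1, v2="u")
        cell(g_rows, "a", 1, 0, v2="v")
        cell(g_rows, "b", 1, 1, v2="v")
        cell(h_rows, "a", 1, 1, v2="u")
        cell(h_rows, "b", 1, 0, v2="u")
        cell(h_rows, "a", 2, 1, v2="v")
        cell(h_rows, "b", 2, 2, v2="v")
        results = double_standardize(
            {"G": build(g_rows), "H": build(h_rows)}, ("layer", "v2")
        )
        # per-level SDARs: u -> (G 0.75, H 0.5); v -> (G 0.5, H 0.75);
        # pooled level weights 6/12 each
        assert results["G"].sdar == pytest.approx(0.625, abs=1e-12)
        assert results["H"].sdar == pytest.approx(0.625, abs=1e-12)

    def test_single_second_level_reduces_to_sdar(self):
        g_rows, h_rows = [], []
        cell(g_rows, "a", 4, 2, v2="u")
        cell(g_rows, "b", 6, 5, v2="u")
        cell(h_rows, "a", 3, 3, v2="u")
        cell(h_rows, "b", 7, 2, v2="u")
        groups = {"G": build(g_rows), "H": build(h_rows)}
        plain = sdar(groups, "layer")
        double = double_standardize(groups, ("layer", "v2"))
        for name in groups:
            assert double[name].sdar == pytest.approx(plain[name].sdar, abs=1e-14)

    def test_both_constant_collapse_to_crude(self):
        g_rows = []
        cell(g_rows, "a", 10, 6, v2="u")
        groups = {"G": build(g_rows)}
        results = double_standardize(groups, ("layer", "v2"))
        assert results["G"].sdar == pytest.approx(0.6, abs=1e-14)
        assert results["G"].crude_dar == pytest.approx(0.6)

    def test_same_variable_twice_rejected(self):
        with pytest.raises(ValueError):
            double_standardize({"G": build([])}, ("layer", "layer"))


class TestStratumTable:
    def test_pooled_counts(self):
        g_rows, h_rows = [], []
        cell(g_rows, "L1", 4, 2)
        cell(g_rows, "L2", 6, 5)
        cell(h_rows, "L1", 6, 1)
        table = stratum_table({"G": build(g_rows), "H": build(h_rows)}, "layer")
        assert table.layers == ("L1", "L2")
        assert table.pooled_counts == (10, 6)
        assert table.total == 16

    def test_invariant_totals(self):
        g_rows = []
        cell(g_rows, "L1", 5, 5)
        cell(g_rows, "L2", 3, 0)
        table = stratum_table({"G": build(g_rows)}, "layer")
        assert sum(table.pooled_counts) == table.total == 8


class TestPatientRecord:
    def test_bin_properties(self):
        rec = PatientRecord("P1", 5.0, "mild", 4.8, "mild", 0.9931, 7)
        assert rec.r2_bin == "[0.99,1.00]"
        assert rec.te_bin == 7
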