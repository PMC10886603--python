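"""DEG calling and the module-activation filtering algebra."""

import numpy as np
import pandas as pd
import pytest

from nbsig import (
    Contrast,
    DEGTable,
    PlantedTruth,
    call_degs,
    combine_callers,
    exclusive_to_32C,
    filter_against_tsp53,
    log1p5_to_log2,
    log2_to_log1p5,
    run_deg_pipeline,
    simulate_cellline_counts,
)


def make_table(entries, temperature="32C", caller="test"):
    """entries: dict gene -> logfc_base1p5."""
    df = pd.DataFrame(
        {
            "gene": list(entries),
            "logfc_base1p5": list(entries.values()),
            "p_adj": 0.001,
            "caller": caller,
        }
    )
    return DEGTable(Contrast("NTRK1_tsp53", "parental", temperature), df)


class TestLogBases:
    def test_round_trip(self):
        assert log1p5_to_log2(log2_to_log1p5(3.0)) == pytest.approx(3.0)

    def test_eightfold_is_5p13_in_log1p5(self):
        assert log2_to_log1p5(3.0) == pytest.approx(np.log(8) / np.log(1.5))
        assert log2_to_log1p5(3.0) == pytest.approx(5.128, abs=5e-3)


class TestCallDegs:
    def test_planted_shift_detected_with_correct_logfc(self):
        # one gene with a true 8-fold shift under module activation
        truth = PlantedTruth(module_genes=("HIT",), effect_log2fc=3.0, dispersion=0.01)
        counts = simulate_cellline_counts(400, truth, seed=17)
        degs = call_degs(counts, "NTRK1_tsp53", "parental", "32C")
        assert "HIT" in degs.genes
        logfc = degs.table.set_index("gene").loc["HIT", "logfc_base1p5"]
        assert abs(abs(logfc) - 5.128) < 0.35

    def test_fold_change_threshold_excludes_small_shifts(self):
        # true fold change ~1.3 < 1.5: significant p is not enough
        truth = PlantedTruth(module_genes=("SMALL",), effect_log2fc=np.log2(1.3), dispersion=0.001)
        counts = simulate_cellline_counts(300, truth, seed=23)
        degs = call_degs(counts, "NTRK1_tsp53", "parental", "32C", min_fc=1.5)
        assert "SMALL" not in degs.genes

    def test_invalid_parameters_rejected(self, planted_counts):
        with pytest.raises(ValueError, match="alpha_fdr"):
            call_degs(planted_counts, "NTRK1_tsp53", "parental", "32C", alpha_fdr=1.5)
        with pytest.raises(ValueError, match="min_fc"):
            call_degs(planted_counts, "NTRK1_tsp53", "parental", "32C", min_fc=0.9)
        with pytest.raises(ValueError, match="unknown caller"):
            call_degs(planted_counts, "NTRK1_tsp53", "parental", "32C", caller="nope")

    def test_welch_caller_runs_and_detects_planted_signal(self, planted_counts, planted_truth):
        # the unmoderated caller has far less power at 3 replicates but must
        # still find some of the strongly planted genes
        degs = call_degs(planted_counts, "NTRK1_tsp53", "parental", "32C", caller="welch_t")
        assert len(degs.genes & set(planted_truth.module_genes)) >= 1


class TestFilterAgainstTsp53:
    def test_same_direction_large_ratio_kept(self):
        target = make_table({"g": 4.0})
        control = make_table({"g": 1.0})
        assert filter_against_tsp53(target, control).genes == {"g"}

    def test_same_direction_within_ratio_removed(self):
        target = make_table({"g": 2.0})
        control = make_table({"g": 1.0})
        assert filter_against_tsp53(target, control).genes == set()

    def test_opposite_direction_kept(self):
        target = make_table({"g": -2.0})
        control = make_table({"g": 2.0})
        assert filter_against_tsp53(target, control).genes == {"g"}

    def test_much_lower_magnitude_kept(self):
        target = make_table({"g": 0.2})
        control = make_table({"g": 1.0})
        assert filter_against_tsp53(target, control).genes == {"g"}

    def test_absent_from_control_kept(self):
        target = make_table({"g": 1.0})
        control = make_table({"other": 1.0})
        assert filter_against_tsp53(target, control).genes == {"g"}

    def test_boundary_exactly_three_times_removed(self):
        # "more than 3 times" is strict
        target = make_table({"g": 3.0})
        control = make_table({"g": 1.0})
        assert filter_against_tsp53(target, control).genes == set()

    def test_result_is_subset_and_idempotent(self):
        target = make_table({"a": 4.0, "b": 2.0, "c": -1.0, "d": 0.1})
        control = make_table({"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0})
        once = filter_against_tsp53(target, control)
        twice = filter_against_tsp53(once, control)
        assert once.genes <= target.genes
        assert once.genes == twice.genes

    def test_temperature_mismatch_rejected(self):
        with pytest.raises(ValueError, match="temperature"):
            filter_against_tsp53(make_table({"g": 1.0}, "32C"), make_table({"g": 1.0}, "37C"))


class TestExclusive32C:
    def test_set_difference(self):
        d32 = make_table({"A": 1.0, "B": 1.0, "C": 1.0}, "32C")
        d37 = make_table({"B": 1.0}, "37C")
        assert exclusive_to_32C(d32, d37).genes == {"A", "C"}

    def test_empty_37_is_identity(self):
        d32 = make_table({"A": 1.0, "B": 1.0}, "32C")
        d37 = make_table({}, "37C")
        assert exclusive_to_32C(d32, d37).genes == {"A", "B"}

    def test_subset_annihilates(self):
        d32 = make_table({"A": 1.0}, "32C")
        d37 = make_table({"A": 1.0, "B": 1.0}, "37C")
        assert exclusive_to_32C(d32, d37).genes == set()

    def test_same_temperature_rejected(self):
        with pytest.raises(ValueError):
            exclusive_to_32C(make_table({"A": 1.0}), make_table({"B": 1.0}))


class TestCombineCallers:
    def test_union(self):
        out = combine_callers([{"A", "B"}, {"B", "C"}, {"C", "D"}])
        assert set(out["gene"]) == {"A", "B", "C", "D"}

    def test_idempotence(self):
        out = combine_callers([{"A", "B"}] * 3)
        assert set(out["gene"]) == {"A", "B"}
        assert (out["n_callers"] == 3).all()

    def test_provenance(self):
        out = combine_callers({"x": {"A"}, "y": {"A", "B"}}).set_index("gene")
        assert out.loc["A", "callers"] == "x,y"
        assert out.loc["B", "callers"] == "y"

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            combine_callers([])


class TestFullPipeline:
    def test_planted_recovery_and_exclusion(self, planted_counts, planted_truth):
        result = run_deg_pipeline(planted_counts)
        genes = set(result["gene"])
        module = set(planted_truth.module_genes)
        off_target = set(planted_truth.tsp53_genes) | set(planted_truth.temp_genes)
        assert len(genes & module) / len(module) >= 0.9
        assert len(genes & off_target) / len(off_target) <= 0.05

    def test_union_at_least_single_caller(self, planted_counts, planted_truth):
        module = set(planted_truth.module_genes)
        both = set(run_deg_pipeline(planted_counts, callers=("moderated_t", "welch_t"))["gene"])
        for caller in ("moderated_t", "welch_t"):
            single = set(run_deg_pipeline(planted_counts, callers=(caller,))["gene"])
            assert len(both & module) >= len(single & module)
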