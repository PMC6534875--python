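"""Marker-gene selection filters, signature assembly and curation."""

import numpy as np
import pandas as pd
import pytest

from quantiseq.signature import (
    CELL_TYPES,
    CURATED_BLACKLIST,
    TUMOR_BLACKLIST,
    LabeledCompendium,
    SignatureMatrix,
    apply_gene_blacklists,
    build_signature,
    build_signature_profiles,
    condition_number,
    filter_fraction_correlation,
    filter_range,
    filter_restricted_expression,
    filter_specificity,
    filter_tumor_expression,
    quantize_expression,
    select_cell_specific_genes,
)
from quantiseq.simulate import generate_design, simulate_dataset
from quantiseq.synthetic import planted_markers


def _mini_compendium(values: dict[str, list[float]], labels: dict[str, str]):
    genes = [f"G{i}" for i in range(len(next(iter(values.values()))))]
    return LabeledCompendium(values=pd.DataFrame(values, index=genes), labels=labels)


def _two_lib_labels(types):
    labels = {}
    for t in types:
        labels[f"{t}_a"] = t
        labels[f"{t}_b"] = t
    return labels


class TestQuantization:
    def test_three_clusters_get_three_bins(self):
        # one gene whose libraries cluster at low/medium/high levels
        libs = {
            "l1": [0.1], "l2": [0.2], "l3": [10.0], "l4": [12.0],
            "l5": [500.0], "l6": [600.0],
        }
        comp = _mini_compendium(libs, {l: "B.cells" for l in libs})
        bins = quantize_expression(comp).iloc[0]
        assert list(bins[["l1", "l2"]]) == [0, 0]
        assert list(bins[["l3", "l4"]]) == [1, 1]
        assert list(bins[["l5", "l6"]]) == [2, 2]

    def test_constant_gene_is_all_low(self):
        libs = {f"l{i}": [5.0] for i in range(6)}
        comp = _mini_compendium(libs, {l: "B.cells" for l in libs})
        assert (quantize_expression(comp).iloc[0] == 0).all()

    def test_bins_monotone_in_expression(self, rng):
        libs = {f"l{i}": [v] for i, v in enumerate(rng.uniform(0, 100, size=12))}
        comp = _mini_compendium(libs, {l: "B.cells" for l in libs})
        bins = quantize_expression(comp).iloc[0]
        vals = comp.values.iloc[0]
        order = vals.sort_values().index
        assert (bins[order].diff().dropna() >= 0).all()

    def test_tied_values_share_a_bin(self):
        libs = {f"l{i}": [v] for i, v in enumerate([0.0, 0.0, 5.0, 5.0, 5.0, 90.0])}
        comp = _mini_compendium(libs, {l: "B.cells" for l in libs})
        bins = quantize_expression(comp).iloc[0]
        assert bins["l2"] == bins["l3"] == bins["l4"]


class TestCellSpecificSelection:
    def _bins(self, rows, labels):
        return pd.DataFrame(rows, columns=list(labels)).astype(np.int8)

    def test_high_in_one_type_low_elsewhere_is_candidate(self, compendium):
        bins = quantize_expression(compendium)
        owners = select_cell_specific_genes(bins, compendium)
        truth = planted_markers()
        found = set(owners) & set(truth)
        assert all(owners[g] == truth[g] for g in found)
        assert len(found) >= 0.9 * len(truth)

    def test_high_in_two_types_is_candidate_for_neither(self):
        labels = _two_lib_labels(["B.cells", "NK.cells", "Monocytes"])
        values = {
            l: [100.0 if labels[l] in ("B.cells", "NK.cells") else 0.1]
            # add spread so three bins exist
            for l in labels
        }
        values["Monocytes_a"] = [5.0]
        comp = _mini_compendium(values, labels)
        bins = quantize_expression(comp)
        assert select_cell_specific_genes(bins, comp) == {}

    def test_high_in_only_part_of_own_libraries_is_rejected(self):
        labels = _two_lib_labels(["B.cells", "NK.cells", "Monocytes"])
        values = {l: [0.1] for l in labels}
        values["B.cells_a"] = [100.0]  # 1 of 2 B libraries high
        values["NK.cells_a"] = [5.0]
        comp = _mini_compendium(values, labels)
        bins = quantize_expression(comp)
        assert select_cell_specific_genes(bins, comp) == {}

    def test_detection_prefilter_drops_sparsely_detected_genes(self):
        labels = _two_lib_labels(["B.cells", "NK.cells", "Monocytes"])
        # detected (non-zero) in only one immune library
        values = {l: [0.0] for l in labels}
        values["B.cells_a"] = [100.0]
        comp = _mini_compendium(values, labels)
        bins = quantize_expression(comp)
        assert select_cell_specific_genes(bins, comp) == {}


class TestTumorExpressionFilter:
    def test_high_in_all_cancer_lines_removed(self):
        ccle = pd.DataFrame({"l1": [8.0], "l2": [9.0], "l3": [10.0]}, index=["G1"])
        assert filter_tumor_expression({"G1": "B.cells"}, ccle, None) == {}

    def test_high_in_some_lines_kept(self):
        ccle = pd.DataFrame({"l1": [8.0], "l2": [3.0], "l3": [10.0]}, index=["G1"])
        assert filter_tumor_expression({"G1": "B.cells"}, ccle, None) == {"G1": "B.cells"}

    def test_low_bulk_mean_removed(self):
        tcga = pd.Series({"G1": 0.5, "G2": 2.0})
        out = filter_tumor_expression({"G1": "B.cells", "G2": "B.cells"}, None, tcga)
        assert out == {"G2": "B.cells"}

    def test_missing_gene_retained_with_warning(self):
        tcga = pd.Series({"G2": 2.0})
        with pytest.warns(UserWarning, match="absent"):
            out = filter_tumor_expression({"G1": "B.cells", "G2": "B.cells"}, None, tcga)
        assert set(out) == {"G1", "G2"}


class TestSpecificityFilter:
    def test_cross_type_listing_removes_gene(self):
        sets = [("mono_set", "Monocytes", ["G1"])]
        assert filter_specificity({"G1": "NK.cells"}, sets) == {}

    def test_cd4_sets_do_not_filter_treg_candidates(self):
        sets = [("cd4_set", "T.cells.CD4", ["FOXP3_LIKE"])]
        genes = {"FOXP3_LIKE": "Tregs"}
        assert filter_specificity(genes, sets) == genes

    def test_gene_in_no_set_kept(self):
        assert filter_specificity({"G1": "B.cells"}, []) == {"G1": "B.cells"}

    def test_own_type_listing_is_harmless(self):
        sets = [("b_set", "B.cells", ["G1"])]
        assert filter_specificity({"G1": "B.cells"}, sets) == {"G1": "B.cells"}


class TestRangeFilter:
    def _comp(self, peak):
        labels = {"l1": "B.cells", "l2": "B.cells"}
        return _mini_compendium({"l1": [peak], "l2": [10.0]}, labels)

    def test_exceeding_700_removed(self):
        assert filter_range({"G0": "B.cells"}, self._comp(800.0)) == {}

    def test_exactly_700_kept(self):
        assert filter_range({"G0": "B.cells"}, self._comp(700.0)) == {"G0": "B.cells"}

    def test_all_below_threshold_unchanged(self):
        assert filter_range({"G0": "B.cells"}, self._comp(650.0)) == {"G0": "B.cells"}


class TestFractionCorrelationFilter:
    def test_linear_gene_kept_and_noise_gene_removed(self, rng):
        n = 40
        frac = pd.DataFrame({"B.cells": rng.uniform(0, 0.5, size=n)})
        linear = 100 * frac["B.cells"].to_numpy()
        noise = rng.permutation(linear)
        mixtures = pd.DataFrame({"m%d" % i: [linear[i], noise[i]] for i in range(n)},
                                index=["LIN", "NOISE"])
        genes = {"LIN": "B.cells", "NOISE": "B.cells"}
        kept, corr = filter_fraction_correlation(genes, mixtures, frac)
        assert "LIN" in kept and corr["LIN"] == pytest.approx(1.0)
        assert "NOISE" not in kept

    def test_boundary_r_of_0p6_is_kept(self):
        # fractions (1,2,3,4) vs expression (1,0,3,2): Pearson r is exactly
        # 0.6 in floating point, and the threshold is inclusive
        frac = pd.DataFrame({"B.cells": [1.0, 2.0, 3.0, 4.0]})
        mixtures = pd.DataFrame(
            [[1.0, 0.0, 3.0, 2.0]], index=["G"], columns=list("abcd")
        )
        kept, corr = filter_fraction_correlation({"G": "B.cells"}, mixtures, frac)
        assert corr["G"] == 0.6
        assert kept == {"G": "B.cells"}

    def test_constant_gene_removed_with_warning(self):
        frac = pd.DataFrame({"B.cells": [0.1, 0.2, 0.3]})
        mixtures = pd.DataFrame([[5.0, 5.0, 5.0]], index=["G"], columns=["a", "b", "c"])
        with pytest.warns(UserWarning, match="constant"):
            kept, _ = filter_fraction_correlation({"G": "B.cells"}, mixtures, frac)
        assert kept == {}


class TestRestrictedExpressionFilter:
    def _dataset(self, in_value, out_value, gene="G1", owner="B.cells"):
        labels = _two_lib_labels([owner, "NK.cells", "Monocytes"])
        values = {
            l: [in_value if labels[l] == owner else out_value] for l in labels
        }
        comp = LabeledCompendium(values=pd.DataFrame(values, index=[gene]), labels=labels)
        return comp

    def test_ratio_computed_and_gene_retained(self):
        external = {"d1": self._dataset(10.0, 2.0), "d2": self._dataset(10.0, 2.0)}
        kept, ratios = filter_restricted_expression({"G1": "B.cells"}, external)
        assert ratios.loc["G1"].tolist() == [5.0, 5.0]
        assert kept == {"G1": "B.cells"}

    def test_median_ratio_below_2_removed(self):
        external = {"d1": self._dataset(3.0, 2.0)}
        kept, _ = filter_restricted_expression({"G1": "B.cells"}, external)
        assert kept == {}

    def test_zero_out_group_median_is_infinite_ratio(self):
        external = {"d1": self._dataset(10.0, 0.0)}
        kept, ratios = filter_restricted_expression({"G1": "B.cells"}, external)
        assert np.isinf(ratios.loc["G1", "d1"])
        assert kept == {"G1": "B.cells"}

    def test_top_30_cap_per_cell_type(self):
        labels = _two_lib_labels(["B.cells", "NK.cells", "Monocytes"])
        genes = {f"G{i:02d}": "B.cells" for i in range(40)}
        values = {
            l: [10.0 + i if labels[l] == "B.cells" else 1.0 for i in range(40)]
            for l in labels
        }
        comp = LabeledCompendium(
            values=pd.DataFrame(values, index=sorted(genes)), labels=labels
        )
        kept, _ = filter_restricted_expression(genes, {"d1": comp})
        assert len(kept) == 30
        # ranked by ratio: the 30 highest-expressed survive
        assert "G39" in kept and "G00" not in kept

    def test_treg_pass_drops_cd4_indistinct_genes(self):
        labels = _two_lib_labels(["Tregs", "T.cells.CD4", "B.cells"])
        # TREG_OK is Treg >> CD4; TREG_BAD is higher in CD4 than Treg
        values = pd.DataFrame(
            {
                l: [
                    20.0 if labels[l] == "Tregs" else (2.0 if labels[l] == "T.cells.CD4" else 1.0),
                    5.0 if labels[l] == "Tregs" else (50.0 if labels[l] == "T.cells.CD4" else 1.0),
                ]
                for l in labels
            },
            index=["TREG_OK", "TREG_BAD"],
        )
        comp = LabeledCompendium(values=values, labels=labels)
        genes = {"TREG_OK": "Tregs", "TREG_BAD": "Tregs"}
        kept, _ = filter_restricted_expression(genes, {"d1": comp}, treg_vs_cd4={"d1": comp})
        assert "TREG_OK" in kept and "TREG_BAD" not in kept


class TestProfilesAndBlacklists:
    def test_median_profile_over_type_libraries(self):
        labels = {"a": "B.cells", "b": "B.cells", "c": "B.cells", "d": "NK.cells"}
        values = pd.DataFrame(
            {"a": [1.0], "b": [3.0], "c": [5.0], "d": [9.0]}, index=["G1"]
        )
        comp = LabeledCompendium(values=values, labels=labels)
        sig = build_signature_profiles(comp, {"G1": "B.cells"})
        assert sig.values.loc["G1", "B.cells"] == 3.0
        assert sig.values.loc["G1", "NK.cells"] == 9.0  # single-library type

    def test_default_blacklist_shrinks_170_to_153(self, signature_standin):
        assert signature_standin.values.shape[0] == 170
        reduced = apply_gene_blacklists(signature_standin, rmgenes="default")
        assert reduced.values.shape[0] == 153

    def test_rmgenes_none_is_identity(self, signature_standin):
        out = apply_gene_blacklists(signature_standin, rmgenes="none")
        pd.testing.assert_frame_equal(out.values, signature_standin.values)

    def test_custom_list_skips_absent_genes(self, signature_standin, tmp_path):
        present = signature_standin.gene_ids[0]
        path = tmp_path / "rm.txt"
        path.write_text(f"{present}\nNOT_A_GENE\n")
        out = apply_gene_blacklists(signature_standin, rmgenes=path)
        assert out.values.shape[0] == 169

    def test_tumor_mode_removes_tumor_list_too(self, signature_standin):
        out = apply_gene_blacklists(signature_standin, rmgenes="default", tumor=True)
        expected = 170 - len(set(CURATED_BLACKLIST) | set(TUMOR_BLACKLIST))
        assert out.values.shape[0] == expected
        assert not set(out.gene_ids) & set(TUMOR_BLACKLIST)


class TestConditionNumber:
    def test_identity_matrix_is_one(self):
        sig = SignatureMatrix(values=pd.DataFrame(np.eye(10)))
        assert condition_number(sig) == pytest.approx(1.0)

    def test_diagonal_ratio(self):
        sig = SignatureMatrix(values=pd.DataFrame(np.diag([1.0, 2.0])))
        assert condition_number(sig) == pytest.approx(2.0)

    def test_rank_deficient_reports_infinity(self):
        values = pd.DataFrame([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.warns(UserWarning, match="rank-deficient"):
            assert condition_number(SignatureMatrix(values=values)) == np.inf

    def test_blacklist_improves_conditioning(self, signature_standin):
        full = condition_number(signature_standin)
        reduced = condition_number(apply_gene_blacklists(signature_standin, "default"))
        assert reduced < full


class TestFullPipeline:
    def test_planted_markers_recovered_with_high_precision(self, bundle):
        design = generate_design(n_mixtures=40, depths=(1e6,), base_depth=1e6, seed=11)
        mixtures, truth = simulate_dataset(bundle.profiles, design)
        signature, report = build_signature(
            bundle.compendium,
            ccle_summary=bundle.ccle_summary,
            tcga_summary=bundle.tcga_summary,
            gene_sets=bundle.gene_sets,
            mixtures=mixtures,
            true_fractions=truth[list(CELL_TYPES)].astype(float),
            external=bundle.external,
            treg_vs_cd4=bundle.external,
        )
        selected = set(signature.gene_ids)
        truth_markers = set(planted_markers())
        precision = len(selected & truth_markers) / len(selected)
        assert precision >= 0.9
        assert not any(g.startswith("DECOY") for g in selected)
        # every selected gene has exactly one owner
        assert set(signature.owners) == selected

    def test_independent_filters_commute(self, bundle):
        genes = dict(planted_markers())
        a = filter_range(
            filter_tumor_expression(genes, bundle.ccle_summary, bundle.tcga_summary),
            bundle.compendium,
        )
        b = filter_tumor_expression(
            filter_range(genes, bundle.compendium),
            bundle.ccle_summary,
            bundle.tcga_summary,
        )
        assert a == b
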