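"""Expression gates, specificity filters and the transition taxonomy."""

import numpy as np
import pandas as pd
import pytest

from sgnseq.design import generate_design, SGN_AGE_ORDER, HC_GROUP, GLIA_GROUP
from sgnseq.classify import (
    Thresholds,
    expression_gate,
    specificity_calls,
    constant_specific_filter,
    dynamic_specific_filter,
    call_transitions,
    pattern_string,
    assign_patterns,
    group_patterns,
    specificity_on_true_means,
    transitions_on_true_means,
    CONSTANT_SPECIFIC,
    DYNAMIC_SPECIFIC,
)
from sgnseq.synthetic import true_means_frame
from conftest import make_matrix

AGES = list(SGN_AGE_ORDER)
DESIGN_FULL = generate_design(3, include_refs=True, n_reps_refs=3)


def contrast_table(genes, entries):
    """Build a contrast DataFrame from {(a, b): (lfc, q)} per gene."""
    rows = []
    for (a, b), per_gene in entries.items():
        for g, (lfc, q) in zip(genes, per_gene):
            rows.append(
                {
                    "gene_id": g,
                    "contrast": f"{a}_vs_{b}",
                    "group_a": a,
                    "group_b": b,
                    "log2FC": lfc,
                    "t": 0.0,
                    "p": q,
                    "q": q,
                    "mean_expr": 5.0,
                }
            )
    return pd.DataFrame(rows)


def full_entries(genes, lfc_vs_ref=6.0, q_vs_ref=1e-6, lfc_pairs=0.0, q_pairs=0.9):
    """All contrasts needed by the filters, uniform per gene."""
    n = len(genes)
    entries = {}
    for age in AGES:
        for ref in (HC_GROUP, GLIA_GROUP):
            entries[(age, ref)] = [(lfc_vs_ref, q_vs_ref)] * n
    for i, a in enumerate(AGES):
        for b in AGES[i + 1:]:
            entries[(a, b)] = [(lfc_pairs, q_pairs)] * n
    return entries


def tpm_frame(genes, sgn=100.0, hc=0.5, glia=0.5):
    data = {a: sgn for a in AGES}
    data[HC_GROUP] = hc
    data[GLIA_GROUP] = glia
    return pd.DataFrame({g: data for g in genes}).T


class TestThresholds:
    def test_defaults_valid(self):
        th = Thresholds()
        assert th.fc_specific == 4.0 and th.tpm_dyn_max == 75.0

    @pytest.mark.parametrize(
        "kwargs", [{"q_specific": 1.5}, {"fc_trans": 0.5}, {"cpm_expr_gate": -1}]
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Thresholds(**kwargs)


class TestExpressionGate:
    def test_kept_when_all_replicates_pass_in_one_group(self):
        design = generate_design(3, include_refs=False)
        # gene 2 fills the library; gene 0 clears CPM 1 in every E15.5
        # replicate, gene 1 misses it in one replicate
        c = np.zeros((3, 15), dtype=int)
        c[2, :] = 1_000_000
        c[0, 0:3] = [2, 3, 4]   # CPM ~2-4 in every E15.5 replicate
        c[1, 0:3] = [2, 0, 4]   # one replicate at CPM 0
        m = make_matrix(c, design)
        kept = expression_gate(m, Thresholds(), "de_universe")
        assert "g0" in kept and "g1" not in kept and "g2" in kept

    def test_all_zero_matrix_empty(self):
        design = generate_design(2, include_refs=False)
        m = make_matrix(np.zeros((3, 10), dtype=int), design)
        assert expression_gate(m, Thresholds(), "dynamics_universe") == []

    def test_dynamics_gate_ignores_references(self):
        # a gene expressed only in HC/Glia enters the DE universe but
        # never the SGN-only dynamics universe
        design = generate_design(2, include_refs=True, n_reps_refs=2)
        c = np.zeros((2, 14), dtype=int)
        c[1, :] = 1_000_000
        c[0, 10:] = 5000  # reference samples only
        m = make_matrix(c, design)
        th = Thresholds()
        assert "g0" in expression_gate(m, th, "de_universe")
        assert "g0" not in expression_gate(m, th, "dynamics_universe")


class TestConstantFilter:
    def test_prototype_constant_gene_selected(self):
        genes = ["x"]
        tab = contrast_table(genes, full_entries(genes))
        calls = specificity_calls(tab, tpm_frame(genes), Thresholds(), DESIGN_FULL)
        assert calls.loc["x", "call"] == CONSTANT_SPECIFIC

    def test_parvalbumin_like_rejected_by_reference_tpm(self):
        # expressed in both SGNs and HCs: fails the refs-below-5-TPM condition
        genes = ["pvalb"]
        entries = full_entries(genes)
        tab = contrast_table(genes, entries)
        calls = specificity_calls(
            tab, tpm_frame(genes, sgn=100.0, hc=80.0), Thresholds(), DESIGN_FULL
        )
        assert not calls.loc["pvalb", "const_c3"]
        assert calls.loc["pvalb", "call"] != CONSTANT_SPECIFIC

    def test_low_sgn_tpm_rejected(self):
        genes = ["low"]
        tab = contrast_table(genes, full_entries(genes))
        calls = specificity_calls(
            tab, tpm_frame(genes, sgn=20.0), Thresholds(), DESIGN_FULL
        )
        assert not calls.loc["low", "const_c4"]
        assert calls.loc["low", "call"] != CONSTANT_SPECIFIC

    def test_missing_contrast_names_pair(self):
        genes = ["x"]
        entries = full_entries(genes)
        del entries[("SGN_P8", HC_GROUP)]
        tab = contrast_table(genes, entries)
        with pytest.raises(KeyError, match="SGN_P8_vs_HC"):
            specificity_calls(tab, tpm_frame(genes), Thresholds(), DESIGN_FULL)


class TestDynamicFilter:
    def dynamic_entries(self, genes):
        entries = full_entries(genes, lfc_vs_ref=0.0, q_vs_ref=0.9)
        # P30 strongly above both references; P30-vs-E15.5 pair significant
        for ref in (HC_GROUP, GLIA_GROUP):
            entries[("SGN_P30", ref)] = [(6.0, 1e-6)] * len(genes)
        entries[("SGN_E15.5", "SGN_P30")] = [(-3.0, 1e-4)] * len(genes)
        return entries

    def dynamic_tpm(self, genes, peak=200.0, hc=1.0, glia=1.0):
        df = tpm_frame(genes, sgn=10.0, hc=hc, glia=glia)
        df["SGN_P30"] = peak
        return df

    def test_prototype_dynamic_gene_selected(self):
        genes = ["celf4"]
        tab = contrast_table(genes, self.dynamic_entries(genes))
        calls = specificity_calls(tab, self.dynamic_tpm(genes), Thresholds(), DESIGN_FULL)
        assert calls.loc["celf4", "call"] == DYNAMIC_SPECIFIC

    def test_low_peak_tpm_rejected(self):
        genes = ["low"]
        tab = contrast_table(genes, self.dynamic_entries(genes))
        calls = specificity_calls(
            tab, self.dynamic_tpm(genes, peak=50.0), Thresholds(), DESIGN_FULL
        )
        assert not calls.loc["low", "dyn_c3"]

    def test_insufficient_ref_ratio_rejected(self):
        genes = ["weak"]
        tab = contrast_table(genes, self.dynamic_entries(genes))
        calls = specificity_calls(
            tab, self.dynamic_tpm(genes, peak=200.0, hc=10.0), Thresholds(), DESIGN_FULL
        )
        assert not calls.loc["weak", "dyn_c4"]  # 200 < 25 * 10


class TestFiltersOnPipeline:
    def test_mutual_exclusivity(self, pipeline_result):
        spec = pipeline_result.specificity
        assert not ((spec.const_c2) & (spec.dyn_c2)).any()

    def test_filter_wrappers_split_calls(self, pipeline_result, panel):
        m, _ = panel
        const = constant_specific_filter(
            pipeline_result.contrasts,
            pipeline_result.tpm_group_means,
            Thresholds(),
            m.design,
        )
        dyn = dynamic_specific_filter(
            pipeline_result.contrasts,
            pipeline_result.tpm_group_means,
            Thresholds(),
            m.design,
        )
        assert const and dyn and not (const & dyn)

    def test_noise_free_truth_recovers_planted_sets_exactly(self, panel):
        m, truth = panel
        tm = true_means_frame(truth, m.design)
        calls = specificity_on_true_means(tm, Thresholds(), m.design)
        assert set(calls.index[calls == CONSTANT_SPECIFIC]) == set(
            truth.index[truth.class_label == "constant_specific"]
        )
        assert set(calls.index[calls == DYNAMIC_SPECIFIC]) == set(
            truth.index[truth.class_label == "dynamic_specific"]
        )

    def test_noise_free_patterns_match_intent(self, panel):
        m, truth = panel
        tm = true_means_frame(truth, m.design)
        pat = truth[truth.class_label == "patterned"]
        cats = transitions_on_true_means(tm.loc[pat.index], Thresholds(), m.design)
        assert (cats == pat.intended_pattern).all()


class TestTransitions:
    def make_transition_inputs(self, lfc, q, elem_ratio=1.5):
        """One gene; every transition carries the same (lfc, q)."""
        design = generate_design(3, include_refs=False)
        genes = ["g"]
        entries = {}
        for a, b in zip(AGES[1:], AGES[:-1]):  # later vs earlier
            entries[(a, b)] = [(lfc, q)]
        tab = contrast_table(genes, entries)
        cpm = pd.DataFrame(
            [[100.0] * 3 * 2 + [100.0 * elem_ratio] * 9],
            index=genes,
            columns=list(design.sample_ids),
        )
        return tab, cpm, design

    def test_up_call(self):
        tab, cpm, design = self.make_transition_inputs(lfc=1.6, q=0.01)
        tr = call_transitions(tab, cpm, Thresholds(), design)
        assert (tr.loc["g"] == "u").all()

    def test_unchanged_call(self):
        tab, cpm, design = self.make_transition_inputs(lfc=0.3, q=0.5)
        tr = call_transitions(tab, cpm, Thresholds(), design)
        assert (tr.loc["g"] == "-").all()

    def test_noisy_call(self):
        tab, cpm, design = self.make_transition_inputs(lfc=0.6, q=0.07)
        tr = call_transitions(tab, cpm, Thresholds(), design)
        assert (tr.loc["g"] == "n").all()

    def test_elementwise_fc_blocks_unchanged(self):
        # flat model estimate but one replicate pair ratio above 4
        design = generate_design(3, include_refs=False)
        genes = ["g"]
        entries = {(a, b): [(0.1, 0.9)] for a, b in zip(AGES[1:], AGES[:-1])}
        tab = contrast_table(genes, entries)
        cpm = pd.DataFrame(
            [[100.0, 100, 100, 600, 100, 100] + [100.0] * 9],
            index=genes,
            columns=list(design.sample_ids),
        )
        tr = call_transitions(tab, cpm, Thresholds(), design)
        # the outlier replicate sits in P1, so both adjacent transitions
        # carry a >4x replicate-pair ratio and lose their unchanged call
        assert tr.loc["g"].iloc[0] == "n"
        assert tr.loc["g"].iloc[1] == "n"
        assert (tr.loc["g"].iloc[2:] == "-").all()


class TestPatternStrings:
    @pytest.mark.parametrize(
        "calls,raw,category",
        [
            (["-", "d", "-", "-"], "-d--", "-d--"),
            (["u", "d", "-", "-"], "ud--", "ud--"),
            (["n", "-", "-", "-"], "n---", "----"),
            (["u", "n", "d", "n"], "undn", "u-d-"),
        ],
    )
    def test_examples(self, calls, raw, category):
        r, c = pattern_string(calls)
        assert r == raw and c == category

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            pattern_string(["u", "d"])

    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValueError):
            pattern_string(["u", "d", "-", "x"])


class TestGroupPatterns:
    def test_partition_property(self, pipeline_result):
        cats = pipeline_result.categories
        all_genes = [g for genes in cats.values() for g in genes]
        assert len(all_genes) == len(set(all_genes))
        assert set(all_genes) == set(pipeline_result.patterns.index)

    def test_all_unchanged_single_category(self):
        pats = pd.DataFrame(
            {"raw": ["----"] * 5, "category": ["----"] * 5},
            index=[f"g{i}" for i in range(5)],
        )
        mapping, summary = group_patterns(pats, Thresholds())
        assert list(mapping) == ["----"] and len(mapping["----"]) == 5

    def test_small_categories_flagged_not_dropped(self):
        pats = pd.DataFrame(
            {"raw": ["u---"] * 3 + ["----"] * 15,
             "category": ["u---"] * 3 + ["----"] * 15},
            index=[f"g{i}" for i in range(18)],
        )
        mapping, summary = group_patterns(pats, Thresholds())
        assert set(mapping) == {"u---", "----"}
        flags = summary.set_index("category").shown_in_report
        assert not flags["u---"] and flags["----"]
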