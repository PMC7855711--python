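"""miRNA selection, evidence merging, target expansion and axis assembly."""

import numpy as np
import pandas as pd
import pytest

from cernax.cerna_axes import (AnnotatedMirna, AxisThresholds, assemble_axes,
                               expand_validated_targets, filter_oncomirs,
                               merge_mirna_evidence, select_negative_mirnas)
from cernax.datatypes import CorrelationRecord, InteractionTable

from .conftest import make_dataset


def _table(kind, rows, annotation=""):
    return InteractionTable(kind=kind, rows=pd.DataFrame(
        [{"id_a": a, "id_b": b, "source_db": s, "annotation": ann}
         for a, b, s, ann in rows]))


def _corr(a, b, r, p, ds="REF", n=120):
    return CorrelationRecord(dataset_id=ds, feature_a=a, feature_b=b, r=r, p=p, n=n)


class TestSelectNegativeMirnas:
    def test_antagonistic_mirna_selected(self):
        rng = np.random.default_rng(3)
        lnc = rng.normal(size=100)
        mir = -lnc + rng.normal(0, 0.3, size=100)
        ds = make_dataset(np.vstack([lnc, mir]), ["LNC1", "miR-1"],
                          [f"S{i}" for i in range(100)],
                          biotypes={"LNC1": "lncRNA", "miR-1": "miRNA"})
        recs = select_negative_mirnas("LNC1", ds)
        assert [r.feature_b for r in recs] == ["miR-1"]
        assert recs[0].r < 0

    def test_positively_correlated_mirna_never_selected(self):
        rng = np.random.default_rng(4)
        lnc = rng.normal(size=50)
        ds = make_dataset(np.vstack([lnc, lnc]), ["LNC1", "miR-1"],
                          [f"S{i}" for i in range(50)],
                          biotypes={"LNC1": "lncRNA", "miR-1": "miRNA"})
        assert select_negative_mirnas("LNC1", ds, alpha=1.0) == []

    def test_independent_mirna_selected_at_half_alpha_rate(self):
        # negative sign + two-sided p <= alpha happens with prob ~ alpha/2
        rng = np.random.default_rng(55)
        alpha = 0.05
        hits = 0
        n_rep = 2000
        lncs = rng.normal(size=(n_rep, 100))
        mirs = rng.normal(size=(n_rep, 100))
        for i in range(n_rep):
            ds = make_dataset(np.vstack([lncs[i], mirs[i]]), ["L", "miR-x"],
                              [f"S{j}" for j in range(100)],
                              biotypes={"L": "lncRNA", "miR-x": "miRNA"})
            hits += bool(select_negative_mirnas("L", ds, alpha=alpha))
        rate = hits / n_rep
        assert abs(rate - alpha / 2) < 3 * np.sqrt(alpha / 2 * (1 - alpha / 2) / n_rep)

    def test_unmeasured_lncrna_raises(self, small_dataset):
        with pytest.raises(KeyError):
            select_negative_mirnas("NOPE", small_dataset)


class TestMergeEvidence:
    def test_union_with_channel_flags(self):
        corr = [_corr("LNC1", "miR-1", -0.4, 1e-5)]
        binding = _table("lncrna_mirna_binding",
                         [("LNC1", "miR-1", "db", ""), ("LNC1", "miR-2", "db", ""),
                          ("OTHER", "miR-3", "db", "")])
        merged = merge_mirna_evidence(corr, binding, "LNC1")
        assert set(merged) == {"mir-1", "mir-2"}  # miR-3 binds a different lncRNA
        assert merged["mir-1"].correlation_selected and merged["mir-1"].binding_predicted
        assert not merged["mir-2"].correlation_selected and merged["mir-2"].binding_predicted

    def test_empty_binding_table_is_union_identity(self):
        corr = [_corr("LNC1", "miR-1", -0.4, 1e-5)]
        binding = InteractionTable("lncrna_mirna_binding", pd.DataFrame(
            columns=["id_a", "id_b", "source_db", "annotation"]))
        merged = merge_mirna_evidence(corr, binding, "LNC1")
        assert set(merged) == {"mir-1"}

    def test_case_insensitive_identifier_match(self):
        corr = [_corr("LNC1", "MIR-1", -0.4, 1e-5)]
        binding = _table("lncrna_mirna_binding", [("lnc1", "miR-1", "db", "")])
        merged = merge_mirna_evidence(corr, binding, "LNC1")
        assert len(merged) == 1 and merged["mir-1"].binding_predicted


class TestExpandTargets:
    def test_mirnas_without_targets_excluded(self):
        mirnas = {m.lower(): AnnotatedMirna(mirna_id=m, binding_predicted=True)
                  for m in ["miR-4464", "miR-4660", "miR-4743-3p", "miR-7978", "miR-30a-5p"]}
        targets = _table("mirna_mrna_validated", [("miR-30a-5p", "DSP", "db", "")])
        kept, excluded = expand_validated_targets(mirnas, targets)
        assert excluded == ["miR-4464", "miR-4660", "miR-4743-3p", "miR-7978"]
        assert set(kept) == {"mir-30a-5p"}
        assert kept["mir-30a-5p"].targets == {"DSP"}

    def test_targets_deduplicated_across_sources(self):
        mirnas = {"mir-1": AnnotatedMirna(mirna_id="miR-1", binding_predicted=True)}
        targets = _table("mirna_mrna_validated",
                         [("miR-1", "A", "db1", ""), ("miR-1", "A", "db2", ""),
                          ("miR-1", "B", "db1", "")])
        kept, _ = expand_validated_targets(mirnas, targets)
        assert kept["mir-1"].targets == {"A", "B"}

    def test_empty_input(self):
        targets = _table("mirna_mrna_validated", [("miR-1", "A", "db", "")])
        kept, excluded = expand_validated_targets({}, targets)
        assert kept == {} and excluded == []


class TestFilterOncomirs:
    def test_disease_annotation_retained_with_direction(self):
        mirnas = {"mir-30a-5p": AnnotatedMirna(mirna_id="miR-30a-5p")}
        cancer = _table("mirna_cancer", [("miR-30a-5p", "CRC", "db", "Downregulated")])
        kept = filter_oncomirs(mirnas, cancer, "CRC")
        assert kept["mir-30a-5p"].cancer_directions == ("Downregulated",)

    def test_other_disease_dropped(self):
        mirnas = {"mir-1": AnnotatedMirna(mirna_id="miR-1")}
        cancer = _table("mirna_cancer", [("miR-1", "glioma", "db", "Upregulated")])
        assert filter_oncomirs(mirnas, cancer, "CRC") == {}

    def test_conflicting_directions_both_reported(self):
        mirnas = {"mir-1": AnnotatedMirna(mirna_id="miR-1")}
        cancer = _table("mirna_cancer",
                        [("miR-1", "CRC", "db1", "Upregulated"),
                         ("miR-1", "CRC", "db2", "Downregulated")])
        kept = filter_oncomirs(mirnas, cancer, "CRC")
        assert set(kept["mir-1"].cancer_directions) == {"Upregulated", "Downregulated"}


def _published_row_mirnas():
    """Annotated miRNAs mirroring two published axis rows: one with the
    full negative sign pattern, one whose miRNA-mRNA correlation is
    positive (emitted only leniently)."""
    m30 = AnnotatedMirna(
        mirna_id="miR-30a-5p", correlation_selected=True, binding_predicted=True,
        correlation=_corr("LINC00483", "miR-30a-5p", -0.25, 1e-4),
        cancer_directions=("Downregulated",), targets=frozenset({"DSP"}),
    )
    m544 = AnnotatedMirna(
        mirna_id="miR-544a", correlation_selected=True, binding_predicted=True,
        correlation=_corr("LINC00483", "miR-544a", -0.2, 5e-4),
        cancer_directions=("Upregulated",), targets=frozenset({"CD9"}),
    )
    lnc_mrna = [_corr("LINC00483", "DSP", 0.406, 2.68e-12),
                _corr("LINC00483", "CD9", 0.391, 1.89e-10)]
    mirna_mrna = [_corr("miR-30a-5p", "DSP", -0.11, 2.00e-2),
                  _corr("miR-544a", "CD9", 0.014, 7.73e-1)]
    return {"mir-30a-5p": m30, "mir-544a": m544}, lnc_mrna, mirna_mrna


class TestAssembleAxes:
    def test_negative_pattern_row_is_strict_pass(self):
        mirnas, lnc_mrna, mirna_mrna = _published_row_mirnas()
        axes = assemble_axes("LINC00483", mirnas, lnc_mrna, mirna_mrna, strict=True)
        assert [(a.mirna_id, a.mrna_id) for a in axes] == [("miR-30a-5p", "DSP")]
        assert axes[0].strict_pass
        assert axes[0].r_mirna_mrna == pytest.approx(-0.11)
        assert axes[0].r_lnc_mrna == pytest.approx(0.406)

    def test_positive_mirna_mrna_row_emitted_only_leniently(self):
        mirnas, lnc_mrna, mirna_mrna = _published_row_mirnas()
        lenient = assemble_axes("LINC00483", mirnas, lnc_mrna, mirna_mrna, strict=False)
        pairs = {(a.mirna_id, a.mrna_id): a for a in lenient}
        assert ("miR-544a", "CD9") in pairs
        assert not pairs[("miR-544a", "CD9")].strict_pass

    def test_strict_subset_of_lenient(self):
        mirnas, lnc_mrna, mirna_mrna = _published_row_mirnas()
        strict = assemble_axes("LINC00483", mirnas, lnc_mrna, mirna_mrna, strict=True)
        lenient = assemble_axes("LINC00483", mirnas, lnc_mrna, mirna_mrna, strict=False)
        strict_pairs = {(a.mirna_id, a.mrna_id) for a in strict}
        lenient_pairs = {(a.mirna_id, a.mrna_id) for a in lenient}
        assert strict_pairs <= lenient_pairs

    def test_no_strict_pass_axis_has_nonnegative_mirna_mrna_r(self):
        mirnas, lnc_mrna, mirna_mrna = _published_row_mirnas()
        axes = assemble_axes("LINC00483", mirnas, lnc_mrna, mirna_mrna, strict=False)
        assert not any(a.strict_pass and a.r_mirna_mrna >= 0 for a in axes)

    def test_mrna_outside_target_sets_never_forms_axis(self):
        mirnas, lnc_mrna, mirna_mrna = _published_row_mirnas()
        lnc_mrna.append(_corr("LINC00483", "NOTARGET", 0.9, 1e-20))
        axes = assemble_axes("LINC00483", mirnas, lnc_mrna, mirna_mrna)
        assert not any(a.mrna_id == "NOTARGET" for a in axes)

    def test_missing_mirna_mrna_record_skips_axis(self):
        mirnas, lnc_mrna, _ = _published_row_mirnas()
        axes = assemble_axes("LINC00483", mirnas, lnc_mrna, [])
        assert axes == []

    def test_ranked_by_descending_lnc_mrna_r(self):
        mirnas, lnc_mrna, mirna_mrna = _published_row_mirnas()
        axes = assemble_axes("LINC00483", mirnas, lnc_mrna, mirna_mrna)
        rs = [a.r_lnc_mrna for a in axes]
        assert rs == sorted(rs, reverse=True)

    def test_top_k_filter(self):
        mirnas, lnc_mrna, mirna_mrna = _published_row_mirnas()
        axes = assemble_axes("LINC00483", mirnas, lnc_mrna, mirna_mrna,
                             thresholds=AxisThresholds(top_k_mrnas=1))
        assert {a.mrna_id for a in axes} == {"DSP"}  # highest lnc-mRNA r
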