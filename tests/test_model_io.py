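"""Domain types, TSV readers/writers, assembly, and the ranked report."""

import numpy as np
import pandas as pd
import pytest

from fusionchip import (
    AssemblyError,
    FormatError,
    FusionCandidate,
    IntensityTable,
    MissingProbeError,
    ProbeAnnotation,
    ProbeType,
    ScoringParams,
    TranscriptVariant,
    ValidationError,
    assemble,
    build_annotations,
    load_annotations,
    load_intensities,
    load_panel,
    sarcoma_panel,
    score_sample,
    toy_panel,
    write_annotations,
    write_intensities,
    write_panel,
    write_report,
)
from fusionchip.simulate import intensities_from_log2_offsets
from fusionchip.panels import chimeric_probe_id


class TestDomainTypes:
    def test_variant_generates_1based_exon_ids(self):
        v = TranscriptVariant("EWSR1", "v1", 3)
        assert v.exon_ids == ("1", "2", "3")

    def test_variant_rejects_bad_exon_lists(self):
        with pytest.raises(ValidationError):
            TranscriptVariant("G", "v1", 0)
        with pytest.raises(ValidationError):
            TranscriptVariant("G", "v1", 2, ("1", "1"))

    def test_candidate_rejects_self_fusion(self):
        v = TranscriptVariant("G", "v1", 3)
        with pytest.raises(ValidationError):
            FusionCandidate("G-G", ((v, v),))

    def test_chimeric_annotation_needs_both_exons(self):
        with pytest.raises(ValidationError):
            ProbeAnnotation("p", "F", ProbeType.CHIMERIC, "A::B", "v1::v1", exon_a=1)

    def test_intragenic_annotation_needs_exactly_one_exon(self):
        with pytest.raises(ValidationError):
            ProbeAnnotation("p", "F", ProbeType.INTRAGENIC, "A", "v1", exon_a=1, exon_b=2)
        with pytest.raises(ValidationError):
            ProbeAnnotation("p", "F", ProbeType.INTRAGENIC, "A", "v1")

    def test_negative_intensities_rejected(self):
        with pytest.raises(ValidationError):
            IntensityTable("s", {"p": -5.0})

    def test_scoring_params_invariants(self):
        with pytest.raises(ValidationError):
            ScoringParams(halfbinder_level_weak=0.8, halfbinder_level_strong=0.7)
        with pytest.raises(ValidationError):
            ScoringParams(adjusted_to_max=2.0)  # below the chimeric cutoff


class TestPanelIO:
    def test_toy_panel_round_trip(self, tmp_path, toy):
        panel, _ = toy
        p = tmp_path / "panel.tsv"
        write_panel(panel, p)
        loaded = load_panel(p)
        assert loaded == panel
        assert len(loaded) == 3

    def test_sarcoma_panel_has_38_candidates(self, tmp_path):
        panel = sarcoma_panel()
        p = tmp_path / "panel.tsv"
        write_panel(panel, p)
        assert len(load_panel(p)) == 38

    def test_duplicate_row_is_error(self, tmp_path):
        p = tmp_path / "panel.tsv"
        row = "F1\tGA\tv1\t4\tGB\tv1\t5"
        p.write_text("fusion_id\tgene_a\tvariant_a\tn_exons_a\tgene_b\tvariant_b\tn_exons_b\n" + row + "\n" + row + "\n")
        with pytest.raises(FormatError, match="duplicate"):
            load_panel(p)

    def test_same_fusion_with_distinct_variant_pairs_aggregates(self, tmp_path):
        p = tmp_path / "panel.tsv"
        p.write_text(
            "fusion_id\tgene_a\tvariant_a\tn_exons_a\tgene_b\tvariant_b\tn_exons_b\n"
            "F1\tGA\tv1\t4\tGB\tv1\t5\n"
            "F1\tGA\tv2\t3\tGB\tv1\t5\n"
        )
        (cand,) = load_panel(p)
        assert len(cand.variant_pairs) == 2

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "panel.tsv"
        p.write_text("fusion_id\tgene_a\n" "F1\tGA\n")
        with pytest.raises(FormatError, match="missing required column"):
            load_panel(p)


class TestAnnotationIO:
    def test_round_trip(self, tmp_path, toy):
        _, ann = toy
        p = tmp_path / "ann.tsv"
        write_annotations(ann, p)
        assert load_annotations(p) == ann

    def test_duplicate_annotation_rejected(self, tmp_path, toy):
        _, ann = toy
        p = tmp_path / "ann.tsv"
        write_annotations(list(ann) + [ann[0]], p)
        with pytest.raises(ValidationError, match="duplicate"):
            load_annotations(p)


class TestIntensityIO:
    @staticmethod
    def _write(tmp_path, pairs):
        p = tmp_path / "s.tsv"
        p.write_text("probe_id\tintensity\n" + "".join(f"{k}\t{v}\n" for k, v in pairs))
        return p

    def test_all_probes_present(self, tmp_path):
        ann = [
            ProbeAnnotation(f"p{i}", "F", ProbeType.INTRAGENIC, "A", "v1", exon_a=i + 1)
            for i in range(10)
        ]
        p = self._write(tmp_path, [(f"p{i}", 100 + i) for i in range(10)])
        t = load_intensities(p, ann)
        assert len(t) == 10 and t.values["p3"] == 103.0

    def test_missing_probe_named_in_error(self, tmp_path):
        ann = [ProbeAnnotation("present", "F", ProbeType.INTRAGENIC, "A", "v1", exon_a=1),
               ProbeAnnotation("absent", "F", ProbeType.INTRAGENIC, "A", "v1", exon_a=2)]
        p = self._write(tmp_path, [("present", 5.0)])
        with pytest.raises(MissingProbeError, match="absent"):
            load_intensities(p, ann)

    def test_negative_intensity_rejected(self, tmp_path):
        ann = [ProbeAnnotation("p0", "F", ProbeType.INTRAGENIC, "A", "v1", exon_a=1)]
        p = self._write(tmp_path, [("p0", -5)])
        with pytest.raises(ValidationError, match="negative"):
            load_intensities(p, ann)

    def test_round_trip(self, tmp_path, toy):
        panel, ann = toy
        t = intensities_from_log2_offsets(ann, {}, sample_id="s")
        p = tmp_path / "s.tsv"
        write_intensities(t, p)
        assert load_intensities(p, ann, sample_id="s") == t


@pytest.fixture(scope="module")
def big_pair():
    panel = [
        FusionCandidate(
            "GA-GB", ((TranscriptVariant("GA", "v1", 13), TranscriptVariant("GB", "v1", 10)),)
        )
    ]
    return panel, build_annotations(panel)


class TestAssemble:
    def test_heatmap_shape_and_profile_lengths(self, big_pair):
        panel, ann = big_pair
        t = intensities_from_log2_offsets(ann, {})
        hm, pa, pb = assemble(t, ann, panel[0])
        assert hm.matrix.shape == (13, 10)
        assert pa.n_exons == 13 and pb.n_exons == 10

    def test_cell_13_3_holds_probe_joining_exon13_to_exon3(self, big_pair):
        panel, ann = big_pair
        va, vb = panel[0].variant_pairs[0]
        pid = chimeric_probe_id(va, vb, 13, 3)
        t = intensities_from_log2_offsets(ann, {pid: 5.0})
        hm, _, _ = assemble(t, ann, panel[0])
        assert hm.matrix[12, 2] == hm.matrix.max() > 4.5
        assert np.count_nonzero(hm.matrix > 1.0) == 1

    def test_every_cell_filled_exactly_once(self, big_pair):
        panel, ann = big_pair
        rng = np.random.default_rng(3)
        offsets = {a.probe_id: float(rng.uniform(0.5, 4)) for a in ann}
        t = intensities_from_log2_offsets(ann, offsets)
        hm, _, _ = assemble(t, ann, panel[0])
        assert np.all(np.isfinite(hm.matrix))

    def test_missing_combination_is_assembly_error(self, big_pair):
        panel, ann = big_pair
        va, vb = panel[0].variant_pairs[0]
        drop = chimeric_probe_id(va, vb, 7, 7)
        pruned = [a for a in ann if a.probe_id != drop]
        t = intensities_from_log2_offsets(pruned, {})
        with pytest.raises(AssemblyError, match="missing"):
            assemble(t, pruned, panel[0])


class TestReport:
    def test_full_panel_report_has_ranked_rows(self, tmp_path):
        panel = sarcoma_panel()
        ann = build_annotations(panel)
        t = intensities_from_log2_offsets(ann, {})
        ranked = score_sample(t, ann, panel)
        p = tmp_path / "report.tsv"
        write_report(ranked, p)
        df = pd.read_csv(p, sep="\t")
        assert len(df) == 38
        assert df["rank"].tolist() == list(range(1, 39))

    def test_empty_results_header_only(self, tmp_path):
        p = tmp_path / "report.tsv"
        write_report([], p)
        assert p.read_text().strip() == "rank\tfusion_id\tfusion_score\texon_a\texon_b\tchimeric_value\tbreak_score_a\tbreak_score_b\ttags"

    def test_rerun_is_byte_identical(self, tmp_path, toy):
        panel, ann = toy
        t = intensities_from_log2_offsets(ann, {"g|AAA.v1.e1": 2.0})
        ranked = score_sample(t, ann, panel)
        p1, p2 = tmp_path / "r1.tsv", tmp_path / "r2.tsv"
        write_report(ranked, p1)
        write_report(score_sample(t, ann, panel), p2)
        assert p1.read_bytes() == p2.read_bytes()
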