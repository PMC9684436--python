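"""QTY conversion: substitution rule, locality, idempotence, stats, rendering."""

import pytest

from qtyshift import (
    ProteinRecord,
    QtyCodeMap,
    qty_convert,
    render_alignment,
    variation_stats,
)
from qtyshift.errors import (
    AlphabetError,
    AnnotationError,
    ComparisonError,
    ParameterError,
)
from qtyshift.qty import CHARGED_RESIDUES, read_tm_intervals, round2


class TestQtyConvert:
    def test_livf_inside_tm_becomes_qtty(self):
        rec = ProteinRecord(id="t", sequence="LIVF", tm_segments=((1, 4),))
        res = qty_convert(rec)
        assert res.variant_sequence == "QTTY"
        assert res.substitutions == ((1, "L", "Q"), (2, "I", "T"), (3, "V", "T"), (4, "F", "Y"))
        assert res.stats.tm_variation_pct == 100.0

    def test_no_tm_segments_no_substitution(self):
        res = qty_convert(ProteinRecord(id="t", sequence="LIVF"))
        assert res.variant_sequence == "LIVF"
        assert res.stats.overall_variation_pct == 0.0

    def test_substitutions_respect_segment_boundaries(self):
        rec = ProteinRecord(id="t", sequence="LLLLLLLLLL", tm_segments=((3, 5), (8, 9)))
        res = qty_convert(rec)
        assert res.variant_sequence == "LLQQQLLQQL"

    def test_x_passes_through(self):
        rec = ProteinRecord(id="t", sequence="LXVF", tm_segments=((1, 4),))
        assert qty_convert(rec).variant_sequence == "QXTY"

    def test_idempotent_on_synthetic_records(self, synthetic_records):
        for rec in synthetic_records:
            once = qty_convert(rec)
            variant_rec = once.variant_record
            twice = qty_convert(variant_rec)
            assert twice.variant_sequence == once.variant_sequence
            assert twice.substitutions == ()

    def test_locality_and_length_on_synthetic_records(self, synthetic_records):
        for rec in synthetic_records:
            res = qty_convert(rec)
            assert len(res.variant_sequence) == len(rec.sequence)
            mask = rec.tm_mask
            for i, (a, b) in enumerate(zip(rec.sequence, res.variant_sequence)):
                if a != b:
                    assert mask[i], f"substitution outside TM at {i + 1}"

    def test_charged_residue_counts_conserved(self, synthetic_records):
        # the code never touches D/E/K/R/H, the basis of pI stability
        for rec in synthetic_records:
            res = qty_convert(rec)
            for aa in CHARGED_RESIDUES:
                assert rec.sequence.count(aa) == res.variant_sequence.count(aa)

    def test_non_idempotent_code_map_rejected(self):
        with pytest.raises(AnnotationError):
            QtyCodeMap(mapping={"L": "Q", "Q": "E"})

    def test_interval_out_of_bounds_rejected(self):
        with pytest.raises(AnnotationError):
            ProteinRecord(id="t", sequence="LIVF", tm_segments=((1, 5),))
        with pytest.raises(AnnotationError):
            ProteinRecord(id="t", sequence="LIVFLIVF", tm_segments=((1, 4), (3, 6)))

    def test_unknown_letter_rejected(self):
        with pytest.raises(AlphabetError):
            ProteinRecord(id="t", sequence="LIVZ")


class TestVariationStats:
    def test_direct_count(self):
        # 20 residues, TM covers 10, 5 of them LIVF
        rec = ProteinRecord(
            id="t", sequence="GGGGGLLIVFAGSTMGGGGG", tm_segments=((6, 15),)
        )
        res = qty_convert(rec)
        assert res.stats.tm_substituted == 5
        assert res.stats.tm_variation_pct == pytest.approx(50.0)
        assert res.stats.overall_variation_pct == pytest.approx(25.0)

    def test_identical_variant_zero_percent(self):
        rec = ProteinRecord(id="t", sequence="GGGGG", tm_segments=((2, 4),))
        stats = variation_stats(rec, "GGGGG")
        assert stats.tm_variation_pct == 0.0
        assert stats.overall_variation_pct == 0.0

    def test_overall_never_exceeds_tm_variation(self, synthetic_records):
        for rec in synthetic_records:
            s = qty_convert(rec).stats
            if s.tm_residues:
                assert 0.0 <= s.overall_variation_pct <= s.tm_variation_pct <= 100.0

    def test_length_mismatch_rejected(self):
        rec = ProteinRecord(id="t", sequence="GGG")
        with pytest.raises(ComparisonError):
            variation_stats(rec, "GG")

    def test_agrees_with_ledger(self, synthetic_records):
        for rec in synthetic_records[:10]:
            res = qty_convert(rec)
            recount = variation_stats(rec, res.variant_sequence)
            assert recount.tm_substituted == len(res.substitutions)

    def test_half_up_rounding(self):
        assert round2(50.785) == 50.79
        assert round2(25.545) == 25.55


class TestRenderAlignment:
    def test_all_different_marker_row(self):
        rec = ProteinRecord(id="t", sequence="LIVFGGGGGG", tm_segments=((1, 4),))
        text = render_alignment(rec, "QTTYGGGGGG")
        lines = text.splitlines()
        assert "****||||||" in lines[2]

    def test_identical_sequences_all_pipes(self):
        rec = ProteinRecord(id="t", sequence="GAVLIKRSTN")
        text = render_alignment(rec, "GAVLIKRSTN")
        assert "||||||||||" in text

    def test_mixed_marker(self):
        rec = ProteinRecord(id="t", sequence="LGLGLGLGLG", tm_segments=((1, 2),))
        text = render_alignment(rec, "QGLGLGLGLG")
        assert "*|||||||||" in text

    def test_blocks_respect_line_width(self):
        rec = ProteinRecord(id="t", sequence="G" * 130)
        text = render_alignment(rec, "G" * 130, line_width=50)
        seq_lines = [ln for ln in text.splitlines() if ln.startswith("t ")]
        assert [len(ln.split()[-1]) for ln in seq_lines] == [50, 50, 30]

    def test_tm_span_annotation_line(self):
        rec = ProteinRecord(id="t", sequence="GGLLLLGGGG", tm_segments=((3, 6),))
        first = render_alignment(rec, "GGQQQQGGGG").splitlines()[0]
        assert first == "TM        HHHH"

    def test_narrow_width_rejected(self):
        rec = ProteinRecord(id="t", sequence="GGGG")
        with pytest.raises(ParameterError):
            render_alignment(rec, "GGGG", line_width=5)


class TestTmIntervalParsing:
    def test_tsv_and_gff_mixed(self, tmp_path):
        p = tmp_path / "tm.txt"
        p.write_text(
            "# comment\n"
            "P11166\tUniProtKB\tTransmembrane\t12\t33\t.\t.\t.\tNote=Helical\n"
            "myid\t5\t25\n"
            "myid\t40\t60\n"
        )
        table = read_tm_intervals(p)
        assert table["P11166"] == [(12, 33)]
        assert table["myid"] == [(5, 25), (40, 60)]
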