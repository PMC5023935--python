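"""Transcript geometry: region classification, HGVS conversion, GC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varconcord.gene_models import (
    CODING,
    INTRONIC_DEEP,
    INTRONIC_NEAR,
    OUTSIDE_TRANSCRIPT,
    UTR,
    GeneModel,
    GeneModelError,
    HgvsParseError,
    HgvsRangeError,
    classify_position,
    gc_content,
    genomic_to_hgvs_c,
    hgvs_c_to_genomic,
    read_gene_models_bed12,
    read_gene_models_tsv,
    region_stratum,
    reverse_complement,
    write_gene_models_tsv,
)

from _oracles import brute_c_to_g_map, brute_region
from conftest import random_model


class TestModelValidation:
    def test_rejects_structural_defects(self):
        with pytest.raises(GeneModelError):
            GeneModel("G", "c", "+", exons=())
        with pytest.raises(GeneModelError):
            GeneModel("G", "c", "+", exons=((10, 5),))
        with pytest.raises(GeneModelError):
            GeneModel("G", "c", "+", exons=((10, 30), (20, 40)))
        with pytest.raises(GeneModelError):
            GeneModel("G", "c", "*", exons=((10, 30),))
        with pytest.raises(GeneModelError):
            GeneModel("G", "c", "+", exons=((10, 30),), cds_start=5, cds_end=20)

    def test_footprint_is_padded_exon_union(self):
        m = GeneModel("G", "c", "+", exons=((30, 60), (70, 100)), flank_pad=20)
        # pads overlap across the short intron, so the footprint merges
        assert m.footprint() == [(10, 120)]
        assert m.footprint_bases() == 110
        # clipping at zero keeps coordinates non-negative
        m2 = GeneModel("G", "c", "+", exons=((5, 30),), flank_pad=20)
        assert m2.footprint() == [(0, 50)]


class TestClassifyPosition:
    def test_far_upstream_position(self):
        m = GeneModel("G", "c", "+", exons=((500, 650), (900, 1050)),
                      cds_start=530, cds_end=1020)
        label = classify_position(m, 500 - 176 + 1)  # 176 bp upstream of exon 1
        assert label.category == OUTSIDE_TRANSCRIPT
        assert label.distance_to_exon == 176
        assert region_stratum(label) == INTRONIC_DEEP

    def test_exon_first_base_in_cds_is_coding(self):
        m = GeneModel("G", "c", "+", exons=((100, 200),), cds_start=100,
                      cds_end=200)
        label = classify_position(m, 101)  # 1-based first exon base
        assert (label.category, label.distance_to_exon) == (CODING, 0)

    def test_single_exon_gene_scan(self):
        # brute-force distance scan over every position around the gene
        m = GeneModel("G", "c", "+", exons=((100, 200),), cds_start=100,
                      cds_end=200)
        assert classify_position(m, 130).category == CODING
        label = classify_position(m, 221)
        assert label.category == OUTSIDE_TRANSCRIPT
        assert label.distance_to_exon == 21
        assert region_stratum(label) == INTRONIC_DEEP
        for pos in range(90, 231):
            got = classify_position(m, pos)
            assert (got.category, got.distance_to_exon) == brute_region(m, pos)

    def test_utr_and_intron_bins(self, plus_model):
        assert classify_position(plus_model, 105).category == UTR
        assert region_stratum(classify_position(plus_model, 105)) == INTRONIC_NEAR
        # first intronic base after exon 1 ends at 160 (0-based open)
        lab = classify_position(plus_model, 161)
        assert (lab.category, lab.distance_to_exon) == (INTRONIC_NEAR, 1)
        assert classify_position(plus_model, 180).category == INTRONIC_NEAR
        assert classify_position(plus_model, 181).category == INTRONIC_DEEP
        # approaching the downstream exon the distance falls again
        assert classify_position(plus_model, 220).category == INTRONIC_NEAR

    def test_partition_matches_brute_force_on_fuzzed_models(self, rng):
        categories = {CODING, UTR, INTRONIC_NEAR, INTRONIC_DEEP,
                      OUTSIDE_TRANSCRIPT}
        for _ in range(25):
            m = random_model(rng)
            for pos in range(1, m.tx_end + 40):
                got = classify_position(m, pos)
                assert got.category in categories
                assert (got.category, got.distance_to_exon) == brute_region(m, pos)


class TestHgvsConversion:
    def test_first_coding_base_plus_strand(self):
        m = GeneModel("G", "c", "+", exons=((100, 200),), cds_start=120,
                      cds_end=180)
        assert hgvs_c_to_genomic(m, "c.1") == 121  # 1-based of 0-based 120

    def test_intron_offset_from_exon_end(self, plus_model):
        # last coding base of exon 1 is 0-based 159 -> c.50; +1 steps into
        # the intron's first base (0-based 160, 1-based 161)
        assert hgvs_c_to_genomic(plus_model, "c.50+1") == 161
        assert hgvs_c_to_genomic(plus_model, "c.51-1") == 220

    def test_utr_numbering(self, plus_model):
        assert hgvs_c_to_genomic(plus_model, "c.-1") == 110
        assert hgvs_c_to_genomic(plus_model, "c.-10") == 101
        # beyond the transcript start the numbering continues upstream
        assert hgvs_c_to_genomic(plus_model, "c.-30") == 81
        assert hgvs_c_to_genomic(plus_model, "c.*1") == 281
        assert hgvs_c_to_genomic(plus_model, "c.*25") == 305

    def test_errors(self, plus_model):
        with pytest.raises(HgvsParseError):
            hgvs_c_to_genomic(plus_model, "g.100A>T")
        with pytest.raises(HgvsParseError):
            hgvs_c_to_genomic(plus_model, "c.0")
        with pytest.raises(HgvsRangeError):
            hgvs_c_to_genomic(plus_model, "c.9999")
        noncoding = GeneModel("N", "c", "+", exons=((10, 50),))
        with pytest.raises(HgvsParseError):
            hgvs_c_to_genomic(noncoding, "c.1")

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_exhaustive_map_on_two_exon_transcript(self, strand, plus_model,
                                                   minus_model):
        model = plus_model if strand == "+" else minus_model
        for cstr, g in brute_c_to_g_map(model).items():
            assert hgvs_c_to_genomic(model, cstr) == g, cstr

    def test_round_trip_identity_on_fuzzed_transcripts(self, rng):
        for _ in range(20):
            m = random_model(rng)
            for pos in range(max(1, m.tx_start - 30), m.tx_end + 31):
                cstr = genomic_to_hgvs_c(m, pos)
                assert hgvs_c_to_genomic(m, cstr) == pos, (m, pos, cstr)


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GGCC", 1.0), ("ATAT", 0.0), ("GCAT", 0.5), ("GCATNN", 0.5)],
    )
    def test_examples(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_degenerate_inputs(self):
        for bad in ("", "NNN", "GCXT"):
            with pytest.raises(ValueError):
                gc_content(bad)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=1).filter(lambda s: set(s) != {"N"}))
    def test_invariant_under_reversal_and_complement(self, seq):
        assert gc_content(seq) == pytest.approx(gc_content(seq[::-1]))
        assert gc_content(seq) == pytest.approx(gc_content(reverse_complement(seq)))


class TestModelFiles:
    def test_tsv_round_trip(self, tmp_path, plus_model, minus_model):
        path = tmp_path / "genes.tsv"
        models = {m.gene_name: m for m in (plus_model, minus_model)}
        write_gene_models_tsv(models, path)
        assert read_gene_models_tsv(path) == models

    def test_bed12_matches_tsv_dialect(self, tmp_path, plus_model):
        bed = tmp_path / "genes.bed"
        m = plus_model
        sizes = ",".join(str(e - s) for s, e in m.exons)
        offsets = ",".join(str(s - m.tx_start) for s, _ in m.exons)
        bed.write_text(
            f"{m.chrom}\t{m.tx_start}\t{m.tx_end}\t{m.gene_name}\t0\t{m.strand}"
            f"\t{m.cds_start}\t{m.cds_end}\t0\t{len(m.exons)}\t{sizes}\t{offsets}\n"
        )
        assert read_gene_models_bed12(bed) == {m.gene_name: m}

    def test_missing_column_is_named(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("gene\tchrom\tstrand\n")
        with pytest.raises(GeneModelError, match="exon_starts"):
            read_gene_models_tsv(p)
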