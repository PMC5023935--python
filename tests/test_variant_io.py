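"""Truth-table and VCF I/O, and allele normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varconcord.gene_models import GeneModel
from varconcord.variant_io import (
    HET,
    HOM,
    MISSING,
    CalledVariant,
    NormalizedAllele,
    ReferenceMismatchError,
    TruthTableError,
    normalize,
    read_truth_table,
    read_vcf,
    write_vcf,
)

from _oracles import apply_edit, equivalent_representations


class TestTruthTable:
    HEADER = "patient_id\tgene\tchrom\tpos\tref\talt\tzygosity\thgvs_c\n"

    def test_well_formed_rows(self, tmp_path):
        p = tmp_path / "truth.tsv"
        p.write_text(
            self.HEADER
            + "P1\tG1\tchr1\t100\tA\tG\thet\t\n"
            + "P1\tG1\tchr1\t200\tC\tCT\thom\t\n"
            + "P2\tG2\tchr2\t50\tGA\tG\thet\t\n"
        )
        records, rejects = read_truth_table(p)
        assert len(records) == 3 and rejects == []
        assert records[0].pos == 100 and records[1].zygosity == HOM

    def test_missing_column_is_named(self, tmp_path):
        p = tmp_path / "truth.tsv"
        p.write_text("patient_id\tgene\tchrom\tpos\tref\talt\n")
        with pytest.raises(TruthTableError, match="zygosity"):
            read_truth_table(p)

    def test_position_resolved_from_hgvs(self, tmp_path):
        model = GeneModel("TOY", "chrT", "+", exons=((100, 160), (220, 300)),
                          cds_start=110, cds_end=280)
        p = tmp_path / "truth.tsv"
        p.write_text(self.HEADER + "P1\tTOY\tchrT\t\tA\tG\thet\tc.50+9\n")
        records, rejects = read_truth_table(p, models={"TOY": model})
        assert rejects == []
        # c.50 is the last coding base of exon 1 (0-based 159); +9 -> 169
        assert records[0].pos == 169

    def test_bad_rows_become_rejects_not_drops(self, tmp_path):
        p = tmp_path / "truth.tsv"
        p.write_text(
            self.HEADER
            + "P1\tG1\tchr1\t100\tA\tG\thet\t\n"
            + "P1\tG1\tchr1\t\tA\tG\thet\t\n"  # no pos, no model
            + "P1\tG1\tchr1\t100\tA\tA\thet\t\n"  # ref == alt
        )
        records, rejects = read_truth_table(p)
        assert len(records) == 1
        assert len(rejects) == 2 and all("reason" in r for r in rejects)


class TestVcf:
    def _write_text_vcf(self, path, body):
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n" + body
        )

    def test_simple_het_with_depth(self, tmp_path):
        p = tmp_path / "a.vcf"
        self._write_text_vcf(p, "chr1\t100\t.\tA\tG\t.\t.\t.\tGT:DP\t0/1:42\n")
        sample, calls = read_vcf(p)
        assert sample == "S1"
        assert calls == [CalledVariant("chr1", 100, "A", "G", HET, 42, None)]

    def test_multiallelic_split_each_het(self, tmp_path):
        p = tmp_path / "a.vcf"
        self._write_text_vcf(p, "chr1\t100\t.\tA\tG,T\t.\t.\t.\tGT:DP\t1/2:30\n")
        _, calls = read_vcf(p)
        assert [(c.alt, c.zygosity) for c in calls] == [("G", HET), ("T", HET)]

    def test_missing_genotype_and_phased_het(self, tmp_path):
        p = tmp_path / "a.vcf"
        self._write_text_vcf(
            p,
            "chr1\t100\t.\tA\tG\t.\t.\t.\tGT:DP\t./.:10\n"
            "chr1\t200\t.\tC\tT\t.\t.\t.\tGT:DP\t0|1:20\n",
        )
        _, calls = read_vcf(p)
        assert calls[0].zygosity == MISSING
        assert calls[1].zygosity == HET

    def test_write_read_round_trip_preserves_normalized_alleles(self, tmp_path):
        reference = {"chr1": "GGACTTTTGCCAGTCA" * 10}
        calls = [
            CalledVariant("chr1", 12, "A", "T", HET, 33),
            CalledVariant("chr1", 4, "CTT", "C", HOM, 21),
            CalledVariant("chr1", 14, "T", "TGC", HET, 55),
        ]
        path = tmp_path / "rt.vcf"
        write_vcf(calls, "S1", path, {"chr1": len(reference["chr1"])})
        sample, back = read_vcf(path)
        assert sample == "S1"
        orig = {
            (normalize(c.chrom, c.pos, c.ref, c.alt, reference), c.zygosity,
             c.site_depth)
            for c in calls
        }
        rt = {
            (normalize(c.chrom, c.pos, c.ref, c.alt, reference), c.zygosity,
             c.site_depth)
            for c in back
        }
        assert orig == rt


class TestNormalize:
    REF = {"chr1": "GGACTTTTGCA"}

    def test_snv_unchanged(self):
        got = normalize("chr1", 3, "A", "G", self.REF)
        assert got == NormalizedAllele("chr1", 3, "A", "G")

    def test_padded_snv_is_trimmed(self):
        got = normalize("chr1", 3, "ACT", "AGT", self.REF)
        assert got == NormalizedAllele("chr1", 4, "C", "G")

    def test_homopolymer_deletion_left_aligned(self):
        # deleting two T's anywhere in the TTTT run is the same edit; every
        # written form must land on the leftmost anchored representation
        edited = apply_edit(self.REF["chr1"], 6, "TTT", "T")
        reps = equivalent_representations(self.REF["chr1"], edited)
        assert len(reps) > 3
        norms = {
            normalize("chr1", pos, ref, alt, self.REF) for pos, ref, alt in reps
        }
        assert norms == {NormalizedAllele("chr1", 4, "CTT", "C")}

    def test_reference_mismatch_raises(self):
        with pytest.raises(ReferenceMismatchError):
            normalize("chr1", 3, "T", "G", self.REF)
        with pytest.raises(ReferenceMismatchError):
            normalize("chrX", 3, "A", "G", self.REF)

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(st.data())
    def test_equivalence_classes_and_idempotence(self, data):
        # fuzz a 60 bp reference and a random indel/SNV in its interior;
        # all equivalent representations must normalize identically and
        # normalization must be a fixed point
        seq = data.draw(
            st.text(alphabet="ACGT", min_size=60, max_size=60), label="ref"
        )
        pos = data.draw(st.integers(min_value=10, max_value=45), label="pos")
        lr = data.draw(st.integers(min_value=1, max_value=4), label="len_ref")
        alt = data.draw(
            st.text(alphabet="ACGT", min_size=1, max_size=4), label="alt"
        )
        reference = {"c": seq}
        ref = seq[pos - 1 : pos - 1 + lr]
        if ref == alt:
            return
        edited = apply_edit(seq, pos, ref, alt)
        reps = equivalent_representations(seq, edited)
        assert (pos, ref, alt) in reps
        norms = {normalize("c", p, r, a, reference) for p, r, a in reps}
        assert len(norms) == 1
        n = norms.pop()
        again = normalize(n.chrom, n.pos, n.ref, n.alt, reference)
        assert again == n
        # minimality: no shared suffix (waived for an indel shifted to the
        # contig start, which keeps a right anchor instead), and a shared
        # leading base only as the single anchor of an indel
        assert n.ref != n.alt
        if n.pos > 1:
            assert n.ref[-1] != n.alt[-1]
        if n.ref[0] == n.alt[0]:
            assert min(len(n.ref), len(n.alt)) == 1
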