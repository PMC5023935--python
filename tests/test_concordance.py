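"""Matching, adjudication, rates and the stratified table."""

import numpy as np
import pytest

from varconcord.concordance import (
    BOTH_INCORRECT,
    CONCORDANT,
    DISCORDANT_BASE,
    DISCORDANT_ZYGOSITY,
    MISSING_STATUS,
    SANGER_CORRECT,
    UNRESOLVED,
    WES_CORRECT,
    adjudicate,
    build_call_index,
    concordance_table,
    match_all,
    match_variant,
    rate,
)
from varconcord.coverage_qc import DepthTrack
from varconcord.gene_models import GeneModel
from varconcord.variant_io import HET, HOM, CalledVariant, TruthVariant

from _oracles import quadratic_counts

REF = {"chrT": "".join("ACGT"[i % 4] for i in range(400))}
MODEL = GeneModel("TOY", "chrT", "+", exons=((100, 160), (220, 300)),
                  cds_start=110, cds_end=280)
TRACK = DepthTrack.from_intervals([("chrT", 80, 320, 45)])


def truth(pos, ref, alt, zyg=HET, patient="P1", gene="TOY"):
    return TruthVariant(patient, gene, "chrT", pos, ref, alt, zyg)


def call(pos, ref, alt, zyg=HET, dp=40):
    return CalledVariant("chrT", pos, ref, alt, zyg, dp)


def one_match(t, calls, track=TRACK, excluded=()):
    index = build_call_index({t.patient_id: calls}, REF)
    return match_variant(t, index[t.patient_id], track, REF, MODEL, excluded)


def base_at(pos):
    return REF["chrT"][pos - 1]


def alt_for(pos, avoid=""):
    return next(b for b in "ACGT" if b != base_at(pos) and b not in avoid)


class TestMatchVariant:
    def test_identical_call_is_concordant(self):
        pos, r = 130, base_at(130)
        a = alt_for(pos)
        rec = one_match(truth(pos, r, a), [call(pos, r, a)])
        assert rec.status == CONCORDANT
        assert rec.site_depth == 40 and not rec.low_depth
        assert rec.region.category == "coding"

    def test_same_allele_other_zygosity_is_discordant_zygosity(self):
        pos, r = 130, base_at(130)
        a = alt_for(pos)
        rec = one_match(truth(pos, r, a, zyg=HOM), [call(pos, r, a, zyg=HET)])
        assert rec.status == DISCORDANT_ZYGOSITY

    def test_absent_call_is_missing_with_track_depth(self):
        pos, r = 130, base_at(130)
        rec = one_match(truth(pos, r, alt_for(pos)), [])
        assert rec.status == MISSING_STATUS
        assert rec.site_depth == 45  # from the depth track
        assert not rec.low_depth

    def test_other_alternate_at_same_position_is_discordant_base(self):
        pos, r = 130, base_at(130)
        a = alt_for(pos)
        b = alt_for(pos, avoid=a)
        rec = one_match(truth(pos, r, a), [call(pos, r, b)])
        assert rec.status == DISCORDANT_BASE
        assert rec.matched_call.alt == b

    def test_indel_representations_match_through_normalization(self):
        # the same deletion written at two different anchors still matches
        seq = "GG" + "ACTTTTG" * 40
        ref2 = {"chrT": seq}
        track = DepthTrack.from_intervals([("chrT", 0, len(seq), 50)])
        t = TruthVariant("P1", "TOY", "chrT", 4, "CTT", "C", HET)
        c = CalledVariant("chrT", 6, "TTT", "T", HET, 50)
        index = build_call_index({"P1": [c]}, ref2)
        rec = match_variant(t, index["P1"], track, ref2, MODEL, ())
        assert rec.status == CONCORDANT

    def test_low_depth_flag_is_strictly_below_ten(self):
        pos, r = 130, base_at(130)
        a = alt_for(pos)
        assert one_match(truth(pos, r, a), [call(pos, r, a, dp=9)]).low_depth
        assert not one_match(truth(pos, r, a), [call(pos, r, a, dp=10)]).low_depth


class TestAdjudicate:
    def _confirm(self, t, allele, zyg=""):
        return {
            "patient_id": t.patient_id,
            "chrom": t.chrom,
            "pos": t.pos,
            "observed_ref": t.ref,
            "observed_allele": allele,
            "observed_zygosity": zyg,
        }

    def test_missing_with_reference_confirmation_is_wes_correct(self):
        pos, r = 130, base_at(130)
        t = truth(pos, r, alt_for(pos))
        rec = one_match(t, [])
        [adj] = adjudicate([rec], [self._confirm(t, r)])
        assert adj.resolution == WES_CORRECT

    def test_missing_with_variant_confirmation_is_sanger_correct(self):
        pos, r = 130, base_at(130)
        t = truth(pos, r, alt_for(pos))
        rec = one_match(t, [])
        [adj] = adjudicate([rec], [self._confirm(t, t.alt, HET)])
        assert adj.resolution == SANGER_CORRECT

    def test_discordant_base_matching_neither_is_both_incorrect(self):
        pos, r = 130, base_at(130)
        a = alt_for(pos)
        b = alt_for(pos, avoid=a)
        t = truth(pos, r, a)
        rec = one_match(t, [call(pos, r, b)])
        [adj] = adjudicate([rec], [self._confirm(t, r)])  # wild-type
        assert adj.resolution == BOTH_INCORRECT

    def test_zygosity_resolves_toward_confirmatory(self):
        pos, r = 130, base_at(130)
        a = alt_for(pos)
        t = truth(pos, r, a, zyg=HOM)
        rec = one_match(t, [call(pos, r, a, zyg=HET)])
        [adj] = adjudicate([rec], [self._confirm(t, a, HOM)])
        assert adj.resolution == SANGER_CORRECT
        [adj] = adjudicate([rec], [self._confirm(t, a, HET)])
        assert adj.resolution == WES_CORRECT

    def test_record_without_confirmatory_row_is_unresolved(self):
        pos, r = 130, base_at(130)
        rec = one_match(truth(pos, r, alt_for(pos)), [])
        [adj] = adjudicate([rec], [])
        assert adj.resolution == UNRESOLVED


class TestRate:
    @pytest.mark.parametrize(
        "num,den,expected",
        [
            (146, 150, 97.3),
            (48, 52, 92.3),
            (44, 58, 75.9),
            (90, 110, 81.8),
            (236, 260, 90.8),
            (79, 131, 60.3),
            (9, 51, 17.6),
            (3, 150, 2.0),
            (1, 150, 0.7),
            (0, 1, 0.0),
            (1, 16, 6.3),  # 6.25 rounds half-up
        ],
    )
    def test_half_up_percentages(self, num, den, expected):
        assert rate(num, den) == expected

    def test_empty_denominator(self):
        assert rate(0, 0) is None


class TestTable:
    def _cohort(self, rng, n=60, p_miss=0.2, p_flip=0.1, p_base=0.05):
        truths, calls = [], []
        positions = rng.choice(np.arange(90, 330), size=n, replace=False)
        for pos in sorted(int(p) for p in positions):
            r = base_at(pos)
            a = alt_for(pos)
            zyg = HOM if rng.random() < 0.3 else HET
            truths.append(truth(pos, r, a, zyg=zyg))
            u = rng.random()
            if u < p_miss:
                continue
            if u < p_miss + p_flip:
                calls.append(call(pos, r, a, zyg=HET if zyg == HOM else HOM))
            elif u < p_miss + p_flip + p_base:
                calls.append(call(pos, r, alt_for(pos, avoid=a)))
            else:
                calls.append(call(pos, r, a, zyg=zyg))
        return truths, calls

    def test_single_concordant_record_rates_100(self):
        pos, r = 130, base_at(130)
        a = alt_for(pos)
        recs = match_all([truth(pos, r, a)], {"P1": [call(pos, r, a)]},
                         TRACK, REF, {"TOY": MODEL})
        table = concordance_table(recs)
        assert table.rows["coding"].total == 1
        assert table.rows["coding"].rate_percent == 100.0
        assert table.rows["overall"].rate_percent == 100.0

    def test_conservation_and_quadratic_oracle(self, rng):
        truths, calls = self._cohort(rng, n=120)
        models = {"TOY": MODEL}
        recs = match_all(truths, {"P1": calls}, TRACK, REF, models)
        table = concordance_table(recs)
        # statuses per stratum sum to the stratum total
        for name, c in table.rows.items():
            assert (c.concordant + c.discordant_base + c.discordant_zygosity
                    + c.missing + c.indeterminate) == c.total
        included = [table.rows[s].total for s in
                    ("coding", "intronic_near", "intronic_deep")]
        assert sum(included) == table.rows["overall"].total
        assert table.rows["overall"].total + table.rows["excluded_genes"].total \
            == len(truths)
        # quadratic every-truth-vs-every-call re-implementation agrees
        oracle = quadratic_counts(truths, {"P1": calls}, REF, models, set())
        for name, c in oracle.items():
            got = table.rows[name]
            assert got.total == c["total"]
            assert got.concordant == c["concordant"]
            assert got.discordant_zygosity == c["discordant_zygosity"]
            assert got.discordant_base == c["discordant_base"]
            assert got.missing == c["missing"]

    def test_order_invariance(self, rng):
        truths, calls = self._cohort(rng, n=80)
        models = {"TOY": MODEL}
        base = concordance_table(
            match_all(truths, {"P1": calls}, TRACK, REF, models)
        ).as_dict()
        perm_t = [truths[i] for i in rng.permutation(len(truths))]
        perm_c = [calls[i] for i in rng.permutation(len(calls))]
        shuffled = concordance_table(
            match_all(perm_t, {"P1": perm_c}, TRACK, REF, models)
        ).as_dict()
        assert base == shuffled

    def test_excluded_genes_report_only_in_their_stratum(self):
        pos, r = 130, base_at(130)
        a = alt_for(pos)
        recs = match_all([truth(pos, r, a)], {"P1": [call(pos, r, a)]},
                         TRACK, REF, {"TOY": MODEL}, excluded_genes={"TOY"})
        table = concordance_table(recs)
        assert table.rows["excluded_genes"].total == 1
        assert table.rows["overall"].total == 0
        assert table.rows["coding"].total == 0

    def test_error_rates_need_adjudication(self):
        pos, r = 130, base_at(130)
        t = truth(pos, r, alt_for(pos))
        recs = match_all([t], {"P1": []}, TRACK, REF, {"TOY": MODEL})
        plain = concordance_table(recs)
        assert plain.wes_false_negative_rate_percent is None
        adj = adjudicate(recs, [{
            "patient_id": "P1", "chrom": "chrT", "pos": pos,
            "observed_ref": r, "observed_allele": t.alt,
            "observed_zygosity": HET,
        }])
        table = concordance_table(recs, adj)
        assert table.wes_false_negative_rate_percent == 100.0
        assert table.sanger_false_positive_rate_percent == 0.0
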