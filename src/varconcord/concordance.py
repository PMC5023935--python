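"""Matching truth variants to WES calls, adjudication, and the stratified
concordance table.

Matching uses the normalized allele as the equivalence engine: a call is
the same variant iff its :class:`~varconcord.variant_io.NormalizedAllele`
equals the truth variant's.  A call whose normalized *position* matches but
whose alternate differs is a discordant base; no window search is ever
performed.  Zygosity is compared only after allele identity.

Accounting in the table (see docs/methods.md for the rationale):

* The per-stratum rows (coding, near-exon intronic, deep intronic,
  excluded genes) report the rate at which the Sanger-reported allele was
  *seen* in WES — concordant plus zygosity-discordant records — which is
  what a raw truth-vs-VCF tally can know before any re-sequencing.
* The synthesized ``noncoding_total`` and ``overall`` rows report the
  post-adjudication rate: strictly concordant records plus zygosity
  discordances that confirmatory sequencing resolved in WES's favour
  (those are the truth table's errors, not the exome's).  Without a
  confirmatory table they fall back to the allele-seen numerator.

WES false-negative and Sanger false-positive rates are defined over coding
variants in adequately covered genes: a coding variant absent from WES and
confirmed real is a WES false negative; one shown to be reference on
re-sequencing is a Sanger false positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

from .coverage_qc import DepthTrack, position_depth
from .gene_models import GeneModel, RegionLabel, classify_position, region_stratum
from .variant_io import (
    HET,
    HOM,
    CalledVariant,
    NormalizedAllele,
    TruthVariant,
    normalize,
)

__all__ = [
    "CONCORDANT",
    "DISCORDANT_BASE",
    "DISCORDANT_ZYGOSITY",
    "MISSING_STATUS",
    "SANGER_CORRECT",
    "WES_CORRECT",
    "BOTH_INCORRECT",
    "UNRESOLVED",
    "ConcordanceRecord",
    "AdjudicatedRecord",
    "StratumCounts",
    "ConcordanceTable",
    "rate",
    "build_call_index",
    "match_variant",
    "match_all",
    "adjudicate",
    "concordance_table",
    "gene_breakdown",
]

# record statuses
CONCORDANT = "concordant"
DISCORDANT_BASE = "discordant_base"
DISCORDANT_ZYGOSITY = "discordant_zygosity"
MISSING_STATUS = "missing"

# adjudication resolutions
SANGER_CORRECT = "sanger_correct"
WES_CORRECT = "wes_correct"
BOTH_INCORRECT = "both_incorrect"
UNRESOLVED = "unresolved"

STRATA = ["coding", "intronic_near", "intronic_deep"]
TABLE_ROWS = STRATA + ["noncoding_total", "overall", "excluded_genes"]


@dataclass(frozen=True)
class ConcordanceRecord:
    """Per-variant verdict of the truth-vs-WES comparison."""

    truth: TruthVariant
    status: str
    region: RegionLabel
    site_depth: int
    low_depth: bool
    gene_excluded: bool
    matched_call: Optional[CalledVariant] = None
    normalized: Optional[NormalizedAllele] = None


@dataclass(frozen=True)
class AdjudicatedRecord:
    """A record plus the verdict of confirmatory re-sequencing."""

    record: ConcordanceRecord
    resolution: str = UNRESOLVED
    confirmatory_allele: Optional[str] = None
    confirmatory_zygosity: Optional[str] = None


def rate(numerator: int, denominator: int) -> Optional[float]:
    """Percentage rounded half-up to one decimal; None for an empty
    denominator."""
    if denominator == 0:
        return None
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# -- matching ----------------------------------------------------------------


def build_call_index(
    calls_by_patient: Mapping[str, Sequence[CalledVariant]], reference
) -> dict[str, dict[tuple[str, int], list[tuple[NormalizedAllele, CalledVariant]]]]:
    """Normalize every call once and index it by (chrom, normalized pos),
    per patient."""
    index: dict[str, dict[tuple[str, int], list]] = {}
    for patient, calls in calls_by_patient.items():
        per: dict[tuple[str, int], list] = {}
        for call in calls:
            norm = normalize(call.chrom, call.pos, call.ref, call.alt, reference)
            per.setdefault((norm.chrom, norm.pos), []).append((norm, call))
        index[patient] = per
    return index


def match_variant(
    truth: TruthVariant,
    patient_index: Mapping[tuple[str, int], list],
    track: DepthTrack,
    reference,
    model: GeneModel,
    excluded_genes: Iterable[str] = (),
    near_max: int = 20,
    low_depth_below: int = 10,
) -> ConcordanceRecord:
    """Classify one truth variant against one patient's indexed calls."""
    norm = normalize(truth.chrom, truth.pos, truth.ref, truth.alt, reference)
    candidates = patient_index.get((norm.chrom, norm.pos), [])
    matched: Optional[CalledVariant] = None
    status = MISSING_STATUS
    for cand_norm, cand_call in candidates:
        if cand_norm == norm:
            matched = cand_call
            status = (
                CONCORDANT
                if _zygosity_equal(truth.zygosity, cand_call.zygosity)
                else DISCORDANT_ZYGOSITY
            )
            break
    if matched is None and candidates:
        # same normalized position, different alternate
        matched = candidates[0][1]
        status = DISCORDANT_BASE
    if matched is not None and matched.site_depth is not None:
        depth = matched.site_depth
    else:
        depth = position_depth(track, truth.chrom, truth.pos)
    region = classify_position(model, truth.pos, near_max=near_max)
    return ConcordanceRecord(
        truth=truth,
        status=status,
        region=region,
        site_depth=depth,
        low_depth=depth < low_depth_below,
        gene_excluded=truth.gene in set(excluded_genes),
        matched_call=matched,
        normalized=norm,
    )


def _zygosity_equal(truth_zyg: str, call_zyg: str) -> bool:
    # hemizygous calls count as homozygous for comparison purposes
    a = HOM if truth_zyg == "hemi" else truth_zyg
    b = HOM if call_zyg == "hemi" else call_zyg
    return a == b


def match_all(
    truths: Sequence[TruthVariant],
    calls_by_patient: Mapping[str, Sequence[CalledVariant]],
    track: DepthTrack,
    reference,
    models: Mapping[str, GeneModel],
    excluded_genes: Iterable[str] = (),
    near_max: int = 20,
    low_depth_below: int = 10,
) -> list[ConcordanceRecord]:
    """Match every truth variant to its patient's calls (patients are
    independent: a truth row is only compared to its own patient's VCF)."""
    index = build_call_index(calls_by_patient, reference)
    excluded = set(excluded_genes)
    records = []
    for truth in truths:
        if truth.gene not in models:
            raise KeyError(f"no gene model for {truth.gene!r}")
        patient_index = index.get(truth.patient_id, {})
        records.append(
            match_variant(
                truth,
                patient_index,
                track,
                reference,
                models[truth.gene],
                excluded,
                near_max=near_max,
                low_depth_below=low_depth_below,
            )
        )
    return records


# -- adjudication -------------------------------------------------------------


def adjudicate(
    records: Sequence[ConcordanceRecord],
    confirmatory: Sequence[dict],
) -> list[AdjudicatedRecord]:
    """Resolve discordances against confirmatory re-sequencing results.

    ``confirmatory`` rows are dicts keyed by (patient_id, chrom, pos) with
    ``observed_allele`` (the re-sequenced allele; equal to ``observed_ref``
    when the position is wild-type) and ``observed_zygosity``.  A missing
    record whose confirmatory allele supports the truth alternate is a WES
    false negative (sanger_correct); one shown to be reference is a Sanger
    false positive (wes_correct).  A discordant base matching neither side
    is both_incorrect.  Zygosity discordances resolve toward whichever
    zygosity the confirmatory call shows.  Confirmatory rows matching no
    record are ignored with a warning-level note.
    """
    by_key = {
        (row["patient_id"], row["chrom"], int(row["pos"])): row
        for row in confirmatory
    }
    out: list[AdjudicatedRecord] = []
    for rec in records:
        key = (rec.truth.patient_id, rec.truth.chrom, rec.truth.pos)
        row = by_key.pop(key, None)
        if row is None:
            out.append(AdjudicatedRecord(record=rec))
            continue
        obs_ref = row.get("observed_ref", "").upper()
        obs_allele = row.get("observed_allele", "").upper()
        obs_zyg = (row.get("observed_zygosity") or "").strip().lower() or None
        resolution = UNRESOLVED
        if rec.status == MISSING_STATUS:
            if obs_allele == rec.truth.alt.upper():
                resolution = SANGER_CORRECT
            elif obs_allele == obs_ref or obs_allele == rec.truth.ref.upper():
                resolution = WES_CORRECT
            else:
                resolution = BOTH_INCORRECT
        elif rec.status == DISCORDANT_BASE:
            called_alt = rec.matched_call.alt.upper() if rec.matched_call else None
            if obs_allele == rec.truth.alt.upper():
                resolution = SANGER_CORRECT
            elif called_alt is not None and obs_allele == called_alt:
                resolution = WES_CORRECT
            else:
                resolution = BOTH_INCORRECT
        elif rec.status == DISCORDANT_ZYGOSITY and obs_zyg is not None:
            if obs_zyg == rec.truth.zygosity:
                resolution = SANGER_CORRECT
            elif rec.matched_call is not None and obs_zyg == rec.matched_call.zygosity:
                resolution = WES_CORRECT
            else:
                resolution = BOTH_INCORRECT
        out.append(
            AdjudicatedRecord(
                record=rec,
                resolution=resolution,
                confirmatory_allele=obs_allele or None,
                confirmatory_zygosity=obs_zyg,
            )
        )
    return out


# -- the table ----------------------------------------------------------------


@dataclass
class StratumCounts:
    total: int = 0
    concordant: int = 0
    discordant_base: int = 0
    discordant_zygosity: int = 0
    missing: int = 0
    indeterminate: int = 0
    rate_percent: Optional[float] = None
    n_patients: int = 0

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "concordant": self.concordant,
            "discordant_base": self.discordant_base,
            "discordant_zygosity": self.discordant_zygosity,
            "missing": self.missing,
            "indeterminate": self.indeterminate,
            "rate_percent": self.rate_percent,
            "n_patients": self.n_patients,
        }


@dataclass
class ConcordanceTable:
    rows: dict[str, StratumCounts]
    wes_false_negative_rate_percent: Optional[float] = None
    sanger_false_positive_rate_percent: Optional[float] = None
    adjudicated: bool = False

    #: The error rates below count polymorphisms and variants of unknown
    #: significance, not clinically actionable findings; they are not
    #: false-positive/negative rates in the diagnostic sense.
    RATE_CAVEAT = (
        "False negative/positive rates are computed over reported "
        "polymorphisms and variants of unknown significance, not "
        "clinically relevant results."
    )

    def as_dict(self) -> dict:
        d = {name: counts.as_dict() for name, counts in self.rows.items()}
        d["wes_false_negative_rate_percent"] = self.wes_false_negative_rate_percent
        d["sanger_false_positive_rate_percent"] = self.sanger_false_positive_rate_percent
        d["adjudicated"] = self.adjudicated
        d["rate_caveat"] = self.RATE_CAVEAT
        return d

    def render_text(self) -> str:
        titles = {
            "coding": "Coding",
            "intronic_near": "Intronic (<=20 bp)",
            "intronic_deep": "Intronic (>20 bp)",
            "noncoding_total": "Noncoding (all)",
            "overall": "Overall (included genes)",
            "excluded_genes": "Excluded genes",
        }
        lines = [
            f"{'Variants':<26}{'Total':>7}{'Concord.':>10}{'Rate %':>8}"
            f"{'Disc.base':>11}{'Disc.zyg':>10}{'Missing':>9}{'Indet.':>8}{'Patients':>10}"
        ]
        for name in TABLE_ROWS:
            c = self.rows[name]
            r = "" if c.rate_percent is None else f"{c.rate_percent:.1f}"
            lines.append(
                f"{titles[name]:<26}{c.total:>7}{c.concordant:>10}{r:>8}"
                f"{c.discordant_base:>11}{c.discordant_zygosity:>10}"
                f"{c.missing:>9}{c.indeterminate:>8}{c.n_patients:>10}"
            )
        if self.wes_false_negative_rate_percent is not None:
            lines.append(
                f"WES false negative rate (coding, included genes): "
                f"{self.wes_false_negative_rate_percent:.1f}%"
            )
        if self.sanger_false_positive_rate_percent is not None:
            lines.append(
                f"Sanger false positive rate (coding, included genes): "
                f"{self.sanger_false_positive_rate_percent:.1f}%"
            )
        lines.append(self.RATE_CAVEAT)
        return "\n".join(lines)


def _stratum_of(rec: ConcordanceRecord, near_max: int) -> str:
    if rec.gene_excluded:
        return "excluded_genes"
    return region_stratum(rec.region, near_max=near_max)


def concordance_table(
    records: Sequence[ConcordanceRecord],
    adjudicated: Optional[Sequence[AdjudicatedRecord]] = None,
    near_max: int = 20,
) -> ConcordanceTable:
    """Aggregate per-variant records into the stratified table.

    Records in excluded genes appear only in the excluded-genes row.  With
    adjudications, a discordant base resolved as both-incorrect is
    displayed as indeterminate (kept in the row total), the total rows use
    the post-adjudication numerator, and coding WES-FN / Sanger-FP rates
    are populated; without them the discordances stay as observed and the
    error rates are absent.
    """
    resolution_by_id: dict[int, str] = {}
    if adjudicated is not None:
        resolution_by_id = {id(a.record): a.resolution for a in adjudicated}

    rows = {name: StratumCounts() for name in TABLE_ROWS}
    patients: dict[str, set] = {name: set() for name in TABLE_ROWS}
    seen_alleles: dict[str, int] = {name: 0 for name in TABLE_ROWS}
    wes_ok_flips: dict[str, int] = {name: 0 for name in TABLE_ROWS}
    fn = fp = 0

    def _absorb(name: str, rec: ConcordanceRecord, resolution: Optional[str]) -> None:
        c = rows[name]
        c.total += 1
        patients[name].add(rec.truth.patient_id)
        if rec.status == CONCORDANT:
            c.concordant += 1
            seen_alleles[name] += 1
        elif rec.status == DISCORDANT_ZYGOSITY:
            c.discordant_zygosity += 1
            seen_alleles[name] += 1
            if resolution == WES_CORRECT:
                wes_ok_flips[name] += 1
        elif rec.status == DISCORDANT_BASE:
            if resolution == BOTH_INCORRECT:
                c.indeterminate += 1
            else:
                c.discordant_base += 1
        else:
            c.missing += 1

    for rec in records:
        resolution = resolution_by_id.get(id(rec))
        stratum = _stratum_of(rec, near_max)
        _absorb(stratum, rec, resolution)
        if stratum in ("intronic_near", "intronic_deep"):
            _absorb("noncoding_total", rec, resolution)
        if stratum in STRATA:
            _absorb("overall", rec, resolution)
        if stratum == "coding":
            if rec.status == MISSING_STATUS and resolution == SANGER_CORRECT:
                fn += 1
            if rec.status == MISSING_STATUS and resolution == WES_CORRECT:
                fp += 1

    for name in TABLE_ROWS:
        c = rows[name]
        c.n_patients = len(patients[name])
        if name in ("noncoding_total", "overall") and adjudicated is not None:
            numerator = c.concordant + wes_ok_flips[name]
        else:
            numerator = seen_alleles[name]
        c.rate_percent = rate(numerator, c.total)

    table = ConcordanceTable(rows=rows, adjudicated=adjudicated is not None)
    coding_total = rows["coding"].total
    if adjudicated is not None and coding_total > 0:
        table.wes_false_negative_rate_percent = rate(fn, coding_total)
        table.sanger_false_positive_rate_percent = rate(fp, coding_total)
    return table


def gene_breakdown(records: Sequence[ConcordanceRecord]) -> list[dict]:
    """Per-gene coding tally: variants reported by Sanger vs seen in WES
    (allele identity, regardless of zygosity).  Covers every gene,
    including coverage-excluded ones."""
    per_gene: dict[str, list[int]] = {}
    for rec in records:
        if rec.region.category != "coding":
            continue
        row = per_gene.setdefault(rec.truth.gene, [0, 0])
        row[0] += 1
        if rec.status in (CONCORDANT, DISCORDANT_ZYGOSITY):
            row[1] += 1
    return [
        {"gene": g, "sanger": s, "wes": w}
        for g, (s, w) in sorted(per_gene.items())
    ]
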