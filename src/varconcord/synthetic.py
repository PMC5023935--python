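"""Synthetic study generator.

Builds complete, self-consistent study inputs — gene models, reference
sequences, a clinical truth table, per-patient call sets, a per-base depth
track and a confirmatory re-sequencing table — with controlled statistical
structure.  Outcomes are *planted*, not emergent: the generator decides
each variant's fate (concordant, missing, discordant base, zygosity flip)
and constructs the calls and depths consistent with it, recording every
decision in a manifest.  The pipeline must then recover the manifest
exactly.

Two entry points:

* :func:`simulate_cohort` / :func:`generate_study` — a configurable cohort
  whose per-stratum discordance probabilities, coverage profiles and
  GC targets are free parameters (defaults mirror a 26-patient, 51-gene
  clinical comparison cohort);
* :func:`build_paper_fixture` — a deterministic 391-variant, 26-patient,
  51-gene cohort whose planted per-stratum outcome counts are fixed, so the
  full pipeline reproduces its concordance table exactly for any seed (the
  seed only varies sequence content).

The toy site-level caller (:func:`toy_site_caller`) embodies the upstream
calling thresholds: a site needs at least 3 reads to be called at all and
at least 20% of reads supporting the alternate; an alternate fraction of
80% or more is called homozygous (the homozygous bound is this package's
choice, symmetric to the 20% floor).  No emitted call violates it.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .coverage_qc import (
    DepthTrack,
    flag_low_coverage_genes,
    gene_coverage_fraction,
    write_depth_track,
    read_depth_track,
)
from .gene_models import (
    GeneModel,
    read_gene_models_tsv,
    write_gene_models_tsv,
)
from .variant_io import (
    HET,
    HOM,
    CalledVariant,
    TruthVariant,
    normalize,
    read_truth_table,
    read_vcf,
    write_truth_table,
    write_vcf,
)

__all__ = [
    "CallerThresholds",
    "GeneSpec",
    "StratumRates",
    "SimConfig",
    "StudyBundle",
    "InfeasibleConfigError",
    "toy_site_caller",
    "simulate_cohort",
    "generate_study",
    "build_paper_fixture",
    "write_bundle",
    "load_bundle",
    "sim_config_from_yaml",
]


class InfeasibleConfigError(ValueError):
    """Config asks for more planted variants than the gene can host."""


# -- toy site-level caller ---------------------------------------------------


@dataclass(frozen=True)
class CallerThresholds:
    min_reads: int = 3
    min_allele_fraction: float = 0.20
    hom_fraction: float = 0.80


def toy_site_caller(
    ref_reads: int, alt_reads: int, thresholds: Optional[CallerThresholds] = None
) -> str:
    """Site-level genotype from read counts: ``no_call`` under 3 total
    reads; ``ref`` under 20% alternate support (boundary inclusive for the
    alternate); ``hom`` at 80% or more; ``het`` between."""
    t = thresholds or CallerThresholds()
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = ref_reads + alt_reads
    if total < t.min_reads:
        return "no_call"
    frac = alt_reads / total
    if frac < t.min_allele_fraction:
        return "ref"
    if frac >= t.hom_fraction:
        return "hom"
    return "het"


# -- configuration ------------------------------------------------------------


@dataclass(frozen=True)
class GeneSpec:
    """Shape and coverage profile of one synthetic gene."""

    name: str
    n_exons: int = 4
    exon_len: int = 150
    intron_len: int = 250
    gc_target: float = 0.37
    mean_depth: int = 50
    low_coverage_fraction: float = 0.0  # share of footprint kept below QC depth


@dataclass(frozen=True)
class StratumRates:
    p_missing: float = 0.0
    p_discordant_base: float = 0.0
    p_zygosity_flip: float = 0.0

    def __post_init__(self) -> None:
        probs = (self.p_missing, self.p_discordant_base, self.p_zygosity_flip)
        if any(p < 0 or p > 1 for p in probs) or sum(probs) > 1:
            raise InfeasibleConfigError(
                "stratum probabilities must lie in [0,1] and sum to <= 1"
            )


def _default_genes() -> tuple[GeneSpec, ...]:
    # 51 genes; the last nine carry the poor-coverage profile, seven of
    # them GC-rich (capture bias) and two near-average GC (kit targeting).
    genes = []
    for i in range(51):
        name = f"G{i + 1:02d}"
        if i >= 42:
            gc = 0.60 if i < 49 else 0.40
            genes.append(
                GeneSpec(name=name, gc_target=gc, low_coverage_fraction=0.45)
            )
        else:
            genes.append(GeneSpec(name=name))
    return tuple(genes)


def _default_rates() -> dict[str, StratumRates]:
    # Per-stratum discordance structure of a Sanger-vs-WES comparison:
    # rare coding misses, more frequent near-exon misses, deep intronic
    # positions missed often (off-target), occasional zygosity flips.
    return {
        "coding": StratumRates(p_missing=4 / 150),
        "intronic_near": StratumRates(p_missing=4 / 52, p_zygosity_flip=2 / 52),
        "intronic_deep": StratumRates(
            p_missing=13 / 58, p_discordant_base=1 / 58, p_zygosity_flip=2 / 58
        ),
    }


@dataclass
class SimConfig:
    """Configuration of one simulated cohort.

    ``seed`` fully determines all outputs.  Per-gene variant counts are
    split by stratum; fates are drawn per variant from the per-stratum
    probabilities and then planted deterministically.
    """

    seed: int = 0
    n_patients: int = 26
    genes: tuple[GeneSpec, ...] = field(default_factory=_default_genes)
    n_coding_per_gene: int = 4
    n_near_per_gene: int = 1
    n_deep_per_gene: int = 1
    rates: dict[str, StratumRates] = field(default_factory=_default_rates)
    thresholds: CallerThresholds = field(default_factory=CallerThresholds)
    indel_every: int = 15  # every k-th concordant variant is a small indel
    p_hom: float = 0.3
    flank_pad: int = 20


def sim_config_from_yaml(path) -> SimConfig:
    """Load a :class:`SimConfig` from a YAML file (documented schema:
    top-level scalars as in SimConfig; ``genes`` a list of GeneSpec
    mappings; ``rates`` a mapping stratum -> {p_missing, ...})."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key in (
        "seed",
        "n_patients",
        "n_coding_per_gene",
        "n_near_per_gene",
        "n_deep_per_gene",
        "indel_every",
        "p_hom",
        "flank_pad",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "genes" in raw:
        kwargs["genes"] = tuple(GeneSpec(**g) for g in raw["genes"])
    if "rates" in raw:
        kwargs["rates"] = {k: StratumRates(**v) for k, v in raw["rates"].items()}
    if "thresholds" in raw:
        kwargs["thresholds"] = CallerThresholds(**raw["thresholds"])
    return SimConfig(**kwargs)


# -- bundle -------------------------------------------------------------------


@dataclass
class StudyBundle:
    """In-memory study inputs plus the generator's ground-truth manifest."""

    models: dict[str, GeneModel]
    reference: Mapping[str, str]
    truth: list[TruthVariant]
    calls_by_patient: dict[str, list[CalledVariant]]
    depth_track: DepthTrack
    confirmatory: list[dict]
    manifest: dict


# -- sequence and geometry helpers --------------------------------------------

_BASES = np.array(list("ACGT"))


def _make_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _gene_layout(
    name: str,
    chrom: str,
    strand: str,
    spec: GeneSpec,
    offset: int = 500,
    utr: int = 30,
    flank_pad: int = 20,
) -> GeneModel:
    exons = []
    s = offset
    for _ in range(spec.n_exons):
        exons.append((s, s + spec.exon_len))
        s += spec.exon_len + spec.intron_len
    cds_start = exons[0][0] + utr
    cds_end = exons[-1][1] - utr
    return GeneModel(
        gene_name=name,
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        cds_start=cds_start,
        cds_end=cds_end,
        flank_pad=flank_pad,
    )


def _chrom_length(spec: GeneSpec, offset: int = 500, tail: int = 500) -> int:
    span = spec.n_exons * spec.exon_len + (spec.n_exons - 1) * spec.intron_len
    return offset + span + tail


class _Slots:
    """Deterministic candidate positions (0-based) per region of one gene."""

    def __init__(self, model: GeneModel):
        self.model = model
        cds_s, cds_e = model.cds_start, model.cds_end
        coding: list[int] = []
        for s, e in model.exons:
            coding.extend(range(max(s, cds_s) + 4, min(e, cds_e) - 6, 9))
        near: list[int] = []
        deep: list[int] = []
        for i in range(len(model.exons) - 1):
            left_end = model.exons[i][1]
            right_start = model.exons[i + 1][0]
            for off in (3, 7, 11, 15, 18):
                near.append(left_end + off - 1)  # distance `off` from exon i
                near.append(right_start - off)  # distance `off` from exon i+1
            for t in range(0, 20):
                p = left_end + 30 + 7 * t
                if right_start - p > 24:
                    deep.append(p)
        self.pools = {"coding": coding, "intronic_near": near, "intronic_deep": deep}
        self.cursors = {k: 0 for k in self.pools}
        self.reserved: set[int] = set()

    def take(self, stratum: str, span: int = 1) -> int:
        pool = self.pools[stratum]
        while self.cursors[stratum] < len(pool):
            p = pool[self.cursors[stratum]]
            self.cursors[stratum] += 1
            window = set(range(p - 6, p + span + 6))
            if not (window & self.reserved):
                self.reserved.update(range(p - 2, p + span + 2))
                return p
        raise InfeasibleConfigError(
            f"{self.model.gene_name}: no free {stratum} positions left"
        )


def _pick_alt(rng_or_idx, ref_base: str, avoid: str = "") -> str:
    order = "ACGT"
    banned = set(ref_base.upper()) | set(avoid.upper())
    choices = [b for b in order if b not in banned]
    if isinstance(rng_or_idx, np.random.Generator):
        return choices[int(rng_or_idx.integers(len(choices)))]
    return choices[rng_or_idx % len(choices)]


def _plant_allele(
    reference: Mapping[str, str],
    chrom: str,
    slots: _Slots,
    stratum: str,
    kind: tuple[str, int],
    alt_idx: int,
) -> tuple[int, str, str]:
    """Choose a stable (pos, ref, alt) of the requested kind.

    Stability means the representation is already normalized (no left
    shift), so the planted coordinates survive the pipeline unchanged.
    """
    seq = reference[chrom]
    what, size = kind
    for _ in range(80):
        p0 = slots.take(stratum, span=size + 1)
        if what == "snv":
            ref = seq[p0]
            alt = _pick_alt(alt_idx, ref)
        elif what == "del":
            ref = seq[p0 : p0 + size + 1]
            alt = seq[p0]
        elif what == "ins":
            ref = seq[p0]
            ins = "".join("ACGT"[(alt_idx + j) % 4] for j in range(size))
            alt = ref + ins
        else:  # pragma: no cover
            raise ValueError(what)
        if ref == alt or len(set(ref)) == 0:
            continue
        try:
            norm = normalize(chrom, p0 + 1, ref, alt, reference)
        except ValueError:
            continue
        if norm.pos == p0 + 1 and norm.ref == ref and norm.alt == alt:
            return p0 + 1, ref, alt
    raise InfeasibleConfigError(
        f"could not place a stable {what} in {stratum} on {chrom}"
    )


def _depth_profile(
    model: GeneModel, spec: GeneSpec, arr: np.ndarray, low_depth: int = 8
) -> None:
    """Paint the gene's footprint coverage profile into ``arr``."""
    footprint = [
        (s, e) for s, e in model.footprint()
    ]
    bases = [p for s, e in footprint for p in range(s, min(e, len(arr)))]
    n_low = int(round(spec.low_coverage_fraction * len(bases)))
    for i, p in enumerate(bases):
        arr[p] = low_depth if i < n_low else spec.mean_depth


def _reads_for(zygosity: str, depth: int) -> tuple[int, int]:
    """(ref_reads, alt_reads) consistent with the planted genotype."""
    if zygosity == HOM:
        return 0, depth
    alt = depth // 2
    return depth - alt, alt


# -- generic simulator ---------------------------------------------------------

_STRATA = ("coding", "intronic_near", "intronic_deep")


def simulate_cohort(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> StudyBundle:
    """Generate one cohort according to ``config``.

    Every variant's fate is drawn from the stratum's probabilities
    (missing / discordant base / zygosity flip / else concordant), then
    planted; the manifest records each decision.  The confirmatory table
    always supports the truth row, so planted missing variants adjudicate
    as WES false negatives.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    models: dict[str, GeneModel] = {}
    reference: dict[str, str] = {}
    depth_arrays: dict[str, np.ndarray] = {}
    slots: dict[str, _Slots] = {}
    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    gene_patient: dict[str, str] = {}

    for i, spec in enumerate(config.genes):
        chrom = f"chrS{i + 1}"
        strand = "+" if i % 2 == 0 else "-"
        model = _gene_layout(spec.name, chrom, strand, spec, flank_pad=config.flank_pad)
        models[spec.name] = model
        reference[chrom] = _make_sequence(rng, _chrom_length(spec), spec.gc_target)
        arr = np.zeros(_chrom_length(spec), dtype=np.int64)
        _depth_profile(model, spec, arr)
        depth_arrays[chrom] = arr
        slots[spec.name] = _Slots(model)
        gene_patient[spec.name] = patients[i % len(patients)]

    truth: list[TruthVariant] = []
    calls: dict[str, list[CalledVariant]] = {p: [] for p in patients}
    confirmatory: list[dict] = []
    planted: list[dict] = []
    counts = {
        s: {"total": 0, "concordant": 0, "missing": 0, "discordant_base": 0,
            "discordant_zygosity": 0}
        for s in _STRATA + ("excluded_genes",)
    }
    excluded_plan = sorted(
        s.name for s in config.genes if s.low_coverage_fraction > 0.25
    )
    k_global = 0

    per_stratum_n = {
        "coding": config.n_coding_per_gene,
        "intronic_near": config.n_near_per_gene,
        "intronic_deep": config.n_deep_per_gene,
    }

    for spec in config.genes:
        model = models[spec.name]
        chrom = model.chrom
        patient = gene_patient[spec.name]
        for stratum in _STRATA:
            rates = config.rates.get(stratum, StratumRates())
            for _ in range(per_stratum_n[stratum]):
                k_global += 1
                u = float(rng.random())
                if u < rates.p_missing:
                    fate = "missing"
                elif u < rates.p_missing + rates.p_discordant_base:
                    fate = "discordant_base"
                elif u < (
                    rates.p_missing + rates.p_discordant_base + rates.p_zygosity_flip
                ):
                    fate = "zygosity_flip"
                else:
                    fate = "concordant"
                kind = ("snv", 0)
                if (
                    fate == "concordant"
                    and config.indel_every
                    and k_global % config.indel_every == 0
                ):
                    kind = ("del", 1 + k_global % 3) if k_global % 2 else ("ins", 1 + k_global % 2)
                alt_idx = int(rng.integers(0, 3))
                pos, ref, alt = _plant_allele(
                    reference, chrom, slots[spec.name], stratum, kind, alt_idx
                )
                zyg = HOM if rng.random() < config.p_hom else HET
                depth = int(rng.integers(30, 61))
                tv = TruthVariant(
                    patient_id=patient,
                    gene=spec.name,
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    zygosity=zyg,
                )
                truth.append(tv)
                depth_arrays[chrom][pos - 1 : pos - 1 + len(ref)] = depth
                call_info = None
                if fate == "concordant":
                    call = CalledVariant(chrom, pos, ref, alt, zyg, depth)
                elif fate == "zygosity_flip":
                    flipped = HET if zyg == HOM else HOM
                    call = CalledVariant(chrom, pos, ref, alt, flipped, depth)
                elif fate == "discordant_base":
                    # discordant-base fates are always planted as SNVs
                    other = _pick_alt(alt_idx + 1, ref, avoid=alt)
                    call = CalledVariant(chrom, pos, ref, other, HET, depth)
                else:
                    call = None
                if call is not None:
                    calls[patient].append(call)
                    rr, ar = _reads_for(call.zygosity, depth)
                    assert toy_site_caller(rr, ar, config.thresholds) == call.zygosity
                    call_info = {"zygosity": call.zygosity, "ref_reads": rr,
                                 "alt_reads": ar}
                if fate != "concordant":
                    confirmatory.append(
                        {
                            "patient_id": patient,
                            "chrom": chrom,
                            "pos": pos,
                            "observed_ref": ref,
                            "observed_allele": alt,
                            "observed_zygosity": zyg,
                        }
                    )
                status = {
                    "concordant": "concordant",
                    "missing": "missing",
                    "discordant_base": "discordant_base",
                    "zygosity_flip": "discordant_zygosity",
                }[fate]
                bucket = (
                    "excluded_genes" if spec.name in excluded_plan else stratum
                )
                counts[bucket]["total"] += 1
                counts[bucket][status] += 1
                planted.append(
                    {
                        "patient_id": patient,
                        "gene": spec.name,
                        "chrom": chrom,
                        "pos": pos,
                        "ref": ref,
                        "alt": alt,
                        "zygosity": zyg,
                        "stratum": bucket,
                        "status": status,
                        "depth": depth,
                        "call": call_info,
                    }
                )

    track = _track_from_arrays(depth_arrays)
    _check_exclusions(track, models, excluded_plan)

    manifest = {
        "kind": "simulated_cohort",
        "seed": config.seed,
        "n_patients": config.n_patients,
        "gene_patient": gene_patient,
        "excluded_genes": excluded_plan,
        "counts": counts,
        "variants": planted,
    }
    return StudyBundle(
        models=models,
        reference=reference,
        truth=truth,
        calls_by_patient=calls,
        depth_track=track,
        confirmatory=confirmatory,
        manifest=manifest,
    )


def _track_from_arrays(depth_arrays: Mapping[str, np.ndarray]) -> DepthTrack:
    intervals = []
    for chrom in sorted(depth_arrays):
        arr = depth_arrays[chrom]
        if not arr.any():
            continue
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(arr)]))
        for s, e in zip(starts, ends):
            d = int(arr[s])
            if d > 0:
                intervals.append((chrom, int(s), int(e), d))
    return DepthTrack.from_intervals(intervals)


def _check_exclusions(
    track: DepthTrack, models: Mapping[str, GeneModel], excluded_plan: Sequence[str]
) -> None:
    stats = [gene_coverage_fraction(track, m) for m in models.values()]
    got = flag_low_coverage_genes(stats)
    if got != set(excluded_plan):
        raise InfeasibleConfigError(
            f"planted coverage profile does not reproduce the intended "
            f"exclusions (planned {sorted(excluded_plan)}, got {sorted(got)})"
        )


# -- the deterministic study fixture -------------------------------------------

# Per-gene coding variant counts (Sanger-reported, seen-in-WES).  One extra
# concordant coding variant is carried by DYSF so the included-gene coding
# stratum totals 150/146; see docs/methods.md.
_FIXTURE_CODING: tuple[tuple[str, int, int], ...] = (
    ("GAA", 35, 9),
    ("DYSF", 14, 14),
    ("POMT2", 10, 10),
    ("GALC", 10, 10),
    ("ZFYVE26", 9, 9),
    ("FKTN", 8, 8),
    ("POMT1", 8, 8),
    ("TTN", 8, 8),
    ("DES", 7, 7),
    ("KCNA1", 6, 6),
    ("SLC12A6", 6, 6),
    ("COX10", 5, 5),
    ("KIAA1840", 5, 5),
    ("SGCG", 5, 5),
    ("CHAT", 5, 5),
    ("CACNA1A", 5, 5),
    ("RAPSN", 5, 4),
    ("CAPN3", 4, 4),
    ("SGCD", 4, 4),
    ("TCAP", 4, 4),
    ("CLN10", 3, 3),
    ("DOK7", 3, 3),
    ("MUSK", 3, 1),
    ("FKRP", 2, 2),
    ("LMNA", 2, 2),
    ("CC2D2A", 2, 2),
    ("CLN2", 2, 2),
    ("EIF2B5", 2, 2),
    ("FAM134B", 2, 2),
    ("KCNC3", 2, 2),
    ("POMGnT1", 2, 2),
    ("MYH7", 2, 2),
    ("APTX", 1, 1),
    ("ARL13B", 1, 1),
    ("CHRND", 1, 1),
    ("CHRNE", 1, 1),
    ("CLN1", 1, 1),
    ("CLN5", 1, 1),
    ("COL6A2", 1, 1),
    ("EIF2B4", 1, 1),
    ("EPM2A", 1, 1),
    ("NPHP1", 1, 1),
    ("PLEKHG4", 1, 1),
    ("SACS", 1, 1),
    ("SCO2", 1, 1),
    ("SETX", 1, 1),
    ("SPG7", 1, 1),
    ("SYNE1", 1, 1),
    ("TRPV4", 1, 1),
    ("COLQ", 1, 0),
    ("TMEM67", 1, 0),
)

_FIXTURE_EXCLUDED = frozenset(
    {"CC2D2A", "DES", "DOK7", "EPM2A", "FKRP", "GAA", "KCNC3", "LMNA", "RAPSN"}
)
_FIXTURE_HIGH_GC = frozenset(
    {"DOK7", "KCNC3", "GAA", "DES", "RAPSN", "LMNA", "FKRP"}
)

_FIXTURE_EXPECTED = {
    "strata": {
        "coding": {"total": 150, "concordant": 146, "missing": 4,
                   "discordant_zygosity": 0, "indeterminate": 0,
                   "rate_percent": 97.3},
        "intronic_near": {"total": 52, "concordant": 46, "missing": 4,
                          "discordant_zygosity": 2, "indeterminate": 0,
                          "rate_percent": 92.3},
        "intronic_deep": {"total": 58, "concordant": 42, "missing": 13,
                          "discordant_zygosity": 2, "indeterminate": 1,
                          "rate_percent": 75.9},
        "noncoding_total": {"total": 110, "concordant": 88, "missing": 17,
                            "discordant_zygosity": 4, "indeterminate": 1,
                            "rate_percent": 81.8},
        "overall": {"total": 260, "concordant": 234, "missing": 21,
                    "discordant_zygosity": 4, "indeterminate": 1,
                    "rate_percent": 90.8},
        "excluded_genes": {"total": 131, "concordant": 79, "missing": 52,
                           "discordant_zygosity": 0, "indeterminate": 0,
                           "rate_percent": 60.3},
    },
    "wes_false_negative_rate_percent": 2.0,
    "sanger_false_positive_rate_percent": 0.7,
    "excluded_gene_count": 9,
    "gene_count": 51,
    "excluded_gene_rate_percent": 17.6,
    "low_depth_concordant_coding": 3,
    "low_depth_concordant_intronic": 6,
}


def _fixture_gene_specs() -> list[GeneSpec]:
    specs = []
    for name, _, _ in _FIXTURE_CODING:
        if name in _FIXTURE_EXCLUDED:
            gc = 0.60 if name in _FIXTURE_HIGH_GC else 0.40
            specs.append(
                GeneSpec(name=name, gc_target=gc, low_coverage_fraction=0.45)
            )
        else:
            specs.append(GeneSpec(name=name))
    return specs


def build_paper_fixture(seed: int = 2016) -> StudyBundle:
    """Deterministic 26-patient, 51-gene, 391-variant study fixture.

    The planted outcome inventory is fixed (it does not depend on the
    seed): 150/146 coding, 52/46(+2 flips) near-exon intronic,
    58/42(+2 flips, 1 discordant base) deep intronic in the 42 adequately
    covered genes; 131/79 in the nine coverage-excluded genes; four coding
    variants absent from the calls (three adjudicating in favour of the
    truth table, one a truth-table false positive); four zygosity flips
    (two resolving each way); one far-upstream discordant base that
    confirmatory sequencing shows to be wild-type; three coding and six
    intronic concordant variants under 10 reads.  The seed only varies
    sequence content and allele identities.
    """
    rng = np.random.default_rng(seed)
    specs = {s.name: s for s in _fixture_gene_specs()}
    gene_order = [name for name, _, _ in _FIXTURE_CODING]
    included = [g for g in gene_order if g not in _FIXTURE_EXCLUDED]

    models: dict[str, GeneModel] = {}
    reference: dict[str, str] = {}
    depth_arrays: dict[str, np.ndarray] = {}
    slots: dict[str, _Slots] = {}

    for i, name in enumerate(gene_order):
        spec = specs[name]
        chrom = f"chrS{i + 1}"
        strand = "+" if i % 2 == 0 else "-"
        model = _gene_layout(name, chrom, strand, spec)
        models[name] = model
        reference[chrom] = _make_sequence(rng, _chrom_length(spec), spec.gc_target)
        arr = np.zeros(_chrom_length(spec), dtype=np.int64)
        _depth_profile(model, spec, arr)
        depth_arrays[chrom] = arr
        slots[name] = _Slots(model)

    # patient assignment: the two discordant-coding patients and the
    # upstream-variant patient are pinned; everything else cycles.
    patients = [f"P{i + 1:02d}" for i in range(26)]
    gene_patient = {"TMEM67": "P02", "COLQ": "P05", "MUSK": "P05", "DYSF": "P03"}
    cycle = 0
    for name in gene_order:
        if name in gene_patient:
            continue
        gene_patient[name] = patients[cycle % 26]
        cycle += 1

    truth: list[TruthVariant] = []
    calls: dict[str, list[CalledVariant]] = {p: [] for p in patients}
    confirmatory: list[dict] = []
    planted: list[dict] = []

    depth_cycle = [0]

    def _next_depth() -> int:
        depth_cycle[0] += 1
        return 30 + (depth_cycle[0] * 7) % 31

    zyg_cycle = [0]

    def _next_zyg() -> str:
        zyg_cycle[0] += 1
        return HOM if zyg_cycle[0] % 3 == 0 else HET

    def _emit(
        gene: str,
        stratum: str,
        status: str,
        kind: tuple[str, int] = ("snv", 0),
        depth: Optional[int] = None,
        truth_zyg: Optional[str] = None,
        call_zyg: Optional[str] = None,
        pinned_pos: Optional[int] = None,
        resolution: Optional[str] = None,
        confirm: Optional[dict] = None,
    ) -> dict:
        model = models[gene]
        chrom = model.chrom
        patient = gene_patient[gene]
        alt_idx = int(rng.integers(0, 3))
        if pinned_pos is None:
            pos, ref, alt = _plant_allele(
                reference, chrom, slots[gene], stratum, kind, alt_idx
            )
        else:
            p0 = pinned_pos - 1
            ref = reference[chrom][p0]
            alt = _pick_alt(alt_idx, ref)
            pos = pinned_pos
        zyg = truth_zyg or _next_zyg()
        d = depth if depth is not None else _next_depth()
        tv = TruthVariant(
            patient_id=patient, gene=gene, chrom=chrom, pos=pos,
            ref=ref, alt=alt, zygosity=zyg,
        )
        truth.append(tv)
        depth_arrays[chrom][pos - 1 : pos - 1 + len(ref)] = d
        call_info = None
        if status == "concordant":
            cv = CalledVariant(chrom, pos, ref, alt, zyg, d)
        elif status == "discordant_zygosity":
            cv = CalledVariant(chrom, pos, ref, alt, call_zyg, d)
        elif status == "discordant_base":
            other = _pick_alt(alt_idx + 1, ref, avoid=alt)
            cv = CalledVariant(chrom, pos, ref, other, HET, d)
        else:
            cv = None
        if cv is not None:
            calls[patient].append(cv)
            rr, ar = _reads_for(cv.zygosity, d)
            assert toy_site_caller(rr, ar) == cv.zygosity
            call_info = {"zygosity": cv.zygosity, "ref_reads": rr, "alt_reads": ar}
        if confirm is not None:
            row = {
                "patient_id": patient,
                "chrom": chrom,
                "pos": pos,
                "observed_ref": ref,
            }
            if confirm["supports"] == "truth":
                row["observed_allele"] = alt
                row["observed_zygosity"] = zyg
            elif confirm["supports"] == "reference":
                row["observed_allele"] = ref
                row["observed_zygosity"] = ""
            elif confirm["supports"] == "call":
                row["observed_allele"] = alt
                row["observed_zygosity"] = cv.zygosity
            confirmatory.append(row)
        entry = {
            "patient_id": patient,
            "gene": gene,
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "zygosity": zyg,
            "stratum": stratum if gene not in _FIXTURE_EXCLUDED else "excluded_genes",
            "status": status,
            "depth": d,
            "resolution": resolution,
            "call": call_info,
        }
        planted.append(entry)
        return entry

    # ---- coding variants, gene by gene ------------------------------------
    coding_indels = [("del", 1), ("del", 3), ("del", 5)]
    low_depth_coding = 3
    for name, n_sanger, n_wes in _FIXTURE_CODING:
        n_missing = n_sanger - n_wes
        for j in range(n_wes):
            kind = ("snv", 0)
            depth = None
            if name not in _FIXTURE_EXCLUDED:
                if coding_indels and j == 0 and name in ("DYSF", "GALC", "TTN"):
                    kind = coding_indels.pop(0)
                if low_depth_coding and name in ("POMT2", "ZFYVE26", "FKTN") and j == 1:
                    depth = 8
                    low_depth_coding -= 1
            else:
                depth = 24 + (j % 10)
            _emit(name, "coding", "concordant", kind=kind, depth=depth)
        for _ in range(n_missing):
            if name in _FIXTURE_EXCLUDED:
                _emit(name, "coding", "missing", depth=5)
            elif name == "TMEM67":
                _emit(
                    name, "coding", "missing", depth=45,
                    resolution="wes_correct",
                    confirm={"supports": "reference"},
                )
            else:  # MUSK x2, COLQ x1
                _emit(
                    name, "coding", "missing", depth=45,
                    resolution="sanger_correct",
                    confirm={"supports": "truth"},
                )

    # ---- zygosity flips and the upstream discordant base ------------------
    _emit("COLQ", "intronic_near", "discordant_zygosity", depth=40,
          truth_zyg=HOM, call_zyg=HET, resolution="wes_correct",
          confirm={"supports": "call"})
    _emit("MUSK", "intronic_near", "discordant_zygosity", depth=40,
          truth_zyg=HOM, call_zyg=HET, resolution="sanger_correct",
          confirm={"supports": "truth"})
    _emit("COLQ", "intronic_deep", "discordant_zygosity", depth=40,
          truth_zyg=HOM, call_zyg=HET, resolution="wes_correct",
          confirm={"supports": "call"})
    _emit("DYSF", "intronic_deep", "discordant_zygosity", depth=40,
          truth_zyg=HET, call_zyg=HOM, resolution="sanger_correct",
          confirm={"supports": "truth"})
    # far-upstream discordant base; confirmatory shows wild-type
    dysf_up = models["DYSF"].exons[0][0] - 176 + 1  # 1-based, distance 176
    _emit("DYSF", "intronic_deep", "discordant_base", depth=12,
          pinned_pos=dysf_up, resolution="both_incorrect",
          confirm={"supports": "reference"})

    # ---- remaining noncoding variants in included genes --------------------
    near_indels = [("del", 1), ("del", 2), ("del", 1), ("ins", 2)]
    deep_indels = [("del", 2), ("del", 1), ("del", 3), ("del", 1), ("del", 2),
                   ("ins", 1), ("ins", 3)]
    low_near, low_deep = 3, 3

    def _noncoding(stratum: str, n_conc: int, n_miss: int, indels: list,
                   low_left: int, miss_depth: int) -> None:
        events = ["concordant"] * n_conc + ["missing"] * n_miss
        for k, status in enumerate(events):
            gene = included[k % len(included)]
            kind = ("snv", 0)
            depth = None
            if status == "concordant":
                if indels:
                    kind = indels.pop(0)
                elif low_left > 0:
                    depth = 8
                    low_left -= 1
            else:
                depth = miss_depth
            _emit(gene, stratum, status, kind=kind, depth=depth)

    _noncoding("intronic_near", 46, 4, near_indels, low_near, miss_depth=15)
    _noncoding("intronic_deep", 42, 13, deep_indels, low_deep, miss_depth=6)

    # ---- noncoding variants in the excluded genes ---------------------------
    excluded = sorted(_FIXTURE_EXCLUDED)
    ex_events = ["concordant"] * 47 + ["missing"] * 25
    for k, status in enumerate(ex_events):
        gene = excluded[k % len(excluded)]
        stratum = "intronic_near" if k % 2 == 0 else "intronic_deep"
        depth = (24 + k % 10) if status == "concordant" else 5
        _emit(gene, stratum, status, depth=depth)

    # ---- decoy calls (extra WES variants never reported by Sanger) ---------
    for i, patient in enumerate(patients):
        name = next(g for g in gene_order if gene_patient[g] == patient)
        model = models[name]
        chrom = model.chrom
        for j in range(2):
            p0 = model.tx_end + 100 + 30 * j
            ref = reference[chrom][p0]
            alt = _pick_alt(i + j, ref)
            depth_arrays[chrom][p0] = 35
            calls[patient].append(
                CalledVariant(chrom, p0 + 1, ref, alt, HET, 35)
            )

    track = _track_from_arrays(depth_arrays)
    _check_exclusions(track, models, sorted(_FIXTURE_EXCLUDED))

    manifest = {
        "kind": "paper_fixture",
        "seed": seed,
        "n_patients": 26,
        "gene_patient": gene_patient,
        "excluded_genes": sorted(_FIXTURE_EXCLUDED),
        "expected": _FIXTURE_EXPECTED,
        "variants": planted,
    }
    return StudyBundle(
        models=models,
        reference=reference,
        truth=truth,
        calls_by_patient=calls,
        depth_track=track,
        confirmatory=confirmatory,
        manifest=manifest,
    )


# -- bundle I/O -----------------------------------------------------------------

_CONFIRM_COLS = [
    "patient_id", "chrom", "pos", "observed_ref", "observed_allele",
    "observed_zygosity",
]


def write_confirmatory(rows: Sequence[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_CONFIRM_COLS) + "\n")
        for r in rows:
            fh.write("\t".join(str(r.get(c, "")) for c in _CONFIRM_COLS) + "\n")


def read_confirmatory(path) -> list[dict]:
    rows = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if header is None:
                header = f
                continue
            rows.append(dict(zip(header, f)))
    return rows


def write_bundle(bundle: StudyBundle, out_dir) -> None:
    """Write a bundle to a directory: gene models TSV, reference FASTA,
    truth TSV, bedGraph depth track, one VCF per patient, confirmatory TSV
    and the JSON manifest.  Identical bundles produce identical bytes."""
    out = Path(out_dir)
    (out / "vcf").mkdir(parents=True, exist_ok=True)
    write_gene_models_tsv(bundle.models, out / "genes.tsv")
    with open(out / "reference.fa", "w") as fh:
        for chrom in sorted(bundle.reference):
            seq = str(bundle.reference[chrom])
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    write_truth_table(bundle.truth, out / "truth.tsv")
    write_depth_track(bundle.depth_track, out / "depth.bedgraph")
    write_confirmatory(bundle.confirmatory, out / "confirmatory.tsv")
    contigs = {c: len(str(bundle.reference[c])) for c in sorted(bundle.reference)}
    for patient in sorted(bundle.calls_by_patient):
        write_vcf(
            bundle.calls_by_patient[patient],
            patient,
            out / "vcf" / f"{patient}.vcf",
            contigs,
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_bundle(in_dir) -> StudyBundle:
    """Read a written bundle back through the package's own readers."""
    from pyfaidx import Fasta

    src = Path(in_dir)
    models = read_gene_models_tsv(src / "genes.tsv")
    reference = Fasta(os.fspath(src / "reference.fa"))
    truth, rejects = read_truth_table(src / "truth.tsv", models=models)
    if rejects:
        raise ValueError(f"{src}: truth table has {len(rejects)} unreadable rows")
    track = read_depth_track(src / "depth.bedgraph")
    calls: dict[str, list[CalledVariant]] = {}
    for vcf_path in sorted((src / "vcf").glob("*.vcf")):
        sample, recs = read_vcf(vcf_path)
        calls[sample] = recs
    confirmatory = read_confirmatory(src / "confirmatory.tsv")
    with open(src / "manifest.json") as fh:
        manifest = json.load(fh)
    return StudyBundle(
        models=models,
        reference=reference,
        truth=truth,
        calls_by_patient=calls,
        depth_track=track,
        confirmatory=confirmatory,
        manifest=manifest,
    )


def generate_study(config: SimConfig, out_dir) -> StudyBundle:
    """Simulate one cohort and write it to ``out_dir``."""
    bundle = simulate_cohort(config)
    write_bundle(bundle, out_dir)
    return bundle
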