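"""Reading the clinical truth table and the WES VCF; allele normalization.

The truth table is a documented TSV dialect (one row per Sanger-reported
variant); the VCF side goes through pysam.  Every allele — from either
source — is reduced to one canonical :class:`NormalizedAllele` (minimal,
left-aligned against the reference) so that Sanger-reported and
VCF-reported indels can be compared by simple equality.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import pysam

__all__ = [
    "TruthVariant",
    "CalledVariant",
    "NormalizedAllele",
    "TruthTableError",
    "VcfFormatError",
    "ReferenceMismatchError",
    "HET",
    "HOM",
    "HEMI",
    "MISSING",
    "read_truth_table",
    "write_truth_table",
    "write_rejects",
    "read_vcf",
    "write_vcf",
    "normalize",
]

# zygosity values
HET = "het"
HOM = "hom"
HEMI = "hemi"
MISSING = "missing"

_TRUTH_REQUIRED = ["patient_id", "gene", "chrom", "pos", "ref", "alt", "zygosity"]
_TRUTH_OPTIONAL = ["hgvs_c", "dbsnp_id", "source_test"]


class TruthTableError(ValueError):
    """Malformed truth table (missing column, bad header...)."""


class VcfFormatError(ValueError):
    """Unreadable or garbled VCF."""


class ReferenceMismatchError(ValueError):
    """REF allele does not match the reference sequence at its position."""


@dataclass(frozen=True)
class TruthVariant:
    """One Sanger-reported variant from the clinical truth table."""

    patient_id: str
    gene: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    zygosity: str  # het | hom
    hgvs_c: Optional[str] = None
    dbsnp_id: Optional[str] = None
    source_test: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.gene}: position must be >= 1")
        if not self.ref or not self.alt:
            raise ValueError(f"{self.gene}@{self.pos}: empty ref/alt")
        if self.ref == self.alt:
            raise ValueError(f"{self.gene}@{self.pos}: ref == alt")
        if self.zygosity not in (HET, HOM):
            raise ValueError(
                f"{self.gene}@{self.pos}: zygosity must be het or hom, "
                f"got {self.zygosity!r}"
            )


@dataclass(frozen=True)
class CalledVariant:
    """One VCF record after multi-allelic splitting (a single alternate)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    zygosity: str  # het | hom | hemi | missing
    site_depth: Optional[int] = None
    qual: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("position must be >= 1")
        if self.site_depth is not None and self.site_depth < 0:
            raise ValueError("negative site depth")
        if self.zygosity not in (HET, HOM, HEMI, MISSING):
            raise ValueError(f"bad zygosity {self.zygosity!r}")


@dataclass(frozen=True)
class NormalizedAllele:
    """Minimal left-aligned representation of one alternate allele."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


# -- reference access --------------------------------------------------------


def ref_slice(reference, chrom: str, start: int, end: int) -> str:
    """Reference bases [start, end), 0-based; works for a dict of strings or
    a pyfaidx.Fasta."""
    try:
        seq = reference[chrom]
    except KeyError:
        raise ReferenceMismatchError(f"chromosome {chrom!r} not in reference")
    return str(seq[start:end]).upper()


# -- normalization -----------------------------------------------------------


def normalize(chrom: str, pos: int, ref: str, alt: str, reference) -> NormalizedAllele:
    """Canonicalize one allele: trim shared suffix/prefix, left-align indels.

    The algorithm repeatedly trims a shared terminal base (extending to the
    left with reference sequence whenever an allele would become empty),
    then trims the shared leading bases keeping one anchor base for indels.
    It is idempotent, and every equivalent written representation of the
    same edit reduces to the same output.  At the extreme left edge of a
    contig, where no anchor base exists to the left, the representation
    keeps its right-side context instead.
    """
    r, a = ref.upper(), alt.upper()
    if not r or not a:
        raise ValueError("ref and alt must be non-empty (VCF-style anchored alleles)")
    if r == a:
        raise ValueError("ref == alt is not a variant")
    p0 = pos - 1
    if p0 < 0:
        raise ValueError("position must be >= 1")
    observed = ref_slice(reference, chrom, p0, p0 + len(r))
    if observed != r:
        raise ReferenceMismatchError(
            f"{chrom}:{pos} REF {r!r} does not match reference {observed!r}"
        )
    # right-trim with left extension (left-aligns indels through repeats)
    while r[-1] == a[-1]:
        if len(r) > 1 and len(a) > 1:
            r, a = r[:-1], a[:-1]
        elif p0 > 0:
            p0 -= 1
            b = ref_slice(reference, chrom, p0, p0 + 1)
            r, a = b + r, b + a
        else:
            break  # contig edge: keep right-anchored representation
    # left-trim shared prefix, keeping one anchor base for indels
    while len(r) > 1 and len(a) > 1 and r[0] == a[0]:
        r, a = r[1:], a[1:]
        p0 += 1
    return NormalizedAllele(chrom=chrom, pos=p0 + 1, ref=r, alt=a)


# -- truth table --------------------------------------------------------------


def read_truth_table(
    path, models: Optional[Mapping[str, "object"]] = None
) -> tuple[list[TruthVariant], list[dict]]:
    """Read the truth-table TSV.

    Returns ``(records, rejects)``.  A row whose ``pos`` is empty but whose
    ``hgvs_c`` is present is resolved through the gene model (when
    ``models`` is given).  Rows that cannot be turned into a record are
    collected into ``rejects`` (dicts with ``line``, ``reason`` and the raw
    fields), never silently dropped.
    """
    from .gene_models import hgvs_c_to_genomic  # local import to avoid cycle

    records: list[TruthVariant] = []
    rejects: list[dict] = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in _TRUTH_REQUIRED if c not in header]
                if missing:
                    raise TruthTableError(
                        f"{path}: missing mandatory column(s) {missing}"
                    )
                continue
            row = {k: v for k, v in zip(header, fields)}
            try:
                pos_text = row.get("pos", "").strip()
                if pos_text:
                    pos = int(pos_text)
                elif row.get("hgvs_c"):
                    if models is None or row["gene"] not in models:
                        raise ValueError(
                            "no genomic position and no gene model to resolve "
                            f"hgvs_c {row['hgvs_c']!r}"
                        )
                    pos = hgvs_c_to_genomic(models[row["gene"]], row["hgvs_c"])
                else:
                    raise ValueError("row has neither pos nor hgvs_c")
                records.append(
                    TruthVariant(
                        patient_id=row["patient_id"],
                        gene=row["gene"],
                        chrom=row["chrom"],
                        pos=pos,
                        ref=row["ref"].upper(),
                        alt=row["alt"].upper(),
                        zygosity=row["zygosity"].strip().lower(),
                        hgvs_c=row.get("hgvs_c") or None,
                        dbsnp_id=row.get("dbsnp_id") or None,
                        source_test=row.get("source_test") or None,
                    )
                )
            except (ValueError, KeyError) as exc:
                rejects.append({"line": lineno, "reason": str(exc), **row})
    if header is None:
        raise TruthTableError(f"{path}: empty truth table")
    return records, rejects


def write_truth_table(records: Iterable[TruthVariant], path) -> None:
    cols = _TRUTH_REQUIRED + _TRUTH_OPTIONAL
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in records:
            fh.write(
                "\t".join(
                    [
                        t.patient_id,
                        t.gene,
                        t.chrom,
                        str(t.pos),
                        t.ref,
                        t.alt,
                        t.zygosity,
                        t.hgvs_c or "",
                        t.dbsnp_id or "",
                        t.source_test or "",
                    ]
                )
                + "\n"
            )


def write_rejects(rejects: Sequence[dict], path) -> None:
    cols = ["line", "reason"] + _TRUTH_REQUIRED + _TRUTH_OPTIONAL
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rejects:
            fh.write("\t".join(str(r.get(c, "")) for c in cols) + "\n")


# -- VCF ----------------------------------------------------------------------


def _zygosity_from_gt(gt: Optional[tuple], allele_index: int) -> Optional[str]:
    """Zygosity of one alternate from a GT tuple; None if the alternate is
    not present in the genotype."""
    if gt is None or all(g is None for g in gt):
        return MISSING
    count = sum(1 for g in gt if g == allele_index)
    if count == 0:
        return None
    if len(gt) == 1:
        return HEMI
    return HOM if count == len(gt) else HET


def read_vcf(path, sample: Optional[str] = None) -> tuple[str, list[CalledVariant]]:
    """Read a VCF 4.x file into per-alternate :class:`CalledVariant` records.

    Multi-allelic records are split; the zygosity of each alternate comes
    only from the GT field (``0/1`` het, ``1/1`` hom, ``1/2`` het for each
    alternate, ``./.`` missing; phased separators are treated like
    unphased).  Depth prefers FORMAT/DP, then INFO/DP; absent depth is left
    as None for later lookup in a depth track.  The FILTER column is
    ignored (the comparison is against the unfiltered call set).

    Returns ``(sample_name, records)``.
    """
    try:
        vf = pysam.VariantFile(os.fspath(path))
    except (OSError, ValueError) as exc:
        raise VcfFormatError(f"{path}: cannot read VCF: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        if sample is None:
            if not samples:
                raise VcfFormatError(f"{path}: VCF has no sample columns")
            sample = samples[0]
        elif sample not in samples:
            raise VcfFormatError(f"{path}: sample {sample!r} not in VCF")
        out: list[CalledVariant] = []
        for rec in vf:
            try:
                sm = rec.samples[sample]
                gt = sm.get("GT")
                dp = sm.get("DP")
                if dp is None:
                    dp = rec.info.get("DP")
                alts = rec.alts or ()
                for i, alt in enumerate(alts, start=1):
                    if alt is None or alt.startswith("<"):
                        continue  # symbolic alleles are out of scope
                    zyg = _zygosity_from_gt(gt, i)
                    if zyg is None:
                        continue  # alternate absent from the genotype
                    out.append(
                        CalledVariant(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref.upper(),
                            alt=alt.upper(),
                            zygosity=zyg,
                            site_depth=int(dp) if dp is not None else None,
                            qual=rec.qual,
                        )
                    )
            except (ValueError, TypeError) as exc:
                raise VcfFormatError(
                    f"{path}: bad record at {rec.chrom}:{rec.pos}: {exc}"
                ) from exc
    return sample, out


_GT_BY_ZYGOSITY = {HET: (0, 1), HOM: (1, 1), HEMI: (1,), MISSING: (None, None)}


def write_vcf(
    calls: Sequence[CalledVariant],
    sample: str,
    path,
    contigs: Mapping[str, int],
) -> None:
    """Write calls as a single-sample uncompressed VCF (GT and DP FORMAT)."""
    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth at the site")
    header.add_sample(sample)
    ordered = sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for c in ordered:
            rec = out.new_record(
                contig=c.chrom,
                start=c.pos - 1,
                alleles=(c.ref, c.alt),
                qual=c.qual,
            )
            rec.samples[sample]["GT"] = _GT_BY_ZYGOSITY[c.zygosity]
            rec.samples[sample].phased = False
            if c.site_depth is not None:
                rec.samples[sample]["DP"] = c.site_depth
            out.write(rec)
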