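"""Gene/transcript coordinate machinery.

One :class:`GeneModel` per gene stores the transcript's exons as genomic
intervals (0-based, half-open, in genomic order) plus optional CDS bounds.
Three kinds of questions are answered here:

* where does a genomic position sit relative to the transcript
  (:func:`classify_position`) — coding, UTR, near-exon intronic, deep
  intronic, or outside the transcript entirely;
* what genomic base does an HGVS coding-DNA position like ``c.76+9`` refer
  to (:func:`hgvs_c_to_genomic`, with :func:`genomic_to_hgvs_c` as its
  inverse);
* what is the GC fraction of a sequence (:func:`gc_content`).

Region classification is strand-agnostic (it works on genomic intervals);
HGVS conversion walks the transcript in transcript orientation and is
strand-aware.  Exon lists are always stored in genomic order regardless of
strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

__all__ = [
    "GeneModel",
    "RegionLabel",
    "GeneModelError",
    "HgvsParseError",
    "HgvsRangeError",
    "CODING",
    "INTRONIC_NEAR",
    "INTRONIC_DEEP",
    "UTR",
    "OUTSIDE_TRANSCRIPT",
    "NEAR_INTRON_MAX",
    "classify_position",
    "region_stratum",
    "hgvs_c_to_genomic",
    "genomic_to_hgvs_c",
    "gc_content",
    "read_gene_models_tsv",
    "read_gene_models_bed12",
    "write_gene_models_tsv",
]


class GeneModelError(ValueError):
    """Structurally invalid gene model."""


class HgvsParseError(ValueError):
    """Unparseable HGVS c. position string."""


class HgvsRangeError(ValueError):
    """HGVS position walks outside the representable span."""


# Region categories
CODING = "coding"
INTRONIC_NEAR = "intronic_near"
INTRONIC_DEEP = "intronic_deep"
UTR = "utr"
OUTSIDE_TRANSCRIPT = "outside_transcript"

#: An intronic base within this many bp of the nearest exon counts as
#: "near"; the first intronic base on either side has distance 1 and the
#: bound is inclusive.
NEAR_INTRON_MAX = 20


@dataclass(frozen=True)
class RegionLabel:
    """Classification of one genomic position relative to a transcript.

    ``distance_to_exon`` is 0 for exonic positions and uses the HGVS-style
    convention otherwise: the first base beyond an exon boundary (into an
    intron or beyond the transcript edge) has distance 1.
    """

    category: str
    distance_to_exon: int


@dataclass(frozen=True)
class GeneModel:
    """A single transcript: exons in genomic order plus optional CDS bounds.

    Coordinates are 0-based half-open.  ``flank_pad`` widens each exon when
    building the coverage footprint (the base set over which per-gene
    coverage fractions are computed).
    """

    gene_name: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    flank_pad: int = 20

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"{self.gene_name}: strand must be '+' or '-'")
        if not self.exons:
            raise GeneModelError(f"{self.gene_name}: no exons")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if s < 0 or e <= s:
                raise GeneModelError(
                    f"{self.gene_name}: bad exon interval [{s},{e})"
                )
            if prev_end is not None and s < prev_end:
                raise GeneModelError(
                    f"{self.gene_name}: exons unsorted or overlapping"
                )
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise GeneModelError(
                f"{self.gene_name}: cds_start and cds_end must be set together"
            )
        if self.cds_start is not None:
            if not (
                exons[0][0] <= self.cds_start < self.cds_end <= exons[-1][1]
            ):
                raise GeneModelError(
                    f"{self.gene_name}: CDS bounds outside exon span"
                )
        if self.flank_pad < 0:
            raise GeneModelError(f"{self.gene_name}: negative flank_pad")

    # -- geometry ---------------------------------------------------------

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def footprint(self, flank_pad: Optional[int] = None) -> list[tuple[int, int]]:
        """Union of exons each widened by ``flank_pad``, clipped at 0."""
        pad = self.flank_pad if flank_pad is None else flank_pad
        merged: list[list[int]] = []
        for s, e in self.exons:
            s, e = max(0, s - pad), e + pad
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]

    def footprint_bases(self, flank_pad: Optional[int] = None) -> int:
        return sum(e - s for s, e in self.footprint(flank_pad))

    # transcript-order genomic positions of exonic bases
    def _tx_positions(self) -> list[int]:
        pos = [p for s, e in self.exons for p in range(s, e)]
        if self.strand == "-":
            pos.reverse()
        return pos


def classify_position(
    model: GeneModel, pos: int, near_max: int = NEAR_INTRON_MAX
) -> RegionLabel:
    """Classify a 1-based genomic position relative to ``model``.

    Exonic positions are ``coding`` (inside the CDS) or ``utr``; intronic
    positions are near/deep by distance to the closer flanking exon
    boundary; positions beyond the transcript get ``outside_transcript``
    with the distance from the transcript edge.
    """
    if pos < 1:
        raise ValueError("genomic position must be >= 1")
    p = pos - 1
    exons = model.exons
    if p < exons[0][0]:
        return RegionLabel(OUTSIDE_TRANSCRIPT, exons[0][0] - p)
    if p >= exons[-1][1]:
        return RegionLabel(OUTSIDE_TRANSCRIPT, p - exons[-1][1] + 1)
    for i, (s, e) in enumerate(exons):
        if s <= p < e:
            if model.is_coding and model.cds_start <= p < model.cds_end:
                return RegionLabel(CODING, 0)
            return RegionLabel(UTR, 0)
        if p < s:  # in the intron between exon i-1 and exon i
            d_left = p - exons[i - 1][1] + 1
            d_right = s - p
            d = min(d_left, d_right)
            return RegionLabel(INTRONIC_NEAR if d <= near_max else INTRONIC_DEEP, d)
    raise AssertionError("unreachable")  # pragma: no cover


def region_stratum(label: RegionLabel, near_max: int = NEAR_INTRON_MAX) -> str:
    """Map a region label onto the reporting strata.

    Coding positions form their own stratum; every noncoding position is
    binned by its distance to the nearest exon with the same inclusive
    ``near_max`` bound, so exonic UTR bases (distance 0) report as
    near-exon noncoding and far-upstream positions as deep noncoding.
    """
    if label.category == CODING:
        return CODING
    return INTRONIC_NEAR if label.distance_to_exon <= near_max else INTRONIC_DEEP


# -- HGVS c. <-> genomic ---------------------------------------------------

_HGVS_C = re.compile(
    r"^c\.(?P<anchor>(?:-|\*)?\d+)(?P<offset>[+-]\d+)?$"
)


def _tx_index_to_genomic(model: GeneModel, idx: int) -> int:
    """Genomic 0-based position of transcript index ``idx``.

    Indices beyond the transcript extend linearly off the ends (strand
    aware), so positions upstream of the first exon / downstream of the
    last remain addressable (e.g. a variant 176 nt upstream of a gene).
    """
    tx = model._tx_positions()
    n = len(tx)
    sign = 1 if model.strand == "+" else -1
    if idx < 0:
        g = tx[0] + sign * idx
    elif idx >= n:
        g = tx[-1] + sign * (idx - (n - 1))
    else:
        return tx[idx]
    if g < 0:
        raise HgvsRangeError("position walks before the start of the contig")
    return g


def _cds_tx_bounds(model: GeneModel) -> tuple[int, int]:
    """Transcript indices of the first and last coding base."""
    if not model.is_coding:
        raise HgvsParseError(
            f"{model.gene_name}: transcript has no CDS; c. numbering undefined"
        )
    tx = model._tx_positions()
    coding_idx = [
        i for i, g in enumerate(tx) if model.cds_start <= g < model.cds_end
    ]
    if not coding_idx:
        raise GeneModelError(f"{model.gene_name}: CDS covers no exonic base")
    return coding_idx[0], coding_idx[-1]


def hgvs_c_to_genomic(model: GeneModel, cdna_string: str) -> int:
    """Resolve an HGVS c. position (``c.76``, ``c.76+9``, ``c.-30``,
    ``c.*12`` ...) to a 1-based genomic coordinate.

    Coding positions are counted along exons in transcript orientation;
    ``+k``/``-k`` intronic offsets step into the adjacent intron from the
    anchoring exonic base; ``-N``/``*N`` number the 5'/3' UTR (continuing
    past the transcript edge if N exceeds the UTR length).
    """
    m = _HGVS_C.match(cdna_string.strip())
    if not m:
        raise HgvsParseError(f"cannot parse HGVS c. position: {cdna_string!r}")
    anchor = m.group("anchor")
    first_c, last_c = _cds_tx_bounds(model)
    if anchor.startswith("-"):
        idx = first_c - int(anchor[1:])
    elif anchor.startswith("*"):
        idx = last_c + int(anchor[1:])
    else:
        n = int(anchor)
        if n < 1:
            raise HgvsParseError(f"coding position must be >= 1: {cdna_string!r}")
        idx = first_c + n - 1
        if idx > last_c:
            raise HgvsRangeError(
                f"{cdna_string!r}: c.{n} beyond the last coding base "
                f"(c.{last_c - first_c + 1}) of {model.gene_name}"
            )
    offset = m.group("offset")
    if offset is None:
        return _tx_index_to_genomic(model, idx) + 1
    n_tx = len(model._tx_positions())
    if idx < 0 or idx >= n_tx:
        raise HgvsRangeError(
            f"{cdna_string!r}: intronic offset from a position outside the transcript"
        )
    g = _tx_index_to_genomic(model, idx)
    k = int(offset)
    sign = 1 if model.strand == "+" else -1
    g2 = g + sign * k
    if g2 < 0:
        raise HgvsRangeError(f"{cdna_string!r} walks before the contig start")
    return g2 + 1


def genomic_to_hgvs_c(model: GeneModel, pos: int) -> str:
    """Inverse of :func:`hgvs_c_to_genomic` (canonical form).

    Exonic bases map to plain/UTR numbering; intronic bases anchor to the
    closer exon boundary in transcript orientation (ties anchor upstream);
    positions beyond the transcript continue the UTR numbering.
    """
    if pos < 1:
        raise ValueError("genomic position must be >= 1")
    p = pos - 1
    tx = model._tx_positions()
    first_c, last_c = _cds_tx_bounds(model)

    def _anchor_str(idx: int) -> str:
        if idx < first_c:
            return f"-{first_c - idx}"
        if idx > last_c:
            return f"*{idx - last_c}"
        return f"{idx - first_c + 1}"

    # exonic?
    for i, (s, e) in enumerate(model.exons):
        if s <= p < e:
            idx = tx.index(p)
            return f"c.{_anchor_str(idx)}"
    # outside the transcript: extend UTR numbering linearly
    if p < model.tx_start or p >= model.tx_end:
        if p < model.tx_start:
            d = model.tx_start - p
            edge_idx = 0 if model.strand == "+" else len(tx) - 1
        else:
            d = p - model.tx_end + 1
            edge_idx = len(tx) - 1 if model.strand == "+" else 0
        idx = edge_idx - d if edge_idx == 0 else edge_idx + d
        return f"c.{_anchor_str(idx)}"
    # intronic: distances to flanking exon boundaries in genomic terms
    for i in range(len(model.exons) - 1):
        left_end = model.exons[i][1]
        right_start = model.exons[i + 1][0]
        if left_end <= p < right_start:
            d_left = p - left_end + 1  # from exon i's last base
            d_right = right_start - p  # from exon i+1's first base
            if model.strand == "+":
                up_idx, up_d = tx.index(left_end - 1), d_left
                down_idx, down_d = tx.index(right_start), d_right
            else:
                up_idx, up_d = tx.index(right_start), d_right
                down_idx, down_d = tx.index(left_end - 1), d_left
            if up_d <= down_d:
                return f"c.{_anchor_str(up_idx)}+{up_d}"
            return f"c.{_anchor_str(down_idx)}-{down_d}"
    raise AssertionError("unreachable")  # pragma: no cover


# -- GC content ------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def gc_content(sequence: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T); Ns are excluded from the denominator."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGTN"}
    if sum(counts.values()) != len(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"sequence contains non-ACGTN characters: {bad}")
    denom = len(seq) - counts["N"]
    if denom == 0:
        raise ValueError("sequence is all N; GC content undefined")
    return (counts["G"] + counts["C"]) / denom


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


# -- file formats -----------------------------------------------------------

_TSV_COLUMNS = [
    "gene",
    "chrom",
    "strand",
    "exon_starts",
    "exon_ends",
    "cds_start",
    "cds_end",
    "flank_pad",
]


def read_gene_models_tsv(path) -> dict[str, GeneModel]:
    """Read the package's gene-model TSV dialect.

    Header columns: gene, chrom, strand, exon_starts, exon_ends
    (comma-separated 0-based half-open bounds), cds_start, cds_end (both
    empty for a noncoding transcript), flank_pad (optional, default 20).
    Lines starting with ``#`` are comments.
    """
    models: dict[str, GeneModel] = {}
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in _TSV_COLUMNS[:7] if c not in header]
                if missing:
                    raise GeneModelError(
                        f"{path}: missing gene-model columns {missing}"
                    )
                continue
            row = dict(zip(header, fields))
            starts = [int(x) for x in row["exon_starts"].split(",") if x]
            ends = [int(x) for x in row["exon_ends"].split(",") if x]
            if len(starts) != len(ends):
                raise GeneModelError(
                    f"{path}:{lineno}: exon_starts/exon_ends length mismatch"
                )
            cds_s = int(row["cds_start"]) if row.get("cds_start") else None
            cds_e = int(row["cds_end"]) if row.get("cds_end") else None
            pad = int(row["flank_pad"]) if row.get("flank_pad") else 20
            model = GeneModel(
                gene_name=row["gene"],
                chrom=row["chrom"],
                strand=row["strand"],
                exons=tuple(zip(starts, ends)),
                cds_start=cds_s,
                cds_end=cds_e,
                flank_pad=pad,
            )
            models[model.gene_name] = model
    if header is None:
        raise GeneModelError(f"{path}: empty gene-model file")
    return models


def write_gene_models_tsv(models: Mapping[str, GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for m in models.values():
            fh.write(
                "\t".join(
                    [
                        m.gene_name,
                        m.chrom,
                        m.strand,
                        ",".join(str(s) for s, _ in m.exons),
                        ",".join(str(e) for _, e in m.exons),
                        "" if m.cds_start is None else str(m.cds_start),
                        "" if m.cds_end is None else str(m.cds_end),
                        str(m.flank_pad),
                    ]
                )
                + "\n"
            )


def read_gene_models_bed12(path, flank_pad: int = 20) -> dict[str, GeneModel]:
    """Read gene models from BED12 (thickStart/thickEnd as CDS bounds).

    A record with thickStart == thickEnd is treated as noncoding.
    """
    models: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise GeneModelError(f"{path}:{lineno}: BED12 needs 12 columns")
            chrom, start = f[0], int(f[1])
            name, strand = f[3], f[5]
            thick_s, thick_e = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != int(f[9]) or len(offsets) != int(f[9]):
                raise GeneModelError(f"{path}:{lineno}: blockCount mismatch")
            exons = tuple(
                (start + o, start + o + sz) for o, sz in zip(offsets, sizes)
            )
            coding = thick_e > thick_s
            models[name] = GeneModel(
                gene_name=name,
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds_start=thick_s if coding else None,
                cds_end=thick_e if coding else None,
                flank_pad=flank_pad,
            )
    return models
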