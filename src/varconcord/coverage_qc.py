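"""Per-base depth handling and per-gene coverage QC.

A :class:`DepthTrack` maps genomic intervals to read depth; positions
absent from the track have depth 0.  On top of it sit the per-gene
coverage fraction (share of the gene footprint with depth strictly above a
threshold), the exclusion rule that drops genes whose fraction falls below
a minimum (default: less than 75% of the footprint above 20x), single-base
depth lookup, and region-set exceedance summaries (share of bases above
10x / 20x, the conventional exome coverage report).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .gene_models import GeneModel

__all__ = [
    "DepthTrack",
    "GeneCoverageStat",
    "DepthTrackError",
    "read_depth_track",
    "write_depth_track",
    "gene_coverage_fraction",
    "flag_low_coverage_genes",
    "position_depth",
    "coverage_summary",
    "read_bed3",
]


class DepthTrackError(ValueError):
    """Malformed depth input (negative depth, unsorted/overlapping runs)."""


@dataclass(frozen=True)
class GeneCoverageStat:
    """Coverage verdict for one gene footprint."""

    gene: str
    footprint_bases: int
    fraction_over_threshold: float
    excluded: bool
    gc_fraction: Optional[float] = None


class DepthTrack:
    """Non-overlapping depth runs per chromosome (0-based half-open)."""

    def __init__(self, runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._runs = runs

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int, int]]) -> "DepthTrack":
        """Build from (chrom, start, end, depth) tuples; runs on a
        chromosome must not overlap."""
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for chrom, s, e, d in intervals:
            if d < 0:
                raise DepthTrackError(f"negative depth {d} at {chrom}:{s}-{e}")
            if e <= s:
                raise DepthTrackError(f"empty/inverted interval {chrom}:{s}-{e}")
            by_chrom.setdefault(chrom, []).append((int(s), int(e), int(d)))
        runs = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
            depths = np.array([d for _, _, d in ivs], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise DepthTrackError(f"{chrom}: overlapping depth intervals")
            runs[chrom] = (starts, ends, depths)
        return cls(runs)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._runs)

    def intervals(self) -> Iterable[tuple[str, int, int, int]]:
        for chrom in self.chroms:
            starts, ends, depths = self._runs[chrom]
            for s, e, d in zip(starts, ends, depths):
                yield chrom, int(s), int(e), int(d)

    def depth_at(self, chrom: str, pos0: int) -> int:
        """Depth at a single 0-based position (0 when absent)."""
        if chrom not in self._runs:
            return 0
        starts, ends, depths = self._runs[chrom]
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        if i >= 0 and pos0 < ends[i]:
            return int(depths[i])
        return 0

    def overlap(self, chrom: str, start: int, end: int):
        """Yield (start, end, depth) runs clipped to [start, end)."""
        if chrom not in self._runs or end <= start:
            return
        starts, ends, depths = self._runs[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            yield max(start, int(starts[i])), min(end, int(ends[i])), int(depths[i])

    def bases_over(self, chrom: str, start: int, end: int, threshold: int) -> int:
        """Number of bases in [start, end) with depth strictly > threshold."""
        return sum(e - s for s, e, d in self.overlap(chrom, start, end) if d > threshold)


# -- I/O ------------------------------------------------------------------


def read_depth_track(path) -> DepthTrack:
    """Read a depth track; dialect is auto-detected by column count.

    3 columns: samtools-depth style (chrom, 1-based position, depth).
    4 columns: bedGraph (chrom, 0-based start, end, depth); intervals must
    be sorted and non-overlapping within a chromosome.
    """
    intervals: list[tuple[str, int, int, int]] = []
    ncols = None
    # run-compression state for the 3-column dialect
    cur: Optional[list] = None  # [chrom, start0, end0, depth]
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if ncols is None:
                if len(f) not in (3, 4):
                    raise DepthTrackError(
                        f"{path}:{lineno}: expected 3 (samtools depth) or 4 "
                        f"(bedGraph) columns, got {len(f)}"
                    )
                ncols = len(f)
            elif len(f) != ncols:
                raise DepthTrackError(f"{path}:{lineno}: inconsistent column count")
            try:
                if ncols == 3:
                    chrom, pos, d = f[0], int(f[1]), int(f[2])
                    if d < 0:
                        raise ValueError(f"negative depth {d}")
                    p0 = pos - 1
                    if cur is not None and cur[0] == chrom and cur[2] == p0 and cur[3] == d:
                        cur[2] += 1
                    else:
                        if cur is not None:
                            intervals.append(tuple(cur))
                        cur = [chrom, p0, p0 + 1, d]
                else:
                    chrom, s, e, d = f[0], int(f[1]), int(f[2]), int(f[3])
                    if d < 0:
                        raise ValueError(f"negative depth {d}")
                    intervals.append((chrom, s, e, d))
            except ValueError as exc:
                raise DepthTrackError(f"{path}:{lineno}: {exc}") from exc
    if cur is not None:
        intervals.append(tuple(cur))
    try:
        return DepthTrack.from_intervals(intervals)
    except DepthTrackError as exc:
        raise DepthTrackError(f"{path}: {exc}") from exc


def write_depth_track(track: DepthTrack, path) -> None:
    """Write a track as bedGraph, skipping zero-depth runs."""
    with open(path, "w") as fh:
        for chrom, s, e, d in track.intervals():
            if d > 0:
                fh.write(f"{chrom}\t{s}\t{e}\t{d}\n")


def read_bed3(path) -> list[tuple[str, int, int]]:
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            regions.append((f[0], int(f[1]), int(f[2])))
    return regions


# -- per-gene QC -----------------------------------------------------------


def gene_coverage_fraction(
    track: DepthTrack,
    model: GeneModel,
    depth_threshold: int = 20,
    min_fraction: float = 0.75,
    gc_fraction: Optional[float] = None,
) -> GeneCoverageStat:
    """Fraction of the gene footprint with depth strictly > depth_threshold.

    The footprint is the exon union widened by the model's flank pad; a
    gene is excluded when its fraction falls below ``min_fraction`` (strict
    inequality: exactly 75% is kept).
    """
    footprint = model.footprint()
    total = sum(e - s for s, e in footprint)
    if total == 0:
        raise ValueError(f"{model.gene_name}: empty coverage footprint")
    over = sum(
        track.bases_over(model.chrom, s, e, depth_threshold) for s, e in footprint
    )
    frac = over / total
    return GeneCoverageStat(
        gene=model.gene_name,
        footprint_bases=total,
        fraction_over_threshold=frac,
        excluded=frac < min_fraction,
        gc_fraction=gc_fraction,
    )


def flag_low_coverage_genes(
    stats: Sequence[GeneCoverageStat], min_fraction: float = 0.75
) -> set[str]:
    """Genes whose covered fraction is strictly below ``min_fraction``."""
    return {s.gene for s in stats if s.fraction_over_threshold < min_fraction}


def position_depth(track: DepthTrack, chrom: str, pos: int) -> int:
    """Depth at a 1-based genomic position (0 when absent from the track)."""
    return track.depth_at(chrom, pos - 1)


def coverage_summary(
    track: DepthTrack, regions: Sequence[tuple[str, int, int]]
) -> tuple[float, float]:
    """Fractions of region bases with depth > 10 and > 20."""
    total = sum(e - s for _, s, e in regions)
    if total == 0:
        raise ValueError("empty region set")
    over10 = sum(track.bases_over(c, s, e, 10) for c, s, e in regions)
    over20 = sum(track.bases_over(c, s, e, 20) for c, s, e in regions)
    return over10 / total, over20 / total
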