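"""End-to-end orchestration: coverage QC -> gene exclusion -> matching ->
adjudication -> stratified table -> reports on disk.

The analysis path contains no randomness; every number in the rendered
reports is recomputable from the per-variant TSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .concordance import (
    AdjudicatedRecord,
    ConcordanceRecord,
    ConcordanceTable,
    adjudicate,
    concordance_table,
    gene_breakdown,
    match_all,
)
from .coverage_qc import (
    DepthTrack,
    GeneCoverageStat,
    flag_low_coverage_genes,
    gene_coverage_fraction,
    read_depth_track,
)
from .gene_models import GeneModel, gc_content, read_gene_models_tsv
from .synthetic import StudyBundle, read_confirmatory
from .variant_io import read_truth_table, read_vcf, ref_slice, write_rejects

logger = logging.getLogger("varconcord")

__all__ = ["Thresholds", "AnalysisResult", "analyze_bundle", "analyze_paths",
           "write_reports"]


@dataclass(frozen=True)
class Thresholds:
    """Every tunable cut of the comparison, in one place."""

    coverage_depth: int = 20  # per-base depth must exceed this
    coverage_min_fraction: float = 0.75  # gene kept iff fraction >= this
    low_depth_below: int = 10  # variant flagged when depth < this
    intronic_near_max: int = 20  # near/deep intronic boundary (inclusive)

    def as_dict(self) -> dict:
        return {
            "coverage_depth": self.coverage_depth,
            "coverage_min_fraction": self.coverage_min_fraction,
            "low_depth_below": self.low_depth_below,
            "intronic_near_max": self.intronic_near_max,
        }


@dataclass
class AnalysisResult:
    records: list[ConcordanceRecord]
    adjudicated: Optional[list[AdjudicatedRecord]]
    table: ConcordanceTable
    coverage_stats: list[GeneCoverageStat]
    excluded_genes: set[str]
    breakdown: list[dict]
    thresholds: Thresholds
    rejects: list[dict] = field(default_factory=list)


def _gene_gc(model: GeneModel, reference) -> Optional[float]:
    try:
        seq = "".join(
            ref_slice(reference, model.chrom, s, e) for s, e in model.footprint()
        )
        return gc_content(seq)
    except (KeyError, ValueError):
        return None


def analyze_bundle(
    bundle: StudyBundle,
    thresholds: Optional[Thresholds] = None,
    use_confirmatory: bool = True,
    rejects: Optional[Sequence[dict]] = None,
) -> AnalysisResult:
    """Run the full comparison on in-memory study inputs."""
    th = thresholds or Thresholds()
    logger.info("thresholds: %s", th.as_dict())
    coverage_stats = [
        gene_coverage_fraction(
            bundle.depth_track,
            model,
            depth_threshold=th.coverage_depth,
            min_fraction=th.coverage_min_fraction,
            gc_fraction=_gene_gc(model, bundle.reference),
        )
        for model in bundle.models.values()
    ]
    excluded = flag_low_coverage_genes(coverage_stats, th.coverage_min_fraction)
    logger.info("excluded %d of %d genes: %s", len(excluded),
                len(bundle.models), sorted(excluded))
    records = match_all(
        bundle.truth,
        bundle.calls_by_patient,
        bundle.depth_track,
        bundle.reference,
        bundle.models,
        excluded_genes=excluded,
        near_max=th.intronic_near_max,
        low_depth_below=th.low_depth_below,
    )
    adjudicated = None
    if use_confirmatory and bundle.confirmatory:
        adjudicated = adjudicate(records, bundle.confirmatory)
    table = concordance_table(records, adjudicated, near_max=th.intronic_near_max)
    return AnalysisResult(
        records=records,
        adjudicated=adjudicated,
        table=table,
        coverage_stats=coverage_stats,
        excluded_genes=excluded,
        breakdown=gene_breakdown(records),
        thresholds=th,
        rejects=list(rejects or []),
    )


def analyze_paths(
    truth_path,
    vcf_paths: Sequence,
    depth_path,
    genes_path,
    reference_path,
    confirmatory_path=None,
    thresholds: Optional[Thresholds] = None,
) -> AnalysisResult:
    """Run the full comparison from files on disk."""
    from pyfaidx import Fasta

    models = read_gene_models_tsv(genes_path)
    reference = Fasta(str(reference_path))
    truth, rejects = read_truth_table(truth_path, models=models)
    if rejects:
        logger.warning("%d truth rows rejected", len(rejects))
    track = read_depth_track(depth_path)
    calls = {}
    for vp in vcf_paths:
        sample, recs = read_vcf(vp)
        calls[sample] = recs
    confirmatory = read_confirmatory(confirmatory_path) if confirmatory_path else []
    bundle = StudyBundle(
        models=models,
        reference=reference,
        truth=truth,
        calls_by_patient=calls,
        depth_track=track,
        confirmatory=confirmatory,
        manifest={},
    )
    return analyze_bundle(bundle, thresholds=thresholds, rejects=rejects)


# -- reports -------------------------------------------------------------------

_RECORD_COLS = [
    "patient_id", "gene", "chrom", "pos", "ref", "alt", "zygosity",
    "status", "region", "distance_to_exon", "stratum", "site_depth",
    "low_depth", "gene_excluded", "called_zygosity", "resolution",
]


def write_reports(result: AnalysisResult, out_dir) -> None:
    """Write per-variant TSV, table TSV/JSON, plain-text summary, per-gene
    coverage TSV, per-gene coding breakdown TSV, and the rejects TSV."""
    from .concordance import _stratum_of  # stable stratum assignment

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = result.thresholds
    resolution_by_id = {}
    if result.adjudicated:
        resolution_by_id = {
            id(a.record): a.resolution for a in result.adjudicated
        }

    with open(out / "records.tsv", "w") as fh:
        fh.write("\t".join(_RECORD_COLS) + "\n")
        for rec in result.records:
            t = rec.truth
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        t.patient_id, t.gene, t.chrom, t.pos, t.ref, t.alt,
                        t.zygosity, rec.status, rec.region.category,
                        rec.region.distance_to_exon,
                        _stratum_of(rec, th.intronic_near_max),
                        rec.site_depth, rec.low_depth, rec.gene_excluded,
                        rec.matched_call.zygosity if rec.matched_call else "",
                        resolution_by_id.get(id(rec), ""),
                    ]
                )
                + "\n"
            )

    table_dict = result.table.as_dict()
    table_dict["thresholds"] = th.as_dict()
    with open(out / "concordance_table.json", "w") as fh:
        json.dump(table_dict, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(out / "concordance_table.tsv", "w") as fh:
        cols = ["stratum", "total", "concordant", "discordant_base",
                "discordant_zygosity", "missing", "indeterminate",
                "rate_percent", "n_patients"]
        fh.write("\t".join(cols) + "\n")
        for name, counts in result.table.rows.items():
            d = counts.as_dict()
            fh.write("\t".join([name] + [str(d[c]) for c in cols[1:]]) + "\n")
    with open(out / "summary.txt", "w") as fh:
        fh.write(result.table.render_text() + "\n")

    with open(out / "gene_coverage.tsv", "w") as fh:
        fh.write("gene\tfootprint_bases\tfraction_over_threshold\texcluded\tgc\n")
        for s in sorted(result.coverage_stats, key=lambda s: s.gene):
            gc = "" if s.gc_fraction is None else f"{s.gc_fraction:.3f}"
            fh.write(
                f"{s.gene}\t{s.footprint_bases}\t"
                f"{s.fraction_over_threshold:.4f}\t{s.excluded}\t{gc}\n"
            )

    with open(out / "gene_breakdown.tsv", "w") as fh:
        fh.write("gene\tsanger\twes\n")
        for row in result.breakdown:
            fh.write(f"{row['gene']}\t{row['sanger']}\t{row['wes']}\n")

    write_rejects(result.rejects, out / "rejects.tsv")
    logger.info("reports written to %s", out)
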