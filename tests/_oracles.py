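"""Independent brute-force oracles used by the test suite.

Each oracle is a direct transcription of a definition, kept deliberately
naive (per-base loops, exhaustive enumeration) and independent of the
implementation paths it checks.
"""

from __future__ import annotations

from varconcord.gene_models import GeneModel
from varconcord.variant_io import normalize


# -- region classification ----------------------------------------------------


def brute_region(model: GeneModel, pos: int, near_max: int = 20) -> tuple[str, int]:
    """Classify a 1-based position by scanning the interval definitions."""
    p = pos - 1
    for s, e in model.exons:
        if s <= p < e:
            if model.cds_start is not None and model.cds_start <= p < model.cds_end:
                return ("coding", 0)
            return ("utr", 0)
    if p < model.exons[0][0]:
        return ("outside_transcript", model.exons[0][0] - p)
    if p >= model.exons[-1][1]:
        return ("outside_transcript", p - model.exons[-1][1] + 1)
    dists = []
    for s, e in model.exons:
        if p < s:
            dists.append(s - p)
        elif p >= e:
            dists.append(p - e + 1)
    d = min(dists)
    return ("intronic_near" if d <= near_max else "intronic_deep", d)


# -- HGVS c. -> genomic -------------------------------------------------------


def brute_c_to_g_map(model: GeneModel) -> dict[str, int]:
    """Exhaustive c.-string -> 1-based genomic map for every exonic base and
    every intronic offset, built by direct transcript walking."""
    tx = [p for s, e in model.exons for p in range(s, e)]
    if model.strand == "-":
        tx.reverse()
    coding = [
        i for i, g in enumerate(tx) if model.cds_start <= g < model.cds_end
    ]
    first_c, last_c = coding[0], coding[-1]

    def name_of(idx: int) -> str:
        if idx < first_c:
            return f"-{first_c - idx}"
        if idx > last_c:
            return f"*{idx - last_c}"
        return str(idx - first_c + 1)

    out: dict[str, int] = {}
    for i, g in enumerate(tx):
        out[f"c.{name_of(i)}"] = g + 1
    # intronic offsets from each exon boundary, in transcript orientation
    sign = 1 if model.strand == "+" else -1
    n_ex = len(model.exons)
    # transcript-ordered exon index list
    order = range(n_ex) if model.strand == "+" else range(n_ex - 1, -1, -1)
    order = list(order)
    for k, ei in enumerate(order):
        s, e = model.exons[ei]
        last_base = e - 1 if model.strand == "+" else s
        first_base = s if model.strand == "+" else e - 1
        if k < n_ex - 1:  # intron after this exon (transcript order)
            intron_len = (
                model.exons[ei + 1][0] - e
                if model.strand == "+"
                else s - model.exons[ei - 1][1]
            )
            for off in range(1, intron_len + 1):
                idx = tx.index(last_base)
                out[f"c.{name_of(idx)}+{off}"] = last_base + sign * off + 1
        if k > 0:  # intron before this exon (transcript order)
            intron_len = (
                s - model.exons[ei - 1][1]
                if model.strand == "+"
                else model.exons[ei + 1][0] - e
            )
            for off in range(1, intron_len + 1):
                idx = tx.index(first_base)
                out[f"c.{name_of(idx)}-{off}"] = first_base - sign * off + 1
    return out


# -- variant representation equivalence ---------------------------------------


def apply_edit(ref_seq: str, pos: int, ref: str, alt: str) -> str:
    p0 = pos - 1
    assert ref_seq[p0 : p0 + len(ref)] == ref
    return ref_seq[:p0] + alt + ref_seq[p0 + len(ref) :]


def equivalent_representations(
    ref_seq: str, edited: str, max_len: int = 8
) -> list[tuple[int, str, str]]:
    """All (pos, ref, alt) with allele length <= max_len whose application
    to ref_seq yields ``edited``."""
    reps = []
    for p0 in range(len(ref_seq)):
        if edited[:p0] != ref_seq[:p0]:
            break  # an earlier base differs; no representation can start here
        for lr in range(1, max_len + 1):
            if p0 + lr > len(ref_seq):
                break
            la = len(edited) - (len(ref_seq) - lr)
            if la < 1 or la > max_len:
                continue
            if ref_seq[p0 + lr :] != edited[p0 + la :]:
                continue
            ref, alt = ref_seq[p0 : p0 + lr], edited[p0 : p0 + la]
            if ref != alt:
                reps.append((p0 + 1, ref, alt))
    return reps


# -- per-base coverage loop ----------------------------------------------------


def brute_coverage_fraction(track, model: GeneModel, threshold: int = 20) -> float:
    total = over = 0
    for s, e in model.footprint():
        for p in range(s, e):
            total += 1
            if track.depth_at(model.chrom, p) > threshold:
                over += 1
    return over / total


# -- quadratic concordance matcher --------------------------------------------


def quadratic_counts(
    truths, calls_by_patient, reference, models, excluded, near_max=20
) -> dict[str, dict[str, int]]:
    """Naive matcher: compare every truth row against every call of its
    patient; tally per reporting stratum."""
    strata = ["coding", "intronic_near", "intronic_deep", "excluded_genes"]
    counts = {
        s: {"total": 0, "concordant": 0, "discordant_base": 0,
            "discordant_zygosity": 0, "missing": 0}
        for s in strata
    }
    for t in truths:
        nt = normalize(t.chrom, t.pos, t.ref, t.alt, reference)
        status = "missing"
        base_hit = False
        for c in calls_by_patient.get(t.patient_id, []):
            nc = normalize(c.chrom, c.pos, c.ref, c.alt, reference)
            if (nc.chrom, nc.pos) != (nt.chrom, nt.pos):
                continue
            if (nc.ref, nc.alt) == (nt.ref, nt.alt):
                zt = "hom" if t.zygosity == "hemi" else t.zygosity
                zc = "hom" if c.zygosity == "hemi" else c.zygosity
                status = "concordant" if zt == zc else "discordant_zygosity"
                base_hit = False
                break
            base_hit = True
        if status == "missing" and base_hit:
            status = "discordant_base"
        model = models[t.gene]
        if t.gene in excluded:
            stratum = "excluded_genes"
        else:
            cat, dist = brute_region(model, t.pos, near_max)
            if cat == "coding":
                stratum = "coding"
            else:
                stratum = "intronic_near" if dist <= near_max else "intronic_deep"
        counts[stratum]["total"] += 1
        counts[stratum][status] += 1
    return counts


# -- toy caller rule transcription --------------------------------------------


def caller_rules(ref_reads: int, alt_reads: int) -> str:
    total = ref_reads + alt_reads
    if total < 3:
        return "no_call"
    if alt_reads / total < 0.20:
        return "ref"
    if alt_reads / total >= 0.80:
        return "hom"
    return "het"


# -- exact binomial interval ---------------------------------------------------


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    from scipy.stats import beta

    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi
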