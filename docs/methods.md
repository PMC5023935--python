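# Methods

## Problem and scope

`varconcord` mechanizes the comparison of a clinical *truth table* —
variants reported by Sanger sequencing of single genes, the historical
gold standard — against the variant calls of whole-exome sequencing (WES)
for the same patients. The question it answers is operational: when a
clinically reported variant exists, does the exome see it, with the same
allele and the same zygosity? The package covers everything downstream of
variant calling: reading the truth table and per-patient VCFs, allele
normalization, per-gene coverage QC, region stratification, matching,
adjudication against confirmatory re-sequencing, and stratified
concordance/error-rate reporting. Read alignment, duplicate marking and
calling on reads are out of scope; the VCFs and per-base depth tracks
arrive precomputed.

## Gene models and region strata

One transcript per gene is stored as genomic exon intervals (0-based,
half-open, genomic order) with optional CDS bounds; user-facing variant
positions are 1-based, matching VCF. Classification of a position is
strand-agnostic:

* exonic in CDS → **coding**; exonic outside CDS → UTR;
* intronic → distance to the closer flanking exon boundary, HGVS-style
  (first intronic base has distance 1); distance ≤ 20 bp → **near-exon
  intronic**, > 20 bp → **deep intronic** (the bound is inclusive and
  configurable);
* beyond the transcript → distance from the transcript edge.

For reporting, every noncoding position (UTR, intronic, outside the
transcript) is binned by the same ≤20/>20 distance rule. This is how the
fixture's far-upstream variant (176 nt before the first exon) lands in the
deep-intronic stratum: no published convention exists for such sites, and
this package's choice is the distance rule applied uniformly.

HGVS c. positions (`c.76`, `c.76+9`, `c.-30`, `c.*12`) are resolved by
walking exonic bases in transcript orientation (strand-aware), with
intronic offsets stepping genomically from the anchoring exonic base and
UTR numbering continuing linearly past the transcript edge. A full
`g.→c.` inverse exists and the pair is identity-tested on fuzzed
transcripts of both strands. The HGVS grammar beyond position terms
(dup/inv/protein level) is out of scope.

## Allele normalization

Sanger reports and VCFs often write the same indel differently. Every
allele is reduced to a canonical minimal left-aligned form: repeatedly
trim a shared terminal base, extending leftward with reference sequence
whenever an allele would empty (this is what shifts indels left through
repeat tracts), then trim shared leading bases keeping one anchor base.
The procedure is idempotent, and a brute-force oracle that enumerates
*every* written representation of an edit on fuzzed references confirms
all of them reduce to the same normalized allele. Degenerate corner: an
indel whose equivalence class touches the first base of a contig has no
left anchor; the representation then keeps its right-side context (the
alternative would be to reject the variant, which would silently drop real
telomeric edits). Matching uses normalized position and alleles only — no
window search; normalization is the entire equivalence engine, so nearby
compound representations (vcfeval-style haplotype matching) are a
non-goal.

## Coverage QC

A depth track maps intervals to integer read depth (absent = 0); both
samtools-depth TSV and bedGraph dialects are read, auto-detected by column
count. Per gene, the *footprint* is the exon union widened by 20 bp
flanks — WES targets exons, and near-exon intronic variants are evaluable
in practice, so the footprint rather than the whole locus is the denominator
(a documented choice; the alternative full-locus reading would make every
gene fail). A gene is excluded when **less than 75%** of its footprint has
depth **strictly greater than 20** (so exactly 75% is kept, and exactly
20× does not count). A per-variant low-depth flag marks sites with depth
**< 10**; of the two plausible readings ("10× or less" vs "fewer than
10"), the stricter is the default and both thresholds are configurable.
Depth at a matched call prefers the VCF's DP and falls back to the track.

## Matching, adjudication and accounting

Per patient (truth rows are only compared against their own patient's
calls), each truth variant gets one status:

* **concordant** — identical normalized allele, equal zygosity
  (hemizygous counts as homozygous for comparison);
* **discordant_zygosity** — identical allele, unequal zygosity;
* **discordant_base** — a call at the same normalized position with a
  different alternate;
* **missing** — no call at the position.

Confirmatory re-sequencing rows (keyed by patient/chrom/pos) resolve
discordances: a missing variant confirmed real is a WES false negative
(`sanger_correct`); one shown reference is a truth-table false positive
(`wes_correct`); a discordant base matching neither side is
`both_incorrect`; zygosity flips resolve toward whichever zygosity the
confirmatory call shows. Unmatched records stay `unresolved`.

The stratified table reports, per stratum, strict status counts plus a
rate. Two numerators coexist, deliberately:

* **stratum rows** (coding, near, deep, excluded genes) use the
  *allele-seen* numerator — concordant plus zygosity-discordant — i.e.
  what a raw truth-vs-VCF tally can know before any re-sequencing;
* the synthesized **noncoding-total and overall rows** use the
  *post-adjudication* numerator — strictly concordant plus zygosity flips
  resolved in WES's favour (those discordances are the truth table's
  errors, and charging them to the exome would misstate its performance).
  Without a confirmatory table these rows fall back to the allele-seen
  numerator, and a discordant base resolved as `both_incorrect` is
  displayed as *indeterminate*, kept in the row total but in neither
  numerator.

This dual accounting is what a self-consistent reading of clinical
concordance reports requires: the raw per-stratum tallies and the final
"confirmed" totals are produced at different stages of the workflow and
count zygosity evidence differently.

False-negative and false-positive rates are defined over coding variants
in adequately covered genes only: FN = coding missing records adjudicated
`sanger_correct` / coding total; FP = coding missing records adjudicated
`wes_correct` / coding total. These count polymorphisms and variants of
unknown significance, not clinically actionable findings — the caveat is
carried verbatim into every rendered report. Percentages are rounded
half-up to one decimal (`decimal.Decimal`), which is the rounding that
reproduces conventional clinical-report formatting; banker's rounding
would not.

## Synthetic data generator

The generator *plants* outcomes rather than let them emerge: it decides
each variant's fate, constructs calls, depths and confirmatory rows
consistent with that fate, and records everything in a manifest; the
pipeline must recover the manifest exactly (a property test enforces
this, with no stochastic slippage). Genes live on separate synthetic
chromosomes (`chrS1`…) so no coordinate can collide with a real genome
build. Default cohort shape mirrors a clinical comparison study:
26 patients, 51 genes (four 150 bp exons, 250 bp introns, 30 bp UTRs),
~6 variants per gene split across strata, per-stratum discordance
probabilities of a few percent (coding) to ~22% (deep intronic).
Sequences are drawn per-base with a GC target; poorly covered genes get
GC ≈ 0.60 (seven of nine) or ≈ 0.40 (two — emulating pure capture-kit
targeting failures), against a 0.37 background, and their footprint is
painted so that only ~55% exceeds the QC depth. The coupling of GC to
coverage is qualitative by design; no functional form is claimed.

Indel planting scans candidate sites until the representation is already
normalized (no left shift), so planted coordinates survive the pipeline;
variant sites are spaced so normalized positions cannot collide. The toy
site-level caller requires ≥ 3 reads to call at all and ≥ 20% alternate
support (boundary inclusive); ≥ 80% alternate support is homozygous —
the homozygous bound is not a published threshold but the symmetric
counterpart of the 20% floor. Every emitted call is checked against the
caller on its implied read counts. Identical seeds give byte-identical
bundles.

**The deterministic study fixture** (`build_paper_fixture`) fixes the
planted inventory: 391 truth variants in 26 patients across 51 genes;
nine genes planted poorly covered (131 variants, 79 seen); in the 42
adequately covered genes 150 coding (146 seen, 4 missing), 52 near-exon
intronic (46 concordant, 2 flips, 4 missing) and 58 deep intronic
(42 concordant, 2 flips, 13 missing, 1 far-upstream discordant base shown
wild-type on re-sequencing, hence indeterminate); adjudication resolves
three coding misses in the truth table's favour and one against it, and
the four flips two-and-two; three coding and six intronic concordant
variants sit below 10 reads, while the missed coding positions are well
covered (depth 45). The per-gene coding tallies follow the published
per-gene inventory, with one deliberate reconciliation: the per-gene sums
give 149 included coding variants while the stratified table says 150
(and 111 vs 110 noncoding), an inconsistency in the source tallies; the
fixture treats the stratified table as canonical and gives DYSF one extra
concordant coding variant. Only sequence content varies with the seed —
every count and rate above is seed-invariant, which is why the
acceptance script can accept any seed and still reproduce the same
percentages. Zygosity flips are placed in the noncoding strata (2 near,
2 deep, resolving 2+2); this placement is forced by the only accounting
under which all published per-stratum and total rates are simultaneously
consistent (see the dual-numerator note above).

## What the synthetic data does and does not show

The generator emulates cohort structure, per-stratum discordance rates,
coverage profiles and GC-coverage coupling. It does **not** model reads
(no FASTQ/BAM), sequencing error, capture-bait geometry, multi-transcript
genes, or real allele-frequency spectra; depth values are planted, not
sampled from capture chemistry. Passing tests therefore demonstrate that
the *accounting machinery* is correct — matching, normalization,
stratification, QC thresholds, rate arithmetic — not that any particular
real cohort would show these rates. Cohort-level properties of real
patient data (diagnostic yield, genome-wide CCDS coverage percentages)
are deliberately not reproduced; the coverage-summary operation is
exercised only on synthetic tracks with known exceedance fractions.

## Numerical and design notes

* Problem sizes: the fixture runs end to end in ~1 s; the parameter
  recovery study uses 200 replicate cohorts of 60 variants per
  probability (0.01 / 0.05 / 0.2), pooled, checked against the exact
  Clopper-Pearson 95% interval.
* Ties and boundaries: intronic distance ties anchor to the
  transcript-upstream exon (`+` offset); the near/deep bound is inclusive
  at 20; coverage thresholds are strict (`> 20×`, `> 10×`); exclusion is
  strict (`< 0.75`); the caller's 20% floor is inclusive, the 80%
  homozygous bound is inclusive.
* Degenerate inputs: empty truth tables yield a zero-count table with
  rates absent (never 0/0 = 0); all-N sequences are a GC error; rows that
  cannot be parsed or resolved go to a rejects report, never silently
  dropped.
* One reference build per run; no liftover. Phased and unphased genotypes
  are treated identically. The VCF FILTER column is ignored — the
  comparison is explicitly against the unfiltered call set.
* Multi-sample VCFs: one sample is selected by name (default: first);
  patients are matched by VCF sample name equal to the truth table's
  patient id.

## Known limitations

Single transcript per gene; no structural variants; no haplotype-aware
matching of compound representations; confirmatory rows are keyed by the
reported (not normalized) position; the dual-numerator accounting is a
modeling choice for clinical-report semantics and should be re-examined
before applying the table to benchmark-style truth sets (hap.py/vcfeval
conventions differ).
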