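# Methods

## Problem and model

Genes with alternative promoters produce isoforms that differ only in their
5' exons. Whole-gene read counting sums the isoforms and therefore cannot
detect a developmental *switch* between them: when one isoform falls as the
other rises, the total stays roughly flat. The package quantifies such
isoforms directly by counting reads against the isoform-specific 5' exons,
with the shared downstream exons kept as a separate, isoform-uninformative
class, and demonstrates the masking effect by also quantifying a standard
whole-gene exon-union reference.

Exon classification is by genomic-interval intersection: an exon interval is
specific to isoform *i* iff it intersects exons of transcripts of exactly
one isoform label, and common iff it intersects exons of two or more labels.
Intersection rather than exact identity is used so near-identical exon
variants share a label. Coordinates are 0-based half-open internally; GTF's
1-based inclusive convention is converted only at the parse/write boundary.

## Read assignment rule

The index maps every length-*k* word of every feature sequence to the set of
classes containing it (k = 21 by default: much shorter than the 50-base
reads, long enough to be effectively unique in the toy genomes; configurable
up to 31 for the packed integer path). Feature sequences are stored in sense
orientation; the isoform-specific exon sets enter as separate co-classed
records, so k-mers spanning exon junctions are deliberately absent.

For a read, let a *hit* be a k-mer present in the index and a *unique hit*
for class *c* one whose class set is exactly {c}. Then:

* hits confined to one class: **assigned** to it if it has ≥ `min_hits`
  unique hits (default 2, suppressing single-k-mer error hits), otherwise
  **unassigned** (too little evidence — the contract for this sub-case was
  open, and insufficient evidence is not conflicting evidence);
* hits spanning several classes: assigned to the single class with
  ≥ `min_hits` unique hits if exactly one qualifies; when several qualify
  and exactly one of them is isoform-specific (non-common), the specific
  class wins, so junction reads crossing a specific/common boundary count as
  isoform evidence; otherwise **ambiguous**;
* no hits: **unassigned**.

Ambiguous and unassigned reads are tallied but excluded from all feature
counts. The vectorized batch path (2-bit k-mer packing, sorted-array
membership, per-class bitmask tallies) implements the identical rule and is
tested for equality against the scalar per-read path.

cpm uses the sample's total read count as denominator — "per million reads"
stays well defined for tiny feature sets — not the assigned-read total. TPM
normalizes count rates by effective length (length − read length + 1,
floored at 1) and rescales to 10⁶ over the quantified feature set.

## Synthetic study design

The generator emulates a bulk developmental time course:

* **Gene structure.** A two-isoform target gene on one toy chromosome: four
  isoform-1-specific 5' exons (110 bp each; two flagged non-coding), one
  isoform-2-specific exon (440 bp), and six shared exons (150 bp) beyond a
  6.2 kb intron. Both isoforms carry 440 specific bases and identical
  1340-nt spliced lengths, so their specific-exon cpm values are directly
  comparable and the crossing of estimated profiles estimates the crossing
  of the underlying trajectories. Five constant two-exon housekeeping genes
  (600 nt, amplitude 200) provide background library mass (~85% of reads),
  so target classes are a minority of each library as in real data, if far
  less extreme.
* **Trajectories** (expression in cpm-scale units against age in days,
  birth = 0): isoform 2 early peak A·exp(−(t−t₀)²/2σ²) with A=100, t₀=−5
  (E14), σ=6 — high embryonically, steep postnatal decline, near zero in
  adults; isoform 1 late plateau A/(1+e^−(t−t₅₀)/s) with A=60, t₅₀=8, s=3 —
  very low embryonically, ~90% of plateau by P15, maintained to P60. The
  true curves cross at 5.8 days.
* **Age panel.** 12 ages, E14 → P60, dense over the perinatal window where
  the trajectories change fastest (E14, E17, P1, P2, P3, P5, P7, P9, P11)
  with three maintenance ages (P21, P30, P60) for the adult plateau. The
  spacing is chosen so consecutive expected values outside the plateau group
  differ by more than the replicate noise; a panel spending many ages inside
  the plateau would make rank-based trajectory recovery ill-posed
  regardless of method quality, because plateau ages are true rank ties.
* **Noise.** Per-transcript read totals are negative binomial with mean
  proportional to expression × transcript length (molar expression) and
  variance m + φm², φ = 0.05 by default (≈22% replicate CV, a typical
  magnitude for pooled-tissue RNA-seq replicates); φ = 0 gives Poisson.
  Read starts are uniform over valid positions; substitution errors occur
  per base at 0.002 (≈Q27 average) with the erroneous base uniform over the
  other three; qualities are constant "I" (Phred 40) and unused downstream.
  3 replicates per age and 200,000 reads per sample by default; the
  `analysis/` drivers use 20,000 reads per sample, which preserves every
  qualitative result at a fraction of the cost.
* **Truth table.** Per-sample realized transcript read fractions and each
  read's source transcript and position, enabling exact specificity checks.

What the generator does **not** emulate: the real *Thrb* locus sequence, GC
or positional bias, fragment-length effects, PCR duplicates, paired ends,
strandedness ambiguity, indels, or annotation errors. Passing tests
therefore show that the assignment rule and statistics behave correctly
under idealized read generation — not that the pipeline is robust to every
artifact of real libraries.

## Statistical conventions

* Group summaries: sample mean ± SD (n−1); single-sample groups report
  SD 0 with an explicit `sd_defined = False` flag.
* Heatmap-style filtering: grand-mean cpm ≥ cutoff, boundary inclusive,
  default cutoff 10 cpm.
* PCA: samples as observations on log2(x+1) values, feature-centering only
  (no unit-variance scaling); explained-variance fractions are eigenvalues
  over trace. Constant matrices are an error.
* t-tests: pooled-variance Student form by default because that is the
  named test in the field's common practice for these designs; Welch is one
  flag away. Log transform is log2(x+1); the pseudocount and base are
  recorded in output metadata. Zero-variance degenerate input: equal means
  give t=0, p=1, unequal means raise. No multiple-testing correction by
  default (per-gene tests at α=0.05); Benjamini–Hochberg available.
* 2^−ΔΔCt: ΔCt = Ct_target − Ct_reference per sample; ΔΔCt subtracts the
  calibrator group's mean ΔCt, so the calibrator group's mean relative
  expression is exactly 1.
* Switch report: crossing age is the first age with a strict isoform-1 >
  isoform-2 inequality (ties break to no crossing); the masking diagnostic
  compares Spearman correlations of the whole-gene profile vs each true
  trajectory against that isoform's own estimated-vs-true correlation.
  Profiles that are constant across ages are flagged degenerate and skip
  the correlation stage.
* Sigmoid midpoint recovery: nonlinear least squares (Levenberg–Marquardt
  via `scipy.optimize.curve_fit`) of A/(1+e^−(t−t₅₀)/s) on per-age means,
  initialized at the observed maximum, median age and a tenth of the age
  range.

## Numerical and design choices

* k ≤ 31 in the packed path (2 bits/base in int64); the dict-backed scalar
  path has no such limit.
* The vectorized assigner computes rolling k-mer codes incrementally to
  avoid materializing large intermediate windows; N bases invalidate
  exactly the windows containing them (prefix-sum check).
* Library size for cpm is the FASTQ read total, so empty samples are an
  explicit error for cpm and a zero row for counting.
* `analytic_crossing` brackets sign changes of the trajectory difference on
  a 512-point grid and polishes with Brent's method.
* Seeds: every stage consumes a single `numpy` Generator derived from the
  configured seed; equal configs give byte-identical FASTQ and numeric
  outputs.

## Known limitations

* The assignment rule redistributes nothing: ambiguous reads are dropped,
  not EM-reassigned, so shared-k-mer classes bias counts conservatively.
* Specific-exon cpm comparability across isoforms assumes equal specific
  lengths, as constructed in the fixture; with unequal specific lengths the
  crossing of raw cpm profiles is not the crossing of the underlying
  expression trajectories (TPM on specific features would be).
* Rank-based recovery metrics saturate on plateaus; with many true
  rank-tied ages they are noise-dominated by construction (see the age
  panel rationale above).
* The qPCR module assumes perfect amplification efficiency (exact base 2).
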