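# isoswitch

Isoform-resolved expression analysis for genes with alternative promoters,
where standard whole-gene read counting hides the biology. The motivating
case is the thyroid hormone receptor beta gene (*Thrb*/*THRB*): its TRβ1 and
TRβ2 isoforms share all downstream exons (DNA-binding and ligand-binding
domains) and differ only in 5' exons driven by separate promoters. In the
developing retina the two isoforms switch — TRβ2 peaks embryonically and
declines after birth while TRβ1 rises postnatally to an adult plateau — yet
a whole-gene count, summing both, shows no switch at all.

`isoswitch` separates the isoforms by counting reads against k-mer indices
of the isoform-specific 5' exons (four specific exons for the TRβ1-like
isoform, the single specific exon for the TRβ2-like isoform, and a separate
index for the shared exons), then provides the downstream statistics used in
developmental expression profiling. A synthetic-study generator makes the
whole pipeline runnable on a laptop with no downloads.

## Method

**Read assignment.** Each feature class *c* (an isoform's specific exon set,
the common exon set, or a whole-gene exon union) contributes all length-*k*
words of its sequences to an index mapping word → set of classes (default
*k* = 21; words containing N are skipped). A read is assigned to *c* when its
k-mer hits are confined to *c* and at least `min_hits` (default 2) of them
are unique to *c*; reads whose hits span classes are resolved in favour of a
single qualifying isoform-specific class (so specific/common junction reads
count as isoform evidence) and are otherwise ambiguous. No alignment, no
indel handling: mismatched k-mers simply fail to match.

**Normalization.** cpm = count / library size × 10⁶ with library size the
total read count of the sample; TPM_f = (count_f / ℓ̃_f) / Σ_g (count_g / ℓ̃_g)
× 10⁶ with effective length ℓ̃ = max(ℓ − read length + 1, 1).

**Profiles and statistics.** Group summaries are mean ± SD (n−1); heatmap
filtering keeps features with grand-mean cpm ≥ 10; PCA runs on log2(x+1),
feature-centered data with samples as observations; hypothesis tests are
unpaired two-tailed Student's t on log2(x+1) values (Welch optional); qPCR
fold changes use 2^−ΔΔCt against a reference gene and calibrator group.

**Synthetic study.** The generator emits a two-isoform target gene (4 + 1
specific 5' exons, shared exons beyond a >6 kb intron), constant
housekeeping genes, and 50-base single-end reads over a 12-age panel
(E14 → P60, 3 replicates): an early-peak Gaussian trajectory
A·exp(−(t−t₀)²/2σ²) for the TRβ2-like isoform against a late-plateau sigmoid
A/(1+e^−(t−t₅₀)/s) for the TRβ1-like isoform, negative-binomial count noise,
uniform read starts, and a truth table of every read's origin.

## Worked example

The numbered scripts under `analysis/` run the desk-scale study (36 samples,
20,000 reads each, seed 7) and write their tables under `results/`:

```
$ python analysis/02_quantify_isoforms.py
assigned 86,525 target-gene reads across 36 samples (ambiguous: 2, unassigned incl. non-target: 630)
trajectory recovery (Spearman estimated vs true): iso1 0.944, iso2 0.998

$ python analysis/03_switch_and_pca.py
switch detected at P7 (analytic crossing of true curves: 5.83 days)
masking: whole-gene vs true iso1/iso2 Spearman -0.51/0.51; isoform self-recovery 0.94/1.00 -> masked=True
iso1 sigmoid midpoint refit t50 = 6.90 days (simulated 8.0)
PCA: first component 92.7% of variance (developmental age dominates)
```

Reading: the isoform-specific indices recover both trajectories (Spearman
0.94/1.00 against truth) and place the switch at P7, adjacent to the true
crossing at 5.8 days — while the whole-gene profile correlates with
*neither* isoform's trajectory (|ρ| ≈ 0.5), reproducing how total-gene
counting masks the switch. `analysis/04_qpcr_ddct.py` shows the same switch
by 2^−ΔΔCt (adult iso1 ≈ 78-fold up, iso2 down to ~0 relative to embryo),
and `analysis/05_regional_gradients.py` demonstrates the superior/inferior
counter-gradient statistics.

The same pipeline is available as a CLI
(`isoswitch simulate | index | quantify | profile | qpcr | report | demo`),
e.g. `isoswitch demo --seed 7 --out demo_out/`.

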