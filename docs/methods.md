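# Methods

`raredex` re-implements, as a tested library, a classical two-colour
cDNA-microarray differential-expression workflow together with its two
companion analyses: ΔΔCt relative quantification of validation qPCR, and an
in-silico scan for retinoic-acid response elements (RAREs) in aligned
promoter pairs. A synthetic-data module generates all three data types with
known ground truth, so every stage is testable end to end without external
downloads.

## Microarray model and pipeline

Each slide co-hybridises a treated and a control sample labelled with the
635 nm and 532 nm dyes; replicate slides come in dye-swap pairs (the dye
assignment reversed in the second slide). Per spot the pipeline uses the
foreground and background fluorescence medians of both channels.

**Quality filtering.** Spots are excluded, in priority order, when (1)
flagged bad by the scanner software, (2) saturated — either channel's
foreground median at the scanner ceiling (default 65535, a 16-bit scanner),
or (3) low quality — signal-to-background ratio strictly below 1.5 in
either channel. Requiring both channels to pass S/B is a deliberate,
dye-symmetric reading of the usual "S/B < 1.5" rule; a zero background
with positive foreground counts as S/B = +∞. Lowering `sb_min` can only
retain more spots (monotonicity is property-tested).

**Background decision.** Whether local background is subtracted is decided
per slide and per channel from the data, following the correlation
heuristic: Pearson correlation of log2 foreground vs log2 background
medians over retained spots; subtract only when r ≥ 0.5. The statistic,
direction and threshold are all configurable because published
descriptions of this rule rarely pin them down; the decision and the
correlation are logged in the provenance record. An undefined correlation
(constant channel) means no subtraction. Background-corrected signals are
floored at 1 count rather than dropped, keeping logarithms finite; floored
spots are annotated.

**M/A and lowess.** Per retained spot, M = log2(treated/control) with the
treated channel resolved from the slide's dye orientation, and
A = ½·log2 of the product of the two signals. The intensity-dependent dye
bias is removed per slide (global, not per print-tip) by robust lowess of
M on A — smoother span 2/3, three robustifying iterations — subtracting
the fitted trend. Lowess runs before dye-swap combination; the order is a
design choice (the pair average of two per-slide-corrected values equals
the corrected pair average when the bias curve is shared, and per-slide
fitting also handles pair-specific curves).

**Replicate unit.** Duplicate spots of a gene are collapsed by median
within each slide. The package exposes two replicate conventions:

* *slide-level* (default): each sign-resolved slide contributes one
  observation per gene, so three dye-swap pairs give n = 6 and the
  one-sample t-test has 5 degrees of freedom. This is the unit used for
  inference: with df = 2 (pair-level) a BH-controlled selection at
  q < 0.05 has essentially no power at realistic noise (sensitivity < 1%
  in simulation), whereas slide-level replication achieves the >90%
  recovery the pipeline is designed for. Within a pair the two slides
  carry independent measurement noise; the shared dye bias enters with
  opposite signs after sign resolution, so the gene-level mean is
  unbiased and the residual bias inflates the variance estimate, which is
  conservative.
* *pair-level* (`collapse_pairs=True`): each dye-swap pair is averaged
  into one column. This is the estimator with the exact-cancellation
  property — if a gene's dye bias is additive in log2 and equal within a
  pair, the pair mean equals the true log2 ratio to machine precision —
  and is what the dye-swap-exactness check exercises.

Both conventions give the same per-gene mean M when all slides measure the
gene.

**Inference and selection.** Per gene, a two-sided one-sample t-test of
the replicate M values against zero (genes with fewer than 2 replicates or
zero variance get no p-value and are never selected); Benjamini–Hochberg
step-up adjustment over the defined p-values (via
`statsmodels.multipletests`, verified in tests against a brute-force
transcription of the step-up definition). Effects are reported on the
symmetric signed fold-change scale: FC = 2^mean(M), FC < 1 mapped to
FC* = −1/FC, so |FC| ≥ 1 always and a halving reads −2.0. Selection takes
|FC| ≥ 1.5 (boundary inclusive); a q-value threshold is optional and off
by default, because published FC-selected gene lists often do not state
whether significance was additionally required — q is always reported so
either convention is reproducible. FC is computed from the mean of
per-replicate log ratios, consistent with the log-scale normalization.

Cross-comparison overlap classifies shared selected genes as concordant or
discordant by sign agreement of the two signed fold changes. GO summaries
count categories over an externally supplied gene→category map;
percentages are relative to the full input list with unannotated genes
tallied as "unknown" (no enrichment statistics are computed).

## qPCR (comparative Ct)

Per replicate well, ΔCt = Ct(target) − Ct(reference) (the endogenous
reference, e.g. ribosomal 18S, is measured in the same well). Per
(group, gene), ΔΔCt is the group's mean ΔCt minus the calibrator group's,
and RQ = 2^−ΔΔCt. Dispersion is taken at the per-replicate ΔCt level:
SEM(RQ) = RQ·ln2·sd(ΔCt)/√n (delta method at the point estimate). Group
differences are tested on per-replicate ΔCt with one-way ANOVA plus
pairwise two-sample t-tests (scipy), significance at p < 0.05 by default.
RQ can additionally be expressed on the microarray's signed FC* scale
(RQ 0.57 ↔ −1.76) for side-by-side comparison. Amplification-efficiency
correction (Pfaffl) and standard curves are out of scope.

## RARE scanning

The half-site consensus is PuG(G/T)TCA (IUPAC `RGKTCA`); a RARE is a
direct repeat of two half-sites separated by 1, 2 or 5 intervening bases
(DR1/DR2/DR5), the spacings preferentially bound by RAR/RXR heterodimers.
The scanner reports every qualifying ordered pair of same-strand half-site
matches (chained repeats yield one hit per pair; no greedy
de-duplication). Minus-strand geometry is evaluated on the reverse
complement and mapped back. Other RARE variants (e.g. a DR3, or degenerate
half-sites) are reachable by widening the spacer set or the per-half-site
mismatch budget — never by special cases. `N` never matches.

Offsets are 1-based distances upstream of the region's 3′ anchor, negative
by convention, measured to the hit's 5′-most base on the plus strand; the
anchor can be the TSS or the ATG (both conventions appear in the
literature for "upstream region"; TSS is the default and nothing depends
on the choice beyond labelling).

Conservation: the promoter pair is globally aligned (Biopython
`PairwiseAligner`, match +1, mismatch −1, gap open −5, gap extend −1;
among co-optimal alignments the aligner's canonical first traceback is
used). Sliding windows of 100 alignment columns with identity ≥ 0.7 (gaps
and N count as mismatches) are merged into maximal conserved blocks, whose
identity is recomputed over the merged span — so block edges carry up to
window−1 columns of sub-threshold slack. A hit is *conserved* when all its
footprint columns fall inside one block; its partner offset locates the
aligned columns in the other species. The window and identity threshold
are explicit configuration: published "highly conserved region" calls
rarely state theirs, and block boundaries are sensitive to both.

To scan real promoters, fetch the 5-kb regions upstream of the orthologous
TSS/ATG from a genome browser as FASTA (two records, plain or pre-aligned
with `-` gaps) and run `raredex rare-scan --fasta pair.fasta --out out/`.

## Synthetic data: what it emulates, and what it does not

**Arrays.** Per gene, a baseline log2 intensity ~ N(11, 1.2) (median
foreground ≈ 2000 counts — a realistic mid-range scan); per spot and
channel, latent log2 intensity = baseline ± M_true/2 ± bias/2 plus
Gaussian noise of sd `noise_sd`/√2 per channel (so the spot's M has sd
`noise_sd`, default 0.3). The dye bias is a quadratic polynomial in A
(default amplitude ≈ 0.2–0.4, the typical banana shape of unnormalised
Cy-dye data), identical across the slides of a pair so that dye-swap
cancellation is exact and testable; an optional arbitrary per-gene dye
bias exercises the same algebra. Foreground counts are 2^latent plus an
additive log-normal local background (mean 150, sd 50 counts), rounded and
clipped at 65535; the measured background median is the same local draw
that contaminated the foreground. 2% of spots are flagged bad; planted
genes (default 10% at |log2FC| = 1) are recorded in a truth table. Because
background is additive and (by default) not subtracted, low-intensity
effects are slightly attenuated — visible in the recovery tests as a mean
recovered |M| a few percent below the planted value, exactly as in real
two-colour data.

Not modelled: print-tip/spatial block effects, between-array batch
effects, pixel-level image artefacts, correlated noise between channels.
Passing tests therefore demonstrate correctness of the algebra and
calibration of the statistics under clean replicate structure, not
robustness to spatial artefacts.

**Promoters.** Uniform-random ACGT background with direct repeats planted
at stated offsets/strands/spacers (half-sites drawn from the consensus
expansion); the second species is a copy substituted at a given per-base
rate outside planted footprints, so planted motifs stay perfectly
conserved while flank conservation is tunable. Indels are not simulated
(the identity "alignment" of a generated pair is gap-free); alignment with
gaps is exercised on constructed fixtures instead.

**qPCR.** Target Ct = per-gene baseline − log2(true FC) + N(0, sd) per
well; reference Ct independent of group. Efficiency is implicitly exactly
2 (one cycle per doubling); pipetting/plate effects are not modelled.

## Problem sizes and numerical choices

Simulation-based checks run at the design's stated conditions: recovery at
1,000 genes (100 planted, 3 dye-swap pairs, noise 0.3) averaged over 20
seeds; null calibration at 10,000 genes over 50 seeds; scanner/oracle
equality on 100 random sequences of 200–5,000 nt. These sizes give
binomial standard errors well below the asserted margins while keeping the
whole suite to about a minute of compute. Lowess uses an interpolation
delta of 0.5% of the A-range above 2,000 spots (indistinguishable from the
exact fit at these densities, much faster). All generators take explicit
integer seeds; equal seeds give byte-identical outputs.

Known limitations: no moderated (empirical-Bayes) variance — genes with
accidentally tiny sample variance rely on BH to stay controlled; the
background-subtraction rule is a heuristic with configurable threshold,
not an estimate of the optimal decision; conserved-block edges depend on
the window length; the aligner's tie-breaking among co-optimal alignments
follows Biopython's canonical order.
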