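# Methods

This note documents the models, conventions and numerical choices behind
`promsnp`, what the synthetic data does and does not emulate, and the
problem sizes the test suite and `scripts/acceptance.py` run at.

## Coordinate conventions

Relative coordinates around a transcription start site (TSS) have **no
position 0**: they run …, −2, −1, +1, +2, … and the TSS base itself is +1.
Under this convention the core-promoter window [−200, +50] contains exactly
250 bases (200 upstream, the TSS, 49 downstream), matching the classifier's
input length without an off-by-one adjustment; the downstream non-promoter
window [+751, +1000] likewise holds 250 bases and never overlaps the
promoter window of the same gene. All windows are strand-aware:
minus-strand windows are mirrored around the TSS and reverse-complemented.
Internally every interval is 0-based half-open; GFF3 I/O (1-based,
inclusive) converts at the boundary. The TSS is taken from the `gene`
feature (start on `+`, end on `−`); genes sharing a (chrom, start, strand)
window are deduplicated to prevent train/test leakage.

## Dataset construction

Promoters: [−200, +50] windows of protein-coding genes. Non-promoters come
from three sources: gene-body windows [+751, +1000]; random genomic 250-mers
whose full extent avoids the union of [TSS−1000, TSS+500] zones over all
genes (a capacity error names the shortfall when the eligible territory is
too small); and, optionally, 250-mers sampled from a user-supplied
transcript FASTA. Sequences containing non-ACGT characters, or whose ids
match a configurable unplaced-scaffold pattern, are dropped and counted.
Splits are stratified by label (90/10 by default) and exhaustive.

## Classifier

Input: 250×4 one-hot matrix (columns A, C, G, T). Architecture: four
1D-convolutional layers with 64/128/256/512 filters, width 21, stride 2,
zero ("same") padding and ReLU, each followed by dropout 0.2; a flattening
layer, where an optional auxiliary feature vector is concatenated; dense
layers of 128 and 64 units (ReLU); one sigmoid output. Stride-2
convolutions provide all downsampling — there are no pooling layers — and
dropout is applied after convolutions only. Training: Adam (β₁ = 0.9,
β₂ = 0.999), L2 penalty on weights (default 1e-4), binary cross-entropy;
defaults epochs 20, batch 64, learning rate 1e-3. For unbalanced
promoter/non-promoter pools, `class_weight="balanced"` weights samples by
inverse class frequency in the loss.

The network is implemented directly in numpy (im2col convolutions with
exact backpropagation), which keeps single-CPU training deterministic for a
fixed seed: initialisation, dropout masks and batch shuffling all derive
from one generator, and two runs with the same seed produce bit-identical
weights. The layer count is fixed at four; filter counts are configurable,
and desk-scale work in this repository uses (8, 16, 32, 64) — large enough
to learn planted-motif structure in seconds per epoch on one CPU.
Checkpoints are single `.npz` files.

Evaluation thresholds the sigmoid at 0.5 (configurable) and reports ACC,
sensitivity, specificity and MCC from the confusion counts. MCC is defined
as 0 whenever a marginal of the confusion table is zero. Cross-group
evaluation (`cross_species_matrix`) trains one model per labeled group and
scores every model on every group's held-out split; the feature-ablation
grid retrains the same split/seed with different auxiliary feature sets so
rows differ only in features.

## Auxiliary sequence features

Motif frequencies (overlapping occurrences over |s|−|m|+1 positions),
CG skew (#C−#G)/(#C+#G) with the zero-denominator case defined as 0 (logged)
to keep the feature bounded, k-mer spectra (all 4^k k-mers, lexicographic
order, overlapping counts), horizontal mutual information and generalized
topological entropy.

**HMI(d)** is estimated from all |s|−d overlapping position pairs with
0·log(·) := 0; the log base defaults to 2 (bits) and is configurable — the
base only rescales the feature and is irrelevant after z-normalisation.
HMI ≥ 0 always (information inequality), with equality on homopolymers.

**GTE** uses contiguous substrings. The order n_ω is the largest integer
with 4ⁿ + n − 1 ≤ |ω| — the standard bracket of the topological-entropy
literature, which partitions the lengths exactly (a 250 bp window has
n_ω = 3) — and k = n_ω, so all substring lengths 1…n_ω contribute. Since
p_ω(i) ≤ 4^i, GTE ∈ [0, 1].

Default auxiliary set: 2-mers, HMI at d ∈ {1…5}, TATAA/CA/CG frequencies,
CG skew and GTE (26 values). Features joined at the flattening layer are
z-normalised with statistics fit on training data only; constant features
get unit scale.

## Contig scanning

Each contig ≥ 250 bp is read in four orientation variants — identity,
complement (direction kept), reverse (direction flipped) and reverse
complement — because GBS assembly leaves the reading direction unknown. The
two biologically unusual variants (complement-without-reverse and
reverse-without-complement) are retained deliberately: the workflow treats
direction and strand as independent unknowns. Windows are tiled at a
configurable stride (default 50 bp; the pipeline default is 10 bp, dense
enough that some window aligns within 5 bp of any planted promoter), always
including the final full window. A contig counts as "classified as
promoter" if any window of any variant passes the threshold; the summary
also reports the per-window call fraction, which is the more informative
statistic under dense tiling — with ~140 windows per contig, the
per-contig union saturates even at modest per-window call rates. SNP
positions (VCF, identity orientation) are intersected with calls after
mapping call intervals back through the transform (p → L−1−p for the two
direction-flipping variants).

## Binding-site scoring and consequence calling

TRANSFAC plain-matrix files (DE / P0 / numbered rows / XX / `//`) are
parsed into count matrices; a configurable pseudocount (default 0.01 in the
pipeline) is added per cell before normalisation to avoid −∞ information
terms. The matrix similarity score follows the published MATCH convention:
position i contributes I(i)·f(i, bᵢ) with I(i) = Σ_b f(i,b)·ln(4·f(i,b)),
and the sum is min–max normalised so the consensus scores 1 and the worst
window 0. Degenerate matrices with min = max (e.g. uniform) score 1 by
definition. MATCH's separate 5-position core-similarity pre-filter is not
implemented; a single MSS threshold (default 0.85) defines putative sites.
Both strands are scanned; minus-strand hits are reported in plus-strand
coordinates.

For each SNP, ±25 bp flanks (51-mers) are built in reference and alternate
versions. Sites are matched between the versions by (matrix, offset,
strand): both present → `no_effect` if |ΔMSS| ≤ 1e-9 else `score_change`;
reference-only → `loss`; alternate-only → `gain`. The tolerance is far
below the 1e-3 score granularity at which published examples distinguish a
change. Sites not overlapping the SNP base cannot differ and are excluded
by default (a flag reports them). A SNP with ≥1 score-change/loss/gain call
is an rSNP.

## Association testing

Each inbred line contributes two alleles (heterozygotes one to each cell;
the synthetic cohort never produces them). The statistic is Pearson's
chi-square without continuity correction, χ² = N(ad−bc)²/(r₁r₂c₁c₂), with
the p-value from the 1-df upper tail; a zero row/column margin is flagged
monomorphic (χ² = 0, p = 1). SNPs with quality < 400 are excluded
beforehand (strict inequality). Benjamini–Hochberg adjustment (statsmodels
step-up, verified in tests against an independent implementation) runs over
exactly the tested subset — the promoter SNPs — not the genome-wide count;
all-missing SNPs are excluded from the test count. Both the 0.1 FDR level
and a 0.05 significance level on adjusted values are configuration, not
hard-coded.

## Synthetic data: what it emulates, and what it does not

The generator produces the statistical structure the analysis assumes:

- **Genomes** with genes on both strands and core-promoter motifs planted
  at fixed offsets with per-gene inclusion probabilities. Defaults emulate
  a plant core promoter: TATA box (TATAAA) at −30 with probability 0.9,
  CAAT box (CCAAT) at −75 with 0.7, GC box (GGGCGG) at −120 with 0.5, on a
  slightly AT-rich background (A=T=0.29, C=G=0.21). Offsets are the 5′
  base of the motif in relative coordinates.
- **Contigs** cut from the genome with uniformly random orientation
  transform; provenance (source interval + transform) goes to a sidecar
  table so tests can invert the bookkeeping exactly. Intervals that must
  be recoverable (the causal promoter) can be forced into coverage.
- **Cohort**: 20 inbred lines, 6 low / 14 high phenotype, strictly
  homozygous genotypes. The causal SNP sits inside a planted motif
  occurrence covered by a contig; its reference allele is the consensus
  base, so the alternate allele destroys the site (expected consequence:
  loss). Segregation: all low lines homozygous reference; one "exception"
  high line also homozygous reference; the remaining high lines homozygous
  alternate — the alternate allele never appears in low lines. With one
  exception the allele table is [[12, 0], [2, 26]], giving χ² ≈ 31.84 and
  p ≈ 1.67e-8; two such SNPs tied among 14 tests adjust to
  p×14/2 ≈ 1.17e-7. Non-causal SNPs segregate independently of phenotype
  with MAF ~ U(0.05, 0.5).
- **Quality scores** from a two-Gaussian mixture (weight 0.636 at 200 ± 60,
  the rest at 800 ± 120, truncated at zero), straddling the 400 threshold
  with a clear minimum between the modes; the causal SNP draws from the
  high component, since a causal variant filtered out for sequencing
  quality is a different failure mode than the one under study.
- **PWM library**: near-consensus matrices (97% consensus base per
  position) for the planted motifs plus random decoy matrices, written and
  re-read in TRANSFAC format.

Not emulated: read-level GBS simulation, restriction-site biology, assembly
artefacts, linkage disequilibrium, population structure, heterozygosity and
genotyping error. Passing tests therefore demonstrate that the pipeline's
logic recovers a planted regulatory signal under its own assumptions — not
that those assumptions hold for any real cohort.

## Problem sizes and design choices at desk scale

- Separable-training checks use the planted-TATA genome at inclusion 1.0 on
  a **uniform** background with 1000 genes (2000 labeled sequences, 90/10
  split): on the AT-rich background, chance TATAAA occurrences contaminate
  ~13% of non-promoter windows and cap accuracy near 0.93, so a uniform
  background is what makes "separable by construction" true. The
  (8, 16, 32, 64)-filter model exceeds 0.95 held-out accuracy within 10
  epochs across seeds.
- The end-to-end pipeline default: 2 × 520 kb chromosomes, 400 genes, 150
  contigs of 450–800 bp, 60 SNPs, 400 random-genomic negatives added to the
  400 promoter / 400 downstream windows with balanced class weights
  (random genomic background is otherwise out-of-distribution for the
  scanner and inflates false calls), 12 epochs, scan stride 10. A full run
  takes well under a minute on one CPU; the demo seed-robustly ranks the
  planted causal SNP first and calls its loss consequence.
- Hyperparameters the architecture leaves open (epochs, batch size,
  learning rate, L2 coefficient) default to 20 / 64 / 1e-3 / 1e-4 and are
  all exposed in config, as are the classification threshold (0.5), the
  MSS threshold (0.85), the quality cutoff (400) and the FDR level (0.1).

## Known limitations

- The numpy CNN is CPU-only and desk-scale; genome-scale training sets
  (tens of thousands of windows) would need hours, not minutes.
- Per-contig promoter fractions are not comparable across tiling strides or
  contig-length distributions; use the per-window fraction for that.
- TSS selection from gene records ignores transcript isoforms; a
  five_prime_UTR-based refinement is out of scope.
- The TRANSFAC parser supports the plain-matrix dialect only (the format of
  the generator's own output and of common motif-library exports).
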