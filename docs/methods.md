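# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical decisions a maintainer would want to know.

## Differential expression and core sets

Each contrast is a per-gene two-group linear model on log2 intensities
(the package assumes data arrive normalised; probe-level summarisation is
out of scope). Residual variances are moderated by empirical Bayes: with
per-gene variance `s_g²` on `d` degrees of freedom and a scaled-F prior
`s_g² ~ s₀²·F(d, d₀)`, the moments of `log s_g²` are digamma/trigamma
expressions in `d` and `d₀`; we fit `d₀` and `s₀²` by matching the
empirical mean and variance of `log s_g²` (inverting the trigamma with
Newton's method). Degenerate fits are handled totally: if the observed
spread of log-variances does not exceed the sampling spread, `d₀ = ∞`
(fully pooled variance); with fewer than two informative genes, `d₀ = 0`
(no shrinkage — the statistic reduces exactly to the ordinary two-sample
t, which the tests assert). The posterior variance
`(d₀s₀² + d s_g²)/(d₀+d)` feeds a t statistic on `d + d₀` df. A
zero-variance, zero-difference gene gets p = 1 by definition rather than
NaN.

Multiple testing uses Benjamini–Hochberg step-up at q = 0.05 (the
procedure is a config knob; BH is the default the surrounding toolchain
uses). A gene adjusted exactly to the threshold is rejected (≤, per the
step-up definition). "Up" requires strictly positive log-fold-change in
addition to significance. Core sets are the intersection of same-direction
calls across all contrasts, minus genes flagged as cross-hybridizing;
cross-hybridization is abstracted to a per-gene boolean because the
probe-to-gene mapping behind such flags is not modelled.

One test cross-checks the moderated statistics against the Bioconductor
limma implementation (via Rscript) on a shared dataset: log-fold-changes
agree to numerical precision and the moderated t ranks correlate > 0.99;
small differences in the fitted prior df are expected because the two
packages fit the prior by different methods.

## GO-SLIM enrichment

Counting is annotation-level, not gene-level: a gene with two
molecular-function terms contributes one count to each category, so a
column can sum to more annotations than genes (the packaged reference
table has 132 annotations for 117 up-regulated genes). The 2×2 exact test
is the classical two-sided probability-mass Fisher test. The omnibus
15×2 exact p is estimated by Monte Carlo with fixed margins (Patefield
sequential sampling via `scipy.stats.random_table`): with a universe of
~23,000 annotations the network algorithm is impractical, while the MC
estimator is unbiased with binomial standard error and a +1/(n+1)
pseudo-count so zero is never reported. Because the table probability
with fixed margins is `const/∏ n_ij!`, "probability ≤ observed" is
evaluated as `Σ ln Γ(n_ij+1) ≥ observed` with an 1e-9 tolerance against
round-off. All-zero categories are dropped with a warning. Pearson
residuals `(O−E)/√E` identify the driving categories.

## Novel-miRNA discovery

The cascade mirrors how candidate miRNAs are corroborated from multiple
independent lines of evidence; every stage only removes candidates, and
the per-stage survivor counts ("funnel") are part of the report.

* **Antisense matching** is gapless: the reverse complement of the sRNA
  slides along each mRNA and every offset with Hamming distance ≤ 3 is a
  hit. G·U wobble counts as a mismatch at the target (target recognition
  is scored like a DNA duplex, as empirical plant target rules do), and
  ambiguous bases always mismatch. Mismatch positions are 1-based from
  the sRNA's 5′ end. Batch matching concatenates mRNAs with N spacers
  longer than any sRNA so one vectorised pass per sRNA suffices.
* **Conserved-20mer filter**: perfect, same-strand substring equality
  (sense-only; a flag could relax this, but the conserved-20mer resource
  the filter models is strand-resolved).
* **Genomic placement** is exact full-length matching on both strands;
  coordinates are 1-based inclusive and strand-tagged throughout.
* **Windows** of ~500 nt are centred on the locus midpoint (the extra
  base of an uneven split goes 3′), truncated at chromosome ends, and
  reverse-complemented for minus-strand loci so they read 5′→3′ in
  transcript sense.
* **Folding** is a Nussinov-style maximum base-pairing dynamic program
  (Watson–Crick plus G·U; minimum hairpin loop 3), chosen because the
  hairpin verdict depends on duplex geometry, not free energy, and the
  backend stays dependency-free and pluggable. The traceback is
  deterministic: pairing (i, j) is preferred over leaving i unpaired and
  over bifurcation at ties, resolved outermost-first with the 5′-most
  partner. The fill is validated against a brute-force interval recursion
  on random ≤ 60-mers.
* **Hairpin screening** counts, along the mature: unpaired bases,
  asymmetric bulges (a gap between consecutive paired mature bases whose
  opposite-arm gap differs in length), terminal-loop overlap, and infers
  the star span and arm (5′/3′) from the partners. Acceptance thresholds
  are ≤ 4 unpaired mature bases and 0 asymmetric bulges — published
  screening defaults for plant precursors — both exposed in
  `DiscoveryConfig`. A mature pairing into itself or reaching into a
  terminal loop fails outright.
* **Target-site rule**: no mismatch at positions 10–11, at most one in
  positions 2–12 (5′-anchored), the empirically derived plant
  miRNA:target constraints.
* **Known-mature comparison** uses Hamming distance, extended to unequal
  lengths by sliding the shorter sequence and adding the length
  difference. Distance 0 marks a known mature; distance ≤ 2 marks a
  "variant of known"; only more distant candidates are reported novel.
* **Expression criterion**: a candidate must occur in the miRNA-enriched
  library (an *rdr2*-like genotype) and be absent from the
  miRNA-depleted one (a *dcl1*-like genotype), by exact same-strand read
  equality.

## Tissue-corrected distributional bias test

Expression is reduced to within-gene ranks across the 23 atlas tissues
(midranks on ties; each gene's ranks sum to 276), which makes every
downstream quantity invariant under monotone transformations of the
atlas — a property the tests assert by transforming the atlas and
comparing results bit for bit.

Per tissue the core set is compared with its complement through one-sided
ECDF gaps `D_high = sup(F_ref − F_core)` and `D_low`, evaluated on the
half-integer midrank grid with a vectorised histogram/cumsum routine (the
generic `ks_two_sample` wraps scipy and is used for raw two-sided
reporting; exact small-sample p-values there match full enumeration, and
the asymptotic mode is within 10% of a 10⁵-resample permutation oracle at
moderate n).

The correction: gene sets ascertained in inflorescence tissue are rank-
shifted wherever transcriptomes resemble the inflorescence, so `n_perm =
1000` random sets are drawn with the same inflorescence ranks as the core
genes — each core gene replaced by a uniform draw, without replacement,
from non-core genes in the same integer rank bin (bins widen
symmetrically, with a warning, if underpopulated) — and
`p_corrected = (1 + #{null D ≥ observed D})/(n_perm + 1)` per direction.
The null sets are drawn once per core set and reused across tissues, as
the procedure's design implies (matching depends only on the
inflorescence). Significance tiers are assigned at α ∈ {0.05, 0.01};
direction-specific one-sided statistics keep each (tissue, set,
direction) result marginally calibrated, which the acceptance suite
verifies: under a bias-free atlas, sets drawn from the matched-null
generator are flagged at 1% within the binomial interval.

The reporting helpers pivot results into a tissue × (set, direction) tier
matrix and a log₁₀-p panel for the inflorescence tissues.

## Synthetic data: what it emulates and what it does not

`SimConfig` defaults define the study conditions:

* 4 canonical mutants + wild type, 3 replicate arrays each; i.i.d.
  Gaussian noise on the log2 scale with sd 0.35 (typical replicate-level
  spread of normalised expression arrays) and planted effects of ±2 log2
  units for shared (core) and genotype-private differential genes.
  Private fractions are set so pairwise up-regulated overlaps land in the
  30–36% range, within the band such mutant panels show. A configurable
  fraction of genes carries a cross-hybridization flag; flagged shared
  genes still change in every mutant but are excluded from the answer
  key, mirroring the probe-filtering step the core sets undergo.
* A universe of 8,000 genes with ~120 up / ~100 down core genes. The
  ratio matters: the rank-matched null draws non-core genes per
  inflorescence-rank bin, and when a tested set occupies a large fraction
  of a bin's pool the 1,000 "random" sets become near-copies of each
  other and the permutation p loses calibration. The defaults keep the
  per-bin draw fraction below ~10%, the regime the procedure was designed
  for (real arrays have a ~200:1 universe-to-core ratio).
* A 23-tissue atlas whose background genes are exchangeable across
  tissues; core genes get a +0.35 (1 sd) tendency in the designated
  inflorescence tissue — enrichment, not determinism, so every
  inflorescence rank bin retains non-core genes for matching — and the
  planted tissue biases are ±2 in a meristem tissue (up-set high,
  down-set low) and mirrored in mature pollen.
* Ten planted stem-loop precursors (five novel, five copied into the
  known-mature list), alternating arms and random strands. Constructed
  precursors extend pairing beyond the miRNA/miRNA* duplex (a 12 nt
  perfectly paired lower stem and 8 nt upper stem), as real pre-miRNAs
  do; under a maximum-pairing objective this keeps the mature in the
  helix interior where crossing constraints protect it from co-optimal
  rearrangements with the surrounding genomic window. Star-arm mismatches
  are placed interior, non-adjacent, and with substitutes that cannot
  pair the opposing base or its neighbours — otherwise a register-shifted
  co-optimal fold exists and the planted duplex geometry is not what the
  fold reports. Matures whose composition admits no such placement are
  re-drawn.
* sRNA libraries with the published 454 library depths as defaults; reads
  are planted matures (only in their designated genotypes) plus random
  genome substrings of 20–24 nt drawn from a fixed pool of 2,000 distinct
  background species resampled with replacement (sequencing re-reads the
  same molecules; the real enriched library had 1,984 unique among 4,573
  reads). Background draws exclude the planted precursor loci so a
  shifted fragment of a planted hairpin cannot masquerade as an extra
  candidate.
* Conserved 20mers: one exact substring per planted mature plus decoys
  rejection-sampled to occur in no mature.
* GO-SLIM annotations over the 15 molecular-function categories with
  genome-like background frequencies; planted-up genes draw the
  transcription-factor category at rate 0.25 (~4× background); ~13% of
  genes carry a second category so annotation counts exceed gene counts.

Not emulated: probe-level microarray structure, sequencing error,
correlated tissue blocks (each non-inflorescence tissue is independent),
multi-locus gene families beyond exact repeats, and genomic base
composition. Passing tests therefore demonstrate the pipeline's logic and
calibration under its stated assumptions, not robustness to array
artefacts or to thermodynamically marginal hairpins — for real data the
folding backend should be swapped for a thermodynamic folder, which the
pluggable `fold` interface anticipates.

## Reproducibility and scale

Every generator is a pure function of (config, seed); the pipeline spawns
per-stage seeds from one master seed, and reruns are byte-identical
(asserted in tests). Test-suite problem sizes — a 0.2 Mb genome, 8,000
genes, 20-seed discovery benchmark, 200 surrogate sets × 1,000
permutations for calibration — were chosen as the smallest scales at
which each statistical claim is testable with stable margins.

## Known limitations

* The maximum-pairing fold over-pairs relative to thermodynamic folding;
  the hairpin screen is validated on planted precursors, and marginal
  real precursors would need the thermodynamic backend.
* The rank-matched permutation test loses calibration when the tested set
  exhausts its inflorescence-rank bins (small universes, extreme
  inflorescence enrichment); the bin-widening fallback warns but cannot
  restore exchangeability.
* The moderated-variance prior is fit by moment matching; limma's
  profile-based fit differs slightly in `d₀` for small gene counts (ranks
  and calls agree).
* Exact r×2 p-values are Monte Carlo estimates; report the standard error
  alongside.
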