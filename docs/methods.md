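# Methods

This note documents the models and procedures `refstab` implements, the
choices made where conventions diverge, and what the synthetic-data tests
do and do not demonstrate.

## Data model and QC

Cq values are accepted in (0, 45] cycles (a 45-cycle protocol cannot yield
more) and must form a complete gene × sample matrix before stability
analysis (≥3 genes, ≥3 samples). Technical replicates of a (gene, sample)
cell are averaged when their sample SD (n−1 denominator) is below 0.5
cycles — the conventional acceptance rule for triplicate wells. Cells
failing the rule are excluded and flagged, never imputed: the caller
chooses `drop_policy` ∈ {error, drop_sample, drop_gene} (default error),
because silently repairing a failed triplicate would hide a wet-lab
problem. Single-replicate cells are accepted (SD defined as 0) but flagged.

Per-gene QC reports mean/min/max Cq, the max−min range (flagged at ≥5
cycles, a screen for degraded or inconsistently handled RNA), and a
transcript-level class: mean Cq < 25 → "high", otherwise "low". The
boundary Cq = 25.0 is assigned to "low" (strict less-than for "high"); the
class matters when matching reference genes to the expression level of the
genes of interest.

## Efficiency correction

Standard curves are ordinary least squares of Cq on log10 relative
dilution; E = (10^(−1/slope) − 1) × 100. Replicate curve estimates are
combined as the arithmetic mean of the percent values. A positive slope is
physically invalid and returns a flagged curve rather than an exception,
so batch processing can continue and report it.

The correction uses the amplification factor f = 1 + E/100, not the raw
percentage: Cq_corr = Cq_min + (Cq − Cq_min)·log2 f. This is the only
reading under which 100% efficiency is the identity map (f = 2,
log2 f = 1) and corrected Cq stays commensurate with raw Cq; interpreting
"E" as 0.98-ish would invert expression ordering. At exactly 100% the
implementation short-circuits to a bitwise identity, since the algebraic
form differs in the last ulp. Cq_min is each gene's minimum over the
*currently analyzed* sample set, so subsampled analyses rescale against
their own minimum — this matters for reproducibility of subset reruns.

Relative quantities Q = 2^(Cq_min − Cq_corr) = f^(−ΔCq) have per-gene
maximum exactly 1. geNorm and NormFinder consume Q (log2 Q for
NormFinder); BestKeeper and comparative ΔCt consume corrected Cq directly,
matching how those tools are defined (Cq-scale dispersion and Cq-scale
pair differences). Whether a published study applied efficiency correction
before all four algorithms is often unrecoverable; `refstab` applies it
uniformly, which is the defensible default and keeps the four scores on
consistent footing.

## Stability algorithms

All SDs below use the n−1 denominator.

**geNorm.** Pairwise variation V_jk = SD over samples of log2(Q_j/Q_k);
M_j = mean over k ≠ j. Iterative exclusion removes the largest-M gene
(ties broken by lexicographically smallest gene ID, for determinism) and
recomputes until two genes remain; these share rank 1. The per-gene score
reported is the *stepwise* M at the step of exclusion — the convention
under which the final pair shares a single value, namely their mutual
pairwise SD — with full-panel M available in the diagnostics. Stepwise M
is not guaranteed monotone in exclusion order and no such invariant is
asserted. Normalization factors NF_n are per-sample geometric means of Q
over the top n genes (exclusion order reversed); V(n/n+1) = SD over
samples of log2(NF_n/NF_{n+1}) for n = 2..K−1, and the recommended gene
count is the smallest n with V < 0.15 (cutoff parameterized). M < 1.5 is
reported as the usability limit.

**NormFinder** (single-group variant). With y = log2 Q, double-centering
gives residuals r_ij = y_ij − ȳ_i· − ȳ·_j + ȳ··, per-gene mean squares
a_i = Σ_j r_ij²/(n−1), and the bias-corrected variance
σ̂²_i = (a_i − A/(k(k−1)))·k/(k−2) with A = Σ a_i. The estimator is exactly
unbiased under the additive model (E[a_i] = σ_i²(k−2)/k + Σσ²/k²), which
the test suite confirms by Monte-Carlo; it requires k ≥ 3 and can go
negative in finite samples, in which case it is floored at 0 (floored
genes recorded). No between-group variance term is computed: the intended
use case supplies no condition groups, and the grouped decomposition is
out of scope.

**BestKeeper.** Per-gene SD and MAD (mean absolute deviation from the
mean) of Cq across samples, CV%, and the SD < 1 cycle stability flag. The
ranking dispersion defaults to SD with MAD selectable, since published
implementations differ and the choice is rarely stated. Optionally the
BestKeeper index (per-sample geometric mean Cq) and per-gene Pearson
correlations against it are computed; the full regression workflow is not.

**Comparative ΔCt.** score_j = mean over k ≠ j of SD over samples of
(Cq_j − Cq_k). Per-sample offsets common to all genes cancel here and in
geNorm/NormFinder, but not in BestKeeper — BestKeeper's SD absorbs
sample-loading variation, which is why it often disagrees with the other
three; the test suite asserts all four directions of this invariance.

## Aggregation

Scores map to competition (minimum) ranks: ties share the smallest
applicable rank, the next distinct score skips (1, 1, 3). The
comprehensive value is the unweighted geometric mean of the per-algorithm
integer ranks — computed from ranks, not scores, which is the arithmetic
that reproduces published comprehensive-ranking tables exactly — displayed
rounded half-even to 2 decimals. The final ordering competition-ranks the
*unrounded* geomeans; display ties break by mean rank then gene ID. With a
single algorithm selected, the geomean degenerates to that algorithm's
rank, so restricted runs remain well-defined.

## Subsampling

For each requested size, subsets are drawn uniformly without replacement;
each draw's generator is keyed by (seed, size, draw index), so draw d is
reproducible regardless of how many draws run. Optional stratification
apportions the subset over animals by largest-remainder quotas (off by
default; the emulated protocol used simple random selection). The full
pipeline — including per-gene Cq_min — is recomputed within each subset,
and concordance with the full-data ranking is summarized by Spearman rho on
final ranks (average-rank tie correction inside the correlation only) and
the overlap of the rank ≤ 3 sets, capped at 3. Single draws per size
reproduce the published protocol; the default 100 draws characterize the
distribution instead of a point sample.

## Synthetic generator

Cq_gij = mean_g + s_j + u_animal(j) + λ_g·F_b(g),j + e_gj + t_gij, all
terms normal on the Cq (log2) scale — i.e. log-normal expression, the
standard qPCR error model. Defaults emulate a repeated-measures blood
panel study: 15 genes × 75 samples from 7 animals (preset `paper_design`
splits 13, 12, 10, 10, 10, 10, 10), gene mean Cq evenly spread 21–32
cycles, per-gene efficiencies 95–105%, sample effect SD 0.4 cycles
(RNA input/quality), animal effect SD 0.2, per-gene noise SDs evenly
spread 0.1–0.8, triplicates with technical SD 0.1. The noise spread was
chosen once so that collapsed per-gene Cq SDs (≈0.46–0.93 cycles) bracket
the 0.5–0.8 range typical of published blood panels; it is a calibration
to qualitative features, not ground truth. Co-regulated blocks share a
standard-normal latent factor per sample with per-gene loading λ (cycles);
a gene's true "instability" is sqrt(e_SD² + λ²), and the intended
stability order (ties lexicographic) is recorded alongside the latent
factors and pre-technical-noise Cq for recovery tests.

What the generator does *not* emulate: plate/batch structure, amplification
curve shape, outlier samples, condition-dependent expression shifts, and
non-normal heavy-tailed noise. Passing recovery tests therefore show the
algorithms rank genes correctly when the additive log-scale model holds —
not that any particular wet-lab panel satisfies that model.

## Problem sizes and observed behavior

The test suite runs Monte-Carlo checks at sizes chosen to make sampling
error negligible relative to the asserted margins: estimator unbiasedness
at k = 6, n = 200 over 500 replicates; noise-magnitude recovery at k = 5,
n = 2000 over 100 replicates (mean absolute error < 0.03 cycles);
truth-order recovery over 100 generator seeds (mean Spearman rho ≈ 0.99
for geNorm, NormFinder and ΔCt); co-regulation bias over 200 seeds.

Two behaviors deserve explicit note:

- **Co-regulation bias.** With a two-gene block at λ = 0.6 and tiny
  independent noise among genes of comparable total noise (0.4–0.9),
  geNorm's final pair is the block in essentially every seed while
  NormFinder's top two almost never is: the pairwise approach rewards
  correlated candidates, the model-based one does not. The contrast
  requires the block's total noise to sit mid-panel; if the block genes
  are simply the least stable genes overall, no method selects them and
  the comparison is vacuous.
- **Top-3 robustness under subsampling is near-tie limited.** With the
  default noise grid, adjacent genes differ by only 0.05 cycles, so the
  3rd- and 4th-ranked genes of any one dataset are nearly exchangeable.
  35-sample subsets recover the full-data ranking almost perfectly as an
  ordering (mean rho ≈ 0.98) but reproduce the exact top-3 *set* in only
  ~55–100% of draws depending on the dataset realization (≈85% averaged
  over realizations). Conclusions about "the top three genes" under these
  conditions are sensitive to near-ties in a way conclusions about the
  ordering as a whole are not; this is a property of the study conditions,
  not of the estimators.

## Known limitations

- No plate/NTC handling or fluorescence-level processing; the pipeline
  starts at Cq values.
- NormFinder's grouped (inter/intra-condition) decomposition is not
  implemented.
- BestKeeper beyond dispersion + optional index correlation (the original
  tool's regression tables) is not implemented.
- Rank aggregation is the unweighted geometric mean only; other schemes
  (Borda, Kemeny) are out of scope.
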