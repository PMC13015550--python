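# Methods note

This note records the statistical models, assumptions, parameter
defaults, and numerical choices implemented in `perturbnuc`, and what
the synthetic-data generator does and does not emulate. No empirical
claim is made here beyond what the test suite and
`scripts/acceptance.py` compute.

## 1. Amplicon classification and pool QC (`perturbnuc.amplicon`)

**Model.** A dual-guide cassette read is classified by searching for
each library spacer inside two offset windows (the expected position of
guide 1 and guide 2 ± `slop` bases) using infix semi-global alignment
(Levenshtein distance, `edlib` HW mode) with at most `max_edit`
mismatches/indels. A spacer is *detected* in a window only when exactly
one library spacer attains the minimum distance there (unique-best
rule; ties reject the window). Both read orientations are tried and the
orientation with more detections (then lower total distance) wins. A
read is `on_target_pair` when both detections belong to the same
designed pair, `chimeric` when they belong to different pairs, and
`unassigned` otherwise.

**Parameters.** `max_edit = 3` (per 20-nt spacer; tolerant of long-read
error while staying below half the minimum pairwise spacer distance in
any sensibly designed library), `slop = 12` (cassette length jitter).
Pool QC reports per-pair counts (on-target reads only), per-guide
counts (every detection in on-target and chimeric reads), the on-target
fraction, coefficient of variation (population SD / mean over pair
counts), Gini coefficient, and a depth flag requiring mean reads per
guide strictly above `min_mean_depth = 100`.

**Assumptions / limits.** Spacer sets must be mutually distinguishable
at distance > 2·`max_edit` for the unique-best rule to be safe; the
classifier does not model cassette truncations beyond the slop window.

## 2. Guide assignment (`perturbnuc.assign`)

**Model.** Guide UMI counts per cell are a mixture of ambient
background (low counts in cells not carrying the guide) and true
capture. For each guide, counts > 0 are log2-transformed and fit with a
two-component Gaussian mixture (scikit-learn `GaussianMixture`,
k-means++ initialization, `tol = 1e-6`, `max_iter = 500`, fixed
`random_state`). The higher-mean component is the signal. A cell
receives guide *g* iff `count ≥ min_umi` **and** the signal posterior
at its count is `≥ posterior_cut`. Labels follow the assigned-guide
count: one → `single`, several → `Doublet`, none → `Not assigned`.

**Parameters.** `min_umi = 3` (removes ambient counts that would
otherwise be assignable when the mixture is poorly separated),
`posterior_cut = 0.5` (maximum-posterior rule). Guides with < 10
positive cells, zero spread, or coincident fitted means fall back to
threshold-only mode (posterior 1 for any positive count), because a
2-component fit is not identifiable there.

**Numerics.** Posteriors are computed with log-density differences and
a logistic transform, avoiding underflow for extreme counts; zero
counts have posterior 0 by construction.

**Diagnostics.** Assignment/single rates (overall and per metadata
group), cross-guide Pearson correlation of UMI profiles (low off-diagonal
values are expected under low-MOI delivery), and an on-target knockdown
check comparing log-normalized target-gene expression in each targeting
guide's single cells against safe-targeting control cells (two-sided
rank-sum test, BH across targets). Assignment labels may be guide ids
or cassette/pair ids; both are matched.

## 3. Indel validation (`perturbnuc.indel`)

**Model.** For every assignment group and every guide target window,
the indel ratio is the fraction of reads *fully spanning* the window
(aligned reference span contains the window) that carry an insertion or
deletion intersecting it. CIGAR semantics: reference-consuming ops are
{M, D, N, =, X}; a deletion occupies its deleted reference interval and
counts when that interval overlaps the half-open window; an insertion
sits between two reference bases and counts only when that junction is
strictly interior to the window (`start < p < end`), so insertions
flush against a window edge do not count. N (splice) is never an indel.
The default numerator is a per-read boolean (ratio bounded in [0, 1]);
an `events` mode counts every I/D event instead.

**Outputs.** The full group × target grid (zero-spanning combinations
kept and flagged), and an enrichment matrix where each row is divided
by its own maximum (all-zero rows left at zero, NaN propagates), making
on-target editing visually block-diagonal.

## 4. Nucleus QC (`perturbnuc.qc`)

Stated filters with **strict-inequality boundary semantics** (a cell at
a boundary is kept): RNA — `n_genes ≥ 500`, `1000 ≤ n_umi ≤ 15000`,
`doublet_score ≤ 1.5`, optional cluster-median rules (drop clusters with
median genes < 1000, median mito % > 8, or median intronic fraction
> 0.55), optional sample-tag confidence gate. ATAC —
`200 ≤ n_count_peaks ≤ 10000`, `FRiP ≥ 0.10`, `TSS enrichment ≥ 1`,
`blacklist fraction ≤ 0.075`, `nucleosome signal ≤ 0.3`. Every decision
carries its list of failure reasons; downstream analysis uses the
intersection of RNA-kept and ATAC-kept barcodes.

## 5. Differential testing (`perturbnuc.diff`, `perturbnuc.glm`)

**Pseudobulk.** Single-assignment cells of one cell type are summed
into (guide, sample) columns; column totals conserve the contributing
single-cell counts exactly. RNA features are prefiltered to those with
strictly more than 10 UMIs in at least 2 columns; ATAC keeps all
non-zero rows by default (`dar_prefilter` enables the RNA rule there).

**Normalization.** Hand-implemented TMM (trimmed mean of M-values):
the reference column is the one whose 75th-percentile of library-scaled
counts is closest to the column mean; per-column factors are weighted
means of log2 ratios after double trimming (30 % on M, 5 % on A) with
delta-method inverse-variance weights, renormalized to geometric mean
one. Offsets are `log(library size × factor)`.

**GLM.** NB log-linear models are fit for all features simultaneously
by IRLS (working weights `μ/(1+φμ)`, batched normal equations via
einsum with a 1e-8 ridge for degenerate designs, η clipped at ±700).
Dispersion: Cox–Reid adjusted profile likelihood
(`APL = ℓ − ½ log|XᵀWX|`), common value maximized over a log-scale grid
(−10 … 2, step 0.1) with golden-section refinement; tagwise values are
shrunk toward the common value by a weighted average on the log scale
with prior weight 10 (a pragmatic empirical-Bayes squeeze). The design
is intercept + guide dummies (control guide as reference) + sample
dummies (first tag as reference). Each perturbation is tested by an LRT
dropping its coefficient (χ², df = 1, LR clipped at 0), with BH
correction per contrast. `logFC` is the coefficient divided by ln 2.
Features that are all-zero across the contrast get `p = 1`, `logFC = 0`
and a `separation` flag; when exactly one group is all-zero the
*reported* (never tested) logFC adds 0.125 to the group sums to stay
finite.

**Calibration.** On null NB data (dispersion 0.1, 2,000 features, 4 + 4
columns) the type-I error at p < 0.05 stays within 3 binomial SEs of
0.05 and p-values pass a KS uniformity test (see
`tests/test_acceptance.py`); in the Poisson limit the LRT matches an
independent Poisson-deviance oracle within 1e-3. The χ² reference is
asymptotic: with very few pseudobulk columns the test is expected to be
slightly liberal.

## 6. Peak–gene links (`perturbnuc.links`)

An **explicitly simplified** correlation linker, labeled as such in the
output metadata. Candidate pairs are peaks within `window_bp`
(default 500,000) of a gene body (or TSS with `tss_anchored`). For each
pair, Pearson r between log-normalized accessibility and expression is
z-scored against the correlations of up to `n_background = 200`
background peaks drawn (seeded) from the same mean-accessibility decile
as the tested peak, widening to neighboring deciles until at least
`min(max(20, n_background/4), n_peaks−1)` candidates exist; p is the
two-sided normal tail and BH runs across all tested pairs.
Zero-variance vectors and degenerate backgrounds are flagged, not
dropped. Unlike full published linkers there is no GC matching (no
genome sequence is consumed) and the normal tail replaces an explicit
permutation null; the z-based p tracks a 10,000-shuffle permutation p
within a factor of two on a 50-cell fixture.

## 7. Log-normalization and BH (`perturbnuc.stats`)

Log-normalized expression is `ln(1 + 1e4 · count / cell_total)`
(counts-per-10k), computed sparsely; zero-total cells are an error
naming the barcode. BH is the standard step-up procedure (validated
against statsmodels).

## 8. Synthetic data generator (`perturbnuc.simulate`)

**What it emulates.** Low-MOI delivery (truncated-Poisson vectors per
cell, default mean 1, max 3, or a fixed count), cassette-level guide
capture (one polyadenylated transcript per vector; a `per_guide` mode
exists), ambient Poisson background (rate 0.05) vs NB signal (mean 40,
dispersion 0.3), cell-type-restricted perturbation effects on genes and
peaks plus on-target knockdown everywhere, NB expression/accessibility
with log2 fold-change injection, optional gene↔peak coupling through a
shared latent scaling, cassette amplicons with per-base error and a
chimera fraction, barcode-tagged alignments whose reads carry a
deletion at the cut site iff the cell is edited and carries that pair,
planted QC failures at a set rate, and per-sample tags. All randomness
flows from one `numpy` Generator seeded by `SimConfig.seed`; outputs
round-trip through the documented text formats byte-identically.

**What it does not emulate.** Sequencing-depth variation per cell
beyond NB noise, doublet transcriptomes, batch effects beyond the
sample tag, fragment-length structure in ATAC, genome sequence (no GC
content), guide position effects within the cassette, or partial
editing outcomes (a single fixed-length deletion stands in for the
indel spectrum).

**Defaults as study conditions.** The defaults above are the simulated
study conditions used by the test suite and the acceptance script; they
were not tuned against outcomes.

## 9. Numerical and engineering choices

- All matrices are CSR sparse with int64 counts; MatrixMarket files are
  written with `field="integer"` so round-trips are lossless.
- SAM input uses pysam when a header is present and a minimal 11-column
  parser otherwise; unmapped reads and reads without a `CB` tag are
  skipped; positions convert to 0-based half-open.
- Determinism: every stochastic routine takes an explicit seed; derived
  seeds are drawn below 2³¹.
- Known limitations: the mixture model assumes log-normal-ish signal
  (a heavy-tailed signal can push the fallback); the χ² LRT is
  asymptotic in the number of pseudobulk columns; the link null assumes
  the matched-background correlation distribution is approximately
  normal; TMM weights use the delta-method approximation of the
  original formulation.
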