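# Methods

This note documents the models implemented in `shrnakit`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer would want written down.

## Spike-in calibration and normalization

Digital hybridization counters include synthetic positive-control RNAs at
known nominal concentrations. `shrnakit` uses four controls named
POS_B..POS_E on a strictly decreasing 4-fold ladder, 32 / 8 / 2 / 0.5
concentration units by default (the conventional positive-control ladder;
the units are arbitrary and configurable). POS_A and POS_F are excluded by
default; spike rows are recognized by the configurable prefix `POS_`.

Per sample, ordinary least squares of raw counts on concentration yields a
slope (counts per concentration unit — the sample's hybridization
efficiency) and a background. Normalized expression is

    E_i = (R_i - B) / slope,

clipped at zero, with `log2(E_i + pseudocount)` (pseudocount 1 by default)
carried alongside for statistics.

**What B is.** In the default linear-space calibration, B is the line's
fitted background — its value at zero concentration — so that E_i is the
OLS-calibrated concentration estimate and a noise-free simulated run is
inverted exactly. Subtracting the fitted signal *at the POS_B
concentration* instead would be subtracting the top of the ladder and
would drive nearly all features negative; that quantity is still computed
and reported per sample (`SpikeInFit.pos_b_signal`) as a QC readout. A
log-space variant (`log_space=True`) regresses log2 counts on log2
concentrations and subtracts the fitted log2 signal at POS_B, making the
normalized value log2 expression *relative to POS_B*; it is provided
because calibration of log-transformed counts is a legitimate alternative
reading of this normalization family, but the linear-space form is the
default and the one all closure guarantees refer to.

Fits with fewer than three distinct concentrations or non-positive slope
raise a degenerate-fit error rather than silently producing garbage.
Global normalization then rescales every sample multiplicatively so its
mean over all miRNAs equals the grand mean; it is idempotent, preserves
within-sample ratios, and refuses all-zero samples.

## Paired differential expression

Samples are paired across two conditions by shared time point. Per
feature: a classical paired t-test on log2 values (two-sided, df =
n_pairs − 1) and a signed linear fold change computed from the mean linear
expression across the paired samples — r for r ≥ 1, −1/r otherwise, so
thresholds written as |FC| > 1.1 apply symmetrically. The t-test lives on
the log scale where multiplicative noise is additive; the fold change is
reported on the linear scale where thresholds are stated. A feature is
called DE when p < p_thresh **and** |FC| > fc_thresh, both strict.
Defaults: (0.05, 1.1) for miRNA panels, (0.1, 1.25) for gene expression.

Numerical edge cases: differences that are identically zero give an
undefined p (treated as 1 — never called); a zero-variance but nonzero
shift (exactly reproducible effects, e.g. noise-free data) gives the
statistic's limit (±inf, p = 0) so exact planted effects are called. Both
means zero gives an undefined fold change. The fold change uses no
pseudocount by default (exactness at zero noise); a pseudocount argument
exists for degenerate data, and a mean-of-per-pair-ratios variant is
exposed (`fc_mode="mean_of_ratios"`) since either convention appears in
practice.

With three time points the test has two degrees of freedom: honest but
weak. That is a property of the design being modelled, and is documented
rather than "fixed" — no variance moderation is applied. Raw p-values are
used by default (matching the thresholds above); Benjamini–Hochberg
adjustment is available behind a flag (`bh=True`).

## Reporter assay scoring

**Luciferase.** Replicate RLUs are aggregated by arithmetic mean with a
delta-method standard error on the ratio (consistent with error bars shown
as SE). Ratios chain exactly: vs-control ÷ vs-control(reference) =
vs-reference. Day strata (readouts 1 and 2 days post-transfection) are
never pooled; asking for a ratio on a multi-day table without selecting a
day is an error.

**Flow cytometry.** The positivity threshold is an empirical quantile of an
untransfected control's intensity distribution, default 0.999 (≈0.1%
false-positive events); the exact gating quantile is an instrument/analyst
choice, so it is a parameter. A sample's composite score is
(percent of events strictly above threshold) × (median intensity of those
positive events — positives only, and an even count averages the two
central order statistics), reported as a ratio to the control sample's
score. A sample with no positive events scores 0 with a warning flag.

**qPCR.** Standard ΔΔCt with a reference gene (default GAPDH) and a
calibrator sample, assuming amplification efficiency 2 (one doubling per
cycle) unless calibrated otherwise; replicate Cts are averaged. The result
is invariant to any constant shift of a sample's Cts.

## Hairpin oligo parsing

A pLKO.1 sense-strand cloning oligo is `CCGG` + sense arm + `CTCGAG` +
antisense arm + poly-T terminator. The parser searches jointly over loop
occurrences and terminator lengths for the segmentation with equal-length
arms followed by an all-T run of ≥ 5 nt. The joint search matters: when an
antisense arm itself ends in T, the terminator is not simply the maximal
trailing T-run. If no segmentation — or more than one — satisfies the
constraints, parsing fails loudly rather than guessing, because a silent
misparse would corrupt every downstream arm comparison. The first arm is
labelled "sense" by pLKO.1 convention; no guide/passenger assignment is
made.

The packaged reference table (30 constructs: five PIAS2-targeting shRNAs,
a seven-member mutant series, eGFP/scrambled controls, and
GAPDH/HDAC/PPP2CA/Bcl2l11 panels) all parse to 21-nt arms. Twenty-nine
have perfectly complementary stems; `shPias2_mu4` as printed carries a
single C·A mismatch at arm position 13 (its antisense arm retains the
parental base opposite the mutated sense position) — the table is
transcribed faithfully and the mismatch is reported, not corrected.
RNA secondary-structure free energies are *inputs* here (an optional
precomputed MFE column), never computed: folding is out of scope.

## Integration

Set overlaps are exact, with direction concordance counted when both sets
carry directions. The miRNA-target intersection annotates each (miRNA,
gene) pair for consistency with miRNA-mediated repression (opposite
directions). Family enrichment is the upper-tail hypergeometric
P(X ≥ k) for k family members among n DE genes drawn from an annotated
background; the percentage 100k/n is rounded half-up to two decimals
(7 of 320 → 2.19%). The background universe is whatever annotation the
caller supplies — enrichment p-values are only comparable for a stated
background, which is why the package reports the background size alongside
p. Identifiers are case-sensitive exact strings; ID mapping/aliasing is
out of scope. R² is the squared Pearson correlation, undefined (NaN) for
constant inputs.

## Synthetic data: what it emulates, and what it does not

The generators produce every input the pipeline consumes, with the
statistical structure the estimators assume:

- **Counts** (`simulate_ncounter`): one row per miRNA and spike-in, one
  column per condition × time point. Each sample gets a lognormal
  hybridization-efficiency factor scaling slope and background jointly
  (default CV = the noise CV), making global normalization non-trivial
  while remaining exactly invertible through the spike-in fit. Per-cell
  counts are `background + slope × level × ε` with ε lognormal, unit mean,
  CV = `noise_cv`; counts are rounded and floored at zero, with the
  pseudo-continuous truth retained on the returned matrix for oracles.
  Defaults: 541 miRNA features (the panel size observed expressed in the
  assay this models), conditions CRX/NRL control + two shRNA
  co-transfections, time points 15/24/48 h, slope 200 counts per
  concentration unit, background 20 counts, abundances log-uniform on
  2–200 concentration units, noise CV 0.1. The noise magnitude is a stated
  default, not an estimate from any particular instrument.
- **Reporter plates**: per-well RLU = control × fold(condition) × lognormal
  noise, always including a fold-1 control, with day strata.
- **Flow events**: a two-component lognormal mixture with Bernoulli
  positivity per event; event count is exact.
- **qPCR**: Ct = ref_ct − log_eff(relative expression) + Gaussian noise,
  with the reference gene present in every sample.

The multiplicative lognormal noise family was chosen because count and
luminescence data are positive and right-skewed, and because its zero-noise
limit is exact — every closure test (normalization inversion, planted-FC
recovery, ΔΔCt inversion) holds to machine precision at `noise_cv = 0`.

What the generators do **not** emulate: probe-level microarray structure
(expression is simulated at the summarized level), sequencing reads,
count overdispersion beyond lognormal, batch effects, plate-position or
edge effects, spectral spillover/autofluorescence in flow, or qPCR
efficiency drift. Passing tests therefore demonstrate that the estimator
chain is correct *under its own assumptions* and well-behaved at realistic
noise, not that those assumptions hold on any particular instrument's
output.

## Problem sizes and determinism

All simulations are driven by `numpy.random.default_rng` seeds; equal
seeds give bit-identical outputs, and every pipeline output file carries
the seed and a hash of the scientific configuration. The shipped checks
use desk-scale problems — 541-feature panels, 2000-feature null runs for
type-I calibration (five seeds), 1000-gene expression arms — sizes at
which every statistical property being asserted (binomial CIs on the
false-positive rate, KS uniformity, median recovery error) is already
stable; all of them run in seconds.

## Known limitations

- The spike-in fit is unweighted OLS on a heteroscedastic ladder; with
  multiplicative noise the top control dominates, giving per-sample scale
  errors of a few percent at CV 0.05. Global normalization absorbs these
  into a common scale. A weighted fit would be a natural extension.
- Raw p-values with df = 2 (miRNA arm) or df = 1 (gene arm) are low-power
  and noisy; the package reproduces that design honestly rather than
  moderating it.
- The hypergeometric enrichment p depends entirely on the supplied
  background annotation; no default universe is bundled.
- NanoString-style QC (negative-control thresholding, lane/FOV/binding
  density), housekeeping normalization, and the full RCC schema are out of
  scope; the RCC dialect covers the CodeSummary count section only.
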