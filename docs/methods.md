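# Methods

## The direct multifractal estimator

The analysed object is a nonnegative displacement series `u(t)` treated
as a mass-like measure. For each bin size `L` (samples), the series is
cut into `N_L = floor(n/L)` complete, non-overlapping bins; the trailing
partial bin is discarded. Bin proportions `P_i(L)` are normalized over
the complete bins. The q-distorted mass `μ_i(q, L) = P_i^q / Σ_j P_j^q`
re-weights the measure to emphasize large (`q > 0`) or small (`q < 0`)
proportions. Two q-weighted sums are regressed on `ln L` across the
scale set: the slope of `Σ μ ln μ` (negative Shannon entropy) is the
Hausdorff-like dimension `f(q)`, and the slope of `Σ μ ln P` is the
singularity strength `α(q)`. The spectrum is the downward-opening curve
`(α(q), f(q))` over the retained q; its width `W = α_max − α_min`
summarizes heterogeneity. This direct construction avoids both the
Legendre transform of a partition function and any finite-variance
assumption, which matters because strongly quasiperiodic sway series
defeat SD-based scaling estimators.

**Retention rule.** A value of q contributes only when *both*
regressions are convincingly linear: |Pearson r| > `r_threshold`
(default .995) for each, with |r| used because slopes of interest can be
negative. Heavily multifractal series destabilize the power-law form at
extreme q, so wider spectra retain fewer q — an inverse relation the
`q_retention_profile` diagnostic makes visible. If no q survives, the
width is undefined (NaN) and flagged, never silently zero. The
threshold is a floor: q survives only when |r| exceeds it.

**Defaults.** Integer q from −200 to 200. Very wide q sweeps are safe
here precisely because the retention rule discards unstable q; testing
many q sharpens, rather than inflates, evidence of low multifractality.
`L` runs from 4 samples to one quarter of the series length (1503 for a
6012-sample series, 250 for a 1000-sample block).

**Scale set.** Octave spacing: `L = l_min·2^j` up to `l_max`, appending
`l_max` itself when it extends the top octave by ≥ 25%. Octave spacing
weights every doubling of scale equally in the log-log regression, is
the standard convention for direct spectrum estimation, and aligns
exactly with dyadic cascade benchmarks (where it recovers the
closed-form width to machine precision). A log-spaced scale set of any
count remains available via `n_scales`; note that non-dyadic bin sizes
degrade the scaling of dyadic test measures and push their extreme q
below the retention floor, biasing W downward on such benchmarks.

**Numerics.** `P^q` at `q = ±200` overflows any direct power, so all
masses are formed in the logarithmic domain with max-subtraction;
`Σ μ = 1` holds to 1e-9 across the full q range. Bins with `P_i = 0`
contribute nothing for `q > 0`; for `q ≤ 0` they would receive infinite
weight, so the affected scale is dropped for those q rather than
flooring the proportion (flooring invents mass and biases negative-q
moments; dropping is visible to the retention filter). Regressions are
computed on centered sums to avoid cancellation near |r| = 1. At least
3 valid scales are required per regression.

## IAAFT surrogates and t_MF

Each surrogate starts from a conjugate-symmetric random-phase
realization of the original amplitude spectrum (DC and Nyquist phases
fixed so the series is real), then iterates a fixed 1000 times:
(a) impose the original amplitude spectrum keeping current phases,
(b) rank-replace values with the original's sorted values. Ending on
(b) makes the surrogate's value multiset equal the original's
bit-exactly, while the periodogram converges to the original's
(correlation > .95 on kilosample test signals). A fixed iteration count
is used rather than a convergence stop; the per-iteration relative
amplitude mismatch is available for diagnostics. Surrogate `i` of an
ensemble uses seed `seed + i`, so ensembles are reproducible and
members independent. Each surrogate is analysed under the identical
scaling configuration as its original.

The nonlinearity statistic is
`t_MF = (W − mean(W_surr)) / SE(W_surr)`. The standard error is read as
`sd/√n` by default; the phrase is genuinely ambiguous and the plain-sd
(z-score) reading is exposed as `se_mode="sd"` and recorded in output.
The two readings differ in scale by `√n` (~7 at n = 50), which matters
for interpreting significance counts: under the default reading a
genuinely linear series — whose W is just one more draw from the
surrogate-width distribution — exceeds |t| = 1.96 about two thirds of
the time, because the statistic measures distance from the ensemble
*mean* in units of the mean's uncertainty. The sd/√n reading is the
default as the more literal reading of "standard error of W_surr";
calibration *as a test* (false-positive rate ≈ 5%) holds under the
z-score reading,
and the package's null-calibration checks are phrased accordingly:
mean t centered on zero under the default, rare rejections under
`se_mode="sd"`.

## Cohort pipeline

Whole-series measures (`W_ALL`, `t_ALL`) always use the entire stored
series. Block measures use the first four contiguous 1000-sample (20 s
at 50 samples/s) blocks counted from a per-series `onset_index`
(default 0) supplied by the dataset manifest — stimulation onset is a
property of the recording, not of the algorithm. Block t statistics are
computed against surrogates of that block alone, so each unit is
compared with the best-fitting linear model of that same unit;
surrogates of the whole series sliced at block spans are available via
`block_surrogate_scope="series"`. Series longer or shorter than 6012
samples simply rescale `l_max = length/4` for the ALL measures. A
series that cannot supply four full blocks contributes an ALL-only row
with a logged warning; a duplicate subject × condition pair is a hard
error; an unreadable file is skipped with a logged warning and the run
continues. Per-condition summaries report mean and SD of `W_ALL` and
`t_ALL` and the counts of series with `t_ALL > 1.96` and `< −1.96`.

## Mixed-effects models

Both models have a random intercept per subject and exactly 16 fixed
terms: intercept; Condition (1 = wind, 0 = no-wind); three Block terms;
the whole-series covariate (`W_ALL` or `t_ALL`, matching the response);
and all two- and three-way interactions. The `W_BLOCK` model codes
Block as orthogonal polynomials (linear, quadratic, cubic; columns
orthonormal over the design, signed so the linear term increases with
block) to estimate smooth change; the `t_BLOCK` model codes Block as a
class variable with Block 1 as reference. Covariates enter uncentered,
on their raw scale. Estimation is REML via statsmodels MixedLM; when
the default optimizer stalls at a boundary variance, derivative-free
refits (Powell, Nelder–Mead) recover the fit. Fixed-effect p-values are
t tests on residual degrees of freedom (observations − 16), with the
method recorded in the fit object; Satterthwaite-based p-values from
other tools will differ slightly in small samples, so comparisons
should be made on B and SE, which the test suite cross-checks against
an independent lme4/lmerTest fit to 1e-4.

## Synthetic data: what it emulates and what it does not

`synth_cohort` emulates a repeated-measures sway experiment: 21
subjects × 2 conditions (wind / no-wind),
6012 nonnegative samples at 50 samples/s (four 20-s analysis blocks plus
margin), a quasiperiodic sway carrier (default 1 s period, amplitude 0.5
about a baseline of 1, arbitrary length units), 1/f observation noise
(scale 0.1), and a condition-dependent sign of nonlinearity — wind
narrows the spectrum relative to the linear null, no-wind widens it.
The carrier period reflects the slow postural oscillation visible in
sway records; amplitudes are chosen so the displacement stays positive
and the absolute-value guard at the end of generation almost never
activates (keeping the "none" regime genuinely linear).

Mechanisms, chosen because each is demonstrably nonlinear (or linear)
in the surrogate-test sense and verified at design time:

* **widening** — the whole series is multiplied by a random-branch
  binomial-cascade envelope (default weight p = 0.35, normalized to
  mean 1). Multiplicative cascades place their large values in
  phase-organized clusters that phase randomization destroys, so
  originals are wider than their surrogates (measured mean t_MF ≈ +12
  across 20 series at 20 surrogates × 300 iterations).
* **narrowing** — the carrier-plus-noise fluctuation is divided by its
  own running RMS over ~2 carrier periods (dynamic gain control, a
  stabilizing feedback). The original's envelope is flatter than any
  rearrangement of the same values with the same spectrum can be, so
  originals are narrower than their surrogates (measured mean
  t_MF ≈ −3.8 under the same settings).
* **none** — carrier plus 1/f noise only; measured mean t_MF 0.37,
  within 2 SE of zero.

The cascade generator itself assigns the weight p to the left or right
child by an independent fair coin per node from one seeded generator,
giving a statistically symmetric measure with the same spectrum as the
deterministic cascade; masses sum to 1 to < 1e-9 accumulated error.

What the generator does **not** emulate: biomechanics or aerodynamics,
measurement noise structure of video tracking, inter-subject
correlation beyond independent seeds, onset misalignment (synthetic
onsets are 0), or the amplitude scale of any particular dataset — the
synthetic W values are larger than typical real-sway widths. Passing
tests therefore certify the estimators and the inference chain, not any
empirical claim about real animals.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` scale the study design down
to keep full-chain runs at desk scale while leaving every stage intact:
cohorts of 4–8 subjects, ensembles of 8–15 surrogates at 100–300 IAAFT
iterations for pipeline checks (the analysis defaults remain 50 and
1000), and 20-series batches for null calibration. Directional and
calibration checks at these sizes are conservative: the default
statistic's magnitude grows with ensemble size, so full-size ensembles
separate the regimes more sharply, not less.

## Known limitations

* Width is undefined (not zero) when retention is empty; downstream
  ensembles fail if more than 20% of surrogate widths are undefined.
* The SE-convention ambiguity of t_MF means absolute t magnitudes are
  comparable across analyses only under a stated `se_mode`.
* MixedLM p-values use residual df, not Satterthwaite; with 21 subjects
  and 168 block rows the difference is small but nonzero.
* IAAFT surrogates of strongly quasiperiodic series carry a known
  slight spectral-leakage bias; the "peaked" null shows a small positive
  mean t at desk sample sizes without exceeding the 2-SE band.
* 5th and later blocks are deliberately out of scope (unbalanced
  designs); the pipeline always takes the first `n_blocks` full blocks.
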