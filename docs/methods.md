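# Methods

This note documents the models, numeric conventions and design choices
behind `vamsquant`, and what the synthetic-data generator does and does
not emulate. Concentrations are ng/mL throughout; hematocrit (Hct) is a
volume fraction.

## Whole-blood compartment model

A VAMS tip absorbs whole blood, so its total analyte concentration is the
volume-weighted mixture of the serum and red-blood-cell compartments:

    c_VAMS = (1 − h)·c_serum + h·c_RBC,        h = hematocrit.

Partition behaviour per analyte:

* **ratio mode** — an equilibrium plasma-to-RBC ratio *r* ties the
  compartments, `c_RBC = c_serum / r`. Defaults: 4:1 for A4, DHEA-S and
  testosterone, 5:1 for cortisol, 3.2:1 for T3.
* **fixed mode** — thyroxine's RBC level is treated as a constant
  0.54 ng/mL (midpoint of the 0.30–0.78 ng/mL range reported for RBCs),
  independent of the serum level.

The printed back-conversion `c_serum = (c_VAMS − h·c_RBC)/(1 − h)` is
circular in ratio mode (`c_RBC` depends on `c_serum`); we solve the two
linear relations simultaneously, giving the exact closed form

    c_serum = c_VAMS / ((1 − h) + h/r).

This is order-free and reproduces the 0.6/0.4 arithmetic at the
standardization hematocrit of 0.40 (a 30 µL tip then holds 18 µL of
serum). Fixed-mode back-conversion can go negative when the measured
total falls below `h·c_RBC` (a near-blank sample with measurement noise);
it is clamped to 0 and flagged rather than raised, so a noisy batch does
not crash.

Conversions use the sample's own hematocrit when recorded, else the
0.40 standardization value. P4 and E2 have no established partition
ratio; they default to the steroid 4:1 with `defaulted=True`, and every
serum conversion through a defaulted ratio carries a
`partition_defaulted` flag in the output rather than silently refusing
or silently converting.

**Hematocrit bias.** For a sample of fixed serum concentration, an
uncorrected measurement calibrated at the reference hematocrit deviates
by `100·(c_VAMS(h)/c_VAMS(h_ref) − 1)`. In ratio mode this is independent
of the concentration (asserted internally at 0.01, 1 and 1000 ng/mL);
for a 4:1 partition and reference 0.40 it is `(1 − 0.75·h)/0.7 − 1`,
i.e. ±10.71% at the ends of the 0.30–0.50 interval — inside the ±20%
robustness band, which first breaks beyond Hct ≈ 0.59.

## Calibration and quantification

Quantification uses the analyte/ISTD peak-area ratio, which cancels any
common rescaling of both areas (preparation and detection losses).
Calibration is ordinary least squares of (nominal concentration,
blank-corrected mean ratio), replicates averaged per level, at least
three distinct levels. A 1/x weighting is available behind an explicit
option but off by default, matching the stated procedure.

**Blank correction.** The surrogate blank matrix retains trace endogenous
hormone (defaults 45 ng/mL DHEA-S, 0.001 ng/mL T, 0.15 ng/mL T4). The
run's mean blank area-ratio is subtracted from calibrators *and*
unknowns — the symmetric treatment, flagged in the report
(`blank_correction` field); re-anchoring nominals instead would be a
one-line change. Correction at the response level keeps the fitted curve
invariant to a constant ratio shift accompanied by the same blank shift.

**Linearity.** Accepted when R² ≥ 0.99 and a Wald–Wolfowitz sign-runs
test on the residuals shows no systematic pattern at α = 0.05. The runs
test is one-sided (lower tail): too *few* runs means clustered residuals,
the signature of curvature; too many runs is alternation and is not
flagged. Residuals below 10⁻¹⁰ of the largest response are treated as
zero so that noise-free fits are not rejected on floating-point sign
patterns. With 8% multiplicative noise (P4) a six-level unweighted fit
has E[1 − R²] ≈ 1.2%, so its linearity gate sits at a genuine knife
edge — roughly one in ten synthetic P4 curves fails honestly, as a real
assay's would.

Quantification inverts the curve; negative results are reported as 0 and
anything below the analyte's LOQ carries a `below_loq` flag. A rejected
curve refuses to quantify.

## Validation battery

* **Imprecision** — intraday CV per run (100·SD/mean of area ratios,
  SD with n−1), interday CV over all replicate values pooled across runs.
  The pooled reading matches the bandwidth-based description of the
  original design; an ANOVA variance-component estimate
  (within + between run) is available as an option for the stricter
  reading. Acceptance: ≤ 15% everywhere.
* **Accuracy** — 100·mean(measured)/nominal at the mid-range QC;
  acceptance ±15%.
* **LOQ** — lowest level of the replicate ladder whose CV ≤ 20% and mean
  SNR ≥ 10 *with monotone closure*: every higher level must also pass,
  so a noisy mid-level cannot produce a nonsensically low LOQ. SNR is an
  input column (measured upstream or simulated), never derived from
  areas, because no SNR estimator is prescribed.
* **Recovery / matrix effect** — mean-area ratios of pre- vs
  post-extraction spikes and matrix- vs solvent-spikes. Reported
  informationally: the isotope-labelled ISTDs compensate losses, so no
  numeric acceptance gate applies (a 27% thyroid-hormone recovery is
  acceptable given the achieved LOQ).
* **Carryover** — numeric, 100·blank-after-high/high area, gate 0.01%.
  The original protocol inspected chromatograms visually; a package must
  compute, and the reported result is numeric anyway.
* **Hct robustness** — measured-concentration deviation vs the Hct-0.40
  reference (interpolated if not sampled); the pass range is the maximal
  contiguous grid interval containing the reference with |deviation| ≤ 20%.
* **Stability** — scheduled-day means (0, 1, 3, 5, 7, 14, 28 days at
  20 °C and −18 °C); `stable_days` is the largest day d with every day
  ≤ d within ±15% of day 0, with a ">28" sentinel when day 28 passes.

The aggregate report takes the conjunction of the boolean components
(precision, accuracy, LOQ confirmation, carryover, frozen stability,
linearity, selectivity when supplied); missing components are listed as
not assessed and excluded. Selectivity is chromatographic inspection and
enters only as a pass-through boolean.

## Agreement analysis

Differences are fixed to serum − corrected-VAMS. (The reported table we
reconstruct limits from contains one row whose bias sign contradicts its
own limits' midpoint; fixing the direction and property-testing flip
invariance — bias negates, limits swap and negate, p-values unchanged —
is more robust than chasing a printed sign.) Statistics per analyte:

* bias = mean difference, SD with n−1, LoA = bias ± 1.96·SD (exactly
  symmetric by construction; the midpoint recovers the bias to 1e−12);
* CI of bias: t-based, variance sd²/n; CI of each limit: the standard
  large-sample Bland–Altman approximation, variance 3·sd²/n;
* percentage differences for plotting: 100·difference / pairwise mean,
  zero-mean pairs excluded and recorded;
* Shapiro–Wilk on the differences; paired t-test when p ≥ 0.05, else
  Wilcoxon signed-rank with a flag — and the t-test p-value is always
  reported alongside. The same 1.96 multiplier is assumed for the
  percentage-scale limits. All-zero differences short-circuit to p = 1
  with a degenerate flag.

## Synthetic-data generator

The forward model composes, per measurement:

1. truth — lognormal between-subject serum levels parameterized by the
   arithmetic mean/SD of the proof-of-concept cohort (e.g. testosterone
   5.2 ± 1.4 ng/mL male, 0.2 ± 0.1 female; P4 and E2 female-only, using
   luteal-phase statistics); hematocrit truncated-normal
   (mean 0.40 female / 0.47 male, SD 0.02, bounds 0.30–0.55);
2. the compartment mixture at the subject's hematocrit, plus the blank
   matrix's endogenous residual (present in calibrators, QCs and blanks
   alike, so the symmetric blank correction is exact in expectation);
3. first-order storage degradation `exp(−k·days)`. Defaults: k = 0
   frozen for all analytes; at 20 °C cortisol uses k = −ln(0.86)/14
   (≈86% retention at day 14, 74% at day 28 — classified 14-day stable),
   all others −ln(0.95)/28 (95% at day 28, above the 85% floor);
4. response: area ratio = slope · conc · recovery · matrix-effect ·
   exp(δ_run) · (1 + ε), with a fixed nominal ISTD area. Noise is
   multiplicative because the figures of merit are scale-free CVs and the
   panel spans four orders of magnitude in concentration.

**Noise calibration.** The per-analyte defaults are the validated assay's
figures of merit (e.g. testosterone: intraday 2%, interday 3%, recovery
84%, matrix effect 92%). The interday entry is the *pooled* interday CV
the generator should reproduce as an observable, so the between-run
component is drawn with sd √(interday² − intraday²) (floored at 0);
injecting the printed interday value directly as the run effect would
pool to √(intra² + inter²) and overshoot the published magnitudes.

SNR is simulated deterministically as conc/LOQ × 10 — it is an input
column downstream, and a deterministic SNR keeps the LOQ estimator's
10:1 gate exactly at the claimed LOQ instead of coin-flipping at the
boundary.

Calibrator nominal levels are config-driven (the original calibrator
concentrations are not available); defaults are six geometric levels
spanning each analyte's working range, chosen once to cover the LOQs and
the physiological concentration scales. Carryover is injected as a fixed
5 × 10⁻⁵ fraction of the preceding high signal (half the 0.01% gate).

**Paired studies.** Default n = 11 (one male), VAMS duplicates averaged,
single analytical run; the serum arm reuses the analyte's intraday CV
(no separate serum-assay CV is available). A noisy single-run calibration
injects a *shared* error into every subject of the run
(calibration-transfer bias) — realistic, and large enough to dominate the
per-subject noise for analytes quantified near the bottom of their
curve. `exact_calibration=True` generates the run's calibrators without
noise; it is used when studying the significance tests under exchangeable
error, where the shared component would otherwise confound the level of
the test. Even then the paired t-test runs slightly conservative
(≈3.8% rejection at nominal 5% in a 1000-seed study): differences scale
with each subject's concentration, so they form a scale mixture rather
than an iid normal sample — and with the default one-male composition the
male subject's 26-fold larger scale makes the test grossly conservative.
This is a property of raw-scale paired testing on lognormal biology, not
an implementation artifact.

**What the generator does not emulate:** chromatograms and spectra (the
pipeline starts at integrated peak areas), drift within a run, E2
derivatization chemistry (E2 is just another analyte with its own noise
and LOQ), menstrual-cycle time structure (cohort E2/P4 draws use the
luteal-phase statistics as given), and venous-vs-capillary matrix
differences beyond the compartment model. Passing tests therefore show
that the *computational* pipeline is correct and well-calibrated under
the stated error model, not that a particular laboratory will reproduce
the published figures.

## Problem sizes and numerics

Monte-Carlo suites use 200–1000 seeds (type-I-error studies), 500 seeds
(parameter recovery) and 10⁴ draws (round-trip and coverage properties);
these sizes give sampling errors an order of magnitude below the bounds
they are tested against. Round-trip conversions are exact to 1e−9
relative; the noise-free pipeline identity holds to 1e−6. Monte-Carlo
bounds frozen in tests were precomputed with brute-force oracles before
the corresponding checks were finalized (recovery 84.01 ± 0.04, matrix
effect 92.02 ± 0.06, null rejection 0.038 ± 0.006 over 1000 seeds).
Degenerate inputs (zero means, empty sets, missing day 0, hematocrit 1)
raise structured errors naming the offending quantity.
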