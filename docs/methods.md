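# Methods

## Paradigms and analytical time windows

Two built-in boxcar hypercapnia paradigms are supported. Design A
alternates 2 min room air / 3 min 6% CO₂ / 2 min / 3 min / 2 min
(TR 1.55 s, 478 volumes, 25 discarded for signal equilibrium). Design B is
a targeted-step protocol with unequal blocks — 45 s rest, 45 s CO₂, 90 s
rest, 120 s CO₂, 180 s rest (TR 2.0 s, 255 volumes, 5 discarded), aiming
at a 10 mmHg PETCO₂ change.

All analysis windows are fixed per design and interpreted on the
**post-discard** axis (t = 0 at the first retained volume): dilation
windows CVR-1/CVR-2 at 40–280 s and 360–580 s (A) or 10–80 s and
135–280 s (B), and hyper-to-normocapnia transition windows at 280–360 s /
580–660 s (A) or 80–135 s / 280–390 s (B) — the first half of each rest
period. Windows are closed-open `[start, end)` on sample times `k·TR`, so
adjacent windows never double-count a boundary sample. The pre- vs
post-discard reading of the window table is not decidable from the
protocol alone; post-discard is adopted because the windows are applied to
post-discard series throughout.

Baseline windows are not part of the published window set. Each is taken
as the 30 s immediately preceding the challenge's dilation window,
truncated at t = 0 (A: 10–40 s and 330–360 s; B: 0–10 s and 105–135 s):
late-rest samples least contaminated by the preceding transition. The
duration is configurable (`windows_for_design(..., baseline_duration_s)`).

## Non-parametric CVR

For each challenge the dilation-window excerpt gives the Sen's slope — the
exact median of all n(n−1)/2 pairwise slopes `(x_j − x_i)/(j − i)` on
sample indices, with the even-count median taken as the mean of the two
central order statistics. Percent signal change is
`slope · n_points / baseline_mean · 100`; because the pairwise slopes use
index differences and are then scaled by the sample count, the TR cancels
and the quantity is unit-less. CVR is that percentage divided by ΔPETCO₂
(% per mmHg). NaN samples are dropped before the slope (original indices
kept for the index differences) and excluded from `n_points`.

The companion Sen intercept `median(y_k − slope·k)` exists only to define
residuals for the AIC comparison; the CVR metric itself never uses it.

## Transition rate

BOLD is regressed on time in **seconds** (absolute post-discard time) over
the transition window; τ is the OLS slope and the transition rate is
τ/ΔPETCO₂. Seconds rather than volumes keep rates comparable across
designs with different TR (1.55 vs 2.0 s).

## PETCO₂

End-tidal values are expiration peaks: local maxima of the capnometer
trace separated by at least a minimum breath period (default 2 s) and
rising at least 0.5 mmHg above their surroundings (rejects sensor noise —
a real expiration swings several mmHg). The envelope holds each peak until
the next breath (PETCO₂ is a per-breath quantity; no interpolation) and is
resampled to the BOLD grid the same way. ΔPETCO₂ is the mean over the
challenge's baseline window subtracted from the mean over the **second
half** of the dilation window — the plateau, excluding the dilatory ramp.
When no trace exists (targeted-step rigs report the achieved change), a
scalar ΔPETCO₂ can be supplied directly.

## Parametric comparator and AIC

The conventional estimate regresses the series on an HRF-convolved
paradigm boxcar. The HRF is a single gamma density moment-matched to a
6 s mean lag and 3 s spread (shape 4, scale 1.5 s, mode 4.5 s), sampled at
the TR, truncated at 30 s and renormalized to unit sum; all three
parameters are configurable. The COPE is the regressor coefficient of the
OLS fit, computed on the ROI-mean series (a voxelwise-max variant is
deliberately not implemented; ROI means are the package's unit of
analysis). Its normalization to % per mmHg (divide by baseline and
ΔPETCO₂) is exposed separately because conventions differ across tools.

Both models are scored with the Gaussian pseudo-likelihood AIC
`n·ln(RSS/n) + 2k` with the additive constant dropped consistently, so AIC
differences are convention-free. Both estimate two parameters (k = 2):
intercept + COPE, or Sen slope + Sen intercept. Using Sen-line residuals
under a Gaussian pseudo-likelihood is a choice — the non-parametric fit
has no likelihood of its own — made so the two criteria share a residual
scale. A zero-residual fit is reported as −∞ in comparisons.

## Simulation study

Single normocapnia→hypercapnia epochs are 60 s baseline + 180 s dilation
at TR 1.55 s, baseline 1000 a.u., amplitude 2%. The *fast* response is a
logistic rise, `B·(1 + (a/100)·logistic((t − onset − r/2)·8/r))` with rise
time r = 20 s (the factor 8 spans 2%→98% of the swing in one rise time);
the *slow* response ramps linearly over the full dilation period. White
Gaussian noise sets the temporal SNR (baseline mean over baseline sd); the
default grid crosses 2 shapes × 20 tSNR targets (geometric, 5–100) × 100
replicates = 4,000 epochs; only the total is fixed by convention, so the
factorization of the grid is the package's choice. Tests and the
acceptance script use a scaled 2 × 10 × 30 grid, which reproduces the same
qualitative findings in seconds: the parametric model has lower mean AIC
for fast responses, the non-parametric for slow responses at
moderate-to-high tSNR (upper half of the grid), and mean AIC decreases
with tSNR for every shape × model (Spearman ρ ≤ −0.9).

## Synthetic subjects and cohorts

A subject's noise-free BOLD series is baseline (1000 a.u.) plus a linear
dilation ramp spanning each CVR analysis window (so the planted amplitude
is exactly what the Sen pipeline should recover, up to one-sample
discretization), with a recovery toward baseline between and after
challenges.

**Recovery shape.** The default recovery is an exponential washout with a
subject-specific time constant θ. A linear decay over the fixed transition
window was considered and kept as an option (`recovery="linear"`), but
rejected as the default for cohort work: a linear decay that ends exactly
at baseline has its rate fully determined by the challenge amplitude (no
independent rate information), clamping a steeper decay at baseline
saturates the window-averaged rate, and letting a shallow decay run past
the window leaks the unfinished recovery into the next challenge — which
contaminates β = 0 calibration cohorts with a spurious association.
Exponential washout with θ ∈ [dur/16, dur/3.5] of the transition window
varies the measured window rate smoothly while returning to within
e^(−3.5) ≈ 3% of baseline before the next challenge. The stored ground
truth τ is the noise-free OLS rate over transition window 1 — exactly the
quantity the read-out estimates.

**Cohorts** mirror a 54-participant, two-design study: 20 cognitive +
20 sleep-apnea subjects on Design A and 14 cognitive subjects on Design B,
with group-typical age distributions (70 ± 9, 59 ± 12, 72 ± 11 y) and sex
ratios (45/65/21% male). Per subject: a₁ ~ N(2.0, 0.5)%,
θ ~ U(dur/16, dur/3.5) s, noise sd 8 a.u. (tSNR 125 — conservative for an
ROI-mean series averaged over hundreds of voxels), and
a₂ = 2.0 + β·(τ% − τ%_ref) + ε with ε ~ N(0, 0.15)%, τ% the
window-linearized rate in %/s, τ%_ref that of a design-typical subject
(centring keeps a₂ near 2%), and a₂ clipped below at 0.2% (rarely
binding). β is in % per (%/s); β < 0 plants the faster-washout →
larger-next-response effect.

Two generator conditions deserve emphasis:

* **ΔPETCO₂ spread.** Because the *same* per-subject Δ divides both the
  transition rate and CVR-2, between-subject Δ variance couples the two
  normalized metrics mechanically. With a realistic free-breathing spread
  (sd ≈ 1.5 mmHg) this coupling alone produces r ≈ −0.3 between the
  metrics of a β = 0 cohort — the calibration "null" would not be null.
  Cohorts therefore draw Δ tightly around the design target
  (8 ± 0.25 mmHg for A, 10 ± 0.25 for B, as a targeted-step rig
  delivers). Passing null-calibration tests consequently says nothing
  about free-breathing cohorts, where shared-normalizer variance is a real
  confound an analyst must consider.
* **Strong-effect preset.** β = −80 was sized by a variance-component
  design, not by simulation tuning: the measured transition rate carries
  OLS slope noise ≈ 0.006 %/s at this tSNR against a true spread
  ≈ 0.007 %/s (reliability ≈ 0.5), and the measured CVR-2 carries
  ≈ 0.24% amplitude noise; β = −80 then yields a partial correlation
  ≈ 0.6 and predicted power ≈ 99% at p ≤ 0.0125 with n = 54.

Residual known imperfections: the challenge-2 baseline window sits on the
washout tail and the washout leaves ≤ 3% of the challenge-1 rise at
challenge-2 onset; both effects are two orders of magnitude below the
noise floor. All generators are seed-deterministic (identical parameters
and seed give byte-identical serializations).

What the generator does **not** emulate: hemodynamic lag/dispersion
between PETCO₂ and BOLD, autocorrelated or physiological (cardiac,
respiratory, motion) noise, drift, regional heterogeneity within an ROI,
and free-breathing ΔPETCO₂ variability. Passing recovery tests therefore
demonstrates the estimators' correctness and calibration under the stated
model, not robustness to everything real data contains.

## Group models

Model 1: `CVR-2 ~ transition_rate_1 + age + sex + group + design`;
Model 2 adds CVR-1 and replaces the rate with its residual from an OLS on
CVR-1. Orthogonalizing a predictor against the *outcome* would trivially
distort inference, so the co-regressor CVR-1 is the default target (the
outcome variant is selectable for sensitivity checks and is flagged as
such). The transition rate entering both models is period 1 — the washout
preceding challenge 2, matching the hypothesis that recovery from the
first challenge conditions the response to the next.

Continuous variables including the outcome are z-scored (ddof 1), so
coefficients are standardized parameter estimates; sex (F=0/M=1), group
(cognitive=0/sleep-apnea=1) and design (A=0/B=1) enter as indicators.
Rows with missing modeled values are dropped listwise with a reported
count; rank-deficient designs error naming the candidate columns.
Significance uses p ≤ α/m with α = 0.05, m = 4 ROIs (threshold 0.0125,
inclusive), computed rather than hard-coded.

## Preprocessing scope

ROI extraction binarizes masks at > 0.5 (down-sampled anatomical masks are
fractional; the exact threshold is a convention), averages unweighted over
voxels, excludes NaN voxels per volume, and errors when more than 10% of
volumes contain NaNs. The optional high-pass detrend is a
Gaussian-weighted running-line subtraction (sd = half the cutoff period)
with the series mean re-added so baseline normalization stays meaningful;
it removes a pure linear drift almost completely and passes a
half-Nyquist oscillation within 5%. Motion correction, slice timing,
smoothing and registration are out of scope.

## Numerical choices and problem sizes

* Sen's slope: exact vectorized enumeration (O(n²) memory on pairs);
  windows here are ≤ 160 samples, so no randomized approximation is
  needed. Verified against explicit brute-force enumeration (exact
  equality on 1,000 random series up to n = 200) and against an
  independent library implementation.
* OLS fits use closed-form/least-squares solves verified against
  normal-equation oracles to 1e-8.
* Degenerate inputs error loudly: constant regressors, zero residuals
  (AIC), non-positive ΔPETCO₂ or baselines, constant columns in
  standardization, empty window overlaps.
* Test and acceptance problem sizes: 2 × 10 × 30 simulation grid, 200
  cohorts per group-model condition in tests (100 in the acceptance
  script), 500 contamination trials — sized to finish in minutes on one
  CPU while leaving Monte-Carlo margins far from the asserted thresholds.

## Known limitations

Lag/dispersion modeling of the BOLD–PETCO₂ relationship, event-related
paradigms, voxelwise analyses, mixed-effects or longitudinal models and
imputation are out of scope. The Sen-line AIC rests on a Gaussian
pseudo-likelihood; it is a comparison device, not a likelihood-based
model selection in the strict sense. The COPE normalization convention is
exposed rather than fixed, since tool conventions differ.
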