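# Methods

This note documents the models, parameters and numerical choices behind
`effortnirs`, what the synthetic-data generator does and does not emulate,
and the known limitations of both.

## Signal model and pipeline

A continuous-wave recording is a strictly positive intensity series
I(t, channel, wavelength) at fs = 10 Hz from a prefrontal band with six long
(~3.5 cm emitter–detector separation) and two short (~1.0 cm) channels at
760 and 850 nm. The pipeline applies, in fixed order:

1. **Step-artifact removal.** Per channel × wavelength, the first difference
   d is computed and samples with |d| > mean(d) + k·SD(d) (default k = 2)
   are zeroed; the series is rebuilt as the first sample plus the cumulative
   sum of the modified derivative. We read "two SDs over the mean" literally
   as mean + 2·SD of the signed derivative over the whole recording; k is
   configurable. A small relative tolerance (1e−9 of the largest derivative)
   keeps a constant-derivative ramp exactly invariant under floating-point
   ties.
2. **Channel QC by scalp coupling index.** Both wavelengths are zero-phase
   band-passed to the cardiac band (0.5–1.5 Hz, 3rd-order Butterworth,
   forward–backward) and Pearson-correlated; channels with SCI < 0.75 are
   rejected whole. The SCI is computed on the full recording (no windowing);
   if the filtered variance is at numerical-residue level the SCI is 0 with
   a warning. Rejected channels are flagged, never dropped silently.
3. **Optical density.** OD(t) = −ln(I(t)/mean(I)), per channel × wavelength;
   OD is therefore mean-referenced and invariant to intensity scaling.
4. **Wavelet motion correction.** Daubechies-2 discrete wavelet
   decomposition to 5 levels (or the maximum the record length allows);
   per detail level, coefficients outside
   [Q1 − 0.1·IQR, Q3 + 0.1·IQR] are set to zero before reconstruction.
   Approximation coefficients (the slow trend, where the hemodynamic
   response lives) are untouched. `iqr_k = inf` is the identity up to
   reconstruction round-off (~1e−10).
5. **Modified Beer–Lambert law.** Per channel, the 2×2 system
   OD_λ = (ε_HbO,λ·ΔHbO + ε_HbR,λ·ΔHbR)·d·DPF is inverted with compiled
   extinction coefficients (760 nm: 0.5863/1.5485; 850 nm: 1.0580/0.6913
   cm⁻¹·mM⁻¹ for HbO/HbR), separation d in cm, and DPF 6.0 at both
   wavelengths (configurable). Concentrations are reported in µM.
6. **Band-pass 0.01–1.5 Hz**, 3rd-order Butterworth, zero-phase
   (`filtfilt`); note zero-phase application squares the magnitude response,
   so the single-pass −3 dB edges become ≈ −6 dB.
7. **Short-separation regression.** Each long channel's HbO (and separately
   HbR) series is regressed on the nearest short channel (Euclidean distance
   between channel midpoints, ties to the lower index) with an intercept;
   the residual — orthogonal to the regressor by construction — replaces
   the long channel. A rejected short channel falls back to the remaining
   one, logged in the QC report.
8. **Band-pass 0.01–0.09 Hz**, as above.

The stage order is part of the method, not configuration: `run_pipeline`
refuses a permuted stage list. Every stage preserves sample count and
sampling rate.

## Event-related quantification

The response to a sentence sequence is mean(series over [onset+10 s,
offset)) − mean(series over [onset−5 s, onset)), computed after the full
pipeline (the baseline is taken on the filtered series, which the stage
order implies). Sequences shorter than the 10-s response delay (the decoys)
are excluded and logged. HbDiff = HbO − HbR exactly. Subregion values are
the mean of each subregion's two channels, or the single surviving channel;
if both were rejected the row is kept with a missing value, which the
mixed models tolerate. Only low-context, non-practice sequences enter
statistics. Decoy exclusion happens at this stage — not during
preprocessing — so QC still covers all data.

## Staircase

20 sentences per run, 8 dB SNR start against fixed 70 dB(A) noise; correct
→ −step, incorrect → +step, with the adjustments applied after trials 1–5
using 4 dB and later ones 2 dB. (Whether the adjustment after trial 5 — in
response to sentence 5 — uses the large or small step is ambiguous in the
source rules; we apply the large step, and `n_large_steps` is
configurable.) The run estimate is the mean of the ten values {SNR presented
at trials 12–20, SNR that would be presented at trial 21}; the protocol
takes three runs and tests at mean(run 2, run 3) + 2 dB. The simulated
listener is logistic, P(correct | snr) = 1/(1+exp(−slope·(snr−SNR50))); the
estimator's Monte-Carlo bias is below 0.1 dB for slopes ≥ 0.5 dB⁻¹.
Sentence-list content is out of scope: responses are i.i.d. Bernoulli.

## Behavioural statistics

Accuracy counts are transformed with Studebaker's rationalized arcsine
units, RAU = (146/π)·[asin√(x/(n+1)) + asin√((x+1)/(n+1))] − 23, monotone
with range ≈ (−23, 123). Effort ratings and RAU scores are averaged per
participant per condition and compared with two-sided paired t-tests
(95% CI from the t quantile on n−1 df); the paired effect size is
d = |t|/√n. Identical samples return the null result (t = 0, p = 1) rather
than a zero-variance error; a constant nonzero difference is an error.

## Multilevel models

The outcome is trial × subregion HbDiff in long format (one row per
participant × sequence × subregion; Table-style df of ~1775 at 26
participants × 12 trials × 2 programs × 3 subregions implies this
observation level). All models carry a participant random intercept and are
estimated by full maximum likelihood (statsmodels `MixedLM`, `reml=False`)
so nested fits are LRT-comparable: χ² = 2·Δloglik, df = added fixed
parameters, AIC = 2k − 2·loglik with k counting fixed effects, the random
intercept variance and the residual variance. Dummy coding uses the
standard program, left-lateral subregion, and left-handedness as
references, so a negative program coefficient means lower oxygenation under
the DNN program. The hierarchy is unconditional → program main effect
(+ handedness) → program × subregion interaction; handedness enters only
when both groups are present in the sample.

Denominator df use a containment-style approximation: terms constant within
participants (intercept, handedness) are tested on participant-level df
(n_groups − n_between_terms), within-participant terms on observation-level
df (n_obs − n_fixed − n_groups + 1); p-values come from the t distribution
on those df. Satterthwaite df are not available in the backend; at this
design's sizes (hundreds to thousands of within-cell observations) the
approximation is indistinguishable from the normal reference in practice.
ML standard errors are mildly anticonservative (no REML small-sample
correction); measured null rejection rates for simple slopes are ~6–8% at
nominal 5%.

Simple slopes are obtained two algebraically equivalent ways — refitting
with each subregion as the reference level, or linear combinations
β_program + β_program:region with delta-method SEs — and the test suite
asserts their equality to 1e−6. A zero-variance outcome short-circuits to
the exact degenerate fit (intercept = constant, all slopes 0).

The brain–behaviour model restricts to one subregion (default left-lateral),
optionally to correct trials only, and fits HbDiff ~ effort (trial-level
rating, not the participant mean) with the participant random intercept,
compared to the unconditional model on the same rows by LRT. Note a design
caveat: when a program effect exists on both HbDiff and effort, the
trial-level effort slope absorbs part of the between-condition contrast;
recovery tests for the estimator therefore simulate no program effect.

## Synthetic data generator

The generator is the package's ground-truth instrument, emulating the study
design: one practice block (standard program) plus four test blocks split
evenly between programs in seed-randomised order; each block holds six
low-context sequences of 3–5 sentences (6 s per sentence, so 18–30 s) and
two 1–2-sentence decoys, separated by 30-s baselines.

Neural responses are canonical double-gamma impulse responses (peak 6 s,
undershoot 16 s, undershoot ratio 1/6) convolved with per-sentence boxcars
and superposed; HbR is the HbO shape lagged 2 s and scaled so that
HbO − HbR equals the programmed HbDiff amplitude (HbO takes 0.75 of HbDiff,
HbR −0.25). Each event's response is normalised so that an isolated event's
epoch window mean equals the programmed amplitude exactly. Default
amplitudes place the effect in the left-lateral subregion only: +4.2 µM
(standard) vs −14.8 µM (DNN), i.e. a 19 µM program effect, zero elsewhere.

Raw intensities are built by running the Beer–Lambert law forward
(I = I₀·exp(−OD)) and layering: a shared superficial component (cardiac
2 µM at 1.1 Hz with per-channel weights, respiration 1.5 µM at 0.25 Hz,
Mayer 2 µM at 0.1 Hz — projected onto HbO only, as arterial pulsation),
per-channel linear plus random-walk drift, multiplicative white intensity
noise (0.1% SD), and scheduled step/spike artifacts (multiplicative in
intensity, additive in OD). Long channels receive the superficial component
at gain 0.4; short channels receive it at gain 1 and **no neural signal**,
which is what makes short-separation regression a valid nuisance control.
Behaviour is a rounded clipped normal on the 1–7 effort scale
(means 4.02/3.08, SD 0.9) and Bernoulli correctness (0.63/0.77) per
program. A direct trial-table generator (participant intercept SD 15 µM,
residual SD 60 µM, handedness effect +13.46 µM) serves the multilevel
machinery at study size without the signal chain.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: photon transport and partial-volume effects
(amplitudes are programmed at the channel, not propagated through tissue),
wavelength-dependent DPF, serial correlation of trial-level noise,
motion-correlated artifact bursts, inter-individual HRF variability, and
trial noise at realistic magnitude (simulated trial-level SE is far smaller
than in vivo, so significance levels on simulated pipelines are optimistic).

## Parameter-recovery behaviour

With default noise, the full chain (preprocess → epoch → MLM) recovers the
programmed −19 µM effect at about −13 to −16 µM, a systematic 20–30%
attenuation with the correct sign in every seeded run. The attenuation is a
property of the published pipeline parameters, not an estimator defect (the
mixed-model coefficient equals the raw left-lateral condition contrast to
machine precision): the 0.1-IQR wavelet threshold is aggressive and clips
detail coefficients carrying 6-s sentence-rate response energy (~0.17 Hz
falls in the level-5 detail band), and the zero-phase 0.01–0.09 Hz band
smears responses into their baselines (~6% alone). On noiseless input the
outlier-based artifact stages degenerate — their IQR collapses to zero and
they clip the signal itself — so clean-recovery checks disable those
thresholds (k large, iqr_k = ∞), recovering within the band-pass cost.

## Numerical choices and degenerate inputs

Butterworth order 3 forward–backward everywhere a band is stated; FFT-based
gain checks in the tests, not analytic formulas. Wavelet reconstruction is
truncated to the input length; series shorter than one filter length pass
through with a warning. Channel ordering is canonical (long before short,
left to right by channel midpoint) after reading a container, with ties
broken by stored index. All randomness flows from explicit integer seeds;
sub-seeds are drawn deterministically from a parent generator and kept
below 2³¹. SNIRF files are HDF5 with one data block per wavelength; the
montage ships with invented 2-D coordinates (the device's true optode
coordinates are not public) satisfying the geometric invariants, and the
short-channel separation defaults to 1.0 cm, configurable.

## Known limitations

- The acquisition-time signal-quality index, spline or PCA motion
  correction alternatives, HRF-shape estimation and DOT image
  reconstruction are out of scope.
- The deposited study data are not required or downloaded;
  `load_osf_export` maps a locally supplied export onto the trial-table
  contract on a best-effort column-alias basis.
- Satterthwaite/Kenward–Roger df and REML are not offered (full ML is
  required for the LRT hierarchy); df are containment-approximate.
- The simple-slopes joint localisation rate (significant left-lateral slope
  with both null regions non-significant) is capped near 0.95² ≈ 90% by the
  per-region false-positive rate at α = 0.05, independent of power.
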