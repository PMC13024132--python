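# Methods

This note documents the numerical model behind each pipeline stage, the
design of the synthetic-cohort generator, the parameters that matter, and
the known limitations of both.

## Preprocessing and montage

Recordings are referential 10–20 acquisitions (19 scalp electrodes,
classical T3/T4/T5/T6 nomenclature; modern T7/T8/P7/P8 labels are accepted
and mapped). The band-pass is a sixth-order Butterworth between 0.5 and
30 Hz, applied forward–backward (zero phase) by default: clinical
acquisition filters are typically causal, but zero-phase application avoids
group-delay distortion that would bias the cross-correlation lag estimates
by several samples. A causal mode (`zero_phase=False`) is available for
sensitivity checks.

Artifact handling is by exclusion: the caller supplies artifact-free
chunks, which are concatenated with their boundaries recorded, and no
analysis window ever straddles a splice (splices would inject spurious
broadband power). At least 120 s of retained signal is required unless
explicitly overridden; 120 s yields 133 one-second windows at 10 % overlap.

The double-banana montage is the fixed 18-channel set of anode−cathode
differences along two parasagittal chains, two temporal chains and the
midline; channel sign is `V(anode) − V(cathode)` in printed label order.
Channel scalp placement (used for reporting only) is the geodesic midpoint
of the electrode pair on the unit sphere, with electrode positions taken
from the standard 10–20 montage. The average-reference montage subtracts
the instantaneous mean of all 19 electrodes.

## Spectral estimation

Each 1-s window (512 samples) is zero-padded to 1024 points before the
FFT. This is the only construction that reconciles one-second windows with
a 0.5-Hz grid; it interpolates the spectrum rather than adding resolution,
which is the behaviour the 0.5-Hz "sensitivity" of the peak-frequency
metrics requires. The default taper is rectangular (any scipy window can
be configured). Scaling is Parseval-consistent: the one-sided density in
µV²/Hz integrates to the window variance.

Band areas integrate the window-averaged density over half-open intervals
(δ [0.5, 4), θ [4, 8), α [8, 13), β [13, 30) Hz) so shared edges count
once and the four bands sum exactly to the total 0.5–30 Hz area. Band
`logPS` is log₁₀ of the area; a zero area is reported missing rather than
−∞. Regional values average the transformed (logPS) channel values, not
the raw areas — consistent with regional summaries in the 1.5–3.7 log₁₀ µV²
range typical of clinical bipolar recordings.

Spectral entropy is computed per window on the probability distribution
`p_k ∝ S_k·Δk` over the inclusive 0.5–30 Hz grid (60 bins), averaged over
windows, and normalized by log₂ 60, giving SSE ∈ [0, 1] (1 = flat
spectrum, 0 = single-bin line). SSE is invariant to any positive rescaling
of the spectrum.

**Estimator bias to be aware of.** The rectangular taper leaks power from
a strong narrow-band α peak into neighbouring bands through the Fejér
kernel sidelobes; with a posterior α of ~90 µV² this adds roughly
1–2 µV² to the small β area. Similarly, the window-averaged coherence of
a pure-delay pair loses O(delay/window length) at the window edges
(~2 % at 1-s windows for a 5-sample delay; the analytic value 1 is
approached as windows grow), and coherence of independent signals is
biased upward to ~1/W for W averaged windows. These are properties of the
standard estimators, not of the generator; tests verify each at its
appropriate regime.

## Synchronization

Pearson matrices are the arithmetic mean of per-window correlation
matrices (windows are mean-centred by construction of r; windows with a
zero-variance channel are skipped and counted). Coherence averages the
complex cross-spectra over all windows first, then forms
`|S_ij|²/(S_ii·S_jj)` per bin and takes the unweighted mean over each
band's bins (a power-weighted mean is available). Regional
synchronization is the mean over all unordered channel pairs of a region:
3 pairs per three-channel lobe, 28 pairs per eight-channel hemisphere.

Cross-correlation evaluates the Pearson correlation on an integer-sample
lag grid within ±50 ms per window, averages across windows, and reports
the maximum and its lag; positive lag means the second (right-hemisphere)
series is delayed. Ties break toward the smaller |lag|. The ±50 ms
default comfortably covers physiological interhemispheric delays (≤10 ms).

## Lobe and hemisphere grouping

Bipolar lobes are frontal {Fp1–F3, F3–C3, Fp1–F7}, parieto-occipital
{C3–P3, P3–O1, T5–O1} and temporal {F7–T3, T3–T5, T5–O1} per hemisphere
(T5–O1/T6–O2 deliberately belong to both posterior lobes); midline
channels belong to no lobe. The hemisphere aggregate defaults to the 8
distinct lateral channels; `strict_nine_term` reproduces a clinically used
9-term hemisphere list that counts the posterior temporo-occipital channel twice
(divisor 9). The strict variant is retained for value averaging only —
for pair-averaged synchronization a duplicated channel would create
self-pairs with r = 1, so the 28-pair distinct set is always used there.
AVG-montage lobes use the referential electrodes spanned by the same
bipolar channels (e.g. frontal {Fp1, F3, C3, F7}).

## PDR metrics and the normative-age fit

Alpha peaks are the argmax of the mean spectrum within 8–13 Hz (a 7.5-Hz
lower edge is configurable), ties broken to the lower frequency, with
explicit flags when the maximum sits on a band edge. No sub-bin
interpolation is performed: the grid already matches the 0.5-Hz
sensitivity the metrics are defined at. The derived metrics (alphap,
alphao, ihDif, mlPO, five-channel SD with n−1 normalization) are exact
arithmetic on the five peaks; the asynchrony classification uses the
strict inequality |ihDif| > 0.5 Hz, the physiological limit in euploid
adults.

The normative fit treats the group as rigid: it minimizes
`D(Δ) = Σᵢ (PDR(ageᵢ + Δ) − freqᵢ)²` over a common age translation Δ by a
coarse grid scan (66 points over [−50, +80] years, guarding against local
minima of non-monotone curves) refined by bounded scalar minimization to
0.01-year tolerance, and reports the group mass centre `mean(age) + Δ*`.
The normative PDR(age) curve is user-supplied (callable or two-column
table); no published coefficients are hard-coded. Constant curves are
rejected as non-identifiable and boundary minima are flagged.

## Statistics

The two-group decision tree gates on Shapiro–Wilk normality (and
Brown–Forsythe variance homogeneity for independent designs) at α = 0.05:
parametric Student t when the gates pass, Wilcoxon signed-rank /
Mann–Whitney otherwise; three groups go to Kruskal–Wallis with Dunn's
post-hoc z tests (hand-implemented with tie correction). Bonferroni
families are one variable across the six lobes by default and are
configurable.

`critical_r` inverts `t = r√(n−2)/√(1−r²)` at the **two-sided** critical t
with n−2 df. The two-sided point is the one that reproduces the reference
threshold 0.4224 at n = 22, α = 0.05 (a one-tailed inversion gives 0.360
and is available via `tail="one-sided"`).

Polynomial fits are ordinary least squares on powers of x (degree 1–4),
summarized by the Pearson r between fitted and observed values (√R² for a
fit with intercept). Degree selection takes the lowest degree whose r
reaches 75 % of the best over degrees 1–4 — a deliberate simplification
of sigmoid-based selection curves to their quoted decision rule.

## Synthetic-cohort generator

The generator emulates the statistical structure the analysis assumes, not
the biophysics. Per electrode and band, the signal is a weighted sum of
unit-variance Gaussian sources band-pass shaped to the band and then
spectrally confined to it (the Butterworth response shapes the in-band
spectrum; out-of-band skirts are removed so targets do not bleed across
bands):

    x_eb = √P_b · [ √c · s_(lobe,b)  +  g_e·√w · h_b  +  √(1−c−g_e²w) · u_eb ]

- `s` (regional common, uniform gain) sets the referential intra-lobe
  Pearson correlation to `c`; being uniform it cancels exactly in every
  bipolar derivation.
- `h` (carrier) enters through a monotone front-to-back gain ramp `g_e`
  (+2 … −2 along each chain), so every double-banana channel retains it
  with gain +1; `w` (its per-lobe variance share) is the knob that moves
  bipolar-montage synchronization. For the non-α bands the carrier and
  commons are shared between hemispheres with the configured
  integer-sample delay (right hemisphere lagging); α sources are strictly
  per-side so asynchronous subjects keep clean, distinct peaks.
- `u` is per-electrode and independent; it is explicitly orthogonalized
  against the shared sources so realized band powers hit their µV²
  targets exactly rather than within the cross-term sampling error.

The α band uses narrow-band sources (second-order band-pass of
width `alpha_bandwidth`, default 1 Hz, centred on the region's
`alpha_peak`) normalized to the full 8–13 Hz band, producing a detectable
peak over the broadband floor. Referential pairwise correlation between
electrodes i, j of a region is predictable as `c + g_i g_j w(1−f_α)` with
`f_α` the α power fraction.

Group profiles (the defaults of `default_profile`): controls carry
δ/θ/α/β ≈ 25/18/90/8 µV² posteriorly with a 10.5-Hz α peak (posterior
dominance, logPS in the clinical 1–2 log₁₀ µV² range after bipolar
derivation); the trisomy-21 profile multiplies δ by 2.5 and θ by 2.2
globally, doubles frontal β, halves posterior α and slows the peak to
9.5 Hz; its asynchronous variant splits the hemispheric posterior peaks
(left 9.0 / right 10.5 Hz, |ihDif| = 1.5 Hz). Peaks sit on the 0.5-Hz
analysis grid so the injected shift and the >0.5-Hz asynchrony are
unambiguous at the stated sensitivity. Absolute µV² levels are a
modelling choice — no clinical per-channel values are claimed — but all
group *contrasts* follow the direction and rough magnitude of reported
findings, with effect sizes at several times the measurement SD so a
22-per-group cohort resolves every direction. Cohorts default to 22
subjects of 120 s at 512 Hz (the analysis minimum; longer records only
tighten estimates), with the asynchronous fraction 8/22 assigned
deterministically to the first subjects so ground-truth counts are exact,
and a latent IQ (mean 45 ± 8 for the DS profile, 100 ± 8 for controls)
that mildly modulates slow-band power (−0.4 %/point) and posterior
carrier share (+0.4 %/point).

What the generator does **not** emulate: volume conduction, 1/f spectral
slopes, ocular/muscle artifacts (an optional white contaminant only),
non-stationarity, and realistic coherence topography. One structural
consequence matters when interpreting tests: consecutive bipolar channels
share an electrode, so their independent components induce a negative
correlation floor (≈ −(1−c−w)/2 for adjacent pairs) that is *stronger*
when regional coupling is weaker. Reduced posterior coupling therefore
shows as a lower (more negative) regional mean Pearson — the signed
metric — while the magnitude-based regional coherence is dominated by
this adjacency floor and is not a monotone readout of the coupling knob
on bipolar derivations. Passing cohort tests demonstrate that the
pipeline recovers what was injected under this model, not that clinical
effect sizes would be recovered from real recordings.

EDF output uses an in-package minimal writer (16-bit, one 1-s record per
second, physical range per channel from the data extrema); round-trips
are verified against an independent EDF reader and agree to the
quantization step. Ground-truth sidecars are tab-separated with
shortest-round-trip float formatting, so they read back bit-identically.

## Problem sizes used in verification

Method constants are exact and instantaneous. Estimator oracles use 16–120
second two-channel records. Cohort-level checks run 22-vs-22 subjects of
120 s (the minimum analyzable duration, which is also the cheapest
faithful configuration); montage-consistency checks use a six-subject
subset per group under both montages. The full verification suite runs in
about two minutes on one CPU; the acceptance script in about one.
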