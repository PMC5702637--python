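# Methods

This note documents the models, parameter choices, and numerical decisions
behind each stage of the measurement chain, and what the synthetic-data tests
do and do not establish about real recordings.

## Synthetic physiology and camera model

The generator lays beats down iteratively: the next beat follows the current
one after `IBI(t)/1000` seconds, where

```
IBI(t) = HP0 + m·t + A_rsa·sin(2π f_rsa t) + A_lf·sin(2π f_lf t + φ) + ε,
ε ~ N(0, σ_beat²)
```

with the modulators evaluated at the current beat time (event-driven
sampling, matching the beat-wise definition of an IBI, rather than a
continuous-phase integration). Defaults describe a resting adult: HP0 =
800 ms (75 bpm), A_rsa = 40 ms at f_rsa = 0.25 Hz (mid respiratory band,
0.12–0.40 Hz), A_lf = 20 ms at f_lf = 0.08 Hz (mid vasomotor band,
0.04–0.10 Hz), σ_beat = 5 ms. The optional linear slope `m` produces heart
rate drifts for detector stress tests. Any IBI outside 200–3000 ms aborts
generation as non-physiological.

Ground truth carries the *analytic* ln-variances ln(A²/2) of each modulator,
not filtered values; recovery tests must therefore account for the chain's
gain (below). Peripheral pulse arrivals are the cardiac times plus a transit
delay (default 200 ms) and per-beat Gaussian jitter (default SD 10 ms). The
jitter magnitude is not a measured quantity; 5–15 ms makes windowed
sensor-agreement behavior qualitatively realistic (beat-level R² well below
1, 5-s-window R² near 1), and 10 ms was fixed as the default.

Waveform templates: the ECG-like channel uses a unit Gaussian R-wave with
σ = 6 ms (full width ≈ 15 ms); the pulse-like channel a piecewise Gaussian
with a 50 ms rise σ and 120 ms decay σ — a single-maximum asymmetric bump;
the exact shape is deliberately uncommitted. Pulse templates are truncated
at 3σ so tachycardic trains (IBI ≈ 600 ms) stay within the template-overlap
guard; the truncation step is ~1% of amplitude.

Video frames are 160×120 with a centered 60×60 "face" block (desk-scale
speed). The face block carries a sub-LSB spatial shading gradient so the ROI
mean resolves below one 8-bit quantization step. Green (and, more weakly,
red) face intensity decreases proportionally to the instantaneous
blood-volume waveform. Illumination drift is a slow *multiplicative* gain on
every pixel — truly common-mode, so the green/red ratio cancels it — while
pixel noise is additive and independent. Frame timestamps are jittered
(default SD 1 ms) around the nominal 60 fps grid and forced monotone.

What the generator does **not** emulate: facial appearance and motion,
occlusion, Bayer mosaics (demosaiced planes only), skin-tone variation,
ectopic beats, and waveform-shape changes with autonomic state. Passing
tests therefore demonstrate the correctness of the algorithms under the
assumed signal model, not robustness to motion artifact or morphology
variation in real video.

## Pulse extraction

ROI channel means are plain arithmetic means over masked pixels. The
green/red ratio is a ratio of means (channel means are computed first, then
divided), not a mean of per-pixel ratios. Irregular-to-uniform resampling
uses monotone-preserving piecewise cubics (PCHIP): linear interpolation of a
~60 Hz series upsampled to 1 kHz leaves spectral kinks inside the 0.5–2 Hz
heart band. No extrapolation beyond the first/last frame; inter-frame gaps
longer than 500 ms are treated as tracking loss and refused.

## Conditioning

The band-pass is a 2nd-order Butterworth prototype per edge (0.5 / 2.0 Hz),
applied forward–backward by default: beat *timing* is the product, and a
causal pass would add frequency-dependent delay that biases IBIs. The
squared magnitude puts each cutoff at gain 0.5. A causal single-pass mode is
available for comparison with online processing. "Inversion" is
mean-centered negation, not the reciprocal: for a ratio near 2.0 the
reciprocal is an affine flip to first order and negation is numerically
safe. The first and last 2 s of any filtered series are flagged
(`edge_exclude_s`) and skipped by peak detection — filter transients there
produce spurious extrema.

## Adaptive beat detection

Scanner geometry: ECG defaults 700 ms window / 400 ms step / 15 ms fit
width; pulse defaults 1200/600/150 ms (pulse waves are roughly an order of
magnitude broader). After the third accepted peak, window = 0.875·Δ and
step = 0.5·Δ where Δ is the last inter-peak interval, clamped to
300–2000 ms; the factors reproduce the initial ECG ratios at a nominal
800 ms heart period.

Within a window the threshold is `median + 0.5·(max − median)` of the window
samples — robust to baseline shifts, and the window maximum always
qualifies. Two additional guards handle windows that happen to contain no
beat (possible because the adapted window, 0.875·Δ, is shorter than Δ): a
record-wide amplitude floor at `median + 0.25·(max − median)` of the whole
scanned region, and a gate requiring candidates to reach 0.4× the median of
the last five accepted amplitudes. Without these, noise maxima in beat-free
windows become false peaks and derail window adaptation. All constants are
`DetectorParams` fields and are reported in the run log.

Candidates are refined by a least-squares parabola over the fit width;
convex fits (quadratic coefficient ≥ 0) are rejected, the vertex is clamped
to the fit window, and the fit window is clipped at the record boundaries so
edge beats remain detectable. When several candidates survive in one
window, the earliest is compared with the window maximum and the larger
amplitude is kept — one peak per window; overlapping windows then see each
beat more than once, and refined times closer than 200 ms (the physiological
refractory bound) are merged, keeping the higher amplitude.

Known behavior: during the first three beats (fixed initial geometry) a
window can span two beats and keep only the larger one, so a record's very
first beats are occasionally dropped at high heart rates; this is inherent
to the one-peak-per-window selection and is the dominant contributor to the
~0.5% missed-beat rate measured by `scripts/acceptance.py`. On asymmetric
pulse waves the parabola vertex is pulled a few tens of ms toward the slow
decay; this offset is constant, cancels in IBIs, and is removed with the
transit lag in cross-sensor comparisons.

## HRV quantification

2 Hz resampling assigns each 500 ms bin the time-weighted average of the
IBI values of the intervals overlapping it (each interval weighted by the
fraction of the bin it covers) — the historical treatment of the heart
period as a piecewise-constant function of time. Sample-and-hold is not the
default. Artifact-flagged intervals (outside 200–3000 ms) contribute no
coverage, so bins they span come out missing; a segment with > 10% missing
bins reports RSA/LF as unavailable, below that gaps are linearly
interpolated before filtering.

The moving polynomial filter is the sliding local least-squares cubic
(Savitzky–Golay): the trend at k is the center value of a cubic fit over the
21 (RSA) or 51 (LF) samples around k. Edges are trimmed by (points−1)/2
samples per side rather than extrapolated — edge fits blow up — and epochs
are formed after trimming. The kernel reproduces any global cubic exactly on
interior points (a frozen test).

Kaiser FIR design: 0.04 Hz transition width, 60 dB stopband (β ≈ 5.65), odd
length (183 taps at 2 Hz), applied by centered convolution so the linear
phase is exactly compensated. A consequence: band estimates need segments of
at least ~100 s (filter length plus one 30-s epoch after MPF trimming);
shorter segments report "unavailable" rather than a number. Epoch variances
use the n−1 sample convention; a zero-variance epoch is an error (ln
undefined) rather than a sentinel. Trailing partial epochs are discarded —
"sequential 30-s epochs" means complete ones.

**Chain gain.** The measured estimate of a modulation of amplitude A is
attenuated relative to ln(A²/2): the beat process samples the modulator at
the beat rate and holds it over each interval (≈ sinc(πfT) with T the heart
period, ~−0.13 ln-units at f = 0.25 Hz, T = 0.8 s), bin averaging adds
≈ −0.05, and the MPF/FIR passband is slightly below unity. Recovery tests
therefore measure the chain gain once — on a noise-free generated series
with a reference amplitude of 50 ms — and check recovered estimates at other
amplitudes against `ln(A²/2) + gain` within 0.2 ln-units. The reference run
shares no noise realization with the tested runs.

Windowed IBI averages (2 s / 5 s) use the same time-weighted binning with
wider bins.

## Agreement statistics

Beat matching removes the median inter-train offset (the pulse-transit
delay), then greedily pairs each beat with the nearest unclaimed counterpart
within 250 ms. An IBI pair is kept only when its bounding beats are matched
and consecutive in both trains, so a missed beat drops the interval on each
side of it instead of corrupting the pairing. The matching rule is this
package's own construction — cross-sensor pairing has no canonical
definition — and both the lag and unmatched counts are reported.

Bland–Altman limits of agreement are mean ± 1.96·SD of the paired
differences (sample SD, n−1), with a one-sample t-test of the differences
against zero; zero-variance differences are reported as exact agreement
rather than an undefined t. Regression is ordinary least squares with R² the
squared correlation. The repeated-measures effect size is the one-way
decomposition of a subject × condition matrix: η²p = SS_cond/(SS_cond +
SS_error) with F on ((c−1), (c−1)(s−1)) dof and no sphericity correction by
default (the F test is exact under sphericity; Greenhouse–Geisser adjustment
would only change the p-value, not η²p). Missing cells are an error — no
imputation.

## Problem sizes

Defaults used by the test-suite batteries: 300 s records for HRV recovery
(ten 30-s epochs per band), 60–120 s for the detector battery (≈ 2000 pooled
beats over 20 signals), and a 60 s, 60 fps, 160×120 video for the full
camera path. These sizes give stable statistics for every estimate the
suite checks while keeping a full run desk-scale.

## Known limitations

- The detector's initial-window phase can drop a beat at the very start of
  a record at high heart rates (see above).
- RSA/LF need ≥ ~100 s segments at 2 Hz; the classical 30-s-epoch Porges–
  Bohrer construction is simply not defined below that.
- The synthetic video contains no motion; real rPPG performance is
  motion-limited, and nothing here measures that.
- `partial_eta_squared` implements the one-way (time) repeated-measures
  decomposition only; multi-factor designs are out of scope.
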