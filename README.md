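# pulsecam

Camera-based (non-contact) measurement of heart rate variability: from face
video to beats to autonomic indices, with the statistics needed to judge how
well a camera agrees with contact sensors (ECG, earlobe PPG).

## Who this is for

Psychophysiology and biomedical-engineering groups who want to derive
interbeat intervals (IBIs) and HRV metrics from an ordinary color video of a
person's face — remote photoplethysmography (rPPG) — and need the whole
chain to be testable: signal extraction, beat timing, HRV quantification, and
sensor-agreement analysis. Because real recordings of this kind are rarely
shareable, the package includes a ground-truthed synthetic generator that
emulates the physiology (respiratory and low-frequency IBI modulation,
pulse-transit delay and jitter) and the camera (frame-timestamp jitter, pixel
noise, illumination drift), so every stage can be validated against known
truth.

## The measurement chain

1. **Pulse extraction** (`pulse_extract`): per-frame means of the ROI's red
   and green planes (blue carries melanin information and is discarded); the
   green/red ratio cancels illumination and motion components common to both
   channels; the irregular ~60 Hz camera series is PCHIP-interpolated onto a
   uniform 1 kHz grid.
2. **Conditioning** (`conditioning`): inversion onto a blood-volume
   convention, zero-phase 2nd-order Butterworth band-pass (0.5–2.0 Hz,
   bracketing plausible heart rates), first derivative to sharpen pulse
   arrival.
3. **Beat detection** (`cpvd`): an adaptive windowed peak scanner. A window
   sized to contain at least one beat (ECG default 700 ms, step 400 ms)
   slides over the record; candidate maxima above a distribution-derived
   threshold are refined by a least-squares parabola, giving sub-sample
   timing (the fit interpolates between samples). After three beats the
   window and step adapt to the latest inter-peak interval, tracking heart
   rate accelerations and decelerations.
4. **HRV quantification** (`hrv`): IBIs are resampled to an equally spaced
   2 Hz heart-period series. Heart period (HP) is its mean. Respiratory
   sinus arrhythmia (RSA) and low-frequency HRV (LF) follow the
   Porges–Bohrer construction: a third-order moving polynomial filter
   (21 points for RSA, 51 for LF) removes slow trend, a Kaiser FIR band-pass
   isolates the band (0.12–0.40 Hz for RSA, 0.04–0.10 Hz for LF), and the
   estimate is the mean of ln-variances [ln(ms²)] over sequential 30-s
   epochs.
5. **Agreement** (`agreement`): beat matching across sensors (after removing
   the pulse-transit lag), Bland–Altman differences with ±1.96 SD limits of
   agreement and a bias t-test, OLS regression with R², repeated-measures
   partial eta-squared for task effects, and change-from-baseline scores.
   Averaging IBIs over 2-s and 5-s windows shows how beat-level transit
   jitter washes out of slower dynamics.

## Worked example

Generate a 300-s synthetic subject (resting heart period 800 ms, 40 ms RSA
modulation at 0.25 Hz, 20 ms LF modulation at 0.08 Hz, 10 ms pulse-transit
jitter), detect beats on the ECG-like and pulse-like channels, and compare:

```
$ pulsecam synth --out fix --duration 300 --seed 9
wrote fixture with 376 beats to fix
$ pulsecam detect --channel fix/ecg.csv --mode ecg \
    --peaks-out ecg_peaks.csv --ibi-out ecg_ibi.csv
376 peaks, 375 intervals (0 flagged)
$ pulsecam detect --channel fix/pulse.csv --mode pulse \
    --peaks-out p_peaks.csv --ibi-out p_ibi.csv
376 peaks, 375 intervals (0 flagged)
$ pulsecam hrv --ibi ecg_ibi.csv --out hrv.json
all: HP 800.3 ms, RSA 6.744, LF 5.659 ln(ms^2)
$ pulsecam agree --ibi-a ecg_ibi.csv --ibi-b p_ibi.csv --out agree.json
375 pairs: bias -0.05 ms (SD 14.34), R^2 0.825
```

Reading the numbers: all 376 true beats were found on both channels; the
mean heart period (800.3 ms) recovers the configured 800 ms; RSA in ln(ms²)
sits close to the analytic value for a 40 ms sinusoid (ln(40²/2) ≈ 6.68,
minus a small, measurable chain attenuation); the two sensors show no bias
(−0.05 ms) and the beat-level R² of 0.83 reflects the injected 10 ms
vascular transit jitter — averaging IBIs over 5-s windows drives it above
0.97, which is exactly the behavior that makes camera-derived HP and LF
usable even when beat-level agreement is imperfect. The full pipeline
(`pulsecam run --config run.yaml`) produces the same artifacts for every
channel and channel pair in one pass, plus a JSON report.

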