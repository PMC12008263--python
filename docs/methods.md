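# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of the `cuffwave` simulator and analysis stack.

## Protocol model

The schedule builder realizes the seven-phase stimulation protocol with
rest gaps of `rest_interval` (default 15 s) between every pair of
consecutive phases, so the default total duration is 420 s of phases plus
90 s of gaps = 510 s. Pressure targets:

- `MP → 30` in the deflation phases is read as "vent from the maximum
  pressure down to a 30 mmHg floor". The alternative reading ("start at
  MP − 30") is possible but inconsistent with oscillometric practice, which
  must sweep the envelope through diastolic pressure; the floor is the
  `deflation_floor` config field.
- `vent_rate` defaults to 1.25 mmHg/s so that a full 180 → 30 sweep spans
  the nominal 120 s deflation phase.
- `inflation_rate` defaults to 20 mmHg/s and the inflation ramp lives
  *inside* the nominal phase duration; with the default MP this leaves
  111 s of deflation, ending near 41 mmHg — below every plausible
  diastolic pressure, so the envelope is fully swept where it matters.
- Cuff pressure drops to zero instantly at phase end (fast dump valve);
  between phases every cuff is at zero.

MPAP (maximum pulse amplitude pressure) is computed per cuff from that
cuff's own preceding deflation, never pooled across cuffs. The envelope is
built from the band-passed pulse (0.5–20 Hz zero-phase Butterworth,
mimicking the front-end AC coupling): per cycle, amplitude = max − min
against the mean cuff pressure of the cycle; ties at the maximum resolve
to the higher pressure.

## Simulator

The simulator generates ground-truth-known recordings with the structure
the analysis assumes. It is **not** a hemodynamic model: waveform shapes
are plausibility-driven, and tests rely only on recovery of configured
quantities.

**Randomness.** One root seed; each channel draws its noise from
`SeedSequence([seed, crc32(channel_id)])`, so any subset of channels is
bit-identical to the same channels in a full simulation. Beat times use
the stream named `"beats"`.

**Beats and ECG.** RR = 60/HR plus Gaussian jitter (default SD 0.02 s).
A premature beat (probability `premature_rate` per beat) shortens its RR
to 0.6× and stretches the following interval to 1.4× (compensatory
pause), and weakens that beat's S1 to 0.6×. The ECG is a sum of Gaussian
bumps per beat (P −160 ms/0.12 mV, Q −25 ms/−0.12, R 0/1.0, S +30 ms/
−0.25, T +260 ms/+0.30; widths 25/10/12/10/45 ms). Because the bumps
overlap, the composite waveform's extrema are *not* at the bump centers —
tests therefore compare measured fiducials against a brute-force extremum
search on the noise-free composite template, not against the centers.

**Sounds.** S1 and S2 are damped-oscillation bursts (50 Hz, 18 ms decay)
at fixed delays of 40 ms and 330 ms after each R peak. Both use the same
burst shape so the measured envelope-amplitude ratio equals the
configured `s2_s1_ratio` (default 0.6) exactly; with distinct shapes the
smoothed-envelope ratio would be biased by the shape difference. The
fixed S2 delay places S2 in the second third of the cycle for heart rates
up to ≈120 bpm; above that the thirds-based S2 estimate degrades (known
limitation). The lung sound is 150–600 Hz band noise under a respiration
envelope (default 0.25 Hz).

**Pulse channels.** Each beat contributes a gamma-shaped kernel
(x² e^{2(1−x)}, time-to-peak 0.15 s) delayed so that the kernel's
maximum-slope point lands exactly at R + transit_time(site) — i.e. the
configured transit time *is* the R-to-upstroke (RWMACR) delay, making
transit recovery well-defined. Default transit times (s): earlobe 0.08,
arm 0.12, wrist 0.16, finger 0.20, ankle 0.22, toe 0.26.

**Oscillometric envelope.** A pressure pulse under its own cuff is
modulated by a two-sided Gaussian in cuff pressure with peak at the
site's MAP = DBP + PP/3. A single symmetric width cannot encode both the
profile's systolic and diastolic pressures, so the upper and lower widths
are chosen so the normalized envelope equals the standard systolic and
diastolic amplitude ratios (0.55 and 0.75) exactly at SBP and DBP — the
normalized-oscillogram model that the analysis inverts. Recovery tests
therefore validate the pipeline (envelope construction, MPAP location,
crossing interpolation), not the empirical coefficient values, which are
the common literature defaults and per-site overridable. An uninflated
cuff couples a weak constant pulse (0.5× base) into the sensor so the
channel stays analyzable in the no-pressure phase.

**Occlusion.** Distal channels (finger, toe) are attenuated by
∏ clip(1 − p_cuff/SBP_upstream, 0, 1) over their upstream cuffs (fingers:
wrist and arm of the same side; toes: ankle), reaching zero when any
upstream cuff reaches that artery's systolic pressure. Earlobe channels
ignore all cuffs.

**Blood-oxygen channels.** Per extremity, the 940 nm AC/DC modulation is
fixed (default 5%) and the 660 nm modulation is R × that, with R obtained
by inverting the SpO2 calibration parabola at the profile's SpO2 — so the
analysis-side ratio-of-ratios recovers SpO2 by construction. The pulse
train is made locally zero-mean (slow component removed with a 1.2 s
moving average) because a one-sided kernel would inflate each channel's
per-cycle mean in proportion to its AC amplitude and bias R by ≈3%. The
BODWS noise floor (0.02 a.u. on a DC of 2000) is set so the max−min
pulsation estimator stays within instrument-grade SpO2 accuracy (<1%);
the calibration parabola's slope (≈1370 %/R at a working R of ≈0.19)
makes SpO2 extremely sensitive to relative amplitude errors, which is a
property of the printed calibration scale, not of this implementation.
During the flow-blocking holds the DC level drifts linearly at
`occlusion_drift[wavelength]` (defaults −1.0 / +0.8 a.u./s for 660/940 nm,
the deoxygenation direction) and resets at the hold's end.

**Quantization.** `quantize_adcv` maps to 14-bit acquisition values
(four summed 12-bit conversions): affine gain/offset, round half away
from zero, clip to [0, 16383]. Recordings are emitted in calibrated
physical units by default; quantization is available for studies of the
acquisition path itself.

## Cycle selection

RR intervals are computed from integer sample-index differences divided
by fs (not from differenced float times), so boundary cases of the
inclusive acceptance rule are numerically exact. "Middle 50%" trims
⌈N/4⌉ intervals from each end of the ascending RR list (configurable
reading; for N < 4 after trimming, the full list is averaged). The
acceptance interval [0.7, 1.6]×base is closed at both ends.

The R-peak detector squares the first difference, thresholds it at 0.4 ×
the 98th percentile computed per 10 s block, refines each candidate to
the local ECG maximum within ±50 ms, and enforces a 250 ms refractory
period keeping the larger peak. All constants are config fields
(`RPeakConfig`); they were chosen once for the noise-free-to-mild-noise
regime the simulator produces and achieve F1 ≥ 0.99 there from 40 to
150 bpm. Real pathological ECG would need retuning — out of scope.

## Time-domain parameters

- ECG fiducial windows (relative to R): Q = min over [−60, 0] ms,
  S = min over [0, 100] ms, P = max over [−250, −80] ms, T = max over
  [80, 400] ms after the S point. The windows are fixed, config-exposed
  constants.
- Derivatives are central differences × fs, one-sided at endpoints.
- K is implemented literally as mean/(max − min); the conventional
  (mean − min)/(max − min) variant is available via
  `k_convention="normalized"`.
- The RWMACR time is located on a lightly smoothed |derivative| (20 ms
  moving average) and refined to sub-sample precision by quadratic
  interpolation: the raw derivative peak is broad, so its raw argmax
  wanders by ~10 ms under noise and is quantized to 2.5 ms at 400 Hz,
  either of which would dominate transit-time *differences* between
  sites. NMACR/NMARR magnitudes still use the raw derivative.
- Sound envelopes are |x| smoothed with a 20 ms moving average with
  edge-preserving (nearest) boundary handling, so a constant signal has a
  constant envelope. Thirds are equal-duration sub-intervals of the
  cycle; S1/S2 are the envelope maxima of the first/second thirds.
- Oscillometric BP uses only cycles after the cuff-pressure peak within
  the deflation window, excluding the inflation ramp whose fast pressure
  change smears the per-cycle mean pressure.
- ACR is implemented with the printed grouping ACR_λ = A_λ/(DI_λ·T) with
  A_λ = mean per-cycle (last − first); note that on a pure linear drift
  this grouping cancels the drift rate (both A and DI are proportional to
  it), so the 660/940 ratio ROS is 1 regardless of the rates. The plain
  rate reading DI/T, under which ROS equals the drift-rate ratio, is
  available via `acr_mode="rate"`; both are exercised in tests against
  hand-computed toys.
- Degenerate inputs (flat cycles, zero denominators, empty windows) are
  flagged, never silently zero; NSD of a zero-mean parameter is flagged.

## Frequency-domain statistics

Spectra are magnitudes of the FFT of the mean-removed phase window, with
no zero-padding (N = window length); mean removal keeps the DC bin from
contaminating the first harmonic band at low heart rates. Harmonic band
n spans bins Round((n − 0.2)·HR/FN) to Round((n + 0.2)·HR/FN) inclusive,
HR in Hz (derived from the accepted cycles of the same phase) and FN =
fs/N in Hz per bin; Round is half-away-from-zero. Dimensional analysis
requires dividing by FN (bin index = frequency/bin width); a
strict-literal mode multiplying by FN is retained for audit only. Bands
extending past the spectrum are truncated with a warning.

## Container format

A recording directory holds one `channel_id.csv` per channel
(`sample_index,value`, shortest round-trip float repr, read back with
pandas' round-trip parser — bit-exact for float64) plus a
schema-versioned `recording.json` sidecar (channel table, sampling rates,
phase windows in seconds as 0-based half-open intervals, seed, subject
metadata). Calibrated pressures are rounded to 0.01 mmHg only at the I/O
boundary.

## Problem sizes used in tests and the acceptance script

The recovery studies simulate 20 subjects with randomized profiles
(HR 55–95 bpm, wrist/arm SBP 105–135 over DBP 65–85 mmHg, ankles
+5–15/+2–8 mmHg, transit times scaled 0.85–1.15×, SpO2 90–99%) over the
full default 510 s protocol, restricted to the channel subset each
quantity needs; structural and I/O tests use a compressed schedule
(6/14/5/6/14/5/6 s phases, 3 s gaps). The cycle-rule oracle comparison
uses 1000 random RR lists; the MPAP sweep uses 100 synthetic deflations
with envelope centers uniform in 70–110 mmHg.

## Known limitations

- No hemodynamic PDE modeling, sensor optics, or motion artifacts beyond
  white/band-limited noise; pulse morphology is schematic.
- The simulator and the BP analysis share the normalized-oscillogram
  coefficient convention; agreement demonstrates pipeline correctness,
  not clinical accuracy of the 0.55/0.75 defaults.
- BODWS DC resets at the end of each flow-blocking hold rather than
  modeling reperfusion dynamics.
- EDF import/export is not provided; the CSV + JSON container is the only
  recording format.
- Thirds-based S2 location degrades above ≈120 bpm with the default
  fixed S2 delay.
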