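# cuffwave

Simulation and analysis of **pressure-stimulation multichannel cardiovascular
recordings** — the kind produced by an acquisition system that applies
controlled cuff pressures to both wrists, arms and ankles while synchronously
recording 27 physiological channels: four photoplethysmograms (both earlobes
and fingers), one lead-II ECG, heart and lung sounds, six pressure pulses and
six cuff pressures (wrists/arms/ankles, left and right), and eight
dual-wavelength (660/940 nm) blood-oxygen series at fingers and toes.

The package is for biomedical-signal researchers who want to prototype or
validate analysis methods for such recordings without the hardware: a seeded
simulator generates recordings with known ground truth (heart rate, per-site
blood pressure, SpO2, pulse transit times, occlusion responses), and the
analysis stack recovers cardiovascular parameters from them — or from any
recording stored in the package's CSV + JSON container format.

## The protocol

Acquisition is divided into seven analyzed phases (RMPS1–RMPS7) separated by
15 s rest gaps:

| phase | pressure mode     | target           | cuffs            | duration |
|-------|-------------------|------------------|------------------|----------|
| RMPS1 | none              | 0                | none             | 40 s     |
| RMPS2 | gradual decrease  | MP → 30 mmHg     | wrists + ankles  | 120 s    |
| RMPS3 | constant          | MPAP             | wrists + ankles  | 30 s     |
| RMPS4 | constant          | MP               | wrists + ankles  | 40 s     |
| RMPS5 | gradual decrease  | MP → 30 mmHg     | arms + ankles    | 120 s    |
| RMPS6 | constant          | MPAP             | arms + ankles    | 30 s     |
| RMPS7 | constant          | MP               | arms + ankles    | 40 s     |

MP is the maximum cuff pressure (default 180 mmHg). MPAP — the *maximum pulse
amplitude pressure* — is the cuff pressure at which the per-cycle pulse
amplitude peaks during the preceding deflation; holding it personalizes the
stimulation. The constant-MP holds block blood flow distal to the cuff
(occluding fingers/toes), which the blood-oxygen channels record as DC drift.

## The analysis

All signals are 5-point smoothed; ECG R peaks are found by a differential
threshold detector; RR intervals are sorted, the mean of the middle 50% is the
**base time**, and intervals within [0.7, 1.6]× the base time become
**calculated cycles** — the unit of all per-cycle analysis. Per cycle:

- **ECG** — t_RR, Q/S/P/T fiducials, amplitude differences
  (A_RQ, A_SR, A_ST, A_SP), intervals (t_QS, t_RP, t_RT), normalized maximum
  amplitude-change rates (NMACR) of the Q→R / R→S limbs;
- **heart/lung sound** — S1/S2 envelope amplitudes and their ratio, NMACR,
  per-third mean/max ratios;
- **pulse channels** — A_d = max − min, K = mean/(max − min), NMACR,
  NMARR = max rising slope / (max − min), and times from the R peak to the
  maximum, minimum and maximum-slope points (RWMACR).

Per phase, every parameter is aggregated as mean, SD and NSD = SD/mean, and
left/right channel pairs as ratios of means. Cross-channel quantities:

- **oscillometric blood pressure** — the per-cycle pulse amplitude vs mean
  cuff pressure during a deflation forms the oscillometric envelope; its peak
  is MPAP, and systolic/diastolic pressures are the cuff pressures where the
  normalized envelope crosses 0.55 (above MPAP) and 0.75 (below);
- **pulse wave velocity** — PWV = L_ab / t_ab, with t_ab the mean RWMACR-time
  difference between two sites and L from the printed regressions
  L_heart→ankle = 0.8129·H + 12.328 cm, L_heart→arm = 0.2195·H − 2.0734 cm;
- **SpO2** — per cycle, R = [(max−min)/mean]₆₆₀ / [(max−min)/mean]₉₄₀, mapped
  through SPO2 = −160.01396 + 1370.04653·R + 41.14279·R² (%);
- **occlusion trends** — ACR_λ = A_λ/(DI_λ·T) per wavelength during the
  flow-blocking holds, their ratio ROS = ACR₆₆₀/ACR₉₄₀ and the
  baseline-normalized NROS;
- **harmonic-band spectra** — per channel and phase, AveF/MaxF/RAMF within
  bands Round((n ± 0.2)·HR/FN) around harmonics n = 1..10 of the heart rate,
  and RMMF_k = MaxF_k/MaxF₁.

## Worked example

```python
import cuffwave as cw

profile = cw.SubjectProfile(seed=1)        # HR 70 bpm, wrist/arm BP 120/80,
recording = cw.simulate_recording(profile)  # ankle 130/85, SpO2 98 %
result = cw.analyze_recording(recording)
cw.write_report(result, "report")
print(open("report/summary.txt").read())
```

prints (abridged):

```
Cardiovascular analysis summary
================================
heart rate (bpm): 69.87
mean t_QS (s): 0.06457
mean S1/S2 amplitude ratio: 1.667
BP wrist_L@rmps2: 119.3/79.36 mmHg (MPAP 93.58)
BP ankle_L@rmps2: 129.1/84.54 mmHg (MPAP 98.88)
BP arm_L@rmps5: 119.5/79.54 mmHg (MPAP 93.42)
PWV heart_to_ankle_L: 6.807 m/s over 151.3 cm
PWV heart_to_arm_L: 2.91 m/s over 35.46 cm
SpO2 finger_L: 98.07 %
...
```

The recovered values sit on the simulated ground truth: heart rate 69.87 vs
70 bpm, wrist pressure 119.3/79.4 vs 120/80 mmHg with MPAP 93.6 vs a true
mean arterial pressure of 93.3 mmHg (MAP = DBP + pulse pressure/3), ankle
129.1/84.5 vs 130/85 mmHg, finger SpO2 98.07 vs 98 %. The PWV of 6.8 m/s is
the 151.3 cm heart→ankle path (height 171 cm) divided by the 0.22 s
configured ankle transit time. The S1/S2 ratio 1.667 is the inverse of the
configured S2/S1 amplitude ratio 0.6.

The same flows are available from the shell:

```sh
cuffwave protocol                      # emit the schedule as JSON
cuffwave simulate --seed 1 --out rec/  # write a recording directory
cuffwave analyze rec/ --out report/    # parameter tables + summary
cuffwave calibrate points.csv --kind linear --out cal.json
```

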