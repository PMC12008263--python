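import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cuffwave as cw
from cuffwave.cycles import select_calculated_cycles
from cuffwave.simulator import (
    ECG_WAVES,
    SubjectProfile,
    channel_rng,
    generate_beat_times,
    simulate_ecg,
    simulate_sounds,
)
from cuffwave.timedomain import (
    aggregate_rmps,
    bodws_trend,
    ecg_cycle_params,
    heart_to_ankle_cm,
    heart_to_arm_cm,
    left_right_ratios,
    oscillometric_bp,
    pulse_cycle_params,
    pwv,
    sound_cycle_params,
)


def ecg_template_truth(fs=1600.0):
    """Independent oracle: fiducials of the noise-free composite template
    located by brute-force extremum search on a dense evaluation."""
    t = np.arange(-0.4, 0.7, 1.0 / fs)
    x = np.zeros_like(t)
    for off, width, amp in ECG_WAVES.values():
        x += amp * np.exp(-0.5 * ((t - off) / width) ** 2)
    r = int(np.argmax(x))

    def ext(lo, hi, ref, kind):
        i0, i1 = ref + int(lo * fs), ref + int(hi * fs) + 1
        seg = x[i0:i1]
        return i0 + (np.argmin(seg) if kind == "min" else np.argmax(seg))

    q = ext(-0.060, 0.0, r, "min")
    s = ext(0.0, 0.100, r, "min")
    p = ext(-0.250, -0.080, r, "max")
    tp = ext(0.080, 0.400, s, "max")
    return {"t_QS": (s - q) / fs, "t_RP": (r - p) / fs, "t_RT": (tp - r) / fs,
            "A_RQ": x[r] - x[q], "A_SR": x[s] - x[r]}


@pytest.fixture(scope="module")
def measured():
    p = SubjectProfile(heart_rate=60.0, rr_jitter_sd=0.0)
    beats, _ = generate_beat_times(p, 20.0, channel_rng(0, "beats"))
    ecg = simulate_ecg(beats, 20.0, 1600.0)
    out = []
    for r, nxt in zip(beats[1:-1], beats[2:]):
        out.append(ecg_cycle_params(ecg, 1600.0, int(round(r * 1600.0)), nxt - r))
    return out


class TestEcgCycleParams:
    def test_t_qs_matches_template_truth(self, measured):
        truth = ecg_template_truth()
        vals = [m.t_QS for m in measured]
        assert np.mean(vals) == pytest.approx(truth["t_QS"], abs=2 / 1600.0)

    def test_amplitude_ratio_matches_template(self, measured):
        truth = ecg_template_truth()
        want = truth["A_RQ"] / truth["A_SR"]
        vals = [m.ratio_RQ_SR for m in measured]
        assert np.mean(vals) == pytest.approx(want, rel=0.02)

    def test_timing_intervals_match_template(self, measured):
        truth = ecg_template_truth()
        assert np.mean([m.t_RP for m in measured]) == pytest.approx(
            truth["t_RP"], abs=3 / 1600.0)
        assert np.mean([m.t_RT for m in measured]) == pytest.approx(
            truth["t_RT"], abs=3 / 1600.0)

    def test_constant_slice_flagged(self):
        x = np.full(4000, 2.0)
        p = ecg_cycle_params(x, 1600.0, 2000, 1.0)
        assert p.A_RQ == 0 and p.A_SR == 0 and p.A_ST == 0
        assert math.isnan(p.nmacr_QR) or p.nmacr_QR == pytest.approx(0.0)


class TestPulseCycleParams:
    def test_k_of_sinusoid_closed_form(self):
        # x = m + a*sin -> K = mean/(max-min) = m/(2a)
        fs, f = 500.0, 1.25
        t = np.arange(int(fs / f)) / fs
        x = 2.0 + 0.5 * np.sin(2 * np.pi * f * t)
        p = pulse_cycle_params(x, fs)
        assert p.K == pytest.approx(2.0, rel=0.01)
        assert p.A_d == pytest.approx(1.0, rel=0.01)

    def test_constant_slice_flagged(self):
        p = pulse_cycle_params(np.full(100, 5.0), 400.0)
        assert p.A_d == 0.0
        assert math.isnan(p.K) and math.isnan(p.nmarr)
        assert "flat_cycle" in p.flags

    def test_scaling_behaviour(self):
        """A_d and mean scale linearly with a positive gain; K, NMACR, NMARR
        and the timing fields are scale-invariant."""
        rng = np.random.default_rng(1)
        x = 1.0 + np.cumsum(rng.normal(size=200)) * 0.01 + np.sin(np.linspace(0, 6, 200))
        x = x - x.min() + 0.5  # keep positive
        a, b = pulse_cycle_params(x, 400.0), pulse_cycle_params(3.0 * x, 400.0)
        assert b.A_d == pytest.approx(3.0 * a.A_d)
        assert b.mean == pytest.approx(3.0 * a.mean)
        for attr in ("K", "nmacr", "nmarr", "t_to_max", "t_to_min", "t_to_maxslope"):
            assert getattr(b, attr) == pytest.approx(getattr(a, attr), rel=1e-9)

    def test_timing_fields_from_cycle_start(self):
        fs = 400.0
        x = np.zeros(400)
        x[100] = 1.0  # max at 0.25 s
        x[300] = -1.0  # min at 0.75 s
        p = pulse_cycle_params(x, fs)
        assert p.t_to_max == pytest.approx(0.25)
        assert p.t_to_min == pytest.approx(0.75)

    def test_k_convention_variant(self):
        fs = 500.0
        t = np.arange(400) / fs
        x = 2.0 + 0.5 * np.sin(2 * np.pi * 1.25 * t)
        p = pulse_cycle_params(x, fs, k_convention="normalized")
        # (mean - min)/(max - min) = (2 - 1.5)/1 = 0.5
        assert p.K == pytest.approx(0.5, rel=0.01)


class TestSoundCycleParams:
    def test_simulated_ratio_recovered(self):
        p = SubjectProfile(heart_rate=60.0, rr_jitter_sd=0.0, s2_s1_ratio=0.6)
        beats, _ = generate_beat_times(p, 30.0, channel_rng(0, "beats"))
        hs, _ = simulate_sounds(p, beats, 30.0, 3200.0)
        ratios = []
        for r, nxt in zip(beats[:-1], beats[1:]):
            sl = hs[int(r * 3200): int(nxt * 3200)]
            ratios.append(sound_cycle_params(sl, 3200.0, "HS").s2_s1_ratio)
        assert np.mean(ratios) == pytest.approx(0.6, abs=0.1)

    def test_silence_flagged(self):
        p = sound_cycle_params(np.zeros(3200), 3200.0, "HS")
        assert "silent" in p.flags
        assert math.isnan(p.nmacr)

    def test_constant_envelope_thirds_unity(self):
        x = np.ones(3000)  # |x| envelope constant
        p = sound_cycle_params(x, 3200.0, "LS")
        assert all(v == pytest.approx(1.0) for v in p.thirds_mean_max)
        assert p.amp_ratio_23_1 == pytest.approx(1.0)


class TestAggregate:
    def test_basic_arithmetic(self):
        agg = aggregate_rmps([1.0, 2.0, 3.0])
        assert agg.mean == pytest.approx(2.0)
        assert agg.sd == pytest.approx(1.0)
        assert agg.nsd == pytest.approx(0.5)

    def test_constant_nsd_zero(self):
        agg = aggregate_rmps([4.2] * 10)
        assert agg.nsd == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=30, deadline=None)
    def test_nsd_scale_invariant(self, c):
        vals = [1.0, 1.3, 0.8, 1.1, 0.95]
        assert aggregate_rmps([c * v for v in vals]).nsd == pytest.approx(
            aggregate_rmps(vals).nsd, rel=1e-9)

    def test_nan_values_skipped_zero_mean_flagged(self):
        agg = aggregate_rmps([1.0, math.nan, 3.0])
        assert agg.n == 2 and agg.mean == pytest.approx(2.0)
        z = aggregate_rmps([-1.0, 1.0])
        assert math.isnan(z.nsd) and "zero_mean" in z.flags


def toy_table(rows):
    return pd.DataFrame(rows, columns=["channel_id", "rmps", "cycle_index",
                                       "parameter", "value"])


class TestLeftRightRatios:
    def test_symmetric_and_scaled_pairs(self):
        rows = []
        for cyc in range(3):
            rows += [("pps_wrist_L", 1, cyc, "A_d", 2.0),
                     ("pps_wrist_R", 1, cyc, "A_d", 2.0),
                     ("ppg_finger_L", 1, cyc, "A_d", 4.0),
                     ("ppg_finger_R", 1, cyc, "A_d", 2.0)]
        out = left_right_ratios(toy_table(rows))
        wrist = out[out.channel_pair == "pps_wrist_X"].ratio.iloc[0]
        finger = out[out.channel_pair == "ppg_finger_X"].ratio.iloc[0]
        assert wrist == pytest.approx(1.0)
        assert finger == pytest.approx(2.0)

    def test_wavelength_suffix_pairing(self):
        rows = [("bodws_toe_L_660", 4, 0, "A_d", 3.0),
                ("bodws_toe_R_660", 4, 0, "A_d", 1.5)]
        out = left_right_ratios(toy_table(rows))
        assert out.channel_pair.iloc[0] == "bodws_toe_X_660"
        assert out.ratio.iloc[0] == pytest.approx(2.0)

    def test_zero_right_flagged(self):
        rows = [("pps_arm_L", 1, 0, "A_d", 1.0), ("pps_arm_R", 1, 0, "A_d", 0.0)]
        out = left_right_ratios(toy_table(rows))
        assert math.isnan(out.ratio.iloc[0])


def drift_partition(fs=100.0, n_cycles=30, rr=1.0, start=0.0):
    peaks = (np.arange(n_cycles + 1) * rr + start) * fs
    return select_calculated_cycles(peaks.astype(int), fs,
                                    {1: (0.0, 10.0), 4: (10.0, 30.0)})


class TestBodwsTrend:
    def test_identical_series_give_unity(self):
        fs = 100.0
        part = drift_partition(fs)
        t = np.arange(int(30 * fs)) / fs
        x = 100.0 + 0.5 * t + np.sin(2 * np.pi * t)
        tr = bodws_trend(x, x, fs, part, 4, (10.0, 30.0), part.cycles(1),
                         smooth=False)
        assert tr.ros == pytest.approx(1.0)
        assert tr.nros == pytest.approx(1.0)

    def test_linear_drift_hand_computation(self):
        """On pure linear drifts the printed grouping A/(DI*T) cancels the
        rate (ROS = 1); the plain-rate reading DI/T preserves it (ROS = 2)."""
        fs, t_rmps = 100.0, 20.0
        part = drift_partition(fs)
        t = np.arange(int(30 * fs)) / fs
        d940 = 0.5
        x660 = 1000.0 + 2 * d940 * t
        x940 = 1000.0 + d940 * t
        # hand computation, literal grouping: per-cycle change = rate*rr,
        # DI = rate*(T - dt), ACR = (rate*rr)/(rate*(T-dt)*T) -> rate cancels
        tr = bodws_trend(x660, x940, fs, part, 4, (10.0, 30.0), part.cycles(1),
                         smooth=False)
        rr = 1.0
        # half-open slices end one sample before the next boundary
        expected_acr = (d940 * (rr - 1 / fs)) / ((d940 * (t_rmps - 1 / fs)) * t_rmps)
        assert tr.acr[940] == pytest.approx(expected_acr, rel=1e-6)
        assert tr.ros == pytest.approx(1.0, rel=1e-9)
        tr_rate = bodws_trend(x660, x940, fs, part, 4, (10.0, 30.0),
                              part.cycles(1), acr_mode="rate", smooth=False)
        assert tr_rate.ros == pytest.approx(2.0, rel=1e-9)

    def test_zero_drift_flagged(self):
        fs = 100.0
        part = drift_partition(fs)
        flat = np.full(int(30 * fs), 5.0)
        tr = bodws_trend(flat, flat, fs, part, 4, (10.0, 30.0), part.cycles(1),
                         smooth=False)
        assert math.isnan(tr.ros)
        assert any(f.startswith("zero_or_missing_DI") for f in tr.flags)

    def test_only_hold_phases_allowed(self):
        fs = 100.0
        part = drift_partition(fs)
        with pytest.raises(ValueError, match="flow-blocking"):
            bodws_trend(np.ones(3000), np.ones(3000), fs, part, 2,
                        (10.0, 30.0), part.cycles(1))


class TestPwv:
    def test_path_length_regressions(self):
        assert heart_to_ankle_cm(171.0) == pytest.approx(0.8129 * 171 + 12.328)
        assert heart_to_ankle_cm(171.0) == pytest.approx(151.33, abs=0.005)
        assert heart_to_arm_cm(171.0) == pytest.approx(0.2195 * 171 - 2.0734)

    def test_heart_reference_velocity(self):
        times = np.full(20, 0.15)
        res = pwv(None, times, heart_to_ankle_cm(171.0), "heart", "ankle_L")
        assert res.t_ab == pytest.approx(0.15)
        assert res.pwv_m_s == pytest.approx(1.5133 / 0.15, rel=1e-4)

    def test_equal_delays_flagged(self):
        res = pwv(np.full(10, 0.2), np.full(10, 0.2), 30.0, "wrist", "arm")
        assert math.isnan(res.pwv_m_s)
        assert "nonpositive_transit" in res.flags

    def test_nan_cycles_dropped(self):
        a = np.array([0.10, math.nan, 0.10])
        b = np.array([0.25, 0.25, math.nan])
        res = pwv(a, b, 30.0)
        assert res.n_cycles == 1
        assert res.t_ab == pytest.approx(0.15)


def bp_fixture(sbp=120.0, dbp=80.0, fs=400.0):
    """Deflation pressure + pulses whose envelope is the analysis model."""
    from cuffwave.simulator import oscillometric_amplitude

    duration, rr = 110.0, 1.0
    n = int(duration * fs)
    t = np.arange(n) / fs
    pressure = np.maximum(160.0 - 1.25 * t, 20.0)
    pulse = np.zeros(n)
    beat = 0.3
    while beat + rr < duration:
        i0, i1 = int(beat * fs), int((beat + rr) * fs)
        amp = oscillometric_amplitude(pressure[i0], sbp, dbp)
        pulse[i0:i1] += amp * np.sin(np.pi * (t[i0:i1] - beat) / rr) ** 2
        beat += rr
    peaks = (np.arange(0.3, duration, rr) * fs).astype(int)
    part = select_calculated_cycles(peaks, fs, {2: (0.0, duration)})
    return pressure, pulse, part


class TestOscillometricBp:
    def test_recovers_configured_pressures(self):
        pressure, pulse, part = bp_fixture(120.0, 80.0)
        res = oscillometric_bp(pressure, pulse, 400.0, part, 2, site="wrist_L")
        assert res.systolic == pytest.approx(120.0, abs=3.0)
        assert res.diastolic == pytest.approx(80.0, abs=3.0)
        assert res.diastolic < res.mpap < res.systolic

    def test_envelope_not_crossing_flags_value(self):
        # deflation never above MAP: systolic side has no crossing
        pressure, pulse, part = bp_fixture(200.0, 150.0)
        res = oscillometric_bp(pressure, pulse, 400.0, part, 2)
        assert math.isnan(res.systolic)
        assert "systolic_no_crossing" in res.flags

    def test_requires_deflation_phase(self):
        pressure, pulse, part = bp_fixture()
        with pytest.raises(ValueError, match="deflation"):
            oscillometric_bp(pressure, pulse, 400.0, part, 4)

    def test_requires_enough_cycles(self):
        fs = 400.0
        pressure = np.linspace(160, 150, int(6 * fs))
        pulse = np.sin(2 * np.pi * np.arange(len(pressure)) / fs)
        peaks = (np.arange(0.3, 5.5, 1.0) * fs).astype(int)
        part = select_calculated_cycles(peaks, fs, {2: (0.0, 6.0)})
        with pytest.raises(ValueError, match="8"):
            oscillometric_bp(pressure, pulse, fs, part, 2)


class TestEndToEndSignatures:
    def test_premature_beats_raise_trr_nsd(self, default_analysis):
        """Premature-beat subjects show a larger cardiac-cycle NSD."""
        table = [c for c in cw.default_channel_table() if c.kind == "ECG"]
        prof = SubjectProfile(seed=21, premature_rate=0.12)
        rec = cw.simulate_recording(prof, channel_table=table)
        res = cw.analyze_recording(rec)

        def trr_nsd(result):
            t = result.param_table
            vals = t[(t.channel_id == "ecg") & (t.parameter == "t_RR")].value
            agg = aggregate_rmps(vals.to_numpy())
            return agg.nsd

        assert trr_nsd(res) > 2.0 * trr_nsd(default_analysis)

    def test_earlobe_params_unaffected_by_occlusion(self, default_analysis):
        t = default_analysis.param_table
        for param in ("A_d", "K"):
            sel = t[(t.channel_id == "ppg_earlobe_L") & (t.parameter == param)]
            m1 = sel[sel.rmps == 1].value.mean()
            m4 = sel[sel.rmps == 4].value.mean()
            assert abs(m4 / m1 - 1.0) < 0.02

    def test_transit_time_ordering_in_rwmacr(self, default_analysis):
        t = default_analysis.param_table
        means = {}
        for cid in ("ppg_earlobe_L", "pps_arm_L", "pps_wrist_L", "ppg_finger_L"):
            sel = t[(t.channel_id == cid) & (t.rmps == 1)
                    & (t.parameter == "t_to_maxslope")]
            means[cid] = sel.value.mean()
        assert (means["ppg_earlobe_L"] < means["pps_arm_L"]
                < means["pps_wrist_L"] < means["ppg_finger_L"])
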