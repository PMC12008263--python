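"""Seeded synthetic 27-channel cardiovascular recordings.

The simulator stands in for the acquisition hardware: it emits the full
27-channel recording structure (4 photoplethysmographic pulses, 1 ECG,
heart + lung sounds, 6 pressure pulses, 6 cuff pressures, 8 dual-wavelength
blood-oxygen series) over the seven-phase cuff-pressure protocol, with the
statistical and physiological structure the analysis stack assumes:

* ECG as a sum of Gaussian P/Q/R/S/T bumps per beat, RR = 60/HR + jitter,
  optional premature beats (shortened RR + compensatory pause);
* heart sounds as damped-oscillation S1/S2 bursts tied to each R peak,
  lung sound as band-limited noise under a respiration envelope;
* peripheral pulses as asymmetric (gamma-shaped) waves delayed from the
  R peak by per-site transit times, with the point of maximum upstroke
  slope landing exactly at the configured transit time;
* oscillometric amplitude modulation of a pressure pulse under its own
  cuff: a two-sided Gaussian envelope in cuff pressure peaking at the
  site's mean arterial pressure (MAP = DBP + PP/3) whose upper/lower
  widths place the standard systolic/diastolic amplitude ratios exactly
  at the profile's SBP/DBP;
* occlusion of distal (finger/toe) channels when an upstream cuff
  reaches the upstream artery's systolic pressure;
* dual-wavelength (660/940 nm) signals whose per-cycle AC/DC ratio pair
  encodes the profile's SpO2 through the system's R-value calibration,
  with linear DC drift during the blood-flow-blocking holds.

All randomness derives from one root seed, split per channel by a stable
CRC32 hash of the channel id, so any channel subset reproduces bit-
identically.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, sosfiltfilt

from .calibration import r_from_spo2
from .protocol import (
    CuffSite,
    PressureMode,
    ProtocolSchedule,
    build_default_protocol,
    cuff_pressure_trace,
)

__all__ = [
    "SubjectProfile",
    "ChannelSpec",
    "MultiChannelRecording",
    "default_channel_table",
    "simulate_recording",
    "simulate_ecg",
    "simulate_sounds",
    "simulate_pulse_channel",
    "simulate_bodws_channel",
    "generate_beat_times",
    "quantize_adcv",
    "dequantize_adcv",
    "oscillometric_amplitude",
    "OSC_C_SYS",
    "OSC_C_DIA",
]

# ----------------------------------------------------------------------
# constants

#: Table of per-kind sampling rates (s^-1) used by the acquisition front-end.
KIND_FS = {
    "PPG": 400.0,
    "ECG": 1600.0,
    "HS": 3200.0,
    "LS": 3200.0,
    "PPS": 400.0,
    "CUFF_PRESSURE": 400.0,
    "BODWS": 400.0,
}

#: normalized oscillogram amplitude ratios defining SBP/DBP on the envelope
OSC_C_SYS = 0.55
OSC_C_DIA = 0.75

ADC_MAX = 16383  # 14-bit acquisition range (sum of four 12-bit conversions)

# ECG wave template: name -> (center offset from R in s, width s, amplitude mV)
ECG_WAVES = {
    "P": (-0.160, 0.025, 0.12),
    "Q": (-0.025, 0.010, -0.12),
    "R": (0.000, 0.012, 1.00),
    "S": (0.030, 0.010, -0.25),
    "T": (0.260, 0.045, 0.30),
}

# pulse kernel: gamma shape, peak 1 at t = _PULSE_TAU
_PULSE_TAU = 0.15
_PULSE_SUPPORT = 0.80
# offset of the maximum-slope point of the kernel: u = tau * (1 - 1/sqrt(2))
_PULSE_MAXSLOPE_OFFSET = _PULSE_TAU * (1.0 - 1.0 / math.sqrt(2.0))


def _pulse_kernel(fs: float) -> np.ndarray:
    u = np.arange(0.0, _PULSE_SUPPORT, 1.0 / fs)
    x = u / _PULSE_TAU
    return x**2 * np.exp(2.0 * (1.0 - x))


# ----------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class ChannelSpec:
    channel_id: str
    kind: str  # ECG | HS | LS | PPG | PPS | CUFF_PRESSURE | BODWS
    site: str  # earlobe | finger | toe | wrist | arm | ankle | chest
    side: str  # "L" | "R" | "none"
    wavelength: int | None = None  # 660 | 940 | None (nm)
    fs: float = 400.0

    def __post_init__(self):
        if self.kind not in KIND_FS:
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if self.kind == "BODWS" and self.wavelength not in (660, 940):
            raise ValueError(
                f"BODWS channel requires wavelength 660 or 940 nm (got {self.wavelength})"
            )


def default_channel_table() -> list[ChannelSpec]:
    """The 27-channel acquisition table at the standard sampling rates."""
    chans: list[ChannelSpec] = []
    for site in ("earlobe", "finger"):
        for side in ("L", "R"):
            chans.append(ChannelSpec(f"ppg_{site}_{side}", "PPG", site, side, None, 400.0))
    chans.append(ChannelSpec("ecg", "ECG", "chest", "none", None, 1600.0))
    chans.append(ChannelSpec("hs", "HS", "chest", "none", None, 3200.0))
    chans.append(ChannelSpec("ls", "LS", "chest", "none", None, 3200.0))
    for site in ("wrist", "arm", "ankle"):
        for side in ("L", "R"):
            chans.append(ChannelSpec(f"pps_{site}_{side}", "PPS", site, side, None, 400.0))
    for site in ("wrist", "arm", "ankle"):
        for side in ("L", "R"):
            chans.append(
                ChannelSpec(f"cuff_{site}_{side}", "CUFF_PRESSURE", site, side, None, 400.0)
            )
    for site in ("finger", "toe"):
        for side in ("L", "R"):
            for wl in (660, 940):
                chans.append(
                    ChannelSpec(f"bodws_{site}_{side}_{wl}", "BODWS", site, side, wl, 400.0)
                )
    assert len(chans) == 27
    return chans


def _default_bp():
    # (systolic, diastolic) mmHg per cuffed site; ankle pressures run higher
    return {
        "wrist_L": (120.0, 80.0),
        "wrist_R": (120.0, 80.0),
        "arm_L": (120.0, 80.0),
        "arm_R": (120.0, 80.0),
        "ankle_L": (130.0, 85.0),
        "ankle_R": (130.0, 85.0),
    }


def _default_spo2():
    return {"finger_L": 98.0, "finger_R": 98.0, "toe_L": 98.0, "toe_R": 98.0}


def _default_transit():
    # s from R peak to peripheral upstroke (maximum slope point)
    return {
        "earlobe": 0.08,
        "arm": 0.12,
        "wrist": 0.16,
        "finger": 0.20,
        "ankle": 0.22,
        "toe": 0.26,
    }


def _default_drift():
    # a.u./s DC drift during blood-flow-blocking holds; deoxygenation pulls
    # the 660 nm level down and pushes 940 nm up
    return {660: -1.0, 940: 0.8}


def _default_noise():
    return {
        "ECG": 0.01,  # mV
        "HS": 0.02,
        "LS": 0.02,
        "PPG": 0.004,
        "PPS": 0.008,
        "CUFF_PRESSURE": 0.15,  # mmHg
        # low-noise averaged optical front-end: the floor is set so the
        # per-cycle ratio-of-ratios stays within instrument-grade SpO2
        # accuracy (<1%) given the steep R -> SpO2 calibration slope
        "BODWS": 0.02,  # a.u. (DC level 2000)
    }


@dataclass
class SubjectProfile:
    """Ground truth driving the simulator (units in field comments)."""

    heart_rate: float = 70.0  # bpm
    rr_jitter_sd: float = 0.02  # s
    bp: dict = field(default_factory=_default_bp)  # site_side -> (SBP, DBP) mmHg
    spo2: dict = field(default_factory=_default_spo2)  # extremity_side -> %
    height_H: float = 171.0  # cm
    transit_time: dict = field(default_factory=_default_transit)  # site[_side] -> s
    occlusion_drift: dict = field(default_factory=_default_drift)  # wavelength -> a.u./s
    noise_sd: dict = field(default_factory=_default_noise)  # kind -> a.u.
    premature_rate: float = 0.0  # probability a beat is premature
    s2_s1_ratio: float = 0.6
    respiration_hz: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if not 40.0 <= self.heart_rate <= 150.0:
            raise ValueError(f"heart_rate must be in [40, 150] bpm (got {self.heart_rate})")
        for k, v in self.spo2.items():
            if not 0.0 < v <= 100.0:
                raise ValueError(f"spo2[{k!r}] must be in (0, 100] (got {v})")
        tt = self.transit_time
        if not (tt["earlobe"] < tt["arm"] < tt["wrist"] < tt["finger"]):
            raise ValueError("transit times must satisfy earlobe < arm < wrist < finger")
        if not tt["ankle"] < tt["toe"]:
            raise ValueError("transit times must satisfy ankle < toe")
        if any(v <= 0 for v in tt.values()):
            raise ValueError("transit times must be positive")

    def transit(self, site: str, side: str) -> float:
        key = f"{site}_{side}"
        return self.transit_time.get(key, self.transit_time[site])

    def map_pressure(self, site_side: str) -> float:
        """Mean arterial pressure, MAP = DBP + (SBP - DBP)/3."""
        sbp, dbp = self.bp[site_side]
        return dbp + (sbp - dbp) / 3.0


@dataclass
class MultiChannelRecording:
    channels: list  # list[(ChannelSpec, np.ndarray)]
    rmps_windows: dict  # rmps id -> (t0, t1) seconds, half-open
    total_duration: float
    seed: int
    subject: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)  # simulator ground truth (beat times ...)

    def get(self, channel_id: str) -> tuple[ChannelSpec, np.ndarray]:
        for spec, x in self.channels:
            if spec.channel_id == channel_id:
                return spec, x
        raise KeyError(f"no channel {channel_id!r} in recording")

    @property
    def channel_ids(self) -> list[str]:
        return [spec.channel_id for spec, _ in self.channels]


# ----------------------------------------------------------------------
# randomness

def channel_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-channel generator: root seed + CRC32(channel id)."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


# ----------------------------------------------------------------------
# beats

def generate_beat_times(
    profile: SubjectProfile, duration: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """R-peak times over [0, duration) and per-beat premature flags.

    A premature beat shortens its RR to 0.6x and the following
    (compensatory) interval stretches to 1.4x.
    """
    rr0 = 60.0 / profile.heart_rate
    times = [0.4]
    premature = [False]
    compensate = False
    while times[-1] < duration:
        rr = rr0 + (rng.normal(0.0, profile.rr_jitter_sd) if profile.rr_jitter_sd > 0 else 0.0)
        if compensate:
            rr *= 1.4
            compensate = False
            flag = False
        elif profile.premature_rate > 0 and rng.random() < profile.premature_rate:
            rr *= 0.6
            compensate = True
            flag = True
        else:
            flag = False
        rr = max(rr, 0.25)
        times.append(times[-1] + rr)
        premature.append(flag)
    t = np.array(times)
    keep = t < duration
    return t[keep], np.array(premature)[keep]


# ----------------------------------------------------------------------
# per-kind generators

def simulate_ecg(
    beat_times: np.ndarray,
    duration: float,
    fs: float = 1600.0,
    waves: dict | None = None,
) -> np.ndarray:
    """Noise-free ECG (mV) as Gaussian P/Q/R/S/T bumps around each R time."""
    waves = waves or ECG_WAVES
    n = math.ceil(duration * fs)
    t = np.arange(n) / fs
    x = np.zeros(n)
    for _, (off, width, amp) in waves.items():
        for r in beat_times:
            c = r + off
            lo = max(0, int((c - 5 * width) * fs))
            hi = min(n, int((c + 5 * width) * fs) + 1)
            if hi > lo:
                x[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - c) / width) ** 2)
    return x


def _burst(fs: float, freq: float, tau: float, length: float) -> np.ndarray:
    u = np.arange(0.0, length, 1.0 / fs)
    return np.exp(-u / tau) * np.sin(2 * np.pi * freq * u)


def simulate_sounds(
    profile: SubjectProfile,
    beat_times: np.ndarray,
    duration: float,
    fs: float = 3200.0,
    rng: np.random.Generator | None = None,
    premature: np.ndarray | None = None,
    s1_delay: float = 0.04,
    s2_delay: float = 0.33,
) -> tuple[np.ndarray, np.ndarray]:
    """(heart sound, lung sound) series.

    S1/S2 are damped-oscillation bursts at fixed delays after each R peak
    (S1 amplitude 1, S2 = s2_s1_ratio); premature beats get a weakened S1.
    The lung sound is 150-600 Hz band noise under a respiration envelope.
    """
    n = math.ceil(duration * fs)
    hs = np.zeros(n)
    # S1 and S2 share one burst shape so the measured envelope-amplitude
    # ratio equals the configured amplitude ratio exactly
    b1 = _burst(fs, 50.0, 0.018, 0.10)
    b2 = b1
    if premature is None:
        premature = np.zeros(len(beat_times), dtype=bool)
    for r, pm in zip(beat_times, premature):
        a1 = 0.6 if pm else 1.0
        for burst, delay, amp in ((b1, s1_delay, a1), (b2, s2_delay, profile.s2_s1_ratio)):
            i0 = int(round((r + delay) * fs))
            i1 = min(n, i0 + len(burst))
            if 0 <= i0 < n:
                hs[i0:i1] += amp * burst[: i1 - i0]
    if rng is None:
        rng = np.random.default_rng(0)
    noise = rng.normal(0.0, 1.0, n)
    nyq = fs / 2.0
    sos = butter(4, [150.0 / nyq, 600.0 / nyq], btype="band", output="sos")
    band = sosfiltfilt(sos, noise)
    t = np.arange(n) / fs
    envelope = 0.55 + 0.45 * np.sin(2 * np.pi * profile.respiration_hz * t)
    ls = 0.3 * band * envelope
    return hs, ls


def oscillometric_amplitude(
    cuff_p: float | np.ndarray, sbp: float, dbp: float,
    c_sys: float = OSC_C_SYS, c_dia: float = OSC_C_DIA,
) -> np.ndarray:
    """Two-sided Gaussian oscillometric envelope, peak 1 at MAP.

    The upper/lower widths are set so the envelope equals ``c_sys`` at
    SBP and ``c_dia`` at DBP — the normalized-oscillogram model the
    analysis inverts.
    """
    mapp = dbp + (sbp - dbp) / 3.0
    sig_hi = (sbp - mapp) / math.sqrt(2.0 * math.log(1.0 / c_sys))
    sig_lo = (mapp - dbp) / math.sqrt(2.0 * math.log(1.0 / c_dia))
    p = np.asarray(cuff_p, dtype=float)
    sig = np.where(p >= mapp, sig_hi, sig_lo)
    return np.exp(-0.5 * ((p - mapp) / sig) ** 2)


def _occlusion_factor(p_up: np.ndarray, sbp_up: float) -> np.ndarray:
    """Monotone attenuation of distal flow: 1 at zero cuff pressure, 0 at SBP."""
    return np.clip(1.0 - p_up / sbp_up, 0.0, 1.0)


def _pulse_train(
    beat_times: np.ndarray,
    amplitudes: np.ndarray,
    transit: float,
    duration: float,
    fs: float,
) -> np.ndarray:
    """Superposed pulse kernels; max-slope point lands at R + transit."""
    n = math.ceil(duration * fs)
    x = np.zeros(n)
    kern = _pulse_kernel(fs)
    onset_delay = transit - _PULSE_MAXSLOPE_OFFSET
    for r, a in zip(beat_times, amplitudes):
        if a == 0.0:
            continue
        i0 = int(round((r + onset_delay) * fs))
        i1 = min(n, i0 + len(kern))
        if i0 >= n:
            continue
        k0 = 0
        if i0 < 0:
            k0, i0 = -i0, 0
        x[i0:i1] += a * kern[k0 : k0 + (i1 - i0)]
    return x


def simulate_pulse_channel(
    profile: SubjectProfile,
    spec: ChannelSpec,
    beat_times: np.ndarray,
    duration: float,
    cuff_pressure: np.ndarray | None = None,
    upstream: list | None = None,
) -> np.ndarray:
    """Noise-free pulse series for a PPG or PPS channel.

    ``cuff_pressure`` is this site's own cuff trace (PPS channels on a
    cuffed site); ``upstream`` is a list of (pressure trace, upstream SBP)
    for distal channels (fingers: wrist + arm cuffs; toes: ankle cuff).
    Earlobe channels ignore all cuffs.
    """
    if spec.kind not in ("PPG", "PPS"):
        raise ValueError(f"not a pulse channel kind: {spec.kind}")
    fs = spec.fs
    transit = profile.transit(spec.site, spec.side)
    idx = np.clip((beat_times * fs).astype(int), 0, None)

    if spec.kind == "PPS":
        site_side = f"{spec.site}_{spec.side}"
        if site_side not in profile.bp:
            raise ValueError(f"no blood pressure configured for PPS site {site_side}")
        if cuff_pressure is None:
            raise ValueError(f"cuff pressure trace required for PPS channel {spec.channel_id}")
        sbp, dbp = profile.bp[site_side]
        p_at_beats = cuff_pressure[np.minimum(idx, len(cuff_pressure) - 1)]
        env = oscillometric_amplitude(p_at_beats, sbp, dbp)
        # an uninflated cuff still couples a weak pulse into the sensor
        amps = np.where(p_at_beats > 5.0, env, 0.5)
        return _pulse_train(beat_times, amps, transit, duration, fs)

    # PPG
    amps = np.ones(len(beat_times))
    if spec.site != "earlobe":
        if not upstream:
            raise ValueError(
                f"upstream cuff traces required for distal PPG channel {spec.channel_id}"
            )
        for trace, sbp_up in upstream:
            p_at_beats = trace[np.minimum(idx, len(trace) - 1)]
            amps = amps * _occlusion_factor(p_at_beats, sbp_up)
    pulses = _pulse_train(beat_times, 0.3 * amps, transit, duration, fs)
    return 1.0 + pulses  # DC perfusion level + pulsatile component


def simulate_bodws_channel(
    profile: SubjectProfile,
    spec: ChannelSpec,
    beat_times: np.ndarray,
    duration: float,
    upstream: list,
    drift_windows: Sequence[tuple[float, float]],
    dc_level: float = 2000.0,
    ac_dc_940: float = 0.05,
) -> np.ndarray:
    """Noise-free dual-wavelength blood-oxygen series for one wavelength.

    The per-cycle (AC/DC) pair across 660/940 nm is constructed so the
    ratio-of-ratios R matches the extremity's SpO2 through the system's
    R-value calibration; AC/DC at 940 nm is fixed (default 5%).  During
    blood-flow-blocking holds pulsation is suppressed by the occlusion
    factor and the DC level drifts linearly at the configured rate.
    """
    if spec.kind != "BODWS":
        raise ValueError(f"not a BODWS channel: {spec.channel_id}")
    if spec.wavelength not in (660, 940):
        raise ValueError(f"invalid wavelength {spec.wavelength}")
    fs = spec.fs
    n = math.ceil(duration * fs)
    t = np.arange(n) / fs
    spo2 = profile.spo2[f"{spec.site}_{spec.side}"]
    r = r_from_spo2(spo2)
    ratio = ac_dc_940 * (r if spec.wavelength == 660 else 1.0)
    transit = profile.transit(spec.site, spec.side)

    idx = np.clip((beat_times * fs).astype(int), 0, None)
    amps = np.ones(len(beat_times))
    for trace, sbp_up in upstream:
        p_at_beats = trace[np.minimum(idx, len(trace) - 1)]
        amps = amps * _occlusion_factor(p_at_beats, sbp_up)
    # kernel max-min equals its peak (baseline 0), so scale to the target AC;
    # the pulsation oscillates about the DC perfusion level, so remove the
    # slow component of the train (otherwise the per-cycle mean would be
    # inflated in proportion to the AC amplitude, biasing the 660/940 ratio)
    ac_amp = ratio * dc_level
    train = _pulse_train(beat_times, ac_amp * amps, transit, duration, fs)
    train -= uniform_filter1d(train, max(3, int(round(1.2 * fs))), mode="nearest")
    x = dc_level + train

    drift_rate = profile.occlusion_drift.get(spec.wavelength, 0.0)
    if drift_rate != 0.0:
        for t0, t1 in drift_windows:
            mask = (t >= t0) & (t < t1)
            x[mask] += drift_rate * (t[mask] - t0)
    return x


# ----------------------------------------------------------------------
# quantization

def quantize_adcv(x: np.ndarray, gain: float, offset: float) -> np.ndarray:
    """Affine map to 14-bit acquisition values.

    ``adcv = round(gain * x + offset)`` with round-half-away-from-zero,
    clipped to [0, 16383] (each acquisition value is the sum of four
    adjacent 12-bit conversions).
    """
    y = gain * np.asarray(x, dtype=float) + offset
    rounded = np.sign(y) * np.floor(np.abs(y) + 0.5)
    return np.clip(rounded, 0, ADC_MAX).astype(np.int64)


def dequantize_adcv(adcv: np.ndarray, gain: float, offset: float) -> np.ndarray:
    """Inverse of :func:`quantize_adcv` up to the rounding error <= 0.5/gain."""
    return (np.asarray(adcv, dtype=float) - offset) / gain


# ----------------------------------------------------------------------
# full recording

def _upstream_cuffs(site: str, side: str) -> list[str]:
    if site == "finger":
        return [f"wrist_{side}", f"arm_{side}"]
    if site == "toe":
        return [f"ankle_{side}"]
    return []


def simulate_recording(
    profile: SubjectProfile,
    schedule: ProtocolSchedule | None = None,
    channel_table: list[ChannelSpec] | None = None,
) -> MultiChannelRecording:
    """Generate a full synthetic recording over the protocol schedule.

    Deterministic for a given (profile, schedule, channel table): every
    channel derives its noise stream from the root seed and its own id,
    and all channels share the protocol clock and beat times.
    """
    schedule = schedule or build_default_protocol()
    channel_table = channel_table if channel_table is not None else default_channel_table()
    if not channel_table:
        raise ValueError("channel_table must be non-empty")
    duration = schedule.total_duration
    seed = profile.seed

    beat_times, premature = generate_beat_times(
        profile, duration, channel_rng(seed, "beats")
    )

    # ideal cuff traces on the shared 400 Hz pulse-channel grid
    cuff_traces: dict[str, np.ndarray] = {}
    for cuff in CuffSite:
        mpap = profile.map_pressure(cuff.value) if cuff.value in profile.bp else None
        cuff_traces[cuff.value] = cuff_pressure_trace(schedule, cuff, mpap=mpap, fs=400.0)

    # blood-flow-blocking holds (constant-MP phases) drive BODWS drift
    drift_windows = [
        (seg.start_time, seg.end_time)
        for seg in schedule.segments
        if seg.pressure_mode is PressureMode.CONSTANT and seg.pressure_target == "MP"
    ]

    def upstream_for(spec: ChannelSpec) -> list:
        ups = []
        for cuff in _upstream_cuffs(spec.site, spec.side):
            sbp_up = profile.bp[cuff][0]
            ups.append((cuff_traces[cuff], sbp_up))
        return ups

    channels = []
    hs_ls_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for spec in channel_table:
        rng = channel_rng(seed, spec.channel_id)
        if spec.kind == "ECG":
            x = simulate_ecg(beat_times, duration, spec.fs)
        elif spec.kind in ("HS", "LS"):
            if spec.fs not in hs_ls_cache:
                hs_ls_cache[spec.fs] = simulate_sounds(
                    profile, beat_times, duration, spec.fs,
                    rng=channel_rng(seed, "ls_noise"), premature=premature,
                )
            x = hs_ls_cache[spec.fs][0 if spec.kind == "HS" else 1]
        elif spec.kind == "CUFF_PRESSURE":
            x = cuff_traces[f"{spec.site}_{spec.side}"].copy()
        elif spec.kind == "PPS":
            x = simulate_pulse_channel(
                profile, spec, beat_times, duration,
                cuff_pressure=cuff_traces[f"{spec.site}_{spec.side}"],
            )
        elif spec.kind == "PPG":
            x = simulate_pulse_channel(
                profile, spec, beat_times, duration, upstream=upstream_for(spec)
            )
        elif spec.kind == "BODWS":
            x = simulate_bodws_channel(
                profile, spec, beat_times, duration,
                upstream=upstream_for(spec), drift_windows=drift_windows,
            )
        else:  # pragma: no cover
            raise ValueError(f"unhandled channel kind {spec.kind}")
        sd = profile.noise_sd.get(spec.kind, 0.0)
        if sd > 0:
            x = x + rng.normal(0.0, sd, len(x))
        channels.append((spec, x))

    return MultiChannelRecording(
        channels=channels,
        rmps_windows=schedule.rmps_windows(),
        total_duration=duration,
        seed=seed,
        subject={"height_H": profile.height_H, "heart_rate": profile.heart_rate},
        truth={"beat_times": beat_times, "premature": premature},
    )
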