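"""Seven-phase cuff-pressure stimulation protocol.

The acquisition protocol applies pressure stimulation through six cuffs
(both wrists, arms and ankles) in seven analyzed phases ("RMPS" — real
meaningful procedural segments):

======  =================  ==========  ====================  ========
phase   pressure mode      pressure    cuffs                 duration
======  =================  ==========  ====================  ========
RMPS1   none               0           none                  40 s
RMPS2   gradual decrease   MP -> 30    wrists + ankles       120 s
RMPS3   constant           MPAP        wrists + ankles       30 s
RMPS4   constant           MP          wrists + ankles       40 s
RMPS5   gradual decrease   MP -> 30    arms + ankles         120 s
RMPS6   constant           MPAP        arms + ankles         30 s
RMPS7   constant           MP          arms + ankles         40 s
======  =================  ==========  ====================  ========

MP is the maximum cuff pressure (default 180 mmHg); MPAP, the maximum
pulse amplitude pressure, is the cuff pressure at which the per-cycle
pulse amplitude peaks during the preceding deflation (RMPS2 for RMPS3,
RMPS5 for RMPS6).  A ~15 s zero-pressure rest gap separates consecutive
phases.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt, find_peaks

logger = logging.getLogger(__name__)

__all__ = [
    "CuffSite",
    "PressureMode",
    "ProtocolConfig",
    "RMPSSegment",
    "ProtocolSchedule",
    "MPAPResult",
    "build_default_protocol",
    "cuff_pressure_trace",
    "compute_mpap",
    "mpap_from_envelope",
    "pulse_amplitude_envelope",
]


class CuffSite(str, Enum):
    """The six cuff positions."""

    WRIST_L = "wrist_L"
    WRIST_R = "wrist_R"
    ARM_L = "arm_L"
    ARM_R = "arm_R"
    ANKLE_L = "ankle_L"
    ANKLE_R = "ankle_R"


class PressureMode(str, Enum):
    NONE = "none"
    GRADUAL_DECREASE = "gradual_decrease"
    CONSTANT = "constant"


#: cuff groups stimulated together
WRISTS_ANKLES = frozenset(
    {CuffSite.WRIST_L, CuffSite.WRIST_R, CuffSite.ANKLE_L, CuffSite.ANKLE_R}
)
ARMS_ANKLES = frozenset(
    {CuffSite.ARM_L, CuffSite.ARM_R, CuffSite.ANKLE_L, CuffSite.ANKLE_R}
)

#: default phase durations in seconds, RMPS1..RMPS7
DEFAULT_DURATIONS = (40.0, 120.0, 30.0, 40.0, 120.0, 30.0, 40.0)


@dataclass(frozen=True)
class ProtocolConfig:
    """Settable protocol parameters.

    Parameters
    ----------
    max_pressure_MP
        Maximum cuff pressure MP in mmHg (default 180).
    deflation_floor
        Pressure the gradual-decrease phases vent down to, mmHg
        (default 30; the "MP -> 30" deflation).
    vent_rate
        Deflation speed in mmHg/s (default 1.25, so 180 -> 30 spans
        the nominal 120 s deflation phase).
    rest_interval
        Zero-pressure gap between consecutive phases, s (default 15).
    durations
        Per-phase nominal durations in seconds, RMPS1..RMPS7.
    inflation_rate
        Inflation speed in mmHg/s; the inflation ramp lives inside the
        nominal phase duration.
    """

    max_pressure_MP: float = 180.0
    deflation_floor: float = 30.0
    vent_rate: float = 1.25
    rest_interval: float = 15.0
    durations: tuple[float, ...] = DEFAULT_DURATIONS
    inflation_rate: float = 20.0

    def __post_init__(self) -> None:
        if not self.max_pressure_MP > self.deflation_floor:
            raise ValueError(
                "max_pressure_MP must exceed deflation_floor "
                f"(got max_pressure_MP={self.max_pressure_MP}, "
                f"deflation_floor={self.deflation_floor})"
            )
        if self.deflation_floor < 0:
            raise ValueError(f"deflation_floor must be >= 0 (got {self.deflation_floor})")
        if self.vent_rate <= 0:
            raise ValueError(f"vent_rate must be > 0 (got {self.vent_rate})")
        if self.inflation_rate <= 0:
            raise ValueError(f"inflation_rate must be > 0 (got {self.inflation_rate})")
        if self.rest_interval < 0:
            raise ValueError(f"rest_interval must be >= 0 (got {self.rest_interval})")
        if len(self.durations) != 7:
            raise ValueError(f"durations must have 7 entries (got {len(self.durations)})")
        if any(d <= 0 for d in self.durations):
            raise ValueError(f"durations must all be > 0 (got {self.durations})")


@dataclass(frozen=True)
class RMPSSegment:
    """One analyzed phase of the protocol (half-open [start_time, end_time))."""

    id: int  # 1..7
    pressure_mode: PressureMode
    pressure_target: str  # "zero" | "MP" | "MPAP" | "MP_to_floor"
    cuffs: frozenset[CuffSite]
    start_time: float
    end_time: float

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass(frozen=True)
class ProtocolSchedule:
    segments: tuple[RMPSSegment, ...]
    config: ProtocolConfig
    total_duration: float

    def segment(self, rmps_id: int) -> RMPSSegment:
        for seg in self.segments:
            if seg.id == rmps_id:
                return seg
        raise KeyError(f"no RMPS segment with id {rmps_id}")

    def rmps_windows(self) -> dict[int, tuple[float, float]]:
        """Half-open [start, end) window per RMPS id, in seconds."""
        return {s.id: (s.start_time, s.end_time) for s in self.segments}

    def to_json(self) -> str:
        payload = {
            "schema_version": "1",
            "total_duration_s": self.total_duration,
            "config": asdict(self.config),
            "segments": [
                {
                    "id": s.id,
                    "pressure_mode": s.pressure_mode.value,
                    "pressure_target": s.pressure_target,
                    "cuffs": sorted(c.value for c in s.cuffs),
                    "start_time_s": s.start_time,
                    "end_time_s": s.end_time,
                }
                for s in self.segments
            ],
        }
        return json.dumps(payload, indent=2)


@dataclass
class MPAPResult:
    """Maximum pulse amplitude pressure and the envelope it came from."""

    cuff: str
    mpap: float
    envelope: list[tuple[float, float]]  # (mean cuff pressure mmHg, pulse amplitude)


# --------------------------------------------------------------------------
# schedule construction

_SEGMENT_PLAN = (
    # (mode, target, cuffs)
    (PressureMode.NONE, "zero", frozenset()),
    (PressureMode.GRADUAL_DECREASE, "MP_to_floor", WRISTS_ANKLES),
    (PressureMode.CONSTANT, "MPAP", WRISTS_ANKLES),
    (PressureMode.CONSTANT, "MP", WRISTS_ANKLES),
    (PressureMode.GRADUAL_DECREASE, "MP_to_floor", ARMS_ANKLES),
    (PressureMode.CONSTANT, "MPAP", ARMS_ANKLES),
    (PressureMode.CONSTANT, "MP", ARMS_ANKLES),
)


def build_default_protocol(config: ProtocolConfig | None = None) -> ProtocolSchedule:
    """Build the seven-phase schedule with rest gaps between phases."""
    config = config or ProtocolConfig()
    segments = []
    t = 0.0
    for idx, (mode, target, cuffs) in enumerate(_SEGMENT_PLAN):
        if idx > 0:
            t += config.rest_interval
        dur = config.durations[idx]
        segments.append(
            RMPSSegment(
                id=idx + 1,
                pressure_mode=mode,
                pressure_target=target,
                cuffs=cuffs,
                start_time=t,
                end_time=t + dur,
            )
        )
        t += dur
    return ProtocolSchedule(segments=tuple(segments), config=config, total_duration=t)


# --------------------------------------------------------------------------
# ideal cuff-pressure traces

def cuff_pressure_trace(
    schedule: ProtocolSchedule,
    cuff: CuffSite | str,
    mpap: float | None = None,
    fs: float = 400.0,
) -> np.ndarray:
    """Ideal pressure trace (mmHg) of one cuff over the whole schedule.

    Each phase inflates linearly from 0 at ``inflation_rate`` to its
    target, then holds (constant phases) or vents at ``vent_rate`` down
    to ``deflation_floor`` (gradual-decrease phases); pressure drops to
    zero instantly at phase end (fast dump valve).  ``mpap`` is required
    if the cuff participates in a constant-MPAP phase.
    """
    if fs <= 0:
        raise ValueError(f"fs must be > 0 (got {fs})")
    cuff = CuffSite(cuff)
    cfg = schedule.config
    n = math.ceil(schedule.total_duration * fs)
    t = np.arange(n) / fs
    p = np.zeros(n)
    for seg in schedule.segments:
        if cuff not in seg.cuffs or seg.pressure_mode is PressureMode.NONE:
            continue
        if seg.pressure_target == "MPAP":
            if mpap is None:
                raise ValueError(
                    f"mpap is required: cuff {cuff.value} is held at MPAP in RMPS{seg.id}"
                )
            target = float(mpap)
        else:
            target = cfg.max_pressure_MP
        mask = (t >= seg.start_time) & (t < seg.end_time)
        tau = t[mask] - seg.start_time  # time since phase start
        t_inflate = target / cfg.inflation_rate
        seg_p = np.minimum(tau * cfg.inflation_rate, target)
        if seg.pressure_mode is PressureMode.GRADUAL_DECREASE:
            deflating = tau > t_inflate
            seg_p[deflating] = np.maximum(
                target - (tau[deflating] - t_inflate) * cfg.vent_rate,
                cfg.deflation_floor,
            )
        p[mask] = seg_p
    return p


# --------------------------------------------------------------------------
# MPAP from a deflation segment

def _bandpass_pulse(pulse: np.ndarray, fs: float, band=(0.5, 20.0)) -> np.ndarray:
    """Zero-phase 0.5-20 Hz band-pass mimicking the front-end AC coupling."""
    nyq = fs / 2.0
    hi = min(band[1], 0.9 * nyq)
    sos = butter(2, [band[0] / nyq, hi / nyq], btype="band", output="sos")
    return sosfiltfilt(sos, pulse)


def pulse_amplitude_envelope(
    pressure: np.ndarray,
    pulse: np.ndarray,
    fs: float,
    band=(0.5, 20.0),
) -> list[tuple[float, float]]:
    """Per-cycle (mean cuff pressure, pulse max-min amplitude) pairs.

    Cycles are delimited by successive peaks of the band-passed pulse.
    """
    ac = _bandpass_pulse(np.asarray(pulse, dtype=float), fs, band)
    min_dist = max(1, int(round(0.3 * fs)))  # <= 200 bpm
    prominence = 0.1 * float(np.std(ac))
    peaks, _ = find_peaks(ac, distance=min_dist, prominence=prominence)
    env = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        seg = ac[a:b]
        env.append((float(np.mean(pressure[a:b])), float(np.max(seg) - np.min(seg))))
    return env


def mpap_from_envelope(envelope) -> float:
    """Pressure at the envelope amplitude maximum; ties -> higher pressure."""
    best = max(envelope, key=lambda e: (e[1], e[0]))
    return float(best[0])


def compute_mpap(
    pressure: np.ndarray,
    pulse: np.ndarray,
    fs: float,
    cuff: str = "",
    band=(0.5, 20.0),
) -> MPAPResult:
    """Maximum pulse amplitude pressure from a co-registered deflation.

    The oscillometric envelope is the per-cycle pulse amplitude
    (max-min of the band-passed pulse) against the mean cuff pressure of
    that cycle; MPAP is the pressure at the envelope maximum, ties broken
    toward the higher pressure.
    """
    pressure = np.asarray(pressure, dtype=float)
    pulse = np.asarray(pulse, dtype=float)
    if pressure.shape != pulse.shape:
        raise ValueError("pressure and pulse must be co-registered (equal length)")
    diffs = np.diff(pressure)
    if np.any(diffs > 1e-9) and np.any(diffs < -1e-9):
        logger.warning("pressure segment is not monotone; proceeding")
    env = pulse_amplitude_envelope(pressure, pulse, fs, band)
    if len(env) < 5:
        raise ValueError(
            f"insufficient data: need >= 5 detectable pulse cycles, found {len(env)}"
        )
    return MPAPResult(cuff=cuff, mpap=mpap_from_envelope(env), envelope=env)
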