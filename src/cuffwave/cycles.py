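"""Smoothing, R-peak detection, and calculated-cycle selection.

All per-cycle analysis is anchored on "calculated cycles": RR intervals
between adjacent ECG R peaks that pass the base-time rule.  The RR list
is sorted ascending, the mean of its middle 50% is the base time, and an
interval is accepted iff it lies within [0.7, 1.6] times the base time
(closed interval).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CyclePartition",
    "smooth5",
    "detect_r_peaks",
    "base_time_middle50",
    "select_calculated_cycles",
    "slice_cycles",
    "RPeakConfig",
]

ACCEPT_LO = 0.7
ACCEPT_HI = 1.6


@dataclass(frozen=True)
class RPeakConfig:
    """Differential-threshold detector constants (all config-exposed)."""

    percentile: float = 98.0
    threshold_factor: float = 0.4
    refractory_s: float = 0.25
    refine_window_s: float = 0.05
    block_s: float = 10.0  # running-percentile block length


@dataclass
class CyclePartition:
    """R peaks plus the accepted calculated cycles, per protocol phase."""

    r_peak_indices: np.ndarray  # sample indices on the ECG clock
    fs: float
    rr_intervals: np.ndarray  # s, len = len(r_peak_indices) - 1
    base_time: float  # s
    accepted: np.ndarray  # bool per RR interval
    rmps_of_cycle: np.ndarray  # phase id per RR interval (0 = outside any phase)
    rejection_reasons: list = field(default_factory=list)

    @property
    def r_times(self) -> np.ndarray:
        return self.r_peak_indices / self.fs

    def cycles(self, rmps: int | None = None) -> list[tuple[float, float]]:
        """Accepted cycles as (t_start, t_end) seconds; optionally one phase."""
        t = self.r_times
        out = []
        for i in range(len(self.rr_intervals)):
            if not self.accepted[i]:
                continue
            if rmps is not None and self.rmps_of_cycle[i] != rmps:
                continue
            out.append((float(t[i]), float(t[i + 1])))
        return out

    def heart_rate_bpm(self, rmps: int | None = None) -> float:
        """HR from the mean accepted RR (of one phase, or overall)."""
        sel = self.accepted.copy()
        if rmps is not None:
            sel &= self.rmps_of_cycle == rmps
        rr = self.rr_intervals[sel]
        if len(rr) == 0:
            return float("nan")
        return 60.0 / float(np.mean(rr))


def smooth5(x: np.ndarray) -> np.ndarray:
    """Centered 5-point moving average; edges use shrinking windows.

    Each output sample is the mean of the input over [i-2, i+2] clipped
    to the valid range, so the first/last samples average 3 and 4 points.
    Inputs shorter than 5 samples are passed through with a warning.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 5:
        logger.warning("smooth5: input length %d < 5; passthrough", n)
        return x.copy()
    c = np.concatenate(([0.0], np.cumsum(x)))
    i = np.arange(n)
    lo = np.maximum(i - 2, 0)
    hi = np.minimum(i + 2, n - 1)
    return (c[hi + 1] - c[lo]) / (hi - lo + 1)


def detect_r_peaks(
    ecg: np.ndarray, fs: float, config: RPeakConfig | None = None
) -> np.ndarray:
    """R-peak sample indices by the differential-threshold method.

    The squared first difference is compared against an adaptive
    threshold (a fraction of a running percentile computed per block);
    candidates are refined to the local ECG maximum within a +-50 ms
    window and a 250 ms refractory period keeps the larger peak.
    """
    cfg = config or RPeakConfig()
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < 2 * fs:
        raise ValueError("need at least 2 s of ECG signal")
    d = np.diff(ecg) * fs
    sq = d * d
    # running percentile threshold per block
    thresh = np.empty_like(sq)
    block = max(1, int(cfg.block_s * fs))
    for start in range(0, len(sq), block):
        seg = sq[start : start + block]
        thresh[start : start + block] = cfg.threshold_factor * np.percentile(
            seg, cfg.percentile
        )
    above = sq > thresh
    if not np.any(above):
        logger.warning("detect_r_peaks: no candidates above threshold")
        return np.array([], dtype=int)
    # group consecutive supra-threshold runs into candidates
    idx = np.flatnonzero(above)
    splits = np.flatnonzero(np.diff(idx) > int(0.05 * fs)) + 1
    groups = np.split(idx, splits)
    half = int(round(cfg.refine_window_s * fs))
    n = len(ecg)
    candidates = []
    for g in groups:
        center = g[np.argmax(sq[g])]
        lo, hi = max(0, center - half), min(n, center + half + 1)
        candidates.append(lo + int(np.argmax(ecg[lo:hi])))
    # refractory: keep the larger of peaks closer than refractory_s
    refractory = int(round(cfg.refractory_s * fs))
    peaks: list[int] = []
    for c in sorted(set(candidates)):
        if peaks and c - peaks[-1] < refractory:
            if ecg[c] > ecg[peaks[-1]]:
                peaks[-1] = c
        else:
            peaks.append(c)
    return np.asarray(peaks, dtype=int)


def base_time_middle50(rr: np.ndarray) -> float:
    """Mean of the middle 50% of the ascending RR list.

    "Middle 50%" trims ceil(N/4) intervals from each end of the sorted
    list (for N not divisible by 4 this keeps fewer than N/2 values).
    """
    rr = np.sort(np.asarray(rr, dtype=float))
    n = len(rr)
    trim = math.ceil(n / 4)
    mid = rr[trim : n - trim]
    if len(mid) == 0:  # tiny lists: fall back to the overall mean
        mid = rr
    return float(np.mean(mid))


def select_calculated_cycles(
    r_peaks: np.ndarray,
    fs: float,
    rmps_windows: dict[int, tuple[float, float]] | None = None,
) -> CyclePartition:
    """Apply the base-time rule to the RR intervals of detected R peaks.

    Cycles are assigned to the protocol phase containing their starting
    R peak (phase 0 if the peak falls in a rest gap).
    """
    r_peaks = np.asarray(r_peaks, dtype=int)
    if len(r_peaks) < 5:
        raise ValueError("need >= 4 RR intervals to establish the base time")
    t = r_peaks / fs
    rr = np.diff(r_peaks) / fs  # integer sample differences stay exact
    base = base_time_middle50(rr)
    accepted = (rr >= ACCEPT_LO * base) & (rr <= ACCEPT_HI * base)
    reasons = [
        None if ok else ("short" if v < ACCEPT_LO * base else "long")
        for ok, v in zip(accepted, rr)
    ]
    rmps_of_cycle = np.zeros(len(rr), dtype=int)
    if rmps_windows:
        for rid, (t0, t1) in rmps_windows.items():
            rmps_of_cycle[(t[:-1] >= t0) & (t[:-1] < t1)] = rid
    return CyclePartition(
        r_peak_indices=r_peaks,
        fs=fs,
        rr_intervals=rr,
        base_time=base,
        accepted=accepted,
        rmps_of_cycle=rmps_of_cycle,
        rejection_reasons=reasons,
    )


def slice_cycles(
    x: np.ndarray, fs: float, cycles: list[tuple[float, float]]
) -> list[np.ndarray]:
    """Views of a channel over [t_start, t_end) windows on its own clock."""
    x = np.asarray(x)
    n = len(x)
    out = []
    for t0, t1 in cycles:
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        i0, i1 = max(0, i0), min(n, i1)
        if i1 <= i0:
            logger.warning("empty cycle slice [%.3f, %.3f)", t0, t1)
            out.append(x[0:0])
        else:
            out.append(x[i0:i1])
    return out


def partition_to_frame(partition: CyclePartition):
    """Long-form export: one row per RR interval."""
    import pandas as pd

    t = partition.r_times
    return pd.DataFrame(
        {
            "r_index": partition.r_peak_indices[:-1],
            "t_seconds": t[:-1],
            "rr_s": partition.rr_intervals,
            "accepted": partition.accepted,
            "rmps": partition.rmps_of_cycle,
            "reason": partition.rejection_reasons,
        }
    )
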