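"""System calibration formulas and per-cycle blood-oxygen R values.

Three calibrations tie raw 14-bit acquisition values (ADCV) to physical
units:

* ECG voltage: linear, ``V_ECG = -0.01042 + 4.30532e-4 * ADCV`` (mV);
* SpO2: parabola in the ratio-of-ratios R,
  ``SPO2 = -160.01396 + 1370.04653 R + 41.14279 R**2`` (%), where R is
  the per-cycle (pulsation/mean) ratio at 660 nm divided by the same
  ratio at 940 nm;
* cuff pressure: per-channel linear fit (intercept/slope, adjusted R²).

Note the stored parabola places physiological SpO2 near R ~ 0.19 for
98%, unlike the textbook ratio-of-ratios scale; it is the instrument's
own calibration and is used as printed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "EcgCalibration",
    "Spo2Calibration",
    "PressureCalibration",
    "adcv_to_ecg_mv",
    "spo2_from_r",
    "r_from_spo2",
    "r_value_per_cycle",
    "fit_linear_calibration",
    "fit_spo2_parabola",
]


@dataclass(frozen=True)
class EcgCalibration:
    intercept: float = -0.01042  # mV
    slope: float = 4.30532e-4  # mV per ADCV unit

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError(f"slope must be > 0 (got {self.slope})")


@dataclass(frozen=True)
class Spo2Calibration:
    c0: float = -160.01396
    c1: float = 1370.04653
    c2: float = 41.14279


@dataclass(frozen=True)
class PressureCalibration:
    """Per-channel linear pressure calibration (mmHg vs ADCV)."""

    intercept: float
    slope: float
    adjusted_r2: float

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError(f"slope must be > 0 (got {self.slope})")

    def to_mmhg(self, adcv) -> np.ndarray:
        # the instrument reports pressure with 0.01 mmHg resolution
        return np.round(self.intercept + self.slope * np.asarray(adcv, float), 2)


def adcv_to_ecg_mv(adcv, cal: EcgCalibration | None = None) -> np.ndarray | float:
    """ECG voltage (mV) from acquisition values."""
    cal = cal or EcgCalibration()
    return cal.intercept + cal.slope * np.asarray(adcv, dtype=float)


def spo2_from_r(r, cal: Spo2Calibration | None = None, *, allow_zero: bool = False):
    """SpO2 (%) from the ratio-of-ratios R via the calibration parabola."""
    cal = cal or Spo2Calibration()
    r = np.asarray(r, dtype=float)
    bound = 0.0 if allow_zero else np.nextafter(0.0, -1.0)
    if np.any(r < bound) or (not allow_zero and np.any(r <= 0.0)):
        raise ValueError("R value must be > 0")
    out = cal.c0 + cal.c1 * r + cal.c2 * r**2
    return float(out) if out.ndim == 0 else out


def r_from_spo2(spo2: float, cal: Spo2Calibration | None = None) -> float:
    """Positive root of the calibration parabola for a target SpO2 (%)."""
    cal = cal or Spo2Calibration()
    # c2 r^2 + c1 r + (c0 - spo2) = 0
    a, b, c = cal.c2, cal.c1, cal.c0 - spo2
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise ValueError(f"no real R solves the calibration parabola for SpO2={spo2}")
    roots = [(-b + math.sqrt(disc)) / (2 * a), (-b - math.sqrt(disc)) / (2 * a)]
    pos = [r for r in roots if r >= 0]
    if not pos:
        raise ValueError(f"no positive R solves the calibration parabola for SpO2={spo2}")
    return min(pos)


def r_value_per_cycle(ch660, ch940, cycles, fs: float) -> list[float]:
    """Per-cycle R = (pulsation/mean)_660 / (pulsation/mean)_940.

    "Pulsation" is the within-cycle max-min, "mean" the within-cycle mean.
    ``cycles`` is a sequence of (t_start, t_end) in seconds on the shared
    clock; cycles with a zero mean or zero 940 nm ratio are excluded and
    logged.
    """
    ch660 = np.asarray(ch660, dtype=float)
    ch940 = np.asarray(ch940, dtype=float)
    if len(ch660) != len(ch940):
        raise ValueError("channels must be co-registered (equal length)")
    if len(cycles) == 0:
        raise ValueError("need at least one accepted cycle")
    out = []
    for t0, t1 in cycles:
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        s660, s940 = ch660[i0:i1], ch940[i0:i1]
        if len(s660) < 2:
            logger.warning("cycle [%.3f, %.3f) too short for R value; skipped", t0, t1)
            continue
        m660, m940 = np.mean(s660), np.mean(s940)
        if m660 == 0 or m940 == 0:
            logger.warning("cycle [%.3f, %.3f) has zero mean; skipped", t0, t1)
            continue
        ratio660 = (np.max(s660) - np.min(s660)) / m660
        ratio940 = (np.max(s940) - np.min(s940)) / m940
        if ratio940 == 0:
            logger.warning("cycle [%.3f, %.3f) has zero 940 nm pulsation; skipped", t0, t1)
            continue
        out.append(float(ratio660 / ratio940))
    return out


def fit_linear_calibration(x, y) -> PressureCalibration:
    """Least-squares line y = intercept + slope*x with adjusted R²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError(f"need >= 3 calibration points (got {len(x)})")
    if np.ptp(x) == 0:
        raise ValueError("calibration inputs have zero variance")
    res = stats.linregress(x, y)
    n = len(x)
    r2 = res.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return PressureCalibration(intercept=float(res.intercept), slope=float(res.slope),
                               adjusted_r2=float(adj))


def fit_spo2_parabola(r_means, spo2_refs) -> Spo2Calibration:
    """Least-squares quadratic SpO2(R) from calibration points."""
    r = np.asarray(r_means, dtype=float)
    s = np.asarray(spo2_refs, dtype=float)
    if len(np.unique(r)) < 3:
        raise ValueError("need >= 3 distinct R values to fit a parabola")
    c2, c1, c0 = np.polyfit(r, s, 2)
    return Spo2Calibration(c0=float(c0), c1=float(c1), c2=float(c2))


def save_calibration(cal, path) -> None:
    with open(path, "w") as fh:
        json.dump({"type": type(cal).__name__, **asdict(cal)}, fh, indent=2)
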