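"""Per-cycle and per-phase time-domain cardiovascular parameters.

For every calculated cycle the stack extracts:

* ECG: t_RR, the Q/S/P/T fiducials relative to the R peak, pairwise
  amplitude differences (A_RQ, A_SR, A_ST, A_SP), timing intervals
  (t_QS, t_RP, t_RT) and their ratios, and the normalized maximum
  amplitude-change rate (NMACR) of the Q->R and S->R limbs;
* heart/lung sound: S1/S2 envelope amplitudes and their ratio, NMACR,
  and mean/max ratios within each third of the cycle;
* pulse channels (pressure pulses, photoplethysmograms, dual-wavelength
  optic pulses): A_d = max-min, K = mean/(max-min), NMACR, NMARR
  (max rising slope / (max-min)), and the times from the R peak to the
  maximum, minimum and maximum-slope points (the last is the RWMACR
  time used for transit-time differences).

Across cycles of one protocol phase, each parameter is summarized as
mean, sample SD and NSD = SD/mean; left/right channel pairs are compared
as ratios of means.  Cross-channel quantities: the blood-oxygen
change-rate statistics ACR/ROS/NROS during the flow-blocking holds,
pulse wave velocity from RWMACR-time differences and path-length
regressions, and oscillometric systolic/diastolic pressure from the
deflation envelopes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cycles import CyclePartition, smooth5
from .protocol import MPAPResult

logger = logging.getLogger(__name__)

__all__ = [
    "EcgCycleParams",
    "SoundCycleParams",
    "PulseCycleParams",
    "RmpsAggregate",
    "BodwsTrend",
    "PwvResult",
    "BpResult",
    "ecg_cycle_params",
    "sound_cycle_params",
    "pulse_cycle_params",
    "aggregate_rmps",
    "left_right_ratios",
    "bodws_trend",
    "pwv",
    "oscillometric_bp",
    "heart_to_ankle_cm",
    "heart_to_arm_cm",
    "DEFAULT_C_SYS",
    "DEFAULT_C_DIA",
]

DEFAULT_C_SYS = 0.55
DEFAULT_C_DIA = 0.75

# ECG fiducial search windows, s relative to the R peak (config-exposed)
ECG_WINDOWS = {
    "Q": (-0.060, 0.0),       # minimum before R
    "S": (0.0, 0.100),        # minimum after R
    "P": (-0.250, -0.080),    # maximum before R
    "T_after_S": (0.080, 0.400),  # maximum after the S point
}


def _derivative(x: np.ndarray, fs: float) -> np.ndarray:
    """Central differences scaled by fs; one-sided at the endpoints."""
    return np.gradient(x) * fs


def _refine_peak(y: np.ndarray, i: int) -> float:
    """Sub-sample peak location by quadratic interpolation around bin i."""
    if not 0 < i < len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(i) + float(np.clip(delta, -0.5, 0.5))


# ----------------------------------------------------------------------
# ECG

@dataclass
class EcgCycleParams:
    t_RR: float
    A_RQ: float
    A_SR: float
    A_ST: float
    A_SP: float
    ratio_RQ_SR: float
    ratio_SP_ST: float
    t_QS: float
    t_RP: float
    t_RT: float
    ratio_RP_RT: float
    nmacr_QR: float
    nmacr_SR: float
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d.pop("flags")
        return d


def ecg_cycle_params(
    ecg: np.ndarray, fs: float, r_index: int, rr_s: float,
    windows: dict | None = None,
) -> EcgCycleParams:
    """ECG fiducials and amplitudes for the cycle starting at ``r_index``.

    Q/S are the minima within fixed windows before/after R, P the maximum
    in a window before R, T the maximum in a window after the S point.
    """
    win = windows or ECG_WINDOWS
    ecg = np.asarray(ecg, dtype=float)
    n = len(ecg)
    flags: list[str] = []

    def extremum(lo_s, hi_s, ref, kind):
        lo = max(0, ref + int(round(lo_s * fs)))
        hi = min(n, ref + int(round(hi_s * fs)) + 1)
        if hi <= lo:
            return None
        seg = ecg[lo:hi]
        off = int(np.argmin(seg)) if kind == "min" else int(np.argmax(seg))
        return lo + off

    q = extremum(*win["Q"], r_index, "min")
    s = extremum(*win["S"], r_index, "min")
    p = extremum(*win["P"], r_index, "max")
    t_pt = extremum(*win["T_after_S"], s, "max") if s is not None else None
    if any(v is None for v in (q, s, p, t_pt)):
        flags.append("fiducial_window_empty")

    def amp(a, b):
        if a is None or b is None:
            return math.nan
        return float(ecg[a] - ecg[b])

    A_RQ = amp(r_index, q)
    A_SR = amp(s, r_index)
    A_ST = amp(s, t_pt)
    A_SP = amp(s, p)
    t_QS = (s - q) / fs if (q is not None and s is not None) else math.nan
    t_RP = (r_index - p) / fs if p is not None else math.nan
    t_RT = (t_pt - r_index) / fs if t_pt is not None else math.nan

    def nmacr(limb_lo, limb_hi):
        if limb_lo is None or limb_hi is None or limb_hi <= limb_lo:
            return math.nan
        seg = ecg[limb_lo : limb_hi + 1]
        d = _derivative(seg, fs)
        peak = np.max(np.abs(seg))
        return float(np.max(np.abs(d)) / peak) if peak > 0 else math.nan

    return EcgCycleParams(
        t_RR=rr_s,
        A_RQ=A_RQ, A_SR=A_SR, A_ST=A_ST, A_SP=A_SP,
        ratio_RQ_SR=A_RQ / A_SR if A_SR else math.nan,
        ratio_SP_ST=A_SP / A_ST if A_ST else math.nan,
        t_QS=t_QS, t_RP=t_RP, t_RT=t_RT,
        ratio_RP_RT=t_RP / t_RT if t_RT else math.nan,
        nmacr_QR=nmacr(q, r_index),
        nmacr_SR=nmacr(r_index, s),  # the R->S downstroke limb (S follows R)
        flags=flags,
    )


# ----------------------------------------------------------------------
# heart / lung sounds

@dataclass
class SoundCycleParams:
    s1_amp: float
    s2_amp: float
    s2_s1_ratio: float
    max_amp: float
    nmacr: float
    thirds_mean_max: tuple  # mean/max of the envelope within each third
    amp_ratio_23_1: float  # mean envelope over thirds 2-3 / third 1
    rate_ratio_23_1: float  # same for |envelope derivative|
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {
            "s1_amp": self.s1_amp,
            "s2_amp": self.s2_amp,
            "s2_s1_ratio": self.s2_s1_ratio,
            "max_amp": self.max_amp,
            "nmacr": self.nmacr,
            "amp_ratio_23_1": self.amp_ratio_23_1,
            "rate_ratio_23_1": self.rate_ratio_23_1,
        }
        for i, v in enumerate(self.thirds_mean_max, start=1):
            d[f"mean_max_third{i}"] = v
        return d


def _envelope(x: np.ndarray, fs: float, window_s: float = 0.020) -> np.ndarray:
    """Rectified signal smoothed by a moving average (default 20 ms).

    Edge samples are smoothed against their nearest neighbours rather
    than zero-padded, so a constant signal keeps a constant envelope.
    """
    from scipy.ndimage import uniform_filter1d

    w = max(1, int(round(window_s * fs)))
    return uniform_filter1d(np.abs(x), w, mode="nearest")


def sound_cycle_params(
    slice_: np.ndarray, fs: float, kind: str = "HS"
) -> SoundCycleParams:
    """Heart/lung sound per-cycle features from the smoothed envelope.

    Thirds are equal-duration sub-intervals of the cycle; for HS, S1 is
    the envelope maximum in the first third and S2 in the second third.
    """
    x = np.asarray(slice_, dtype=float)
    flags: list[str] = []
    if len(x) < 6:
        flags.append("slice_too_short")
        nan = math.nan
        return SoundCycleParams(nan, nan, nan, nan, nan, (nan, nan, nan), nan, nan, flags)
    env = _envelope(x, fs)
    n = len(env)
    b1, b2 = n // 3, 2 * n // 3
    thirds = [env[:b1], env[b1:b2], env[b2:]]
    peak = float(np.max(env))
    if peak <= 0:
        flags.append("silent")
    s1 = float(np.max(thirds[0])) if kind == "HS" else math.nan
    s2 = float(np.max(thirds[1])) if kind == "HS" else math.nan
    ratio = s2 / s1 if kind == "HS" and s1 > 0 else math.nan
    d = np.abs(_derivative(env, fs))
    nmacr = float(np.max(d) / peak) if peak > 0 else math.nan
    mean_max = tuple(
        float(np.mean(t) / np.max(t)) if np.max(t) > 0 else math.nan for t in thirds
    )
    m1 = float(np.mean(thirds[0]))
    m23 = float(np.mean(env[b1:]))
    amp_ratio = m23 / m1 if m1 > 0 else math.nan
    d1 = float(np.mean(d[:b1]))
    d23 = float(np.mean(d[b1:]))
    rate_ratio = d23 / d1 if d1 > 0 else math.nan
    return SoundCycleParams(
        s1_amp=s1, s2_amp=s2, s2_s1_ratio=ratio, max_amp=peak, nmacr=nmacr,
        thirds_mean_max=mean_max, amp_ratio_23_1=amp_ratio, rate_ratio_23_1=rate_ratio,
        flags=flags,
    )


# ----------------------------------------------------------------------
# pulse channels

@dataclass
class PulseCycleParams:
    A_d: float
    K: float  # mean / (max - min)
    nmacr: float  # max |derivative| / max
    nmarr: float  # max rising derivative / (max - min)
    t_to_max: float  # s from R peak
    t_to_min: float
    t_to_maxslope: float  # RWMACR time
    mean: float
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d.pop("flags")
        return d


def pulse_cycle_params(
    slice_: np.ndarray, fs: float, k_convention: str = "literal"
) -> PulseCycleParams:
    """Per-cycle pulse features; the slice starts at the cycle's R peak.

    K follows the literal definition mean/(max-min); the conventional
    normalized-mean variant (mean-min)/(max-min) is available with
    ``k_convention="normalized"``.  Argmax ties resolve to the earliest
    sample.
    """
    x = np.asarray(slice_, dtype=float)
    flags: list[str] = []
    if len(x) < 3:
        flags.append("slice_too_short")
        nan = math.nan
        return PulseCycleParams(nan, nan, nan, nan, nan, nan, nan, nan, flags)
    xmax, xmin = float(np.max(x)), float(np.min(x))
    a_d = xmax - xmin
    mean = float(np.mean(x))
    d = _derivative(x, fs)
    i_max = int(np.argmax(x))
    i_min = int(np.argmin(x))
    # RWMACR timing feeds transit-time differences, so it is located on a
    # lightly smoothed derivative (the raw derivative peak is broad and its
    # argmax wanders under noise) and refined to sub-sample precision
    from scipy.ndimage import uniform_filter1d

    w = max(1, min(int(round(0.02 * fs)), len(x) // 4))
    ad = uniform_filter1d(np.abs(d), w, mode="nearest")
    t_slope = _refine_peak(ad, int(np.argmax(ad)))
    nmacr = float(np.max(np.abs(d)) / xmax) if xmax > 0 else math.nan
    if a_d == 0:
        flags.append("flat_cycle")
        k = math.nan
        nmarr = math.nan
    else:
        rising = float(np.max(d))
        nmarr = rising / a_d if rising > 0 else math.nan
        k = (mean / a_d) if k_convention == "literal" else ((mean - xmin) / a_d)
    return PulseCycleParams(
        A_d=a_d, K=k, nmacr=nmacr, nmarr=nmarr,
        t_to_max=i_max / fs, t_to_min=i_min / fs, t_to_maxslope=t_slope / fs,
        mean=mean, flags=flags,
    )


# ----------------------------------------------------------------------
# aggregation

@dataclass
class RmpsAggregate:
    mean: float
    sd: float
    nsd: float
    n: int
    flags: list = field(default_factory=list)


def aggregate_rmps(values) -> RmpsAggregate:
    """Mean, sample SD (n-1) and NSD = SD/mean over cycles of one phase."""
    v = np.asarray([x for x in values if not (isinstance(x, float) and math.isnan(x))],
                   dtype=float)
    flags: list[str] = []
    if len(v) == 0:
        return RmpsAggregate(math.nan, math.nan, math.nan, 0, ["no_values"])
    m = float(np.mean(v))
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    if m == 0:
        flags.append("zero_mean")
        nsd = math.nan
    else:
        nsd = sd / m
    return RmpsAggregate(mean=m, sd=sd, nsd=nsd, n=len(v), flags=flags)


def left_right_ratios(table: pd.DataFrame) -> pd.DataFrame:
    """Left/right ratios of per-phase parameter means.

    ``table`` is long-form with columns (channel_id, rmps, parameter,
    value); channel ids are paired by replacing the side suffix/infix.
    Returns (channel_pair, rmps, parameter, ratio).
    """
    df = table.copy()
    df["side"] = df["channel_id"].str.extract(r"_(L|R)(?:_|$)")
    df = df.dropna(subset=["side"])
    df["pair"] = [
        cid.replace("_L_", "_X_") if "_L_" in cid or "_R_" in cid else cid
        for cid in df["channel_id"].str.replace(r"_(L|R)(_|$)", r"_X\2", regex=True)
    ]
    means = (
        df.groupby(["pair", "side", "rmps", "parameter"])["value"]
        .mean()
        .unstack("side")
    )
    out = means.reset_index()
    if "L" not in out or "R" not in out:
        return pd.DataFrame(columns=["channel_pair", "rmps", "parameter", "ratio"])
    out["ratio"] = out["L"] / out["R"]
    out.loc[out["R"] == 0, "ratio"] = math.nan
    return out.rename(columns={"pair": "channel_pair"})[
        ["channel_pair", "rmps", "parameter", "ratio"]
    ]


# ----------------------------------------------------------------------
# blood-oxygen change-rate statistics (flow-blocking holds)

@dataclass
class BodwsTrend:
    rmps: int
    di: dict  # wavelength -> last-first over the phase window
    a_mean: dict  # wavelength -> mean per-cycle last-first
    t_rmps: float
    acr: dict  # wavelength -> average change rate
    ros: float
    nros: float
    md1: dict  # wavelength -> mean per-cycle max-min during phase 1
    flags: list = field(default_factory=list)


def _window_slice(x, fs, window):
    i0, i1 = int(round(window[0] * fs)), int(round(window[1] * fs))
    return x[max(0, i0) : min(len(x), i1)]


def bodws_trend(
    ch660: np.ndarray,
    ch940: np.ndarray,
    fs: float,
    partition: CyclePartition,
    rmps: int,
    rmps_window: tuple[float, float],
    rmps1_cycles: list[tuple[float, float]],
    acr_mode: str = "literal",
    smooth: bool = True,
) -> BodwsTrend:
    """ACR/ROS/NROS for one extremity during a flow-blocking hold.

    ``acr_mode="literal"`` follows the printed grouping
    ACR = A/(DI*T) with A the mean per-cycle (last-first) change;
    ``acr_mode="rate"`` uses the simpler overall rate DI/T.
    """
    if rmps not in (4, 7):
        raise ValueError("blood-oxygen trends are defined for the flow-blocking holds (4, 7)")
    flags: list[str] = []
    chans = {660: np.asarray(ch660, float), 940: np.asarray(ch940, float)}
    if smooth:
        chans = {wl: smooth5(x) for wl, x in chans.items()}
    t_rmps = rmps_window[1] - rmps_window[0]
    cyc = partition.cycles(rmps)
    di, a_mean, acr, md1 = {}, {}, {}, {}
    for wl, x in chans.items():
        w = _window_slice(x, fs, rmps_window)
        di[wl] = float(w[-1] - w[0]) if len(w) >= 2 else math.nan
        per_cycle = []
        for t0, t1 in cyc:
            s = _window_slice(x, fs, (t0, t1))
            if len(s) >= 2:
                per_cycle.append(s[-1] - s[0])
        a_mean[wl] = float(np.mean(per_cycle)) if per_cycle else math.nan
        m = []
        for t0, t1 in rmps1_cycles:
            s = _window_slice(x, fs, (t0, t1))
            if len(s) >= 2:
                m.append(np.max(s) - np.min(s))
        md1[wl] = float(np.mean(m)) if m else math.nan
        if di[wl] == 0 or math.isnan(di[wl]):
            flags.append(f"zero_or_missing_DI_{wl}")
            acr[wl] = math.nan
        elif acr_mode == "rate":
            acr[wl] = di[wl] / t_rmps
        else:
            acr[wl] = a_mean[wl] / (di[wl] * t_rmps)
    if any(math.isnan(acr[wl]) for wl in (660, 940)) or acr[940] == 0:
        ros = math.nan
        flags.append("ros_undefined")
    else:
        ros = acr[660] / acr[940]
    if (
        math.isnan(ros)
        or acr[660] == 0
        or any(md1[wl] == 0 or math.isnan(md1[wl]) for wl in (660, 940))
    ):
        nros = math.nan
        flags.append("nros_undefined")
    else:
        nros = (acr[940] * md1[660]) / (acr[660] * md1[940])
    return BodwsTrend(
        rmps=rmps, di=di, a_mean=a_mean, t_rmps=t_rmps, acr=acr,
        ros=ros, nros=nros, md1=md1, flags=flags,
    )


# ----------------------------------------------------------------------
# pulse wave velocity

def heart_to_ankle_cm(height_cm: float) -> float:
    """Heart-to-ankle path length regression, cm."""
    return 0.8129 * height_cm + 12.328


def heart_to_arm_cm(height_cm: float) -> float:
    """Heart-to-arm path length regression, cm."""
    return 0.2195 * height_cm - 2.0734


@dataclass
class PwvResult:
    site_a: str
    site_b: str
    length_cm: float
    t_ab: float  # s
    pwv_m_s: float
    n_cycles: int
    flags: list = field(default_factory=list)


def pwv(
    t_rwmacr_a: np.ndarray | None,
    t_rwmacr_b: np.ndarray,
    length_cm: float,
    site_a: str = "heart",
    site_b: str = "",
) -> PwvResult:
    """Pulse wave velocity PWV = L_ab / t_ab.

    ``t_rwmacr_*`` are per-cycle R-to-maximum-slope times on common
    accepted cycles; pass ``None`` for site a when the proximal event is
    the ECG R peak itself (heart reference, time 0).
    """
    b = np.asarray(t_rwmacr_b, dtype=float)
    a = np.zeros_like(b) if t_rwmacr_a is None else np.asarray(t_rwmacr_a, dtype=float)
    if len(a) != len(b):
        raise ValueError("RWMACR time arrays must cover common cycles")
    good = ~(np.isnan(a) | np.isnan(b))
    diffs = b[good] - a[good]
    flags: list[str] = []
    if len(diffs) == 0:
        return PwvResult(site_a, site_b, length_cm, math.nan, math.nan, 0, ["no_cycles"])
    t_ab = float(np.mean(diffs))
    if t_ab <= 0:
        flags.append("nonpositive_transit")
        v = math.nan
    else:
        v = (length_cm / 100.0) / t_ab
    return PwvResult(site_a, site_b, length_cm, t_ab, v, int(good.sum()), flags)


# ----------------------------------------------------------------------
# oscillometric blood pressure

@dataclass
class BpResult:
    site: str
    systolic: float
    diastolic: float
    mpap: float
    envelope: list  # (pressure mmHg, normalized amplitude)
    c_sys: float
    c_dia: float
    flags: list = field(default_factory=list)


def _crossing(pressures, amps, level, side):
    """Interpolated pressure where the normalized envelope crosses ``level``.

    ``side="high"`` scans the branch above MPAP (descending amplitudes as
    pressure rises), ``side="low"`` the branch below.
    """
    for i in range(len(amps) - 1):
        a0, a1 = amps[i], amps[i + 1]
        if (a0 - level) * (a1 - level) <= 0 and a0 != a1:
            frac = (level - a0) / (a1 - a0)
            return pressures[i] + frac * (pressures[i + 1] - pressures[i])
    return None


def oscillometric_bp(
    pressure: np.ndarray,
    pulse: np.ndarray,
    fs: float,
    partition: CyclePartition,
    rmps: int,
    c_sys: float = DEFAULT_C_SYS,
    c_dia: float = DEFAULT_C_DIA,
    site: str = "",
) -> BpResult:
    """Systolic/diastolic pressure from a deflation phase envelope.

    Per accepted cycle of the deflation (samples after the pressure peak,
    so the inflation ramp is excluded), the band-passed pulse amplitude
    vs mean cuff pressure forms the oscillometric envelope; its maximum
    is MPAP, and the systolic (diastolic) pressure is the interpolated
    cuff pressure above (below) MPAP where the normalized amplitude
    equals ``c_sys`` (``c_dia``).
    """
    from .protocol import _bandpass_pulse  # shared AC-coupling filter

    if rmps not in (2, 5):
        raise ValueError("oscillometric BP is computed from the deflation phases (2, 5)")
    pressure = np.asarray(pressure, dtype=float)
    cyc = partition.cycles(rmps)
    if len(cyc) < 8:
        raise ValueError(f"need >= 8 accepted cycles in the deflation (got {len(cyc)})")
    ac = _bandpass_pulse(np.asarray(pulse, dtype=float), fs)
    # deflation starts at the cuff-pressure peak within the phase window
    t0_phase = min(t0 for t0, _ in cyc)
    t1_phase = max(t1 for _, t1 in cyc)
    i0, i1 = int(t0_phase * fs), int(t1_phase * fs)
    t_peak = (i0 + int(np.argmax(pressure[i0:i1]))) / fs

    env = []
    for t0, t1 in cyc:
        if t0 < t_peak:
            continue
        j0, j1 = int(round(t0 * fs)), int(round(t1 * fs))
        seg = ac[j0:j1]
        if len(seg) < 2:
            continue
        env.append((float(np.mean(pressure[j0:j1])), float(np.max(seg) - np.min(seg))))
    flags: list[str] = []
    if len(env) < 5:
        raise ValueError(f"insufficient deflation cycles for an envelope (got {len(env)})")
    env.sort(key=lambda e: e[0])  # ascending pressure
    pressures = np.array([e[0] for e in env])
    amps = np.array([e[1] for e in env])
    peak = float(np.max(amps))
    norm = amps / peak
    i_pk = int(np.argmax(amps))
    # ties toward higher pressure
    i_pk = max(i for i in range(len(amps)) if amps[i] == amps[i_pk])
    mpap = float(pressures[i_pk])

    sbp = _crossing(pressures[i_pk:], norm[i_pk:], c_sys, "high")
    dbp = _crossing(pressures[: i_pk + 1], norm[: i_pk + 1], c_dia, "low")
    if sbp is None:
        flags.append("systolic_no_crossing")
        sbp = math.nan
    if dbp is None:
        flags.append("diastolic_no_crossing")
        dbp = math.nan
    return BpResult(
        site=site, systolic=float(sbp), diastolic=float(dbp), mpap=mpap,
        envelope=list(zip(pressures.tolist(), norm.tolist())),
        c_sys=c_sys, c_dia=c_dia, flags=flags,
    )
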