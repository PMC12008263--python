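"""End-to-end analysis of a multichannel recording.

Runs the full stack in method order: 5-point smoothing, R-peak
detection, calculated-cycle selection, per-cycle parameter extraction on
every analyzable channel, per-phase aggregation, left/right ratios,
oscillometric blood pressure from the deflation phases, pulse wave
velocity, per-extremity SpO2, blood-oxygen change-rate trends during the
flow-blocking holds, and (optionally) harmonic-band spectral statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import timedomain as td
from .calibration import r_value_per_cycle, spo2_from_r
from .cycles import (
    CyclePartition,
    detect_r_peaks,
    select_calculated_cycles,
    slice_cycles,
    smooth5,
)
from .freqdomain import band_stats, spectrum
from .simulator import MultiChannelRecording

logger = logging.getLogger(__name__)

__all__ = ["AnalysisResult", "analyze_recording"]

# deflation phase -> cuffed sites swept by it
_DEFLATION_SITES = {2: ("wrist_L", "wrist_R", "ankle_L", "ankle_R"),
                    5: ("arm_L", "arm_R", "ankle_L", "ankle_R")}


@dataclass
class AnalysisResult:
    partition: CyclePartition
    param_table: pd.DataFrame  # (channel_id, rmps, cycle_index, parameter, value)
    hr_bpm: dict  # rmps -> heart rate
    bp: dict = field(default_factory=dict)  # "site@rmps" -> BpResult
    pwv: dict = field(default_factory=dict)  # name -> PwvResult
    spo2: dict = field(default_factory=dict)  # extremity -> %
    bodws: dict = field(default_factory=dict)  # "extremity@rmps" -> BodwsTrend
    lr_ratios: pd.DataFrame | None = None
    bands: dict = field(default_factory=dict)  # (channel_id, rmps) -> SpectrumBandStats

    def aggregates(self) -> pd.DataFrame:
        """Per (channel, rmps, parameter): mean, SD, NSD over accepted cycles."""
        rows = []
        for (cid, rmps, param), grp in self.param_table.groupby(
            ["channel_id", "rmps", "parameter"]
        ):
            agg = td.aggregate_rmps(grp["value"].to_numpy())
            rows.append(
                {"channel_id": cid, "rmps": rmps, "parameter": param,
                 "mean": agg.mean, "sd": agg.sd, "nsd": agg.nsd, "n": agg.n}
            )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        t = self.param_table
        tqs = t.loc[(t["channel_id"] == "ecg") & (t["parameter"] == "t_QS"), "value"]
        s2s1 = t.loc[(t["channel_id"] == "hs") & (t["parameter"] == "s2_s1_ratio"), "value"]
        s2s1_m = float(np.nanmean(s2s1)) if len(s2s1) else math.nan
        return {
            "heart_rate_bpm": self.hr_bpm.get(0, math.nan),
            "heart_rate_by_rmps": self.hr_bpm,
            "t_qs_mean_s": float(np.nanmean(tqs)) if len(tqs) else math.nan,
            "s1_s2_ratio_mean": 1.0 / s2s1_m if s2s1_m and not math.isnan(s2s1_m) else math.nan,
            "blood_pressure": {
                k: {"systolic": v.systolic, "diastolic": v.diastolic, "mpap": v.mpap}
                for k, v in self.bp.items()
            },
            "pwv": {
                k: {"pwv_m_s": v.pwv_m_s, "t_ab_s": v.t_ab, "length_cm": v.length_cm}
                for k, v in self.pwv.items()
            },
            "spo2": self.spo2,
            "bodws": {
                k: {"ros": v.ros, "nros": v.nros, "acr_660": v.acr[660],
                    "acr_940": v.acr[940]}
                for k, v in self.bodws.items()
            },
        }


def _param_rows(cid, rmps, cycle_idx, params: dict, rows: list):
    for name, value in params.items():
        rows.append(
            {"channel_id": cid, "rmps": rmps, "cycle_index": cycle_idx,
             "parameter": name, "value": value}
        )


def analyze_recording(
    rec: MultiChannelRecording,
    compute_bands: bool = False,
    channels: list[str] | None = None,
    height_cm: float | None = None,
) -> AnalysisResult:
    """Run the complete analysis pipeline on a recording.

    ``channels`` restricts per-cycle parameter extraction (and band
    statistics) to a subset of channel ids; cross-channel quantities are
    computed whenever the channels they need are present.
    """
    ecg_spec, ecg_raw = rec.get("ecg")
    ecg = smooth5(ecg_raw)
    peaks = detect_r_peaks(ecg, ecg_spec.fs)
    partition = select_calculated_cycles(peaks, ecg_spec.fs, rec.rmps_windows)

    wanted = set(channels) if channels is not None else set(rec.channel_ids)
    smoothed: dict[str, np.ndarray] = {}
    for spec, x in rec.channels:
        if spec.channel_id in wanted or spec.kind == "CUFF_PRESSURE":
            smoothed[spec.channel_id] = smooth5(x) if spec.kind != "CUFF_PRESSURE" else x

    rows: list[dict] = []
    rmps_ids = sorted(rec.rmps_windows)
    hr_bpm = {0: partition.heart_rate_bpm()}
    for rid in rmps_ids:
        hr_bpm[rid] = partition.heart_rate_bpm(rid)

    for spec, _ in rec.channels:
        cid = spec.channel_id
        if cid not in wanted or spec.kind == "CUFF_PRESSURE":
            continue
        x = smoothed[cid]
        for rid in rmps_ids:
            cyc = partition.cycles(rid)
            if not cyc:
                continue
            if spec.kind == "ECG":
                for ci, (t0, t1) in enumerate(cyc):
                    p = td.ecg_cycle_params(
                        x, spec.fs, int(round(t0 * spec.fs)), t1 - t0
                    )
                    _param_rows(cid, rid, ci, p.as_dict(), rows)
            elif spec.kind in ("HS", "LS"):
                for ci, sl in enumerate(slice_cycles(x, spec.fs, cyc)):
                    p = td.sound_cycle_params(sl, spec.fs, kind=spec.kind)
                    _param_rows(cid, rid, ci, p.as_dict(), rows)
            else:  # pulse channels: PPS, PPG, BODWS
                for ci, sl in enumerate(slice_cycles(x, spec.fs, cyc)):
                    p = td.pulse_cycle_params(sl, spec.fs)
                    _param_rows(cid, rid, ci, p.as_dict(), rows)

    param_table = pd.DataFrame(
        rows, columns=["channel_id", "rmps", "cycle_index", "parameter", "value"]
    )

    result = AnalysisResult(partition=partition, param_table=param_table, hr_bpm=hr_bpm)

    # oscillometric blood pressure from the two deflations
    for rid, sites in _DEFLATION_SITES.items():
        if rid not in rec.rmps_windows:
            continue
        for site in sites:
            cuff_id, pps_id = f"cuff_{site}", f"pps_{site}"
            if cuff_id not in rec.channel_ids or pps_id not in rec.channel_ids:
                continue
            try:
                result.bp[f"{site}@rmps{rid}"] = td.oscillometric_bp(
                    rec.get(cuff_id)[1], smoothed.get(pps_id, rec.get(pps_id)[1]),
                    400.0, partition, rid, site=site,
                )
            except ValueError as exc:
                logger.warning("BP at %s (RMPS%d) skipped: %s", site, rid, exc)

    # per-cycle RWMACR times during the no-pressure phase -> PWV
    h = height_cm if height_cm is not None else rec.subject.get("height_H")

    def rwmacr_times(cid: str, rid: int = 1) -> np.ndarray | None:
        t = param_table
        sel = t[(t["channel_id"] == cid) & (t["rmps"] == rid)
                & (t["parameter"] == "t_to_maxslope")]
        return sel["value"].to_numpy() if len(sel) else None

    if h is not None:
        for side in ("L", "R"):
            for site, length in (("ankle", td.heart_to_ankle_cm(h)),
                                 ("arm", td.heart_to_arm_cm(h))):
                times = rwmacr_times(f"pps_{site}_{side}")
                if times is not None and len(times):
                    result.pwv[f"heart_to_{site}_{side}"] = td.pwv(
                        None, times, length, "heart", f"{site}_{side}"
                    )

    # SpO2 per extremity from the no-pressure phase
    cyc1 = partition.cycles(1)
    for ext in ("finger_L", "finger_R", "toe_L", "toe_R"):
        id660, id940 = f"bodws_{ext}_660", f"bodws_{ext}_940"
        if id660 in smoothed and id940 in smoothed and cyc1:
            rvals = r_value_per_cycle(smoothed[id660], smoothed[id940], cyc1, 400.0)
            if rvals:
                result.spo2[ext] = float(spo2_from_r(float(np.mean(rvals))))

    # blood-oxygen change-rate trends during the flow-blocking holds
    for rid in (4, 7):
        if rid not in rec.rmps_windows:
            continue
        for ext in ("finger_L", "finger_R", "toe_L", "toe_R"):
            id660, id940 = f"bodws_{ext}_660", f"bodws_{ext}_940"
            if id660 in smoothed and id940 in smoothed:
                result.bodws[f"{ext}@rmps{rid}"] = td.bodws_trend(
                    smoothed[id660], smoothed[id940], 400.0, partition,
                    rid, rec.rmps_windows[rid], cyc1, smooth=False,
                )

    if len(param_table):
        result.lr_ratios = td.left_right_ratios(param_table)

    if compute_bands:
        for spec, _ in rec.channels:
            cid = spec.channel_id
            if cid not in wanted or spec.kind == "CUFF_PRESSURE":
                continue
            x = smoothed[cid]
            for rid in rmps_ids:
                t0, t1 = rec.rmps_windows[rid]
                hr = hr_bpm.get(rid, math.nan)
                if math.isnan(hr):
                    continue
                seg = x[int(t0 * spec.fs) : int(t1 * spec.fs)]
                if len(seg) < 4 * spec.fs:
                    continue
                fftd = spectrum(seg, spec.fs)
                result.bands[(cid, rid)] = band_stats(
                    fftd, hr / 60.0, spec.fs, len(seg)
                )
    return result
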