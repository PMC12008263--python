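"""Recording container I/O and report generation.

A recording is a directory with one two-column CSV per channel
(``sample_index,value``) plus a ``recording.json`` sidecar carrying the
schema version, channel table (id, kind, site, side, wavelength, fs,
units), the protocol-phase windows in seconds (0-based, half-open), the
seed and subject metadata.  Values are written with 17 significant
digits, so a write/read round-trip is bit-exact for float64.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .simulator import ChannelSpec, MultiChannelRecording

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

__all__ = ["write_recording", "read_recording", "write_report"]


def write_recording(rec: MultiChannelRecording, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "total_duration_s": rec.total_duration,
        "seed": rec.seed,
        "subject": rec.subject,
        "rmps_windows": {str(k): list(v) for k, v in rec.rmps_windows.items()},
        "channels": [],
    }
    for spec, x in rec.channels:
        fname = f"{spec.channel_id}.csv"
        sidecar["channels"].append(
            {
                "channel_id": spec.channel_id,
                "kind": spec.kind,
                "site": spec.site,
                "side": spec.side,
                "wavelength": spec.wavelength,
                "fs": spec.fs,
                "file": fname,
                "n_samples": int(len(x)),
            }
        )
        arr = np.asarray(x, dtype=float)
        with open(path / fname, "w") as fh:
            fh.write("sample_index,value\n")
            # shortest repr that round-trips float64 exactly
            for i, v in enumerate(arr.tolist()):
                fh.write(f"{i},{v!r}\n")
    with open(path / "recording.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return path


def read_recording(path) -> MultiChannelRecording:
    path = Path(path)
    sidecar_path = path / "recording.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"no recording.json sidecar in {path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    if sidecar.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"schema version mismatch: expected {SCHEMA_VERSION!r}, "
            f"got {sidecar.get('schema_version')!r}"
        )
    channels = []
    for ch in sidecar["channels"]:
        fpath = path / ch["file"]
        if not fpath.exists():
            raise FileNotFoundError(
                f"sidecar lists channel {ch['channel_id']!r} but {ch['file']} is missing"
            )
        df = pd.read_csv(fpath, float_precision="round_trip")
        x = df["value"].to_numpy(dtype=float)
        if len(x) != ch["n_samples"]:
            raise ValueError(
                f"channel {ch['channel_id']!r}: expected {ch['n_samples']} samples, "
                f"file has {len(x)}"
            )
        spec = ChannelSpec(
            channel_id=ch["channel_id"], kind=ch["kind"], site=ch["site"],
            side=ch["side"],
            wavelength=ch["wavelength"] if ch["wavelength"] else None,
            fs=float(ch["fs"]),
        )
        channels.append((spec, x))
    return MultiChannelRecording(
        channels=channels,
        rmps_windows={int(k): tuple(v) for k, v in sidecar["rmps_windows"].items()},
        total_duration=float(sidecar["total_duration_s"]),
        seed=int(sidecar.get("seed", 0)),
        subject=sidecar.get("subject", {}),
    )


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "flagged"
    return f"{v:.4g}"


def write_report(result, path) -> Path:
    """Write machine-readable (CSV/JSON) and human-readable report files.

    ``result`` is a :class:`cuffwave.pipeline.AnalysisResult`.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    result.param_table.to_csv(path / "parameters.csv", index=False)
    summary = result.summary()
    with open(path / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)

    lines = ["Cardiovascular analysis summary", "=" * 32]
    lines.append(f"heart rate (bpm): {_fmt(summary.get('heart_rate_bpm'))}")
    lines.append(f"mean t_QS (s): {_fmt(summary.get('t_qs_mean_s'))}")
    lines.append(f"mean S1/S2 amplitude ratio: {_fmt(summary.get('s1_s2_ratio_mean'))}")
    for site, bp in summary.get("blood_pressure", {}).items():
        lines.append(
            f"BP {site}: {_fmt(bp['systolic'])}/{_fmt(bp['diastolic'])} mmHg "
            f"(MPAP {_fmt(bp['mpap'])})"
        )
    for name, p in summary.get("pwv", {}).items():
        lines.append(f"PWV {name}: {_fmt(p['pwv_m_s'])} m/s over {_fmt(p['length_cm'])} cm")
    for ext, s in summary.get("spo2", {}).items():
        lines.append(f"SpO2 {ext}: {_fmt(s)} %")
    for key, tr in summary.get("bodws", {}).items():
        lines.append(f"ROS {key}: {_fmt(tr['ros'])}  NROS {key}: {_fmt(tr['nros'])}")
    (path / "summary.txt").write_text("\n".join(lines) + "\n")
    return path
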