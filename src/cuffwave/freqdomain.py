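"""Harmonic-band spectral statistics per channel per protocol phase.

Each analyzable channel is Fourier-transformed over one protocol phase
(no zero-padding, mean removed) and summarized within narrow bands
around the first ten harmonics of the heart rate:

* AveF_n — mean magnitude within harmonic band n,
* MaxF_n — maximum magnitude within the band,
* RAMF_n — AveF_n / MaxF_n (1 iff the band is flat),
* RMMF_k — MaxF_k / MaxF_1 for k = 2..10.

Band n spans bins Round((n-0.2)*HR/FN) .. Round((n+0.2)*HR/FN)
inclusive, with FN = fs/N the bin width in Hz and HR the phase's heart
rate in Hz (from the accepted cycles).  Round is half-away-from-zero.
A strict-literal mode multiplying by FN instead of dividing (the
dimensionally inconsistent printed form) is retained for audit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SpectrumBandStats",
    "spectrum",
    "harmonic_band",
    "band_stats",
    "round_half_away",
]


def round_half_away(x: float) -> int:
    """Round half away from zero (3.5 -> 4, -3.5 -> -4)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def spectrum(x: np.ndarray, fs: float) -> np.ndarray:
    """One-sided magnitude spectrum of the mean-removed window.

    The transform length equals the window length (no zero-padding);
    index m corresponds to frequency m * fs / N for m = 0..N//2.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 4 * fs:
        raise ValueError(f"need >= 4 s of data for a spectrum (got {len(x)/fs:.2f} s)")
    return np.abs(np.fft.rfft(x - np.mean(x)))


def harmonic_band(
    n: int, hr_hz: float, fn: float, n_bins: int | None = None,
    half_width: float = 0.2, mode: str = "ratio",
) -> tuple[int, int]:
    """Inclusive bin-index range of harmonic band n.

    ``mode="ratio"`` (default) uses bin = Round((n +- 0.2) * HR / FN);
    ``mode="literal"`` preserves the printed multiplication by FN.
    """
    if fn <= 0:
        raise ValueError(f"FN must be > 0 (got {fn})")
    if hr_hz <= 0:
        raise ValueError(f"HR must be > 0 Hz (got {hr_hz})")
    if not 1 <= n <= 10:
        raise ValueError(f"harmonic index n must be in 1..10 (got {n})")
    scale = hr_hz * fn if mode == "literal" else hr_hz / fn
    lo = round_half_away((n - half_width) * scale)
    hi = round_half_away((n + half_width) * scale)
    if n_bins is not None and hi >= n_bins:
        logger.warning("harmonic band %d truncated to spectrum length %d", n, n_bins)
        hi = n_bins - 1
    return lo, hi


@dataclass
class SpectrumBandStats:
    hr_hz: float
    fn: float
    n_fft: int
    ave_f: dict  # n -> AveF
    max_f: dict  # n -> MaxF
    ramf: dict  # n -> AveF/MaxF
    rmmf: dict  # k (2..10) -> MaxF_k / MaxF_1
    bands: dict  # n -> (lo, hi) inclusive bin range
    flags: list = field(default_factory=list)


def band_stats(
    fftd: np.ndarray, hr_hz: float, fs: float, n_fft: int,
    harmonics: range = range(1, 11), mode: str = "ratio",
) -> SpectrumBandStats:
    """AveF/MaxF/RAMF per harmonic band and RMMF_k relative to band 1."""
    fftd = np.asarray(fftd, dtype=float)
    fn = fs / n_fft
    ave, mx, ramf, bands = {}, {}, {}, {}
    flags: list[str] = []
    for n in harmonics:
        lo, hi = harmonic_band(n, hr_hz, fn, n_bins=len(fftd), mode=mode)
        bands[n] = (lo, hi)
        if hi < lo or lo >= len(fftd) or lo < 0:
            flags.append(f"empty_band_{n}")
            ave[n] = mx[n] = ramf[n] = math.nan
            continue
        seg = fftd[lo : hi + 1]
        ave[n] = float(np.mean(seg))
        mx[n] = float(np.max(seg))
        ramf[n] = ave[n] / mx[n] if mx[n] > 0 else math.nan
    rmmf = {}
    m1 = mx.get(1, math.nan)
    for k in harmonics:
        if k == 1:
            continue
        rmmf[k] = mx[k] / m1 if (m1 and not math.isnan(m1) and m1 > 0) else math.nan
    return SpectrumBandStats(
        hr_hz=hr_hz, fn=fn, n_fft=n_fft,
        ave_f=ave, max_f=mx, ramf=ramf, rmmf=rmmf, bands=bands, flags=flags,
    )
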