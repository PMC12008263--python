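import numpy as np
import pytest
from hypothesis import settings

import cuffwave as cw

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")
from cuffwave.protocol import ProtocolConfig, build_default_protocol


@pytest.fixture(scope="session")
def default_schedule():
    return build_default_protocol()


@pytest.fixture(scope="session")
def short_schedule():
    """A compressed schedule for I/O and structural tests."""
    return build_default_protocol(
        ProtocolConfig(durations=(6.0, 14.0, 5.0, 6.0, 14.0, 5.0, 6.0), rest_interval=3.0)
    )


@pytest.fixture(scope="session")
def default_recording():
    """One full-protocol 27-channel recording, analyzed once per session."""
    profile = cw.SubjectProfile(seed=1)
    return cw.simulate_recording(profile)


@pytest.fixture(scope="session")
def default_analysis(default_recording):
    return cw.analyze_recording(default_recording)


def synthetic_deflation(center_mmhg, fs=400.0, duration=80.0, hr_bpm=70.0,
                        p0=180.0, vent_rate=1.25, width=20.0, noise_sd=0.0, seed=0):
    """Deflating cuff pressure + pulses whose amplitude peaks at ``center_mmhg``."""
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    t = np.arange(n) / fs
    pressure = np.maximum(p0 - vent_rate * t, 20.0)
    pulse = np.zeros(n)
    rr = 60.0 / hr_bpm
    beat = 0.3
    while beat + rr < duration:
        i0, i1 = int(beat * fs), int((beat + rr) * fs)
        tt = t[i0:i1] - beat
        amp = np.exp(-0.5 * ((pressure[i0] - center_mmhg) / width) ** 2)
        pulse[i0:i1] += amp * np.sin(np.pi * tt / rr) ** 2
        beat += rr
    if noise_sd > 0:
        pulse = pulse + rng.normal(0.0, noise_sd, n)
    return pressure, pulse


def cycle_rule_oracle(rr_list):
    """Verbatim accept/reject rule: sort RR ascending, trim ceil(N/4) per
    end, base = mean of the rest, accept iff 0.7*base <= rr <= 1.6*base."""
    import math

    rr = sorted(rr_list)
    n = len(rr)
    trim = math.ceil(n / 4)
    mid = rr[trim : n - trim] or rr
    base = sum(mid) / len(mid)
    return [0.7 * base <= v <= 1.6 * base for v in rr_list], base
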