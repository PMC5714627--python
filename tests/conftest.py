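import numpy as np
import pytest

from surro4d.waveform_io import SurrogateLabel, SurrogateTrace


def make_trace(
    times,
    amplitudes,
    beam_on=None,
    label=SurrogateLabel.OTHER,
    rate=30.0,
    phase=None,
):
    times = np.asarray(times, dtype=float)
    if beam_on is None:
        beam_on = np.ones(len(times), dtype=bool)
    return SurrogateTrace(
        label=label,
        times=times,
        amplitudes=np.asarray(amplitudes, dtype=float),
        beam_on=np.asarray(beam_on, dtype=bool),
        nominal_rate=rate,
        phase=phase,
    )


def sine_trace(duration_s=60.0, period_s=4.0, rate_hz=30.0, amplitude=1.0, clip=None):
    t = np.arange(0.0, duration_s, 1.0 / rate_hz)
    a = amplitude * np.sin(2 * np.pi * t / period_s)
    if clip is not None:
        a = np.minimum(a, clip)
    return make_trace(t, a, rate=rate_hz)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
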