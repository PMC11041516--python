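import numpy as np
import pytest

from breathradar import synth


def make_spec(
    duration=60.0,
    rate=15.0,
    amplitude=5.0,
    noise_sd=0.0,
    jitter_cv=0.0,
    seed=0,
    sample_rate=20.0,
):
    """Single-segment breathing scenario with everything else quiet."""
    return synth.ScenarioSpec(
        segments=(
            synth.BreathingSegment(
                duration=duration, kind="breathing", rate=rate, amplitude=amplitude
            ),
        ),
        noise_sd=noise_sd,
        period_jitter_cv=jitter_cv,
        seed=seed,
        sample_rate=sample_rate,
    )


def analytic_extrema(rate, duration):
    """Closed-form extremum times of the jitter-free raised-cosine waveform.

    Returns (maxima_times, minima_times): distance maxima at multiples of the
    period (cycle boundaries), minima at the half-cycle points.
    """
    period = 60.0 / rate
    maxima = np.arange(0.0, duration + 1e-9, period)
    minima = np.arange(period / 2.0, duration + 1e-9, period)
    return maxima, minima


@pytest.fixture
def clean_trace():
    spec = make_spec()
    return synth.generate_radar_trace(spec)
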