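"""Synthetic chest-distance and reference-belt signal generation.

The simulator abstracts the radar sensor to a one-dimensional chest-distance
signal (millimetres, larger = chest farther from the sensor, i.e. exhaling).
Breathing is modelled as a raised-cosine displacement per cycle with optional
per-cycle period jitter; breath-holds and apnea clamp the signal at its
current value; large postural motions are smooth baseline steps with a burst
of extra noise. Every scenario carries its own ground truth so downstream
components can be tested without recorded data.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from .errors import EmptyTraceError, InvalidScenarioError, UnknownPresetError

SEGMENT_KINDS = ("breathing", "breath_hold", "apnea", "motion_transient")

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class RadarTrace:
    """Uniformly sampled chest distance in millimetres."""

    start_time: float
    sample_interval: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.sample_interval <= 0:
            raise InvalidScenarioError("sample_interval must be positive")
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise InvalidScenarioError("samples must be one-dimensional")
        if samples.size and not np.all(np.isfinite(samples)):
            raise InvalidScenarioError("samples must be finite")
        object.__setattr__(self, "samples", samples)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) * self.sample_interval

    @property
    def duration(self) -> float:
        if self.samples.size == 0:
            return 0.0
        return (self.samples.size - 1) * self.sample_interval

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class BeltTrace(RadarTrace):
    """Uniformly sampled chest-wall force in arbitrary force units.

    Shares the timebase contract of :class:`RadarTrace`; the value axis is
    force, maximal at full chest expansion (radar distance minima).
    """


@dataclass(frozen=True)
class BreathingSegment:
    """One piecewise element of a scenario.

    ``shift`` is only meaningful for ``motion_transient`` segments: the signed
    baseline displacement (mm) accumulated over the segment.
    """

    duration: float
    kind: str = "breathing"
    rate: float = 0.0
    amplitude: float = 0.0
    shift: float = 100.0

    def validate(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise InvalidScenarioError(f"unknown segment kind {self.kind!r}")
        if self.duration <= 0:
            raise InvalidScenarioError("segment duration must be positive")
        if self.amplitude < 0:
            raise InvalidScenarioError("amplitude must be non-negative")
        if self.kind == "breathing" and self.rate <= 0:
            raise InvalidScenarioError("breathing segments need rate > 0")
        if self.kind in ("breath_hold", "apnea") and self.amplitude != 0.0:
            raise InvalidScenarioError(f"{self.kind} segments must have amplitude 0")


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of a simulated recording, including all randomness."""

    segments: tuple[BreathingSegment, ...]
    baseline_distance: float = 1000.0
    noise_sd: float = 0.25
    drift_rate: float = 0.0
    seed: int = 0
    sample_rate: float = 20.0
    period_jitter_cv: float = 0.05
    motion_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def total_duration(self) -> float:
        return float(sum(seg.duration for seg in self.segments))

    def validate(self) -> None:
        if not self.segments:
            raise InvalidScenarioError("scenario needs at least one segment")
        for seg in self.segments:
            seg.validate()
        if self.noise_sd < 0 or self.motion_noise_sd < 0:
            raise InvalidScenarioError("noise_sd must be non-negative")
        if self.sample_rate <= 0:
            raise InvalidScenarioError("sample_rate must be positive")
        if self.period_jitter_cv < 0:
            raise InvalidScenarioError("period_jitter_cv must be non-negative")

    def to_json(self) -> str:
        payload = asdict(self)
        payload["segments"] = [asdict(s) for s in self.segments]
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioSpec":
        payload = json.loads(text)
        segments = tuple(BreathingSegment(**s) for s in payload.pop("segments"))
        return cls(segments=segments, **payload)


@dataclass(frozen=True)
class SegmentTruth:
    start: float
    end: float
    kind: str
    rate: float
    amplitude: float


@dataclass(frozen=True)
class GroundTruth:
    """Programmed truth recorded during generation; the oracle for tests.

    ``cycle_boundaries`` are the exact times (not sample-quantised) at which a
    breathing cycle completes, i.e. the exhale-end distance maxima of the
    noise-free waveform.
    """

    cycle_boundaries: np.ndarray
    motion_intervals: tuple[tuple[float, float], ...]
    hold_intervals: tuple[tuple[float, float], ...]
    segments: tuple[SegmentTruth, ...]

    def rate_at(self, time: float) -> float:
        """Programmed instantaneous rate (bpm); 0 outside breathing segments."""
        for seg in self.segments:
            if seg.start <= time < seg.end and seg.kind == "breathing":
                return seg.rate
        return 0.0

    @property
    def cycle_periods(self) -> np.ndarray:
        return np.diff(self.cycle_boundaries)

    def to_json(self) -> str:
        return json.dumps(
            {
                "cycle_boundaries": list(map(float, self.cycle_boundaries)),
                "motion_intervals": [list(iv) for iv in self.motion_intervals],
                "hold_intervals": [list(iv) for iv in self.hold_intervals],
                "segments": [asdict(s) for s in self.segments],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        return cls(
            cycle_boundaries=np.asarray(payload["cycle_boundaries"], dtype=float),
            motion_intervals=tuple(tuple(iv) for iv in payload["motion_intervals"]),
            hold_intervals=tuple(tuple(iv) for iv in payload["hold_intervals"]),
            segments=tuple(SegmentTruth(**s) for s in payload["segments"]),
        )


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def generate_radar_trace(spec: ScenarioSpec) -> tuple[RadarTrace, GroundTruth]:
    """Render a scenario into a radar distance trace plus its ground truth.

    The waveform is phase-continuous across segments: holds and motion
    transients freeze the breathing phase, and breathing resumes from the
    frozen phase. A breathing cycle spans phase ``2*pi``; distance maxima
    (exhale end) sit at phase multiples of ``2*pi`` and the inhale minimum at
    the half-cycle point.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.sample_rate
    total = spec.total_duration
    n = int(round(total / dt)) + 1
    t = np.arange(n) * dt

    knot_t: list[float] = [0.0]
    knot_phi: list[float] = [0.0]
    boundaries: list[float] = []
    motion_iv: list[tuple[float, float]] = []
    hold_iv: list[tuple[float, float]] = []
    seg_truth: list[SegmentTruth] = []

    # piecewise-constant arrays built per segment
    amp_steps: list[tuple[float, float]] = []  # (segment start, amplitude)
    baseline = np.zeros(n)

    seg_start = 0.0
    phi = 0.0
    carried_amp = 0.0
    accumulated_shift = 0.0
    for seg in spec.segments:
        seg_end = seg_start + seg.duration
        seg_truth.append(
            SegmentTruth(seg_start, seg_end, seg.kind,
                         seg.rate if seg.kind == "breathing" else 0.0,
                         seg.amplitude if seg.kind == "breathing" else carried_amp)
        )
        if seg.kind == "breathing":
            carried_amp = seg.amplitude
            amp_steps.append((seg_start, seg.amplitude))
            nominal = 60.0 / seg.rate
            tcur = seg_start
            frac = phi % _TWO_PI
            on_boundary = frac < 1e-9 or _TWO_PI - frac < 1e-9
            if on_boundary:
                phi = _TWO_PI * round(phi / _TWO_PI)  # snap off float drift
                if not boundaries or boundaries[-1] < tcur - 1e-9:
                    boundaries.append(tcur)
            while True:
                frac = phi % _TWO_PI
                on_boundary = frac < 1e-9 or _TWO_PI - frac < 1e-9
                rem_phase = _TWO_PI if on_boundary else _TWO_PI - frac
                jitter = 1.0 + spec.period_jitter_cv * rng.standard_normal()
                period = nominal * max(0.2, jitter)
                t_next = tcur + rem_phase / _TWO_PI * period
                if t_next <= seg_end + 1e-12:
                    phi = _TWO_PI * round((phi + rem_phase) / _TWO_PI)
                    knot_t.append(t_next)
                    knot_phi.append(phi)
                    boundaries.append(t_next)
                    tcur = t_next
                else:
                    phi += (seg_end - tcur) / period * _TWO_PI
                    knot_t.append(seg_end)
                    knot_phi.append(phi)
                    break
        else:
            amp_steps.append((seg_start, carried_amp))
            knot_t.append(seg_end)
            knot_phi.append(phi)
            if seg.kind in ("breath_hold", "apnea"):
                hold_iv.append((seg_start, seg_end))
            else:  # motion_transient
                motion_iv.append((seg_start, seg_end))
                ramp = min(1.5, seg.duration)
                mask = (t >= seg_start) & (t <= seg_end + 1e-12)
                u = (t[mask] - seg_start) / ramp
                baseline[mask] = accumulated_shift + seg.shift * _smoothstep(u)
                accumulated_shift += seg.shift
                after = t > seg_end + 1e-12
                baseline[after] = accumulated_shift
        seg_start = seg_end

    # evaluate the piecewise waveform on the sample grid
    phi_arr = np.interp(t, knot_t, knot_phi)
    step_times = np.array([s for s, _ in amp_steps])
    step_amps = np.array([a for _, a in amp_steps])
    idx = np.searchsorted(step_times, t, side="right") - 1
    idx = np.clip(idx, 0, len(step_amps) - 1)
    amp_arr = step_amps[idx]

    x = (
        spec.baseline_distance
        + spec.drift_rate * t
        + baseline
        - 0.5 * amp_arr * (1.0 - np.cos(phi_arr))
    )
    if spec.noise_sd > 0:
        x = x + rng.normal(0.0, spec.noise_sd, n)
    if spec.motion_noise_sd > 0 and motion_iv:
        for s, e in motion_iv:
            mask = (t >= s) & (t <= e + 1e-12)
            x[mask] += rng.normal(0.0, spec.motion_noise_sd, int(mask.sum()))

    truth = GroundTruth(
        cycle_boundaries=np.asarray(boundaries, dtype=float),
        motion_intervals=tuple(motion_iv),
        hold_intervals=tuple(hold_iv),
        segments=tuple(seg_truth),
    )
    return RadarTrace(0.0, dt, x), truth


def derive_belt_trace(
    radar: RadarTrace,
    truth: GroundTruth | None = None,
    gain: float = 1.0,
    lag: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> BeltTrace:
    """Build a coupled strain-belt force trace from a radar distance trace.

    The belt responds to chest expansion, so force is maximal where radar
    distance is minimal; ``lag`` delays the belt response. With ``lag`` 0 and
    no noise the belt is an exact inverted copy, which preserves the per-cycle
    period sequence.
    """
    if len(radar) == 0:
        raise EmptyTraceError("cannot derive a belt trace from an empty radar trace")
    if gain <= 0:
        raise InvalidScenarioError("gain must be positive")
    rng = np.random.default_rng(seed)
    t = radar.times
    shifted = np.interp(t - lag, t, radar.samples)
    ref = float(np.max(radar.samples))
    samples = gain * (ref - shifted)
    if noise_sd > 0:
        samples = samples + rng.normal(0.0, noise_sd, samples.size)
    return BeltTrace(radar.start_time, radar.sample_interval, samples)


def _breathing(duration: float, rate: float, amplitude: float = 5.0) -> BreathingSegment:
    return BreathingSegment(duration=duration, kind="breathing", rate=rate,
                            amplitude=amplitude)


def preset_scenario(name: str, seed: int = 0) -> ScenarioSpec:
    """Return one of the documented scenario presets.

    ``respiration_validation``
        ~5 s of comfortable breathing, a 3 s breath-hold used as the
        synchronisation event, then continued breathing.
    ``position_tuning``
        Breathing held constant at 15 bpm.
    ``overdose_simulation``
        Five 30 s comfortable-breathing blocks separated by four large slump
        motion transients.
    ``oird_decline``
        Rate ramping from normal to below 8 bpm, then apnea.
    ``cessation``
        Comfortable breathing followed by a long apnea.
    """
    presets = {
        "respiration_validation": dict(
            segments=(
                _breathing(5.0, 15.0),
                BreathingSegment(duration=3.0, kind="breath_hold"),
                _breathing(30.0, 15.0),
            ),
        ),
        # metronome-paced protocol: near-constant period
        "position_tuning": dict(
            segments=(_breathing(60.0, 15.0),),
            period_jitter_cv=0.01,
        ),
        "overdose_simulation": dict(
            segments=(
                _breathing(30.0, 12.0),
                BreathingSegment(duration=3.0, kind="motion_transient", shift=100.0),
                _breathing(30.0, 13.0),
                BreathingSegment(duration=3.0, kind="motion_transient", shift=-100.0),
                _breathing(30.0, 12.0),
                BreathingSegment(duration=3.0, kind="motion_transient", shift=80.0),
                _breathing(30.0, 14.0),
                BreathingSegment(duration=3.0, kind="motion_transient", shift=-80.0),
                _breathing(30.0, 12.0),
            ),
        ),
        "oird_decline": dict(
            segments=(
                _breathing(30.0, 15.0),
                _breathing(20.0, 12.0),
                _breathing(20.0, 10.0),
                _breathing(30.0, 6.0),
                BreathingSegment(duration=30.0, kind="apnea"),
            ),
        ),
        "cessation": dict(
            # 29 s of 15 bpm ends mid-slope so the apnea onset is sharp
            segments=(
                _breathing(29.0, 15.0),
                BreathingSegment(duration=30.0, kind="apnea"),
            ),
            period_jitter_cv=0.02,
        ),
    }
    if name not in presets:
        raise UnknownPresetError(
            f"unknown preset {name!r}; choose from {sorted(presets)}"
        )
    return ScenarioSpec(seed=seed, **presets[name])


def preset_names() -> Sequence[str]:
    return (
        "respiration_validation",
        "position_tuning",
        "overdose_simulation",
        "oird_decline",
        "cessation",
    )
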