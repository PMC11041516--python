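"""Breath-cycle segmentation and respiration-rate estimation.

A breath cycle is one inhale plus one exhale, found from direction reversals
of the chest-distance signal: distance decreasing = inhale, increasing =
exhale. A reversal is committed only after the signal retraces at least
``min_excursion`` (0.75 mm by default) from the candidate extremum, which
makes the lower displacement bound double as noise hysteresis. Any phase
excursion beyond ``max_excursion`` (20 mm) is treated as body motion: cycle
emission stops, a MotionEvent is opened, and tracking recalibrates from
scratch ``motion_blank_time`` after the signal re-stabilises.

Cycles run exhale-end (local distance maximum) to the next exhale-end, with
the interior minimum as the inhale peak.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, EmptyTraceError
from .synth import RadarTrace

_STABILIZE_WINDOW = 1.0  # s of sub-gate peak-to-peak movement ending a motion event
_ACTIVITY_LAG = 0.5  # s lag used to score respiratory-scale movement


@dataclass(frozen=True)
class TrackerConfig:
    min_excursion: float = 0.75
    max_excursion: float = 20.0
    smoothing_cutoff: float = 1.0
    motion_blank_time: float = 2.0
    sample_interval: Optional[float] = None
    rate_interval: float = 0.25
    staleness_horizon: float = 15.0

    def validate(self) -> None:
        if not 0 < self.min_excursion < self.max_excursion:
            raise ConfigError("need 0 < min_excursion < max_excursion")
        if self.motion_blank_time < 0:
            raise ConfigError("motion_blank_time must be non-negative")
        if self.rate_interval <= 0:
            raise ConfigError("rate_interval must be positive")


@dataclass(frozen=True)
class BreathCycle:
    start_time: float
    end_time: float
    inhale_peak_time: float
    excursion: float

    @property
    def period(self) -> float:
        return self.end_time - self.start_time


@dataclass(frozen=True)
class RespirationEstimate:
    time: float
    rate: float
    source_cycle: Optional[BreathCycle]
    valid: bool


@dataclass(frozen=True)
class MotionEvent:
    start_time: float
    end_time: float
    magnitude: float


@dataclass(frozen=True)
class TrackingResult:
    cycles: tuple[BreathCycle, ...]
    rate_series: tuple[RespirationEstimate, ...]
    motion_events: tuple[MotionEvent, ...]
    activity_times: np.ndarray = None  # type: ignore[assignment]
    activity: np.ndarray = None  # type: ignore[assignment]
    evidence_time: np.ndarray = None  # type: ignore[assignment]


def preprocess(trace: RadarTrace, cfg: TrackerConfig = TrackerConfig()) -> RadarTrace:
    """Zero-phase low-pass the trace, preserving respiration-band content."""
    if len(trace) == 0:
        raise EmptyTraceError("cannot preprocess an empty trace")
    fs = 1.0 / trace.sample_interval
    nyq = 0.5 * fs
    if cfg.smoothing_cutoff is None or cfg.smoothing_cutoff >= nyq:
        return trace
    sos = sps.butter(4, cfg.smoothing_cutoff / nyq, btype="low", output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1 - min(1, 1))
    if len(trace) <= 3 * padlen:
        return trace
    filtered = sps.sosfiltfilt(sos, trace.samples)
    return replace(trace, samples=filtered)


def _check_sample_interval(trace: RadarTrace, cfg: TrackerConfig) -> None:
    if cfg.sample_interval is not None and not np.isclose(
        cfg.sample_interval, trace.sample_interval, rtol=1e-6, atol=1e-9
    ):
        raise ConfigError(
            f"config sample_interval {cfg.sample_interval} does not match "
            f"trace sample_interval {trace.sample_interval}"
        )


def _find_extrema_and_motion(
    t: np.ndarray, y: np.ndarray, cfg: TrackerConfig
) -> tuple[list[list[tuple[str, float, float]]], list[MotionEvent]]:
    """Scan the signal once, returning extrema per quiet block plus motion events.

    Each block is a list of committed ``(kind, time, value)`` extrema with
    kinds alternating between ``"max"`` and ``"min"``; blocks are separated by
    motion events (plus the blanking period after each).
    """
    dt = t[1] - t[0] if t.size > 1 else 0.0
    stab_k = max(1, int(round(_STABILIZE_WINDOW / dt))) if dt > 0 else 1

    blocks: list[list[tuple[str, float, float]]] = [[]]
    motions: list[MotionEvent] = []

    phase: Optional[str] = None  # None / "up" / "down"
    cand_min_v, cand_min_t = y[0], t[0]
    cand_max_v, cand_max_t = y[0], t[0]
    last_committed_v: Optional[float] = None
    in_motion = False
    motion_start = 0.0
    m_lo = m_hi = 0.0
    resume_time: Optional[float] = None

    def reset_candidates(i: int) -> None:
        nonlocal cand_min_v, cand_min_t, cand_max_v, cand_max_t, phase, last_committed_v
        cand_min_v = cand_max_v = y[i]
        cand_min_t = cand_max_t = t[i]
        phase = None
        last_committed_v = None

    i = 0
    n = y.size
    while i < n:
        ti, yi = t[i], y[i]
        if resume_time is not None:
            if ti < resume_time:
                i += 1
                continue
            resume_time = None
            reset_candidates(i)
            i += 1
            continue
        if in_motion:
            m_lo = min(m_lo, yi)
            m_hi = max(m_hi, yi)
            j0 = max(0, i - stab_k + 1)
            window = y[j0 : i + 1]
            if (
                ti - motion_start >= _STABILIZE_WINDOW
                and window.max() - window.min() <= cfg.max_excursion
            ):
                in_motion = False
                motions.append(MotionEvent(motion_start, ti, m_hi - m_lo))
                blocks.append([])
                resume_time = ti + cfg.motion_blank_time
            i += 1
            continue

        # motion gate: excursion of the current phase beyond max_excursion
        ref = last_committed_v
        if ref is None:
            gate = max(cand_max_v, yi) - min(cand_min_v, yi) > cfg.max_excursion
        elif phase == "up":
            gate = yi - ref > cfg.max_excursion
        else:
            gate = ref - yi > cfg.max_excursion
        if gate:
            in_motion = True
            motion_start = ti
            m_lo = min(cand_min_v, yi)
            m_hi = max(cand_max_v, yi)
            i += 1
            continue

        if yi < cand_min_v:
            cand_min_v, cand_min_t = yi, ti
        if yi > cand_max_v:
            cand_max_v, cand_max_t = yi, ti

        if phase is None:
            if yi >= cand_min_v + cfg.min_excursion:
                blocks[-1].append(("min", cand_min_t, cand_min_v))
                last_committed_v = cand_min_v
                phase = "up"
                cand_max_v, cand_max_t = yi, ti
            elif yi <= cand_max_v - cfg.min_excursion:
                blocks[-1].append(("max", cand_max_t, cand_max_v))
                last_committed_v = cand_max_v
                phase = "down"
                cand_min_v, cand_min_t = yi, ti
        elif phase == "up":
            if yi <= cand_max_v - cfg.min_excursion:
                blocks[-1].append(("max", cand_max_t, cand_max_v))
                last_committed_v = cand_max_v
                phase = "down"
                cand_min_v, cand_min_t = yi, ti
        else:  # "down"
            if yi >= cand_min_v + cfg.min_excursion:
                blocks[-1].append(("min", cand_min_t, cand_min_v))
                last_committed_v = cand_min_v
                phase = "up"
                cand_max_v, cand_max_t = yi, ti

        i += 1

    if in_motion:
        motions.append(MotionEvent(motion_start, t[-1], m_hi - m_lo))
    return blocks, motions


def segment_breaths(trace: RadarTrace, cfg: TrackerConfig = TrackerConfig()) -> TrackingResult:
    """Segment a trace into breath cycles, rejecting large body motions."""
    cfg.validate()
    if len(trace) == 0:
        raise EmptyTraceError("cannot segment an empty trace")
    _check_sample_interval(trace, cfg)
    t = trace.times
    y = trace.samples
    blocks, motions = _find_extrema_and_motion(t, y, cfg)

    cycles: list[BreathCycle] = []
    for block in blocks:
        for j in range(len(block) - 2):
            k0, t0, v0 = block[j]
            k1, t1_, v1 = block[j + 1]
            k2, t2, v2 = block[j + 2]
            if (k0, k1, k2) == ("max", "min", "max"):
                excursion = 0.5 * ((v0 - v1) + (v2 - v1))
                cycles.append(BreathCycle(t0, t2, t1_, excursion))
    return TrackingResult(
        cycles=tuple(cycles),
        rate_series=(),
        motion_events=tuple(motions),
        activity_times=np.empty(0),
        activity=np.empty(0, dtype=bool),
        evidence_time=np.empty(0),
    )


def estimate_rate(
    cycles,
    at_time: float,
    staleness_horizon: float = 15.0,
) -> RespirationEstimate:
    """Rate from the most recent completed cycle at or before ``at_time``."""
    best = None
    for c in cycles:
        if c.end_time <= at_time and (best is None or c.end_time > best.end_time):
            best = c
    if best is None or at_time - best.end_time > staleness_horizon:
        return RespirationEstimate(at_time, float("nan"), None, False)
    return RespirationEstimate(at_time, 60.0 / best.period, best, True)


def track(trace: RadarTrace, cfg: TrackerConfig = TrackerConfig()) -> TrackingResult:
    """Preprocess, segment, and attach a sampled rate series and activity flags."""
    if len(trace) == 0:
        raise EmptyTraceError("cannot track an empty trace")
    cfg.validate()
    _check_sample_interval(trace, cfg)
    pre = preprocess(trace, cfg)
    res = segment_breaths(pre, cfg)

    t = pre.times
    y = pre.samples
    dt = trace.sample_interval
    # respiratory-scale movement: displacement over a short lag, attributed to
    # the lag midpoint so silence onsets are located to within half the lag;
    # the reduced threshold compensates for the short lag on slow breathing
    lag_k = max(1, int(round(_ACTIVITY_LAG / dt)))
    thr = 2.0 / 3.0 * cfg.min_excursion
    moving = np.zeros(y.size, dtype=bool)
    if y.size > lag_k:
        diff = np.abs(y[lag_k:] - y[:-lag_k]) >= thr
        half = lag_k // 2
        moving[lag_k - half : y.size - half] = diff

    end = t[-1]
    n_ticks = int(np.floor((end - trace.start_time) / cfg.rate_interval)) + 1
    tick_times = trace.start_time + np.arange(n_ticks) * cfg.rate_interval
    estimates = []
    activity = np.zeros(n_ticks, dtype=bool)
    evidence_time = np.full(n_ticks, np.nan)
    cycles_sorted = sorted(res.cycles, key=lambda c: c.end_time)
    prev_idx = 0
    for k, tk in enumerate(tick_times):
        estimates.append(estimate_rate(cycles_sorted, tk, cfg.staleness_horizon))
        idx = int(np.searchsorted(t, tk, side="right"))
        hits = np.flatnonzero(moving[prev_idx:idx])
        if hits.size:
            activity[k] = True
            evidence_time[k] = t[prev_idx + hits[-1]]
        prev_idx = idx
    return TrackingResult(
        cycles=res.cycles,
        rate_series=tuple(estimates),
        motion_events=res.motion_events,
        activity_times=tick_times,
        activity=activity,
        evidence_time=evidence_time,
    )
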