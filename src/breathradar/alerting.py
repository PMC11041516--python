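"""Overdose-detection state machine.

Two alarm conditions, evaluated on every step:

* low_rate — the estimated respiration rate stays below ``rate_threshold``
  (default 8 bpm) for ``sustain_time`` seconds (default 15), or
  ``sustain_breaths`` consecutive completed cycles (default 2) are each slower
  than the threshold; either condition suffices.
* cessation — no respiratory motion (no completed cycle and no
  respiration-scale movement) for ``cessation_time`` seconds (default 10).
  Large body motion pauses the silence clock rather than resetting it: a
  moving body is not a silent one, but movement is no evidence of breathing.

Alerts latch: once fired, no further events until an explicit ``reset``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from typing import Optional

from .errors import MonotonicTimeError
from .synth import RadarTrace
from .tracker import (
    BreathCycle,
    RespirationEstimate,
    TrackerConfig,
    TrackingResult,
    track,
)


@dataclass(frozen=True)
class AlertConfig:
    rate_threshold: float = 8.0
    sustain_time: float = 15.0
    sustain_breaths: float = 2
    cessation_time: float = 10.0

    def validate(self) -> None:
        if min(self.rate_threshold, self.sustain_time,
               self.sustain_breaths, self.cessation_time) <= 0:
            raise ValueError("all alert thresholds must be positive")

    @property
    def slow_period(self) -> float:
        """Cycle period above which a breath counts as slow."""
        return 60.0 / self.rate_threshold


@dataclass(frozen=True)
class AlertEvent:
    time: float
    kind: str  # "low_rate" | "cessation"
    triggering_rate: Optional[float]
    condition_duration: float


@dataclass(frozen=True)
class MonitorState:
    mode: str = "normal"  # normal | low_rate_pending | silent_pending | alerted
    condition_onset: Optional[float] = None
    slow_breath_count: int = 0
    last_cycle_end: Optional[float] = None
    # internal bookkeeping
    low_onset: Optional[float] = None
    slow_onset: Optional[float] = None
    silent_accum: float = 0.0
    prev_time: Optional[float] = None

    def reset(self) -> "MonitorState":
        """Re-arm after an alert; history is discarded."""
        return MonitorState()


@dataclass(frozen=True)
class AlertLog:
    events: tuple[AlertEvent, ...] = ()

    def append(self, event: AlertEvent) -> "AlertLog":
        return AlertLog(self.events + (event,))

    def __len__(self) -> int:
        return len(self.events)


def _mode(alerted: bool, low_onset, silent_accum) -> tuple[str, Optional[float]]:
    if alerted:
        return "alerted", None
    if low_onset is not None:
        return "low_rate_pending", low_onset
    if silent_accum > 0:
        return "silent_pending", None
    return "normal", None


def step(
    state: MonitorState,
    now: float,
    estimate: Optional[RespirationEstimate],
    new_cycle: Optional[BreathCycle],
    motion_active: bool,
    cfg: AlertConfig = AlertConfig(),
    breath_motion: Optional[bool] = None,
) -> tuple[MonitorState, Optional[AlertEvent]]:
    """Advance the monitor by one tick.

    ``breath_motion`` reports respiration-scale chest movement seen since the
    previous tick: ``True``/``False``, or a float giving the time the movement
    was observed (sharper silence-onset location). When unknown (None) only
    completed cycles count as evidence of breathing for the cessation clock.
    """
    if state.prev_time is not None and now < state.prev_time:
        raise MonotonicTimeError(f"time stepped back from {state.prev_time} to {now}")
    if state.mode == "alerted":
        return replace(state, prev_time=now), None

    dt = 0.0 if state.prev_time is None else now - state.prev_time

    low_onset = state.low_onset
    slow_count = state.slow_breath_count
    slow_onset = state.slow_onset
    silent_accum = state.silent_accum
    last_cycle_end = state.last_cycle_end

    # --- low-rate, sustained-window path ------------------------------------
    if estimate is not None and estimate.valid:
        if estimate.rate < cfg.rate_threshold:
            if low_onset is None:
                low_onset = now
        else:
            low_onset = None
    # invalid estimates neither start nor reset the window: a fading signal
    # must not defeat both triggers, the cessation path covers it

    # --- low-rate, consecutive-slow-breaths path ----------------------------
    if new_cycle is not None:
        last_cycle_end = new_cycle.end_time
        if new_cycle.period > cfg.slow_period:
            if slow_count == 0:
                slow_onset = new_cycle.start_time
            slow_count += 1
        else:
            slow_count = 0
            slow_onset = None

    # --- cessation path ------------------------------------------------------
    if isinstance(breath_motion, bool) or breath_motion is None:
        evidence = now if breath_motion else None
    else:
        evidence = float(breath_motion)
    if new_cycle is not None:
        evidence = max(evidence, new_cycle.end_time) if evidence is not None \
            else new_cycle.end_time
    if evidence is not None:
        silent_accum = max(0.0, now - evidence)
    elif motion_active:
        pass  # paused, not reset
    else:
        silent_accum += dt

    event: Optional[AlertEvent] = None
    if low_onset is not None and now - low_onset >= cfg.sustain_time:
        rate = estimate.rate if estimate is not None and estimate.valid else None
        event = AlertEvent(now, "low_rate", rate, now - low_onset)
    elif slow_count >= cfg.sustain_breaths:
        rate = 60.0 / new_cycle.period if new_cycle is not None else None
        onset = slow_onset if slow_onset is not None else now
        event = AlertEvent(now, "low_rate", rate, now - onset)
    elif silent_accum >= cfg.cessation_time:
        event = AlertEvent(now, "cessation", None, silent_accum)

    alerted = event is not None
    mode, onset = _mode(alerted, low_onset, silent_accum)
    new_state = MonitorState(
        mode=mode,
        condition_onset=onset,
        slow_breath_count=slow_count,
        last_cycle_end=last_cycle_end,
        low_onset=low_onset,
        slow_onset=slow_onset,
        silent_accum=silent_accum,
        prev_time=now,
    )
    return new_state, event


def monitor_result(
    result: TrackingResult,
    acfg: AlertConfig = AlertConfig(),
    tcfg: TrackerConfig = TrackerConfig(),
) -> AlertLog:
    """Fold :func:`step` over an existing tracking result."""
    acfg.validate()
    state = MonitorState()
    log = AlertLog()
    cycles = sorted(result.cycles, key=lambda c: c.end_time)
    ci = 0
    prev_tick = None
    for k, est in enumerate(result.rate_series):
        now = est.time
        new_cycle = None
        while ci < len(cycles) and cycles[ci].end_time <= now:
            if prev_tick is None or cycles[ci].end_time > prev_tick:
                new_cycle = cycles[ci]
            ci += 1
        motion_active = any(
            ev.start_time <= now <= ev.end_time + tcfg.motion_blank_time
            for ev in result.motion_events
        )
        if result.activity is None or not result.activity.size:
            breath_motion = None
        elif result.activity[k]:
            ev = result.evidence_time[k] if result.evidence_time is not None else None
            breath_motion = float(ev) if ev is not None and not np.isnan(ev) else True
        else:
            breath_motion = False
        state, event = step(state, now, est, new_cycle, motion_active, acfg,
                            breath_motion=breath_motion)
        if event is not None:
            log = log.append(event)
        prev_tick = now
    return log


def monitor(
    trace: RadarTrace,
    tcfg: TrackerConfig = TrackerConfig(),
    acfg: AlertConfig = AlertConfig(),
) -> AlertLog:
    """Track a trace and run the alert state machine over it."""
    return monitor_result(track(trace, tcfg), acfg, tcfg)
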