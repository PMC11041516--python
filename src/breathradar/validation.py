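"""Two-source agreement statistics: radar vs reference belt.

The protocol embeds a short breath-hold near the start of each recording;
both sources detect it independently and the onset difference gives the
clock offset. Per-cycle periods are then extracted from breath peaks in each
source, paired by nearest peak time, and differenced with sign retained
(radar minus belt), because a shifted single peak yields one positive and
one negative adjacent error that cancel in the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptyTraceError, InsufficientPeaksError, NoHoldFoundError
from .synth import BeltTrace, RadarTrace
from .tracker import TrackerConfig, _find_extrema_and_motion, preprocess


@dataclass(frozen=True)
class SyncResult:
    radar_hold_onset: float
    belt_hold_onset: float

    @property
    def offset(self) -> float:
        """Belt time minus radar time; subtract from belt times to co-register."""
        return self.belt_hold_onset - self.radar_hold_onset


@dataclass(frozen=True)
class PeriodErrorReport:
    paired_errors: np.ndarray
    pair_times: np.ndarray
    unmatched_radar: int
    unmatched_belt: int

    @property
    def n_cycles(self) -> int:
        return int(self.paired_errors.size)

    @property
    def mean_error(self) -> float:
        return float(np.mean(self.paired_errors)) if self.n_cycles else float("nan")

    @property
    def sd_error(self) -> float:
        if self.n_cycles < 2:
            return 0.0 if self.n_cycles == 1 else float("nan")
        return float(np.std(self.paired_errors, ddof=1))

    def to_dict(self) -> dict:
        return {
            "n_cycles": self.n_cycles,
            "mean_error_s": self.mean_error,
            "sd_error_s": self.sd_error,
            "unmatched_radar": self.unmatched_radar,
            "unmatched_belt": self.unmatched_belt,
        }


def detect_breath_hold(
    trace: RadarTrace,
    min_hold: float = 2.5,
    quiet_threshold: float | None = None,
    smooth: bool = True,
) -> tuple[float, float]:
    """First interval of length >= min_hold with excursion below threshold.

    ``quiet_threshold`` defaults to 15% of the trace's overall peak-to-peak
    excursion, which sits above sensor noise but well below breathing motion.
    Returns the maximal quiet interval ``(onset, end)`` in trace time.
    """
    if len(trace) == 0:
        raise EmptyTraceError("cannot search an empty trace for a breath-hold")
    y = preprocess(trace).samples if smooth else trace.samples
    t = trace.times
    dt = trace.sample_interval
    if quiet_threshold is None:
        quiet_threshold = 0.15 * float(np.max(y) - np.min(y))
    w = int(round(min_hold / dt)) + 1
    if w > y.size:
        raise NoHoldFoundError("trace shorter than the minimum hold duration")
    # peak-to-peak over forward-looking windows [i, i+w)
    hi = ndimage.maximum_filter1d(y, size=w, origin=-(w // 2))
    lo = ndimage.minimum_filter1d(y, size=w, origin=-(w // 2))
    valid = np.arange(y.size) + w <= y.size
    quiet = (hi - lo < quiet_threshold) & valid
    idx = np.flatnonzero(quiet)
    if idx.size == 0:
        raise NoHoldFoundError(
            f"no interval of {min_hold} s stays within {quiet_threshold:.3g}"
        )
    start = int(idx[0])
    # extend to the maximal quiet interval starting there
    end = start + w - 1
    lo_v, hi_v = float(y[start:end + 1].min()), float(y[start:end + 1].max())
    j = end + 1
    while j < y.size:
        lo_v = min(lo_v, float(y[j]))
        hi_v = max(hi_v, float(y[j]))
        if hi_v - lo_v >= quiet_threshold:
            break
        end = j
        j += 1
    return float(t[start]), float(t[end])


def align(
    radar: RadarTrace,
    belt: BeltTrace,
    min_hold: float = 2.5,
    quiet_threshold: float | None = None,
) -> SyncResult:
    """Co-register the two sources on their breath-hold onsets."""
    r_on, _ = detect_breath_hold(radar, min_hold, quiet_threshold)
    b_on, _ = detect_breath_hold(belt, min_hold, quiet_threshold)
    return SyncResult(radar_hold_onset=r_on, belt_hold_onset=b_on)


def peak_periods(
    trace: RadarTrace,
    cfg: TrackerConfig = TrackerConfig(),
    extremum: str = "max",
    smooth: bool = True,
) -> list[tuple[float, float]]:
    """Per-cycle periods as successive differences of breath peaks.

    Returns ``(peak_time, period)`` pairs, the period being the interval
    ending at ``peak_time``'s successor — each entry is timestamped at the
    peak that opens it. ``extremum`` selects distance maxima ("max") or
    minima ("min"); belt force maxima mark the same physiological instant as
    radar distance minima.
    """
    if len(trace) == 0:
        raise EmptyTraceError("cannot extract periods from an empty trace")
    if extremum not in ("max", "min"):
        raise ValueError("extremum must be 'max' or 'min'")
    pre = preprocess(trace, cfg) if smooth else trace
    blocks, _ = _find_extrema_and_motion(pre.times, pre.samples, cfg)
    out: list[tuple[float, float]] = []
    total_peaks = 0
    for block in blocks:
        peaks = [tt for kind, tt, _v in block if kind == extremum]
        total_peaks += len(peaks)
        for a, b in zip(peaks, peaks[1:]):
            out.append((a, b - a))
    if total_peaks < 2:
        raise InsufficientPeaksError(
            f"found {total_peaks} peak(s); need at least 2 to form a period"
        )
    return out


def compare_periods(
    radar_periods,
    belt_periods,
    max_pairing_gap: float | None = None,
) -> PeriodErrorReport:
    """Pair cycles greedily by nearest peak time and difference the periods.

    Error sign convention: radar period minus belt period. The default
    pairing gap is half the median radar period. Input sequences must already
    be co-registered (see :func:`align`).
    """
    radar_periods = list(radar_periods)
    belt_periods = list(belt_periods)
    if not radar_periods or not belt_periods:
        raise EmptyTraceError("both period sequences must be non-empty")
    if max_pairing_gap is None:
        max_pairing_gap = 0.5 * float(np.median([p for _, p in radar_periods]))

    candidates = []
    for i, (rt, _) in enumerate(radar_periods):
        for j, (bt, _) in enumerate(belt_periods):
            gap = abs(rt - bt)
            if gap <= max_pairing_gap:
                candidates.append((gap, i, j))
    candidates.sort()
    used_r: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if i in used_r or j in used_b:
            continue
        used_r.add(i)
        used_b.add(j)
        pairs.append((i, j))
    pairs.sort()
    errors = np.array(
        [radar_periods[i][1] - belt_periods[j][1] for i, j in pairs], dtype=float
    )
    times = np.array([radar_periods[i][0] for i, _ in pairs], dtype=float)
    return PeriodErrorReport(
        paired_errors=errors,
        pair_times=times,
        unmatched_radar=len(radar_periods) - len(pairs),
        unmatched_belt=len(belt_periods) - len(pairs),
    )


def validate_pair(
    radar: RadarTrace,
    belt: BeltTrace,
    cfg: TrackerConfig = TrackerConfig(),
    max_pairing_gap: float | None = None,
    sync: bool = True,
) -> PeriodErrorReport:
    """Full pipeline: sync on the breath-hold, extract periods, compare.

    Radar periods are taken between distance minima and belt periods between
    force maxima so both peak trains mark full chest expansion and share
    timestamps; the belt timestamps are shifted by the recovered offset.
    """
    radar_p = peak_periods(radar, cfg, extremum="min")
    belt_p = peak_periods(belt, cfg, extremum="max")
    if sync:
        offset = align(radar, belt).offset
        belt_p = [(t - offset, p) for t, p in belt_p]
    return compare_periods(radar_p, belt_p, max_pairing_gap)
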