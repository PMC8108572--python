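"""Topic-phase demarcation from a daily tweet-volume series.

The issue-attention cycle predicts that public attention to an issue rises
sharply around triggering events.  This module locates those onsets in a
daily count series: the series is low-pass smoothed, its first and second
discrete differences ("velocity" and "acceleration") are computed, detection
thresholds are calibrated at a single ground-truth anchor date (the first
confirmed case in the stream's country), and every later date whose
derivatives satisfy the joint condition

    0 < velocity < v_thresh   and   acceleration > a_thresh

opens a new phase (consecutive qualifying days collapse to the earliest).
The thresholds come from the anchor date's own derivatives via floor rules:
``v_thresh = floor(v_GT) + 1`` and ``a_thresh = floor(a_GT)``, i.e. the
anchor date itself just satisfies the condition, and later onsets must show
at least comparable acceleration at not-yet-higher velocity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Sequence

import numpy as np
from scipy import signal

from .io_ingest import DailySeries

logger = logging.getLogger(__name__)

__all__ = [
    "SmoothedSeries",
    "DerivativeSeries",
    "ThresholdPair",
    "Phase",
    "PhaseSegmentation",
    "lowpass_smooth",
    "compute_derivatives",
    "learn_thresholds",
    "detect_phase_starts",
    "segment_phases",
    "detect_phases",
]

#: Minimum length accepted by the zero-phase filter (padlen for a
#: first-order Butterworth under filtfilt is 6).
MIN_FILTER_LENGTH = 7


@dataclass(frozen=True)
class SmoothedSeries:
    """Low-pass filtered daily series, date-aligned with its source."""

    start_date: date
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)

    def date_of(self, index: int) -> date:
        return self.start_date + timedelta(days=int(index))

    def index_of(self, day: date) -> int:
        idx = (day - self.start_date).days
        if not 0 <= idx < len(self):
            raise KeyError(f"{day} outside series range")
        return idx


@dataclass(frozen=True)
class DerivativeSeries:
    """Velocity and acceleration of a (smoothed) daily series.

    Arrays are date-aligned with the source series; ``velocity[0]`` and
    ``acceleration[:2]`` are NaN because the differences are undefined there.
    """

    start_date: date
    velocity: np.ndarray
    acceleration: np.ndarray

    def __len__(self) -> int:
        return len(self.velocity)

    def index_of(self, day: date) -> int:
        idx = (day - self.start_date).days
        if not 0 <= idx < len(self):
            raise KeyError(f"{day} outside series range")
        return idx

    def date_of(self, index: int) -> date:
        return self.start_date + timedelta(days=int(index))


@dataclass(frozen=True)
class ThresholdPair:
    """Detection thresholds calibrated at the ground-truth anchor date."""

    v_thresh: float
    a_thresh: float
    gt_date: date
    v_gt: float
    a_gt: float


@dataclass(frozen=True)
class Phase:
    phase_id: int
    start: date
    end: date  # inclusive

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def contains(self, day: date) -> bool:
        return self.start <= day <= self.end


@dataclass(frozen=True)
class PhaseSegmentation:
    """Ordered, contiguous, non-overlapping phases covering the window."""

    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", tuple(self.phases))
        for prev, nxt in zip(self.phases, self.phases[1:]):
            if nxt.start != prev.end + timedelta(days=1):
                raise ValueError("phases must be contiguous and ordered")
        for ph in self.phases:
            if ph.end < ph.start:
                raise ValueError(f"phase {ph.phase_id} ends before it starts")

    def __len__(self) -> int:
        return len(self.phases)

    def __iter__(self):
        return iter(self.phases)

    @property
    def window(self) -> tuple[date, date]:
        return self.phases[0].start, self.phases[-1].end

    def phase_of(self, day: date) -> Phase:
        for ph in self.phases:
            if ph.contains(day):
                return ph
        raise KeyError(f"{day} outside segmentation window")

    def to_dicts(self) -> list[dict]:
        return [
            {"phase_id": p.phase_id, "start": p.start.isoformat(),
             "end": p.end.isoformat()}
            for p in self.phases
        ]


def lowpass_smooth(
    series: DailySeries,
    cutoff: float = 0.2,
    order: int = 1,
) -> SmoothedSeries:
    """Zero-phase Butterworth low-pass smoothing of a daily series.

    ``cutoff`` is the normalized cutoff as a fraction of the Nyquist
    frequency (0.5 cycles/day); the default 0.2 passes fluctuations slower
    than roughly ten days per cycle.  The filter is applied forward and
    backward (``filtfilt``) so smoothing shifts no dates, and its DC gain is
    exactly 1, so a constant series passes through unchanged.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be a fraction of Nyquist in (0, 1)")
    if len(series) < MIN_FILTER_LENGTH:
        raise ValueError(
            f"series of length {len(series)} too short to smooth: "
            f"need at least {MIN_FILTER_LENGTH} days for edge padding"
        )
    b, a = signal.butter(order, cutoff, btype="low")
    values = signal.filtfilt(b, a, series.counts)
    return SmoothedSeries(start_date=series.start_date, values=values)


def identity_smooth(series: DailySeries) -> SmoothedSeries:
    """No-op smoothing; useful for hand-checkable fixtures."""
    return SmoothedSeries(start_date=series.start_date,
                          values=series.counts.copy())


def compute_derivatives(
    smoothed: SmoothedSeries, form: str = "difference"
) -> DerivativeSeries:
    """First (velocity) and second (acceleration) discrete differences.

    ``v[t] = S[t] - S[t-1]`` and ``a[t] = v[t] - v[t-1]``; undefined entries
    (the first day for velocity, first two for acceleration) are NaN.
    ``form`` selects the series the differences act on: ``"difference"``
    (raw values, default), ``"log"`` (log1p of the values, a relative-growth
    reading) or ``"ratio"`` (v[t] = S[t]/S[t-1] - 1).
    """
    if len(smoothed) < 3:
        raise ValueError("need at least 3 days to compute acceleration")
    s = smoothed.values
    if form == "difference":
        base = s
    elif form == "log":
        base = np.log1p(np.maximum(s, 0.0))
    elif form == "ratio":
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.full(len(s), np.nan)
            v[1:] = s[1:] / s[:-1] - 1.0
        a = np.full(len(s), np.nan)
        a[2:] = v[2:] - v[1:-1]
        return DerivativeSeries(smoothed.start_date, v, a)
    else:
        raise ValueError(f"unknown derivative form {form!r}")
    v = np.full(len(base), np.nan)
    v[1:] = np.diff(base)
    a = np.full(len(base), np.nan)
    a[2:] = np.diff(base, n=2)
    return DerivativeSeries(smoothed.start_date, v, a)


def learn_thresholds(deriv: DerivativeSeries, gt_date: date) -> ThresholdPair:
    """Calibrate detection thresholds at the ground-truth anchor date.

    The velocity threshold is the anchor-date velocity rounded down plus one;
    the acceleration threshold is the anchor-date acceleration rounded down.
    Once learned, the pair is immutable for the rest of the study window.
    """
    idx = deriv.index_of(gt_date)
    if idx < 2:
        raise ValueError(
            "gt_date must be at least 2 days after the series start so that "
            "velocity and acceleration are defined"
        )
    v_gt = float(deriv.velocity[idx])
    a_gt = float(deriv.acceleration[idx])
    if not (math.isfinite(v_gt) and math.isfinite(a_gt)):
        raise ValueError("derivatives at gt_date are undefined")
    if v_gt <= 0:
        logger.warning(
            "velocity at gt_date is %.3f <= 0: the detection condition "
            "0 < v < v_thresh may be vacuous", v_gt,
        )
    return ThresholdPair(
        v_thresh=math.floor(v_gt) + 1,
        a_thresh=float(math.floor(a_gt)),
        gt_date=gt_date,
        v_gt=v_gt,
        a_gt=a_gt,
    )


def detect_phase_starts(
    deriv: DerivativeSeries,
    thr: ThresholdPair,
    window: tuple[date, date] | None = None,
) -> list[date]:
    """Dates opening a new topic phase.

    Returns the anchor date plus every later in-window date where
    ``0 < velocity < v_thresh`` and ``acceleration > a_thresh`` (strict
    comparisons), with runs of consecutive qualifying days collapsed to
    their earliest day.  An empty tail means a single post-anchor phase.
    """
    if window is None:
        window = (deriv.date_of(0), deriv.date_of(len(deriv) - 1))
    start_w, end_w = window
    starts = [thr.gt_date]
    prev_qualified = False
    for idx in range(len(deriv)):
        day = deriv.date_of(idx)
        if day <= thr.gt_date or day < start_w or day > end_w:
            prev_qualified = False
            continue
        v = deriv.velocity[idx]
        a = deriv.acceleration[idx]
        qualifies = (
            math.isfinite(v) and math.isfinite(a)
            and 0 < v < thr.v_thresh and a > thr.a_thresh
        )
        if qualifies and not prev_qualified:
            starts.append(day)
        prev_qualified = qualifies
    return starts


def segment_phases(
    starts: Sequence[date], window: tuple[date, date]
) -> PhaseSegmentation:
    """Partition the study window at the given phase-start dates.

    Phase 0 runs from the window start to the day before the first start;
    each later phase runs to the day before the next start; the last phase
    ends at the window end.  A start equal to the window start would make
    phase 0 empty; it is omitted and logged, and numbering still begins at
    the first non-empty phase as phase 0.
    """
    start_w, end_w = window
    if end_w < start_w:
        raise ValueError("window end before start")
    ordered = sorted(set(starts))
    for s in ordered:
        if not start_w <= s <= end_w:
            raise ValueError(f"phase start {s} outside window")
    boundaries = [start_w] + [s for s in ordered if s != start_w]
    if ordered and ordered[0] == start_w:
        logger.info("phase start coincides with window start; "
                    "empty leading phase omitted")
    phases = []
    for i, b in enumerate(boundaries):
        end = boundaries[i + 1] - timedelta(days=1) if i + 1 < len(boundaries) else end_w
        phases.append(Phase(phase_id=i, start=b, end=end))
    return PhaseSegmentation(phases=tuple(phases))


def detect_phases(
    series: DailySeries,
    gt_date: date,
    cutoff: float = 0.2,
    smooth: bool = True,
    derivative_form: str = "difference",
) -> tuple[PhaseSegmentation, ThresholdPair]:
    """End-to-end demarcation: smooth, differentiate, calibrate, segment."""
    smoothed = lowpass_smooth(series, cutoff) if smooth else identity_smooth(series)
    deriv = compute_derivatives(smoothed, form=derivative_form)
    thr = learn_thresholds(deriv, gt_date)
    window = (series.start_date, series.end_date)
    starts = detect_phase_starts(deriv, thr, window)
    return segment_phases(starts, window), thr
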