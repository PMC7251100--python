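"""Threshold-based event detection and event-level scoring.

A seizure is declared when the connectivity feature (lambda_2 or its EMA)
stays above a fixed threshold for a decision time tau_d (default 6 s);
the event onset is reported at the *first* threshold crossing, so the
detection delay d = onset - annotated onset and the latency L = d + tau_d
separate cleanly.  Scoring is event-based: one true positive per
annotated seizure, everything else a false positive, with sensitivity
100*TP/NS and a false-positive rate per recorded hour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import SeizureInterval

__all__ = [
    "DetectorConfig",
    "DetectionEvent",
    "DetectionReport",
    "threshold_detect",
    "calibrate_threshold",
    "moving_threshold",
    "evaluate",
    "aggregate_reports",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Detector parameters.

    threshold: fixed lambda_2 threshold theta (per-recording, typically
    calibrated from a seizure-free baseline); decision_time: seconds a
    super-threshold excursion must persist before an event is confirmed;
    min_gap: events closer than this merge into one; pre_onset_tolerance:
    how far before the annotated onset a detection still counts as a true
    positive (annotated onsets are imprecise and detections a few seconds
    early occur in practice).
    """

    threshold: float
    decision_time: float = 6.0
    min_gap: float = 10.0
    pre_onset_tolerance: float = 10.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.decision_time < 0:
            raise ValueError("decision_time must be nonnegative")


@dataclass(frozen=True)
class DetectionEvent:
    """A confirmed super-threshold excursion."""

    onset: float
    confirm_time: float
    offset: float

    def __post_init__(self) -> None:
        if not (self.onset <= self.confirm_time <= self.offset):
            raise ValueError("need onset <= confirm_time <= offset")


@dataclass
class DetectionReport:
    """Event-level scores for one recording (or a pooled set).

    delays may be None when the report was built from summary statistics
    (e.g. published per-patient table rows); then mean_delay/mean_latency
    are carried directly.
    """

    ns: int
    tp: int
    fp: int
    duration_h: float
    decision_time: float = 6.0
    delays: list[float] | None = None
    _mean_delay: float | None = None
    _mean_latency: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.tp <= self.ns):
            raise ValueError(f"need 0 <= TP <= NS, got TP={self.tp}, NS={self.ns}")
        if self.fp < 0:
            raise ValueError("FP must be nonnegative")

    @property
    def sensitivity(self) -> float:
        """S = 100 * TP / NS, in percent."""
        return 100.0 * self.tp / self.ns if self.ns else 0.0

    @property
    def fp_per_hour(self) -> float:
        if self.duration_h <= 0:
            raise ValueError("duration must be positive")
        return self.fp / self.duration_h

    @property
    def latencies(self) -> list[float] | None:
        if self.delays is None:
            return None
        return [d + self.decision_time for d in self.delays]

    @property
    def mean_delay(self) -> float | None:
        if self.delays is not None:
            return float(np.mean(self.delays)) if self.delays else None
        return self._mean_delay

    @property
    def mean_latency(self) -> float | None:
        if self.delays is not None:
            lats = self.latencies
            return float(np.mean(lats)) if lats else None
        return self._mean_latency

    @classmethod
    def from_summary(
        cls,
        ns: int,
        tp: int,
        fp: int,
        duration_h: float = float("nan"),
        mean_delay: float | None = None,
        mean_latency: float | None = None,
        decision_time: float = 6.0,
    ) -> "DetectionReport":
        return cls(
            ns=ns, tp=tp, fp=fp, duration_h=duration_h,
            decision_time=decision_time, delays=None,
            _mean_delay=mean_delay, _mean_latency=mean_latency,
        )

    def to_dict(self) -> dict:
        return {
            "NS": self.ns,
            "TP": self.tp,
            "FP": self.fp,
            "sensitivity_pct": self.sensitivity,
            "fp_per_hour": self.fp_per_hour if self.duration_h > 0 else None,
            "mean_delay_s": self.mean_delay,
            "mean_latency_s": self.mean_latency,
            "decision_time_s": self.decision_time,
        }


def threshold_detect(
    times: np.ndarray, values: np.ndarray, config: DetectorConfig
) -> list[DetectionEvent]:
    """Detect events: runs of samples above theta lasting >= decision_time.

    The event onset is the time of the first super-threshold sample, the
    confirm time onset + decision_time, and the offset the time the
    series next falls below theta.  Confirmed events separated by less
    than min_gap seconds are merged.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size != values.size:
        raise ValueError("times and values must have the same length")
    if times.size == 0:
        return []
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    hop = float(np.median(np.diff(times))) if times.size > 1 else 1.0

    above = values > config.threshold
    events: list[DetectionEvent] = []
    idx = 0
    n = times.size
    while idx < n:
        if not above[idx]:
            idx += 1
            continue
        run_start = idx
        while idx < n and above[idx]:
            idx += 1
        run_len_s = (idx - run_start) * hop
        if run_len_s >= config.decision_time:
            onset = times[run_start]
            offset = times[idx] if idx < n else times[-1] + hop
            events.append(
                DetectionEvent(
                    onset=onset,
                    confirm_time=onset + config.decision_time,
                    offset=offset,
                )
            )

    if config.min_gap > 0 and len(events) > 1:
        merged = [events[0]]
        for ev in events[1:]:
            if ev.onset - merged[-1].offset < config.min_gap:
                last = merged.pop()
                merged.append(
                    DetectionEvent(
                        onset=last.onset,
                        confirm_time=last.confirm_time,
                        offset=ev.offset,
                    )
                )
            else:
                merged.append(ev)
        events = merged
    return events


def calibrate_threshold(
    baseline: np.ndarray,
    k: float = 6.0,
    clip_percentile: float | None = None,
) -> float:
    """theta = mean + k * std of a seizure-free baseline series.

    Stands in for per-patient visual threshold choice.  If
    clip_percentile is set, baseline samples above that percentile are
    removed first (robustness against isolated spikes).
    """
    baseline = np.asarray(baseline, dtype=float)
    if baseline.size < 60:
        warnings.warn(
            f"baseline of {baseline.size} windows is short; "
            "threshold calibration may be unreliable"
        )
    if clip_percentile is not None:
        cut = np.percentile(baseline, clip_percentile)
        baseline = baseline[baseline <= cut]
    return float(baseline.mean() + k * baseline.std())


def moving_threshold(values: np.ndarray, k: float = 6.0, span: int = 300) -> np.ndarray:
    """Adaptive variant: causal moving mean + k * moving std over the
    previous ``span`` samples (threshold based on recent activity)."""
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    for t in range(values.size):
        lo = max(0, t - span)
        w = values[lo : t + 1]
        out[t] = w.mean() + k * w.std()
    return out


def evaluate(
    events: Sequence[DetectionEvent],
    annotations: Sequence[SeizureInterval],
    duration_h: float,
    config: DetectorConfig,
) -> tuple[DetectionReport, list[DetectionEvent]]:
    """Score events against annotated seizures.

    An event is a true positive if its onset falls in
    [annotated onset - pre_onset_tolerance, annotated offset]; at most
    one TP per annotated seizure (extra events inside the same seizure
    are collapsed, not counted as FP); all remaining events are false
    positives.  Returns the report and the list of FP events.
    """
    if duration_h <= 0:
        raise ValueError("duration_h must be positive")
    anns = sorted(annotations, key=lambda a: a.onset)
    for prev, nxt in zip(anns, anns[1:]):
        if nxt.onset < prev.offset:
            raise ValueError(f"overlapping annotations: {prev} and {nxt}")

    tol = config.pre_onset_tolerance
    matched_events: set[int] = set()
    delays: list[float] = []
    tp = 0
    for ann in anns:
        first_delay = None
        for idx, ev in enumerate(events):
            if idx in matched_events:
                continue
            if ann.onset - tol <= ev.onset <= ann.offset:
                matched_events.add(idx)
                if first_delay is None:
                    first_delay = ev.onset - ann.onset
        if first_delay is not None:
            tp += 1
            delays.append(first_delay)
    fp_events = [ev for idx, ev in enumerate(events) if idx not in matched_events]
    report = DetectionReport(
        ns=len(anns), tp=tp, fp=len(fp_events), duration_h=duration_h,
        decision_time=config.decision_time, delays=delays,
    )
    return report, fp_events


def aggregate_reports(
    reports: Sequence[DetectionReport], mode: str = "unweighted"
) -> dict:
    """Pool per-recording (per-patient) reports into one summary row.

    Counts (NS, TP, FP) are summed and the pooled sensitivity is
    100*sum(TP)/sum(NS) regardless of mode.  Mean delay/latency follow
    the named mode: "unweighted" averages the per-report means across
    reports, "tp_weighted" weights each report's mean by its TP count.
    """
    if len(reports) == 0:
        raise ValueError("no reports to aggregate")
    if mode not in {"unweighted", "tp_weighted"}:
        raise ValueError(f"unknown aggregation mode: {mode!r}")
    ns = sum(r.ns for r in reports)
    tp = sum(r.tp for r in reports)
    fp = sum(r.fp for r in reports)
    durations = [r.duration_h for r in reports]
    total_h = float(np.nansum(durations))
    have_hours = all(np.isfinite(d) and d > 0 for d in durations)

    def _mean(attr: str) -> float | None:
        vals, weights = [], []
        for r in reports:
            v = getattr(r, attr)
            if v is None:
                continue
            vals.append(v)
            weights.append(r.tp if mode == "tp_weighted" else 1)
        if not vals or sum(weights) == 0:
            return None
        return float(np.average(vals, weights=weights))

    return {
        "NS": ns,
        "TP": tp,
        "FP": fp,
        "sensitivity_pct": 100.0 * tp / ns if ns else 0.0,
        "fp_per_hour": fp / total_h if have_hours and total_h > 0 else None,
        "mean_delay_s": _mean("mean_delay"),
        "mean_latency_s": _mean("mean_latency"),
        "mode": mode,
        "n_reports": len(reports),
    }
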