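"""Event extraction and evaluation statistics.

Per-segment probabilities become a binary track (strictly more than 0.5 is
scratching), maximal runs of positive segments become *events* with a
count and a duration, and prediction/observation track pairs yield the
confusion matrix, sensitivity / specificity / predictive values, the
per-video event-count correlation, event duration matching, and a
three-way error taxonomy:

* boundary — an error segment whose enclosing event overlaps a
  counterpart event in the other track (a start/end disagreement);
* false detection — a predicted event overlapping no observed event;
* oversight — an observed event overlapping no predicted event.

Every false positive and false negative segment falls in exactly one bin,
so boundary + false_detection + oversight = fp + fn.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_CUTOFF = 0.5
DEFAULT_FPS = 60

__all__ = [
    "BinaryTrack",
    "ProbabilityTrack",
    "ScratchEvent",
    "ConfusionMatrix",
    "MetricSet",
    "ErrorBreakdown",
    "threshold_track",
    "extract_events",
    "events_to_track",
    "confusion",
    "metrics",
    "classify_errors",
    "count_correlation",
    "match_durations",
    "grooming_confusion",
]


@dataclass
class ProbabilityTrack:
    """Per-segment scratch probability, indexed by centre time."""

    times: np.ndarray
    probs: np.ndarray
    video_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=int)
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.times) != len(self.probs):
            raise ValueError("times and probs differ in length")
        if len(self.times) > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("segment times must be strictly increasing")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"segment_time": self.times, "probability": self.probs}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, video_id: str = "") -> "ProbabilityTrack":
        df = pd.read_csv(path)
        return cls(df["segment_time"].to_numpy(), df["probability"].to_numpy(), video_id)


@dataclass
class BinaryTrack:
    """Per-segment 0/1 values, indexed by centre time.

    ``role`` documents what the track encodes: "prediction",
    "observation" or "grooming".
    """

    times: np.ndarray
    values: np.ndarray
    role: str = "prediction"
    video_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=int)
        self.values = np.asarray(self.values, dtype=np.uint8)
        if len(self.times) != len(self.values):
            raise ValueError("times and values differ in length")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("track values must be binary")

    def __len__(self) -> int:
        return len(self.times)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"segment_time": self.times, "label": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, role: str = "prediction", video_id: str = "") -> "BinaryTrack":
        df = pd.read_csv(path)
        return cls(df["segment_time"].to_numpy(), df["label"].to_numpy(), role, video_id)


@dataclass(frozen=True)
class ScratchEvent:
    """A maximal run of contiguous scratch segments."""

    start_t: int
    end_t: int
    fps: int = DEFAULT_FPS

    @property
    def n_segments(self) -> int:
        return self.end_t - self.start_t + 1

    @property
    def duration_s(self) -> float:
        return self.n_segments / self.fps

    def overlaps(self, other: "ScratchEvent") -> bool:
        return self.start_t <= other.end_t and other.start_t <= self.end_t


def threshold_track(
    probs: ProbabilityTrack, cutoff: float = DEFAULT_CUTOFF
) -> BinaryTrack:
    """Classify segments: scratching iff probability strictly exceeds cutoff
    (a value of exactly 0.5 is *not* scratching)."""
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError(f"cutoff={cutoff} must be in [0, 1]")
    return BinaryTrack(
        probs.times, (probs.probs > cutoff).astype(np.uint8), "prediction", probs.video_id
    )


def extract_events(track: BinaryTrack, fps: int = DEFAULT_FPS) -> list[ScratchEvent]:
    """Maximal runs of 1s; a gap in the time index splits a run."""
    events: list[ScratchEvent] = []
    start = None
    prev_t = None
    for t, v in zip(track.times, track.values):
        contiguous = prev_t is not None and t == prev_t + 1
        if v and start is not None and not contiguous:
            events.append(ScratchEvent(int(start), int(prev_t), fps))
            start = t
        elif v and start is None:
            start = t
        elif not v and start is not None:
            events.append(ScratchEvent(int(start), int(prev_t), fps))
            start = None
        prev_t = t
    if start is not None:
        events.append(ScratchEvent(int(start), int(prev_t), fps))
    return events


def events_to_track(
    events: list[ScratchEvent], times: np.ndarray, role: str = "prediction"
) -> BinaryTrack:
    """Rebuild the binary track of the given time axis from its events."""
    times = np.asarray(times, dtype=int)
    values = np.zeros(len(times), dtype=np.uint8)
    pos = {int(t): i for i, t in enumerate(times)}
    for ev in events:
        for t in range(ev.start_t, ev.end_t + 1):
            if t in pos:
                values[pos[t]] = 1
    return BinaryTrack(times, values, role)


# ---------------------------------------------------------------------------
# Confusion and metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricSet:
    """Percentages; ``None`` marks an undefined (0/0) metric."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None


def _aligned(a: BinaryTrack, b: BinaryTrack) -> None:
    if len(a) != len(b) or not np.array_equal(a.times, b.times):
        raise ValueError(
            f"track index mismatch: {len(a)} segments vs {len(b)} "
            "(times must be identical)"
        )


def confusion(pred: BinaryTrack, obs: BinaryTrack) -> ConfusionMatrix:
    """Segment-level confusion counts of prediction against observation."""
    _aligned(pred, obs)
    p = pred.values.astype(bool)
    o = obs.values.astype(bool)
    return ConfusionMatrix(
        tp=int((p & o).sum()),
        fn=int((~p & o).sum()),
        fp=int((p & ~o).sum()),
        tn=int((~p & ~o).sum()),
    )


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Sensitivity, specificity, PPV and NPV as percentages."""
    return MetricSet(
        sensitivity=_pct(cm.tp, cm.tp + cm.fn),
        specificity=_pct(cm.tn, cm.tn + cm.fp),
        ppv=_pct(cm.tp, cm.tp + cm.fp),
        npv=_pct(cm.tn, cm.tn + cm.fn),
    )


# ---------------------------------------------------------------------------
# Error taxonomy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ErrorBreakdown:
    boundary: int
    false_detection: int
    oversight: int

    @property
    def total(self) -> int:
        return self.boundary + self.false_detection + self.oversight


def classify_errors(pred: BinaryTrack, obs: BinaryTrack) -> ErrorBreakdown:
    """Sort every error segment into boundary / false detection / oversight.

    A false-positive segment belongs to a predicted event; it is a
    *boundary* error when that event overlaps at least one observed event,
    otherwise the whole event is a *false detection*.  Symmetrically a
    false-negative segment is *boundary* when its observed event overlaps
    some predicted event, otherwise an *oversight*.
    """
    _aligned(pred, obs)
    pred_events = extract_events(pred)
    obs_events = extract_events(obs)
    boundary = false_detection = oversight = 0
    o = dict(zip(pred.times.tolist(), obs.values.tolist()))
    p = dict(zip(obs.times.tolist(), pred.values.tolist()))
    for ev in pred_events:
        n_fp = sum(1 for t in range(ev.start_t, ev.end_t + 1) if not o[t])
        if any(ev.overlaps(oe) for oe in obs_events):
            boundary += n_fp
        else:
            false_detection += n_fp
    for ev in obs_events:
        n_fn = sum(1 for t in range(ev.start_t, ev.end_t + 1) if not p[t])
        if any(ev.overlaps(pe) for pe in pred_events):
            boundary += n_fn
        else:
            oversight += n_fn
    return ErrorBreakdown(boundary, false_detection, oversight)


# ---------------------------------------------------------------------------
# Counts, durations, grooming
# ---------------------------------------------------------------------------


def count_correlation(pairs: list[tuple[int, int]]) -> float | None:
    """Pearson r between per-video predicted and observed event counts.

    Undefined (None) when either coordinate has zero variance.
    """
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 (prediction, observation) pairs, got {len(pairs)}")
    a = np.asarray([p for p, _ in pairs], dtype=float)
    b = np.asarray([o for _, o in pairs], dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    return float(stats.pearsonr(a, b).statistic)


def match_durations(
    pred_events: list[ScratchEvent], obs_events: list[ScratchEvent]
) -> tuple[list[tuple[float, float]], list[ScratchEvent]]:
    """Observed-event-centric duration pairing.

    Each observed event is paired with the summed duration of every
    predicted event overlapping it (0 when none overlaps).  Returns
    ``(pairs, unmatched_pred)`` where pairs are (observed duration,
    matched predicted duration) in seconds and ``unmatched_pred`` lists
    predicted events overlapping no observed event.
    """
    pairs = []
    for oe in obs_events:
        matched = sum(pe.duration_s for pe in pred_events if pe.overlaps(oe))
        pairs.append((oe.duration_s, matched))
    unmatched = [pe for pe in pred_events if not any(pe.overlaps(oe) for oe in obs_events)]
    return pairs, unmatched


def grooming_confusion(pred: BinaryTrack, grooming: BinaryTrack) -> int:
    """Number of grooming segments the detector classified as scratching."""
    _aligned(pred, grooming)
    return int((pred.values.astype(bool) & grooming.values.astype(bool)).sum())


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


def evaluation_report(
    pred: BinaryTrack, obs: BinaryTrack, fps: int = DEFAULT_FPS
) -> dict:
    """Full evaluation of one prediction/observation pair as a JSON-ready dict."""
    cm = confusion(pred, obs)
    ms = metrics(cm)
    errs = classify_errors(pred, obs)
    pred_events = extract_events(pred, fps)
    obs_events = extract_events(obs, fps)
    return {
        "confusion": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn},
        "metrics": {
            "sensitivity_pct": ms.sensitivity,
            "specificity_pct": ms.specificity,
            "ppv_pct": ms.ppv,
            "npv_pct": ms.npv,
        },
        "errors": {
            "boundary": errs.boundary,
            "false_detection": errs.false_detection,
            "oversight": errs.oversight,
        },
        "events": {
            "predicted_count": len(pred_events),
            "observed_count": len(obs_events),
            "predicted_total_s": sum(e.duration_s for e in pred_events),
            "observed_total_s": sum(e.duration_s for e in obs_events),
        },
    }


def format_report(report: dict) -> str:
    """Human-readable rendering of :func:`evaluation_report` output."""
    cm = report["confusion"]
    ms = report["metrics"]
    er = report["errors"]
    ev = report["events"]

    def fmt(v):
        return "undefined" if v is None else f"{v:.1f}%"

    return "\n".join(
        [
            f"segments: {cm['tp'] + cm['fn'] + cm['fp'] + cm['tn']}",
            f"confusion: tp={cm['tp']} fn={cm['fn']} fp={cm['fp']} tn={cm['tn']}",
            f"sensitivity {fmt(ms['sensitivity_pct'])}  specificity {fmt(ms['specificity_pct'])}  "
            f"ppv {fmt(ms['ppv_pct'])}  npv {fmt(ms['npv_pct'])}",
            f"errors: boundary={er['boundary']} false_detection={er['false_detection']} "
            f"oversight={er['oversight']}",
            f"events: predicted {ev['predicted_count']} ({ev['predicted_total_s']:.2f} s), "
            f"observed {ev['observed_count']} ({ev['observed_total_s']:.2f} s)",
        ]
    )
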