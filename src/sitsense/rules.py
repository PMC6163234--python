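"""Ergonomic rule discrimination, posture subtypes, and temporal smoothing.

The frame-level rule classifier follows the ergonomics literature's
healthy-sitting definition:

* lumbar angle and cervical angle strictly greater than 20 deg are
  unhealthy (20 deg exactly is healthy),
* the healthy sight distance is the closed interval 0.40–0.70 m,
* the healthy sight angle is 15–30 deg below horizontal sight
  (gamma in [-30 deg, -15 deg]).

A frame with any required feature invalid is ``unknown`` — never
unhealthy — so missing screen detections cannot raise false alarms.
Posture subtypes (lean forward, hold head, lean backward, bend over,
looking up, body sideways, too-small sight distance) are decided by a
fixed-order decision list over the same features plus the lateral spine
lean.

Temporal smoothing suppresses transient changes: a run of consecutive
unhealthy frames shorter than ``min_event_frames`` (default 150 frames,
five seconds at 30 fps) is merged into the surrounding state and never
emitted as an unhealthy event.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace

import numpy as np

from .errors import LabelingError, SequencingError
from .features import FEATURE_NAMES, SemanticFeatureVector

__all__ = [
    "ErgonomicThresholds",
    "FrameLabel",
    "PostureEvent",
    "SUBTYPES",
    "classify_frame",
    "classify_subtype",
    "label_clusters",
    "smooth_events",
    "video_verdict",
    "confusion_counts",
    "precision_recall_accuracy",
]

STATES = ("healthy", "unhealthy", "not_sitting", "unknown")
SUBTYPES = ("lean_forward", "hold_head", "lean_backward", "bend_over",
            "looking_up", "body_side", "small_sight_distance", "none")


@dataclass(frozen=True)
class ErgonomicThresholds:
    """Rule thresholds with the ergonomics-literature defaults.

    Angles in degrees, distances in meters. ``sight_angle_healthy_deg`` is
    the below-horizontal magnitude band: gamma is healthy when
    -hi <= gamma_deg <= -lo. ``bend_over_deg`` and ``body_side_deg`` are
    secondary bounds used only by the subtype decision list.
    """

    max_lumbar_deg: float = 20.0
    max_cervical_deg: float = 20.0
    sight_distance_healthy_m: tuple[float, float] = (0.40, 0.70)
    sight_angle_healthy_deg: tuple[float, float] = (15.0, 30.0)
    min_event_frames: int = 150
    bend_over_deg: float = 50.0
    body_side_deg: float = 15.0

    def __post_init__(self) -> None:
        lo_d, hi_d = self.sight_distance_healthy_m
        lo_a, hi_a = self.sight_angle_healthy_deg
        if not (0 < lo_d <= hi_d and 0 < lo_a <= hi_a):
            raise ValueError("healthy intervals must be non-empty and positive")
        if self.max_lumbar_deg <= 0 or self.max_cervical_deg <= 0:
            raise ValueError("angle thresholds must be positive")
        if self.min_event_frames < 1:
            raise ValueError("min_event_frames must be >= 1")


DEFAULT_THRESHOLDS = ErgonomicThresholds()


@dataclass(frozen=True)
class FrameLabel:
    """Per-frame verdict: state, the rules that fired, and the subtype."""

    frame_index: int
    state: str
    violated_rules: frozenset[str] = frozenset()
    subtype: str = "none"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.state == "healthy" and self.violated_rules:
            raise ValueError("healthy label cannot carry violated rules")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")


@dataclass(frozen=True)
class PostureEvent:
    """A maximal contiguous frame segment of one state."""

    start_frame: int
    end_frame: int  # inclusive
    state: str
    subtype: str = "none"
    mean_features: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise ValueError("event end before start")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def classify_frame(fv: SemanticFeatureVector, sitting: bool,
                   thr: ErgonomicThresholds = DEFAULT_THRESHOLDS) -> FrameLabel:
    """Apply the ergonomic rules to one frame's features.

    not_sitting when the person is not seated; unknown when any of the
    four posture features (alpha, beta, gamma, delta) is invalid;
    otherwise unhealthy iff at least one rule fires, with every firing
    rule listed.
    """
    if not sitting:
        return FrameLabel(fv.frame_index, "not_sitting")
    required = ("alpha", "beta", "gamma", "delta")
    if not all(fv.is_valid(n) for n in required):
        return FrameLabel(fv.frame_index, "unknown")

    fired: set[str] = set()
    if math.degrees(fv.alpha) > thr.max_lumbar_deg:
        fired.add("lumbar_angle")
    if math.degrees(fv.beta) > thr.max_cervical_deg:
        fired.add("cervical_angle")
    lo_d, hi_d = thr.sight_distance_healthy_m
    if not (lo_d <= fv.delta <= hi_d):
        fired.add("sight_distance")
    lo_a, hi_a = thr.sight_angle_healthy_deg
    gamma_deg = math.degrees(fv.gamma)
    if not (-hi_a <= gamma_deg <= -lo_a):
        fired.add("sight_angle")

    if not fired:
        return FrameLabel(fv.frame_index, "healthy")
    return FrameLabel(fv.frame_index, "unhealthy", violated_rules=frozenset(fired))


def classify_subtype(fv: SemanticFeatureVector, label: FrameLabel,
                     thr: ErgonomicThresholds = DEFAULT_THRESHOLDS) -> str:
    """Name the unhealthy-posture subtype by a fixed-order decision list.

    Order: bend_over -> looking_up -> lean_forward -> lean_backward ->
    small_sight_distance -> body_side -> hold_head -> none. Only unhealthy
    labels receive a subtype.
    """
    if label.state != "unhealthy":
        return "none"
    a = math.degrees(fv.alpha)
    b = math.degrees(fv.beta)
    g = math.degrees(fv.gamma)
    d = fv.delta
    lat = math.degrees(fv.lateral) if fv.is_valid("lateral") else 0.0
    lo_d, hi_d = thr.sight_distance_healthy_m

    if a > thr.bend_over_deg:
        return "bend_over"
    if g > 0.0:
        return "looking_up"
    if a > thr.max_lumbar_deg and b > thr.max_cervical_deg and d < lo_d:
        return "lean_forward"
    if a > thr.max_lumbar_deg and b > thr.max_cervical_deg and d > hi_d:
        return "lean_backward"
    if d < lo_d and a <= thr.max_lumbar_deg and b <= thr.max_cervical_deg:
        return "small_sight_distance"
    if lat > thr.body_side_deg:
        return "body_side"
    if b > thr.max_cervical_deg and a <= thr.max_lumbar_deg:
        return "hold_head"
    return "none"


def label_and_subtype(fv: SemanticFeatureVector, sitting: bool,
                      thr: ErgonomicThresholds = DEFAULT_THRESHOLDS) -> FrameLabel:
    """Convenience: classify the frame and attach its subtype."""
    label = classify_frame(fv, sitting, thr)
    if label.state == "unhealthy":
        label = replace(label, subtype=classify_subtype(fv, label, thr))
    return label


def label_clusters(model, scaler, thr: ErgonomicThresholds = DEFAULT_THRESHOLDS,
                   ) -> dict[int, str]:
    """Map each mixture component to healthy/unhealthy semantics.

    Each component's mean vector is brought back to original units through
    the scaler's inverse transform, interpreted as a seated frame, and run
    through the rule classifier. Cluster semantics thereby inherit the
    ergonomic definition without any labelled training data.
    """
    means = scaler.inverse_transform(model.means) if scaler is not None else model.means
    out: dict[int, str] = {}
    for i, row in enumerate(np.atleast_2d(means)):
        vals = dict(zip(FEATURE_NAMES, (float(v) for v in row)))
        if not all(math.isfinite(v) for v in vals.values()):
            raise LabelingError(f"component {i} mean has non-finite features")
        fv = SemanticFeatureVector(frame_index=0, **vals, lateral=0.0, sitting=True)
        state = classify_frame(fv, sitting=True, thr=thr).state
        if state not in ("healthy", "unhealthy"):
            raise LabelingError(f"component {i} mean implies state {state!r}")
        out[i] = state
    return out


def _runs(states: list[str]) -> list[tuple[str, int, int]]:
    runs = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            runs.append((states[start], start, i - 1))
            start = i
    return runs


def smooth_events(labels: list[FrameLabel],
                  thr: ErgonomicThresholds = DEFAULT_THRESHOLDS,
                  features: list[SemanticFeatureVector] | None = None,
                  ) -> list[PostureEvent]:
    """Collapse per-frame labels into ordered, non-overlapping events.

    Unhealthy runs shorter than ``min_event_frames`` are transients: they
    are relabelled to the preceding run's state (the following run's when
    at the start; ``unknown`` if the sequence holds nothing else) and never
    surface as unhealthy events. The emitted events partition the frame
    range.
    """
    if not labels:
        return []
    idx = [l.frame_index for l in labels]
    if any(b - a != 1 for a, b in zip(idx, idx[1:])):
        raise SequencingError("frame labels must be ordered and gap-free")
    if features is not None and [f.frame_index for f in features] != idx:
        raise SequencingError("features must align with labels")

    states = [l.state for l in labels]
    runs = _runs(states)
    smoothed = list(states)
    for state, a, b in runs:
        if state == "unhealthy" and (b - a + 1) < thr.min_event_frames:
            if a > 0:
                fill = smoothed[a - 1]
            elif b + 1 < len(states):
                fill = states[b + 1]
            else:
                fill = "unknown"
            for j in range(a, b + 1):
                smoothed[j] = fill

    events: list[PostureEvent] = []
    offset = idx[0]
    for state, a, b in _runs(smoothed):
        subtype = "none"
        if state == "unhealthy":
            counts = Counter(l.subtype for l in labels[a:b + 1]
                             if l.state == "unhealthy" and l.subtype != "none")
            if counts:
                top = max(counts.values())
                subtype = sorted(s for s, c in counts.items() if c == top)[0]
        mean_fv = None
        if features is not None:
            block = np.array([f.as_array() for f in features[a:b + 1]])
            with np.errstate(invalid="ignore"):
                mean_fv = {n: float(v) for n, v in
                           zip(FEATURE_NAMES, np.nanmean(block, axis=0))}
        events.append(PostureEvent(start_frame=offset + a, end_frame=offset + b,
                                   state=state, subtype=subtype,
                                   mean_features=mean_fv))
    return events


def video_verdict(events: list[PostureEvent]) -> str:
    """Video-level verdict: unhealthy iff at least one unhealthy event survives."""
    return "unhealthy" if any(e.state == "unhealthy" for e in events) else "healthy"


def confusion_counts(y_true: list[str], y_pred: list[str]) -> dict[str, int]:
    """TP/TN/FP/FN with 'unhealthy' the positive class."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    tp = sum(t == "unhealthy" and p == "unhealthy" for t, p in zip(y_true, y_pred))
    tn = sum(t != "unhealthy" and p != "unhealthy" for t, p in zip(y_true, y_pred))
    fp = sum(t != "unhealthy" and p == "unhealthy" for t, p in zip(y_true, y_pred))
    fn = sum(t == "unhealthy" and p != "unhealthy" for t, p in zip(y_true, y_pred))
    return {"TP": tp, "TN": tn, "FP": fp, "FN": fn}


def precision_recall_accuracy(counts: dict[str, int]) -> dict[str, float]:
    """Precision = TP/(TP+FP), Recall = TP/(TP+FN), Accuracy = (TP+TN)/all."""
    tp, tn, fp, fn = counts["TP"], counts["TN"], counts["FP"], counts["FN"]
    total = tp + tn + fp + fn
    return {
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
        "accuracy": (tp + tn) / total if total else float("nan"),
    }
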