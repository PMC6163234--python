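"""Empirical recovery of the classifier's decision boundaries.

Sweeps synthetic single-frame feature vectors along one feature while
holding every other feature inside its healthy range, and reads off where
the rule classifier flips between healthy and unhealthy. Used to verify
that the implemented rules realize the ergonomic constants (20 deg angle
rule, 0.40–0.70 m sight-distance band, 150-frame event minimum) as actual
decision boundaries rather than just stored numbers.
"""

from __future__ import annotations

import math

from .features import SemanticFeatureVector
from .rules import DEFAULT_THRESHOLDS, ErgonomicThresholds, FrameLabel, classify_frame, smooth_events

__all__ = [
    "healthy_reference_features",
    "empirical_angle_boundary_deg",
    "empirical_sight_distance_bounds_cm",
    "empirical_min_event_frames",
]

# mid-band healthy reference values: small body angles, gaze 22.5 deg below
# horizontal, 0.55 m sight distance, nominal seated scene relations
_HEALTHY_REF = dict(alpha=math.radians(5.0), beta=math.radians(5.0),
                    gamma=math.radians(-22.5), delta=0.55,
                    d_pc=70.0, d_sc=270.0, oa_pc=16800.0, oa_sc=0.0)


def healthy_reference_features(frame_index: int = 0, **overrides
                               ) -> SemanticFeatureVector:
    """A seated frame with every feature mid-band healthy; override freely."""
    vals = {"lateral": 0.0, **_HEALTHY_REF, **overrides}
    return SemanticFeatureVector(frame_index=frame_index, sitting=True, **vals)


def empirical_angle_boundary_deg(which: str = "lumbar",
                                 thr: ErgonomicThresholds = DEFAULT_THRESHOLDS,
                                 step_deg: float = 0.01,
                                 max_deg: float = 40.0) -> float:
    """Largest body angle (degrees) still classified healthy.

    Sweeps the lumbar (or cervical) angle from 0 up in ``step_deg`` steps
    with all other features mid-band healthy.
    """
    feature = {"lumbar": "alpha", "cervical": "beta"}[which]
    last_healthy = math.nan
    n = int(round(max_deg / step_deg))
    for i in range(n + 1):
        deg = round(i * step_deg, 6)
        fv = healthy_reference_features(**{feature: math.radians(deg)})
        if classify_frame(fv, sitting=True, thr=thr).state == "healthy":
            last_healthy = deg
    return round(last_healthy, 2)


def empirical_sight_distance_bounds_cm(thr: ErgonomicThresholds = DEFAULT_THRESHOLDS,
                                       step_cm: float = 0.1,
                                       lo_cm: float = 10.0,
                                       hi_cm: float = 120.0) -> tuple[float, float]:
    """(smallest, largest) sight distance in cm classified healthy."""
    smallest = largest = math.nan
    n = int(round((hi_cm - lo_cm) / step_cm))
    for i in range(n + 1):
        cm = round(lo_cm + i * step_cm, 6)
        fv = healthy_reference_features(delta=cm / 100.0)
        if classify_frame(fv, sitting=True, thr=thr).state == "healthy":
            if math.isnan(smallest):
                smallest = cm
            largest = cm
    return round(smallest, 1), round(largest, 1)


def empirical_min_event_frames(thr: ErgonomicThresholds = DEFAULT_THRESHOLDS,
                               max_run: int = 300, total: int = 600,
                               insert_at: int = 200) -> int:
    """Smallest unhealthy run length the temporal smoother emits as an event.

    For each run length, embeds a run of unhealthy frames in an otherwise
    healthy sequence and checks whether smoothing lets it survive.
    """
    for run in range(1, max_run + 1):
        labels = []
        for i in range(total):
            if insert_at <= i < insert_at + run:
                labels.append(FrameLabel(i, "unhealthy",
                                         violated_rules=frozenset({"lumbar_angle"}),
                                         subtype="lean_forward"))
            else:
                labels.append(FrameLabel(i, "healthy"))
        events = smooth_events(labels, thr)
        if any(e.state == "unhealthy" for e in events):
            return run
    return -1
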