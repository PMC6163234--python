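"""End-to-end analysis: detections + skeletons -> features -> labels -> events.

Ties the stages together the way the CLI and the benchmark use them:
per-frame scene association (sticky across frames), semantic feature
extraction, ergonomic rule classification with subtype naming, temporal
event smoothing, and the video-level verdict.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .features import SemanticFeatureVector, extract_features
from .geometry import DEFAULT_CONVENTIONS, CameraConventions, ScreenPoint, SkeletonFrame
from .io import RunConfig
from .rules import FrameLabel, PostureEvent, label_and_subtype, smooth_events, video_verdict
from .scene import Detection, associate_objects
from .synthetic import SyntheticVideo

__all__ = ["VideoAnalysis", "analyze_stream", "analyze_video", "benchmark_confusion"]


@dataclass
class VideoAnalysis:
    """All per-frame and aggregate outputs of one analyzed stream."""

    features: list[SemanticFeatureVector]
    labels: list[FrameLabel]
    events: list[PostureEvent]
    verdict: str


def analyze_stream(skeletons: list[SkeletonFrame], detections: list[Detection],
                   screen: ScreenPoint | None,
                   config: RunConfig | None = None,
                   conv: CameraConventions = DEFAULT_CONVENTIONS,
                   person_id: int | None = None) -> VideoAnalysis:
    """Run the full per-frame pipeline over one stream.

    Frames are processed in skeleton order; the scene assignment is carried
    frame to frame so pairings stay sticky. When several persons are
    tracked, ``person_id`` selects the subject (default: the first
    skeleton's person).
    """
    config = config or RunConfig()
    thr = config.thresholds.to_thresholds()
    assoc_cfg = config.association.to_config()

    by_frame: dict[int, list[Detection]] = defaultdict(list)
    for d in detections:
        by_frame[d.frame_index].append(d)

    if person_id is None and skeletons:
        person_id = skeletons[0].person_id
    skels = sorted((s for s in skeletons if s.person_id == person_id),
                   key=lambda s: s.frame_index)

    prev = None
    features: list[SemanticFeatureVector] = []
    labels: list[FrameLabel] = []
    for sk in skels:
        assignment = associate_objects(by_frame.get(sk.frame_index, []),
                                       prev=prev, config=assoc_cfg)
        prev = assignment
        fv = extract_features(sk, assignment, screen, conv,
                              association=assoc_cfg)
        features.append(fv)
        labels.append(label_and_subtype(fv, fv.sitting, thr))

    events = smooth_events(labels, thr, features=features) if labels else []
    return VideoAnalysis(features=features, labels=labels, events=events,
                         verdict=video_verdict(events))


def analyze_video(video: SyntheticVideo,
                  config: RunConfig | None = None) -> VideoAnalysis:
    """Analyze one synthetic video."""
    return analyze_stream(list(video.frames), list(video.detections),
                          video.screen, config)


def benchmark_confusion(videos: list[SyntheticVideo],
                        config: RunConfig | None = None
                        ) -> tuple[dict[str, int], list[str], list[str]]:
    """Video-level confusion counts over a labelled benchmark.

    Ground truth is unhealthy for every class except 'healthy'; the
    prediction is each video's smoothed verdict.
    Returns (counts, y_true, y_pred).
    """
    from .rules import confusion_counts

    y_true = ["healthy" if v.truth_class == "healthy" else "unhealthy"
              for v in videos]
    y_pred = [analyze_video(v, config).verdict for v in videos]
    return confusion_counts(y_true, y_pred), y_true, y_pred
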