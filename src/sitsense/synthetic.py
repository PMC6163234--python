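"""Seeded synthetic Kinect-style pose streams for the eight posture classes.

The generator emulates the study conditions the pipeline assumes: a
side-mounted depth camera 1.4 m above the floor viewing a seated person
2–3 m away at 30 fps, with one person, one chair and one screen per scene
(distractors can be added). Streams are built by *inverse geometry*: the
per-frame lumbar/cervical angles are drawn from a posture class's
truncated-normal ranges and the three joints are placed so the realized
angles equal the draws exactly; the screen point is placed from the
noise-free head pose so that the sight angle and distance realize the
class means (exactly at zero noise, within the joint noise otherwise).
Class ranges straddle the ergonomic thresholds — e.g. healthy lumbar
~N(8 deg, 3 deg) truncated below 18 deg, lean-forward ~N(33 deg, 4 deg)
truncated above 22 deg, matching the magnitudes the worked examples
report — so every unhealthy class violates its defining rule in every
frame and the healthy class violates none.

Everything is deterministic per seed; no global random state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import SpecError
from .geometry import DEFAULT_CONVENTIONS, CameraConventions, ScreenPoint, SkeletonFrame
from .scene import BoundingBox, Detection

__all__ = [
    "TruncNorm",
    "PostureClassSpec",
    "SyntheticVideo",
    "CLASS_NAMES",
    "DEFAULT_CLASS_SPECS",
    "generate_video",
    "generate_benchmark",
    "generate_cluttered_scene",
    "generate_gmm_samples",
]

CLASS_NAMES = ("healthy", "lean_forward", "hold_head", "lean_backward",
               "bend_over", "looking_up", "body_side", "small_sight_distance")

# torso (spine-base -> neck) and neck (neck -> head) segment lengths, meters
_TORSO_LEN = 0.45
_NECK_LEN = 0.25
# spine-base of a seated person: ~0.6 m above floor, 2.5 m from the camera
_SPINE_BASE = np.array([0.0, 0.60, 2.5])


@dataclass(frozen=True)
class TruncNorm:
    """Truncated normal draw spec: mean/sd with hard bounds (draws clipped)."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.hi < self.lo:
            raise SpecError(f"empty range [{self.lo}, {self.hi}]")
        if self.sd < 0:
            raise SpecError("sd must be non-negative")

    def draw(self, rng: np.random.Generator, n: int, noise_scale: float = 1.0
             ) -> np.ndarray:
        x = self.mean + noise_scale * self.sd * rng.standard_normal(n)
        return np.clip(x, self.lo, self.hi)


@dataclass(frozen=True)
class PostureClassSpec:
    """Generating ranges of one posture class (angles degrees, delta meters).

    ``azimuth_deg`` rotates the body tilt out of the sagittal plane
    (0 = toward the screen, 90 = fully sideways) and drives the lateral
    lean the body-sideways subtype rule detects. ``noise_scale`` globally
    scales every feature's sd (0 = noise-free). ``seated`` controls the
    box layout template.
    """

    name: str
    alpha_deg: TruncNorm
    beta_deg: TruncNorm
    gamma_deg: TruncNorm
    delta_m: TruncNorm
    azimuth_deg: float = 0.0
    n_frames: int = 600
    fps: float = 30.0
    noise_scale: float = 1.0
    box_jitter_px: float = 2.0
    seated: bool = True

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.fps <= 0:
            raise SpecError("n_frames must be >= 1 and fps > 0")
        if self.delta_m.lo < 0:
            raise SpecError("sight-distance range must be non-negative")


DEFAULT_CLASS_SPECS: dict[str, PostureClassSpec] = {
    "healthy": PostureClassSpec(
        "healthy", TruncNorm(8, 3, 0, 18), TruncNorm(8, 3, 0, 18),
        TruncNorm(-22, 3, -29, -16), TruncNorm(0.55, 0.05, 0.42, 0.68)),
    "lean_forward": PostureClassSpec(
        "lean_forward", TruncNorm(33, 4, 22, 45), TruncNorm(25, 3, 21, 40),
        TruncNorm(-39, 4, -50, -31), TruncNorm(0.35, 0.04, 0.20, 0.39)),
    "hold_head": PostureClassSpec(
        "hold_head", TruncNorm(12, 3, 0, 19), TruncNorm(30, 4, 22, 45),
        TruncNorm(-22, 3, -29, -16), TruncNorm(0.55, 0.05, 0.42, 0.68)),
    "lean_backward": PostureClassSpec(
        "lean_backward", TruncNorm(30, 4, 21, 45), TruncNorm(28, 4, 21, 45),
        TruncNorm(-20, 3, -29, -16), TruncNorm(0.85, 0.06, 0.72, 1.05)),
    "bend_over": PostureClassSpec(
        "bend_over", TruncNorm(60, 5, 52, 75), TruncNorm(40, 5, 25, 55),
        TruncNorm(-45, 5, -60, -32), TruncNorm(0.35, 0.05, 0.22, 0.45)),
    "looking_up": PostureClassSpec(
        "looking_up", TruncNorm(8, 3, 0, 18), TruncNorm(10, 3, 0, 18),
        TruncNorm(12, 4, 3, 25), TruncNorm(0.55, 0.05, 0.42, 0.68)),
    "body_side": PostureClassSpec(
        "body_side", TruncNorm(28, 4, 21, 42), TruncNorm(25, 4, 21, 40),
        TruncNorm(-22, 3, -29, -16), TruncNorm(0.55, 0.05, 0.42, 0.68),
        azimuth_deg=90.0),
    "small_sight_distance": PostureClassSpec(
        "small_sight_distance", TruncNorm(10, 3, 0, 18), TruncNorm(10, 3, 0, 18),
        TruncNorm(-25, 3, -29, -16), TruncNorm(0.30, 0.03, 0.18, 0.38)),
}

# pixel-space box layout (y-up, top-left anchored); a seated person
# overlaps the chair, the screen sits one desk-width away from the chair
_CHAIR_BOX = (280.0, 240.0, 120.0, 140.0)
_PERSON_SEATED_BOX = (270.0, 380.0, 140.0, 280.0)
_PERSON_STANDING_OFFSET = 420.0  # px shift away from the chair
_SCREEN_BOX = (460.0, 420.0, 100.0, 80.0)


@dataclass(frozen=True)
class SyntheticVideo:
    """One generated labelled stream: skeletons, detections, screen, truth."""

    frames: tuple[SkeletonFrame, ...]
    detections: tuple[Detection, ...]
    screen: ScreenPoint
    truth_class: str
    seed: int
    spec: PostureClassSpec
    truth_alpha: tuple[float, ...] = ()   # radians, per frame
    truth_beta: tuple[float, ...] = ()


def _tilt_direction(angle_rad: float, azimuth_rad: float) -> np.ndarray:
    """Unit vector at ``angle`` from vertical, rotated by ``azimuth`` out of
    the sagittal plane (azimuth 0 tilts toward the screen/+x)."""
    s = math.sin(angle_rad)
    return np.array([s * math.cos(azimuth_rad),
                     math.cos(angle_rad),
                     s * math.sin(azimuth_rad)])


def _build_skeleton(frame_index: int, alpha: float, beta: float,
                    azimuth: float, person_id: int = 1) -> SkeletonFrame:
    neck = _SPINE_BASE + _TORSO_LEN * _tilt_direction(alpha, azimuth)
    head = neck + _NECK_LEN * _tilt_direction(beta, azimuth)
    return SkeletonFrame(frame_index=frame_index,
                         spine_base=tuple(_SPINE_BASE), neck=tuple(neck),
                         head=tuple(head), person_id=person_id)


def _jitter_box(base: tuple[float, float, float, float],
                rng: np.random.Generator, jitter: float) -> BoundingBox:
    dx, dy = (rng.uniform(-jitter, jitter, size=2) if jitter > 0 else (0.0, 0.0))
    return BoundingBox(base[0] + float(dx), base[1] + float(dy), base[2], base[3])


def generate_video(spec: PostureClassSpec, seed: int = 0,
                   conv: CameraConventions = DEFAULT_CONVENTIONS) -> SyntheticVideo:
    """Generate one labelled video for a posture class, deterministic per seed."""
    rng = np.random.default_rng(seed)
    n = spec.n_frames
    az = math.radians(spec.azimuth_deg)

    alpha = np.radians(spec.alpha_deg.draw(rng, n, spec.noise_scale))
    beta = np.radians(spec.beta_deg.draw(rng, n, spec.noise_scale))

    # screen point from the noise-free head pose and the class-mean gaze
    head0 = (_SPINE_BASE
             + _TORSO_LEN * _tilt_direction(math.radians(spec.alpha_deg.mean), az)
             + _NECK_LEN * _tilt_direction(math.radians(spec.beta_deg.mean), az))
    g_mean = math.radians(spec.gamma_deg.mean)
    d_mean = spec.delta_m.mean
    if d_mean <= 0:
        raise SpecError("mean sight distance must be positive")
    screen = ScreenPoint(tuple(head0 + d_mean * np.array(
        [math.cos(g_mean), math.sin(g_mean), 0.0])))

    frames = tuple(_build_skeleton(i, float(alpha[i]), float(beta[i]), az)
                   for i in range(n))

    jitter = spec.box_jitter_px * spec.noise_scale
    person_base = list(_PERSON_SEATED_BOX)
    if not spec.seated:
        person_base[0] += _PERSON_STANDING_OFFSET
    detections = []
    for i in range(n):
        detections.append(Detection(i, "person",
                                    _jitter_box(tuple(person_base), rng, jitter),
                                    confidence=0.99, instance_id=1))
        detections.append(Detection(i, "chair",
                                    _jitter_box(_CHAIR_BOX, rng, jitter),
                                    confidence=0.98, instance_id=2))
        detections.append(Detection(i, "screen",
                                    _jitter_box(_SCREEN_BOX, rng, jitter),
                                    confidence=0.97, instance_id=3))

    return SyntheticVideo(frames=frames, detections=tuple(detections),
                          screen=screen, truth_class=spec.name, seed=seed,
                          spec=spec,
                          truth_alpha=tuple(float(a) for a in alpha),
                          truth_beta=tuple(float(b) for b in beta))


def generate_benchmark(n_per_class: int = 10, seed: int = 0,
                       specs: dict[str, PostureClassSpec] | None = None,
                       n_frames: int | None = None) -> list[SyntheticVideo]:
    """Balanced 8-class video set; per-video seeds derive from the master seed."""
    specs = dict(DEFAULT_CLASS_SPECS if specs is None else specs)
    rng = np.random.default_rng(seed)
    videos: list[SyntheticVideo] = []
    for name in CLASS_NAMES:
        if name not in specs:
            raise SpecError(f"missing class spec {name!r}")
        spec = specs[name]
        if n_frames is not None:
            spec = replace(spec, n_frames=n_frames)
        for _ in range(n_per_class):
            videos.append(generate_video(spec, seed=int(rng.integers(2 ** 31 - 1))))
    return videos


def generate_cluttered_scene(base: SyntheticVideo, extra_persons: int = 0,
                             extra_screens: int = 0, extra_chairs: int = 0,
                             seed: int = 0,
                             include_skeletons: bool = False) -> SyntheticVideo:
    """Add distractor detections the association rule must exclude.

    Extra screens/chairs are placed far from the primary chair; extra
    persons stand clear of every chair (no box overlap), so the primary
    triple and the ground truth are unchanged. Zero extras returns the
    base video unchanged.
    """
    if extra_persons == extra_screens == extra_chairs == 0:
        return base
    rng = np.random.default_rng(seed)
    n = base.spec.n_frames
    extras: list[Detection] = []
    next_id = 1 + max(d.instance_id for d in base.detections)

    def far_boxes(template, count, x_step):
        nonlocal next_id
        placed = []
        for j in range(count):
            x = template[0] + x_step * (j + 1) + float(rng.uniform(-5, 5))
            placed.append((BoundingBox(x, template[1], template[2], template[3]),
                           next_id))
            next_id += 1
        return placed

    screen_boxes = far_boxes(_SCREEN_BOX, extra_screens, 500.0)
    chair_boxes = far_boxes(_CHAIR_BOX, extra_chairs, 700.0)
    # extra persons go to the opposite side of the scene so they can never
    # overlap any chair (primary or distractor)
    person_boxes = far_boxes(
        (_PERSON_SEATED_BOX[0] - _PERSON_STANDING_OFFSET,) + _PERSON_SEATED_BOX[1:],
        extra_persons, -300.0)

    for i in range(n):
        for box, iid in screen_boxes:
            extras.append(Detection(i, "screen", box, 0.9, iid))
        for box, iid in chair_boxes:
            extras.append(Detection(i, "chair", box, 0.9, iid))
        for box, iid in person_boxes:
            extras.append(Detection(i, "person", box, 0.9, iid))

    frames = base.frames
    if include_skeletons and extra_persons:
        standing = []
        for i in range(n):
            sk = _build_skeleton(i, 0.0, 0.0, 0.0,
                                 person_id=person_boxes[0][1])
            standing.append(sk)
        frames = tuple(list(base.frames) + standing)

    return replace(base, frames=frames,
                   detections=tuple(list(base.detections) + extras))


def generate_gmm_samples(model, n: int, seed: int = 0
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral sampling from a mixture: component by weight, then Gaussian.

    Returns (samples, component_labels).
    """
    rng = np.random.default_rng(seed)
    k, d = model.means.shape
    labels = rng.choice(k, size=n, p=model.weights)
    X = np.empty((n, d))
    for i in range(k):
        idx = np.nonzero(labels == i)[0]
        if len(idx) == 0:
            continue
        L = np.linalg.cholesky(model.covariances[i])
        X[idx] = model.means[i] + rng.standard_normal((len(idx), d)) @ L.T
    return X, labels
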