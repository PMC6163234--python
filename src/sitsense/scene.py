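"""Scene-object spatial relations and person–chair–screen association.

Bounding boxes use the convention of the extraction formulas: (x, y) is the
top-left corner in a y-up pixel frame, so a box spans x..x+w horizontally
and y−h..y vertically, its center is (x + w/2, y − h/2). Image-style y-down
boxes can be converted with :func:`flip_box_y`.

Spatial relations are the per-frame semantic features C and D:

* center distance d between two boxes,
* overlapping area Oa, with signed extents clamped at zero so that
  disjoint rectangles report zero overlap.

:func:`associate_objects` resolves the person–chair–screen triple in
cluttered scenes (multiple persons / chairs / screens): each person claims
the chair with the greatest box overlap, each claimed chair the nearest
screen, with configurable gates and a sticky memory across frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidBoxError

__all__ = [
    "BoundingBox",
    "Detection",
    "PersonAssignment",
    "SceneAssignment",
    "AssociationConfig",
    "box_center_distance",
    "box_overlap_area",
    "associate_objects",
    "is_sitting",
    "flip_box_y",
]

LABELS = ("person", "chair", "screen")


@dataclass(frozen=True)
class BoundingBox:
    """Pixel-space rectangle: top-left (x, y) in a y-up frame, size (w, h)."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        vals = (self.x, self.y, self.w, self.h)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidBoxError(f"non-finite box {vals}")
        if self.w <= 0 or self.h <= 0:
            raise InvalidBoxError(f"non-positive box extent w={self.w}, h={self.h}")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y - self.h / 2.0)

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def diagonal(self) -> float:
        return math.hypot(self.w, self.h)


@dataclass(frozen=True)
class Detection:
    """One labelled object detection in one frame."""

    frame_index: int
    label: str
    box: BoundingBox
    confidence: float = 1.0
    instance_id: int = 0

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise InvalidBoxError(f"unknown label {self.label!r}; expected one of {LABELS}")
        if not 0.0 <= self.confidence <= 1.0:
            raise InvalidBoxError(f"confidence {self.confidence} outside [0, 1]")


def flip_box_y(box: BoundingBox, image_height: float) -> BoundingBox:
    """Convert an image-style y-down top-left box to the y-up convention."""
    return BoundingBox(box.x, image_height - box.y, box.w, box.h)


def box_center_distance(b1: BoundingBox, b2: BoundingBox) -> float:
    """Euclidean distance between box centers (x + w/2, y − h/2), pixels."""
    (cx1, cy1), (cx2, cy2) = b1.center, b2.center
    return math.hypot(cx1 - cx2, cy1 - cy2)


def box_overlap_area(b1: BoundingBox, b2: BoundingBox) -> float:
    """Intersection area in pixels^2; zero for disjoint boxes.

    Signed extents ox = min(x1+w1, x2+w2) − max(x1, x2) and
    oy = min(y1, y2) − max(y1−h1, y2−h2) are clamped at zero before the
    product, so disjoint rectangles report no overlap.
    """
    ox = min(b1.x + b1.w, b2.x + b2.w) - max(b1.x, b2.x)
    oy = min(b1.y, b2.y) - max(b1.y - b1.h, b2.y - b2.h)
    return max(ox, 0.0) * max(oy, 0.0)


@dataclass(frozen=True)
class AssociationConfig:
    """Gates and stickiness for the person–chair–screen association.

    ``min_chair_overlap_frac``: person–chair overlap must be at least this
    fraction of the person-box area for the chair to be claimable.
    ``max_screen_chair_diagonals``: screen–chair center distance gate in
    units of the chair diagonal.
    ``sitting_overlap_frac`` / ``sitting_max_diagonals``: the (tighter)
    gates :func:`is_sitting` applies.
    ``sticky_patience``: number of consecutive frames a previous pairing may
    fail its gate before it is dropped and re-associated.
    """

    min_chair_overlap_frac: float = 0.2
    max_screen_chair_diagonals: float = 4.0
    sitting_overlap_frac: float = 0.2
    sitting_max_diagonals: float = 1.0
    sticky_patience: int = 5


DEFAULT_ASSOCIATION = AssociationConfig()


@dataclass(frozen=True)
class PersonAssignment:
    """The chair/screen pairing of one tracked person, with pair metrics."""

    person_id: int
    chair_id: int | None = None
    screen_id: int | None = None
    pc_overlap: float = float("nan")   # person–chair overlap area, px^2
    pc_distance: float = float("nan")  # person–chair center distance, px
    sc_overlap: float = float("nan")   # screen–chair overlap area, px^2
    sc_distance: float = float("nan")  # screen–chair center distance, px
    person_area: float = float("nan")
    chair_diagonal: float = float("nan")
    gate_failures: int = 0


@dataclass(frozen=True)
class SceneAssignment:
    """All person assignments of one frame (at most one per person)."""

    frame_index: int
    assignments: tuple[PersonAssignment, ...] = field(default_factory=tuple)

    def for_person(self, person_id: int) -> PersonAssignment | None:
        for a in self.assignments:
            if a.person_id == person_id:
                return a
        return None


def _pair_metrics(person: Detection, chair: Detection | None,
                  screen: Detection | None) -> dict:
    m: dict = {"person_area": person.box.area}
    if chair is not None:
        m["pc_overlap"] = box_overlap_area(person.box, chair.box)
        m["pc_distance"] = box_center_distance(person.box, chair.box)
        m["chair_diagonal"] = chair.box.diagonal
        if screen is not None:
            m["sc_overlap"] = box_overlap_area(screen.box, chair.box)
            m["sc_distance"] = box_center_distance(screen.box, chair.box)
    return m


def _gates_pass(person: Detection, chair: Detection | None,
                screen: Detection | None, cfg: AssociationConfig) -> bool:
    if chair is None:
        return False
    ov = box_overlap_area(person.box, chair.box)
    if ov < cfg.min_chair_overlap_frac * person.box.area:
        return False
    if screen is not None:
        d = box_center_distance(screen.box, chair.box)
        if d > cfg.max_screen_chair_diagonals * chair.box.diagonal:
            return False
    return True


def associate_objects(detections: list[Detection],
                      prev: SceneAssignment | None = None,
                      config: AssociationConfig = DEFAULT_ASSOCIATION) -> SceneAssignment:
    """Resolve the person–chair–screen triples of one frame.

    Persons are processed in instance-id order; each claims the chair with
    the greatest box overlap (ties: smaller center distance, then smaller
    instance id) among chairs whose overlap clears the configured fraction
    of the person-box area, chairs being exclusive. The claimed chair takes
    the screen with the smallest center distance within the distance gate.
    A previous frame's pairing is kept while its objects are still detected
    and its gates pass, and survives up to ``sticky_patience`` consecutive
    gate failures before re-association. An empty detection list yields an
    empty assignment.
    """
    frame_index = detections[0].frame_index if detections else (
        prev.frame_index + 1 if prev is not None else 0)
    persons = sorted((d for d in detections if d.label == "person"),
                     key=lambda d: d.instance_id)
    chairs = {d.instance_id: d for d in detections if d.label == "chair"}
    screens = {d.instance_id: d for d in detections if d.label == "screen"}

    out: list[PersonAssignment] = []
    free_chairs = dict(sorted(chairs.items()))

    for person in persons:
        prev_a = prev.for_person(person.instance_id) if prev is not None else None
        assigned: PersonAssignment | None = None

        # sticky: keep the previous pairing while objects persist and gates pass
        if prev_a is not None and prev_a.chair_id in free_chairs:
            chair = free_chairs[prev_a.chair_id]
            screen = screens.get(prev_a.screen_id) if prev_a.screen_id is not None else None
            ok = _gates_pass(person, chair, screen, config)
            if ok or prev_a.gate_failures + 1 < config.sticky_patience:
                assigned = PersonAssignment(
                    person_id=person.instance_id,
                    chair_id=chair.instance_id,
                    screen_id=screen.instance_id if screen is not None else None,
                    gate_failures=0 if ok else prev_a.gate_failures + 1,
                    **_pair_metrics(person, chair, screen))
                del free_chairs[chair.instance_id]

        if assigned is None:
            best = None
            for cid, chair in free_chairs.items():
                ov = box_overlap_area(person.box, chair.box)
                if ov < config.min_chair_overlap_frac * person.box.area:
                    continue
                key = (-ov, box_center_distance(person.box, chair.box), cid)
                if best is None or key < best[0]:
                    best = (key, chair)
            if best is None:
                assigned = PersonAssignment(person_id=person.instance_id,
                                            person_area=person.box.area)
            else:
                chair = best[1]
                del free_chairs[chair.instance_id]
                screen = None
                best_s = None
                for sid, s in sorted(screens.items()):
                    d = box_center_distance(s.box, chair.box)
                    if d > config.max_screen_chair_diagonals * chair.box.diagonal:
                        continue
                    if best_s is None or (d, sid) < best_s[0]:
                        best_s = ((d, sid), s)
                if best_s is not None:
                    screen = best_s[1]
                assigned = PersonAssignment(
                    person_id=person.instance_id,
                    chair_id=chair.instance_id,
                    screen_id=screen.instance_id if screen is not None else None,
                    **_pair_metrics(person, chair, screen))
        out.append(assigned)

    return SceneAssignment(frame_index=frame_index, assignments=tuple(out))


def is_sitting(assignment: PersonAssignment,
               config: AssociationConfig = DEFAULT_ASSOCIATION) -> bool:
    """True iff the person is seated in their assigned chair.

    Requires a chair, a person–chair overlap of at least
    ``sitting_overlap_frac`` of the person-box area, and a center distance
    of at most ``sitting_max_diagonals`` chair diagonals. Absent chair
    (standing/walking person) is simply False, never an error.
    """
    if assignment.chair_id is None:
        return False
    if assignment.pc_overlap < config.sitting_overlap_frac * assignment.person_area:
        return False
    return assignment.pc_distance <= config.sitting_max_diagonals * assignment.chair_diagonal
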