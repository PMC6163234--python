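"""Readers/writers for the pipeline's text formats, and the run config.

Formats:

* skeleton streams — CSV ``frame,person_id,joint,x,y,z`` (joint one of
  spine_base/neck/head, meters) and an equivalent JSON array of row
  objects; both round-trip floats bit-exactly (repr-formatted),
* object detections — COCO-style JSON (images/annotations/categories with
  ``bbox`` = [x, y, w, h]) and a flat CSV
  ``frame,label,x,y,w,h,confidence,instance_id``; boxes are y-up top-left
  (use ``flip_y_image_height`` when reading image-style y-down boxes),
* per-frame features — CSV with the eight feature columns plus validity
  flags,
* mixture models — a JSON document with weights/means/covariances
  (row-major), scaler parameters and the EM trace,
* events — a JSON array of posture events; per-frame labels — CSV.

Output files carry a provenance comment/field (config digest + seed) so
runs are reproducible and attributable.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .errors import SitsenseError
from .features import FEATURE_NAMES, SemanticFeatureVector
from .geometry import ScreenPoint, SkeletonFrame
from .gmm import EMTrace, GMMModel, model_from_dict, model_to_dict
from .rules import ErgonomicThresholds, FrameLabel, PostureEvent
from .scene import AssociationConfig, BoundingBox, Detection, flip_box_y

__all__ = [
    "RunConfig",
    "load_config",
    "read_skeleton_csv", "write_skeleton_csv",
    "read_skeleton_json", "write_skeleton_json",
    "read_detections_csv", "write_detections_csv",
    "read_detections_coco", "write_detections_coco",
    "read_features_csv", "write_features_csv",
    "load_model", "save_model",
    "read_labels_csv", "write_labels_csv",
    "read_events_json", "write_events_json",
]

_JOINTS = ("spine_base", "neck", "head")


class GMMSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k: int = 2
    init: str = "kmeans++"
    seed: int = 0
    tol: float = 1e-7
    max_iter: int = 500
    reg_covar: float = 1e-6


class ThresholdSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_lumbar_deg: float = 20.0
    max_cervical_deg: float = 20.0
    sight_distance_healthy_m: tuple[float, float] = (0.40, 0.70)
    sight_angle_healthy_deg: tuple[float, float] = (15.0, 30.0)
    min_event_frames: int = 150
    bend_over_deg: float = 50.0
    body_side_deg: float = 15.0

    def to_thresholds(self) -> ErgonomicThresholds:
        return ErgonomicThresholds(**self.model_dump())


class AssociationSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_chair_overlap_frac: float = 0.2
    max_screen_chair_diagonals: float = 4.0
    sitting_overlap_frac: float = 0.2
    sitting_max_diagonals: float = 1.0
    sticky_patience: int = 5

    def to_config(self) -> AssociationConfig:
        return AssociationConfig(**self.model_dump())


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    thresholds: ThresholdSettings = Field(default_factory=ThresholdSettings)
    association: AssociationSettings = Field(default_factory=AssociationSettings)
    gmm: GMMSettings = Field(default_factory=GMMSettings)
    scaling: str = "zscore"  # zscore | minmax | none
    log_level: str = "INFO"

    def provenance(self, seed: int | None = None) -> str:
        doc = self.model_dump()
        if seed is not None:
            doc["seed"] = seed
        return json.dumps(doc, sort_keys=True)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML/JSON config file; missing path yields the defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


# ---------------------------------------------------------------- skeletons

def write_skeleton_csv(frames: list[SkeletonFrame], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "person_id", "joint", "x", "y", "z"])
        for f in frames:
            for joint in _JOINTS:
                x, y, z = getattr(f, joint)
                w.writerow([f.frame_index, f.person_id, joint,
                            repr(float(x)), repr(float(y)), repr(float(z))])


def _frames_from_rows(rows) -> list[SkeletonFrame]:
    acc: dict[tuple[int, int], dict] = {}
    order: list[tuple[int, int]] = []
    for r in rows:
        key = (int(r["frame"]), int(r["person_id"]))
        if key not in acc:
            acc[key] = {}
            order.append(key)
        acc[key][r["joint"]] = (float(r["x"]), float(r["y"]), float(r["z"]))
    out = []
    for frame, pid in order:
        joints = acc[(frame, pid)]
        missing = [j for j in _JOINTS if j not in joints]
        if missing:
            raise SitsenseError(
                f"frame {frame}, person {pid}: missing joints {missing}")
        out.append(SkeletonFrame(frame_index=frame, person_id=pid,
                                 spine_base=joints["spine_base"],
                                 neck=joints["neck"], head=joints["head"]))
    return out


def read_skeleton_csv(path: str | Path) -> list[SkeletonFrame]:
    with open(path, newline="") as fh:
        rows = [r for r in csv.DictReader(fh) if not r["frame"].startswith("#")]
    return _frames_from_rows(rows)


def write_skeleton_json(frames: list[SkeletonFrame], path: str | Path) -> None:
    rows = []
    for f in frames:
        for joint in _JOINTS:
            x, y, z = getattr(f, joint)
            rows.append({"frame": f.frame_index, "person_id": f.person_id,
                         "joint": joint, "x": float(x), "y": float(y),
                         "z": float(z)})
    Path(path).write_text(json.dumps(rows, indent=1))


def read_skeleton_json(path: str | Path) -> list[SkeletonFrame]:
    return _frames_from_rows(json.loads(Path(path).read_text()))


# --------------------------------------------------------------- detections

def write_detections_csv(dets: list[Detection], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "label", "x", "y", "w", "h", "confidence",
                    "instance_id"])
        for d in dets:
            w.writerow([d.frame_index, d.label, repr(d.box.x), repr(d.box.y),
                        repr(d.box.w), repr(d.box.h), repr(d.confidence),
                        d.instance_id])


def read_detections_csv(path: str | Path,
                        flip_y_image_height: float | None = None
                        ) -> list[Detection]:
    out = []
    with open(path, newline="") as fh:
        for i, r in enumerate(csv.DictReader(fh)):
            try:
                box = BoundingBox(float(r["x"]), float(r["y"]),
                                  float(r["w"]), float(r["h"]))
                if flip_y_image_height is not None:
                    box = flip_box_y(box, flip_y_image_height)
                out.append(Detection(int(r["frame"]), r["label"], box,
                                     float(r.get("confidence", 1.0)),
                                     int(r.get("instance_id", 0))))
            except (KeyError, ValueError, TypeError) as exc:
                raise SitsenseError(f"{path}: malformed detection row "
                                    f"{i + 2}: {exc}") from exc
    return out


def write_detections_coco(dets: list[Detection], path: str | Path) -> None:
    cats = [{"id": i + 1, "name": n} for i, n in
            enumerate(("person", "chair", "screen"))]
    cat_id = {c["name"]: c["id"] for c in cats}
    frames = sorted({d.frame_index for d in dets})
    images = [{"id": f + 1, "frame_index": f} for f in frames]
    img_id = {f: f + 1 for f in frames}
    anns = []
    for j, d in enumerate(dets):
        anns.append({"id": j + 1, "image_id": img_id[d.frame_index],
                     "category_id": cat_id[d.label],
                     "bbox": [d.box.x, d.box.y, d.box.w, d.box.h],
                     "score": d.confidence, "instance_id": d.instance_id})
    Path(path).write_text(json.dumps(
        {"images": images, "annotations": anns, "categories": cats}, indent=1))


def read_detections_coco(path: str | Path,
                         flip_y_image_height: float | None = None
                         ) -> list[Detection]:
    doc = json.loads(Path(path).read_text())
    cat_name = {c["id"]: c["name"] for c in doc["categories"]}
    frame_of = {im["id"]: im.get("frame_index", im["id"] - 1)
                for im in doc["images"]}
    out = []
    for a in doc["annotations"]:
        x, y, w, h = a["bbox"]
        box = BoundingBox(x, y, w, h)
        if flip_y_image_height is not None:
            box = flip_box_y(box, flip_y_image_height)
        out.append(Detection(frame_of[a["image_id"]], cat_name[a["category_id"]],
                             box, a.get("score", 1.0), a.get("instance_id", 0)))
    return out


def write_screen_json(screen: ScreenPoint, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"position": list(screen.position)}))


def read_screen_json(path: str | Path) -> ScreenPoint:
    doc = json.loads(Path(path).read_text())
    return ScreenPoint(tuple(doc["position"]))


# ----------------------------------------------------------------- features

def write_features_csv(fvs: list[SemanticFeatureVector], path: str | Path,
                       provenance: str | None = None) -> None:
    with open(path, "w", newline="") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        w = csv.writer(fh)
        w.writerow(["frame", "person_id", *FEATURE_NAMES,
                    *[f"valid_{n}" for n in FEATURE_NAMES],
                    "lateral", "sitting"])
        for f in fvs:
            vals = [repr(float(getattr(f, n))) for n in FEATURE_NAMES]
            flags = [int(f.is_valid(n)) for n in FEATURE_NAMES]
            w.writerow([f.frame_index, f.person_id, *vals, *flags,
                        repr(float(f.lateral)), int(f.sitting)])


def read_features_csv(path: str | Path) -> list[SemanticFeatureVector]:
    out = []
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    for r in csv.DictReader(lines):
        kwargs = {n: float(r[n]) for n in FEATURE_NAMES}
        for n in FEATURE_NAMES:
            if r[f"valid_{n}"] == "0":
                kwargs[n] = math.nan
        out.append(SemanticFeatureVector(
            frame_index=int(r["frame"]), person_id=int(r["person_id"]),
            lateral=float(r["lateral"]), sitting=r["sitting"] == "1", **kwargs))
    return out


# -------------------------------------------------------------------- model

def save_model(path: str | Path, model: GMMModel, scaler_state: dict | None = None,
               trace: EMTrace | None = None, seed: int | None = None,
               provenance: str | None = None) -> None:
    doc = model_to_dict(model, scaler_state=scaler_state, trace=trace, seed=seed)
    if provenance:
        doc["provenance"] = provenance
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> tuple[GMMModel, dict]:
    """Returns (model, full document) — the document holds scaler/trace/seed."""
    doc = json.loads(Path(path).read_text())
    return model_from_dict(doc), doc


# ------------------------------------------------------------ labels/events

def write_labels_csv(labels: list[FrameLabel], path: str | Path,
                     provenance: str | None = None) -> None:
    with open(path, "w", newline="") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        w = csv.writer(fh)
        w.writerow(["frame", "state", "subtype", "violated_rules"])
        for l in labels:
            w.writerow([l.frame_index, l.state, l.subtype,
                        ";".join(sorted(l.violated_rules))])


def read_labels_csv(path: str | Path) -> list[FrameLabel]:
    out = []
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    for r in csv.DictReader(lines):
        rules = frozenset(r["violated_rules"].split(";")) if r["violated_rules"] else frozenset()
        out.append(FrameLabel(int(r["frame"]), r["state"],
                              violated_rules=rules, subtype=r["subtype"]))
    return out


def write_events_json(events: list[PostureEvent], path: str | Path,
                      provenance: str | None = None) -> None:
    doc = {"events": [
        {"start_frame": e.start_frame, "end_frame": e.end_frame,
         "state": e.state, "subtype": e.subtype,
         "mean_features": e.mean_features} for e in events]}
    if provenance:
        doc["provenance"] = provenance
    Path(path).write_text(json.dumps(doc, indent=1))


def read_events_json(path: str | Path) -> list[PostureEvent]:
    doc = json.loads(Path(path).read_text())
    items = doc["events"] if isinstance(doc, dict) else doc
    return [PostureEvent(e["start_frame"], e["end_frame"], e["state"],
                         e.get("subtype", "none"), e.get("mean_features"))
            for e in items]
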