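"""Per-frame semantic feature vectors and the standardized feature matrix.

Each frame yields eight numeric features, mixing units (radians, meters,
pixels):

====== ============================================ =========
name   meaning                                      unit
====== ============================================ =========
alpha  lumbar angle (trunk lean vs vertical)        radians
beta   cervical angle (neck flexion vs vertical)    radians
gamma  signed gaze elevation (down = negative)      radians
delta  head-to-screen sight distance                meters
d_pc   person–chair box center distance             pixels
d_sc   screen–chair box center distance             pixels
oa_pc  person–chair box overlap area                pixels^2
oa_sc  screen–chair box overlap area                pixels^2
====== ============================================ =========

A feature whose inputs are missing (no screen detection, no assigned
chair, no 3-D screen point) is flagged invalid and stored as NaN — never
zero-filled. Because the units are mixed, the feature matrix used for
clustering is standardized (z-score by default, min-max or none by
configuration) with the parameters retained for the inverse transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import MinMaxScaler, StandardScaler

from . import geometry, scene
from .errors import AlignmentError, InsufficientDataError
from .geometry import CameraConventions, DEFAULT_CONVENTIONS, ScreenPoint, SkeletonFrame
from .scene import PersonAssignment, SceneAssignment

__all__ = [
    "FEATURE_NAMES",
    "SemanticFeatureVector",
    "FeatureMatrix",
    "SemanticFeatureScaler",
    "extract_features",
    "standardize",
]

FEATURE_NAMES = ("alpha", "beta", "gamma", "delta", "d_pc", "d_sc", "oa_pc", "oa_sc")


@dataclass(frozen=True)
class SemanticFeatureVector:
    """The eight per-frame semantic features of one tracked person.

    ``lateral`` is auxiliary (not one of the eight): the out-of-sagittal
    spine lean used only for the sideways-lean posture subtype. ``sitting``
    records the scene-level seated verdict for the frame.
    """

    frame_index: int
    alpha: float = math.nan
    beta: float = math.nan
    gamma: float = math.nan
    delta: float = math.nan
    d_pc: float = math.nan
    d_sc: float = math.nan
    oa_pc: float = math.nan
    oa_sc: float = math.nan
    person_id: int = 0
    lateral: float = math.nan
    sitting: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    def is_valid(self, name: str) -> bool:
        return math.isfinite(getattr(self, name))

    @property
    def validity(self) -> dict[str, bool]:
        return {n: self.is_valid(n) for n in FEATURE_NAMES}

    @property
    def all_valid(self) -> bool:
        return all(self.validity.values())

    def with_values(self, **kwargs) -> "SemanticFeatureVector":
        return replace(self, **kwargs)


def extract_features(skeleton: SkeletonFrame,
                     assignment: SceneAssignment | PersonAssignment | None,
                     screen: ScreenPoint | None,
                     conv: CameraConventions = DEFAULT_CONVENTIONS,
                     association: scene.AssociationConfig = scene.DEFAULT_ASSOCIATION,
                     ) -> SemanticFeatureVector:
    """Assemble the 8-feature vector of one frame.

    Body angles come from the skeleton, gaze features from the head joint
    and the 3-D screen point, spatial relations from the person's scene
    assignment. Missing chair/screen inputs flag the corresponding
    features invalid (NaN). Skeleton and assignment must agree on the
    frame index.
    """
    pa: PersonAssignment | None
    if isinstance(assignment, SceneAssignment):
        if assignment.frame_index != skeleton.frame_index:
            raise AlignmentError(
                f"skeleton frame {skeleton.frame_index} != "
                f"assignment frame {assignment.frame_index}")
        pa = assignment.for_person(skeleton.person_id)
    else:
        pa = assignment

    alpha = geometry.lumbar_angle(skeleton, conv)
    beta = geometry.cervical_angle(skeleton, conv)
    lateral = geometry.lateral_angle(skeleton, conv)

    gamma = delta = math.nan
    if screen is not None:
        gamma = geometry.sight_angle(skeleton.head, screen, conv)
        delta = geometry.sight_distance(skeleton.head, screen)

    d_pc = oa_pc = d_sc = oa_sc = math.nan
    sitting = False
    if pa is not None:
        if pa.chair_id is not None:
            d_pc, oa_pc = pa.pc_distance, pa.pc_overlap
            sitting = scene.is_sitting(pa, association)
            if pa.screen_id is not None:
                d_sc, oa_sc = pa.sc_distance, pa.sc_overlap

    return SemanticFeatureVector(
        frame_index=skeleton.frame_index, person_id=skeleton.person_id,
        alpha=alpha, beta=beta, gamma=gamma, delta=delta,
        d_pc=d_pc, d_sc=d_sc, oa_pc=oa_pc, oa_sc=oa_sc,
        lateral=lateral, sitting=sitting)


class SemanticFeatureScaler(BaseEstimator, TransformerMixin):
    """Column scaler for the mixed-unit feature matrix.

    ``mode='zscore'`` (default) centers and scales to unit variance with
    constant columns given scale 1; ``'minmax'`` maps to [0, 1];
    ``'none'`` is the identity. The fitted parameters support an exact
    inverse transform.
    """

    def __init__(self, mode: str = "zscore"):
        self.mode = mode

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.mode == "zscore":
            self._impl = StandardScaler().fit(X)
        elif self.mode == "minmax":
            self._impl = MinMaxScaler().fit(X)
        elif self.mode == "none":
            self._impl = None
        else:
            raise ValueError(f"unknown scaling mode {self.mode!r}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X.copy() if self._impl is None else self._impl.transform(X)

    def inverse_transform(self, X):
        X = np.asarray(X, dtype=float)
        return X.copy() if self._impl is None else self._impl.inverse_transform(X)

    def get_state(self) -> dict:
        """JSON-serializable fitted state."""
        st = {"mode": self.mode, "n_features_in": int(self.n_features_in_)}
        if self.mode == "zscore":
            st["mean"] = self._impl.mean_.tolist()
            st["scale"] = self._impl.scale_.tolist()
        elif self.mode == "minmax":
            st["min"] = self._impl.min_.tolist()
            st["scale"] = self._impl.scale_.tolist()
            st["data_min"] = self._impl.data_min_.tolist()
            st["data_max"] = self._impl.data_max_.tolist()
        return st

    @classmethod
    def from_state(cls, st: dict) -> "SemanticFeatureScaler":
        obj = cls(mode=st["mode"])
        obj.n_features_in_ = st["n_features_in"]
        if st["mode"] == "zscore":
            impl = StandardScaler()
            impl.mean_ = np.array(st["mean"], dtype=float)
            impl.scale_ = np.array(st["scale"], dtype=float)
            impl.var_ = impl.scale_ ** 2
            impl.n_features_in_ = obj.n_features_in_
            obj._impl = impl
        elif st["mode"] == "minmax":
            impl = MinMaxScaler()
            impl.min_ = np.array(st["min"], dtype=float)
            impl.scale_ = np.array(st["scale"], dtype=float)
            impl.data_min_ = np.array(st["data_min"], dtype=float)
            impl.data_max_ = np.array(st["data_max"], dtype=float)
            impl.n_features_in_ = obj.n_features_in_
            obj._impl = impl
        else:
            obj._impl = None
        return obj


@dataclass
class FeatureMatrix:
    """Standardized feature matrix over the frames entering clustering.

    Rows are the frames where all eight features are valid (and, when
    ``require_sitting``, the person is seated — clustering operates on
    seated behavior only); ``frame_indices`` maps rows back to frames.
    """

    X: np.ndarray                     # standardized, m x 8
    raw: np.ndarray                   # original units, m x 8
    frame_indices: np.ndarray         # m
    scaler: SemanticFeatureScaler
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def inverse(self, X=None) -> np.ndarray:
        return self.scaler.inverse_transform(self.X if X is None else X)


def standardize(features: list[SemanticFeatureVector], mode: str = "zscore",
                require_sitting: bool = True) -> FeatureMatrix:
    """Build the standardized matrix from per-frame feature vectors.

    Keeps rows with all eight features valid (optionally seated frames
    only); fewer than two such rows is an error.
    """
    rows = [f for f in features
            if f.all_valid and (f.sitting or not require_sitting)]
    if len(rows) < 2:
        raise InsufficientDataError(
            f"need >= 2 all-valid rows for standardization, got {len(rows)}")
    raw = np.vstack([f.as_array() for f in rows])
    idx = np.array([f.frame_index for f in rows], dtype=int)
    scaler = SemanticFeatureScaler(mode=mode).fit(raw)
    return FeatureMatrix(X=scaler.transform(raw), raw=raw,
                         frame_indices=idx, scaler=scaler)
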