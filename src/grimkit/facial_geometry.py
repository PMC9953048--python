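"""The seven facial parameters computed from profile landmarks.

Every parameter is a pure ratio of distances or an angle in degrees, so
all outputs are invariant under camera translation, rotation, uniform
zoom and reflection — measurements from different recordings and animal
sizes are directly comparable.

Parameter semantics (direction of change):

==================  ======================================================
eye_opening         larger = rounder, more open eye; 1 = perfectly round
ear_opening         larger = ear pavilion deployed sideways and visible
ear_angle           smaller = ear tilted instead of straight
ear_position        larger = ear positioned backward on the head
snout_position      smaller = pointier snout; larger = rounder
mouth_position      smaller = bottom lip brought forward
face_inclination    smaller = more convex profile; 0 = right angle at eye
==================  ======================================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .landmark_model import (
    PARAMETER_NAMES,
    LandmarkSet,
    ParameterVector,
    required_landmarks,
)

__all__ = [
    "GeometryConfig",
    "GeometryError",
    "IncompleteLandmarkSetError",
    "DegenerateGeometryError",
    "angle_at",
    "eye_opening",
    "ear_opening",
    "ear_angle",
    "ear_position",
    "snout_position",
    "mouth_position",
    "face_inclination",
    "compute_parameters",
    "compute_parameters_partial",
    "measure_table",
]


class GeometryError(ValueError):
    """Base class for landmark-geometry failures."""


class IncompleteLandmarkSetError(GeometryError):
    """A required landmark is absent from the set."""

    def __init__(self, landmark: str, parameter: Optional[str] = None):
        self.landmark = landmark
        self.parameter = parameter
        where = f" (required by {parameter})" if parameter else ""
        super().__init__(f"incomplete landmark set: missing {landmark!r}{where}")


class DegenerateGeometryError(GeometryError):
    """Two required landmarks coincide (or nearly so)."""

    def __init__(self, a: str, b: str, parameter: Optional[str] = None):
        self.pair = (a, b)
        self.parameter = parameter
        where = f" (parameter {parameter})" if parameter else ""
        super().__init__(f"degenerate geometry: coincident landmarks {a}/{b}{where}")


@dataclass(frozen=True)
class GeometryConfig:
    """Numerical settings for parameter computation.

    ``epsilon_coincident`` is the minimum allowed distance between any two
    required landmarks, expressed as a fraction of the skull-fixed
    eye_back–ear_orifice distance (falling back to an absolute pixel
    threshold when those landmarks are unavailable).
    """

    angle_units: str = "degrees"
    epsilon_coincident: float = 1e-9

    def __post_init__(self):
        if self.angle_units != "degrees":
            raise ValueError("angle_units is fixed to 'degrees'")
        if self.epsilon_coincident <= 0:
            raise ValueError("epsilon_coincident must be > 0")


_DEFAULT_CONFIG = GeometryConfig()


def angle_at(
    vertex: tuple[float, float], a: tuple[float, float], b: tuple[float, float]
) -> float:
    """Interior angle at ``vertex`` between rays vertex→a and vertex→b, degrees.

    Symmetric in ``(a, b)``; invariant under rotation, translation, uniform
    scaling and reflection; always in [0, 180].
    """
    ux, uy = a[0] - vertex[0], a[1] - vertex[1]
    vx, vy = b[0] - vertex[0], b[1] - vertex[1]
    if (ux == 0.0 and uy == 0.0) or (vx == 0.0 and vy == 0.0):
        raise DegenerateGeometryError("vertex", "ray-endpoint")
    # atan2 of |cross| and dot is numerically stable near 0 and 180 degrees,
    # unlike the arccos-of-normalized-dot form.
    cross = ux * vy - uy * vx
    dot = ux * vx + uy * vy
    return math.degrees(math.atan2(abs(cross), dot))


def _dist(p: tuple[float, float], q: tuple[float, float]) -> float:
    return math.hypot(p[0] - q[0], p[1] - q[1])


def _scale_reference(lm: LandmarkSet) -> float:
    if "eye_back" in lm and "ear_orifice" in lm:
        d = _dist(lm["eye_back"], lm["ear_orifice"])
        if d > 0:
            return d
    return 1.0


def _require(lm: LandmarkSet, parameter: str, cfg: GeometryConfig) -> dict:
    """Fetch required landmarks, raising on absence or coincidence."""
    names = sorted(required_landmarks(parameter))
    pts = {}
    for name in names:
        if name not in lm:
            raise IncompleteLandmarkSetError(name, parameter)
        pts[name] = lm[name]
    eps = cfg.epsilon_coincident * _scale_reference(lm)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if _dist(pts[a], pts[b]) <= eps:
                raise DegenerateGeometryError(a, b, parameter)
    return pts


def eye_opening(lm: LandmarkSet, cfg: GeometryConfig = _DEFAULT_CONFIG) -> float:
    """Vertical/horizontal eye aperture ratio; 1 for a perfectly round eye."""
    p = _require(lm, "eye_opening", cfg)
    return _dist(p["eye_top"], p["eye_bottom"]) / _dist(p["eye_front"], p["eye_back"])


def ear_opening(lm: LandmarkSet, cfg: GeometryConfig = _DEFAULT_CONFIG) -> float:
    """Ear-base width over base-midpoint→tip length; near 1 = deployed pavilion."""
    p = _require(lm, "ear_opening", cfg)
    base_front, base_back = p["ear_base_front"], p["ear_base_back"]
    mid = ((base_front[0] + base_back[0]) / 2.0, (base_front[1] + base_back[1]) / 2.0)
    return _dist(base_front, base_back) / _dist(mid, p["ear_tip"])


def ear_angle(lm: LandmarkSet, cfg: GeometryConfig = _DEFAULT_CONFIG) -> float:
    """Angle between the ear axis and the skull-fixed face axis, degrees.

    Ear axis: midpoint of the ear bases → ear tip.  Face axis: eye_back →
    ear_orifice; both endpoints are skull-fixed so head tilt cancels.
    Near 90 for a straight (erect) ear; decreases as the ear tilts.
    """
    p = _require(lm, "ear_angle", cfg)
    base_front, base_back = p["ear_base_front"], p["ear_base_back"]
    mid = ((base_front[0] + base_back[0]) / 2.0, (base_front[1] + base_back[1]) / 2.0)
    ear_vec = (p["ear_tip"][0] - mid[0], p["ear_tip"][1] - mid[1])
    face_vec = (
        p["ear_orifice"][0] - p["eye_back"][0],
        p["ear_orifice"][1] - p["eye_back"][1],
    )
    origin = (0.0, 0.0)
    return angle_at(origin, ear_vec, face_vec)


def ear_position(lm: LandmarkSet, cfg: GeometryConfig = _DEFAULT_CONFIG) -> float:
    """Eye→ear-base distance over the skull-fixed eye→ear-orifice distance.

    The denominator is rigid, making the ratio a zoom-free measure of ear
    displacement: larger values = ear positioned backward.
    """
    p = _require(lm, "ear_position", cfg)
    return _dist(p["eye_back"], p["ear_base_front"]) / _dist(
        p["eye_back"], p["ear_orifice"]
    )


def snout_position(lm: LandmarkSet, cfg: GeometryConfig = _DEFAULT_CONFIG) -> float:
    """Aperture angle at the snout tip, degrees; small = pointy snout."""
    p = _require(lm, "snout_position", cfg)
    return angle_at(p["snout_tip"], p["nose_top"], p["lower_snout"])


def mouth_position(lm: LandmarkSet, cfg: GeometryConfig = _DEFAULT_CONFIG) -> float:
    """Snout-tip→lower-lip distance over the snout-tip→eye distance.

    0 iff the lower lip coincides with the snout tip (maximally forward).
    """
    p = _require(lm, "mouth_position", cfg)
    return _dist(p["snout_tip"], p["lower_lip"]) / _dist(p["snout_tip"], p["eye_back"])


def face_inclination(lm: LandmarkSet, cfg: GeometryConfig = _DEFAULT_CONFIG) -> float:
    """Angle lower_snout–eye_back–ear_orifice minus 90 degrees.

    Zero when the profile makes a right angle at the eye corner; smaller
    values indicate a more convex profile.
    """
    p = _require(lm, "face_inclination", cfg)
    return angle_at(p["eye_back"], p["lower_snout"], p["ear_orifice"]) - 90.0


_PARAMETER_FUNCS = {
    "eye_opening": eye_opening,
    "ear_opening": ear_opening,
    "ear_angle": ear_angle,
    "ear_position": ear_position,
    "snout_position": snout_position,
    "mouth_position": mouth_position,
    "face_inclination": face_inclination,
}


def compute_parameters(
    lm: LandmarkSet, cfg: GeometryConfig = _DEFAULT_CONFIG
) -> ParameterVector:
    """Compute all seven facial parameters from a full landmark set.

    Identical to calling the seven parameter operations individually.
    Raises the first per-parameter error, annotated with the parameter
    name, if any landmark is missing or degenerate.
    """
    return ParameterVector(
        **{name: _PARAMETER_FUNCS[name](lm, cfg) for name in PARAMETER_NAMES}
    )


def compute_parameters_partial(
    lm: LandmarkSet, cfg: GeometryConfig = _DEFAULT_CONFIG
) -> tuple[dict[str, Optional[float]], dict[str, str]]:
    """Best-effort parameter computation.

    Returns ``(values, status)`` where ``status[name]`` is ``"ok"``,
    ``"missing"`` or ``"degenerate"``; values for non-ok parameters are
    ``None``.  Degenerate geometry is never silently reported as zero:
    silent zeros would corrupt downstream unit averages.
    """
    values: dict[str, Optional[float]] = {}
    status: dict[str, str] = {}
    for name in PARAMETER_NAMES:
        try:
            values[name] = _PARAMETER_FUNCS[name](lm, cfg)
            status[name] = "ok"
        except IncompleteLandmarkSetError:
            values[name] = None
            status[name] = "missing"
        except DegenerateGeometryError:
            values[name] = None
            status[name] = "degenerate"
    return values, status


_META_COLUMNS = (
    "frame_id",
    "animal_id",
    "experiment_id",
    "condition",
    "phase_time_s",
    "observer_id",
    "excluded",
    "exclusion_reason",
)


def measure_table(
    landmarks_long: pd.DataFrame, cfg: GeometryConfig = _DEFAULT_CONFIG
) -> pd.DataFrame:
    """Measure all frames of a long-format landmark table.

    ``landmarks_long`` has one row per (frame, landmark) with at least
    columns ``frame_id``, ``landmark``, ``x``, ``y``; metadata columns are
    carried through.  Returns one row per frame with the seven parameter
    columns plus a ``<name>_status`` column each (ok/missing/degenerate).
    """
    rows = []
    meta_cols = [c for c in _META_COLUMNS if c in landmarks_long.columns]
    for frame_id, grp in landmarks_long.groupby("frame_id", sort=False):
        points = {
            str(r.landmark): (float(r.x), float(r.y)) for r in grp.itertuples()
        }
        side = str(grp["side"].iloc[0]) if "side" in grp.columns else "right-profile"
        lm = LandmarkSet(points, side=side)
        values, status = compute_parameters_partial(lm, cfg)
        row = {c: grp[c].iloc[0] for c in meta_cols}
        row["frame_id"] = frame_id
        row.update(values)
        row.update({f"{name}_status": status[name] for name in PARAMETER_NAMES})
        rows.append(row)
    out = pd.DataFrame(rows)
    ordered = (
        meta_cols
        + [c for c in PARAMETER_NAMES]
        + [f"{c}_status" for c in PARAMETER_NAMES]
    )
    # frame_id may not be in meta_cols when absent from input metadata list
    if "frame_id" not in ordered:
        ordered = ["frame_id"] + ordered
    return out[[c for c in ordered if c in out.columns]]
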