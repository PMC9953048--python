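"""Canonical profile-landmark schema and frame records.

All downstream geometry consumes the 13-point vocabulary defined here.
Landmarks live in image (pixel) coordinates with y increasing downward;
because every derived facial parameter is a ratio or an angle, the pixel
convention never reaches the outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

#: The 13 canonical profile landmark names.
VOCABULARY: frozenset[str] = frozenset(
    {
        "eye_front",
        "eye_back",
        "eye_top",
        "eye_bottom",
        "ear_tip",
        "ear_base_front",
        "ear_base_back",
        "ear_orifice",
        "nose_top",
        "snout_tip",
        "lower_snout",
        "mouth_corner",
        "lower_lip",
    }
)

#: The seven facial parameters, in canonical order.
PARAMETER_NAMES: tuple[str, ...] = (
    "eye_opening",
    "ear_opening",
    "ear_angle",
    "ear_position",
    "snout_position",
    "mouth_position",
    "face_inclination",
)

#: Parameters measured in degrees; the rest are dimensionless ratios.
ANGLE_PARAMETERS: frozenset[str] = frozenset(
    {"ear_angle", "snout_position", "face_inclination"}
)

#: Valid value range per parameter (inclusive bounds).
PARAMETER_RANGES: dict[str, tuple[float, float]] = {
    "eye_opening": (0.0, math.inf),
    "ear_opening": (0.0, math.inf),
    "ear_angle": (0.0, 180.0),
    "ear_position": (0.0, math.inf),
    "snout_position": (0.0, 180.0),
    "mouth_position": (0.0, math.inf),
    "face_inclination": (-90.0, 90.0),
}

_REQUIRED_LANDMARKS: dict[str, frozenset[str]] = {
    "eye_opening": frozenset({"eye_front", "eye_back", "eye_top", "eye_bottom"}),
    "ear_opening": frozenset({"ear_base_front", "ear_base_back", "ear_tip"}),
    "ear_angle": frozenset(
        {"ear_base_front", "ear_base_back", "ear_tip", "eye_back", "ear_orifice"}
    ),
    "ear_position": frozenset({"eye_back", "ear_base_front", "ear_orifice"}),
    "snout_position": frozenset({"nose_top", "snout_tip", "lower_snout"}),
    "mouth_position": frozenset({"snout_tip", "lower_lip", "eye_back"}),
    "face_inclination": frozenset({"lower_snout", "eye_back", "ear_orifice"}),
}

EXCLUSION_REASONS = ("licking", "scratching", "other", "none")

SIDES = ("left-profile", "right-profile")


def required_landmarks(parameter_name: str) -> frozenset[str]:
    """Return the landmark subset a facial parameter is computed from.

    Parameters
    ----------
    parameter_name
        One of :data:`PARAMETER_NAMES`.

    Raises
    ------
    ValueError
        If ``parameter_name`` is not one of the seven facial parameters.
    """
    try:
        return _REQUIRED_LANDMARKS[parameter_name]
    except KeyError:
        raise ValueError(
            f"unknown facial parameter {parameter_name!r}; "
            f"expected one of {sorted(_REQUIRED_LANDMARKS)}"
        ) from None


@dataclass(frozen=True)
class Landmark:
    """A single named profile point in pixel coordinates."""

    name: str
    x: float
    y: float
    confidence: Optional[float] = None

    def validate(self) -> list[str]:
        violations = []
        if self.name not in VOCABULARY:
            violations.append(f"landmark.name: {self.name!r} not in canonical vocabulary")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            violations.append(f"landmark {self.name}: x/y must be finite")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            violations.append(
                f"landmark {self.name}: confidence {self.confidence} outside [0, 1]"
            )
        return violations


@dataclass(frozen=True)
class LandmarkSet:
    """Named 2-D points for one frame; the substrate of all parameters.

    ``points`` maps landmark names to ``(x, y)`` pixel coordinates.  ``side``
    records which profile the frame shows; all parameters are
    reflection-invariant, so the side is provenance only.
    """

    points: Mapping[str, tuple[float, float]]
    side: str = "right-profile"

    def __post_init__(self):
        object.__setattr__(self, "points", dict(self.points))

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.points[name]

    def get(self, name: str):
        return self.points.get(name)

    def names(self) -> frozenset[str]:
        return frozenset(self.points)

    def validate(self) -> list[str]:
        violations = []
        if self.side not in SIDES:
            violations.append(f"side: {self.side!r} not in {SIDES}")
        for name, (x, y) in self.points.items():
            violations.extend(Landmark(name, x, y).validate())
        return violations


@dataclass(frozen=True)
class ParameterVector:
    """The seven facial parameters for one frame or one averaged unit.

    Angles are in degrees; all other parameters are dimensionless ratios.
    Raw pixel quantities never appear here.
    """

    eye_opening: float
    ear_opening: float
    ear_angle: float
    ear_position: float
    snout_position: float
    mouth_position: float
    face_inclination: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}

    @classmethod
    def from_dict(cls, values: Mapping[str, float]) -> "ParameterVector":
        return cls(**{name: float(values[name]) for name in PARAMETER_NAMES})

    def validate(self) -> list[str]:
        violations = []
        for name in PARAMETER_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value):
                violations.append(f"parameters.{name}: value must be finite")
                continue
            lo, hi = PARAMETER_RANGES[name]
            if not (lo <= value <= hi):
                violations.append(
                    f"parameters.{name}: {value} outside [{lo}, {hi}]"
                )
        return violations


@dataclass
class FrameRecord:
    """One analyzed frame: metadata, exclusion flags, landmarks and/or parameters."""

    frame_id: str
    animal_id: str
    experiment_id: str
    condition: str
    phase_time_s: float
    observer_id: Optional[str] = None
    excluded: bool = False
    exclusion_reason: str = "none"
    landmarks: Optional[LandmarkSet] = None
    parameters: Optional[ParameterVector] = None


def _pairwise_coincidences(lm: LandmarkSet) -> list[str]:
    """Report required-landmark pairs, per parameter, at zero distance."""
    violations = []
    seen: set[tuple[str, str]] = set()
    for parameter in PARAMETER_NAMES:
        required = _REQUIRED_LANDMARKS[parameter]
        if not required <= lm.names():
            continue
        pts = sorted(required)
        for i, a in enumerate(pts):
            for b in pts[i + 1 :]:
                if (a, b) in seen:
                    continue
                (xa, ya), (xb, yb) = lm[a], lm[b]
                if math.hypot(xa - xb, ya - yb) == 0.0:
                    seen.add((a, b))
                    violations.append(
                        f"landmarks: coincident required landmarks "
                        f"{a}/{b} (parameter {parameter})"
                    )
    return violations


def validate_frame(record: FrameRecord) -> list[str]:
    """Check a frame record against all schema invariants.

    Returns an empty list iff the record is well formed; otherwise one
    descriptor per violation, naming the offending field and the rule
    broken.  Validation never raises; it is idempotent and side-effect
    free.
    """
    violations: list[str] = []
    if record.landmarks is None and record.parameters is None:
        violations.append("landmarks/parameters: at least one must be present")
    if record.excluded and record.exclusion_reason == "none":
        violations.append(
            "exclusion_reason: must not be 'none' when excluded is true"
        )
    if record.exclusion_reason not in EXCLUSION_REASONS:
        violations.append(
            f"exclusion_reason: {record.exclusion_reason!r} not in {EXCLUSION_REASONS}"
        )
    if record.landmarks is not None:
        violations.extend(record.landmarks.validate())
        violations.extend(_pairwise_coincidences(record.landmarks))
    if record.parameters is not None:
        violations.extend(record.parameters.validate())
    return violations
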