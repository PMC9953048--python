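"""Synthetic mouse-profile generator with known ground truth.

A canonical 13-point profile template stands in for a real right-profile
frame.  Deformations change exactly one facial parameter by a prescribed
amount through a parameter-specific landmark construction, and the
experiment simulator emulates multi-animal sessions: a baseline phase,
ordered stimulus conditions with per-condition parameter shifts,
per-individual random effects, per-frame measurement noise, camera
similarity jitter (which must never change any parameter) and random
behavioral exclusions.

Effects are expressed the way responses are analysed: multiplicative
factors for ratio parameters and additive degree shifts for angles, so the
generative truth maps directly onto expected proportional changes from
baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .facial_geometry import _PARAMETER_FUNCS, compute_parameters
from .landmark_model import (
    ANGLE_PARAMETERS,
    PARAMETER_NAMES,
    FrameRecord,
    LandmarkSet,
    ParameterVector,
)

__all__ = [
    "TEMPLATE_POINTS",
    "FaceTemplate",
    "EffectSpec",
    "SimulationDesign",
    "GroundTruth",
    "SimulationResult",
    "make_template",
    "deform",
    "similarity_transform",
    "simulate_experiment",
    "formalin_design",
]

#: Canonical right-profile landmark coordinates (pixels, y-down).  The four
#: eye points lie on a circle with top/bottom and front/back diametrically
#: opposed, so the template's eye-opening ratio is exactly 1.
TEMPLATE_POINTS: dict[str, tuple[float, float]] = {
    "eye_front": (452.0, 220.0),
    "eye_back": (428.0, 220.0),
    "eye_top": (440.0, 208.0),
    "eye_bottom": (440.0, 232.0),
    "ear_tip": (310.0, 95.0),
    "ear_base_front": (350.0, 160.0),
    "ear_base_back": (300.0, 170.0),
    "ear_orifice": (330.0, 240.0),
    "nose_top": (560.0, 230.0),
    "snout_tip": (580.0, 250.0),
    "lower_snout": (560.0, 280.0),
    "mouth_corner": (540.0, 285.0),
    "lower_lip": (525.0, 295.0),
}


@dataclass(frozen=True)
class FaceTemplate:
    """The canonical profile; stored coordinates are never mutated."""

    landmarks: LandmarkSet

    @property
    def parameters(self) -> ParameterVector:
        return compute_parameters(self.landmarks)


def make_template() -> FaceTemplate:
    """Return the canonical right-profile template (deterministic)."""
    return FaceTemplate(LandmarkSet(dict(TEMPLATE_POINTS), side="right-profile"))


# ---------------------------------------------------------------------------
# geometric helpers


def _rotate_about(
    p: tuple[float, float], center: tuple[float, float], deg: float
) -> tuple[float, float]:
    rad = math.radians(deg)
    c, s = math.cos(rad), math.sin(rad)
    dx, dy = p[0] - center[0], p[1] - center[1]
    return (center[0] + c * dx - s * dy, center[1] + s * dx + c * dy)


def similarity_transform(
    lm: LandmarkSet,
    rotation_deg: float = 0.0,
    scale: float = 1.0,
    translation: tuple[float, float] = (0.0, 0.0),
    reflect: bool = False,
) -> LandmarkSet:
    """Apply a camera-like similarity transform (optionally mirrored).

    Reflection flips x and swaps the recorded profile side; every facial
    parameter is invariant under all of these operations.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    rad = math.radians(rotation_deg)
    c, s = math.cos(rad), math.sin(rad)
    side = lm.side
    points = {}
    for name, (x, y) in lm.points.items():
        if reflect:
            x = -x
        xr = scale * (c * x - s * y) + translation[0]
        yr = scale * (s * x + c * y) + translation[1]
        points[name] = (xr, yr)
    if reflect:
        side = "left-profile" if side == "right-profile" else "right-profile"
    return LandmarkSet(points, side=side)


# ---------------------------------------------------------------------------
# exact single-parameter deformations

_DEFORM_TOL = 1e-9


def _measure(lm: LandmarkSet, parameter: str) -> float:
    return _PARAMETER_FUNCS[parameter](lm)


def _with_points(lm: LandmarkSet, updates: Mapping[str, tuple[float, float]]) -> LandmarkSet:
    pts = dict(lm.points)
    pts.update(updates)
    return LandmarkSet(pts, side=lm.side)


def _deform_eye_opening(lm: LandmarkSet, factor: float) -> LandmarkSet:
    top, bottom = lm["eye_top"], lm["eye_bottom"]
    mid = ((top[0] + bottom[0]) / 2, (top[1] + bottom[1]) / 2)
    return _with_points(
        lm,
        {
            "eye_top": (mid[0] + factor * (top[0] - mid[0]), mid[1] + factor * (top[1] - mid[1])),
            "eye_bottom": (
                mid[0] + factor * (bottom[0] - mid[0]),
                mid[1] + factor * (bottom[1] - mid[1]),
            ),
        },
    )


def _deform_ear_opening(lm: LandmarkSet, factor: float) -> LandmarkSet:
    # scale the base width about its midpoint; the base-mid -> tip length is
    # untouched, as are ear_angle's axis endpoints
    bf, bb = lm["ear_base_front"], lm["ear_base_back"]
    mid = ((bf[0] + bb[0]) / 2, (bf[1] + bb[1]) / 2)
    return _with_points(
        lm,
        {
            "ear_base_front": (mid[0] + factor * (bf[0] - mid[0]), mid[1] + factor * (bf[1] - mid[1])),
            "ear_base_back": (mid[0] + factor * (bb[0] - mid[0]), mid[1] + factor * (bb[1] - mid[1])),
        },
    )


def _deform_ear_angle(lm: LandmarkSet, delta: float) -> LandmarkSet:
    bf, bb = lm["ear_base_front"], lm["ear_base_back"]
    mid = ((bf[0] + bb[0]) / 2, (bf[1] + bb[1]) / 2)
    target = _measure(lm, "ear_angle") + delta
    best = None
    for sign in (1.0, -1.0):
        cand = _with_points(lm, {"ear_tip": _rotate_about(lm["ear_tip"], mid, sign * delta)})
        err = abs(_measure(cand, "ear_angle") - target)
        if best is None or err < best[0]:
            best = (err, cand)
    if best[0] > _DEFORM_TOL:
        raise ValueError(f"ear_angle delta {delta} leaves the valid range")
    return best[1]


def _deform_ear_position(lm: LandmarkSet, factor: float) -> LandmarkSet:
    # rigid translation of the whole ear along the skull-fixed face axis:
    # preserves ear_opening and ear_angle exactly
    eb, orif = lm["eye_back"], lm["ear_orifice"]
    axis = (orif[0] - eb[0], orif[1] - eb[1])
    norm = math.hypot(*axis)
    u = (axis[0] / norm, axis[1] / norm)
    bf = lm["ear_base_front"]
    v = (bf[0] - eb[0], bf[1] - eb[1])
    d0 = math.hypot(*v)
    b = u[0] * v[0] + u[1] * v[1]
    disc = b * b - d0 * d0 * (1.0 - factor * factor)
    if disc < 0:
        raise ValueError(f"ear_position factor {factor} unreachable along the face axis")
    roots = (-b + math.sqrt(disc), -b - math.sqrt(disc))
    t = min(roots, key=abs)
    shift = (t * u[0], t * u[1])
    updates = {
        name: (lm[name][0] + shift[0], lm[name][1] + shift[1])
        for name in ("ear_tip", "ear_base_front", "ear_base_back")
    }
    return _with_points(lm, updates)


def _deform_snout_position(lm: LandmarkSet, delta: float) -> LandmarkSet:
    tip = lm["snout_tip"]
    target = _measure(lm, "snout_position") + delta
    best = None
    for sign in (1.0, -1.0):
        cand = _with_points(
            lm, {"lower_snout": _rotate_about(lm["lower_snout"], tip, sign * delta)}
        )
        err = abs(_measure(cand, "snout_position") - target)
        if best is None or err < best[0]:
            best = (err, cand)
    if best[0] > _DEFORM_TOL:
        raise ValueError(f"snout_position delta {delta} leaves the valid range")
    return best[1]


def _deform_mouth_position(lm: LandmarkSet, factor: float) -> LandmarkSet:
    tip, lip = lm["snout_tip"], lm["lower_lip"]
    return _with_points(
        lm,
        {"lower_lip": (tip[0] + factor * (lip[0] - tip[0]), tip[1] + factor * (lip[1] - tip[1]))},
    )


def _deform_face_inclination(lm: LandmarkSet, delta: float) -> LandmarkSet:
    eb = lm["eye_back"]
    target = _measure(lm, "face_inclination") + delta
    best = None
    for sign in (1.0, -1.0):
        cand = _with_points(
            lm, {"lower_snout": _rotate_about(lm["lower_snout"], eb, sign * delta)}
        )
        err = abs(_measure(cand, "face_inclination") - target)
        if best is None or err < best[0]:
            best = (err, cand)
    if best[0] > _DEFORM_TOL:
        raise ValueError(f"face_inclination delta {delta} leaves the valid range")
    return best[1]


_DEFORMS = {
    "eye_opening": _deform_eye_opening,
    "ear_opening": _deform_ear_opening,
    "ear_angle": _deform_ear_angle,
    "ear_position": _deform_ear_position,
    "snout_position": _deform_snout_position,
    "mouth_position": _deform_mouth_position,
    "face_inclination": _deform_face_inclination,
}

#: Application order chosen so that earlier deformations are preserved by
#: later ones wherever the constructions allow it (the rigid ear_position
#: translation preserves ear_opening and ear_angle, for example).
_DEFORM_ORDER = (
    "eye_opening",
    "ear_opening",
    "ear_angle",
    "ear_position",
    "mouth_position",
    "snout_position",
    "face_inclination",
)


def deform(template: FaceTemplate | LandmarkSet, parameter_name: str, delta: float) -> LandmarkSet:
    """Deform the template so one parameter changes by exactly ``delta``.

    ``delta`` is a multiplicative factor for ratio parameters (1.0 is a
    no-op) and an additive degree shift for angle parameters (0.0 is a
    no-op).  The target parameter is achieved to within 1e-9; required
    landmarks of non-overlapping parameters are untouched.
    """
    lm = template.landmarks if isinstance(template, FaceTemplate) else template
    if parameter_name not in _DEFORMS:
        raise ValueError(f"unknown facial parameter {parameter_name!r}")
    if parameter_name in ANGLE_PARAMETERS:
        if delta == 0.0:
            return lm
        expected = _measure(lm, parameter_name) + delta
    else:
        if delta <= 0.0:
            raise ValueError("ratio factors must be > 0")
        if delta == 1.0:
            return lm
        expected = _measure(lm, parameter_name) * delta
    out = _DEFORMS[parameter_name](lm, delta)
    achieved = _measure(out, parameter_name)
    if abs(achieved - expected) > max(_DEFORM_TOL, 1e-12 * abs(expected)):
        raise ValueError(
            f"deform({parameter_name}, {delta}) out of range: achieved {achieved}, "
            f"expected {expected}"
        )
    return out


# ---------------------------------------------------------------------------
# experiment simulation


@dataclass(frozen=True)
class EffectSpec:
    """Generative truth for one condition.

    ``deltas`` maps parameter names to a multiplicative factor (ratios) or
    an additive degree shift (angles); parameters absent from the mapping
    are unaffected.
    """

    condition: str
    deltas: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name, delta in self.deltas.items():
            if name not in PARAMETER_NAMES:
                raise ValueError(f"unknown parameter {name!r} in effect spec")
            if name not in ANGLE_PARAMETERS and delta <= 0:
                raise ValueError(f"{name}: ratio factor must be > 0, got {delta}")

    def true_proportional_change(self, base: ParameterVector) -> dict[str, float]:
        """Expected (stimulus - baseline)/baseline per parameter."""
        out = {}
        for name in PARAMETER_NAMES:
            delta = self.deltas.get(name)
            if delta is None:
                out[name] = 0.0
            elif name in ANGLE_PARAMETERS:
                out[name] = delta / getattr(base, name)
            else:
                out[name] = delta - 1.0
        return out


@dataclass(frozen=True)
class SimulationDesign:
    """Session design: animals, condition order, sampling and noise model.

    Defaults emulate a multi-stimulus session: 4-6 analyzable frames per
    condition per animal (mean about 5), 5% between-animal variation, 3%
    per-frame measurement noise, moderate camera jitter, and a 10% chance
    that a frame is excluded for confounding behavior.  SDs are fractions
    of the template value for ratio parameters, and fractions of the
    template value in degrees for angle parameters.
    """

    n_animals: int = 30
    conditions: tuple[str, ...] = ("baseline", "stimulus")
    baseline_condition: str = "baseline"
    frames_per_condition: tuple[int, int] = (4, 6)  # inclusive uniform range
    schedule: str = "count"  # "count" | "per-minute"
    phase_minutes: float = 30.0  # per-minute schedule length per condition
    condition_window_s: float = 120.0
    animal_sd: float = 0.05
    frame_noise_sd: float = 0.03
    jitter_rotation_deg: float = 10.0
    jitter_scale: tuple[float, float] = (0.8, 1.25)
    jitter_translation_px: float = 50.0
    exclusion_rate: float = 0.1
    mechanism: str = "parameter"  # "parameter" | "landmark"
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.baseline_condition not in self.conditions:
            raise ValueError("conditions must include the baseline condition")
        if self.frames_per_condition[0] < 1 or (
            self.frames_per_condition[0] > self.frames_per_condition[1]
        ):
            raise ValueError("frames_per_condition must be an increasing range >= 1")
        if not (0.0 <= self.exclusion_rate < 1.0):
            raise ValueError("exclusion_rate must be in [0, 1)")
        if self.animal_sd < 0 or self.frame_noise_sd < 0:
            raise ValueError("SDs must be >= 0")
        if self.schedule not in ("count", "per-minute"):
            raise ValueError("schedule must be 'count' or 'per-minute'")
        if self.mechanism not in ("parameter", "landmark"):
            raise ValueError("mechanism must be 'parameter' or 'landmark'")


@dataclass(frozen=True)
class GroundTruth:
    """Generative truth emitted alongside each simulated frame table."""

    true_change: dict[str, dict[str, float]]  # condition -> parameter -> change
    animal_effects: pd.DataFrame  # animal_id x parameter fractional effects
    seed: Optional[int]
    design: SimulationDesign


@dataclass(frozen=True)
class SimulationResult:
    frames: pd.DataFrame  # one row per frame with the seven parameters
    landmarks: Optional[pd.DataFrame]  # long format, landmark mechanism only
    truth: GroundTruth


def formalin_design(n_animals: int = 10, seed: Optional[int] = None, **overrides) -> SimulationDesign:
    """Formalin-test sampling schedule: one frame per minute over a 30-min
    baseline phase and a 30-min post-injection phase (60 frames/animal)."""
    kwargs = dict(
        n_animals=n_animals,
        conditions=("baseline", "formalin"),
        schedule="per-minute",
        phase_minutes=30.0,
        exclusion_rate=0.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationDesign(**kwargs)


def _frame_values(
    base: ParameterVector,
    effect: Optional[EffectSpec],
    animal_effect: Mapping[str, float],
    noise: Mapping[str, float],
) -> dict[str, float]:
    out = {}
    for name in PARAMETER_NAMES:
        b = getattr(base, name)
        delta = effect.deltas.get(name) if effect is not None else None
        if name in ANGLE_PARAMETERS:
            shift = delta if delta is not None else 0.0
            out[name] = b + shift + (animal_effect[name] + noise[name]) * abs(b)
        else:
            factor = delta if delta is not None else 1.0
            out[name] = b * factor * (1.0 + animal_effect[name]) * (1.0 + noise[name])
    return out


def _landmark_frame(
    template: FaceTemplate,
    effect: Optional[EffectSpec],
    animal_effect: Mapping[str, float],
    noise: Mapping[str, float],
    base: ParameterVector,
) -> LandmarkSet:
    lm = template.landmarks
    for name in _DEFORM_ORDER:
        delta = effect.deltas.get(name) if effect is not None else None
        wobble = animal_effect[name] + noise[name]
        if name in ANGLE_PARAMETERS:
            total = (delta if delta is not None else 0.0) + wobble * abs(getattr(base, name))
            if total != 0.0:
                lm = deform(lm, name, total)
        else:
            total = (delta if delta is not None else 1.0) * (1.0 + wobble)
            if total != 1.0:
                lm = deform(lm, name, total)
    return lm


def simulate_experiment(
    design: SimulationDesign,
    effects: Sequence[EffectSpec] = (),
    seed: Optional[int] = None,
) -> SimulationResult:
    """Simulate a multi-animal session with known generative truth.

    For every animal and condition the simulator draws a frame count,
    applies the condition effect, the animal's random effect and per-frame
    noise (in the design's mechanism space), applies camera similarity
    jitter per frame — which never changes any parameter — and marks
    random exclusions.  Fully reproducible from ``seed`` (falling back to
    ``design.seed``).
    """
    effect_by_condition = {e.condition: e for e in effects}
    unknown = set(effect_by_condition) - set(design.conditions)
    if unknown:
        raise ValueError(f"effects reference unknown conditions: {sorted(unknown)}")
    if design.baseline_condition in effect_by_condition:
        raise ValueError("the baseline condition cannot carry an effect")
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    template = make_template()
    base = template.parameters

    animal_ids = [f"animal_{i + 1:03d}" for i in range(design.n_animals)]
    animal_eff = pd.DataFrame(
        rng.normal(0.0, design.animal_sd, size=(design.n_animals, len(PARAMETER_NAMES))),
        index=animal_ids,
        columns=list(PARAMETER_NAMES),
    )

    frame_rows: list[dict] = []
    landmark_rows: list[dict] = []
    for animal_id in animal_ids:
        a_eff = animal_eff.loc[animal_id]
        for condition in design.conditions:
            effect = effect_by_condition.get(condition)
            if design.schedule == "per-minute":
                n_frames = int(round(design.phase_minutes))
                times = [60.0 * i for i in range(n_frames)]
            else:
                lo, hi = design.frames_per_condition
                n_frames = int(rng.integers(lo, hi + 1))
                times = sorted(
                    rng.uniform(0.0, design.condition_window_s, size=n_frames).tolist()
                )
            for i in range(n_frames):
                noise = dict(
                    zip(
                        PARAMETER_NAMES,
                        rng.normal(0.0, design.frame_noise_sd, size=len(PARAMETER_NAMES)),
                    )
                )
                excluded = bool(rng.random() < design.exclusion_rate)
                reason = (
                    str(rng.choice(["licking", "scratching"])) if excluded else "none"
                )
                frame_id = f"{animal_id}_{condition}_{i + 1:03d}"
                row = {
                    "frame_id": frame_id,
                    "animal_id": animal_id,
                    "experiment_id": "simulated",
                    "condition": condition,
                    "phase_time_s": times[i],
                    "excluded": excluded,
                    "exclusion_reason": reason,
                }
                rotation = rng.uniform(
                    -design.jitter_rotation_deg, design.jitter_rotation_deg
                )
                scale = rng.uniform(*design.jitter_scale)
                translation = tuple(
                    rng.uniform(
                        -design.jitter_translation_px,
                        design.jitter_translation_px,
                        size=2,
                    )
                )
                if design.mechanism == "parameter":
                    row.update(_frame_values(base, effect, a_eff, noise))
                else:
                    lm = _landmark_frame(template, effect, a_eff, noise, base)
                    lm = similarity_transform(
                        lm, rotation_deg=rotation, scale=scale, translation=translation
                    )
                    row.update(compute_parameters(lm).as_dict())
                    for name, (x, y) in lm.points.items():
                        landmark_rows.append(
                            {
                                "frame_id": frame_id,
                                "animal_id": animal_id,
                                "experiment_id": "simulated",
                                "condition": condition,
                                "phase_time_s": times[i],
                                "observer_id": "",
                                "excluded": excluded,
                                "exclusion_reason": reason,
                                "side": lm.side,
                                "landmark": name,
                                "x": x,
                                "y": y,
                                "confidence": 1.0,
                            }
                        )
                frame_rows.append(row)

    truth = GroundTruth(
        true_change={
            c: (
                effect_by_condition[c].true_proportional_change(base)
                if c in effect_by_condition
                else {name: 0.0 for name in PARAMETER_NAMES}
            )
            for c in design.conditions
        },
        animal_effects=animal_eff,
        seed=seed,
        design=design,
    )
    landmarks = pd.DataFrame(landmark_rows) if landmark_rows else None
    return SimulationResult(frames=pd.DataFrame(frame_rows), landmarks=landmarks, truth=truth)
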