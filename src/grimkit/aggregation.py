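"""Frame selection, per-individual averaging, baseline normalization, binning.

The analysis unit throughout is the per-individual per-condition average of
frame-level parameters ("unit"); stimulus responses are expressed as the
proportional change from the same individual's baseline,
``(stimulus - baseline) / baseline``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .landmark_model import PARAMETER_NAMES

__all__ = [
    "SelectionRules",
    "TASTANT_CONDITIONS",
    "select_frames",
    "unit_average",
    "proportional_change",
    "formalin_bins",
    "formalin_phases",
    "pool_conditions",
]

#: Conditions sampled only around discrete tasting events.
TASTANT_CONDITIONS = frozenset({"water", "sucrose", "quinine", "mentholatum"})


@dataclass
class SelectionRules:
    """Frame-selection configuration.

    ``tasting_events`` maps animal_id to the times (seconds since condition
    onset) at which the animal tasted the solution.  For tastant conditions
    only frames within ``tastant_window_s`` seconds after a tasting event are
    analysed, to avoid taste fading; the window is closed on both ends.
    """

    tasting_events: Mapping[str, Sequence[float]] = field(default_factory=dict)
    tastant_window_s: float = 5.0
    tastant_conditions: frozenset = TASTANT_CONDITIONS


class MissingTastingEventsError(ValueError):
    pass


class MissingBaselineError(ValueError):
    pass


class DuplicateUnitError(ValueError):
    pass


def _param_cols(df: pd.DataFrame) -> list[str]:
    return [c for c in PARAMETER_NAMES if c in df.columns]


def select_frames(
    records: pd.DataFrame, condition: str, rules: Optional[SelectionRules] = None
) -> pd.DataFrame:
    """Select analyzable frames for one condition.

    Frames flagged ``excluded`` (licking, scratching, ...) are always
    dropped.  For tastant conditions, only frames whose ``phase_time_s``
    falls within ``[t, t + window]`` of a tasting event for that animal are
    retained.
    """
    rules = rules or SelectionRules()
    sel = records[records["condition"] == condition]
    if "excluded" in sel.columns:
        sel = sel[~sel["excluded"].astype(bool)]
    if condition not in rules.tastant_conditions:
        return sel.reset_index(drop=True)

    def _in_window(row) -> bool:
        events = rules.tasting_events.get(row.animal_id)
        if events is None:
            raise MissingTastingEventsError(
                f"tastant condition {condition!r}: no tasting events "
                f"for animal {row.animal_id!r}"
            )
        t = row.phase_time_s
        return any(e <= t <= e + rules.tastant_window_s for e in events)

    if sel.empty:
        if not rules.tasting_events:
            raise MissingTastingEventsError(
                f"tastant condition {condition!r}: no tasting events supplied"
            )
        return sel.reset_index(drop=True)
    keep = [_in_window(row) for row in sel.itertuples()]
    return sel[np.asarray(keep, dtype=bool)].reset_index(drop=True)


def unit_average(records: pd.DataFrame) -> pd.DataFrame:
    """Average frames into a single value per (animal, condition).

    Excluded frames are ignored.  Groups with no frames are simply absent
    from the output, never zero-filled.  Returns one row per unit with the
    seven parameter means and ``n_frames``.
    """
    df = records
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    params = _param_cols(df)
    keys = ["animal_id", "condition"]
    if "experiment_id" in df.columns:
        keys = ["experiment_id"] + keys
    grouped = df.groupby(keys, sort=False, dropna=False)
    out = grouped[params].mean()
    out["n_frames"] = grouped.size()
    return out.reset_index()


def proportional_change(
    units: pd.DataFrame, baseline_condition: str = "baseline"
) -> pd.DataFrame:
    """Proportional change from each individual's baseline unit.

    For each stimulus unit, each parameter becomes
    ``(stimulus - baseline) / baseline``.  Baseline rows map to exactly 0.
    A baseline value of exactly 0 yields NaN (undefined) for that
    parameter rather than an infinity.

    Raises
    ------
    MissingBaselineError
        If any animal lacks a baseline unit; the message lists the animals.
    """
    params = _param_cols(units)
    base = units[units["condition"] == baseline_condition]
    missing = sorted(
        set(units["animal_id"]) - set(base["animal_id"])
    )
    if missing:
        raise MissingBaselineError(
            f"no baseline unit for animals: {', '.join(map(str, missing))}"
        )
    base_by_animal = base.set_index("animal_id")[params]
    rows = []
    for row in units.itertuples():
        b = base_by_animal.loc[row.animal_id]
        if isinstance(b, pd.DataFrame):  # duplicate baselines: average them
            b = b.mean()
        rec = {"animal_id": row.animal_id, "condition": row.condition}
        if "experiment_id" in units.columns:
            rec["experiment_id"] = row.experiment_id
        for p in params:
            bv = float(b[p])
            sv = float(getattr(row, p))
            if row.condition == baseline_condition:
                rec[p] = 0.0
            elif bv == 0.0:
                rec[p] = np.nan
            else:
                rec[p] = (sv - bv) / bv
        rows.append(rec)
    return pd.DataFrame(rows)


def formalin_bins(
    records: pd.DataFrame,
    baseline_condition: str = "baseline",
    post_condition: str = "formalin",
    baseline_min: float = 30.0,
    post_min: float = 30.0,
    bin_min: float = 5.0,
) -> pd.DataFrame:
    """Bin a two-phase (baseline + post-injection) time course.

    The whole baseline phase is averaged into one reference bin; the
    post-injection phase is split into half-open ``[start, end)`` intervals
    of ``bin_min`` minutes (six 5-min bins by default).  Frames outside
    both windows are dropped with a warning.  Returns one row per
    (animal, bin) with parameter means, ``n_frames``, ``start_min`` and
    ``end_min``.
    """
    df = records
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    params = _param_cols(df)
    n_bins = int(round(post_min / bin_min))
    rows = []
    n_dropped = 0
    for animal_id, grp in df.groupby("animal_id", sort=False):
        base = grp[grp["condition"] == baseline_condition]
        t_base = base["phase_time_s"] / 60.0
        in_base = (t_base >= 0) & (t_base < baseline_min)
        n_dropped += int((~in_base).sum())
        base = base[in_base]
        if len(base):
            rows.append(
                {
                    "animal_id": animal_id,
                    "bin_label": "baseline",
                    "start_min": 0.0,
                    "end_min": baseline_min,
                    "n_frames": len(base),
                    **{p: base[p].mean() for p in params},
                }
            )
        post = grp[grp["condition"] == post_condition]
        t_post = post["phase_time_s"].to_numpy() / 60.0
        for k in range(n_bins):
            lo, hi = k * bin_min, (k + 1) * bin_min
            mask = (t_post >= lo) & (t_post < hi)
            sub = post[mask]
            if len(sub):
                rows.append(
                    {
                        "animal_id": animal_id,
                        "bin_label": str(k + 1),
                        "start_min": lo,
                        "end_min": hi,
                        "n_frames": len(sub),
                        **{p: sub[p].mean() for p in params},
                    }
                )
        n_dropped += int((t_post >= post_min).sum() + (t_post < 0).sum())
    if n_dropped:
        warnings.warn(
            f"formalin_bins: dropped {n_dropped} frame(s) outside the "
            "baseline/post windows",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def formalin_phases(
    records: pd.DataFrame,
    baseline_condition: str = "baseline",
    post_condition: str = "formalin",
    early_min: tuple[float, float] = (0.0, 5.0),
    late_min: tuple[float, float] = (20.0, 30.0),
) -> pd.DataFrame:
    """Early/late phase summaries of the post-injection time course.

    Early phase: the first 5 min after injection; late phase: the 20–30 min
    interval, matching the biphasic nocifensive response to formalin.
    Returns rows labelled ``baseline``, ``early`` and ``late`` per animal.
    """
    df = records
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    params = _param_cols(df)
    rows = []
    for animal_id, grp in df.groupby("animal_id", sort=False):
        base = grp[grp["condition"] == baseline_condition]
        if len(base):
            rows.append(
                {"animal_id": animal_id, "phase": "baseline", "n_frames": len(base)}
                | {p: base[p].mean() for p in params}
            )
        post = grp[grp["condition"] == post_condition]
        t = post["phase_time_s"].to_numpy() / 60.0
        for label, (lo, hi) in (("early", early_min), ("late", late_min)):
            sub = post[(t >= lo) & (t < hi)]
            if len(sub):
                rows.append(
                    {"animal_id": animal_id, "phase": label, "n_frames": len(sub)}
                    | {p: sub[p].mean() for p in params}
                )
    return pd.DataFrame(rows)


def pool_conditions(
    unit_tables: Iterable[pd.DataFrame],
    condition_map: Optional[Mapping[str, str]] = None,
    allow_duplicates: bool = False,
) -> pd.DataFrame:
    """Pool units from multiple experiments that share stimulations.

    Concatenates unit tables, harmonizing condition labels through
    ``condition_map`` and retaining ``experiment_id`` provenance.  No
    re-averaging across animals occurs.  A duplicated (animal, condition)
    pair across experiments raises unless ``allow_duplicates``.
    """
    frames = []
    for i, df in enumerate(unit_tables):
        df = df.copy()
        if "experiment_id" not in df.columns:
            df["experiment_id"] = f"experiment_{i}"
        if condition_map:
            df["condition"] = df["condition"].map(
                lambda c: condition_map.get(c, c)
            )
        frames.append(df)
    pooled = pd.concat(frames, ignore_index=True)
    dup = pooled.duplicated(subset=["animal_id", "condition"], keep=False)
    if dup.any() and not allow_duplicates:
        pairs = pooled.loc[dup, ["animal_id", "condition"]].drop_duplicates()
        raise DuplicateUnitError(
            "duplicate (animal, condition) units across experiments: "
            + "; ".join(f"({r.animal_id}, {r.condition})" for r in pairs.itertuples())
        )
    return pooled
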