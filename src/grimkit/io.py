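"""Readers and writers for the CSV/JSON interchange formats.

Two landmark dialects are supported: the package's own long format (one row
per frame x landmark) and the DeepLabCut-style wide format with three
header rows (scorer / bodypart / coordinate), whose bodypart names are
mapped onto the canonical vocabulary by a user-supplied mapping.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .landmark_model import VOCABULARY

__all__ = [
    "LONG_COLUMNS",
    "read_landmarks",
    "write_landmarks",
    "read_table",
    "write_table",
    "write_manifest",
]

LONG_COLUMNS = (
    "frame_id",
    "animal_id",
    "experiment_id",
    "condition",
    "phase_time_s",
    "observer_id",
    "excluded",
    "exclusion_reason",
    "side",
    "landmark",
    "x",
    "y",
    "confidence",
)


class MalformedTableError(ValueError):
    pass


def _check_duplicates(df: pd.DataFrame) -> None:
    dup = df.duplicated(subset=["frame_id", "landmark"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["frame_id", "landmark"]].drop_duplicates()
        raise MalformedTableError(
            "duplicate (frame, landmark) rows: "
            + "; ".join(f"({r.frame_id}, {r.landmark})" for r in pairs.itertuples())
        )


def _read_long(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"frame_id", "landmark", "x", "y"} - set(df.columns)
    if missing:
        raise MalformedTableError(f"long landmark CSV lacks columns: {sorted(missing)}")
    for col in LONG_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    _check_duplicates(df)
    df["excluded"] = df["excluded"].fillna(False).astype(bool)
    df["exclusion_reason"] = df["exclusion_reason"].fillna("none")
    return df[list(LONG_COLUMNS)]


def _read_dlc(
    path: Path,
    mapping: Mapping[str, str],
    confidence_threshold: float,
) -> pd.DataFrame:
    wide = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    if wide.columns.nlevels != 3:
        raise MalformedTableError("pose-estimation CSV must have 3 header rows")
    bodyparts = list(dict.fromkeys(wide.columns.get_level_values(1)))
    unmapped = [bp for bp in bodyparts if bp not in mapping]
    rows = []
    for frame_idx, row in wide.iterrows():
        for bp in bodyparts:
            name = mapping.get(bp)
            if name is None:
                continue
            if name not in VOCABULARY:
                raise MalformedTableError(
                    f"mapping sends bodypart {bp!r} to unknown landmark {name!r}"
                )
            sub = row.xs(bp, level=1)
            x = float(sub.xs("x", level=1).iloc[0])
            y = float(sub.xs("y", level=1).iloc[0])
            like_vals = sub.xs("likelihood", level=1)
            confidence = float(like_vals.iloc[0]) if len(like_vals) else np.nan
            if np.isfinite(confidence) and confidence < confidence_threshold:
                continue  # low-confidence landmark treated as missing
            rows.append(
                {
                    "frame_id": str(frame_idx),
                    "animal_id": "",
                    "experiment_id": "",
                    "condition": "",
                    "phase_time_s": np.nan,
                    "observer_id": "",
                    "excluded": False,
                    "exclusion_reason": "none",
                    "side": "right-profile",
                    "landmark": name,
                    "x": x,
                    "y": y,
                    "confidence": confidence,
                }
            )
    df = pd.DataFrame(rows, columns=list(LONG_COLUMNS))
    df.attrs["unmapped_bodyparts"] = unmapped
    _check_duplicates(df)
    return df


def read_landmarks(
    path,
    dialect: str = "long",
    mapping: Optional[Mapping[str, str]] = None,
    confidence_threshold: float = 0.6,
) -> pd.DataFrame:
    """Read a landmark table into the canonical long format.

    ``dialect='long'`` expects the package's own long CSV;
    ``dialect='dlc'`` expects a DeepLabCut-style wide CSV and requires a
    bodypart-to-canonical-name ``mapping``.  Landmarks whose pose
    confidence falls below ``confidence_threshold`` are dropped (treated
    as missing); unmapped bodyparts are reported in
    ``df.attrs['unmapped_bodyparts']``.
    """
    path = Path(path)
    if dialect == "long":
        return _read_long(path)
    if dialect == "dlc":
        if mapping is None:
            raise ValueError("the pose-estimation dialect requires a landmark mapping")
        return _read_dlc(path, mapping, confidence_threshold)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_landmarks(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_manifest(path, config: dict, seeds: Optional[dict] = None) -> dict:
    """Write a reproducibility manifest (JSON, deterministic byte layout).

    Records the package and core dependency versions, all seeds, the run
    configuration and its hash; identical inputs produce identical bytes.
    """
    import numpy
    import pandas
    import scipy

    from . import __version__

    payload = {
        "grimkit_version": __version__,
        "versions": {
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
            "scipy": scipy.__version__,
        },
        "seeds": seeds or {},
        "config": config,
    }
    blob = json.dumps(payload, sort_keys=True, default=str)
    payload["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2, default=str))
    return payload
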