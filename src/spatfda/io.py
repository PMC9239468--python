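"""Reading and writing cell tables, survival tables and summary curves.

Canonical cell-table schema (CSV): ``subject_id,image_id,x,y,cell_type``
plus any number of numeric mark columns.  Non-canonical column names are
handled through a ``column_map`` (plain dict, or loaded from a YAML config).

Canonical survival schema: ``subject_id,time,event`` plus scalar covariate
columns.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .patterns import MarkedPointPattern, ObservationWindow

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "read_cell_table",
    "write_cell_table",
    "read_survival_table",
    "write_curves_csv",
    "read_curves_csv",
    "load_column_map",
]

#: canonical column names; a column_map maps these keys to actual columns
CANONICAL = ("subject_id", "image_id", "x", "y", "cell_type")


class SchemaError(ValueError):
    """A mandatory column is missing from a delimited input table."""


def load_column_map(path: str | Path) -> dict:
    """Load a column mapping (and optional ``marks`` list) from YAML."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg.get("columns", cfg)


def _resolve_columns(df: pd.DataFrame, column_map: dict | None):
    column_map = dict(column_map or {})
    marks = list(column_map.pop("marks", []))
    cols = {key: column_map.get(key, key) for key in CANONICAL}
    missing = [c for c in cols.values() if c not in df.columns]
    missing += [m for m in marks if m not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    if not marks:
        reserved = set(cols.values())
        marks = [
            c for c in df.columns
            if c not in reserved and pd.api.types.is_numeric_dtype(df[c])
        ]
    return cols, marks


def read_cell_table(
    path: str | Path,
    column_map: dict | None = None,
    window: ObservationWindow | None = None,
) -> list[MarkedPointPattern]:
    """Read a delimited cell table into one pattern per (subject, image).

    Rows with non-finite coordinates are dropped with a logged count.  The
    observation window is inferred per image (1%-expanded bounding box)
    unless an explicit ``window`` is supplied for all images.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        logger.warning("cell table %s is empty; returning an empty cohort", path)
        if df.shape[1]:
            _resolve_columns(df, column_map)
        return []
    cols, marks = _resolve_columns(df, column_map)
    xy = df[[cols["x"], cols["y"]]].apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(xy).all(axis=1)
    if bad.any():
        logger.warning(
            "dropping %d row(s) with non-finite coordinates from %s",
            int(bad.sum()), path,
        )
        df = df.loc[~bad]
    patterns = []
    for (subj, img), grp in df.groupby(
        [cols["subject_id"], cols["image_id"]], sort=True
    ):
        patterns.append(
            MarkedPointPattern(
                x=grp[cols["x"]].to_numpy(dtype=float),
                y=grp[cols["y"]].to_numpy(dtype=float),
                types=grp[cols["cell_type"]].astype(str).to_numpy(dtype=object),
                marks={m: grp[m].to_numpy(dtype=float) for m in marks},
                window=window,
                subject_id=str(subj),
                image_id=str(img),
            )
        )
    return patterns


def write_cell_table(patterns: list[MarkedPointPattern], path: str | Path) -> None:
    """Write patterns to the canonical CSV at full float precision.

    ``repr``-based float formatting guarantees a bit-exact round trip through
    :func:`read_cell_table`.
    """
    frames = []
    for p in patterns:
        rec = {
            "subject_id": p.subject_id,
            "image_id": p.image_id,
            "x": p.x,
            "y": p.y,
            "cell_type": p.types.astype(str),
        }
        rec.update(p.marks)
        frames.append(pd.DataFrame(rec))
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(CANONICAL))
    )
    out.to_csv(path, index=False)


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Read ``subject_id,time,event,<scalars>``; validates and drops
    subjects with missing outcomes (logged), mirroring explicit cohort
    exclusion rather than silent imputation."""
    df = pd.read_csv(path, float_precision="round_trip")
    for c in ("subject_id", "time", "event"):
        if c not in df.columns:
            raise SchemaError(f"missing mandatory column(s): {c}")
    bad = df["time"].isna() | df["event"].isna()
    if bad.any():
        logger.warning("dropping %d subject(s) with missing outcomes", int(bad.sum()))
        df = df.loc[~bad]
    if (df["time"] <= 0).any():
        raise ValueError("observed times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return df.reset_index(drop=True)


def write_curves_csv(
    path: str | Path,
    r: np.ndarray,
    matrix: np.ndarray,
    subject_ids: list[str],
    metadata: dict | None = None,
) -> None:
    """Wide-format curve export: first column ``r``, one column per subject.

    Estimator metadata goes to a JSON sidecar ``<path>.meta.json``.
    """
    df = pd.DataFrame({"r": np.asarray(r, dtype=float)})
    for sid, row in zip(subject_ids, np.asarray(matrix, dtype=float)):
        df[str(sid)] = row
    df.to_csv(path, index=False)
    if metadata is not None:
        Path(str(path) + ".meta.json").write_text(json.dumps(metadata, indent=2))


def read_curves_csv(path: str | Path):
    """Inverse of :func:`write_curves_csv` -> (r, matrix, subject_ids)."""
    df = pd.read_csv(path, float_precision="round_trip")
    r = df["r"].to_numpy(dtype=float)
    subject_ids = [c for c in df.columns if c != "r"]
    matrix = df[subject_ids].to_numpy(dtype=float).T
    return r, matrix, subject_ids
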