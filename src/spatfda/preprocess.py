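"""Preprocessing rules for imaging cohorts.

Covers the standard steps between segmentation output and spatial summary
estimation: collapsing pixel runs to cell centroids, choosing one
representative image per subject (the densest one), and marker-positivity
dichotomization of subjects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .patterns import MarkedPointPattern, ObservationWindow

__all__ = [
    "pixels_to_centroids",
    "select_representative_image",
    "dichotomize_by_positive_fraction",
]


def pixels_to_centroids(
    pixel_table: pd.DataFrame,
    window: ObservationWindow | None = None,
    subject_id: str = "",
    image_id: str = "",
) -> MarkedPointPattern:
    """One point per cell at the mean of its pixel coordinates.

    ``pixel_table`` needs columns ``pixel_x, pixel_y, cell_id, cell_type``;
    any additional numeric columns are averaged per cell and kept as marks.
    A cell with conflicting type labels across its pixels is an error.
    """
    required = {"pixel_x", "pixel_y", "cell_id", "cell_type"}
    missing = required - set(pixel_table.columns)
    if missing:
        raise ValueError(f"pixel table missing column(s): {sorted(missing)}")
    grouped = pixel_table.groupby("cell_id", sort=True)
    n_types = grouped["cell_type"].nunique()
    if (n_types > 1).any():
        bad = n_types.index[n_types > 1].tolist()
        raise ValueError(f"conflicting type labels for cell_id(s): {bad}")
    mark_cols = [
        c for c in pixel_table.columns
        if c not in required and pd.api.types.is_numeric_dtype(pixel_table[c])
    ]
    agg = grouped.agg(
        {"pixel_x": "mean", "pixel_y": "mean", "cell_type": "first",
         **{c: "mean" for c in mark_cols}}
    )
    return MarkedPointPattern(
        x=agg["pixel_x"].to_numpy(dtype=float),
        y=agg["pixel_y"].to_numpy(dtype=float),
        types=agg["cell_type"].astype(str).to_numpy(dtype=object),
        marks={c: agg[c].to_numpy(dtype=float) for c in mark_cols},
        window=window,
        subject_id=subject_id,
        image_id=image_id,
    )


def select_representative_image(
    patterns: list[MarkedPointPattern],
) -> MarkedPointPattern:
    """The image with the maximum cell count represents the subject.

    Ties are broken by the lexicographically smallest ``image_id`` so the
    choice is deterministic and permutation-invariant.
    """
    if not patterns:
        raise ValueError("no images supplied for the subject")
    return min(patterns, key=lambda p: (-p.n, str(p.image_id)))


def dichotomize_by_positive_fraction(
    pattern: MarkedPointPattern,
    type_label: str,
    mark: str,
    threshold_value: float,
    fraction: float = 0.05,
) -> str:
    """Label a subject ``"hi"``/``"lo"`` by marker-positive cell fraction.

    A cell of ``type_label`` is positive when its mark strictly exceeds
    ``threshold_value``; the subject is ``"hi"`` when the positive fraction
    strictly exceeds ``fraction`` (default 5%).  Cells with a missing mark
    value are excluded from both numerator and denominator.
    """
    if mark not in pattern.marks:
        raise KeyError(f"pattern has no mark {mark!r}")
    sel = pattern.types.astype(str) == type_label
    if not sel.any():
        raise ValueError(f"no cells of type {type_label!r} in the pattern")
    values = pattern.marks[mark][sel]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError(f"no finite {mark!r} values among {type_label!r} cells")
    positive_fraction = float(np.mean(values > threshold_value))
    return "hi" if positive_fraction > fraction else "lo"
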