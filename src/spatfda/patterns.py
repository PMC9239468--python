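"""Marked point patterns in rectangular observation windows.

A single-cell image is represented as a :class:`MarkedPointPattern`: cell
centroid coordinates in microns, a categorical cell type per point, and zero
or more named continuous marks (e.g. marker intensities).  The observation
window is an axis-aligned rectangle; its area enters every intensity
estimate downstream, so it is validated to be non-degenerate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ObservationWindow",
    "MarkedPointPattern",
    "infer_window",
]


@dataclass(frozen=True)
class ObservationWindow:
    """Axis-aligned rectangular window, lengths in microns."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError(
                f"degenerate window: [{self.xmin}, {self.xmax}] x "
                f"[{self.ymin}, {self.ymax}]"
            )

    @property
    def area(self) -> float:
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)

    @property
    def side_lengths(self) -> tuple[float, float]:
        return (self.xmax - self.xmin, self.ymax - self.ymin)

    @property
    def shorter_side(self) -> float:
        return min(self.side_lengths)

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.xmin + self.xmax), 0.5 * (self.ymin + self.ymax))

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (
            (x >= self.xmin) & (x <= self.xmax)
            & (y >= self.ymin) & (y <= self.ymax)
        )


def infer_window(x: np.ndarray, y: np.ndarray, expand: float = 0.01) -> ObservationWindow:
    """Bounding-box window expanded by ``expand`` of each side length per side.

    A pure bounding box touches the extreme points and biases intensity
    upward; the default 1% margin per side is a mild correction.  Degenerate
    extents (a single point, or collinear points) fall back to a unit margin.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        return ObservationWindow(0.0, 1.0, 0.0, 1.0)
    dx = float(np.ptp(x)) or 1.0
    dy = float(np.ptp(y)) or 1.0
    return ObservationWindow(
        float(x.min()) - expand * dx,
        float(x.max()) + expand * dx,
        float(y.min()) - expand * dy,
        float(y.max()) + expand * dy,
    )


@dataclass
class MarkedPointPattern:
    """Planar point pattern with categorical types and numeric marks.

    Parameters
    ----------
    x, y:
        Coordinates in microns, finite, inside ``window``.
    types:
        Categorical label per point (stored as a numpy object/str array).
    marks:
        Mapping mark name -> float array aligned with the points.  Missing
        values are allowed and are excluded only by the operations that need
        the mark.
    window:
        Observation window; inferred from the points when ``None``.
    """

    x: np.ndarray
    y: np.ndarray
    types: np.ndarray
    marks: dict[str, np.ndarray] = field(default_factory=dict)
    window: ObservationWindow | None = None
    subject_id: str = ""
    image_id: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.types = np.asarray(self.types, dtype=object)
        if not (self.x.shape == self.y.shape == self.types.shape):
            raise ValueError("x, y and types must have identical shapes")
        if self.x.ndim != 1:
            raise ValueError("coordinates must be one-dimensional")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("coordinates must be finite")
        self.marks = {k: np.asarray(v, dtype=float) for k, v in self.marks.items()}
        for name, vals in self.marks.items():
            if vals.shape != self.x.shape:
                raise ValueError(f"mark {name!r} has wrong length")
        if self.window is None:
            self.window = infer_window(self.x, self.y)
        inside = self.window.contains(self.x, self.y)
        if not inside.all():
            raise ValueError(
                f"{int((~inside).sum())} point(s) fall outside the window"
            )
        # duplicates are legal (cells can abut) but worth a trace
        if self.n > 1:
            coords = np.column_stack([self.x, self.y])
            n_dup = self.n - np.unique(coords, axis=0).shape[0]
            if n_dup:
                logger.debug(
                    "pattern %s/%s contains %d duplicated coordinate(s)",
                    self.subject_id, self.image_id, n_dup,
                )

    @property
    def n(self) -> int:
        return self.x.size

    def type_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.types.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def subset(self, *labels: str) -> "MarkedPointPattern":
        """Sub-pattern restricted to the given type labels (window kept)."""
        mask = np.isin(self.types.astype(str), list(labels))
        return MarkedPointPattern(
            x=self.x[mask],
            y=self.y[mask],
            types=self.types[mask],
            marks={k: v[mask] for k, v in self.marks.items()},
            window=self.window,
            subject_id=self.subject_id,
            image_id=self.image_id,
        )

    def rotate(self, angle: float) -> "MarkedPointPattern":
        """Rotate points about the window center by ``angle`` radians.

        The window is replaced by the bounding box of the rotated points, so
        this is only meant for isotropy checks, not as a geometric transform
        of the observation region.
        """
        cx, cy = self.window.center
        c, s = np.cos(angle), np.sin(angle)
        xr = cx + c * (self.x - cx) - s * (self.y - cy)
        yr = cy + s * (self.x - cx) + c * (self.y - cy)
        return MarkedPointPattern(
            x=xr, y=yr, types=self.types.copy(),
            marks={k: v.copy() for k, v in self.marks.items()},
            window=None, subject_id=self.subject_id, image_id=self.image_id,
        )
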