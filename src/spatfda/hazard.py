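"""Cumulative baseline hazard representations.

Two shapes are used throughout: a right-continuous step function (the
Breslow estimator from a fitted Cox-type model) and a smooth parametric
Weibull form used by the simulation engine as a stand-in baseline.  Both
expose evaluation and generalized inversion, which is all that
inverse-transform survival sampling needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StepCumulativeHazard", "WeibullCumulativeHazard"]


@dataclass(frozen=True)
class StepCumulativeHazard:
    """Nondecreasing right-continuous step function, 0 at t = 0.

    ``times`` are the (sorted, positive) jump locations, ``values`` the
    cumulative hazard immediately after each jump.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.shape != values.shape or times.ndim != 1:
            raise ValueError("times and values must be 1-d and aligned")
        if times.size:
            if (np.diff(times) <= 0).any() or times[0] <= 0:
                raise ValueError("jump times must be positive and increasing")
            if (np.diff(values) < 0).any() or (values < 0).any():
                raise ValueError("cumulative hazard must be nondecreasing")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        padded = np.concatenate([[0.0], self.values])
        return padded[idx]

    @property
    def is_trivial(self) -> bool:
        return self.times.size == 0 or self.values[-1] == 0

    @property
    def support_end(self) -> float:
        return float(self.times[-1]) if self.times.size else 0.0

    def inverse(self, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Generalized inverse: the first jump time where the cumulative
        hazard reaches ``v``.  Values beyond the final level are capped at
        the support end; the second return flags those capped entries."""
        if self.is_trivial:
            raise ValueError("cumulative hazard is identically zero")
        v = np.asarray(v, dtype=float)
        idx = np.searchsorted(self.values, v, side="left")
        capped = idx >= self.times.size
        t = self.times[np.minimum(idx, self.times.size - 1)]
        t = np.where(capped, self.support_end, t)
        return t, capped


@dataclass(frozen=True)
class WeibullCumulativeHazard:
    """Weibull cumulative hazard (t / scale) ** shape."""

    shape: float = 1.2
    scale: float = 5.0

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be positive")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (np.maximum(t, 0.0) / self.scale) ** self.shape

    def inverse(self, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        v = np.asarray(v, dtype=float)
        return self.scale * v ** (1.0 / self.shape), np.zeros(v.shape, dtype=bool)
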