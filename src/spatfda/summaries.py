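"""Distance-indexed summary functions of marked point patterns.

Implements Ripley's K function and the pair correlation function g(r)
(with their cross-type variants), the mark connection function between two
cell types, and a distance-band Moran's I profile for a continuous mark
observed on two cell types.  All estimators are isotropic: they depend on
the pattern only through pairwise distances (plus translation edge-correction
weights that depend on coordinate differences).

Conventions
-----------
* Intensities are estimated empirically, lambda_type = n_type / |W|, and the
  "unmarked" intensity of a type pair is their sum.
* Edge correction for K/g is the translation correction, well defined for
  rectangular windows; ``correction="none"`` disables it.
* g(r) is estimated by Epanechnikov kernel smoothing of pair distances
  (Stoyan's bandwidth rule by default) rather than by differentiating K;
  both estimate the same quantity, and smoothing avoids amplifying noise.
* The mark connection function defaults to its normalised form
  g_ij(r) / g(r), whose baseline under random labeling is exactly 1; the
  raw ratio lambda_i lambda_j g_ij / (lambda_dot g) is available with
  ``normalised=False``.
* Moran's I uses no edge correction: it is a ratio of raw sums over
  cross-type pairs whose distance falls in a band around r.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .patterns import MarkedPointPattern

logger = logging.getLogger(__name__)

__all__ = [
    "RGrid",
    "SummaryCurve",
    "estimate_intensities",
    "k_function",
    "pair_correlation",
    "mark_connection",
    "morans_i_profile",
    "common_reference_grid",
    "curves_to_matrix",
    "random_labeling_envelope",
    "EnvelopeResult",
    "stoyan_bandwidth",
]


# ---------------------------------------------------------------------------
# grids and curves


@dataclass(frozen=True)
class RGrid:
    """Uniform grid of inter-point distances (microns)."""

    r: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "r", r)
        if r.ndim != 1 or r.size < 2:
            raise ValueError("r grid must be a 1-d array with >= 2 points")
        if r[0] < 0:
            raise ValueError("r grid must start at a nonnegative distance")
        d = np.diff(r)
        if (d <= 0).any():
            raise ValueError("r grid must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-9, atol=0):
            raise ValueError("r grid must be uniformly spaced")

    @classmethod
    def uniform(cls, r_max: float, n_points: int, r_min: float = 0.0) -> "RGrid":
        return cls(np.linspace(r_min, r_max, n_points))

    @property
    def spacing(self) -> float:
        return float(self.r[1] - self.r[0])

    def __len__(self) -> int:
        return self.r.size


@dataclass
class SummaryCurve:
    """A summary function sampled on an :class:`RGrid`.

    ``kind`` is one of ``{"K", "g", "crossK", "crossg", "mcf", "moran"}``.
    NaN marks grid points where the estimator is undefined (e.g. g at r=0).
    Estimator metadata (edge correction, bandwidth, intensities, per-bin
    pair counts, ...) lives in ``metadata``.
    """

    grid: RGrid
    values: np.ndarray
    kind: str
    type_pair: tuple[str, str] | None = None
    mark: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.r.shape:
            raise ValueError("values and grid have different lengths")


# ---------------------------------------------------------------------------
# intensities and pair geometry


def estimate_intensities(
    pattern: MarkedPointPattern, types: tuple[str, ...] | None = None
) -> dict:
    """Empirical intensities n_type/|W| (points per squared micron).

    When ``types`` is given, the returned dict also holds ``"_dot"``, the
    unmarked intensity of the requested types (sum of their intensities).
    """
    area = pattern.window.area
    counts = pattern.type_counts()
    if types is None:
        return {t: c / area for t, c in counts.items()}
    out = {t: counts.get(t, 0) / area for t in types}
    out["_dot"] = sum(out[t] for t in types)
    return out


def stoyan_bandwidth(intensity: float) -> float:
    """Stoyan & Stoyan's rule of thumb for the pcf kernel: 0.15 / sqrt(lambda)."""
    if intensity <= 0:
        raise ValueError("intensity must be positive")
    return 0.15 / math.sqrt(intensity)


class _PairData:
    """Unordered point pairs (p < q), sorted by distance.

    Stores distances, translation edge-correction weights and the two point
    indices per pair.  Built once per pattern and shared by the estimators,
    which matters for envelope simulation where only labels change.
    """

    def __init__(self, pattern: MarkedPointPattern, correction: str = "translation"):
        if correction not in ("translation", "none"):
            raise ValueError(f"unknown edge correction {correction!r}")
        n = pattern.n
        if n < 2:
            raise ValueError("need at least 2 points to form pairs")
        iu, ju = np.triu_indices(n, k=1)
        dx = pattern.x[iu] - pattern.x[ju]
        dy = pattern.y[iu] - pattern.y[ju]
        d = np.hypot(dx, dy)
        if correction == "translation":
            a, b = pattern.window.side_lengths
            denom = (a - np.abs(dx)) * (b - np.abs(dy))
            if (denom <= 0).any():
                raise ValueError("pair separation exceeds the window size")
            tau = (a * b) / denom
        else:
            tau = np.ones_like(d)
        order = np.argsort(d, kind="stable")
        self.d = d[order]
        self.tau = tau[order]
        self.i = iu[order]
        self.j = ju[order]
        self.correction = correction
        self.window = pattern.window

    def kernel_windows(self, grid: RGrid, bandwidth: float):
        """Per grid point: slice bounds and Epanechnikov * tau weights."""
        lo = np.searchsorted(self.d, grid.r - bandwidth, side="left")
        hi = np.searchsorted(self.d, grid.r + bandwidth, side="right")
        weights = []
        for k, r in enumerate(grid.r):
            u = (self.d[lo[k]:hi[k]] - r) / bandwidth
            weights.append(0.75 / bandwidth * (1.0 - u * u) * self.tau[lo[k]:hi[k]])
        return lo, hi, weights


def _kernel_sum(pairs: _PairData, grid: RGrid, bandwidth: float,
                pair_mask: np.ndarray | None = None) -> np.ndarray:
    """Sum of Epanechnikov(d - r) * tau over (optionally masked) pairs."""
    lo, hi, weights = pairs.kernel_windows(grid, bandwidth)
    out = np.empty(len(grid))
    for k in range(len(grid)):
        w = weights[k]
        if pair_mask is not None:
            w = w * pair_mask[lo[k]:hi[k]]
        out[k] = w.sum()
    return out


def _resolve_types(pattern: MarkedPointPattern, types):
    """Return (sub-pattern, cross pair (i, j) or None)."""
    if types is None or types == "all":
        return pattern, None
    if isinstance(types, str):
        return pattern.subset(types), None
    i, j = types
    if i == j:
        return pattern.subset(i), None
    return pattern.subset(i, j), (i, j)


# ---------------------------------------------------------------------------
# K and pair correlation


def k_function(
    pattern: MarkedPointPattern,
    grid: RGrid,
    types="all",
    correction: str = "translation",
) -> SummaryCurve:
    """Ripley's K (or cross-type K_ij) with translation edge correction.

    K(r) is the edge-weighted count of (ordered) pairs at distance <= r,
    normalised by lambda^2 |W|; the cross version counts type-i -> type-j
    pairs and normalises by lambda_i lambda_j |W|.
    """
    sub, cross = _resolve_types(pattern, types)
    area = sub.window.area
    if cross is None:
        if sub.n < 2:
            raise ValueError("need at least 2 points for the K function")
        pairs = _PairData(sub, correction)
        lam = sub.n / area
        # ordered pairs: each unordered pair contributes twice
        csum = np.concatenate([[0.0], np.cumsum(2.0 * pairs.tau)])
        norm = lam * lam * area
        kind = "K"
    else:
        i, j = cross
        labels = sub.types.astype(str)
        n_i = int((labels == i).sum())
        n_j = int((labels == j).sum())
        if n_i < 1 or n_j < 1:
            raise ValueError(f"need points of both types {i!r} and {j!r}")
        if sub.n < 2:
            raise ValueError("need at least 2 points for the cross K function")
        pairs = _PairData(sub, correction)
        is_cross = labels[pairs.i] != labels[pairs.j]
        csum = np.concatenate([[0.0], np.cumsum(pairs.tau * is_cross)])
        norm = (n_i / area) * (n_j / area) * area
        kind = "crossK"
    idx = np.searchsorted(pairs.d, grid.r, side="right")
    values = csum[idx] / norm
    return SummaryCurve(
        grid=grid, values=values, kind=kind, type_pair=cross,
        metadata={
            "correction": correction,
            "intensities": estimate_intensities(sub, cross),
            "n": sub.n,
        },
    )


def pair_correlation(
    pattern: MarkedPointPattern,
    grid: RGrid,
    types="all",
    bandwidth: float | None = None,
    correction: str = "translation",
) -> SummaryCurve:
    """Kernel estimate of the pair correlation function g(r) (or g_ij).

    g(r) = K'(r) / (2 pi r); the estimator smooths pair distances with an
    Epanechnikov kernel and divides by 2 pi r lambda^2 |W| (cross:
    lambda_i lambda_j |W|).  The value at r = 0 is undefined and set NaN.
    """
    sub, cross = _resolve_types(pattern, types)
    area = sub.window.area
    if sub.n < 2:
        raise ValueError("need at least 2 points for the pair correlation")
    if bandwidth is None:
        bandwidth = stoyan_bandwidth(sub.n / area)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    pairs = _PairData(sub, correction)
    if cross is None:
        s = 2.0 * _kernel_sum(pairs, grid, bandwidth)
        lam2 = (sub.n / area) ** 2
        kind = "g"
    else:
        i, j = cross
        labels = sub.types.astype(str)
        n_i = int((labels == i).sum())
        n_j = int((labels == j).sum())
        if n_i < 1 or n_j < 1:
            raise ValueError(f"need points of both types {i!r} and {j!r}")
        is_cross = (labels[pairs.i] != labels[pairs.j]).astype(float)
        s = _kernel_sum(pairs, grid, bandwidth, pair_mask=is_cross)
        lam2 = (n_i / area) * (n_j / area)
        kind = "crossg"
    with np.errstate(divide="ignore", invalid="ignore"):
        values = s / (2.0 * np.pi * grid.r * lam2 * area)
    values[grid.r == 0] = np.nan
    return SummaryCurve(
        grid=grid, values=values, kind=kind, type_pair=cross,
        metadata={
            "correction": correction,
            "bandwidth": float(bandwidth),
            "intensities": estimate_intensities(sub, cross),
            "n": sub.n,
        },
    )


# ---------------------------------------------------------------------------
# mark connection function


def mark_connection(
    pattern: MarkedPointPattern,
    i: str,
    j: str,
    grid: RGrid,
    bandwidth: float | None = None,
    normalised: bool = True,
    correction: str = "translation",
) -> SummaryCurve:
    """Mark connection function between cell types ``i`` and ``j``.

    The raw form is lambda_i lambda_j g_ij(r) / (lambda_dot g(r)), where g is
    the pair correlation of the pooled (i, j) pattern.  The default
    normalised form g_ij(r) / g(r) has baseline exactly 1 under random
    labeling: values below 1 indicate same-type clustering at distance r,
    values above 1 indicate cross-type mixing.
    """
    if i == j:
        raise ValueError("mark connection requires two distinct types")
    sub = pattern.subset(i, j)
    labels = sub.types.astype(str)
    n_i = int((labels == i).sum())
    n_j = int((labels == j).sum())
    if n_i < 2 or n_j < 2:
        raise ValueError(
            f"need >= 2 points of each type, got n({i})={n_i}, n({j})={n_j}"
        )
    area = sub.window.area
    lam_i, lam_j = n_i / area, n_j / area
    lam_dot = lam_i + lam_j
    if bandwidth is None:
        bandwidth = stoyan_bandwidth(lam_dot)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    pairs = _PairData(sub, correction)
    is_cross = (labels[pairs.i] != labels[pairs.j]).astype(float)
    values, counts = _mcf_from_sums(
        s_cross=_kernel_sum(pairs, grid, bandwidth, pair_mask=is_cross),
        s_all=_kernel_sum(pairs, grid, bandwidth),
        n_i=n_i, n_j=n_j, normalised=normalised,
        lam_i=lam_i, lam_j=lam_j, lam_dot=lam_dot, grid=grid,
    )
    return SummaryCurve(
        grid=grid, values=values, kind="mcf", type_pair=(i, j),
        metadata={
            "correction": correction,
            "bandwidth": float(bandwidth),
            "normalised": bool(normalised),
            "intensities": {i: lam_i, j: lam_j, "_dot": lam_dot},
            "n": sub.n,
        },
    )


def _mcf_from_sums(s_cross, s_all, n_i, n_j, normalised,
                   lam_i, lam_j, lam_dot, grid):
    """mcf values from cross / pooled kernel sums (shared with envelopes).

    g_ij is proportional to s_cross / (n_i n_j) and the pooled g to
    2 s_all / (n_i + n_j)^2; the 2 pi r |W| factors cancel in the ratio.
    """
    n = n_i + n_j
    g_ij_scaled = s_cross / (n_i * n_j)
    g_scaled = 2.0 * s_all / (n * n)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = g_ij_scaled / g_scaled
    ratio[grid.r == 0] = np.nan
    ratio[~np.isfinite(ratio)] = np.nan
    if not normalised:
        ratio = ratio * (lam_i * lam_j / lam_dot)
    return ratio, None


# ---------------------------------------------------------------------------
# Moran's I distance profile


def morans_i_profile(
    pattern: MarkedPointPattern,
    i: str,
    j: str,
    mark: str,
    grid: RGrid,
    band_halfwidth: float | None = None,
) -> SummaryCurve:
    """Distance-band Moran's I correlation of ``mark`` between types i and j.

    For each grid distance r, the numerator sums
    (m_s - mean_i)(m_t - mean_j) over cross-type pairs (s in i, t in j)
    whose distance lies within ``band_halfwidth`` of r; the denominator is
    the pooled sum of squares sum_s (m_s - mean_pool)^2 +
    sum_t (m_t - mean_pool)^2, computed once.  Bands with no cross pairs get
    value 0 with pair count 0.  If all marks equal the pooled mean, the
    denominator vanishes and the whole curve is NaN with a ``degenerate``
    metadata flag.

    The default half-width is half the grid spacing, so the bands tile the
    distance axis without overlap.
    """
    if mark not in pattern.marks:
        raise KeyError(f"pattern has no mark {mark!r}")
    if band_halfwidth is None:
        band_halfwidth = 0.5 * grid.spacing
    if band_halfwidth <= 0:
        raise ValueError("band_halfwidth must be positive")
    sub_i = pattern.subset(i)
    sub_j = pattern.subset(j)
    if sub_i.n == 0 or sub_j.n == 0:
        raise ValueError(f"need points of both types {i!r} and {j!r}")
    m_i = sub_i.marks[mark]
    m_j = sub_j.marks[mark]
    keep_i = np.isfinite(m_i)
    keep_j = np.isfinite(m_j)
    if not keep_i.all() or not keep_j.all():
        logger.warning(
            "excluding %d point(s) with non-finite %r from Moran's I",
            int((~keep_i).sum() + (~keep_j).sum()), mark,
        )
    xi, yi, m_i = sub_i.x[keep_i], sub_i.y[keep_i], m_i[keep_i]
    xj, yj, m_j = sub_j.x[keep_j], sub_j.y[keep_j], m_j[keep_j]
    if m_i.size == 0 or m_j.size == 0:
        raise ValueError(f"no finite {mark!r} values for one of the types")

    mean_i, mean_j = m_i.mean(), m_j.mean()
    pooled = np.concatenate([m_i, m_j])
    mean_pool = pooled.mean()
    denominator = float(np.sum((pooled - mean_pool) ** 2))

    d = np.hypot(xi[:, None] - xj[None, :], yi[:, None] - yj[None, :]).ravel()
    prod = ((m_i - mean_i)[:, None] * (m_j - mean_j)[None, :]).ravel()
    order = np.argsort(d, kind="stable")
    d, prod = d[order], prod[order]
    csum = np.concatenate([[0.0], np.cumsum(prod)])
    lo = np.searchsorted(d, grid.r - band_halfwidth, side="left")
    hi = np.searchsorted(d, grid.r + band_halfwidth, side="right")
    numerator = csum[hi] - csum[lo]
    pair_counts = (hi - lo).astype(int)

    if denominator == 0.0:
        values = np.full(len(grid), np.nan)
        degenerate = True
    else:
        values = numerator / denominator
        degenerate = False
    return SummaryCurve(
        grid=grid, values=values, kind="moran", type_pair=(i, j), mark=mark,
        metadata={
            "band_halfwidth": float(band_halfwidth),
            "pair_counts": pair_counts,
            "degenerate": degenerate,
            "denominator": denominator,
            "means": {i: float(mean_i), j: float(mean_j), "pool": float(mean_pool)},
        },
    )


# ---------------------------------------------------------------------------
# cohort-level plumbing


def common_reference_grid(
    patterns: list[MarkedPointPattern], n_points: int = 64
) -> RGrid:
    """Reference distance grid for a cohort, anchored at the densest image.

    The maximum distance is a quarter of the densest image's shorter window
    side (limiting edge-effect dominance); the grid is uniform from 0.
    """
    if not patterns:
        raise ValueError("need at least one pattern")
    densest = max(patterns, key=lambda p: p.n)
    r_max = densest.window.shorter_side / 4.0
    return RGrid.uniform(r_max, n_points)


def curves_to_matrix(
    curves, grid: RGrid
) -> tuple[list[str], np.ndarray]:
    """Stack summary curves into a (subjects x grid) functional matrix.

    ``curves`` is a dict subject_id -> :class:`SummaryCurve` or a list of
    curves (subject ids then taken from curve metadata, falling back to the
    list index).  Each curve is linearly interpolated onto the target grid;
    NaN stretches (e.g. the undefined r = 0 value) are filled with the
    nearest defined value.  A curve whose own grid does not span the target
    grid raises an error naming the subject.
    """
    if isinstance(curves, dict):
        items = [(str(k), c) for k, c in curves.items()]
    else:
        items = [
            (str(c.metadata.get("subject_id", idx)), c)
            for idx, c in enumerate(curves)
        ]
    matrix = np.empty((len(items), len(grid)))
    for row, (sid, curve) in enumerate(items):
        r = curve.grid.r
        v = np.asarray(curve.values, dtype=float)
        if r[0] > grid.r[0] + 1e-12 or r[-1] < grid.r[-1] - 1e-12:
            raise ValueError(
                f"curve for subject {sid!r} spans [{r[0]}, {r[-1]}], "
                f"not the target grid [{grid.r[0]}, {grid.r[-1]}]"
            )
        finite = np.isfinite(v)
        if not finite.any():
            raise ValueError(f"curve for subject {sid!r} has no defined values")
        # np.interp is constant beyond the end points, which implements the
        # nearest-defined-value fill for NaN heads and tails
        matrix[row] = np.interp(grid.r, r[finite], v[finite])
    return [sid for sid, _ in items], matrix


# ---------------------------------------------------------------------------
# random-labeling envelopes


@dataclass
class EnvelopeResult:
    """Monte-Carlo envelope for an observed summary curve.

    ``lower``/``upper`` bound the curve at the requested level on the grid
    points selected by ``r_mask``; elsewhere they are NaN.  ``inside`` is
    the containment verdict at those points, ``p_value`` the exchangeable
    rank p-value of the observed deviation statistic (global mode only).
    """

    grid: RGrid
    observed: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    inside: bool
    p_value: float | None
    mode: str
    n_sim: int
    level: float


def random_labeling_envelope(
    pattern: MarkedPointPattern,
    i: str,
    j: str,
    grid: RGrid,
    bandwidth: float | None = None,
    n_sim: int = 199,
    level: float = 0.95,
    mode: str = "global",
    r_mask: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> EnvelopeResult:
    """Random-labeling Monte-Carlo envelope for the normalised mcf.

    Labels of the pooled (i, j) points are permuted ``n_sim`` times with
    type counts fixed (random labeling conditional on the observed counts);
    locations, hence pair distances and the pooled pair correlation, stay
    fixed, so only the cross-type kernel sums are recomputed per simulation.

    ``mode="global"`` builds the maximum-deviation envelope (the deviation
    statistic is max_r |mcf(r) - 1| over the selected grid points): the
    containment event has probability exactly ``level`` for a random
    labeling, by rank exchangeability.  ``mode="pointwise"`` returns
    per-point quantile envelopes instead (per-point size 1 - level; joint
    containment is *not* calibrated).
    """
    if mode not in ("global", "pointwise"):
        raise ValueError(f"unknown envelope mode {mode!r}")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sub = pattern.subset(i, j)
    labels = sub.types.astype(str)
    n_i = int((labels == i).sum())
    n_j = int((labels == j).sum())
    if n_i < 2 or n_j < 2:
        raise ValueError("need >= 2 points of each type")
    area = sub.window.area
    lam_i, lam_j = n_i / area, n_j / area
    lam_dot = lam_i + lam_j
    if bandwidth is None:
        bandwidth = stoyan_bandwidth(lam_dot)
    pairs = _PairData(sub, "translation")
    lo, hi, weights = pairs.kernel_windows(grid, bandwidth)
    s_all = np.array([w.sum() for w in weights])

    def mcf_for(lab: np.ndarray) -> np.ndarray:
        is_cross = lab[pairs.i] != lab[pairs.j]
        s_cross = np.array(
            [
                weights[k] @ is_cross[lo[k]:hi[k]]
                for k in range(len(grid))
            ]
        )
        values, _ = _mcf_from_sums(
            s_cross=s_cross, s_all=s_all, n_i=n_i, n_j=n_j, normalised=True,
            lam_i=lam_i, lam_j=lam_j, lam_dot=lam_dot, grid=grid,
        )
        return values

    observed = mcf_for(labels)
    sims = np.empty((n_sim, len(grid)))
    for s in range(n_sim):
        sims[s] = mcf_for(rng.permutation(labels))

    if r_mask is None:
        r_mask = np.ones(len(grid), dtype=bool)
    r_mask = np.asarray(r_mask, dtype=bool)
    usable = r_mask & np.isfinite(observed) & np.isfinite(sims).all(axis=0)

    lower = np.full(len(grid), np.nan)
    upper = np.full(len(grid), np.nan)
    if mode == "global":
        dev_sims = np.max(np.abs(sims[:, usable] - 1.0), axis=1)
        dev_obs = float(np.max(np.abs(observed[usable] - 1.0)))
        # reject when observed deviation ranks in the top k of all n_sim+1
        k = int(np.floor((1.0 - level) * (n_sim + 1)))
        if k < 1:
            raise ValueError("n_sim too small for the requested level")
        crit = np.sort(dev_sims)[-k]
        inside = dev_obs < crit
        p_value = (1 + int((dev_sims >= dev_obs).sum())) / (n_sim + 1)
        lower[usable] = 1.0 - crit
        upper[usable] = 1.0 + crit
    else:
        k = max(int(np.floor(0.5 * (1.0 - level) * (n_sim + 1))), 1)
        srt = np.sort(sims[:, usable], axis=0)
        lower[usable] = srt[k - 1]
        upper[usable] = srt[-k]
        inside = bool(
            np.all(
                (observed[usable] >= lower[usable])
                & (observed[usable] <= upper[usable])
            )
        )
        p_value = None
    return EnvelopeResult(
        grid=grid, observed=observed, lower=lower, upper=upper,
        inside=bool(inside), p_value=p_value, mode=mode,
        n_sim=n_sim, level=level,
    )
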