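"""Dominant-color extraction by generalized-Lloyd vector quantization.

The dominant (main) color descriptor summarizes an image as a small
set of representative HSV colors with the fraction of pixels each one
covers.  Extraction proceeds in two stages:

1. **Seeding** — the nine-region HSV quantizer counts pixels per
   region; every region holding more than a threshold fraction
   (default 15 %) of the image nominates one initial cluster whose
   center is the circular-mean color of its pixels.  This replaces the
   random initialization that plain Lloyd clustering is sensitive to.
2. **Refinement** — Lloyd iterations (nearest-center assignment /
   centroid update) alternate with LBG-style *split* passes (clusters
   whose within-error exceeds a threshold are divided along their
   widest coordinate) and *merge* passes (centers closer than a
   threshold are pooled with count-weighted means) until neither
   operation fires.

All distances are weighted squared HSV distances with hue normalized
to [0, 1) and differenced circularly; the default weights (2, 1, 1)
emphasize hue, which carries most of the class separation between
tongue appearance types.

The traditional baseline descriptor (coarse-region histogram with a
5 % cutoff) and a descriptor-space distance are also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .colorspace import N_AREAS, quantize_hsv, rgb_to_hsv

DEFAULT_WEIGHTS = (2.0, 1.0, 1.0)

#: Fixed normalizer for the dominant-color matching distance: center
#: pairs at least this far apart (weighted, hue-normalized units)
#: contribute zero similarity.
DEFAULT_DCD_DMAX = 0.5


@dataclass(frozen=True)
class GlaParams:
    """Tuning parameters of the clustering pipeline.

    area_threshold
        Fraction of pixels a coarse HSV region must exceed to seed an
        initial cluster (the paper-style 15 % rule).
    split_threshold
        Within-cluster weighted MSE (normalized units) above which a
        cluster is split.
    merge_threshold
        Weighted center distance (normalized units) below which two
        clusters are merged.
    weights
        (ω_h, ω_s, ω_v) of the squared-distance metric; hue measured
        on [0, 1) with circular differences.
    """

    area_threshold: float = 0.15
    split_threshold: float = 0.01
    merge_threshold: float = 0.1
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS
    max_iter: int = 100
    tol: float = 1e-6
    outer_rounds: int = 10

    def __post_init__(self):
        if not 0.0 < self.area_threshold < 1.0:
            raise ValueError("area_threshold must be in (0, 1)")
        if self.split_threshold <= 0 or self.merge_threshold <= 0:
            raise ValueError("split/merge thresholds must be positive")
        if len(self.weights) != 3 or any(w <= 0 for w in self.weights):
            raise ValueError("weights must be three positive numbers")
        if self.max_iter < 1 or self.tol <= 0 or self.outer_rounds < 1:
            raise ValueError("max_iter, outer_rounds must be >= 1 and tol > 0")


@dataclass(frozen=True)
class ColorCluster:
    """One cluster: HSV center (hue in degrees), member count, within-error."""

    center: tuple[float, float, float]
    pixel_count: int
    within_error: float


@dataclass(frozen=True)
class MainColorDescriptor:
    """Dominant-color descriptor: (color, coverage fraction) pairs.

    ``colors`` is a (k, 3) array of HSV centers (hue in degrees),
    ``fractions`` a (k,) array summing to 1, sorted descending.
    """

    colors: np.ndarray
    fractions: np.ndarray

    def __post_init__(self):
        colors = np.asarray(self.colors, dtype=np.float64).reshape(-1, 3)
        fractions = np.asarray(self.fractions, dtype=np.float64).reshape(-1)
        object.__setattr__(self, "colors", colors)
        object.__setattr__(self, "fractions", fractions)
        if len(fractions) == 0 or len(colors) != len(fractions):
            raise ValueError("descriptor needs k >= 1 matching colors/fractions")
        if abs(fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if np.any(np.diff(fractions) > 1e-12):
            raise ValueError("entries must be sorted by fraction descending")

    @property
    def k(self) -> int:
        return len(self.fractions)

    def __eq__(self, other):
        if not isinstance(other, MainColorDescriptor):
            return NotImplemented
        return (
            self.colors.shape == other.colors.shape
            and np.array_equal(self.colors, other.colors)
            and np.array_equal(self.fractions, other.fractions)
        )


# ---------------------------------------------------------------------------
# internal helpers on hue-normalized pixels (h/360, s, v)


def _to_unit(hsv) -> np.ndarray:
    a = np.asarray(hsv, dtype=np.float64).copy()
    a[..., 0] = (a[..., 0] / 360.0) % 1.0
    return a


def _to_degrees(centers: np.ndarray) -> np.ndarray:
    out = np.asarray(centers, dtype=np.float64).copy()
    out[..., 0] = (out[..., 0] % 1.0) * 360.0
    return out


def _wrap(d: np.ndarray) -> np.ndarray:
    """Wrap hue differences into [-0.5, 0.5)."""
    return d - np.round(d)


def _pairwise_sqdist(px: np.ndarray, centers: np.ndarray, w) -> np.ndarray:
    dh = _wrap(px[:, None, 0] - centers[None, :, 0])
    ds = px[:, None, 1] - centers[None, :, 1]
    dv = px[:, None, 2] - centers[None, :, 2]
    return w[0] * dh * dh + w[1] * ds * ds + w[2] * dv * dv


def _circular_mean(h: np.ndarray, weights=None) -> float:
    """Mean of hues on [0, 1).

    A vector mean locates the cluster; the result is refined by
    unwrapping all samples around it and taking the (weighted)
    arithmetic mean, which is the exact minimizer of the summed
    squared circular distance whenever the samples span less than half
    the circle around their mean.
    """
    ang = 2.0 * np.pi * np.asarray(h, dtype=np.float64)
    if weights is None:
        c, s = np.cos(ang).mean(), np.sin(ang).mean()
    else:
        wgt = np.asarray(weights, dtype=np.float64)
        wgt = wgt / wgt.sum()
        c, s = wgt @ np.cos(ang), wgt @ np.sin(ang)
    m = (np.arctan2(s, c) / (2.0 * np.pi)) % 1.0
    dev = _wrap(np.asarray(h) - m)
    shift = dev.mean() if weights is None else wgt @ dev
    return float((m + shift) % 1.0)


def _centroids(px: np.ndarray, labels: np.ndarray, k: int):
    """Per-cluster mean colors (circular on hue); empty clusters dropped."""
    counts = np.bincount(labels, minlength=k)
    keep = np.flatnonzero(counts > 0)
    centers = np.empty((len(keep), 3))
    for row, i in enumerate(keep):
        m = px[labels == i]
        centers[row, 0] = _circular_mean(m[:, 0])
        centers[row, 1:] = m[:, 1:].mean(axis=0)
    return centers, counts[keep]


def _objective(px, labels, centers, w) -> float:
    dh = _wrap(px[:, 0] - centers[labels, 0])
    ds = px[:, 1] - centers[labels, 1]
    dv = px[:, 2] - centers[labels, 2]
    return float((w[0] * dh**2 + w[1] * ds**2 + w[2] * dv**2).mean())


def _lloyd(px: np.ndarray, centers: np.ndarray, params: GlaParams):
    """Alternate assignment/update until centers stop moving.

    Returns ``(centers, labels, counts, objectives)`` where
    ``objectives`` is the mean weighted squared error measured at each
    assignment step (non-increasing).
    """
    w = params.weights
    objectives: list[float] = []
    for _ in range(params.max_iter):
        d = _pairwise_sqdist(px, centers, w)
        labels = d.argmin(axis=1)
        objectives.append(float(d[np.arange(len(px)), labels].mean()))
        new_centers, _ = _centroids(px, labels, len(centers))
        if len(new_centers) != len(centers):
            centers = new_centers  # cluster vanished; keep iterating
            continue
        dh = _wrap(new_centers[:, 0] - centers[:, 0])
        dsv = new_centers[:, 1:] - centers[:, 1:]
        move_sq = w[0] * dh**2 + w[1] * dsv[:, 0] ** 2 + w[2] * dsv[:, 1] ** 2
        centers = new_centers
        if np.sqrt(move_sq.max()) < params.tol:
            break
    d = _pairwise_sqdist(px, centers, w)
    labels = d.argmin(axis=1)
    counts = np.bincount(labels, minlength=len(centers))
    if np.any(counts == 0):
        centers = centers[counts > 0]
        labels = _pairwise_sqdist(px, centers, w).argmin(axis=1)
        counts = np.bincount(labels, minlength=len(centers))
    return centers, labels, counts, objectives


def _split_pass(px, labels, centers, params: GlaParams) -> np.ndarray:
    w = np.asarray(params.weights)
    out = []
    for i in range(len(centers)):
        m = px[labels == i]
        if len(m) < 2:
            out.append(centers[i])
            continue
        dh = _wrap(m[:, 0] - centers[i, 0])
        ds = m[:, 1] - centers[i, 1]
        dv = m[:, 2] - centers[i, 2]
        devs = np.stack([dh, ds, dv])
        err = float((w[:, None] * devs**2).sum(axis=0).mean())
        if err <= params.split_threshold:
            out.append(centers[i])
            continue
        coord_var = w * (devs**2).mean(axis=1)
        cmax = int(coord_var.argmax())
        sd = float(np.sqrt((devs[cmax] ** 2).mean()))
        delta = np.zeros(3)
        delta[cmax] = sd / 2.0
        lo, hi = centers[i] - delta, centers[i] + delta
        for c in (lo, hi):
            c[0] = c[0] % 1.0
            c[1:] = np.clip(c[1:], 0.0, 1.0)
            out.append(c)
    return np.asarray(out)


def _merge_pass(centers, counts, params: GlaParams):
    centers = np.asarray(centers, dtype=np.float64).copy()
    counts = np.asarray(counts, dtype=np.int64).copy()
    w = params.weights
    while len(centers) > 1:
        d = np.sqrt(_pairwise_sqdist(centers, centers, w))
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(int(d.argmin()), d.shape)
        if i > j:
            i, j = j, i
        if d[i, j] >= params.merge_threshold:
            break
        ni, nj = counts[i], counts[j]
        hue = _circular_mean(
            np.array([centers[i, 0], centers[j, 0]]),
            weights=np.array([ni, nj], dtype=np.float64),
        )
        sv = (ni * centers[i, 1:] + nj * centers[j, 1:]) / (ni + nj)
        centers[i] = [hue, sv[0], sv[1]]
        counts[i] = ni + nj
        centers = np.delete(centers, j, axis=0)
        counts = np.delete(counts, j)
    return centers, counts


# ---------------------------------------------------------------------------
# public operations


def area_probabilities(image) -> np.ndarray:
    """Fraction of pixels in each of the nine coarse HSV regions."""
    hsv = np.asarray(image, dtype=np.float64)
    areas = np.asarray(quantize_hsv(hsv)).reshape(-1)
    if areas.size == 0:
        raise ValueError("empty image")
    return np.bincount(areas, minlength=N_AREAS) / areas.size


def initial_palette(image, params: GlaParams = GlaParams()):
    """Seed clusters from over-threshold coarse regions.

    Returns ``(k, centers)`` with centers as a (k, 3) HSV array (hue in
    degrees), one per region whose pixel fraction exceeds
    ``params.area_threshold``; falls back to the single most populated
    region when none does.
    """
    hsv = np.asarray(image, dtype=np.float64)
    flat = hsv.reshape(-1, 3)
    areas = np.asarray(quantize_hsv(hsv)).reshape(-1)
    p = np.bincount(areas, minlength=N_AREAS) / areas.size
    sel = np.flatnonzero(p > params.area_threshold)
    if len(sel) == 0:
        sel = np.array([p.argmax()])
    unit = _to_unit(flat)
    centers = np.empty((len(sel), 3))
    for row, a in enumerate(sel):
        m = unit[areas == a]
        centers[row, 0] = _circular_mean(m[:, 0])
        centers[row, 1:] = m[:, 1:].mean(axis=0)
    return len(sel), _to_degrees(centers)


def assign_pixels(image, centers, weights=DEFAULT_WEIGHTS) -> np.ndarray:
    """Nearest-center label per pixel under the weighted circular metric.

    Ties resolve to the lowest cluster index.
    """
    centers = np.asarray(centers, dtype=np.float64).reshape(-1, 3)
    if len(centers) == 0:
        raise ValueError("need at least one center")
    px = _to_unit(np.asarray(image, dtype=np.float64))
    flat = px.reshape(-1, 3)
    labels = _pairwise_sqdist(flat, _to_unit(centers), weights).argmin(axis=1)
    return labels.reshape(px.shape[:-1])


def update_centers(image, labels) -> np.ndarray:
    """Recompute cluster centers as member means (circular on hue).

    Empty clusters are removed; returns a (k', 3) HSV array in degrees.
    """
    flat = _to_unit(np.asarray(image, dtype=np.float64)).reshape(-1, 3)
    lab = np.asarray(labels).reshape(-1)
    centers, _ = _centroids(flat, lab, int(lab.max()) + 1)
    return _to_degrees(centers)


def summarize_clusters(image, labels, centers, weights=DEFAULT_WEIGHTS):
    """Per-cluster :class:`ColorCluster` summaries (count + within-error)."""
    flat = _to_unit(np.asarray(image, dtype=np.float64)).reshape(-1, 3)
    lab = np.asarray(labels).reshape(-1)
    cu = _to_unit(np.asarray(centers, dtype=np.float64).reshape(-1, 3))
    w = np.asarray(weights)
    out = []
    for i in range(len(cu)):
        m = flat[lab == i]
        if len(m) == 0:
            out.append(ColorCluster(tuple(_to_degrees(cu[i : i + 1])[0]), 0, 0.0))
            continue
        dh = _wrap(m[:, 0] - cu[i, 0])
        ds = m[:, 1] - cu[i, 1]
        dv = m[:, 2] - cu[i, 2]
        err = float((w[0] * dh**2 + w[1] * ds**2 + w[2] * dv**2).mean())
        out.append(ColorCluster(tuple(_to_degrees(cu[i : i + 1])[0]), len(m), err))
    return out


def split_clusters(image, labels, centers, split_threshold=None, weights=None,
                   params: GlaParams | None = None) -> np.ndarray:
    """Split clusters whose within-error exceeds the threshold.

    Each offending cluster is replaced by two centers offset by ± half
    the member standard deviation along the coordinate of largest
    weighted variance.  Returns centers in degrees.
    """
    if params is None:
        params = GlaParams(
            split_threshold=split_threshold if split_threshold is not None else 0.01,
            weights=tuple(weights) if weights is not None else DEFAULT_WEIGHTS,
        )
    flat = _to_unit(np.asarray(image, dtype=np.float64)).reshape(-1, 3)
    cu = _to_unit(np.asarray(centers, dtype=np.float64).reshape(-1, 3))
    return _to_degrees(_split_pass(flat, np.asarray(labels).reshape(-1), cu, params))


def merge_clusters(centers, counts, merge_threshold=None, weights=None,
                   params: GlaParams | None = None):
    """Merge center pairs closer than the threshold (count-weighted mean).

    Returns ``(centers_degrees, counts)``.
    """
    if params is None:
        params = GlaParams(
            merge_threshold=merge_threshold if merge_threshold is not None else 0.1,
            weights=tuple(weights) if weights is not None else DEFAULT_WEIGHTS,
        )
    cu = _to_unit(np.asarray(centers, dtype=np.float64).reshape(-1, 3))
    merged, cnt = _merge_pass(cu, counts, params)
    return _to_degrees(merged), cnt


def extract_main_colors(image, params: GlaParams = GlaParams()) -> MainColorDescriptor:
    """Full dominant-color extraction from an RGB raster.

    Runs the seeding stage, Lloyd refinement to convergence, then
    alternating split/re-converge and merge/re-converge passes until a
    round fires neither operation (bounded by ``params.outer_rounds``).
    Always returns k ≥ 1 entries sorted by coverage fraction.
    """
    hsv = rgb_to_hsv(image)
    flat = _to_unit(hsv.reshape(-1, 3))
    _, centers_deg = initial_palette(hsv, params)
    centers = _to_unit(centers_deg)
    centers, labels, counts, _ = _lloyd(flat, centers, params)
    for _ in range(params.outer_rounds):
        changed = False
        grown = _split_pass(flat, labels, centers, params)
        if len(grown) > len(centers):
            centers, labels, counts, _ = _lloyd(flat, grown, params)
            changed = True
        shrunk, _ = _merge_pass(centers, counts, params)
        if len(shrunk) < len(centers):
            centers, labels, counts, _ = _lloyd(flat, shrunk, params)
            changed = True
        if not changed:
            break
    fractions = counts / len(flat)
    order = np.argsort(-fractions, kind="stable")
    return MainColorDescriptor(_to_degrees(centers[order]), fractions[order])


def traditional_main_colors(image, min_fraction: float = 0.05) -> MainColorDescriptor:
    """Baseline descriptor: coarse regions covering at least ``min_fraction``.

    Takes an HSV raster; per-region circular-mean colors, fractions
    renormalized to sum 1, sorted descending.
    """
    hsv = np.asarray(image, dtype=np.float64)
    flat = hsv.reshape(-1, 3)
    areas = np.asarray(quantize_hsv(hsv)).reshape(-1)
    p = np.bincount(areas, minlength=N_AREAS) / areas.size
    sel = np.flatnonzero(p >= min_fraction)
    if len(sel) == 0:  # unreachable with 9 regions and a 5% cutoff
        sel = np.array([p.argmax()])
    unit = _to_unit(flat)
    centers = np.empty((len(sel), 3))
    for row, a in enumerate(sel):
        m = unit[areas == a]
        centers[row, 0] = _circular_mean(m[:, 0])
        centers[row, 1:] = m[:, 1:].mean(axis=0)
    fractions = p[sel] / p[sel].sum()
    order = np.argsort(-fractions, kind="stable")
    return MainColorDescriptor(_to_degrees(centers[order]), fractions[order])


def dcd_distance(
    f1: MainColorDescriptor,
    f2: MainColorDescriptor,
    weights=DEFAULT_WEIGHTS,
    d_max: float = DEFAULT_DCD_DMAX,
) -> float:
    """Quadratic-form matching distance between dominant-color descriptors.

    ``D² = Σμ1ᵢ² + Σμ2ⱼ² − 2 ΣΣ aᵢⱼ μ1ᵢ μ2ⱼ`` with center similarity
    ``aᵢⱼ = 1 − min(dist(c1ᵢ, c2ⱼ)/d_max, 1)`` under the weighted
    circular HSV metric.  Symmetric, zero for identical descriptors,
    and at most √2 for unit-sum fraction vectors.
    """
    c1 = _to_unit(f1.colors)
    c2 = _to_unit(f2.colors)
    dist = np.sqrt(_pairwise_sqdist(c1, c2, weights))
    a = 1.0 - np.minimum(dist / d_max, 1.0)
    mu1, mu2 = f1.fractions, f2.fractions
    d2 = float(mu1 @ mu1 + mu2 @ mu2 - 2.0 * mu1 @ a @ mu2)
    return float(np.sqrt(max(d2, 0.0)))


def area_histogram_distance(p1, p2) -> float:
    """Euclidean distance between nine-region probability histograms."""
    a, b = np.asarray(p1, float), np.asarray(p2, float)
    if a.shape != b.shape:
        raise ValueError("histogram shapes differ")
    return float(np.linalg.norm(a - b))
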