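"""Distances, distance-to-similarity normalization, and weighted fusion.

Color and texture produce distances on incompatible scales, so each is
mapped to a similarity in [0, 1] via ``(d_max − d) / d_max`` (1 for
identical images, 0 at the maximal distance) before the convex fusion
``ω_color · s_color + ω_texture · s_texture``; the default split is
0.6 : 0.4 in favor of color.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .edge_histogram import EdgeHistogramDescriptor

#: Upper bound of the texture distance for bins in [0, 1]:
#: 80 local terms + 5 global terms at weight 5 + 65 semiglobal terms.
THEORETICAL_MAX_TEXTURE = 80.0 + 5 * 5.0 + 65.0
#: Upper bound of the dominant-color matching distance for unit-sum
#: fraction vectors.
THEORETICAL_MAX_COLOR = float(np.sqrt(2.0))

DEFAULT_WEIGHT_COLOR = 0.6
DEFAULT_WEIGHT_TEXTURE = 0.4


@dataclass(frozen=True)
class SimilarityScore:
    """Per-feature raw distances, normalized similarities, and their fusion."""

    d1_raw: float
    d2_raw: float
    d1: float
    d2: float
    fused: float
    weights: tuple[float, float]


def l1_histogram_distance(h1, h2) -> float:
    """Minkowski r=1 (city-block) distance between equal-length histograms."""
    a = np.asarray(h1, dtype=np.float64).reshape(-1)
    b = np.asarray(h2, dtype=np.float64).reshape(-1)
    if a.shape != b.shape:
        raise ValueError(f"histogram lengths differ: {a.shape} vs {b.shape}")
    return float(np.abs(a - b).sum())


def texture_distance(q: EdgeHistogramDescriptor, t: EdgeHistogramDescriptor) -> float:
    """Weighted L1 distance over the 150 edge bins.

    The 5 global bins carry weight 5 so whole-image edge statistics are
    not swamped by the 145 finer-grained bins.
    """
    for d in (q, t):
        if d.local is None or d.global_ is None or d.semiglobal is None:
            raise ValueError("descriptor missing a histogram component")
    return (
        l1_histogram_distance(q.local, t.local)
        + 5.0 * l1_histogram_distance(q.global_, t.global_)
        + l1_histogram_distance(q.semiglobal, t.semiglobal)
    )


def normalize_distance(d: float, dmax: float) -> float:
    """Map a distance in [0, dmax] to a similarity in [0, 1]."""
    if dmax <= 0:
        raise ValueError("dmax must be positive")
    if d < 0 or d > dmax:
        raise ValueError(f"distance {d} outside [0, {dmax}]")
    return (dmax - d) / dmax


def fuse(
    d1_sim: float,
    d2_sim: float,
    w_color: float = DEFAULT_WEIGHT_COLOR,
    w_texture: float = DEFAULT_WEIGHT_TEXTURE,
) -> float:
    """Convex combination of the two normalized similarities."""
    if w_color < 0 or w_texture < 0 or abs(w_color + w_texture - 1.0) > 1e-9:
        raise ValueError("weights must be nonnegative and sum to 1")
    for s in (d1_sim, d2_sim):
        if s < 0 or s > 1:
            raise ValueError("similarities must lie in [0, 1]")
    return w_color * d1_sim + w_texture * d2_sim


def score(
    d1_raw: float,
    d2_raw: float,
    dmax_color: float,
    dmax_texture: float,
    w_color: float = DEFAULT_WEIGHT_COLOR,
    w_texture: float = DEFAULT_WEIGHT_TEXTURE,
) -> SimilarityScore:
    """Normalize both raw distances and fuse them into one score."""
    s1 = normalize_distance(d1_raw, dmax_color)
    s2 = normalize_distance(d2_raw, dmax_texture)
    return SimilarityScore(
        d1_raw=float(d1_raw),
        d2_raw=float(d2_raw),
        d1=s1,
        d2=s2,
        fused=fuse(s1, s2, w_color, w_texture),
        weights=(w_color, w_texture),
    )
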