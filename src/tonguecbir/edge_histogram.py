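"""Edge-histogram texture descriptor (local + global + semiglobal).

The descriptor follows the MPEG-7 edge-histogram scheme: the gray
image is divided into a 4×4 grid of subimages, each subimage into a
fixed 16×16 grid of blocks (256 blocks), and each block — viewed as
four macroblock mean gray levels — is classified by five directional
filters into vertical, horizontal, 45°, 135°, nondirectional, or no
edge (when the strongest response does not exceed a threshold,
default 20).  Per-subimage edge-type frequencies form the 80-bin
local histogram.

Two aggregate views extend the plain local histogram: a 5-bin global
histogram (mean over the 16 subimages) capturing whole-image edge
statistics, and a 65-bin semiglobal histogram averaging the 13
standard subimage groups (4 columns, 4 rows, 4 corner quadrants and
the center quadrant), capturing intermediate-scale layout.  An
optional uniform 3-bit quantizer encodes bins as integer codes 0–7.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .colorspace import GRAY_COEFFS_STANDARD, rgb_to_gray


class EdgeType(IntEnum):
    VERTICAL = 0       # 0° edge
    HORIZONTAL = 1     # 90° edge
    DIAG45 = 2
    DIAG135 = 3
    NONDIRECTIONAL = 4
    NONE = 5


#: MPEG-7 edge filters on macroblock means (TL, TR, BL, BR); row order
#: fixes the tie-break priority vertical, horizontal, 45°, 135°, nondir.
EDGE_FILTERS = np.array(
    [
        [1.0, -1.0, 1.0, -1.0],
        [1.0, 1.0, -1.0, -1.0],
        [np.sqrt(2.0), 0.0, 0.0, -np.sqrt(2.0)],
        [0.0, np.sqrt(2.0), -np.sqrt(2.0), 0.0],
        [2.0, -2.0, -2.0, 2.0],
    ]
)

N_EDGE_TYPES = 5
N_SUBIMAGES = 16
N_SEMIGLOBAL_GROUPS = 13


@dataclass(frozen=True)
class EhdParams:
    """Extraction parameters.

    blocks_per_subimage must be a perfect square (grid layout); the
    edge threshold applies strictly (response must exceed it).
    """

    blocks_per_subimage: int = 256
    edge_threshold: float = 20.0
    quantize: bool = False

    def __post_init__(self):
        g = int(round(np.sqrt(self.blocks_per_subimage)))
        if g * g != self.blocks_per_subimage or g < 1:
            raise ValueError("blocks_per_subimage must be a positive perfect square")
        if self.edge_threshold < 0:
            raise ValueError("edge_threshold must be nonnegative")

    @property
    def grid(self) -> int:
        return int(round(np.sqrt(self.blocks_per_subimage)))


@dataclass(frozen=True)
class EdgeHistogramDescriptor:
    """80-bin local + 5-bin global + 65-bin semiglobal edge histograms."""

    local: np.ndarray                      # (16, 5)
    global_: np.ndarray                    # (5,)
    semiglobal: np.ndarray                 # (13, 5)
    quantized_local: np.ndarray | None = None  # (80,) int codes 0..7

    def __post_init__(self):
        local = np.asarray(self.local, dtype=np.float64)
        glob = np.asarray(self.global_, dtype=np.float64)
        semi = np.asarray(self.semiglobal, dtype=np.float64)
        if local.shape != (N_SUBIMAGES, N_EDGE_TYPES):
            raise ValueError("local histogram must be 16x5")
        if glob.shape != (N_EDGE_TYPES,):
            raise ValueError("global histogram must have 5 bins")
        if semi.shape != (N_SEMIGLOBAL_GROUPS, N_EDGE_TYPES):
            raise ValueError("semiglobal histogram must be 13x5")
        object.__setattr__(self, "local", local)
        object.__setattr__(self, "global_", glob)
        object.__setattr__(self, "semiglobal", semi)
        if self.quantized_local is not None:
            q = np.asarray(self.quantized_local, dtype=np.int64).reshape(-1)
            if q.shape != (80,) or q.min() < 0 or q.max() > 7:
                raise ValueError("quantized_local must be 80 codes in [0, 7]")
            object.__setattr__(self, "quantized_local", q)

    def flat150(self) -> np.ndarray:
        """All 150 raw bins: 80 local, 5 global, 65 semiglobal."""
        return np.concatenate(
            [self.local.reshape(-1), self.global_, self.semiglobal.reshape(-1)]
        )

    def __eq__(self, other):
        if not isinstance(other, EdgeHistogramDescriptor):
            return NotImplemented
        qa, qb = self.quantized_local, other.quantized_local
        if (qa is None) != (qb is None):
            return False
        return (
            np.array_equal(self.local, other.local)
            and np.array_equal(self.global_, other.global_)
            and np.array_equal(self.semiglobal, other.semiglobal)
            and (qa is None or np.array_equal(qa, qb))
        )


def partition_subimages(image) -> list[np.ndarray]:
    """Split a gray raster into the 4×4 subimage grid, row-major.

    Subimage heights/widths are ``dim // 4`` with remainder pixels
    attached to the last row/column.  Requires at least 8×8 pixels.
    """
    g = np.asarray(image, dtype=np.float64)
    if g.ndim != 2:
        raise ValueError("gray image must be 2-D")
    h, w = g.shape
    if h < 8 or w < 8:
        raise ValueError(f"image too small for 4x4 partition: {h}x{w}")
    bh, bw = h // 4, w // 4
    rows = [0, bh, 2 * bh, 3 * bh, h]
    cols = [0, bw, 2 * bw, 3 * bw, w]
    return [
        g[rows[r] : rows[r + 1], cols[c] : cols[c + 1]]
        for r in range(4)
        for c in range(4)
    ]


def _quadrant_means(block: np.ndarray, grid: int) -> np.ndarray:
    """Macroblock mean grays for a grid×grid tiling of ``block``.

    Returns shape (4, grid, grid) in the order TL, TR, BL, BR; trailing
    pixels beyond an even block side are dropped.
    """
    sh, sw = block.shape
    bh = (sh // grid) // 2 * 2
    bw = (sw // grid) // 2 * 2
    if bh < 2 or bw < 2:
        raise ValueError(
            f"subimage {sh}x{sw} too small for a {grid}x{grid} grid of >=2x2 blocks"
        )
    crop = block[: grid * bh, : grid * bw]
    q = crop.reshape(grid, 2, bh // 2, grid, 2, bw // 2).mean(axis=(2, 5))
    return np.stack([q[:, 0, :, 0], q[:, 0, :, 1], q[:, 1, :, 0], q[:, 1, :, 1]])


def block_edge_type(block, threshold: float = 20.0):
    """Classify one image block; returns ``(EdgeType, max_strength)``.

    The block must have even side lengths ≥ 2.  The five filter
    responses are taken in absolute value; the strongest one wins
    (ties resolve by the fixed filter priority) and the block counts
    as an edge only when it strictly exceeds ``threshold``.
    """
    b = np.asarray(block, dtype=np.float64)
    if b.ndim != 2 or b.shape[0] < 2 or b.shape[1] < 2:
        raise ValueError("block must be 2-D with sides >= 2")
    if b.shape[0] % 2 or b.shape[1] % 2:
        raise ValueError("block sides must be even")
    a = b.reshape(2, b.shape[0] // 2, 2, b.shape[1] // 2).mean(axis=(1, 3))
    a = np.array([a[0, 0], a[0, 1], a[1, 0], a[1, 1]])
    e = np.abs(EDGE_FILTERS @ a)
    idx = int(e.argmax())
    strength = float(e[idx])
    if strength > threshold:
        return EdgeType(idx), strength
    return EdgeType.NONE, strength


def _subimage_bins(sub: np.ndarray, grid: int, threshold: float) -> np.ndarray:
    a = _quadrant_means(sub, grid)
    e = np.abs(np.tensordot(EDGE_FILTERS, a, axes=(1, 0)))  # (5, grid, grid)
    idx = e.argmax(axis=0)
    strength = e.max(axis=0)
    sel = strength > threshold
    counts = np.bincount(idx[sel].reshape(-1), minlength=N_EDGE_TYPES)
    return counts / (grid * grid)


def local_histogram(image, params: EhdParams = EhdParams()) -> np.ndarray:
    """16×5 local edge histogram of a gray raster.

    Bin values are edge-block counts divided by the total block count,
    so each row sums to at most 1 (unclassified blocks leave mass out).
    """
    subs = partition_subimages(image)
    return np.stack(
        [_subimage_bins(s, params.grid, params.edge_threshold) for s in subs]
    )


def global_histogram(local) -> np.ndarray:
    """5-bin global histogram: mean of the 16 subimage rows."""
    loc = np.asarray(local, dtype=np.float64)
    if loc.shape != (N_SUBIMAGES, N_EDGE_TYPES):
        raise ValueError("local histogram must be 16x5")
    return loc.mean(axis=0)


def semiglobal_histogram(local) -> np.ndarray:
    """13×5 semiglobal histogram over the standard subimage groups.

    Groups 1–4: the four columns of the 4×4 grid; 5–8: the four rows;
    9–12: the four corner 2×2 quadrants; 13: the center 2×2 quadrant.
    Each group row is the mean of its member subimage rows.
    """
    loc = np.asarray(local, dtype=np.float64)
    if loc.shape != (N_SUBIMAGES, N_EDGE_TYPES):
        raise ValueError("local histogram must be 16x5")
    g = loc.reshape(4, 4, N_EDGE_TYPES)
    rows = [g[:, c].mean(axis=0) for c in range(4)]
    rows += [g[r].mean(axis=0) for r in range(4)]
    for r0, c0 in ((0, 0), (0, 2), (2, 0), (2, 2)):
        rows.append(g[r0 : r0 + 2, c0 : c0 + 2].reshape(4, N_EDGE_TYPES).mean(axis=0))
    rows.append(g[1:3, 1:3].reshape(4, N_EDGE_TYPES).mean(axis=0))
    return np.stack(rows)


def quantize_bins(values) -> np.ndarray:
    """Uniform 3-bit quantizer: code = min(floor(8·v), 7) for v in [0, 1]."""
    v = np.asarray(values, dtype=np.float64)
    if np.any((v < 0) | (v > 1)):
        raise ValueError("bin values must lie in [0, 1]")
    return np.minimum(np.floor(v * 8.0).astype(np.int64), 7)


def dequantize_bins(codes) -> np.ndarray:
    """Reconstruction levels of the uniform quantizer (cell midpoints)."""
    c = np.asarray(codes, dtype=np.int64)
    if np.any((c < 0) | (c > 7)):
        raise ValueError("codes must lie in [0, 7]")
    return (c + 0.5) / 8.0


def extract_edge_descriptor(
    image,
    params: EhdParams = EhdParams(),
    gray_coeffs=GRAY_COEFFS_STANDARD,
) -> EdgeHistogramDescriptor:
    """Full texture descriptor from an RGB raster."""
    gray = rgb_to_gray(image, coeffs=gray_coeffs)
    local = local_histogram(gray, params)
    glob = global_histogram(local)
    semi = semiglobal_histogram(local)
    quant = quantize_bins(local.reshape(-1)) if params.quantize else None
    return EdgeHistogramDescriptor(local, glob, semi, quant)
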