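"""Color-space conversions and the coarse nine-region HSV quantizer.

The retrieval pipeline moves rasters through three representations:

* **RGB** — 8-bit integer channels in [0, 255], as read from disk.
* **HSV** — hue in degrees [0, 360), saturation and value in [0, 1],
  computed with the classic hexcone formula.  Tongue appearance classes
  (pale, pink, purple, purple-red, yellow coating, white coating) order
  monotonically along hue / saturation / value in this space, which is
  why color clustering happens here rather than in RGB.
* **Gray** — weighted luminance in [0, 255], used for edge analysis.

The module also houses the coarse quantizer that maps every HSV pixel
onto one of nine perceptual regions (black, gray, white plus six hue
bands).  These regions seed the dominant-color extraction: a region
holding more than a threshold fraction of the pixels nominates one
initial cluster center.
"""

from __future__ import annotations

import numpy as np

#: Region labels of the nine-way HSV quantizer, index == label.
AREA_NAMES = (
    "black",
    "gray",
    "white",
    "red",
    "yellow",
    "green",
    "cyan",
    "blue",
    "purple",
)

N_AREAS = 9

#: Hue band boundaries in degrees; bands are half-open [lo, hi).
#: red wraps: [315, 360) ∪ [0, 20); then yellow, green, cyan, blue, purple.
HUE_BAND_EDGES = (20.0, 75.0, 155.0, 190.0, 260.0, 315.0)

#: ITU-R BT.601 luminance coefficients (r, g, b).
GRAY_COEFFS_STANDARD = (0.299, 0.587, 0.114)
#: Variant with blue weight 0.144 (coefficients sum to 1.030); selectable
#: for compatibility, clipped output keeps it in range.
GRAY_COEFFS_VARIANT = (0.299, 0.587, 0.144)

GRAY_COEFF_MODES = {
    "standard": GRAY_COEFFS_STANDARD,
    "variant": GRAY_COEFFS_VARIANT,
}


def _check_rgb(rgb: np.ndarray) -> None:
    if rgb.shape[-1] != 3:
        raise ValueError(f"expected trailing RGB axis of size 3, got shape {rgb.shape}")
    if np.any((rgb < 0) | (rgb > 255)):
        raise ValueError("RGB channel values must lie in [0, 255]")


def rgb_to_hsv(image) -> np.ndarray:
    """Convert an RGB raster to HSV via the hexcone formula.

    Parameters
    ----------
    image
        Array of shape ``(..., 3)`` with integer or float channels in
        [0, 255].

    Returns
    -------
    ndarray of the same shape with ``(h, s, v)`` per pixel, hue in
    degrees [0, 360), saturation and value in [0, 1].  Achromatic
    pixels (max == min) get hue 0; black pixels get saturation 0.
    """
    rgb = np.asarray(image, dtype=np.float64)
    _check_rgb(rgb)
    rgb = rgb / 255.0
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    v = rgb.max(axis=-1)
    mn = rgb.min(axis=-1)
    c = v - mn
    safe_c = np.where(c > 0, c, 1.0)
    rp = (v - r) / safe_c
    gp = (v - g) / safe_c
    bp = (v - b) / safe_c
    # Six-branch hexcone case table; order fixes tie-breaking when two
    # channels share the maximum.
    conds = [
        (r == v) & (g == mn),
        (r == v),
        (g == v) & (b == mn),
        (g == v),
        (b == v) & (r == mn),
    ]
    choices = [5.0 + bp, 1.0 - gp, 1.0 + rp, 3.0 - bp, 3.0 + gp]
    hp = np.select(conds, choices, default=5.0 - rp)
    h = np.where(c > 0, (60.0 * hp) % 360.0, 0.0)
    s = np.where(v > 0, c / np.where(v > 0, v, 1.0), 0.0)
    return np.stack([h, s, v], axis=-1)


def hsv_to_rgb(hsv) -> np.ndarray:
    """Inverse hexcone conversion; returns float RGB in [0, 255]."""
    a = np.asarray(hsv, dtype=np.float64)
    h = (a[..., 0] % 360.0) / 60.0
    s = a[..., 1]
    v = a[..., 2]
    i = np.floor(h).astype(np.int64) % 6
    f = h - np.floor(h)
    p = v * (1.0 - s)
    q = v * (1.0 - s * f)
    t = v * (1.0 - s * (1.0 - f))
    r = np.choose(i, [v, q, p, p, t, v])
    g = np.choose(i, [t, v, v, q, p, p])
    b = np.choose(i, [p, p, t, v, v, q])
    return np.stack([r, g, b], axis=-1) * 255.0


def rgb_to_gray(image, coeffs=GRAY_COEFFS_STANDARD) -> np.ndarray:
    """Weighted-luminance grayscale conversion, output clipped to [0, 255].

    ``coeffs`` is the (r, g, b) weight triple; see
    :data:`GRAY_COEFF_MODES` for the two supported presets.
    """
    rgb = np.asarray(image, dtype=np.float64)
    _check_rgb(rgb)
    w = np.asarray(coeffs, dtype=np.float64)
    return np.clip(rgb @ w, 0.0, 255.0)


def quantize_hsv(hsv):
    """Map HSV pixels to the nine coarse color regions.

    Dark pixels (v ≤ 0.2) are black regardless of hue/saturation;
    unsaturated pixels (s ≤ 0.1) split into gray (v ≤ 0.9) and white
    (v > 0.9); everything else falls into one of six half-open hue
    bands.  The map is total: every in-domain pixel gets exactly one
    label in [0, 8].

    Accepts a single ``(h, s, v)`` triple (returns ``int``) or an
    array of shape ``(..., 3)`` (returns an int array).  Out-of-domain
    values raise ``ValueError``.
    """
    a = np.asarray(hsv, dtype=np.float64)
    if a.shape[-1] != 3:
        raise ValueError(f"expected trailing HSV axis of size 3, got shape {a.shape}")
    h, s, v = a[..., 0], a[..., 1], a[..., 2]
    if np.any((h < 0) | (h >= 360) | (s < 0) | (s > 1) | (v < 0) | (v > 1)):
        raise ValueError("HSV values outside domain h∈[0,360), s,v∈[0,1]")
    hprime = np.select(
        [
            (h >= 20) & (h < 75),
            (h >= 75) & (h < 155),
            (h >= 155) & (h < 190),
            (h >= 190) & (h < 260),
            (h >= 260) & (h < 315),
        ],
        [1, 2, 3, 4, 5],
        default=0,  # red band wraps around 0/360
    )
    area = np.where(
        v <= 0.2,
        0,
        np.where(s <= 0.1, np.where(v <= 0.9, 1, 2), 3 + hprime),
    )
    if area.ndim == 0:
        return int(area)
    return area.astype(np.int64)
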