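"""Seeded synthetic tongue-image phantoms for testing and evaluation.

No public tongue-image collection accompanies the method, so this
module generates labeled stand-ins that carry exactly the structure
the descriptors measure: a small HSV palette covering stated pixel
fractions (the color signal) and an oriented gray-level pattern
superimposed on it (the texture signal).  Phantoms are deterministic
given their spec, so every experiment in the test suite and the
acceptance script is reproducible from a single integer seed.

Three default template sets mirror the study design:

* six color classes with tongue-like hue/saturation/value centers
  (pink, pale, yellow coating, white coating, purple, purple-red
  analogues) and no texture;
* five texture classes (vertical, horizontal, 45°, 135° stripes and a
  checkerboard producing clean nondirectional edges) on a fixed pink
  base;
* six combined classes drawing colors from the first set and textures
  from the second, with deliberate collisions so that neither feature
  alone separates all classes but their fusion does.

A random-walk ``cracks`` texture (fissured-tongue analogue, mixed
edge orientations) is also available.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .colorspace import hsv_to_rgb

TEXTURES = ("none", "vstripes", "hstripes", "diag45", "diag135", "checker", "cracks")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic image.

    palette
        Tuple of ``((h, s, v), fraction)`` pairs; fractions sum to 1
        and are realized exactly (±1 pixel) as contiguous row-major
        runs before noise.
    texture
        One of :data:`TEXTURES`; stripe/checker patterns darken
        alternating cells by ``texture_contrast`` gray levels, cracks
        darken random-walk polylines.
    texture_scale
        Stripe half-period / checker cell pitch in pixels; the default
        4 matches the descriptor's block side on 256×256 images.
    """

    palette: tuple = (((350.0, 0.45, 0.85), 1.0),)
    texture: str = "none"
    texture_contrast: float = 120.0
    noise_sigma: float = 0.0
    size: tuple[int, int] = (256, 256)
    shape: str = "full"
    seed: int = 0
    texture_scale: int = 4

    def __post_init__(self):
        fracs = [f for _, f in self.palette]
        if not fracs or abs(sum(fracs) - 1.0) > 1e-9 or any(f < 0 for f in fracs):
            raise ValueError("palette fractions must be nonnegative and sum to 1")
        if self.texture not in TEXTURES:
            raise ValueError(f"unknown texture {self.texture!r}")
        if self.shape not in ("full", "ellipse"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.size[0] < 8 or self.size[1] < 8:
            raise ValueError("phantom must be at least 8x8")


def _stripe_mask(n: int, scale: int) -> np.ndarray:
    # phase-shift by half a cell so stripe boundaries fall mid-block
    return (((np.arange(n) + scale // 2) // scale) % 2).astype(bool)


def _texture_mask(texture: str, h: int, w: int, scale: int, rng) -> np.ndarray:
    x = np.arange(w)[None, :]
    y = np.arange(h)[:, None]
    if texture == "vstripes":
        return np.broadcast_to(_stripe_mask(w, scale)[None, :], (h, w))
    if texture == "hstripes":
        return np.broadcast_to(_stripe_mask(h, scale)[:, None], (h, w))
    if texture == "diag45":
        return (((x + y) // scale) % 2).astype(bool)
    if texture == "diag135":
        # mirror of diag45: swaps the two diagonal filter responses exactly
        return np.fliplr((((x + y) // scale) % 2).astype(bool))
    if texture == "checker":
        cell = max(scale // 2, 1)
        return (((x // cell) + (y // cell)) % 2).astype(bool)
    if texture == "cracks":
        return _crack_mask(h, w, rng)
    raise ValueError(f"unknown texture {texture!r}")


def _crack_mask(h: int, w: int, rng, n_cracks: int = 6) -> np.ndarray:
    """Dark random-walk polylines mimicking tongue fissures."""
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(n_cracks):
        x = float(rng.integers(0, w))
        y = float(rng.integers(0, h))
        ang = float(rng.uniform(0.0, 2.0 * np.pi))
        for _ in range((h + w) // 2):
            ang += float(rng.normal(0.0, 0.3))
            x += np.cos(ang)
            y += np.sin(ang)
            xi, yi = int(round(x)), int(round(y))
            if not (0 <= xi < w and 0 <= yi < h):
                break
            mask[yi, xi] = True
            mask[yi, min(xi + 1, w - 1)] = True
    return mask


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render a spec to an 8-bit RGB raster, deterministic given its seed."""
    h, w = spec.size
    rng = np.random.default_rng(spec.seed)
    n = h * w
    fracs = np.array([f for _, f in spec.palette], dtype=np.float64)
    bounds = np.round(np.cumsum(fracs) * n).astype(np.int64)
    bounds[-1] = n
    idx = np.searchsorted(bounds, np.arange(n), side="right")
    colors = hsv_to_rgb(np.array([c for c, _ in spec.palette], dtype=np.float64))
    img = colors[idx].reshape(h, w, 3).astype(np.float64)
    if spec.texture != "none":
        m = _texture_mask(spec.texture, h, w, spec.texture_scale, rng)
        img[m] -= spec.texture_contrast
    if spec.shape == "ellipse":
        y = (np.arange(h)[:, None] - (h - 1) / 2.0) / (0.47 * h)
        x = (np.arange(w)[None, :] - (w - 1) / 2.0) / (0.47 * w)
        outside = x * x + y * y > 1.0
        img[outside] = (26.0, 24.0, 30.0)
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def make_fixture_db(
    n_per_class: int,
    templates,
    seed: int,
    hue_jitter: float = 5.0,
) -> list[tuple[str, np.ndarray, str]]:
    """Generate ``n_per_class`` jittered variants of each template.

    ``templates`` maps class label to :class:`PhantomSpec` (dict or
    ``(label, spec)`` pairs).  Each variant gets its palette hues
    jittered uniformly by ±``hue_jitter`` degrees, a fresh image seed,
    and resampled noise; all derived from the single ``seed``.
    Returns ``(image_id, rgb_array, label)`` triples.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    items = list(templates.items()) if isinstance(templates, dict) else list(templates)
    out = []
    for ci, (label, tpl) in enumerate(items):
        for i in range(n_per_class):
            rng = np.random.default_rng([seed, ci, i])
            pal = tuple(
                (
                    (
                        float((c[0] + rng.uniform(-hue_jitter, hue_jitter)) % 360.0),
                        c[1],
                        c[2],
                    ),
                    f,
                )
                for c, f in tpl.palette
            )
            img_seed = int(rng.integers(0, 2**31))
            sp = dataclasses.replace(tpl, palette=pal, seed=img_seed)
            out.append((f"{label}_{i:03d}", make_phantom(sp), label))
    return out


# ---------------------------------------------------------------------------
# default template sets

_PINK = (345.0, 0.45, 0.85)
_PALE = (15.0, 0.20, 0.92)
_YELLOW_COATING = (50.0, 0.55, 0.80)
_WHITE_COATING = (80.0, 0.12, 0.95)
_PURPLE = (290.0, 0.50, 0.60)
_PURPLE_RED = (315.0, 0.55, 0.70)


def _solid(color, **kw) -> PhantomSpec:
    return PhantomSpec(palette=((color, 1.0),), **kw)


def default_color_templates(size=(256, 256), noise_sigma=4.0):
    """Six color classes (texture-free) with well-separated hue centers."""
    kw = dict(size=size, noise_sigma=noise_sigma)
    return {
        "pink": _solid(_PINK, **kw),
        "pale": _solid(_PALE, **kw),
        "yellow_coating": _solid(_YELLOW_COATING, **kw),
        "white_coating": _solid(_WHITE_COATING, **kw),
        "purple": _solid(_PURPLE, **kw),
        "purple_red": _solid(_PURPLE_RED, **kw),
    }


def default_texture_templates(size=(256, 256), noise_sigma=4.0, contrast=120.0):
    """Five texture classes on a fixed pink base, separable by edge type."""
    kw = dict(size=size, noise_sigma=noise_sigma, texture_contrast=contrast)
    return {
        "vstripes": _solid(_PINK, texture="vstripes", **kw),
        "hstripes": _solid(_PINK, texture="hstripes", **kw),
        "diag45": _solid(_PINK, texture="diag45", **kw),
        "diag135": _solid(_PINK, texture="diag135", **kw),
        "checker": _solid(_PINK, texture="checker", **kw),
    }


def default_combined_templates(size=(256, 256), noise_sigma=4.0, contrast=120.0):
    """Six color×texture classes where neither feature alone separates all.

    Two color pairs share their textures (color must disambiguate) and
    the two checker classes share their texture (ditto); every texture
    appears under at least two colors (texture alone confuses them).
    """
    kw = dict(size=size, noise_sigma=noise_sigma, texture_contrast=contrast)
    return {
        "pink_vstripes": _solid(_PINK, texture="vstripes", **kw),
        "pink_diag45": _solid(_PINK, texture="diag45", **kw),
        "yellow_vstripes": _solid(_YELLOW_COATING, texture="vstripes", **kw),
        "yellow_diag45": _solid(_YELLOW_COATING, texture="diag45", **kw),
        "purple_checker": _solid(_PURPLE, texture="checker", **kw),
        "purplered_checker": _solid(_PURPLE_RED, texture="checker", **kw),
    }


TEMPLATE_SETS = {
    "default6color": default_color_templates,
    "default5texture": default_texture_templates,
    "combined6": default_combined_templates,
}
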