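"""Noise canvases, procedural target banks, and composited oddity stimuli.

The unit stimulus is a 2-D Gaussian luminance noise canvas (8-bit grayscale).
Targets — schematic faces or letter-like glyphs — are alpha-blended onto the
centred target region at a configurable opacity, after which a black
elliptical frame and a central fixation cross can be drawn for presentation.

Analyses always operate on the *unframed* pixel planes; framing is a
presentation-layer step (see :func:`apply_frame_and_cross`).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .geometry import DEFAULT_GEOMETRY, StimulusGeometry

CATEGORIES = ("chimpanzee_face", "human_face", "letter")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    """Round with halves away from zero (toward +inf for positive values)."""
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


def _to_uint8(x: np.ndarray) -> np.ndarray:
    return np.clip(_round_half_up(x), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class NoiseCanvas:
    """One Gaussian-noise stimulus plane.

    pixels : uint8 luminance grid, shape (height, width)
    seed   : RNG seed the canvas was drawn from
    id     : unique string identifier within an experiment
    """

    pixels: np.ndarray
    seed: int
    id: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class TargetImage:
    """A procedurally drawn target (face or letter glyph), target-region sized."""

    pixels: np.ndarray
    category: str
    index: int


@dataclass(frozen=True)
class CompositeStimulus:
    """A noise canvas with an optional target blended into its centre."""

    pixels: np.ndarray
    source_noise_id: str
    target_ref: tuple[str, int] | None
    opacity: float
    framed: bool = False


def generate_noise(
    width: int,
    height: int,
    mean: float = 128.0,
    sd: float = 30.0,
    seed: int | None = None,
    canvas_id: str | None = None,
) -> NoiseCanvas:
    """Draw a ``height x width`` canvas of i.i.d. Gaussian luminance noise.

    Values are rounded (half up) and clipped to [0, 255].  The same seed
    always reproduces the same canvas bit-for-bit.
    """
    if width <= 0 or height <= 0:
        raise ValueError(f"canvas dimensions must be positive, got {width}x{height}")
    if sd < 0:
        raise ValueError("noise sd must be non-negative")
    seed = 0 if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    raw = rng.normal(loc=mean, scale=sd, size=(height, width)) if sd > 0 else np.full(
        (height, width), float(mean)
    )
    return NoiseCanvas(pixels=_to_uint8(raw), seed=seed, id=canvas_id or f"noise-{seed}")


# ---------------------------------------------------------------------------
# procedural target banks
# ---------------------------------------------------------------------------


def _ellipse_mask(shape: tuple[int, int], cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    return ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0


def _draw_face(shape: tuple[int, int], rng: np.random.Generator, *, face_tone: float,
               background: float, feature_tone: float) -> np.ndarray:
    """A schematic top-heavy face: two dark eye blobs above one dark mouth blob."""
    h, w = shape
    img = np.full(shape, background, dtype=np.float64)
    # head oval with mild jitter
    head_ry = h * rng.uniform(0.38, 0.44)
    head_rx = w * rng.uniform(0.34, 0.40)
    cy, cx = h * 0.5 + rng.normal(0, h * 0.01), w * 0.5 + rng.normal(0, w * 0.01)
    img[_ellipse_mask(shape, cy, cx, head_ry, head_rx)] = face_tone + rng.normal(0, 4)
    # eyes: horizontally aligned pair in the upper half
    eye_row = cy - head_ry * rng.uniform(0.28, 0.40)
    eye_dx = head_rx * rng.uniform(0.38, 0.50)
    eye_ry = h * rng.uniform(0.045, 0.065)
    eye_rx = w * rng.uniform(0.07, 0.10)
    for side in (-1, 1):
        img[_ellipse_mask(shape, eye_row, cx + side * eye_dx, eye_ry, eye_rx)] = feature_tone
    # mouth: single blob in the lower half, slightly smaller than the eye pair
    mouth_row = cy + head_ry * rng.uniform(0.35, 0.50)
    mouth_ry = h * rng.uniform(0.035, 0.055)
    mouth_rx = w * rng.uniform(0.10, 0.16)
    img[_ellipse_mask(shape, mouth_row, cx + rng.normal(0, w * 0.01), mouth_ry, mouth_rx)] = feature_tone
    return img


def _draw_glyph(shape: tuple[int, int], rng: np.random.Generator, *, background: float,
                stroke_tone: float) -> np.ndarray:
    """A letter-like glyph: dark horizontal/vertical strokes on a light ground."""
    h, w = shape
    img = np.full(shape, background, dtype=np.float64)
    t = max(2, int(round(h * 0.05)))  # stroke thickness
    # glyph box occupies the central ~70%
    top, left = int(h * 0.15), int(w * 0.15)
    bottom, right = int(h * 0.85), int(w * 0.85)
    rows = np.linspace(top, bottom - t, 4).astype(int)
    cols = np.linspace(left, right - t, 4).astype(int)
    n_strokes = rng.integers(3, 7)
    placed = 0
    while placed < n_strokes:
        if rng.random() < 0.5:  # horizontal stroke
            r = rows[rng.integers(0, len(rows))]
            c0, c1 = sorted(rng.choice(cols, size=2, replace=False))
            img[r : r + t, c0 : c1 + t] = stroke_tone
        else:  # vertical stroke
            c = cols[rng.integers(0, len(cols))]
            r0, r1 = sorted(rng.choice(rows, size=2, replace=False))
            img[r0 : r1 + t, c : c + t] = stroke_tone
        placed += 1
    return img


def make_target_bank(
    category: str,
    n: int = 20,
    seed: int = 0,
    geometry: StimulusGeometry = DEFAULT_GEOMETRY,
) -> list[TargetImage]:
    """Generate ``n`` distinct procedural targets for one stimulus category.

    Face categories produce top-heavy two-eyes-plus-mouth layouts with
    jittered geometry; the letter category produces stroke-grid glyphs.
    The bank is deterministic under ``seed``.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}")
    if n < 1:
        raise ValueError("bank size must be at least 1")
    rng = np.random.default_rng([zlib.crc32(category.encode()) % (2**31), int(seed)])
    shape = geometry.target_shape
    bank: list[TargetImage] = []
    for i in range(n):
        if category == "chimpanzee_face":
            img = _draw_face(shape, rng, face_tone=120.0, background=190.0, feature_tone=35.0)
        elif category == "human_face":
            img = _draw_face(shape, rng, face_tone=170.0, background=210.0, feature_tone=50.0)
        else:
            img = _draw_glyph(shape, rng, background=220.0, stroke_tone=25.0)
        bank.append(TargetImage(pixels=_to_uint8(img), category=category, index=i + 1))
    # jittered geometry makes collisions essentially impossible; verify anyway
    for i in range(len(bank)):
        for j in range(i + 1, len(bank)):
            if np.array_equal(bank[i].pixels, bank[j].pixels):
                raise RuntimeError("target bank produced duplicate images")
    return bank


# ---------------------------------------------------------------------------
# compositing and presentation annotations
# ---------------------------------------------------------------------------


def composite_target(
    noise: NoiseCanvas,
    target: TargetImage | None,
    opacity: float,
    geometry: StimulusGeometry = DEFAULT_GEOMETRY,
) -> CompositeStimulus:
    """Blend a target into the centred target region of a noise canvas.

    Inside the region each pixel becomes
    ``round((1 - opacity) * noise + opacity * target)``; pixels outside the
    region are untouched.  ``target=None`` (or opacity 0) yields a
    target-absent composite pixel-identical to the source noise.
    """
    if not 0.0 <= opacity <= 1.0:
        raise ValueError(f"opacity must lie in [0, 1], got {opacity}")
    if noise.shape != geometry.canvas_shape:
        raise ValueError(
            f"noise shape {noise.shape} does not match canvas {geometry.canvas_shape}"
        )
    out = noise.pixels.copy()
    ref: tuple[str, int] | None = None
    if target is not None and opacity > 0:
        if target.pixels.shape != geometry.target_shape:
            raise ValueError(
                f"target shape {target.pixels.shape} does not match {geometry.target_shape}"
            )
        r0, c0 = geometry.target_row_offset, geometry.target_col_offset
        th, tw = geometry.target_shape
        region = out[r0 : r0 + th, c0 : c0 + tw].astype(np.float64)
        blended = (1.0 - opacity) * region + opacity * target.pixels.astype(np.float64)
        out[r0 : r0 + th, c0 : c0 + tw] = _to_uint8(blended)
        ref = (target.category, target.index)
    return CompositeStimulus(
        pixels=out,
        source_noise_id=noise.id,
        target_ref=ref,
        opacity=float(opacity) if ref is not None else 0.0,
    )


def noise_only(noise: NoiseCanvas) -> CompositeStimulus:
    """Wrap a bare noise canvas as a target-absent composite."""
    return composite_target(noise, None, 0.0, geometry=_geometry_for(noise))


def _geometry_for(noise: NoiseCanvas) -> StimulusGeometry:
    # noise-only wrapping never touches pixels, so only the canvas shape matters
    h, w = noise.shape
    return StimulusGeometry(
        canvas_width=w, canvas_height=h,
        target_width=min(w, DEFAULT_GEOMETRY.target_width),
        target_height=min(h, DEFAULT_GEOMETRY.target_height),
    )


def cross_mask(geometry: StimulusGeometry = DEFAULT_GEOMETRY) -> np.ndarray:
    """Boolean canvas mask of the central fixation cross.

    The cross is the union of a horizontal and a vertical bar, each
    ``cross_size`` long and ``cross_size // 3`` thick, centred on the canvas;
    its pixel count is therefore ``2 * size * t - t**2`` (the central overlap
    is counted once).
    """
    h, w = geometry.canvas_shape
    size = geometry.cross_size
    t = max(1, size // 3)
    cy, cx = h // 2, w // 2
    mask = np.zeros((h, w), dtype=bool)
    r0, c0 = cy - size // 2, cx - size // 2
    tr, tc = cy - t // 2, cx - t // 2
    mask[tr : tr + t, c0 : c0 + size] = True  # horizontal bar
    mask[r0 : r0 + size, tc : tc + t] = True  # vertical bar
    return mask


def apply_frame_and_cross(
    stim: CompositeStimulus,
    geometry: StimulusGeometry = DEFAULT_GEOMETRY,
    frame_color: int = 0,
    cross_color: int = 0,
) -> CompositeStimulus:
    """Draw the black elliptical frame and central cross on a composite.

    Pixels outside the ellipse are set to the background (black); the frame
    outline is a ``frame_stroke``-wide black band just inside the ellipse
    boundary.  Framing an already-framed stimulus is an error.
    """
    if stim.framed:
        raise ValueError("stimulus is already framed")
    if stim.pixels.shape != geometry.canvas_shape:
        raise ValueError("stimulus shape does not match geometry")
    h, w = geometry.canvas_shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = geometry.ellipse_height / 2.0, geometry.ellipse_width / 2.0
    outer = _ellipse_mask((h, w), cy, cx, ry, rx)
    inner = _ellipse_mask((h, w), cy, cx, ry - geometry.frame_stroke, rx - geometry.frame_stroke)
    out = stim.pixels.copy()
    out[~outer] = frame_color  # mask noise outside the ellipse
    out[outer & ~inner] = frame_color  # frame outline
    out[cross_mask(geometry)] = cross_color
    return replace(stim, pixels=out, framed=True)


# ---------------------------------------------------------------------------
# PNG I/O
# ---------------------------------------------------------------------------


def save_png(pixels: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit grayscale plane losslessly to PNG."""
    arr = np.asarray(pixels)
    if arr.dtype != np.uint8:
        arr = _to_uint8(arr)
    Image.fromarray(arr, mode="L").save(Path(path), format="PNG")


def load_png(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG back as a uint8 array."""
    with Image.open(Path(path)) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)
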