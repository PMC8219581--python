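"""Procedural per-frame synthesis of visual stimuli.

Every stimulus template is evaluated analytically at pixel centers in a
patch-local coordinate frame: origin at the patch (and stimulus) center,
+x right, +y up, angles in radians counterclockwise from +x.  Stimulus
positions are center coordinates relative to the screen center.  Rendering
is a pure function of (spec, resolved properties, frame index, RNG state),
so identical seeds give bit-identical frames.

Luminance is handled throughout as a linear fraction of the display maximum
in [0, 1]; conversion to cd/m^2 is a display-profile lookup
(:func:`stimkit.units.luminance_fraction_to_cd`).

Contrast semantics: for periodic stimuli ``contrast`` is the Michelson
contrast about the mean luminance; for uniform patches it scales the
deviation from mid-gray.  The noise-bit method (stochastic rounding between
adjacent 8-bit levels, unbiased in expectation) provides quasi-continuous
contrast on an 8-bit panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Optional

import numpy as np

from .model import (
    PROPERTY_ALIASES,
    RenderContext,
    Scene,
    StimulusSpec,
    VISUAL_TYPES,
    resolve_property,
)
from .units import DisplayProfile, deg_to_px, length_to_px, seconds_to_frames

__all__ = [
    "FrameBuffer",
    "RasterPatch",
    "DotFieldState",
    "grating_luminance",
    "checkerboard_value",
    "init_dot_field",
    "update_dot_field",
    "apply_shape_mask",
    "apply_noise_filter",
    "quantize_noise_bit",
    "resolve_stimulus_properties",
    "render_stimulus_frame",
    "composite_scene_frame",
    "frame_to_png",
]


@dataclass
class FrameBuffer:
    """A full synthesized display frame: H x W x RGB in [0, 1]."""

    height: int
    width: int
    pixels: np.ndarray  # (H, W, 3) float

    def __post_init__(self) -> None:
        if self.pixels.shape != (self.height, self.width, 3):
            raise ValueError("pixel array shape does not match height/width")


@dataclass
class RasterPatch:
    """A rendered stimulus raster plus alpha, positioned on the screen.

    ``origin`` is the (column, row) of the patch's top-left pixel in frame
    buffer coordinates; the patch may extend past the screen edges and is
    clipped at composite time.
    """

    origin: tuple[int, int]
    pixels: np.ndarray  # (h, w, 3) float
    alpha: np.ndarray  # (h, w) float in [0, 1]

    def __post_init__(self) -> None:
        if self.pixels.shape[:2] != self.alpha.shape:
            raise ValueError("pixel and alpha arrays must share h x w")


# ---------------------------------------------------------------------------
# Analytic stimulus functions
# ---------------------------------------------------------------------------

def grating_luminance(
    x: np.ndarray | float,
    y: np.ndarray | float,
    mean: float = 0.5,
    contrast: float = 1.0,
    sf: float = 0.02,
    orientation: float = 0.0,
    phase: float = 0.0,
    envelope_sigma: Optional[float] = None,
    carrier_contrast_mod: Optional[dict | float] = None,
):
    """Luminance of a (possibly Gabor) grating at patch coordinates (x, y).

    L = mean * (1 + c_eff(x, y) * cos(2*pi*sf*(x cos t + y sin t) + phase))

    where ``c_eff = contrast * G_env * G_mod``; ``G_env`` is a unit-peak
    isotropic Gaussian of width ``envelope_sigma`` centered on the patch
    (yielding a Gabor) or 1 when absent, and ``G_mod`` is a unit-peak
    Gaussian carrier-contrast modulation of width ``sigma`` (pass a scalar
    or ``{"kind": "gaussian", "sigma": s}``) or 1 when absent.  ``contrast``
    is the Michelson contrast of the un-enveloped carrier.
    """
    if not (0.0 <= contrast <= 1.0):
        raise ValueError(f"contrast must lie in [0, 1], got {contrast!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    carrier = np.cos(
        2.0 * np.pi * sf * (x * math.cos(orientation) + y * math.sin(orientation))
        + phase
    )
    c_eff = contrast
    if envelope_sigma is not None:
        c_eff = c_eff * np.exp(-(x * x + y * y) / (2.0 * envelope_sigma**2))
    if carrier_contrast_mod is not None:
        sigma_c = (
            carrier_contrast_mod["sigma"]
            if isinstance(carrier_contrast_mod, dict)
            else float(carrier_contrast_mod)
        )
        c_eff = c_eff * np.exp(-(x * x + y * y) / (2.0 * sigma_c**2))
    return mean * (1.0 + c_eff * carrier)


def checkerboard_value(
    x: np.ndarray | float,
    y: np.ndarray | float,
    kind: str = "rect",
    params: Optional[dict] = None,
):
    """Checkerboard parity (0 or 1) at patch coordinates (x, y).

    rect: parity = (floor(x / check_w) + floor(y / check_h)) mod 2.
    radial: parity = (sector_index(atan2(y, x)) + floor(r / ring_width)) mod 2
    with ``n_sectors`` equal angular sectors.
    """
    params = params or {}
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if kind == "rect":
        cw = float(params.get("check_w", 20.0))
        ch = float(params.get("check_h", 20.0))
        if cw <= 0 or ch <= 0:
            raise ValueError("check sizes must be positive")
        return ((np.floor(x / cw) + np.floor(y / ch)) % 2).astype(int)
    if kind == "radial":
        n_sectors = int(params.get("n_sectors", 8))
        ring_w = float(params.get("ring_width", 20.0))
        if n_sectors < 1 or ring_w <= 0:
            raise ValueError("need n_sectors >= 1 and ring_width > 0")
        theta = np.mod(np.arctan2(y, x), 2.0 * np.pi)
        sector = np.floor(theta / (2.0 * np.pi) * n_sectors)
        r = np.hypot(x, y)
        return ((sector + np.floor(r / ring_w)) % 2).astype(int)
    raise ValueError(f"unknown checkerboard kind {kind!r}")


# ---------------------------------------------------------------------------
# Random-dot kinematograms
# ---------------------------------------------------------------------------

@dataclass
class DotFieldState:
    """State of a random-dot field, aperture-centered coordinates."""

    positions: np.ndarray  # (n, 2) float px
    directions: np.ndarray  # (n,) rad — motion direction of noise dots
    ages: np.ndarray  # (n,) int frames
    is_signal: np.ndarray  # (n,) bool


def _uniform_disk(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    th = rng.random(n) * 2.0 * np.pi
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def init_dot_field(
    n_dots: int,
    aperture_radius: float,
    coherence: float,
    lifetime: int,
    rng: np.random.Generator,
) -> DotFieldState:
    """Draw a fresh dot field: uniform positions, staggered ages,
    Bernoulli(coherence) signal membership."""
    if aperture_radius <= 0:
        raise ValueError("aperture radius must be positive")
    if not (0.0 <= coherence <= 1.0):
        raise ValueError("coherence must lie in [0, 1]")
    return DotFieldState(
        positions=_uniform_disk(n_dots, aperture_radius, rng),
        directions=rng.random(n_dots) * 2.0 * np.pi,
        ages=rng.integers(0, max(lifetime, 1), n_dots),
        is_signal=rng.random(n_dots) < coherence,
    )


def update_dot_field(
    state: DotFieldState,
    kind: str,
    params: dict,
    rng: np.random.Generator,
) -> DotFieldState:
    """Advance the dot field one frame.

    Signal dots move according to ``kind``: ``linear`` dots translate by
    ``speed`` along ``direction``; ``radial`` dots rotate about the aperture
    center by speed / r radians (tangential motion at constant radius);
    ``expansive`` dots move outward along their ray by ``speed`` (negative
    speed contracts).  Noise dots translate by ``speed`` along their own
    per-lifetime random direction.  Dots that exceed ``lifetime`` or leave
    the aperture are redrawn uniformly inside it with age 0 and membership
    re-sampled from Bernoulli(coherence), keeping the expected signal
    fraction at ``coherence``.
    """
    speed = float(params.get("speed", 1.0))
    direction = float(params.get("direction", 0.0))
    coherence = float(params.get("coherence", 1.0))
    lifetime = int(params.get("lifetime", 60))
    radius = float(params.get("aperture_radius", 100.0))
    if radius <= 0:
        raise ValueError("aperture radius must be positive")
    if not (0.0 <= coherence <= 1.0):
        raise ValueError("coherence must lie in [0, 1]")

    pos = state.positions.copy()
    sig = state.is_signal
    noise = ~sig

    if kind == "linear":
        pos[sig, 0] += speed * math.cos(direction)
        pos[sig, 1] += speed * math.sin(direction)
    elif kind == "radial":
        r = np.hypot(pos[sig, 0], pos[sig, 1])
        with np.errstate(divide="ignore", invalid="ignore"):
            dphi = np.where(r > 0, speed / np.maximum(r, 1e-12), 0.0)
        c, s = np.cos(dphi), np.sin(dphi)
        x0, y0 = pos[sig, 0].copy(), pos[sig, 1].copy()
        pos[sig, 0] = c * x0 - s * y0
        pos[sig, 1] = s * x0 + c * y0
    elif kind == "expansive":
        r = np.hypot(pos[sig, 0], pos[sig, 1])
        scale = np.where(r > 0, (r + speed) / np.maximum(r, 1e-12), 0.0)
        scale = np.maximum(scale, 0.0)  # contraction through center stops there
        pos[sig] *= scale[:, None]
    else:
        raise ValueError(f"unknown dot-field kind {kind!r}")

    pos[noise, 0] += speed * np.cos(state.directions[noise])
    pos[noise, 1] += speed * np.sin(state.directions[noise])

    ages = state.ages + 1
    out = np.hypot(pos[:, 0], pos[:, 1]) > radius
    dead = (ages >= lifetime) | out
    n_dead = int(dead.sum())
    new_sig = sig.copy()
    new_dir = state.directions.copy()
    if n_dead:
        pos[dead] = _uniform_disk(n_dead, radius, rng)
        ages[dead] = 0
        new_sig[dead] = rng.random(n_dead) < coherence
        new_dir[dead] = rng.random(n_dead) * 2.0 * np.pi

    return DotFieldState(positions=pos, directions=new_dir, ages=ages,
                         is_signal=new_sig)


# ---------------------------------------------------------------------------
# Masks, noise, quantization
# ---------------------------------------------------------------------------

def apply_shape_mask(
    patch: RasterPatch,
    shape: str,
    size: tuple[float, float],
    arm_fraction: float = 0.2,
) -> RasterPatch:
    """Mask a patch to a rectangle, ellipse, or cross of the given w x h.

    The cross is the union of a horizontal and a vertical bar of thickness
    ``arm_fraction * min(w, h)``.
    """
    w, h = float(size[0]), float(size[1])
    if w <= 0 or h <= 0:
        raise ValueError("shape size must be positive")
    ph, pw = patch.alpha.shape
    xs = np.arange(pw) - (pw - 1) / 2.0
    ys = (ph - 1) / 2.0 - np.arange(ph)
    X, Y = np.meshgrid(xs, ys)
    if shape == "rectangle":
        mask = (np.abs(X) <= w / 2.0) & (np.abs(Y) <= h / 2.0)
    elif shape == "ellipse":
        mask = (2.0 * X / w) ** 2 + (2.0 * Y / h) ** 2 <= 1.0
    elif shape == "cross":
        t = arm_fraction * min(w, h)
        horiz = (np.abs(Y) <= t / 2.0) & (np.abs(X) <= w / 2.0)
        vert = (np.abs(X) <= t / 2.0) & (np.abs(Y) <= h / 2.0)
        mask = horiz | vert
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return replace(patch, alpha=patch.alpha * mask.astype(float))


def apply_noise_filter(
    patch: RasterPatch, noise_amplitude: float, rng: np.random.Generator
) -> RasterPatch:
    """Add zero-mean uniform luminance noise of half-range ``noise_amplitude``
    per pixel (identical across RGB), then clip to [0, 1]."""
    if not (0.0 <= noise_amplitude <= 1.0):
        raise ValueError("noise amplitude must lie in [0, 1]")
    if noise_amplitude == 0.0:
        return patch
    h, w = patch.alpha.shape
    noise = rng.uniform(-noise_amplitude, noise_amplitude, size=(h, w))
    pixels = np.clip(patch.pixels + noise[:, :, None], 0.0, 1.0)
    return replace(patch, pixels=pixels)


def quantize_noise_bit(
    values: np.ndarray, bit_depth: int = 8, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Stochastically round [0, 1] values to integer levels of a
    ``bit_depth``-bit panel (noise-bit dithering).

    Each value v is mapped to one of the two adjacent levels among
    2**bit_depth uniformly spaced levels, taking the upper level with
    probability equal to v's fractional position between them, independently
    per pixel per frame.  The expected level value is exactly v, so contrast
    becomes quasi-continuous on a discrete panel.
    """
    values = np.asarray(values, dtype=float)
    if values.size and (values.min() < 0.0 or values.max() > 1.0):
        raise ValueError("values must lie in [0, 1] for noise-bit quantization")
    if rng is None:
        rng = np.random.default_rng()
    n_levels = (1 << bit_depth) - 1
    scaled = values * n_levels
    low = np.floor(scaled)
    frac = scaled - low
    out = low + (rng.random(values.shape) < frac)
    dtype = np.uint8 if bit_depth <= 8 else np.uint16
    return out.astype(dtype)


# ---------------------------------------------------------------------------
# Property resolution to pixel/frame units
# ---------------------------------------------------------------------------

_SPATIAL_PROPS = {
    "position_x", "position_y", "size_x", "size_y", "envelope_sigma",
    "check_size_x", "check_size_y", "ring_width", "dot_radius", "char_size",
}

_DEFAULTS: dict[str, Any] = {
    "position_x": 0.0,
    "position_y": 0.0,
    "orientation": 0.0,
    "size_x": 100.0,
    "size_y": 100.0,
    "color": (1.0, 1.0, 1.0),
    "color2": (0.0, 0.0, 0.0),
    "contrast": 1.0,
    "noise_filter": 0.0,
    "mean_luminance": 0.5,
    "spatial_frequency": 2.0,  # cycles/deg before conversion
    "phase": 0.0,
    "envelope_sigma": None,
    "carrier_contrast_modulation": None,
    "check_size_x": 20.0,
    "check_size_y": 20.0,
    "n_sectors": 8,
    "ring_width": 20.0,
    "n_dots": 100,
    "dot_radius": 2.0,
    "dot_speed": 1.0,
    "dot_direction": 0.0,
    "coherence": 1.0,
    "dot_lifetime": 60,
    "text_string": "",
    "char_size": 21.0,
    "start_time": 0.0,
    "duration": None,  # None = whole scene
    "file_path": None,
    "tone_frequency": 440.0,
    "amplitude": 0.5,
    "ramp": 0.005,
}


def resolve_stimulus_properties(
    stim: StimulusSpec,
    display: DisplayProfile,
    bindings: Optional[dict[str, Any]] = None,
    ctx: Optional[RenderContext] = None,
) -> dict[str, Any]:
    """Evaluate all properties of a stimulus for one frame of one trial,
    converting tagged units to pixels / frames / cycles-per-px.

    Aliases (e.g. ``gratingRotation``) are folded onto their canonical
    property names; absent properties take template defaults.
    """
    out: dict[str, Any] = {}
    for name, pv in stim.properties.items():
        value = resolve_property(stim, name, bindings, ctx)
        canonical = PROPERTY_ALIASES.get(name, name)
        unit = pv.unit
        if value is None:
            out[canonical] = None
            continue
        if canonical in _SPATIAL_PROPS and unit is not None:
            value = length_to_px(float(value), unit, display)
        elif canonical == "spatial_frequency":
            if unit in (None, "cpd"):
                value = float(value) / deg_to_px(1.0, display)
            elif unit == "cycles_per_px":
                value = float(value)
        elif canonical in ("duration", "start_time", "dot_lifetime") and unit == "s":
            value = seconds_to_frames(float(value), display.refresh_rate)
        out[canonical] = value
    for name, default in _DEFAULTS.items():
        if name not in out:
            if name == "spatial_frequency":
                default = default / deg_to_px(1.0, display)
            out[name] = default
    return out


# ---------------------------------------------------------------------------
# Bitmap text (5x7 monospace, bundled; no system font dependency)
# ---------------------------------------------------------------------------

_FONT_5X7 = {
    "A": ("01110", "10001", "10001", "11111", "10001", "10001", "10001"),
    "B": ("11110", "10001", "10001", "11110", "10001", "10001", "11110"),
    "C": ("01110", "10001", "10000", "10000", "10000", "10001", "01110"),
    "D": ("11110", "10001", "10001", "10001", "10001", "10001", "11110"),
    "E": ("11111", "10000", "10000", "11110", "10000", "10000", "11111"),
    "F": ("11111", "10000", "10000", "11110", "10000", "10000", "10000"),
    "G": ("01110", "10001", "10000", "10111", "10001", "10001", "01111"),
    "H": ("10001", "10001", "10001", "11111", "10001", "10001", "10001"),
    "I": ("01110", "00100", "00100", "00100", "00100", "00100", "01110"),
    "J": ("00111", "00010", "00010", "00010", "00010", "10010", "01100"),
    "K": ("10001", "10010", "10100", "11000", "10100", "10010", "10001"),
    "L": ("10000", "10000", "10000", "10000", "10000", "10000", "11111"),
    "M": ("10001", "11011", "10101", "10101", "10001", "10001", "10001"),
    "N": ("10001", "11001", "10101", "10011", "10001", "10001", "10001"),
    "O": ("01110", "10001", "10001", "10001", "10001", "10001", "01110"),
    "P": ("11110", "10001", "10001", "11110", "10000", "10000", "10000"),
    "Q": ("01110", "10001", "10001", "10001", "10101", "10010", "01101"),
    "R": ("11110", "10001", "10001", "11110", "10100", "10010", "10001"),
    "S": ("01111", "10000", "10000", "01110", "00001", "00001", "11110"),
    "T": ("11111", "00100", "00100", "00100", "00100", "00100", "00100"),
    "U": ("10001", "10001", "10001", "10001", "10001", "10001", "01110"),
    "V": ("10001", "10001", "10001", "10001", "10001", "01010", "00100"),
    "W": ("10001", "10001", "10001", "10101", "10101", "10101", "01010"),
    "X": ("10001", "10001", "01010", "00100", "01010", "10001", "10001"),
    "Y": ("10001", "10001", "01010", "00100", "00100", "00100", "00100"),
    "Z": ("11111", "00001", "00010", "00100", "01000", "10000", "11111"),
    "0": ("01110", "10001", "10011", "10101", "11001", "10001", "01110"),
    "1": ("00100", "01100", "00100", "00100", "00100", "00100", "01110"),
    "2": ("01110", "10001", "00001", "00010", "00100", "01000", "11111"),
    "3": ("11111", "00010", "00100", "00010", "00001", "10001", "01110"),
    "4": ("00010", "00110", "01010", "10010", "11111", "00010", "00010"),
    "5": ("11111", "10000", "11110", "00001", "00001", "10001", "01110"),
    "6": ("00110", "01000", "10000", "11110", "10001", "10001", "01110"),
    "7": ("11111", "00001", "00010", "00100", "01000", "01000", "01000"),
    "8": ("01110", "10001", "10001", "01110", "10001", "10001", "01110"),
    "9": ("01110", "10001", "10001", "01111", "00001", "00010", "01100"),
    " ": ("00000", "00000", "00000", "00000", "00000", "00000", "00000"),
    ".": ("00000", "00000", "00000", "00000", "00000", "01100", "01100"),
    ",": ("00000", "00000", "00000", "00000", "01100", "00100", "01000"),
    ":": ("00000", "01100", "01100", "00000", "01100", "01100", "00000"),
    "!": ("00100", "00100", "00100", "00100", "00100", "00000", "00100"),
    "?": ("01110", "10001", "00001", "00010", "00100", "00000", "00100"),
    "+": ("00000", "00100", "00100", "11111", "00100", "00100", "00000"),
    "-": ("00000", "00000", "00000", "11111", "00000", "00000", "00000"),
    "/": ("00001", "00010", "00010", "00100", "01000", "01000", "10000"),
}


def _rasterize_text(text: str, char_px: float) -> np.ndarray:
    """Binary raster of a string in the bundled 5x7 monospace font."""
    scale = max(1, round(char_px / 7.0))
    glyphs = []
    fallback = tuple("11111" for _ in range(7))
    for ch in text:
        rows = _FONT_5X7.get(ch.upper(), fallback)
        g = np.array([[int(b) for b in row] for row in rows], dtype=float)
        g = np.pad(g, ((0, 0), (0, 1)))  # 1-column inter-glyph gap
        glyphs.append(g)
    if not glyphs:
        return np.zeros((7, 1), dtype=float)
    raster = np.hstack(glyphs)
    return np.kron(raster, np.ones((scale, scale)))


# ---------------------------------------------------------------------------
# Per-frame rendering and compositing
# ---------------------------------------------------------------------------

# Background-filled frame template, reused across composites of one display.
_BG_CACHE: dict = {}


def _patch_grid(w: int, h: int) -> tuple[np.ndarray, np.ndarray]:
    xs = np.arange(w) - (w - 1) / 2.0
    ys = (h - 1) / 2.0 - np.arange(h)
    return np.meshgrid(xs, ys)


def _as_rgb(value: Any) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(3, float(arr))
    return arr.reshape(3)


def _draw_dots(
    pixels: np.ndarray, alpha: np.ndarray, state: DotFieldState, radius: float,
    color: np.ndarray, w: int, h: int
) -> None:
    r = max(radius, 0.5)
    ri = int(math.ceil(r))
    for px, py in state.positions:
        col = px + (w - 1) / 2.0
        row = (h - 1) / 2.0 - py
        c0, c1 = int(math.floor(col - r)), int(math.ceil(col + r)) + 1
        r0, r1 = int(math.floor(row - r)), int(math.ceil(row + r)) + 1
        c0, c1 = max(c0, 0), min(c1, w)
        r0, r1 = max(r0, 0), min(r1, h)
        if c0 >= c1 or r0 >= r1:
            continue
        cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
        mask = (cc - col) ** 2 + (rr - row) ** 2 <= r * r
        pixels[r0:r1, c0:c1][mask] = color
        alpha[r0:r1, c0:c1][mask] = 1.0


def render_stimulus_frame(
    stim: StimulusSpec,
    resolved_props: dict[str, Any],
    ctx: RenderContext,
    display: DisplayProfile,
    rng: Optional[np.random.Generator] = None,
    dot_state: Optional[dict[str, DotFieldState]] = None,
) -> RasterPatch:
    """Render one visual stimulus for one frame into a RasterPatch.

    ``resolved_props`` comes from :func:`resolve_stimulus_properties` (all
    lengths in px, times in frames).  Random-dot stimuli keep per-trial state
    in ``dot_state`` (keyed by stimulus name) and advance it once per call;
    noise and dot stimuli need ``rng``.
    """
    if stim.type not in VISUAL_TYPES:
        raise ValueError(
            f"stimulus {stim.name!r} of type {stim.type!r} is not a visual "
            "stimulus; it cannot be rendered to a frame"
        )
    p = resolved_props
    w = max(1, int(round(float(p["size_x"]))))
    h = max(1, int(round(float(p["size_y"]))))
    theta = float(p["orientation"])
    color = _as_rgb(p["color"])
    color2 = _as_rgb(p["color2"])
    X, Y = _patch_grid(w, h)
    # rotated sampling frame: U along the stimulus axis, V orthogonal
    U = X * math.cos(theta) + Y * math.sin(theta)
    V = -X * math.sin(theta) + Y * math.cos(theta)

    alpha = np.ones((h, w), dtype=float)

    if stim.type == "patch":
        c = 0.5 + float(p["contrast"]) * (color - 0.5)
        pixels = np.broadcast_to(c, (h, w, 3)).copy()
    elif stim.type == "gradient":
        t = np.clip(U / max(w - 1, 1) + 0.5, 0.0, 1.0)
        pixels = (1.0 - t)[:, :, None] * color + t[:, :, None] * color2
    elif stim.type == "grating":
        L = grating_luminance(
            X, Y,
            mean=float(p["mean_luminance"]),
            contrast=float(p["contrast"]),
            sf=float(p["spatial_frequency"]),
            orientation=theta,
            phase=float(p["phase"]),
            envelope_sigma=p["envelope_sigma"],
            carrier_contrast_mod=p["carrier_contrast_modulation"],
        )
        pixels = L[:, :, None] * color
    elif stim.type == "checkerboard_rect":
        parity = checkerboard_value(
            U, V, "rect",
            {"check_w": float(p["check_size_x"]), "check_h": float(p["check_size_y"])},
        )
        pixels = np.where(parity[:, :, None] == 0, color, color2)
    elif stim.type == "checkerboard_radial":
        parity = checkerboard_value(
            U, V, "radial",
            {"n_sectors": int(p["n_sectors"]), "ring_width": float(p["ring_width"])},
        )
        pixels = np.where(parity[:, :, None] == 0, color, color2)
    elif stim.type in ("dots_linear", "dots_radial", "dots_expansive"):
        if rng is None:
            raise ValueError("dot stimuli need an RNG")
        aperture = min(w, h) / 2.0
        params = {
            "speed": float(p["dot_speed"]),
            "direction": float(p["dot_direction"]),
            "coherence": float(p["coherence"]),
            "lifetime": int(p["dot_lifetime"]),
            "aperture_radius": aperture,
        }
        kind = stim.type.split("_", 1)[1]
        store = dot_state if dot_state is not None else {}
        state = store.get(stim.name)
        if state is None:
            state = init_dot_field(
                int(p["n_dots"]), aperture, params["coherence"],
                params["lifetime"], rng,
            )
        else:
            state = update_dot_field(state, kind, params, rng)
        store[stim.name] = state
        pixels = np.zeros((h, w, 3), dtype=float)
        alpha = np.zeros((h, w), dtype=float)
        _draw_dots(pixels, alpha, state, float(p["dot_radius"]), color, w, h)
    elif stim.type == "text":
        raster = _rasterize_text(str(p["text_string"]), float(p["char_size"]))
        th, tw = raster.shape
        pixels = np.zeros((h, w, 3), dtype=float)
        alpha = np.zeros((h, w), dtype=float)
        r0 = max((h - th) // 2, 0)
        c0 = max((w - tw) // 2, 0)
        sub = raster[: h - r0, : w - c0]
        pixels[r0 : r0 + sub.shape[0], c0 : c0 + sub.shape[1]] = (
            sub[:, :, None] * color
        )
        alpha[r0 : r0 + sub.shape[0], c0 : c0 + sub.shape[1]] = sub
    elif stim.type == "image":
        import imageio.v3 as iio
        from PIL import Image

        path = p.get("file_path")
        if path is None:
            raise ValueError(f"image stimulus {stim.name!r} has no file_path")
        arr = iio.imread(path)
        img = Image.fromarray(arr).convert("RGBA").resize((w, h), Image.BILINEAR)
        rgba = np.asarray(img, dtype=float) / 255.0
        pixels = rgba[:, :, :3]
        alpha = rgba[:, :, 3]
    else:  # pragma: no cover - VISUAL_TYPES guard above
        raise ValueError(f"unhandled visual type {stim.type!r}")

    patch = RasterPatch(origin=(0, 0), pixels=pixels, alpha=alpha)
    patch = apply_shape_mask(patch, stim.shape, (w, h))
    noise_amp = float(p["noise_filter"])
    if noise_amp > 0:
        if rng is None:
            raise ValueError("noise filter needs an RNG")
        patch = apply_noise_filter(patch, noise_amp, rng)

    # place the patch: stimulus position is its center, screen-centered, +y up
    cx = display.width_px / 2.0 + float(p["position_x"])
    cy = display.height_px / 2.0 - float(p["position_y"])
    origin = (int(round(cx - w / 2.0)), int(round(cy - h / 2.0)))
    return replace(patch, origin=origin)


def composite_scene_frame(
    scene: Scene,
    patches: list[RasterPatch],
    display: DisplayProfile,
    background: Any = (0.5, 0.5, 0.5),
) -> FrameBuffer:
    """Alpha-over composite patches (in draw order) onto a background-filled
    buffer; patches are clipped at the screen edges."""
    H, W = display.height_px, display.width_px
    bg = np.clip(_as_rgb(background), 0.0, 1.0)
    key = (H, W, tuple(bg))
    template = _BG_CACHE.get(key)
    if template is None:
        template = np.empty((H, W, 3), dtype=np.float32)
        template[:] = bg
        _BG_CACHE.clear()
        _BG_CACHE[key] = template
    buf = template.copy()
    for patch in patches:
        c0, r0 = patch.origin
        ph, pw = patch.alpha.shape
        rb0, rb1 = max(r0, 0), min(r0 + ph, H)
        cb0, cb1 = max(c0, 0), min(c0 + pw, W)
        if rb0 >= rb1 or cb0 >= cb1:
            continue
        pr0, pc0 = rb0 - r0, cb0 - c0
        a = patch.alpha[pr0 : pr0 + (rb1 - rb0), pc0 : pc0 + (cb1 - cb0)][:, :, None]
        src = patch.pixels[pr0 : pr0 + (rb1 - rb0), pc0 : pc0 + (cb1 - cb0)]
        region = a * src + (1.0 - a) * buf[rb0:rb1, cb0:cb1]
        # background is already in range; only composited regions need clipping
        np.clip(region, 0.0, 1.0, out=region)
        buf[rb0:rb1, cb0:cb1] = region
    return FrameBuffer(height=H, width=W, pixels=buf)


def frame_to_png(frame: FrameBuffer, path) -> None:
    """Write a frame buffer as an 8-bit RGB PNG."""
    import imageio.v3 as iio

    arr = np.clip(np.round(frame.pixels * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr, extension=".png")
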