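"""Unit conversions between physical display quantities and pixels/frames.

Psychophysical stimulus sizes are usually stated in degrees of visual angle,
which depend on the viewing distance and the pixel density of the display.
All conversions here are parameterized by a :class:`DisplayProfile` that
describes the output device (resolution, pixel density, refresh rate, maximum
luminance, viewing distance).

The degree conversion uses the exact chord formula

    size_px = 2 * d * tan(theta / 2) * pixels_per_cm

rather than the small-angle approximation, so it remains correct at large
eccentricities while agreeing with the linear approximation to ~1e-4 below 5
degrees.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass, field

__all__ = [
    "DisplayProfile",
    "deg_to_px",
    "px_to_deg",
    "length_to_px",
    "seconds_to_frames",
    "frame_duration_ms",
    "luminance_fraction_to_cd",
    "load_display_profiles",
]

CM_PER_INCH = 2.54

#: Spatial units accepted by :func:`length_to_px`.
LENGTH_UNITS = ("px", "cm", "inch", "deg")


@dataclass(frozen=True)
class DisplayProfile:
    """Physical and temporal description of an output display.

    Parameters
    ----------
    width_px, height_px
        Panel resolution in pixels.
    pixels_per_cm
        Linear pixel density (px/cm).
    refresh_rate
        Display refresh rate in Hz.
    max_luminance
        Nominal maximum luminance of the panel in cd/m^2.
    viewing_distance
        Eye-to-screen distance in cm; degrees of visual angle depend on it.
    model_name
        Free-form device label.
    """

    width_px: int
    height_px: int
    pixels_per_cm: float
    refresh_rate: float
    max_luminance: float
    viewing_distance: float
    model_name: str = ""

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px"):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and not isinstance(v, bool)):
                raise TypeError(f"{name} must be an integer, got {v!r}")
        for name in (
            "width_px",
            "height_px",
            "pixels_per_cm",
            "refresh_rate",
            "max_luminance",
            "viewing_distance",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")

    @property
    def frame_budget_ms(self) -> float:
        """Per-frame compute budget in ms (see :func:`frame_duration_ms`)."""
        return frame_duration_ms(self.refresh_rate)

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "width_px": self.width_px,
            "height_px": self.height_px,
            "pixels_per_cm": self.pixels_per_cm,
            "refresh_rate": self.refresh_rate,
            "max_luminance": self.max_luminance,
            "viewing_distance": self.viewing_distance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DisplayProfile":
        return cls(
            width_px=int(d["width_px"]),
            height_px=int(d["height_px"]),
            pixels_per_cm=float(d["pixels_per_cm"]),
            refresh_rate=float(d["refresh_rate"]),
            max_luminance=float(d["max_luminance"]),
            viewing_distance=float(d["viewing_distance"]),
            model_name=str(d.get("model_name", "")),
        )


def deg_to_px(angle: float, display: DisplayProfile) -> float:
    """Convert a visual angle (degrees) to an on-screen length in pixels.

    Uses the exact chord formula ``2 * d * tan(angle/2) * pixels_per_cm``.
    """
    if not math.isfinite(angle):
        raise ValueError(f"angle must be finite, got {angle!r}")
    if angle < 0:
        raise ValueError(f"angle must be >= 0, got {angle!r}")
    half = math.radians(angle) / 2.0
    return 2.0 * display.viewing_distance * math.tan(half) * display.pixels_per_cm


def px_to_deg(length: float, display: DisplayProfile) -> float:
    """Inverse of :func:`deg_to_px`: pixels to degrees of visual angle."""
    if not math.isfinite(length):
        raise ValueError(f"length must be finite, got {length!r}")
    if length < 0:
        raise ValueError(f"length must be >= 0, got {length!r}")
    half = math.atan(
        length / (2.0 * display.viewing_distance * display.pixels_per_cm)
    )
    return math.degrees(2.0 * half)


def length_to_px(value: float, unit: str, display: DisplayProfile) -> float:
    """Convert a length in ``px``, ``cm``, ``inch`` or ``deg`` to pixels."""
    if unit == "px":
        return float(value)
    if unit == "cm":
        return float(value) * display.pixels_per_cm
    if unit == "inch":
        return float(value) * CM_PER_INCH * display.pixels_per_cm
    if unit == "deg":
        return deg_to_px(float(value), display)
    raise ValueError(
        f"unknown length unit {unit!r}; valid units are {', '.join(LENGTH_UNITS)}"
    )


def seconds_to_frames(t: float, refresh_rate: float) -> int:
    """Number of display frames closest to a duration in seconds.

    Rounds to nearest, ties away from zero, so an exact multiple of the frame
    period maps back to the same frame count.
    """
    if not math.isfinite(t) or t < 0:
        raise ValueError(f"duration must be finite and >= 0, got {t!r}")
    if refresh_rate <= 0:
        raise ValueError(f"refresh_rate must be > 0, got {refresh_rate!r}")
    return int(math.floor(t * refresh_rate + 0.5))


def frame_duration_ms(refresh_rate: float) -> float:
    """Frame period in ms, rounded to 2 decimals (16.67 at 60 Hz, 8.33 at 120 Hz)."""
    if refresh_rate <= 0:
        raise ValueError(f"refresh_rate must be > 0, got {refresh_rate!r}")
    return round(1000.0 / refresh_rate, 2)


def luminance_fraction_to_cd(fraction: float, display: DisplayProfile) -> float:
    """Map a luminance expressed as a fraction of panel maximum to cd/m^2."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"luminance fraction must lie in [0, 1], got {fraction!r}")
    return fraction * display.max_luminance


def load_display_profiles() -> dict[str, DisplayProfile]:
    """Load the editable device table shipped with the package.

    The table holds a few example entries with nominal panel specs; users add
    their own devices by editing ``data/display_profiles.json`` or supplying a
    profile inline in the test file's ``settings`` object.
    """
    text = (
        importlib.resources.files("stimkit.data")
        .joinpath("display_profiles.json")
        .read_text(encoding="utf-8")
    )
    raw = json.loads(text)
    return {name: DisplayProfile.from_dict(d) for name, d in raw.items()}
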