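"""Declarative test description: tests, sections, scenes, stimuli.

A test is a collection of sections; a section is a sequence of scenes
(e.g. fixation -> target -> feedback) executed once per trial; a scene
presents one or more stimuli simultaneously and may collect a response.
Stimulus property values can be constants, per-frame timelines, or variables
bound to numeric lists whose values are selected across trials by a
constant-stimuli or adaptive procedure (see :mod:`stimkit.procedures`).

The on-disk format is a UTF-8 JSON document (extension ``.stimulitest`` or
``.json``) with top-level keys ``schema_version``, ``name``, ``settings``,
``stimuli``, ``sections``, ``lists`` and ``first_section``.  All
cross-references are by name; variable targets use 1-based
``scene<K>_object<J>_<property>`` paths.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np

from .units import DisplayProfile

__all__ = [
    "SCHEMA_VERSION",
    "ParseError",
    "ValidationError",
    "SequencingError",
    "Issue",
    "PropertyValue",
    "Duration",
    "StimulusSpec",
    "ResponseSpec",
    "Scene",
    "VariableBinding",
    "Section",
    "NumericList",
    "TestSettings",
    "Test",
    "RenderContext",
    "parse_test",
    "parse_test_file",
    "serialize_test",
    "validate_test",
    "make_linear_sequence",
    "resolve_property",
    "parse_target",
]

SCHEMA_VERSION = "1"

END = "END"

VISUAL_TYPES = frozenset(
    {
        "patch",
        "gradient",
        "grating",
        "checkerboard_rect",
        "checkerboard_radial",
        "dots_linear",
        "dots_radial",
        "dots_expansive",
        "text",
        "image",
    }
)
AUDITORY_TYPES = frozenset({"tone", "noise", "audio_file"})
STIMULUS_TYPES = VISUAL_TYPES | AUDITORY_TYPES

SHAPES = ("rectangle", "ellipse", "cross")

# Properties shared by every stimulus type.
GENERAL_PROPERTIES = frozenset(
    {
        "duration",
        "start_time",
        "position_x",
        "position_y",
        "orientation",
        "size_x",
        "size_y",
        "noise_filter",
        "color",
        "contrast",
    }
)

# Extra properties allowed per stimulus type; anything else is a validation
# issue (catches typos like a tone_frequency on a grating).
_DOT_PROPERTIES = frozenset(
    {"n_dots", "dot_radius", "dot_speed", "dot_direction", "coherence", "dot_lifetime"}
)
TYPE_PROPERTIES: dict[str, frozenset[str]] = {
    "patch": frozenset(),
    "gradient": frozenset({"color2"}),
    "grating": frozenset(
        {
            "spatial_frequency",
            "phase",
            "envelope_sigma",
            "carrier_contrast_modulation",
            "gratingRotation",
            "mean_luminance",
        }
    ),
    "checkerboard_rect": frozenset({"check_size_x", "check_size_y", "color2"}),
    "checkerboard_radial": frozenset({"n_sectors", "ring_width", "color2"}),
    "dots_linear": _DOT_PROPERTIES,
    "dots_radial": _DOT_PROPERTIES,
    "dots_expansive": _DOT_PROPERTIES,
    "text": frozenset({"text_string", "char_size"}),
    "image": frozenset({"file_path"}),
    "tone": frozenset({"tone_frequency", "amplitude", "ramp"}),
    "noise": frozenset({"amplitude"}),
    "audio_file": frozenset({"file_path", "amplitude"}),
}

# Property name aliases: the orientation of a grating is exposed under the
# conventional name "gratingRotation" in test files.
PROPERTY_ALIASES = {"gratingRotation": "orientation"}

SPATIAL_UNITS = ("px", "cm", "inch", "deg")
TIME_UNITS = ("s", "frames")
SF_UNITS = ("cpd", "cycles_per_px")

SELECTION_METHODS = (
    "fixed",
    "all_values_random_order",
    "random_with_replacement",
    "adaptive",
)

RESPONSE_KINDS = ("left_or_right", "tap_regions", "touch_path", "keyboard")


class ParseError(ValueError):
    """Malformed JSON in a test description."""


class ValidationError(ValueError):
    """A structurally well-formed test that violates the schema invariants."""


class SequencingError(RuntimeError):
    """A variable property was resolved without a trial assignment."""


@dataclass(frozen=True)
class Issue:
    """One validation finding, located by a slash-separated path."""

    path: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path}: {self.message}"


@dataclass
class PropertyValue:
    """A stimulus property: constant, per-frame timeline, or trial variable.

    Exactly one mode is populated.  ``timeline`` is a dict with ``kind``
    ``"linear"`` (``start_value``/``end_value``, interpolated over the scene)
    or ``"sinusoidal"`` (``start_value`` + ``amplitude`` *
    sin(2*pi*``frequency``*t + ``phase``), t in seconds from scene onset).
    """

    mode: str = "constant"
    value: Any = None
    timeline: Optional[dict] = None
    unit: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "timeline", "variable"):
            raise ValidationError(f"unknown property mode {self.mode!r}")
        if self.mode == "timeline" and not isinstance(self.timeline, dict):
            raise ValidationError("timeline mode requires a timeline definition")

    def to_json(self) -> Any:
        if self.mode == "constant" and self.unit is None:
            return self.value
        d: dict[str, Any] = {"mode": self.mode}
        if self.mode == "constant":
            d["value"] = self.value
        elif self.mode == "timeline":
            d.update(self.timeline or {})
        if self.unit is not None:
            d["unit"] = self.unit
        return d

    @classmethod
    def from_json(cls, raw: Any) -> "PropertyValue":
        if not isinstance(raw, dict):
            return cls(mode="constant", value=raw)
        mode = raw.get("mode", "constant")
        unit = raw.get("unit")
        if mode == "constant":
            return cls(mode="constant", value=raw.get("value"), unit=unit)
        if mode == "variable":
            return cls(mode="variable", unit=unit)
        if mode == "timeline":
            timeline = {k: v for k, v in raw.items() if k not in ("mode", "unit")}
            return cls(mode="timeline", timeline=timeline, unit=unit)
        raise ValidationError(f"unknown property mode {mode!r}")


@dataclass
class Duration:
    """A duration tagged with its unit (seconds or frames)."""

    value: float
    unit: str = "s"

    def to_json(self) -> dict:
        return {"value": self.value, "unit": self.unit}

    @classmethod
    def from_json(cls, raw: Any) -> "Duration":
        if isinstance(raw, dict):
            return cls(value=float(raw["value"]), unit=str(raw.get("unit", "s")))
        return cls(value=float(raw), unit="s")


@dataclass
class StimulusSpec:
    name: str
    type: str
    shape: str = "rectangle"
    properties: dict[str, PropertyValue] = field(default_factory=dict)

    def allowed_properties(self) -> frozenset[str]:
        return GENERAL_PROPERTIES | TYPE_PROPERTIES.get(self.type, frozenset())

    def to_json(self) -> dict:
        return {
            "name": self.name,
            "type": self.type,
            "shape": self.shape,
            "properties": {k: v.to_json() for k, v in self.properties.items()},
        }

    @classmethod
    def from_json(cls, raw: dict) -> "StimulusSpec":
        props = {
            str(k): PropertyValue.from_json(v)
            for k, v in raw.get("properties", {}).items()
        }
        return cls(
            name=str(raw["name"]),
            type=str(raw.get("type", "patch")),
            shape=str(raw.get("shape", "rectangle")),
            properties=props,
        )


@dataclass
class ResponseSpec:
    """How a scene collects a response.

    ``left_or_right`` splits the screen into two half-screen regions with a
    value mapped to each side (default left -> -1, right -> +1).
    ``tap_regions`` lists explicit rectangular regions; ``keyboard`` maps key
    strings to values; ``touch_path`` records a path (headless runs supply it
    scripted).
    """

    kind: str
    values: dict[str, Any] = field(default_factory=lambda: {"left": -1, "right": 1})
    regions: list[dict] = field(default_factory=list)
    timeout: Optional[float] = None

    def to_json(self) -> dict:
        d: dict[str, Any] = {"kind": self.kind, "values": self.values}
        if self.regions:
            d["regions"] = self.regions
        if self.timeout is not None:
            d["timeout"] = self.timeout
        return d

    @classmethod
    def from_json(cls, raw: dict) -> "ResponseSpec":
        return cls(
            kind=str(raw["kind"]),
            values=dict(raw.get("values", {"left": -1, "right": 1})),
            regions=list(raw.get("regions", [])),
            timeout=raw.get("timeout"),
        )


@dataclass
class Scene:
    name: str
    duration: Duration
    objects: list[str] = field(default_factory=list)  # stimulus names, draw order
    response: Optional[ResponseSpec] = None

    def to_json(self) -> dict:
        d: dict[str, Any] = {
            "name": self.name,
            "duration": self.duration.to_json(),
            "objects": list(self.objects),
        }
        if self.response is not None:
            d["response"] = self.response.to_json()
        return d

    @classmethod
    def from_json(cls, raw: dict) -> "Scene":
        resp = raw.get("response")
        return cls(
            name=str(raw["name"]),
            duration=Duration.from_json(raw.get("duration", 1.0)),
            objects=[str(o) for o in raw.get("objects", [])],
            response=ResponseSpec.from_json(resp) if resp else None,
        )


@dataclass
class VariableBinding:
    """Binds a ``scene<K>_object<J>_<property>`` path to a numeric list."""

    target: str
    list: str
    selection_method: str = "all_values_random_order"
    adaptive_config: Optional[dict] = None

    def to_json(self) -> dict:
        d: dict[str, Any] = {
            "target": self.target,
            "list": self.list,
            "selection_method": self.selection_method,
        }
        if self.adaptive_config is not None:
            d["adaptive_config"] = self.adaptive_config
        return d

    @classmethod
    def from_json(cls, raw: dict) -> "VariableBinding":
        return cls(
            target=str(raw["target"]),
            list=str(raw["list"]),
            selection_method=str(
                raw.get("selection_method", "all_values_random_order")
            ),
            adaptive_config=raw.get("adaptive_config"),
        )


@dataclass
class Section:
    name: str
    scenes: list[Scene]
    repetitions: int = 1
    variables: list[VariableBinding] = field(default_factory=list)
    next_section: str = END

    def to_json(self) -> dict:
        return {
            "name": self.name,
            "scenes": [s.to_json() for s in self.scenes],
            "repetitions": self.repetitions,
            "variables": [v.to_json() for v in self.variables],
            "next_section": self.next_section,
        }

    @classmethod
    def from_json(cls, raw: dict) -> "Section":
        return cls(
            name=str(raw["name"]),
            scenes=[Scene.from_json(s) for s in raw.get("scenes", [])],
            repetitions=int(raw.get("repetitions", 1)),
            variables=[VariableBinding.from_json(v) for v in raw.get("variables", [])],
            next_section=str(raw.get("next_section", "")),
        )


@dataclass
class NumericList:
    name: str
    values: list[float]

    def to_json(self) -> dict:
        return {"name": self.name, "values": list(self.values)}

    @classmethod
    def from_json(cls, raw: dict) -> "NumericList":
        return cls(name=str(raw["name"]), values=[float(v) for v in raw["values"]])


@dataclass
class TestSettings:
    display: DisplayProfile
    audio_rate: int = 44100
    av_offset_ms: float = 0.0
    rng_seed: int = 0

    def to_json(self) -> dict:
        return {
            "display": self.display.to_dict(),
            "audio_rate": self.audio_rate,
            "av_offset_ms": self.av_offset_ms,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_json(cls, raw: dict) -> "TestSettings":
        if "display" not in raw:
            raise ValidationError("settings: missing display profile")
        return cls(
            display=DisplayProfile.from_dict(raw["display"]),
            audio_rate=int(raw.get("audio_rate", 44100)),
            av_offset_ms=float(raw.get("av_offset_ms", 0.0)),
            rng_seed=int(raw.get("rng_seed", 0)),
        )


@dataclass
class Test:
    name: str
    settings: TestSettings
    stimuli: list[StimulusSpec]
    sections: list[Section]
    lists: list[NumericList] = field(default_factory=list)
    first_section: str = ""

    def stimulus(self, name: str) -> StimulusSpec:
        for s in self.stimuli:
            if s.name == name:
                return s
        raise KeyError(f"no stimulus named {name!r}")

    def section(self, name: str) -> Section:
        for s in self.sections:
            if s.name == name:
                return s
        raise KeyError(f"no section named {name!r}")

    def numeric_list(self, name: str) -> NumericList:
        for l in self.lists:
            if l.name == name:
                return l
        raise KeyError(f"no list named {name!r}")

    def to_json(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "name": self.name,
            "settings": self.settings.to_json(),
            "stimuli": [s.to_json() for s in self.stimuli],
            "sections": [s.to_json() for s in self.sections],
            "lists": [l.to_json() for l in self.lists],
            "first_section": self.first_section,
        }


# ---------------------------------------------------------------------------
# Parsing / serialization
# ---------------------------------------------------------------------------

def parse_test(json_text: str) -> Test:
    """Parse and fully validate a JSON test description.

    Raises :class:`ParseError` (with position) on malformed JSON and
    :class:`ValidationError` on schema violations or dangling references.
    """
    try:
        raw = json.loads(json_text)
    except json.JSONDecodeError as e:
        raise ParseError(
            f"malformed JSON at line {e.lineno}, column {e.colno}: {e.msg}"
        ) from e
    test = _test_from_dict(raw)
    issues = validate_test(test)
    if issues:
        details = "; ".join(str(i) for i in issues[:10])
        raise ValidationError(
            f"test description has {len(issues)} issue(s): {details}"
        )
    return test


def parse_test_file(path: str | Path) -> Test:
    """Parse a ``.stimulitest`` / ``.json`` file from disk."""
    return parse_test(Path(path).read_text(encoding="utf-8"))


def _test_from_dict(raw: Any) -> Test:
    if not isinstance(raw, dict):
        raise ValidationError("test description must be a JSON object")
    if "sections" not in raw or not raw.get("sections"):
        raise ValidationError("missing sections: a test needs at least one section")
    if "settings" not in raw:
        raise ValidationError("missing settings (display profile required)")
    sections = [Section.from_json(s) for s in raw["sections"]]
    # next_section defaults to the following section in file order, END last.
    for i, sec in enumerate(sections):
        if not sec.next_section:
            sec.next_section = sections[i + 1].name if i + 1 < len(sections) else END
    first = str(raw.get("first_section", "")) or (
        sections[0].name if sections else ""
    )
    return Test(
        name=str(raw.get("name", "test")),
        settings=TestSettings.from_json(raw["settings"]),
        stimuli=[StimulusSpec.from_json(s) for s in raw.get("stimuli", [])],
        sections=sections,
        lists=[NumericList.from_json(l) for l in raw.get("lists", [])],
        first_section=first,
    )


def serialize_test(test: Test) -> str:
    """Serialize a test to versioned JSON with deterministic key order."""
    return json.dumps(test.to_json(), sort_keys=True, indent=2) + "\n"


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def parse_target(target: str) -> tuple[int, int, str]:
    """Split ``scene<K>_object<J>_<property>`` into 1-based (K, J, property)."""
    import re

    m = re.fullmatch(r"scene(\d+)_object(\d+)_(\w+)", target)
    if not m:
        raise ValidationError(
            f"variable target {target!r} does not match scene<K>_object<J>_<property>"
        )
    return int(m.group(1)), int(m.group(2)), m.group(3)


def _check_unit(pv: PropertyValue, prop: str, path: str, issues: list[Issue]) -> None:
    if pv.unit is None:
        return
    spatial = {"position_x", "position_y", "size_x", "size_y", "envelope_sigma",
               "check_size_x", "check_size_y", "ring_width", "dot_radius",
               "char_size"}
    if prop in ("duration", "start_time", "dot_lifetime"):
        valid = TIME_UNITS
    elif prop == "spatial_frequency":
        valid = SF_UNITS
    elif prop in spatial:
        valid = SPATIAL_UNITS
    else:
        valid = SPATIAL_UNITS + TIME_UNITS + SF_UNITS
    if pv.unit not in valid:
        issues.append(
            Issue(path, f"unit {pv.unit!r} not resolvable for property {prop!r}; "
                        f"valid: {', '.join(valid)}")
        )


def validate_test(test: Test) -> list[Issue]:
    """Check every schema invariant; an empty list means the test can run.

    Issues are data (path + message), never exceptions, so callers can report
    all problems at once.
    """
    issues: list[Issue] = []

    def dup_check(names: list[str], what: str) -> None:
        seen: set[str] = set()
        for n in names:
            if n in seen:
                issues.append(Issue(what, f"duplicate {what} name {n!r}"))
            seen.add(n)

    dup_check([s.name for s in test.stimuli], "stimulus")
    dup_check([s.name for s in test.sections], "section")
    dup_check([l.name for l in test.lists], "list")

    section_names = {s.name for s in test.sections}
    stimulus_names = {s.name for s in test.stimuli}
    list_names = {l.name for l in test.lists}

    if test.first_section not in section_names:
        issues.append(
            Issue("first_section",
                  f"first_section {test.first_section!r} names no existing section")
        )

    for st in test.stimuli:
        spath = f"stimuli/{st.name}"
        if st.type not in STIMULUS_TYPES:
            issues.append(Issue(spath, f"unknown stimulus type {st.type!r}"))
            continue
        if st.shape not in SHAPES:
            issues.append(Issue(spath, f"unknown shape {st.shape!r}"))
        allowed = st.allowed_properties()
        for prop, pv in st.properties.items():
            ppath = f"{spath}/{prop}"
            if prop not in allowed:
                issues.append(
                    Issue(ppath,
                          f"property {prop!r} not valid for type {st.type!r}")
                )
            _check_unit(pv, prop, ppath, issues)
            if pv.mode == "timeline":
                kind = (pv.timeline or {}).get("kind")
                if kind not in ("linear", "sinusoidal"):
                    issues.append(Issue(ppath, f"unknown timeline kind {kind!r}"))

    for sec in test.sections:
        base = f"sections/{sec.name}"
        if sec.repetitions < 1:
            issues.append(Issue(f"{base}/repetitions",
                                f"repetitions must be >= 1, got {sec.repetitions}"))
        if not sec.scenes:
            issues.append(Issue(base, "section has no scenes"))
        if sec.next_section != END and sec.next_section not in section_names:
            issues.append(Issue(f"{base}/next_section",
                                f"next_section {sec.next_section!r} does not exist"))
        for sc in sec.scenes:
            scpath = f"{base}/{sc.name}"
            if sc.duration.value <= 0:
                issues.append(Issue(f"{scpath}/duration",
                                    f"duration must be > 0, got {sc.duration.value}"))
            if sc.duration.unit not in TIME_UNITS:
                issues.append(Issue(f"{scpath}/duration",
                                    f"unknown time unit {sc.duration.unit!r}"))
            for obj in sc.objects:
                if obj not in stimulus_names:
                    issues.append(Issue(f"{scpath}/objects",
                                        f"object reference {obj!r} resolves to no stimulus"))
            if sc.response is not None and sc.response.kind not in RESPONSE_KINDS:
                issues.append(Issue(f"{scpath}/response",
                                    f"unknown response kind {sc.response.kind!r}"))
            if sc.response is not None and sc.response.kind == "left_or_right":
                if set(sc.response.values) != {"left", "right"}:
                    issues.append(Issue(
                        f"{scpath}/response",
                        "left_or_right response must map exactly the two keys "
                        "'left' and 'right'"))
        for vb in sec.variables:
            vpath = f"{base}/variables/{vb.target}"
            if vb.selection_method not in SELECTION_METHODS:
                issues.append(Issue(vpath,
                                    f"unknown selection_method {vb.selection_method!r}"))
            if vb.selection_method == "adaptive" and vb.adaptive_config is None:
                issues.append(Issue(vpath, "adaptive selection requires adaptive_config"))
            if vb.list not in list_names:
                if not (vb.selection_method == "adaptive"):
                    issues.append(Issue(vpath, f"list {vb.list!r} does not exist"))
            try:
                k, j, prop = parse_target(vb.target)
            except ValidationError as e:
                issues.append(Issue(vpath, str(e)))
                continue
            if k > len(sec.scenes):
                issues.append(Issue(vpath, f"scene index {k} out of range"))
                continue
            scene = sec.scenes[k - 1]
            if j > len(scene.objects):
                issues.append(Issue(vpath, f"object index {j} out of range"))
                continue
            stim_name = scene.objects[j - 1]
            if stim_name not in stimulus_names:
                continue  # already reported as dangling object reference
            stim = test.stimulus(stim_name)
            if prop not in stim.properties:
                issues.append(Issue(vpath,
                                    f"property {prop!r} does not exist on "
                                    f"stimulus {stim_name!r}"))
            elif stim.properties[prop].mode != "variable":
                issues.append(Issue(vpath,
                                    f"property {prop!r} on {stim_name!r} is not "
                                    "declared variable"))

    for nl in test.lists:
        if not nl.values:
            issues.append(Issue(f"lists/{nl.name}", "numeric list is empty"))

    return issues


# ---------------------------------------------------------------------------
# Lists and property resolution
# ---------------------------------------------------------------------------

def make_linear_sequence(first: float, last: float, n: int,
                         name: str = "sequence") -> NumericList:
    """Evenly spaced inclusive sequence of ``n`` values from first to last."""
    if n < 1:
        raise ValueError(f"number of values must be >= 1, got {n}")
    if n == 1:
        return NumericList(name=name, values=[float(first)])
    return NumericList(name=name, values=[float(v) for v in
                                          np.linspace(first, last, n)])


@dataclass(frozen=True)
class RenderContext:
    """Per-frame evaluation context for dynamic properties."""

    frame_index: int
    total_frames: int
    refresh_rate: float


def resolve_property(stim: StimulusSpec, prop: str,
                     bindings: Optional[dict[str, Any]] = None,
                     ctx: Optional[RenderContext] = None) -> Any:
    """Evaluate a property at one frame of one trial.

    ``bindings`` maps this stimulus instance's variable property names to the
    current trial's values. Timelines need ``ctx`` (frame index, scene length,
    refresh rate).
    """
    if prop not in stim.properties:
        raise KeyError(f"stimulus {stim.name!r} has no property {prop!r}")
    pv = stim.properties[prop]
    if pv.mode == "constant":
        return pv.value
    if pv.mode == "variable":
        if bindings is None or prop not in bindings:
            raise SequencingError(
                f"variable property {prop!r} on {stim.name!r} has no trial assignment"
            )
        return bindings[prop]
    # timeline
    if ctx is None:
        raise ValueError(f"timeline property {prop!r} needs a render context")
    tl = pv.timeline or {}
    kind = tl.get("kind", "linear")
    if kind == "linear":
        start = float(tl["start_value"])
        end = float(tl["end_value"])
        if ctx.total_frames <= 1:
            return start
        frac = ctx.frame_index / (ctx.total_frames - 1)
        return start + (end - start) * frac
    if kind == "sinusoidal":
        start = float(tl.get("start_value", 0.0))
        amp = float(tl["amplitude"])
        freq = float(tl["frequency"])
        phase = float(tl.get("phase", 0.0))
        t = ctx.frame_index / ctx.refresh_rate
        return start + amp * math.sin(2.0 * math.pi * freq * t + phase)
    raise ValidationError(f"unknown timeline kind {kind!r}")
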