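"""End-to-end test execution with simulated responders.

The runner expands each section into trials, resolves bound variables per
trial, synthesizes every scene frame (pure offline rendering: per-frame
compute time is measured for the timing report but the runner never sleeps),
collects simulated touch/keyboard responses, and emits the results bundle:
a settings report (txt), a trial-wise table (csv) and a timing report.

A frame is counted as dropped iff its compute time strictly exceeds the
frame budget 1000/refresh_rate ms — the offline counterpart of a display
holding the previous image when synthesis overruns the refresh interval.

Frames for scenes whose content is provably frame-invariant (no timelines,
no dots, no noise) are rendered once and reused, which keeps desk-scale
runs fast without changing any rendered pixel.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Optional, Protocol

import numpy as np
import pandas as pd

from . import __version__
from .audio import AudioBuffer, AudioEvent, mix_scene_audio, synth_auditory_noise, synth_tone
from .model import (
    AUDITORY_TYPES,
    RenderContext,
    Scene,
    Section,
    Test,
    VISUAL_TYPES,
    parse_target,
    validate_test,
)
from .procedures import (
    PsychometricObserver,
    StaircaseConfig,
    StaircaseState,
    TrialPlan,
    expand_section_trials,
    staircase_next,
)
from .units import frame_duration_ms, seconds_to_frames
from .visual import (
    DotFieldState,
    FrameBuffer,
    composite_scene_frame,
    render_stimulus_frame,
    resolve_stimulus_properties,
)

__all__ = [
    "TouchEvent",
    "KeyEvent",
    "SceneOutcome",
    "ResultsBundle",
    "TimingReport",
    "Responder",
    "ObserverResponder",
    "ScriptedResponder",
    "run_test",
    "run_scene",
    "preview_frame",
    "iter_scene_frames",
    "scene_audio",
    "timing_report",
    "write_results",
    "write_timing",
]

DEFAULT_BACKGROUND = (0.5, 0.5, 0.5)
_ADAPTIVE_TRIAL_CAP = 1000  # safety net if a staircase never finishes


@dataclass(frozen=True)
class TouchEvent:
    """A simulated tap at screen coordinates (px, origin top-left)."""

    x: float
    y: float


@dataclass(frozen=True)
class KeyEvent:
    key: str


@dataclass
class SceneOutcome:
    response_value: Any = None
    response_time: Optional[float] = None
    frames_rendered: int = 0


@dataclass
class ResultsBundle:
    """Settings report plus the trial-wise results table (one row per trial)."""

    settings_report: dict[str, Any]
    trials_table: pd.DataFrame


@dataclass
class TimingReport:
    """Per-frame compute times against the frame budget.

    ``dropped_frames`` lists (frame index, duration ms) for every frame whose
    compute time strictly exceeded the budget.
    """

    refresh_rate: float
    frame_budget_ms: float
    frame_times_ms: list[float]
    dropped_frames: list[tuple[int, float]]

    @property
    def percent_dropped(self) -> float:
        if not self.frame_times_ms:
            return 0.0
        return 100.0 * len(self.dropped_frames) / len(self.frame_times_ms)


def timing_report(frame_times: list[float], refresh_rate: float) -> TimingReport:
    """Classify measured frame times against the budget 1000/refresh ms."""
    budget = frame_duration_ms(refresh_rate)
    dropped = [(i, t) for i, t in enumerate(frame_times) if t > budget]
    return TimingReport(
        refresh_rate=refresh_rate,
        frame_budget_ms=budget,
        frame_times_ms=list(frame_times),
        dropped_frames=dropped,
    )


# ---------------------------------------------------------------------------
# Responders
# ---------------------------------------------------------------------------

class Responder(Protocol):
    """Stands in for the touchscreen in headless runs."""

    def begin_trial(self, trial: TrialPlan, rng: np.random.Generator) -> None: ...

    def respond(
        self,
        scene: Scene,
        frame_index: int,
        total_frames: int,
        display,
        rng: np.random.Generator,
    ) -> Optional[TouchEvent | KeyEvent]: ...


class ObserverResponder:
    """Simulated participant: answers left/right from a psychometric observer.

    The observer reads the trial's value of one bound variable (``target``;
    default: the trial's only assignment), treats positive values as
    "right is correct" and negative as "left is correct", and taps the
    correct side with probability guess + (1-guess-lapse)*F(|value|).
    The tap is issued ``latency_frames`` after scene onset (or on the last
    frame of shorter scenes).
    """

    def __init__(
        self,
        observer: PsychometricObserver,
        target: Optional[str] = None,
        latency_frames: int = 12,
    ) -> None:
        self.observer = observer
        self.target = target
        self.latency_frames = latency_frames
        self._trial: Optional[TrialPlan] = None

    def begin_trial(self, trial: TrialPlan, rng: np.random.Generator) -> None:
        self._trial = trial

    def _trial_value(self) -> float:
        if self._trial is None or not self._trial.assignments:
            return 0.0
        if self.target is not None:
            return float(self._trial.assignments[self.target])
        return float(next(iter(self._trial.assignments.values())))

    def respond(self, scene, frame_index, total_frames, display, rng):
        if scene.response is None:
            return None
        if frame_index < min(self.latency_frames, total_frames - 1):
            return None
        value = self._trial_value()
        correct_right = value >= 0  # positive rotation -> clockwise -> right
        correct = self.observer.simulate_correct(value, rng)
        go_right = correct_right if correct else not correct_right
        x = display.width_px * (0.75 if go_right else 0.25)
        return TouchEvent(x=x, y=display.height_px / 2.0)


class ScriptedResponder:
    """Exact replay: one pre-decided side/key per response scene, in order."""

    def __init__(self, responses: list[Any], frame: int = 0) -> None:
        self.responses = list(responses)
        self.frame = frame
        self._i = 0

    def begin_trial(self, trial, rng) -> None:
        pass

    def respond(self, scene, frame_index, total_frames, display, rng):
        if scene.response is None or self._i >= len(self.responses):
            return None
        if frame_index < min(self.frame, total_frames - 1):
            return None
        r = self.responses[self._i]
        self._i += 1
        if isinstance(r, (TouchEvent, KeyEvent)):
            return r
        if r in ("left", "right"):
            x = display.width_px * (0.25 if r == "left" else 0.75)
            return TouchEvent(x=x, y=display.height_px / 2.0)
        return KeyEvent(key=str(r))


# ---------------------------------------------------------------------------
# Scene execution
# ---------------------------------------------------------------------------

def _scene_frame_count(scene: Scene, refresh_rate: float) -> int:
    if scene.duration.unit == "frames":
        return max(1, int(round(scene.duration.value)))
    return max(1, seconds_to_frames(scene.duration.value, refresh_rate))


def _scene_bindings(
    section: Section, scene_index: int, assignments: dict[str, float]
) -> dict[int, dict[str, float]]:
    """Per-object property bindings for one scene, from trial assignments."""
    out: dict[int, dict[str, float]] = {}
    for target, value in assignments.items():
        k, j, prop = parse_target(target)
        if k == scene_index + 1:
            out.setdefault(j - 1, {})[prop] = value
    return out


def _scene_is_static(test: Test, scene: Scene) -> bool:
    """True iff every frame of the scene is provably identical."""
    for name in scene.objects:
        stim = test.stimulus(name)
        if stim.type.startswith("dots_"):
            return False
        for prop, pv in stim.properties.items():
            if pv.mode == "timeline":
                return False
            if prop == "noise_filter" and pv.mode != "constant":
                return False
            if prop == "noise_filter" and pv.value:
                return False
    return True


def _scene_rng(seed: int, trial_index: int, scene_name: str) -> np.random.Generator:
    return np.random.default_rng(
        [seed & 0x7FFFFFFF, trial_index, zlib.crc32(scene_name.encode())]
    )


def iter_scene_frames(
    test: Test,
    section: Section,
    scene_index: int,
    assignments: dict[str, float],
    rng: np.random.Generator,
    frame_cache: Optional[dict] = None,
) -> Iterator[FrameBuffer]:
    """Yield the frame buffers of one scene in order.

    Static scenes (no timelines, dots or noise) are rendered once and the
    same buffer object is yielded for every frame; dynamic scenes re-render
    per frame, advancing dot-field state and noise RNG identically whether
    frames are consumed by a run, a preview or an export.  A ``frame_cache``
    dict additionally reuses static-scene buffers across trials with the
    same bound values.
    """
    scene = section.scenes[scene_index]
    display = test.settings.display
    total = _scene_frame_count(scene, display.refresh_rate)
    bindings = _scene_bindings(section, scene_index, assignments)
    static = _scene_is_static(test, scene)
    dot_state: dict[str, DotFieldState] = {}
    cached: Optional[FrameBuffer] = None
    cache_key = None
    if static and frame_cache is not None:
        cache_key = (section.name, scene.name,
                     tuple(sorted((k, v) for b in bindings.values()
                                  for k, v in b.items())))
        cached = frame_cache.get(cache_key)
    for frame in range(total):
        if cached is not None and static:
            yield cached
            continue
        ctx = RenderContext(frame_index=frame, total_frames=total,
                            refresh_rate=display.refresh_rate)
        patches = []
        for j, name in enumerate(scene.objects):
            stim = test.stimulus(name)
            if stim.type not in VISUAL_TYPES:
                continue
            props = resolve_stimulus_properties(
                stim, display, bindings.get(j, {}), ctx
            )
            patches.append(
                render_stimulus_frame(stim, props, ctx, display, rng=rng,
                                      dot_state=dot_state)
            )
        buf = composite_scene_frame(scene, patches, display,
                                    background=DEFAULT_BACKGROUND)
        if static:
            cached = buf
            if cache_key is not None and frame_cache is not None:
                frame_cache[cache_key] = buf
        yield buf


def scene_audio(
    test: Test,
    section: Section,
    scene_index: int,
    assignments: dict[str, float],
    rng: Optional[np.random.Generator] = None,
) -> Optional[AudioBuffer]:
    """Mix the auditory track of one scene (None when the scene is silent).

    Tone/noise stimuli are synthesized at the test's audio rate, placed at
    their ``start_time`` and shifted by the device AV-offset correction.
    """
    scene = section.scenes[scene_index]
    display = test.settings.display
    rate = test.settings.audio_rate
    total = _scene_frame_count(scene, display.refresh_rate)
    scene_dur = total / display.refresh_rate
    ctx = RenderContext(frame_index=0, total_frames=total,
                        refresh_rate=display.refresh_rate)
    bindings = _scene_bindings(section, scene_index, assignments)
    events: list[AudioEvent] = []
    for j, name in enumerate(scene.objects):
        stim = test.stimulus(name)
        if stim.type not in AUDITORY_TYPES:
            continue
        props = resolve_stimulus_properties(stim, display, bindings.get(j, {}), ctx)
        onset_frames = float(props.get("start_time") or 0.0)
        onset = onset_frames / display.refresh_rate
        dur_frames = props.get("duration")
        duration = (
            scene_dur - onset if dur_frames is None
            else float(dur_frames) / display.refresh_rate
        )
        if duration <= 0:
            continue
        amp = float(props.get("amplitude", 0.5))
        if stim.type == "tone":
            buf = synth_tone(float(props["tone_frequency"]), duration, amp,
                             ramp=float(props.get("ramp", 0.005)),
                             sample_rate=rate)
        elif stim.type == "noise":
            if rng is None:
                rng = np.random.default_rng()
            buf = synth_auditory_noise(duration, amp, sample_rate=rate, rng=rng)
        else:  # audio_file
            from .audio import read_wav

            buf = read_wav(props["file_path"])
        events.append(AudioEvent(buffer=buf, onset=onset))
    if not events:
        return None
    return mix_scene_audio(events, scene_dur, rate,
                           av_offset_ms=test.settings.av_offset_ms)


def _map_response(scene: Scene, event: TouchEvent | KeyEvent, display) -> Any:
    spec = scene.response
    assert spec is not None
    if spec.kind == "left_or_right" and isinstance(event, TouchEvent):
        side = "left" if event.x < display.width_px / 2.0 else "right"
        return spec.values[side]
    if spec.kind == "tap_regions" and isinstance(event, TouchEvent):
        for region in spec.regions:
            if (region["x"] <= event.x < region["x"] + region["w"]
                    and region["y"] <= event.y < region["y"] + region["h"]):
                return region.get("value", region.get("name"))
        return None
    if spec.kind == "keyboard" and isinstance(event, KeyEvent):
        return spec.values.get(event.key)
    if spec.kind == "touch_path" and isinstance(event, TouchEvent):
        return (event.x, event.y)
    return None


def run_scene(
    test: Test,
    section: Section,
    scene_index: int,
    trial: TrialPlan,
    responder: Responder,
    rng: np.random.Generator,
    responder_rng: np.random.Generator,
    frame_times_ms: Optional[list[float]] = None,
    capture: Optional[list[FrameBuffer]] = None,
    frame_cache: Optional[dict] = None,
) -> SceneOutcome:
    """Run one scene of one trial: render frames, poll the responder.

    The responder is polled once per frame; the first mapped response wins
    and ends the scene after its frame.  ``response_time`` has one-frame
    resolution (frame_index / refresh_rate).
    """
    scene = section.scenes[scene_index]
    display = test.settings.display
    total = _scene_frame_count(scene, display.refresh_rate)
    timeout = scene.response.timeout if scene.response else None
    outcome = SceneOutcome()
    frames = iter_scene_frames(test, section, scene_index, trial.assignments, rng,
                               frame_cache=frame_cache)
    for frame_index, (buf, dt_ms) in enumerate(_timed_pull(frames)):
        if frame_times_ms is not None:
            frame_times_ms.append(dt_ms)
        if capture is not None:
            capture.append(buf)
        outcome.frames_rendered = frame_index + 1
        if scene.response is not None and outcome.response_value is None:
            t = frame_index / display.refresh_rate
            if timeout is None or t <= timeout:
                event = responder.respond(scene, frame_index, total, display,
                                          responder_rng)
                if event is not None:
                    mapped = _map_response(scene, event, display)
                    if mapped is not None:
                        outcome.response_value = mapped
                        outcome.response_time = t
                        break
    return outcome


def _timed_pull(frames: Iterator[FrameBuffer]) -> Iterator[tuple[FrameBuffer, float]]:
    while True:
        t0 = time.perf_counter()
        try:
            buf = next(frames)
        except StopIteration:
            return
        yield buf, (time.perf_counter() - t0) * 1000.0


# ---------------------------------------------------------------------------
# Full test execution
# ---------------------------------------------------------------------------

def _trial_correct(assignments: dict[str, float], response: Any) -> Any:
    """Correctness under the sign convention: positive value <-> response +1."""
    if response is None or not assignments:
        return None
    if response not in (-1, 1):
        return None
    value = next(iter(assignments.values()))
    expected = 1 if value >= 0 else -1
    return int(response == expected)


def run_test(
    test: Test,
    responder: Responder,
    seed: int = 0,
) -> tuple[ResultsBundle, TimingReport]:
    """Execute a test end-to-end, deterministically for a given seed.

    Starts at ``first_section`` and follows ``next_section`` links until END.
    Constant-stimuli sections are expanded up front; adaptive sections are
    sequenced trial-by-trial from their staircase.  Returns the results
    bundle (settings + one table row per executed trial) and the timing
    report over all rendered frames.
    """
    issues = validate_test(test)
    if issues:
        raise ValueError(
            "refusing to run an invalid test: "
            + "; ".join(str(i) for i in issues[:5])
        )
    display = test.settings.display
    base_seed = (int(seed) ^ test.settings.rng_seed) & 0x7FFFFFFF
    responder_rng = np.random.default_rng([base_seed, 7])
    rows: list[dict[str, Any]] = []
    frame_times: list[float] = []
    lists = {l.name: l for l in test.lists}
    frame_cache: dict = {}
    global_trial = 0

    current = test.first_section
    visited: set[str] = set()
    while current != "END":
        if current in visited:
            raise RuntimeError(f"section cycle detected at {current!r}")
        visited.add(current)
        section = test.section(current)
        adaptive = [v for v in section.variables
                    if v.selection_method == "adaptive"]
        plan_rng = np.random.default_rng(
            [base_seed, 13, zlib.crc32(section.name.encode())]
        )

        def execute(trial: TrialPlan) -> None:
            nonlocal global_trial
            responder.begin_trial(trial, responder_rng)
            response: Any = None
            rt: Optional[float] = None
            for k in range(len(section.scenes)):
                rng = _scene_rng(base_seed, trial.trial_index, section.scenes[k].name)
                outcome = run_scene(test, section, k, trial, responder, rng,
                                    responder_rng, frame_times_ms=frame_times,
                                    frame_cache=frame_cache)
                if outcome.response_value is not None:
                    response = outcome.response_value
                    rt = outcome.response_time
            row: dict[str, Any] = {
                "trial": global_trial,
                "section": section.name,
            }
            row.update(trial.assignments)
            row["response"] = response
            row["response_time_s"] = rt
            row["correct"] = _trial_correct(trial.assignments, response)
            rows.append(row)
            global_trial += 1

        if not adaptive:
            for trial in expand_section_trials(section, lists, plan_rng):
                execute(trial)
        else:
            if len(adaptive) > 1:
                raise ValueError(
                    "at most one adaptive binding per section is supported"
                )
            vb = adaptive[0]
            config = StaircaseConfig.from_dict(vb.adaptive_config or {})
            state = StaircaseState.start(config)
            t = 0
            while not state.finished and t < _ADAPTIVE_TRIAL_CAP:
                trial = TrialPlan(
                    trial_index=t,
                    assignments={vb.target: state.current_value},
                    section=section.name,
                )
                execute(trial)
                response = rows[-1]["response"]
                correct = bool(rows[-1]["correct"]) if response is not None else False
                state = staircase_next(state, config, correct)
                t += 1

        current = section.next_section

    table = pd.DataFrame(rows)
    settings = {
        "app_version": __version__,
        "test_name": test.name,
        "device_model": display.model_name,
        "screen_resolution": f"{display.width_px}x{display.height_px}",
        "frame_rate_hz": display.refresh_rate,
        "audio_rate_hz": test.settings.audio_rate,
        "av_offset_ms": test.settings.av_offset_ms,
        "viewing_distance_cm": display.viewing_distance,
        "seed": int(seed),
        "n_trials": len(rows),
    }
    return (
        ResultsBundle(settings_report=settings, trials_table=table),
        timing_report(frame_times, display.refresh_rate),
    )


def preview_frame(
    test: Test,
    scene_name: str,
    frame_index: int,
    bindings: Optional[dict[str, float]] = None,
    seed: int = 0,
    trial_index: int = 0,
) -> FrameBuffer:
    """Render exactly the buffer a run would produce for one scene frame.

    Dynamic scenes are replayed from frame 0 so that dot-field and noise
    state at ``frame_index`` matches a full run with the same seed.
    """
    for section in test.sections:
        for k, scene in enumerate(section.scenes):
            if scene.name == scene_name:
                total = _scene_frame_count(scene,
                                           test.settings.display.refresh_rate)
                if not (0 <= frame_index < total):
                    raise IndexError(
                        f"frame {frame_index} out of range for scene "
                        f"{scene_name!r} ({total} frames)"
                    )
                base_seed = (int(seed) ^ test.settings.rng_seed) & 0x7FFFFFFF
                rng = _scene_rng(base_seed, trial_index, scene.name)
                frames = iter_scene_frames(test, section, k, bindings or {}, rng)
                buf = None
                for i, buf in zip(range(frame_index + 1), frames):
                    pass
                assert buf is not None
                return buf
    raise KeyError(f"no scene named {scene_name!r}")


# ---------------------------------------------------------------------------
# Results output
# ---------------------------------------------------------------------------

def write_results(bundle: ResultsBundle, out_dir) -> tuple[Path, Path]:
    """Write settings.txt (key: value lines) and results.csv (RFC 4180)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    txt_path = out / "settings.txt"
    csv_path = out / "results.csv"
    lines = [f"{k}: {v}" for k, v in bundle.settings_report.items()]
    txt_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    bundle.trials_table.to_csv(csv_path, index=False, lineterminator="\r\n")
    return txt_path, csv_path


def write_timing(report: TimingReport, path) -> Path:
    """Write the timing report as JSON."""
    path = Path(path)
    payload = {
        "refresh_rate_hz": report.refresh_rate,
        "frame_budget_ms": report.frame_budget_ms,
        "n_frames": len(report.frame_times_ms),
        "n_dropped": len(report.dropped_frames),
        "percent_dropped": report.percent_dropped,
        "dropped_frames": [
            {"frame": i, "duration_ms": t} for i, t in report.dropped_frames
        ],
    }
    path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    return path
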