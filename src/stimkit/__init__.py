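"""stimkit: a headless, scriptable engine for declarative psychophysical tests.

Tests (sections -> scenes -> stimuli, with lists and variables) are parsed
from a JSON description; visual stimuli are synthesized procedurally frame
by frame and auditory stimuli sample by sample at 44.1 kHz; trials are
sequenced by constant-stimuli or adaptive staircase procedures; simulated
observers stand in for the touchscreen; results are emitted as a settings
report plus a trial-wise CSV, alongside a frame-timing report.
"""

__version__ = "0.1.0"

from .units import (
    DisplayProfile,
    deg_to_px,
    frame_duration_ms,
    length_to_px,
    load_display_profiles,
    luminance_fraction_to_cd,
    px_to_deg,
    seconds_to_frames,
)
from .model import (
    Duration,
    Issue,
    NumericList,
    ParseError,
    PropertyValue,
    ResponseSpec,
    Scene,
    Section,
    SequencingError,
    StimulusSpec,
    Test,
    TestSettings,
    ValidationError,
    VariableBinding,
    make_linear_sequence,
    parse_test,
    parse_test_file,
    resolve_property,
    serialize_test,
    validate_test,
)
from .visual import (
    DotFieldState,
    FrameBuffer,
    RasterPatch,
    apply_noise_filter,
    apply_shape_mask,
    checkerboard_value,
    composite_scene_frame,
    grating_luminance,
    quantize_noise_bit,
    render_stimulus_frame,
    update_dot_field,
)
from .audio import (
    AudioBuffer,
    AudioEvent,
    mix_scene_audio,
    read_wav,
    synth_auditory_noise,
    synth_tone,
    write_wav,
)
from .procedures import (
    PsychometricFit,
    PsychometricObserver,
    StaircaseConfig,
    StaircaseState,
    TrialPlan,
    expand_section_trials,
    fit_psychometric,
    simulate_response,
    staircase_estimate,
    staircase_next,
)
from .runner import (
    ObserverResponder,
    ResultsBundle,
    ScriptedResponder,
    TimingReport,
    preview_frame,
    run_test,
    timing_report,
    write_results,
    write_timing,
)


def tutorial_test_path():
    """Path to the packaged orientation-discrimination tutorial test."""
    import importlib.resources

    return importlib.resources.files("stimkit.data").joinpath(
        "tutorial.stimulitest"
    )


def load_tutorial_test() -> Test:
    """Parse the packaged tutorial test (orientation discrimination, method
    of constant stimuli: 7 rotations from -0.03 to 0.03 rad, 20 repetitions)."""
    return parse_test(tutorial_test_path().read_text(encoding="utf-8"))
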