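"""Tone and noise synthesis at 44.1 kHz, scene mixing, WAV output.

Buffers are mono float arrays in [-1, 1].  Scene audio is assembled by
sample-accurate placement of event buffers at their onsets; a signed
audiovisual offset (ms) can be applied to every onset to correct a device's
measured AV asynchrony.  Output is 16-bit PCM RIFF WAV.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile

__all__ = [
    "AudioBuffer",
    "AudioEvent",
    "synth_tone",
    "synth_auditory_noise",
    "mix_scene_audio",
    "write_wav",
    "read_wav",
]

DEFAULT_SAMPLE_RATE = 44_100
DEFAULT_RAMP_S = 0.005  # linear on/off ramp to avoid onset clicks


@dataclass
class AudioBuffer:
    """Mono sample buffer; duration in seconds is ``len(samples)/sample_rate``."""

    sample_rate: int
    samples: np.ndarray

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class AudioEvent:
    """An audio buffer scheduled at an onset (s) within a scene."""

    buffer: AudioBuffer
    onset: float = 0.0

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset!r}")


def synth_tone(
    frequency: float,
    duration: float,
    amplitude: float = 0.5,
    ramp: float = DEFAULT_RAMP_S,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> AudioBuffer:
    """Pure sine tone with a linear on/off amplitude ramp (0 allowed).

    samples[i] = amplitude * env(i) * sin(2*pi*frequency*i/sample_rate),
    with round(duration * sample_rate) samples.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration!r}")
    if not (0.0 <= amplitude <= 1.0):
        raise ValueError(f"amplitude must lie in [0, 1], got {amplitude!r}")
    if frequency >= sample_rate / 2.0:
        raise ValueError(
            f"tone frequency {frequency} Hz is at or above the Nyquist limit "
            f"{sample_rate / 2:.0f} Hz and would alias"
        )
    n = round(duration * sample_rate)
    i = np.arange(n)
    samples = amplitude * np.sin(2.0 * np.pi * frequency * i / sample_rate)
    if ramp > 0:
        n_ramp = min(round(ramp * sample_rate), n // 2)
        if n_ramp > 0:
            env = np.ones(n)
            env[:n_ramp] = np.arange(n_ramp) / n_ramp
            env[n - n_ramp :] = env[:n_ramp][::-1]
            samples = samples * env
    return AudioBuffer(sample_rate=sample_rate, samples=samples)


def synth_auditory_noise(
    duration: float,
    amplitude: float = 0.5,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    rng: np.random.Generator | None = None,
) -> AudioBuffer:
    """White noise: independent uniform samples in [-amplitude, amplitude]."""
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration!r}")
    if not (0.0 <= amplitude <= 1.0):
        raise ValueError(f"amplitude must lie in [0, 1], got {amplitude!r}")
    if rng is None:
        rng = np.random.default_rng()
    n = round(duration * sample_rate)
    samples = rng.uniform(-amplitude, amplitude, n)
    return AudioBuffer(sample_rate=sample_rate, samples=samples)


def mix_scene_audio(
    events: list[AudioEvent],
    scene_duration: float,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    av_offset_ms: float = 0.0,
) -> AudioBuffer:
    """Sum event buffers into a scene-long track, hard-clipped to [-1, 1].

    Each event starts at sample round((onset + av_offset_ms/1000) * rate).
    Events pushed before 0 by a negative offset are truncated at 0; events
    running past the scene end are truncated there (both with a warning).
    """
    n = round(scene_duration * sample_rate)
    mix = np.zeros(n)
    for ev in events:
        if ev.buffer.sample_rate != sample_rate:
            raise ValueError(
                f"event sample rate {ev.buffer.sample_rate} != scene rate {sample_rate}"
            )
        start = round((ev.onset + av_offset_ms / 1000.0) * sample_rate)
        buf = ev.buffer.samples
        b0 = 0
        if start < 0:
            warnings.warn(
                f"audio event at onset {ev.onset}s starts before the scene after "
                f"AV offset; truncated at 0", stacklevel=2,
            )
            b0 = -start
            start = 0
        end = start + (len(buf) - b0)
        if end > n:
            warnings.warn(
                f"audio event at onset {ev.onset}s extends past the scene end; "
                "truncated", stacklevel=2,
            )
            end = n
        if end > start:
            mix[start:end] += buf[b0 : b0 + (end - start)]
    if np.any(np.abs(mix) > 1.0):
        warnings.warn("mixed scene audio clipped to [-1, 1]", stacklevel=2)
        np.clip(mix, -1.0, 1.0, out=mix)
    return AudioBuffer(sample_rate=sample_rate, samples=mix)


def write_wav(buffer: AudioBuffer, path) -> None:
    """Write a buffer as 16-bit PCM mono WAV; read-back matches to 1 LSB."""
    pcm = np.round(np.clip(buffer.samples, -1.0, 1.0) * 32767.0).astype(np.int16)
    wavfile.write(path, buffer.sample_rate, pcm)


def read_wav(path) -> AudioBuffer:
    """Read a WAV file back into a mono float buffer in [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if data.dtype == np.int16:
        samples = data.astype(float) / 32767.0
    elif data.dtype == np.int32:
        samples = data.astype(float) / 2147483647.0
    elif data.dtype == np.uint8:
        samples = (data.astype(float) - 128.0) / 127.0
    else:
        samples = data.astype(float)
    return AudioBuffer(sample_rate=int(rate), samples=samples)
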