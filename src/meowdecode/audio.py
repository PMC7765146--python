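"""Audio container and WAV input/output.

The analysis operates on mono PCM recordings at 8 kHz, the format the
original field recordings were captured in (16-bit RIFF WAV from a
collar-mounted Bluetooth microphone).  Anything else is downmixed and
resampled on read, with a logged warning, so downstream stages can assume
a single canonical format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

log = logging.getLogger(__name__)

#: Canonical sampling rate (Hz) for all analysis.
TARGET_RATE = 8000

_PCM16_SCALE = 32768.0


@dataclass(frozen=True)
class AudioClip:
    """A mono audio recording: float samples in [-1, 1) plus sample rate."""

    samples: np.ndarray
    rate: int = TARGET_RATE
    clip_id: str | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioClip samples must be 1-D (mono)")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Clip length in seconds."""
        return len(self.samples) / self.rate

    def __len__(self) -> int:
        return len(self.samples)


def read_wav(path, target_rate: int = TARGET_RATE) -> AudioClip:
    """Read a RIFF WAV file as a mono clip at ``target_rate``.

    Integer PCM is scaled to [-1, 1).  Stereo input is downmixed by
    channel averaging and input at a different rate is resampled with a
    polyphase filter; both conversions emit a warning because the source
    material is nominally mono 8 kHz already.
    """
    rate, data = wavfile.read(path)
    if data.size == 0:
        raise ValueError(f"{path}: WAV file contains no samples")
    if data.ndim == 2:
        log.warning("%s: %d channels downmixed to mono", path, data.shape[1])
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max + 1))
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    if rate != target_rate:
        log.warning("%s: resampling %d Hz -> %d Hz", path, rate, target_rate)
        g = np.gcd(int(rate), int(target_rate))
        samples = resample_poly(samples, target_rate // g, rate // g)
        rate = target_rate
    return AudioClip(samples=samples, rate=int(rate))


def write_wav(path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM RIFF WAV."""
    quantized = np.clip(np.round(clip.samples * _PCM16_SCALE),
                        -_PCM16_SCALE, _PCM16_SCALE - 1).astype(np.int16)
    wavfile.write(path, clip.rate, quantized)
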