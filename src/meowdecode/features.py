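"""Framewise acoustic features and per-recording summaries.

Three feature families are extracted from the short-term Fourier transform
of a recording and reduced to a 10-value per-recording summary (mean and
sample standard deviation of each):

F0 (pitch)
    Estimated per frame by correlating the square-root-compressed
    magnitude spectrum against sawtooth-like harmonic kernels over a
    log-spaced pitch grid, in the spirit of the SWIPE' estimator: the
    kernel for candidate pitch ``p`` is a cosine in ``freq/p`` (positive
    lobes on the harmonics, negative troughs between them) with a
    ``1/sqrt(harmonic)`` decay.  The normalized correlation is the pitch
    strength; clipped to [0, 1] it serves as the confidence score, and
    frames with confidence below a threshold (default 0.15) are treated
    as unvoiced.

Roughness (R)
    Psychoacoustic roughness from rapid amplitude fluctuation, computed
    per frame as the summed pairwise interaction of spectral peaks under
    the partial-pair model of Vassilakis: for peaks (f1, a1), (f2, a2),

        X = (a1 * a2) ** 0.1
        Y = 0.5 * (2 * min(a1, a2) / (a1 + a2)) ** 3.11
        Z = exp(-b1 * s * df) - exp(-b2 * s * df),  s = s* / (s1 * fmin + s2)

    with df = |f2 - f1|, fmin = min(f1, f2) and constants b1 = 3.5,
    b2 = 5.75, s* = 0.24, s1 = 0.0207, s2 = 18.96.  The contribution of a
    pair peaks when the partials sit roughly a critical band apart
    (~tens of Hz in the vocal range) and vanishes for distant partials.

Tristimulus (T1-T3)
    Timbre descriptors adapted from colour perception: T1 is the energy
    fraction of the fundamental, T2 of harmonics 2-4, T3 of the higher
    harmonics, each relative to the frame's total spectral energy (so
    T1 + T2 + T3 <= 1; inharmonic energy is in the denominator only).

F0 and tristimulus statistics are aggregated over voiced frames only;
roughness, which needs no pitch, over all frames.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .audio import AudioClip

FEATURE_NAMES = ("f0_mean", "f0_sd", "r_mean", "r_sd", "t1_mean", "t1_sd",
                 "t2_mean", "t2_sd", "t3_mean", "t3_sd")

#: Default analysis framing: 32 ms frames, 10 ms hop at 8 kHz.
FRAME_LEN = 256
HOP = 80

DEFAULT_CONF_THRESHOLD = 0.15
DEFAULT_FMIN = 75.0
DEFAULT_FMAX = 1800.0

#: Pitch analysis uses a longer window (64 ms) than the spectral features:
#: the extra frequency resolution sharpens the harmonic kernels and keeps
#: the pitch-strength score of unpitched frames (noise, silence) low.
PITCH_FRAME_LEN = 512

# Partial-pair roughness constants (critical-band interaction model).
_B1, _B2 = 3.5, 5.75
_S_STAR, _S1, _S2 = 0.24, 0.0207, 18.96


class UnusableRecordingError(ValueError):
    """Raised when a recording has too few usable frames to summarize."""


# ---------------------------------------------------------------------------
# STFT

@dataclass
class Spectrogram:
    frame_times: np.ndarray  # seconds, frame start + half frame
    freqs: np.ndarray  # Hz
    magnitude: np.ndarray  # (n_frames, n_bins), >= 0
    frame_len: int
    hop: int
    window: str


def _frame_signal(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    n_frames = (len(x) - frame_len) // hop + 1
    if n_frames < 1:
        raise ValueError("clip shorter than one analysis frame")
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def _get_window(name: str, frame_len: int) -> np.ndarray:
    from scipy.signal import get_window
    return get_window(name, frame_len, fftbins=True)


def stft(clip: AudioClip, frame_len: int = FRAME_LEN, hop: int = HOP,
         window: str = "hann", nfft: int | None = None) -> Spectrogram:
    """Magnitude STFT with no padding: floor((n - frame_len)/hop) + 1 frames."""
    if frame_len < 64:
        raise ValueError("frame_len must be >= 64 samples")
    if len(clip) < frame_len:
        raise ValueError("clip shorter than one analysis frame")
    nfft = nfft or frame_len
    frames = _frame_signal(clip.samples, frame_len, hop)
    win = _get_window(window, frame_len)
    mag = np.abs(np.fft.rfft(frames * win, n=nfft, axis=1))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / clip.rate)
    times = (np.arange(frames.shape[0]) * hop + frame_len / 2) / clip.rate
    return Spectrogram(frame_times=times, freqs=freqs, magnitude=mag,
                       frame_len=frame_len, hop=hop, window=window)


# ---------------------------------------------------------------------------
# Pitch

_GRID_STEP = 1.0 / 48.0  # octaves between pitch candidates
_PITCH_NFFT = 2048
_kernel_cache: dict = {}


def _primes_up_to(n: int) -> list[int]:
    sieve = np.ones(n + 1, dtype=bool)
    sieve[:2] = False
    for p in range(2, int(n ** 0.5) + 1):
        if sieve[p]:
            sieve[p * p::p] = False
    return list(np.flatnonzero(sieve))


def _pitch_kernels(rate: int, nfft: int, fmin: float, fmax: float):
    """Kernel matrix, candidate grid and support indices (cached).

    Each candidate pitch gets a sawtooth-spectrum kernel with cosine lobes
    only at the first and the prime harmonics (the trick that suppresses
    subharmonic errors: a candidate at f0/3 collects credit from just one
    of the true harmonics instead of every third lobe), half-weight
    troughs on the lobe shoulders, and a 1/sqrt(harmonic) decay.
    """
    key = (rate, nfft, round(fmin, 6), round(fmax, 6))
    if key in _kernel_cache:
        return _kernel_cache[key]
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rate)
    n_steps = int(np.ceil(np.log2(fmax / fmin) / _GRID_STEP)) + 1
    candidates = fmin * 2.0 ** (_GRID_STEP * np.arange(n_steps))
    candidates = candidates[candidates <= fmax * (1 + 1e-9)]
    x = freqs[None, :] / candidates[:, None]  # frequency in periods of p
    x_max = freqs[-1] / candidates.min()
    harmonics = [1] + [p for p in _primes_up_to(int(np.ceil(x_max)) + 1)
                       if p > 1]
    cosx = np.cos(2.0 * np.pi * x)
    kernel = np.zeros_like(x)
    for k in harmonics:
        d = np.abs(x - k)
        kernel += np.where(d < 0.25, cosx, 0.0)
        kernel += np.where((d >= 0.25) & (d < 0.75), 0.5 * cosx, 0.0)
    kernel /= np.sqrt(np.maximum(x, 1.0))
    kernel_norm = np.linalg.norm(kernel, axis=1)
    # first spectral bin inside each kernel's support (freq >= p/4)
    support_start = np.searchsorted(freqs, candidates / 4.0)
    out = (freqs, candidates, kernel, kernel_norm, support_start)
    _kernel_cache[key] = out
    return out


def estimate_pitch(clip: AudioClip, fmin: float = DEFAULT_FMIN,
                   fmax: float = DEFAULT_FMAX,
                   frame_len: int = PITCH_FRAME_LEN,
                   hop: int = HOP) -> tuple[np.ndarray, np.ndarray]:
    """Framewise pitch candidates and confidence scores.

    Returns ``(f0, confidence)`` arrays, one value per analysis frame,
    with f0 in [fmin, fmax] and confidence in [0, 1].  Silence and noise
    produce low confidence, never an error.
    """
    if not 50.0 <= fmin < fmax <= 2000.0:
        raise ValueError("need 50 <= fmin < fmax <= 2000 Hz")
    freqs, cand, kernel, kernel_norm, support_start = _pitch_kernels(
        clip.rate, _PITCH_NFFT, fmin, fmax)
    frames = _frame_signal(clip.samples, frame_len, hop)
    win = _get_window("hann", frame_len)
    mag = np.abs(np.fft.rfft(frames * win, n=_PITCH_NFFT, axis=1))
    smag = np.sqrt(mag)

    scores = smag @ kernel.T  # (n_frames, n_candidates)
    # norm of the spectrum restricted to each kernel's support
    suffix = np.sqrt(np.cumsum((smag ** 2)[:, ::-1], axis=1)[:, ::-1])
    spec_norm = suffix[:, np.minimum(support_start, smag.shape[1] - 1)]
    denom = kernel_norm[None, :] * spec_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        strength = np.where(denom > 0, scores / denom, 0.0)

    best = np.argmax(strength, axis=1)
    f0 = cand[best].astype(float)
    conf = np.clip(strength[np.arange(len(best)), best], 0.0, 1.0)

    # parabolic refinement on the log-pitch grid
    for i, b in enumerate(best):
        if 0 < b < len(cand) - 1:
            y0, y1, y2 = strength[i, b - 1], strength[i, b], strength[i, b + 1]
            d = y0 - 2.0 * y1 + y2
            if d < 0:
                shift = np.clip(0.5 * (y0 - y2) / d, -0.5, 0.5)
                f0[i] = cand[b] * 2.0 ** (shift * _GRID_STEP)
    return np.clip(f0, fmin, fmax), conf


# ---------------------------------------------------------------------------
# Roughness

def roughness_frame(spectral_peaks) -> float:
    """Total roughness of one frame from its spectral peaks.

    ``spectral_peaks`` is a sequence of (frequency Hz, amplitude) sorted by
    frequency.  Returns the sum of partial-pair contributions over all
    unordered pairs; fewer than two peaks give 0.
    """
    peaks = list(spectral_peaks)
    if len(peaks) < 2:
        return 0.0
    f = np.array([p[0] for p in peaks], dtype=float)
    a = np.array([p[1] for p in peaks], dtype=float)
    if np.any(a < 0):
        raise ValueError("peak amplitudes must be nonnegative")
    if np.any(np.diff(f) < 0):
        raise ValueError("peaks must be sorted by frequency")
    i, j = np.triu_indices(len(f), k=1)
    a1, a2 = a[i], a[j]
    fmin = np.minimum(f[i], f[j])
    df = np.abs(f[j] - f[i])
    with np.errstate(invalid="ignore"):
        x = (a1 * a2) ** 0.1
        amin, asum = np.minimum(a1, a2), a1 + a2
        y = np.where(asum > 0, 0.5 * (2.0 * amin / np.where(asum > 0, asum, 1.0)) ** 3.11, 0.0)
        s = _S_STAR / (_S1 * fmin + _S2)
        z = np.exp(-_B1 * s * df) - np.exp(-_B2 * s * df)
    return float(np.sum(np.where(asum > 0, x * y * z, 0.0)))


def spectral_peaks(mag_frame: np.ndarray, freqs: np.ndarray,
                   floor_db: float = -60.0, max_peaks: int = 20):
    """Local spectral maxima above a relative floor, largest ``max_peaks``.

    The floor is relative to the frame maximum (default -60 dB); capping
    the peak count bounds the quadratic pair cost of the roughness model.
    """
    m = np.asarray(mag_frame, dtype=float)
    if m.max() <= 0:
        return []
    floor = m.max() * 10.0 ** (floor_db / 20.0)
    inner = (m[1:-1] >= m[:-2]) & (m[1:-1] > m[2:]) & (m[1:-1] >= floor)
    idx = np.flatnonzero(inner) + 1
    if len(idx) > max_peaks:
        idx = idx[np.argsort(m[idx])[-max_peaks:]]
        idx = np.sort(idx)
    return [(float(freqs[k]), float(m[k])) for k in idx]


# ---------------------------------------------------------------------------
# Tristimulus

def tristimulus_frame(mag_frame: np.ndarray, freqs: np.ndarray,
                      f0: float, band_frac: float = 0.03):
    """(T1, T2, T3) energy fractions for one frame given its pitch.

    Harmonic k's energy is the summed squared magnitude in a band around
    k*f0 whose half-width is ±``band_frac`` of k*f0, floored at the
    window's spectral resolution (two bin widths) so that a harmonic's
    main lobe is always captured, and capped at f0/2 so neighbouring
    harmonic bands never overlap.  The denominator is the frame's total
    spectral energy, so T1 + T2 + T3 <= 1.  Returns ``None`` for a
    zero-energy frame (dropped from aggregation).
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    power = np.asarray(mag_frame, dtype=float) ** 2
    total = power.sum()
    if total <= 0:
        return None
    bin_width = freqs[1] - freqs[0]
    nyquist = freqs[-1]
    t = np.zeros(3)
    k = 1
    while k * f0 < nyquist:
        center = k * f0
        half = min(max(band_frac * center, 2.0 * bin_width), f0 / 2.0)
        band = (freqs >= center - half) & (freqs <= center + half)
        e = power[band].sum()
        if k == 1:
            t[0] += e
        elif k <= 4:
            t[1] += e
        else:
            t[2] += e
        k += 1
    return tuple(t / total)


# ---------------------------------------------------------------------------
# Tracks and aggregation

@dataclass
class FeatureTrack:
    """Framewise feature values with a voicing validity mask."""

    frame_times: np.ndarray
    f0: np.ndarray
    f0_confidence: np.ndarray
    voiced_mask: np.ndarray
    roughness: np.ndarray
    t1: np.ndarray
    t2: np.ndarray
    t3: np.ndarray
    conf_threshold: float = DEFAULT_CONF_THRESHOLD


@dataclass
class FeatureVector:
    """Per-recording 10-value summary (mean and SD of F0, R, T1-T3)."""

    values: np.ndarray
    names: tuple = FEATURE_NAMES
    clip_id: str | None = None
    context: str | None = None

    def as_dict(self) -> dict:
        return dict(zip(self.names, (float(v) for v in self.values)))


def mask_low_confidence(track: FeatureTrack,
                        threshold: float = DEFAULT_CONF_THRESHOLD) -> FeatureTrack:
    """Mark frames voiced where confidence >= threshold (inclusive)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return replace(track, voiced_mask=track.f0_confidence >= threshold,
                   conf_threshold=threshold)


def extract_track(clip: AudioClip, frame_len: int = FRAME_LEN, hop: int = HOP,
                  window: str = "hann", fmin: float = DEFAULT_FMIN,
                  fmax: float = DEFAULT_FMAX,
                  conf_threshold: float = DEFAULT_CONF_THRESHOLD) -> FeatureTrack:
    """Full framewise analysis of one clip: pitch, roughness, tristimulus."""
    spec = stft(clip, frame_len=frame_len, hop=hop, window=window)
    # Pitch uses its own longer window; zero-pad so that pitch frames stay
    # centered on the spectral frames and the frame counts match.
    pitch_len = max(PITCH_FRAME_LEN, frame_len)
    pad = (pitch_len - frame_len) // 2
    padded = AudioClip(np.pad(clip.samples, pad), rate=clip.rate)
    f0, conf = estimate_pitch(padded, fmin=fmin, fmax=fmax,
                              frame_len=pitch_len, hop=hop)
    n = spec.magnitude.shape[0]
    f0, conf = f0[:n], conf[:n]
    rough = np.empty(n)
    t1 = np.full(n, np.nan)
    t2 = np.full(n, np.nan)
    t3 = np.full(n, np.nan)
    voiced = conf >= conf_threshold
    for i in range(n):
        rough[i] = roughness_frame(spectral_peaks(spec.magnitude[i], spec.freqs))
        if voiced[i]:
            tri = tristimulus_frame(spec.magnitude[i], spec.freqs, f0[i])
            if tri is not None:
                t1[i], t2[i], t3[i] = tri
    return FeatureTrack(frame_times=spec.frame_times, f0=f0,
                        f0_confidence=conf, voiced_mask=voiced,
                        roughness=rough, t1=t1, t2=t2, t3=t3,
                        conf_threshold=conf_threshold)


def aggregate(track: FeatureTrack) -> FeatureVector:
    """Reduce a track to the 10-value summary.

    F0 and tristimulus statistics run over voiced frames (with defined
    tristimulus); roughness over all frames.  Sample SD (ddof=1) is used,
    so at least two usable frames of each kind are required.
    """
    usable = track.voiced_mask & np.isfinite(track.t1)
    if usable.sum() < 2 or len(track.roughness) < 2:
        raise UnusableRecordingError(
            f"only {int(usable.sum())} voiced frames; need >= 2")

    def ms(x):
        return float(np.mean(x)), float(np.std(x, ddof=1))

    f0_m, f0_s = ms(track.f0[usable])
    r_m, r_s = ms(track.roughness)
    t1_m, t1_s = ms(track.t1[usable])
    t2_m, t2_s = ms(track.t2[usable])
    t3_m, t3_s = ms(track.t3[usable])
    values = np.array([f0_m, f0_s, r_m, r_s, t1_m, t1_s, t2_m, t2_s,
                       t3_m, t3_s])
    return FeatureVector(values=values)


def extract_features(clip: AudioClip, clip_id: str | None = None,
                     context: str | None = None, **kwargs) -> FeatureVector:
    """Convenience: clip -> FeatureVector in one call."""
    vec = aggregate(extract_track(clip, **kwargs))
    return replace(vec, clip_id=clip_id or clip.clip_id, context=context)


def features_dataframe(corpus, **kwargs):
    """Per-clip feature table for a labelled corpus.

    ``corpus`` is an iterable of (clip_id, context, AudioClip).  Clips with
    too few voiced frames are skipped with a log entry.  Returns a pandas
    DataFrame with clip_id, context and the 10 feature columns.
    """
    import logging

    import pandas as pd
    rows = []
    for clip_id, context, clip in corpus:
        try:
            vec = extract_features(clip, clip_id=clip_id, context=context,
                                   **kwargs)
        except UnusableRecordingError as exc:
            logging.getLogger(__name__).warning("%s unusable: %s", clip_id, exc)
            continue
        row = {"clip_id": clip_id, "context": context}
        row.update(vec.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
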