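"""ECG trace to audio waveform conversion.

Normalization centers the trace and scales it toward [-1, 1]; two modes
are offered. ``verbatim`` divides the centered signal by the maximum
absolute value of the *raw* signal, x_norm = (x - mu) / max|x| — a form
that can leave centered samples outside [-1, 1] when the signal has a
large offset. ``strict`` (the default) divides by max|x - mu| instead,
which guarantees the advertised [-1, 1] range. After normalization the
trace is band-limited-resampled to a standard audio rate (8000 Hz by
default, the usual choice for heart-sound work whose content sits well
below 4 kHz) and can be written as 16-bit PCM mono WAV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample as _fft_resample

from .synthetic import ECGTrace


@dataclass
class AudioWaveform:
    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.samples.size and np.max(np.abs(self.samples)) > 1 + 1e-9:
            raise ValueError("audio samples must lie in [-1, 1]")


def normalize(trace: ECGTrace, mode: str = "strict") -> ECGTrace:
    """Center and scale a trace; see the module docstring for the modes."""
    if mode not in ("strict", "verbatim"):
        raise ValueError("mode must be 'strict' or 'verbatim'")
    x = trace.samples
    if x.size == 0:
        raise ValueError("trace is empty")
    centred = x - x.mean()
    denom = np.max(np.abs(centred)) if mode == "strict" else np.max(np.abs(x))
    if denom < 1e-15:
        warnings.warn("zero-denominator input; returning an all-zero signal")
        return ECGTrace(np.zeros_like(x), trace.sampling_rate, trace.origin)
    return ECGTrace(centred / denom, trace.sampling_rate, trace.origin)


def resample(trace: ECGTrace, target_rate: float = 8000.0) -> AudioWaveform:
    """Band-limited (FFT) resampling to ``target_rate``; the output length
    is round(L * target / source) and the [-1, 1] bound is preserved."""
    if target_rate <= 0:
        raise ValueError("target_rate must be > 0")
    if trace.sampling_rate <= 0:
        raise ValueError("source sampling rate must be known and > 0")
    x = trace.samples
    if trace.sampling_rate == target_rate:
        y = x.copy()
    else:
        n_out = int(round(x.size * target_rate / trace.sampling_rate))
        y = _fft_resample(x, n_out)
        # FFT resampling can overshoot marginally at sharp peaks
        y = np.clip(y, -1.0, 1.0)
    return AudioWaveform(y, float(target_rate))


def write_wav(w: AudioWaveform, path) -> None:
    """16-bit PCM mono WAV."""
    pcm = np.round(np.clip(w.samples, -1.0, 1.0) * 32767.0).astype(np.int16)
    wavfile.write(path, int(w.sampling_rate), pcm)


def read_wav(path) -> AudioWaveform:
    rate, data = wavfile.read(path)
    if data.dtype != np.int16:
        raise ValueError("expected 16-bit PCM WAV")
    if data.ndim > 1:
        data = data[:, 0]
    return AudioWaveform(data.astype(np.float64) / 32767.0, float(rate))


def trace_to_audio(trace: ECGTrace, target_rate: float = 8000.0,
                   mode: str = "strict",
                   playback_speed: float = 1.0) -> AudioWaveform:
    """Normalize then resample to ``target_rate``.

    ``playback_speed`` > 1 plays the trace faster (the usual sonification
    device for sub-audio biosignals): the source rate is reinterpreted as
    ``speed x`` so a 0.5-60 Hz ECG band maps up toward the audible range
    before resampling.
    """
    if playback_speed <= 0:
        raise ValueError("playback_speed must be > 0")
    norm = normalize(trace, mode)
    if playback_speed != 1.0:
        norm = ECGTrace(norm.samples, norm.sampling_rate * playback_speed,
                        norm.origin)
    return resample(norm, target_rate)
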