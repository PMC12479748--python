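"""STFT -> Mel filterbank -> dB -> 224x224x3 spectrogram image.

The Mel scale used is M(f) = 2595 * log10(1 + f/700). Triangular filters
have unit peak and centers equally spaced on the Mel axis. The decibel
reference is the per-spectrogram maximum (so the strongest cell sits at
0 dB) with a floor at ``db_floor``. Images are min-max scaled, bilinearly
resized and channel-replicated; dB conversion happens before resizing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _resize

from .audio import AudioWaveform

IMAGE_SIZE = 224


@dataclass(frozen=True)
class SpectrogramConfig:
    sampling_rate: float = 22050.0
    n_fft: int = 1024
    hop_length: int = 512
    n_mels: int = 128
    window: str = "hann"
    fmin: float = 0.0
    fmax: float | None = None     # defaults to sampling_rate / 2
    db_floor: float = -80.0
    center_padding: bool = True

    def __post_init__(self):
        if self.hop_length > self.n_fft:
            raise ValueError("hop_length must be <= n_fft")
        if self.n_mels < 1:
            raise ValueError("n_mels must be >= 1")
        if self.window != "hann":
            raise ValueError("only the hann window is supported")
        fmax = self.effective_fmax
        if not self.fmin < fmax <= self.sampling_rate / 2:
            raise ValueError("need fmin < fmax <= sampling_rate / 2")

    @property
    def effective_fmax(self) -> float:
        return self.sampling_rate / 2 if self.fmax is None else self.fmax


@dataclass
class MelSpectrogram:
    values: np.ndarray            # n_mels x n_frames
    config: SpectrogramConfig
    is_db: bool


def _hann(n):
    # periodic Hann, the standard analysis window for hop-based STFTs
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / n))


def stft(w: AudioWaveform, cfg: SpectrogramConfig = SpectrogramConfig()) -> np.ndarray:
    """One-sided STFT, (n_fft/2 + 1) x n_frames complex.

    With center padding (reflect) the signal is padded by n_fft/2 on each
    side and n_frames = 1 + floor(L / hop); frames start at t*hop.
    """
    x = np.asarray(w.samples, dtype=np.float64)
    if x.size < 1:
        raise ValueError("waveform is empty")
    n_fft, hop = cfg.n_fft, cfg.hop_length
    if cfg.center_padding:
        pad = n_fft // 2
        if x.size > 1:
            x = np.pad(x, pad, mode="reflect") if pad < x.size else np.pad(
                x, pad, mode="constant")
        else:
            x = np.pad(x, pad, mode="constant")
        n_frames = 1 + (w.samples.size // hop)
    else:
        if n_fft > x.size:
            raise ValueError("n_fft exceeds the (unpadded) signal length")
        n_frames = 1 + (x.size - n_fft) // hop
    win = _hann(n_fft)
    frames = np.lib.stride_tricks.sliding_window_view(x, n_fft)[::hop][:n_frames]
    return np.fft.rfft(frames * win, axis=1).T


def hz_to_mel(f):
    """M(f) = 2595 * log10(1 + f / 700)."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be >= 0")
    return 2595.0 * np.log10(1.0 + f / 700.0)


def mel_to_hz(m):
    m = np.asarray(m, dtype=np.float64)
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


def mel_center_frequencies(cfg: SpectrogramConfig) -> np.ndarray:
    """Filter center frequencies: n_mels points equally spaced on the Mel
    axis strictly between M(fmin) and M(fmax)."""
    mels = np.linspace(hz_to_mel(cfg.fmin), hz_to_mel(cfg.effective_fmax),
                       cfg.n_mels + 2)
    return mel_to_hz(mels[1:-1])


def mel_filterbank(cfg: SpectrogramConfig = SpectrogramConfig()) -> np.ndarray:
    """Unit-peak triangular filters, n_mels x (n_fft/2 + 1)."""
    n_bins = cfg.n_fft // 2 + 1
    bin_freqs = np.arange(n_bins) * cfg.sampling_rate / cfg.n_fft
    edges = mel_to_hz(np.linspace(hz_to_mel(cfg.fmin),
                                  hz_to_mel(cfg.effective_fmax),
                                  cfg.n_mels + 2))
    fb = np.zeros((cfg.n_mels, n_bins))
    for m in range(cfg.n_mels):
        lo, ctr, hi = edges[m], edges[m + 1], edges[m + 2]
        up = (bin_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - bin_freqs) / max(hi - ctr, 1e-12)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    empty = np.flatnonzero(fb.sum(axis=1) == 0)
    if empty.size:
        warnings.warn(f"empty Mel filters (insufficient FFT resolution): "
                      f"{empty.tolist()}")
    return fb


def mel_spectrogram(w: AudioWaveform,
                    cfg: SpectrogramConfig = SpectrogramConfig()) -> MelSpectrogram:
    """Power Mel-spectrogram: filterbank applied to |STFT|^2."""
    spec = np.abs(stft(w, cfg)) ** 2
    return MelSpectrogram(mel_filterbank(cfg) @ spec, cfg, is_db=False)


def power_to_db(s: MelSpectrogram) -> MelSpectrogram:
    """10 * log10(S / max(S)), clamped below at ``db_floor``."""
    if s.is_db:
        raise ValueError("spectrogram already in dB")
    vals = np.asarray(s.values, dtype=np.float64)
    if np.any(vals < 0):
        raise ValueError("power spectrogram must be non-negative")
    ref = vals.max()
    floor = s.config.db_floor
    if ref <= 0:
        warnings.warn("all-zero spectrogram; every cell set to the dB floor")
        db = np.full_like(vals, floor)
    else:
        with np.errstate(divide="ignore"):
            db = 10.0 * np.log10(vals / ref)
        db = np.maximum(db, floor)
    return MelSpectrogram(db, s.config, is_db=True)


def to_image(m: MelSpectrogram) -> np.ndarray:
    """Min-max scale to [0, 1], bilinear-resize to 224x224, replicate to
    three channels. Constant input maps to an all-0.5 image."""
    if not m.is_db:
        raise ValueError("to_image expects a dB spectrogram")
    v = m.values
    lo, hi = v.min(), v.max()
    if hi - lo < 1e-12:
        warnings.warn("constant spectrogram; emitting an all-0.5 image")
        scaled = np.full_like(v, 0.5)
    else:
        scaled = (v - lo) / (hi - lo)
    img = _resize(scaled, (IMAGE_SIZE, IMAGE_SIZE), order=1, mode="edge",
                  anti_aliasing=False)
    img = np.clip(img, 0.0, 1.0)
    return np.repeat(img[:, :, None], 3, axis=2)


def waveform_to_image(w: AudioWaveform,
                      cfg: SpectrogramConfig = SpectrogramConfig()) -> np.ndarray:
    return to_image(power_to_db(mel_spectrogram(w, cfg)))
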