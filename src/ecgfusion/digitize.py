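"""ECG plot-image digitization.

Pipeline: grayscale -> Gaussian blur -> adaptive (local-mean) threshold
-> largest 8-connected component -> column-wise amplitude extraction.
Coordinate convention, used everywhere: row 0 is the image top, amplitude
increases upward, columns map to time left to right. The pixel-to-seconds
calibration is never guessed; callers pass ``columns_per_second``
explicitly or the trace carries one sample per column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synthetic import ECGTrace


class NoTraceFoundError(ValueError):
    """Raised when a mask or component contains no foreground pixels."""


@dataclass(frozen=True)
class DigitizerConfig:
    blur_kernel: int = 3            # odd, pixels
    blur_sigma: float = 0.6         # pixels
    adaptive_block_size: int = 31   # odd, pixels
    adaptive_offset: float = 30.0   # intensity units
    trace_polarity: str = "dark_on_light"
    column_reducer: str = "mean_row"
    gap_fill: str = "linear_interpolation"

    def __post_init__(self):
        for name in ("blur_kernel", "adaptive_block_size"):
            v = getattr(self, name)
            if v < 3 or v % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 3")
        if self.trace_polarity not in ("dark_on_light", "light_on_dark"):
            raise ValueError("trace_polarity invalid")
        if self.column_reducer not in ("mean_row", "median_row", "topmost_row"):
            raise ValueError("column_reducer invalid")
        if self.gap_fill not in ("linear_interpolation", "hold_last"):
            raise ValueError("gap_fill invalid")


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Reduce a 1- or 3-channel image to one channel (luminance weights
    0.299, 0.587, 0.114); already-grayscale input is returned unchanged."""
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("image is empty")
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] == 1:
        return img[:, :, 0]
    if img.ndim == 3 and img.shape[2] == 3:
        y = img[..., 0] * 0.299 + img[..., 1] * 0.587 + img[..., 2] * 0.114
        return np.round(y).astype(np.uint8) if np.issubdtype(
            img.dtype, np.integer) else y
    raise ValueError("image must have 1 or 3 channels")


def binarize(gray: np.ndarray, cfg: DigitizerConfig = DigitizerConfig()) -> np.ndarray:
    """Gaussian blur then adaptive threshold against the local block mean.

    A pixel is foreground iff its polarity-adjusted intensity lies more
    than ``adaptive_offset`` below the local mean (dark-on-light) or above
    it (light-on-dark). Output values are in {0, 1}.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError("binarize expects a single-channel image")
    if cfg.adaptive_block_size > min(gray.shape):
        raise ValueError("adaptive_block_size larger than the image")
    radius = (cfg.blur_kernel - 1) // 2
    blurred = ndimage.gaussian_filter(
        gray, sigma=cfg.blur_sigma, truncate=radius / max(cfg.blur_sigma, 1e-9),
        mode="nearest")
    local_mean = ndimage.uniform_filter(
        blurred, size=cfg.adaptive_block_size, mode="nearest")
    if cfg.trace_polarity == "dark_on_light":
        mask = blurred < local_mean - cfg.adaptive_offset
    else:
        mask = blurred > local_mean + cfg.adaptive_offset
    return mask.astype(np.uint8)


def largest_contour(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component.

    Ties on pixel count are broken toward the component whose smallest
    row-major pixel index is smallest.
    """
    mask = np.asarray(mask)
    if not mask.any():
        raise NoTraceFoundError("no trace found: mask has no foreground")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 1:
        return (labels == 1).astype(np.uint8)
    flat = labels.ravel()
    counts = np.bincount(flat)[1:]
    best = np.flatnonzero(counts == counts.max()) + 1
    if best.size == 1:
        keep = best[0]
    else:  # tie-break: earliest first pixel in row-major order
        firsts = {lab: np.argmax(flat == lab) for lab in best}
        keep = min(best, key=lambda lab: firsts[lab])
    return (labels == keep).astype(np.uint8)


def extract_trace(component: np.ndarray,
                  cfg: DigitizerConfig = DigitizerConfig(),
                  columns_per_second: float | None = None) -> ECGTrace:
    """One amplitude per column: ``image_height - 1 - reduced_row``.

    Columns with no foreground are filled per ``cfg.gap_fill``. The
    sampling rate is ``columns_per_second`` if given, else 1 per column.
    """
    comp = np.asarray(component).astype(bool)
    if not comp.any():
        raise NoTraceFoundError("no trace found: component empty")
    h, w = comp.shape
    rows_grid = np.arange(h, dtype=np.float64)
    amps = np.full(w, np.nan)
    counts = comp.sum(axis=0)
    have = counts > 0
    for c in np.flatnonzero(have):
        rr = rows_grid[comp[:, c]]
        if cfg.column_reducer == "mean_row":
            red = rr.mean()
        elif cfg.column_reducer == "median_row":
            red = np.median(rr)
        else:
            red = rr.min()
        amps[c] = (h - 1) - red
    idx = np.flatnonzero(have)
    missing = np.flatnonzero(~have)
    if missing.size:
        if cfg.gap_fill == "linear_interpolation":
            amps[missing] = np.interp(missing, idx, amps[idx])
        else:  # hold_last (leading gap holds the first known value)
            pos = np.searchsorted(idx, missing, side="right") - 1
            amps[missing] = amps[idx[np.clip(pos, 0, idx.size - 1)]]
    fs = columns_per_second if columns_per_second is not None else 1.0
    return ECGTrace(amps, float(fs), origin="digitized")


def digitize(img: np.ndarray, cfg: DigitizerConfig = DigitizerConfig(),
             columns_per_second: float | None = None) -> ECGTrace:
    """Full pipeline: grayscale, binarize, largest component, extract."""
    gray = to_grayscale(img)
    mask = binarize(gray, cfg)
    comp = largest_contour(mask)
    return extract_trace(comp, cfg, columns_per_second)


def read_image(path) -> np.ndarray:
    from imageio.v3 import imread

    img = imread(path)
    if img.ndim == 3 and img.shape[2] == 4:  # drop alpha
        img = img[:, :, :3]
    return img
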