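"""Fiducial-point detection and the per-record N x 5 feature matrix.

R peaks are found with a Pan-Tompkins-style detector: first-difference
band emphasis, squaring, 150 ms moving-window integration, an adaptive
threshold at half the running mean of accepted integrated peaks and a
200 ms refractory period; the reported index is the raw-trace maximum
inside each detection window. Per beat the extractor then reads the
P-wave amplitude (window R-200..R-80 ms), the QRS peak-to-peak value and
the QRS maximum (window R+-60 ms). The record's feature lists are packed
into a zero-padded N x 5 matrix with columns

    [RR interval (s), P value, QRS value, QRS peak index, QRS max amplitude]

where N is the longest list length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .synthetic import ECGTrace

FEATURE_COLUMNS = ("rr_interval_s", "p_value", "qrs_value",
                   "qrs_peak_index", "qrs_max_amplitude")

INTEGRATION_S = 0.150
REFRACTORY_S = 0.200
P_WINDOW_S = (-0.200, -0.080)
QRS_HALF_S = 0.060


@dataclass
class FiducialSet:
    r_peak_indices: np.ndarray
    rr_intervals: np.ndarray
    p_values: np.ndarray
    qrs_values: np.ndarray
    qrs_max_amplitudes: np.ndarray
    sampling_rate: float


def detect_r_peaks(trace: ECGTrace) -> np.ndarray:
    """Derivative-emphasis QRS detector; returns R-peak sample indices."""
    x = trace.samples
    fs = trace.sampling_rate
    win = max(1, round(INTEGRATION_S * fs))
    refr = max(1, round(REFRACTORY_S * fs))
    if x.size <= win:
        warnings.warn("trace shorter than the integration window")
        return np.array([], dtype=int)
    # band emphasis: short moving-average lowpass (20 ms) suppresses
    # wideband noise before the first-difference high-pass
    lp = max(1, round(0.020 * fs))
    xs = np.convolve(x, np.ones(lp) / lp, mode="same")
    d = np.diff(xs)
    sq = d * d
    integ = np.convolve(sq, np.ones(win) / win, mode="same")
    cand, _ = find_peaks(integ, distance=refr)
    if cand.size == 0:
        return np.array([], dtype=int)
    heights = integ[cand]
    half = win // 2

    def local_slope(c):
        lo, hi = max(0, c - half), min(d.size, c + half + 1)
        return np.abs(d[lo:hi]).max()

    # adaptive threshold: accept candidates above 0.5x the running mean
    # of accepted integrated peak heights, seeded by the strongest peak;
    # candidates within 360 ms of the last beat whose steepest slope is
    # under half the previous beat's are T waves / noise and are skipped
    running = heights.max()
    twave_win = round(0.360 * fs)
    accepted: list[int] = []
    last_slope = np.inf
    for c, h in zip(cand, heights):
        if h < 0.5 * running:
            continue
        slope = local_slope(c)
        if accepted and c - accepted[-1] < twave_win and slope < 0.5 * last_slope:
            continue
        accepted.append(c)
        last_slope = slope
        running = 0.875 * running + 0.125 * h
    peaks = []
    half = win // 2
    for c in accepted:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        peaks.append(lo + int(np.argmax(x[lo:hi])))
    peaks = np.unique(peaks)
    # enforce the refractory period on the final indices, keeping the
    # taller raw-amplitude peak of any colliding pair
    out: list[int] = []
    for p in peaks:
        if out and p - out[-1] < refr:
            if x[p] > x[out[-1]]:
                out[-1] = int(p)
        else:
            out.append(int(p))
    return np.asarray(out, dtype=int)


def compute_rr(r_peak_indices, sampling_rate: float) -> np.ndarray:
    """Successive R-peak differences in seconds; [] for < 2 peaks."""
    idx = np.asarray(r_peak_indices)
    if idx.size < 2:
        return np.array([], dtype=float)
    return np.diff(idx) / float(sampling_rate)


def locate_waves(trace: ECGTrace, r_peak_indices) -> FiducialSet:
    """Per-beat P amplitude and QRS summaries; edge windows are clipped."""
    x = trace.samples
    fs = trace.sampling_rate
    idx = np.asarray(r_peak_indices, dtype=int)
    p_vals, qrs_vals, qrs_max = [], [], []
    for r in idx:
        plo = max(0, r + round(P_WINDOW_S[0] * fs))
        phi = max(plo + 1, min(x.size, r + round(P_WINDOW_S[1] * fs)))
        p_vals.append(x[plo:phi].max())
        qlo = max(0, r - round(QRS_HALF_S * fs))
        qhi = min(x.size, r + round(QRS_HALF_S * fs) + 1)
        seg = x[qlo:qhi]
        qrs_vals.append(seg.max() - seg.min())
        qrs_max.append(seg.max())
    return FiducialSet(
        r_peak_indices=idx,
        rr_intervals=compute_rr(idx, fs),
        p_values=np.asarray(p_vals),
        qrs_values=np.asarray(qrs_vals),
        qrs_max_amplitudes=np.asarray(qrs_max),
        sampling_rate=fs,
    )


def build_matrix(f: FiducialSet) -> np.ndarray:
    """Zero-padded N x 5 matrix; N is the longest feature-list length."""
    cols = [np.asarray(f.rr_intervals, dtype=float),
            np.asarray(f.p_values, dtype=float),
            np.asarray(f.qrs_values, dtype=float),
            np.asarray(f.r_peak_indices, dtype=float),
            np.asarray(f.qrs_max_amplitudes, dtype=float)]
    n = max((c.size for c in cols), default=0)
    if n == 0:
        warnings.warn("no features extracted; returning a 1x5 zero matrix")
        return np.zeros((1, 5))
    out = np.zeros((n, 5))
    for j, c in enumerate(cols):
        out[:c.size, j] = c
    return out


def extract_features(trace: ECGTrace) -> np.ndarray:
    """trace -> N x 5 feature matrix (detection, delineation, packing)."""
    return build_matrix(locate_waves(trace, detect_r_peaks(trace)))


def write_features_csv(matrix: np.ndarray, path) -> None:
    header = ",".join(FEATURE_COLUMNS)
    np.savetxt(path, matrix, delimiter=",", header=header, comments="")
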