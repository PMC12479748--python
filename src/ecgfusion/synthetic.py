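"""Synthetic single-lead ECG generation with ground-truth fiducials.

Each heartbeat is a sum of five Gaussian bumps (P, Q, R, S, T) whose
amplitudes, widths and offsets relative to the R peak are set by a
:class:`BeatMorphology`. Beats repeat at the spacing implied by the heart
rate; Gaussian noise and low-frequency baseline wander can be added on
top. Two presets encode the study's class contrast: the positive class
has a widened, higher-amplitude QRS complex (the ventricular-hypertrophy
signature), the negative class a textbook-normal beat. Waveforms can be
rasterized as plot images — dark trace on a light background with an
optional grid — so the image-digitization front end has labeled inputs.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

WAVES = ("P", "Q", "R", "S", "T")

LABEL_POSITIVE = "le_positive"
LABEL_NEGATIVE = "le_negative"


@dataclass(frozen=True)
class BeatMorphology:
    """Gaussian-bump beat template: per-wave amplitude (mV), width (s, as
    the Gaussian sigma) and center offset relative to the R peak (s)."""

    amplitudes: dict = field(default_factory=dict)
    widths: dict = field(default_factory=dict)
    offsets: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in WAVES:
            for d, what in ((self.amplitudes, "amplitude"),
                            (self.widths, "width"),
                            (self.offsets, "offset")):
                if name not in d:
                    raise ValueError(f"missing {what} for wave {name}")
        for name, w in self.widths.items():
            if w <= 0:
                raise ValueError(f"width for wave {name} must be > 0")

    def qrs_width(self):
        """Aggregate QRS duration proxy: sum of Q, R, S sigmas."""
        return sum(self.widths[w] for w in ("Q", "R", "S"))


def normal_morphology() -> BeatMorphology:
    return BeatMorphology(
        amplitudes={"P": 0.15, "Q": -0.10, "R": 1.0, "S": -0.18, "T": 0.30},
        widths={"P": 0.030, "Q": 0.010, "R": 0.012, "S": 0.010, "T": 0.060},
        offsets={"P": -0.14, "Q": -0.030, "R": 0.0, "S": 0.030, "T": 0.25},
    )


def qrs_wide_morphology() -> BeatMorphology:
    """Positive-class preset: QRS widened 1.6x and R amplitude raised 1.5x."""
    m = normal_morphology()
    amps = dict(m.amplitudes)
    widths = dict(m.widths)
    amps["R"] = m.amplitudes["R"] * 1.5
    amps["Q"] = m.amplitudes["Q"] * 1.4
    amps["S"] = m.amplitudes["S"] * 1.4
    for w in ("Q", "R", "S"):
        widths[w] = m.widths[w] * 1.6
    return BeatMorphology(amplitudes=amps, widths=widths, offsets=dict(m.offsets))


PRESETS = {LABEL_POSITIVE: qrs_wide_morphology, LABEL_NEGATIVE: normal_morphology}


@dataclass(frozen=True)
class SyntheticECGSpec:
    heart_rate: float = 75.0          # beats / minute
    sampling_rate: float = 250.0      # Hz
    duration: float = 10.0            # seconds
    noise_sd: float = 0.0             # additive Gaussian noise, mV
    baseline_wander_amp: float = 0.0  # sinusoidal drift amplitude, mV
    class_label: str = LABEL_NEGATIVE
    seed: int = 0

    def __post_init__(self):
        if not 30.0 <= self.heart_rate <= 220.0:
            raise ValueError("heart_rate must lie in [30, 220] bpm")
        if self.sampling_rate < 100.0:
            raise ValueError("sampling_rate must be >= 100 Hz")
        if self.duration <= 2.0 / (self.heart_rate / 60.0):
            raise ValueError("duration must exceed two beat periods")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.class_label not in PRESETS:
            raise ValueError(f"class_label must be one of {sorted(PRESETS)}")


@dataclass
class BeatAnnotations:
    """Ground-truth fiducials: R-peak sample indices, RR intervals (s) and
    half-open [start, stop) sample windows for the P, QRS and T waves."""

    r_peak_indices: np.ndarray
    rr_intervals: np.ndarray
    p_windows: list
    qrs_windows: list
    t_windows: list

    def to_dict(self):
        return {
            "r_peak_indices": [int(i) for i in self.r_peak_indices],
            "rr_intervals": [float(v) for v in self.rr_intervals],
            "p_windows": [[int(a), int(b)] for a, b in self.p_windows],
            "qrs_windows": [[int(a), int(b)] for a, b in self.qrs_windows],
            "t_windows": [[int(a), int(b)] for a, b in self.t_windows],
        }


@dataclass
class ECGTrace:
    samples: np.ndarray
    sampling_rate: float
    origin: str = "synthetic"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.size < 1:
            raise ValueError("trace must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite values")


@dataclass(frozen=True)
class RenderSpec:
    image_height: int = 256
    image_width: int = 1280
    trace_thickness: int = 2
    grid: bool = False
    grid_spacing: int = 24
    background: int = 255
    foreground: int = 0
    grid_intensity: int = 215
    margin: int = 10

    def __post_init__(self):
        if self.image_height < 64 or self.image_width < 64:
            raise ValueError("image dimensions must be >= 64 px")
        if self.foreground >= self.background:
            raise ValueError("foreground intensity must be below background")


# QRS half-window and P/T windows relative to R, in seconds; these match
# the delineation windows the feature extractor uses downstream.
QRS_HALF = 0.060
P_WIN = (-0.200, -0.080)
T_WIN = (0.100, 0.420)


def generate_waveform(spec: SyntheticECGSpec, morph: BeatMorphology | None = None):
    """Synthesize one record; returns ``(ECGTrace, BeatAnnotations)``."""
    if morph is None:
        morph = PRESETS[spec.class_label]()
    fs = spec.sampling_rate
    n = round(spec.duration * fs)
    t = np.arange(n) / fs
    period = 60.0 / spec.heart_rate
    first_r = 0.36 * period
    n_beats = int(np.floor((spec.duration - first_r - 1.0 / fs) / period)) + 1
    r_times = first_r + period * np.arange(n_beats)

    x = np.zeros(n)
    for rt in r_times:
        for w in WAVES:
            a, s, off = morph.amplitudes[w], morph.widths[w], morph.offsets[w]
            x += a * np.exp(-0.5 * ((t - rt - off) / s) ** 2)

    rng = np.random.default_rng(spec.seed)
    if spec.baseline_wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x = x + spec.baseline_wander_amp * np.sin(2 * np.pi * 0.33 * t + phase)
    if spec.noise_sd > 0:
        x = x + rng.normal(0.0, spec.noise_sd, size=n)

    r_idx = np.round(r_times * fs).astype(int)

    def window(lo, hi):
        return [(max(0, int(np.round((rt + lo) * fs))),
                 min(n, int(np.round((rt + hi) * fs)))) for rt in r_times]

    ann = BeatAnnotations(
        r_peak_indices=r_idx,
        rr_intervals=np.diff(r_idx) / fs,
        p_windows=window(*P_WIN),
        qrs_windows=window(-QRS_HALF, QRS_HALF),
        t_windows=window(*T_WIN),
    )
    return ECGTrace(x, fs, origin="synthetic"), ann


def render_image(trace: ECGTrace, rs: RenderSpec = RenderSpec()) -> np.ndarray:
    """Rasterize a trace as an 8-bit grayscale plot image.

    The trace's [min, max] range maps affinely onto the vertical plotting
    region with the maximum at the top; samples map to columns left to
    right. A constant trace draws as a horizontal line at mid-plot.
    """
    h, w, m = rs.image_height, rs.image_width, rs.margin
    img = np.full((h, w), rs.background, dtype=np.uint8)
    if rs.grid:
        img[m:h - m:rs.grid_spacing, :] = rs.grid_intensity
        img[:, m:w - m:rs.grid_spacing] = rs.grid_intensity

    x = trace.samples
    cols = np.arange(m, w - m)
    src = np.linspace(0, x.size - 1, cols.size)
    y = np.interp(src, np.arange(x.size), x)
    lo, hi = y.min(), y.max()
    top, bot = m, h - 1 - m
    if hi - lo < 1e-12:
        rows = np.full(cols.size, (top + bot) // 2, dtype=int)
    else:
        rows = np.round(bot - (y - lo) / (hi - lo) * (bot - top)).astype(int)

    half = max(0, (rs.trace_thickness - 1) // 2)
    extra = rs.trace_thickness - 1 - half
    for i, c in enumerate(cols):
        r = rows[i]
        r2 = rows[i + 1] if i + 1 < cols.size else r
        a, b = min(r, r2), max(r, r2)
        img[max(0, a - half):min(h, b + 1 + extra), c] = rs.foreground
    return img


@dataclass
class DatasetRecord:
    image: np.ndarray
    trace: ECGTrace
    annotations: BeatAnnotations
    label: str
    seed: int
    morphology: BeatMorphology


def make_dataset(n_per_class: int, seed: int = 0, *, noise_sd: float = 0.05,
                 baseline_wander_amp: float = 0.02, heart_rate: float = 75.0,
                 sampling_rate: float = 250.0, duration: float = 10.0,
                 render_spec: RenderSpec = RenderSpec(),
                 jitter_heart_rate: float = 5.0) -> list[DatasetRecord]:
    """Generate a balanced two-class labeled collection.

    Heart rate is jittered per record (uniform ±``jitter_heart_rate`` bpm)
    so records are not copies of one another; every record is fully
    reproducible from ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    master = np.random.default_rng(seed)
    records = []
    for label in (LABEL_POSITIVE, LABEL_NEGATIVE):
        for _ in range(n_per_class):
            rec_seed = int(master.integers(0, 2 ** 31 - 1))
            hr = heart_rate + float(
                np.random.default_rng(rec_seed + 1).uniform(-jitter_heart_rate,
                                                            jitter_heart_rate))
            spec = SyntheticECGSpec(
                heart_rate=hr, sampling_rate=sampling_rate, duration=duration,
                noise_sd=noise_sd, baseline_wander_amp=baseline_wander_amp,
                class_label=label, seed=rec_seed)
            morph = PRESETS[label]()
            trace, ann = generate_waveform(spec, morph)
            img = render_image(trace, render_spec)
            records.append(DatasetRecord(img, trace, ann, label, rec_seed, morph))
    return records


def dataset_hash(records) -> str:
    """Stable content hash of a dataset (traces, labels, images)."""
    h = hashlib.sha256()
    for r in records:
        h.update(r.label.encode())
        h.update(np.ascontiguousarray(r.trace.samples).tobytes())
        h.update(np.ascontiguousarray(r.image).tobytes())
    return h.hexdigest()


# ------------------------------------------------------------------ file IO

def write_trace_csv(trace: ECGTrace, path):
    t = np.arange(trace.samples.size) / trace.sampling_rate
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["time_s", "amplitude"])
        for ti, xi in zip(t, trace.samples):
            wr.writerow([f"{ti:.9g}", f"{xi:.9g}"])


def read_trace_csv(path) -> ECGTrace:
    data = np.genfromtxt(path, delimiter=",", skip_header=1)
    data = np.atleast_2d(data)
    t, x = data[:, 0], data[:, 1]
    fs = 1.0 / np.median(np.diff(t)) if t.size > 1 else 1.0
    return ECGTrace(x, float(fs), origin="synthetic")


def write_dataset(records, out_dir) -> Path:
    """Write PNG images, CSV traces, JSON annotations and a manifest."""
    from imageio.v3 import imwrite

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, r in enumerate(records):
        stem = f"rec{i:04d}"
        imwrite(out / f"{stem}.png", r.image)
        write_trace_csv(r.trace, out / f"{stem}.csv")
        (out / f"{stem}.json").write_text(json.dumps(r.annotations.to_dict()))
        manifest.append({"id": stem, "label": r.label, "seed": r.seed,
                         "image": f"{stem}.png", "trace": f"{stem}.csv",
                         "annotations": f"{stem}.json"})
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath
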