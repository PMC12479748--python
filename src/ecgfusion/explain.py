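"""Grad-CAM heatmaps and quantitative region-attention metrics.

Grad-CAM weights each channel of a chosen convolutional activation by
the spatial mean of the class-score gradient, sums the weighted maps,
rectifies, upsamples bilinearly to the input grid and min-max normalizes
to [0, 1]. Two metrics quantify agreement with expected diagnostic
zones: Region Attention Accuracy (RAA), the percentage of samples whose
most-activated connected region touches an expected zone, and QRS
overlap, the fraction of activated area inside the QRS zone. On
synthetic data the generator's ground-truth windows stand in for expert
zone annotation, so the metrics measure ground-truth agreement rather
than expert agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _resize

from .spectrogram import IMAGE_SIZE, SpectrogramConfig


@dataclass(frozen=True)
class Box:
    """Axis-aligned zone in input coordinates, half-open on both axes."""
    label: str
    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self):
        if not self.label:
            raise ValueError("box label must be non-empty")
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ValueError("box must have positive extent")


@dataclass
class RegionAnnotation:
    boxes: list
    shape: tuple

    def mask(self, label: str | None = None) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for b in self.boxes:
            if label is None or b.label == label:
                out[max(0, b.row_start):b.row_stop,
                    max(0, b.col_start):b.col_stop] = True
        return out


def grad_cam(model, image: np.ndarray, target_class: int) -> np.ndarray:
    """Heatmap in [0, 1] on the model's input spatial grid.

    ``model`` must expose ``prepare`` and ``logits_with_activation``
    (activations and gradients at the chosen convolutional layer). A
    constant (fully rectified-away) map returns all zeros with a warning.
    """
    x = model.prepare(image)
    logits, act = model.logits_with_activation(x)
    if act.data.ndim != 4:
        raise ValueError("Grad-CAM layer must have spatial extent")
    score = logits[0, int(target_class)]
    score.backward()
    weights = act.grad[0].mean(axis=(1, 2))            # per-channel
    cam = np.maximum((weights[:, None, None] * act.data[0]).sum(axis=0), 0.0)
    spatial = np.asarray(image).shape[:2]
    cam = _resize(cam, spatial, order=1, mode="edge", anti_aliasing=False)
    lo, hi = cam.min(), cam.max()
    if hi - lo < 1e-12:
        warnings.warn("constant Grad-CAM map; returning zeros")
        return np.zeros(spatial)
    return (cam - lo) / (hi - lo)


def _top_region(heatmap: np.ndarray, threshold: float) -> np.ndarray:
    """Connected region (8-connectivity) containing the heatmap maximum
    among cells >= threshold."""
    active = heatmap >= threshold
    peak = np.unravel_index(np.argmax(heatmap), heatmap.shape)
    active[peak] = True  # the max always belongs to the activated set
    labels, _ = ndimage.label(active, structure=np.ones((3, 3), dtype=int))
    return labels == labels[peak]


def region_attention_accuracy(heatmaps, annotations,
                              activation_threshold: float = 0.5) -> float:
    """Percentage of samples whose most-activated region intersects any
    expected zone. ``annotations`` holds one RegionAnnotation (or boolean
    zone mask) per heatmap."""
    if len(heatmaps) == 0:
        raise ValueError("empty sample set")
    if len(heatmaps) != len(annotations):
        raise ValueError("one annotation set per heatmap required")
    hits = 0
    for hm, ann in zip(heatmaps, annotations):
        zone = ann.mask() if isinstance(ann, RegionAnnotation) else np.asarray(ann)
        if _top_region(np.asarray(hm), activation_threshold)[zone].any():
            hits += 1
    return 100.0 * hits / len(heatmaps)


def qrs_overlap(heatmap: np.ndarray, qrs_zone_mask: np.ndarray,
                activation_threshold: float = 0.5) -> float:
    """100 * |activated cells inside the QRS zone| / |activated cells|."""
    hm = np.asarray(heatmap)
    mask = np.asarray(qrs_zone_mask).astype(bool)
    if hm.shape != mask.shape:
        raise ValueError("mask shape must match heatmap shape")
    active = hm >= activation_threshold
    n_active = int(active.sum())
    if n_active == 0:
        warnings.warn("no cell passes the activation threshold")
        return 0.0
    return 100.0 * int((active & mask).sum()) / n_active


def summarize_metrics(per_sample: dict) -> dict:
    """{"metric": values} -> {"metric": {"mean": .., "sd": ..}} with the
    sample (ddof=1) standard deviation; sd omitted for n < 2."""
    out = {}
    for name, vals in per_sample.items():
        v = np.asarray(vals, dtype=float)
        entry = {"mean": float(v.mean()), "n": int(v.size)}
        if v.size >= 2:
            entry["sd"] = float(v.std(ddof=1))
        else:
            warnings.warn(f"{name}: fewer than 2 samples; sd omitted")
        out[name] = entry
    return out


# ------------------------------------------- fiducial zones -> image boxes

def zones_to_image_annotation(annotations, trace_fs: float, n_samples: int,
                              cfg: SpectrogramConfig = SpectrogramConfig(),
                              image_size: int = IMAGE_SIZE) -> RegionAnnotation:
    """Map time-domain fiducial windows into spectrogram-image columns.

    A trace sample maps to an audio sample by the resampling ratio, to a
    frame via the hop length, and to an image column by the frame-axis
    resize; zones span all frequency rows.
    """
    ratio = cfg.sampling_rate / trace_fs
    n_audio = int(round(n_samples * ratio))
    n_frames = 1 + n_audio // cfg.hop_length

    def col(sample):
        return int(np.clip(round(sample * ratio / cfg.hop_length
                                 / n_frames * image_size), 0, image_size))

    boxes = []
    for name, windows in (("QRS", annotations.qrs_windows),
                          ("P", annotations.p_windows),
                          ("T", annotations.t_windows)):
        for a, b in windows:
            c0, c1 = col(a), col(b)
            if c1 > c0:
                boxes.append(Box(name, 0, image_size, c0, c1))
    return RegionAnnotation(boxes, (image_size, image_size))


def permutation_qrs_test(heatmaps, qrs_masks, n_permutations: int = 200,
                         seed: int = 0,
                         activation_threshold: float = 0.5) -> dict:
    """Is mean QRS overlap higher than chance placement of the QRS zones?

    The null distribution circularly shifts each QRS mask along the time
    axis by a random offset and recomputes the mean overlap. Returns the
    observed mean, the QRS area fraction, and the permutation p-value
    (1 + #null >= observed) / (1 + n_permutations).
    """
    heatmaps = [np.asarray(h) for h in heatmaps]
    masks = [np.asarray(m).astype(bool) for m in qrs_masks]
    obs = float(np.mean([qrs_overlap(h, m, activation_threshold)
                         for h, m in zip(heatmaps, masks)]))
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        vals = []
        for h, m in zip(heatmaps, masks):
            shift = int(rng.integers(0, m.shape[1]))
            vals.append(qrs_overlap(h, np.roll(m, shift, axis=1),
                                    activation_threshold))
        null[i] = np.mean(vals)
    p = (1 + int(np.sum(null >= obs))) / (1 + n_permutations)
    area_fraction = float(np.mean([m.mean() for m in masks]))
    return {"observed_mean_overlap": obs, "null_mean": float(null.mean()),
            "p_value": p, "qrs_area_fraction_pct": 100.0 * area_fraction}
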