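"""Pixel classification: background vs chromatophore (optionally by color).

Two built-in classifiers behind a common interface: a color lookup
table (every representable quantized color pre-assigned to the class of
its nearest training sample) and a random forest on per-pixel
color + multi-scale texture features.  Predictions of several
classifiers can be fused by per-pixel majority vote.  The interface
admits heavier learned models; none are shipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import color as skcolor
from skimage import morphology

log = logging.getLogger("chromatrack.segmentation")

COLOR_LABELS = {0: "background", 1: "dark", 2: "orange", 3: "yellow"}


def _to_space(rgb01: np.ndarray, space: str) -> np.ndarray:
    """RGB in [0,1] -> coordinates in the requested color space."""
    if space == "RGB":
        return rgb01 * 255.0
    if space == "HSV":
        return skcolor.rgb2hsv(rgb01) * np.array([360.0, 100.0, 100.0])
    if space == "Lab":
        return skcolor.rgb2lab(rgb01)
    raise ValueError(f"unknown color space {space!r}")


class PixelClassifier:
    """Interface: fit(frames, labels) -> self; predict(frame) -> mask.

    predict must be deterministic after fit.
    """

    def fit(self, frames, label_images) -> "PixelClassifier":
        raise NotImplementedError

    def predict(self, frame: np.ndarray) -> np.ndarray:
        raise NotImplementedError


@dataclass
class ColorLookupTable(PixelClassifier):
    """Total map from quantized 8-bit RGB to a class label.

    ``quantization`` levels per channel; an RGB pixel is binned by
    integer division and looked up, so classification is a pointwise
    function of color, invariant to pixel order.
    """

    color_space: str = "RGB"
    quantization: int = 4
    table: np.ndarray | None = None  # (q, q, q) uint8

    def fit(self, frames, label_images, max_samples_per_class: int = 500) -> "ColorLookupTable":
        cols = np.concatenate([np.asarray(f)[..., :3].reshape(-1, 3) for f in frames])
        labs = np.concatenate([np.asarray(l).ravel() for l in label_images])
        rng = np.random.default_rng(0)  # deterministic subsample
        samples = []
        for lab in np.unique(labs):
            idx = np.nonzero(labs == lab)[0]
            if len(idx) > max_samples_per_class:
                idx = rng.choice(idx, max_samples_per_class, replace=False)
            samples.extend((tuple(cols[i].tolist()), int(lab)) for i in idx)
        return train_lookup(samples, self.color_space, self.quantization, into=self)

    def predict(self, frame: np.ndarray) -> np.ndarray:
        if self.table is None:
            raise RuntimeError("lookup table not trained")
        frame = np.asarray(frame)
        if frame.ndim != 3 or frame.shape[-1] < 3:
            raise ValueError("lookup classifier needs an RGB frame")
        q = self.quantization
        idx = (frame[..., :3].astype(int) * q) // 256
        idx = np.clip(idx, 0, q - 1)
        return self.table[idx[..., 0], idx[..., 1], idx[..., 2]]


def train_lookup(
    samples: list[tuple[tuple[int, int, int], int]],
    color_space: str = "RGB",
    quantization: int = 4,
    into: ColorLookupTable | None = None,
) -> ColorLookupTable:
    """Build a lookup table from (RGB color, label) samples.

    Every quantized color is assigned the label of its nearest sample in
    the chosen color space (Euclidean distance); exact ties go to the
    lowest label id.
    """
    if not samples:
        raise ValueError("no training samples")
    q = quantization
    cols = np.array([c for c, _ in samples], dtype=float)
    labs = np.array([l for _, l in samples], dtype=int)
    order = np.argsort(labs, kind="stable")  # lowest label wins ties below
    cols, labs = cols[order], labs[order]

    # bin-center representative color of every table cell
    centers = (np.arange(q) + 0.5) * (256.0 / q)
    rr, gg, bb = np.meshgrid(centers, centers, centers, indexing="ij")
    grid = np.stack([rr, gg, bb], axis=-1).reshape(-1, 3)

    grid_cs = _to_space(grid.reshape(-1, 1, 3) / 255.0, color_space).reshape(-1, 3)
    samp_cs = _to_space(cols.reshape(-1, 1, 3) / 255.0, color_space).reshape(-1, 3)
    d2 = ((grid_cs[:, None, :] - samp_cs[None, :, :]) ** 2).sum(-1)
    dmin = d2.min(axis=1, keepdims=True)
    tied = d2 <= dmin + 1e-9
    # first True along sorted-by-label samples = lowest label among ties
    pick = tied.argmax(axis=1)
    table = labs[pick].astype(np.uint8).reshape(q, q, q)

    lut = into or ColorLookupTable(color_space=color_space, quantization=quantization)
    lut.color_space = color_space
    lut.quantization = quantization
    lut.table = table
    return lut


def classify_colors(lut: ColorLookupTable, colors: np.ndarray) -> np.ndarray:
    """Classify an (N, 3) array of RGB colors through the table."""
    return lut.predict(np.asarray(colors, dtype=np.uint8).reshape(1, -1, 3)).ravel()


# ---------------------------------------------------------------------------
# random forest
# ---------------------------------------------------------------------------

def _pixel_features(frame: np.ndarray, scales=(1.0, 2.0, 4.0)) -> np.ndarray:
    """Per-pixel feature stack: raw channels, Gaussian-smoothed channels
    at each scale, and DoG responses between consecutive scales."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim == 2:
        frame = frame[..., None]
    chans = [frame[..., c] for c in range(frame.shape[-1])]
    feats = list(chans)
    for c in chans:
        smoothed = [gaussian_filter(c, s) for s in scales]
        feats.extend(smoothed)
        feats.extend(smoothed[i] - smoothed[i + 1] for i in range(len(smoothed) - 1))
    return np.stack(feats, axis=-1)


class RandomForestPixelClassifier(PixelClassifier):
    def __init__(self, scales=(1.0, 2.0, 4.0), n_estimators: int = 50,
                 max_depth: int | None = 12, seed: int = 0,
                 max_train_pixels: int = 200_000):
        self.scales = tuple(scales)
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.seed = seed
        self.max_train_pixels = max_train_pixels
        self._forest = None

    def fit(self, frames, label_images) -> "RandomForestPixelClassifier":
        from sklearn.ensemble import RandomForestClassifier

        xs, ys = [], []
        for fr, lab in zip(frames, label_images):
            f = _pixel_features(fr, self.scales)
            xs.append(f.reshape(-1, f.shape[-1]))
            ys.append(np.asarray(lab).ravel())
        X = np.concatenate(xs)
        y = np.concatenate(ys)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        if len(y) > self.max_train_pixels:
            rng = np.random.default_rng(self.seed)
            sel = rng.choice(len(y), self.max_train_pixels, replace=False)
            X, y = X[sel], y[sel]
        self._forest = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            random_state=self.seed,
            n_jobs=1,
        ).fit(X, y)
        return self

    def predict(self, frame: np.ndarray) -> np.ndarray:
        if self._forest is None:
            raise RuntimeError("classifier not fitted")
        f = _pixel_features(frame, self.scales)
        pred = self._forest.predict(f.reshape(-1, f.shape[-1]))
        return pred.reshape(f.shape[:2]).astype(np.uint8)


# ---------------------------------------------------------------------------
# fusion and application
# ---------------------------------------------------------------------------

def majority_vote(masks: list[np.ndarray]) -> np.ndarray:
    """Per-pixel modal label over >= 2 masks; ties go to background (0)."""
    if len(masks) < 2:
        raise ValueError("majority vote needs at least two masks")
    masks = [np.asarray(m) for m in masks]
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("mask shapes differ")
    labels = np.unique(np.concatenate([np.unique(m) for m in masks]))
    counts = np.zeros((len(labels), *shape), dtype=np.int32)
    for m in masks:
        for i, lab in enumerate(labels):
            counts[i] += m == lab
    best = counts.max(axis=0)
    out = np.zeros(shape, dtype=masks[0].dtype)
    winner_idx = counts.argmax(axis=0)
    n_at_best = (counts == best).sum(axis=0)
    unique_winner = n_at_best == 1
    out[unique_winner] = labels[winner_idx[unique_winner]]
    return out  # ties stay at 0 = background


def remove_small_components(mask: np.ndarray, min_px: int) -> np.ndarray:
    if min_px <= 0:
        return mask
    binary = mask > 0
    keep = morphology.remove_small_objects(binary, max_size=min_px - 1)
    out = mask.copy()
    out[~keep] = 0
    return out


def segment_video(frames, classifier: PixelClassifier, min_component_px: int = 0) -> np.ndarray:
    """One label mask per frame, stacked as (T, H, W) uint8."""
    masks = []
    for fr in frames:
        m = classifier.predict(fr)
        if min_component_px > 0:
            m = remove_small_components(m, min_component_px)
        masks.append(m.astype(np.uint8))
    return np.stack(masks)


def default_lookup_for_synthetic() -> ColorLookupTable:
    """Lookup classifier trained on the generator's nominal palette,
    used as the default segmenter for synthetic footage."""
    samples = [
        ((182, 172, 158), 0), ((200, 190, 175), 0), ((160, 150, 140), 0),
        ((255, 255, 255), 0), ((120, 113, 104), 0),
        ((45, 32, 30), 1), ((20, 15, 15), 1), ((80, 60, 55), 1),
        ((205, 115, 35), 2), ((225, 205, 60), 3),
    ]
    return train_lookup(samples, "RGB", 8)
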