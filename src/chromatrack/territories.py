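"""Chromatophore territories and area time series.

On the global reference frame each chromatophore owns a *territory*:
the region it can occupy, built from the occupancy (fraction of valid
frames in which each reference pixel is classified chromatophore).
Territories are disjoint by construction — the occupancy footprint is
thresholded, connected components are labelled, and components housing
several chromatophores are split by marker-based watershed seeded at
the occupancy maxima.  The resulting integer label image is the
*cleanqueen*.  Per-frame areas are then read off in the original,
unregistered frames: the cleanqueen is pulled through the inverse maps
onto each frame and a chromatophore's area is the pixel count of the
largest connected component of segmented pixels inside its territory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .config import TerritoriesConfig
from .registration import warp_image

log = logging.getLogger("chromatrack.territories")

MISSING = np.nan  # invalid frames carry NaN, never 0


@dataclass
class Cleanqueen:
    labels: np.ndarray  # int32, 0 = background, territory ids >= 1
    color_class: dict[int, str] = field(default_factory=dict)

    @property
    def ids(self) -> np.ndarray:
        u = np.unique(self.labels)
        return u[u > 0]

    def territory_mask(self, tid: int) -> np.ndarray:
        return self.labels == tid

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [(int(t), (self.labels == t).sum(), self.color_class.get(int(t), ""))
             for t in self.ids],
            columns=["territory_id", "territory_px", "color"],
        ).to_csv(path, index=False)


def occupancy_image(registered_masks) -> np.ndarray:
    """Fraction of frames in which each reference pixel is chromatophore."""
    acc = None
    n = 0
    for m in registered_masks:
        b = (np.asarray(m) > 0).astype(np.float32)
        acc = b if acc is None else acc + b
        n += 1
    if n == 0:
        raise ValueError("no registered masks")
    return acc / n


def build_cleanqueen(
    registered_masks=None,
    cfg: TerritoriesConfig | None = None,
    occupancy: np.ndarray | None = None,
    expected_diameter_px: float = 24.0,
) -> Cleanqueen:
    """Territory label map from mask occupancy on the reference frame.

    Threshold the occupancy at ``occupancy_min`` to get the union
    footprint, label its connected components, and split components
    containing several occupancy maxima with a marker-based watershed
    on the inverted occupancy; territories are disjoint and connected.
    """
    cfg = cfg or TerritoriesConfig()
    occ = occupancy if occupancy is not None else occupancy_image(registered_masks)
    fp = occ >= cfg.occupancy_min
    if not fp.any():
        raise ValueError("zero territories: occupancy never reaches occupancy_min")
    comp = cc_label(fp, connectivity=2)
    min_dist = cfg.seed_min_distance_px
    if min_dist is None:
        min_dist = max(int(expected_diameter_px / 2), 3)
    smooth = ndi.gaussian_filter(occ, 1.5)
    seeds_rc = peak_local_max(
        smooth, min_distance=int(min_dist), labels=comp, exclude_border=False
    )
    markers = np.zeros_like(comp)
    for i, (r, c) in enumerate(seeds_rc, start=1):
        markers[r, c] = i
    # components without a detected peak keep one seed at their occupancy max
    have = np.unique(comp[markers > 0])
    for cid in np.setdiff1d(np.unique(comp), np.r_[0, have]):
        sel = comp == cid
        idx = np.argmax(np.where(sel, smooth, -1))
        markers.flat[idx] = markers.max() + 1
    labels = watershed(-smooth, markers=markers, mask=fp, connectivity=2)
    return Cleanqueen(labels=labels.astype(np.int32))


def attach_colors(cq: Cleanqueen, registered_color_masks) -> Cleanqueen:
    """Per-territory modal color class (labels 1/2/3 -> dark/orange/yellow),
    kept as metadata; downstream identity tracking is binary."""
    from .segmentation import COLOR_LABELS

    votes: dict[int, np.ndarray] = {int(t): np.zeros(4) for t in cq.ids}
    for m in registered_color_masks:
        m = np.asarray(m)
        for t in cq.ids:
            sel = (cq.labels == t) & (m > 0)
            if sel.any():
                votes[int(t)] += np.bincount(m[sel], minlength=4)[:4]
    for t, v in votes.items():
        if v[1:].sum() > 0:
            cq.color_class[t] = COLOR_LABELS[int(v[1:].argmax()) + 1]
    return cq


# ---------------------------------------------------------------------------
# area extraction
# ---------------------------------------------------------------------------

@dataclass
class AreaSeries:
    """(chromatophore x frame) areas in px^2; NaN marks invalid frames."""

    ids: np.ndarray          # (C,) territory ids
    areas: np.ndarray        # (C, T) float
    valid: np.ndarray        # (T,) bool

    def row(self, tid: int) -> np.ndarray:
        return self.areas[int(np.nonzero(self.ids == tid)[0][0])]

    def to_tidy(self) -> pd.DataFrame:
        c, t = self.areas.shape
        return pd.DataFrame({
            "frame": np.tile(np.arange(t), c),
            "chromatophore_id": np.repeat(self.ids, t),
            "area_px2": self.areas.ravel(),
            "valid": np.tile(self.valid, c),
        })

    def to_csv(self, path) -> None:
        self.to_tidy().to_csv(path, index=False)


def largest_component_area(mask: np.ndarray) -> int:
    """Pixel count of the largest 8-connected component (0 if empty)."""
    lab, n = ndi.label(mask, structure=np.ones((3, 3), int))
    if n == 0:
        return 0
    return int(np.bincount(lab.ravel())[1:].max())


def frame_areas(seg_mask: np.ndarray, cq_in_frame: np.ndarray,
                ids: np.ndarray) -> np.ndarray:
    """Per-territory area in one unregistered frame."""
    out = np.zeros(len(ids))
    seg = np.asarray(seg_mask) > 0
    for i, tid in enumerate(ids):
        inside = seg & (cq_in_frame == tid)
        out[i] = largest_component_area(inside)
    return out


def area_series(
    masks,
    cleanqueen: Cleanqueen,
    frame_to_ref_fields,
    valid=None,
) -> AreaSeries:
    """Track every territory's area through the unregistered frames.

    ``frame_to_ref_fields`` yields, per frame, the (2, H, W) field of
    reference coordinates (composed registration + stitching), or None
    when the frame has no usable map — such frames are marked invalid
    and carry NaN areas.  The cleanqueen is warped with nearest-neighbor
    sampling (labels are categorical).
    """
    ids = cleanqueen.ids
    rows = []
    flags = []
    for t, (mask, fld) in enumerate(zip(masks, frame_to_ref_fields)):
        if fld is None or (valid is not None and not valid[t]):
            rows.append(np.full(len(ids), MISSING))
            flags.append(False)
            continue
        cq_in_frame = warp_image(cleanqueen.labels, fld, order=0).astype(np.int32)
        rows.append(frame_areas(mask, cq_in_frame, ids))
        flags.append(True)
    return AreaSeries(ids=ids, areas=np.array(rows).T, valid=np.array(flags))
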