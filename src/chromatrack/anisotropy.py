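"""Anisotropic expansion: epicenters, motion markers and radial slices.

A chromatophore's expansion is driven by 10-15 radial muscles, so its
shape change is directional.  To measure it the chromatophore is cut
into ``n_slices`` (default 36, comfortably above the Nyquist rate for
that muscle count) angular sectors around its *epicenter* — the fixed
skin point it expands from, estimated as the center of mass in its most
contracted frame.  Because the skin itself deforms, epicenters cannot
be tracked by optical flow (flow would chase the expanding pigment);
instead, chromatophores that stay small and constant-sized act as inert
fiducials (*motion markers*): each epicenter is stored in barycentric
coordinates (l1, l2, l3) of its enclosing Delaunay triangle of markers,
c = l1*a1 + l2*a2 + l3*a3, which are invariant under the locally affine
skin deformation.  The markers also pin the angular origin of the
slices over time so slice identity is stable.

Slice areas use the discretization-robust estimate area = pi * rbar^2 / n
with rbar the mean distance from the slice's border pixels to the
epicenter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.ndimage import gaussian_filter1d
from scipy.spatial import Delaunay
from skimage import measure

from .config import AnisotropyConfig
from .territories import AreaSeries, Cleanqueen

log = logging.getLogger("chromatrack.anisotropy")


# ---------------------------------------------------------------------------
# motion markers
# ---------------------------------------------------------------------------

@dataclass
class MotionMarkerSet:
    ids: np.ndarray              # (n,) territory ids
    ref_positions: np.ndarray    # (n, 2) reference-frame (row, col)
    positions: np.ndarray        # (T, n, 2) per-frame positions, NaN if lost
    triangulation: Delaunay

    @property
    def triangles(self) -> np.ndarray:
        return self.triangulation.simplices

    def frame_vertices(self, t: int, simplex: np.ndarray) -> np.ndarray:
        return self.positions[t][simplex]


def select_motion_markers(
    areas: AreaSeries,
    size_max: float | None = None,
    cv_max: float = 0.1,
) -> np.ndarray:
    """Territory ids of small, constant-sized chromatophores.

    size_max defaults to the 25th percentile of mean areas; a marker
    must additionally have a coefficient of variation <= cv_max.
    """
    mean = np.nanmean(areas.areas, axis=1)
    std = np.nanstd(areas.areas, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, std / mean, np.inf)
    if size_max is None:
        size_max = float(np.percentile(mean, 25))
    sel = (mean <= size_max) & (cv <= cv_max) & (mean > 0)
    ids = areas.ids[sel]
    if len(ids) < 3:
        raise ValueError(
            f"only {len(ids)} motion markers found (need >= 3 for a "
            "triangulation); increase cv_max or size_max"
        )
    return ids


def _territory_com(seg: np.ndarray, cq_frame: np.ndarray, tid: int) -> np.ndarray:
    inside = (np.asarray(seg) > 0) & (cq_frame == tid)
    if not inside.any():
        return np.array([np.nan, np.nan])
    lab, n = ndi.label(inside, structure=np.ones((3, 3), int))
    if n > 1:
        big = 1 + np.argmax(np.bincount(lab.ravel())[1:])
        inside = lab == big
    return np.array(ndi.center_of_mass(inside))


def build_marker_set(
    marker_ids: np.ndarray,
    masks,
    cq_frames,
    cleanqueen: Cleanqueen,
) -> MotionMarkerSet:
    """Per-frame marker centers (mask center of mass within the warped
    territory) plus the Delaunay triangulation of reference positions."""
    marker_ids = np.asarray(marker_ids)
    ref = np.array([
        ndi.center_of_mass(cleanqueen.labels == t) for t in marker_ids
    ])
    pos = []
    for seg, cq in zip(masks, cq_frames):
        if cq is None:
            pos.append(np.full((len(marker_ids), 2), np.nan))
            continue
        pos.append(np.array([_territory_com(seg, cq, t) for t in marker_ids]))
    tri = Delaunay(ref)
    return MotionMarkerSet(ids=marker_ids, ref_positions=ref,
                           positions=np.array(pos), triangulation=tri)


# ---------------------------------------------------------------------------
# barycentric coordinates
# ---------------------------------------------------------------------------

def to_barycentric(point, vertices) -> np.ndarray:
    """Solve p = l1*a1 + l2*a2 + l3*a3 with l1+l2+l3 = 1 (closed form).

    Points outside the triangle get some negative weight; the affine
    identity from_barycentric(to_barycentric(p)) = p holds regardless.
    """
    a1, a2, a3 = (np.asarray(v, float) for v in vertices)
    T = np.column_stack([a1 - a3, a2 - a3])
    det = np.linalg.det(T)
    if abs(det) < 1e-12:
        raise ValueError("degenerate (collinear) triangle")
    l12 = np.linalg.solve(T, np.asarray(point, float) - a3)
    return np.array([l12[0], l12[1], 1.0 - l12.sum()])


def from_barycentric(lambdas, vertices) -> np.ndarray:
    lam = np.asarray(lambdas, float)
    verts = np.asarray(vertices, float)
    return lam @ verts


@dataclass
class Epicenter:
    id: int
    ref_position: np.ndarray      # (row, col) on the reference frame
    simplex: np.ndarray           # indices into the marker set (3,)
    lambdas: np.ndarray           # (3,), sums to 1

    def __post_init__(self):
        assert abs(self.lambdas.sum() - 1.0) < 1e-9


def compute_epicenter(
    territory_masks,
    areas_row: np.ndarray,
    to_ref=None,
) -> np.ndarray:
    """Center of mass at the most contracted frame, in reference coords.

    frame* = argmin of the valid nonzero areas (ties -> earliest); the
    epicenter is the largest component's center of mass there, mapped
    through ``to_ref(t, point)`` when the masks are unregistered.
    """
    areas_row = np.asarray(areas_row, float)
    cand = np.where(np.isfinite(areas_row) & (areas_row > 0))[0]
    if len(cand) == 0:
        raise ValueError("territory is empty in every valid frame")
    t_star = int(cand[np.argmin(areas_row[cand])])
    mask = np.asarray(territory_masks[t_star]) > 0
    lab, n = ndi.label(mask, structure=np.ones((3, 3), int))
    if n == 0:
        raise ValueError("empty mask at the most contracted frame")
    big = 1 + np.argmax(np.bincount(lab.ravel())[1:])
    com = np.array(ndi.center_of_mass(lab == big))
    if to_ref is not None:
        com = np.asarray(to_ref(t_star, com), float)
    return com


def locate_epicenter(
    tid: int, ref_position: np.ndarray, markers: MotionMarkerSet
) -> Epicenter:
    """Barycentric storage of an epicenter in its enclosing (or, outside
    the hull, nearest) Delaunay triangle of motion markers."""
    s = int(markers.triangulation.find_simplex(ref_position[None])[0])
    if s >= 0:
        simplex = markers.triangles[s]
    else:
        # hull-exterior epicenter: the triangle whose extrapolated
        # weights are least negative
        best, best_min = None, -np.inf
        for simp in markers.triangles:
            lam = to_barycentric(ref_position, markers.ref_positions[simp])
            if lam.min() > best_min:
                best, best_min = simp, lam.min()
        simplex = best
    lam = to_barycentric(ref_position, markers.ref_positions[simplex])
    return Epicenter(id=int(tid), ref_position=np.asarray(ref_position, float),
                     simplex=np.asarray(simplex), lambdas=lam)


def track_epicenters(
    epicenters: list[Epicenter], markers: MotionMarkerSet
) -> np.ndarray:
    """Per-frame epicenter positions c_t = sum_i l_i * a_i(t).

    Frames where a vertex marker is lost yield NaN for that epicenter.
    """
    n_frames = markers.positions.shape[0]
    out = np.full((len(epicenters), n_frames, 2), np.nan)
    for i, ep in enumerate(epicenters):
        verts = markers.positions[:, ep.simplex, :]        # (T, 3, 2)
        bad = ~np.isfinite(verts).all(axis=(1, 2))
        out[i] = np.einsum("j,tjk->tk", ep.lambdas, verts)
        out[i][bad] = np.nan
        if bad.any():
            log.debug("epicenter %d invalid on %d frames (lost marker)",
                      ep.id, int(bad.sum()))
    return out


# ---------------------------------------------------------------------------
# slice geometry
# ---------------------------------------------------------------------------

def procrustes_rotation(src: np.ndarray, dst: np.ndarray) -> float:
    """Rigid (rotation-only) best-fit angle mapping src onto dst points."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    sh = src - src.mean(0)
    dh = dst - dst.mean(0)
    z = ((dh[:, 1] + 1j * dh[:, 0]) * np.conj(sh[:, 1] + 1j * sh[:, 0])).sum()
    if np.abs(z) < 1e-12:
        raise ValueError("degenerate point set: rotation undefined")
    return float(np.angle(z))


def stabilize_orientation(
    epicenter: Epicenter, markers: MotionMarkerSet, t: int,
    theta_ref0: float = 0.0, previous: float | None = None,
) -> float:
    """Angular origin of the slices at frame t: theta_ref(0) plus the
    rigid rotation of the enclosing marker triangle since the reference.
    A degenerate triangle carries the previous value forward."""
    ref_v = markers.ref_positions[epicenter.simplex]
    cur_v = markers.positions[t][epicenter.simplex]
    if not np.isfinite(cur_v).all():
        if previous is not None:
            return previous
        raise ValueError(f"marker lost at frame {t} and no previous orientation")
    try:
        rot = procrustes_rotation(ref_v, cur_v)
    except ValueError:
        log.warning("degenerate marker triangle at frame %d; carrying theta", t)
        return previous if previous is not None else theta_ref0
    return theta_ref0 + rot


def border_pixels(mask: np.ndarray, step: float = 0.25,
                  smooth_px: float = 1.0) -> np.ndarray:
    """(K, 2) subpixel border points of the largest 8-connected component.

    The outer contour is taken at the half level between mask and
    background (the subpixel estimate of the true edge — raw boundary
    pixel centers sit roughly half a pixel inside it and would bias the
    radius low), resampled at ``step`` px of arc length and smoothed
    with a short periodic Gaussian to suppress the rasterization
    staircase.  Interior holes are ignored: the slice radius measures
    the expansion front.
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        return np.empty((0, 2))
    lab, n = ndi.label(mask, structure=np.ones((3, 3), int))
    big = 1 + np.argmax(np.bincount(lab.ravel())[1:])
    comp = ndi.binary_fill_holes(lab == big)
    padded = np.pad(comp, 1)
    contours = measure.find_contours(padded.astype(float), 0.5)
    if not contours:
        rr, cc = np.nonzero(comp)
        return np.stack([rr, cc], axis=1).astype(float)
    cont = max(contours, key=len) - 1.0  # undo the pad offset
    seg = np.vstack([cont, cont[:1]])
    d = np.hypot(*np.diff(seg, axis=0).T)
    s = np.r_[0.0, np.cumsum(d)]
    if s[-1] < 4 * step:
        return cont
    t = np.arange(0.0, s[-1], step)
    pts = np.stack([np.interp(t, s, seg[:, 0]), np.interp(t, s, seg[:, 1])], axis=1)
    if smooth_px > 0:
        sig = smooth_px / step
        pts = np.stack(
            [gaussian_filter1d(pts[:, i], sig, mode="wrap") for i in (0, 1)], axis=1
        )
    return pts


def slice_areas(
    mask: np.ndarray,
    epicenter_pos: np.ndarray,
    n_slices: int = 36,
    theta_ref: float = 0.0,
) -> np.ndarray:
    """Per-slice areas pi * rbar^2 / n around the epicenter.

    Border pixels are binned by their angle from the epicenter
    (measured from ``theta_ref``); rbar is the mean epicenter-to-border
    distance within the bin.  Slices with no border pixels report 0.
    """
    if n_slices < 4:
        raise ValueError("need n_slices >= 4")
    bp = border_pixels(mask)
    out = np.zeros(n_slices)
    if len(bp) == 0:
        return out
    d = bp - np.asarray(epicenter_pos, float)
    theta = np.mod(np.arctan2(d[:, 0], d[:, 1]) - theta_ref, 2 * np.pi)
    dist = np.hypot(d[:, 0], d[:, 1])
    idx = np.minimum((theta / (2 * np.pi / n_slices)).astype(int), n_slices - 1)
    for k in range(n_slices):
        sel = idx == k
        if sel.any():
            out[k] = np.pi * dist[sel].mean() ** 2 / n_slices
    return out


@dataclass
class SliceAreaSeries:
    ids: np.ndarray        # (C,)
    areas: np.ndarray      # (C, n_slices, T)
    valid: np.ndarray      # (C, T) bool

    def matrix(self, tid: int) -> np.ndarray:
        """(n_slices, T_valid) matrix for one chromatophore."""
        i = int(np.nonzero(self.ids == tid)[0][0])
        return self.areas[i][:, self.valid[i]]

    def to_tidy(self) -> pd.DataFrame:
        c, s, t = self.areas.shape
        return pd.DataFrame({
            "frame": np.tile(np.arange(t), c * s),
            "chromatophore_id": np.repeat(self.ids, s * t),
            "slice": np.tile(np.repeat(np.arange(s), t), c),
            "area_px2": self.areas.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_tidy().to_csv(path, index=False)


def compute_slice_series(
    masks,
    cq_frames,
    cleanqueen: Cleanqueen,
    areas: AreaSeries,
    markers: MotionMarkerSet,
    cfg: AnisotropyConfig | None = None,
    to_ref=None,
    target_ids=None,
) -> tuple[SliceAreaSeries, list[Epicenter]]:
    """Slice decomposition of every (non-marker) territory.

    ``cq_frames`` must be an in-memory sequence of warped cleanqueen
    label images (one per frame, None where the frame is invalid).
    """
    cfg = cfg or AnisotropyConfig()
    if target_ids is None:
        target_ids = [t for t in areas.ids if t not in set(markers.ids.tolist())]
    n_frames = len(cq_frames)
    eps: list[Epicenter] = []
    for tid in target_ids:
        terr_masks = []
        for m, cq in zip(masks, cq_frames):
            if cq is None:
                terr_masks.append(np.zeros(np.asarray(m).shape, bool))
            else:
                terr_masks.append((np.asarray(m) > 0) & (cq == tid))
        ref_pos = compute_epicenter(terr_masks, areas.row(tid), to_ref=to_ref)
        eps.append(locate_epicenter(tid, ref_pos, markers))
    centers = track_epicenters(eps, markers)              # (C, T, 2)
    out = np.zeros((len(target_ids), cfg.n_slices, n_frames))
    valid = np.zeros((len(target_ids), n_frames), dtype=bool)
    for ti in range(n_frames):
        cq = cq_frames[ti]
        if cq is None:
            continue
        seg = np.asarray(masks[ti]) > 0
        for ci, (tid, ep) in enumerate(zip(target_ids, eps)):
            c = centers[ci, ti]
            if not np.isfinite(c).all():
                continue
            theta = stabilize_orientation(ep, markers, ti)
            out[ci, :, ti] = slice_areas(seg & (cq == tid), c, cfg.n_slices, theta)
            valid[ci, ti] = True
    return SliceAreaSeries(ids=np.asarray(target_ids), areas=out, valid=valid), eps
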