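"""Within-chunk motion compensation.

Small chromatophores act as trackable landmarks: centroids of
shape-filtered connected components of the first frame's segmentation
are tracked frame-to-frame with a pyramidal Lucas-Kanade solver, points
that move implausibly far in one step are killed, and dense displacement
maps to the chunk's first frame are interpolated from the surviving
points with an affine moving-least-squares (MLS) scheme evaluated on a
coarse grid and bilinearly upsampled.

All maps are *pull* fields: a warp samples the source image at the
coordinates the field stores, so composing warps is composing lookups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.transform import pyramid_reduce

from .chunking import to_grayscale
from .config import RegistrationConfig

log = logging.getLogger("chromatrack.registration")


class RegistrationError(RuntimeError):
    """Raised when a chunk cannot be registered (too few points, or too
    many lost during tracking); the chunk is flagged unusable."""


# ---------------------------------------------------------------------------
# tracking-point selection
# ---------------------------------------------------------------------------

@dataclass
class TrackPointSet:
    points: np.ndarray              # (N, 2) reference-frame (row, col)
    positions: np.ndarray | None = None  # (T, N, 2) tracked positions
    alive: np.ndarray | None = None      # (T, N) bool; dead never resurrects
    #: area of the mask component under each point per frame (NaN when
    #: no mask was supplied or the point is off-mask)
    component_area: np.ndarray | None = None
    #: sticky skin-fiducial flag: False from the first frame in which
    #: the point's component area left the allowed band around its
    #: initial size.  Expansion drift is irreversible (the tracker ends
    #: up on pigment that moved relative to the skin), so the flag never
    #: recovers; unstable points are tracked but excluded from the MLS
    #: control set
    stable: np.ndarray | None = None


def select_track_points(
    mask: np.ndarray,
    cfg: RegistrationConfig | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> TrackPointSet:
    """Centroids of shape-filtered mask components, evenly subsampled.

    Components are filtered on area, eccentricity and solidity (round,
    compact blobs track well; elongated or ragged ones do not), points
    too close to the border are dropped, and the survivors are thinned
    to at most ``max_points_per_cell`` per grid cell so support for the
    MLS interpolation is spread over the field of view.
    """
    cfg = cfg or RegistrationConfig()
    mask = np.asarray(mask)
    if not mask.any():
        raise RegistrationError("empty mask: no tracking-point candidates")
    h, w = mask.shape
    lab = cc_label(mask > 0, connectivity=2)
    cands = []
    for rp in regionprops(lab):
        if not (cfg.area_min_px <= rp.area <= cfg.area_max_px):
            continue
        if rp.eccentricity > cfg.eccentricity_max:
            continue
        if rp.solidity < cfg.solidity_min:
            continue
        cands.append(rp.centroid)
    pts = np.array(cands).reshape(-1, 2)
    off_r, off_c = cfg.edge_offset_fraction * h, cfg.edge_offset_fraction * w
    if len(pts):
        keep = (
            (pts[:, 0] >= off_r) & (pts[:, 0] <= h - 1 - off_r)
            & (pts[:, 1] >= off_c) & (pts[:, 1] <= w - 1 - off_c)
        )
        pts = pts[keep]
    # even subsampling across a grid
    if len(pts):
        g = cfg.grid_cells
        cell = np.minimum(
            (pts[:, 0] / h * g).astype(int) * g + (pts[:, 1] / w * g).astype(int),
            g * g - 1,
        )
        chosen = []
        for c in np.unique(cell):
            idx = np.nonzero(cell == c)[0]
            chosen.extend(idx[: cfg.max_points_per_cell])
        pts = pts[np.sort(chosen)]
    if len(pts) < 4:
        raise RegistrationError(
            f"only {len(pts)} tracking points survive shape/edge filtering; need >= 4"
        )
    return TrackPointSet(points=pts)


def random_track_points(
    shape: tuple[int, int], n: int, cfg: RegistrationConfig, rng: np.random.Generator
) -> TrackPointSet:
    """Uniform-random fallback when segmentation yields too few candidates."""
    h, w = shape
    off_r, off_c = cfg.edge_offset_fraction * h, cfg.edge_offset_fraction * w
    pts = rng.uniform([off_r, off_c], [h - 1 - off_r, w - 1 - off_c], size=(n, 2))
    return TrackPointSet(points=pts)


# ---------------------------------------------------------------------------
# pyramidal Lucas-Kanade
# ---------------------------------------------------------------------------

def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [img.astype(float)]
    for _ in range(levels - 1):
        if min(pyr[-1].shape) < 16:
            break
        pyr.append(pyramid_reduce(pyr[-1], downscale=2, channel_axis=None))
    return pyr


def _lk_step_level(
    prev: np.ndarray,
    nxt: np.ndarray,
    pts: np.ndarray,
    guess: np.ndarray,
    window: int,
    iters: int,
) -> np.ndarray:
    """One pyramid level of LK for all points at once; returns updated
    per-point displacement guesses (same scale as ``prev``)."""
    half = window // 2
    offs = np.mgrid[-half:half + 1, -half:half + 1].reshape(2, -1)  # (2, W2)
    gy, gx = np.gradient(prev)
    base = pts.T[:, :, None] + offs[:, None, :]          # (2, N, W2)
    flat = base.reshape(2, -1)
    ix = map_coordinates(gx, flat, order=1, mode="nearest").reshape(len(pts), -1)
    iy = map_coordinates(gy, flat, order=1, mode="nearest").reshape(len(pts), -1)
    i0 = map_coordinates(prev, flat, order=1, mode="nearest").reshape(len(pts), -1)
    # structure tensor per point (row = y, col = x ordering kept as (row, col))
    gyy = (iy * iy).sum(1)
    gxx = (ix * ix).sum(1)
    gxy = (ix * iy).sum(1)
    det = gyy * gxx - gxy**2
    ok = det > 1e-6
    v = guess.copy()
    for _ in range(iters):
        cur = (pts + v).T[:, :, None] + offs[:, None, :]
        i1 = map_coordinates(nxt, cur.reshape(2, -1), order=1, mode="nearest").reshape(
            len(pts), -1
        )
        diff = i0 - i1
        br = (diff * iy).sum(1)
        bc = (diff * ix).sum(1)
        dv = np.zeros_like(v)
        with np.errstate(invalid="ignore", divide="ignore"):
            dv[:, 0] = (gxx * br - gxy * bc) / det
            dv[:, 1] = (gyy * bc - gxy * br) / det
        dv[~ok] = 0.0
        v += dv
        if np.abs(dv).max() < 0.01:
            break
    v[~ok] = np.nan
    return v


def lk_track_step(
    prev: np.ndarray,
    nxt: np.ndarray,
    pts: np.ndarray,
    window: int = 21,
    levels: int = 3,
    iters: int = 10,
) -> np.ndarray:
    """Track ``pts`` (N, 2) from ``prev`` to ``nxt``; returns new
    positions, NaN where tracking failed."""
    prev_p = _pyramid(prev, levels)
    next_p = _pyramid(nxt, levels)
    n_levels = len(prev_p)
    v = np.zeros_like(pts, dtype=float)
    for lv in range(n_levels - 1, -1, -1):
        scale = 2.0**lv
        v = _lk_step_level(prev_p[lv], next_p[lv], pts / scale, v, window, iters)
        if lv > 0:
            v = v * 2.0
    return pts + v


def _component_areas(mask: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Area of the 8-connected mask component under each point (NaN if
    the point lies on background)."""
    lab = cc_label(np.asarray(mask) > 0, connectivity=2)
    counts = np.bincount(lab.ravel())
    out = np.full(len(pts), np.nan)
    h, w = lab.shape
    for i, p in enumerate(pts):
        if not np.isfinite(p).all():
            continue
        r, c = int(round(p[0])), int(round(p[1]))
        if 0 <= r < h and 0 <= c < w and lab[r, c] > 0:
            out[i] = counts[lab[r, c]]
    return out


def track_points(
    frames,
    point_set: TrackPointSet,
    cfg: RegistrationConfig | None = None,
    max_step: float | None = None,
    masks=None,
) -> TrackPointSet:
    """Frame-to-frame LK tracking with displacement accumulation.

    Points whose single-step displacement exceeds ``max_step`` (or that
    leave the frame / lose texture) are killed and never resurrect.
    Aborts with RegistrationError when the alive fraction drops below
    ``alive_min_fraction``.  When segmentation ``masks`` are given, the
    area of the component under each point is recorded per frame so the
    map builder can exclude points riding an expanding chromatophore.
    """
    cfg = cfg or RegistrationConfig()
    if max_step is None:
        max_step = cfg.max_step_px if cfg.max_step_px is not None else 12.0
    n = len(point_set.points)
    n_frames = len(frames)
    positions = np.full((n_frames, n, 2), np.nan)
    alive = np.zeros((n_frames, n), dtype=bool)
    comp_area = np.full((n_frames, n), np.nan)
    stable = np.ones((n_frames, n), dtype=bool)
    positions[0] = point_set.points
    alive[0] = True
    if masks is not None:
        comp_area[0] = _component_areas(masks[0], positions[0])
    prev_gray = to_grayscale(frames[0])
    h, w = prev_gray.shape
    for t in range(1, n_frames):
        cur_gray = to_grayscale(frames[t])
        live = alive[t - 1]
        new = lk_track_step(
            prev_gray, cur_gray, positions[t - 1][live],
            cfg.lk_window, cfg.lk_levels, cfg.lk_iterations,
        )
        step = np.hypot(*(new - positions[t - 1][live]).T)
        good = (
            np.isfinite(new).all(axis=1)
            & (step <= max_step)
            & (new[:, 0] >= 0) & (new[:, 0] <= h - 1)
            & (new[:, 1] >= 0) & (new[:, 1] <= w - 1)
        )
        idx = np.nonzero(live)[0]
        alive[t, idx[good]] = True
        positions[t, idx[good]] = new[good]
        if masks is not None:
            comp_area[t] = _component_areas(masks[t], positions[t])
            a0 = np.maximum(comp_area[0], 1.0)
            g = cfg.control_area_growth_max
            with np.errstate(invalid="ignore"):
                ratio = comp_area[t] / a0
                in_band = np.isfinite(ratio) & (ratio <= g) & (ratio >= 1.0 / g)
            stable[t] = stable[t - 1] & (in_band | ~np.isfinite(ratio))
        frac = alive[t].mean()
        if frac < cfg.alive_min_fraction:
            raise RegistrationError(
                f"tracking halted at frame {t}: alive fraction {frac:.2f} < "
                f"{cfg.alive_min_fraction}"
            )
        prev_gray = cur_gray
    return TrackPointSet(points=point_set.points, positions=positions,
                         alive=alive, component_area=comp_area,
                         stable=stable if masks is not None else None)


# ---------------------------------------------------------------------------
# moving least squares
# ---------------------------------------------------------------------------

def mls_transform(
    control_src: np.ndarray,
    control_dst: np.ndarray,
    eval_pts: np.ndarray,
    alpha: float = 1.0,
    deformation_class: str = "affine",
) -> np.ndarray:
    """Affine (or similarity) moving least squares.

    For every evaluation point v an affine map is fitted to the control
    correspondences under inverse-distance-power weights
    w_i = 1 / (|p_i - v|^(2*alpha) + eps); the scheme reproduces any
    global affine field exactly and interpolates the controls in the
    singular-weight limit.  Falls back per-point to a similarity fit
    where the weighted control scatter is (near-)degenerate, e.g. for
    collinear controls.
    """
    p = np.asarray(control_src, float)
    q = np.asarray(control_dst, float)
    v = np.asarray(eval_pts, float)
    if p.shape[0] < 2:
        raise ValueError("need at least 2 control points")
    d2 = ((v[:, None, :] - p[None, :, :]) ** 2).sum(-1)  # (M, N)
    w = 1.0 / (d2**alpha + 1e-8)
    wsum = w.sum(1, keepdims=True)
    p_star = (w @ p) / wsum                               # (M, 2)
    q_star = (w @ q) / wsum
    ph = p[None, :, :] - p_star[:, None, :]               # (M, N, 2)
    qh = q[None, :, :] - q_star[:, None, :]
    if deformation_class == "affine":
        A = np.einsum("mn,mni,mnj->mij", w, ph, ph)       # (M, 2, 2)
        B = np.einsum("mn,mni,mnj->mij", w, ph, qh)
        det = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] * A[:, 1, 0]
        trace = A[:, 0, 0] + A[:, 1, 1]
        good = det > 1e-9 * np.maximum(trace, 1e-12) ** 2
        Minv = np.zeros_like(A)
        safed = np.where(good, det, 1.0)
        Minv[:, 0, 0] = A[:, 1, 1] / safed
        Minv[:, 1, 1] = A[:, 0, 0] / safed
        Minv[:, 0, 1] = -A[:, 0, 1] / safed
        Minv[:, 1, 0] = -A[:, 1, 0] / safed
        M = np.einsum("mij,mjk->mik", Minv, B)
        out = np.einsum("mi,mij->mj", v - p_star, M) + q_star
        if not good.all():
            log.debug("MLS: %d/%d eval points degenerate, similarity fallback",
                      (~good).sum(), len(good))
            out[~good] = _mls_similarity(w[~good], ph[~good], qh[~good],
                                         (v - p_star)[~good]) + q_star[~good]
        return out
    if deformation_class == "similarity":
        return _mls_similarity(w, ph, qh, v - p_star) + q_star
    raise ValueError(f"unknown MLS deformation class {deformation_class!r}")


def _mls_similarity(w, ph, qh, vh):
    """Weighted similarity fit per eval point (complex closed form)."""
    pc = ph[..., 1] + 1j * ph[..., 0]
    qc = qh[..., 1] + 1j * qh[..., 0]
    num = (w * np.conj(pc) * qc).sum(-1)
    den = (w * np.abs(pc) ** 2).sum(-1)
    s = num / np.maximum(den, 1e-12)
    vc = (vh[..., 1] + 1j * vh[..., 0]) * s
    return np.stack([vc.imag, vc.real], axis=-1)


@dataclass
class DisplacementMap:
    """Dense pull fields between one frame and the chunk reference.

    ``ref_to_frame`` gives, for every reference pixel, the frame
    coordinate to sample when registering the frame onto the reference;
    ``frame_to_ref`` gives, for every frame pixel, its reference
    coordinate (the field d with ref = x + d(x); identically x on the
    reference frame itself).  Both shaped (2, H, W).
    """

    frame_index: int
    ref_to_frame: np.ndarray
    frame_to_ref: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.ref_to_frame.shape[1:]

    def displacement(self) -> np.ndarray:
        h, w = self.shape
        return self.frame_to_ref - np.mgrid[0:h, 0:w]


def _coarse_grid(h: int, w: int, step: int) -> tuple[np.ndarray, np.ndarray]:
    rows = np.unique(np.r_[np.arange(0, h, step), h - 1]).astype(float)
    cols = np.unique(np.r_[np.arange(0, w, step), w - 1]).astype(float)
    return rows, cols


def mls_dense_field(
    control_src: np.ndarray,
    control_dst: np.ndarray,
    shape: tuple[int, int],
    grid_step: int = 8,
    alpha: float = 1.0,
    deformation_class: str = "affine",
) -> np.ndarray:
    """Evaluate the MLS map on a coarse grid and bilinearly upsample to
    a full-resolution (2, H, W) coordinate field."""
    from scipy.interpolate import RegularGridInterpolator

    h, w = shape
    rows, cols = _coarse_grid(h, w, grid_step)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    ev = np.stack([rr.ravel(), cc.ravel()], axis=1)
    mapped = mls_transform(control_src, control_dst, ev, alpha, deformation_class)
    field = mapped.reshape(len(rows), len(cols), 2)
    interp = RegularGridInterpolator((rows, cols), field, method="linear")
    gr, gc = np.mgrid[0:h, 0:w]
    full = interp(np.stack([gr.ravel(), gc.ravel()], axis=1)).reshape(h, w, 2)
    return np.moveaxis(full, -1, 0)


def build_displacement_map(
    frame_index: int,
    ref_points: np.ndarray,
    cur_points: np.ndarray,
    shape: tuple[int, int],
    cfg: RegistrationConfig | None = None,
) -> DisplacementMap:
    """Both pull fields from the alive control correspondences.

    The inverse field is computed by MLS with source/target swapped
    (exact for affine fields) rather than by numeric field inversion.
    """
    cfg = cfg or RegistrationConfig()
    if len(ref_points) < 4:
        raise RegistrationError("MLS needs >= 4 alive control points")
    kw = dict(grid_step=cfg.mls_grid_step, alpha=cfg.mls_alpha,
              deformation_class=cfg.mls_class)
    ref_to_frame = mls_dense_field(ref_points, cur_points, shape, **kw)
    frame_to_ref = mls_dense_field(cur_points, ref_points, shape, **kw)
    return DisplacementMap(frame_index, ref_to_frame, frame_to_ref)


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------

def warp_image(image: np.ndarray, coords: np.ndarray, order: int = 1,
               cval: float = 0.0) -> np.ndarray:
    """Pull-warp ``image`` by sampling it at ``coords`` (2, H, W).

    order=1 (bilinear) for intensity images, order=0 (nearest) for
    label masks; out-of-domain pixels become ``cval`` (background).
    """
    image = np.asarray(image)
    if image.ndim == 3:
        return np.stack(
            [map_coordinates(image[..., c].astype(float), coords, order=order,
                             mode="constant", cval=cval)
             for c in range(image.shape[-1])], axis=-1)
    return map_coordinates(image.astype(float) if order else image, coords,
                           order=order, mode="constant", cval=cval)


def apply_map(image: np.ndarray, dmap: DisplacementMap, direction: str = "to_ref",
              order: int | None = None) -> np.ndarray:
    """Warp a frame onto the reference (``to_ref``) or reference-frame
    data onto the frame (``to_frame``)."""
    coords = dmap.ref_to_frame if direction == "to_ref" else dmap.frame_to_ref
    if order is None:
        order = 0 if np.issubdtype(np.asarray(image).dtype, np.integer) else 1
    out = warp_image(image, coords, order=order)
    if order == 0:
        return out
    dt = np.asarray(image).dtype
    return out.astype(dt) if np.issubdtype(dt, np.integer) else out


# ---------------------------------------------------------------------------
# chunk-level driver
# ---------------------------------------------------------------------------

@dataclass
class ChunkRegistration:
    chunk_id: int
    tracks: TrackPointSet
    shape: tuple[int, int]
    cfg: RegistrationConfig

    def alive_controls(self, t: int) -> tuple[np.ndarray, np.ndarray]:
        """Alive control points for frame t, excluding points whose mask
        component grew past ``control_area_growth_max`` times its
        initial size (their motion is pigment expansion, not skin)."""
        live = self.tracks.alive[t].copy()
        if self.tracks.stable is not None:
            filtered = live & self.tracks.stable[t]
            if filtered.sum() >= 4:
                live = filtered
        return self.tracks.points[live], self.tracks.positions[t][live]

    def displacement_map(self, t: int) -> DisplacementMap:
        ref, cur = self.alive_controls(t)
        return build_displacement_map(t, ref, cur, self.shape, self.cfg)

    def report(self):
        import pandas as pd

        return pd.DataFrame({
            "frame": np.arange(self.tracks.alive.shape[0]),
            "alive": self.tracks.alive.sum(axis=1),
            "total": self.tracks.alive.shape[1],
        })


def register_chunk(
    frames,
    first_mask: np.ndarray,
    cfg: RegistrationConfig | None = None,
    chunk_id: int = 0,
    max_step: float | None = None,
    rng: np.random.Generator | None = None,
    masks=None,
) -> ChunkRegistration:
    """Select points on the first frame's mask, track them through the
    chunk, and return the lazy per-frame displacement-map factory."""
    cfg = cfg or RegistrationConfig()
    try:
        pts = select_track_points(first_mask, cfg)
    except RegistrationError:
        log.warning("chunk %d: too few mask candidates, random fallback", chunk_id)
        rng = rng or np.random.default_rng(0)
        pts = random_track_points(first_mask.shape, 40, cfg, rng)
    tracks = track_points(frames, pts, cfg, max_step=max_step, masks=masks)
    shape = to_grayscale(frames[0]).shape
    return ChunkRegistration(chunk_id, tracks, shape, cfg)
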