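"""Chunk-to-chunk alignment via masterframes.

Registration removes motion within a chunk but says nothing about the
gap between chunks.  Each chunk is condensed into its *masterframe*
(the pixelwise mean of its registered frames); successive masterframes
are coarsely aligned — by moment-based ellipse fits of the silhouette
when one is available, by manual point correspondences otherwise, or
starting from the identity — then refined over a grid of patches by
phase correlation with subpixel parabolic peak interpolation, in two
rounds with a halved patch size in the second.  A dense MLS map is
interpolated from the refined correspondences and accepted only if its
reprojection error (forward map then backward map, mean Euclidean
distance to the start) stays below threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .chunking import to_grayscale
from .config import StitchingConfig
from .registration import mls_dense_field, warp_image

log = logging.getLogger("chromatrack.stitching")


# ---------------------------------------------------------------------------
# masterframe
# ---------------------------------------------------------------------------

def compute_masterframe(registered_frames) -> np.ndarray:
    """Pixelwise arithmetic mean of a chunk's registered frames."""
    acc = None
    n = 0
    for fr in registered_frames:
        f = np.asarray(fr, dtype=float)
        acc = f if acc is None else acc + f
        n += 1
    if n == 0:
        raise ValueError("no frames to average")
    return acc / n


# ---------------------------------------------------------------------------
# ellipse fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EllipseFit:
    center: tuple[float, float]  # (row, col)
    semi_major: float
    semi_minor: float
    angle: float  # radians in [0, pi); 0 for a circle by convention

    def __post_init__(self):
        if not self.semi_major >= self.semi_minor > 0:
            raise ValueError("need semi_major >= semi_minor > 0")


def fit_ellipse(mask: np.ndarray) -> EllipseFit:
    """Moment-matching ellipse of a silhouette mask.

    The returned ellipse has the same zeroth, first and second image
    moments as the mask: center = centroid, axes from the eigenvalues
    of the normalized second-central-moment matrix (semi-axis = 2*sqrt
    of the eigenvalue), orientation from the principal eigenvector.
    """
    mask = np.asarray(mask) > 0
    m00 = mask.sum()
    if m00 == 0:
        raise ValueError("empty silhouette mask: use manual correspondences")
    rr, cc = np.nonzero(mask)
    r0, c0 = rr.mean(), cc.mean()
    mu20 = ((rr - r0) ** 2).mean()
    mu02 = ((cc - c0) ** 2).mean()
    mu11 = ((rr - r0) * (cc - c0)).mean()
    cov = np.array([[mu20, mu11], [mu11, mu02]])
    evals, evecs = np.linalg.eigh(cov)  # ascending
    a = 2.0 * np.sqrt(evals[1])
    b = 2.0 * np.sqrt(evals[0])
    if (a - b) / max(a, 1e-12) < 1e-3:
        angle = 0.0  # circle: orientation undefined, report 0
    else:
        vr, vc = evecs[:, 1]
        angle = float(np.mod(np.arctan2(vr, vc), np.pi))
    return EllipseFit(center=(float(r0), float(c0)), semi_major=float(a),
                      semi_minor=float(b), angle=angle)


# ---------------------------------------------------------------------------
# similarity transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityTransform:
    """p_dst = scale * R(rotation) @ (p_src - src_center) + dst_center,
    all points (row, col)."""

    rotation: float = 0.0
    scale: float = 1.0
    src_center: tuple[float, float] = (0.0, 0.0)
    dst_center: tuple[float, float] = (0.0, 0.0)

    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, float))
        return (pts - self.src_center) @ self.matrix().T + self.dst_center

    def inverse(self) -> "SimilarityTransform":
        return SimilarityTransform(
            rotation=-self.rotation, scale=1.0 / self.scale,
            src_center=self.dst_center, dst_center=self.src_center,
        )

    @property
    def translation(self) -> np.ndarray:
        return np.asarray(self.dst_center) - np.asarray(self.src_center)


def similarity_from_correspondences(src: np.ndarray, dst: np.ndarray) -> SimilarityTransform:
    """Least-squares similarity fit (Umeyama/Procrustes) to >= 2 pairs."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if len(src) < 2 or len(src) != len(dst):
        raise ValueError("need >= 2 matched point pairs")
    sc, dc = src.mean(0), dst.mean(0)
    sh, dh = src - sc, dst - dc
    num = (dh[:, 1] + 1j * dh[:, 0]) * np.conj(sh[:, 1] + 1j * sh[:, 0])
    den = (np.abs(sh[:, 1] + 1j * sh[:, 0]) ** 2).sum()
    z = num.sum() / max(den, 1e-12)
    return SimilarityTransform(rotation=float(np.angle(z)), scale=float(np.abs(z)),
                               src_center=tuple(sc), dst_center=tuple(dc))


def _similarity_correlation(img_a, img_b, tr: SimilarityTransform) -> float:
    """Correlation between A and B pulled onto A by ``tr`` (B->A)."""
    h, w = img_a.shape
    grid = np.mgrid[0:h, 0:w].reshape(2, -1).T.astype(float)
    src = tr.inverse().apply(grid).T.reshape(2, h, w)
    warped = warp_image(img_b, src, order=1)
    a = img_a - img_a.mean()
    b = warped - warped.mean()
    den = np.sqrt((a**2).sum() * (b**2).sum())
    return float((a * b).sum() / den) if den > 0 else 0.0


def coarse_align(
    ellipse_a: EllipseFit | None = None,
    ellipse_b: EllipseFit | None = None,
    correspondences: tuple[np.ndarray, np.ndarray] | None = None,
    image_a: np.ndarray | None = None,
    image_b: np.ndarray | None = None,
) -> SimilarityTransform:
    """Similarity transform B -> A from ellipse fits or correspondences.

    Ellipse-based alignment maps B's center/axes/angle onto A's; the
    180-degree ambiguity of an ellipse's orientation is resolved by the
    rotation giving the higher post-transform image correlation.
    Near-circular ellipses fall back to correspondences.
    """
    if ellipse_a is not None and ellipse_b is not None:
        ecc_a = 1.0 - ellipse_a.semi_minor / ellipse_a.semi_major
        ecc_b = 1.0 - ellipse_b.semi_minor / ellipse_b.semi_major
        if min(ecc_a, ecc_b) < 0.02:
            if correspondences is None:
                raise ValueError(
                    "near-circular silhouette: orientation ambiguous, "
                    "provide manual correspondences"
                )
        else:
            scale = 0.5 * (ellipse_a.semi_major / ellipse_b.semi_major
                           + ellipse_a.semi_minor / ellipse_b.semi_minor)
            base = ellipse_a.angle - ellipse_b.angle
            cands = [base, base + np.pi]
            if image_a is not None and image_b is not None:
                trs = [SimilarityTransform(r, scale, ellipse_b.center, ellipse_a.center)
                       for r in cands]
                scores = [_similarity_correlation(to_grayscale(image_a),
                                                  to_grayscale(image_b), t) for t in trs]
                return trs[int(np.argmax(scores))]
            rot = min(cands, key=lambda r: abs(np.mod(r + np.pi, 2 * np.pi) - np.pi))
            return SimilarityTransform(rot, scale, ellipse_b.center, ellipse_a.center)
    if correspondences is not None:
        pa, pb = correspondences
        if len(pa) < 3:
            raise ValueError("need >= 3 manual correspondences")
        return similarity_from_correspondences(np.asarray(pb), np.asarray(pa))
    raise ValueError("no ellipses and no correspondences given")


# ---------------------------------------------------------------------------
# phase correlation
# ---------------------------------------------------------------------------

def phase_correlation(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """Subpixel shift d with b(x) ~ a(x - d), plus the correlation peak.

    Normalized cross-power spectrum (with a relative regularizer in the
    denominator so spectrally empty bins contribute noise-free zeros
    rather than amplified phase noise); the integer peak of its inverse
    transform is refined per axis by a three-point parabola fit.  A
    featureless (constant) patch returns peak 0.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("patches must have equal shape")
    fa = np.fft.fft2(a - a.mean())
    fb = np.fft.fft2(b - b.mean())
    cross = fb * np.conj(fa)
    mag = np.abs(cross)
    if mag.max() < 1e-12:
        return np.zeros(2), 0.0
    r = np.fft.ifft2(cross / (mag + 1e-6 * mag.max())).real
    peak_idx = np.unravel_index(np.argmax(r), r.shape)
    peak = float(r[peak_idx])

    shift = np.array(peak_idx, dtype=float)
    for ax in range(2):
        i = peak_idx[ax]
        prev_i = (i - 1) % r.shape[ax]
        next_i = (i + 1) % r.shape[ax]
        sl = list(peak_idx)
        sl[ax] = prev_i
        y0 = r[tuple(sl)]
        sl[ax] = next_i
        y2 = r[tuple(sl)]
        denom = y0 - 2 * r[peak_idx] + y2
        if abs(denom) > 1e-12:
            shift[ax] += 0.5 * (y0 - y2) / denom
    # wrap to signed shifts
    for ax in range(2):
        if shift[ax] > a.shape[ax] / 2:
            shift[ax] -= a.shape[ax]
    return shift, peak


def _extract_patch(img: np.ndarray, center: np.ndarray, size: int) -> np.ndarray:
    half = size // 2
    rows = np.arange(-half, half) + center[0]
    cols = np.arange(-half, half) + center[1]
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return map_coordinates(img, np.stack([rr, cc]), order=1, mode="nearest")


def texture_grid_mask(bgfrac_a: np.ndarray, bgfrac_b: np.ndarray,
                      patch_size: int, min_fraction: float = 0.55) -> np.ndarray:
    """Where patch matching may anchor: both chunks must show mostly
    skin (not pigment) within a patch around the point.

    ``bgfrac`` images hold the per-pixel fraction of frames classified
    background.  A patch dominated by an organ whose expansion state
    differs between the two chunk averages produces confidently wrong
    correlations; those regions are excluded up front.
    """
    from scipy.ndimage import uniform_filter

    fa = uniform_filter(np.asarray(bgfrac_a, float), patch_size)
    fb = uniform_filter(np.asarray(bgfrac_b, float), patch_size)
    return (fa >= min_fraction) & (fb >= min_fraction)


def refine_alignment(
    master_a: np.ndarray,
    master_b: np.ndarray,
    coarse: SimilarityTransform,
    cfg: StitchingConfig | None = None,
    mask_a: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-round patchwise phase-correlation refinement.

    Grid points on A's body mask get matched positions in B: round one
    correlates ``patch_size`` patches around the coarse estimates, round
    two repeats at half the patch size around the refined positions.
    Points whose correlation peak is below ``peak_min`` are dropped;
    losing more than half of them means the pair cannot be aligned.
    """
    cfg = cfg or StitchingConfig()
    ga = to_grayscale(master_a)
    gb = to_grayscale(master_b)
    h, w = ga.shape
    margin = cfg.patch_size // 2 + 2
    rows = np.arange(margin, h - margin, cfg.grid_spacing)
    cols = np.arange(margin, w - margin, cfg.grid_spacing)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    pts_a = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    if mask_a is not None:
        keep = np.asarray(mask_a)[pts_a[:, 0].astype(int), pts_a[:, 1].astype(int)] > 0
        pts_a = pts_a[keep]
    if len(pts_a) == 0:
        raise ValueError("no grid points inside the mask")
    pts_b = coarse.apply(pts_a)
    n0 = len(pts_a)
    ok = np.ones(n0, dtype=bool)
    size = cfg.patch_size
    for _ in range(cfg.n_rounds):
        for i in range(n0):
            if not ok[i]:
                continue
            pa = _extract_patch(ga, pts_a[i], size)
            pb = _extract_patch(gb, pts_b[i], size)
            shift, peak = phase_correlation(pa, pb)
            if peak < cfg.peak_min:
                ok[i] = False
                continue
            pts_b[i] += shift
        size = max(8, size // 2)
    # robust outlier rejection, two stages.  First, gross outliers far
    # from the median displacement (a periodic patch can lock onto the
    # wrong blob with a confident peak):
    if ok.sum() >= 4:
        disp = pts_b[ok] - pts_a[ok]
        med = np.median(disp, axis=0)
        mad = np.median(np.abs(disp - med), axis=0)
        lim = 3.0 * np.maximum(mad, 0.5) + 2.0
        inlier = (np.abs(disp - med) <= lim).all(axis=1)
        idx = np.nonzero(ok)[0]
        ok[idx[~inlier]] = False
    if ok.sum() < 0.5 * n0:
        raise RuntimeError(
            f"stitch refinement failed: {n0 - ok.sum()}/{n0} grid points dropped"
        )
    # second, leave-one-out consistency against the smooth MLS field: a
    # correspondence the rest of the field cannot predict to within
    # max_loo_residual_px reflects local appearance change (a blob whose
    # expansion state differs between the chunk averages), not motion
    if ok.sum() >= 8:
        pts_a, pts_b = _loo_trim(pts_a[ok], pts_b[ok],
                                 tol=cfg.max_loo_residual_px)
    else:
        pts_a, pts_b = pts_a[ok], pts_b[ok]
    return _border_pass(ga, gb, pts_a, pts_b, cfg, mask_a)


def _border_pass(
    ga: np.ndarray,
    gb: np.ndarray,
    pts_a: np.ndarray,
    pts_b: np.ndarray,
    cfg: StitchingConfig,
    mask_a: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Extend the correspondence set toward the frame border.

    The main grid keeps half a (full-size) patch of margin, so the MLS
    map extrapolates in the outer band and drifts off the local warp
    there.  This pass places grid points in that band, matches them
    with fully interior half-size patches seeded from the MLS
    prediction of the interior correspondences, and keeps only matches
    the joint leave-one-out trim accepts.
    """
    from .registration import mls_transform

    if len(pts_a) < 8:
        return pts_a, pts_b
    size = max(16, cfg.patch_size // 2)
    h, w = ga.shape
    m_out = size // 2 + 2                 # small patches stay interior
    m_in = cfg.patch_size // 2 + 2        # main-grid margin
    if m_out >= m_in:
        return pts_a, pts_b
    band = []
    for r in np.arange(m_out, h - m_out + 1, cfg.grid_spacing):
        for c in np.arange(m_out, w - m_out + 1, cfg.grid_spacing):
            if not (m_in <= r < h - m_in and m_in <= c < w - m_in):
                band.append((float(r), float(c)))
    if not band:
        return pts_a, pts_b
    band = np.array(band)
    if mask_a is not None:
        keep = np.asarray(mask_a)[band[:, 0].astype(int),
                                  band[:, 1].astype(int)] > 0
        band = band[keep]
        if len(band) == 0:
            return pts_a, pts_b
    guesses = mls_transform(pts_a, pts_b, band)
    add_a, add_b = [], []
    for p, g in zip(band, guesses):
        pa = _extract_patch(ga, p, size)
        pb = _extract_patch(gb, g, size)
        shift, peak = phase_correlation(pa, pb)
        if peak >= cfg.peak_min and np.abs(shift).max() <= size / 4:
            add_a.append(p)
            add_b.append(g + shift)
    if not add_a:
        return pts_a, pts_b
    all_a = np.vstack([pts_a, add_a])
    all_b = np.vstack([pts_b, add_b])
    return _loo_trim(all_a, all_b, tol=cfg.max_loo_residual_px)


def _loo_trim(pa: np.ndarray, pb: np.ndarray, tol: float = 1.5,
              max_iter: int = 3) -> tuple[np.ndarray, np.ndarray]:
    from .registration import mls_transform

    pa, pb = pa.copy(), pb.copy()
    for _ in range(max_iter):
        n = len(pa)
        resid = np.empty(n)
        for i in range(n):
            sel = np.arange(n) != i
            pred = mls_transform(pa[sel], pb[sel], pa[i][None])
            resid[i] = np.hypot(*(pred[0] - pb[i]))
        bad = resid > tol
        if not bad.any() or (~bad).sum() < 6:
            break
        pa, pb = pa[~bad], pb[~bad]
    return pa, pb


# ---------------------------------------------------------------------------
# dense maps + quality gate
# ---------------------------------------------------------------------------

@dataclass
class ChunkAlignment:
    """Dense pull fields between two chunk reference frames.

    ``a_to_b`` holds, for each pixel of A's reference, the matching
    coordinate in B's reference (so warping B's data onto A samples at
    ``a_to_b``); ``b_to_a`` is the opposite direction."""

    source_chunk: int
    target_chunk: int
    a_to_b: np.ndarray
    b_to_a: np.ndarray
    reprojection_error_px: float = np.nan
    accepted: bool = False
    n_correspondences: int = 0
    warnings: list[str] = field(default_factory=list)


def reprojection_error(map_ab: np.ndarray, map_ba: np.ndarray,
                       mask: np.ndarray) -> float:
    """Mean ||p - map_ba(map_ab(p))|| over mask pixels p of A."""
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("empty evaluation mask")
    rr, cc = np.nonzero(mask)
    p = np.stack([rr, cc]).astype(float)
    pb = np.stack([map_coordinates(map_ab[i], p, order=1, mode="nearest")
                   for i in range(2)])
    pa = np.stack([map_coordinates(map_ba[i], pb, order=1, mode="nearest")
                   for i in range(2)])
    return float(np.hypot(*(pa - p)).mean())


def stitch_pair(
    master_a: np.ndarray,
    master_b: np.ndarray,
    cfg: StitchingConfig | None = None,
    silhouette_a: np.ndarray | None = None,
    silhouette_b: np.ndarray | None = None,
    correspondences: tuple[np.ndarray, np.ndarray] | None = None,
    source_chunk: int = 1,
    target_chunk: int = 0,
    eval_mask: np.ndarray | None = None,
    grid_mask: np.ndarray | None = None,
) -> ChunkAlignment:
    """Full alignment of chunk B onto chunk A with quality control.

    Coarse alignment uses silhouette ellipses when given, then manual
    correspondences, else the identity (sufficient when the coarse
    offset is within the phase-correlation capture range of one patch).
    """
    cfg = cfg or StitchingConfig()
    tr = None
    if silhouette_a is not None and silhouette_b is not None:
        try:
            tr = coarse_align(fit_ellipse(silhouette_a), fit_ellipse(silhouette_b),
                              correspondences, master_a, master_b)
        except ValueError as e:
            log.info("ellipse coarse alignment unavailable (%s)", e)
    if tr is None and correspondences is not None:
        tr = coarse_align(correspondences=correspondences)
    if tr is None:
        tr = SimilarityTransform()
    sel_mask = silhouette_a
    if grid_mask is not None:
        sel_mask = grid_mask if sel_mask is None else (
            (np.asarray(sel_mask) > 0) & grid_mask)
    pts_a, pts_b = refine_alignment(master_a, master_b, tr, cfg, mask_a=sel_mask)
    ga = to_grayscale(master_a)
    a_to_b = mls_dense_field(pts_a, pts_b, ga.shape, grid_step=cfg.grid_spacing // 2 or 8)
    b_to_a = mls_dense_field(pts_b, pts_a, ga.shape, grid_step=cfg.grid_spacing // 2 or 8)
    if eval_mask is None:
        h, w = ga.shape
        eval_mask = np.zeros((h, w), bool)
        mr, mc = int(0.1 * h), int(0.1 * w)
        eval_mask[mr:h - mr, mc:w - mc] = True
        if silhouette_a is not None:
            eval_mask &= np.asarray(silhouette_a) > 0
    err = reprojection_error(a_to_b, b_to_a, eval_mask)
    align = ChunkAlignment(
        source_chunk=source_chunk, target_chunk=target_chunk,
        a_to_b=a_to_b, b_to_a=b_to_a,
        reprojection_error_px=err,
        accepted=err <= cfg.max_reprojection_error_px,
        n_correspondences=len(pts_a),
    )
    if not align.accepted:
        log.warning("chunk pair (%d, %d) rejected: reprojection error %.2f px",
                    target_chunk, source_chunk, err)
    return align


def compose_fields(outer: np.ndarray, inner: np.ndarray) -> np.ndarray:
    """Pull-field composition: result[y] = inner(outer[y]).

    Warping with the result equals warping with ``inner`` first and the
    ``outer`` lookup second (bilinear interpolation of coordinates)."""
    return np.stack([
        map_coordinates(inner[i], outer, order=1, mode="nearest") for i in range(2)
    ])


def identity_field(shape: tuple[int, int]) -> np.ndarray:
    return np.mgrid[0:shape[0], 0:shape[1]].astype(float)
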