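"""Seeded synthetic skin videos with exact ground truth.

The generator emulates the features of real cephalopod-skin footage that
the pipeline must cope with: quasi-radial pigment organs that expand and
contract about anchors fixed in the skin, smooth global and local skin
deformation (breathing, drift), intermittent blur and brightness
dropouts, and shared motor-neuron drive across groups of radial muscles.
Every rendered frame comes with exact per-frame areas, per-sector areas,
the dense frame-to-reference displacement field, sharp-frame indicators
and the motor wiring, so each downstream stage has an oracle.

Model
-----
A chromatophore is a star-convex shape around an anchor: ``n_muscles``
radial muscles at equally spaced angles each hold a vertex at radius
``r_m(t)``; the boundary radius at intermediate angles is the linear
interpolation of the two neighbouring muscle radii in polar coordinates.
With constant radii the shape is therefore an exact disk, and the area
of the sector between two adjacent muscles has the closed form

    A_m = (dtheta / 6) * (r_m^2 + r_m * r_{m+1} + r_{m+1}^2).

Skin deformation is defined backwards, as the smooth field ``psi_t``
mapping frame coordinates to reference (= skin) coordinates; ``psi_0``
is the identity.  This field is exactly the quantity registration must
recover.  Coordinates are (row, col), 0-based, pixel centers at integer
coordinates, intervals half-open.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d, map_coordinates

log = logging.getLogger("chromatrack.synthetic")

_COLOR_RGB = {
    "dark": (45, 32, 30),
    "orange": (205, 115, 35),
    "yellow": (225, 205, 60),
}
_BACKGROUND_RGB = (182, 172, 158)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class ChromatophoreSpec:
    """One pigment organ: an anchor plus per-muscle radius time series.

    ``radius_signal`` has shape (n_frames, n_muscles), entries in pixels.
    """

    id: int
    anchor: tuple[float, float]  # (row, col), skin coordinates
    radius_signal: np.ndarray
    n_muscles: int = 12
    color: str = "dark"
    orientation: float = 0.0  # angle of muscle 0, radians

    def __post_init__(self) -> None:
        self.radius_signal = np.asarray(self.radius_signal, dtype=float)
        if self.radius_signal.ndim != 2 or self.radius_signal.shape[1] != self.n_muscles:
            raise ValueError("radius_signal must have shape (n_frames, n_muscles)")
        if np.any(self.radius_signal < 0):
            raise ValueError("radial extents must be >= 0")
        if self.n_muscles < 3:
            raise ValueError("n_muscles must be >= 3")
        if self.color not in _COLOR_RGB:
            raise ValueError(f"unknown color class {self.color!r}")

    @property
    def muscle_angles(self) -> np.ndarray:
        return self.orientation + 2.0 * np.pi * np.arange(self.n_muscles) / self.n_muscles

    @property
    def max_radius(self) -> float:
        return float(self.radius_signal.max())

    def is_constant(self, tol: float = 1e-9) -> bool:
        return bool(np.all(self.radius_signal.var(axis=0) < tol))


@dataclass
class MotorDrive:
    """Shared motor-neuron drive: sources in [0, 1] wired onto muscles."""

    source_signals: np.ndarray  # (n_sources, n_frames)
    wiring: dict[tuple[int, int], int]  # (chromatophore id, muscle index) -> source id

    def __post_init__(self) -> None:
        self.source_signals = np.asarray(self.source_signals, dtype=float)
        if self.source_signals.ndim != 2:
            raise ValueError("source_signals must be (n_sources, n_frames)")
        if np.any(self.source_signals < 0) or np.any(self.source_signals > 1):
            raise ValueError("source signals must lie in [0, 1]")
        used = set(self.wiring.values())
        for s in used:
            if not (0 <= s < self.n_sources):
                raise ValueError(f"wiring references unknown source {s}")

    @property
    def n_sources(self) -> int:
        return self.source_signals.shape[0]

    def sources_of(self, chrom_id: int) -> set[int]:
        return {s for (cid, _m), s in self.wiring.items() if cid == chrom_id}


@dataclass
class DeformationSpec:
    breathing_amplitude_px: float = 1.5
    breathing_period_frames: float = 40.0
    drift_velocity_px: tuple[float, float] = (0.02, 0.03)  # (row, col) per frame
    local_amplitude_px: float = 0.8
    local_corr_length_px: float = 64.0
    local_period_frames: float = 90.0
    seed: int = 0


@dataclass
class DegradationSpec:
    """Episodic image degradation; intervals are half-open [start, end)."""

    blur_episodes: list[tuple[int, int, float]] = field(default_factory=list)
    brightness_episodes: list[tuple[int, int, float]] = field(default_factory=list)
    noise_sigma: float = 2.0

    def validate(self, n_frames: int) -> None:
        for s, e, _ in list(self.blur_episodes) + list(self.brightness_episodes):
            if not (0 <= s < e <= n_frames):
                raise ValueError(f"episode [{s}, {e}) outside video of {n_frames} frames")

    def sharp_indicator(self, n_frames: int) -> np.ndarray:
        sharp = np.ones(n_frames, dtype=bool)
        for s, e, _ in list(self.blur_episodes) + list(self.brightness_episodes):
            sharp[s:e] = False
        return sharp


# ---------------------------------------------------------------------------
# deformation model
# ---------------------------------------------------------------------------

class DeformationModel:
    """Evaluates the frame-to-reference field psi_t(y) = y + b_t(y).

    b_t is a sum of a linear drift, a radial breathing term that vanishes
    at the canvas center, and a smooth random local warp; every term is
    zero at t = 0 so the first frame is the reference.
    """

    def __init__(self, spec: DeformationSpec, shape: tuple[int, int]):
        self.spec = spec
        self.shape = shape
        h, w = shape
        rng = np.random.default_rng(spec.seed)
        # smooth unit-normalized random vector field for the local warp
        raw = rng.standard_normal((2, h, w))
        sig = max(spec.local_corr_length_px / 2.0, 1.0)
        fld = np.stack([gaussian_filter(raw[i], sig, mode="reflect") for i in range(2)])
        amp = np.abs(fld).max()
        self._local = (fld / amp if amp > 0 else fld).astype(np.float64)
        self._center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        self._rscale = max(h, w) / 2.0
        self._phase = rng.uniform(0, 2 * np.pi)

    def _coeffs(self, t: float) -> tuple[float, float]:
        s = self.spec
        breath = s.breathing_amplitude_px * np.sin(2 * np.pi * t / s.breathing_period_frames)
        local = s.local_amplitude_px * np.sin(2 * np.pi * t / s.local_period_frames)
        return breath, local

    def displacement(self, t: float, points: np.ndarray) -> np.ndarray:
        """b_t at ``points`` (shape (2, ...), row/col); psi = points + b."""
        pts = np.asarray(points, dtype=float)
        breath, local = self._coeffs(t)
        s = self.spec
        drift = -np.asarray(s.drift_velocity_px, float)[:, None] * t
        radial = (pts - self._center.reshape(2, *([1] * (pts.ndim - 1)))) / self._rscale
        loc = np.stack([
            map_coordinates(self._local[i], pts.reshape(2, -1), order=1, mode="nearest")
            for i in range(2)
        ]).reshape(pts.shape)
        b = drift.reshape(2, *([1] * (pts.ndim - 1))) - breath * radial - local * loc
        return b

    def to_reference(self, t: float, points: np.ndarray) -> np.ndarray:
        """psi_t: frame coordinates -> reference coordinates."""
        return np.asarray(points, float) + self.displacement(t, points)

    def to_frame(self, t: float, ref_points: np.ndarray, n_iter: int = 4) -> np.ndarray:
        """psi_t^{-1} by fixed-point iteration (the field is a contraction
        at the stated amplitudes)."""
        ref = np.asarray(ref_points, dtype=float)
        y = ref.copy()
        for _ in range(n_iter):
            y = ref - self.displacement(t, y)
        return y

    def dense_field(self, t: float) -> np.ndarray:
        """Reference coordinates of every frame pixel, shape (2, H, W)."""
        h, w = self.shape
        grid = np.mgrid[0:h, 0:w].astype(float)
        return self.to_reference(t, grid)

    def max_jacobian_distortion(self, t: float) -> float:
        """Max |J - I| entry of the field's Jacobian; < 0.5 guarantees
        invertibility of psi_t at the stated amplitudes."""
        f = self.dense_field(t)
        dr = np.gradient(f[0], axis=0) - 1.0, np.gradient(f[0], axis=1)
        dc = np.gradient(f[1], axis=0), np.gradient(f[1], axis=1) - 1.0
        return float(max(np.abs(x).max() for x in (*dr, *dc)))


# ---------------------------------------------------------------------------
# star-convex shape helpers
# ---------------------------------------------------------------------------

def boundary_radius(theta: np.ndarray, radii: np.ndarray, orientation: float = 0.0) -> np.ndarray:
    """Boundary radius at polar angles ``theta`` for per-muscle vertex radii.

    Linear interpolation of the radius in the angle between the two
    neighbouring muscles; constant radii give an exact circle.
    """
    m = len(radii)
    step = 2 * np.pi / m
    rel = np.mod(np.asarray(theta) - orientation, 2 * np.pi)
    idx = np.floor(rel / step).astype(int) % m
    frac = rel / step - np.floor(rel / step)
    r0 = np.asarray(radii)[idx]
    r1 = np.asarray(radii)[(idx + 1) % m]
    return r0 * (1 - frac) + r1 * frac


def sector_areas(radii: np.ndarray) -> np.ndarray:
    """Exact area of each inter-muscle sector of the star-convex shape.

    Integrating r(theta)^2 / 2 with r linear in theta over one sector:
    (dtheta / 6) * (r0^2 + r0*r1 + r1^2).
    """
    radii = np.asarray(radii, dtype=float)
    m = radii.shape[-1]
    step = 2 * np.pi / m
    r1 = np.roll(radii, -1, axis=-1)
    return (step / 6.0) * (radii**2 + radii * r1 + r1**2)


def shape_area(radii: np.ndarray) -> np.ndarray:
    return sector_areas(radii).sum(axis=-1)


# ---------------------------------------------------------------------------
# ground truth container
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    specs: list[ChromatophoreSpec]
    drive: MotorDrive | None
    deformation: DeformationModel
    degradation: DegradationSpec
    areas_px: np.ndarray          # (C, T) pixel count of the rendered mask
    polygon_areas: np.ndarray     # (C, T) analytic shape area
    gt_sector_areas: np.ndarray   # (C, n_muscles, T) analytic sector areas
    anchor_positions: np.ndarray  # (C, T, 2) anchor in frame coordinates
    sharp: np.ndarray             # (T,) bool
    warnings: list[str] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.sharp.shape[0]

    @property
    def chrom_ids(self) -> list[int]:
        return [s.id for s in self.specs]

    def sharp_runs(self, min_length: int = 1) -> list[tuple[int, int]]:
        """Half-open intervals of consecutive sharp frames (the ground
        truth for chunk detection)."""
        runs: list[tuple[int, int]] = []
        start = None
        for i, ok in enumerate(self.sharp):
            if ok and start is None:
                start = i
            elif not ok and start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, self.n_frames))
        return [(s, e) for s, e in runs if e - s >= min_length]

    def displacement_field(self, t: float) -> np.ndarray:
        return self.deformation.dense_field(t)

    def save_areas_csv(self, path: str | Path) -> None:
        import pandas as pd

        rows = []
        for ci, spec in enumerate(self.specs):
            for t in range(self.n_frames):
                rows.append((t, spec.id, self.areas_px[ci, t], self.polygon_areas[ci, t]))
        pd.DataFrame(rows, columns=["frame", "chromatophore_id", "area_px2", "polygon_area"]).to_csv(
            path, index=False
        )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _make_texture(shape: tuple[int, int], rng: np.random.Generator, pad: int) -> np.ndarray:
    """Low-amplitude smooth mottle so flow/phase-correlation have signal
    off-chromatophore (flat skin would make registration ill-posed)."""
    h, w = shape
    base = np.empty((h + 2 * pad, w + 2 * pad, 3), dtype=float)
    shape2 = (h + 2 * pad, w + 2 * pad)
    coarse = gaussian_filter(rng.standard_normal(shape2), 6.0)
    mid = gaussian_filter(rng.standard_normal(shape2), 3.0)
    fine = gaussian_filter(rng.standard_normal(shape2), 1.0)
    mottle = (
        6.0 * coarse / max(coarse.std(), 1e-12)
        + 10.0 * mid / max(mid.std(), 1e-12)
        + 3.0 * fine / max(fine.std(), 1e-12)
    )
    mottle = np.clip(mottle, -45.0, 45.0)
    for ch, v in enumerate(_BACKGROUND_RGB):
        base[..., ch] = v + mottle
    return base


def generate_video(
    specs: list[ChromatophoreSpec],
    drive: MotorDrive | None,
    deform: DeformationSpec,
    degrade: DegradationSpec,
    n_frames: int,
    seed: int,
    shape: tuple[int, int] = (512, 512),
) -> tuple[np.ndarray, GroundTruth]:
    """Render a synthetic skin video; returns (frames, ground truth).

    frames: (T, H, W, 3) uint8.  Deterministic for a given seed.
    """
    h, w = shape
    n_ch = len(specs)
    rng = np.random.default_rng(seed)
    degrade.validate(n_frames)
    for s in specs:
        if s.radius_signal.shape[0] != n_frames:
            raise ValueError(f"chromatophore {s.id}: radius_signal length != n_frames")
        margin = s.max_radius + 2.0
        if not (margin <= s.anchor[0] <= h - 1 - margin and margin <= s.anchor[1] <= w - 1 - margin):
            raise ValueError(f"chromatophore {s.id} can leave the canvas at maximal extent")

    warn_list: list[str] = []
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            d = np.hypot(
                specs[i].anchor[0] - specs[j].anchor[0], specs[i].anchor[1] - specs[j].anchor[1]
            )
            if d < specs[i].max_radius + specs[j].max_radius:
                msg = f"chromatophores {specs[i].id} and {specs[j].id} overlap at maximal extent"
                warn_list.append(msg)
                _warnings.warn(msg, stacklevel=2)

    model = DeformationModel(deform, shape)
    pad = int(np.ceil(abs(np.asarray(deform.drift_velocity_px)).max() * n_frames
                      + deform.breathing_amplitude_px + deform.local_amplitude_px)) + 4
    texture = _make_texture(shape, rng, pad)

    frames = np.empty((n_frames, h, w, 3), dtype=np.uint8)
    areas_px = np.zeros((n_ch, n_frames))
    poly_areas = np.zeros((n_ch, n_frames))
    sect = np.zeros((n_ch, specs[0].n_muscles if specs else 0, n_frames))
    anchor_pos = np.zeros((n_ch, n_frames, 2))
    grid = np.mgrid[0:h, 0:w].astype(float)

    blur_sigma = np.zeros(n_frames)
    for s_, e_, sig in degrade.blur_episodes:
        blur_sigma[s_:e_] = np.maximum(blur_sigma[s_:e_], sig)
    bright = np.ones(n_frames)
    for s_, e_, sc in degrade.brightness_episodes:
        bright[s_:e_] *= sc

    for t in range(n_frames):
        skin = model.to_reference(t, grid)  # (2, H, W) reference coords per pixel
        img = np.stack(
            [
                map_coordinates(texture[..., ch], skin + pad, order=1, mode="nearest")
                for ch in range(3)
            ],
            axis=-1,
        )
        for ci, spec in enumerate(specs):
            radii = spec.radius_signal[t]
            if sect.shape[1] == spec.n_muscles:
                sect[ci, :, t] = sector_areas(radii)
            poly_areas[ci, t] = shape_area(radii)
            af = model.to_frame(t, np.asarray(spec.anchor, float))
            anchor_pos[ci, t] = af
            rmax = radii.max()
            if rmax <= 0:
                continue
            ext = rmax + 3.0
            r0, r1 = int(max(0, np.floor(af[0] - ext))), int(min(h, np.ceil(af[0] + ext) + 1))
            c0, c1 = int(max(0, np.floor(af[1] - ext))), int(min(w, np.ceil(af[1] + ext) + 1))
            if r0 >= r1 or c0 >= c1:
                continue
            sk = skin[:, r0:r1, c0:c1]
            dr = sk[0] - spec.anchor[0]
            dc = sk[1] - spec.anchor[1]
            dist = np.hypot(dr, dc)
            theta = np.mod(np.arctan2(dr, dc), 2 * np.pi)
            inside = dist <= boundary_radius(theta, radii, spec.orientation)
            areas_px[ci, t] = int(inside.sum())
            win = img[r0:r1, c0:c1]
            win[inside] = _COLOR_RGB[spec.color]

        if blur_sigma[t] > 0:
            img = gaussian_filter(img, (blur_sigma[t], blur_sigma[t], 0))
        img = img * bright[t]
        if degrade.noise_sigma > 0:
            img = img + rng.normal(0, degrade.noise_sigma, img.shape)
        frames[t] = np.clip(img, 0, 255).astype(np.uint8)

    gt = GroundTruth(
        specs=specs,
        drive=drive,
        deformation=model,
        degradation=degrade,
        areas_px=areas_px,
        polygon_areas=poly_areas,
        gt_sector_areas=sect,
        anchor_positions=anchor_pos,
        sharp=degrade.sharp_indicator(n_frames),
        warnings=warn_list,
    )
    return frames, gt


def make_motion_markers(specs: list[ChromatophoreSpec], tol: float = 1e-9) -> list[int]:
    """Ids of chromatophores with constant radius series (inert fiducials).

    Raises if fewer than three qualify: the downstream Delaunay
    triangulation needs at least three points.
    """
    ids = [s.id for s in specs if s.is_constant(tol)]
    if len(ids) < 3:
        raise ValueError(
            f"only {len(ids)} constant-size chromatophores; need >= 3 motion markers"
        )
    return ids


# ---------------------------------------------------------------------------
# scene builders
# ---------------------------------------------------------------------------

def _smooth_drive(n_sources: int, n_frames: int, rng: np.random.Generator,
                  smooth: float = 6.0) -> np.ndarray:
    """Independent smooth burst-like source signals in [0, 1]."""
    sig = np.zeros((n_sources, n_frames))
    for s in range(n_sources):
        # random telegraph bursts, smoothed, rescaled to [0, 1]
        state, x = 0.0, np.zeros(n_frames)
        flips = rng.random(n_frames) < 0.05
        for t in range(n_frames):
            if flips[t]:
                state = 1.0 - state
            x[t] = state
        y = gaussian_filter1d(x + 0.08 * rng.standard_normal(n_frames), smooth)
        y -= y.min()
        m = y.max()
        sig[s] = y / m if m > 0 else y
    return sig


def _place_anchors(
    n: int, shape: tuple[int, int], margin: float, min_sep: float, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample anchor positions with a minimum separation."""
    h, w = shape
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        p = rng.uniform([margin, margin], [h - 1 - margin, w - 1 - margin])
        if all(np.hypot(*(p - q)) >= min_sep for q in pts):
            pts.append(p)
        tries += 1
        if tries > 20000:
            raise RuntimeError("cannot place anchors with requested separation")
    return np.array(pts)


def make_scene(
    n_chrom: int = 20,
    n_markers: int = 5,
    n_sources: int = 4,
    n_frames: int = 200,
    shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    r_max_range: tuple[float, float] = (9.0, 13.0),
    r_contract: float = 2.5,
    #: marker diameter 10 px honours the resolution floor below which
    #: segmentation becomes unreliable (organs should span >= 10 px)
    marker_radius: float = 5.0,
    n_muscles: int = 12,
    max_sources_per_chrom: int = 3,
    color_mode: bool = False,
) -> tuple[list[ChromatophoreSpec], MotorDrive]:
    """Build a standard scene: ``n_chrom`` driven chromatophores plus
    ``n_markers`` small constant-size ones acting as motion markers.

    Muscles of one chromatophore are wired to 1..max_sources_per_chrom
    motor sources in contiguous arcs, emulating sectorial innervation.
    """
    rng = np.random.default_rng(seed)
    total = n_chrom + n_markers
    max_r = r_max_range[1]
    anchors = _place_anchors(total, shape, margin=max_r + 4, min_sep=2 * max_r + 6, rng=rng)
    sources = _smooth_drive(n_sources, n_frames, rng)
    wiring: dict[tuple[int, int], int] = {}
    specs: list[ChromatophoreSpec] = []
    colors = ["dark", "orange", "yellow"] if color_mode else ["dark"]

    for i in range(n_chrom):
        rmax = rng.uniform(*r_max_range)
        k = int(rng.integers(1, max_sources_per_chrom + 1))
        chosen = rng.choice(n_sources, size=min(k, n_sources), replace=False)
        # contiguous arcs of muscles per source
        cuts = np.sort(rng.choice(np.arange(1, n_muscles), size=len(chosen) - 1, replace=False)) \
            if len(chosen) > 1 else np.array([], dtype=int)
        bounds = np.concatenate([[0], cuts, [n_muscles]])
        radii = np.zeros((n_frames, n_muscles))
        for gi, src in enumerate(chosen):
            for m in range(bounds[gi], bounds[gi + 1]):
                wiring[(i, m)] = int(src)
                radii[:, m] = r_contract + (rmax - r_contract) * sources[src]
        specs.append(
            ChromatophoreSpec(
                id=i,
                anchor=tuple(anchors[i]),
                radius_signal=radii,
                n_muscles=n_muscles,
                color=colors[i % len(colors)],
            )
        )
    for j in range(n_markers):
        cid = n_chrom + j
        radii = np.full((n_frames, n_muscles), marker_radius)
        specs.append(
            ChromatophoreSpec(
                id=cid, anchor=tuple(anchors[cid]), radius_signal=radii, n_muscles=n_muscles
            )
        )
    drive = MotorDrive(source_signals=sources, wiring=wiring)
    return specs, drive


def generate_slice_scene(
    n_chrom: int = 30,
    n_sources: int = 4,
    n_frames: int = 300,
    n_muscles: int = 12,
    n_slices: int = 36,
    snr: float = 10.0,
    seed: int = 0,
    max_sources_per_chrom: int = 3,
) -> tuple[np.ndarray, MotorDrive, np.ndarray]:
    """Slice-area series straight from the muscle model (no rendering).

    Returns (slice_areas with shape (n_chrom, n_slices, n_frames), drive,
    true source count per chromatophore).  Measurement noise is additive
    Gaussian with a per-chromatophore standard deviation of
    signal_std / snr.
    """
    rng = np.random.default_rng(seed)
    sources = _smooth_drive(n_sources, n_frames, rng)
    wiring: dict[tuple[int, int], int] = {}
    slice_series = np.zeros((n_chrom, n_slices, n_frames))
    true_k = np.zeros(n_chrom, dtype=int)
    step = 2 * np.pi / n_slices
    slice_centers = step * (np.arange(n_slices) + 0.5)

    for i in range(n_chrom):
        rmax = rng.uniform(9.0, 13.0)
        k = int(rng.integers(1, max_sources_per_chrom + 1))
        chosen = rng.choice(n_sources, size=min(k, n_sources), replace=False)
        cuts = np.sort(rng.choice(np.arange(1, n_muscles), size=len(chosen) - 1, replace=False)) \
            if len(chosen) > 1 else np.array([], dtype=int)
        bounds = np.concatenate([[0], cuts, [n_muscles]])
        radii = np.zeros((n_frames, n_muscles))
        for gi, src in enumerate(chosen):
            for m in range(bounds[gi], bounds[gi + 1]):
                wiring[(i, m)] = int(src)
                radii[:, m] = 2.5 + (rmax - 2.5) * sources[src]
        true_k[i] = len(chosen)
        # slice area by the pipeline's own definition: pi * rbar^2 / n,
        # with rbar the boundary radius at the slice center angle
        for t in range(n_frames):
            rb = boundary_radius(slice_centers, radii[t])
            slice_series[i, :, t] = np.pi * rb**2 / n_slices
        sd = slice_series[i].std()
        slice_series[i] += rng.normal(0, sd / snr, slice_series[i].shape)
    return slice_series, MotorDrive(source_signals=sources, wiring=wiring), true_k


# ---------------------------------------------------------------------------
# i/o
# ---------------------------------------------------------------------------

def save_frames(frames: np.ndarray, out_dir: str | Path) -> Path:
    """Write frames losslessly as a directory of numbered PNGs."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for t, fr in enumerate(frames):
        iio.imwrite(out / f"frame_{t:06d}.png", fr)
    return out
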