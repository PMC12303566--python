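"""Stage drivers: one function per pipeline verb, plus ``run_all``.

Stages communicate only through dataset artifacts (chunk table CSV,
per-chunk mask stacks, point-track archives, masterframes, alignment
fields, cleanqueen, series CSVs), so each can be re-run independently;
the manifest skips stages whose inputs and config are unchanged.  Dense
displacement maps are never persisted — they are rebuilt on demand from
the (small) point tracks, which keeps artifacts compact and every stage
deterministic for a given seed.
"""

from __future__ import annotations

import logging
from functools import lru_cache

import numpy as np
import pandas as pd

from . import anisotropy as aniso
from . import chunking as ck
from . import motor_units as mu
from . import registration as reg
from . import segmentation as seg
from . import stitching as st
from . import territories as terr
from .dataset import Dataset, StageError
from .longterm import CorrespondenceSet, match_territories, matches_to_csv, prealign

log = logging.getLogger("chromatrack.pipeline")


class QualityGateError(StageError):
    """A stage's quality gate failed (registration halt or stitch
    rejection); exit code 2 at the CLI."""


# ---------------------------------------------------------------------------
# stage: chunk
# ---------------------------------------------------------------------------

def run_chunk(ds: Dataset, frames: np.ndarray | None = None) -> list[ck.Chunk]:
    if ds.is_current("chunk"):
        return ck.chunks_from_csv(ds.path("chunks.csv"))
    ds.check_prerequisites("chunk")
    if frames is None:
        frames = ck.load_video(ds.video_source)
    s1, s2 = ds.config.dog_sigmas()
    scores = ck.score_frames(frames, s1, s2)
    scores.to_frame().to_csv(ds.path("scores.csv"), index=False)
    cfg = ds.config.chunking
    thr = cfg.focus_threshold
    if thr is None:
        thr = ck.relative_focus_threshold(scores.focus, cfg.rel_focus_fraction)
    chunks = ck.detect_chunks(scores, thr, cfg.brightness_threshold, cfg.min_chunk_length)
    ck.chunks_to_csv(chunks, ds.path("chunks.csv"))
    ds.mark_done("chunk", n_chunks=len(chunks), focus_threshold=thr)
    return chunks


# ---------------------------------------------------------------------------
# stage: segment
# ---------------------------------------------------------------------------

def _build_classifier(ds: Dataset) -> seg.PixelClassifier:
    cfg = ds.config.segmentation
    train_dir = ds.root / "training"
    if cfg.classifier == "random_forest" or (
        cfg.classifier == "majority" and train_dir.exists()
    ):
        pass  # handled below
    if train_dir.exists():
        import imageio.v3 as iio

        imgs = [iio.imread(p) for p in sorted(train_dir.glob("image_*.png"))]
        labs = [iio.imread(p) for p in sorted(train_dir.glob("labels_*.png"))]
        if not imgs or len(imgs) != len(labs):
            raise StageError("training/ must hold paired image_*.png / labels_*.png")
        lut = seg.ColorLookupTable(cfg.color_space, cfg.quantization).fit(imgs, labs)
        if cfg.classifier == "lookup":
            return lut
        rf = seg.RandomForestPixelClassifier(
            cfg.rf_scales, cfg.rf_n_estimators, cfg.rf_max_depth, seed=ds.config.seed
        ).fit(imgs, labs)
        if cfg.classifier == "random_forest":
            return rf
        return _MajorityClassifier([lut, rf])
    # no annotations: nominal-palette lookup (synthetic footage default)
    return seg.default_lookup_for_synthetic()


class _MajorityClassifier(seg.PixelClassifier):
    """Majority-vote fusion of several fitted classifiers (three voters:
    the two inputs plus their agreement; with two, ties go background)."""

    def __init__(self, members):
        self.members = members

    def predict(self, frame):
        return seg.majority_vote([m.predict(frame) for m in self.members])


def run_segment(ds: Dataset, frames: np.ndarray | None = None) -> list[np.ndarray]:
    chunks = run_chunk(ds, frames)
    if ds.is_current("segment"):
        return [np.load(ds.path("masks", f"chunk_{c.id:03d}.npy")) for c in chunks]
    ds.check_prerequisites("segment")
    if frames is None:
        frames = ck.load_video(ds.video_source)
    classifier = _build_classifier(ds)
    out = []
    for view in ck.split_video(frames, chunks):
        masks = seg.segment_video(view, classifier, ds.config.segmentation.min_component_px)
        np.save(ds.path("masks", f"chunk_{view.chunk.id:03d}.npy"), masks)
        out.append(masks)
    ds.mark_done("segment")
    return out


# ---------------------------------------------------------------------------
# stage: register
# ---------------------------------------------------------------------------

def run_register(ds: Dataset, frames: np.ndarray | None = None) -> dict[int, reg.ChunkRegistration]:
    chunks = run_chunk(ds, frames)
    if not ds.is_current("segment"):
        run_segment(ds, frames)
    if ds.is_current("register"):
        return _load_registrations(ds, chunks)
    ds.check_prerequisites("register")
    if frames is None:
        frames = ck.load_video(ds.video_source)
    cfg = ds.config.registration
    rng = np.random.default_rng(ds.config.seed)
    rows = []
    usable = {}
    for view in ck.split_video(frames, chunks):
        cid = view.chunk.id
        masks = np.load(ds.path("masks", f"chunk_{cid:03d}.npy"))
        try:
            creg = reg.register_chunk(view, masks[0], cfg, chunk_id=cid,
                                      max_step=ds.config.lk_max_step(), rng=rng,
                                      masks=masks)
        except reg.RegistrationError as e:
            log.warning("chunk %d unusable: %s", cid, e)
            rows.append((cid, False, 0))
            continue
        np.savez(
            ds.path("tracks", f"chunk_{cid:03d}.npz"),
            points=creg.tracks.points,
            positions=creg.tracks.positions,
            alive=creg.tracks.alive,
            component_area=creg.tracks.component_area,
        )
        creg.report().to_csv(ds.path("tracks", f"report_{cid:03d}.csv"), index=False)
        # masterframe: mean of the registered grayscale frames, plus the
        # per-pixel fraction of frames in which the pixel shows skin
        # (not pigment) — stitching uses it to avoid correlating patches
        # dominated by organs whose expansion state differs across chunks
        acc = np.zeros(creg.shape)
        cnt_bg = np.zeros(creg.shape)
        for t, fr in enumerate(view):
            dmap = creg.displacement_map(t)
            acc += reg.warp_image(ck.to_grayscale(fr), dmap.ref_to_frame, order=1)
            cnt_bg += reg.warp_image((masks[t] == 0).astype(float),
                                     dmap.ref_to_frame, order=1)
        np.save(ds.path("masterframes", f"chunk_{cid:03d}.npy"), acc / len(view))
        np.save(ds.path("masterframes", f"bgfrac_{cid:03d}.npy"),
                (cnt_bg / len(view)).astype(np.float32))
        usable[cid] = creg
        rows.append((cid, True, creg.tracks.alive[-1].sum()))
    pd.DataFrame(rows, columns=["chunk_id", "usable", "alive_at_end"]).to_csv(
        ds.path("registration_summary.csv"), index=False
    )
    if not usable:
        raise QualityGateError("registration failed for every chunk")
    ds.mark_done("register", usable=[int(c) for c in usable])
    return usable


def _load_registrations(ds: Dataset, chunks) -> dict[int, reg.ChunkRegistration]:
    out = {}
    for c in chunks:
        f = ds.path("tracks", f"chunk_{c.id:03d}.npz")
        if not f.exists():
            continue
        z = np.load(f)
        tracks = reg.TrackPointSet(
            z["points"], z["positions"], z["alive"],
            z["component_area"] if "component_area" in z else None,
        )
        shape = np.load(ds.path("masterframes", f"chunk_{c.id:03d}.npy")).shape
        out[c.id] = reg.ChunkRegistration(c.id, tracks, shape, ds.config.registration)
    return out


# ---------------------------------------------------------------------------
# stage: stitch
# ---------------------------------------------------------------------------

def run_stitch(ds: Dataset, frames: np.ndarray | None = None) -> dict[int, st.ChunkAlignment]:
    run_register(ds, frames)
    chunks = run_chunk(ds, frames)
    if ds.is_current("stitch"):
        return _load_alignments(ds)
    ds.check_prerequisites("stitch")
    usable = sorted(
        c.id for c in chunks if ds.path("tracks", f"chunk_{c.id:03d}.npz").exists()
    )
    aligns: dict[int, st.ChunkAlignment] = {}
    rows = []
    cfg = ds.config.stitching
    for prev, cur in zip(usable, usable[1:]):
        ma = np.load(ds.path("masterframes", f"chunk_{prev:03d}.npy"))
        mb = np.load(ds.path("masterframes", f"chunk_{cur:03d}.npy"))
        grid_mask = None
        fa = ds.path("masterframes", f"bgfrac_{prev:03d}.npy")
        fb = ds.path("masterframes", f"bgfrac_{cur:03d}.npy")
        if fa.exists() and fb.exists():
            grid_mask = st.texture_grid_mask(np.load(fa), np.load(fb),
                                             cfg.patch_size)
        try:
            al = st.stitch_pair(ma, mb, cfg, source_chunk=cur,
                                target_chunk=prev, grid_mask=grid_mask)
        except RuntimeError as e:
            log.warning("stitching %d->%d failed: %s", cur, prev, e)
            al = st.ChunkAlignment(cur, prev, st.identity_field(ma.shape),
                                   st.identity_field(ma.shape),
                                   reprojection_error_px=np.inf, accepted=False)
        np.savez(
            ds.path("alignments", f"pair_{prev:03d}_{cur:03d}.npz"),
            a_to_b=al.a_to_b.astype(np.float32),
            b_to_a=al.b_to_a.astype(np.float32),
            error=al.reprojection_error_px,
            accepted=al.accepted,
        )
        aligns[cur] = al
        rows.append((prev, cur, al.reprojection_error_px, al.accepted))
    pd.DataFrame(rows, columns=["target", "source", "reprojection_error_px", "accepted"]).to_csv(
        ds.path("stitching_errors.csv"), index=False
    )
    ds.mark_done("stitch")
    return aligns


def _load_alignments(ds: Dataset) -> dict[int, st.ChunkAlignment]:
    out = {}
    for f in sorted((ds.root / "alignments").glob("pair_*.npz")):
        z = np.load(f)
        _, a, b = f.stem.split("_")
        out[int(b)] = st.ChunkAlignment(
            int(b), int(a), z["a_to_b"].astype(float), z["b_to_a"].astype(float),
            float(z["error"]), bool(z["accepted"]),
        )
    return out


# ---------------------------------------------------------------------------
# global composition helpers
# ---------------------------------------------------------------------------

class GlobalMaps:
    """Composed pull fields between frames and the global reference
    (= the reference of the first accepted chunk)."""

    def __init__(self, ds: Dataset, frames):
        self.ds = ds
        self.frames = frames
        self.chunks = run_chunk(ds, frames)
        self.regs = _load_registrations(ds, self.chunks)
        self.aligns = _load_alignments(ds)
        self.shape = next(iter(self.regs.values())).shape if self.regs else None
        self.usable = sorted(self.regs)
        self.accepted = self._accepted_chunks()
        self._g2k: dict[int, np.ndarray] = {}
        self._k2g: dict[int, np.ndarray] = {}

    def _accepted_chunks(self) -> list[int]:
        if not self.usable:
            return []
        ok = [self.usable[0]]
        for cid in self.usable[1:]:
            al = self.aligns.get(cid)
            if al is not None and al.accepted and al.target_chunk in ok:
                ok.append(cid)
        return ok

    def chunk_of_frame(self, t: int):
        for c in self.chunks:
            if c.start <= t < c.end:
                return c
        return None

    def global_to_chunk(self, cid: int) -> np.ndarray:
        if cid not in self._g2k:
            if cid == self.accepted[0]:
                self._g2k[cid] = st.identity_field(self.shape)
            else:
                al = self.aligns[cid]
                self._g2k[cid] = st.compose_fields(
                    self.global_to_chunk(al.target_chunk), al.a_to_b
                )
        return self._g2k[cid]

    def chunk_to_global(self, cid: int) -> np.ndarray:
        if cid not in self._k2g:
            if cid == self.accepted[0]:
                self._k2g[cid] = st.identity_field(self.shape)
            else:
                al = self.aligns[cid]
                self._k2g[cid] = st.compose_fields(
                    al.b_to_a, self.chunk_to_global(al.target_chunk)
                )
        return self._k2g[cid]

    @lru_cache(maxsize=8)
    def frame_to_global(self, t: int) -> np.ndarray | None:
        """Field on frame-t pixels giving global reference coords."""
        c = self.chunk_of_frame(t)
        if c is None or c.id not in self.accepted:
            return None
        dmap = self.regs[c.id].displacement_map(t - c.start)
        return st.compose_fields(dmap.frame_to_ref, self.chunk_to_global(c.id))

    def global_to_frame(self, t: int) -> np.ndarray | None:
        c = self.chunk_of_frame(t)
        if c is None or c.id not in self.accepted:
            return None
        dmap = self.regs[c.id].displacement_map(t - c.start)
        return st.compose_fields(self.global_to_chunk(c.id), dmap.ref_to_frame)

    def mask_of_frame(self, t: int) -> np.ndarray | None:
        c = self.chunk_of_frame(t)
        if c is None:
            return None
        masks = np.load(self.ds.path("masks", f"chunk_{c.id:03d}.npy"), mmap_mode="r")
        return np.asarray(masks[t - c.start])

    @property
    def n_frames(self) -> int:
        return max(c.end for c in self.chunks) if self.chunks else 0


# ---------------------------------------------------------------------------
# stage: area
# ---------------------------------------------------------------------------

def run_area(ds: Dataset, frames: np.ndarray | None = None):
    run_stitch(ds, frames)
    if ds.is_current("area"):
        cq = terr.Cleanqueen(np.load(ds.path("cleanqueen.npy")))
        df = pd.read_csv(ds.path("areas.csv"))
        return cq, _areas_from_tidy(df)
    ds.check_prerequisites("area")
    if frames is None:
        frames = ck.load_video(ds.video_source)
    gm = GlobalMaps(ds, frames)
    if not gm.accepted:
        raise QualityGateError("no accepted chunks: cannot build territories")
    n_total = len(frames)

    # pass 1: occupancy on the global reference
    occ = np.zeros(gm.shape, np.float32)
    n_valid = 0
    for t in range(n_total):
        fld = gm.global_to_frame(t)
        if fld is None:
            continue
        m = reg.warp_image(gm.mask_of_frame(t) > 0, fld, order=0)
        occ += m.astype(np.float32)
        n_valid += 1
    occ /= max(n_valid, 1)
    cq = terr.build_cleanqueen(
        occupancy=occ, cfg=ds.config.territories,
        expected_diameter_px=ds.config.video.expected_diameter_px,
    )
    np.save(ds.path("cleanqueen.npy"), cq.labels)
    cq.to_csv(ds.path("cleanqueen.csv"))

    # pass 2: per-frame areas through the inverse maps
    def fields():
        for t in range(n_total):
            yield gm.frame_to_global(t)

    def masks():
        for t in range(n_total):
            m = gm.mask_of_frame(t)
            yield m if m is not None else np.zeros(gm.shape, np.uint8)

    series = terr.area_series(masks(), cq, fields())
    series.to_csv(ds.path("areas.csv"))
    ds.mark_done("area", n_territories=int(len(cq.ids)))
    return cq, series


def _areas_from_tidy(df: pd.DataFrame) -> terr.AreaSeries:
    pivot = df.pivot(index="chromatophore_id", columns="frame", values="area_px2")
    valid = df.groupby("frame")["valid"].first().sort_index().to_numpy()
    return terr.AreaSeries(
        ids=pivot.index.to_numpy(), areas=pivot.to_numpy(), valid=valid
    )


# ---------------------------------------------------------------------------
# stage: slice
# ---------------------------------------------------------------------------

def run_slice(ds: Dataset, frames: np.ndarray | None = None):
    cq, series = run_area(ds, frames)
    if ds.is_current("slice"):
        return None  # artifacts on disk
    ds.check_prerequisites("slice")
    if frames is None:
        frames = ck.load_video(ds.video_source)
    gm = GlobalMaps(ds, frames)
    acfg = ds.config.anisotropy
    marker_ids = aniso.select_motion_markers(
        series, acfg.marker_size_max_px2, acfg.marker_cv_max
    )
    n_total = len(frames)
    cq_frames: list[np.ndarray | None] = []
    masks: list[np.ndarray] = []
    for t in range(n_total):
        fld = gm.frame_to_global(t)
        if fld is None:
            cq_frames.append(None)
            masks.append(np.zeros(gm.shape, np.uint8))
        else:
            cq_frames.append(reg.warp_image(cq.labels, fld, order=0).astype(np.int32))
            masks.append(gm.mask_of_frame(t))
    markers = aniso.build_marker_set(marker_ids, masks, cq_frames, cq)

    def to_ref(t, pt):
        fld = gm.frame_to_global(int(t))
        from scipy.ndimage import map_coordinates

        return np.array([
            map_coordinates(fld[i], np.asarray(pt, float).reshape(2, 1), order=1)[0]
            for i in range(2)
        ])

    slices, eps = aniso.compute_slice_series(
        masks, cq_frames, cq, series, markers, acfg, to_ref=to_ref
    )
    slices.to_csv(ds.path("slices.csv"))
    np.save(ds.path("slice_areas.npy"), slices.areas)
    np.save(ds.path("slice_valid.npy"), slices.valid)
    np.save(ds.path("slice_ids.npy"), slices.ids)
    pd.DataFrame(
        [(e.id, *e.ref_position, *e.lambdas, *markers.ids[e.simplex]) for e in eps],
        columns=["chromatophore_id", "row", "col", "l1", "l2", "l3", "m1", "m2", "m3"],
    ).to_csv(ds.path("epicenters.csv"), index=False)
    ds.mark_done("slice", n_markers=int(len(marker_ids)))
    return slices, eps, markers


# ---------------------------------------------------------------------------
# stage: analyse (motor units)
# ---------------------------------------------------------------------------

def run_analyse(ds: Dataset, frames: np.ndarray | None = None):
    run_slice(ds, frames)
    if ds.is_current("analyse"):
        return None
    ds.check_prerequisites("analyse")
    areas = np.load(ds.path("slice_areas.npy"))
    valid = np.load(ds.path("slice_valid.npy"))
    ids = np.load(ds.path("slice_ids.npy"))
    common = valid.all(axis=0)
    if common.sum() < 10:
        raise QualityGateError("too few jointly valid frames for motor-unit analysis")
    slices = aniso.SliceAreaSeries(ids=ids, areas=areas[:, :, common],
                                   valid=np.ones((len(ids), int(common.sum())), bool))
    mcfg = ds.config.motor_units
    decomps = mu.decompose_all(slices, seed=ds.config.seed,
                               n_components=mcfg.n_components,
                               max_iter=mcfg.ica_max_iter)
    clustering = mu.cluster_ics(
        decomps, mcfg.algorithm, seed=ds.config.seed,
        damping=mcfg.ap_damping, min_cluster_size=mcfg.hdbscan_min_cluster_size,
    )
    clustering.to_frame().to_csv(ds.path("motor_units.csv"), index=False)
    np.save(ds.path("ic_activations.npy"),
            np.concatenate([d.activations for d in decomps]))
    ds.mark_done("analyse", n_clusters=len(clustering.members))
    return decomps, clustering


# ---------------------------------------------------------------------------
# superstitch (long-term)
# ---------------------------------------------------------------------------

def run_superstitch(ds_a: Dataset, ds_b: Dataset, correspondences: CorrespondenceSet,
                    method: str | None = None):
    """Warp dataset B's cleanqueen onto A's reference and transfer ids."""
    method = method or ds_a.config.longterm.method
    cq_a = np.load(ds_a.path("cleanqueen.npy"))
    cq_b = np.load(ds_b.path("cleanqueen.npy"))
    fld = prealign(correspondences, cq_a.shape, method=method)
    warped_b = reg.warp_image(cq_b, fld, order=0).astype(np.int32)
    matches = match_territories(cq_a, warped_b, ds_a.config.longterm.min_jaccard)
    matches_to_csv(matches, ds_a.path("superstitch_matches.csv"))
    return matches, warped_b


# ---------------------------------------------------------------------------
# run everything
# ---------------------------------------------------------------------------

def run_all(ds: Dataset, frames: np.ndarray | None = None) -> Dataset:
    if frames is None:
        frames = ck.load_video(ds.video_source)
    run_chunk(ds, frames)
    run_segment(ds, frames)
    run_register(ds, frames)
    run_stitch(ds, frames)
    run_area(ds, frames)
    run_slice(ds, frames)
    run_analyse(ds, frames)
    return ds
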