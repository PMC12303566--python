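"""Shared fixtures: small synthetic scenes rendered once per session."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from chromatrack import synthetic as syn
from chromatrack.config import PipelineConfig
from chromatrack.dataset import Dataset


SMALL = dict(n_chrom=10, n_markers=5, n_sources=3, n_frames=60, shape=(256, 256), seed=2)


@pytest.fixture(scope="session")
def small_scene():
    specs, drive = syn.make_scene(**SMALL)
    return specs, drive


@pytest.fixture(scope="session")
def small_video(small_scene):
    """60-frame 256x256 scene with one blur episode (two sharp runs)."""
    specs, drive = small_scene
    degrade = syn.DegradationSpec(blur_episodes=[(25, 32, 8.0)], noise_sigma=2.0)
    frames, gt = syn.generate_video(
        specs, drive, syn.DeformationSpec(seed=2), degrade,
        n_frames=60, seed=2, shape=(256, 256),
    )
    return frames, gt


@pytest.fixture(scope="session")
def small_config():
    cfg = PipelineConfig()
    cfg.chunking.min_chunk_length = 10
    cfg.video.expected_diameter_px = 22.0
    return cfg


@pytest.fixture(scope="session")
def small_dataset(small_video, small_config, tmp_path_factory):
    """The small video run through every pipeline stage once."""
    from chromatrack import pipeline as pl

    frames, gt = small_video
    root = tmp_path_factory.mktemp("ds")
    vid = root / "video.npy"
    np.save(vid, frames)
    ds = Dataset.create(root / "dataset", vid, small_config)
    pl.run_all(ds, frames)
    return ds, frames, gt


def match_territories_to_truth(ds_root: Path, specs) -> dict[int, int]:
    """Territory id -> ground-truth chromatophore id by anchor proximity."""
    from scipy import ndimage as ndi

    cq = np.load(Path(ds_root) / "cleanqueen.npy")
    out = {}
    for t in np.unique(cq):
        if t == 0:
            continue
        c = ndi.center_of_mass(cq == t)
        d = {s.id: np.hypot(c[0] - s.anchor[0], c[1] - s.anchor[1]) for s in specs}
        out[int(t)] = min(d, key=d.get)
    return out
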