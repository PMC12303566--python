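"""Frame-quality scoring and chunk extraction.

Long recordings of behaving animals contain stretches of blur, defocus
and brightness dropouts.  Each frame gets a focus score — the mean
absolute difference-of-Gaussians response, a band-pass tuned to the
typical chromatophore diameter — and a mean brightness; maximal runs of
frames passing both thresholds become *chunks*, the unit all later
stages operate on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

log = logging.getLogger("chromatrack.chunking")

_LUMA = np.array([0.2126, 0.7152, 0.0722])


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame.astype(float)
    if frame.ndim == 3 and frame.shape[-1] in (3, 4):
        return frame[..., :3].astype(float) @ _LUMA
    raise ValueError(f"cannot interpret frame of shape {frame.shape} as an image")


@dataclass(frozen=True)
class Chunk:
    """A half-open interval [start, end) of consecutive usable frames."""

    id: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("chunk interval must be non-empty")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class FrameScoreSeries:
    focus: np.ndarray
    brightness: np.ndarray

    def __post_init__(self) -> None:
        if self.focus.shape != self.brightness.shape:
            raise ValueError("focus and brightness series must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(len(self.focus)), "focus": self.focus,
             "brightness": self.brightness}
        )


def focus_score(
    frame: np.ndarray,
    sigma_small: float,
    sigma_large: float,
    roi: np.ndarray | None = None,
) -> float:
    """Mean |DoG| of the frame: blur at sigma_small minus blur at
    sigma_large, rectified and averaged (optionally over an ROI mask).

    A uniform frame scores exactly 0; defocus suppresses the band the
    DoG passes and lowers the score.
    """
    if not 0 < sigma_small < sigma_large:
        raise ValueError("need 0 < sigma_small < sigma_large")
    g = to_grayscale(frame)
    if g.size == 0:
        raise ValueError("empty frame")
    dog = gaussian_filter(g, sigma_small) - gaussian_filter(g, sigma_large)
    if roi is not None:
        roi = np.asarray(roi, bool)
        if roi.shape != g.shape:
            raise ValueError("ROI shape mismatch")
        if not roi.any():
            raise ValueError("empty ROI")
        return float(np.abs(dog[roi]).mean())
    return float(np.abs(dog).mean())


def score_frames(
    frames,
    sigma_small: float,
    sigma_large: float,
    roi: np.ndarray | None = None,
) -> FrameScoreSeries:
    foc, bri = [], []
    for fr in frames:
        g = to_grayscale(fr)
        foc.append(focus_score(g, sigma_small, sigma_large, roi))
        bri.append(float(g[roi].mean() if roi is not None else g.mean()))
    return FrameScoreSeries(np.asarray(foc), np.asarray(bri))


def relative_focus_threshold(scores: np.ndarray, fraction: float = 0.5) -> float:
    """Threshold as ``fraction`` of the median score of the sharpest
    decile; adapts to lighting differences across recordings."""
    s = np.sort(np.asarray(scores, float))
    top = s[int(np.floor(0.9 * len(s))):]
    return fraction * float(np.median(top))


def detect_chunks(
    scores: FrameScoreSeries,
    focus_threshold: float,
    brightness_threshold: float,
    min_length: int = 20,
) -> list[Chunk]:
    """Maximal runs of frames passing both thresholds, discarding runs
    shorter than ``min_length``."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    ok = (scores.focus >= focus_threshold) & (scores.brightness >= brightness_threshold)
    chunks: list[Chunk] = []
    start = None
    for i, flag in enumerate(ok):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_length:
                chunks.append(Chunk(len(chunks), start, i))
            start = None
    if start is not None and len(ok) - start >= min_length:
        chunks.append(Chunk(len(chunks), start, len(ok)))
    if not chunks:
        log.warning("no frame passes both thresholds; returning no chunks")
    return chunks


class FrameView:
    """Frame accessor for one chunk: view i -> source frame start + i."""

    def __init__(self, frames, chunk: Chunk):
        n = len(frames)
        if not (0 <= chunk.start < chunk.end <= n):
            raise IndexError(f"chunk [{chunk.start}, {chunk.end}) outside video of {n} frames")
        self._frames = frames
        self.chunk = chunk

    def __len__(self) -> int:
        return len(self.chunk)

    def __getitem__(self, i: int):
        if not 0 <= i < len(self):
            raise IndexError(i)
        return self._frames[self.chunk.start + i]

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]


def split_video(frames, chunks: list[Chunk]) -> list[FrameView]:
    return [FrameView(frames, c) for c in chunks]


# ---------------------------------------------------------------------------
# video i/o
# ---------------------------------------------------------------------------

def load_video(path: str | Path) -> np.ndarray:
    """Load a video as (T, H, W, [3]) uint8.

    Accepts a directory of numbered PNG frames (the lossless interchange
    format), a .npy stack, or a container format (MP4/AVI/MOV) when an
    imageio ffmpeg plugin is installed.
    """
    p = Path(path)
    if p.is_dir():
        import imageio.v3 as iio

        files = sorted(p.glob("frame_*.png")) or sorted(p.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG frames in {p}")
        return np.stack([iio.imread(f) for f in files])
    if p.suffix == ".npy":
        return np.load(p)
    import imageio.v3 as iio

    try:
        return iio.imread(p, plugin="pyav")
    except Exception:
        try:
            return np.stack(list(iio.imiter(p)))
        except Exception as e:  # pragma: no cover - depends on installed plugins
            raise RuntimeError(
                f"cannot read {p}: no video plugin available; "
                "use a PNG frame directory or a .npy stack"
            ) from e


def chunks_to_csv(chunks: list[Chunk], path: str | Path) -> None:
    pd.DataFrame(
        [(c.id, c.start, c.end) for c in chunks], columns=["chunk_id", "start", "end"]
    ).to_csv(path, index=False)


def chunks_from_csv(path: str | Path) -> list[Chunk]:
    df = pd.read_csv(path)
    return [Chunk(int(r.chunk_id), int(r.start), int(r.end)) for r in df.itertuples()]
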