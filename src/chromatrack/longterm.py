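"""Long-term ("superstitch") alignment of sessions recorded days apart.

Growth, new chromatophores and color changes defeat automated stitching
across long gaps, so the user supplies a handful of corresponding
points between the two sessions' reference frames.  A warp map is
interpolated from them — thin-plate splines (exact at the landmarks,
zero bending energy for affine data) or the same moving-least-squares
scheme registration uses — and applied to the later session's
masterframe and cleanqueen before the standard stitching refinement.
Territory identities are then transferred by maximal-overlap matching;
unmatched territories of the later session are flagged as new
(chromatophores are continuously added during development).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .registration import mls_dense_field

log = logging.getLogger("chromatrack.longterm")


@dataclass
class CorrespondenceSet:
    """Ordered landmark pairs (session A point, session B point)."""

    points_a: np.ndarray  # (N, 2) (row, col)
    points_b: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.points_a = np.atleast_2d(np.asarray(self.points_a, float))
        self.points_b = np.atleast_2d(np.asarray(self.points_b, float))
        if self.points_a.shape != self.points_b.shape:
            raise ValueError("mismatched correspondence arrays")
        if len(self.points_a) < 3:
            raise ValueError("need >= 3 correspondences")
        if len(np.unique(self.points_a, axis=0)) != len(self.points_a):
            raise ValueError("duplicate source points")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CorrespondenceSet":
        df = pd.read_csv(path)
        return cls(df[["rowA", "colA"]].to_numpy(),
                   df[["rowB", "colB"]].to_numpy(), source=str(path))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            np.hstack([self.points_a, self.points_b]),
            columns=["rowA", "colA", "rowB", "colB"],
        ).to_csv(path, index=False)


def _collinear(pts: np.ndarray) -> bool:
    c = pts - pts.mean(0)
    s = np.linalg.svd(c, compute_uv=False)
    return s[1] < 1e-9 * max(s[0], 1.0)


def prealign(
    corr: CorrespondenceSet,
    shape: tuple[int, int],
    method: str = "tps",
) -> np.ndarray:
    """Dense pull field warping session B onto session A's frame.

    The field gives, per pixel of A's reference, the B coordinate to
    sample.  TPS interpolates the landmarks exactly; MLS shares the
    registration implementation.
    """
    if method == "tps":
        if _collinear(corr.points_a):
            raise ValueError("collinear landmarks: thin-plate splines are "
                             "degenerate, use method='mls'")
        from scipy.interpolate import RBFInterpolator

        interp = RBFInterpolator(corr.points_a, corr.points_b,
                                 kernel="thin_plate_spline")
        h, w = shape
        grid = np.mgrid[0:h, 0:w].reshape(2, -1).T.astype(float)
        return interp(grid).T.reshape(2, h, w)
    if method == "mls":
        return mls_dense_field(corr.points_a, corr.points_b, shape)
    raise ValueError(f"unknown prealign method {method!r}")


# ---------------------------------------------------------------------------
# identity transfer
# ---------------------------------------------------------------------------

@dataclass
class TerritoryMatch:
    id_a: int | None
    id_b: int | None
    jaccard: float
    status: str  # matched | new | lost


def _overlap_table(lab_a: np.ndarray, lab_b: np.ndarray) -> pd.DataFrame:
    ids_a = np.unique(lab_a)
    ids_a = ids_a[ids_a > 0]
    ids_b = np.unique(lab_b)
    ids_b = ids_b[ids_b > 0]
    size_a = {int(i): int((lab_a == i).sum()) for i in ids_a}
    size_b = {int(i): int((lab_b == i).sum()) for i in ids_b}
    both = (lab_a > 0) & (lab_b > 0)
    pairs, counts = np.unique(
        np.stack([lab_a[both], lab_b[both]]), axis=1, return_counts=True
    )
    rows = []
    for (ia, ib), inter in zip(pairs.T, counts):
        union = size_a[int(ia)] + size_b[int(ib)] - int(inter)
        rows.append((int(ia), int(ib), int(inter) / union))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "jaccard"])


def match_territories(
    cleanqueen_a: np.ndarray,
    warped_cleanqueen_b: np.ndarray,
    min_jaccard: float = 0.3,
) -> list[TerritoryMatch]:
    """Greedy one-to-one assignment of territories by descending
    Jaccard overlap (the overlap matrix is near-diagonal after
    prealignment, so greedy is a close approximation to the optimal
    assignment).  B territories left over are flagged ``new``, A
    territories left over ``lost``."""
    lab_a = np.asarray(cleanqueen_a)
    lab_b = np.asarray(warped_cleanqueen_b)
    tab = _overlap_table(lab_a, lab_b)
    tab = tab[tab.jaccard >= min_jaccard].sort_values(
        ["jaccard", "id_a", "id_b"], ascending=[False, True, True]
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    out: list[TerritoryMatch] = []
    for r in tab.itertuples():
        if r.id_a in used_a or r.id_b in used_b:
            continue
        used_a.add(r.id_a)
        used_b.add(r.id_b)
        out.append(TerritoryMatch(r.id_a, r.id_b, r.jaccard, "matched"))
    for ia in np.unique(lab_a):
        if ia > 0 and int(ia) not in used_a:
            out.append(TerritoryMatch(int(ia), None, 0.0, "lost"))
    for ib in np.unique(lab_b):
        if ib > 0 and int(ib) not in used_b:
            out.append(TerritoryMatch(None, int(ib), 0.0, "new"))
    return out


def matches_to_csv(matches: list[TerritoryMatch], path: str | Path) -> None:
    pd.DataFrame(
        [(m.id_a, m.id_b, m.jaccard, m.status) for m in matches],
        columns=["idA", "idB", "jaccard", "status"],
    ).to_csv(path, index=False)
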