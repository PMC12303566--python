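"""Motor-unit inference from slice dynamics.

Each motor neuron drives a subset of a chromatophore's radial muscles,
so its activity appears as one coordinated mode of that chromatophore's
slice-area matrix.  Per chromatophore, PCA on the z-scored slice series
sets the number of sources (elbow of the cumulative explained
variance), FastICA extracts that many independent activation time
series, and the independent components (ICs) of all chromatophores are
then clustered by the sign-invariant similarity |Pearson r| between
activations — ICs moving together, across chromatophores, are putative
fingerprints of one motor neuron.  Affinity propagation (on the
similarity matrix) and HDBSCAN (on the correlation distance 1 - |r|)
are available; both choose the number of clusters from the data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("chromatrack.motor_units")


# ---------------------------------------------------------------------------
# per-chromatophore decomposition
# ---------------------------------------------------------------------------

def _standardize(mat: np.ndarray) -> np.ndarray:
    """z-score each slice series (slice areas scale with chromatophore
    size; without this large slices dominate the PCA)."""
    mat = np.asarray(mat, float)
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    return (mat - mu) / np.where(sd > 0, sd, 1.0)


def pca_elbow(slice_matrix: np.ndarray, max_k: int | None = None,
              straight_tol: float = 0.2) -> int:
    """Number of components at the elbow of the cumulative explained
    variance.

    The curve is anchored at the origin — points (0, 0), (1, cev_1),
    ..., (n, cev_n) — and the elbow is the point of maximum distance to
    the chord from (0, 0) to (n, 1); anchoring at the origin lets k = 1
    win when one component dominates.  A curve whose maximum distance
    stays below ``straight_tol`` is effectively straight (an isotropic
    spectrum has no elbow; its slight concavity reaches ~0.15): k = 1
    with a warning.  Result clipped to [1, n_slices].
    """
    mat = _standardize(slice_matrix)
    n_slices, n_frames = mat.shape
    if n_frames < 2:
        raise ValueError("need >= 2 frames")
    if not mat.any():
        warnings.warn("zero-variance slice matrix; k = 1", stacklevel=2)
        return 1
    cov = mat @ mat.T / (n_frames - 1)
    evals = np.maximum(np.sort(np.linalg.eigvalsh(cov))[::-1], 0.0)
    total = evals.sum()
    if total <= 0:
        warnings.warn("zero-variance slice matrix; k = 1", stacklevel=2)
        return 1
    cev = np.cumsum(evals) / total
    x = np.r_[0.0, np.arange(1, len(cev) + 1, dtype=float)]
    y = np.r_[0.0, cev]
    chord = np.array([x[-1], y[-1]])
    chord /= np.linalg.norm(chord)
    dist = np.abs(x * chord[1] - y * chord[0])
    if dist.max() < straight_tol:
        warnings.warn("no elbow in the variance curve; k = 1", stacklevel=2)
        return 1
    k = int(x[np.argmax(dist)])
    hi = max_k if max_k is not None else n_slices
    return int(np.clip(max(k, 1), 1, hi))


@dataclass
class ComponentDecomposition:
    chrom_id: int
    k: int
    loadings: np.ndarray     # (k, n_slices) spatial loadings over slices
    activations: np.ndarray  # (k, T) zero-mean activation time series
    explained_variance: np.ndarray  # (k,) share of variance, descending


def ica_decompose(
    slice_matrix: np.ndarray,
    k: int,
    seed: int = 0,
    chrom_id: int = -1,
    max_iter: int = 500,
) -> ComponentDecomposition:
    """FastICA with ``k`` sources on the standardized slice matrix.

    Components come out in decreasing explained-variance order with the
    sign fixed so each activation's skewness is non-negative (expansion
    bursts point up).  Deterministic for a fixed seed; on
    non-convergence one retry with a derived seed, then an error.
    """
    from scipy.stats import skew
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    mat = _standardize(slice_matrix)
    k = int(max(1, min(k, mat.shape[0])))
    X = mat.T  # (T, n_slices): rows are observations
    last_err: Exception | None = None
    for attempt, s in enumerate((seed, seed + 104729)):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                ica = FastICA(n_components=k, random_state=int(s) % (2**31 - 1),
                              max_iter=max_iter, tol=1e-3, whiten="unit-variance")
                S = ica.fit_transform(X)  # (T, k)
            break
        except (ConvergenceWarning, ValueError) as e:  # retry once
            last_err = e
            log.warning("FastICA attempt %d failed (%s)", attempt + 1, e)
    else:
        raise RuntimeError(f"FastICA did not converge: {last_err}")

    act = S.T - S.T.mean(axis=1, keepdims=True)          # (k, T)
    load = ica.mixing_.T                                  # (k, n_slices)
    # sign convention: non-negative skewness of each activation
    sg = np.where(skew(act, axis=1) < 0, -1.0, 1.0)
    act *= sg[:, None]
    load *= sg[:, None]
    # order by explained variance of the reconstructed contribution
    ev = (load**2).sum(axis=1) * act.var(axis=1)
    order = np.argsort(ev)[::-1]
    ev = ev[order]
    tot = ev.sum()
    return ComponentDecomposition(
        chrom_id=chrom_id, k=k, loadings=load[order], activations=act[order],
        explained_variance=ev / tot if tot > 0 else ev,
    )


def decompose_all(
    slice_series,
    seed: int = 0,
    n_components: int | None = None,
    max_iter: int = 500,
) -> list[ComponentDecomposition]:
    """pca_elbow + ica_decompose per chromatophore of a SliceAreaSeries
    (or of a plain (C, n_slices, T) array)."""
    if hasattr(slice_series, "areas"):
        ids = slice_series.ids
        mats = [slice_series.matrix(t) for t in ids]
    else:
        arr = np.asarray(slice_series)
        ids = np.arange(arr.shape[0])
        mats = [arr[i] for i in ids]
    out = []
    for i, (cid, mat) in enumerate(zip(ids, mats)):
        k = n_components if n_components is not None else pca_elbow(mat)
        # a k too large for the data can defeat FastICA's fixed-point
        # iteration; fall back to fewer components rather than dropping
        # the chromatophore
        while True:
            try:
                out.append(ica_decompose(mat, k, seed=seed + i, chrom_id=int(cid),
                                         max_iter=max_iter))
                break
            except RuntimeError:
                if k <= 1:
                    raise
                k -= 1
                log.warning("chromatophore %s: ICA retry with k=%d", cid, k)
    return out


# ---------------------------------------------------------------------------
# cross-chromatophore clustering
# ---------------------------------------------------------------------------

@dataclass
class MotorUnitClustering:
    algorithm: str
    ic_chrom: np.ndarray        # (n_ics,) chromatophore id per IC
    ic_index: np.ndarray        # (n_ics,) component index within its owner
    cluster: np.ndarray         # (n_ics,) cluster id; -1 = noise (hdbscan)
    similarity: np.ndarray      # (n_ics, n_ics) |Pearson r| between activations
    members: dict[int, set] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chromatophore_id": self.ic_chrom,
            "component": self.ic_index,
            "cluster": self.cluster,
            "algorithm": self.algorithm,
        })


def ic_similarity(activations: np.ndarray) -> np.ndarray:
    """|Pearson r| between IC activation series (ICA sign is arbitrary,
    so anticorrelated ICs are as similar as correlated ones)."""
    z = _standardize(activations)
    r = z @ z.T / z.shape[1]
    return np.clip(np.abs(r), 0.0, 1.0)


def _merge_fragments(labels: np.ndarray, sim: np.ndarray,
                     merge_sim: float = 0.7) -> np.ndarray:
    """Merge clusters whose mean cross-similarity exceeds ``merge_sim``.

    With a tiny minimum cluster size HDBSCAN happily splits one tight
    correlation block into several micro-clusters; repeated single-link
    merging at the cluster level repairs that without touching noise
    points.
    """
    labels = np.asarray(labels).copy()
    changed = True
    while changed:
        changed = False
        ids = [l for l in np.unique(labels) if l >= 0]
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                ma, mb = labels == a, labels == b
                if sim[np.ix_(ma, mb)].mean() >= merge_sim:
                    labels[mb] = a
                    changed = True
                    break
            if changed:
                break
    # compact ids
    out = labels.copy()
    for new, old in enumerate(sorted(l for l in np.unique(labels) if l >= 0)):
        out[labels == old] = new
    return out


def cluster_ics(
    decomps: list[ComponentDecomposition],
    algorithm: str = "affinity_propagation",
    seed: int = 0,
    damping: float = 0.7,
    min_cluster_size: int = 2,
) -> MotorUnitClustering:
    """Cluster all ICs across chromatophores into putative motor units."""
    acts = np.concatenate([d.activations for d in decomps])
    chrom = np.concatenate([[d.chrom_id] * d.k for d in decomps])
    comp = np.concatenate([np.arange(d.k) for d in decomps])
    if len(acts) < 2:
        raise ValueError("need >= 2 ICs to cluster")
    sim = ic_similarity(acts)

    if algorithm == "affinity_propagation":
        from sklearn.cluster import AffinityPropagation
        from sklearn.exceptions import ConvergenceWarning

        pref = float(np.median(sim))
        labels = None
        for damp in (damping, min(0.95, damping + 0.2)):
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                try:
                    ap = AffinityPropagation(
                        affinity="precomputed", damping=damp, preference=pref,
                        random_state=int(seed) % (2**31 - 1), max_iter=500,
                    ).fit(sim)
                    labels = ap.labels_
                    break
                except ConvergenceWarning:
                    log.warning("affinity propagation: raising damping from %.2f", damp)
        if labels is None:
            raise RuntimeError("affinity propagation did not converge")
    elif algorithm == "hdbscan":
        from sklearn.cluster import HDBSCAN

        dist = 1.0 - sim
        np.fill_diagonal(dist, 0.0)
        labels = HDBSCAN(
            min_cluster_size=min_cluster_size, metric="precomputed", copy=True
        ).fit(dist).labels_
        labels = _merge_fragments(labels, sim, merge_sim=0.6)
    else:
        raise ValueError(f"unknown clustering algorithm {algorithm!r}")

    members: dict[int, set] = {}
    for lab, cid in zip(labels, chrom):
        if lab >= 0:
            members.setdefault(int(lab), set()).add(int(cid))
    return MotorUnitClustering(
        algorithm=algorithm, ic_chrom=chrom, ic_index=comp,
        cluster=np.asarray(labels), similarity=sim, members=members,
    )


def evaluate_recovery(
    decomps: list[ComponentDecomposition],
    clustering: MotorUnitClustering,
    drive,
) -> dict:
    """Compare the inference against ground-truth wiring.

    Each IC is labelled with the true source its activation correlates
    with best; the adjusted Rand index then scores the IC clustering
    against those labels.  Also reports how often the retained
    component count k is within +/-1 of the true source count.
    """
    from sklearn.metrics import adjusted_rand_score

    z_src = _standardize(drive.source_signals)
    true_label = []
    for d in decomps:
        z_act = _standardize(d.activations)
        r = np.abs(z_act @ z_src.T / z_src.shape[1])  # (k, n_sources)
        true_label.extend(r.argmax(axis=1))
    true_label = np.asarray(true_label)
    keep = clustering.cluster >= 0  # hdbscan noise excluded from ARI
    ari = adjusted_rand_score(true_label[keep], clustering.cluster[keep])
    k_ok = np.mean([
        abs(d.k - len(drive.sources_of(d.chrom_id))) <= 1 for d in decomps
    ])
    return {"ari": float(ari), "k_within_1": float(k_ok),
            "n_ics": int(len(true_label)), "n_clusters": int(len(clustering.members))}
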