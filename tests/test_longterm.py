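"""Cross-session pre-alignment and territory identity transfer."""

import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from chromatrack import longterm as lt


class TestCorrespondenceSet:
    def test_roundtrips_through_csv(self, tmp_path):
        c = lt.CorrespondenceSet(np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
                                 np.array([[2.0, 3.0], [4.0, 5.0], [6.0, 7.0]]))
        p = tmp_path / "corr.csv"
        c.to_csv(p)
        c2 = lt.CorrespondenceSet.from_csv(p)
        assert np.allclose(c.points_a, c2.points_a)
        assert np.allclose(c.points_b, c2.points_b)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            lt.CorrespondenceSet(np.array([[0.0, 0.0], [1.0, 1.0]]),
                                 np.array([[0.0, 0.0], [1.0, 1.0]]))

    def test_duplicate_source_points_rejected(self):
        pa = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="duplicate"):
            lt.CorrespondenceSet(pa, pa + 1)


class TestPrealign:
    def _affine_corr(self, n=8, seed=0):
        rng = np.random.default_rng(seed)
        A = np.array([[1.3, 0.05], [-0.02, 1.25]])
        b = np.array([4.0, -6.0])
        pa = rng.uniform(10, 54, (n, 2))
        return lt.CorrespondenceSet(pa, pa @ A.T + b), A, b

    def test_tps_reproduces_affine_exactly(self):
        corr, A, b = self._affine_corr()
        fld = lt.prealign(corr, (64, 64), method="tps")
        # zero residual at the landmarks
        at_marks = np.stack([
            map_coordinates(fld[i], corr.points_a.T, order=1) for i in range(2)
        ], axis=1)
        assert np.abs(at_marks - corr.points_b).max() < 0.05
        # and the affine map between them (zero bending energy)
        rng = np.random.default_rng(1)
        probe = rng.uniform(12, 52, (30, 2))
        sampled = np.stack([
            map_coordinates(fld[i], probe.T, order=1) for i in range(2)
        ], axis=1)
        assert np.abs(sampled - (probe @ A.T + b)).max() < 0.1

    def test_identity_correspondences_identity_map(self):
        rng = np.random.default_rng(2)
        pa = rng.uniform(5, 27, (6, 2))
        fld = lt.prealign(lt.CorrespondenceSet(pa, pa.copy()), (32, 32),
                          method="tps")
        ident = np.mgrid[0:32, 0:32].astype(float)
        assert np.abs(fld - ident).max() < 0.05

    def test_mls_method_available(self):
        corr, A, b = self._affine_corr()
        fld = lt.prealign(corr, (64, 64), method="mls")
        rng = np.random.default_rng(3)
        probe = rng.uniform(12, 52, (20, 2))
        sampled = np.stack([
            map_coordinates(fld[i], probe.T, order=1) for i in range(2)
        ], axis=1)
        assert np.abs(sampled - (probe @ A.T + b)).max() < 0.1

    def test_collinear_landmarks_tps_error_suggests_mls(self):
        pa = np.array([[10.0, 10.0], [20.0, 20.0], [30.0, 30.0], [40.0, 40.0]])
        corr = lt.CorrespondenceSet(pa, pa + 2.0)
        with pytest.raises(ValueError, match="mls"):
            lt.prealign(corr, (64, 64), method="tps")


def _label_disks(shape, centers, radius, start=1):
    lab = np.zeros(shape, np.int32)
    gr, gc = np.mgrid[0:shape[0], 0:shape[1]]
    for k, (r, c) in enumerate(centers, start=start):
        lab[np.hypot(gr - r, gc - c) <= radius] = k
    return lab


class TestMatchTerritories:
    def test_identical_maps_identity_matching(self):
        lab = _label_disks((64, 64), [(16, 16), (16, 48), (48, 16)], 8)
        out = lt.match_territories(lab, lab)
        matched = {m.id_a: m for m in out if m.status == "matched"}
        assert set(matched) == {1, 2, 3}
        assert all(m.id_b == m.id_a and m.jaccard == 1.0
                   for m in matched.values())

    def test_extra_territory_flagged_new(self):
        lab_a = _label_disks((64, 64), [(16, 16), (48, 48)], 8)
        lab_b = _label_disks((64, 64), [(16, 16), (48, 48), (16, 48)], 8)
        out = lt.match_territories(lab_a, lab_b)
        assert sum(m.status == "matched" for m in out) == 2
        news = [m for m in out if m.status == "new"]
        assert len(news) == 1 and news[0].id_b == 3

    def test_missing_territory_flagged_lost(self):
        lab_a = _label_disks((64, 64), [(16, 16), (48, 48)], 8)
        lab_b = _label_disks((64, 64), [(16, 16)], 8)
        out = lt.match_territories(lab_a, lab_b)
        assert [m.id_a for m in out if m.status == "lost"] == [2]

    def test_agrees_with_optimal_assignment_on_small_instances(self):
        # oracle: Hungarian assignment maximizing total Jaccard
        from scipy.optimize import linear_sum_assignment

        rng = np.random.default_rng(4)
        for trial in range(5):
            centers = rng.uniform(12, 84, (8, 2))
            lab_a = _label_disks((96, 96), centers, 7)
            jitter = centers + rng.normal(0, 2.0, centers.shape)
            lab_b = _label_disks((96, 96), jitter, 7)
            got = lt.match_territories(lab_a, lab_b, min_jaccard=0.1)
            pairs = {(m.id_a, m.id_b) for m in got if m.status == "matched"}
            J = np.zeros((8, 8))
            for ia in range(1, 9):
                for ib in range(1, 9):
                    inter = ((lab_a == ia) & (lab_b == ib)).sum()
                    union = ((lab_a == ia) | (lab_b == ib)).sum()
                    if union:
                        J[ia - 1, ib - 1] = inter / union
            ri, ci = linear_sum_assignment(-J)
            optimal = {(r + 1, c + 1) for r, c in zip(ri, ci)
                       if J[r, c] >= 0.1}
            # near-diagonal overlap structure: greedy equals optimal here
            assert pairs == optimal

    def test_raising_threshold_never_increases_matches(self):
        rng = np.random.default_rng(5)
        centers = rng.uniform(12, 52, (6, 2))
        lab_a = _label_disks((64, 64), centers, 6)
        lab_b = _label_disks((64, 64), centers + rng.normal(0, 3, centers.shape), 6)
        counts = []
        for thr in (0.1, 0.3, 0.5, 0.7):
            out = lt.match_territories(lab_a, lab_b, min_jaccard=thr)
            counts.append(sum(m.status == "matched" for m in out))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_one_to_one_by_construction(self):
        lab_a = _label_disks((64, 64), [(20, 20), (20, 34)], 8)
        lab_b = _label_disks((64, 64), [(20, 27)], 10)
        out = lt.match_territories(lab_a, lab_b, min_jaccard=0.05)
        ids_b = [m.id_b for m in out if m.status == "matched"]
        assert len(ids_b) == len(set(ids_b)) <= 1


class TestGrowthScenario:
    def test_scaled_session_with_new_organs_matched(self):
        """Session B = session A scaled 1.3x about the canvas center plus
        30% new chromatophores; 8 landmark pairs from the known
        transform must recover >= 95% of A's territories."""
        rng = np.random.default_rng(7)
        shape = (200, 200)
        center = np.array([100.0, 100.0])
        n_a = 20
        centers_a = []
        while len(centers_a) < n_a:
            p = rng.uniform(35, 165, 2)
            if all(np.hypot(*(p - q)) > 16 for q in centers_a):
                centers_a.append(p)
        centers_a = np.array(centers_a)
        centers_b = (centers_a - center) * 1.3 + center
        extra = []
        while len(extra) < 6:
            p = rng.uniform(15, 185, 2)
            if all(np.hypot(*(p - q)) > 16 for q in list(centers_b) + extra):
                extra.append(p)
        lab_a = _label_disks(shape, centers_a, 6)
        lab_b = _label_disks(shape, list(centers_b) + extra, 7)

        marks_a = np.array([[40.0, 40.0], [40.0, 160.0], [160.0, 40.0],
                            [160.0, 160.0], [100.0, 40.0], [40.0, 100.0],
                            [160.0, 100.0], [100.0, 160.0]])
        marks_b = (marks_a - center) * 1.3 + center
        corr = lt.CorrespondenceSet(marks_a, marks_b)
        fld = lt.prealign(corr, shape, method="tps")
        from chromatrack.registration import warp_image

        warped_b = warp_image(lab_b, fld, order=0).astype(np.int32)
        out = lt.match_territories(lab_a, warped_b)
        matched = {m.id_a: m.id_b for m in out if m.status == "matched"}
        correct = sum(matched.get(k, -1) == k for k in range(1, n_a + 1))
        assert correct / n_a >= 0.95
        new_ids = {m.id_b for m in out if m.status == "new"}
        assert new_ids == set(range(n_a + 1, n_a + 7))
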