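import numpy as np
import pytest
from scipy.spatial.distance import cdist

from barcodegap.cda_validation import (
    CdaError, choose_n_components, distances_to_coordinates, fit_cda,
    loocv_classify,
)
from barcodegap.distance import PairwiseDistanceMatrix, distance_matrix
from barcodegap.synthetic_data import ComplexConfig, simulate_complex


def matrix_from_points(points, ids=None):
    d = cdist(points, points)
    n = len(points)
    return PairwiseDistanceMatrix(
        ids=ids or [f"p{i}" for i in range(n)], model="p", d=d,
        sites=np.full((n, n), 1, dtype=np.int64),
    )


class TestPcoa:
    def test_equilateral_triangle(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        m = PairwiseDistanceMatrix(ids=["a", "b", "c"], model="p", d=d,
                                   sites=np.ones((3, 3), dtype=np.int64))
        coords = distances_to_coordinates(m)
        emb = cdist(coords.coords, coords.coords)
        off = emb[np.triu_indices(3, 1)]
        assert np.allclose(off, off[0])

    def test_euclidean_matrix_reproduced(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 2))
        m = matrix_from_points(pts)
        coords = distances_to_coordinates(m)
        assert np.allclose(cdist(coords.coords, coords.coords), m.d, atol=1e-8)

    def test_eigenvalues_sorted_and_positive(self):
        rng = np.random.default_rng(3)
        m = matrix_from_points(rng.normal(size=(8, 3)))
        coords = distances_to_coordinates(m)
        ev = coords.eigenvalues
        assert (ev > 0).all() and (np.diff(ev) <= 1e-9).all()
        assert coords.n_components <= m.n - 1

    def test_matches_reference_pcoa(self):
        """Cross-check against the independent scikit-bio implementation."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(7)
        m = matrix_from_points(rng.normal(size=(9, 4)))
        ours = distances_to_coordinates(m)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(m.d, ids=m.ids))
        ref_ev = np.asarray(ref.eigvals)[: ours.n_components]
        assert np.allclose(np.sort(ours.eigenvalues), np.sort(ref_ev[ref_ev > 1e-9]),
                           atol=1e-8)

    def test_undefined_pairs_rejected(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        m = PairwiseDistanceMatrix(ids=["a", "b"], model="k2p", d=d,
                                   sites=np.ones((2, 2), dtype=np.int64))
        with pytest.raises(ValueError, match="undefined"):
            distances_to_coordinates(m)

    def test_separated_clusters_split_on_first_axis(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 0.1, size=(6, 3)),
                         rng.normal(5, 0.1, size=(6, 3))])
        coords = distances_to_coordinates(matrix_from_points(pts), n_components=1)
        axis1 = coords.coords[:, 0]
        assert (axis1[:6].max() < axis1[6:].min()) or \
               (axis1[6:].max() < axis1[:6].min())


class TestFitCda:
    def test_one_dimensional_groups(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 1, 30), rng.normal(10, 1, 30)])
        labels = ["a"] * 30 + ["b"] * 30
        model = fit_cda(x[:, None], labels)
        assert model.n_axes == 1
        scores = model.scores[:, 0]
        assert abs(np.corrcoef(scores, x)[0, 1]) > 0.999

    def test_axes_capped_by_groups(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 5))
        labels = (["a"] * 10) + (["b"] * 10) + (["c"] * 10)
        model = fit_cda(x, labels)
        assert model.n_axes == 2  # min(g-1, p)

    def test_permutation_invariance_up_to_sign(self):
        rng = np.random.default_rng(6)
        x = np.vstack([rng.normal(0, 1, size=(8, 3)),
                       rng.normal(4, 1, size=(8, 3))])
        labels = ["a"] * 8 + ["b"] * 8
        model1 = fit_cda(x, labels)
        perm = rng.permutation(16)
        model2 = fit_cda(x[perm], [labels[i] for i in perm])
        assert np.allclose(np.abs(model1.axes), np.abs(model2.axes), atol=1e-8)

    def test_singular_within_scatter_raises(self):
        # p >= n - g guarantees singular pooled within-group scatter
        rng = np.random.default_rng(2)
        x = rng.normal(size=(6, 6))
        labels = ["a", "a", "a", "b", "b", "b"]
        with pytest.raises(CdaError):
            fit_cda(x, labels)

    def test_distant_clade_separates_on_axis1(self):
        # four designated groups simulated far from the rest fall on one side
        rng = np.random.default_rng(8)
        near = [rng.normal(0, 0.5, size=(3, 4)) + rng.normal(0, 4, size=4)
                for _ in range(8)]
        far = [rng.normal(60, 0.5, size=(3, 4)) + rng.normal(0, 4, size=4)
               for _ in range(4)]
        x = np.vstack(near + far)
        labels = [f"n{k}" for k in range(8) for _ in range(3)] + \
                 [f"f{k}" for k in range(4) for _ in range(3)]
        model = fit_cda(x, labels)
        axis1 = model.scores[:, 0]
        near_scores, far_scores = axis1[:24], axis1[24:]
        assert near_scores.max() < far_scores.min() or \
            far_scores.max() < near_scores.min()


class TestLoocv:
    def test_separated_groups_fully_recovered(self):
        rng = np.random.default_rng(3)
        x = np.vstack([rng.normal(k * 10, 0.5, size=(5, 3)) for k in range(4)])
        labels = [f"g{k}" for k in range(4) for _ in range(5)]
        rep = loocv_classify(x, labels)
        assert rep.overall_correct == 100.0
        assert (rep.row_totals == 5).all()

    def test_single_group_trivially_correct(self):
        rng = np.random.default_rng(4)
        rep = loocv_classify(rng.normal(size=(6, 2)), ["only"] * 6)
        assert rep.overall_correct == 100.0

    def test_singleton_group_can_only_be_misclassified(self):
        rng = np.random.default_rng(5)
        x = np.vstack([rng.normal(0, 0.5, size=(4, 2)),
                       rng.normal(8, 0.5, size=(4, 2)),
                       [[20.0, 20.0]]])
        labels = ["a"] * 4 + ["b"] * 4 + ["solo"]
        rep = loocv_classify(x, labels)
        solo = rep.groups.index("solo")
        assert rep.confusion[solo, solo] == 0
        assert rep.row_totals[solo] == 1

    def test_overlapping_groups_near_chance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(60, 2))
        labels = ["a", "b"] * 30
        rep = loocv_classify(x, labels)
        assert 20.0 <= rep.overall_correct <= 80.0  # chance is 50%

    def test_scale_invariance(self):
        aln, truth = simulate_complex(ComplexConfig(
            n_species=5, members_per_species=3, seed=13))
        m = distance_matrix(aln)
        labels = [truth[i] for i in m.ids]
        coords = distances_to_coordinates(m)
        k = choose_n_components(coords.eigenvalues, m.n, 5)
        rep1 = loocv_classify(coords.take(k), labels)
        m2 = PairwiseDistanceMatrix(ids=m.ids, model=m.model, d=3.0 * m.d,
                                    sites=m.sites)
        coords2 = distances_to_coordinates(m2)
        rep2 = loocv_classify(coords2.take(k), labels)
        assert (rep1.confusion == rep2.confusion).all()

    def test_confusion_rows_conserve_group_sizes(self):
        rng = np.random.default_rng(7)
        sizes = [3, 1, 5, 2]
        x = np.vstack([rng.normal(k * 6, 1.0, size=(s, 2))
                       for k, s in enumerate(sizes)])
        labels = [f"g{k}" for k, s in enumerate(sizes) for _ in range(s)]
        rep = loocv_classify(x, labels)
        assert rep.row_totals.tolist() == sizes
        assert rep.confusion.sum() == sum(sizes)
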