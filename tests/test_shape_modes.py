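"""Registration, alignment, PCA shape space, and mode assignment."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import make_disc, make_rod, make_star
from owhshapes.morphometrics import circularity, perimeter, polygon_area
from owhshapes.shape_modes import (
    align_shapes,
    align_to_reference,
    assign_shape_mode,
    fit_pca,
    fit_shape_mode_model,
    fit_shape_modes,
    load_model,
    normalize_shape,
    reconstruct_mode_shape,
    resample_contour,
    save_model,
)

SQUARE = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0], [1.0, 0.0]])


def rotate(points, angle):
    R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    return points @ R.T


class TestResample:
    def test_square_four_points_are_corners(self):
        out = resample_contour(SQUARE, 4)
        assert np.allclose(out, SQUARE)

    def test_circle_spacing_uniform(self):
        th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        circle = np.column_stack([np.sin(th), np.cos(th)])
        out = resample_contour(circle, 50)
        gaps = np.hypot(*np.diff(np.vstack([out, out[:1]]), axis=0).T)
        assert np.ptp(gaps) / gaps.mean() < 1e-4

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            resample_contour(SQUARE, 2)

    def test_self_intersecting_rejected(self):
        bowtie = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="self-intersecting"):
            resample_contour(bowtie, 10)


class TestNormalize:
    def test_translation_and_scale_invariance(self, rng):
        pts = make_star(rng)
        ref = normalize_shape(pts)
        assert np.allclose(normalize_shape(pts + [100.0, -7.0]), ref)
        assert np.allclose(normalize_shape(3.0 * pts), ref)

    def test_unit_rms_and_zero_centroid(self, rng):
        out = normalize_shape(make_rod(rng))
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-9)
        assert np.sqrt(np.mean(np.sum(out**2, axis=1))) == pytest.approx(1.0, abs=1e-9)

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            normalize_shape(np.zeros((5, 2)))


def procrustes_bruteforce(shape, reference, n_angles=360):
    """Grid search over rotation x cyclic start shift (independent oracle)."""
    best = (np.inf, None, None)
    n = len(shape)
    for s in range(n):
        rolled = np.roll(shape, -s, axis=0)
        for a in np.linspace(0, 2 * np.pi, n_angles, endpoint=False):
            d = np.sum((rotate(rolled, a) - reference) ** 2)
            if d < best[0]:
                best = (d, a, s)
    return best


class TestAlignment:
    def test_recovers_rotated_shifted_copies(self, rng):
        base = normalize_shape(resample_contour(make_star(rng), 50))
        shapes = [base]
        for _ in range(10):
            ang = rng.uniform(0, 2 * np.pi)
            shift = rng.integers(0, 50)
            shapes.append(np.roll(rotate(base, ang), shift, axis=0))
        aligned, mean, _ = align_shapes(shapes)
        for a in aligned:
            assert np.allclose(a, aligned[0], atol=1e-6)
        assert np.allclose(mean, aligned[0], atol=1e-6)

    def test_matches_bruteforce_grid(self, rng):
        """Closed-form rotation + exhaustive shift equals a 360 x 50 grid
        search within grid resolution."""
        ref = normalize_shape(resample_contour(make_star(rng), 50))
        target = normalize_shape(resample_contour(make_rod(rng), 50))
        aligned, _, _ = align_to_reference(target, ref)
        d_impl = np.sum((aligned - ref) ** 2)
        d_grid, _, _ = procrustes_bruteforce(target, ref)
        # the analytic optimum can only improve on the grid
        assert d_impl <= d_grid + 1e-9
        assert d_impl == pytest.approx(d_grid, abs=5e-3)

    def test_objective_nonincreasing(self, rng):
        shapes = [normalize_shape(resample_contour(make_star(rng), 50))
                  for _ in range(20)]

        def objective(arr, mean):
            return float(np.sum((arr - mean) ** 2))

        arr = np.stack(shapes)
        mean = arr[0]
        prev = np.inf
        for _ in range(5):
            arr = np.stack([align_to_reference(s, mean)[0] for s in arr])
            obj = objective(arr, mean)
            assert obj <= prev + 1e-9
            prev = obj
            mean = normalize_shape(arr.mean(axis=0))


class TestPCA:
    def test_identical_shapes_rejected(self, rng):
        s = normalize_shape(resample_contour(make_disc(rng), 50))
        with pytest.raises(ValueError, match="degenerate"):
            fit_pca(np.stack([s] * 10))

    def test_full_reconstruction(self, rng):
        aligned, _, _ = align_shapes(
            [resample_contour(make_star(rng), 50) for _ in range(12)]
        )
        pca, n_pcs, _ = fit_pca(aligned, var_retained=0.95)
        X = aligned.reshape(len(aligned), -1)
        full = pca.inverse_transform(pca.transform(X))
        assert np.allclose(full, X, atol=1e-8)

    def test_variance_rule(self, rng):
        aligned, _, _ = align_shapes(
            [resample_contour(make_star(rng), 50) for _ in range(40)]
        )
        pca, n_pcs, _ = fit_pca(aligned, var_retained=0.95)
        evr = pca.explained_variance_ratio_
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr[:n_pcs].sum() >= 0.95 - 1e-9
        assert evr[:n_pcs - 1].sum() < 0.95 if n_pcs > 1 else True


class TestModes:
    def test_three_families_recovered(self, shape_families):
        contours, truth = shape_families
        model, labels, _ = fit_shape_mode_model(contours, n=50, k=3, seed=1)
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_deterministic_under_seed(self, shape_families):
        contours, _ = shape_families
        m1, l1, _ = fit_shape_mode_model(contours[:150], k=3, seed=5)
        m2, l2, _ = fit_shape_mode_model(contours[:150], k=3, seed=5)
        assert np.array_equal(l1, l2)
        assert np.allclose(m1.centroids, m2.centroids)

    def test_k5_on_three_families_concentrates(self, shape_families):
        contours, truth = shape_families
        _, labels, _ = fit_shape_mode_model(contours, n=50, k=5, seed=2)
        for fam in np.unique(truth):
            counts = np.bincount(labels[truth == fam], minlength=6)[1:]
            top2 = np.sort(counts)[-2:].sum()
            assert top2 / counts.sum() >= 0.8

    def test_labels_ordered_by_cluster_size(self, shape_families):
        contours, _ = shape_families
        model, labels, _ = fit_shape_mode_model(contours, k=3, seed=1)
        assert np.all(np.diff(model.cluster_sizes) <= 0)

    def test_too_few_distinct_points_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_shape_modes(np.zeros((10, 3)), k=5)


class TestAssignment:
    @pytest.fixture
    def trained(self, shape_families):
        contours, truth = shape_families
        model, labels, _ = fit_shape_mode_model(contours, k=3, seed=1)
        return contours, truth, model, labels

    def test_training_cells_reassigned_consistently(self, trained):
        contours, _, model, labels = trained
        hits = sum(
            assign_shape_mode(c, model)[0] == l
            for c, l in zip(contours[:60], labels[:60])
        )
        assert hits >= 58  # boundary cells may flip; the bulk must not

    def test_similarity_transform_invariance(self, trained, rng):
        contours, _, model, _ = trained
        for c in contours[:20]:
            sm0, d0 = assign_shape_mode(c, model)
            moved = 2.5 * rotate(c, rng.uniform(0, 2 * np.pi)) + [50.0, -3.0]
            sm1, d1 = assign_shape_mode(moved, model)
            assert sm1 == sm0
            assert d1 == pytest.approx(d0, abs=1e-9)

    def test_reconstructions_distinct(self, trained):
        _, _, model, _ = trained
        recs = [reconstruct_mode_shape(model, s) for s in range(1, model.k + 1)]
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                assert np.sqrt(np.mean((recs[i] - recs[j]) ** 2)) > 1e-3

    def test_invalid_mode_rejected(self, trained):
        _, _, model, _ = trained
        with pytest.raises(ValueError):
            reconstruct_mode_shape(model, 0)

    def test_disc_only_model_reconstructs_circle(self, rng):
        contours = [make_disc(rng) for _ in range(30)]
        model, _, _ = fit_shape_mode_model(contours, k=1, seed=0)
        rec = reconstruct_mode_shape(model, 1)
        assert circularity(polygon_area(rec), perimeter(rec)) >= 0.95

    def test_model_roundtrip(self, trained, tmp_path):
        contours, _, model, _ = trained
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        for c in contours[:10]:
            sm_a, d_a = assign_shape_mode(c, loaded)
            sm_b, d_b = assign_shape_mode(c, model)
            assert sm_a == sm_b
            assert d_a == pytest.approx(d_b, abs=1e-9)
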