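"""Mahalanobis clustering, density contours, geometric median."""

import numpy as np
import pytest

from ecogprop import ClusterModel, density_contours, fit_clusters, geometric_median


def _clouds(centers, n_per, sd, seed):
    rng = np.random.default_rng(seed)
    pts, labs = [], []
    for i, c in enumerate(centers):
        pts.append(rng.normal(c, sd, size=(n_per, 2)))
        labs += [i] * n_per
    return np.vstack(pts), np.array(labs)


CENTERS = [(0.9, 0.9), (0.5, 0.3), (0.1, 0.05)]


def test_separated_clouds_fully_recovered():
    X, true = _clouds(CENTERS, 200, 0.03, seed=0)
    model, labels = fit_clusters(X, k=3, seed=0)
    names = np.array([model.names[int(l)] for l in labels])
    expect = np.array(["propagated", "attenuated", "nonpropagated"])[true]
    assert (names == expect).mean() == 1.0


def test_overlapping_mixture_mostly_recovered():
    X, true = _clouds(CENTERS, 200, 0.12, seed=1)
    model, labels = fit_clusters(X, k=3, seed=0)
    names = np.array([model.names[int(l)] for l in labels])
    expect = np.array(["propagated", "attenuated", "nonpropagated"])[true]
    assert (names == expect).mean() >= 0.95


def test_identity_covariance_reduces_to_euclidean():
    X, _ = _clouds(CENTERS, 50, 0.1, seed=2)
    means = np.array(CENTERS)
    model = ClusterModel(k=3, means=means, covariances=np.array([np.eye(2)] * 3), names={})
    euclid = np.linalg.norm(X[:, None, :] - means[None], axis=2).argmin(axis=1)
    np.testing.assert_array_equal(model.predict(X), euclid)


def test_fit_is_deterministic():
    X, _ = _clouds(CENTERS, 100, 0.08, seed=3)
    m1, l1 = fit_clusters(X, k=3, seed=5)
    m2, l2 = fit_clusters(X, k=3, seed=5)
    np.testing.assert_array_equal(l1, l2)
    np.testing.assert_array_equal(m1.means, m2.means)
    np.testing.assert_array_equal(m1.covariances, m2.covariances)


def test_objective_non_increasing():
    X, _ = _clouds(CENTERS, 150, 0.10, seed=4)
    model, _ = fit_clusters(X, k=3, seed=0)
    h = model.objective_history
    assert all(a >= b - 1e-6 for a, b in zip(h, h[1:]))
    assert model.converged


def test_cluster_names_are_a_bijection():
    X, _ = _clouds(CENTERS, 80, 0.05, seed=5)
    model, _ = fit_clusters(X, k=3, seed=0)
    assert sorted(model.names.values()) == ["attenuated", "nonpropagated", "propagated"]
    hi = max(range(3), key=lambda c: model.means[c].sum())
    lo = min(range(3), key=lambda c: model.means[c].sum())
    assert model.names[hi] == "propagated" and model.names[lo] == "nonpropagated"


def test_covariances_positive_definite():
    X, _ = _clouds(CENTERS, 60, 0.04, seed=6)
    model, _ = fit_clusters(X, k=3, seed=0)
    for c in model.covariances:
        assert np.all(np.linalg.eigvalsh(c) > 0)


def test_too_few_points_and_nonsemantic_k():
    X, _ = _clouds(CENTERS, 4, 0.01, seed=7)
    with pytest.raises(ValueError):
        fit_clusters(X, k=3)
    X2, _ = _clouds(CENTERS, 40, 0.05, seed=8)
    model, labels = fit_clusters(X2, k=4, seed=0)
    assert model.names == {}
    assert set(labels) <= {0, 1, 2, 3}


def test_model_dict_roundtrip():
    X, _ = _clouds(CENTERS, 50, 0.05, seed=9)
    model, _ = fit_clusters(X, k=3, seed=0)
    back = ClusterModel.from_dict(model.to_dict())
    np.testing.assert_allclose(back.means, model.means)
    assert back.names == model.names


# ---------------------------------------------------------------------------
# density contours


def test_gaussian_contour_radii_match_closed_form():
    """Isotropic Gaussian: a contour at fraction L of peak density is a
    circle of radius sigma * sqrt(-2 ln L).  The KDE peak estimate at
    n = 5,000 carries sampling noise that the near-flat density top
    amplifies, so the check averages the radius over five independent
    samples; the mean agrees within 15%."""
    sigma = 0.1
    radii = {0.80: [], 0.33: []}
    for seed in range(5):
        X = np.random.default_rng(seed).normal(0.0, sigma, size=(5000, 2))
        contours = density_contours(X, grid_resolution=161, levels=(0.80, 0.33))
        for level, polys in contours.items():
            assert polys, f"no contour at level {level}"
            pts = np.vstack(polys)
            radii[level].append(
                np.median(np.linalg.norm(pts - X.mean(axis=0), axis=1))
            )
    for level, rs in radii.items():
        expected = sigma * np.sqrt(-2 * np.log(level))
        assert np.mean(rs) == pytest.approx(expected, rel=0.15)


def test_higher_level_region_nested_inside_lower():
    rng = np.random.default_rng(1)
    X = rng.normal(0.0, 0.1, size=(3000, 2))
    contours = density_contours(X, grid_resolution=151, levels=(0.80, 0.33))
    r80 = np.linalg.norm(np.vstack(contours[0.80]), axis=1)
    r33 = np.linalg.norm(np.vstack(contours[0.33]), axis=1)
    assert r80.max() < r33.min() + 0.02  # nested up to grid resolution


def test_contour_level_validation():
    X = np.random.default_rng(2).normal(size=(100, 2))
    with pytest.raises(ValueError):
        density_contours(X, levels=(1.5,))
    with pytest.raises(ValueError):
        density_contours(X[:5])


# ---------------------------------------------------------------------------
# geometric median


def brute_geometric_median(points, span=2.0, res=61, refinements=3):
    """Grid search, refined around the best cell each pass."""
    X = np.asarray(points, dtype=float)
    center = X.mean(axis=0)
    half = span / 2
    best = center
    for _ in range(refinements):
        gx = np.linspace(best[0] - half, best[0] + half, res)
        gy = np.linspace(best[1] - half, best[1] + half, res)
        GX, GY = np.meshgrid(gx, gy)
        cost = np.zeros_like(GX)
        for p in X:
            cost += np.hypot(GX - p[0], GY - p[1])
        i, j = np.unravel_index(cost.argmin(), cost.shape)
        best = np.array([GX[i, j], GY[i, j]])
        half = 2 * (gx[1] - gx[0])
    return best


def test_square_corners_median_is_center():
    square = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    np.testing.assert_allclose(geometric_median(square), [0.5, 0.5], atol=1e-8)


def test_single_point_is_its_own_median():
    np.testing.assert_allclose(geometric_median(np.array([[0.3, -0.7]])), [0.3, -0.7])


def assert_median_beats_grid(X, got, want, pos_tol=2e-3):
    """Position agreement with the grid oracle, or — where the distance
    surface is flat (median pinned at a data point) — an objective at
    least as small as the grid optimum."""
    if np.linalg.norm(got - want) >= pos_tol:
        cost = lambda y: np.linalg.norm(X - y, axis=1).sum()
        assert cost(got) <= cost(want) + 1e-9


def test_median_matches_grid_search_oracle():
    rng = np.random.default_rng(3)
    for _ in range(20):
        X = rng.uniform(-1, 1, size=(5, 2))
        assert_median_beats_grid(X, geometric_median(X), brute_geometric_median(X))


def test_median_handles_coincident_points():
    X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    m = geometric_median(X)
    cost = lambda y: np.linalg.norm(X - y, axis=1).sum()
    assert cost(m) <= cost(X.mean(axis=0)) + 1e-9
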