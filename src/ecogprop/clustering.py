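"""Mahalanobis-metric clustering of propagation profiles.

Events live in the (r_1mm, r_2mm) plane.  With k = 3 the clusters map
onto the three propagation classes: the cluster with the highest mean
r_1mm + r_2mm is ``propagated``, the lowest is ``nonpropagated``, and
the remaining one is ``attenuated``.

The fit is a hard-assignment EM scheme under a per-cluster Mahalanobis
metric: each point goes to the cluster minimizing its squared
Mahalanobis distance plus the covariance log-determinant (the
equal-weight Gaussian classification score, which reduces to plain
nearest-Mahalanobis whenever cluster covariances have equal volume and
to Euclidean for identity covariances); means and covariances are then
refit with εI regularization until the assignment stabilizes.  With the
log-det term the negative classification log-likelihood is provably
non-increasing across iterations, which a pure minimum-distance
assignment does not guarantee once covariances rescale the metric.

Initialization is a deterministic farthest-first traversal (first
center at the point farthest from the data mean, then greedy max-min,
each anchor smoothed to the mean of its nearest neighbours), which
finds small peripheral clusters — such as the few propagated events
that survive a circumscribing cut — that quantile-based anchors miss.
A percentile-anchor scheme remains available via ``init="percentile"``.

The module also provides the two visual-summary primitives used for
longitudinal tracking: kernel-density contours at fractions of the
peak density, and the geometric median (Weiszfeld iteration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde
from skimage import measure

CLUSTER_NAMES = ("propagated", "attenuated", "nonpropagated")


@dataclass
class ClusterModel:
    """Fitted Mahalanobis cluster model over (r_1mm, r_2mm)."""

    k: int
    means: np.ndarray  # (k, 2)
    covariances: np.ndarray  # (k, 2, 2)
    names: dict[int, str]  # cluster index -> semantic label (k == 3 only)
    iterations: int = 0
    converged: bool = False
    seed: int = 0
    objective_history: list[float] = field(default_factory=list)

    def mahalanobis(self, points: np.ndarray) -> np.ndarray:
        """Squared Mahalanobis distance of each point to each cluster."""
        X = np.atleast_2d(np.asarray(points, dtype=float))
        D = np.empty((len(X), self.k))
        for c in range(self.k):
            inv = np.linalg.inv(self.covariances[c])
            d = X - self.means[c]
            D[:, c] = np.einsum("ij,jk,ik->i", d, inv, d)
        return D

    def score(self, points: np.ndarray) -> np.ndarray:
        """Gaussian classification score: d² + log det Σ, per cluster."""
        logdets = np.array(
            [np.linalg.slogdet(self.covariances[c])[1] for c in range(self.k)]
        )
        return self.mahalanobis(points) + logdets

    def predict(self, points: np.ndarray) -> np.ndarray:
        """Index of the best cluster (minimum classification score)."""
        return self.score(points).argmin(axis=1)

    def predict_names(self, points: np.ndarray) -> list[str]:
        if not self.names:
            raise ValueError("semantic names require k == 3")
        return [self.names[i] for i in self.predict(points)]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "names": {str(i): n for i, n in self.names.items()},
            "iterations": self.iterations,
            "converged": self.converged,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterModel":
        return cls(
            k=int(d["k"]),
            means=np.asarray(d["means"], dtype=float),
            covariances=np.asarray(d["covariances"], dtype=float),
            names={int(i): n for i, n in d["names"].items()},
            iterations=int(d["iterations"]),
            converged=bool(d["converged"]),
            seed=int(d["seed"]),
        )


def _init_farthest_first(X: np.ndarray, k: int) -> np.ndarray:
    anchors = [X[np.linalg.norm(X - X.mean(axis=0), axis=1).argmax()]]
    while len(anchors) < k:
        dmin = np.min([np.linalg.norm(X - c, axis=1) for c in anchors], axis=0)
        anchors.append(X[dmin.argmax()])
    # anchors are extreme points; smooth each to the mean of its
    # nearest neighbours so an outlier cannot seed an empty cluster
    m = max(5, len(X) // 50)
    centers = []
    for a in anchors:
        near = np.argsort(np.linalg.norm(X - a, axis=1))[:m]
        centers.append(X[near].mean(axis=0))
    return np.array(centers, dtype=float)


def _init_percentile(X: np.ndarray, k: int) -> np.ndarray:
    if k == 3:
        qs = (90.0, 10.0, 50.0)
    else:
        qs = np.linspace(90.0, 10.0, k)
    return np.array(
        [[np.percentile(X[:, 0], q), np.percentile(X[:, 1], q)] for q in qs]
    )


def fit_clusters(
    points: np.ndarray,
    k: int = 3,
    seed: int = 0,
    max_iter: int = 100,
    reg_eps: float = 1e-6,
    init: str = "farthest_first",
) -> tuple[ClusterModel, np.ndarray]:
    """Fit the k-cluster Mahalanobis model; returns (model, labels).

    Deterministic given (points, seed, init).  Requires at least 5k
    points.  Semantic names are attached only for k = 3; other k return
    plain index labels.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = len(X)
    if n < 5 * k:
        raise ValueError(f"need at least {5 * k} points for k={k}, got {n}")
    if k < 2:
        raise ValueError("k must be >= 2")

    if init == "farthest_first":
        centers = _init_farthest_first(X, k)
    elif init == "percentile":
        centers = _init_percentile(X, k)
    else:
        raise ValueError(f"unknown init {init!r}")

    # Euclidean Lloyd warm start: settles the centers into their basins
    # before the covariance-adaptive phase, which otherwise can lock
    # onto a poor split of heavily overlapping clouds
    for _ in range(10):
        d = np.linalg.norm(X[:, None, :] - centers[None], axis=2)
        assign = d.argmin(axis=1)
        moved = False
        for c in range(k):
            m = assign == c
            if m.any():
                new_c = X[m].mean(axis=0)
                moved = moved or not np.allclose(new_c, centers[c])
                centers[c] = new_c
        if not moved:
            break

    eye = reg_eps * np.eye(2)
    gcov = np.cov(X.T) + eye
    covs = np.broadcast_to(gcov, (k, 2, 2)).copy()
    labels = np.full(n, -1)
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        model = ClusterModel(k=k, means=centers, covariances=covs, names={})
        S = model.score(X)
        new = S.argmin(axis=1)
        # negative classification log-likelihood (up to constants)
        history.append(float(S[np.arange(n), new].sum()))
        if np.array_equal(new, labels):
            converged = True
            break
        labels = new
        for c in range(k):
            m = labels == c
            if m.sum() >= 3:
                centers[c] = X[m].mean(axis=0)
                covs[c] = np.cov(X[m].T) + eye
            else:  # empty / tiny cluster: keep center, fall back to pooled cov
                covs[c] = gcov

    names: dict[int, str] = {}
    if k == 3:
        order = np.argsort(-(centers[:, 0] + centers[:, 1]))
        names = {
            int(order[0]): "propagated",
            int(order[1]): "attenuated",
            int(order[2]): "nonpropagated",
        }
    model = ClusterModel(
        k=k,
        means=centers,
        covariances=covs,
        names=names,
        iterations=it,
        converged=converged,
        seed=seed,
        objective_history=history,
    )
    return model, labels


# ---------------------------------------------------------------------------
# density contours


def density_contours(
    points: np.ndarray,
    grid_resolution: int = 201,
    levels: tuple[float, ...] = (0.80, 0.33),
    extent: tuple[float, float, float, float] = (-1.0, 1.0, -1.0, 1.0),
) -> dict[float, list[np.ndarray]]:
    """Contours of a Gaussian KDE at fractions of its peak density.

    Bandwidth follows Silverman's rule.  Returns, per level, a list of
    polylines in data coordinates (each an (m, 2) array of (x, y)).
    """
    X = np.asarray(points, dtype=float)
    if len(X) < 10:
        raise ValueError("need at least 10 points for a density estimate")
    for lv in levels:
        if not 0.0 < lv < 1.0:
            raise ValueError(f"contour level must be in (0, 1), got {lv}")

    kde = gaussian_kde(X.T, bw_method="silverman")
    x0, x1, y0, y1 = extent
    gx = np.linspace(x0, x1, grid_resolution)
    gy = np.linspace(y0, y1, grid_resolution)
    GX, GY = np.meshgrid(gx, gy, indexing="ij")
    Z = kde(np.vstack([GX.ravel(), GY.ravel()])).reshape(GX.shape)
    peak = Z.max()

    out: dict[float, list[np.ndarray]] = {}
    dx = (x1 - x0) / (grid_resolution - 1)
    dy = (y1 - y0) / (grid_resolution - 1)
    for lv in levels:
        polylines = []
        for seg in measure.find_contours(Z, lv * peak):
            xy = np.column_stack([x0 + seg[:, 0] * dx, y0 + seg[:, 1] * dy])
            polylines.append(xy)
        out[lv] = polylines
    return out


# ---------------------------------------------------------------------------
# geometric median


def geometric_median(
    points: np.ndarray, tol: float = 1e-9, max_iter: int = 10_000
) -> np.ndarray:
    """Point minimizing the sum of Euclidean distances (Weiszfeld).

    Uses the Vardi–Zhang correction when an iterate coincides with a
    data point, so convergence holds for every input.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    if len(X) == 0:
        raise ValueError("need at least one point")
    if len(X) == 1:
        return X[0].copy()
    y = X.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(X - y, axis=1)
        coincident = d < 1e-15
        if coincident.any():
            d = np.where(coincident, np.inf, d)
        w = 1.0 / d
        T = (w[:, None] * X).sum(axis=0) / w.sum()
        if coincident.any():
            # Vardi–Zhang: pull toward T, damped by the coincident mass
            r = np.linalg.norm((w[:, None] * (X - y)).sum(axis=0))
            eta = coincident.sum()
            if r == 0:  # y is the median already
                return y
            step = min(1.0, eta / r)
            T = (1 - step) * T + step * y
        if np.linalg.norm(T - y) < tol:
            return T
        y = T
    return y
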