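"""Shape-mode model: contour registration, PCA shape space, k-means modes.

Every cell outline is reduced to N = 50 registration coordinates (points
equally spaced by arc length along the closed contour), normalized to zero
centroid and unit root-mean-square radius, and rotationally aligned to a
common mean by generalized Procrustes analysis.  The start-index ambiguity
of a traced contour is removed inside alignment by exhaustive search over
all N cyclic shifts; reflections are never applied, so the chirality of a
ramification pattern is preserved.  PCA of the flattened 2N-dimensional
coordinates retains the smallest basis explaining >= 95% of variance
(configurable), and k-means with k = 5 modes (20 restarts, fixed seed)
clusters the retained scores.  Cluster labels are mapped to shape-mode
indices 1..k by descending cluster size (ties by centroid norm) so the
numbering is reproducible.

Assignment of a new cell repeats registration against the trained mean
(rotation + cyclic shift only), projects onto the retained basis and takes
the nearest centroid, ties going to the lowest mode index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LinearRing
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "RegisteredShape",
    "ShapeModeModel",
    "SMAssignment",
    "resample_contour",
    "normalize_shape",
    "align_to_reference",
    "align_shapes",
    "fit_pca",
    "fit_shape_modes",
    "fit_shape_mode_model",
    "assign_shape_mode",
    "assign_cells",
    "reconstruct_mode_shape",
    "save_model",
    "load_model",
]

N_COORDS = 50
N_MODES = 5


@dataclass(frozen=True)
class RegisteredShape:
    """One registered outline plus the transform that produced it."""

    cell_id: str
    coordinates: np.ndarray          # (N, 2) (row, col), centered, rms 1
    translation: tuple[float, float]
    scale: float
    rotation: float                  # radians applied during alignment
    start_shift: int


@dataclass
class ShapeModeModel:
    """Trained shape space + mode centroids."""

    n_points: int
    k: int
    mean_shape: np.ndarray                 # (N, 2)
    pca_mean: np.ndarray                   # (2N,)
    components: np.ndarray                 # (n_pcs, 2N), orthonormal rows
    explained_variance_ratio: np.ndarray   # full spectrum, nonincreasing
    n_pcs_retained: int
    centroids: np.ndarray                  # (k, n_pcs) in retained PC space
    cluster_sizes: np.ndarray              # training cells per mode, SM order
    seed: int = 0
    var_retained: float = 0.95


@dataclass(frozen=True)
class SMAssignment:
    cell_id: str
    sm: int              # 1..k
    distance: float


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def _closed_vertices(contour: np.ndarray) -> np.ndarray:
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("contour must be an (n, 2) array")
    if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 3:
        raise ValueError("contour needs at least 3 distinct vertices")
    return pts


def resample_contour(contour: np.ndarray, n: int = N_COORDS) -> np.ndarray:
    """Resample a closed simple contour to ``n`` equal-arc-length points.

    Points sit at arc-length positions ``i * L / n`` measured from the
    contour's first vertex, preserving traversal direction.  Raises for
    fewer than 3 requested points or a self-intersecting outline.
    """
    if n < 3:
        raise ValueError("need at least 3 registration coordinates")
    pts = _closed_vertices(contour)
    ring = LinearRing(pts[:, ::-1])  # shapely wants (x, y)
    if not ring.is_simple:
        raise ValueError("self-intersecting contour cannot be registered")
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    L = cum[-1]
    if L <= 0:
        raise ValueError("zero-length contour")
    targets = np.arange(n) * L / n
    out = np.column_stack(
        [np.interp(targets, cum, closed[:, 0]), np.interp(targets, cum, closed[:, 1])]
    )
    return out


def normalize_shape(points: np.ndarray) -> np.ndarray:
    """Center at the origin and scale to unit root-mean-square radius."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum(centered**2, axis=1)))
    if rms <= 0:
        raise ValueError("degenerate shape: zero spread")
    return centered / rms


def _to_complex(points: np.ndarray) -> np.ndarray:
    # (row, col) -> col + i*row so rotations are complex multiplication
    return points[:, 1] + 1j * points[:, 0]


def _to_points(z: np.ndarray) -> np.ndarray:
    return np.column_stack([z.imag, z.real])


def align_to_reference(
    points: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, float, int]:
    """Best rotation + cyclic start shift of ``points`` onto ``reference``.

    Both inputs are normalized N-point shapes.  For every cyclic shift the
    optimal rotation has the closed form ``exp(i*theta) = conj(s)/|s|`` with
    ``s = sum(z_shifted * conj(ref))``; the shift with the largest ``|s|``
    wins.  Reflections are never considered.

    Returns (aligned points, rotation angle, start shift).
    """
    z = _to_complex(np.asarray(points, float))
    m = _to_complex(np.asarray(reference, float))
    if len(m) != len(z):
        raise ValueError("shapes must share the number of points")
    # corr[s] = sum_i z[(i+s) % N] * conj(m[i]) for all shifts at once
    corr = np.fft.ifft(np.fft.fft(z) * np.conj(np.fft.fft(m)))
    best = int(np.argmax(np.abs(corr)))
    s = corr[best]
    rot = np.conj(s) / abs(s) if abs(s) > 0 else 1.0 + 0j
    aligned = _to_points(rot * np.roll(z, -best))
    return aligned, float(np.angle(rot)), best


def align_shapes(
    shapes: list[np.ndarray],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Generalized Procrustes alignment of normalized shapes.

    Iteratively aligns every shape (rotation + cyclic shift) to the current
    mean, recomputes and renormalizes the mean, and stops when the mean
    moves by less than ``tol`` (RMS) or after ``max_iter`` rounds.

    Returns (aligned array (n, N, 2), mean shape (N, 2), per-shape
    transform dicts with ``rotation`` and ``start_shift``).
    """
    if not shapes:
        raise ValueError("no shapes to align")
    arr = np.stack([normalize_shape(s) for s in shapes])
    mean = arr[0].copy()
    transforms = [{"rotation": 0.0, "start_shift": 0} for _ in shapes]
    for _ in range(max_iter):
        aligned = np.empty_like(arr)
        for i, shape in enumerate(arr):
            aligned[i], rot, shift = align_to_reference(shape, mean)
            transforms[i] = {"rotation": rot, "start_shift": shift}
        new_mean = normalize_shape(aligned.mean(axis=0))
        delta = np.sqrt(np.mean((new_mean - mean) ** 2))
        mean = new_mean
        if delta < tol:
            break
    return aligned, mean, transforms


# ---------------------------------------------------------------------------
# shape space + modes
# ---------------------------------------------------------------------------

def fit_pca(aligned: np.ndarray, var_retained: float = 0.95) -> tuple[PCA, int, np.ndarray]:
    """PCA of flattened aligned coordinates.

    Returns the fitted decomposition, the number of leading components
    whose cumulative explained variance reaches ``var_retained``, and the
    per-shape scores on those components.
    """
    X = np.asarray(aligned, float).reshape(len(aligned), -1)
    if len(X) < 2:
        raise ValueError("need at least 2 shapes for a shape space")
    if float(np.var(X, axis=0).sum()) <= 1e-24:
        raise ValueError("degenerate shape set: zero variance")
    pca = PCA(svd_solver="full")
    scores_full = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_pcs = int(np.searchsorted(cum, var_retained - 1e-12) + 1)
    n_pcs = min(n_pcs, X.shape[1], len(X) - 1)
    return pca, n_pcs, scores_full[:, :n_pcs]


def fit_shape_modes(
    scores: np.ndarray, k: int = N_MODES, seed: int = 0, n_init: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """k-means over PC scores; labels renumbered to SM order 1..k.

    The best of ``n_init`` greedy-seeded restarts (squared-Euclidean
    inertia) is kept.  Clusters are ordered by descending size, ties by
    centroid norm, so SM numbering does not depend on k-means internals.

    Returns (centroids in SM order, SM label 1..k per training shape).
    """
    scores = np.asarray(scores, float)
    if len(np.unique(scores, axis=0)) < k:
        raise ValueError(f"fewer than k={k} distinct score vectors")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(scores)
    sizes = np.bincount(raw, minlength=k)
    norms = np.linalg.norm(km.cluster_centers_, axis=1)
    order = sorted(range(k), key=lambda c: (-sizes[c], norms[c]))
    relabel = np.empty(k, dtype=int)
    for sm_index, cluster in enumerate(order):
        relabel[cluster] = sm_index
    centroids = km.cluster_centers_[order]
    labels = relabel[raw] + 1
    return centroids, labels


def fit_shape_mode_model(
    contours: list[np.ndarray],
    cell_ids: list[str] | None = None,
    n: int = N_COORDS,
    k: int = N_MODES,
    seed: int = 0,
    var_retained: float = 0.95,
) -> tuple[ShapeModeModel, np.ndarray, np.ndarray]:
    """Train the full shape-mode model from raw cell outlines.

    Returns (model, training SM labels 1..k, aligned coordinates).
    """
    if len(contours) < k + 1:
        raise ValueError(f"need more than k={k} cells to train")
    resampled = [resample_contour(c, n) for c in contours]
    aligned, mean, _ = align_shapes(resampled)
    pca, n_pcs, scores = fit_pca(aligned, var_retained)
    centroids, labels = fit_shape_modes(scores, k=k, seed=seed)
    sizes = np.bincount(labels - 1, minlength=k)
    model = ShapeModeModel(
        n_points=n,
        k=k,
        mean_shape=mean,
        pca_mean=pca.mean_,
        components=pca.components_[:n_pcs],
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_pcs_retained=n_pcs,
        centroids=centroids,
        cluster_sizes=sizes,
        seed=seed,
        var_retained=var_retained,
    )
    return model, labels, aligned


def _register_to_model(contour: np.ndarray, model: ShapeModeModel) -> np.ndarray:
    pts = normalize_shape(resample_contour(contour, model.n_points))
    aligned, _, _ = align_to_reference(pts, model.mean_shape)
    return aligned


def assign_shape_mode(
    contour: np.ndarray, model: ShapeModeModel
) -> tuple[int, float]:
    """Assign one outline to its nearest shape mode.

    Registration against the trained mean (rotation + cyclic shift only),
    projection on the retained basis, nearest centroid; ties go to the
    lowest SM index.  Returns (sm in 1..k, distance to centroid).
    """
    aligned = _register_to_model(contour, model)
    score = (aligned.ravel() - model.pca_mean) @ model.components.T
    d = np.linalg.norm(model.centroids - score, axis=1)
    best = int(np.argmin(d))  # argmin is first minimizer -> lowest SM on ties
    return best + 1, float(d[best])


def assign_cells(cells, model: ShapeModeModel) -> tuple[list[SMAssignment], int]:
    """Assign a batch of :class:`CellObject`; degenerate outlines are
    counted as unassignable instead of raising."""
    out: list[SMAssignment] = []
    n_unassignable = 0
    for cell in cells:
        try:
            sm, dist = assign_shape_mode(cell.contour, model)
        except ValueError:
            n_unassignable += 1
            continue
        out.append(SMAssignment(cell_id=cell.cell_id, sm=sm, distance=dist))
    return out, n_unassignable


def reconstruct_mode_shape(model: ShapeModeModel, sm: int) -> np.ndarray:
    """Mean outline of one shape mode, mapped back to coordinate space."""
    if not 1 <= sm <= model.k:
        raise ValueError(f"shape mode must be in 1..{model.k}")
    flat = model.pca_mean + model.centroids[sm - 1] @ model.components
    return flat.reshape(model.n_points, 2)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: ShapeModeModel, path) -> None:
    """Single-archive NPZ serialization (config stored as JSON)."""
    config = json.dumps(
        {
            "n_points": model.n_points,
            "k": model.k,
            "n_pcs_retained": model.n_pcs_retained,
            "seed": model.seed,
            "var_retained": model.var_retained,
        }
    )
    np.savez(
        path,
        mean_shape=model.mean_shape,
        pca_mean=model.pca_mean,
        components=model.components,
        explained_variance_ratio=model.explained_variance_ratio,
        centroids=model.centroids,
        cluster_sizes=model.cluster_sizes,
        config=np.array(config),
    )


def load_model(path) -> ShapeModeModel:
    with np.load(path, allow_pickle=False) as npz:
        config = json.loads(str(npz["config"]))
        return ShapeModeModel(
            n_points=config["n_points"],
            k=config["k"],
            mean_shape=npz["mean_shape"],
            pca_mean=npz["pca_mean"],
            components=npz["components"],
            explained_variance_ratio=npz["explained_variance_ratio"],
            n_pcs_retained=config["n_pcs_retained"],
            centroids=npz["centroids"],
            cluster_sizes=npz["cluster_sizes"],
            seed=config["seed"],
            var_retained=config["var_retained"],
        )
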