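"""Landmark-based geometric morphometrics.

Implements the shape-analysis chain used to compare fly head shapes:
generalized Procrustes alignment (GPA), removal of projection artifacts
(pitch/yaw of a 3D head photographed in 2D) by pooled within-group
regression on principal components, dimension reduction with back-rotation
into landmark space, and group discrimination by canonical variate /
discriminant function analysis with permutation inference.

Shapes are ordered 2D landmark configurations.  After GPA every
configuration is centered at the origin, scaled to unit centroid size and
rotated (no reflection) to a common consensus, so differences between
aligned configurations are pure shape differences.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "LandmarkConfiguration",
    "AlignedShapes",
    "ShapeSubspace",
    "NuisanceCorrection",
    "GroupShapeResult",
    "centroid_size",
    "procrustes_align",
    "pca_shapes",
    "remove_nuisance_axes",
    "reduce_backrotate",
    "cva",
    "dfa",
    "procrustes_distance",
    "allometric_decomposition",
]


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2D landmarks with a group label.

    ``coords`` has shape (n_landmarks, 2); landmark order must be identical
    across all specimens entering a joint analysis.
    """

    specimen_id: str
    group: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must have shape (n_landmarks, 2)")
        if self.coords.shape[0] < 3:
            raise ValueError("a shape needs at least 3 landmarks")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain NaN or infinite values")


@dataclass
class AlignedShapes:
    """Output of :func:`procrustes_align`.

    ``procrustes_coords``: (n_specimens, 2·n_landmarks) flat coordinates
    (x1, y1, x2, y2, ...), each row centered with unit centroid size.
    """

    procrustes_coords: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    specimen_ids: list = field(default_factory=list)
    groups: list = field(default_factory=list)

    @property
    def n_landmarks(self) -> int:
        return self.procrustes_coords.shape[1] // 2


@dataclass
class ShapeSubspace:
    """Principal-component basis of aligned shapes.

    ``basis`` columns are orthonormal directions in flat landmark space;
    ``scores`` are specimen projections; ``variance_fraction`` is per-axis,
    descending; ``mean`` is the grand mean needed for reconstruction.
    """

    basis: np.ndarray
    scores: np.ndarray
    variance_fraction: np.ndarray
    mean: np.ndarray


@dataclass
class NuisanceCorrection:
    """Corrected coordinates plus a record of the removed axes."""

    coords: np.ndarray
    removed_axes: list
    removed_scores: list
    centering: str


@dataclass
class GroupShapeResult:
    """Group discrimination output (CVA or its two-group DFA special case)."""

    cv_axes: np.ndarray
    cv_scores: np.ndarray
    cv_variance_fraction: np.ndarray
    mean_shapes: dict
    mahalanobis_distances: dict
    procrustes_distances: dict
    p_values: dict
    n_perm: int
    discriminant_scores: np.ndarray | None = None
    cv_misclassification: float | None = None


# ---------------------------------------------------------------------------
# basic geometry


def centroid_size(coords: np.ndarray) -> float:
    """Square root of the summed squared landmark distances to the centroid."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2:
        coords = coords.reshape(-1, 2)
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs <= 0 or not np.isfinite(cs):
        raise ValueError("degenerate configuration: centroid size is zero")
    return cs


def _optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation R (det +1, no reflection) minimizing ||a @ R - b||_F."""
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    # flip the smallest singular direction if the best orthogonal map reflects
    corr = np.diag([1.0, d])
    return u @ corr @ vt


def _to_matrix(configs) -> tuple[np.ndarray, list, list]:
    shapes = []
    ids, groups = [], []
    for c in configs:
        if isinstance(c, LandmarkConfiguration):
            shapes.append(np.asarray(c.coords, dtype=float))
            ids.append(c.specimen_id)
            groups.append(c.group)
        else:
            shapes.append(np.asarray(c, dtype=float).reshape(-1, 2))
            ids.append(str(len(ids)))
            groups.append("")
    k = shapes[0].shape[0]
    if any(s.shape[0] != k for s in shapes):
        raise ValueError("all configurations must share the landmark count")
    return np.stack(shapes), ids, groups


def procrustes_align(configs, tol: float = 1e-10, max_iter: int = 200) -> AlignedShapes:
    """Generalized Procrustes analysis.

    Each configuration is centered, scaled to unit centroid size, and
    iteratively rotated to the running consensus until the consensus moves
    by less than ``tol``.  Reflections are not allowed.
    """
    x, ids, groups = _to_matrix(configs)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 configurations")
    n, k, _ = x.shape
    sizes = np.empty(n)
    for i in range(n):
        x[i] -= x[i].mean(axis=0)
        sizes[i] = np.sqrt((x[i] ** 2).sum())
        if sizes[i] <= 0:
            raise ValueError(f"degenerate configuration at index {i}")
        x[i] /= sizes[i]
    consensus = x[0].copy()
    for _ in range(max_iter):
        for i in range(n):
            x[i] = x[i] @ _optimal_rotation(x[i], consensus)
        new = x.mean(axis=0)
        new -= new.mean(axis=0)
        new /= np.sqrt((new**2).sum())
        delta = np.sqrt(((new - consensus) ** 2).sum())
        consensus = new
        if delta < tol:
            break
    return AlignedShapes(
        procrustes_coords=x.reshape(n, 2 * k),
        centroid_sizes=sizes,
        consensus=consensus.reshape(-1),
        specimen_ids=ids,
        groups=groups,
    )


def procrustes_distance(shape_a, shape_b, superimpose: bool = False) -> float:
    """Square root of summed squared distances between comparable landmarks.

    By default both shapes are assumed already superimposed in a common
    frame (e.g. group mean shapes from one GPA).  With ``superimpose=True``
    the two shapes are first centered, scaled to unit centroid size and
    optimally rotated onto each other (partial Procrustes distance).
    """
    a = np.asarray(shape_a, dtype=float)
    b = np.asarray(shape_b, dtype=float)
    if a.size != b.size:
        raise ValueError("landmark counts differ")
    if superimpose:
        a = a.reshape(-1, 2)
        b = b.reshape(-1, 2)
        a = a - a.mean(axis=0)
        b = b - b.mean(axis=0)
        a /= np.sqrt((a**2).sum())
        b /= np.sqrt((b**2).sum())
        a = a @ _optimal_rotation(a, b)
    return float(np.sqrt(((a - b) ** 2).sum()))


# ---------------------------------------------------------------------------
# subspaces


def _coords_of(aligned) -> np.ndarray:
    if isinstance(aligned, AlignedShapes):
        return aligned.procrustes_coords
    if isinstance(aligned, NuisanceCorrection):
        return aligned.coords
    return np.asarray(aligned, dtype=float)


def pca_shapes(aligned) -> ShapeSubspace:
    """PCA of (aligned) shape coordinates; axes ordered by variance."""
    x = _coords_of(aligned)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 specimens")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    return ShapeSubspace(basis=vt.T, scores=u * s, variance_fraction=frac, mean=mean)


def _pooled_pca_axis(xc: np.ndarray, axis_index: int) -> np.ndarray:
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    return vt[axis_index]


def remove_nuisance_axes(
    aligned,
    groups,
    n_steps: int = 2,
    axes: tuple = (1, 2),
    centering: str = "pooled",
) -> NuisanceCorrection:
    """Two-step removal of projection artifacts (pitch, then yaw).

    Step 1: a PCA is computed on group-mean-centered ("pooled within-group")
    coordinates and every coordinate is regressed, pooled within groups, on
    the score along PC ``axes[0]`` (default PC1); the residuals keep the
    group structure.  Step 2 repeats the procedure on the corrected data,
    removing PC ``axes[1]`` (default: the *new* PC2).

    The PCA centering is configurable: ``"pooled"`` (group-mean-centered,
    default) or ``"global"`` (grand-mean-centered); the removal regression
    is always pooled within groups, so group mean shapes are preserved.
    """
    x = _coords_of(aligned).copy()
    groups = np.asarray(groups)
    if groups.shape[0] != x.shape[0]:
        raise ValueError("one group label per specimen required")
    labels, inv, counts = np.unique(groups, return_inverse=True, return_counts=True)
    if np.any(counts < 2):
        bad = labels[counts < 2]
        raise ValueError(f"within-group regression undefined for singleton group(s): {list(bad)}")
    if centering not in ("pooled", "global"):
        raise ValueError("centering must be 'pooled' or 'global'")

    removed_axes, removed_scores = [], []
    for step in range(n_steps):
        gmeans = np.stack([x[inv == g].mean(axis=0) for g in range(len(labels))])
        within = x - gmeans[inv]
        centered = within if centering == "pooled" else x - x.mean(axis=0)
        v = _pooled_pca_axis(centered, axes[step] - 1)
        score = within @ v  # zero-mean within every group
        ss = score @ score
        if ss <= 0:
            removed_axes.append(v)
            removed_scores.append(score)
            continue
        beta = (score @ within) / ss  # pooled within-group regression slope
        x = x - np.outer(score, beta)
        removed_axes.append(v)
        removed_scores.append(score)
    return NuisanceCorrection(
        coords=x, removed_axes=removed_axes, removed_scores=removed_scores, centering=centering
    )


def reduce_backrotate(coords, variance_target: float = 0.90):
    """Keep the smallest PC set reaching ``variance_target`` and back-rotate.

    Returns ``(reconstructed, k, subspace)`` where ``reconstructed`` lives in
    the original landmark space (scores · basisᵀ + mean).
    """
    if not (0.0 < variance_target <= 1.0):
        raise ValueError("variance_target must be in (0, 1]")
    sub = pca_shapes(coords)
    cum = np.cumsum(sub.variance_fraction)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, sub.basis.shape[1])
    recon = sub.scores[:, :k] @ sub.basis[:, :k].T + sub.mean
    return recon, k, sub


# ---------------------------------------------------------------------------
# group discrimination


def _rank_reduce(x: np.ndarray, rtol: float = 1e-9):
    """Project onto the non-null principal subspace (lossless)."""
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    keep = s > (s[0] * rtol if s.size and s[0] > 0 else 0)
    v = vt[keep].T
    return xc @ v, v, mean


def _pooled_within_cov(y: np.ndarray, inv: np.ndarray, n_groups: int) -> np.ndarray:
    n, p = y.shape
    w = np.zeros((p, p))
    for g in range(n_groups):
        yg = y[inv == g]
        yg = yg - yg.mean(axis=0)
        w += yg.T @ yg
    dof = n - n_groups
    if dof <= 0:
        raise ValueError("not enough specimens for a pooled covariance")
    return w / dof


def _t2(z1: np.ndarray, z2: np.ndarray) -> float:
    n1, n2 = len(z1), len(z2)
    d = z1.mean(axis=0) - z2.mean(axis=0)
    s = ((z1 - z1.mean(axis=0)).T @ (z1 - z1.mean(axis=0)) +
         (z2 - z2.mean(axis=0)).T @ (z2 - z2.mean(axis=0))) / (n1 + n2 - 2)
    try:
        sol = np.linalg.solve(s, d)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(s, d, rcond=None)[0]
    return float(n1 * n2 / (n1 + n2) * d @ sol)


def _perm_p(z1: np.ndarray, z2: np.ndarray, n_perm: int, rng: np.random.Generator) -> float:
    """Permutation p for Hotelling T²; observed table counted in both tallies."""
    obs = _t2(z1, z2)
    z = np.vstack([z1, z2])
    n1 = len(z1)
    b = 0
    for _ in range(n_perm):
        idx = rng.permutation(len(z))
        if _t2(z[idx[:n1]], z[idx[n1:]]) >= obs - 1e-12:
            b += 1
    return (b + 1) / (n_perm + 1)


def cva(coords, groups, n_perm: int = 10000, seed: int | None = 0) -> GroupShapeResult:
    """Canonical variate analysis with pairwise permutation inference.

    Canonical axes are eigenvectors of (pooled within)⁻¹ · between
    covariance.  Pairwise Mahalanobis distances use the pooled within-group
    covariance of all groups; pairwise p-values come from permuting labels
    within each pair of groups on the two-sample T² statistic, with
    p = (b + 1)/(n_perm + 1).

    Rank-deficient input (e.g. back-rotated coordinates) is first projected
    losslessly onto its non-null principal subspace.  A singular pooled
    within-group covariance on that subspace raises an error.
    """
    x = _coords_of(coords)
    groups = np.asarray(groups)
    labels, inv = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    rng = np.random.default_rng(seed)

    y, v, mean = _rank_reduce(x)
    w = _pooled_within_cov(y, inv, len(labels))
    if np.linalg.cond(w) > 1e10:
        raise np.linalg.LinAlgError(
            "pooled within-group covariance is singular; reduce dimensions first "
            "(e.g. reduce_backrotate with a lower variance target)"
        )
    n = len(y)
    gmeans = np.stack([y[inv == g].mean(axis=0) for g in range(len(labels))])
    gn = np.array([(inv == g).sum() for g in range(len(labels))])
    grand = y.mean(axis=0)
    between = (gn[:, None] * (gmeans - grand)).T @ (gmeans - grand) / max(len(labels) - 1, 1)

    evals, evecs = scipy.linalg.eigh(between, w)
    order = np.argsort(evals)[::-1]
    n_cv = min(len(labels) - 1, y.shape[1])
    evals = np.clip(evals[order][:n_cv], 0, None)
    axes_y = evecs[:, order][:, :n_cv]
    cv_axes = v @ axes_y  # back in landmark space
    cv_scores = (y - grand) @ axes_y
    total = evals.sum()
    cv_var = evals / total if total > 0 else np.zeros_like(evals)

    winv = np.linalg.inv(w)
    mean_shapes = {lab: x[inv == g].mean(axis=0) for g, lab in enumerate(labels)}
    maha, proc, pvals = {}, {}, {}
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            d = gmeans[a] - gmeans[b]
            maha[(labels[a], labels[b])] = float(np.sqrt(d @ winv @ d))
            proc[(labels[a], labels[b])] = procrustes_distance(
                mean_shapes[labels[a]], mean_shapes[labels[b]]
            )
            pvals[(labels[a], labels[b])] = _perm_p(
                y[inv == a], y[inv == b], n_perm, rng
            )
    return GroupShapeResult(
        cv_axes=cv_axes,
        cv_scores=cv_scores,
        cv_variance_fraction=cv_var,
        mean_shapes=mean_shapes,
        mahalanobis_distances=maha,
        procrustes_distances=proc,
        p_values=pvals,
        n_perm=n_perm,
    )


def dfa(coords, groups, n_perm: int = 1000, seed: int | None = 0) -> GroupShapeResult:
    """Discriminant function analysis: two-group special case of CVA.

    Returns the single discriminant axis, per-specimen discriminant scores,
    the Procrustes distance between group means, a permutation p-value on
    T² (n_perm defaults to 1000), and a leave-one-out cross-validated
    misclassification rate (reported separately from the permutation test).
    """
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError("dfa requires exactly 2 groups")
    res = cva(coords, groups, n_perm=n_perm, seed=seed)

    # canonical axis orientation: from the first label's mean toward the
    # second's, so relabelling the groups flips the score signs
    x = _coords_of(coords)
    y, v, _ = _rank_reduce(x)
    inv = (groups == labels[1]).astype(int)
    w = _pooled_within_cov(y, inv, 2)
    m0 = y[inv == 0].mean(axis=0)
    m1 = y[inv == 1].mean(axis=0)
    try:
        axis = np.linalg.solve(w, m1 - m0)
    except np.linalg.LinAlgError:
        axis = np.linalg.lstsq(w, m1 - m0, rcond=None)[0]
    axis = axis / np.linalg.norm(axis)
    res.discriminant_scores = (y - y.mean(axis=0)) @ axis
    res.cv_axes = (v @ axis).reshape(-1, 1)
    res.cv_scores = res.discriminant_scores.reshape(-1, 1)
    mis = 0
    for i in range(len(y)):
        mask = np.ones(len(y), bool)
        mask[i] = False
        yi, gi = y[mask], inv[mask]
        if len(np.unique(gi)) < 2:
            continue
        w = _pooled_within_cov(yi, gi, 2)
        m0, m1 = yi[gi == 0].mean(axis=0), yi[gi == 1].mean(axis=0)
        try:
            a = np.linalg.solve(w, m1 - m0)
        except np.linalg.LinAlgError:
            a = np.linalg.lstsq(w, m1 - m0, rcond=None)[0]
        score = (y[i] - (m0 + m1) / 2) @ a
        if (score > 0) != bool(inv[i]):
            mis += 1
    res.cv_misclassification = mis / len(y)
    return res


# ---------------------------------------------------------------------------
# allometry


def allometric_decomposition(coords, centroid_sizes):
    """Split shape into its allometric component and non-allometric residuals.

    Each coordinate is regressed on centroid size; the fitted values are the
    allometric component, the residuals (plus the grand mean) are the
    size-independent shape used for chromosome-effect testing.
    Returns ``(allometric_component, residuals, slopes)``.
    """
    x = _coords_of(coords)
    cs = np.asarray(centroid_sizes, dtype=float)
    if np.any(cs <= 0):
        raise ValueError("centroid sizes must be positive")
    if np.std(cs) == 0:
        raise ValueError("constant centroid size: allometric regression undefined")
    csc = cs - cs.mean()
    xc = x - x.mean(axis=0)
    slopes = (csc @ xc) / (csc @ csc)
    fitted = np.outer(csc, slopes)
    residuals = x - fitted
    return fitted, residuals, slopes
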