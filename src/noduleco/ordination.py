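"""Bray-Curtis dissimilarity and 2-D nonmetric multidimensional scaling.

The nMDS engine is SMACOF majorization with isotonic (monotone) disparities
(:func:`sklearn.manifold.smacof`, ``metric=False``), run from a classical
metric-scaling start plus random restarts; the reported badness-of-fit is
Kruskal stress-1 recomputed from the final configuration,

    stress1 = sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 ),

with dhat the isotonic regression of embedding distances on the input
dissimilarity order.  Coordinates are centered and rotated to principal axes
(dimension 1 carries the larger variance); a reproducible sign convention
ties dimension 1 to the nodule-cover gradient.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import squareform
from scipy.stats import chi2, spearmanr
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: np.ndarray     # (n, 2), centered, principal-axis rotated
    stress: float               # Kruskal stress-1 of the best restart
    restarts_used: int
    converged: bool
    labels: np.ndarray          # (n,) class_index per sample


def bray_curtis(X) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity sum|x-y| / sum(x+y) on rows of X.

    Entries lie in [0, 1] for nonnegative input; a pair of all-zero rows is
    assigned d = 0 by convention (with a warning).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative entries")
    n = X.shape[0]
    D = np.zeros((n, n))
    zero_pair = False
    for i in range(n - 1):
        diff = np.abs(X[i + 1:] - X[i]).sum(axis=1)
        tot = (X[i + 1:] + X[i]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
        if (tot == 0).any():
            zero_pair = True
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    if zero_pair:
        warnings.warn("all-zero sample pair(s): Bray-Curtis set to 0 "
                      "by convention")
    return D


def kruskal_stress1(D: np.ndarray, coords: np.ndarray) -> float:
    """Stress-1 of a configuration against dissimilarities D (isotonic fit)."""
    d = squareform(D, checks=False)
    e = squareform(_pairwise(coords), checks=False)
    # primary approach to ties: within tied dissimilarities, order by
    # embedding distance so the monotone fit may track them freely
    order = np.lexsort((e, d))
    iso = IsotonicRegression()
    dhat = np.empty_like(e)
    dhat[order] = iso.fit_transform(np.arange(order.size), e[order])
    denom = (e ** 2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((e - dhat) ** 2).sum() / denom))


def _pairwise(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def classical_mds(D: np.ndarray, dims: int = 2) -> np.ndarray:
    """Torgerson classical scaling, used as the deterministic first start."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dims]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def nmds_embed(D, dims: int = 2, restarts: int = 16, max_iter: int = 300,
               tol: float = 1e-6, rng=None,
               labels=None) -> OrdinationResult:
    """Nonmetric MDS of a dissimilarity matrix; best of ``restarts`` starts.

    The first start is classical metric scaling, the remainder are random
    Gaussian configurations.  Non-convergence within ``max_iter`` is reported
    via ``converged=False`` with a warning, never an exception.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("D must be a symmetric square matrix")
    if rng is None:
        rng = np.random.default_rng(0)
    if labels is None:
        labels = np.zeros(n, dtype=int)
    labels = np.asarray(labels)

    best = None
    for r in range(max(1, restarts)):
        if r == 0:
            init = classical_mds(D, dims)
            if not np.isfinite(init).all() or np.allclose(init, 0):
                init = rng.standard_normal((n, dims))
        else:
            init = rng.standard_normal((n, dims))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords, _, n_iter = smacof(
                D, metric=False, n_components=dims, init=init, n_init=1,
                max_iter=max_iter, eps=tol, random_state=0,
                normalized_stress=True, return_n_iter=True)
        stress = kruskal_stress1(D, coords)
        if best is None or stress < best[0]:
            best = (stress, coords, n_iter)
    stress, coords, n_iter = best
    converged = n_iter < max_iter
    if not converged:
        warnings.warn(f"nMDS did not converge within {max_iter} iterations "
                      f"(best stress-1 {stress:.4f})")
    coords = _principal_axes(coords)
    return OrdinationResult(coordinates=coords, stress=stress,
                            restarts_used=max(1, restarts),
                            converged=converged, labels=labels)


def _principal_axes(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    return centered @ Vt.T


def orient_axes(result: OrdinationResult,
                class_mean_covers: dict) -> OrdinationResult:
    """Fix axis signs: dimension 1 increases with nodule cover.

    Dimension 1 is flipped if the Spearman correlation between class-mean
    dimension-1 scores and class mean covers is negative; dimension 2 is
    flipped so its largest-magnitude coordinate is positive.  The operation
    is an involution on already-oriented results.
    """
    coords = result.coordinates.copy()
    classes = sorted(class_mean_covers)
    d1_means = [coords[result.labels == c, 0].mean() for c in classes]
    covers = [class_mean_covers[c] for c in classes]
    if len(classes) >= 2:
        rs = spearmanr(d1_means, covers).statistic
        if np.isfinite(rs) and rs < 0:
            coords[:, 0] = -coords[:, 0]
    if coords.shape[1] > 1:
        j = np.argmax(np.abs(coords[:, 1]))
        if coords[j, 1] < 0:
            coords[:, 1] = -coords[:, 1]
    return replace(result, coordinates=coords)


@dataclass(frozen=True)
class ClassEllipse:
    class_index: int
    centroid: np.ndarray        # (2,)
    covariance: np.ndarray      # (2, 2) of replicate coordinates
    semi_axes: np.ndarray       # (2,) major, minor
    angle_deg: float            # major-axis angle from dimension 1


def class_ellipses(result: OrdinationResult,
                   level: float = 0.95) -> list[ClassEllipse]:
    """Per-class centroid and coverage ellipse of replicate coordinates.

    The replicate-cloud covariance is scaled by the chi-square(2) quantile at
    ``level`` (5.991 at 0.95); semi-axes are the square roots of the scaled
    eigenvalues.  A degenerate covariance collapses the ellipse to a segment
    or point (warning, not an error).
    """
    scale = chi2.ppf(level, df=2)
    out = []
    for c in sorted(set(result.labels.tolist())):
        pts = result.coordinates[result.labels == c]
        if pts.shape[0] < 3:
            raise ValueError(f"class {c}: need >= 3 samples for an ellipse")
        centroid = pts.mean(axis=0)
        cov = np.cov(pts.T)
        vals, vecs = np.linalg.eigh(cov)
        vals = np.clip(vals, 0.0, None)
        if vals.min() == 0.0:
            warnings.warn(f"class {c}: degenerate coordinate covariance; "
                          "ellipse collapses to a segment/point")
        semi = np.sqrt(vals[::-1] * scale)       # major first
        major = vecs[:, -1]
        angle = float(np.degrees(np.arctan2(major[1], major[0])))
        out.append(ClassEllipse(class_index=int(c), centroid=centroid,
                                covariance=cov, semi_axes=semi,
                                angle_deg=angle))
    return out
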