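"""Shape-space statistics: PCA, two-block PLS, RV, allometry, group variance.

All operations consume flat tangent-space coordinate matrices (n specimens x
3k coordinates) produced by :mod:`dentomorph.gpa`. Covariances use the n-1
divisor throughout. Eigenvectors and singular vectors are sign-fixed so
their largest-magnitude loading is positive, removing the SVD sign
ambiguity from stored outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tps import TPSModel, fit_tps

__all__ = [
    "PCAResult",
    "shape_pca",
    "pc_warp_endpoints",
    "PLSResult",
    "two_block_pls",
    "rv_coefficient",
    "RegressionResult",
    "size_shape_regression",
    "group_shape_variance",
]


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Orient each column so its largest-magnitude loading is positive."""
    v = vectors.copy()
    for j in range(v.shape[1]):
        i = np.argmax(np.abs(v[:, j]))
        if v[i, j] < 0:
            v[:, j] *= -1.0
    return v


@dataclass
class PCAResult:
    """Eigenstructure of the specimen covariance of tangent coordinates."""

    eigenvalues: np.ndarray
    variance_fractions: np.ndarray  # percent, sums to 100
    scores: np.ndarray  # (n, n_components)
    eigenvectors: np.ndarray  # (3k, n_components), columns unit norm
    consensus: np.ndarray | None = None  # (k, 3) reference for warping
    mean_: np.ndarray | None = None  # column mean of the input coordinates

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]


def shape_pca(
    tangent_coords: np.ndarray,
    n_components: int | None = None,
    consensus: np.ndarray | None = None,
) -> PCAResult:
    """Principal component analysis of Procrustes tangent coordinates.

    Eigen-decomposition of the specimen covariance (divisor n-1); scores are
    the centered coordinates projected on the eigenvectors.
    ``variance_fractions`` are percentages of the *total* variance, so they
    sum to 100 across all positive eigenvalues (of which there are at most
    min(n-1, 3k)).
    """
    x = np.asarray(tangent_coords, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least 3 specimens")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s**2 / (n - 1)
    keep = eig > eig[0] * 1e-12 if eig[0] > 0 else np.zeros_like(eig, bool)
    eig = eig[keep]
    vecs = _fix_signs(vt[keep].T)
    scores = xc @ vecs
    frac = 100.0 * eig / eig.sum()
    if n_components is not None:
        eig = eig[:n_components]
        vecs = vecs[:, :n_components]
        scores = scores[:, :n_components]
        frac = frac[:n_components]
    return PCAResult(eig, frac, scores, vecs, consensus=consensus, mean_=x.mean(axis=0))


def pc_warp_endpoints(
    pca: PCAResult,
    pc: int,
    score: float = 0.15,
    range_check: bool = True,
) -> tuple[np.ndarray, np.ndarray, TPSModel | None]:
    """Shape configurations at ``+-score`` along one PC, for warping displays.

    Returns ``(minus, plus, tps_model)`` where each endpoint is the consensus
    displaced by ``score`` times the eigenvector, mapped back to a (k, 3)
    configuration, and ``tps_model`` warps the consensus onto the ``plus``
    endpoint (``None`` when the PCA has no consensus attached). The two
    endpoints are reflections of each other through the consensus in tangent
    space.
    """
    if not 0 <= pc < pca.n_components:
        raise IndexError(f"pc {pc} out of range (have {pca.n_components} components)")
    if range_check and pca.scores.size:
        limit = 3.0 * np.max(np.abs(pca.scores[:, pc]))
        if abs(score) > limit and limit > 0:
            raise ValueError(
                f"score {score} exceeds 3x the observed PC{pc + 1} score range "
                f"({limit:.4g}); pass range_check=False to override"
            )
    axis = pca.eigenvectors[:, pc]
    base = pca.mean_ if pca.mean_ is not None else np.zeros_like(axis)
    plus_flat = base + score * axis
    minus_flat = base - score * axis
    if pca.consensus is not None:
        k3 = pca.consensus.size
        plus = pca.consensus + (plus_flat - base).reshape(pca.consensus.shape)
        minus = pca.consensus + (minus_flat - base).reshape(pca.consensus.shape)
        model = fit_tps(pca.consensus, plus)
        assert plus.size == k3
        return minus, plus, model
    return minus_flat, plus_flat, None


@dataclass
class PLSResult:
    """Two-block partial least squares (singular warp) decomposition."""

    singular_values: np.ndarray
    pct_total_squared_covariance: np.ndarray  # percent, sums to 100
    x_scores: np.ndarray
    y_scores: np.ndarray
    x_vectors: np.ndarray
    y_vectors: np.ndarray
    pairwise_correlations: np.ndarray  # r_i of paired scores
    rv_coefficient: float
    p_value: float | None = None
    n_permutations: int = 0


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0)


def two_block_pls(
    block_x: np.ndarray,
    block_y: np.ndarray,
    n_perm: int = 0,
    seed: int | None = None,
) -> PLSResult:
    """Singular-warp decomposition of the between-block cross-covariance.

    Blocks must hold the same specimens in the same row order (paired
    individuals), each block separately superimposed. The percentage of
    total squared covariance per singular-warp pair is ``100 d_i^2 / sum
    d_j^2``; ``r_i`` is the Pearson correlation of the paired block scores
    on axis i. With ``n_perm > 0`` a permutation p-value for the first
    singular value is computed by permuting the specimen pairing.
    """
    x = np.asarray(block_x, dtype=float)
    y = np.asarray(block_y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("blocks are unpaired: different specimen counts")
    n = x.shape[0]
    if n < 4:
        raise ValueError("2B-PLS needs at least 4 paired specimens")
    xc, yc = _center(x), _center(y)
    cross = xc.T @ yc / (n - 1)
    u, s, vt = np.linalg.svd(cross, full_matrices=False)
    keep = s > (s[0] * 1e-12 if s[0] > 0 else np.inf)
    s = s[keep]
    u = u[:, keep]
    v = vt[keep].T
    # orient each X-block vector so its largest loading is positive and
    # carry the same flip to its Y partner: the pair's sign is joint, and
    # flipping them independently would negate the score covariance d_i
    for j in range(u.shape[1]):
        if u[np.argmax(np.abs(u[:, j])), j] < 0:
            u[:, j] *= -1.0
            v[:, j] *= -1.0
    xs, ys = xc @ u, yc @ v
    r = np.array(
        [np.corrcoef(xs[:, i], ys[:, i])[0, 1] for i in range(len(s))]
    )
    pct = 100.0 * s**2 / np.sum(s**2)
    rv = rv_coefficient(x, y)

    p_value = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        observed = s[0]
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            cp = xc.T @ yc[perm] / (n - 1)
            d1 = np.linalg.svd(cp, compute_uv=False)[0]
            if d1 >= observed:
                exceed += 1
        p_value = (1 + exceed) / (1 + n_perm)
    return PLSResult(s, pct, xs, ys, u, v, r, rv, p_value, n_perm)


def rv_coefficient(block_x: np.ndarray, block_y: np.ndarray) -> float:
    """Escoufier's RV: matrix correlation between two multivariate blocks.

    ``RV = tr(Sxy Syx) / sqrt(tr(Sxx^2) tr(Syy^2))`` with S the centered
    cross-/auto-covariance blocks; lies in [0, 1] and is invariant to
    orthogonal transforms and scaling of either block.
    """
    x = np.asarray(block_x, dtype=float)
    y = np.asarray(block_y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("blocks are unpaired: different specimen counts")
    n = x.shape[0]
    xc, yc = _center(x), _center(y)
    sxx = xc.T @ xc / (n - 1)
    syy = yc.T @ yc / (n - 1)
    sxy = xc.T @ yc / (n - 1)
    denom = np.sqrt(np.sum(sxx * sxx) * np.sum(syy * syy))
    if denom == 0:
        raise ValueError("zero-variance block")
    return float(np.trace(sxy @ sxy.T) / denom)


@dataclass
class RegressionResult:
    """Multivariate regression of shape on lnCS (allometry)."""

    coefficients: np.ndarray  # shape change per unit lnCS (3k,)
    intercept: np.ndarray
    pct_variance_explained: float

    def predict(self, ln_cs) -> np.ndarray:
        ln_cs = np.atleast_1d(np.asarray(ln_cs, dtype=float))
        return self.intercept + np.outer(ln_cs, self.coefficients)


def size_shape_regression(tangent_coords: np.ndarray, ln_centroid_sizes) -> RegressionResult:
    """Least-squares regression of all tangent coordinates on lnCS.

    ``pct_variance_explained`` is Goodall-style: 100 x (total squared
    predicted deviation) / (total squared deviation), pooled over all
    coordinates.
    """
    x = np.asarray(tangent_coords, dtype=float)
    g = np.asarray(ln_centroid_sizes, dtype=float)
    if x.shape[0] != g.shape[0]:
        raise ValueError("tangent_coords and ln_centroid_sizes differ in length")
    if x.shape[0] < 3:
        raise ValueError("regression needs at least 3 specimens")
    gc = g - g.mean()
    ss_g = gc @ gc
    if ss_g < 1e-30:
        raise ValueError("lnCS is constant; allometric regression undefined")
    xc = x - x.mean(axis=0)
    coef = xc.T @ gc / ss_g  # per-coordinate OLS slopes
    pred = np.outer(gc, coef)
    ss_pred = float(np.sum(pred**2))
    ss_tot = float(np.sum(xc**2))
    pct = 100.0 * ss_pred / ss_tot if ss_tot > 0 else 0.0
    intercept = x.mean(axis=0) - coef * g.mean()
    return RegressionResult(coef, intercept, pct)


def group_shape_variance(
    tangent_coords: np.ndarray, labels, min_n: int = 2
) -> dict[str, float]:
    """Procrustes variance per group.

    For each group: the sum of squared tangent-space distances to the group
    mean divided by (n-1). Singleton groups are excluded with a warning.
    """
    import warnings

    x = np.asarray(tangent_coords, dtype=float)
    labels = np.asarray(labels)
    out: dict[str, float] = {}
    for lab in dict.fromkeys(labels.tolist()):  # preserve first-seen order
        sub = x[labels == lab]
        if len(sub) < min_n:
            warnings.warn(f"group {lab!r} has n={len(sub)} < {min_n}; excluded", stacklevel=2)
            continue
        dev = sub - sub.mean(axis=0)
        out[str(lab)] = float(np.sum(dev**2) / (len(sub) - 1))
    return out
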