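"""Generalized Procrustes analysis, centroid size, and Procrustes distances.

Superimposition removes location, scale and orientation so that only shape
remains: configurations are centered, scaled to unit centroid size, and
iteratively rotated to the running consensus until the consensus stops
moving. Reflections are never part of the optimal rotation (det = +1);
anatomical mirroring is an explicit, recorded operation
(:func:`mirror_to_left`).

Two fitting variants are provided. The default ("partial" fitting) keeps
every specimen at unit centroid size throughout. With ``scale_refine=True``
each specimen is additionally scaled optimally toward the consensus when the
consensus is updated ("full" Procrustes fitting); the resulting consensus is
the full Procrustes mean, i.e. the leading eigenvector of the sum of
preshape outer products.

The outline feature sets are digitized in a common cervical frame, so for
them only centering and scaling are applied (``mode="scale_only"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import LandmarkConfiguration, ShapeDataset

__all__ = [
    "centroid_size",
    "ln_centroid_size",
    "mirror_to_left",
    "optimal_rotation",
    "generalized_procrustes",
    "tangent_coordinates",
    "procrustes_distance",
    "ProcrustesResult",
    "DegenerateConfigurationError",
]

# bucco-lingual axis of the reoriented tooth frame (x = mesial, z = occlusal)
_BUCCOLINGUAL_AXIS = 1


class DegenerateConfigurationError(ValueError):
    """All points coincide (or nearly so); size and shape are undefined."""


def _as_points(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.points
    return np.asarray(config, dtype=float)


def centroid_size(config) -> float:
    """Centroid size: sqrt of summed squared distances of points from their centroid."""
    pts = _as_points(config)
    centered = pts - pts.mean(axis=0)
    cs = float(np.linalg.norm(centered))
    if cs < 1e-12 * max(1.0, np.abs(pts).max()):
        raise DegenerateConfigurationError("all points coincident; centroid size is zero")
    return cs


def ln_centroid_size(config) -> float:
    """Natural logarithm of centroid size (lnCS), the size measure of the study."""
    return float(np.log(centroid_size(config)))


def mirror_to_left(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Reflect a right-side configuration across the tooth's mid-sagittal plane.

    The bucco-lingual (y) coordinate is negated; point order, roles and
    centroid size are unchanged. Applying the function to an already-left
    configuration warns and returns an unchanged copy.
    """
    out = config.copy()
    if config.side != "right":
        warnings.warn(
            f"{config.specimen_id}: already on the left side; mirroring skipped",
            stacklevel=2,
        )
        return out
    out.points[:, _BUCCOLINGUAL_AXIS] *= -1.0
    out.side = "left"
    out.mirrored = True
    return out


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R (det = +1) minimizing ``||source @ R - target||``."""
    m = source.T @ target
    u, _, vt = np.linalg.svd(m)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return r


def _preshape(pts: np.ndarray) -> np.ndarray:
    centered = pts - pts.mean(axis=0)
    nrm = np.linalg.norm(centered)
    if nrm < 1e-12 * max(1.0, np.abs(pts).max()):
        raise DegenerateConfigurationError("degenerate configuration (zero centroid size)")
    return centered / nrm


@dataclass
class ProcrustesResult:
    """Output of :func:`generalized_procrustes`.

    ``aligned`` holds the unit-size superimposed configurations (n, k, 3);
    ``consensus`` the unit-size mean shape (k, 3); ``tangent_coords`` the
    flattened tangent-space coordinates (n, 3k) from
    :func:`tangent_coordinates`.
    """

    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    ln_centroid_sizes: np.ndarray
    iterations: int
    converged: bool
    mode: str
    dataset: ShapeDataset | None = None
    tangent_coords: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.tangent_coords = tangent_coordinates(self)

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    def aligned_dataset(self) -> ShapeDataset:
        if self.dataset is None:
            raise ValueError("no source dataset attached to this result")
        return self.dataset.with_coords(self.aligned)


def generalized_procrustes(
    dataset,
    mode: str = "full",
    tol: float = 1e-10,
    max_iter: int = 100,
    scale_refine: bool = False,
) -> ProcrustesResult:
    """Superimpose a template-consistent set of configurations.

    Parameters
    ----------
    dataset:
        :class:`ShapeDataset` or array of shape (n, k, 3).
    mode:
        ``"full"`` -- center, scale to unit centroid size, and iteratively
        rotate each configuration to the consensus;
        ``"scale_only"`` -- center and scale only (outline sets digitized in
        a common frame).
    tol:
        convergence threshold on the relative consensus change.
    scale_refine:
        also scale each specimen optimally toward the consensus during the
        consensus update (full Procrustes fitting). Aligned output stays at
        unit centroid size either way.
    """
    if isinstance(dataset, ShapeDataset):
        coords = dataset.coords()
        src = dataset
    else:
        coords = np.asarray(dataset, dtype=float)
        src = None
    if coords.ndim != 3 or coords.shape[0] < 2:
        raise ValueError("GPA needs at least 2 configurations of shape (k, d)")
    if mode not in ("full", "scale_only"):
        raise ValueError(f"unknown GPA mode {mode!r}")

    n = coords.shape[0]
    sizes = np.empty(n)
    pre = np.empty_like(coords)
    for i, pts in enumerate(coords):
        sizes[i] = centroid_size(pts)
        pre[i] = _preshape(pts)

    if mode == "scale_only":
        consensus = pre.mean(axis=0)
        consensus = consensus - consensus.mean(axis=0)
        consensus /= np.linalg.norm(consensus)
        return ProcrustesResult(
            aligned=pre,
            consensus=consensus,
            centroid_sizes=sizes,
            ln_centroid_sizes=np.log(sizes),
            iterations=1,
            converged=True,
            mode=mode,
            dataset=src,
        )

    aligned = pre.copy()
    # initialize from the preshape mean so a pre-aligned dataset converges
    # immediately; fall back to the first specimen if rotations cancel out
    init = pre.mean(axis=0)
    init_norm = np.linalg.norm(init)
    consensus = init / init_norm if init_norm > 1e-6 else _preshape(aligned[0])
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        betas = np.ones(n)
        for i in range(n):
            r = optimal_rotation(pre[i], consensus)
            aligned[i] = pre[i] @ r
            if scale_refine:
                betas[i] = float(np.sum(aligned[i] * consensus))
        new = np.tensordot(betas, aligned, axes=1) / n
        new = new - new.mean(axis=0)
        nrm = np.linalg.norm(new)
        if nrm < 1e-12:
            raise DegenerateConfigurationError("consensus collapsed to a point")
        new /= nrm
        change = np.linalg.norm(new - consensus)
        consensus = new
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations (last change {change:.3e})",
            stacklevel=2,
        )
    # final alignment to the converged consensus
    for i in range(n):
        aligned[i] = pre[i] @ optimal_rotation(pre[i], consensus)
    return ProcrustesResult(
        aligned=aligned,
        consensus=consensus,
        centroid_sizes=sizes,
        ln_centroid_sizes=np.log(sizes),
        iterations=iterations,
        converged=converged,
        mode=mode,
        dataset=src,
    )


def tangent_coordinates(result: ProcrustesResult) -> np.ndarray:
    """Project aligned shapes orthogonally onto the tangent space at the consensus.

    Returns an (n, 3k) array of flat coordinate vectors; the consensus maps
    to the zero vector.
    """
    mu = result.consensus.ravel()
    flat = result.aligned.reshape(result.aligned.shape[0], -1)
    return flat - np.outer(flat @ mu, mu)


def procrustes_distance(a, b) -> float:
    """Full Procrustes distance between two configurations.

    Root-sum-of-squares between the unit-size, centered configurations after
    the optimal proper rotation; symmetric, and zero iff the shapes are
    identical up to a similarity transform.
    """
    za = _preshape(_as_points(a))
    zb = _preshape(_as_points(b))
    if za.shape != zb.shape:
        raise ValueError(f"configurations differ in shape: {za.shape} vs {zb.shape}")
    r = optimal_rotation(za, zb)
    return float(np.linalg.norm(za @ r - zb))
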