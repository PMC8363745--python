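"""Thin-plate splines, bending energy, and semilandmark sliding.

The thin-plate spline (TPS) interpolates a deformation between two landmark
sets as an affine part plus radial-basis warp terms. The radial kernel is
dimension dependent: ``U(r) = r^2 log r`` in 2D and ``U(r) = r`` in 3D
(triharmonic). The bending energy of a deformation is a quadratic form in
the landmark displacements; its matrix is the kernel-matrix inverse block
restricted to the non-affine subspace, sign-normalized so the form is
positive semi-definite for both kernels, with all affine displacement
fields in its null space.

Curve semilandmarks have one free degree of freedom: their position along
the curve they resample. :func:`slide_semilandmarks` iteratively moves each
slidable point along its local curve tangent so that the TPS bending energy
of the deformation from the sample consensus to the specimen is minimal,
then re-projects the points onto the specimen's original polyline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import EDJ_LOOPS, ShapeDataset, template_for
from .gpa import centroid_size, generalized_procrustes, optimal_rotation

__all__ = [
    "TPSModel",
    "fit_tps",
    "tps_warp",
    "bending_energy_matrix",
    "Curve",
    "CurveTemplate",
    "edj_curve_template",
    "slide_semilandmarks",
    "SlidingResult",
    "SingularityError",
]


class SingularityError(ValueError):
    """Reference geometry is degenerate; the TPS system is singular."""


def _kernel_matrix(a: np.ndarray, b: np.ndarray, dim: int) -> np.ndarray:
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    if dim == 3:
        return d
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(d > 0, d * d * np.log(d), 0.0)


def _tps_system(source: np.ndarray) -> tuple[np.ndarray, int]:
    k, dim = source.shape
    kmat = _kernel_matrix(source, source, dim)
    p = np.hstack([np.ones((k, 1)), source])
    q = dim + 1
    lmat = np.zeros((k + q, k + q))
    lmat[:k, :k] = kmat
    lmat[:k, k:] = p
    lmat[k:, :k] = p.T
    return lmat, q


@dataclass
class TPSModel:
    """A fitted TPS map from ``source`` landmarks onto ``target`` landmarks."""

    source: np.ndarray
    target: np.ndarray
    warp_coeffs: np.ndarray  # (k, dim)
    affine_coeffs: np.ndarray  # (dim+1, dim)
    bending_energy: float

    @property
    def kernel(self) -> str:
        return "r_3d" if self.source.shape[1] == 3 else "r2logr_2d"


def fit_tps(source: np.ndarray, target: np.ndarray) -> TPSModel:
    """Fit the TPS interpolant mapping each source landmark to its target."""
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape:
        raise ValueError("source and target must have the same shape")
    k, dim = source.shape
    if dim not in (2, 3):
        raise ValueError("TPS is implemented for 2D and 3D landmarks")
    lmat, q = _tps_system(source)
    rhs = np.vstack([target, np.zeros((q, dim))])
    try:
        sol = np.linalg.solve(lmat, rhs)
    except np.linalg.LinAlgError as exc:
        raise SingularityError(f"singular TPS system: {exc}") from None
    w, a = sol[:k], sol[k:]
    be = bending_energy_matrix(source)
    disp = target - source
    energy = float(sum(disp[:, d] @ be @ disp[:, d] for d in range(dim)))
    return TPSModel(source, target, w, a, energy)


def tps_warp(model: TPSModel, query: np.ndarray) -> np.ndarray:
    """Evaluate a fitted TPS map at arbitrary query points."""
    query = np.atleast_2d(np.asarray(query, dtype=float))
    dim = model.source.shape[1]
    if query.shape[1] != dim:
        raise ValueError(f"query dimension {query.shape[1]} != model dimension {dim}")
    kq = _kernel_matrix(query, model.source, dim)
    p = np.hstack([np.ones((len(query), 1)), query])
    return kq @ model.warp_coeffs + p @ model.affine_coeffs


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Bending-energy quadratic form of the TPS at a reference landmark set.

    Returns a symmetric positive semi-definite (k, k) matrix ``B``; the
    bending energy of a per-landmark displacement field ``d`` (k, dim) is
    ``sum_d  d[:, j] @ B @ d[:, j]``. Affine displacement fields lie in the
    null space.
    """
    reference = np.asarray(reference, dtype=float)
    k, dim = reference.shape
    lmat, q = _tps_system(reference)
    try:
        inv = np.linalg.inv(lmat)
    except np.linalg.LinAlgError:
        raise SingularityError(
            "degenerate reference geometry (coincident or coplanar landmarks)"
        ) from None
    b = inv[:k, :k]
    if dim == 3:
        b = -b  # U(r) = r gives a negative semi-definite inverse block
    return 0.5 * (b + b.T)


# --------------------------------------------------------------------------
# semilandmark sliding


@dataclass
class Curve:
    """One resampled curve: the ordered polyline of template point indices.

    ``indices`` lists every point on the curve in order (anchors and
    semilandmarks); ``slidable`` is the subset free to slide. Anchors are
    the non-slidable members.
    """

    indices: tuple[int, ...]
    slidable: frozenset[int]
    closed: bool = True

    def __post_init__(self) -> None:
        self.indices = tuple(int(i) for i in self.indices)
        self.slidable = frozenset(int(i) for i in self.slidable)
        if not self.slidable:
            raise ValueError("a curve needs at least one slidable point")
        if not self.slidable <= set(self.indices):
            raise ValueError("slidable indices must lie on the curve")

    @property
    def anchors(self) -> frozenset[int]:
        return frozenset(self.indices) - self.slidable


@dataclass
class CurveTemplate:
    curves: list[Curve] = field(default_factory=list)

    def slidable_indices(self) -> list[int]:
        out: list[int] = []
        for c in self.curves:
            out.extend(i for i in c.indices if i in c.slidable)
        return out


def edj_curve_template(tooth_class: str, feature_set: str = "dentinal_crown") -> CurveTemplate:
    """Curve template for the EDJ marginal-ridge loop of a tooth class.

    The loop runs through the on-loop anatomical anchors with the curve
    semilandmark block distributed along the gaps, matching the frozen
    storage order of the landmark templates.
    """
    tpl = template_for(tooth_class, feature_set)
    if tpl.n_curve == 0:
        raise ValueError(f"feature set {feature_set!r} has no curve semilandmarks")
    cycle, gaps = EDJ_LOOPS[tooth_class]
    assert sum(gaps) == tpl.n_curve
    seq: list[int] = []
    s = tpl.n_anatomical
    for anchor, gap in zip(cycle, gaps):
        seq.append(anchor)
        seq.extend(range(s, s + gap))
        s += gap
    slidable = frozenset(tpl.curve_indices().tolist())
    return CurveTemplate([Curve(tuple(seq), slidable, closed=True)])


def _curve_tangents(points: np.ndarray, curve: Curve) -> dict[int, np.ndarray]:
    """Unit tangents at slidable points by central differences along the curve."""
    seq = curve.indices
    m = len(seq)
    tangents: dict[int, np.ndarray] = {}
    for pos, idx in enumerate(seq):
        if idx not in curve.slidable:
            continue
        if curve.closed:
            prv, nxt = seq[(pos - 1) % m], seq[(pos + 1) % m]
        else:
            prv, nxt = seq[max(pos - 1, 0)], seq[min(pos + 1, m - 1)]
        # central difference; fall back to one-sided if neighbors coincide
        # (sliding can collapse adjacent points onto one polyline vertex)
        candidates = (points[nxt] - points[prv],
                      points[nxt] - points[idx],
                      points[idx] - points[prv])
        for t in candidates:
            nrm = np.linalg.norm(t)
            if nrm > 1e-12:
                tangents[idx] = t / nrm
                break
        # a fully degenerate point simply does not slide this iteration
    return tangents


def _project_points_to_polyline(pts: np.ndarray, poly: np.ndarray, closed: bool) -> np.ndarray:
    """Nearest points on a piecewise-linear curve, vectorized over segments."""
    a = poly if closed else poly[:-1]
    b = np.roll(poly, -1, axis=0) if closed else poly[1:]
    e = b - a  # (nseg, d)
    denom = np.einsum("sd,sd->s", e, e)
    denom = np.where(denom == 0, 1.0, denom)
    # t[i, s]: parameter of point i on segment s, clamped to the segment
    t = np.clip(np.einsum("isd,sd->is", pts[:, None, :] - a[None], e) / denom, 0.0, 1.0)
    q = a[None] + t[..., None] * e[None]  # (npts, nseg, d)
    d2 = np.sum((pts[:, None, :] - q) ** 2, axis=-1)
    best = np.argmin(d2, axis=1)
    return q[np.arange(len(pts)), best]


@dataclass
class SlidingResult:
    """Slid dataset plus per-iteration diagnostics.

    ``energy_history[t]`` is the total TPS bending energy of the
    consensus-to-specimen deformations after sliding in outer iteration t
    (measured against that iteration's consensus).
    """

    dataset: ShapeDataset
    energy_history: list[float]
    max_displacements: list[float]
    iterations: int
    polylines: list | None = None  # per-specimen reference curves, reusable


def _total_energy(aligned: np.ndarray, consensus: np.ndarray, bmat: np.ndarray) -> float:
    total = 0.0
    for spec in aligned:
        disp = spec - consensus
        total += sum(disp[:, d] @ bmat @ disp[:, d] for d in range(disp.shape[1]))
    return float(total)


def slide_semilandmarks(
    dataset: ShapeDataset,
    curves: CurveTemplate | None = None,
    outer_iters: int = 3,
    displacement_tol: float = 1e-6,
    update_reference: bool = False,
    polylines: list | None = None,
) -> SlidingResult:
    """Slide curve semilandmarks to minimize bending energy toward the consensus.

    The target consensus (and its bending-energy form) is estimated by GPA
    of the input dataset and held fixed across outer iterations, which makes
    the reported energy sequence provably non-increasing; pass
    ``update_reference=True`` to re-estimate the consensus each iteration
    instead (the classical alternating scheme, without that guarantee).

    Each outer iteration: (1) superimpose; (2) per specimen, a joint linear
    solve for the tangential displacement of every slidable point that
    minimizes the TPS bending energy of the consensus-to-specimen
    deformation; (3) re-projection of the slid points onto the specimen's
    original polyline. Anchored anatomical landmarks never move. A specimen
    update is damped (backtracking, factors 1 .. 1/16) and rejected outright
    if re-projection would raise its bending energy.

    Stops early when the largest per-point displacement falls below
    ``displacement_tol`` in consensus (unit centroid size) units.
    """
    if curves is None:
        curves = edj_curve_template(dataset.tooth_class, dataset.feature_set)
    slidable = curves.slidable_indices()
    if not slidable:
        raise ValueError("curve template has no slidable points")

    orig_coords = dataset.coords()
    work = orig_coords.copy()
    n, k, dim = work.shape

    # reference polylines (fixed): per specimen, per curve; a caller may pass
    # the specimens' digitized curves so repeated passes share one constraint
    if polylines is None:
        orig_polys = [
            [orig_coords[i][list(c.indices)] for c in curves.curves] for i in range(n)
        ]
    else:
        if len(polylines) != n:
            raise ValueError("polylines must have one entry per specimen")
        orig_polys = polylines

    energy_history: list[float] = []
    max_disp_history: list[float] = []
    res = generalized_procrustes(work, mode="full")
    consensus = res.consensus
    bmat = bending_energy_matrix(consensus)
    iterations = 0
    for iterations in range(1, outer_iters + 1):
        if update_reference and iterations > 1:
            res = generalized_procrustes(work, mode="full")
            consensus = res.consensus
            bmat = bending_energy_matrix(consensus)
        max_disp = 0.0
        aligned_new_store = np.empty((n, k, dim))
        for i in range(n):
            pts = work[i]
            mean_i = pts.mean(axis=0)
            cs_i = centroid_size(pts)
            pre = (pts - mean_i) / cs_i
            rot = optimal_rotation(pre, consensus)
            aligned = pre @ rot

            tangents: dict[int, np.ndarray] = {}
            for c in curves.curves:
                tangents.update(_curve_tangents(aligned, c))
            slid_idx = sorted(tangents)
            m = len(slid_idx)
            # assemble the joint system  (sum_d T_d' B T_d) t = -sum_d T_d' B y_d
            y = aligned - consensus
            lhs = np.zeros((m, m))
            rhs = np.zeros(m)
            bsub = bmat[np.ix_(slid_idx, range(k))]
            for d in range(dim):
                u_d = np.array([tangents[j][d] for j in slid_idx])
                b_ss = bmat[np.ix_(slid_idx, slid_idx)]
                lhs += np.outer(u_d, u_d) * b_ss
                rhs -= u_d * (bsub @ y[:, d])
            try:
                t = np.linalg.solve(lhs, rhs)
            except np.linalg.LinAlgError:
                t, *_ = np.linalg.lstsq(lhs, rhs, rcond=None)

            # apply the tangential step, re-project onto the original
            # polyline, and accept the longest damped step that does not
            # raise the bending energy toward the current consensus
            e_old = _total_energy(aligned[None], consensus, bmat)
            for damp in (1.0, 0.5, 0.25, 0.125, 0.0625):
                cand = aligned.copy()
                for s, j in enumerate(slid_idx):
                    cand[j] = aligned[j] + damp * t[s] * tangents[j]
                cand_orig = cand @ rot.T * cs_i + mean_i
                new_pts = pts.copy()
                for ci, c in enumerate(curves.curves):
                    poly = orig_polys[i][ci]
                    idx = [j for j in c.indices if j in c.slidable]
                    new_pts[idx] = _project_points_to_polyline(
                        cand_orig[idx], poly, c.closed
                    )
                new_pre = (new_pts - new_pts.mean(axis=0)) / centroid_size(new_pts)
                new_aligned = new_pre @ optimal_rotation(new_pre, consensus)
                e_new = _total_energy(new_aligned[None], consensus, bmat)
                if e_new <= e_old + 1e-12:
                    disp = float(np.max(np.linalg.norm(new_aligned - aligned, axis=1)))
                    max_disp = max(max_disp, disp)
                    work[i] = new_pts
                    aligned_new_store[i] = new_aligned
                    break
            else:
                aligned_new_store[i] = aligned

        energy_history.append(_total_energy(aligned_new_store, consensus, bmat))
        max_disp_history.append(max_disp)
        if max_disp < displacement_tol:
            break

    slid = dataset.with_coords(work)
    # anchors must be untouched
    anchor_idx = sorted(
        set().union(*(c.anchors for c in curves.curves)) if curves.curves else set()
    )
    if anchor_idx and not np.allclose(
        slid.coords()[:, anchor_idx], orig_coords[:, anchor_idx]
    ):
        warnings.warn("anchor landmarks moved during sliding", stacklevel=2)
    return SlidingResult(slid, energy_history, max_disp_history, iterations, orig_polys)
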