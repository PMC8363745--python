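"""Cervical-plane projection and equiangular outline resampling.

Crown and cervical outlines are closed 3D contours digitized on the
reoriented tooth surface. They are projected orthogonally onto the cervical
plane and resampled into ``k`` pseudo-landmarks at the intersections of
equiangular rays from the centroid of the outline *area* (not the vertex
mean, which would depend on vertex density) with the polygon boundary.

The reference ray (j = 0) points along +x of the cervical frame, i.e. the
mesial anatomical direction of the reoriented tooth. For non-star-shaped
outlines the intersection farthest from the centroid is kept, so the
pseudo-landmarks stay on the outer silhouette.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PlanarOutline",
    "GeometryError",
    "project_to_cervical_plane",
    "area_centroid",
    "vertex_mean",
    "resample_equiangular",
]


class GeometryError(ValueError):
    """Degenerate outline geometry (zero area, collinear projection, ...)."""


@dataclass
class PlanarOutline:
    """A simple closed polygon in the cervical-plane frame.

    ``vertices`` is an (m, 2) array; the first vertex is not repeated at the
    end. ``orientation`` is ``ccw`` or ``cw`` by signed area.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise GeometryError(f"vertices must be (m, 2), got {self.vertices.shape}")
        if len(self.vertices) < 3:
            raise GeometryError("an outline needs at least 3 vertices")
        if np.allclose(self.vertices[0], self.vertices[-1]):
            self.vertices = self.vertices[:-1]
        if len(self.vertices) < 3:
            raise GeometryError("an outline needs at least 3 distinct vertices")

    @property
    def orientation(self) -> str:
        return "ccw" if self.signed_area > 0 else "cw"

    @property
    def signed_area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        return 0.5 * float(np.sum(x * yn - xn * y))


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal in-plane basis (u, v) with u x v = normal."""
    n = np.asarray(normal, dtype=float)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = helper - (helper @ n) * n
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def project_to_cervical_plane(
    points3d: np.ndarray,
    plane_point: np.ndarray,
    plane_normal: np.ndarray,
    basis: tuple[np.ndarray, np.ndarray] | None = None,
) -> PlanarOutline:
    """Orthogonally project a closed 3D outline onto a plane.

    The plane is given by a point and a unit normal; the output coordinates
    are expressed in an orthonormal in-plane basis (a deterministic basis is
    derived from the normal unless ``basis`` is supplied). Vertex order is
    preserved.
    """
    pts = np.asarray(points3d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise GeometryError(f"points3d must be (m, 3), got {pts.shape}")
    n = np.asarray(plane_normal, dtype=float)
    if not np.isclose(np.linalg.norm(n), 1.0, atol=1e-8):
        raise GeometryError("plane normal must have unit length")
    if basis is None:
        u, v = _plane_basis(n)
    else:
        u, v = (np.asarray(b, dtype=float) for b in basis)
    rel = pts - np.asarray(plane_point, dtype=float)
    coords = np.column_stack([rel @ u, rel @ v])
    spread = coords - coords.mean(axis=0)
    # all points collinear after projection -> rank deficient
    if np.linalg.matrix_rank(spread, tol=1e-10 * max(1.0, np.abs(spread).max())) < 2:
        raise GeometryError("outline is degenerate (collinear) after projection")
    return PlanarOutline(coords)


def vertex_mean(outline: PlanarOutline) -> np.ndarray:
    """Plain mean of the polygon vertices (density-dependent fallback)."""
    return outline.vertices.mean(axis=0)


def area_centroid(outline: PlanarOutline) -> np.ndarray:
    """Centroid of the polygon area (shoelace-weighted).

    Independent of how densely the boundary is sampled, unlike the vertex
    mean.
    """
    v = outline.vertices
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * np.sum(cross)
    if abs(area) < 1e-14 * max(1.0, np.abs(v).max() ** 2):
        raise GeometryError("outline has zero area")
    cx = np.sum((x + xn) * cross) / (6.0 * area)
    cy = np.sum((y + yn) * cross) / (6.0 * area)
    return np.array([cx, cy])


def resample_equiangular(
    outline: PlanarOutline,
    k: int = 24,
    reference_direction: np.ndarray | None = None,
    center: str = "area",
) -> np.ndarray:
    """Resample a closed outline into ``k`` equiangular pseudo-landmarks.

    Rays are cast from the outline centroid at angles ``2*pi*j/k``
    (j = 0..k-1) measured counter-clockwise from ``reference_direction``
    (default +x, the mesial direction of the cervical frame). Each
    pseudo-landmark is the ray-boundary intersection; when a ray crosses the
    boundary more than once the intersection farthest from the centroid is
    taken. Edges are treated as half-open along the boundary orientation so
    a ray through a vertex yields a single intersection.

    Parameters
    ----------
    center:
        ``"area"`` uses the polygon-area centroid (default); ``"vertex"``
        uses the vertex mean.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    if center == "area":
        c = area_centroid(outline)
    elif center == "vertex":
        c = vertex_mean(outline)
    else:
        raise ValueError(f"unknown center rule {center!r}")
    if reference_direction is None:
        ref = np.array([1.0, 0.0])
    else:
        ref = np.asarray(reference_direction, dtype=float)
        nrm = np.linalg.norm(ref)
        if nrm == 0:
            raise ValueError("reference_direction must be nonzero")
        ref = ref / nrm
    perp = np.array([-ref[1], ref[0]])

    verts = outline.vertices - c
    nv = len(verts)
    out = np.empty((k, 2))
    for j in range(k):
        ang = 2.0 * np.pi * j / k
        d = np.cos(ang) * ref + np.sin(ang) * perp
        best_t = -np.inf
        for i in range(nv):
            a = verts[i]
            b = verts[(i + 1) % nv]
            e = b - a
            denom = d[0] * e[1] - d[1] * e[0]
            if abs(denom) < 1e-15:
                continue  # ray parallel to edge
            # solve a + s*e = t*d (Cramer)
            s = (a[0] * d[1] - a[1] * d[0]) / denom
            t = (a[0] * e[1] - a[1] * e[0]) / denom
            # half-open edge [0, 1) along boundary orientation
            if -1e-12 <= s < 1.0 - 1e-12 and t > 1e-12 and t > best_t:
                best_t = t
        if not np.isfinite(best_t) or best_t < 0:
            raise GeometryError(f"ray {j} found no boundary intersection")
        out[j] = c + best_t * d
    return out
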