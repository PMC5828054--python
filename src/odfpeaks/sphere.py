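"""Unit-sphere sampling, coordinates, triangulation, interpolation and angular metrics.

Coordinate convention used throughout the package: ``theta`` is the azimuth,
measured in the x-y plane from the +x axis, and ``phi`` is the elevation,
measured from the x-y plane toward +z.  Hence ``(theta, phi) = (0, 0)`` is the
+x axis and ``phi = pi/2`` the north pole.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

__all__ = [
    "sph_to_unit",
    "unit_to_sph",
    "normalize_angles",
    "SphereMesh",
    "SphericalSamples",
    "even_sphere",
    "interpolate",
    "arc_angle",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def normalize_angles(theta, phi):
    """Map arbitrary (theta, phi) pairs to theta in [0, 2pi), phi in [-pi/2, pi/2].

    Crossing a pole (|phi| > pi/2) reflects the elevation and shifts the
    azimuth by pi, which is the identity on the underlying unit vector.
    Vectorized; returns arrays of the broadcast shape.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    # reduce phi to [-pi, pi), then reflect the |phi| > pi/2 band
    phi = np.mod(phi + np.pi, 2.0 * np.pi) - np.pi
    over = phi > np.pi / 2
    under = phi < -np.pi / 2
    theta = np.where(over | under, theta + np.pi, theta)
    phi = np.where(over, np.pi - phi, phi)
    phi = np.where(under, -np.pi - phi, phi)
    theta = np.mod(theta, 2.0 * np.pi)
    theta = np.where(theta >= 2.0 * np.pi, 0.0, theta)  # guard rounding at the seam
    return theta, phi


def sph_to_unit(theta, phi):
    """Spherical angles -> unit vector(s) (cos phi cos theta, cos phi sin theta, sin phi).

    Accepts scalars or arrays; the result has shape ``(..., 3)``.  The map is
    well defined for any real angles (no prior normalization required).
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    cp = np.cos(phi)
    return np.stack([cp * np.cos(theta), cp * np.sin(theta), np.sin(phi)], axis=-1)


def unit_to_sph(v, *, atol: float = 1e-6):
    """Unit vector(s) -> (theta, phi) with theta in [0, 2pi), phi in [-pi/2, pi/2].

    At the poles (|v_z| = 1) the azimuth is undefined; the convention here is
    theta = 0.  Raises ``ValueError`` for non-unit input.
    """
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1)
    if not np.allclose(n, 1.0, atol=atol):
        raise ValueError("unit_to_sph requires unit vectors (|v| = 1)")
    phi = np.arcsin(np.clip(v[..., 2], -1.0, 1.0))
    theta = np.mod(np.arctan2(v[..., 1], v[..., 0]), 2.0 * np.pi)
    at_pole = np.abs(v[..., 2]) >= 1.0 - 1e-15
    theta = np.where(at_pole, 0.0, theta)
    if theta.ndim == 0:
        return float(theta), float(phi)
    return theta, phi


@dataclass(frozen=True)
class SphereMesh:
    """Closed triangulated unit sphere: vertices, triangles and 1-ring adjacency."""

    vertices: np.ndarray          # (V, 3) unit vectors
    triangles: np.ndarray         # (F, 3) int vertex indices
    neighbors: tuple = field(repr=False, default=())  # per-vertex 1-ring index arrays
    equal_area: bool = False      # vertices sample equal-area strata (Fibonacci)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def vertex_weights(self) -> np.ndarray:
        """Quadrature weight per vertex.

        For equal-area lattices (spherical Fibonacci) every vertex covers the
        same solid angle, so the equal-weight rule 4 pi / V applies and is
        markedly more accurate than triangle lumping.  For a general mesh the
        weight is one third of the incident spherical (Girard) triangle
        areas; either way the weights sum to 4 pi.
        """
        if self.equal_area:
            return np.full(self.n_vertices, 4.0 * np.pi / self.n_vertices)
        v = self.vertices
        t = self.triangles
        a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
        # spherical excess via l'Huilier
        ang_a = np.arccos(np.clip(np.einsum("ij,ij->i", b, c), -1, 1))
        ang_b = np.arccos(np.clip(np.einsum("ij,ij->i", a, c), -1, 1))
        ang_c = np.arccos(np.clip(np.einsum("ij,ij->i", a, b), -1, 1))
        s = 0.5 * (ang_a + ang_b + ang_c)
        tanprod = (
            np.tan(s / 2)
            * np.tan((s - ang_a) / 2)
            * np.tan((s - ang_b) / 2)
            * np.tan((s - ang_c) / 2)
        )
        area = 4.0 * np.arctan(np.sqrt(np.maximum(tanprod, 0.0)))
        w = np.zeros(self.n_vertices)
        for k in range(3):
            np.add.at(w, t[:, k], area / 3.0)
        return w

    def edge_lengths_deg(self) -> np.ndarray:
        """Arc length in degrees of every unique mesh edge."""
        t = self.triangles
        edges = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        edges.sort(axis=1)
        edges = np.unique(edges, axis=0)
        u = self.vertices[edges[:, 0]]
        v = self.vertices[edges[:, 1]]
        return np.degrees(np.arccos(np.clip(np.einsum("ij,ij->i", u, v), -1, 1)))


@dataclass(frozen=True)
class SphericalSamples:
    """A nonnegative scalar field sampled at the vertices of a sphere mesh."""

    mesh: SphereMesh
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.mesh.n_vertices,):
            raise ValueError("one value per mesh vertex required")
        if np.any(values < 0):
            raise ValueError("spherical samples must be nonnegative")
        object.__setattr__(self, "values", values)

    def integral(self) -> float:
        """Quadrature integral of the field over the sphere."""
        return float(self.mesh.vertex_weights() @ self.values)


def _build_neighbors(n_vertices: int, triangles: np.ndarray) -> tuple:
    nbr = [set() for _ in range(n_vertices)]
    for i, j, k in triangles:
        nbr[i].update((j, k))
        nbr[j].update((i, k))
        nbr[k].update((i, j))
    return tuple(np.array(sorted(s), dtype=np.intp) for s in nbr)


def even_sphere(n: int = 724) -> SphereMesh:
    """Deterministic quasi-uniform sphere mesh with ``n`` vertices.

    Vertices are a spherical Fibonacci lattice (area-uniform in z, azimuth
    stepped by the golden angle); the triangulation is the convex hull of the
    vertex set.  For points in general position this gives 2n - 4 triangles.
    """
    if n < 4:
        raise ValueError("need at least 4 points for a closed triangulation")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = np.mod(i * _GOLDEN_ANGLE, 2.0 * np.pi)
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    verts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    hull = ConvexHull(verts)
    tris = hull.simplices.astype(np.intp)
    # orient all triangles outward (positive determinant)
    a, b, c = verts[tris[:, 0]], verts[tris[:, 1]], verts[tris[:, 2]]
    flip = np.einsum("ij,ij->i", np.cross(b - a, c - a), a) < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    return SphereMesh(verts, tris, _build_neighbors(n, tris), equal_area=True)


def _candidate_triangles(mesh: SphereMesh, q: np.ndarray) -> np.ndarray:
    """Indices of triangles incident to the vertex nearest ``q`` or its 1-ring."""
    dots = mesh.vertices @ q
    i = int(np.argmax(dots))
    ring = np.concatenate([[i], mesh.neighbors[i]]) if mesh.neighbors else [i]
    mask = np.isin(mesh.triangles, ring).any(axis=1)
    return np.nonzero(mask)[0]


def _bary_weights(mesh: SphereMesh, q: np.ndarray, tri_idx: np.ndarray):
    """Normalized barycentric weights of the central projection of q in each triangle."""
    mats = mesh.vertices[mesh.triangles[tri_idx]]  # (F, 3 verts, 3 xyz)
    rhs = np.broadcast_to(q, (len(tri_idx), 3))[..., None]
    try:
        w = np.linalg.solve(np.transpose(mats, (0, 2, 1)), rhs)[..., 0]
    except np.linalg.LinAlgError:
        raise ValueError("degenerate mesh: singular triangle basis")
    s = w.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = w / s[:, None]
    w[s <= 0] = -np.inf
    return w


def _enclosing_triangle(mesh: SphereMesh, q: np.ndarray):
    """Triangle containing the central projection of ``q``, plus barycentric weights.

    The enclosing triangle is the one whose (normalized) barycentric
    coordinates of the query are all >= -1e-12.  Candidates incident to the
    nearest vertex are tried first; brute force over all triangles is the
    fallback.  Adequate for meshes up to a few thousand vertices.
    """
    for tri_idx in (_candidate_triangles(mesh, q), np.arange(mesh.n_triangles)):
        w = _bary_weights(mesh, q, tri_idx)
        mins = w.min(axis=1)
        best = int(np.argmax(mins))
        if mins[best] >= -1e-12:
            return int(tri_idx[best]), w[best]
    if mins[best] > -1e-6:  # numerically marginal but acceptable
        return int(tri_idx[best]), np.clip(w[best], 0.0, None)
    raise ValueError("degenerate mesh: no enclosing triangle found")


def interpolate(samples: SphericalSamples, query, mode: str = "nearest") -> float:
    """Interpolate a spherical sample field at a unit direction.

    ``mode='nearest'`` returns the value at the nearest vertex of the
    enclosing triangle; ``mode='barycentric'`` the barycentric-weighted
    average over the triangle.
    """
    if mode not in ("nearest", "barycentric"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    q = np.asarray(query, dtype=float)
    nq = np.linalg.norm(q)
    if not np.isclose(nq, 1.0, atol=1e-6):
        raise ValueError("query direction must be a unit vector")
    q = q / nq
    f, w = _enclosing_triangle(samples.mesh, q)
    idx = samples.mesh.triangles[f]
    if mode == "nearest":
        tri_verts = samples.mesh.vertices[idx]
        nearest = int(np.argmax(tri_verts @ q))
        return float(samples.values[idx[nearest]])
    return float(np.clip(w, 0.0, None) @ samples.values[idx] / np.clip(w, 0.0, None).sum())


def arc_angle(u, v, antipodal: bool = False):
    """Arc between unit directions in degrees.

    With ``antipodal=True`` the sign of the directions is ignored
    (arccos |u.v|, in [0, 90]), the natural metric for orientation data such
    as ODF peaks; otherwise plain arccos(u.v) in [0, 180].  Broadcasts over
    leading axes.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    d = np.einsum("...i,...i->...", u, v)
    if antipodal:
        d = np.abs(d)
    ang = np.degrees(np.arccos(np.clip(d, -1.0, 1.0)))
    return float(ang) if ang.ndim == 0 else ang


def write_directions(path, directions) -> None:
    """Write unit directions as plain text, one ``x y z`` row per direction."""
    np.savetxt(path, np.atleast_2d(np.asarray(directions, dtype=float)), fmt="%.17g")


def read_directions(path) -> np.ndarray:
    """Read a plain-text direction list written by :func:`write_directions`."""
    d = np.loadtxt(path, ndmin=2)
    if d.shape[1] != 3:
        raise ValueError("direction files must have three columns (x y z)")
    return d
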