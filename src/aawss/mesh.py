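"""Idealized vessel surface meshes.

Aneurysm lumina are represented as open triangulated tubes (two boundary
loops, Euler characteristic 0) built as surfaces of revolution around the
z axis, with an optional azimuthally localized bulge for saccular shapes.
All coordinates are in meters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import integrate
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra


@dataclass(frozen=True)
class VesselMesh:
    """Open triangulated tube surface.

    Attributes
    ----------
    vertices : (n, 3) float array, meters.
    triangles : (m, 3) int array of vertex indices, counter-clockwise
        seen from outside.
    node_areas : (n,) float array, lumped (one-third barycentric) area
        per vertex, m**2.  Sums to the total surface area.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    node_areas: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        t = np.asarray(self.triangles, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if t.ndim != 2 or t.shape[1] != 3:
            raise ValueError("triangles must be (m, 3)")
        if t.min() < 0 or t.max() >= len(v):
            raise ValueError("triangle indices out of range")
        areas = triangle_areas(v, t)
        if np.any(areas <= 0):
            bad = int(np.sum(areas <= 0))
            raise ValueError(f"{bad} degenerate (zero-area) triangles")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "triangles", t)
        if self.node_areas is None:
            object.__setattr__(self, "node_areas", lumped_node_areas(v, t))
        else:
            object.__setattr__(self, "node_areas",
                               np.asarray(self.node_areas, dtype=float))

    @property
    def n_nodes(self) -> int:
        return len(self.vertices)

    @property
    def area(self) -> float:
        """Total surface area, m**2."""
        return float(triangle_areas(self.vertices, self.triangles).sum())

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (k, 2) sorted-index array."""
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_nodes - len(self.edges()) + len(self.triangles)

    def edge_graph(self):
        """Sparse symmetric adjacency weighted by edge length."""
        e = self.edges()
        w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]],
                           axis=1)
        n = self.n_nodes
        g = coo_matrix((np.r_[w, w], (np.r_[e[:, 0], e[:, 1]],
                                      np.r_[e[:, 1], e[:, 0]])), shape=(n, n))
        return g.tocsr()

    def geodesic_ball(self, center: int, radius: float) -> np.ndarray:
        """Node indices within graph-geodesic ``radius`` of ``center``."""
        d = dijkstra(self.edge_graph(), indices=center, limit=radius * 1.001)
        return np.flatnonzero(np.isfinite(d) & (d <= radius))

    def axial_directions(self) -> np.ndarray:
        """Per-node unit tangent along the tube axis (+z projected onto
        the local tangent plane); the dominant WSS direction for
        axially-aligned flow."""
        normals = vertex_normals(self.vertices, self.triangles)
        axis = np.array([0.0, 0.0, 1.0])
        tang = axis - normals * (normals @ axis)[:, None]
        nrm = np.linalg.norm(tang, axis=1)
        nrm[nrm == 0] = 1.0
        return tang / nrm[:, None]


def triangle_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    p = vertices[triangles]
    cr = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    return 0.5 * np.linalg.norm(cr, axis=1)


def lumped_node_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """One-third of each incident triangle's area assigned to each vertex."""
    areas = triangle_areas(vertices, triangles)
    out = np.zeros(len(vertices))
    np.add.at(out, triangles.ravel(), np.repeat(areas / 3.0, 3))
    return out


def vertex_normals(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    p = vertices[triangles]
    fn = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    out = np.zeros_like(vertices)
    for k in range(3):
        np.add.at(out, triangles[:, k], fn)
    nrm = np.linalg.norm(out, axis=1)
    nrm[nrm == 0] = 1.0
    return out / nrm[:, None]


def make_vessel_mesh(
    profile: Callable[[np.ndarray], np.ndarray],
    length: float,
    n_circ: int = 64,
    n_axial: int = 64,
    bulge: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> VesselMesh:
    """Triangulated surface of revolution ``r = profile(z)`` for
    z in [0, length], optionally plus an azimuth-dependent ``bulge(z, theta)``
    term for saccular (one-sided) shapes.

    Parameters
    ----------
    profile : callable mapping axial position (m) to radius (m); must be
        strictly positive on [0, length].
    length : tube length, m.
    n_circ, n_axial : circumferential / axial segment counts (>= 8 each).

    Returns
    -------
    VesselMesh with ``(n_axial+1) * n_circ`` vertices and
    ``2 * n_axial * n_circ`` triangles; the two end rings are left open.
    """
    if n_circ < 8 or n_axial < 8:
        raise ValueError("resolution must be at least 8 x 8")
    if length <= 0:
        raise ValueError("length must be positive")
    z = np.linspace(0.0, length, n_axial + 1)
    r = np.asarray(profile(z), dtype=float)
    if np.any(r <= 0):
        zbad = z[np.argmin(r)]
        raise ValueError(f"profile non-positive at axial position {zbad:.6g} m")
    theta = np.linspace(0.0, 2 * np.pi, n_circ, endpoint=False)
    zz, tt = np.meshgrid(z, theta, indexing="ij")
    rr = np.broadcast_to(r[:, None], zz.shape).copy()
    if bulge is not None:
        rr = rr + np.asarray(bulge(zz, tt), dtype=float)
        if np.any(rr <= 0):
            zbad = zz[rr <= 0].flat[0]
            raise ValueError(
                f"profile non-positive at axial position {zbad:.6g} m")
    verts = np.column_stack([(rr * np.cos(tt)).ravel(),
                             (rr * np.sin(tt)).ravel(), zz.ravel()])
    tris = []
    for i in range(n_axial):
        for j in range(n_circ):
            a = i * n_circ + j
            b = i * n_circ + (j + 1) % n_circ
            c = (i + 1) * n_circ + j
            d = (i + 1) * n_circ + (j + 1) % n_circ
            tris.append([a, b, d])
            tris.append([a, d, c])
    return VesselMesh(vertices=verts, triangles=np.array(tris, dtype=np.int64))


def cylinder_profile(radius: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda z: np.full_like(np.asarray(z, dtype=float), radius)


def fusiform_profile(radius: float, bulge_amplitude: float, center: float,
                     width: float) -> Callable[[np.ndarray], np.ndarray]:
    """Axisymmetric Gaussian dilation: spindle-shaped (fusiform) aneurysm."""
    def f(z):
        z = np.asarray(z, dtype=float)
        return radius + bulge_amplitude * np.exp(-0.5 * ((z - center) / width) ** 2)
    return f


def saccular_bulge(amplitude: float, center_z: float, width_z: float,
                   center_theta: float = 0.0,
                   width_theta: float = 0.7) -> Callable:
    """One-sided balloon-like outpouching for ``make_vessel_mesh(bulge=...)``."""
    def b(z, theta):
        dth = np.angle(np.exp(1j * (theta - center_theta)))
        return amplitude * np.exp(-0.5 * ((z - center_z) / width_z) ** 2
                                  - 0.5 * (dth / width_theta) ** 2)
    return b


def revolution_area(profile: Callable, length: float, n_quad: int = 2000) -> float:
    """Independent quadrature of the surface-of-revolution area integral
    2*pi * int r * sqrt(1 + r'^2) dz, used to check mesh area convergence."""
    z = np.linspace(0.0, length, n_quad + 1)
    r = np.asarray(profile(z), dtype=float)
    dr = np.gradient(r, z)
    return float(integrate.trapezoid(2 * np.pi * r * np.sqrt(1 + dr ** 2), z))
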