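"""Computational domain: deformed-sphere surface meshes and the discrete
Laplace-Beltrami operator.

The tissue is modelled as a closed surface obtained by stretching the unit
sphere S^2 along its third Eulerian coordinate: a vertex at (s1, s2, s3) on
S^2 is displaced to (s1, s2, s3 + stretch * s3), giving a prolate spheroid
(1:1:5 for the default stretch of 4).  The geometry is frozen in time; all
diffusion terms act through the cotangent Laplace-Beltrami operator with
barycentric lumped-mass normalization assembled on the deformed surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra
import trimesh


class MeshError(ValueError):
    """Raised when a mesh violates the closed-manifold contract."""


@dataclass
class SurfaceMesh:
    """Triangulated closed surface with its diffusion operator.

    Attributes
    ----------
    vertices : (n, 3) float array
        Vertex positions on the deformed surface (dimensionless model units).
    faces : (m, 3) int array
        Triangles as vertex-index triples (consistently oriented).
    sphere_coords : (n, 3) float array
        Per-vertex Eulerian coordinates (s1, s2, s3) on the unit sphere
        before deformation; unit norm.
    vertex_areas : (n,) float array
        Barycentric (lumped) area associated with each vertex, computed on
        the deformed geometry.
    lb_operator : (n, n) CSR matrix
        Mass-normalized cotangent Laplace-Beltrami operator; rows sum to
        zero, annihilates constants, approximates the surface Laplacian.
    lb_weak : (n, n) CSR matrix
        Un-normalized (weak-form) cotangent Laplacian: symmetric, negative
        semidefinite, zero row sums.  ``lb_operator = M^-1 lb_weak`` with
        M = diag(vertex_areas).
    subdivision_level : int
        Icosphere refinement index (n = 10 * 4**level + 2).
    stretch_factor : float
        Displacement amplitude applied along s3.
    """

    vertices: np.ndarray
    faces: np.ndarray
    sphere_coords: np.ndarray
    vertex_areas: np.ndarray
    lb_operator: sp.csr_matrix
    lb_weak: sp.csr_matrix
    subdivision_level: int
    stretch_factor: float
    _edge_graph: sp.csr_matrix | None = field(default=None, repr=False)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    @property
    def total_area(self) -> float:
        return float(self.vertex_areas.sum())

    @property
    def equal_area_radius(self) -> float:
        """Radius of the sphere with the same total area as this surface."""
        return float(np.sqrt(self.total_area / (4.0 * np.pi)))

    def edge_graph(self) -> sp.csr_matrix:
        """Sparse symmetric adjacency weighted by Euclidean edge length."""
        if self._edge_graph is None:
            e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                           self.faces[:, [2, 0]]])
            e.sort(axis=1)
            e = np.unique(e, axis=0)
            w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]],
                               axis=1)
            n = self.n_vertices
            g = sp.coo_matrix((np.r_[w, w], (np.r_[e[:, 0], e[:, 1]],
                                             np.r_[e[:, 1], e[:, 0]])),
                              shape=(n, n))
            self._edge_graph = g.tocsr()
        return self._edge_graph

    def geodesic_distances(self, sources: np.ndarray | list[int]) -> np.ndarray:
        """Graph-geodesic distances from each source vertex to all vertices."""
        return dijkstra(self.edge_graph(), directed=False, indices=sources)

    def graph_diameter(self) -> float:
        """Approximate geodesic diameter (double sweep from the s3-max pole)."""
        top = int(np.argmax(self.sphere_coords[:, 2]))
        d = self.geodesic_distances([top])[0]
        far = int(np.argmax(d))
        return float(self.geodesic_distances([far])[0].max())


def _check_closed_manifold(vertices: np.ndarray, faces: np.ndarray) -> None:
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    if not np.all(counts == 2):
        bad = uniq[counts != 2]
        raise MeshError(
            f"mesh is not a closed 2-manifold: {len(bad)} edges not shared "
            f"by exactly 2 faces (first offenders: {bad[:5].tolist()})")
    v, e, f = len(vertices), len(uniq), len(faces)
    if v - e + f != 2:
        raise MeshError(f"Euler characteristic V-E+F = {v - e + f}, expected 2 "
                        "for a closed genus-0 surface")


def _cotangent_laplacian(vertices: np.ndarray, faces: np.ndarray
                         ) -> tuple[sp.csr_matrix, np.ndarray]:
    """Assemble the weak-form cotangent Laplacian and barycentric masses.

    Returns (L, areas) with L symmetric negative semidefinite, zero row
    sums, and areas the per-vertex lumped (1/3 of incident triangle) areas.
    Degenerate (zero-area) triangles are rejected with their face indices.
    """
    i0, i1, i2 = faces[:, 0], faces[:, 1], faces[:, 2]
    p0, p1, p2 = vertices[i0], vertices[i1], vertices[i2]
    # edge opposite to each corner
    e0 = p2 - p1
    e1 = p0 - p2
    e2 = p1 - p0
    cross = np.cross(e1, -e0)
    double_area = np.linalg.norm(cross, axis=1)
    degenerate = np.nonzero(double_area < 1e-14)[0]
    if degenerate.size:
        raise MeshError(f"degenerate (zero-area) triangles at face indices "
                        f"{degenerate.tolist()}")
    # cot(angle at corner k) = dot of adjacent edges / (2 * area)
    cot0 = np.einsum("ij,ij->i", -e1, e2) / double_area
    cot1 = np.einsum("ij,ij->i", -e2, e0) / double_area
    cot2 = np.einsum("ij,ij->i", -e0, e1) / double_area

    # off-diagonal weight w_ij = (cot alpha + cot beta) / 2, assembled per face
    rows = np.concatenate([i1, i2, i2, i0, i0, i1])
    cols = np.concatenate([i2, i1, i0, i2, i1, i0])
    vals = 0.5 * np.concatenate([cot0, cot0, cot1, cot1, cot2, cot2])
    n = vertices.shape[0]
    w = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    # L = W - diag(row sums): zero row sums by construction
    row_sums = np.asarray(w.sum(axis=1)).ravel()
    lap = w - sp.diags(row_sums)

    areas = np.zeros(n)
    tri_area = 0.5 * double_area
    for idx in (i0, i1, i2):
        np.add.at(areas, idx, tri_area / 3.0)
    return lap.tocsr(), areas


def build_spheroid_mesh(subdivision_level: int = 4,
                        stretch_factor: float = 4.0,
                        stretch_mode: str = "displacement") -> SurfaceMesh:
    """Build the deformed-sphere computational domain.

    Parameters
    ----------
    subdivision_level : int
        Icosphere refinement level; level L gives 10*4**L + 2 vertices.
    stretch_factor : float
        Amplitude of the axial deformation.  In ``displacement`` mode a
        vertex at (s1, s2, s3) moves to (s1, s2, s3 + stretch_factor*s3)
        (default 4, i.e. a 1:1:5 prolate spheroid); in ``absolute-z`` mode
        the z coordinate is replaced by stretch_factor*s3.
    stretch_mode : {"displacement", "absolute-z"}
        Interpretation of the deformation (see module docstring).

    Returns
    -------
    SurfaceMesh
        Validated closed manifold with areas and Laplace-Beltrami operator
        assembled on the deformed geometry.
    """
    if subdivision_level < 0:
        raise ValueError("subdivision_level must be >= 0")
    if stretch_factor < 0:
        raise ValueError("stretch_factor must be non-negative")
    if stretch_mode not in ("displacement", "absolute-z"):
        raise ValueError(f"unknown stretch_mode {stretch_mode!r}")
    base = trimesh.creation.icosphere(subdivisions=subdivision_level,
                                      radius=1.0)
    sphere = np.asarray(base.vertices, dtype=float)
    sphere /= np.linalg.norm(sphere, axis=1, keepdims=True)
    faces = np.asarray(base.faces, dtype=np.int64)
    _check_closed_manifold(sphere, faces)

    verts = sphere.copy()
    if stretch_mode == "displacement":
        verts[:, 2] = sphere[:, 2] * (1.0 + stretch_factor)
    else:
        if stretch_factor == 0:
            raise ValueError("absolute-z mode requires stretch_factor > 0")
        verts[:, 2] = sphere[:, 2] * stretch_factor

    lap, areas = _cotangent_laplacian(verts, faces)
    if np.any(areas <= 0):
        raise MeshError("non-positive lumped vertex areas")
    lb = sp.diags(1.0 / areas) @ lap
    return SurfaceMesh(vertices=verts, faces=faces, sphere_coords=sphere,
                       vertex_areas=areas, lb_operator=lb.tocsr(),
                       lb_weak=lap, subdivision_level=subdivision_level,
                       stretch_factor=float(stretch_factor))


def laplace_beltrami(mesh: SurfaceMesh) -> sp.csr_matrix:
    """Mass-normalized cotangent Laplace-Beltrami operator of a mesh."""
    return mesh.lb_operator


def geodesic_separation(mesh: SurfaceMesh, vertex_a: int, vertex_b: int
                        ) -> float:
    """Shortest-path distance along mesh edges between two vertices.

    Edge weights are Euclidean edge lengths on the deformed surface, so the
    value upper-bounds (and, under refinement, converges from above to) the
    intrinsic geodesic distance.
    """
    n = mesh.n_vertices
    for v in (vertex_a, vertex_b):
        if not (0 <= v < n):
            raise IndexError(f"vertex index {v} out of range [0, {n})")
    if vertex_a == vertex_b:
        return 0.0
    d = dijkstra(mesh.edge_graph(), directed=False, indices=[vertex_a],
                 min_only=False)[0]
    return float(d[vertex_b])


def write_vtk(path, mesh: SurfaceMesh, point_data: dict | None = None) -> None:
    """Write geometry plus named per-vertex scalar fields as legacy ASCII VTK."""
    lines = ["# vtk DataFile Version 3.0", "hydrapattern surface", "ASCII",
             "DATASET POLYDATA", f"POINTS {mesh.n_vertices} double"]
    for p in mesh.vertices:
        lines.append(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}")
    lines.append(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_vertices}")
        for name, values in point_data.items():
            values = np.asarray(values, dtype=float)
            if values.shape != (mesh.n_vertices,):
                raise ValueError(f"field {name!r} has shape {values.shape}, "
                                 f"expected ({mesh.n_vertices},)")
            safe = name.replace(" ", "_")
            lines.append(f"SCALARS {safe} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.10g}" for v in values)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def export_mesh(path, mesh: SurfaceMesh) -> None:
    """Export geometry as OFF or PLY (by file extension) via trimesh."""
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                         process=False)
    tm.export(path)
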