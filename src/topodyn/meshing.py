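"""Radius-cutoff simplicial complexes from atomic point clouds.

Atoms become vertices; any two atoms strictly closer than the cutoff ``r``
are joined by an edge; every triangle whose three edges exist becomes a face.
Isolated vertices are retained.  All meshes of one analysis are normalized to
the unit ball by a single dataset-wide scale so that topological features are
comparable across frames.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structures import StructureFrame


@dataclass
class SimplicialMesh:
    """Vertices, edges, and triangular faces of one frame's complex.

    ``scale_factor`` is the dataset-wide normalizing radius in Angstroms
    (1.0 for an unnormalized mesh); edge membership always refers to
    pre-normalization distances, so ``||v_i - v_j|| * scale_factor < r_cutoff``
    for every edge.
    """

    vertices: np.ndarray          # (V, 3)
    edges: np.ndarray             # (E, 2) int, each row sorted, lexsorted
    faces: np.ndarray             # (F, 3) int, each row sorted, lexsorted
    r_cutoff: float
    scale_factor: float = 1.0
    atom_index_map: Optional[np.ndarray] = None  # mesh vertex -> source atom

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if self.atom_index_map is None:
            self.atom_index_map = np.arange(self.vertices.shape[0])

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    @property
    def euler_characteristic(self) -> int:
        """chi = V - E + F of the full complex."""
        return self.n_vertices - self.n_edges + self.n_faces

    def export_off(self, path: str) -> None:
        """Write the mesh (vertices + triangular faces) in OFF format."""
        with open(path, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{self.n_vertices} {self.n_faces} {self.n_edges}\n")
            for v in self.vertices:
                fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
            for f in self.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def build_mesh(frame_or_coords, r: float) -> SimplicialMesh:
    """Build the radius-cutoff complex of a frame (strict ``< r`` rule).

    Edges connect every atom pair with Euclidean distance strictly below
    ``r``; faces fill every triangle of three mutually connected atoms.
    Exactness matches brute-force pair/triple enumeration.
    """
    if r <= 0:
        raise ValueError("radius cutoff r must be positive")
    if isinstance(frame_or_coords, StructureFrame):
        coords = frame_or_coords.coords
    else:
        coords = np.asarray(frame_or_coords, dtype=float)
    n = coords.shape[0]

    tree = cKDTree(coords)
    pairs = tree.query_pairs(r, output_type="ndarray")  # strict upper bound
    if pairs.size:
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d < r]  # enforce strict inequality against fp ties
        pairs = np.sort(pairs, axis=1)
        pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    edges = pairs.reshape(-1, 2)

    # faces: for each edge (i, j) with i < j, common neighbors k > j
    neighbors = [set() for _ in range(n)]
    for i, j in edges:
        neighbors[i].add(j)
        neighbors[j].add(i)
    faces = []
    for i, j in edges:
        common = neighbors[i] & neighbors[j]
        for k in common:
            if k > j:
                faces.append((i, j, k))
    faces = np.array(sorted(faces), dtype=int).reshape(-1, 3)

    return SimplicialMesh(vertices=coords.copy(), edges=edges, faces=faces, r_cutoff=r)


def normalize_meshes(meshes: Sequence[SimplicialMesh],
                     origin: Optional[np.ndarray] = None) -> List[SimplicialMesh]:
    """Scale all meshes into the unit ball by one common factor.

    The scale factor is the largest vertex distance from ``origin`` over the
    whole dataset (``origin`` defaults to the zero vector; the caller is
    expected to have centered coordinates on the reference CA centroid during
    alignment).  Connectivity is unchanged.
    """
    meshes = list(meshes)
    if not meshes:
        raise ValueError("empty mesh list")
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    scale = max(
        float(np.linalg.norm(m.vertices - origin, axis=1).max()) for m in meshes
    )
    if scale <= 0:
        raise ValueError("all vertices coincide with the origin; cannot normalize")
    out = []
    for m in meshes:
        out.append(
            replace(
                m,
                vertices=(m.vertices - origin) / scale,
                scale_factor=scale * m.scale_factor,
            )
        )
    return out
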