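"""Euler characteristic transforms over cones of filtration directions.

For a unit-ball-normalized simplicial mesh and a unit direction ``nu``, the
height function ``h_nu(x) = x . nu`` induces a sublevel-set filtration: the
complex at threshold ``a`` contains a vertex iff its height is <= ``a`` and an
edge/face iff all of its vertices are included (max-height convention).  The
Euler characteristic (EC) curve records ``V - E + F`` of each sublevel
complex over ``l`` ascending thresholds spanning [-1, 1]; the differential EC
(DEC) curve is its lag-``t`` difference, which tracks the appearance and
disappearance of topological features step to step.

Directions are grouped into ``c`` cones of ``d`` directions each: cone
centers are placed near-uniformly on the sphere (Fibonacci lattice, with a
seed-controlled global rotation) and within each cone the directions sit
equidistantly on the circle of angular radius ``theta`` about the center
(built with Rodrigues' rotation formula).  Concatenating the DEC curves over
all ``m = c*d`` directions yields a feature vector of length ``J = l*m`` per
frame, assembled into an N x J design matrix with full per-column provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .meshing import SimplicialMesh


@dataclass
class DirectionSet:
    """Cones of unit filtration directions."""

    c: int
    d: int
    theta: float
    centers: np.ndarray      # (c, 3)
    directions: np.ndarray   # (c*d, 3), grouped by cone

    @property
    def m(self) -> int:
        return self.c * self.d

    def cone_slice(self, k: int) -> slice:
        return slice(k * self.d, (k + 1) * self.d)


@dataclass
class FiltrationSpec:
    """Sublevel-set thresholds: ``l`` ascending values spanning [-1, 1]."""

    l: int
    thresholds: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.l < 1:
            raise ValueError("l must be >= 1")
        if self.thresholds is None:
            if self.l == 1:
                self.thresholds = np.array([1.0])
            else:
                self.thresholds = np.linspace(-1.0, 1.0, self.l)
        else:
            self.thresholds = np.asarray(self.thresholds, dtype=float)
            if len(self.thresholds) != self.l:
                raise ValueError("thresholds length != l")
            if np.any(np.diff(self.thresholds) <= 0):
                raise ValueError("thresholds must be strictly increasing")


@dataclass
class ECCurve:
    values: np.ndarray          # length l, ints
    direction: np.ndarray
    counts: np.ndarray          # (l, 3): V, E, F per step


@dataclass
class DECCurve:
    values: np.ndarray          # length l, ints
    direction: np.ndarray
    lag: int
    counts: np.ndarray          # (l, 3): delta V, E, F per step


def generate_cones(c: int, d: int, theta: float, seed: int = 0) -> DirectionSet:
    """Generate ``c`` cones of ``d`` directions with cap radius ``theta``.

    Cone centers are a deterministic Fibonacci-sphere set, rotated as a whole
    by a seed-controlled random rotation.  Within each cone the ``d``
    directions are equidistant on the circle at angular distance ``theta``
    from the center (``d = 1`` returns the center itself).
    """
    if c < 1 or d < 1:
        raise ValueError("c and d must be >= 1")
    if not (0 < theta <= 2 * np.pi):
        raise ValueError("theta must be in (0, 2*pi]")

    i = np.arange(c) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / c
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    centers = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    rng = np.random.default_rng(seed)
    global_rot = Rotation.random(random_state=rng).as_matrix()
    centers = centers @ global_rot.T

    directions = np.empty((c * d, 3))
    for k, center in enumerate(centers):
        if d == 1:
            directions[k * d] = center
            continue
        # orthonormal basis in the plane perpendicular to the center
        helper = np.array([1.0, 0.0, 0.0])
        if abs(center @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        u = np.cross(center, helper)
        u /= np.linalg.norm(u)
        w = np.cross(center, u)
        angles = 2 * np.pi * np.arange(d) / d
        ring = (
            np.cos(theta) * center[None, :]
            + np.sin(theta) * (np.cos(angles)[:, None] * u + np.sin(angles)[:, None] * w)
        )
        directions[k * d:(k + 1) * d] = ring
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    return DirectionSet(c=c, d=d, theta=theta, centers=centers, directions=directions)


# ---------------------------------------------------------------------------
# EC / DEC curves
# ---------------------------------------------------------------------------

def _simplex_heights(mesh: SimplicialMesh, nu: np.ndarray):
    """Heights of vertices, edges, faces (max-vertex convention)."""
    hv = mesh.vertices @ nu
    he = hv[mesh.edges].max(axis=1) if mesh.n_edges else np.empty(0)
    hf = hv[mesh.faces].max(axis=1) if mesh.n_faces else np.empty(0)
    return hv, he, hf


def _counts(heights: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    return np.searchsorted(np.sort(heights), thresholds, side="right")


def ec_curve(mesh: SimplicialMesh, nu: np.ndarray, filt: FiltrationSpec) -> ECCurve:
    """Euler characteristic curve of ``mesh`` along direction ``nu``."""
    nu = np.asarray(nu, dtype=float)
    norm = np.linalg.norm(nu)
    if abs(norm - 1.0) > 1e-9:
        import warnings

        warnings.warn("direction is not unit length; normalizing")
        nu = nu / norm
    hv, he, hf = _simplex_heights(mesh, nu)
    v = _counts(hv, filt.thresholds)
    e = _counts(he, filt.thresholds)
    f = _counts(hf, filt.thresholds)
    return ECCurve(values=v - e + f, direction=nu, counts=np.column_stack([v, e, f]))


def dec_curve(mesh: SimplicialMesh, nu: np.ndarray, filt: FiltrationSpec,
              t: int = 1) -> DECCurve:
    """Differential EC curve with lag ``t`` (steps ``k <= t`` difference
    against the empty complex, so the lag-1 curve telescopes back to EC)."""
    if not (1 <= t < filt.l):
        raise ValueError("lag t must satisfy 1 <= t < l")
    ec = ec_curve(mesh, nu, filt)
    padded = np.vstack([np.zeros((t, 3), dtype=int), ec.counts])
    dcounts = ec.counts - padded[: filt.l]
    values = dcounts[:, 0] - dcounts[:, 1] + dcounts[:, 2]
    return DECCurve(values=values, direction=ec.direction, lag=t, counts=dcounts)


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

@dataclass
class TopologyDesignMatrix:
    """N x J matrix of DEC features with provenance.

    Column order is fixed: cones outer, directions within a cone middle,
    sublevel index inner, so ``column = (cone*d + direction)*l + sublevel``.
    ``atom_feature_maps[i]`` is an ``(n_atoms, m)`` integer array giving, for
    every atom of frame ``i`` and every direction, the column at which that
    atom first enters the filtration.
    """

    X: np.ndarray
    direction_set: DirectionSet
    filtration: FiltrationSpec
    atom_feature_maps: List[np.ndarray]
    lag: int = 1
    scale_factor: float = 1.0

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def provenance(self, column: int) -> Tuple[int, int, int]:
        """Decode a column index into (cone, direction-in-cone, sublevel)."""
        d, l = self.direction_set.d, self.filtration.l
        if not (0 <= column < self.X.shape[1]):
            raise IndexError("column out of range")
        cone, rest = divmod(column, d * l)
        direction, sublevel = divmod(rest, l)
        return cone, direction, sublevel

    def provenance_table(self):
        import pandas as pd

        cols = np.arange(self.X.shape[1])
        decoded = np.array([self.provenance(c) for c in cols])
        return pd.DataFrame(
            {"feature_index": cols, "cone": decoded[:, 0],
             "direction": decoded[:, 1], "sublevel": decoded[:, 2]}
        )

    def save(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            h5.create_dataset("X", data=self.X)
            h5.create_dataset("centers", data=self.direction_set.centers)
            h5.create_dataset("directions", data=self.direction_set.directions)
            h5.create_dataset("thresholds", data=self.filtration.thresholds)
            grp = h5.create_group("atom_feature_maps")
            for i, fmap in enumerate(self.atom_feature_maps):
                grp.create_dataset(str(i), data=fmap)
            h5.attrs.update(
                c=self.direction_set.c, d=self.direction_set.d,
                theta=self.direction_set.theta, l=self.filtration.l,
                lag=self.lag, scale_factor=self.scale_factor,
            )

    @classmethod
    def load(cls, path: str) -> "TopologyDesignMatrix":
        import h5py

        with h5py.File(path, "r") as h5:
            dirs = DirectionSet(
                c=int(h5.attrs["c"]), d=int(h5.attrs["d"]),
                theta=float(h5.attrs["theta"]),
                centers=h5["centers"][...], directions=h5["directions"][...],
            )
            filt = FiltrationSpec(l=int(h5.attrs["l"]), thresholds=h5["thresholds"][...])
            maps = [h5["atom_feature_maps"][k][...]
                    for k in sorted(h5["atom_feature_maps"], key=int)]
            return cls(X=h5["X"][...], direction_set=dirs, filtration=filt,
                       atom_feature_maps=maps, lag=int(h5.attrs["lag"]),
                       scale_factor=float(h5.attrs["scale_factor"]))


def build_design_matrix(meshes: Sequence[SimplicialMesh], dirs: DirectionSet,
                        filt: FiltrationSpec, t: int = 1) -> TopologyDesignMatrix:
    """Concatenate per-direction DEC curves of every mesh into an N x J matrix."""
    meshes = list(meshes)
    if not meshes:
        raise ValueError("no meshes")
    scales = {round(m.scale_factor, 9) for m in meshes}
    if len(scales) > 1:
        raise ValueError("meshes do not share one normalization scale")
    if not (1 <= t < filt.l):
        raise ValueError("lag t must satisfy 1 <= t < l")

    m = dirs.m
    l = filt.l
    thresholds = filt.thresholds
    N = len(meshes)
    X = np.empty((N, m * l))
    maps = []
    D = dirs.directions.T  # (3, m)

    for i, mesh in enumerate(meshes):
        hv = mesh.vertices @ D                              # (V, m)
        he = hv[mesh.edges].max(axis=1) if mesh.n_edges else np.empty((0, m))
        hf = hv[mesh.faces].max(axis=1) if mesh.n_faces else np.empty((0, m))
        row = np.empty((m, l))
        for g in range(m):
            v = np.searchsorted(np.sort(hv[:, g]), thresholds, side="right")
            e = np.searchsorted(np.sort(he[:, g]), thresholds, side="right")
            f = np.searchsorted(np.sort(hf[:, g]), thresholds, side="right")
            counts = np.column_stack([v, e, f])
            padded = np.vstack([np.zeros((t, 3), dtype=counts.dtype), counts])[:l]
            dc = counts - padded
            row[g] = dc[:, 0] - dc[:, 1] + dc[:, 2]
        X[i] = row.ravel()

        # first threshold index at which each atom enters, per direction
        sub = np.searchsorted(thresholds, hv, side="left")   # (V, m)
        sub = np.minimum(sub, l - 1)
        maps.append(np.arange(m)[None, :] * l + sub)

    return TopologyDesignMatrix(
        X=X, direction_set=dirs, filtration=filt, atom_feature_maps=maps,
        lag=t, scale_factor=meshes[0].scale_factor,
    )
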