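"""Reading, writing, and aligning ensembles of protein conformations.

PDB parsing and writing are delegated to :mod:`biotite`; plain XYZ tables
(``name x y z`` per line) are read directly.  Two alignment routes are
provided: classic Kabsch superposition on alpha-carbons, and a
correspondence-free rotational alignment that matches per-direction
differential Euler characteristic curves with RANSAC.
"""

from __future__ import annotations

import os
import warnings
from typing import Iterable, List, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .structures import StructureFrame, EnsembleDataset, parse_selection


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _frames_from_pdb(path: str) -> List[StructureFrame]:
    try:
        pdb = PDBFile.read(path)
        stack = pdb.get_structure(model=None, altloc="occupancy")
    except Exception as exc:  # noqa: BLE001 - reraise with file context
        raise ValueError(f"cannot parse PDB file {path!r}: {exc}") from exc
    if isinstance(stack, bst.AtomArray):
        stack = bst.stack([stack])
    frames = []
    for model in stack:
        frames.append(
            StructureFrame(
                coords=np.asarray(model.coord, dtype=float),
                atom_names=np.asarray(model.atom_name),
                residue_ids=np.asarray(model.res_id, dtype=int),
                residue_names=np.asarray(model.res_name),
                chain_ids=np.asarray(model.chain_id),
            )
        )
    return frames


def _frames_from_xyz(path: str) -> List[StructureFrame]:
    names, coords = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 4:
                raise ValueError(f"cannot parse XYZ file {path!r}: bad line {line!r}")
            names.append(parts[0])
            try:
                coords.append([float(v) for v in parts[1:4]])
            except ValueError as exc:
                raise ValueError(f"cannot parse XYZ file {path!r}: bad line {line!r}") from exc
    if not coords:
        raise ValueError(f"cannot parse XYZ file {path!r}: no atom records")
    n = len(names)
    return [
        StructureFrame(
            coords=np.asarray(coords, dtype=float),
            atom_names=np.asarray(names),
            residue_ids=np.arange(1, n + 1),
            residue_names=np.full(n, "UNK"),
            chain_ids=np.full(n, "A"),
        )
    ]


def read_frames(paths, selection: str = "all", class_label: int = 0) -> EnsembleDataset:
    """Read one or more structure files into an :class:`EnsembleDataset`.

    Parameters
    ----------
    paths : str or sequence of str
        PDB files (single- or multi-model; MODEL/ENDMDL delimits frames) or
        XYZ tables.  Frames are returned in input order.
    selection : str
        Atom-subset specification applied to every frame, e.g.
        ``"chain A, residues 1-99, heavy"``.
    class_label : int
        Binary class assigned to every frame read.
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    sel = parse_selection(selection)
    frames: List[StructureFrame] = []
    for path in paths:
        path = os.fspath(path)
        if path.lower().endswith(".xyz"):
            new = _frames_from_xyz(path)
        else:
            new = _frames_from_pdb(path)
        for frame in new:
            frame.class_label = class_label
            mask = sel(frame)
            if mask.sum() == 0:
                raise ValueError(f"selection {selection!r} is empty for {path!r}")
            frames.append(frame.select(mask) if not mask.all() else frame)
    return EnsembleDataset(frames=frames, selection=selection)


def write_frames(path: str, frames: Iterable[StructureFrame],
                 b_factors: Optional[np.ndarray] = None) -> None:
    """Write frames as a (multi-model) PDB file.

    ``b_factors`` (per-atom values, clamped to [0, 99.99]) are written into
    the B-factor column of every model when given.
    """
    frames = list(frames)
    arrays = []
    for frame in frames:
        n = frame.n_atoms
        arr = bst.AtomArray(n)
        arr.coord = np.asarray(frame.coords, dtype=np.float32)
        arr.atom_name = frame.atom_names.astype(str)
        arr.res_id = frame.residue_ids
        arr.res_name = frame.residue_names.astype(str)
        arr.chain_id = frame.chain_ids.astype(str)
        arr.element = np.array([str(nm).strip()[:1] for nm in frame.atom_names])
        arr.hetero = np.zeros(n, dtype=bool)
        if b_factors is not None:
            vals = np.clip(np.asarray(b_factors, dtype=float), 0.0, 99.99)
            if vals.shape[0] != n:
                raise ValueError("b_factors length does not match atom count")
            arr.set_annotation("b_factor", vals)
        else:
            arr.set_annotation("b_factor", np.zeros(n))
        arrays.append(arr)
    stack = bst.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)


# ---------------------------------------------------------------------------
# RMSD (Kabsch) alignment
# ---------------------------------------------------------------------------

def kabsch_rotation(ref: np.ndarray, mobile: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||ref - mobile @ R.T|| for centered inputs."""
    rot, _ = Rotation.align_vectors(ref, mobile)
    return rot.as_matrix()


def align_rmsd(ds: EnsembleDataset, reference: Optional[StructureFrame] = None) -> EnsembleDataset:
    """Superpose every frame onto the reference by alpha-carbon Kabsch fit.

    The rotation and translation are estimated on CA atoms only and then
    applied rigidly to all atoms of the frame.  By default the reference is
    the first class-0 frame of the dataset (falling back to the first frame).
    """
    if reference is None:
        class_a = ds.by_class(0)
        reference = class_a[0] if class_a else ds.frames[0]
    ref_ca = reference.ca_coords()
    ref_centroid = ref_ca.mean(axis=0)
    ref_centered = ref_ca - ref_centroid

    aligned = []
    for frame in ds.frames:
        ca = frame.ca_coords()
        if ca.shape[0] != ref_ca.shape[0]:
            raise ValueError(
                f"CA count mismatch: frame has {ca.shape[0]}, reference has {ref_ca.shape[0]}"
            )
        centroid = ca.mean(axis=0)
        centered = ca - centroid
        rank = np.linalg.matrix_rank(centered, tol=1e-8)
        if rank < 2:
            warnings.warn("degenerate (collinear) CA set; proceeding with best-fit rotation")
        rot = kabsch_rotation(ref_centered, centered)
        new_coords = (frame.coords - centroid) @ rot.T + ref_centroid
        aligned.append(frame.with_coords(new_coords))
    return EnsembleDataset(frames=aligned, selection=ds.selection,
                           offsets=ds.offsets, frame_offsets=ds.frame_offsets)


# ---------------------------------------------------------------------------
# topological (correspondence-free) rotational alignment
# ---------------------------------------------------------------------------

def _uniform_sphere_directions(n: int) -> np.ndarray:
    """Deterministic near-uniform directions on S^2 (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _dec_summary(frame: StructureFrame, directions: np.ndarray, r: float, l: int) -> np.ndarray:
    """Per-direction DEC curves of a single centered frame (own-scale mesh)."""
    from .meshing import build_mesh, normalize_meshes
    from .dec_transform import FiltrationSpec, dec_curve

    mesh = build_mesh(frame, r=r)
    mesh = normalize_meshes([mesh])[0]
    filt = FiltrationSpec(l=l)
    return np.array([dec_curve(mesh, nu, filt).values for nu in directions], dtype=float)


def align_topological(frame_a: StructureFrame, frame_b: StructureFrame,
                      n_dirs: int = 500, dot_threshold: float = 0.9,
                      r: float = 6.0, l: int = 60, n_iter: int = 1000,
                      seed: int = 0, return_consensus: bool = False):
    """Rotation aligning ``frame_b`` to ``frame_a`` via topological summaries.

    Both frames are centered on their CA centroids; DEC curves are computed
    along ``n_dirs`` near-uniform directions; each direction of ``frame_a`` is
    matched to the direction of ``frame_b`` with the closest curve (squared
    Euclidean distance), and RANSAC searches for the proper rotation under
    which the largest number of matched direction pairs agree to within the
    ``dot_threshold`` inlier rule (dot product of rotated pair > threshold).

    Returns the 3x3 rotation matrix (apply to centered frame_b coordinates);
    with ``return_consensus=True`` also returns the consensus size.
    """
    if n_dirs < 3:
        raise ValueError("n_dirs must be >= 3")
    rng = np.random.default_rng(seed)
    dirs = _uniform_sphere_directions(n_dirs)

    ca_a = frame_a.ca_coords().mean(axis=0)
    ca_b = frame_b.ca_coords().mean(axis=0)
    fa = frame_a.with_coords(frame_a.coords - ca_a)
    fb = frame_b.with_coords(frame_b.coords - ca_b)

    curves_a = _dec_summary(fa, dirs, r=r, l=l)
    curves_b = _dec_summary(fb, dirs, r=r, l=l)

    # match each a-direction to its lowest-cost b-direction
    cost = ((curves_a[:, None, :] - curves_b[None, :, :]) ** 2).sum(axis=2)
    match = cost.argmin(axis=1)
    a_dirs = dirs                      # target
    b_dirs = dirs[match]               # source (rotate these onto a_dirs)

    best_inliers = None
    for _ in range(n_iter):
        pick = rng.choice(n_dirs, size=3, replace=False)
        rot, _ = Rotation.align_vectors(a_dirs[pick], b_dirs[pick])
        rotated = b_dirs @ rot.as_matrix().T
        inliers = np.einsum("ij,ij->i", rotated, a_dirs) > dot_threshold
        if best_inliers is None or inliers.sum() > best_inliers.sum():
            best_inliers = inliers
    if best_inliers is None or best_inliers.sum() < 3:
        raise ValueError("no stable topological alignment (consensus < 3)")
    rot, _ = Rotation.align_vectors(a_dirs[best_inliers], b_dirs[best_inliers])
    R = rot.as_matrix()
    if return_consensus:
        return R, int(best_inliers.sum())
    return R
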