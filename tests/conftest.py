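import numpy as np
import pytest

from topodyn.structures import StructureFrame
from topodyn.meshing import build_mesh, normalize_meshes


PDB_3MODEL = """\
MODEL        1
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.759   7.095  -4.966  1.00  0.00           C
ATOM      4  CA  GLY A   2      14.428   8.740  -4.496  1.00  0.00           C
ATOM      5  CA  SER A   3      17.093   9.005  -3.106  1.00  0.00           C
ATOM      6  CA  THR B   1       5.326   3.020  -1.213  1.00  0.00           C
ATOM      7  CA  VAL B   2       7.011   4.332   0.511  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1      11.204   6.234  -6.404  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.739   6.171  -5.047  1.00  0.00           C
ATOM      3  C   ALA A   1      12.859   7.195  -4.866  1.00  0.00           C
ATOM      4  CA  GLY A   2      14.528   8.840  -4.396  1.00  0.00           C
ATOM      5  CA  SER A   3      17.193   9.105  -3.006  1.00  0.00           C
ATOM      6  CA  THR B   1       5.426   3.120  -1.113  1.00  0.00           C
ATOM      7  CA  VAL B   2       7.111   4.432   0.611  1.00  0.00           C
ENDMDL
MODEL        3
ATOM      1  N   ALA A   1      11.304   6.334  -6.304  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.839   6.271  -4.947  1.00  0.00           C
ATOM      3  C   ALA A   1      12.959   7.295  -4.766  1.00  0.00           C
ATOM      4  CA  GLY A   2      14.628   8.940  -4.296  1.00  0.00           C
ATOM      5  CA  SER A   3      17.293   9.205  -2.906  1.00  0.00           C
ATOM      6  CA  THR B   1       5.526   3.220  -1.013  1.00  0.00           C
ATOM      7  CA  VAL B   2       7.211   4.532   0.711  1.00  0.00           C
ENDMDL
END
"""


@pytest.fixture
def pdb_3model(tmp_path):
    path = tmp_path / "three_models.pdb"
    path.write_text(PDB_3MODEL)
    return str(path)


def make_frame(coords, label=0, atom_names=None, residue_ids=None):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    return StructureFrame(
        coords=coords,
        atom_names=np.array(atom_names) if atom_names is not None else np.full(n, "CA"),
        residue_ids=np.asarray(residue_ids) if residue_ids is not None else np.arange(1, n + 1),
        residue_names=np.full(n, "GLY"),
        chain_ids=np.full(n, "A"),
        class_label=label,
    )


@pytest.fixture
def frame_factory():
    return make_frame


def random_points(n, box=10.0, seed=0):
    return np.random.default_rng(seed).uniform(-box / 2, box / 2, size=(n, 3))


@pytest.fixture
def random_mesh():
    def _make(n=30, r=4.0, box=10.0, seed=0, normalized=False):
        mesh = build_mesh(random_points(n, box=box, seed=seed), r=r)
        if normalized:
            mesh = normalize_meshes([mesh])[0]
        return mesh

    return _make


def brute_force_complex(coords, r):
    """Edge/face enumeration oracle over all pairs and triples."""
    n = len(coords)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(coords[i] - coords[j]) < r:
                edges.add((i, j))
    faces = set()
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                if {(i, j), (i, k), (j, k)} <= edges:
                    faces.add((i, j, k))
    return edges, faces


def brute_force_ec_curve(mesh, nu, thresholds):
    """Rebuild every sublevel complex from scratch and count V - E + F."""
    hv = mesh.vertices @ nu
    values = []
    for a in thresholds:
        keep = hv <= a
        v = int(keep.sum())
        e = sum(1 for i, j in mesh.edges if keep[i] and keep[j])
        f = sum(1 for i, j, k in mesh.faces if keep[i] and keep[j] and keep[k])
        values.append(v - e + f)
    return np.array(values)
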