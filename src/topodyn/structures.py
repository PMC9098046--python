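"""Core containers for protein conformations and ensembles."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np


@dataclass
class StructureFrame:
    """One protein conformation.

    Parameters
    ----------
    coords : (n_atoms, 3) float array
        Cartesian atomic positions in Angstroms.
    atom_names : (n_atoms,) str array
        Atom identifiers (e.g. ``CA``, ``N``, ``O``).
    residue_ids : (n_atoms,) int array
        Residue sequence numbers.
    residue_names : (n_atoms,) str array
        Three-letter residue codes.
    chain_ids : (n_atoms,) str array
        Chain labels.
    class_label : int
        Binary ensemble membership (0 or 1).
    frame_time : float, optional
        Simulation time of the frame in nanoseconds.
    """

    coords: np.ndarray
    atom_names: np.ndarray
    residue_ids: np.ndarray
    residue_names: np.ndarray
    chain_ids: np.ndarray
    class_label: int = 0
    frame_time: Optional[float] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n_atoms, 3) array")
        if self.coords.shape[0] < 4:
            raise ValueError("a frame needs at least 4 atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.class_label not in (0, 1):
            raise ValueError("class_label must be 0 or 1")
        n = self.coords.shape[0]
        for name in ("atom_names", "residue_ids", "residue_names", "chain_ids"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ValueError(f"{name} length {arr.shape[0]} != n_atoms {n}")
            setattr(self, name, arr)
        self.residue_ids = self.residue_ids.astype(int)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def ca_mask(self) -> np.ndarray:
        return np.char.strip(self.atom_names.astype(str)) == "CA"

    def ca_coords(self) -> np.ndarray:
        mask = self.ca_mask
        if not mask.any():
            raise ValueError("frame has no alpha-carbon (CA) atoms")
        return self.coords[mask]

    def select(self, mask: np.ndarray) -> "StructureFrame":
        """Return a new frame restricted to atoms where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() == 0:
            raise ValueError("selection is empty")
        return StructureFrame(
            coords=self.coords[mask].copy(),
            atom_names=self.atom_names[mask].copy(),
            residue_ids=self.residue_ids[mask].copy(),
            residue_names=self.residue_names[mask].copy(),
            chain_ids=self.chain_ids[mask].copy(),
            class_label=self.class_label,
            frame_time=self.frame_time,
        )

    def with_coords(self, coords: np.ndarray) -> "StructureFrame":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass
class EnsembleDataset:
    """An ordered collection of frames from one study.

    ``selection`` records the atom-subset specification the frames were
    filtered with; ``offsets`` lists the time offsets (ns) identifying
    sampling series when frames interleave several offset trajectories.
    """

    frames: list
    selection: str = "all"
    offsets: Sequence[float] = field(default_factory=lambda: [0.0])
    frame_offsets: Optional[np.ndarray] = None  # per-frame offset-series index

    def __post_init__(self):
        if len(self.frames) == 0:
            raise ValueError("EnsembleDataset needs at least one frame")
        if self.frame_offsets is not None:
            self.frame_offsets = np.asarray(self.frame_offsets, dtype=int)
            if len(self.frame_offsets) != len(self.frames):
                raise ValueError("frame_offsets length mismatch")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    @property
    def labels(self) -> np.ndarray:
        return np.array([f.class_label for f in self.frames], dtype=int)

    def by_class(self, label: int) -> list:
        return [f for f in self.frames if f.class_label == label]


def parse_selection(spec: str):
    """Parse a simple atom-selection string.

    Supported clauses, comma separated: ``all``, ``chain X``,
    ``residues A-B`` (inclusive), ``heavy`` (drop hydrogens), ``name CA``.
    """
    spec = (spec or "all").strip()

    def _apply(frame: StructureFrame) -> np.ndarray:
        mask = np.ones(frame.n_atoms, dtype=bool)
        for clause in spec.split(","):
            clause = clause.strip()
            if not clause or clause == "all":
                continue
            parts = clause.split()
            key = parts[0].lower()
            if key == "chain":
                mask &= np.isin(frame.chain_ids.astype(str), parts[1:])
            elif key in ("residues", "resid"):
                lo, _, hi = parts[1].partition("-")
                hi = hi or lo
                mask &= (frame.residue_ids >= int(lo)) & (frame.residue_ids <= int(hi))
            elif key == "heavy":
                names = np.char.strip(frame.atom_names.astype(str))
                mask &= ~np.char.startswith(names, "H")
            elif key == "name":
                names = np.char.strip(frame.atom_names.astype(str))
                mask &= np.isin(names, parts[1:])
            else:
                raise ValueError(f"unknown selection clause: {clause!r}")
        return mask

    return _apply
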