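"""Mapping feature-level association measures back onto atoms and residues.

Each atom corresponds to ``m`` gamma values (one per filtration direction,
through the sublevel set in which the atom first appears).  Sweeping a rising
threshold over the sorted gamma values kills an atom exactly when the
threshold passes the minimum of its associated values, so the atom's evidence
score ``gamma_hat`` is that minimum in closed form.  The ``gamma_hat`` values
are rank-scaled to [0, 100] per atom and, after averaging within residues,
per residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .structures import StructureFrame
from .gp_inference import AssociationScores


@dataclass
class EvidenceScores:
    """Per-atom and per-residue evidence potentials on a 0-100 scale."""

    gamma_hat: np.ndarray            # per-atom mean minimum-gamma
    atom_score: np.ndarray           # rank-scaled to [0, 100]
    residue_ids: np.ndarray          # unique residues, sorted
    residue_gamma_hat: np.ndarray
    residue_score: np.ndarray        # rank-scaled to [0, 100]
    series_mean: Optional[np.ndarray] = None   # (n_series, n_residues)
    series_se: Optional[np.ndarray] = None     # per-residue SE across series

    def atom_table(self, frame: StructureFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {"atom": np.arange(len(self.gamma_hat)),
             "atom_name": frame.atom_names.astype(str),
             "residue_id": frame.residue_ids,
             "gamma_hat": self.gamma_hat,
             "atom_score": self.atom_score}
        )

    def residue_table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"residue_id": self.residue_ids,
             "gamma_hat": self.residue_gamma_hat,
             "residue_score": self.residue_score}
        )
        if self.series_se is not None:
            df["se"] = self.series_se
        return df


def atom_gamma_hat(atom_feature_map: np.ndarray, gamma: AssociationScores) -> np.ndarray:
    """Per-atom minimum of the atom's m associated gamma values."""
    fmap = np.asarray(atom_feature_map)
    if fmap.ndim != 2:
        raise ValueError("atom_feature_map must be (n_atoms, m)")
    g = np.asarray(gamma.gamma if isinstance(gamma, AssociationScores) else gamma)
    if fmap.min() < 0 or fmap.max() >= len(g):
        raise ValueError("atom feature mapping refers to missing features")
    return g[fmap].min(axis=1)


def _rank_scale(values: np.ndarray) -> np.ndarray:
    """Scale by average rank to [0, 100]; a single value maps to 100."""
    n = len(values)
    if n == 1:
        return np.array([100.0])
    ranks = rankdata(values, method="average")
    return 100.0 * (ranks - 1.0) / (n - 1.0)


def scale_scores(gamma_hat_per_frame: Sequence[np.ndarray],
                 frames: Sequence[StructureFrame],
                 frame_series: Optional[np.ndarray] = None) -> EvidenceScores:
    """Aggregate per-frame gamma_hat into atom and residue evidence scores.

    Per-frame values are averaged per atom before rank-scaling; residue-level
    values are the mean gamma_hat over the residue's atoms, rank-scaled over
    residues.  With ``frame_series`` (per-frame offset-series index), residue
    profiles are also averaged within each series and a standard error across
    series is reported.
    """
    mat = np.asarray(list(gamma_hat_per_frame), dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 1:
        raise ValueError("need at least one frame of gamma_hat values")
    gamma_hat = mat.mean(axis=0)
    atom_score = _rank_scale(gamma_hat)

    res_ids = frames[0].residue_ids
    uniq = np.unique(res_ids)
    res_gh = np.array([gamma_hat[res_ids == rid].mean() for rid in uniq])
    res_score = _rank_scale(res_gh)

    series_mean = series_se = None
    if frame_series is not None:
        frame_series = np.asarray(frame_series, dtype=int)
        series_ids = np.unique(frame_series)
        profiles = []
        for s in series_ids:
            gh_s = mat[frame_series == s].mean(axis=0)
            profiles.append([gh_s[res_ids == rid].mean() for rid in uniq])
        series_mean = np.asarray(profiles)
        if len(series_ids) > 1:
            series_se = series_mean.std(axis=0, ddof=1) / np.sqrt(len(series_ids))
        else:
            series_se = np.zeros(len(uniq))

    return EvidenceScores(
        gamma_hat=gamma_hat, atom_score=atom_score,
        residue_ids=uniq, residue_gamma_hat=res_gh, residue_score=res_score,
        series_mean=series_mean, series_se=series_se,
    )


def export_scored_pdb(path: str, frame: StructureFrame, scores: EvidenceScores) -> None:
    """Write the representative frame with atom scores in the B-factor column
    (clamped to [0, 99.99], PDB column precision)."""
    from .trajectory_io import write_frames

    if len(scores.atom_score) != frame.n_atoms:
        raise ValueError("score length does not match frame atom count")
    write_frames(path, [frame], b_factors=scores.atom_score)
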