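"""Per-residue root mean square fluctuation on aligned trajectories.

For residue n over M frames in the analysis window,

    RMSF_n = sqrt( (1/M) Σ_m |r_nm − ⟨r_n⟩|² ),

with ⟨r_n⟩ the within-window mean position and the divisor M (population
form).  The trajectory must already be superimposed on a common reference;
the statistic is otherwise inflated by rigid-body motion, which a heuristic
warning tries to catch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .trajio import Selection, Trajectory

logger = logging.getLogger("kinfield")

__all__ = ["RMSFProfile", "rmsf"]

#: Default analysis window [ps): the production interval after equilibration.
DEFAULT_WINDOW = (10_000.0, 30_000.0)


@dataclass(frozen=True)
class RMSFProfile:
    residue_ids: np.ndarray
    rmsf: np.ndarray  # Å, one value per selected residue
    window: tuple[float, float]
    n_frames: int

    def __post_init__(self) -> None:
        if np.any(self.rmsf < 0):
            raise ValueError("rmsf must be non-negative")
        if len(self.residue_ids) != len(self.rmsf):
            raise ValueError("residue_ids and rmsf lengths differ")


def rmsf(
    traj: Trajectory,
    selection: Selection,
    window: tuple[float, float] = DEFAULT_WINDOW,
    fit_selection: Selection | None = None,
    unaligned_rmsd_threshold: float = 3.0,
) -> RMSFProfile:
    """RMSF per selected atom over the half-open time window.

    ``traj`` may be a single aligned run or joined replicates (frames are
    simply pooled; with joined input the window applies to the re-based
    joined times, pass ``window=None``-like full range by using the
    trajectory's own span).  If ``fit_selection`` is given, the mean RMSD
    of that subset about its average position is checked and a warning is
    logged above ``unaligned_rmsd_threshold`` Å, a hint that the caller
    forgot to superimpose.
    """
    selection.validate(traj.structure)
    tw = traj.window(*window) if window is not None else traj
    if tw.n_frames < 2:
        raise ValueError(f"need at least 2 frames in window, got {tw.n_frames}")
    if fit_selection is not None:
        fit_selection.validate(traj.structure)
        sub = tw.frames[:, fit_selection.atom_indices, :]
        dev = sub - sub.mean(axis=0)
        fit_rmsd = np.sqrt((dev**2).sum(axis=(1, 2)) / sub.shape[1]).mean()
        if fit_rmsd > unaligned_rmsd_threshold:
            logger.warning(
                "rmsf: fit-subset RMSD %.2f Å exceeds %.2f Å — "
                "was the trajectory aligned?",
                fit_rmsd,
                unaligned_rmsd_threshold,
            )
    idx = selection.atom_indices
    coords = tw.frames[:, idx, :]
    dev = coords - coords.mean(axis=0)
    vals = np.sqrt((dev**2).sum(axis=2).mean(axis=0))
    return RMSFProfile(
        residue_ids=traj.structure.residue_indices[idx],
        rmsf=vals,
        window=(float(tw.times[0]), float(tw.times[-1])),
        n_frames=tw.n_frames,
    )
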