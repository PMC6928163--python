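"""Least-squares rigid superposition and per-residue displacement analysis.

Frames are superimposed by the Kabsch algorithm on a small subset of
low-fluctuation backbone atoms (uniform weights), then all atoms are carried
through the fitted transform.  Displacement of a field-exposed trajectory is
measured per residue as the mean ± SD of one coordinate component relative
to a reference built as the pooled average structure of the field-free
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trajio import Selection, Structure, Trajectory

__all__ = [
    "RigidTransform",
    "DisplacementProfile",
    "DegenerateGeometryError",
    "kabsch_fit",
    "align_trajectory",
    "average_structure",
    "displacement_profile",
]


class DegenerateGeometryError(ValueError):
    """Fewer than 3 fit points, or all fit points (nearly) collinear."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation mapping mobile onto reference
    coordinates: x' = R·x + t (Å).  ``rmsd_fit`` is the residual RMSD over
    the fitted subset."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd_fit: float

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3×3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthogonal within 1e-9")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, coordinates: np.ndarray) -> np.ndarray:
        return np.asarray(coordinates) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation, self.rmsd_fit)


@dataclass(frozen=True)
class DisplacementProfile:
    """Per-residue mean ± SD of one coordinate component relative to a
    reference structure, pooled over frames (population SD, divisor n)."""

    residue_ids: np.ndarray
    component: str
    mean: np.ndarray
    sd: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        if not (len(self.residue_ids) == len(self.mean) == len(self.sd)):
            raise ValueError("residue_ids, mean, sd must have equal length")
        if np.any(self.sd < 0):
            raise ValueError("sd must be non-negative")


_COMPONENTS = {"x": 0, "y": 1, "z": 2}


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Optimal proper rotation + translation superimposing ``mobile`` onto
    ``reference`` (both K×3, K ≥ 3, not collinear) in the least-squares
    sense, with reflection suppressed by the determinant correction."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(
            f"mobile and reference must share a K×3 shape, got "
            f"{mobile.shape} vs {reference.shape}"
        )
    K = mobile.shape[0]
    if K < 3:
        raise DegenerateGeometryError(f"need at least 3 fit points, got {K}")
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    scale = max(np.linalg.norm(mob_c), 1e-300)
    if np.linalg.matrix_rank(mob_c, tol=1e-8 * scale) < 2:
        raise DegenerateGeometryError("fit points are collinear")

    H = mob_c.T @ ref_c  # 3×3 cross-covariance
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = reference.mean(axis=0) - R @ mobile.mean(axis=0)
    resid = mob_c @ R.T - ref_c
    rmsd = float(np.sqrt((resid**2).sum() / K))
    return RigidTransform(R, t, rmsd)


def align_trajectory(
    traj: Trajectory, reference: Structure, fit_selection: Selection
) -> Trajectory:
    """Superimpose every frame onto ``reference`` via its own Kabsch fit on
    ``fit_selection``; the fitted transform is applied to all atoms."""
    fit_selection.validate(traj.structure)
    fit_selection.validate(reference)
    idx = fit_selection.atom_indices
    ref_sub = reference.coordinates[idx]
    out = np.empty_like(traj.frames)
    for i in range(traj.n_frames):
        tf = kabsch_fit(traj.frames[i][idx], ref_sub)
        out[i] = tf.apply(traj.frames[i])
    return traj.with_frames(out)


def average_structure(
    trajs: Sequence[Trajectory], selection: Selection | None = None
) -> Structure:
    """Per-atom arithmetic mean over all frames pooled across trajectories
    (the trajectories must already be aligned to a common reference).

    With ``selection`` the returned Structure is restricted to those atoms.
    """
    trajs = list(trajs)
    if not trajs or sum(t.n_frames for t in trajs) == 0:
        raise ValueError("no frames to average")
    n_atoms = trajs[0].n_atoms
    for t in trajs[1:]:
        if t.n_atoms != n_atoms:
            raise ValueError("trajectories have different atom counts")
    total = np.zeros((n_atoms, 3))
    n = 0
    for t in trajs:
        total += t.frames.sum(axis=0)
        n += t.n_frames
    mean = total / n
    ref = trajs[0].structure.with_coordinates(mean)
    if selection is not None:
        selection.validate(ref)
        ref = ref.subset(selection)
    return ref


def displacement_profile(
    field_trajs: Sequence[Trajectory],
    reference: Structure,
    selection: Selection,
    component: str,
    window: tuple[float, float] | None = None,
) -> DisplacementProfile:
    """Mean ± SD of one coordinate component of selected atoms relative to
    the reference, pooled over all frames in the half-open time window
    across replicates.

    The field trajectories must be aligned with the same fit subset used to
    build the reference; the statistic is then the drift of each residue
    along the stated laboratory axis under the field.
    """
    if component not in _COMPONENTS:
        raise ValueError(f"component must be one of {sorted(_COMPONENTS)}")
    c = _COMPONENTS[component]
    trajs = list(field_trajs)
    if not trajs:
        raise ValueError("no trajectories given")
    selection.validate(reference)
    idx = selection.atom_indices
    ref_comp = reference.coordinates[idx, c]
    deltas = []
    for t in trajs:
        selection.validate(t.structure)
        tw = t.window(*window) if window is not None else t
        deltas.append(tw.frames[:, idx, c] - ref_comp)
    pooled = np.concatenate(deltas, axis=0)  # (n_frames_total, n_sel)
    resids = reference.residue_indices[idx]
    return DisplacementProfile(
        residue_ids=resids,
        component=component,
        mean=pooled.mean(axis=0),
        sd=pooled.std(axis=0),  # population SD: descriptive spread over frames
        n_frames=pooled.shape[0],
    )
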