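"""Essential dynamics: positional covariance, eigendecomposition, and
trajectory projection onto collective modes.

Over M aligned frames and N selected atoms the 3N×3N covariance is

    C_ij = (1/M) Σ_t (x_i(t) − ⟨x_i⟩)(x_j(t) − ⟨x_j⟩),

diagonalised as C = T Λ Tᵀ with eigenpairs sorted by decreasing eigenvalue;
the leading eigenvectors are the dominant collective motions and projecting
centered frames onto them gives the essential-coordinate time series.
The decomposition is dense (3N here is a few hundred at most) and the sign
of each eigenvector is fixed so its largest-magnitude component is
positive, making outputs deterministic; among exactly equal eigenvalues the
order is resolved by the sign-fixed eigenvectors' lexicographic order.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .fluctuations import RMSFProfile
from .trajio import Selection, Trajectory

__all__ = [
    "EDModel",
    "ProjectionSeries",
    "build_covariance",
    "decompose",
    "fit_ed_model",
    "project",
    "cluster_spread",
    "high_fluctuation_residues",
]


@dataclass(frozen=True)
class EDModel:
    """Mean coordinates (3N, Å), eigenvalues (Ų, descending) and the
    orthonormal eigenvector matrix (columns) of the positional covariance."""

    selection: Selection
    mean_coords: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    def __post_init__(self) -> None:
        n3 = len(self.mean_coords)
        if self.eigenvalues.shape != (n3,) or self.eigenvectors.shape != (n3, n3):
            raise ValueError("inconsistent EDModel dimensions")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")
        lam_max = max(self.eigenvalues.max(initial=0.0), 0.0)
        if np.any(self.eigenvalues < -1e-8 * max(lam_max, 1.0)):
            raise ValueError("covariance eigenvalues significantly negative")
        if not np.allclose(
            self.eigenvectors.T @ self.eigenvectors, np.eye(n3), atol=1e-8
        ):
            raise ValueError("eigenvectors not orthonormal within 1e-8")

    def save(self, path: str | os.PathLike) -> None:
        """Serialise to a single JSON file (text; arrays as nested lists)."""
        with open(path, "w") as fh:
            json.dump(
                {
                    "selection": self.selection.atom_indices.tolist(),
                    "mean_coords": self.mean_coords.tolist(),
                    "eigenvalues": self.eigenvalues.tolist(),
                    "eigenvectors": self.eigenvectors.tolist(),
                },
                fh,
            )

    @classmethod
    def load(cls, path: str | os.PathLike) -> "EDModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            Selection(np.array(d["selection"], dtype=int)),
            np.array(d["mean_coords"]),
            np.array(d["eigenvalues"]),
            np.array(d["eigenvectors"]),
        )


@dataclass(frozen=True)
class ProjectionSeries:
    """Per-frame projections (Å) onto the first k modes."""

    times: np.ndarray
    proj: np.ndarray  # M×k
    condition_label: str = ""
    replicate_id: int = 0


def build_covariance(traj: Trajectory, selection: Selection) -> np.ndarray:
    """Mean-centered positional covariance (3N×3N, Ų) of the selected
    atoms over all frames of an aligned trajectory (divisor M)."""
    selection.validate(traj.structure)
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    X = traj.frames[:, selection.atom_indices, :].reshape(traj.n_frames, -1)
    Xc = X - X.mean(axis=0)
    C = (Xc.T @ Xc) / traj.n_frames
    return 0.5 * (C + C.T)  # symmetrise against rounding


def decompose(
    C: np.ndarray,
    selection: Selection | None = None,
    mean_coords: np.ndarray | None = None,
) -> EDModel:
    """Eigendecomposition C = T Λ Tᵀ with deterministic ordering and signs."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("covariance must be square")
    scale = max(np.abs(C).max(), 1.0)
    if np.abs(C - C.T).max() > 1e-8 * scale:
        raise ValueError("covariance not symmetric within 1e-8")
    lam, T = np.linalg.eigh(C)
    order = np.argsort(lam)[::-1]
    lam, T = lam[order], T[:, order]
    # sign fix: largest-|component| entry of each eigenvector made positive
    piv = np.abs(T).argmax(axis=0)
    signs = np.sign(T[piv, np.arange(T.shape[1])])
    signs[signs == 0] = 1.0
    T = T * signs
    # deterministic order among exactly equal eigenvalues
    for start in range(len(lam)):
        stop = start
        while stop + 1 < len(lam) and lam[stop + 1] == lam[start]:
            stop += 1
        if stop > start:
            block = T[:, start : stop + 1]
            lex = np.lexsort(block[::-1])
            T[:, start : stop + 1] = block[:, lex]
    n3 = C.shape[0]
    if selection is None:
        selection = Selection(np.arange(n3 // 3))
    if mean_coords is None:
        mean_coords = np.zeros(n3)
    return EDModel(selection, np.asarray(mean_coords, dtype=float), lam, T)


def fit_ed_model(traj: Trajectory, selection: Selection) -> EDModel:
    """Covariance + decomposition of an aligned (typically joined no-field)
    trajectory; the returned model carries the within-window mean structure
    the projections are centered on."""
    C = build_covariance(traj, selection)
    X = traj.frames[:, selection.atom_indices, :].reshape(traj.n_frames, -1)
    return decompose(C, selection=selection, mean_coords=X.mean(axis=0))


def project(traj: Trajectory, model: EDModel, k: int = 2) -> ProjectionSeries:
    """Project each frame's centered coordinate vector onto the first k
    modes (the trajectory must be superimposed on the model's reference)."""
    n3 = len(model.mean_coords)
    if k < 1 or k > n3:
        raise ValueError(f"k must be in [1, {n3}], got {k}")
    model.selection.validate(traj.structure)
    X = traj.frames[:, model.selection.atom_indices, :].reshape(traj.n_frames, -1)
    P = (X - model.mean_coords) @ model.eigenvectors[:, :k]
    return ProjectionSeries(
        times=traj.times.copy(),
        proj=P,
        condition_label=traj.condition_label,
        replicate_id=traj.replicate_id,
    )


def cluster_spread(series: ProjectionSeries) -> float:
    """Total variance (Ų) of the first-two-mode point cloud: the trace of
    its 2×2 covariance.  A per-condition scalar for comparing how widely
    the essential-coordinate points scatter (e.g. one tight cluster versus
    two separated ones)."""
    if series.proj.shape[1] < 2:
        raise ValueError("cluster_spread needs at least 2 retained modes")
    pts = series.proj[:, :2]
    dev = pts - pts.mean(axis=0)
    return float((dev**2).sum() / len(pts))


def high_fluctuation_residues(
    profile: RMSFProfile, quantile: float = 0.8
) -> np.ndarray:
    """Residue ids whose RMSF exceeds the given quantile — a helper for
    building the 'drop loose ends and unstructured coils' deselection list;
    the cut is the caller's decision, not an automatic filter."""
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    thr = np.quantile(profile.rmsf, quantile)
    return profile.residue_ids[profile.rmsf > thr]
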