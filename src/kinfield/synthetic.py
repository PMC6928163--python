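"""Synthetic two-domain Brownian trajectories with the statistical
structure the analyses assume.

The generator builds a coarse (one pseudo-atom per residue) complex of a
mobile charged "motor" domain docked in +X contact with a positionally
restrained "track" domain whose long axis is Y, then integrates overdamped
(inertia-free) Langevin dynamics on an elastic network:

    dx = (F_elastic + F_restraint + q·E) / γ · dt + sqrt(2 k_B T / γ) dW.

Harmonic springs connect every atom pair within a cutoff of the initial
geometry at its native distance; track atoms are additionally tethered to
their initial positions, mirroring the fixed-track restraint of docked
motor-protein simulations.  A uniform field E exerts qᵢ·E on each charged
pseudo-residue, so the motor drifts and its dipole reorients with the
field — exactly the signals the dipole, displacement, RMSF, essential-
dynamics and contact-surface analyses are built to detect.  Everything is
bit-reproducible for a given seed.

Domain membership is carried in residue names: track residues are ``TRK``,
motor residues ``MTR``; every pseudo-atom is named ``CA``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Sequence

import numpy as np

from .constants import BOLTZMANN_KCALMOL_PER_K, KCALMOL_PER_ANGSTROM_PER_E_MVM
from .energetics import FieldCondition
from .surface import golden_spiral_points
from .trajio import Atom, Selection, Structure, Trajectory

__all__ = [
    "GeneratorSpec",
    "StabilityError",
    "NO_FIELD",
    "standard_conditions",
    "make_toy_complex",
    "motor_selection",
    "track_selection",
    "simulate_trajectory",
    "plant_modes",
    "emulate_study_design",
    "derive_seed",
]

NO_FIELD = FieldCondition("none", np.zeros(3))

#: Laboratory field magnitude of the emulated study design, MV/m.
STUDY_FIELD_MVM = 100.0


class StabilityError(RuntimeError):
    """A displacement exceeded 10 Å in one step; reduce the timestep."""


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for the synthetic generator.

    Defaults mirror the emulated study where it states them: 30 ns runs
    sampled every 20 ps (1,500 frames), track restraint and elastic-network
    springs of 1 kcal mol⁻¹ Å⁻², motor net charge −5 e, 100 MV/m field
    conditions, 300 K.  Sizes, friction and timestep are desk-scale choices
    documented in the methods note.
    """

    n_motor_residues: int = 24
    n_track_residues: int = 36
    motor_net_charge: float = -5.0
    en_cutoff: float = 10.0  # Å
    k_spring: float = 1.0  # kcal/mol/Ų
    k_restraint: float = 1.0  # kcal/mol/Ų
    temperature: float = 300.0  # K
    friction: float = 50.0  # kcal/mol·ps/Ų
    timestep: float = 0.5  # ps
    duration: float = 30_000.0  # ps
    stride: float = 20.0  # ps between written frames
    field: FieldCondition = dc_field(default_factory=lambda: NO_FIELD)
    seed: int = 0
    planted_drift: np.ndarray | None = None  # per-residue offsets, (N,3) Å
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.duration < self.stride:
            raise ValueError("duration must cover at least one stride")
        for name in ("k_spring", "k_restraint"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def standard_conditions(magnitude: float = STUDY_FIELD_MVM) -> list[FieldCondition]:
    """The five study field conditions: none, ±X, ±Y at ``magnitude`` MV/m."""
    return [
        FieldCondition("none", np.zeros(3)),
        FieldCondition("X", np.array([magnitude, 0.0, 0.0])),
        FieldCondition("-X", np.array([-magnitude, 0.0, 0.0])),
        FieldCondition("Y", np.array([0.0, magnitude, 0.0])),
        FieldCondition("-Y", np.array([0.0, -magnitude, 0.0])),
    ]


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

_TRACK_SPACING = 3.8  # Å between adjacent track pseudo-residues
_TRACK_ROWS = 3  # rows of the YZ-plane track patch (non-collinear by design)
_MOTOR_RADIUS = 6.0  # Å, motor globule radius
_MOTOR_CENTER_X = 10.0  # Å, motor center on the track→motor (+X) axis
#: In-plane direction of the motor's built-in dipole (≈20° from +X in XY).
_DIPOLE_DIR = np.array([np.cos(np.radians(20.0)), np.sin(np.radians(20.0)), 0.0])


def make_toy_complex(spec: GeneratorSpec) -> Structure:
    """Deterministic coarse motor-on-track complex.

    Track: a 3-row lattice patch in the YZ plane (long axis Y) centered at
    the origin — a flat wall fragment, deliberately non-collinear so a
    least-squares fit on track atoms pins all rotational degrees of
    freedom.  Motor: a golden-spiral shell of radius 6 Å centered at
    (+10, 0, 0) Å, i.e. docked in +X contact.  Motor charges are ±1 e
    placed by each atom's projection onto an in-plane dipole direction
    (≈20° from +X), with enough extra −1 e sites to reach the configured
    net charge, so the resting dipole points near +X with a small +Y
    component.  Masses are uniform 110 Da, radii uniform 3 Å.
    """
    nm, nt = spec.n_motor_residues, spec.n_track_residues
    if nm < 3 or nt < 3:
        raise ValueError("need at least 3 residues in each domain")
    # track: _TRACK_ROWS rows along Y in the YZ plane, centered at origin
    per_row = int(np.ceil(nt / _TRACK_ROWS))
    row = np.arange(nt) // per_row
    col = np.arange(nt) % per_row
    y = (col - (per_row - 1) / 2.0) * _TRACK_SPACING
    z = (row - (_TRACK_ROWS - 1) / 2.0) * _TRACK_SPACING
    track = np.column_stack([np.zeros(nt), y, z])
    # motor shell
    motor = _MOTOR_RADIUS * golden_spiral_points(nm)
    motor[:, 0] += _MOTOR_CENTER_X

    q_net = spec.motor_net_charge
    s = golden_spiral_points(nm) @ _DIPOLE_DIR  # projection, motor frame
    order = np.argsort(s)
    charges = np.zeros(nm)
    n_pos = max(nm // 3, 1)
    n_neg = n_pos + int(round(-q_net)) if q_net <= 0 else n_pos
    n_pos_eff = n_pos if q_net <= 0 else n_pos + int(round(q_net))
    if n_neg + n_pos_eff > nm:
        raise ValueError("net charge too large for the motor size")
    charges[order[:n_neg]] = -1.0
    charges[order[-n_pos_eff:]] = 1.0

    atoms = []
    for i in range(nt):
        atoms.append(
            Atom(i, "CA", i + 1, "TRK", mass=110.0, charge=0.0, radius=3.0)
        )
    for k in range(nm):
        atoms.append(
            Atom(
                nt + k,
                "CA",
                nt + k + 1,
                "MTR",
                mass=110.0,
                charge=float(charges[k]),
                radius=3.0,
            )
        )
    return Structure(atoms, np.vstack([track, motor]))


def motor_selection(structure: Structure) -> Selection:
    return Selection(
        np.array([a.index for a in structure.atoms if a.residue_name == "MTR"])
    )


def track_selection(structure: Structure) -> Selection:
    return Selection(
        np.array([a.index for a in structure.atoms if a.residue_name == "TRK"])
    )


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def _elastic_pairs(coords: np.ndarray, cutoff: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ii, jj = np.triu_indices(len(coords), k=1)
    d = np.linalg.norm(coords[ii] - coords[jj], axis=1)
    keep = d < cutoff
    return ii[keep], jj[keep], d[keep]


def simulate_trajectory(structure: Structure, spec: GeneratorSpec) -> Trajectory:
    """Euler–Maruyama integration of the overdamped elastic-network model.

    Frames are written every ``spec.stride`` ps at times stride, 2·stride,
    …, duration (so a 30 ns run at 20 ps stride yields 1,500 frames and the
    half-open window [25000, 30000) holds exactly 250 of them).  Track
    atoms (residue name ``TRK``) are tethered to their initial positions.
    Identical seeds give byte-identical trajectories, and the noise stream
    depends only on the seed — not the field — so runs under different
    conditions with the same seed are paired samples.
    """
    x0 = structure.coordinates.copy()
    n = len(x0)
    ii, jj, r0 = _elastic_pairs(x0, spec.en_cutoff)
    is_track = structure.residue_names == "TRK"
    q = structure.charges
    E = spec.field.E_vec
    f_field = q[:, None] * (KCALMOL_PER_ANGSTROM_PER_E_MVM * E)[None, :]

    dt, gamma = spec.timestep, spec.friction
    kBT = BOLTZMANN_KCALMOL_PER_K * spec.temperature
    noise_scale = np.sqrt(2.0 * kBT * dt / gamma)
    steps_per_frame = int(round(spec.stride / dt))
    n_frames = int(round(spec.duration / spec.stride))
    rng = np.random.default_rng(np.uint64(spec.seed))

    x = x0.copy()
    frames = np.empty((n_frames, n, 3))
    times = spec.stride * np.arange(1, n_frames + 1)
    k, kr = spec.k_spring, spec.k_restraint
    for f in range(n_frames):
        for _ in range(steps_per_frame):
            dvec = x[ii] - x[jj]
            r = np.linalg.norm(dvec, axis=1)
            fmag = -k * (r - r0) / np.maximum(r, 1e-12)
            fpair = fmag[:, None] * dvec
            force = np.empty((n, 3))
            for c in range(3):
                force[:, c] = np.bincount(
                    ii, weights=fpair[:, c], minlength=n
                ) - np.bincount(jj, weights=fpair[:, c], minlength=n)
            force[is_track] += -kr * (x[is_track] - x0[is_track])
            force += f_field
            step = force * (dt / gamma) + noise_scale * rng.standard_normal((n, 3))
            if np.abs(step).max() > 10.0:
                raise StabilityError(
                    f"displacement {np.abs(step).max():.1f} Å in one step; "
                    "reduce the timestep or increase friction"
                )
            x = x + step
        frames[f] = x
    if spec.planted_drift is not None:
        drift = np.asarray(spec.planted_drift, dtype=float)
        if drift.shape != (n, 3):
            raise ValueError(f"planted_drift must be {(n, 3)}, got {drift.shape}")
        frames = frames + drift[None, :, :]
    return Trajectory(
        structure,
        frames,
        times,
        condition_label=spec.field.label,
        replicate_id=spec.replicate_id,
    )


def plant_modes(
    traj: Trajectory,
    modes: Sequence[tuple[np.ndarray, float]],
    selection: Selection | None = None,
    seed: int = 0,
) -> Trajectory:
    """Superpose independent Gaussian collective motions onto a trajectory.

    Each mode is (direction, variance): an orthonormal 3K displacement
    pattern over the selected atoms and the variance (Ų) of its Gaussian
    amplitude, drawn independently per frame.  The planted variances are
    what an essential-dynamics analysis of the result should recover on
    top of the trajectory's own background.
    """
    if selection is None:
        selection = Selection.all(traj.structure)
    selection.validate(traj.structure)
    idx = selection.atom_indices
    k3 = 3 * len(idx)
    dirs = []
    for d, var in modes:
        d = np.asarray(d, dtype=float).ravel()
        if d.shape != (k3,):
            raise ValueError(f"mode direction must have length {k3}")
        if var < 0:
            raise ValueError("mode variance must be non-negative")
        dirs.append(d)
    if dirs:
        D = np.column_stack(dirs)
        if not np.allclose(D.T @ D, np.eye(len(dirs)), atol=1e-8):
            raise ValueError("mode directions must be orthonormal")
    rng = np.random.default_rng(np.uint64(seed))
    frames = traj.frames.copy()
    for d, (_, var) in zip(dirs, modes):
        if var == 0:
            continue
        amp = rng.normal(0.0, np.sqrt(var), size=traj.n_frames)
        frames[:, idx, :] += amp[:, None, None] * d.reshape(-1, 3)[None, :, :]
    return traj.with_frames(frames)


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------

_MASK64 = (1 << 64) - 1


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (z ^ (z >> 31)) & _MASK64


def derive_seed(master_seed: int, condition_label: str, replicate: int) -> int:
    """Per-run seed: splitmix64 chain over the master seed, the condition
    label's bytes, and the replicate number (documented so independent
    implementations can match fixtures only by matching this)."""
    h = _splitmix64(master_seed & _MASK64)
    for b in condition_label.encode("utf-8"):
        h = _splitmix64(h ^ b)
    return _splitmix64(h ^ (replicate & _MASK64))


def emulate_study_design(
    template: GeneratorSpec,
    conditions: Sequence[FieldCondition] | None = None,
    n_replicates: int = 3,
    structure: Structure | None = None,
) -> list[Trajectory]:
    """The full study layout: ``n_replicates`` runs for each field
    condition (default: none, X, −X, Y, −Y at 100 MV/m — 15 trajectories),
    all from one shared structure, with per-run seeds derived from the
    template's seed."""
    if conditions is None:
        conditions = standard_conditions()
    if structure is None:
        structure = make_toy_complex(template)
    out = []
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            spec = replace(
                template,
                field=cond,
                replicate_id=rep,
                seed=derive_seed(template.seed, cond.label, rep),
            )
            out.append(simulate_trajectory(structure, spec))
    return out
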