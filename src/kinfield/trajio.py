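"""Structures, trajectories, selections and tables: the canonical in-memory
model every analysis module consumes.

Coordinates are ångström internally everywhere (GRO nanometres are converted
on read), times are picoseconds, charges elementary charges, radii ångström.
Atom indices are 0-based internally; residue numbers stay as authored in the
source file (typically 1-based) so reports match published residue labels.

Binary trajectory formats (DCD, XTC) are handled by MDAnalysis readers and
writers.  A plain-text fallback format is also supported, one frame per
block::

    t <time_ps>
    x y z          (one line per atom, ångström)

Lines starting with ``#`` are comments.  Charge/radius tables are
whitespace-delimited text keyed by (residue_name, atom_name)::

    # resname atomname value
    LYS NZ  1.0
    *   CA  0.0        ( '*' wildcards the residue name )
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("kinfield")

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "Selection",
    "TrajioError",
    "TrajioParseError",
    "DimensionError",
    "read_structure",
    "write_structure",
    "read_charge_table",
    "read_trajectory",
    "write_trajectory",
    "join_replicates",
    "write_table",
]


class TrajioError(Exception):
    """Base class for structure/trajectory I/O failures."""


class TrajioParseError(TrajioError):
    """A file could not be parsed; the message names file and line."""


class DimensionError(TrajioError):
    """Atom/frame counts of two objects do not agree."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    """One atom: identity plus the per-atom physics the analyses need.

    ``charge`` is in elementary charges, ``mass`` in daltons, ``radius``
    (van der Waals) in ångström.  ``index`` is the 0-based position within
    its Structure; ``residue_index`` is the residue number as authored.
    """

    index: int
    name: str
    residue_index: int
    residue_name: str = "UNK"
    mass: float = 0.0
    charge: float = 0.0
    radius: float = 0.0

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError(f"atom {self.index}: negative mass {self.mass}")
        if self.radius < 0:
            raise ValueError(f"atom {self.index}: negative radius {self.radius}")


class Structure:
    """An ordered set of atoms with one coordinate set (N×3, Å)."""

    def __init__(self, atoms: Sequence[Atom], coordinates: np.ndarray):
        coordinates = np.asarray(coordinates, dtype=float)
        if coordinates.ndim != 2 or coordinates.shape[1] != 3:
            raise DimensionError(
                f"coordinates must be N×3, got shape {coordinates.shape}"
            )
        if len(atoms) != coordinates.shape[0]:
            raise DimensionError(
                f"{len(atoms)} atoms but {coordinates.shape[0]} coordinate rows"
            )
        if not np.all(np.isfinite(coordinates)):
            raise ValueError("non-finite coordinates")
        indices = [a.index for a in atoms]
        if len(set(indices)) != len(indices):
            raise ValueError("duplicate atom indices")
        self.atoms = list(atoms)
        self.coordinates = coordinates

    # -- array views ----------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def names(self) -> np.ndarray:
        return np.array([a.name for a in self.atoms])

    @property
    def residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms], dtype=int)

    @property
    def residue_names(self) -> np.ndarray:
        return np.array([a.residue_name for a in self.atoms])

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def with_coordinates(self, coordinates: np.ndarray) -> "Structure":
        return Structure(self.atoms, coordinates)

    def subset(self, selection: "Selection") -> "Structure":
        idx = selection.atom_indices
        atoms = [replace(self.atoms[i], index=k) for k, i in enumerate(idx)]
        return Structure(atoms, self.coordinates[idx])

    def same_topology(self, other: "Structure") -> bool:
        return self.n_atoms == other.n_atoms and all(
            a.name == b.name and a.residue_index == b.residue_index
            for a, b in zip(self.atoms, other.atoms)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Structure: {self.n_atoms} atoms>"


@dataclass(frozen=True)
class Selection:
    """An ordered, duplicate-free list of 0-based atom indices."""

    atom_indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.atom_indices, dtype=int)
        if idx.ndim != 1:
            raise ValueError("atom_indices must be one-dimensional")
        if len(np.unique(idx)) != len(idx):
            raise ValueError("duplicate indices in selection")
        object.__setattr__(self, "atom_indices", idx)

    def __len__(self) -> int:
        return len(self.atom_indices)

    def validate(self, structure: Structure) -> None:
        idx = self.atom_indices
        if len(idx) and (idx.min() < 0 or idx.max() >= structure.n_atoms):
            raise IndexError(
                f"selection index out of range for {structure.n_atoms}-atom structure"
            )

    @classmethod
    def from_residues(
        cls,
        structure: Structure,
        residue_indices: Iterable[int],
        atom_name: str | None = None,
    ) -> "Selection":
        """Select atoms by residue number, optionally restricted to one
        atom name per residue (e.g. ``"CA"``)."""
        wanted = set(int(r) for r in residue_indices)
        idx = [
            a.index
            for a in structure.atoms
            if a.residue_index in wanted
            and (atom_name is None or a.name == atom_name)
        ]
        return cls(np.array(idx, dtype=int))

    @classmethod
    def from_names(cls, structure: Structure, atom_name: str) -> "Selection":
        idx = [a.index for a in structure.atoms if a.name == atom_name]
        return cls(np.array(idx, dtype=int))

    @classmethod
    def all(cls, structure: Structure) -> "Selection":
        return cls(np.arange(structure.n_atoms))


class Trajectory:
    """Ordered frames (M×N×3 Å) with strictly increasing times (ps).

    ``provenance``, when present, maps each frame to its origin as a list of
    ``(replicate_id, original_frame_index, original_time_ps)`` tuples; it is
    populated by :func:`join_replicates`.
    """

    def __init__(
        self,
        structure: Structure,
        frames: np.ndarray,
        times: np.ndarray,
        condition_label: str = "",
        replicate_id: int = 0,
        provenance: list[tuple[int, int, float]] | None = None,
    ):
        frames = np.asarray(frames, dtype=float)
        times = np.asarray(times, dtype=float)
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise DimensionError(f"frames must be M×N×3, got {frames.shape}")
        if frames.shape[0] < 1:
            raise DimensionError("trajectory must contain at least one frame")
        if frames.shape[1] != structure.n_atoms:
            raise DimensionError(
                f"frames have {frames.shape[1]} atoms but structure has "
                f"{structure.n_atoms}"
            )
        if times.shape != (frames.shape[0],):
            raise DimensionError(
                f"{len(times)} timestamps for {frames.shape[0]} frames"
            )
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        self.structure = structure
        self.frames = frames
        self.times = times
        self.condition_label = condition_label
        self.replicate_id = int(replicate_id)
        self.provenance = provenance

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def window(self, t0: float, t1: float) -> "Trajectory":
        """Frames with time in the half-open interval [t0, t1) ps."""
        mask = (self.times >= t0) & (self.times < t1)
        if not mask.any():
            raise ValueError(f"no frames in window [{t0}, {t1}) ps")
        prov = (
            [p for p, m in zip(self.provenance, mask) if m]
            if self.provenance is not None
            else None
        )
        return Trajectory(
            self.structure,
            self.frames[mask],
            self.times[mask],
            self.condition_label,
            self.replicate_id,
            prov,
        )

    def with_frames(self, frames: np.ndarray) -> "Trajectory":
        return Trajectory(
            self.structure,
            frames,
            self.times,
            self.condition_label,
            self.replicate_id,
            self.provenance,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<Trajectory '{self.condition_label}' rep={self.replicate_id}: "
            f"{self.n_frames} frames × {self.n_atoms} atoms>"
        )


# ---------------------------------------------------------------------------
# charge / radius tables
# ---------------------------------------------------------------------------


def read_charge_table(path: str | os.PathLike) -> dict[tuple[str, str], float]:
    """Parse a whitespace-delimited per-atom value table.

    Columns: residue_name atom_name value.  ``*`` in the residue column
    matches any residue.  Returns a dict keyed by (residue_name, atom_name).
    """
    table: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise TrajioParseError(
                    f"{path}:{lineno}: expected 'resname atomname value', "
                    f"got {len(parts)} fields"
                )
            try:
                value = float(parts[2])
            except ValueError:
                raise TrajioParseError(
                    f"{path}:{lineno}: third field {parts[2]!r} is not a number"
                ) from None
            table[(parts[0], parts[1])] = value
    return table


def _apply_table(
    atoms: list[Atom],
    table: Mapping[tuple[str, str], float],
    attr: str,
    label: str,
) -> list[Atom]:
    """Assign table values onto atoms; unknown table keys are an error,
    atoms missing from the table keep 0 with a logged warning."""
    known = {(a.residue_name, a.name) for a in atoms}
    known_names = {a.name for a in atoms}
    misses = [
        k
        for k in table
        if k not in known and not (k[0] == "*" and k[1] in known_names)
    ]
    if misses:
        shown = ", ".join(f"{r}/{n}" for r, n in misses[:5])
        raise LookupError(
            f"{label} table has {len(misses)} keys matching no atom "
            f"(first: {shown})"
        )
    out = []
    n_missing = 0
    for a in atoms:
        key = (a.residue_name, a.name)
        if key in table:
            out.append(replace(a, **{attr: table[key]}))
        elif ("*", a.name) in table:
            out.append(replace(a, **{attr: table[("*", a.name)]}))
        else:
            n_missing += 1
            out.append(a)
    if n_missing:
        logger.warning(
            "%s table: %d of %d atoms had no entry; %s left at 0",
            label,
            n_missing,
            len(atoms),
            attr,
        )
    return out


# ---------------------------------------------------------------------------
# structure I/O
# ---------------------------------------------------------------------------

_STRUCTURE_FORMATS = {".pdb": "PDB", ".gro": "GRO"}


def read_structure(
    path: str | os.PathLike,
    charge_table: str | os.PathLike | None = None,
    radius_table: str | os.PathLike | None = None,
    fmt: str | None = None,
) -> Structure:
    """Read a PDB or GRO file (format by extension, ``fmt`` overrides).

    Charges and radii default to zero unless tables are given, so purely
    geometric analyses run on bare coordinate files.  GRO nanometre
    coordinates arrive already converted to Å (MDAnalysis convention).
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = _STRUCTURE_FORMATS.get(path.suffix.lower())
        if fmt is None:
            raise TrajioParseError(
                f"{path}: unknown structure extension {path.suffix!r} "
                "(expected .pdb or .gro; pass fmt= to override)"
            )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=fmt)
    except Exception as exc:  # MDAnalysis raises assorted types
        raise TrajioParseError(f"{path}: cannot parse as {fmt}: {exc}") from exc

    ag = u.atoms
    try:
        masses = ag.masses
    except (AttributeError, mda.exceptions.NoDataError):
        masses = np.zeros(len(ag))
    masses = np.where(np.isfinite(masses) & (masses > 0), masses, 0.0)
    resnames = (
        ag.resnames
        if hasattr(ag, "resnames")
        else np.array(["UNK"] * len(ag))
    )
    atoms = [
        Atom(
            index=i,
            name=str(ag.names[i]),
            residue_index=int(ag.resids[i]),
            residue_name=str(resnames[i]),
            mass=float(masses[i]),
        )
        for i in range(len(ag))
    ]
    if charge_table is not None:
        atoms = _apply_table(atoms, read_charge_table(charge_table), "charge", "charge")
    if radius_table is not None:
        atoms = _apply_table(atoms, read_charge_table(radius_table), "radius", "radius")
    return Structure(atoms, ag.positions.astype(float))


def write_structure(structure: Structure, path: str | os.PathLike) -> None:
    """Write a Structure as PDB (coordinates in Å, residue numbers as held)."""
    import MDAnalysis as mda

    resids_per_atom = structure.residue_indices
    uniq, resindex = np.unique(resids_per_atom, return_inverse=True)
    u = mda.Universe.empty(
        structure.n_atoms,
        n_residues=len(uniq),
        atom_resindex=resindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", structure.names)
    resname_by_resid = {}
    for a in structure.atoms:
        resname_by_resid.setdefault(a.residue_index, a.residue_name)
    u.add_TopologyAttr("resnames", [resname_by_resid[r] for r in uniq])
    u.add_TopologyAttr("resids", uniq)
    u.atoms.positions = structure.coordinates
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

_TRAJ_BINARY = {".dcd": "DCD", ".xtc": "XTC"}
_TRAJ_TEXT = {".trj", ".txt", ".traj"}


def _read_text_trajectory(path: Path) -> tuple[np.ndarray, np.ndarray]:
    frames: list[np.ndarray] = []
    times: list[float] = []
    current: list[list[float]] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("t "):
                if current is not None and frames and len(current) != len(frames[0]):
                    raise TrajioParseError(
                        f"{path}:{lineno}: frame has {len(current)} atom lines, "
                        f"expected {len(frames[0])}"
                    )
                if current is not None:
                    frames.append(np.array(current))
                try:
                    times.append(float(line.split()[1]))
                except (IndexError, ValueError):
                    raise TrajioParseError(
                        f"{path}:{lineno}: malformed time line {line!r}"
                    ) from None
                current = []
            else:
                if current is None:
                    raise TrajioParseError(
                        f"{path}:{lineno}: coordinate line before any 't' line"
                    )
                parts = line.split()
                if len(parts) != 3:
                    raise TrajioParseError(
                        f"{path}:{lineno}: expected 'x y z', got {len(parts)} fields"
                    )
                try:
                    current.append([float(v) for v in parts])
                except ValueError:
                    raise TrajioParseError(
                        f"{path}:{lineno}: non-numeric coordinate in {line!r}"
                    ) from None
    if current is not None:
        if frames and len(current) != len(frames[0]):
            raise TrajioParseError(
                f"{path}: final frame has {len(current)} atom lines, "
                f"expected {len(frames[0])}"
            )
        frames.append(np.array(current))
    if not frames:
        raise TrajioParseError(f"{path}: no frames found")
    return np.stack(frames), np.array(times)


def read_trajectory(
    path: str | os.PathLike,
    structure: Structure,
    fmt: str | None = None,
    dt: float | None = None,
    t0: float = 0.0,
    condition_label: str = "",
    replicate_id: int = 0,
) -> Trajectory:
    """Read DCD, XTC or the plain-text fallback into a Trajectory.

    When the file carries no usable timestamps (common for DCD) pass ``dt``
    (ps per frame) to impose a uniform stride starting at ``t0``.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise TrajioParseError(f"{path}: file is empty")
    suffix = path.suffix.lower()
    if fmt is None:
        fmt = _TRAJ_BINARY.get(suffix, "TEXT" if suffix in _TRAJ_TEXT else None)
        if fmt is None:
            raise TrajioParseError(
                f"{path}: unknown trajectory extension {path.suffix!r}"
            )

    if fmt == "TEXT":
        frames, times = _read_text_trajectory(path)
    else:
        reader_cls = {
            "DCD": mda.coordinates.DCD.DCDReader,
            "XTC": mda.coordinates.XTC.XTCReader,
        }[fmt]
        frames_l, times_l = [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with reader_cls(str(path)) as reader:
                if reader.n_atoms != structure.n_atoms:
                    raise DimensionError(
                        f"{path}: trajectory has {reader.n_atoms} atoms but "
                        f"structure has {structure.n_atoms}"
                    )
                for ts in reader:
                    frames_l.append(ts.positions.astype(float).copy())
                    times_l.append(float(ts.time))
        frames = np.stack(frames_l)
        times = np.array(times_l)

    if frames.shape[1] != structure.n_atoms:
        raise DimensionError(
            f"{path}: trajectory has {frames.shape[1]} atoms but structure "
            f"has {structure.n_atoms}"
        )
    if dt is not None:
        times = t0 + dt * np.arange(len(frames))
    elif len(times) > 1 and not np.all(np.diff(times) > 0):
        logger.warning(
            "%s: file timestamps not strictly increasing; imposing 1 ps stride",
            path,
        )
        times = t0 + np.arange(len(frames), dtype=float)
    return Trajectory(structure, frames, times, condition_label, replicate_id)


def write_trajectory(traj: Trajectory, path: str | os.PathLike, fmt: str | None = None) -> None:
    """Write a Trajectory as DCD, XTC, or the plain-text fallback.

    The binary dialects store the frame stride but not an absolute time
    origin, so a round trip preserves coordinates and stride while the
    first frame reads back at t = 0 (use ``read_trajectory(..., dt=, t0=)``
    to re-base).  The plain-text format preserves times exactly.
    """
    import MDAnalysis as mda

    path = Path(path)
    suffix = path.suffix.lower()
    if fmt is None:
        fmt = _TRAJ_BINARY.get(suffix, "TEXT" if suffix in _TRAJ_TEXT else None)
        if fmt is None:
            raise TrajioParseError(f"{path}: unknown trajectory extension")
    if fmt == "TEXT":
        with open(path, "w") as fh:
            fh.write("# kinfield plain-text trajectory: 't <ps>' then x y z per atom (Å)\n")
            for i in range(traj.n_frames):
                fh.write(f"t {traj.times[i]:.6f}\n")
                for x, y, z in traj.frames[i]:
                    fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
        return
    writer_cls = {
        "DCD": mda.coordinates.DCD.DCDWriter,
        "XTC": mda.coordinates.XTC.XTCWriter,
    }[fmt]
    dts = np.diff(traj.times)
    dt = float(dts[0]) if len(dts) else 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # MDAnalysis writers take an AtomGroup; a bare empty Universe
        # carries the per-frame positions and timestamps.
        u = mda.Universe.empty(traj.n_atoms, trajectory=True)
        with writer_cls(str(path), n_atoms=traj.n_atoms, dt=dt) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.frames[i]
                u.trajectory.ts.frame = i
                u.trajectory.ts.time = traj.times[i]
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# replicate joining and tables
# ---------------------------------------------------------------------------


def join_replicates(trajs: Sequence[Trajectory]) -> Trajectory:
    """Concatenate replicate trajectories of one condition into one long
    trajectory (e.g. three 1,500-frame runs into 4,500 frames).

    Times are re-based to stay strictly increasing across the join; the
    provenance map records (replicate_id, original frame, original time)
    for every output frame.
    """
    if not trajs:
        raise ValueError("no trajectories to join")
    first = trajs[0]
    for t in trajs[1:]:
        if t.n_atoms != first.n_atoms or not t.structure.same_topology(first.structure):
            raise DimensionError(
                f"cannot join: atom counts/topologies differ "
                f"({t.n_atoms} vs {first.n_atoms})"
            )
        if t.condition_label != first.condition_label:
            raise ValueError(
                f"cannot join different conditions "
                f"{t.condition_label!r} vs {first.condition_label!r}"
            )
    if len(trajs) == 1:
        prov = [
            (first.replicate_id, i, float(first.times[i]))
            for i in range(first.n_frames)
        ]
        return Trajectory(
            first.structure,
            first.frames.copy(),
            first.times.copy(),
            first.condition_label,
            first.replicate_id,
            prov,
        )
    frames = np.concatenate([t.frames for t in trajs], axis=0)
    times_out: list[float] = []
    prov = []
    offset = 0.0
    for t in trajs:
        local = t.times - t.times[0]
        stride = float(np.median(np.diff(t.times))) if t.n_frames > 1 else 1.0
        for i in range(t.n_frames):
            times_out.append(offset + local[i])
            prov.append((t.replicate_id, i, float(t.times[i])))
        offset = times_out[-1] + stride
    return Trajectory(
        first.structure,
        frames,
        np.array(times_out),
        first.condition_label,
        first.replicate_id,
        prov,
    )


def write_table(rows, path: str | os.PathLike) -> None:
    """Write tabular results as CSV (UTF-8, '.' decimal, header row,
    deterministic column order)."""
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if not rows:
            raise ValueError("no rows to write")
        df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no rows to write")
    df.to_csv(path, index=False, encoding="utf-8")
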