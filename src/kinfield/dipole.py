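"""Dipole-moment dynamics: per-frame dipole vector from partial charges,
magnitude and signed azimuth time series, and window statistics.

The dipole of a selection is p = Σᵢ qᵢ (rᵢ − O) with charges in elementary
charges, positions in Å, converted to debye.  For a net-charged selection p
depends on the origin O, so the origin mode is explicit: the default is the
selection's center of mass, recomputed each frame.

The azimuth is the signed angle of the dipole's in-plane projection,
measured in the XY plane from +X toward +Y by default, range (−180°, 180°].
Window averages of the azimuth use the circular (vector) mean with the SD
of wrapped deviations, so angles straddling ±180° average correctly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import DEBYE_PER_E_ANGSTROM
from .trajio import Selection, Trajectory

logger = logging.getLogger("kinfield")

__all__ = [
    "DipoleSeries",
    "WindowStats",
    "dipole_moment",
    "azimuth",
    "dipole_series",
    "window_stats",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class DipoleSeries:
    """Per-frame dipole vectors (debye) with magnitude and azimuth series."""

    times: np.ndarray
    p_vec: np.ndarray  # M×3, debye
    magnitude: np.ndarray  # M, debye
    azimuth: np.ndarray  # M, degrees in (−180, 180]; NaN if in-plane part is 0
    condition_label: str = ""
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if not np.allclose(
            self.magnitude, np.linalg.norm(self.p_vec, axis=1), rtol=1e-12, atol=1e-12
        ):
            raise ValueError("magnitude must equal |p_vec| per frame")


@dataclass(frozen=True)
class WindowStats:
    """Pooled window statistics of a dipole series set: plain mean ± SD of
    the magnitude, circular mean ± SD of the azimuth."""

    magnitude_mean: float
    magnitude_sd: float
    azimuth_mean: float
    azimuth_sd: float
    n_frames: int
    condition_label: str = ""


def dipole_moment(
    coordinates: np.ndarray, charges: np.ndarray, origin: np.ndarray
) -> np.ndarray:
    """Dipole vector in debye: Σ qᵢ(rᵢ − origin) · C, C = 4.80321 D/(e·Å)."""
    coordinates = np.asarray(coordinates, dtype=float)
    charges = np.asarray(charges, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if coordinates.shape != (len(charges), 3):
        raise ValueError(
            f"{coordinates.shape} coordinates vs {len(charges)} charges"
        )
    return DEBYE_PER_E_ANGSTROM * ((coordinates - origin) * charges[:, None]).sum(axis=0)


def azimuth(
    vector: np.ndarray, plane: str = "xy", zero_axis: str = "x"
) -> float:
    """Signed angle (degrees, (−180, 180]) of the projection of ``vector``
    onto ``plane``, measured from ``zero_axis`` toward the plane's second
    axis.  Raises on a zero in-plane projection (angle undefined)."""
    a = _azimuth_arr(np.asarray(vector, dtype=float)[None, :], plane, zero_axis)[0]
    if np.isnan(a):
        raise ValueError("azimuth undefined: zero in-plane projection")
    return float(a)


def _azimuth_arr(vectors: np.ndarray, plane: str, zero_axis: str) -> np.ndarray:
    if len(plane) != 2 or any(c not in _AXES for c in plane) or plane[0] == plane[1]:
        raise ValueError(f"plane must be two distinct axes, got {plane!r}")
    if zero_axis not in plane:
        raise ValueError(f"zero_axis {zero_axis!r} not in plane {plane!r}")
    i = _AXES[zero_axis]
    other = plane[0] if plane[1] == zero_axis else plane[1]
    j = _AXES[other]
    u, v = vectors[:, i], vectors[:, j]
    ang = np.degrees(np.arctan2(v, u))
    ang[(u == 0) & (v == 0)] = np.nan
    # atan2 yields [−180, 180]; fold −180 to +180 for the (−180, 180] range
    ang[ang == -180.0] = 180.0
    return ang


def dipole_series(
    traj: Trajectory,
    selection: Selection | None = None,
    origin_mode: str = "center_of_mass",
    origin_point: np.ndarray | None = None,
    plane: str = "xy",
    zero_axis: str = "x",
) -> DipoleSeries:
    """Per-frame dipole of the selected atoms along the trajectory.

    ``origin_mode`` is one of ``center_of_mass`` (default; recomputed per
    frame), ``center_of_geometry`` or ``fixed`` (requires ``origin_point``).
    The origin choice matters whenever the selection carries net charge.
    """
    if selection is None:
        selection = Selection.all(traj.structure)
    selection.validate(traj.structure)
    idx = selection.atom_indices
    q = traj.structure.charges[idx]
    if np.all(q == 0):
        logger.warning("dipole_series: all selected charges are zero")
    coords = traj.frames[:, idx, :]  # M×K×3
    if origin_mode == "center_of_mass":
        m = traj.structure.masses[idx]
        if m.sum() <= 0:
            raise ValueError("center_of_mass origin needs positive masses")
        origins = (coords * m[None, :, None]).sum(axis=1) / m.sum()
    elif origin_mode == "center_of_geometry":
        origins = coords.mean(axis=1)
    elif origin_mode == "fixed":
        if origin_point is None:
            raise ValueError("origin_mode='fixed' requires origin_point")
        origins = np.broadcast_to(
            np.asarray(origin_point, dtype=float), (traj.n_frames, 3)
        )
    else:
        raise ValueError(f"unknown origin_mode {origin_mode!r}")
    rel = coords - origins[:, None, :]
    p = DEBYE_PER_E_ANGSTROM * (rel * q[None, :, None]).sum(axis=1)
    return DipoleSeries(
        times=traj.times.copy(),
        p_vec=p,
        magnitude=np.linalg.norm(p, axis=1),
        azimuth=_azimuth_arr(p, plane, zero_axis),
        condition_label=traj.condition_label,
        replicate_id=traj.replicate_id,
    )


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    """Direction of the vector mean of unit vectors at the given angles."""
    rad = np.radians(np.asarray(angles_deg, dtype=float))
    s, c = np.sin(rad).mean(), np.cos(rad).mean()
    if s == 0 and c == 0:
        raise ValueError("circular mean undefined: resultant is zero")
    ang = float(np.degrees(np.arctan2(s, c)))
    return 180.0 if ang == -180.0 else ang


def _wrap_deg(angles: np.ndarray) -> np.ndarray:
    """Wrap to (−180, 180]."""
    out = (np.asarray(angles, dtype=float) + 180.0) % 360.0 - 180.0
    out[out == -180.0] = 180.0
    return out


def window_stats(
    series: Sequence[DipoleSeries], window: tuple[float, float] | None = None
) -> WindowStats:
    """Magnitude and azimuth statistics pooled across replicate series over
    a half-open time window [t0, t1) ps.

    The azimuth mean is circular (vector mean) and its SD is the standard
    deviation of deviations wrapped to (−180, 180] about that mean, which
    degenerates to the arithmetic mean ± SD for narrow angle ranges.
    """
    series = list(series)
    if not series:
        raise ValueError("no series given")
    labels = {s.condition_label for s in series}
    if len(labels) > 1:
        raise ValueError(f"series mix conditions: {sorted(labels)}")
    mags, azis = [], []
    for s in series:
        if window is None:
            mask = np.ones(len(s.times), dtype=bool)
        else:
            mask = (s.times >= window[0]) & (s.times < window[1])
        mags.append(s.magnitude[mask])
        azis.append(s.azimuth[mask])
    mag = np.concatenate(mags)
    azi = np.concatenate(azis)
    if mag.size == 0:
        raise ValueError(f"no frames in window {window}")
    azi = azi[~np.isnan(azi)]
    if azi.size:
        a_mean = circular_mean_deg(azi)
        a_sd = float(np.sqrt(np.mean(_wrap_deg(azi - a_mean) ** 2)))
    else:
        a_mean, a_sd = float("nan"), float("nan")
    return WindowStats(
        magnitude_mean=float(mag.mean()),
        magnitude_sd=float(mag.std()),
        azimuth_mean=a_mean,
        azimuth_sd=a_sd,
        n_frames=int(mag.size),
        condition_label=series[0].condition_label,
    )
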