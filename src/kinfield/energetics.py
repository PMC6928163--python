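"""Field–protein energetics: net charge, the linear Coulomb force on it,
and the dipole–field interaction energy.

For a protein of net charge q in a uniform field E the linear force is
F = q·E (reported in pN); the dipole–field interaction energy is U = p·E
(reported in joules and in units of kT at a stated temperature, default
296 K).  All conversions go through the CODATA constants in
:mod:`kinfield.constants`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    BOLTZMANN_J_PER_K,
    DEBYE_CM,
    PN_PER_E_MVM,
    ROOM_TEMPERATURE_K,
)

__all__ = [
    "FieldCondition",
    "EnergeticsReport",
    "net_charge",
    "coulomb_force",
    "dipole_field_energy",
    "energetics_report",
]


@dataclass(frozen=True)
class FieldCondition:
    """A labelled uniform electric field, MV/m."""

    label: str
    E_vec: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.E_vec, dtype=float)
        if v.shape != (3,):
            raise ValueError("E_vec must be a 3-vector")
        object.__setattr__(self, "E_vec", v)

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.E_vec))


@dataclass(frozen=True)
class EnergeticsReport:
    q_net: float  # e
    force_pN: np.ndarray  # 3-vector
    force_magnitude_pN: float
    U_joule: float
    U_kT: float
    temperature: float  # K

    def as_dict(self) -> dict:
        return {
            "q_net_e": self.q_net,
            "force_pN": list(self.force_pN),
            "force_magnitude_pN": self.force_magnitude_pN,
            "U_joule": self.U_joule,
            "U_kT": self.U_kT,
            "temperature_K": self.temperature,
        }


def net_charge(charges) -> float:
    """Arithmetic sum of partial charges, elementary charges."""
    return float(np.sum(np.asarray(charges, dtype=float)))


def coulomb_force(q: float, E_vec) -> np.ndarray:
    """F = q·E in pN for q in e and E in MV/m
    (1 e · 1 MV/m = 0.160218 pN)."""
    return q * PN_PER_E_MVM * np.asarray(E_vec, dtype=float)


def dipole_field_energy(
    p, E_vec, temperature: float = ROOM_TEMPERATURE_K
) -> tuple[float, float]:
    """U = p·E for p in debye and E in MV/m, returned as (joules, kT).

    ``p`` may be a 3-vector or a scalar magnitude; a scalar is treated as
    parallel to E (the maximal-coupling orientation).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    E = np.asarray(E_vec, dtype=float)
    p_arr = np.asarray(p, dtype=float)
    if p_arr.ndim == 0:
        U = float(p_arr) * DEBYE_CM * np.linalg.norm(E) * 1e6
    else:
        U = float(np.dot(p_arr * DEBYE_CM, E * 1e6))
    return U, U / (BOLTZMANN_J_PER_K * temperature)


def energetics_report(
    charges,
    p_debye,
    condition: FieldCondition,
    temperature: float = ROOM_TEMPERATURE_K,
) -> EnergeticsReport:
    """Combined charge/force/energy summary for one field condition."""
    q = net_charge(charges)
    F = coulomb_force(q, condition.E_vec)
    U, U_kT = dipole_field_energy(p_debye, condition.E_vec, temperature)
    return EnergeticsReport(
        q_net=q,
        force_pN=F,
        force_magnitude_pN=float(np.linalg.norm(F)),
        U_joule=U,
        U_kT=U_kT,
        temperature=temperature,
    )
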