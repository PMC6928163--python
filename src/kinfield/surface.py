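"""Solvent-accessible surface area (SASA) by deterministic sphere-point
sampling and the contact-surface-area statistic for a two-domain complex.

Each atom's accessible area is the fraction of a fixed golden-spiral point
set on its probe-expanded sphere (radius rᵢ + probe) lying outside every
other expanded sphere, times 4π(rᵢ + probe)².  The point set is
deterministic — no RNG — so results are bit-reproducible at a fixed point
count.  Contact surface area between disjoint selections A and B is

    CSA = ½ (SASA(A alone) + SASA(B alone) − SASA(A ∪ B)),

the buried interface area, reported in nm².  Absolute values depend on the
atomic radii table supplied by the caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .constants import A2_PER_NM2
from .trajio import Selection, Trajectory

logger = logging.getLogger("kinfield")

__all__ = [
    "SASAResult",
    "CSASeries",
    "golden_spiral_points",
    "sasa",
    "contact_surface_area",
    "csa_series",
    "DEFAULT_PROBE_A",
    "DEFAULT_N_POINTS",
]

#: Solvent probe radius, Å (0.14 nm water probe).
DEFAULT_PROBE_A = 1.4
#: Sphere sample points per atom.
DEFAULT_N_POINTS = 960


@dataclass(frozen=True)
class SASAResult:
    per_atom: np.ndarray  # Ų, aligned with the input atoms
    total: float  # nm²
    probe_radius: float  # nm
    n_points: int

    def __post_init__(self) -> None:
        if np.any(self.per_atom < 0):
            raise ValueError("per-atom SASA must be non-negative")


@dataclass(frozen=True)
class CSASeries:
    """Per-frame contact surface area with 5-ns-style block statistics."""

    times: np.ndarray
    csa: np.ndarray  # nm² per frame
    block_edges: np.ndarray  # (n_blocks, 2) ps
    block_means: np.ndarray
    block_sds: np.ndarray
    n_per_block: np.ndarray
    condition_label: str = ""


def golden_spiral_points(n: int) -> np.ndarray:
    """n approximately uniform unit vectors via the golden-angle spiral."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(1.0 - z * z)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _accessible_fractions(
    coords: np.ndarray,
    expanded: np.ndarray,
    points: np.ndarray,
    neighbors: list[np.ndarray],
) -> np.ndarray:
    n = len(coords)
    frac = np.empty(n)
    for i in range(n):
        nb = neighbors[i]
        if len(nb) == 0:
            frac[i] = 1.0
            continue
        pts = coords[i] + expanded[i] * points  # (P, 3)
        d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
        buried = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
        frac[i] = 1.0 - buried.mean()
    return frac


def _neighbor_lists(
    coords: np.ndarray, expanded: np.ndarray, all_pairs: bool = False
) -> list[np.ndarray]:
    """Indices of atoms whose expanded spheres can bury points of atom i.

    The default uses a KD-tree on the maximal interaction distance and is
    contractually identical to the brute-force all-pairs loop (tested)."""
    n = len(coords)
    rmax = expanded.max()
    if all_pairs or n < 8:
        out = []
        for i in range(n):
            d = np.linalg.norm(coords - coords[i], axis=1)
            mask = (d < expanded[i] + expanded) & (np.arange(n) != i)
            out.append(np.nonzero(mask)[0])
        return out
    tree = cKDTree(coords)
    cand = tree.query_ball_tree(tree, 2.0 * rmax)
    out = []
    for i in range(n):
        nb = np.array([j for j in cand[i] if j != i], dtype=int)
        if len(nb):
            d = np.linalg.norm(coords[nb] - coords[i], axis=1)
            nb = nb[d < expanded[i] + expanded[nb]]
        out.append(nb)
    return out


def sasa(
    coordinates: np.ndarray,
    radii: np.ndarray,
    probe: float = DEFAULT_PROBE_A,
    n_points: int = DEFAULT_N_POINTS,
    all_pairs: bool = False,
) -> SASAResult:
    """Shrake–Rupley-style SASA.  Inputs in Å; per-atom areas in Ų, total
    in nm².  Atoms with zero radius are excluded (their area is 0) with a
    warning, so geometry-only structures fail loudly rather than silently
    contributing point spheres."""
    coordinates = np.asarray(coordinates, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coordinates.shape != (len(radii), 3):
        raise ValueError("coordinates and radii lengths differ")
    if n_points < 32:
        raise ValueError("n_points < 32 is below the accuracy floor")
    if np.any(radii < 0):
        raise ValueError("negative radii")
    include = radii > 0
    if not include.all():
        logger.warning(
            "sasa: excluding %d zero-radius atoms", int((~include).sum())
        )
    # exactly coincident spheres (same center and radius) are duplicates:
    # only the first copy carries area, so a union with a coincident copy
    # has the surface counted once
    keyed: dict[tuple, int] = {}
    for i in np.nonzero(include)[0]:
        key = (*coordinates[i], radii[i])
        if key in keyed:
            include[i] = False
        else:
            keyed[key] = i
    per_atom = np.zeros(len(radii))
    if include.any():
        coords = coordinates[include]
        expanded = radii[include] + probe
        pts = golden_spiral_points(n_points)
        nb = _neighbor_lists(coords, expanded, all_pairs=all_pairs)
        frac = _accessible_fractions(coords, expanded, pts, nb)
        per_atom[include] = frac * 4.0 * np.pi * expanded**2
    return SASAResult(
        per_atom=per_atom,
        total=float(per_atom.sum() / A2_PER_NM2),
        probe_radius=probe / 10.0,
        n_points=n_points,
    )


def contact_surface_area(
    coordinates: np.ndarray,
    radii: np.ndarray,
    selA: Selection,
    selB: Selection,
    probe: float = DEFAULT_PROBE_A,
    n_points: int = DEFAULT_N_POINTS,
) -> float:
    """Buried interface area between two disjoint selections, nm²:
    ½(SASA(A) + SASA(B) − SASA(A∪B)), all terms with the same probe and
    point set."""
    ia, ib = selA.atom_indices, selB.atom_indices
    if np.intersect1d(ia, ib).size:
        raise ValueError("selections A and B overlap")
    coordinates = np.asarray(coordinates, dtype=float)
    radii = np.asarray(radii, dtype=float)
    sA = sasa(coordinates[ia], radii[ia], probe, n_points).total
    sB = sasa(coordinates[ib], radii[ib], probe, n_points).total
    iab = np.concatenate([ia, ib])
    sAB = sasa(coordinates[iab], radii[iab], probe, n_points).total
    return 0.5 * (sA + sB - sAB)


def csa_series(
    traj: Trajectory | Sequence[Trajectory],
    selA: Selection,
    selB: Selection,
    probe: float = DEFAULT_PROBE_A,
    n_points: int = DEFAULT_N_POINTS,
    block: float = 5000.0,
) -> CSASeries:
    """Per-frame contact surface area with block statistics.

    A single trajectory gives per-block mean ± SD over its own frames; a
    list of replicates pools frames block-by-block across replicates
    (blocks are defined on each replicate's own time axis, so three 30-ns
    runs at 20 ps stride give 750 values per 5-ns block).  A trailing
    partial block is dropped with a warning.
    """
    trajs = [traj] if isinstance(traj, Trajectory) else list(traj)
    if not trajs:
        raise ValueError("no trajectories given")
    for t in trajs:
        selA.validate(t.structure)
        selB.validate(t.structure)
    radii = trajs[0].structure.radii
    all_times, all_csa = [], []
    for t in trajs:
        vals = np.array(
            [
                contact_surface_area(f, radii, selA, selB, probe, n_points)
                for f in t.frames
            ]
        )
        all_times.append(t.times)
        all_csa.append(vals)

    # end-anchored half-open blocks (t0, t1]: frames written at stride
    # multiples s, 2s, …, T then fill each block exactly (e.g. 250 frames
    # per 5-ns block at 20 ps stride); a leading partial block is dropped
    t_end = min(t.times[-1] for t in trajs)
    t_start = min(t.times[0] for t in trajs)
    ref = trajs[0].times
    stride = float(np.median(np.diff(ref))) if len(ref) > 1 else 0.0
    span = t_end - t_start + stride
    n_blocks = int(span / block + 1e-9)
    if n_blocks * block < span - 1e-6:
        logger.warning(
            "csa_series: %.0f ps span not a whole number of %.0f ps blocks; "
            "partial block dropped",
            span,
            block,
        )
    edges = np.array(
        [
            (t_end - (n_blocks - k) * block, t_end - (n_blocks - k - 1) * block)
            for k in range(n_blocks)
        ]
    ).reshape(-1, 2)
    means, sds, counts = [], [], []
    for t0, t1 in edges:
        pooled = np.concatenate(
            [
                c[(tt > t0) & (tt <= t1)]
                for tt, c in zip(all_times, all_csa)
            ]
        )
        means.append(pooled.mean() if pooled.size else np.nan)
        sds.append(pooled.std() if pooled.size else np.nan)
        counts.append(pooled.size)
    return CSASeries(
        times=np.concatenate(all_times),
        csa=np.concatenate(all_csa),
        block_edges=edges,
        block_means=np.array(means),
        block_sds=np.array(sds),
        n_per_block=np.array(counts, dtype=int),
        condition_label=trajs[0].condition_label,
    )
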