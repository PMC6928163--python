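"""Full-study orchestration: simulate (or load) the five-condition
replicate design, superimpose, and run every analysis stage to CSV/JSON
with a manifest, deterministically for a fixed config + seed.

Configuration is a flat ``key = value`` text file (``#`` comments).  Two
modes:

* ``mode = synthetic`` (default) — generate the study with
  :func:`kinfield.synthetic.emulate_study_design`; generator keys
  (``n_motor_residues``, ``duration``, ``stride``, ``temperature``, …)
  override the defaults.
* ``mode = files`` — load ``structure`` (PDB/GRO) with optional
  ``charge_table``/``radius_table`` and trajectories given as
  ``trajectory.<condition>.<replicate> = path`` keys.

Stages: dipole series + window statistics, RMSF, per-residue displacement
(field conditions vs the pooled no-field reference), essential-dynamics
fit/projection/spread, contact-surface-area series + blocks, and the
energetics report.  A stage failure writes a ``<stage>.FAILED`` marker and
the pipeline continues; numeric outputs go only to files, never stdout.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import align_trajectory, average_structure, displacement_profile
from .dipole import dipole_series, window_stats
from .energetics import FieldCondition, energetics_report
from .essential_dynamics import cluster_spread, fit_ed_model, project
from .fluctuations import rmsf
from .synthetic import (
    GeneratorSpec,
    emulate_study_design,
    make_toy_complex,
    motor_selection,
    standard_conditions,
    track_selection,
)
from .trajio import Selection, Structure, Trajectory, read_structure, read_trajectory, write_table

logger = logging.getLogger("kinfield")

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline"]

_GENERATOR_KEYS = {
    "n_motor_residues": int,
    "n_track_residues": int,
    "motor_net_charge": float,
    "en_cutoff": float,
    "k_spring": float,
    "k_restraint": float,
    "temperature": float,
    "friction": float,
    "timestep": float,
    "duration": float,
    "stride": float,
}


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists every problem found."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass
class RunConfig:
    mode: str = "synthetic"
    seed: int = 0
    out_dir: Path = Path("kinfield_out")
    structure_path: Path | None = None
    charge_table: Path | None = None
    radius_table: Path | None = None
    trajectory_paths: dict[tuple[str, int], Path] = field(default_factory=dict)
    generator: dict = field(default_factory=dict)
    field_magnitude: float = 100.0  # MV/m
    n_replicates: int = 3
    rmsf_window: tuple[float, float] = (10_000.0, 30_000.0)
    displacement_window: tuple[float, float] = (25_000.0, 30_000.0)
    origin_mode: str = "center_of_mass"
    azimuth_plane: str = "xy"
    azimuth_zero: str = "x"
    probe: float = 1.4  # Å
    n_points: int = 240
    block: float = 5000.0  # ps
    csa_frame_stride: int = 5
    ed_modes: int = 2
    report_temperature: float = 296.0


def _parse_window(text: str) -> tuple[float, float]:
    t0, t1 = text.split(":")
    return float(t0), float(t1)


def validate_config(path) -> RunConfig:
    """Parse and validate a flat config file, collecting all errors before
    raising (unknown keys warn, they do not fail)."""
    path = Path(path)
    errors: list[str] = []
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    kv: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                errors.append(f"line {lineno}: expected 'key = value'")
                continue
            k, v = (s.strip() for s in line.split("=", 1))
            kv[k] = v

    cfg = RunConfig()
    simple = {
        "mode": str,
        "seed": int,
        "field_magnitude": float,
        "n_replicates": int,
        "origin_mode": str,
        "azimuth_plane": str,
        "azimuth_zero": str,
        "probe": float,
        "n_points": int,
        "block": float,
        "csa_frame_stride": int,
        "ed_modes": int,
        "report_temperature": float,
    }
    attr_of = {
        "mode": "mode", "seed": "seed", "field_magnitude": "field_magnitude",
        "n_replicates": "n_replicates", "origin_mode": "origin_mode",
        "azimuth_plane": "azimuth_plane", "azimuth_zero": "azimuth_zero",
        "probe": "probe", "n_points": "n_points", "block": "block",
        "csa_frame_stride": "csa_frame_stride", "ed_modes": "ed_modes",
        "report_temperature": "report_temperature",
    }
    for key, value in kv.items():
        try:
            if key in simple:
                setattr(cfg, attr_of[key], simple[key](value))
            elif key == "out":
                cfg.out_dir = Path(value)
            elif key == "structure":
                cfg.structure_path = Path(value)
            elif key == "charge_table":
                cfg.charge_table = Path(value)
            elif key == "radius_table":
                cfg.radius_table = Path(value)
            elif key == "rmsf_window":
                cfg.rmsf_window = _parse_window(value)
            elif key == "displacement_window":
                cfg.displacement_window = _parse_window(value)
            elif key in _GENERATOR_KEYS:
                cfg.generator[key] = _GENERATOR_KEYS[key](value)
            elif key.startswith("trajectory."):
                _, cond, rep = key.split(".")
                cfg.trajectory_paths[(cond, int(rep))] = Path(value)
            else:
                logger.warning("config: unknown key %r ignored", key)
        except (ValueError, TypeError) as exc:
            errors.append(f"key {key!r}: {exc}")

    if cfg.mode not in ("synthetic", "files"):
        errors.append(f"mode must be 'synthetic' or 'files', got {cfg.mode!r}")
    if cfg.mode == "files":
        if cfg.structure_path is None:
            errors.append("files mode requires 'structure ='")
        elif not cfg.structure_path.exists():
            errors.append(f"structure file not found: {cfg.structure_path}")
        if not cfg.trajectory_paths:
            errors.append("files mode requires at least one 'trajectory.<cond>.<rep> ='")
        for key, p in cfg.trajectory_paths.items():
            if not p.exists():
                errors.append(f"trajectory {key} file not found: {p}")
        for name in ("charge_table", "radius_table"):
            p = getattr(cfg, name)
            if p is not None and not p.exists():
                errors.append(f"{name} not found: {p}")
    for name in ("rmsf_window", "displacement_window"):
        w = getattr(cfg, name)
        if w[1] <= w[0]:
            errors.append(f"{name}: empty window {w}")
    if errors:
        raise ConfigError(errors)
    return cfg


def _config_hash(cfg: RunConfig) -> str:
    payload = {}
    for f in dc_fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, Path):
            v = str(v)
        elif isinstance(v, dict):
            v = {str(k): str(val) for k, val in sorted(v.items(), key=lambda kv: str(kv[0]))}
        payload[f.name] = v
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _load_study(cfg: RunConfig) -> tuple[Structure, list[Trajectory], bool]:
    """Returns (structure, trajectories, charges_available)."""
    if cfg.mode == "synthetic":
        spec = GeneratorSpec(seed=cfg.seed, **cfg.generator)
        structure = make_toy_complex(spec)
        trajs = emulate_study_design(
            spec,
            conditions=standard_conditions(cfg.field_magnitude),
            n_replicates=cfg.n_replicates,
            structure=structure,
        )
        return structure, trajs, True
    structure = read_structure(
        cfg.structure_path,
        charge_table=cfg.charge_table,
        radius_table=cfg.radius_table,
    )
    trajs = [
        read_trajectory(p, structure, condition_label=cond, replicate_id=rep)
        for (cond, rep), p in sorted(cfg.trajectory_paths.items(), key=lambda kv: (kv[0][0], kv[0][1]))
    ]
    return structure, trajs, cfg.charge_table is not None


def _join(trajs: list[Trajectory]):
    from .trajio import join_replicates

    return join_replicates(trajs)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns a manifest dict (also written as
    ``manifest.json``) listing outputs, seeds and failures."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    manifest: dict = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "outputs": [],
        "failed_stages": [],
    }

    def _run_stage(name: str, fn) -> None:
        try:
            fn()
        except Exception:
            logger.error("stage %s failed:\n%s", name, traceback.format_exc())
            (out / f"{name}.FAILED").write_text(traceback.format_exc())
            manifest["failed_stages"].append(name)

    def _emit(df: pd.DataFrame, name: str) -> None:
        write_table(df, out / name)
        manifest["outputs"].append(name)

    try:
        structure, trajs, have_charges = _load_study(config)
        conditions = sorted({t.condition_label for t in trajs})
        by_cond = {c: [t for t in trajs if t.condition_label == c] for c in conditions}
        no_field = by_cond.get("none", [])

        # --- superposition --------------------------------------------
        fit_sel = track_selection(structure)
        if len(fit_sel) < 3:
            fit_sel = Selection.all(structure)
        aligned = {
            c: [align_trajectory(t, structure, fit_sel) for t in ts]
            for c, ts in by_cond.items()
        }
        if no_field:
            reference = average_structure(aligned["none"])
            manifest["reference_frames"] = int(
                sum(t.n_frames for t in aligned["none"])
            )
            aligned = {
                c: [align_trajectory(t, reference, fit_sel) for t in ts]
                for c, ts in aligned.items()
            }
        else:
            reference = structure

        motor_sel = motor_selection(structure)
        if len(motor_sel) == 0:
            motor_sel = Selection.all(structure)
        track_sel = fit_sel

        # --- dipole ----------------------------------------------------
        def stage_dipole():
            if not have_charges or np.all(structure.charges == 0):
                logger.warning("dipole stage skipped: no charges available")
                manifest["skipped_dipole"] = True
                return
            stats_rows = []
            for c in conditions:
                for t in aligned[c]:
                    ds = dipole_series(
                        t, motor_sel, origin_mode=config.origin_mode,
                        plane=config.azimuth_plane, zero_axis=config.azimuth_zero,
                    )
                    _emit(
                        pd.DataFrame(
                            {
                                "time_ps": ds.times,
                                "px_D": ds.p_vec[:, 0],
                                "py_D": ds.p_vec[:, 1],
                                "pz_D": ds.p_vec[:, 2],
                                "magnitude_D": ds.magnitude,
                                "azimuth_deg": ds.azimuth,
                            }
                        ),
                        f"dipole_{c}_rep{t.replicate_id}.csv",
                    )
                all_ds = [
                    dipole_series(
                        t, motor_sel, origin_mode=config.origin_mode,
                        plane=config.azimuth_plane, zero_axis=config.azimuth_zero,
                    )
                    for t in aligned[c]
                ]
                ws = window_stats(all_ds, config.displacement_window)
                stats_rows.append(
                    {
                        "condition": c,
                        "magnitude_mean_D": ws.magnitude_mean,
                        "magnitude_sd_D": ws.magnitude_sd,
                        "azimuth_mean_deg": ws.azimuth_mean,
                        "azimuth_sd_deg": ws.azimuth_sd,
                        "n_frames": ws.n_frames,
                    }
                )
            _emit(pd.DataFrame(stats_rows), "dipole_window_stats.csv")

        # --- RMSF ------------------------------------------------------
        def stage_rmsf():
            sel = Selection.all(structure)
            for c in conditions:
                # window each replicate on its own clock, then pool frames
                windowed = [t.window(*config.rmsf_window) for t in aligned[c]]
                prof = rmsf(_join(windowed), sel, window=None)
                _emit(
                    pd.DataFrame(
                        {"residue_id": prof.residue_ids, "rmsf_A": prof.rmsf}
                    ),
                    f"rmsf_{c}.csv",
                )

        # --- displacement ---------------------------------------------
        def stage_displacement():
            if not no_field:
                logger.warning("displacement stage skipped: no no-field reference")
                return
            sel = Selection.all(structure)
            for c in conditions:
                if c == "none":
                    continue
                comp = "y" if "Y" in c.upper() else "x"
                prof = displacement_profile(
                    aligned[c], reference, sel, comp, config.displacement_window
                )
                _emit(
                    pd.DataFrame(
                        {
                            "residue_id": prof.residue_ids,
                            "component": prof.component,
                            "mean_A": prof.mean,
                            "sd_A": prof.sd,
                            "n_frames": prof.n_frames,
                        }
                    ),
                    f"displacement_{c}.csv",
                )

        # --- essential dynamics ---------------------------------------
        def stage_ed():
            if not no_field:
                logger.warning("ED stage skipped: no no-field training set")
                return
            model = fit_ed_model(_join(aligned["none"]), motor_sel)
            model.save(out / "ed_model.json")
            manifest["outputs"].append("ed_model.json")
            rows = []
            for c in conditions:
                ps = project(_join(aligned[c]), model, k=config.ed_modes)
                _emit(
                    pd.DataFrame(
                        {
                            "time_ps": ps.times,
                            **{
                                f"pc{k + 1}_A": ps.proj[:, k]
                                for k in range(ps.proj.shape[1])
                            },
                        }
                    ),
                    f"ed_projection_{c}.csv",
                )
                rows.append({"condition": c, "spread_A2": cluster_spread(ps)})
            _emit(pd.DataFrame(rows), "ed_spread.csv")

        # --- contact surface area -------------------------------------
        def stage_csa():
            from .surface import csa_series

            if np.all(structure.radii == 0):
                logger.warning("CSA stage skipped: no atomic radii available")
                return
            for c in conditions:
                sub = [
                    Trajectory(
                        t.structure,
                        t.frames[:: config.csa_frame_stride],
                        t.times[:: config.csa_frame_stride],
                        t.condition_label,
                        t.replicate_id,
                    )
                    for t in aligned[c]
                ]
                cs = csa_series(
                    sub, motor_sel, track_sel,
                    probe=config.probe, n_points=config.n_points,
                    block=config.block,
                )
                _emit(
                    pd.DataFrame({"time_ps": cs.times, "csa_nm2": cs.csa}),
                    f"csa_{c}.csv",
                )
                _emit(
                    pd.DataFrame(
                        {
                            "t0_ps": cs.block_edges[:, 0],
                            "t1_ps": cs.block_edges[:, 1],
                            "mean_nm2": cs.block_means,
                            "sd_nm2": cs.block_sds,
                            "n": cs.n_per_block,
                        }
                    ),
                    f"csa_blocks_{c}.csv",
                )

        # --- energetics ------------------------------------------------
        def stage_energetics():
            if not have_charges or np.all(structure.charges == 0):
                logger.warning("energetics stage skipped: no charges available")
                manifest["skipped_energetics"] = True
                return
            q = structure.charges[motor_sel.atom_indices]
            reports = {}
            for cond in standard_conditions(config.field_magnitude):
                ds = [
                    dipole_series(t, motor_sel, origin_mode=config.origin_mode)
                    for t in aligned.get(cond.label, aligned[conditions[0]])
                ]
                ws = window_stats(ds, config.displacement_window)
                rep = energetics_report(
                    q, ws.magnitude_mean, cond, config.report_temperature
                )
                reports[cond.label] = rep.as_dict() | {
                    "dipole_magnitude_window_mean_D": ws.magnitude_mean
                }
            with open(out / "energetics.json", "w") as fh:
                json.dump(reports, fh, indent=2, sort_keys=True)
            manifest["outputs"].append("energetics.json")

        _run_stage("dipole", stage_dipole)
        _run_stage("rmsf", stage_rmsf)
        _run_stage("displacement", stage_displacement)
        _run_stage("essential_dynamics", stage_ed)
        _run_stage("csa", stage_csa)
        _run_stage("energetics", stage_energetics)
    finally:
        logger.removeHandler(handler)
        handler.close()

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
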