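"""End-to-end comparative analysis over multiple trajectory systems.

A run config names a set of systems (trajectory + starting conformation +
variant), one domain definition, and a closed and an open reference
structure.  The pipeline computes, per system: whole-protein and per-domain
RMSD, the equilibration point (all later statistics use production frames
only), RMSF, radius of gyration, inter-domain distance and hinge angle, the
delta-RMSD progress variable with a state call, the persistence-filtered
protein structure network, and the domain I–III interaction table; then,
across systems: hub reports at each degree threshold, per-variant
open-vs-closed degree changes, and a comparison summary.

The pipeline is a pure function of (config, input files): repeated runs
produce byte-identical outputs.  A failing stage is recorded in the report
and does not abort independent stages.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conformational_similarity as sim
from . import domain_geometry as geom
from . import psn as psn_mod
from . import trajectory_metrics as tm
from .errors import ConfigError, HingemdError
from .structure_io import (
    DomainSet,
    Trajectory,
    read_multimodel_pdb,
    read_structure,
    select,
    write_metric_series,
    write_residue_profile,
)

__all__ = ["SystemSpec", "RunConfig", "run_pipeline", "compare_systems"]

SCHEMA_VERSION = 1


@dataclass
class SystemSpec:
    name: str
    trajectory: Path
    conformation: str  # "closed" or "open" (starting conformation label)
    variant: str = "WT"
    topology: Path | None = None

    def __post_init__(self) -> None:
        if self.conformation not in ("closed", "open"):
            raise ConfigError(
                f"system {self.name!r}: conformation must be closed/open"
            )
        self.trajectory = Path(self.trajectory)


@dataclass
class RunConfig:
    systems: list
    domains: Path
    ref_closed: Path
    ref_open: Path
    output_dir: Path
    dt_ns: float = 0.1
    threshold_frac: float = 0.2
    k_min: tuple = (4, 6)
    equil_window: int | None = None
    equil_slope_tol: float = 0.02
    psn_mode: str = "residue_center"
    psn_cutoffs: dict | None = None
    p_crit_override: dict | float | None = None
    interdomain_pair: tuple = ("I", "III")
    seed: int = 0  # reserved for subsampling; current stages are deterministic

    def __post_init__(self) -> None:
        names = [s.name for s in self.systems]
        if len(set(names)) != len(names):
            raise ConfigError("system names must be unique")
        for attr in ("domains", "ref_closed", "ref_open", "output_dir"):
            setattr(self, attr, Path(getattr(self, attr)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        systems = [
            SystemSpec(
                name=s["name"],
                trajectory=resolve(s["trajectory"]),
                conformation=s["conformation"],
                variant=s.get("variant", "WT"),
                topology=resolve(s["topology"]) if s.get("topology") else None,
            )
            for s in raw["systems"]
        ]
        kwargs = {}
        for key in ("dt_ns", "threshold_frac", "equil_window",
                    "equil_slope_tol", "psn_mode", "psn_cutoffs",
                    "p_crit_override", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "k_min" in raw:
            kwargs["k_min"] = tuple(raw["k_min"])
        if "interdomain_pair" in raw:
            kwargs["interdomain_pair"] = tuple(raw["interdomain_pair"])
        return cls(
            systems=systems,
            domains=resolve(raw["domains"]),
            ref_closed=resolve(raw["ref_closed"]),
            ref_open=resolve(raw["ref_open"]),
            output_dir=resolve(raw["output_dir"]),
            **kwargs,
        )


def _interaction_params(config: RunConfig) -> psn_mod.InteractionParams:
    kwargs = {"mode": config.psn_mode}
    if config.psn_cutoffs:
        cutoffs = dict(psn_mod.InteractionParams().cutoffs)
        cutoffs.update(config.psn_cutoffs)
        kwargs["cutoffs"] = cutoffs
    return psn_mod.InteractionParams(**kwargs)


def _production_stats(values: np.ndarray, start: int) -> dict:
    v = values[start:]
    return {"mean": float(np.mean(v)), "sd": float(np.std(v)),
            "n_frames": int(len(v))}


def _analyze_system(spec: SystemSpec, config: RunConfig, domains: DomainSet,
                    ref_closed, ref_open, out_dir: Path) -> tuple[dict, dict]:
    """Run every per-system stage; returns (report entry, artifacts)."""
    entry: dict = {"name": spec.name, "conformation": spec.conformation,
                   "variant": spec.variant, "errors": [], "stages": {}}
    artifacts: dict = {}
    out_dir.mkdir(parents=True, exist_ok=True)

    if not spec.trajectory.exists():
        raise ConfigError(
            f"system {spec.name!r}: trajectory file not found: "
            f"{spec.trajectory}"
        )
    traj = read_multimodel_pdb(spec.trajectory, dt_ns=config.dt_ns)
    ca = select(traj, "CA", domains)

    def stage(name, fn):
        try:
            fn()
            entry["stages"][name] = "ok"
        except HingemdError as exc:
            entry["errors"].append({"stage": name, "error": str(exc)})
            entry["stages"][name] = "failed"

    # --- whole-protein RMSD and equilibration ---------------------------
    production = {"start": 0, "t_eq_ns": None}

    def _rmsd_stage():
        series = tm.rmsd_series(traj, None, fit_indices=ca,
                                selection_label="CA")
        write_metric_series(series, out_dir / "rmsd.csv")
        t_eq = tm.estimate_equilibration(series, window=config.equil_window,
                                         slope_tol=config.equil_slope_tol)
        production["t_eq_ns"] = t_eq
        production["start"] = tm.production_start_index(series, t_eq)
        entry["equilibration"] = {
            "t_eq_ns": t_eq,
            "equilibrated": t_eq is not None,
            "production_start_frame": production["start"],
        }
        artifacts["rmsd"] = series

    stage("rmsd", _rmsd_stage)
    start = production["start"]

    def _domain_rmsd_stage():
        per_dom = tm.per_domain_rmsd(traj, None, domains)
        for name, series in per_dom.items():
            write_metric_series(series, out_dir / f"rmsd_domain_{name}.csv")
        artifacts["rmsd_domains"] = per_dom

    stage("rmsd_domains", _domain_rmsd_stage)

    def _rmsf_stage():
        prod = Trajectory(traj.topology, traj.frames[start:],
                          times=traj.times[start:]) if start else traj
        profile = tm.rmsf_profile(prod, domains=domains)
        write_residue_profile(profile, out_dir / "rmsf.csv")
        artifacts["rmsf"] = profile

    stage("rmsf", _rmsf_stage)

    def _rg_stage():
        series = geom.radius_of_gyration(traj)
        write_metric_series(series, out_dir / "rg.csv")
        entry["rg"] = _production_stats(series.values, start)
        artifacts["rg"] = series

    stage("rg", _rg_stage)

    def _geometry_stage():
        a, b = config.interdomain_pair
        com = geom.domain_centers(traj, domains, flavor="com")
        cog = geom.domain_centers(traj, domains, flavor="cog")
        dist = geom.interdomain_distance(com, a, b)
        angle = geom.hinge_angle(cog, "I", "II", "III")
        write_metric_series(dist, out_dir / f"dist_{a}_{b}.csv")
        write_metric_series(angle, out_dir / "angle_I_II_III.csv")
        entry["distance"] = _production_stats(dist.values, start)
        entry["angle"] = _production_stats(angle.values, start)
        artifacts["distance"] = dist
        artifacts["angle"] = angle

    stage("geometry", _geometry_stage)

    def _delta_stage():
        series = sim.delta_rmsd(traj, ref_closed, ref_open, indices=ca)
        df = pd.DataFrame({
            "time_ns": series.times,
            "sigma_closed_A": series.sigma_closed,
            "sigma_open_A": series.sigma_open,
            "delta_A": series.delta,
        })
        df.to_csv(out_dir / "delta_rmsd.csv", index=False,
                  float_format="%.10g")
        call = sim.classify_state(series, config.threshold_frac, start)
        transition = sim.detect_transition(
            series, baseline_frames=max(2, min(50, len(series) // 4)))
        entry["delta_rmsd"] = {
            "ref_separation_A": series.ref_separation,
            **{f"{k}_frac": v for k, v in call.fractions.items()},
            "state_call": call.system_label,
            "transition_frame": transition,
            "production_mean": float(np.mean(series.delta[start:])),
            "production_sd": float(np.std(series.delta[start:])),
        }
        artifacts["delta"] = series
        artifacts["state_call"] = call

    stage("delta_rmsd", _delta_stage)

    def _psn_stage():
        params = _interaction_params(config)
        records = {
            cls: psn_mod.interaction_persistence(
                traj, cls, params, production_start=start,
                offset=domains.offset)
            for cls in psn_mod.CLASSES
        }
        if config.p_crit_override is not None:
            p_crit = config.p_crit_override
        else:
            p_crit = psn_mod.persistence_threshold(records["HC"])
        seq_residues = sorted(set(
            traj.topology.residue_numbers.astype(int) - domains.offset))
        graph = psn_mod.build_psn(records, p_crit, nodes=seq_residues)
        graph.to_edge_dataframe().to_csv(out_dir / "psn_edges.csv",
                                         index=False, float_format="%.10g")
        graph.write_graphml(out_dir / "psn.graphml")
        a, b = config.interdomain_pair
        all_records = [r for recs in records.values() for r in recs]
        table = psn_mod.interdomain_table(all_records, p_crit, domains, a, b)
        table.to_csv(out_dir / f"interdomain_{a}_{b}.csv", index=False,
                     float_format="%.10g")
        entry["psn"] = {
            "p_crit": p_crit if isinstance(p_crit, (int, float))
            else dict(p_crit),
            "n_edges": graph.n_edges,
            "n_interdomain": int(len(table)),
        }
        artifacts["psn_graph"] = graph
        artifacts["psn_records"] = records
        artifacts["interdomain"] = table

    stage("psn", _psn_stage)
    return entry, artifacts


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage for every system and write the report bundle.

    Returns the report dict (also written to ``<output_dir>/report.json``).
    """
    domains = DomainSet.from_yaml(config.domains)
    for p in (config.ref_closed, config.ref_open):
        if not Path(p).exists():
            raise ConfigError(f"reference structure not found: {p}")
    ref_closed = read_structure(config.ref_closed)
    ref_open = read_structure(config.ref_open)
    config.output_dir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "parameters": {
            "dt_ns": config.dt_ns,
            "threshold_frac": config.threshold_frac,
            "k_min": list(config.k_min),
            "equil_window": config.equil_window,
            "equil_slope_tol": config.equil_slope_tol,
            "psn_mode": config.psn_mode,
            "ref_closed": str(config.ref_closed),
            "ref_open": str(config.ref_open),
        },
        "systems": {},
    }
    graphs: dict = {}
    for spec in config.systems:
        entry, artifacts = _analyze_system(
            spec, config, domains, ref_closed, ref_open,
            config.output_dir / spec.name)
        report["systems"][spec.name] = entry
        if "psn_graph" in artifacts:
            graphs[spec.name] = artifacts["psn_graph"]

    # --- cross-system: hubs and per-variant degree changes ---------------
    report["hubs"] = {}
    if graphs:
        for k in config.k_min:
            hub_report = psn_mod.find_hubs(graphs, k_min=k)
            hub_report.table.to_csv(config.output_dir / f"hubs_k{k}.csv")
            report["hubs"][f"k>{k}"] = {
                str(res): {s: int(d) for s, d in row.items()}
                for res, row in hub_report.table.iterrows()
            }
    report["delta_degree"] = {}
    by_variant: dict = {}
    for spec in config.systems:
        if spec.name in graphs:
            by_variant.setdefault(spec.variant, {})[spec.conformation] = spec.name
    for variant, confs in sorted(by_variant.items()):
        if "closed" in confs and "open" in confs:
            dd = psn_mod.delta_degree(graphs[confs["open"]],
                                      graphs[confs["closed"]])
            report["delta_degree"][variant] = {
                str(r): int(v) for r, v in sorted(dd.items())
            }

    report["comparison"] = compare_systems(report)

    with open(config.output_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def compare_systems(report: dict) -> dict:
    """Cross-system production-run summary from a pipeline report.

    Tabulates the per-system production means/SDs of the delta-RMSD progress
    variable, Rg, inter-domain distance and hinge angle, and flags systems
    whose mean delta lies in the intermediate band.
    """
    systems = report.get("systems", {})
    if len(systems) < 2:
        raise ConfigError("compare_systems needs at least 2 analyzed systems")
    rows = {}
    flagged = []
    for name, entry in sorted(systems.items()):
        row = {}
        delta = entry.get("delta_rmsd")
        if delta:
            row["delta_mean_A"] = delta["production_mean"]
            row["delta_sd_A"] = delta["production_sd"]
            row["state_call"] = delta["state_call"]
            band = 0.2 * delta["ref_separation_A"]
            if abs(delta["production_mean"]) <= band:
                flagged.append(name)
        for key, label in (("rg", "rg"), ("distance", "distance"),
                           ("angle", "angle")):
            if key in entry:
                row[f"{label}_mean"] = entry[key]["mean"]
                row[f"{label}_sd"] = entry[key]["sd"]
        rows[name] = row
    return {"table": rows, "intermediate_flagged": sorted(flagged)}
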