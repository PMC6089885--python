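"""End-to-end orchestration of the analysis stages from one YAML config.

A run config names one trajectory (topology + optional coordinate file),
a list of monomer channels (each with its own water selection and
channel geometry), the stages to run, a seed, and per-stage parameters.
The pipeline validates the config against an explicit schema (unknown
keys are rejected), runs the requested stages per monomer, assembles a
per-monomer report table plus an unweighted mean row over monomers, and
stamps every output with a hash of the config so results are traceable.

Selections in the config use the in-memory mini-grammar of
:mod:`chanflux.trajectory_model` (``resname``, ``chain``, ``name``,
``heavy``, ...); the trajectory is loaded in full first.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd
import yaml

from . import contacts as contacts_mod
from . import essential_dynamics as ed_mod
from . import permeation as perm_mod
from . import pmf as pmf_mod
from . import pore_radius as pore_mod
from .errors import ChanfluxError, ParameterError
from .trajectory_model import ChannelGeometry, TrajectoryView, define_channel_geometry, load_trajectory

_GEOMETRY_KEYS = {
    "axis_mode", "anchor_selection", "axis", "origin",
    "z_lower", "z_upper", "lateral_cutoff",
}
_MONOMER_KEYS = {"label", "water_selection", "wall_selection", "geometry"}
_TOP_KEYS = {"seed", "output_dir", "stages", "trajectory", "monomers", "params"}
_TRAJ_KEYS = {"topology", "coordinates", "selection"}
_STAGES = ("permeation", "pf", "pmf", "pore", "contacts", "ed")
_PARAM_KEYS = {
    "permeation": set(),
    "pf": {"bin_ps", "v_w"},
    "pmf": {"bin_width", "temperature_K", "frame_stride_ps"},
    "pore": {"z_step", "time_bin_ns", "snapshot_stride_ps", "n_restarts"},
    "contacts": {"monomer_A", "monomer_B", "distance_cutoff", "min_fraction"},
    "ed": {"selection", "n_top"},
}


def _check_keys(d: Dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ParameterError(f"unknown config key(s) {sorted(unknown)} in {where}")


class RunConfig:
    """Validated run configuration."""

    def __init__(self, raw: Dict):
        if not isinstance(raw, dict):
            raise ParameterError("config must be a mapping")
        _check_keys(raw, _TOP_KEYS, "top level")
        self.seed = int(raw.get("seed", 0))
        self.output_dir = Path(raw.get("output_dir", "chanflux_run"))
        self.stages = list(raw.get("stages", []))
        for s in self.stages:
            if s not in _STAGES:
                raise ParameterError(f"unknown stage {s!r}; valid: {_STAGES}")
        if not self.stages:
            raise ParameterError("no stages requested")
        traj = raw.get("trajectory")
        if not isinstance(traj, dict):
            raise ParameterError("config needs a 'trajectory' mapping")
        _check_keys(traj, _TRAJ_KEYS, "trajectory")
        if "topology" not in traj:
            raise ParameterError("trajectory.topology is required")
        self.trajectory = traj
        self.monomers = raw.get("monomers", [])
        if not self.monomers:
            raise ParameterError("at least one monomer entry is required")
        for m in self.monomers:
            _check_keys(m, _MONOMER_KEYS, f"monomer {m.get('label', '?')}")
            _check_keys(m.get("geometry", {}), _GEOMETRY_KEYS, "geometry")
        self.params = raw.get("params", {})
        _check_keys(self.params, set(_PARAM_KEYS), "params")
        for stage, p in self.params.items():
            _check_keys(p, _PARAM_KEYS[stage], f"params.{stage}")
        self.raw = raw

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _resolve_geometry(traj: TrajectoryView, spec: Dict) -> ChannelGeometry:
    spec = dict(spec or {})
    if "anchor_selection" in spec:
        return define_channel_geometry(
            traj,
            spec["anchor_selection"],
            axis_mode=spec.get("axis_mode", "fixed_z"),
            z_lower=float(spec.get("z_lower", -15.0)),
            z_upper=float(spec.get("z_upper", 15.0)),
            lateral_cutoff=float(spec.get("lateral_cutoff", 6.0)),
        )
    return ChannelGeometry(
        axis=tuple(spec.get("axis", (0.0, 0.0, 1.0))),
        origin=tuple(spec.get("origin", (0.0, 0.0, 0.0))),
        z_lower=float(spec.get("z_lower", -15.0)),
        z_upper=float(spec.get("z_upper", 15.0)),
        lateral_cutoff=float(spec.get("lateral_cutoff", 6.0)),
    )


def run_pipeline(config: RunConfig | Dict | str | Path) -> pd.DataFrame:
    """Run all configured stages; return the per-monomer report table.

    Writes ``report.csv``, ``report.json`` and ``run.log`` (plus
    per-stage artifacts) under ``output_dir``.  Raises ChanfluxError
    after logging if any stage failed.
    """
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig(config)
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()

    logger = logging.getLogger(f"chanflux.run.{cfg_hash}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.info("config hash %s; stages %s", cfg_hash, config.stages)

    traj = load_trajectory(
        config.trajectory["topology"],
        config.trajectory.get("coordinates"),
        selection=config.trajectory.get("selection", "all"),
    )
    logger.info("loaded %d atoms x %d frames", traj.n_atoms, traj.n_frames)

    rows: List[Dict] = []
    failed: List[str] = []
    for mon in config.monomers:
        label = mon.get("label", "monomer")
        row: Dict = {"monomer": label, "config_hash": cfg_hash}
        geom = _resolve_geometry(traj, mon.get("geometry"))
        wsel = mon.get("water_selection", "resname HOH")
        for stage in config.stages:
            p = config.params.get(stage, {})
            try:
                if stage == "permeation":
                    traces = perm_mod.extract_axial_traces(traj, geom, wsel)
                    recs, total, up_n, down_n = perm_mod.count_permeation_events(traces)
                    row.update(events_total=total, events_up=up_n, events_down=down_n)
                    pd.DataFrame([r.__dict__ for r in recs]).to_csv(
                        out / f"events_{label}.csv", index=False
                    )
                elif stage == "pf":
                    traces = perm_mod.extract_axial_traces(traj, geom, wsel)
                    series = perm_mod.collective_coordinate(traces, geom)
                    res = perm_mod.osmotic_permeability(
                        series, bin_width_ps=float(p.get("bin_ps", 200.0)),
                        v_w=float(p.get("v_w", perm_mod.V_W_CM3)),
                    )
                    row.update(D_n_per_ns=res.D_n, p_f_1e14_cm3_s=res.p_f)
                elif stage == "pmf":
                    hist = pmf_mod.occupancy_histogram(
                        traj, geom, wsel,
                        bin_width=float(p.get("bin_width", 0.5)),
                        frame_stride_ps=float(p.get("frame_stride_ps", 10.0)),
                    )
                    prof = pmf_mod.pmf_from_occupancy(
                        hist, temperature_K=float(p.get("temperature_K", 310.0))
                    )
                    row.update(pmf_barrier_kJ_mol=prof.barrier_height())
                    pd.DataFrame(
                        {"z_center": prof.z_centers, "G_kJ_per_mol": prof.G,
                         "defined": prof.defined}
                    ).to_csv(out / f"pmf_{label}.csv", index=False)
                elif stage == "pore":
                    wall = mon.get("wall_selection", "heavy")
                    prof2d = pore_mod.temporal_radius_profile(
                        traj, geom, monomers=[wall],
                        snapshot_stride_ps=float(p.get("snapshot_stride_ps", 10.0)),
                        time_bin_ns=float(p.get("time_bin_ns", 2.0)),
                        z_step=float(p.get("z_step", 0.5)),
                        rng_seed=config.seed,
                        n_restarts=int(p.get("n_restarts", 3)),
                    )
                    long = [
                        {"time_bin_ns": prof2d.time_bin_edges[b], "z": z,
                         "radius_A": prof2d.radius[b, k]}
                        for b in range(prof2d.radius.shape[0])
                        for k, z in enumerate(prof2d.z_grid)
                    ]
                    pd.DataFrame(long).to_csv(out / f"pore_{label}.csv", index=False)
                    row.update(min_radius_A=float(np.nanmin(prof2d.radius)))
                elif stage == "contacts":
                    cm = contacts_mod.persistent_contact_map(
                        traj, p["monomer_A"], p["monomer_B"],
                        contacts_mod.ContactCriteria(
                            distance_cutoff=float(p.get("distance_cutoff", 4.0)),
                            min_fraction=float(p.get("min_fraction", 0.70)),
                        ),
                    )
                    cm.to_dataframe().to_csv(out / f"contacts_{label}.csv", index=False)
                    row.update(persistent_contacts=len(cm.persistent_pairs))
                elif stage == "ed":
                    sel = p.get("selection", "name CA")
                    fitted = ed_mod.superpose_trajectory(traj, "mean", sel)
                    modes = ed_mod.covariance_and_modes(fitted, sel)
                    k = min(int(p.get("n_top", 10)), len(modes.eigenvalues))
                    row.update(
                        ed_total_variance_A2=modes.total_variance,
                        ed_top_fraction=ed_mod.cumulative_fluctuation_fraction(modes, k),
                    )
            except ChanfluxError as exc:
                logger.error("stage %s failed for %s: %s", stage, label, exc)
                row[f"{stage}_failed"] = str(exc)
                failed.append(f"{label}/{stage}")
        rows.append(row)
        logger.info("monomer %s done", label)

    report = pd.DataFrame(rows)
    numeric = report.select_dtypes(include=[np.number])
    if len(report) > 1 and not numeric.empty:
        mean_row = {c: numeric[c].mean() for c in numeric.columns}
        mean_row["monomer"] = "mean_over_monomers"
        mean_row["config_hash"] = cfg_hash
        report = pd.concat([report, pd.DataFrame([mean_row])], ignore_index=True)
    report.to_csv(out / "report.csv", index=False)
    report.to_json(out / "report.json", orient="records", indent=2)
    if failed:
        raise ChanfluxError(f"stage failures: {failed} (see {out / 'run.log'})")
    return report
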