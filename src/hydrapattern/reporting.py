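"""Batch runs, manifests, figure panels and configuration plumbing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from hydrapattern import __version__
from hydrapattern.geometry import SurfaceMesh, build_spheroid_mesh, write_vtk
from hydrapattern.model import SPECIES, ModelParameters, get_scenario
from hydrapattern.initial_conditions import InitialConditionSpec
from hydrapattern.simulator import SimulationConfig, SimulationResult, run
from hydrapattern.pattern_analysis import PatternSummary, summarize_state

#: colour assignment used by the figure panels
FIELD_COLORMAPS = {"has": "Blues", "wnt3": "Reds", "tent": "Greens"}

DEFAULT_CONFIG = {
    "mesh": {"subdivision_level": 4, "stretch_factor": 0.0,
             "stretch_mode": "displacement"},
    "parameters": {},
    "initial_conditions": {"noise_low": 0.0, "noise_high": 1.0,
                           "sd_amplitude": 4.0},
    "simulation": {"dt": 1.0, "t_end": 20000.0, "steady_tol": 5e-5,
                   "steady_window": 50.0, "scheme": "imex"},
    "analysis": {"rel_threshold": 0.5, "cv_min": 0.2, "min_area_vertices": 3,
                 "broadened_factor": 2.0},
    "scan": {"mode": "strict"},
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge the packaged defaults with a YAML file and explicit overrides."""
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, entries in user.items():
            config.setdefault(section, {}).update(entries or {})
    for section, entries in (overrides or {}).items():
        config.setdefault(section, {}).update(entries)
    return config


def config_hash(config: dict) -> str:
    """Content hash of a configuration (stable across key order)."""
    blob = json.dumps(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def build_from_config(config: dict):
    """Instantiate (mesh, params, sim_config) from a merged configuration."""
    mesh = build_spheroid_mesh(**config["mesh"])
    params = ModelParameters(**config["parameters"])
    sim = SimulationConfig(**{k: v for k, v in config["simulation"].items()})
    return mesh, params, sim


@dataclass
class RunManifest:
    """Reproducibility record of one simulation run."""

    scenario: str
    seed: int
    parameters: dict
    config_hash: str
    version: str
    started: str
    finished: str
    converged: bool
    steps_taken: int
    phenotype: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def simulate_scenario(name: str, seed: int, config: dict,
                      mesh: SurfaceMesh | None = None
                      ) -> tuple[SimulationResult, PatternSummary, RunManifest]:
    """Run one scenario end to end and summarize the resulting pattern."""
    if mesh is None:
        mesh = build_spheroid_mesh(**config["mesh"])
    params = ModelParameters(**config["parameters"])
    sim = SimulationConfig(**config["simulation"])
    scenario = get_scenario(name, seed=seed)
    ic = InitialConditionSpec(sd_offset=scenario.sd_offset, seed=seed,
                              **config["initial_conditions"])
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    result = run(scenario, sim, mesh, params=params, ic_spec=ic)
    a = config["analysis"]
    summary = summarize_state(result.final_state, mesh,
                              rel_threshold=a["rel_threshold"],
                              cv_min=a["cv_min"],
                              min_area_vertices=a["min_area_vertices"],
                              broadened_factor=a["broadened_factor"])
    manifest = RunManifest(scenario=name, seed=seed,
                           parameters=result.parameters.to_dict(),
                           config_hash=config_hash(config),
                           version=__version__, started=started,
                           finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
                           converged=result.converged,
                           steps_taken=result.steps_taken,
                           phenotype=summary.phenotype)
    return result, summary, manifest


def run_scenario_suite(scenarios: list[str], seeds: list[int], config: dict,
                       out_dir=None, mesh: SurfaceMesh | None = None
                       ) -> pd.DataFrame:
    """One row of pattern readouts per (scenario, seed).

    Individual run failures are recorded in the row (``error`` column) and
    the suite continues.  When ``out_dir`` is given the per-run table and a
    per-scenario phenotype frequency table are written as CSV.
    """
    if mesh is None:
        mesh = build_spheroid_mesh(**config["mesh"])
    rows = []
    for name in scenarios:
        for seed in seeds:
            row = {"scenario": name, "seed": seed,
                   "config_hash": config_hash(config), "error": ""}
            try:
                _, summary, manifest = simulate_scenario(name, seed, config,
                                                         mesh=mesh)
                row.update({
                    "converged": manifest.converged,
                    "steps_taken": manifest.steps_taken,
                    "wnt3_spot_count": summary.wnt3_spot_count,
                    "axis_count": summary.axis_count,
                    "tentacle_spot_count": summary.tentacle_spot_count,
                    "body_tentacle_spot_count":
                        summary.body_tentacle_spot_count,
                    "tentacle_ring_score": summary.tentacle_ring_score,
                    "has_ring_score": summary.has_ring_score,
                    "has_body_level": summary.has_body_level,
                    "wnt3_spot_area": summary.wnt3_spot_area,
                    "wnt3_spot_s3": summary.details.get("wnt3_spot_s3"),
                    "phenotype": summary.phenotype,
                })
            except Exception as exc:  # suite continues past single failures
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "suite.csv", index=False)
        ok = table[table["error"] == ""]
        if len(ok):
            freq = (ok.groupby(["scenario", "phenotype"]).size()
                    .rename("count").reset_index())
            freq.to_csv(out_dir / "phenotype_frequencies.csv", index=False)
    return table


def render_panels(result: SimulationResult, mesh: SurfaceMesh,
                  fields: list[str], out_dir, prefix: str = "panel",
                  dpi: int = 110) -> list[Path]:
    """Render per-field views of the final state plus a composite panel.

    Each field is shown as the deformed surface coloured by concentration
    (HAS blue, Wnt3 red, tentacle activator green); layout and colour limits
    are deterministic functions of the result.
    """
    for f in fields:
        if f not in SPECIES:
            raise KeyError(f"unknown field {f!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    state = result.final_state
    written = []

    def _plot(ax, field_name):
        values = getattr(state, field_name)
        cmap = FIELD_COLORMAPS.get(field_name, "viridis")
        v = mesh.vertices
        order = np.argsort(v[:, 1])  # paint back-to-front for a stable view
        ax.scatter(v[order, 0], v[order, 2], c=values[order], cmap=cmap, s=6,
                   vmin=0.0, vmax=max(values.max(), 1e-12), linewidths=0)
        ax.set_aspect("equal")
        ax.set_axis_off()
        ax.set_title(field_name)

    for field_name in fields:
        fig, ax = plt.subplots(figsize=(2.2, 7))
        _plot(ax, field_name)
        path = out_dir / f"{prefix}_{field_name}.png"
        fig.savefig(path, dpi=dpi, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    fig, axes = plt.subplots(1, len(fields), figsize=(2.2 * len(fields), 7))
    axes = np.atleast_1d(axes)
    for ax, field_name in zip(axes, fields):
        _plot(ax, field_name)
    path = out_dir / f"{prefix}_composite.png"
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    written.append(path)
    return written


def write_result(result: SimulationResult, mesh: SurfaceMesh, out_dir,
                 manifest: RunManifest | None = None) -> None:
    """Write final-state VTK, snapshot series and the JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fields = {name: getattr(result.final_state, name) for name in SPECIES}
    write_vtk(out_dir / "final.vtk", mesh, fields)
    for t, snap in result.snapshots:
        snap_fields = {name: getattr(snap, name) for name in SPECIES}
        write_vtk(out_dir / f"snapshot_t{t:g}.vtk", mesh, snap_fields)
    if manifest is not None:
        (out_dir / "manifest.json").write_text(manifest.to_json() + "\n")
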