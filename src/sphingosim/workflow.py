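"""End-to-end analysis workflow: model → network + quantitative stages → drugs.

:func:`run` executes the requested stages in workflow order on either the
flagship model or a user json-table model, writing CSV/JSON/GraphML
artifacts plus a machine-readable run manifest; :func:`report` condenses a
finished run directory into a one-page markdown summary.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .centrality import centrality_report, model_to_graph, write_graphml
from .dosing import (
    apoptosis_reduction,
    attach_drug,
    builtin_dose_schedule,
    builtin_drug,
    simulate_with_dosing,
)
from .flagship import build_flagship_model, build_toy_model, default_kinetics
from .io import load_model
from .scan import scan_initial_value, scan_parameter, write_scan_csv
from .sensitivity import sensitivity_to_parameters
from .simulate import (
    DEATH_ID,
    SURVIVAL_ID,
    SimulationSettings,
    balance_gap,
    simulate,
    terminal_state,
    write_trajectory_csv,
)

__all__ = ["RunConfig", "run", "report", "STAGES"]

log = logging.getLogger("sphingosim")

STAGES = ("simulate", "scan", "sensitivity", "network", "dose")

DRUGS = ("Etanercept", "Nivocasan", "Scyphostatin")


@dataclass
class RunConfig:
    """Configuration for one workflow run."""

    model_source: str = "flagship"  # "flagship" | "toy" | path to json-table
    kinetics_scheme: str = "adjusted"
    stages: tuple[str, ...] = STAGES
    out_dir: str | Path = "sphingosim_run"
    settings: SimulationSettings = field(default_factory=SimulationSettings)
    scan_parameters: tuple[int, ...] = (1, 8, 12)
    scan_entities: tuple[str, ...] = ("TNFa",)
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        if not self.stages:
            raise ValueError("at least one stage must be requested")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        settings = SimulationSettings(**raw.pop("settings", {}))
        return cls(settings=settings, **raw)


def _load_model(config: RunConfig):
    if config.model_source == "flagship":
        return build_flagship_model(kinetics=default_kinetics(config.kinetics_scheme))
    if config.model_source == "toy":
        return build_toy_model()
    return load_model(config.model_source)


def _has_outcomes(model) -> bool:
    ids = set(model.species_index)
    return SURVIVAL_ID in ids and DEATH_ID in ids


def run(config: RunConfig) -> dict:
    """Execute the requested stages; returns the manifest dictionary."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = _load_model(config)
    manifest: dict = {
        "version": __version__,
        "model": model.name,
        "model_source": str(config.model_source),
        "kinetics_scheme": config.kinetics_scheme,
        "seed": config.seed,
        "stages": list(config.stages),
        "settings": {
            "t_end": config.settings.t_end,
            "output_points": config.settings.output_points,
            "rel_tol": config.settings.rel_tol,
            "abs_tol": config.settings.abs_tol,
        },
        "artifacts": [],
    }

    def artifact(name: str) -> Path:
        manifest["artifacts"].append(name)
        return out / name

    if "simulate" in config.stages:
        log.info("stage simulate: %s", model.name)
        traj = simulate(model, config.settings)
        write_trajectory_csv(traj, artifact("trajectory.csv"))
        summary = {"terminal": terminal_state(traj)}
        if _has_outcomes(model):
            summary["balance_gap"] = balance_gap(traj)
        (out / "simulation_summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True)
        )
        manifest["artifacts"].append("simulation_summary.json")

    if "scan" in config.stages and _has_outcomes(model):
        for idx in config.scan_parameters:
            log.info("stage scan: parameter %d", idx)
            res = scan_parameter(model, idx, settings=config.settings)
            write_scan_csv(res, artifact(f"scan_parameter_{idx}.csv"))
        for sid in config.scan_entities:
            log.info("stage scan: entity %s", sid)
            res = scan_initial_value(model, sid, settings=config.settings)
            write_scan_csv(res, artifact(f"scan_entity_{sid}.csv"))

    if "sensitivity" in config.stages:
        log.info("stage sensitivity")
        matrix = sensitivity_to_parameters(model, config.settings)
        matrix.to_csv(artifact("sensitivity_parameters.csv"))

    if "network" in config.stages:
        log.info("stage network")
        rep = centrality_report(model)
        rep.to_csv(artifact("centrality.csv"))
        write_graphml(
            model_to_graph(model, kind="bipartite"), artifact("network.graphml")
        )

    if "dose" in config.stages and _has_outcomes(model):
        baseline = simulate(model, config.settings)
        dose_rows = []
        for name in DRUGS:
            try:
                drug = builtin_drug(name)
                schedule = builtin_dose_schedule(name, 1)
            except KeyError:
                continue
            if any(t not in model.species_index for t in drug.targets):
                continue
            log.info("stage dose: %s", name)
            dosed_model = attach_drug(model, drug)
            dosed = simulate_with_dosing(dosed_model, drug, schedule, config.settings)
            summary = apoptosis_reduction(dosed, baseline)
            write_trajectory_csv(dosed, artifact(f"dose_{name}.csv"))
            dose_rows.append({"drug": name, **summary})
        if dose_rows:
            (out / "dose_summary.json").write_text(
                json.dumps(dose_rows, indent=1, sort_keys=True)
            )
            manifest["artifacts"].append("dose_summary.json")

    manifest["wall_time_s"] = round(time.time() - t_start, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def report(run_dir: str | Path) -> str:
    """One-page markdown summary of a finished run directory."""
    out = Path(run_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {out}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupted artifact file: {manifest_path}") from exc

    lines = [f"# Run summary: {manifest.get('model', '?')}", ""]
    missing: list[str] = []

    sim = out / "simulation_summary.json"
    if sim.exists():
        try:
            summary = json.loads(sim.read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"corrupted artifact file: {sim}") from exc
        if "balance_gap" in summary:
            lines += [f"- terminal balance gap (survival − death): "
                      f"{summary['balance_gap']:.4g}"]

    cent = out / "centrality.csv"
    if cent.exists():
        import pandas as pd

        table = pd.read_csv(cent, index_col=0)
        top = table.sort_values("betweenness", ascending=False).head(5)
        lines += ["", "## Top-5 betweenness species", ""]
        lines += [f"- {sid}: {row.betweenness:.4f}" for sid, row in top.iterrows()]
    elif "network" in manifest.get("stages", []):
        missing.append("centrality.csv")

    sens = out / "sensitivity_parameters.csv"
    if sens.exists():
        import pandas as pd

        table = pd.read_csv(sens, index_col=0)
        for outcome in (DEATH_ID, SURVIVAL_ID):
            if outcome in table.index:
                row = table.loc[outcome].sort_values(ascending=False).head(5)
                lines += ["", f"## Top-5 parameter sensitivities for {outcome}", ""]
                lines += [f"- reaction {k}: {v:.4g}" for k, v in row.items()]

    dose = out / "dose_summary.json"
    if dose.exists():
        rows = json.loads(dose.read_text())
        lines += ["", "## Drug dosing (repeat-dose regimen 1)", ""]
        lines += [
            f"- {r['drug']}: survival/death fold {r['fold']:.3g}, "
            f"death reduction {100 * r['reduction']:.2f}%"
            for r in rows
        ]

    if missing:
        raise FileNotFoundError(f"run artifacts missing: {missing}")
    return "\n".join(lines) + "\n"
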