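"""Deterministic time-course integration and trajectory summaries.

Models are integrated with a stiff-capable adaptive solver (LSODA) from 0 to
``t_end`` relative time units (RTU) and sampled on an even output grid; the
dense grid (1001 points by default) is what peak detection and terminal
summaries read from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import CompiledRateSystem, PathwayModel, assemble_rate_system

__all__ = [
    "SimulationSettings",
    "Trajectory",
    "SimulationError",
    "simulate",
    "peak",
    "terminal_state",
    "balance_gap",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

SURVIVAL_ID = "CellSurvival"
DEATH_ID = "CellDeath"


class SimulationError(RuntimeError):
    """Integration failure; carries the last time the solver reached."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


@dataclass(frozen=True)
class SimulationSettings:
    """Solver configuration for :func:`simulate`."""

    t_end: float = 100.0
    output_points: int = 1001
    rel_tol: float = 1e-6
    abs_tol: float = 1e-9
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.output_points < 2:
            raise ValueError("output_points must be at least 2")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("solver tolerances must be positive")

    @property
    def time_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.t_end, self.output_points)


@dataclass
class Trajectory:
    """Time-indexed concentrations of all species from one integration run."""

    time_grid: np.ndarray
    values: np.ndarray  # species x time
    species_ids: list[str]
    model_ref: str = "model"
    solver_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.species_ids), len(self.time_grid)):
            raise ValueError("values must be species x time")

    def series(self, species_id: str) -> np.ndarray:
        try:
            i = self.species_ids.index(species_id)
        except ValueError:
            raise KeyError(f"trajectory has no species {species_id!r}") from None
        return self.values[i]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values.T, columns=self.species_ids)
        frame.insert(0, "time", self.time_grid)
        return frame


def simulate(
    model: PathwayModel,
    settings: SimulationSettings | None = None,
    *,
    system: CompiledRateSystem | None = None,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """Integrate a model's mass-action ODEs on the settings' output grid.

    ``system`` and ``x0`` let callers reuse a compiled rate system / supply a
    perturbed initial state without rebuilding the model (used by the scan
    and sensitivity engines).
    """
    settings = settings or SimulationSettings()
    if system is None:
        system = assemble_rate_system(model)
    if x0 is None:
        x0 = model.initial_state()
    grid = settings.time_grid
    sol = solve_ivp(
        system,
        (0.0, settings.t_end),
        np.asarray(x0, dtype=float),
        method=settings.method,
        t_eval=grid,
        rtol=settings.rel_tol,
        atol=settings.abs_tol,
        jac=lambda t, x: system.state_jacobian(x),
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise SimulationError(f"integration failed: {sol.message}", last)
    return Trajectory(
        time_grid=grid,
        values=sol.y,
        species_ids=list(system.species_ids),
        model_ref=model.name,
        solver_meta={
            "method": settings.method,
            "rel_tol": settings.rel_tol,
            "abs_tol": settings.abs_tol,
        },
    )


def peak(traj: Trajectory, species_id: str) -> tuple[float, float]:
    """Global maximum of one species over the grid: (value, earliest time)."""
    series = traj.series(species_id)
    i = int(np.argmax(series))  # argmax returns the earliest maximizer
    return float(series[i]), float(traj.time_grid[i])


def terminal_state(traj: Trajectory) -> dict[str, float]:
    """Concentration of every species at the final grid time."""
    if traj.time_grid.size == 0:
        raise ValueError("empty trajectory")
    return {sid: float(v) for sid, v in zip(traj.species_ids, traj.values[:, -1])}


def balance_gap(traj: Trajectory) -> float:
    """Signed terminal difference CellSurvival - CellDeath.

    A small magnitude relative to CellSurvival indicates the homeostatic
    balanced state between the survival and apoptosis accumulators.
    """
    missing = [s for s in (SURVIVAL_ID, DEATH_ID) if s not in traj.species_ids]
    if missing:
        raise KeyError(f"trajectory lacks outcome species: {missing}")
    return float(traj.series(SURVIVAL_ID)[-1] - traj.series(DEATH_ID)[-1])


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    traj.to_frame().to_csv(path, index=False)


def read_trajectory_csv(path: str | Path, model_ref: str = "model") -> Trajectory:
    frame = pd.read_csv(path)
    if "time" not in frame.columns:
        raise ValueError("trajectory CSV must have a 'time' column")
    species = [c for c in frame.columns if c != "time"]
    return Trajectory(
        time_grid=frame["time"].to_numpy(),
        values=frame[species].to_numpy().T,
        species_ids=species,
        model_ref=model_ref,
    )
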