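"""One-dimensional parameter and entity scans with crossing detection.

A scan varies either one reaction's rate constant (parameter scanning) or
one species' initial amount (entity scanning) over an increasing grid,
integrates the model to ``t_end`` at every grid point, and records the
terminal values of the two outcome accumulators.  The crossing point is the
grid value at which the terminal survival and death curves intersect --
the scanned quantity's balanced-state value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import PathwayModel, assemble_rate_system
from .simulate import (
    DEATH_ID,
    SURVIVAL_ID,
    SimulationSettings,
    simulate,
    terminal_state,
)

__all__ = [
    "ScanResult",
    "scan_parameter",
    "scan_initial_value",
    "crossing_point",
    "fold_difference",
    "write_scan_csv",
    "PARAMETER_GRID",
    "INITIAL_GRID",
]

#: default grids: 21 points over [0, 0.2] for rate constants,
#: 26 points over [0, 50] for initial amounts
PARAMETER_GRID = np.linspace(0.0, 0.2, 21)
INITIAL_GRID = np.linspace(0.0, 50.0, 26)


@dataclass
class ScanResult:
    """Terminal survival/death outcomes across a one-dimensional scan."""

    kind: str  # "parameter" | "initial"
    target: str  # reaction index (as str) or species id
    grid: np.ndarray
    survival_terminal: np.ndarray
    death_terminal: np.ndarray
    crossing: float | None = None
    n_crossings: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.survival_terminal = np.asarray(self.survival_terminal, dtype=float)
        self.death_terminal = np.asarray(self.death_terminal, dtype=float)
        if not (
            len(self.grid)
            == len(self.survival_terminal)
            == len(self.death_terminal)
        ):
            raise ValueError("grid and terminal arrays must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scan_value": self.grid,
                "survival_terminal": self.survival_terminal,
                "death_terminal": self.death_terminal,
            }
        )


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("scan grid needs at least two values")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("scan grid must be strictly increasing")
    if grid[0] < 0:
        raise ValueError("scan grid values must be nonnegative")
    return grid


def _terminal_outcomes(model: PathwayModel, settings: SimulationSettings):
    traj = simulate(model, settings)
    ts = terminal_state(traj)
    return ts[SURVIVAL_ID], ts[DEATH_ID]


def scan_parameter(
    model: PathwayModel,
    reaction_index: int,
    grid: np.ndarray = PARAMETER_GRID,
    settings: SimulationSettings | None = None,
) -> ScanResult:
    """Vary one reaction's rate constant and record terminal outcomes."""
    settings = settings or SimulationSettings()
    model.reaction_by_index(reaction_index)  # existence check
    grid = _check_grid(grid)
    surv, death = [], []
    for value in grid:
        s, d = _terminal_outcomes(
            model.with_rate_constant(reaction_index, value), settings
        )
        surv.append(s)
        death.append(d)
    result = ScanResult(
        "parameter", str(reaction_index), grid, np.array(surv), np.array(death)
    )
    result.crossing = crossing_point(result)
    return result


def scan_initial_value(
    model: PathwayModel,
    species_id: str,
    grid: np.ndarray = INITIAL_GRID,
    settings: SimulationSettings | None = None,
) -> ScanResult:
    """Vary one species' initial amount and record terminal outcomes."""
    settings = settings or SimulationSettings()
    model.species_by_id(species_id)  # existence check
    grid = _check_grid(grid)
    system = assemble_rate_system(model)
    i = model.species_index[species_id]
    x0 = model.initial_state()
    surv, death = [], []
    for value in grid:
        x = x0.copy()
        x[i] = value
        traj = simulate(model, settings, system=system, x0=x)
        ts = terminal_state(traj)
        surv.append(ts[SURVIVAL_ID])
        death.append(ts[DEATH_ID])
    result = ScanResult(
        "initial", species_id, grid, np.array(surv), np.array(death)
    )
    result.crossing = crossing_point(result)
    return result


def crossing_point(scan: ScanResult) -> float | None:
    """First survival/death intersection along the grid, linearly interpolated.

    Scans the sign of (survival - death) between consecutive grid points and
    interpolates the first change; returns None when the curves never cross.
    Multiple crossings raise a warning and only the first is reported.
    """
    diff = scan.survival_terminal - scan.death_terminal
    crossings = []
    for i in range(len(diff) - 1):
        a, b = diff[i], diff[i + 1]
        if a == 0.0:
            crossings.append(float(scan.grid[i]))
        elif a * b < 0:
            frac = a / (a - b)
            crossings.append(float(scan.grid[i] + frac * (scan.grid[i + 1] - scan.grid[i])))
    if diff[-1] == 0.0:
        crossings.append(float(scan.grid[-1]))
    scan.n_crossings = len(crossings)
    if len(crossings) > 1:
        warnings.warn(
            f"scan of {scan.kind} {scan.target} has {len(crossings)} crossings; "
            "reporting the first",
            stacklevel=2,
        )
    return crossings[0] if crossings else None


def fold_difference(scan: ScanResult, at: float, eps: float = 1e-12) -> float:
    """Terminal max/min outcome ratio at a scan position (interpolated)."""
    if not (scan.grid[0] <= at <= scan.grid[-1]):
        raise ValueError(
            f"position {at} outside scan range [{scan.grid[0]}, {scan.grid[-1]}]"
        )
    s = float(np.interp(at, scan.grid, scan.survival_terminal))
    d = float(np.interp(at, scan.grid, scan.death_terminal))
    hi, lo = max(s, d), min(s, d)
    return hi / max(lo, eps)


def write_scan_csv(scan: ScanResult, path: str | Path) -> None:
    """CSV of the scan plus a companion ``<path>.meta.json`` with crossing info."""
    scan.to_frame().to_csv(path, index=False)
    meta = {
        "kind": scan.kind,
        "target": scan.target,
        "crossing": scan.crossing,
        "n_crossings": scan.n_crossings,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))
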