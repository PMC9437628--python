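"""Local sensitivity analysis via forward sensitivity equations.

For a mass-action system dx/dt = f(x; k), the forward sensitivities
S_ij(t) = ∂x_i(t)/∂p_j obey the variational system

    dS/dt = J_x(x) S + ∂f/∂p,        S(0) = ∂x(0)/∂p,

integrated alongside the state.  Inputs p are either all rate constants
(entities-vs-parameters) or all initial amounts (entities-vs-entities, where
∂f/∂p = 0 and S(0) = I).  Sensitivities are unnormalized and aggregated over
the horizon as the time integral of |S_ij| on the output grid (trapezoid
rule); max-over-time and terminal-value aggregations are also available.

A repeated central-finite-difference estimator (:func:`finite_difference_check`)
is provided as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import PathwayModel, assemble_rate_system
from .simulate import SimulationSettings, SimulationError

__all__ = [
    "SensitivityMatrix",
    "sensitivity_to_parameters",
    "sensitivity_to_initials",
    "rank_influences",
    "finite_difference_check",
]

AGGREGATIONS = ("time-integrated-abs", "max-abs", "terminal-abs")


@dataclass
class SensitivityMatrix:
    """Aggregated sensitivities of every species to every input."""

    outputs: list[str]  # species ids
    inputs: list[str]  # reaction indices (as str) or species ids
    values: np.ndarray  # outputs x inputs, >= 0
    aggregation: str = "time-integrated-abs"
    horizon: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.outputs), len(self.inputs)):
            raise ValueError("values must be outputs x inputs")

    def entry(self, output: str, input_id: str) -> float:
        return float(
            self.values[self.outputs.index(output), self.inputs.index(input_id)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.outputs, columns=self.inputs)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="output")


def _aggregate(S: np.ndarray, grid: np.ndarray, how: str) -> np.ndarray:
    """Collapse time axis of S (outputs x inputs x time)."""
    if how == "time-integrated-abs":
        return np.trapezoid(np.abs(S), grid, axis=2)
    if how == "max-abs":
        return np.abs(S).max(axis=2)
    if how == "terminal-abs":
        return np.abs(S[:, :, -1])
    raise ValueError(f"unknown aggregation {how!r}; choose from {AGGREGATIONS}")


def _integrate_augmented(
    model: PathwayModel,
    settings: SimulationSettings,
    mode: str,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Integrate state + sensitivities; returns (grid, S, n_inputs)."""
    system = assemble_rate_system(model)
    n = system.n_species
    n_in = system.n_reactions if mode == "parameters" else n
    x0 = model.initial_state()
    s0 = np.zeros((n, n_in)) if mode == "parameters" else np.eye(n)
    y0 = np.concatenate([x0, s0.ravel()])

    def rhs(t, y):
        x = y[:n]
        S = y[n:].reshape(n, n_in)
        dx = system(t, x)
        dS = system.state_jacobian(x) @ S
        if mode == "parameters":
            dS = dS + system.dfdk(x)
        return np.concatenate([dx, dS.ravel()])

    grid = settings.time_grid
    sol = solve_ivp(
        rhs,
        (0.0, settings.t_end),
        y0,
        method=settings.method,
        t_eval=grid,
        rtol=settings.rel_tol,
        atol=settings.abs_tol,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise SimulationError(f"sensitivity integration failed: {sol.message}", last)
    S = sol.y[n:].reshape(n, n_in, grid.size)
    return grid, S, n_in


def sensitivity_to_parameters(
    model: PathwayModel,
    settings: SimulationSettings | None = None,
    aggregation: str = "time-integrated-abs",
) -> SensitivityMatrix:
    """Sensitivity of every species to every reaction rate constant."""
    settings = settings or SimulationSettings()
    grid, S, _ = _integrate_augmented(model, settings, "parameters")
    return SensitivityMatrix(
        outputs=[s.id for s in model.species],
        inputs=[str(r.index) for r in model.reactions],
        values=_aggregate(S, grid, aggregation),
        aggregation=aggregation,
        horizon=(0.0, settings.t_end),
    )


def sensitivity_to_initials(
    model: PathwayModel,
    settings: SimulationSettings | None = None,
    aggregation: str = "time-integrated-abs",
) -> SensitivityMatrix:
    """Sensitivity of every species to every species' initial amount."""
    settings = settings or SimulationSettings()
    grid, S, _ = _integrate_augmented(model, settings, "initials")
    ids = [s.id for s in model.species]
    return SensitivityMatrix(
        outputs=ids,
        inputs=list(ids),
        values=_aggregate(S, grid, aggregation),
        aggregation=aggregation,
        horizon=(0.0, settings.t_end),
    )


def rank_influences(
    matrix: SensitivityMatrix, output: str, top_n: int | None = None
) -> list[tuple[str, float]]:
    """Inputs sorted by descending aggregate sensitivity of one output."""
    if output not in matrix.outputs:
        raise KeyError(f"unknown output {output!r}")
    row = matrix.values[matrix.outputs.index(output)]
    order = sorted(range(len(row)), key=lambda j: (-row[j], j))
    ranked = [(matrix.inputs[j], float(row[j])) for j in order]
    if top_n is not None:
        ranked = ranked[: max(0, top_n)]
    return ranked


def finite_difference_check(
    model: PathwayModel,
    mode: str = "parameters",
    settings: SimulationSettings | None = None,
    aggregation: str = "time-integrated-abs",
    rel_step: float = 0.01,
    inputs: list[str] | None = None,
) -> SensitivityMatrix:
    """Central-finite-difference estimate of the same aggregated sensitivities.

    Each input is perturbed by ±``rel_step`` (relative; absolute step of
    ``rel_step`` when the nominal value is 0) and the pointwise sensitivity
    is estimated from the two trajectories before aggregation.  Purely an
    oracle: much slower than the forward system, used to validate it.
    """
    from .simulate import simulate  # local import to avoid cycle at module load

    settings = settings or SimulationSettings()
    grid = settings.time_grid
    ids = [s.id for s in model.species]
    if mode == "parameters":
        all_inputs = [str(r.index) for r in model.reactions]
    elif mode == "initials":
        all_inputs = list(ids)
    else:
        raise ValueError("mode must be 'parameters' or 'initials'")
    use = all_inputs if inputs is None else list(inputs)

    n = len(ids)
    S = np.zeros((n, len(use), grid.size))
    for j, inp in enumerate(use):
        if mode == "parameters":
            nominal = model.reaction_by_index(int(inp)).rate_constant
            step = rel_step * nominal if nominal != 0 else rel_step
            lo = model.with_rate_constant(int(inp), nominal - step)
            hi = model.with_rate_constant(int(inp), nominal + step)
        else:
            nominal = model.species_by_id(inp).initial_amount
            step = rel_step * nominal if nominal != 0 else rel_step
            lo = model.with_initial_amount(inp, nominal - step)
            hi = model.with_initial_amount(inp, nominal + step)
        y_lo = simulate(lo, settings).values
        y_hi = simulate(hi, settings).values
        S[:, j, :] = (y_hi - y_lo) / (2.0 * step)
    return SensitivityMatrix(
        outputs=ids,
        inputs=use,
        values=_aggregate(S, grid, aggregation),
        aggregation=aggregation,
        horizon=(0.0, settings.t_end),
    )
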