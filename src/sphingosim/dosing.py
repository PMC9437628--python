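"""Drug species, repeat-dose schedules, and dosed simulation.

Drugs are assimilated into a pathway model as species: each drug gets one
species (initial amount 0), one inert-complex sink species per target, and
one irreversible mass-action sequestration reaction per target
(``drug + target -> complex``).  A repeat-dose schedule (start time, amount,
rate, interval, repeat count per row) expands into timed bolus events; dosed
simulation integrates piecewise, incrementing the drug species at each event
time with the same solver settings throughout.

The three bundled drugs mirror the intervention study: Etanercept
(sequesters TNF-α), Nivocasan (pro-caspase-8 and pro-caspase-9) and
Scyphostatin (neutral sphingomyelinase).
"""

from __future__ import annotations

import warnings
from typing import Mapping
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .model import PathwayModel, ReactionDef, SpeciesDef, assemble_rate_system
from .simulate import (
    DEATH_ID,
    SURVIVAL_ID,
    SimulationSettings,
    Trajectory,
    terminal_state,
)

__all__ = [
    "DrugSpec",
    "DoseRow",
    "DoseSchedule",
    "DEFAULT_BINDING_CONSTANT",
    "builtin_drug",
    "attach_drug",
    "expand_schedule",
    "simulate_with_dosing",
    "apoptosis_reduction",
    "load_dose_schedules",
    "builtin_dose_schedule",
]

#: default drug-target sequestration rate constant (the model's standard
#: adjusted kinetic value)
DEFAULT_BINDING_CONSTANT = 0.1


@dataclass(frozen=True)
class DrugSpec:
    """A drug species and its sequestration mechanism.

    ``binding_constant`` is the mass-action kf of each drug-target
    sequestration reaction: either one shared value or a per-target mapping.
    """

    name: str
    targets: tuple[str, ...]
    binding_constant: float | Mapping[str, float] = DEFAULT_BINDING_CONSTANT
    irreversible: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(self.targets))
        if not self.targets:
            raise ValueError(f"drug {self.name!r} has no targets")
        if isinstance(self.binding_constant, Mapping):
            kf = {t: float(self.binding_constant.get(t, DEFAULT_BINDING_CONSTANT))
                  for t in self.targets}
        else:
            kf = {t: float(self.binding_constant) for t in self.targets}
        if any(v <= 0 for v in kf.values()):
            raise ValueError("binding constants must be positive")
        object.__setattr__(self, "_kf", kf)

    def kf(self, target: str) -> float:
        return self._kf[target]

    @property
    def species_id(self) -> str:
        return self.name

    def complex_id(self, target: str) -> str:
        return f"{self.name}_{target}_complex"


#: bundled drug targets and calibrated sequestration constants
_BUILTIN_TARGETS: dict[str, dict[str, float]] = {
    "Etanercept": {"TNFa": DEFAULT_BINDING_CONSTANT},
    "Nivocasan": {"CASP8": 0.005, "CASP9": 0.1},
    "Scyphostatin": {"neutral_SMase": DEFAULT_BINDING_CONSTANT},
}


def builtin_drug(
    name: str, binding_constant: float | Mapping[str, float] | None = None
) -> DrugSpec:
    """One of the three bundled drug specifications."""
    if name not in _BUILTIN_TARGETS:
        raise KeyError(
            f"unknown drug {name!r}; built-ins: {sorted(_BUILTIN_TARGETS)}"
        )
    if binding_constant is None:
        binding_constant = dict(_BUILTIN_TARGETS[name])
    return DrugSpec(name, tuple(_BUILTIN_TARGETS[name]), binding_constant)


@dataclass(frozen=True)
class DoseRow:
    """One repeat-dose row: repeat_count boluses spaced by interval."""

    start_time: float
    amount: float
    rate: float = 1.0  # parsed and retained; boluses are instantaneous
    interval: float = 5.0
    repeat_count: int = 3

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("dose amount must be nonnegative")
        if self.interval <= 0:
            raise ValueError("dose interval must be positive")
        if self.repeat_count < 1:
            raise ValueError("repeat_count must be at least 1")


@dataclass
class DoseSchedule:
    """A repeat-dose description for one drug species."""

    drug: str
    doses: list[DoseRow] = field(default_factory=list)

    @property
    def total_amount(self) -> float:
        return sum(d.amount * d.repeat_count for d in self.doses)


def expand_schedule(schedule: DoseSchedule) -> list[tuple[float, float]]:
    """Expand a schedule into time-ordered (event time, bolus amount) pairs.

    Each row yields ``repeat_count`` events at ``start + j*interval``;
    coincident events are merged with summed amounts.
    """
    events: dict[float, float] = {}
    for row in schedule.doses:
        for j in range(row.repeat_count):
            t = row.start_time + j * row.interval
            events[t] = events.get(t, 0.0) + row.amount
    return sorted(events.items())


def attach_drug(model: PathwayModel, drug: DrugSpec) -> PathwayModel:
    """Return a copy of the model with the drug species and reactions added."""
    ids = set(model.species_index)
    unknown = [t for t in drug.targets if t not in ids]
    if unknown:
        raise KeyError(f"drug {drug.name!r} targets unknown species: {unknown}")
    species = list(model.species) + [
        SpeciesDef(drug.species_id, drug.name, 0.0, role="drug")
    ]
    next_index = max((r.index for r in model.reactions), default=0) + 1
    reactions = list(model.reactions)
    for i, target in enumerate(drug.targets):
        species.append(
            SpeciesDef(
                drug.complex_id(target),
                f"{drug.name}/{target} inert complex",
                0.0,
                role="drug",
            )
        )
        reactions.append(
            ReactionDef(
                index=next_index + i,
                name=f"{drug.name} sequestration of {target}",
                reactants={drug.species_id: 1, target: 1},
                products={drug.complex_id(target): 1},
                rate_constant=drug.kf(target),
                is_inhibitory=True,
            )
        )
    return PathwayModel(species, reactions, name=f"{model.name}+{drug.name}")


def simulate_with_dosing(
    model: PathwayModel,
    drug: DrugSpec,
    schedule: DoseSchedule,
    settings: SimulationSettings | None = None,
) -> Trajectory:
    """Simulate the model with the drug attached and boluses applied.

    Integration halts at every event time, the drug amount is incremented by
    the bolus, and integration restarts with the same tolerances; all
    non-drug species are continuous across events.  Events past ``t_end``
    raise a warning and are ignored.
    """
    settings = settings or SimulationSettings()
    if drug.species_id not in model.species_index:
        model = attach_drug(model, drug)
    system = assemble_rate_system(model)
    drug_i = model.species_index[drug.species_id]

    events = expand_schedule(schedule)
    late = [t for t, _ in events if t > settings.t_end]
    if late:
        warnings.warn(
            f"{len(late)} dose event(s) after t_end={settings.t_end} ignored",
            stacklevel=2,
        )
        events = [(t, a) for t, a in events if t <= settings.t_end]

    grid = settings.time_grid
    values = np.empty((len(model.species), grid.size))
    x = model.initial_state()
    # apply any t=0 events before the first sample
    k = 0
    while k < len(events) and events[k][0] <= 0.0:
        x[drug_i] += events[k][1]
        k += 1

    t_now = 0.0
    filled = 0
    from scipy.integrate import solve_ivp

    boundaries = [t for t, _ in events[k:]] + [settings.t_end]
    amounts = [a for _, a in events[k:]] + [0.0]
    for t_next, bolus in zip(boundaries, amounts):
        if t_next > t_now:
            sub = grid[(grid >= t_now) & (grid <= t_next)]
            t_eval = np.unique(np.concatenate([[t_now], sub, [t_next]]))
            sol = solve_ivp(
                system,
                (t_now, t_next),
                x,
                method=settings.method,
                t_eval=t_eval,
                rtol=settings.rel_tol,
                atol=settings.abs_tol,
                jac=lambda t, v: system.state_jacobian(v),
            )
            if not sol.success:
                from .simulate import SimulationError

                raise SimulationError(
                    f"dosed integration failed: {sol.message}", float(sol.t[-1])
                )
            for ti, col in zip(sol.t, sol.y.T):
                # a sample exactly at the event instant reports the
                # post-bolus state, so defer it to the next segment
                limit = min(ti, t_next - 1e-9) if bolus else ti
                while filled < grid.size and grid[filled] <= limit + 1e-12:
                    values[:, filled] = col
                    filled += 1
            x = sol.y[:, -1].copy()
            t_now = t_next
        x[drug_i] += bolus
    while filled < grid.size:  # numerical guard for the last sample
        values[:, filled] = x
        filled += 1

    return Trajectory(
        time_grid=grid,
        values=values,
        species_ids=model.species_ids,
        model_ref=model.name,
        solver_meta={
            "method": settings.method,
            "rel_tol": settings.rel_tol,
            "abs_tol": settings.abs_tol,
            "dosing": [{"time": t, "amount": a} for t, a in events],
        },
    )


def apoptosis_reduction(dosed: Trajectory, baseline: Trajectory) -> dict[str, float]:
    """Summaries of a dosed run against its undosed baseline.

    ``fold``: terminal CellSurvival / CellDeath in the dosed run;
    ``reduction``: 1 - dosed terminal CellDeath / baseline terminal CellDeath.
    """
    ts_dosed = terminal_state(dosed)
    ts_base = terminal_state(baseline)
    for ts, label in ((ts_dosed, "dosed"), (ts_base, "baseline")):
        for sid in (SURVIVAL_ID, DEATH_ID):
            if sid not in ts:
                raise KeyError(f"{label} trajectory lacks outcome species {sid!r}")
    if ts_base[DEATH_ID] == 0:
        raise ZeroDivisionError("baseline terminal CellDeath is zero")
    return {
        "fold": ts_dosed[SURVIVAL_ID] / ts_dosed[DEATH_ID],
        "reduction": 1.0 - ts_dosed[DEATH_ID] / ts_base[DEATH_ID],
    }


# ---------------------------------------------------------------------------
# schedule fixtures
# ---------------------------------------------------------------------------

def load_dose_schedules(source: str | Path | None = None) -> dict[str, list[DoseSchedule]]:
    """Read repeat-dose schedules from YAML (defaults to the bundled table).

    The YAML maps drug name -> list of rows with keys ``start_time``,
    ``amount``, ``rate``, ``interval``, ``repeat_count``; each row becomes
    its own single-row :class:`DoseSchedule` (the dosage regimens are
    evaluated one at a time).
    """
    if source is None:
        path = resources.files("sphingosim").joinpath("data", "table4_doses.yaml")
        raw = yaml.safe_load(path.read_text())
    else:
        raw = yaml.safe_load(Path(source).read_text())
    out: dict[str, list[DoseSchedule]] = {}
    for drug, rows in raw.items():
        out[drug] = [DoseSchedule(drug, [DoseRow(**row)]) for row in rows]
    return out


def builtin_dose_schedule(drug: str, dose_number: int = 1) -> DoseSchedule:
    """One bundled repeat-dose row (1-based) for one of the three drugs."""
    schedules = load_dose_schedules()
    if drug not in schedules:
        raise KeyError(f"no bundled schedule for drug {drug!r}")
    rows = schedules[drug]
    if not (1 <= dose_number <= len(rows)):
        raise IndexError(f"dose_number must be in 1..{len(rows)}")
    return rows[dose_number - 1]
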