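"""Core domain types and the mass-action rate engine.

A :class:`PathwayModel` is a declarative description of a reaction network:
an ordered list of species (with nonnegative initial amounts, expressed as
dimensionless relative concentrations, "RC") and an ordered list of
mass-action reactions.  Every reaction follows the law of mass action: its
rate is the rate constant times the product of the concentrations of its
reactants (raised to their stoichiometric coefficients) and of its
modifiers.  Modifiers ("read arcs") enter the rate like reactants but are
not consumed -- this is how catalysis by an enzyme is represented without
consuming the enzyme.

:func:`assemble_rate_system` compiles a model into a vectorized derivative
function suitable for ``scipy.integrate.solve_ivp``, together with the
analytic state Jacobian and rate-constant gradient needed by the forward
sensitivity equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SpeciesDef",
    "ReactionDef",
    "PathwayModel",
    "KineticParameterSet",
    "ValidationReport",
    "mass_action_rate",
    "assemble_rate_system",
    "validate_model",
    "CompiledRateSystem",
    "SPECIES_ROLES",
]

#: allowed values for :attr:`SpeciesDef.role`
SPECIES_ROLES = frozenset(
    {
        "receptor",
        "ligand",
        "adaptor",
        "enzyme",
        "sphingolipid",
        "caspase",
        "second-messenger",
        "outcome",
        "drug",
        "other",
    }
)


@dataclass(frozen=True)
class SpeciesDef:
    """One chemical species of a pathway model.

    Parameters
    ----------
    id:
        Short unique identifier used everywhere else to refer to the species.
    display_name:
        Free-text label (may contain Unicode, e.g. ``"TNF-α"``).
    initial_amount:
        Nonnegative initial relative concentration.
    role:
        One of :data:`SPECIES_ROLES`.
    is_input:
        True for species whose initial amount comes from an expression table.
    """

    id: str
    display_name: str = ""
    initial_amount: float = 0.0
    role: str = "other"
    is_input: bool = False

    def __post_init__(self) -> None:
        if not self.display_name:
            object.__setattr__(self, "display_name", self.id)


@dataclass(frozen=True)
class ReactionDef:
    """One irreversible mass-action reaction.

    ``reactants`` and ``products`` map species ids to positive integer
    stoichiometric coefficients; ``modifiers`` is a set of species ids that
    multiply into the rate (coefficient 1) without being consumed.  A species
    may appear in both ``reactants`` and ``products`` (net coefficient 0),
    which models a catalytic reactant; reactants and modifiers must be
    disjoint.
    """

    index: int
    name: str
    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate_constant: float
    modifiers: frozenset[str] = field(default_factory=frozenset)
    is_inhibitory: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", dict(self.reactants))
        object.__setattr__(self, "products", dict(self.products))
        object.__setattr__(self, "modifiers", frozenset(self.modifiers))

    @property
    def rate_species(self) -> list[tuple[str, int]]:
        """Species entering the rate law, with exponents."""
        out = [(s, int(c)) for s, c in self.reactants.items()]
        out.extend((s, 1) for s in sorted(self.modifiers))
        return out

    def net_coefficient(self, species_id: str) -> int:
        return int(self.products.get(species_id, 0)) - int(
            self.reactants.get(species_id, 0)
        )


class ValidationReport:
    """Outcome of :func:`validate_model`: either a pass or a list of violations."""

    def __init__(self, violations: Sequence[str], n_species: int, n_reactions: int):
        self.violations = list(violations)
        self.n_species = n_species
        self.n_reactions = n_reactions

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok

    def __repr__(self) -> str:
        status = "pass" if self.ok else f"{len(self.violations)} violation(s)"
        return (
            f"<ValidationReport {status}: {self.n_species} species / "
            f"{self.n_reactions} reactions>"
        )


@dataclass
class PathwayModel:
    """An ordered species/reaction container for a mass-action network."""

    species: list[SpeciesDef]
    reactions: list[ReactionDef]
    name: str = "model"
    time_unit: str = "RTU"

    def __post_init__(self) -> None:
        self.species = list(self.species)
        self.reactions = list(self.reactions)

    # -- lookups ---------------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def species_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def species_by_id(self, species_id: str) -> SpeciesDef:
        for s in self.species:
            if s.id == species_id:
                return s
        raise KeyError(f"unknown species id: {species_id!r}")

    def reaction_by_index(self, index: int) -> ReactionDef:
        for r in self.reactions:
            if r.index == index:
                return r
        raise KeyError(f"no reaction with index {index}")

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_amount for s in self.species], dtype=float)

    # -- functional updates ---------------------------------------------
    def with_initial_amount(self, species_id: str, value: float) -> "PathwayModel":
        """Return a copy with one species' initial amount replaced."""
        if species_id not in self.species_index:
            raise KeyError(f"unknown species id: {species_id!r}")
        new_species = [
            replace(s, initial_amount=float(value)) if s.id == species_id else s
            for s in self.species
        ]
        return PathwayModel(new_species, self.reactions, self.name, self.time_unit)

    def with_rate_constant(self, reaction_index: int, value: float) -> "PathwayModel":
        """Return a copy with one reaction's rate constant replaced."""
        found = False
        new_reactions = []
        for r in self.reactions:
            if r.index == reaction_index:
                r = replace(r, rate_constant=float(value))
                found = True
            new_reactions.append(r)
        if not found:
            raise KeyError(f"no reaction with index {reaction_index}")
        return PathwayModel(self.species, new_reactions, self.name, self.time_unit)

    def with_kinetics(self, kinetics: "KineticParameterSet") -> "PathwayModel":
        new_reactions = [
            replace(r, rate_constant=kinetics[r.index]) if r.index in kinetics else r
            for r in self.reactions
        ]
        return PathwayModel(self.species, new_reactions, self.name, self.time_unit)

    # -- degree bookkeeping (Fig-3 style counting) -----------------------
    def degree_counts(self, species_id: str) -> tuple[int, int]:
        """(incoming, outgoing) interaction counts for one species.

        A reaction counts as incoming when the species is among its products,
        outgoing when among its reactants; a read arc (modifier role) counts
        in both directions, matching how the source network draws dotted
        enzyme arcs.
        """
        if species_id not in self.species_index:
            raise KeyError(f"unknown species id: {species_id!r}")
        n_in = n_out = 0
        for r in self.reactions:
            is_mod = species_id in r.modifiers
            if species_id in r.products or is_mod:
                n_in += 1
            if species_id in r.reactants or is_mod:
                n_out += 1
        return n_in, n_out


class KineticParameterSet:
    """A map reaction-index -> rate constant, with per-entry provenance.

    Provenance is one of ``"literature"``, ``"adjusted"`` or ``"user"``;
    adjusted entries must lie in [0, 0.1] (the calibration interval used for
    rate constants with no literature value).
    """

    PROVENANCES = ("literature", "adjusted", "user")

    def __init__(self, values: Mapping[int, float] | None = None,
                 provenance: Mapping[int, str] | None = None):
        self._values: dict[int, float] = {}
        self._prov: dict[int, str] = {}
        if values:
            prov = dict(provenance or {})
            for idx, v in values.items():
                self.set(int(idx), float(v), prov.get(int(idx), "user"))

    def set(self, index: int, value: float, provenance: str = "user") -> None:
        if provenance not in self.PROVENANCES:
            raise ValueError(f"unknown provenance {provenance!r}")
        if value < 0:
            raise ValueError(f"rate constant for reaction {index} is negative")
        if provenance == "adjusted" and not (0.0 <= value <= 0.1):
            raise ValueError(
                f"adjusted rate constant for reaction {index} outside [0, 0.1]: {value}"
            )
        self._values[int(index)] = float(value)
        self._prov[int(index)] = provenance

    def provenance(self, index: int) -> str:
        return self._prov[index]

    def __getitem__(self, index: int) -> float:
        return self._values[index]

    def __contains__(self, index: int) -> bool:
        return index in self._values

    def __iter__(self):
        return iter(sorted(self._values))

    def __len__(self) -> int:
        return len(self._values)

    def items(self):
        return ((i, self._values[i]) for i in sorted(self._values))

    def as_dict(self) -> dict[int, float]:
        return {i: self._values[i] for i in sorted(self._values)}


# ---------------------------------------------------------------------------
# rate engine
# ---------------------------------------------------------------------------

def mass_action_rate(reaction: ReactionDef, state: Mapping[str, float]) -> float:
    """Mass-action rate of one reaction at a given state.

    ``rate = kf * prod [X]^coeff`` over reactants and modifiers; zero whenever
    any required concentration is zero.
    """
    rate = float(reaction.rate_constant)
    for sid, exponent in reaction.rate_species:
        try:
            conc = state[sid]
        except KeyError:
            raise KeyError(
                f"state does not define species {sid!r} required by reaction "
                f"{reaction.index} ({reaction.name})"
            ) from None
        rate *= float(conc) ** exponent
    return rate


class CompiledRateSystem:
    """Vectorized derivative function for a :class:`PathwayModel`.

    Padded factor indexing: every reaction's rate-law species are stored as
    column indices into the state vector extended by one virtual species held
    at 1.0, so that ``rates = k * prod(X[factors], axis=1)`` evaluates all
    reactions at once regardless of how many factors each has.
    """

    def __init__(self, model: PathwayModel):
        idx = model.species_index
        self.n_species = len(model.species)
        self.n_reactions = len(model.reactions)
        self.species_ids = model.species_ids
        self.reaction_indices = [r.index for r in model.reactions]
        self.k = np.array([r.rate_constant for r in model.reactions], dtype=float)

        factor_lists: list[list[int]] = []
        for r in model.reactions:
            cols: list[int] = []
            for sid, exponent in r.rate_species:
                cols.extend([idx[sid]] * exponent)
            factor_lists.append(cols)
        width = max((len(c) for c in factor_lists), default=1)
        width = max(width, 1)
        pad = self.n_species  # virtual species fixed at 1.0
        self.factors = np.full((self.n_reactions, width), pad, dtype=np.intp)
        for j, cols in enumerate(factor_lists):
            self.factors[j, : len(cols)] = cols

        # net stoichiometry, species x reactions
        self.net = np.zeros((self.n_species, self.n_reactions))
        for j, r in enumerate(model.reactions):
            for sid, c in r.reactants.items():
                self.net[idx[sid], j] -= c
            for sid, c in r.products.items():
                self.net[idx[sid], j] += c

    # -- evaluation ------------------------------------------------------
    def _extended(self, x: np.ndarray) -> np.ndarray:
        return np.append(x, 1.0)

    def unit_rates(self, x: np.ndarray) -> np.ndarray:
        """Rates with the rate constants divided out (d rate / d k)."""
        return np.prod(self._extended(x)[self.factors], axis=1)

    def rates(self, x: np.ndarray) -> np.ndarray:
        return self.k * self.unit_rates(x)

    def __call__(self, t: float, x: np.ndarray) -> np.ndarray:
        return self.net @ self.rates(x)

    def rate_jacobian(self, x: np.ndarray) -> np.ndarray:
        """d rates / d state, shape (n_reactions, n_species + 1 pad)."""
        X = self._extended(x)[self.factors]  # (R, W)
        width = self.factors.shape[1]
        dR = np.zeros((self.n_reactions, self.n_species + 1))
        for m in range(width):
            partial = self.k.copy()
            for mp in range(width):
                if mp != m:
                    partial = partial * X[:, mp]
            np.add.at(dR, (np.arange(self.n_reactions), self.factors[:, m]), partial)
        return dR

    def state_jacobian(self, x: np.ndarray) -> np.ndarray:
        """d(dx/dt)/dx, shape (n_species, n_species)."""
        return self.net @ self.rate_jacobian(x)[:, : self.n_species]

    def dfdk(self, x: np.ndarray) -> np.ndarray:
        """d(dx/dt)/dk, shape (n_species, n_reactions)."""
        return self.net * self.unit_rates(x)[np.newaxis, :]


def assemble_rate_system(model: PathwayModel) -> CompiledRateSystem:
    """Compile a validated model into its ODE right-hand side.

    The returned object is callable as ``f(t, x) -> dx/dt`` and also exposes
    the analytic state Jacobian and rate-constant gradient used by the
    forward sensitivity system.  Raises ``ValueError`` if the model does not
    validate.
    """
    report = validate_model(model)
    if not report.ok:
        raise ValueError(
            "model failed validation:\n  " + "\n  ".join(report.violations)
        )
    return CompiledRateSystem(model)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_model(model: PathwayModel) -> ValidationReport:
    """Check a model's structural invariants, reporting all violations."""
    violations: list[str] = []
    seen: set[str] = set()
    for s in model.species:
        if s.id in seen:
            violations.append(f"duplicate species id {s.id!r}")
        seen.add(s.id)
        if s.initial_amount < 0:
            violations.append(
                f"species {s.id!r} has negative initial amount {s.initial_amount}"
            )
        if s.role not in SPECIES_ROLES:
            violations.append(f"species {s.id!r} has unknown role {s.role!r}")
    ids = {s.id for s in model.species}

    seen_idx: set[int] = set()
    for r in model.reactions:
        label = f"reaction {r.index} ({r.name})"
        if r.index in seen_idx:
            violations.append(f"duplicate reaction index {r.index}")
        seen_idx.add(r.index)
        if r.rate_constant < 0:
            violations.append(f"{label} has negative rate constant {r.rate_constant}")
        for group, mapping in (("reactant", r.reactants), ("product", r.products)):
            for sid, c in mapping.items():
                if sid not in ids:
                    violations.append(f"{label} references undefined {group} {sid!r}")
                if not (isinstance(c, (int, np.integer)) and c >= 1):
                    violations.append(
                        f"{label} has non positive-integer coefficient {c!r} for {sid!r}"
                    )
        for sid in r.modifiers:
            if sid not in ids:
                violations.append(f"{label} references undefined modifier {sid!r}")
        overlap = set(r.reactants) & r.modifiers
        if overlap:
            violations.append(
                f"{label} lists species as both reactant and modifier: "
                + ", ".join(sorted(overlap))
            )
        if not r.reactants and not r.modifiers:
            violations.append(f"{label} has an empty rate law (no reactants/modifiers)")
    return ValidationReport(violations, len(model.species), len(model.reactions))
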