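"""Synthetic data generators for property testing.

Three generators stand in for the study's raw inputs: expression tables with
the statistical shape of the real input table (positive, roughly symmetric
around ~8.8), perturbed variants of a table, and random valid mass-action
networks for exercising the ODE engine, the scans and the centralities.
All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from .flagship import (
    DESCRIPTION_TO_SPECIES,
    ExpressionRow,
    ExpressionTable,
)
from .model import PathwayModel, ReactionDef, SpeciesDef, validate_model

__all__ = [
    "GeneratorConfig",
    "synthetic_expression_table",
    "perturb_table",
    "random_mass_action_model",
]

#: lower truncation bound for expression-like values
_TRUNCATION = 0.5


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration shared by the synthetic generators.

    Expression defaults (mean 8.8, spread 1.4) are the sample mean and
    standard deviation of the bundled 39-entry input expression table.
    """

    seed: int = 0
    n_species: int = 8
    n_reactions: int = 10
    expression_mean: float = 8.8
    expression_spread: float = 1.4
    perturbation_fold_range: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        if self.expression_spread <= 0:
            raise ValueError("expression_spread must be positive")
        if self.n_reactions < 1:
            raise ValueError("n_reactions must be at least 1")


def synthetic_expression_table(config: GeneratorConfig = GeneratorConfig()) -> ExpressionTable:
    """An expression table with synthetic values for the model input species.

    Values are drawn from a normal distribution truncated below at 0.5
    (expression-like values are strictly positive and show no heavy tail).
    """
    rng = np.random.default_rng(config.seed)
    a = (_TRUNCATION - config.expression_mean) / config.expression_spread
    dist = truncnorm(a, np.inf, loc=config.expression_mean, scale=config.expression_spread)
    values = dist.ppf(rng.uniform(size=len(DESCRIPTION_TO_SPECIES)))
    rows = [
        ExpressionRow(gene_id=f"synthetic:{i}", description=desc, average_expression=float(v))
        for i, (desc, v) in enumerate(zip(DESCRIPTION_TO_SPECIES, values))
    ]
    return ExpressionTable(rows)


def perturb_table(
    table: ExpressionTable, species_id: str, fold: float
) -> ExpressionTable:
    """Multiply one species' expression value by ``fold`` (> 0)."""
    if fold <= 0:
        raise ValueError("fold must be positive (values must stay positive)")
    species_to_desc = {v: k for k, v in DESCRIPTION_TO_SPECIES.items()}
    target_descs = {species_to_desc.get(species_id), species_id}
    if not any(r.description in target_descs for r in table.rows):
        raise KeyError(f"table has no row for species {species_id!r}")
    rows = [
        ExpressionRow(r.gene_id, r.description, r.average_expression * fold)
        if r.description in target_descs
        else r
        for r in table.rows
    ]
    return ExpressionTable(rows)


def random_mass_action_model(config: GeneratorConfig = GeneratorConfig()) -> PathwayModel:
    """A random, connected, valid mass-action network.

    Unimolecular (A -> B) and bimolecular (A + B -> C) reactions only; rate
    constants uniform on (0, 0.1]; initial amounts from the synthetic
    expression distribution.  Synthesis-from-nothing is excluded so moiety
    conservation stays testable, and the first ``n_species - 1`` reactions
    form a chain guaranteeing a weakly connected network.
    """
    if config.n_species < 2:
        raise ValueError("random networks need at least 2 species")
    rng = np.random.default_rng(config.seed)
    n, m = config.n_species, config.n_reactions

    a = (_TRUNCATION - config.expression_mean) / config.expression_spread
    dist = truncnorm(a, np.inf, loc=config.expression_mean, scale=config.expression_spread)
    initials = dist.ppf(rng.uniform(size=n))
    species = [
        SpeciesDef(f"S{i}", initial_amount=float(initials[i])) for i in range(n)
    ]
    ids = [s.id for s in species]

    reactions: list[ReactionDef] = []
    for j in range(m):
        if j < n - 1:
            # spanning chain: keeps the species-interaction graph connected
            src, dst = ids[j], ids[j + 1]
        else:
            src, dst = rng.choice(ids, size=2, replace=False)
        reactants = {src: 1}
        if rng.uniform() < 0.5:
            partner = ids[int(rng.integers(n))]
            if partner != dst and partner != src:
                reactants[partner] = 1
        k = float(rng.uniform(0.0, 0.1))
        k = k if k > 0 else 0.05
        reactions.append(
            ReactionDef(j + 1, f"r{j + 1}", reactants, {dst: 1}, rate_constant=k)
        )
    model = PathwayModel(species, reactions, name=f"random_{config.seed}")
    report = validate_model(model)
    if not report.ok:  # pragma: no cover - generator is constructed to pass
        raise AssertionError(f"generated model invalid: {report.violations}")
    return model
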