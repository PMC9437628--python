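"""The TNF-α mediated sphingomyelin signaling model, plus the teaching fixture.

This module holds the concrete 73-species / 51-reaction reconstruction of the
neuronal TNF-α → sphingomyelin → apoptosis/survival network:

* the TNFR1 arm: TNF-α binding, TRADD/RAIDD/FAN recruitment, FADD/TRAF2/RIP
  recruitment, caspase-2 and caspase-8 activation, and the NIK → IKK → NF-κB
  → cIAP2 survival branch (cIAP2 neutralizes active caspase-8);
* the sphingolipid arm: acid and neutral sphingomyelinase activation,
  sphingomyelin → ceramide hydrolysis, ceramide → cathepsin D → BID →
  cytochrome C → caspase-3/9 → death, ceramide → CAPK → Raf → MEK → ERK with
  both survival and death outputs, ceramide → CAPP inhibiting AKT, and the
  ceramide → sphingosine → S1P → S1PR → Gi → PI3K → PIP3 → AKT survival axis
  with Ras/GAP cycling and SMS back-conversion;
* two non-consumed accumulators, ``CellSurvival`` and ``CellDeath``, fed by
  the terminal survival and apoptosis reactions.

Input species take their initial relative concentrations from the bundled
average-gene-expression table (39 rows; three entries -- SM, CAPK and the
mitochondrial pool -- are assumed at 8.0, the average of the measured ones).
Rate constants are dimensionless "adjusted" values in [0, 0.1]; a handful of
interactions also have literature mass-action constants (0.185) that can be
swapped in via :func:`default_kinetics`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .model import (
    KineticParameterSet,
    PathwayModel,
    ReactionDef,
    SpeciesDef,
    validate_model,
)

__all__ = [
    "ExpressionTable",
    "ExpressionRow",
    "load_expression_table",
    "build_flagship_model",
    "default_kinetics",
    "build_toy_model",
    "INPUT_SPECIES",
    "OUTCOME_SURVIVAL",
    "OUTCOME_DEATH",
    "ADJUSTED_CITED",
    "LITERATURE_RATES",
]

OUTCOME_SURVIVAL = "CellSurvival"
OUTCOME_DEATH = "CellDeath"

# ---------------------------------------------------------------------------
# expression table (model inputs)
# ---------------------------------------------------------------------------

#: table description -> model species id, in table order
DESCRIPTION_TO_SPECIES: dict[str, str] = {
    "TNFR": "TNFR",
    "TNF-α": "TNFa",
    "RAIDD": "RAIDD",
    "RIP": "RIP",
    "CASP 2": "CASP2",
    "TRADD": "TRADD",
    "FADD": "FADD",
    "CASP 8 (pro CASP 8)": "CASP8",
    "TRAF2": "TRAF2",
    "NIK": "NIK",
    "IKK": "IKK",
    "NFkB": "NFkB",
    "cIAP2": "cIAP2",
    "FAN": "FAN",
    "acid_SMase": "acid_SMase",
    "neutral_SMase": "neutral_SMase",
    "PKC": "PKC",
    "SM*": "SM",
    "CAPK*": "CAPK",
    "CAPP": "CAPP",
    "Cathepsin D": "CathepsinD",
    "BID": "BID",
    "CASP3": "CASP3",
    "CASP9": "CASP9",
    "CDase": "CDase",
    "SPHK": "SPHK",
    "S1PR1": "S1PR",
    "Gi": "Gi",
    "RasGDP": "RasGDP",
    "GAP": "GAP",
    "PI3K": "PI3K",
    "PIP2": "PIP2",
    "AKT": "AKT",
    "PDK1": "PDK1",
    "RAF": "RAF",
    "MEK": "MEK",
    "ERK": "ERK",
    "Mitochondria": "Mitochondria",
    "SMS": "SMS",
}

#: the three entries whose expression was assumed rather than measured
ASSUMED_DESCRIPTIONS = ("SM*", "CAPK*", "Mitochondria")
ASSUMED_VALUE = 8.0

INPUT_SPECIES: tuple[str, ...] = tuple(DESCRIPTION_TO_SPECIES.values())


@dataclass(frozen=True)
class ExpressionRow:
    gene_id: str
    description: str
    average_expression: float


class ExpressionTable:
    """Average gene-expression values for the model's input species."""

    def __init__(self, rows: Iterable[ExpressionRow]):
        self.rows = list(rows)
        seen: set[str] = set()
        for row in self.rows:
            if row.average_expression <= 0:
                raise ValueError(
                    f"non-positive expression value for {row.description!r}: "
                    f"{row.average_expression}"
                )
            if row.description in seen:
                raise ValueError(f"duplicate description {row.description!r}")
            seen.add(row.description)

    def __len__(self) -> int:
        return len(self.rows)

    def __getitem__(self, description: str) -> float:
        for row in self.rows:
            if row.description == description:
                return row.average_expression
        raise KeyError(f"no expression row with description {description!r}")

    def by_species(self) -> dict[str, float]:
        """Map model species id -> initial amount."""
        out: dict[str, float] = {}
        for row in self.rows:
            sid = DESCRIPTION_TO_SPECIES.get(row.description)
            if sid is not None:
                out[sid] = row.average_expression
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in self.rows],
                "description": [r.description for r in self.rows],
                "average_expression": [r.average_expression for r in self.rows],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _data_path(name: str):
    return resources.files("sphingosim").joinpath("data", name)


def load_expression_table(source: str | Path | None = None) -> ExpressionTable:
    """Load an expression table from CSV, or the built-in fixture.

    The CSV must have columns ``gene_id``, ``description`` and
    ``average_expression``.  With ``source=None`` the bundled 39-row table of
    average expression values for the model inputs is returned.
    """
    if source is None:
        with resources.as_file(_data_path("table3_expression.csv")) as p:
            frame = pd.read_csv(p, dtype={"gene_id": str})
    else:
        frame = pd.read_csv(source, dtype={"gene_id": str})
    missing = {"gene_id", "description", "average_expression"} - set(frame.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    rows = [
        ExpressionRow(
            gene_id="" if pd.isna(r.gene_id) else str(r.gene_id),
            description=str(r.description),
            average_expression=float(r.average_expression),
        )
        for r in frame.itertuples()
    ]
    return ExpressionTable(rows)


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

#: adjusted rate constants pinned by the pathway analysis
ADJUSTED_CITED: dict[int, float] = {
    1: 0.1, 2: 0.1, 8: 0.1, 9: 0.1, 12: 0.1, 15: 0.1, 27: 0.1, 31: 0.1, 38: 0.1,
    7: 0.01, 49: 0.01, 51: 0.01,
}

#: literature mass-action constants (μM⁻¹ s⁻¹) for reactions with known rates
LITERATURE_RATES: dict[int, float] = {
    1: 0.185,   # TNFR + TNF-α binding
    8: 0.185,   # TRADD + TNF-α_TNFR complex
    9: 0.185,   # IKK/NF-κB
    10: 0.185,  # FADD + TRADD association
    11: 0.185,  # FADD-dependent caspase-8 activation
    12: 0.185,  # TRAF2 + TNFR_TRADD complex
    49: 0.185,  # RIP + TNFR_TRADD recruitment
}


def _calibrated_adjusted() -> dict[int, float]:
    with resources.as_file(_data_path("kinetics_adjusted.json")) as p:
        raw = json.loads(Path(p).read_text())
    return {int(k): float(v) for k, v in raw.items()}


def default_kinetics(scheme: str = "adjusted") -> KineticParameterSet:
    """Return one of the two bundled kinetic parameter schemes.

    ``"adjusted"``
        All 51 rate constants in [0, 0.1]: the cited adjusted values (0.1 for
        reactions 1, 2, 8, 9, 12, 15, 27, 31, 38; 0.01 for 7, 49, 51) plus the
        calibrated values for the uncited reactions, frozen in the shipped
        parameter file so that the balanced survival/death state holds.
    ``"literature-where-known"``
        The adjusted scheme with the reactions that have literature
        mass-action constants overridden by those constants (0.185).
    """
    if scheme not in ("adjusted", "literature-where-known"):
        raise ValueError(f"unknown kinetics scheme {scheme!r}")
    values = _calibrated_adjusted()
    ks = KineticParameterSet()
    for idx, v in values.items():
        ks.set(idx, v, "adjusted")
    if scheme == "literature-where-known":
        for idx, v in LITERATURE_RATES.items():
            ks.set(idx, v, "literature")
    return ks


# ---------------------------------------------------------------------------
# reaction table
# ---------------------------------------------------------------------------

# (index, name, reactants, products, modifiers, is_inhibitory)
_R = lambda *ids: {i: 1 for i in ids}  # noqa: E731 - compact stoichiometry
REACTION_TABLE: list[tuple[int, str, dict, dict, tuple, bool]] = [
    (1, "TNF-α binding to TNFR1", _R("TNFa", "TNFR"), _R("TNFa_TNFR"), (), False),
    (2, "RAIDD recruitment", _R("TNFa_TNFR", "RAIDD"), _R("recruitRAIDD"), (), False),
    (3, "RIP-RAIDD complex formation", _R("recruitRIP", "recruitRAIDD"), _R("RIP_RAIDD"), (), False),
    (4, "caspase-2 activation", _R("RIP_RAIDD", "CASP2"), _R("actCASP2"), (), False),
    (5, "caspase-2/8 driven cell death", _R("actCASP2"), _R("CellDeath"), ("actCASP8",), False),
    (6, "direct TRADD binding to TNFR1", _R("TNFR", "TRADD"), _R("TNFR_TRADD"), (), False),
    (7, "FADD recruitment", _R("TNFR_TRADD", "FADD"), _R("recruitFADD"), (), False),
    (8, "TNFR_TRADD complex formation", _R("TNFa_TNFR", "TRADD"), _R("TNFR_TRADD"), (), False),
    (9, "NF-κB activation by phospho-IKK", _R("NFkB", "phIKK"), _R("actNFkB"), (), False),
    (10, "TRADD-FADD association", _R("TRADD", "FADD"), _R("recruitFADD"), (), False),
    (11, "caspase-8 activation", _R("recruitFADD", "CASP8"), _R("actCASP8"), (), False),
    (12, "TRADD_TRAF2 complex formation", _R("TNFR_TRADD", "TRAF2"), _R("TRADD_TRAF2"), (), False),
    (13, "NIK-mediated IKK phosphorylation", _R("NIK", "IKK"), _R("phIKK"), ("TRADD_TRAF2",), False),
    (14, "NF-κB driven cIAP2 induction", _R("actNFkB"), _R("actNFkB", "cIAP2"), (), False),
    (15, "FAN association with TNFR1", _R("TNFR", "FAN"), _R("TNFR_FAN"), (), False),
    (16, "cIAP2 neutralization of caspase-8", _R("cIAP2", "actCASP8"), _R("cIAP2", "CellSurvival"), (), True),
    (17, "acid SMase activation (TRADD/FADD arm)", _R("acid_SMase", "recruitFADD"), _R("actSMase"), (), False),
    (18, "CAPK activation by ceramide", _R("ceramide", "CAPK"), _R("actCAPK"), (), False),
    (19, "FAN-driven neutral SMase translocation", _R("neutral_SMase", "TNFR_FAN"), _R("SMase_translocated"), ("ceramide",), False),
    (20, "RIP-arm acid SMase activation", _R("acid_SMase", "recruitRIP"), _R("actSMase"), (), False),
    (21, "activation of translocated SMase", _R("SMase_translocated"), _R("actSMase"), (), False),
    (22, "sphingomyelin hydrolysis (read-arc SMase)", _R("SM"), _R("ceramide"), ("actSMase",), False),
    (23, "sphingomyelin hydrolysis (enzyme-bound pool)", _R("SM", "actSMase"), _R("ceramide", "actSMase"), (), False),
    (24, "ceramide salvage from sphingosine", _R("Sphingosine"), _R("ceramide"), (), False),
    (25, "SMS back-conversion to sphingomyelin", _R("ceramide"), _R("SM"), ("SMS",), False),
    (26, "ceramidase conversion to sphingosine", _R("ceramide"), _R("Sphingosine"), ("CDase",), False),
    (27, "cathepsin D activation by ceramide", _R("CathepsinD", "ceramide"), _R("actCathepsinD"), (), False),
    (28, "caspase-3/9 driven cell death", _R("actCASP3and9"), _R("CellDeath"), (), False),
    (29, "BID cleavage by cathepsin D", _R("BID"), _R("actBID"), ("actCathepsinD", "ceramide"), False),
    (30, "cytochrome C release from mitochondria", _R("Mitochondria", "actBID"), _R("CytochromeC"), (), False),
    (31, "S1P receptor activation", _R("S1P", "S1PR"), _R("actS1PR", "S1P"), (), False),
    (32, "caspase-3/9 activation (apoptosome)", _R("CytochromeC", "CASP3", "CASP9"), _R("actCASP3and9", "Mitochondria"), (), False),
    (33, "CAPP activation by ceramide", _R("CAPP"), _R("actCAPP"), ("ceramide",), False),
    (34, "GAP-catalysed RasGTP hydrolysis", _R("RasGTP"), _R("RasGDP"), ("GAP",), False),
    (35, "Raf-1 activation by CAPK", _R("actCAPK", "RAF"), _R("actRAF"), (), False),
    (36, "Raf-1 activation by Ras", _R("RasGTP", "RAF"), _R("actRAF"), (), False),
    (37, "Ras activation by Gi-coupled receptor", _R("GiCoupledReceptor", "RasGDP"), _R("RasGTP"), (), False),
    (38, "AKT recruitment by PIP3", _R("AKT", "PIP3"), _R("recruitAKT"), (), False),
    (39, "MEK activation by Raf-1", _R("actRAF", "MEK"), _R("actMEK"), (), False),
    (40, "CAPP-mediated AKT dephosphorylation", _R("actAKT"), _R("AKT"), ("actCAPP",), True),
    (41, "ERK activation by MEK", _R("actMEK", "ERK"), _R("actERK"), (), False),
    (42, "sphingosine phosphorylation by SPHK", _R("Sphingosine"), _R("S1P"), ("SPHK",), False),
    (43, "ERK-mediated cell survival", _R("actERK"), _R("CellSurvival"), (), False),
    (44, "sphingosine inhibition of PKC", _R("Sphingosine", "PKC"), _R("Sphingosine"), (), True),
    (45, "sphingosine-driven apoptosis", _R("Sphingosine"), _R("CellDeath"), (), False),
    (46, "Gi coupling to activated S1PR", _R("Gi"), _R("GiCoupledReceptor"), ("actS1PR",), False),
    (47, "PI3K-catalysed PIP3 production", _R("PIP2"), _R("PIP3"), ("GiCoupledReceptor", "PI3K"), False),
    (48, "PDK1 phosphorylation of AKT", _R("recruitAKT"), _R("actAKT"), ("PDK1",), False),
    (49, "RIP recruitment", _R("RIP", "TNFR_TRADD"), _R("recruitRIP"), (), False),
    (50, "AKT-mediated cell survival", _R("actAKT"), _R("CellSurvival"), (), False),
    (51, "ERK-mediated cell death", _R("actERK"), _R("CellDeath"), (), False),
]

#: derived (non-input) species with display names and roles, in pathway order
_DERIVED: list[tuple[str, str, str]] = [
    ("TNFa_TNFR", "TNF-α/TNFR1 complex", "receptor"),
    ("recruitRAIDD", "recruited RAIDD", "adaptor"),
    ("TNFR_TRADD", "TNFR/TRADD complex", "adaptor"),
    ("recruitRIP", "recruited RIP", "adaptor"),
    ("RIP_RAIDD", "RIP/RAIDD complex", "adaptor"),
    ("actCASP2", "active caspase-2", "caspase"),
    ("recruitFADD", "recruited FADD", "adaptor"),
    ("actCASP8", "active caspase-8", "caspase"),
    ("TRADD_TRAF2", "TRADD/TRAF2 complex", "adaptor"),
    ("phIKK", "phosphorylated IKK", "enzyme"),
    ("actNFkB", "active NF-κB", "other"),
    ("TNFR_FAN", "TNFR/FAN complex", "adaptor"),
    ("SMase_translocated", "membrane-translocated SMase", "enzyme"),
    ("actSMase", "active sphingomyelinase", "enzyme"),
    ("ceramide", "ceramide", "sphingolipid"),
    ("actCathepsinD", "active cathepsin D", "enzyme"),
    ("actBID", "truncated BID", "other"),
    ("CytochromeC", "cytochrome C", "second-messenger"),
    ("actCASP3and9", "active caspases 3 and 9", "caspase"),
    ("actCAPK", "active CAPK", "enzyme"),
    ("actCAPP", "active CAPP", "enzyme"),
    ("actRAF", "active Raf-1", "enzyme"),
    ("actMEK", "active MEK", "enzyme"),
    ("actERK", "active ERK", "enzyme"),
    ("Sphingosine", "sphingosine", "sphingolipid"),
    ("S1P", "sphingosine-1-phosphate", "sphingolipid"),
    ("GiCoupledReceptor", "Gi-coupled receptor", "receptor"),
    ("actS1PR", "activated S1P receptor", "receptor"),
    ("PIP3", "PIP3", "second-messenger"),
    ("recruitAKT", "membrane-recruited AKT", "enzyme"),
    ("actAKT", "active AKT", "enzyme"),
    ("RasGTP", "Ras-GTP", "enzyme"),
    (OUTCOME_SURVIVAL, "neuronal survival", "outcome"),
    (OUTCOME_DEATH, "neuronal death", "outcome"),
]

_INPUT_ROLES: dict[str, str] = {
    "TNFR": "receptor", "TNFa": "ligand", "RAIDD": "adaptor", "RIP": "adaptor",
    "CASP2": "caspase", "TRADD": "adaptor", "FADD": "adaptor", "CASP8": "caspase",
    "TRAF2": "adaptor", "NIK": "enzyme", "IKK": "enzyme", "NFkB": "other",
    "cIAP2": "other", "FAN": "adaptor", "acid_SMase": "enzyme",
    "neutral_SMase": "enzyme", "PKC": "enzyme", "SM": "sphingolipid",
    "CAPK": "enzyme", "CAPP": "enzyme", "CathepsinD": "enzyme", "BID": "other",
    "CASP3": "caspase", "CASP9": "caspase", "CDase": "enzyme", "SPHK": "enzyme",
    "S1PR": "receptor", "Gi": "other", "RasGDP": "enzyme", "GAP": "enzyme",
    "PI3K": "enzyme", "PIP2": "second-messenger", "AKT": "enzyme",
    "PDK1": "enzyme", "RAF": "enzyme", "MEK": "enzyme", "ERK": "enzyme",
    "Mitochondria": "other", "SMS": "enzyme",
}


def build_flagship_model(
    expr: ExpressionTable | None = None,
    kinetics: KineticParameterSet | None = None,
) -> PathwayModel:
    """Assemble the 73-species / 51-reaction TNF-α sphingomyelin model.

    ``expr`` supplies initial amounts for the 39 input species (defaults to
    the bundled expression table); ``kinetics`` supplies all 51 rate
    constants (defaults to the calibrated adjusted scheme).  Raises
    ``ValueError`` if the expression table does not cover every input species
    or the kinetics miss a reaction index.
    """
    if expr is None:
        expr = load_expression_table()
    if kinetics is None:
        kinetics = default_kinetics("adjusted")

    initials = expr.by_species()
    missing = [sid for sid in INPUT_SPECIES if sid not in initials]
    if missing:
        raise ValueError(f"expression table does not cover input species: {missing}")

    display = {v: k for k, v in DESCRIPTION_TO_SPECIES.items()}
    display["TNFa"] = "TNF-α"
    display["SM"] = "SM"
    display["CAPK"] = "CAPK"
    display["CASP8"] = "CASP 8"
    display["CASP2"] = "CASP 2"
    species = [
        SpeciesDef(
            id=sid,
            display_name=display.get(sid, sid),
            initial_amount=initials[sid],
            role=_INPUT_ROLES[sid],
            is_input=True,
        )
        for sid in INPUT_SPECIES
    ]
    species.extend(
        SpeciesDef(id=sid, display_name=name, initial_amount=0.0, role=role)
        for sid, name, role in _DERIVED
    )

    reactions = []
    for index, name, reactants, products, modifiers, inhib in REACTION_TABLE:
        if index not in kinetics:
            raise ValueError(f"kinetic parameter set has no entry for reaction {index}")
        reactions.append(
            ReactionDef(
                index=index,
                name=name,
                reactants=reactants,
                products=products,
                modifiers=frozenset(modifiers),
                rate_constant=kinetics[index],
                is_inhibitory=inhib,
            )
        )

    model = PathwayModel(species, reactions, name="tnf_sphingomyelin")
    report = validate_model(model)
    if not report.ok:  # pragma: no cover - construction is static
        raise AssertionError("flagship model failed validation: " + str(report.violations))
    return model


def build_toy_model() -> PathwayModel:
    """The two-reactant teaching fixture: A + B -> C with A0=20, B0=10, k=1."""
    species = [
        SpeciesDef("A", initial_amount=20.0),
        SpeciesDef("B", initial_amount=10.0),
        SpeciesDef("C", initial_amount=0.0),
    ]
    reactions = [
        ReactionDef(1, "A + B -> C", {"A": 1, "B": 1}, {"C": 1}, rate_constant=1.0)
    ]
    return PathwayModel(species, reactions, name="toy_bimolecular")
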