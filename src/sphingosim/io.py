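"""Model serialization: the canonical json-table dialect and SBML Level 3.

The json-table dialect is the round-trippable format: a UTF-8 JSON document
with top-level keys ``"species"`` and ``"reactions"`` written with stable
key order.  SBML export emits Level 3 Version 1 with a single compartment
and explicit mass-action kinetic laws (k * product of reactant/modifier
concentrations); a matching importer reads those documents back.  Species
role/input flags and reaction inhibitory flags ride along in a small
annotation namespace so that both formats round-trip exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

from lxml import etree

from .model import PathwayModel, ReactionDef, SpeciesDef, validate_model

__all__ = [
    "export_model",
    "import_model",
    "model_to_json_table",
    "model_from_json_table",
    "model_to_sbml",
    "model_from_sbml",
]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "urn:sphingosim:model-annotations"


def _check_exportable(model: PathwayModel) -> None:
    if not model.species:
        raise ValueError("refusing to export a degenerate model with no species")
    report = validate_model(model)
    if not report.ok:
        raise ValueError("model failed validation: " + "; ".join(report.violations))


# ---------------------------------------------------------------------------
# json-table
# ---------------------------------------------------------------------------

def model_to_json_table(model: PathwayModel) -> str:
    _check_exportable(model)
    doc = {
        "name": model.name,
        "time_unit": model.time_unit,
        "species": [
            {
                "id": s.id,
                "name": s.display_name,
                "initial_amount": s.initial_amount,
                "role": s.role,
                "is_input": s.is_input,
            }
            for s in model.species
        ],
        "reactions": [
            {
                "index": r.index,
                "name": r.name,
                "reactants": dict(r.reactants),
                "products": dict(r.products),
                "modifiers": sorted(r.modifiers),
                "rate_constant": r.rate_constant,
                "is_inhibitory": r.is_inhibitory,
            }
            for r in model.reactions
        ],
    }
    return json.dumps(doc, indent=1, ensure_ascii=False)


def model_from_json_table(text: str) -> PathwayModel:
    doc = json.loads(text)
    species = [
        SpeciesDef(
            id=s["id"],
            display_name=s.get("name", s["id"]),
            initial_amount=float(s["initial_amount"]),
            role=s.get("role", "other"),
            is_input=bool(s.get("is_input", False)),
        )
        for s in doc["species"]
    ]
    reactions = [
        ReactionDef(
            index=int(r["index"]),
            name=r.get("name", f"r{r['index']}"),
            reactants={k: int(v) for k, v in r["reactants"].items()},
            products={k: int(v) for k, v in r["products"].items()},
            modifiers=frozenset(r.get("modifiers", ())),
            rate_constant=float(r["rate_constant"]),
            is_inhibitory=bool(r.get("is_inhibitory", False)),
        )
        for r in doc["reactions"]
    ]
    return PathwayModel(
        species,
        reactions,
        name=doc.get("name", "model"),
        time_unit=doc.get("time_unit", "RTU"),
    )


# ---------------------------------------------------------------------------
# SBML Level 3 Version 1
# ---------------------------------------------------------------------------

def _sb(tag: str) -> str:
    return f"{{{SBML_NS}}}{tag}"


def model_to_sbml(model: PathwayModel) -> str:
    _check_exportable(model)
    nsmap = {None: SBML_NS, "ann": ANNOT_NS}
    sbml = etree.Element(_sb("sbml"), nsmap=nsmap, level="3", version="1")
    mdl = etree.SubElement(sbml, _sb("model"), id=model.name.replace("+", "_"))
    mdl.set("timeUnits", "dimensionless")

    comps = etree.SubElement(mdl, _sb("listOfCompartments"))
    etree.SubElement(
        comps, _sb("compartment"), id="cell", size="1", constant="true",
        spatialDimensions="3",
    )

    sps = etree.SubElement(mdl, _sb("listOfSpecies"))
    for s in model.species:
        el = etree.SubElement(
            sps,
            _sb("species"),
            id=s.id,
            name=s.display_name,
            compartment="cell",
            initialAmount=repr(s.initial_amount),
            hasOnlySubstanceUnits="true",
            boundaryCondition="false",
            constant="false",
        )
        ann = etree.SubElement(el, _sb("annotation"))
        meta = etree.SubElement(ann, f"{{{ANNOT_NS}}}speciesMeta")
        meta.set("role", s.role)
        meta.set("isInput", "true" if s.is_input else "false")

    params = etree.SubElement(mdl, _sb("listOfParameters"))
    for r in model.reactions:
        etree.SubElement(
            params, _sb("parameter"), id=f"kf_{r.index}",
            value=repr(r.rate_constant), constant="true",
        )

    rxns = etree.SubElement(mdl, _sb("listOfReactions"))
    for r in model.reactions:
        el = etree.SubElement(
            rxns, _sb("reaction"), id=f"r{r.index}", name=r.name,
            reversible="false",
        )
        ann = etree.SubElement(el, _sb("annotation"))
        meta = etree.SubElement(ann, f"{{{ANNOT_NS}}}reactionMeta")
        meta.set("isInhibitory", "true" if r.is_inhibitory else "false")
        if r.reactants:
            lo = etree.SubElement(el, _sb("listOfReactants"))
            for sid, c in r.reactants.items():
                etree.SubElement(
                    lo, _sb("speciesReference"), species=sid,
                    stoichiometry=str(int(c)), constant="true",
                )
        if r.products:
            lo = etree.SubElement(el, _sb("listOfProducts"))
            for sid, c in r.products.items():
                etree.SubElement(
                    lo, _sb("speciesReference"), species=sid,
                    stoichiometry=str(int(c)), constant="true",
                )
        if r.modifiers:
            lo = etree.SubElement(el, _sb("listOfModifiers"))
            for sid in sorted(r.modifiers):
                etree.SubElement(lo, _sb("modifierSpeciesReference"), species=sid)
        # kinetic law: kf * prod [X]^coeff over reactants and modifiers
        kl = etree.SubElement(el, _sb("kineticLaw"))
        math = etree.SubElement(kl, f"{{{MATHML_NS}}}math")
        apply_ = etree.SubElement(math, f"{{{MATHML_NS}}}apply")
        etree.SubElement(apply_, f"{{{MATHML_NS}}}times")
        ci = etree.SubElement(apply_, f"{{{MATHML_NS}}}ci")
        ci.text = f" kf_{r.index} "
        for sid, exponent in r.rate_species:
            for _ in range(exponent):
                ci = etree.SubElement(apply_, f"{{{MATHML_NS}}}ci")
                ci.text = f" {sid} "
    return etree.tostring(
        sbml, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


def model_from_sbml(text: str) -> PathwayModel:
    root = etree.fromstring(text.encode("utf-8"))
    mdl = root.find(_sb("model"))
    if mdl is None:
        raise ValueError("document has no <model> element")

    species = []
    for el in mdl.findall(f"{_sb('listOfSpecies')}/{_sb('species')}"):
        meta = el.find(f"{_sb('annotation')}/{{{ANNOT_NS}}}speciesMeta")
        species.append(
            SpeciesDef(
                id=el.get("id"),
                display_name=el.get("name", el.get("id")),
                initial_amount=float(el.get("initialAmount", "0")),
                role=meta.get("role", "other") if meta is not None else "other",
                is_input=(meta is not None and meta.get("isInput") == "true"),
            )
        )

    kvals = {
        el.get("id"): float(el.get("value"))
        for el in mdl.findall(f"{_sb('listOfParameters')}/{_sb('parameter')}")
    }

    reactions = []
    for el in mdl.findall(f"{_sb('listOfReactions')}/{_sb('reaction')}"):
        rid = el.get("id")
        index = int(rid[1:]) if rid and rid[1:].isdigit() else len(reactions) + 1
        reactants = {
            sr.get("species"): int(float(sr.get("stoichiometry", "1")))
            for sr in el.findall(f"{_sb('listOfReactants')}/{_sb('speciesReference')}")
        }
        products = {
            sr.get("species"): int(float(sr.get("stoichiometry", "1")))
            for sr in el.findall(f"{_sb('listOfProducts')}/{_sb('speciesReference')}")
        }
        modifiers = frozenset(
            sr.get("species")
            for sr in el.findall(
                f"{_sb('listOfModifiers')}/{_sb('modifierSpeciesReference')}"
            )
        )
        meta = el.find(f"{_sb('annotation')}/{{{ANNOT_NS}}}reactionMeta")
        reactions.append(
            ReactionDef(
                index=index,
                name=el.get("name", rid),
                reactants=reactants,
                products=products,
                modifiers=modifiers,
                rate_constant=kvals.get(f"kf_{index}", 0.0),
                is_inhibitory=(meta is not None and meta.get("isInhibitory") == "true"),
            )
        )
    return PathwayModel(species, reactions, name=mdl.get("id", "model"))


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def export_model(model: PathwayModel, format: str = "json-table") -> str:
    """Serialize a model to ``"json-table"`` or ``"sbml"``."""
    if format == "json-table":
        return model_to_json_table(model)
    if format == "sbml":
        return model_to_sbml(model)
    raise ValueError(f"unsupported export format {format!r}")


def import_model(text: str, format: str = "json-table") -> PathwayModel:
    """Parse a model from ``"json-table"`` or ``"sbml"`` text."""
    if format == "json-table":
        return model_from_json_table(text)
    if format == "sbml":
        return model_from_sbml(text)
    raise ValueError(f"unsupported import format {format!r}")


def save_model(model: PathwayModel, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json-table"
    path.write_text(export_model(model, format), encoding="utf-8")


def load_model(path: str | Path, format: str | None = None) -> PathwayModel:
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json-table"
    return import_model(path.read_text(encoding="utf-8"), format)
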