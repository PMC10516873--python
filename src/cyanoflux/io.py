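"""Model readers and writers.

Two dialects are supported:

* SBML Level 3 Version 1 with the ``fbc`` version-2 package (the exchange
  format genome-scale reconstructions such as iJN678 are distributed in),
  via python-libsbml.
* A native tabular dialect: a directory containing ``metabolites.tsv``,
  ``reactions.tsv`` and a ``model.json`` header.  This dialect round-trips
  every field of the in-memory model and doubles as the declarative reaction
  format used by curation and pathway config files.

Gene associations are reduced to a per-reaction boolean: a reaction is
gene-associated iff it carries any gene-product association in the SBML
source.  When writing SBML, gene-associated reactions reference a single
placeholder gene product so the flag survives a round trip.
"""

from __future__ import annotations

import json
import logging
import math
import os
from pathlib import Path

import pandas as pd

from .core import MetabolicModel, Metabolite, ModelConsistencyError, Reaction

__all__ = [
    "ModelIOError",
    "read_sbml",
    "write_model",
    "read_native",
    "parse_stoichiometry_string",
    "format_stoichiometry_string",
]

logger = logging.getLogger(__name__)

_SBML_INF = 1e30  # bounds at or beyond this magnitude are treated as infinite
_PLACEHOLDER_GENE = "G_unspecified"


class ModelIOError(IOError):
    """Raised for unreadable, unwritable or structurally invalid model files."""


# ---------------------------------------------------------------------------
# stoichiometry strings ("atp_c:-1;h2o_c:-1;adp_c:1;pi_c:1;h_c:1")
# ---------------------------------------------------------------------------

def parse_stoichiometry_string(text: str) -> dict[str, float]:
    stoich: dict[str, float] = {}
    text = text.strip()
    if not text:
        return stoich
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        met, _, coeff = part.rpartition(":")
        if not met:
            raise ModelIOError(f"malformed stoichiometry entry {part!r}")
        try:
            value = float(coeff)
        except ValueError as exc:
            raise ModelIOError(f"malformed coefficient in {part!r}") from exc
        if met in stoich:
            raise ModelIOError(f"duplicate metabolite {met!r} in stoichiometry")
        stoich[met] = value
    return stoich


def format_stoichiometry_string(stoich: dict[str, float]) -> str:
    # repr gives the shortest exact round-trip representation of the float
    return ";".join(f"{met}:{float(coeff)!r}" for met, coeff in sorted(stoich.items()))


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def _import_libsbml():
    import libsbml

    return libsbml


def read_sbml(path: str | os.PathLike) -> MetabolicModel:
    """Read an SBML Level 3 + fbc file into a :class:`MetabolicModel`.

    Flux bounds must be given through fbc bound parameters and the objective
    through the active fbc objective; their absence is a structured
    :class:`ModelIOError`.  A file with species but no reactions is accepted
    with a warning.
    """
    libsbml = _import_libsbml()
    path = Path(path)
    if not path.exists():
        raise ModelIOError(f"cannot read SBML file {path}: no such file")
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise ModelIOError(f"SBML parse errors in {path}: {msgs[:3]}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelIOError(f"{path} contains no SBML model")
    fbc = sbml_model.getPlugin("fbc")
    if fbc is None:
        raise ModelIOError(f"{path}: missing required fbc package information")

    metabolites = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        sfbc = sp.getPlugin("fbc")
        formula = ""
        charge = 0
        if sfbc is not None:
            if sfbc.isSetChemicalFormula():
                formula = sfbc.getChemicalFormula() or ""
            if sfbc.isSetCharge():
                charge = sfbc.getCharge()
        metabolites.append(
            Metabolite(
                id=_strip_sbml_prefix(sp.getId(), "M_"),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "",
                formula=formula,
                charge=charge,
            )
        )

    if sbml_model.getNumReactions() == 0:
        logger.warning("SBML model %s declares species but zero reactions", path)

    def bound_value(param_id: str, rxn_id: str, which: str) -> float:
        if not param_id:
            raise ModelIOError(
                f"{path}: reaction {rxn_id!r} lacks an fbc {which} flux bound"
            )
        param = sbml_model.getParameter(param_id)
        if param is None or not param.isSetValue():
            raise ModelIOError(
                f"{path}: flux bound parameter {param_id!r} of reaction "
                f"{rxn_id!r} is undefined"
            )
        value = param.getValue()
        if value <= -_SBML_INF:
            return -math.inf
        if value >= _SBML_INF:
            return math.inf
        return value

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        rid = _strip_sbml_prefix(rxn.getId(), "R_")
        stoich: dict[str, float] = {}
        for k in range(rxn.getNumReactants()):
            ref = rxn.getReactant(k)
            met = _strip_sbml_prefix(ref.getSpecies(), "M_")
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for k in range(rxn.getNumProducts()):
            ref = rxn.getProduct(k)
            met = _strip_sbml_prefix(ref.getSpecies(), "M_")
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0.0}
        rfbc = rxn.getPlugin("fbc")
        if rfbc is None:
            raise ModelIOError(f"{path}: reaction {rid!r} lacks fbc bounds")
        lb = bound_value(rfbc.getLowerFluxBound(), rid, "lower")
        ub = bound_value(rfbc.getUpperFluxBound(), rid, "upper")
        gene_associated = (
            rfbc.isSetGeneProductAssociation()
            and rfbc.getGeneProductAssociation().getAssociation() is not None
        )
        notes = rxn.getNotesString() if rxn.isSetNotes() else ""
        subsystem = _subsystem_from_notes(notes)
        reactions.append(
            Reaction(
                id=rid,
                name=rxn.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gene_associated=gene_associated,
                subsystem=subsystem,
            )
        )

    active = fbc.getActiveObjective()
    if active is None:
        raise ModelIOError(f"{path}: no active fbc objective defined")
    objective: dict[str, float] = {}
    for i in range(active.getNumFluxObjectives()):
        fo = active.getFluxObjective(i)
        coeff = fo.getCoefficient()
        if coeff != 0.0:
            objective[_strip_sbml_prefix(fo.getReaction(), "R_")] = coeff

    annotations = {"model_id": sbml_model.getId() or path.stem}
    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective_coefficients=objective,
        annotations=annotations,
    )
    return model


def _strip_sbml_prefix(identifier: str, prefix: str) -> str:
    return identifier[len(prefix):] if identifier.startswith(prefix) else identifier


def _subsystem_from_notes(notes: str) -> str:
    marker = "SUBSYSTEM:"
    if marker in notes:
        tail = notes.split(marker, 1)[1]
        return tail.split("<", 1)[0].strip()
    return ""


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    libsbml = _import_libsbml()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(str(model.annotations.get("model_id", "model")))
    mfbc = sbml_model.getPlugin("fbc")
    mfbc.setStrict(True)

    compartments = sorted({m.compartment for m in model.metabolites} | {"c"})
    for comp in compartments:
        c = sbml_model.createCompartment()
        c.setId(comp)
        c.setConstant(True)

    for met in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId(f"M_{met.id}")
        sp.setName(met.name)
        sp.setCompartment(met.compartment or "c")
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        sfbc = sp.getPlugin("fbc")
        if met.formula:
            sfbc.setChemicalFormula(met.formula)
        sfbc.setCharge(int(met.charge))

    if any(r.gene_associated for r in model.reactions):
        gp = mfbc.createGeneProduct()
        gp.setId(_PLACEHOLDER_GENE)
        gp.setLabel("unspecified")

    def make_bound_param(value: float, suffix: str, rid: str) -> str:
        pid = f"B_{rid}_{suffix}"
        param = sbml_model.createParameter()
        param.setId(pid)
        param.setConstant(True)
        if math.isinf(value):
            param.setValue(math.copysign(_SBML_INF, value))
        else:
            param.setValue(value)
        return pid

    for rxn in model.reactions:
        r = sbml_model.createReaction()
        r.setId(f"R_{rxn.id}")
        r.setName(rxn.name)
        r.setFast(False)
        r.setReversible(rxn.lower_bound < 0)
        if rxn.subsystem:
            r.setNotes(
                f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>SUBSYSTEM: {rxn.subsystem}</p></body>"
            )
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff < 0:
                ref = r.createReactant()
                ref.setStoichiometry(-coeff)
            else:
                ref = r.createProduct()
                ref.setStoichiometry(coeff)
            ref.setSpecies(f"M_{met_id}")
            ref.setConstant(True)
        rfbc = r.getPlugin("fbc")
        rfbc.setLowerFluxBound(make_bound_param(rxn.lower_bound, "lb", rxn.id))
        rfbc.setUpperFluxBound(make_bound_param(rxn.upper_bound, "ub", rxn.id))
        if rxn.gene_associated:
            gpa = rfbc.createGeneProductAssociation()
            ref = gpa.createGeneProductRef()
            ref.setGeneProduct(_PLACEHOLDER_GENE)

    objective = mfbc.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    for rxn_id, coeff in model.objective_coefficients.items():
        fo = objective.createFluxObjective()
        fo.setReaction(f"R_{rxn_id}")
        fo.setCoefficient(coeff)
    mfbc.setActiveObjectiveId("obj")

    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(doc, str(path)):
        raise ModelIOError(f"failed to write SBML to {path}")


# ---------------------------------------------------------------------------
# native tabular dialect
# ---------------------------------------------------------------------------

_MET_COLUMNS = ["id", "name", "compartment", "formula", "charge"]
_RXN_COLUMNS = [
    "id", "name", "stoichiometry", "lower_bound", "upper_bound",
    "gene_associated", "subsystem",
]


def _write_native(model: MetabolicModel, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    met_frame = pd.DataFrame(
        [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "charge": m.charge,
            }
            for m in model.metabolites
        ],
        columns=_MET_COLUMNS,
    )
    rxn_frame = pd.DataFrame(
        [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": format_stoichiometry_string(r.stoichiometry),
                "lower_bound": repr(r.lower_bound),
                "upper_bound": repr(r.upper_bound),
                "gene_associated": int(r.gene_associated),
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
        columns=_RXN_COLUMNS,
    )
    met_frame.to_csv(path / "metabolites.tsv", sep="\t", index=False)
    rxn_frame.to_csv(path / "reactions.tsv", sep="\t", index=False)
    header = {
        "model_id": model.annotations.get("model_id", "model"),
        "biomass_reactions": model.annotations.get("biomass_reactions", []),
        "objective": model.objective_coefficients,
        "annotations": {
            k: v
            for k, v in model.annotations.items()
            if k not in {"model_id", "biomass_reactions"}
        },
    }
    (path / "model.json").write_text(json.dumps(header, indent=2, sort_keys=True))


def read_native(path: str | os.PathLike) -> MetabolicModel:
    """Read a model from a native-dialect directory."""
    path = Path(path)
    for required in ("metabolites.tsv", "reactions.tsv", "model.json"):
        if not (path / required).exists():
            raise ModelIOError(f"native model at {path} is missing {required}")
    met_frame = pd.read_csv(
        path / "metabolites.tsv", sep="\t", dtype=str, keep_default_na=False
    )
    rxn_frame = pd.read_csv(
        path / "reactions.tsv", sep="\t", dtype=str, keep_default_na=False
    )
    header = json.loads((path / "model.json").read_text())
    metabolites = [
        Metabolite(
            id=row["id"],
            name=row["name"],
            compartment=row["compartment"],
            formula=row["formula"],
            charge=int(row["charge"]) if row["charge"] else 0,
        )
        for row in met_frame.to_dict("records")
    ]
    reactions = [
        Reaction(
            id=row["id"],
            name=row["name"],
            stoichiometry=parse_stoichiometry_string(row["stoichiometry"]),
            lower_bound=float(row["lower_bound"]),
            upper_bound=float(row["upper_bound"]),
            gene_associated=row["gene_associated"] in {"1", "True", "true"},
            subsystem=row["subsystem"],
        )
        for row in rxn_frame.to_dict("records")
    ]
    annotations = dict(header.get("annotations", {}))
    annotations["model_id"] = header.get("model_id", path.name)
    if header.get("biomass_reactions"):
        annotations["biomass_reactions"] = header["biomass_reactions"]
    try:
        return MetabolicModel(
            metabolites=metabolites,
            reactions=reactions,
            objective_coefficients={
                k: float(v) for k, v in header.get("objective", {}).items()
            },
            annotations=annotations,
        )
    except ModelConsistencyError as exc:
        raise ModelIOError(f"native model at {path} is inconsistent: {exc}") from exc


def write_model(
    model: MetabolicModel, path: str | os.PathLike, dialect: str = "native"
) -> None:
    """Write a model to ``path`` in the requested dialect.

    ``dialect="sbml"`` writes a single SBML file; ``dialect="native"`` writes
    a directory with the two tables and the JSON header.  Both round-trip all
    model fields.
    """
    path = Path(path)
    try:
        if dialect == "sbml":
            _write_sbml(model, path)
        elif dialect == "native":
            _write_native(model, path)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    except OSError as exc:
        raise ModelIOError(f"cannot write model to {path}: {exc}") from exc
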