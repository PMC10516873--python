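"""Model curation: declarative edit sets, heterologous pathway grafting and
trophic-condition constraints.

The curated *Synechocystis* network (iJN678_AK) is derived from the BiGG
iJN678 reconstruction by a literature edit set: TCA-cycle shunt reactions,
phosphoketolases, the Entner-Doudoroff pathway, light-independent L-serine
biosynthesis, prephenate/arogenate reactions, NDH-2 / alternative
respiratory terminal oxidase / flavodiiron additions, zero constraints on
cytochrome b6f, cytochrome c oxidase and one NAD(P)H dehydrogenase
isoform, a reversible-then-inactivated transhydrogenase, zeroed LEUTAi and
lumped glycine cleavage (replaced by three explicit reactions), and an ATP
maintenance pseudo-reaction.  All edits live in version-controlled YAML
(``data/curation_ijn678_ak.yaml``) so a user holding the original
supplementary tables can correct the transcription without code changes.

Four alkene biosynthesis pathways (isoprene, isobutene, ethylene,
1-undecene) ship the same way, each ending in a cytoplasmic export
pseudo-reaction that scenario layers may set as objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .core import (
    MetabolicModel,
    Metabolite,
    Reaction,
    check_mass_balance,
)
from .io import parse_stoichiometry_string

__all__ = [
    "CurationError",
    "EditSet",
    "PathwayDefinition",
    "TrophicCondition",
    "AUTOTROPHIC",
    "MIXOTROPHIC",
    "TROPHIC_PRESETS",
    "apply_edit_set",
    "add_atpm",
    "add_pathway",
    "set_trophic_condition",
    "build_ijn678_ak",
    "load_edit_set",
    "load_pathway",
    "shipped_curation_path",
    "shipped_pathway_path",
]

logger = logging.getLogger(__name__)

INF = float("inf")


class CurationError(ValueError):
    """Raised when an edit set or pathway cannot be applied."""


@dataclass
class EditSet:
    """A declarative model edit: new species, new reactions, bound changes
    and removals, applied in that order."""

    additions: list[Reaction] = field(default_factory=list)
    bound_changes: list[tuple[str, float, float]] = field(default_factory=list)
    removals: list[str] = field(default_factory=list)
    new_metabolites: list[Metabolite] = field(default_factory=list)
    name: str = "edit_set"


@dataclass
class PathwayDefinition:
    """A heterologous pathway plus its product export pseudo-reaction."""

    name: str
    reactions: list[Reaction]
    export_reaction_id: str
    new_metabolites: list[Metabolite] = field(default_factory=list)

    def validate(self) -> None:
        ids = [r.id for r in self.reactions]
        if self.export_reaction_id not in ids:
            raise CurationError(
                f"pathway {self.name!r}: export reaction "
                f"{self.export_reaction_id!r} is not among its reactions"
            )
        export = next(r for r in self.reactions if r.id == self.export_reaction_id)
        consumed = [m for m, c in export.stoichiometry.items() if c < 0]
        if len(export.stoichiometry) != 1 or len(consumed) != 1:
            raise CurationError(
                f"pathway {self.name!r}: export reaction must consume exactly "
                f"one product species, got {export.stoichiometry}"
            )


@dataclass(frozen=True)
class TrophicCondition:
    """Uptake bounds and biomass objective for one growth mode.

    ``uptake_bounds`` maps exchange reaction id to the maximal uptake rate
    (mmol/gDW/h); each is applied as ``lower_bound = -uptake`` on the
    exchange so secretion stays allowed, and an uptake of zero simply
    forbids import.
    """

    name: str
    uptake_bounds: dict[str, float]
    biomass_reaction_id: str


AUTOTROPHIC = TrophicCondition(
    name="autotrophic",
    uptake_bounds={
        "EX_co2_e": 0.0,
        "EX_hco3_e": 3.7,
        "EX_glc__D_e": 0.0,
        "EX_photon_e": 45.0,
    },
    biomass_reaction_id="BIOMASS_Ec_SynAuto",
)

MIXOTROPHIC = TrophicCondition(
    name="mixotrophic",
    uptake_bounds={
        "EX_co2_e": 0.0,
        "EX_hco3_e": 0.0,
        "EX_glc__D_e": 0.38,
        "EX_photon_e": 45.0,
    },
    biomass_reaction_id="BIOMASS_Ec_SynMixo",
)

TROPHIC_PRESETS = {"autotrophic": AUTOTROPHIC, "mixotrophic": MIXOTROPHIC}


# ---------------------------------------------------------------------------
# core edit application
# ---------------------------------------------------------------------------

def apply_edit_set(model: MetabolicModel, edit_set: EditSet) -> MetabolicModel:
    """Apply an edit set, returning a new model; the input is untouched.

    Additions are appended (id collisions are errors), bound changes replace
    bounds in order, removals drop reactions.  Every added reaction is
    mass-checked where formulas permit; imbalances are logged, not fatal
    (pseudo-reactions are legitimately unbalanced).
    """
    result = model.copy()
    existing_rxns = set(result.reaction_ids)

    offenders = [r.id for r in edit_set.additions if r.id in existing_rxns]
    if offenders:
        raise CurationError(f"edit {edit_set.name!r}: id collisions: {offenders}")
    dangling = [
        rid for rid, _, _ in edit_set.bound_changes if rid not in existing_rxns
    ] + [rid for rid in edit_set.removals if rid not in existing_rxns]
    if dangling:
        raise CurationError(
            f"edit {edit_set.name!r}: unknown reaction ids: {sorted(set(dangling))}"
        )

    for met in edit_set.new_metabolites:
        if not result.has_metabolite(met.id):
            result.metabolites.append(met)

    known_mets = set(result.metabolite_ids)
    for rxn in edit_set.additions:
        missing = set(rxn.stoichiometry) - known_mets
        if missing:
            raise CurationError(
                f"edit {edit_set.name!r}: reaction {rxn.id!r} references "
                f"undeclared metabolites: {sorted(missing)}"
            )
        result.reactions.append(rxn)
    result.validate()

    for rxn in edit_set.additions:
        balance = check_mass_balance(rxn, result)
        if not balance.skipped and not balance.unverifiable and not balance.balanced:
            logger.warning(
                "added reaction %s is elementally imbalanced: %s",
                rxn.id,
                balance.imbalance,
            )

    for rid, lb, ub in edit_set.bound_changes:
        result.replace_reaction(result.reaction(rid).with_bounds(lb, ub))

    if edit_set.removals:
        keep = set(result.reaction_ids) - set(edit_set.removals)
        result.reactions = [r for r in result.reactions if r.id in keep]
        result.objective_coefficients = {
            k: v for k, v in result.objective_coefficients.items() if k in keep
        }
    return result


def add_atpm(model: MetabolicModel, flux_floor: float = 0.0) -> MetabolicModel:
    """Add the non-growth-associated ATP maintenance pseudo-reaction
    (ATP + H2O -> ADP + Pi + H) with the given flux floor.

    The default floor of zero lets maintenance consumption emerge from the
    optimization rather than being imposed.
    """
    species = ["atp_c", "h2o_c", "adp_c", "pi_c", "h_c"]
    for met_id in species:
        if not model.has_metabolite(met_id):
            raise CurationError(f"cannot add ATPM: missing species {met_id!r}")
    atpm = Reaction(
        id="ATPM",
        name="ATP maintenance requirement",
        stoichiometry={"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
        lower_bound=flux_floor,
        upper_bound=INF,
        gene_associated=False,
        subsystem="Maintenance",
    )
    return apply_edit_set(model, EditSet(additions=[atpm], name="atpm"))


def add_pathway(model: MetabolicModel, pathway: PathwayDefinition) -> MetabolicModel:
    """Graft a heterologous pathway (plus export reaction) onto a model.

    The objective is left untouched; scenario layers decide whether the
    export becomes the objective.  The returned model is annotated
    ``<base>_<pathway name>``.
    """
    pathway.validate()
    declared = {m.id for m in pathway.new_metabolites}
    known = set(model.metabolite_ids)
    for rxn in pathway.reactions:
        unknown = set(rxn.stoichiometry) - known - declared
        if unknown:
            raise CurationError(
                f"pathway {pathway.name!r}: reaction {rxn.id!r} references "
                f"unknown precursor metabolites: {sorted(unknown)}"
            )
    edit = EditSet(
        additions=pathway.reactions,
        new_metabolites=pathway.new_metabolites,
        name=f"pathway:{pathway.name}",
    )
    result = apply_edit_set(model, edit)
    base = str(result.annotations.get("model_id", "model"))
    result.annotations["model_id"] = f"{base}_{pathway.name}"
    result.annotations["export_reaction"] = pathway.export_reaction_id
    return result


def set_trophic_condition(
    model: MetabolicModel, condition: TrophicCondition
) -> MetabolicModel:
    """Install a trophic condition: exchange uptake bounds and the biomass
    objective.

    Each uptake bound u becomes ``lower_bound = -u`` on the exchange (BiGG
    convention: uptake is negative flux); upper bounds are untouched so
    secretion stays possible.  The objective is cleared and set to the
    condition's biomass reaction; a scenario layer may override it with a
    product objective afterwards.  Idempotent.
    """
    result = model.copy()
    for ex_id, uptake in condition.uptake_bounds.items():
        try:
            rxn = result.reaction(ex_id)
        except KeyError:
            raise CurationError(
                f"trophic condition {condition.name!r}: no exchange {ex_id!r}"
            ) from None
        result.replace_reaction(rxn.with_bounds(-float(uptake), rxn.upper_bound))
    if not result.has_reaction(condition.biomass_reaction_id):
        raise CurationError(
            f"trophic condition {condition.name!r}: no biomass reaction "
            f"{condition.biomass_reaction_id!r}"
        )
    result.set_objective({condition.biomass_reaction_id: 1.0})
    result.annotations["trophic_condition"] = condition.name
    return result


# ---------------------------------------------------------------------------
# declarative config loading
# ---------------------------------------------------------------------------

def _reaction_from_row(row: dict) -> Reaction:
    def bound(value, default):
        if value is None:
            return default
        if isinstance(value, str) and value.strip().lower() in {"inf", "+inf", "-inf"}:
            return INF if not value.strip().startswith("-") else -INF
        return float(value)

    return Reaction(
        id=str(row["id"]),
        name=str(row.get("name", "")),
        stoichiometry=parse_stoichiometry_string(str(row["stoichiometry"])),
        lower_bound=bound(row.get("lower_bound"), 0.0),
        upper_bound=bound(row.get("upper_bound"), 1000.0),
        gene_associated=bool(row.get("gene_associated", True)),
        subsystem=str(row.get("subsystem", "")),
    )


def _metabolite_from_row(row: dict) -> Metabolite:
    return Metabolite(
        id=str(row["id"]),
        name=str(row.get("name", "")),
        compartment=str(row.get("compartment", "c")),
        formula=str(row.get("formula", "") or ""),
        charge=int(row.get("charge", 0)),
    )


def load_edit_set(path: str | Path) -> EditSet:
    """Load an edit set from a YAML config with sections ``new_metabolites``,
    ``additions``, ``bound_changes`` and ``removals``."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return EditSet(
            name=str(data.get("name", Path(path).stem)),
            new_metabolites=[
                _metabolite_from_row(r) for r in data.get("new_metabolites", [])
            ],
            additions=[_reaction_from_row(r) for r in data.get("additions", [])],
            bound_changes=[
                (str(bc["id"]), float(bc["lower_bound"]), float(bc["upper_bound"]))
                for bc in data.get("bound_changes", [])
            ],
            removals=[str(r) for r in data.get("removals", [])],
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise CurationError(f"malformed edit config {path}: {exc}") from exc


def load_pathway(path: str | Path) -> PathwayDefinition:
    """Load a pathway definition from YAML (reaction rows plus
    ``export_reaction_id``)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    try:
        pathway = PathwayDefinition(
            name=str(data["name"]),
            new_metabolites=[
                _metabolite_from_row(r) for r in data.get("new_metabolites", [])
            ],
            reactions=[_reaction_from_row(r) for r in data.get("reactions", [])],
            export_reaction_id=str(data["export_reaction_id"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise CurationError(f"malformed pathway config {path}: {exc}") from exc
    pathway.validate()
    return pathway


def shipped_curation_path() -> Path:
    return Path(resources.files("cyanoflux.data") / "curation_ijn678_ak.yaml")


def shipped_pathway_path(name: str) -> Path:
    path = Path(resources.files("cyanoflux.data") / "pathways" / f"{name}.yaml")
    if not path.exists():
        raise CurationError(f"no shipped pathway named {name!r}")
    return path


def build_ijn678_ak(
    base_model: MetabolicModel, curation_config: str | Path | None = None
) -> tuple[MetabolicModel, list[str]]:
    """Apply the full curation edit set to an iJN678-shaped model.

    Returns the curated model (annotated ``iJN678_AK``) together with a
    report listing every applied edit.  Any single failing edit aborts with
    the edit named; an already-curated model raises id-collision errors.
    """
    config = Path(curation_config) if curation_config else shipped_curation_path()
    edit_set = load_edit_set(config)
    report: list[str] = []
    try:
        model = apply_edit_set(base_model, edit_set)
    except CurationError as exc:
        raise CurationError(f"curation aborted ({config.name}): {exc}") from exc
    for met in edit_set.new_metabolites:
        report.append(f"metabolite {met.id}: declared")
    for rxn in edit_set.additions:
        report.append(f"addition {rxn.id}: [{rxn.lower_bound}, {rxn.upper_bound}]")
    for rid, lb, ub in edit_set.bound_changes:
        report.append(f"bounds {rid}: -> [{lb}, {ub}]")
    for rid in edit_set.removals:
        report.append(f"removal {rid}")
    model.annotations["model_id"] = "iJN678_AK"
    model.annotations["curation_config"] = str(config.name)
    model.annotations.setdefault(
        "biomass_reactions", ["BIOMASS_Ec_SynAuto", "BIOMASS_Ec_SynMixo"]
    )
    return model, report
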