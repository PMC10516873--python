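"""Core stoichiometric data model.

A :class:`MetabolicModel` is a plain in-memory description of a
stoichiometric network: metabolites, reactions with bounds, and a linear
objective.  Fluxes are expressed in mmol/gDW/h throughout; a biomass
pseudo-reaction's flux is the specific growth rate in 1/h.

Sign conventions follow BiGG: a boundary (exchange/demand/sink) reaction is
written ``met ->`` so that uptake is a negative flux and secretion a
positive one.  A reaction is irreversible iff its lower bound is >= 0.
"""

from __future__ import annotations

import hashlib
import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxState",
    "FormulaError",
    "ModelConsistencyError",
    "parse_formula",
    "formula_weight",
    "carbon_count",
    "stoichiometric_matrix",
    "check_mass_balance",
]

FEASIBILITY_TOL = 1e-6

# IUPAC 2021 standard atomic weights, abridged; enough for biomass-scale
# biochemistry.  Extend via the `extra` argument of formula_weight.
ATOMIC_WEIGHTS = {
    "C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007, "P": 30.974,
    "S": 32.06, "Fe": 55.845, "Mg": 24.305, "Ca": 40.078, "K": 39.098,
    "Na": 22.990, "Cl": 35.45, "Zn": 65.38, "Cu": 63.546, "Mn": 54.938,
    "Mo": 95.95, "Co": 58.933, "Se": 78.971, "R": 0.0, "X": 0.0,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for elemental formula strings that do not parse."""


class ModelConsistencyError(ValueError):
    """Raised when a model violates a structural invariant."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula string into an element -> count map.

    Empty strings are allowed and yield an empty map.  Counts omitted in the
    string default to 1 (``CH4`` -> ``{"C": 1, "H": 4}``).  Malformed input
    raises :class:`FormulaError` naming the offending position.
    """
    counts: dict[str, int] = {}
    pos = 0
    n = len(formula)
    while pos < n:
        m = _FORMULA_TOKEN.match(formula, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(
                f"malformed formula {formula!r} at position {pos}: "
                f"expected element symbol, found {formula[pos:pos + 3]!r}"
            )
        element, digits = m.group(1), m.group(2)
        count = int(digits) if digits else 1
        if count <= 0:
            raise FormulaError(
                f"malformed formula {formula!r} at position {pos}: "
                "element counts must be positive"
            )
        counts[element] = counts.get(element, 0) + count
        pos = m.end()
    return counts


def formula_weight(formula: str, extra: dict[str, float] | None = None) -> float:
    """Molecular weight (g/mol) of an elemental formula string."""
    weights = dict(ATOMIC_WEIGHTS)
    if extra:
        weights.update(extra)
    total = 0.0
    for element, count in parse_formula(formula).items():
        if element not in weights:
            raise FormulaError(f"no atomic weight for element {element!r}")
        total += weights[element] * count
    return total


def carbon_count(formula: str) -> int:
    """Number of carbon atoms in a formula string (0 for empty formulas)."""
    return parse_formula(formula).get("C", 0)


@dataclass(frozen=True)
class Metabolite:
    """A chemical species localized to one compartment."""

    id: str
    name: str = ""
    compartment: str = "c"
    formula: str = ""
    charge: int = 0

    def __post_init__(self) -> None:
        parse_formula(self.formula)  # validate eagerly


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric conversion with flux bounds.

    ``stoichiometry`` maps metabolite id to a signed coefficient; negative
    coefficients are consumed, positive produced.  ``gene_associated`` marks
    enzyme-catalyzed reactions subject to the parsimonious flux penalty;
    boundary, biomass and maintenance pseudo-reactions carry ``False``.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    name: str = ""
    gene_associated: bool = True
    subsystem: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelConsistencyError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} "
                f"exceeds upper bound {self.upper_bound}"
            )

    @property
    def is_boundary(self) -> bool:
        """True for exchange/demand/sink pseudo-reactions (one participant)."""
        return len(self.stoichiometry) <= 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def with_bounds(self, lower: float, upper: float) -> "Reaction":
        return replace(self, lower_bound=lower, upper_bound=upper)


@dataclass
class MetabolicModel:
    """A stoichiometric network with bounds and a linear objective."""

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective_coefficients: dict[str, float] = field(default_factory=dict)
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ---------------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return next(m for m in self.metabolites if m.id == met_id)
        except StopIteration:
            raise KeyError(f"no metabolite {met_id!r} in model") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return next(r for r in self.reactions if r.id == rxn_id)
        except StopIteration:
            raise KeyError(f"no reaction {rxn_id!r} in model") from None

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    def has_metabolite(self, met_id: str) -> bool:
        return any(m.id == met_id for m in self.metabolites)

    # -- structure -------------------------------------------------------

    def validate(self) -> None:
        met_ids = self.metabolite_ids
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ModelConsistencyError(f"duplicate metabolite ids: {dup}")
        rxn_ids = self.reaction_ids
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ModelConsistencyError(f"duplicate reaction ids: {dup}")
        met_set = set(met_ids)
        for rxn in self.reactions:
            missing = set(rxn.stoichiometry) - met_set
            if missing:
                raise ModelConsistencyError(
                    f"reaction {rxn.id!r} references unknown metabolites: "
                    f"{sorted(missing)}"
                )
        rxn_set = set(rxn_ids)
        dangling = set(self.objective_coefficients) - rxn_set
        if dangling:
            raise ModelConsistencyError(
                f"objective references unknown reactions: {sorted(dangling)}"
            )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            objective_coefficients=dict(self.objective_coefficients),
            annotations={
                k: (dict(v) if isinstance(v, dict) else list(v) if isinstance(v, list) else v)
                for k, v in self.annotations.items()
            },
        )

    def set_objective(self, coefficients: dict[str, float]) -> None:
        missing = set(coefficients) - set(self.reaction_ids)
        if missing:
            raise ModelConsistencyError(
                f"objective references unknown reactions: {sorted(missing)}"
            )
        self.objective_coefficients = dict(coefficients)

    def replace_reaction(self, rxn: Reaction) -> None:
        for idx, existing in enumerate(self.reactions):
            if existing.id == rxn.id:
                self.reactions[idx] = rxn
                return
        raise KeyError(f"no reaction {rxn.id!r} in model")

    def content_hash(self) -> str:
        """Stable SHA-256 over the model content (ids, stoichiometry, bounds,
        objective); used by run manifests to pin provenance."""
        h = hashlib.sha256()
        for m in self.metabolites:
            h.update(f"M|{m.id}|{m.name}|{m.compartment}|{m.formula}|{m.charge}\n".encode())
        for r in self.reactions:
            stoich = ";".join(f"{k}:{r.stoichiometry[k]!r}" for k in sorted(r.stoichiometry))
            h.update(
                f"R|{r.id}|{r.name}|{stoich}|{r.lower_bound!r}|{r.upper_bound!r}"
                f"|{int(r.gene_associated)}|{r.subsystem}\n".encode()
            )
        obj = ";".join(
            f"{k}:{self.objective_coefficients[k]!r}"
            for k in sorted(self.objective_coefficients)
        )
        h.update(f"O|{obj}".encode())
        return h.hexdigest()


@dataclass
class FluxState:
    """One steady-state flux vector with its objective value and status."""

    fluxes: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded
    method: str  # fba | pfba | loopless | two_step
    meta: dict = field(default_factory=dict)

    def flux(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    def as_vector(self, model: MetabolicModel) -> np.ndarray:
        return np.array([self.fluxes[r] for r in model.reaction_ids])


def stoichiometric_matrix(model: MetabolicModel, sparse_format: bool = False):
    """Stoichiometric matrix S with metabolites as rows, reactions as columns.

    Row order follows ``model.metabolites``, column order ``model.reactions``.
    Returns a dense ndarray by default or a CSR matrix on request.
    """
    n_met = len(model.metabolites)
    n_rxn = len(model.reactions)
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rows, cols, data = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            rows.append(met_index[met_id])
            cols.append(j)
            data.append(float(coeff))
    mat = sparse.csr_matrix((data, (rows, cols)), shape=(n_met, n_rxn))
    return mat if sparse_format else mat.toarray()


@dataclass(frozen=True)
class MassBalanceResult:
    """Per-element imbalance of one reaction.

    ``imbalance`` maps element -> sum over participants of coefficient times
    atom count; an all-zero map means elementally balanced.  Boundary and
    declared pseudo-reactions are skipped, and reactions touching a
    metabolite with an empty formula are unverifiable rather than wrong.
    """

    reaction_id: str
    imbalance: dict[str, float]
    skipped: bool = False
    unverifiable: bool = False

    @property
    def balanced(self) -> bool:
        return (
            not self.skipped
            and not self.unverifiable
            and all(abs(v) < 1e-9 for v in self.imbalance.values())
        )


def check_mass_balance(
    reaction: Reaction,
    model: MetabolicModel,
    pseudo_reactions: set[str] | frozenset[str] = frozenset(),
) -> MassBalanceResult:
    """Elemental balance check for one reaction against the model's formulas."""
    if reaction.is_boundary or reaction.id in pseudo_reactions:
        return MassBalanceResult(reaction.id, {}, skipped=True)
    totals: dict[str, float] = {}
    for met_id, coeff in reaction.stoichiometry.items():
        formula = model.metabolite(met_id).formula
        if not formula:
            return MassBalanceResult(reaction.id, {}, unverifiable=True)
        for element, count in parse_formula(formula).items():
            totals[element] = totals.get(element, 0.0) + coeff * count
    return MassBalanceResult(reaction.id, totals)


def steady_state_residual(model: MetabolicModel, flux_state: FluxState) -> float:
    """Infinity norm of S.v for a flux state; ~0 at steady state."""
    s = stoichiometric_matrix(model, sparse_format=True)
    v = flux_state.as_vector(model)
    if s.shape[0] == 0:
        return 0.0
    return float(np.max(np.abs(s @ v)))


def bound_violation(model: MetabolicModel, flux_state: FluxState) -> float:
    """Largest amount by which any flux leaves its bounds (0 if none)."""
    worst = 0.0
    for rxn in model.reactions:
        v = flux_state.fluxes[rxn.id]
        worst = max(worst, rxn.lower_bound - v, v - rxn.upper_bound)
    return max(worst, 0.0)


def assert_feasible(
    model: MetabolicModel, flux_state: FluxState, tol: float = FEASIBILITY_TOL
) -> None:
    """Raise if an allegedly optimal flux state violates mass balance or bounds."""
    if flux_state.status != "optimal":
        return
    residual = steady_state_residual(model, flux_state)
    if residual > tol:
        raise ModelConsistencyError(
            f"steady-state residual {residual:.3e} exceeds tolerance {tol:g}"
        )
    violation = bound_violation(model, flux_state)
    if violation > tol:
        raise ModelConsistencyError(
            f"flux bound violation {violation:.3e} exceeds tolerance {tol:g}"
        )


def net_metabolite_rates(model: MetabolicModel, flux_state: FluxState) -> dict[str, float]:
    """Per-metabolite net production rate sum_j S_ij v_j (zero at steady state)."""
    s = stoichiometric_matrix(model, sparse_format=True)
    v = flux_state.as_vector(model)
    rates = s @ v
    return {m.id: float(rates[i]) for i, m in enumerate(model.metabolites)}


def infinity() -> float:
    return math.inf
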