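"""Metabolite-centric flux analysis and production-strain evaluation.

The flux-sum of a metabolite i under a steady-state flux vector v is

    Phi_i = sum_{j in P_i} S_ij v_j = sum_{j in C_i} S_ij v_j
          = 0.5 * sum_j |S_ij v_j|

where P_i / C_i are the reactions producing / consuming i.  Because net
accumulation is zero at steady state, production and consumption agree and
Phi_i is a proxy for the metabolite's turnover rate (pool usage).  The
module also derives cofactor turnover reports (ATP, NADPH, NADH and the
ATP/NADPH ratio) and productivity / mass-yield / c-mol-yield summaries for
production strains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .core import (
    FluxState,
    MetabolicModel,
    carbon_count,
    formula_weight,
)

__all__ = [
    "FluxSumReport",
    "CofactorReport",
    "YieldReport",
    "flux_sum",
    "producer_consumer_table",
    "cofactor_report",
    "yields",
]

# contributions below this are numerical noise, not metabolism
_ZERO_TOL = 1e-9

#: display convention for table outputs: fluxes below this render as zero
DISPLAY_THRESHOLD = 0.01

DEFAULT_COFACTORS = {"atp": "atp_c", "nadph": "nadph_c", "nadh": "nadh_c"}


@dataclass
class FluxSumReport:
    """Turnover of one metabolite with its producer/consumer breakdown.

    ``producers``/``consumers`` hold ``(reaction_id, contribution, percent)``
    tuples; contributions are |S_ij v_j| and percents are shares of Phi.
    """

    metabolite_id: str
    phi: float
    producers: list[tuple[str, float, float]] = field(default_factory=list)
    consumers: list[tuple[str, float, float]] = field(default_factory=list)

    @property
    def production(self) -> float:
        return sum(c for _, c, _ in self.producers)

    @property
    def consumption(self) -> float:
        return sum(c for _, c, _ in self.consumers)


@dataclass
class CofactorReport:
    """Energy/redox carrier turnover and the ATP/NADPH ratio.

    ``atp_nadph_ratio`` is ``None`` (undefined) when the NADPH flux-sum is
    zero rather than an infinity.
    """

    atp_turnover: float
    nadph_turnover: float
    nadh_turnover: float
    atp_nadph_ratio: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"carrier": "ATP", "turnover": self.atp_turnover},
                {"carrier": "NADPH", "turnover": self.nadph_turnover},
                {"carrier": "NADH", "turnover": self.nadh_turnover},
                {
                    "carrier": "ATP/NADPH",
                    "turnover": (
                        self.atp_nadph_ratio
                        if self.atp_nadph_ratio is not None
                        else math.nan
                    ),
                },
            ]
        )


@dataclass
class YieldReport:
    """Productivity and yields of one objective under one scenario.

    productivity: 1/h for biomass, mmol/gDW/h for products.
    mass_yield:  g product per g substrate consumed.
    cmol_yield:  mol C in product per mol C in substrate.
    """

    objective_id: str
    productivity: float
    mass_yield: float | None
    cmol_yield: float | None
    substrate_uptake: dict[str, float] = field(default_factory=dict)
    diagnostics: str = ""


def flux_sum(
    model: MetabolicModel,
    flux_state: FluxState,
    metabolite_id: str,
    threshold: float = _ZERO_TOL,
) -> FluxSumReport:
    """Flux-sum of one metabolite with producer/consumer attribution.

    Reactions with ``S_ij v_j`` above ``threshold`` are producers, below
    ``-threshold`` consumers; each reaction sits on exactly one side per
    solution.  Phi is computed as half the absolute weighted flux sum.
    An inactive metabolite yields Phi = 0 and empty sides.
    """
    model.metabolite(metabolite_id)  # raise on unknown id
    producers: list[tuple[str, float, float]] = []
    consumers: list[tuple[str, float, float]] = []
    half_abs = 0.0
    for rxn in model.reactions:
        coeff = rxn.stoichiometry.get(metabolite_id)
        if coeff is None:
            continue
        rate = coeff * flux_state.fluxes[rxn.id]
        half_abs += abs(rate)
        if rate > threshold:
            producers.append((rxn.id, rate, 0.0))
        elif rate < -threshold:
            consumers.append((rxn.id, -rate, 0.0))
    phi = 0.5 * half_abs
    if phi > 0:
        producers = [(r, c, 100.0 * c / phi) for r, c, _ in producers]
        consumers = [(r, c, 100.0 * c / phi) for r, c, _ in consumers]
    producers.sort(key=lambda t: -t[1])
    consumers.sort(key=lambda t: -t[1])
    return FluxSumReport(
        metabolite_id=metabolite_id, phi=phi, producers=producers, consumers=consumers
    )


def producer_consumer_table(
    model: MetabolicModel,
    flux_state: FluxState,
    metabolite_id: str,
    display_threshold: float = DISPLAY_THRESHOLD,
) -> pd.DataFrame:
    """Formatted producer/consumer breakdown of one metabolite.

    Rows are sorted by contribution within each side.  Contributions below
    ``display_threshold`` are rendered as zero in the ``display_flux``
    column but keep their exact values in the percent bookkeeping, matching
    the reporting convention for small fluxes.
    """
    report = flux_sum(model, flux_state, metabolite_id)
    rows = []
    for side, entries in (("producer", report.producers), ("consumer", report.consumers)):
        for rxn_id, contribution, percent in entries:
            signed = contribution if side == "producer" else -contribution
            rows.append(
                {
                    "metabolite": metabolite_id,
                    "side": side,
                    "reaction": rxn_id,
                    "flux_contribution": signed,
                    "display_flux": (
                        0.0 if contribution < display_threshold else round(signed, 2)
                    ),
                    "percent": percent,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "metabolite", "side", "reaction", "flux_contribution",
            "display_flux", "percent",
        ],
    )


def cofactor_report(
    model: MetabolicModel,
    flux_state: FluxState,
    cofactor_ids: dict[str, str] | None = None,
    aggregate_compartments: bool = False,
) -> CofactorReport:
    """ATP/NADPH/NADH turnover rates and the ATP/NADPH ratio.

    By default the cytoplasmic species (``atp_c``/``nadph_c``/``nadh_c``)
    are used; with ``aggregate_compartments=True`` flux-sums of all species
    sharing the same base id (prefix before the compartment suffix) are
    summed.
    """
    ids = dict(DEFAULT_COFACTORS)
    if cofactor_ids:
        ids.update(cofactor_ids)

    def turnover(met_id: str) -> float:
        if aggregate_compartments:
            base = met_id.rsplit("_", 1)[0]
            total = 0.0
            for met in model.metabolites:
                if met.id.rsplit("_", 1)[0] == base:
                    total += flux_sum(model, flux_state, met.id).phi
            return total
        return flux_sum(model, flux_state, met_id).phi

    atp = turnover(ids["atp"])
    nadph = turnover(ids["nadph"])
    nadh = turnover(ids["nadh"])
    ratio = atp / nadph if nadph > _ZERO_TOL else None
    return CofactorReport(
        atp_turnover=atp,
        nadph_turnover=nadph,
        nadh_turnover=nadh,
        atp_nadph_ratio=ratio,
    )


def yields(
    model: MetabolicModel,
    flux_state: FluxState,
    product_id: str,
    substrate_exchange_ids: list[str],
    product_mass: float | None = None,
    substrate_masses: dict[str, float] | None = None,
    productivity_flux_id: str | None = None,
) -> YieldReport:
    """Productivity, mass yield and c-mol yield of one objective.

    ``product_id`` is the exported/objective reaction; its flux is the
    productivity (for a biomass objective this is the growth rate in 1/h).
    Substrate uptake is read as the absolute value of negative fluxes
    through the listed exchange reactions.  Masses (g/mmol) default to
    values computed from the metabolite formulas; c-mol accounting always
    uses the formulas.  Zero total substrate uptake yields undefined yields
    with a diagnostic instead of a division error.
    """
    flux_id = productivity_flux_id or product_id
    productivity = flux_state.fluxes[flux_id]

    def sole_metabolite(rxn_id: str) -> str:
        stoich = model.reaction(rxn_id).stoichiometry
        if len(stoich) != 1:
            raise ValueError(
                f"reaction {rxn_id!r} is not a single-metabolite boundary reaction"
            )
        return next(iter(stoich))

    uptakes: dict[str, float] = {}
    for ex_id in substrate_exchange_ids:
        flux = flux_state.fluxes[ex_id]
        uptakes[ex_id] = max(-flux, 0.0)
    total_uptake = sum(uptakes.values())
    if total_uptake <= _ZERO_TOL:
        return YieldReport(
            objective_id=product_id,
            productivity=productivity,
            mass_yield=None,
            cmol_yield=None,
            substrate_uptake=uptakes,
            diagnostics="zero substrate uptake: yields undefined",
        )

    product_met = sole_metabolite(product_id)
    product_formula = model.metabolite(product_met).formula
    c_product = carbon_count(product_formula)
    if product_mass is None:
        product_mass = formula_weight(product_formula) / 1000.0 if product_formula else None

    mass_denominator = 0.0
    cmol_denominator = 0.0
    mass_ok = product_mass is not None
    for ex_id, uptake in uptakes.items():
        met = model.metabolite(sole_metabolite(ex_id))
        if substrate_masses and ex_id in substrate_masses:
            mass_denominator += uptake * substrate_masses[ex_id]
        elif met.formula:
            mass_denominator += uptake * formula_weight(met.formula) / 1000.0
        else:
            mass_ok = False
        cmol_denominator += uptake * carbon_count(met.formula)

    mass_yield = (
        productivity * product_mass / mass_denominator
        if mass_ok and mass_denominator > 0
        else None
    )
    cmol_yield = (
        productivity * c_product / cmol_denominator if cmol_denominator > 0 else None
    )
    return YieldReport(
        objective_id=product_id,
        productivity=productivity,
        mass_yield=mass_yield,
        cmol_yield=cmol_yield,
        substrate_uptake=uptakes,
    )
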