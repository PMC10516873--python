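"""Small stoichiometric networks with known analytic properties.

Every pipeline stage is testable against these generators without any
external model download:

* linear chains with a unique optimum,
* a frozen minimal phototroph with hand-derived closed-form optima,
* a chain carrying a thermodynamically infeasible internal cycle,
* random feasible networks built by planting a flux vector in the null
  space of a randomly drawn stoichiometric matrix.

Randomness is confined to this module and controlled by a single integer
seed; the rest of the pipeline is deterministic linear programming.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np

from .core import MetabolicModel, Metabolite, Reaction
from .io import read_native

__all__ = [
    "make_linear_chain",
    "make_phototroph_toy",
    "make_internal_cycle_model",
    "make_random_feasible",
    "PHOTOTROPH_CLOSED_FORMS",
]

#: Hand-derived optima of the frozen phototroph toy (see docs/methods.md for
#: the derivation).  Photon uptake is capped at 45; linear electron flow
#: yields 0.32 ATP and 0.25 NADPH per photon (output ratio 1.28); fixing one
#: CO2 costs 3 ATP + 2 NADPH; one biomass unit costs one fixed carbon plus
#: 1 ATP, one product unit one fixed carbon plus 2 ATP + 1 NADPH.  ATP is
#: the binding resource over the whole biomass/product frontier, giving
#:   4 mu + 5 p = 0.32 * 45 = 14.4
#: hence mu_max = 3.6, p_max = 2.88, and a linear frontier
#:   p(mu) = p_max * (1 - mu / mu_max).
#: At either optimum the photon budget is saturated, so the ATP flux-sum is
#: 14.4 and the NADPH flux-sum 11.25 (surplus NADPH leaves through the
#: flavodiiron-like valve), with ATP/NADPH = 1.28.
PHOTOTROPH_CLOSED_FORMS = {
    "photon_bound": 45.0,
    "lef_atp_per_photon": 0.32,
    "lef_nadph_per_photon": 0.25,
    "lef_atp_nadph_ratio": 1.28,
    "mu_max": 3.6,
    "p_max": 2.88,
    "two_step_product_at_0.10": 2.592,
    "atp_flux_sum_biomass": 14.4,
    "nadph_flux_sum_biomass": 11.25,
    "nadh_flux_sum_biomass": 0.0,
    "atp_nadph_ratio_biomass": 1.28,
    "co2_uptake_biomass": 3.6,
    "flv_flux_biomass": 4.05,
}


def make_linear_chain(n_steps: int, uptake_bound: float) -> MetabolicModel:
    """An uptake -> n-step conversion -> secretion chain.

    The flux polytope is a single line: every reaction carries exactly the
    secretion flux, and the maximal secretion equals ``uptake_bound``.
    Interior conversions are gene-associated; the two exchanges are not.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if uptake_bound < 0:
        raise ValueError("uptake_bound must be >= 0")
    metabolites = [
        Metabolite(id=f"m{i}_c", name=f"chain metabolite {i}") for i in range(n_steps + 1)
    ]
    reactions = [
        Reaction(
            id="EX_in",
            name="substrate exchange",
            stoichiometry={"m0_c": -1},
            lower_bound=-uptake_bound,
            upper_bound=0.0,
            gene_associated=False,
        )
    ]
    for i in range(n_steps):
        reactions.append(
            Reaction(
                id=f"STEP{i + 1}",
                name=f"conversion {i + 1}",
                stoichiometry={f"m{i}_c": -1, f"m{i + 1}_c": 1},
                lower_bound=0.0,
                upper_bound=1000.0,
            )
        )
    reactions.append(
        Reaction(
            id="EX_out",
            name="product exchange",
            stoichiometry={f"m{n_steps}_c": -1},
            lower_bound=0.0,
            upper_bound=1000.0,
            gene_associated=False,
        )
    )
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective_coefficients={"EX_out": 1.0},
        annotations={"model_id": f"linear_chain_{n_steps}"},
    )


def make_phototroph_toy() -> MetabolicModel:
    """Load the frozen minimal phototroph fixture.

    The stoichiometry ships as native-dialect data files so the
    hand-derived constants in :data:`PHOTOTROPH_CLOSED_FORMS` stay valid;
    see that constant and docs/methods.md for the closed-form solution.
    """
    path = Path(resources.files("cyanoflux.data") / "phototroph_toy")
    return read_native(path)


def make_internal_cycle_model(cycle_len: int = 3) -> MetabolicModel:
    """A linear chain plus an internal directed cycle detached from all
    exchanges.

    The cycle can carry arbitrary flux without affecting any exchange —
    exactly the thermodynamically infeasible mode that loopless correction
    must remove.  FVA without loop correction reports the full bound range
    for cycle reactions; with correction their range collapses to zero.
    """
    if cycle_len < 3:
        raise ValueError("cycle_len must be >= 3")
    model = make_linear_chain(2, 10.0)
    metabolites = list(model.metabolites) + [
        Metabolite(id=f"c{i}_c", name=f"cycle metabolite {i}") for i in range(cycle_len)
    ]
    cycle_reactions = [
        Reaction(
            id=f"CYC{i + 1}",
            name=f"cycle step {i + 1}",
            stoichiometry={f"c{i}_c": -1, f"c{(i + 1) % cycle_len}_c": 1},
            lower_bound=0.0,
            upper_bound=1000.0,
        )
        for i in range(cycle_len)
    ]
    return MetabolicModel(
        metabolites=metabolites,
        reactions=list(model.reactions) + cycle_reactions,
        objective_coefficients=dict(model.objective_coefficients),
        annotations={"model_id": f"internal_cycle_{cycle_len}"},
    )


def make_random_feasible(n_mets: int, n_rxns: int, seed: int) -> MetabolicModel:
    """A random stoichiometric network that is feasible by construction.

    A strictly positive flux vector is sampled first; a sparse random S is
    then adjusted so the vector lies in its null space (the last column
    absorbs the residual), and bounds are drawn to enclose the planted
    vector.  Deterministic per seed.
    """
    if n_mets < 2 or n_rxns <= n_mets:
        raise ValueError("need n_rxns > n_mets >= 2")
    rng = np.random.default_rng(seed)
    v = rng.uniform(1.0, 5.0, size=n_rxns)
    s = np.zeros((n_mets, n_rxns))
    for j in range(n_rxns - 1):
        k = rng.integers(2, min(4, n_mets) + 1)
        rows = rng.choice(n_mets, size=k, replace=False)
        s[rows, j] = rng.choice([-2.0, -1.0, 1.0, 2.0], size=k)
    residual = s[:, :-1] @ v[:-1]
    s[:, -1] = -residual / v[-1]
    assert np.allclose(s @ v, 0)
    metabolites = [Metabolite(id=f"m{i}_c") for i in range(n_mets)]
    reactions = []
    for j in range(n_rxns):
        stoich = {f"m{i}_c": float(s[i, j]) for i in range(n_mets) if s[i, j] != 0.0}
        lower = 0.0 if rng.random() < 0.7 else -float(rng.uniform(1.0, 10.0))
        upper = float(v[j] + rng.uniform(1.0, 10.0))
        reactions.append(
            Reaction(
                id=f"R{j}",
                stoichiometry=stoich,
                lower_bound=lower,
                upper_bound=upper,
            )
        )
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective_coefficients={reactions[-1].id: 1.0},
        annotations={"model_id": f"random_feasible_{n_mets}x{n_rxns}_s{seed}"},
    )
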