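"""Shared fixtures and independent LP oracles for the test suite.

The oracles here deliberately re-derive results through formulations that
differ from the package's own (vertex enumeration instead of simplex,
epigraph absolute values instead of reversible splits, per-reaction LPs
built from scratch) so agreement is evidence, not tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import linprog

from cyanoflux.core import MetabolicModel, Metabolite, Reaction, stoichiometric_matrix
from cyanoflux.synthetic import (
    make_internal_cycle_model,
    make_linear_chain,
    make_phototroph_toy,
)


@pytest.fixture
def chain():
    return make_linear_chain(3, 10.0)


@pytest.fixture
def toy():
    return make_phototroph_toy()


@pytest.fixture
def cycle_model():
    return make_internal_cycle_model(3)


@pytest.fixture
def parallel_routes():
    """A -> B through two equal single-step routes; classic alternate optima."""
    mets = [Metabolite(id="a_c"), Metabolite(id="b_c")]
    rxns = [
        Reaction(id="EX_a", stoichiometry={"a_c": -1}, lower_bound=-10, upper_bound=0,
                 gene_associated=False),
        Reaction(id="R1", stoichiometry={"a_c": -1, "b_c": 1}),
        Reaction(id="R2", stoichiometry={"a_c": -1, "b_c": 1}),
        Reaction(id="EX_b", stoichiometry={"b_c": -1}, lower_bound=0, upper_bound=1000,
                 gene_associated=False),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns,
                          objective_coefficients={"EX_b": 1.0})


@pytest.fixture
def detour_routes():
    """A -> B directly or through an intermediate; pFBA must take the shortcut."""
    mets = [Metabolite(id="a_c"), Metabolite(id="b_c"), Metabolite(id="x_c")]
    rxns = [
        Reaction(id="EX_a", stoichiometry={"a_c": -1}, lower_bound=-10, upper_bound=0,
                 gene_associated=False),
        Reaction(id="DIRECT", stoichiometry={"a_c": -1, "b_c": 1}),
        Reaction(id="DETOUR1", stoichiometry={"a_c": -1, "x_c": 1}),
        Reaction(id="DETOUR2", stoichiometry={"x_c": -1, "b_c": 1}),
        Reaction(id="EX_b", stoichiometry={"b_c": -1}, lower_bound=0, upper_bound=1000,
                 gene_associated=False),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns,
                          objective_coefficients={"EX_b": 1.0})


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def vertex_enumeration_optimum(model: MetabolicModel, objective_id: str) -> float:
    """Brute-force FBA oracle: enumerate basic feasible solutions of the flux
    polytope {v : S v = 0, lb <= v <= ub} and return the best objective.

    Fixes (n - rank S) fluxes at a bound, solves the remaining square system,
    keeps feasible solutions.  Exponential; only for tiny models with finite
    bounds.
    """
    s = stoichiometric_matrix(model)
    n = s.shape[1]
    rank = np.linalg.matrix_rank(s) if s.size else 0
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    assert np.all(np.isfinite(lb)) and np.all(np.isfinite(ub)), "finite bounds only"
    j_obj = model.reaction_ids.index(objective_id)
    n_fix = n - rank
    best = -math.inf
    for fixed in itertools.combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed]
        a_free = s[:, free]
        for corners in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            rhs = -s[:, fixed] @ np.array(corners)
            sol, residuals, rk, _ = np.linalg.lstsq(a_free, rhs, rcond=None)
            v = np.empty(n)
            v[list(fixed)] = corners
            v[free] = sol
            if np.max(np.abs(s @ v)) > 1e-8:
                continue
            if np.any(v < lb - 1e-8) or np.any(v > ub + 1e-8):
                continue
            best = max(best, v[j_obj])
    return best


def epigraph_pfba_oracle(model: MetabolicModel, objective_id: str | None = None):
    """Independent pFBA oracle using the t_j >= |v_j| epigraph formulation.

    Returns (fba_optimum, minimal L1 norm over gene-associated reactions).
    """
    s = stoichiometric_matrix(model)
    n = s.shape[1]
    c = np.zeros(n)
    if objective_id is not None:
        c[model.reaction_ids.index(objective_id)] = 1.0
    else:
        for rid, coeff in model.objective_coefficients.items():
            c[model.reaction_ids.index(rid)] = coeff
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    bounds = [
        (None if math.isinf(lo) else lo, None if math.isinf(hi) else hi)
        for lo, hi in bounds
    ]
    res = linprog(-c, A_eq=s, b_eq=np.zeros(s.shape[0]), bounds=bounds, method="highs")
    assert res.status == 0, res.message
    z_star = float(c @ res.x)

    pen = [j for j, r in enumerate(model.reactions) if r.gene_associated]
    n_pen = len(pen)
    # variables: v | t ;  t_j >= v_j and t_j >= -v_j
    a_ub = np.zeros((2 * n_pen, n + n_pen))
    for k, j in enumerate(pen):
        a_ub[2 * k, j] = 1.0
        a_ub[2 * k, n + k] = -1.0
        a_ub[2 * k + 1, j] = -1.0
        a_ub[2 * k + 1, n + k] = -1.0
    a_eq = np.hstack([s, np.zeros((s.shape[0], n_pen))])
    a_eq = np.vstack([a_eq, np.concatenate([c, np.zeros(n_pen)])])
    b_eq = np.concatenate([np.zeros(s.shape[0]), [z_star]])
    obj = np.concatenate([np.zeros(n), np.ones(n_pen)])
    res2 = linprog(
        obj, A_ub=a_ub, b_ub=np.zeros(2 * n_pen), A_eq=a_eq, b_eq=b_eq,
        bounds=bounds + [(0, None)] * n_pen, method="highs",
    )
    assert res2.status == 0, res2.message
    return z_star, float(np.sum(res2.x[n:]))


def per_reaction_fva_oracle(model: MetabolicModel, objective_id: str, fraction: float):
    """Independent FVA oracle: one freshly built LP per reaction per sense."""
    s = stoichiometric_matrix(model)
    n = s.shape[1]
    c = np.zeros(n)
    c[model.reaction_ids.index(objective_id)] = 1.0
    bounds = [
        (None if math.isinf(r.lower_bound) else r.lower_bound,
         None if math.isinf(r.upper_bound) else r.upper_bound)
        for r in model.reactions
    ]
    base = linprog(-c, A_eq=s, b_eq=np.zeros(s.shape[0]), bounds=bounds, method="highs")
    assert base.status == 0
    z_star = float(c @ base.x)
    a_ub = -c.reshape(1, -1)
    b_ub = np.array([-fraction * z_star])
    lo, hi = {}, {}
    for j, rid in enumerate(model.reaction_ids):
        e = np.zeros(n)
        e[j] = 1.0
        for sign, store in ((1.0, lo), (-1.0, hi)):
            res = linprog(sign * e, A_ub=a_ub, b_ub=b_ub, A_eq=s,
                          b_eq=np.zeros(s.shape[0]), bounds=bounds, method="highs")
            assert res.status == 0, f"{rid}: {res.message}"
            store[rid] = float(res.x[j])
    return lo, hi
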