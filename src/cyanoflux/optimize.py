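"""Constraint-based optimization.

Implements the linear-programming layer of the pipeline:

* FBA — maximize (or minimize) a linear objective c.v subject to steady
  state S.v = 0 and flux bounds.
* pFBA — fix the FBA optimum, then minimize the summed absolute flux
  through gene-associated reactions, realized by splitting each penalized
  reaction into two non-negative components.
* FVA — per-reaction flux minima/maxima at a stated fraction of the
  optimum, optionally cycle-corrected.
* Loopless correction — removal of flux around internal cycles that carry
  no exchange.  The default is a post-hoc L1 minimization with boundary
  fluxes and objective fixed (CycleFreeFlux-style LP); a strict MILP
  loop-law mode is available for small instances.
* Two-step biomass-coupled production and phenotypic phase planes.

All LPs are solved with scipy's HiGHS interface using deterministic
settings, so repeated runs agree at reporting precision.  Degenerate LPs
still admit alternate optima; pFBA narrows but does not always uniquify
individual fluxes, and downstream reporting compares fluxes at 1e-4.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize as scipy_opt
from scipy.linalg import null_space

from .core import (
    FEASIBILITY_TOL,
    FluxState,
    MetabolicModel,
    assert_feasible,
    stoichiometric_matrix,
)

__all__ = [
    "OptimizationError",
    "FvaResult",
    "PhasePlane",
    "fba",
    "pfba",
    "fva",
    "remove_loops",
    "two_step_optimize",
    "phenotypic_phase_plane",
]

logger = logging.getLogger(__name__)

SOLVER_TOL = 1e-9
_BIG = 1e6  # artificial box used only to diagnose unbounded rays
_MILP_BIG = 1000.0


class OptimizationError(RuntimeError):
    """Raised when an optimization cannot deliver a usable result."""


@dataclass
class FvaResult:
    """Per-reaction flux ranges at a stated fraction of the optimum."""

    fraction: float
    minimum: dict[str, float]
    maximum: dict[str, float]
    failures: dict[str, str] = field(default_factory=dict)

    def range(self, rxn_id: str) -> tuple[float, float]:
        return self.minimum[rxn_id], self.maximum[rxn_id]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"reaction": r, "minimum": self.minimum[r], "maximum": self.maximum[r]}
            for r in self.minimum
        ]
        return pd.DataFrame(rows, columns=["reaction", "minimum", "maximum"])


@dataclass
class PhasePlane:
    """Production envelope: max attainable axis-y flux over an axis-x grid."""

    axis_x: str
    axis_y: str
    points: pd.DataFrame  # columns: x, y_max, feasible

    def frontier(self) -> pd.DataFrame:
        return self.points[self.points["feasible"]]


# ---------------------------------------------------------------------------
# LP scaffolding
# ---------------------------------------------------------------------------

def _linprog(c, A_ub, b_ub, A_eq, b_eq, bounds):
    return scipy_opt.linprog(
        c,
        A_ub=A_ub if A_ub is not None and len(A_ub) else None,
        b_ub=b_ub if b_ub is not None and len(b_ub) else None,
        A_eq=A_eq if A_eq is not None and len(A_eq) else None,
        b_eq=b_eq if b_eq is not None and len(b_eq) else None,
        bounds=bounds,
        method="highs",
        options={
            "presolve": True,
            "primal_feasibility_tolerance": SOLVER_TOL,
            "dual_feasibility_tolerance": SOLVER_TOL,
        },
    )


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _objective_vector(model: MetabolicModel, objective_reaction_id: str | None) -> np.ndarray:
    rxn_ids = model.reaction_ids
    c = np.zeros(len(rxn_ids))
    if objective_reaction_id is not None:
        if objective_reaction_id not in rxn_ids:
            raise KeyError(f"no reaction {objective_reaction_id!r} in model")
        c[rxn_ids.index(objective_reaction_id)] = 1.0
    else:
        if not model.objective_coefficients:
            raise OptimizationError("model defines no objective and none was given")
        for rid, coeff in model.objective_coefficients.items():
            c[rxn_ids.index(rid)] = coeff
    return c


def _bounds(model: MetabolicModel) -> list[tuple[float, float]]:
    return [
        (
            None if math.isinf(r.lower_bound) else r.lower_bound,
            None if math.isinf(r.upper_bound) else r.upper_bound,
        )
        for r in model.reactions
    ]


def _flux_state_from(model, v, c, method, meta=None) -> FluxState:
    fluxes = {rid: float(v[j]) for j, rid in enumerate(model.reaction_ids)}
    meta = dict(meta or {})
    meta.setdefault(
        "objective_row",
        {rid: float(c[j]) for j, rid in enumerate(model.reaction_ids) if c[j] != 0.0},
    )
    state = FluxState(
        fluxes=fluxes,
        objective_value=float(c @ v),
        status="optimal",
        method=method,
        meta=meta,
    )
    assert_feasible(model, state)
    return state


def _unbounded_ray_support(model, c, sense) -> list[str]:
    """Identify reactions driving an unbounded objective by re-solving inside
    an artificial box and reporting fluxes that hit it."""
    s = stoichiometric_matrix(model)
    boxed = [
        (
            max(lb if lb is not None else -_BIG, -_BIG),
            min(ub if ub is not None else _BIG, _BIG),
        )
        for lb, ub in _bounds(model)
    ]
    res = _linprog(-c if sense == "max" else c, None, None, s, np.zeros(s.shape[0]), boxed)
    if res.status != 0:
        return []
    return [
        rid
        for rid, x in zip(model.reaction_ids, res.x)
        if abs(x) >= 0.999 * _BIG
    ]


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

def fba(
    model: MetabolicModel,
    objective_reaction_id: str | None = None,
    sense: str = "max",
) -> FluxState:
    """Flux balance analysis: optimize one linear objective at steady state.

    With ``objective_reaction_id=None`` the model's own objective
    coefficients are used.  Returns a :class:`FluxState` whose status is
    ``optimal``, ``infeasible`` or ``unbounded``; in the unbounded case
    ``meta["unbounded_ray"]`` lists the support of an unbounded direction.
    """
    if sense not in {"max", "min"}:
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    c = _objective_vector(model, objective_reaction_id)
    s = stoichiometric_matrix(model)
    res = _linprog(
        -c if sense == "max" else c, None, None, s, np.zeros(s.shape[0]), _bounds(model)
    )
    status = _STATUS.get(res.status, "numerical")
    if status == "optimal":
        return _flux_state_from(model, res.x, c, "fba", {"sense": sense})
    if status == "unbounded":
        support = _unbounded_ray_support(model, c, sense)
        logger.warning("FBA objective unbounded; ray support: %s", support)
        return FluxState(
            fluxes={},
            objective_value=math.inf if sense == "max" else -math.inf,
            status="unbounded",
            method="fba",
            meta={"unbounded_ray": support, "sense": sense},
        )
    if status == "infeasible":
        return FluxState({}, math.nan, "infeasible", "fba", {"sense": sense})
    raise OptimizationError(f"LP solver failed with status {status}: {res.message}")


# ---------------------------------------------------------------------------
# pFBA
# ---------------------------------------------------------------------------

def pfba(
    model: MetabolicModel,
    objective_reaction_id: str | None = None,
    fix_tol: float = 1e-9,
) -> FluxState:
    """Parsimonious FBA.

    First solves FBA, then fixes the objective at its optimum (equality,
    relaxed to ``1e-6`` relative on numerical failure) and minimizes the
    summed absolute flux through gene-associated reactions.  Each penalized
    reaction is split into two non-negative components so the L1 objective
    is linear.
    """
    base = fba(model, objective_reaction_id, sense="max")
    if base.status != "optimal":
        raise OptimizationError(
            f"pFBA requires a finite FBA optimum; FBA status was {base.status!r}"
        )
    z_star = base.objective_value
    c = _objective_vector(model, objective_reaction_id)
    s = stoichiometric_matrix(model)
    n_met, n_rxn = s.shape
    penalized = [j for j, r in enumerate(model.reactions) if r.gene_associated]
    n_pen = len(penalized)

    # columns: v (n_rxn) | p (n_pen) | n (n_pen), with v_j - p_j + n_j = 0
    n_var = n_rxn + 2 * n_pen
    a_eq = np.zeros((n_met + n_pen, n_var))
    a_eq[:n_met, :n_rxn] = s
    for k, j in enumerate(penalized):
        a_eq[n_met + k, j] = 1.0
        a_eq[n_met + k, n_rxn + k] = -1.0
        a_eq[n_met + k, n_rxn + n_pen + k] = 1.0
    b_eq = np.zeros(n_met + n_pen)
    bounds = _bounds(model) + [(0, None)] * (2 * n_pen)
    obj = np.zeros(n_var)
    obj[n_rxn:] = 1.0

    def solve(fix_rows_eq: bool, tol: float):
        if fix_rows_eq:
            a_eq_full = np.vstack([a_eq, np.concatenate([c, np.zeros(2 * n_pen)])])
            b_eq_full = np.concatenate([b_eq, [z_star]])
            return _linprog(obj, None, None, a_eq_full, b_eq_full, bounds)
        slack = max(tol * abs(z_star), tol)
        row = np.concatenate([c, np.zeros(2 * n_pen)])
        a_ub = np.vstack([-row, row])
        b_ub = np.array([-(z_star - slack), z_star + slack])
        return _linprog(obj, a_ub, b_ub, a_eq, b_eq, bounds)

    res = solve(fix_rows_eq=True, tol=fix_tol)
    if res.status != 0:
        logger.info("pFBA equality fixing infeasible; retrying with 1e-6 relaxation")
        res = solve(fix_rows_eq=False, tol=1e-6)
    if res.status != 0:
        raise OptimizationError(
            f"pFBA restoration failed after relaxed objective fixing: {res.message}"
        )
    v = res.x[:n_rxn]
    meta = {
        "fba_objective": z_star,
        "l1_norm": float(np.sum(res.x[n_rxn:])),
        "penalized_reactions": n_pen,
    }
    state = _flux_state_from(model, v, c, "pfba", meta)
    return state


# ---------------------------------------------------------------------------
# FVA
# ---------------------------------------------------------------------------

def fva(
    model: MetabolicModel,
    objective_reaction_id: str | None = None,
    fraction: float = 0.95,
    loopless: bool = False,
    reactions: list[str] | None = None,
) -> FvaResult:
    """Flux variability analysis at a fraction of the optimum.

    For each reaction the minimum and maximum flux are computed subject to
    the model constraints plus ``c.v >= fraction * Z*``.  With
    ``loopless=True`` each subproblem's solution is cycle-corrected before
    the reaction's flux is read off.  Per-reaction solver failures are
    recorded in ``failures`` instead of aborting the scan.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    base = fba(model, objective_reaction_id, sense="max")
    if base.status != "optimal":
        raise OptimizationError(
            f"FVA requires a finite FBA optimum; status was {base.status!r}"
        )
    z_star = base.objective_value
    c = _objective_vector(model, objective_reaction_id)
    s = stoichiometric_matrix(model)
    rxn_ids = model.reaction_ids
    targets = reactions if reactions is not None else rxn_ids
    bounds = _bounds(model)
    # c.v >= fraction * Z*  (objective values can be negative; keep the sign)
    a_ub = -c.reshape(1, -1)
    b_ub = np.array([-fraction * z_star])

    minimum: dict[str, float] = {}
    maximum: dict[str, float] = {}
    failures: dict[str, str] = {}
    for rid in targets:
        j = rxn_ids.index(rid)
        e = np.zeros(len(rxn_ids))
        e[j] = 1.0
        for sense, store in (("min", minimum), ("max", maximum)):
            res = _linprog(
                e if sense == "min" else -e, a_ub, b_ub, s, np.zeros(s.shape[0]), bounds
            )
            if res.status == 3:
                store[rid] = -math.inf if sense == "min" else math.inf
                continue
            if res.status != 0:
                failures[rid] = _STATUS.get(res.status, "numerical")
                store[rid] = math.nan
                continue
            value = float(res.x[j])
            if loopless:
                state = _flux_state_from(model, res.x, c, "fba")
                corrected = remove_loops(model, state)
                value = corrected.fluxes[rid]
            store[rid] = value
    return FvaResult(fraction=fraction, minimum=minimum, maximum=maximum, failures=failures)


# ---------------------------------------------------------------------------
# loopless correction
# ---------------------------------------------------------------------------

def _internal_indices(model: MetabolicModel) -> list[int]:
    return [j for j, r in enumerate(model.reactions) if not r.is_boundary]


def remove_loops(
    model: MetabolicModel, flux_state: FluxState, strict: bool = False
) -> FluxState:
    """Remove flux around thermodynamically infeasible internal cycles.

    The default mode keeps every boundary flux and the objective value fixed
    and minimizes the total absolute flux through internal reactions, each
    constrained to keep its sign and not exceed its current magnitude
    (CycleFreeFlux).  Pure internal cycles are driven to zero while the
    physiology of the solution is untouched.  ``strict=True`` instead solves
    the MILP loop-law formulation (small instances only).
    """
    if flux_state.status != "optimal":
        raise OptimizationError("loop removal requires an optimal flux state")
    if strict:
        return _remove_loops_milp(model, flux_state)
    s = stoichiometric_matrix(model)
    rxn_ids = model.reaction_ids
    v0 = flux_state.as_vector(model)
    internal = set(_internal_indices(model))
    bounds: list[tuple[float | None, float | None]] = []
    obj = np.zeros(len(rxn_ids))
    for j, rid in enumerate(rxn_ids):
        if j in internal:
            if v0[j] >= 0:
                bounds.append((0.0, v0[j]))
                obj[j] = 1.0
            else:
                bounds.append((v0[j], 0.0))
                obj[j] = -1.0
        else:
            bounds.append((v0[j], v0[j]))
    # pin the original objective value (guards objective reactions that are
    # internal, e.g. biomass pseudo-reactions)
    a_eq = s
    b_eq = np.zeros(s.shape[0])
    c_obj = np.zeros(len(rxn_ids))
    for rid, coeff in flux_state.meta.get("objective_row", {}).items():
        c_obj[rxn_ids.index(rid)] = coeff
    if c_obj.any():
        a_eq = np.vstack([a_eq, c_obj])
        b_eq = np.concatenate([b_eq, [flux_state.objective_value]])
    res = _linprog(obj, None, None, a_eq, b_eq, bounds)
    if res.status != 0:
        raise OptimizationError(f"loopless correction LP failed: {res.message}")
    fluxes = {rid: float(res.x[j]) for j, rid in enumerate(rxn_ids)}
    state = FluxState(
        fluxes=fluxes,
        objective_value=flux_state.objective_value,
        status="optimal",
        method="loopless",
        meta={"source_method": flux_state.method},
    )
    assert_feasible(model, state)
    return state


def _remove_loops_milp(model: MetabolicModel, flux_state: FluxState) -> FluxState:
    """Strict MILP loop-law mode: re-optimize the boundary-fixed instance with
    binary direction variables and a potential vector excluded from every
    internal null-space cycle (ll-COBRA formulation)."""
    try:
        from scipy.optimize import LinearConstraint, milp
    except ImportError as exc:  # pragma: no cover
        raise OptimizationError(
            "strict loopless mode requires an integer-capable scipy.optimize.milp"
        ) from exc
    s = stoichiometric_matrix(model)
    rxn_ids = model.reaction_ids
    v0 = flux_state.as_vector(model)
    internal = _internal_indices(model)
    n_rxn = len(rxn_ids)
    n_int = len(internal)
    if n_int == 0:
        return flux_state
    s_int = s[:, internal]
    null = null_space(s_int)
    k_big = _MILP_BIG

    # variables: v (n_rxn) | G (n_int) | a (n_int, binary)
    n_var = n_rxn + 2 * n_int
    integrality = np.zeros(n_var)
    integrality[n_rxn + n_int:] = 1

    lb = np.empty(n_var)
    ub = np.empty(n_var)
    internal_set = set(internal)
    for j, r in enumerate(model.reactions):
        if j in internal_set:
            # sign-fixed box: keep direction, never exceed current magnitude
            lb[j], ub[j] = (0.0, v0[j]) if v0[j] >= 0 else (v0[j], 0.0)
        else:
            lb[j] = ub[j] = v0[j]
    lb[n_rxn:n_rxn + n_int] = -k_big
    ub[n_rxn:n_rxn + n_int] = k_big
    lb[n_rxn + n_int:] = 0
    ub[n_rxn + n_int:] = 1

    constraints = []
    a_steady = np.hstack([s, np.zeros((s.shape[0], 2 * n_int))])
    constraints.append(LinearConstraint(a_steady, 0, 0))
    obj_row = flux_state.meta.get("objective_row", {})
    if obj_row:
        row = np.zeros(n_var)
        for rid, coeff in obj_row.items():
            row[rxn_ids.index(rid)] = coeff
        z = flux_state.objective_value
        constraints.append(LinearConstraint(row, z - 1e-9, z + 1e-9))
    for k, j in enumerate(internal):
        row_v_ub = np.zeros(n_var)  # v_j - k_big * a_k <= 0
        row_v_ub[j] = 1.0
        row_v_ub[n_rxn + n_int + k] = -k_big
        constraints.append(LinearConstraint(row_v_ub, -np.inf, 0))
        row_v_lb = np.zeros(n_var)  # v_j + k_big * (1 - a_k) >= 0
        row_v_lb[j] = 1.0
        row_v_lb[n_rxn + n_int + k] = -k_big
        constraints.append(LinearConstraint(row_v_lb, -k_big, np.inf))
        row_g_ub = np.zeros(n_var)  # G_k <= -1 + (k_big + 1)(1 - a_k)
        row_g_ub[n_rxn + k] = 1.0
        row_g_ub[n_rxn + n_int + k] = k_big + 1
        constraints.append(LinearConstraint(row_g_ub, -np.inf, k_big))
        row_g_lb = np.zeros(n_var)  # G_k >= 1 - (k_big + 1) a_k
        row_g_lb[n_rxn + k] = 1.0
        row_g_lb[n_rxn + n_int + k] = k_big + 1
        constraints.append(LinearConstraint(row_g_lb, 1, np.inf))
    if null.shape[1]:
        a_loop = np.hstack(
            [np.zeros((null.shape[1], n_rxn)), null.T, np.zeros((null.shape[1], n_int))]
        )
        constraints.append(LinearConstraint(a_loop, 0, 0))

    # minimize total absolute internal flux, signs fixed by v0 where nonzero
    obj = np.zeros(n_var)
    for k, j in enumerate(internal):
        obj[j] = 1.0 if v0[j] >= 0 else -1.0
    res = milp(
        c=obj,
        constraints=constraints,
        integrality=integrality,
        bounds=scipy_opt.Bounds(lb, ub),
    )
    if res.status != 0 or res.x is None:
        raise OptimizationError(f"strict loopless MILP failed: {res.message}")
    fluxes = {rid: float(res.x[j]) for j, rid in enumerate(rxn_ids)}
    state = FluxState(
        fluxes=fluxes,
        objective_value=flux_state.objective_value,
        status="optimal",
        method="loopless",
        meta={"source_method": flux_state.method, "strict": True},
    )
    assert_feasible(model, state)
    return state


# ---------------------------------------------------------------------------
# two-step biomass-coupled production
# ---------------------------------------------------------------------------

def two_step_optimize(
    model: MetabolicModel,
    biomass_id: str,
    target_id: str,
    biomass_fraction: float = 0.10,
) -> FluxState:
    """Growth-coupled production: maximize biomass, pin it at a fraction of
    the maximum, then maximize the product export via pFBA.

    Returns the product-optimal flux state; ``meta`` records the biomass
    maximum ``mu_max`` and the biomass flux actually achieved.
    """
    if not (0 <= biomass_fraction <= 1):
        raise ValueError("biomass_fraction must lie in [0, 1]")
    growth = fba(model, biomass_id, sense="max")
    if growth.status != "optimal":
        raise OptimizationError(
            f"biomass optimization failed with status {growth.status!r}"
        )
    mu_max = growth.objective_value
    if mu_max <= FEASIBILITY_TOL:
        raise OptimizationError("growth infeasible under scenario (mu_max = 0)")
    coupled = model.copy()
    biomass_rxn = coupled.reaction(biomass_id)
    coupled.replace_reaction(
        biomass_rxn.with_bounds(biomass_fraction * mu_max, biomass_rxn.upper_bound)
    )
    state = pfba(coupled, target_id)
    state.method = "two_step"
    state.meta.update(
        {
            "mu_max": mu_max,
            "biomass_fraction": biomass_fraction,
            "biomass_flux": state.fluxes[biomass_id],
            "biomass_id": biomass_id,
            "target_id": target_id,
        }
    )
    return state


# ---------------------------------------------------------------------------
# phenotypic phase plane
# ---------------------------------------------------------------------------

def phenotypic_phase_plane(
    model: MetabolicModel,
    rxn_x: str,
    rxn_y: str,
    n_points: int = 50,
) -> PhasePlane:
    """Production envelope between two fluxes.

    The x-axis reaction is swept from zero to its maximal rate on an
    inclusive grid; at each grid value the attainable maximum of the y-axis
    flux is computed.  Infeasible grid points are flagged, never dropped.
    Swap the arguments to sweep the other axis.
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    for rid in (rxn_x, rxn_y):
        model.reaction(rid)  # raises KeyError if absent
    cap = fba(model, rxn_x, sense="max")
    if cap.status != "optimal":
        raise OptimizationError(
            f"cannot bound phase-plane axis {rxn_x!r}: status {cap.status!r}"
        )
    max_x = cap.objective_value
    rows = []
    for x in np.linspace(0.0, max_x, n_points):
        pinned = model.copy()
        rxn = pinned.reaction(rxn_x)
        pinned.replace_reaction(rxn.with_bounds(x, x))
        sub = fba(pinned, rxn_y, sense="max")
        feasible = sub.status == "optimal"
        rows.append(
            {
                "x": float(x),
                "y_max": sub.objective_value if feasible else math.nan,
                "feasible": feasible,
            }
        )
    points = pd.DataFrame(rows, columns=["x", "y_max", "feasible"])
    return PhasePlane(axis_x=rxn_x, axis_y=rxn_y, points=points)
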