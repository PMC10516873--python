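"""Tests for FBA, pFBA, FVA, loopless correction, two-step optimization and
phase planes, each checked against an independent oracle where one exists."""

import math

import pytest

from cyanoflux.core import (
    FluxState,
    MetabolicModel,
    Metabolite,
    Reaction,
    steady_state_residual,
)
from cyanoflux.optimize import (
    OptimizationError,
    fba,
    fva,
    pfba,
    phenotypic_phase_plane,
    remove_loops,
    two_step_optimize,
)
from cyanoflux.synthetic import (
    PHOTOTROPH_CLOSED_FORMS,
    make_internal_cycle_model,
    make_random_feasible,
)

from conftest import (
    epigraph_pfba_oracle,
    per_reaction_fva_oracle,
    vertex_enumeration_optimum,
)


class TestFba:
    def test_chain_optimum_is_uptake_bound(self, chain):
        state = fba(chain, "EX_out")
        assert state.status == "optimal"
        assert state.objective_value == pytest.approx(10.0)
        assert state.fluxes["EX_in"] == pytest.approx(-10.0)

    def test_model_objective_used_when_unspecified(self, chain):
        assert fba(chain).objective_value == pytest.approx(10.0)

    def test_minimization_sense(self, chain):
        assert fba(chain, "EX_out", sense="min").objective_value == pytest.approx(0.0)

    def test_unknown_objective_raises(self, chain):
        with pytest.raises(KeyError):
            fba(chain, "GHOST")

    def test_infeasible_status(self, chain):
        model = chain.copy()
        model.replace_reaction(model.reaction("STEP1").with_bounds(5.0, 6.0))
        model.replace_reaction(model.reaction("STEP2").with_bounds(0.0, 1.0))
        assert fba(model, "EX_out").status == "infeasible"

    def test_unbounded_reports_ray_support(self):
        mets = [Metabolite(id="a_c")]
        rxns = [
            Reaction(id="IN", stoichiometry={"a_c": 1}, lower_bound=0,
                     upper_bound=math.inf),
            Reaction(id="OUT", stoichiometry={"a_c": -1}, lower_bound=0,
                     upper_bound=math.inf),
        ]
        model = MetabolicModel(metabolites=mets, reactions=rxns)
        state = fba(model, "OUT")
        assert state.status == "unbounded"
        assert set(state.meta["unbounded_ray"]) == {"IN", "OUT"}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_vertex_enumeration_oracle(self, seed):
        """The LP optimum must equal the best basic feasible solution found
        by brute-force vertex enumeration of the small flux polytope."""
        model = make_random_feasible(4, 8, seed)
        objective = model.reaction_ids[-1]
        lp = fba(model, objective)
        assert lp.status == "optimal"
        brute = vertex_enumeration_optimum(model, objective)
        assert lp.objective_value == pytest.approx(brute, abs=1e-6)


class TestPfba:
    def test_prefers_shortest_route(self, detour_routes):
        state = pfba(detour_routes, "EX_b")
        assert state.objective_value == pytest.approx(10.0)
        assert state.fluxes["DIRECT"] == pytest.approx(10.0)
        assert state.fluxes["DETOUR1"] == pytest.approx(0.0, abs=1e-9)

    def test_objective_equals_fba(self, toy):
        z_fba = fba(toy, "BIOMASS").objective_value
        state = pfba(toy, "BIOMASS")
        assert state.objective_value == pytest.approx(z_fba, rel=1e-6)

    def test_l1_not_exceeding_fba_solution(self, parallel_routes):
        state = pfba(parallel_routes, "EX_b")
        fba_state = fba(parallel_routes, "EX_b")
        def l1(s):
            return sum(
                abs(s.fluxes[r.id])
                for r in parallel_routes.reactions if r.gene_associated
            )
        assert l1(state) <= l1(fba_state) + 1e-8

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_epigraph_oracle(self, seed):
        """pFBA via reversible splitting must agree with an independently
        formulated epigraph (t >= |v|) L1 minimization."""
        model = make_random_feasible(5, 9, seed)
        state = pfba(model)
        z_oracle, l1_oracle = epigraph_pfba_oracle(model)
        assert state.objective_value == pytest.approx(z_oracle, rel=1e-6, abs=1e-9)
        assert state.meta["l1_norm"] == pytest.approx(l1_oracle, abs=1e-5)

    def test_infeasible_base_raises(self, chain):
        model = chain.copy()
        model.replace_reaction(model.reaction("STEP1").with_bounds(5.0, 6.0))
        model.replace_reaction(model.reaction("STEP2").with_bounds(0.0, 1.0))
        with pytest.raises(OptimizationError):
            pfba(model, "EX_out")


class TestFva:
    def test_unique_optimum_pins_all_fluxes(self, chain):
        result = fva(chain, "EX_out", fraction=1.0)
        for rid in chain.reaction_ids:
            lo, hi = result.range(rid)
            expected = -10.0 if rid == "EX_in" else 10.0
            assert lo == pytest.approx(expected, abs=1e-6)
            assert hi == pytest.approx(expected, abs=1e-6)

    def test_alternate_optima_span_full_range(self, parallel_routes):
        result = fva(parallel_routes, "EX_b", fraction=1.0)
        for rid in ("R1", "R2"):
            lo, hi = result.range(rid)
            assert lo == pytest.approx(0.0, abs=1e-6)
            assert hi == pytest.approx(10.0, abs=1e-6)

    def test_fraction_widens_ranges(self, chain):
        result = fva(chain, "EX_out", fraction=0.95)
        lo, hi = result.range("EX_out")
        assert lo == pytest.approx(9.5, abs=1e-6)
        assert hi == pytest.approx(10.0, abs=1e-6)

    @pytest.mark.parametrize("seed,fraction", [(0, 1.0), (1, 0.95), (2, 0.9)])
    def test_matches_per_reaction_oracle(self, seed, fraction):
        model = make_random_feasible(4, 7, seed)
        objective = model.reaction_ids[-1]
        result = fva(model, objective, fraction=fraction)
        lo, hi = per_reaction_fva_oracle(model, objective, fraction)
        for rid in model.reaction_ids:
            assert result.minimum[rid] == pytest.approx(lo[rid], abs=1e-6)
            assert result.maximum[rid] == pytest.approx(hi[rid], abs=1e-6)

    def test_pfba_fluxes_inside_fva_band(self, toy):
        state = pfba(toy, "BIOMASS")
        result = fva(toy, "BIOMASS", fraction=1.0)
        for rid in toy.reaction_ids:
            lo, hi = result.range(rid)
            assert lo - 1e-6 <= state.fluxes[rid] <= hi + 1e-6

    def test_loopless_collapses_cycle_ranges(self, cycle_model):
        plain = fva(cycle_model, "EX_out", fraction=1.0)
        corrected = fva(cycle_model, "EX_out", fraction=1.0, loopless=True)
        for rid in ("CYC1", "CYC2", "CYC3"):
            assert plain.maximum[rid] == pytest.approx(1000.0, abs=1e-6)
            assert corrected.maximum[rid] == pytest.approx(0.0, abs=1e-6)
            assert corrected.minimum[rid] == pytest.approx(0.0, abs=1e-6)


class TestRemoveLoops:
    def _loaded_state(self, model, cycle_flux=50.0):
        state = fba(model, "EX_out")
        for rid in model.reaction_ids:
            if rid.startswith("CYC"):
                state.fluxes[rid] = cycle_flux
        return state

    def test_zeroes_pure_cycle_keeps_objective(self, cycle_model):
        state = self._loaded_state(cycle_model)
        clean = remove_loops(cycle_model, state)
        for rid in ("CYC1", "CYC2", "CYC3"):
            assert clean.fluxes[rid] == pytest.approx(0.0, abs=1e-9)
        assert clean.objective_value == pytest.approx(state.objective_value)
        assert steady_state_residual(cycle_model, clean) <= 1e-6

    def test_loop_free_state_is_fixed_point(self, chain):
        state = fba(chain, "EX_out")
        clean = remove_loops(chain, state)
        for rid in chain.reaction_ids:
            assert clean.fluxes[rid] == pytest.approx(state.fluxes[rid], abs=1e-9)

    def test_exchanges_and_total_flux_preserved_or_reduced(self, cycle_model):
        state = self._loaded_state(cycle_model)
        clean = remove_loops(cycle_model, state)
        for rxn in cycle_model.reactions:
            if rxn.is_boundary:
                assert clean.fluxes[rxn.id] == pytest.approx(
                    state.fluxes[rxn.id], abs=1e-9
                )
        total = lambda s: sum(abs(f) for f in s.fluxes.values())
        assert total(clean) <= total(state) + 1e-9

    @pytest.mark.parametrize("cycle_len", [3, 4, 5])
    def test_default_mode_matches_strict_milp(self, cycle_len):
        """Post-hoc LP correction must agree with the MILP loop-law oracle on
        objective value and every exchange flux."""
        model = make_internal_cycle_model(cycle_len)
        state = fba(model, "EX_out")
        for rid in model.reaction_ids:
            if rid.startswith("CYC"):
                state.fluxes[rid] = 25.0
        lp_clean = remove_loops(model, state)
        milp_clean = remove_loops(model, state, strict=True)
        assert lp_clean.objective_value == pytest.approx(
            milp_clean.objective_value, abs=1e-6
        )
        for rxn in model.reactions:
            if rxn.is_boundary:
                assert lp_clean.fluxes[rxn.id] == pytest.approx(
                    milp_clean.fluxes[rxn.id], abs=1e-6
                )
            if rxn.id.startswith("CYC"):
                assert milp_clean.fluxes[rxn.id] == pytest.approx(0.0, abs=1e-6)

    def test_requires_optimal_state(self, cycle_model):
        bad = FluxState(fluxes={}, objective_value=math.nan,
                        status="infeasible", method="fba")
        with pytest.raises(OptimizationError):
            remove_loops(cycle_model, bad)


class TestTwoStep:
    def test_linear_frontier_gives_090_pmax(self, toy):
        state = two_step_optimize(toy, "BIOMASS", "EX_alkene", 0.10)
        assert state.objective_value == pytest.approx(
            0.9 * PHOTOTROPH_CLOSED_FORMS["p_max"]
        )
        assert state.meta["mu_max"] == pytest.approx(PHOTOTROPH_CLOSED_FORMS["mu_max"])
        assert state.meta["biomass_flux"] == pytest.approx(
            0.10 * PHOTOTROPH_CLOSED_FORMS["mu_max"]
        )

    def test_fraction_zero_equals_plain_fba(self, toy):
        state = two_step_optimize(toy, "BIOMASS", "EX_alkene", 0.0)
        assert state.objective_value == pytest.approx(
            fba(toy, "EX_alkene").objective_value
        )

    def test_fraction_one_equals_fva_maximum(self, toy):
        state = two_step_optimize(toy, "BIOMASS", "EX_alkene", 1.0)
        result = fva(toy, "BIOMASS", fraction=1.0, reactions=["EX_alkene"])
        assert state.objective_value == pytest.approx(
            result.maximum["EX_alkene"], abs=1e-6
        )

    def test_product_monotone_in_fraction(self, toy):
        fractions = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
        products = [
            two_step_optimize(toy, "BIOMASS", "EX_alkene", f).objective_value
            for f in fractions
        ]
        for a, b in zip(products, products[1:]):
            assert b <= a + 1e-9

    def test_no_growth_is_error(self, toy):
        dark = toy.copy()
        dark.replace_reaction(dark.reaction("EX_photon").with_bounds(0.0, 0.0))
        with pytest.raises(OptimizationError, match="growth infeasible"):
            two_step_optimize(dark, "BIOMASS", "EX_alkene", 0.10)


class TestPhasePlane:
    def test_toy_frontier_is_linear(self, toy):
        plane = phenotypic_phase_plane(toy, "BIOMASS", "EX_alkene", 11)
        mu_max = PHOTOTROPH_CLOSED_FORMS["mu_max"]
        p_max = PHOTOTROPH_CLOSED_FORMS["p_max"]
        assert plane.points["feasible"].all()
        for _, row in plane.points.iterrows():
            expected = p_max * (1 - row["x"] / mu_max)
            assert row["y_max"] == pytest.approx(expected, abs=1e-8)

    def test_endpoints_of_strict_tradeoff(self, toy):
        plane = phenotypic_phase_plane(toy, "BIOMASS", "EX_alkene", 5)
        assert plane.points.iloc[0]["y_max"] == pytest.approx(
            PHOTOTROPH_CLOSED_FORMS["p_max"]
        )
        assert plane.points.iloc[-1]["y_max"] == pytest.approx(0.0, abs=1e-9)
        # and symmetrically: at maximal product, no biomass is attainable
        swapped = phenotypic_phase_plane(toy, "EX_alkene", "BIOMASS", 5)
        assert swapped.points.iloc[-1]["y_max"] == pytest.approx(0.0, abs=1e-9)

    def test_grid_matches_per_point_fba(self, toy):
        plane = phenotypic_phase_plane(toy, "BIOMASS", "EX_alkene", 7)
        for _, row in plane.points.iterrows():
            pinned = toy.copy()
            rxn = pinned.reaction("BIOMASS")
            pinned.replace_reaction(rxn.with_bounds(row["x"], row["x"]))
            assert row["y_max"] == pytest.approx(
                fba(pinned, "EX_alkene").objective_value, abs=1e-8
            )

    def test_rejects_tiny_grid(self, toy):
        with pytest.raises(ValueError):
            phenotypic_phase_plane(toy, "BIOMASS", "EX_alkene", 1)


class TestSolutionInvariants:
    @pytest.mark.parametrize("seed", range(8))
    def test_random_models_solve_clean(self, seed):
        model = make_random_feasible(5, 9, seed)
        state = fba(model)
        assert state.status == "optimal"
        assert steady_state_residual(model, state) <= 1e-6
        assert state.objective_value >= -1e-9
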