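"""Flux balance analysis: LP correctness, conditions, derived quantities."""

import math

import numpy as np
import pytest

import methyloflux as mf
from methyloflux.bruteforce import brute_force_lp
from methyloflux.fba import effective_bounds
from methyloflux.model import ModelError


def _mass_balance_residual(model, solution):
    S, _, rxn_ids = model.stoichiometric_matrix()
    v = np.array([solution.fluxes[r] for r in rxn_ids])
    return float(np.max(np.abs(S @ v)))


class TestMaximizeObjective:
    def test_chain_analytic_optimum(self, chain_model):
        sol = mf.maximize_objective(chain_model)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(0.5, abs=1e-9)

    def test_uptake_fixed_as_equality(self, chain_model):
        cond = mf.SimulationConditions(fixed_uptakes={"EX_a": 0.4})
        sol = mf.maximize_objective(chain_model, cond)
        assert sol.fluxes["EX_a"] == pytest.approx(-0.4, abs=1e-9)
        assert sol.objective_value == pytest.approx(0.2, abs=1e-9)

    def test_ngam_without_carbon_is_infeasible(self, toy_model):
        cond = mf.SimulationConditions(ngam=1.0)  # all carbon uptakes closed
        sol = mf.maximize_objective(toy_model, cond)
        assert sol.status == "infeasible"
        assert sol.fluxes == {}

    def test_mass_balance(self, toy_model, glucose_solution):
        assert _mass_balance_residual(toy_model, glucose_solution) <= 1e-6

    def test_bounds_respected(self, toy_model, glucose_conditions,
                              glucose_solution):
        lb, ub, rxn_ids = effective_bounds(toy_model, glucose_conditions)
        for j, rid in enumerate(rxn_ids):
            v = glucose_solution.fluxes[rid]
            assert lb[j] - 1e-7 <= v <= ub[j] + 1e-7

    def test_growth_monotone_in_uptake_and_ngam(self, toy_model):
        growths = [
            mf.maximize_objective(
                toy_model,
                mf.SimulationConditions(fixed_uptakes={"EX_glc": u}, ngam=1.0),
            ).objective_value
            for u in (0.5, 1.0, 2.0)
        ]
        assert growths[0] <= growths[1] <= growths[2]
        by_ngam = [
            mf.maximize_objective(
                toy_model,
                mf.SimulationConditions(fixed_uptakes={"EX_glc": 1.0}, ngam=n),
            ).objective_value
            for n in (0.0, 2.0, 6.0)
        ]
        assert by_ngam[0] >= by_ngam[1] >= by_ngam[2]

    def test_two_stage_determinism(self, toy_model, glucose_conditions):
        s1 = mf.maximize_objective(toy_model, glucose_conditions)
        s2 = mf.maximize_objective(toy_model, glucose_conditions)
        assert s1.objective_value == s2.objective_value
        assert s1.fluxes == s2.fluxes
        assert mf.compute_po_ratio(s1) == mf.compute_po_ratio(s2)
        assert mf.gaseous_exchange(s1) == mf.gaseous_exchange(s2)

    def test_parsimonious_not_larger_total_flux(self, toy_model,
                                                glucose_conditions):
        full = mf.maximize_objective(toy_model, glucose_conditions)
        stage1 = mf.maximize_objective(
            toy_model, glucose_conditions, parsimonious=False
        )
        assert full.objective_value == pytest.approx(
            stage1.objective_value, abs=1e-7
        )
        assert sum(map(abs, full.fluxes.values())) <= sum(
            map(abs, stage1.fluxes.values())
        ) + 1e-6

    def test_agrees_with_vertex_oracle(self, chain_model):
        S, _, rxn_ids = chain_model.stoichiometric_matrix()
        lb, ub, _ = effective_bounds(chain_model, mf.SimulationConditions())
        lb = np.maximum(lb, -20.0)
        ub = np.minimum(ub, 20.0)
        c = np.zeros(len(rxn_ids))
        c[rxn_ids.index("BIOMASS")] = 1.0
        obj_bf, _ = brute_force_lp(c, S, lb, ub)
        sol = mf.maximize_objective(chain_model, parsimonious=False)
        assert sol.objective_value == pytest.approx(obj_bf, abs=1e-6)

    def test_agrees_with_cobra(self, toy_model):
        """Independent cross-check of the growth optimum via cobrapy."""
        import cobra

        cm = cobra.Model("toy")
        mets = {
            mid: cobra.Metabolite(
                mid.replace("[", "_").replace("]", ""),
                compartment=toy_model.metabolites[mid].compartment,
            )
            for mid in toy_model.metabolites
        }
        for rid, rxn in toy_model.reactions.items():
            cr = cobra.Reaction(rid)
            cr.lower_bound = max(rxn.lower_bound, -1000.0)
            cr.upper_bound = min(rxn.upper_bound, 1000.0)
            cm.add_reactions([cr])
            cr.add_metabolites(
                {mets[m]: c for m, c in rxn.stoichiometry.items()}
            )
        cm.reactions.EX_glc.lower_bound = -1.0
        cm.reactions.EX_glc.upper_bound = -1.0
        cm.reactions.ATPM.lower_bound = 1.0
        cm.reactions.ATPM.upper_bound = 1.0
        cm.objective = "BIOMASS"
        mu_cobra = cm.optimize().objective_value

        sol = mf.maximize_objective(
            toy_model,
            mf.SimulationConditions(fixed_uptakes={"EX_glc": 1.0}, ngam=1.0),
        )
        assert sol.objective_value == pytest.approx(mu_cobra, abs=1e-6)


class TestDeletions:
    def test_empty_deletion_equals_plain_fba(self, toy_model,
                                             glucose_conditions):
        plain = mf.maximize_objective(toy_model, glucose_conditions)
        deleted = mf.simulate_deletion(toy_model, set(), glucose_conditions)
        assert deleted.objective_value == pytest.approx(
            plain.objective_value, abs=1e-9
        )

    def test_essential_gene_kills_growth(self, chain_model):
        sol = mf.simulate_deletion(chain_model, {"g1"})
        assert sol.optimal
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_or_isozyme_is_redundant(self, toy_model):
        cond = mf.SimulationConditions(fixed_uptakes={"EX_mthl": 1.0})
        base = mf.maximize_objective(toy_model, cond)
        one = mf.simulate_deletion(toy_model, {"g_aod1"}, cond)
        assert one.objective_value == pytest.approx(
            base.objective_value, abs=1e-9
        )

    def test_and_complex_matches_reaction_removal(self, toy_model):
        """Deleting one AND-complex gene equals removing the reaction."""
        cond = mf.SimulationConditions(max_uptakes={"EX_glc": 1.0})
        by_gene = mf.simulate_deletion(toy_model, {"g_pfk"}, cond)

        pruned = toy_model.copy()
        for rid in ("HEXUP", "FRUUP"):  # both carry the g_hxk and g_pfk GPR
            pruned.reactions[rid].lower_bound = 0.0
            pruned.reactions[rid].upper_bound = 0.0
        direct = mf.maximize_objective(pruned, cond)
        assert by_gene.objective_value == pytest.approx(
            direct.objective_value, abs=1e-9
        )

    def test_unknown_gene_errors(self, toy_model):
        with pytest.raises(ModelError, match="unknown gene"):
            mf.simulate_deletion(toy_model, {"no_such_gene"})


class TestPORatio:
    def test_arithmetic(self):
        sol = mf.FluxSolution(
            "optimal", 0.1, {"ATPS3m": 10.36, "CYOOm": 3.5}
        )
        assert mf.compute_po_ratio(sol) == pytest.approx(1.48, abs=1e-9)

    def test_zero_oxidase_flux_errors(self):
        sol = mf.FluxSolution("optimal", 0.1, {"ATPS3m": 1.0, "CYOOm": 0.0})
        with pytest.raises(ZeroDivisionError):
            mf.compute_po_ratio(sol)

    @pytest.mark.parametrize("target", [1.48, 2.0, 1.0])
    def test_retune_hits_target(self, toy_model, target):
        model = mf.set_po_ratio(toy_model, target)
        sol = mf.maximize_objective(
            model, mf.SimulationConditions(fixed_uptakes={"EX_glc": 1.0},
                                           ngam=1.0)
        )
        assert mf.compute_po_ratio(sol) == pytest.approx(target, rel=0.01)

    def test_retune_to_current_is_fixed_point(self, toy_model):
        current = 1.48  # the build default
        model = mf.set_po_ratio(toy_model, current)
        a = toy_model.reactions["CYOOm"].stoichiometry
        b = model.reactions["CYOOm"].stoichiometry
        assert a == pytest.approx(b)

    def test_nonpositive_target_errors(self, toy_model):
        with pytest.raises(ValueError):
            mf.set_po_ratio(toy_model, 0.0)


class TestGaseousExchange:
    def test_closed_form_respiration(self, toy_model):
        """Zero growth on glucose burns everything: CER = OUR = 6/glc, RQ 1."""
        model = toy_model.copy()
        model.reactions["BIOMASS"].upper_bound = 0.0
        # drive maintenance at the maximal ATP yield: complete oxidation
        y_atp = mf.atp_yield_per_substrate(model, "EX_glc")
        assert y_atp == pytest.approx(21.76, abs=1e-6)  # hand-computed
        cond = mf.SimulationConditions(
            fixed_uptakes={"EX_glc": 1.0}, ngam=y_atp
        )
        sol = mf.maximize_objective(model, cond, objective_id="ATPM")
        cer, our = mf.gaseous_exchange(sol)
        assert cer == pytest.approx(6.0, abs=1e-6)
        assert our == pytest.approx(6.0, abs=1e-6)

    def test_zero_flux_solution(self):
        sol = mf.FluxSolution("optimal", 0.0, {"EX_co2": 0.0, "EX_o2": 0.0})
        assert mf.gaseous_exchange(sol) == (0.0, 0.0)

    def test_missing_exchange_errors(self):
        sol = mf.FluxSolution("optimal", 0.0, {"EX_co2": 1.0})
        with pytest.raises(ModelError):
            mf.gaseous_exchange(sol)

    def test_aerobic_growth_rates_positive(self, glucose_solution):
        cer, our = mf.gaseous_exchange(glucose_solution)
        assert cer > 0 and our > 0
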