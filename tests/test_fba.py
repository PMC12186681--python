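"""Protein-production capacity on the toy metabolic network.

The fixture's optima are known analytically: a length-L protein with g GTP
per peptide bond costs L + g*(L-1) precursor units; rich carbon yields two
precursors per unit taken up, poor carbon one, and a fixed biomass flux b
subtracts b precursors, so

    max protein flux = (yield * uptake - b) / (L + g*(L-1)).
"""

import numpy as np
import pytest

from cellecon import fba


@pytest.fixture(scope="module")
def toy():
    return fba.toy_network_fixture()


@pytest.fixture(scope="module")
def toy_mg(toy):
    """Toy network with a demand for the dipeptide MG (L=2, g=2 -> 4 prec)."""
    return fba.add_protein_demand(toy, "MG", gtp_per_bond=2.0)


class TestFixture:
    def test_deterministic_serialization(self, toy, tmp_path):
        p1, p2 = tmp_path / "a.xml", tmp_path / "b.xml"
        fba.write_network(fba.toy_network_fixture(), p1)
        fba.write_network(fba.toy_network_fixture(), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_round_trip(self, toy, tmp_path):
        path = tmp_path / "toy.xml"
        fba.write_network(toy, path)
        back = fba.read_network(path)
        assert sorted(r.id for r in back.reactions) == \
            sorted(r.id for r in toy.reactions)
        assert sorted(m.id for m in back.metabolites) == \
            sorted(m.id for m in toy.metabolites)
        for r in toy.reactions:
            rb = back.reactions.get_by_id(r.id)
            assert rb.bounds == r.bounds
            assert rb.subsystem == r.subsystem

    def test_every_reaction_has_a_subsystem(self, toy):
        assert all(r.subsystem for r in toy.reactions)

    def test_malformed_file_rejected(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<not sbml>")
        with pytest.raises(ValueError, match="parse"):
            fba.read_network(bad)


class TestProteinDemand:
    def test_dipeptide_composition(self, toy_mg):
        rxn = toy_mg.reactions.get_by_id(fba.PROTEIN_DEMAND_ID)
        mets = {m.id: c for m, c in rxn.metabolites.items()}
        assert mets["met__L_c"] == -1
        assert mets["gly_c"] == -1
        assert mets["gtp_c"] == -2
        assert mets["gdp_c"] == 2 and mets["pi_c"] == 2
        assert mets["protein_c"] == 1

    def test_empty_sequence_rejected(self, toy):
        with pytest.raises(ValueError, match="empty"):
            fba.add_protein_demand(toy, "")

    def test_unknown_residue_rejected(self, toy):
        with pytest.raises(ValueError, match="residue"):
            fba.add_protein_demand(toy, "MGX")

    def test_missing_metabolite_reported(self, toy):
        incomplete = toy.copy()
        incomplete.remove_metabolites([incomplete.metabolites.get_by_id("trp__L_c")])
        with pytest.raises(ValueError, match="trp__L_c"):
            fba.add_protein_demand(incomplete, "MW")

    def test_gfp_sized_demand_totals_length(self, toy):
        seq = fba.synthetic_gfp_like_sequence()
        assert len(seq) == 239
        net = fba.add_protein_demand(toy, seq, gtp_per_bond=2.0)
        rxn = net.reactions.get_by_id(fba.PROTEIN_DEMAND_ID)
        aa_ids = set(fba.AA_METABOLITES.values())
        total_aa = -sum(c for m, c in rxn.metabolites.items() if m.id in aa_ids)
        assert total_aa == 239
        gtp = -rxn.metabolites[net.metabolites.get_by_id("gtp_c")]
        assert gtp == 2.0 * 238

    def test_input_model_not_mutated(self, toy):
        n = len(toy.reactions)
        fba.add_protein_demand(toy, "MG")
        assert len(toy.reactions) == n


class TestMaxProteinFlux:
    def test_analytic_optimum_rich(self, toy_mg):
        assert fba.max_protein_flux(toy_mg, "EX_rich_e", 10.0) == \
            pytest.approx(2 * 10 / 4)

    def test_rich_beats_poor_at_equal_uptake(self, toy_mg):
        rich = fba.max_protein_flux(toy_mg, "EX_rich_e", 10.0)
        poor = fba.max_protein_flux(toy_mg, "EX_poor_e", 10.0)
        assert rich > poor
        assert poor == pytest.approx(10 / 4)

    def test_lp_homogeneity(self, toy_mg):
        v1 = fba.max_protein_flux(toy_mg, "EX_rich_e", 5.0)
        v2 = fba.max_protein_flux(toy_mg, "EX_rich_e", 10.0)
        assert v2 == pytest.approx(2 * v1)

    def test_fixed_biomass_subtracts_precursor(self, toy_mg):
        v = fba.max_protein_flux(toy_mg, "EX_rich_e", 10.0, "BIOMASS_toy", 4.0)
        assert v == pytest.approx((20 - 4) / 4)

    def test_no_uptake_no_protein(self, toy_mg):
        assert fba.max_protein_flux(toy_mg, "EX_rich_e", 0.0) == pytest.approx(0.0)

    def test_capacity_grid_shape_and_values(self, toy_mg):
        grid = fba.capacity_grid(toy_mg, "EX_rich_e", [2.0, 4.0],
                                 "BIOMASS_toy", [0.0, 2.0])
        assert grid.flux.shape == (2, 2)
        assert grid.flux[1, 0] == pytest.approx(2.0)       # (8-0)/4
        assert grid.flux[1, 1] == pytest.approx(1.5)       # (8-2)/4

    def test_infeasible_biomass_flagged_not_zero(self, toy_mg):
        with pytest.raises(fba.InfeasibleError):
            fba.max_protein_flux(toy_mg, "EX_rich_e", 1.0, "BIOMASS_toy", 50.0)
        grid = fba.capacity_grid(toy_mg, "EX_rich_e", [1.0],
                                 "BIOMASS_toy", [50.0])
        assert np.isnan(grid.flux[0, 0])

    def test_mass_balance_of_solution(self, toy_mg):
        with toy_mg as m:
            fba._configure(m, "EX_rich_e", 10.0, None, 0.0)
            m.objective = fba.PROTEIN_DEMAND_ID
            sol = m.optimize()
            S, v = [], []
            for met in m.metabolites:
                net = sum(r.metabolites[met] * sol.fluxes[r.id]
                          for r in met.reactions)
                assert net == pytest.approx(0.0, abs=1e-6)


class TestFva:
    def test_parallel_paths_are_the_flexible_set(self, toy_mg):
        rep = fba.run_fva(toy_mg, "EX_rich_e", 10.0)
        assert set(rep.flexible_reactions) == {"P_PATH1", "P_PATH2"}
        assert rep.threshold == 0.001

    def test_ranges_bracket_the_fba_solution(self, toy_mg):
        rep = fba.run_fva(toy_mg, "EX_rich_e", 10.0)
        with toy_mg as m:
            fba._configure(m, "EX_rich_e", 10.0, None, 0.0)
            m.objective = fba.PROTEIN_DEMAND_ID
            sol = m.optimize()
        for rid in rep.table.index:
            lo, hi = rep.table.loc[rid, "min"], rep.table.loc[rid, "max"]
            assert lo - 1e-6 <= sol.fluxes[rid] <= hi + 1e-6

    def test_parallel_range_spans_total_flux(self, toy_mg):
        rep = fba.run_fva(toy_mg, "EX_rich_e", 10.0)
        # each parallel branch can carry anything from none to all of the
        # intermediate flux (5 protein * 2 aa = 10 inter units)
        row = rep.table.loc["P_PATH1"]
        assert row["min"] == pytest.approx(0.0, abs=1e-6)
        assert row["max"] == pytest.approx(10.0, abs=1e-6)


class TestSubsystemNetFlux:
    def test_hand_computed_sums(self, toy_mg):
        with toy_mg as m:
            fba._configure(m, "EX_rich_e", 10.0, None, 0.0)
            m.objective = fba.PROTEIN_DEMAND_ID
            sol = m.optimize()
        rep = fba.run_fva(toy_mg, "EX_rich_e", 10.0)
        tab = fba.subsystem_net_flux(toy_mg, sol.fluxes, rep)
        # protein 5/h: uptake 10 rich; 20 prec; 10 inter; 10 gtp
        assert tab.loc["Amino Acid Biosynthesis", "net_flux"] == pytest.approx(10.0)
        assert tab.loc["Protein Production", "net_flux"] == pytest.approx(10.0)
        # flexible parallel reactions are excluded from the restricted sum
        cm = tab.loc["Central Metabolism"]
        assert cm["net_flux"] - cm["inflexible_net_flux"] == pytest.approx(10.0)
        assert cm["n_reactions"] - cm["n_inflexible"] == 2

    def test_all_flexible_subsystem_contributes_zero(self, toy_mg):
        rep = fba.run_fva(toy_mg, "EX_rich_e", 10.0)
        sub = {r.id: r.subsystem for r in toy_mg.reactions}
        flexible_subs = {sub[r] for r in rep.flexible_reactions}
        assert flexible_subs == {"Central Metabolism"}
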