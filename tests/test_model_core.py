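"""Assembled-model behaviour: resource competition, conservation, growth
rate and the right-hand side."""

import numpy as np
import pytest

import cellecon as ce
from cellecon.params import ValidationError
from conftest import random_states


@pytest.fixture(scope="module")
def model():
    return ce.CellModel(ce.default_parameters())


class TestStateLayout:
    def test_layout_and_round_trip(self, model):
        assert model.species[:5] == ["S", "N", "M", "tu", "tc"]
        assert {"m_E", "m_Q", "m_P", "m_R", "p_E", "p_Q", "Ptot", "p_R",
                "r", "Rtot", "Pab", "Rab"} <= set(model.species)
        vec = np.arange(model.n_species, dtype=float)
        st = model.state(vec.copy())
        assert np.array_equal(st.vector, vec)
        st["M"] = 42.0
        assert st.as_dict()["M"] == 42.0

    def test_rrna_gene_has_no_mrna_or_protein_state(self, model):
        assert "m_rrn" not in model.species
        assert "p_rrn" not in model.species

    def test_gene_table_requires_one_rrna_flag(self):
        p = ce.default_parameters()
        genes = tuple(g for g in p.genes if not g.is_rRNA)
        with pytest.raises(ValidationError, match="is_rRNA"):
            ce.CellModel(p.with_(genes=genes))


class TestResourceCompetition:
    def test_conservation_on_random_states(self, model):
        for y in random_states(model, 200, seed=1):
            d = model.derived(y)
            ktot = sum(d.ktilde.values()) + d.free_rnap
            ctot = sum(d.ctilde.values()) + d.free_ribosomes
            Ptot = y[model.index("Ptot")]
            Rtot = y[model.index("Rtot")]
            assert ktot == pytest.approx(max(Ptot, 0.0), rel=1e-9, abs=1e-9)
            assert ctot == pytest.approx(max(Rtot, 0.0), rel=1e-9, abs=1e-9)

    def test_rrna_competes_for_rnap_but_not_ribosomes(self, model, single_cell_steady):
        d = model.derived(single_cell_steady.state)
        assert "rrn" in d.ktilde and d.ktilde["rrn"] > 0
        assert "rrn" not in d.ctilde

    def test_single_competitor_splits_polymerase(self):
        # one gene with sequestration potential K=1 binds half the pool
        p = ce.default_parameters()
        model = ce.CellModel(p)
        y = ce.default_initial_state(model).vector.copy()
        d = model.derived(y)
        # scale check on the closed form instead: k~_j = K_j*Ptot/(1+sum K)
        K = {g: d.ktilde[g] / d.free_rnap for g in d.ktilde}
        Ptot = y[model.index("Ptot")]
        for g, kj in d.ktilde.items():
            assert kj == pytest.approx(K[g] * Ptot / (1 + sum(K.values())))

    def test_sequestration_ratio_property(self, model, single_cell_steady):
        # doubling a gene's copy number doubles its transcription complexes
        # relative to any competitor, at a fixed state
        y = single_cell_steady.state.vector
        d1 = model.derived(y)
        m2 = model.with_gene("E", g0=model.params.gene("E").g0 * 2)
        d2 = m2.derived(y)
        r1 = d1.ktilde["E"] / d1.ktilde["Q"]
        r2 = d2.ktilde["E"] / d2.ktilde["Q"]
        assert r2 == pytest.approx(2 * r1, rel=1e-9)

    def test_more_mrna_attracts_ribosomes_from_competitors(self, model,
                                                           single_cell_steady):
        y = single_cell_steady.state.vector.copy()
        d1 = model.derived(y)
        y2 = y.copy()
        y2[model.index("m_E")] *= 2
        d2 = model.derived(y2)
        assert d2.ctilde["E"] > d1.ctilde["E"]
        for g in ("Q", "P", "R"):
            assert d2.ctilde[g] < d1.ctilde[g]

    def test_no_mrna_means_free_ribosomes(self, model):
        y = ce.default_initial_state(model).vector.copy()
        d = model.derived(y)          # all mRNAs start at zero
        assert d.free_ribosomes == pytest.approx(y[model.index("Rtot")])
        assert all(v == 0 for v in d.ctilde.values())


class TestGrowthRate:
    def test_no_ribosomes_no_growth(self, model):
        y = ce.default_initial_state(model).vector.copy()
        y[model.index("Rtot")] = 0.0
        assert model.growth_rate(y) == 0.0

    def test_no_charged_trna_no_growth(self, model, single_cell_steady):
        y = single_cell_steady.state.vector.copy()
        y[model.index("tc")] = 0.0
        assert model.growth_rate(y) == 0.0

    def test_growth_is_translation_flux_over_mass(self, model, single_cell_steady):
        y = single_cell_steady.state.vector
        d = model.derived(y)
        lam = d.gamma_X * sum(d.ctilde.values()) / model.params.M0
        assert d.growth_rate == pytest.approx(lam, rel=1e-12)

    def test_doubling_cell_mass_halves_growth(self, model, single_cell_steady):
        y = single_cell_steady.state.vector
        lam1 = model.growth_rate(y)
        lam2 = model.with_params(M0=2 * model.params.M0).growth_rate(y)
        assert lam2 == pytest.approx(lam1 / 2, rel=1e-12)


class TestRhs:
    def test_single_cell_mode_freezes_culture(self, model, single_cell_steady):
        dy = model.rhs(0.0, single_cell_steady.state.vector)
        assert dy[model.index("S")] == 0.0
        assert dy[model.index("N")] == 0.0

    def test_trna_flux_conservation(self, model):
        # charging and translation cancel in d(tu+tc); what remains is
        # synthesis minus dilution
        p = model.params
        for y in random_states(model, 50, seed=2):
            dy = model.rhs(0.0, y)
            d = model.derived(y)
            tu, tc = max(y[3], 0), max(y[4], 0)
            act = d.theta / (d.theta + p.kappa_theta)
            expected = p.D_psi * p.psi_max * act - d.growth_rate * (tu + tc)
            assert dy[3] + dy[4] == pytest.approx(expected, rel=1e-9, abs=1e-6)

    def test_charging_flux_enters_three_balances(self, model, single_cell_steady):
        fl = model.fluxes(single_cell_steady.state)
        y = single_cell_steady.state.vector
        dy = model.rhs(0.0, y)
        d = model.derived(y)
        lam = d.growth_rate
        p = model.params
        M, tu, tc = y[2], y[3], y[4]
        # reconstruct each balance from the named fluxes
        assert dy[2] == pytest.approx(
            p.phi * fl["substrate_import"] - fl["trna_charging"] - lam * M,
            rel=1e-9)
        assert dy[3] == pytest.approx(
            fl["trna_production"] - fl["trna_charging"]
            + fl["translation_trna_use"] - lam * tu, rel=1e-9)
        assert dy[4] == pytest.approx(
            fl["trna_charging"] - fl["translation_trna_use"] - lam * tc,
            rel=1e-9)

    def test_trna_terms_vanish_without_machinery(self):
        # with no tRNA synthesis, no charging enzyme flux and no mRNAs the
        # uncharged pool only dilutes
        p = ce.default_parameters().with_(psi_max=0.0, v_T=0.0)
        model = ce.CellModel(p)
        y = ce.default_initial_state(model).vector.copy()
        dy = model.rhs(0.0, y)
        lam = model.growth_rate(y)
        assert dy[model.index("tu")] == pytest.approx(-lam * y[model.index("tu")])

    def test_nonfinite_state_raises(self, model):
        y = ce.default_initial_state(model).vector.copy()
        y[2] = np.nan
        with pytest.raises(FloatingPointError):
            model.rhs(0.0, y)

    def test_chemostat_dilution_sign(self, ):
        p = ce.default_parameters()
        m = ce.CellModel(p, ce.CultureMode(mode="chemostat", delta=0.9, k_in=0.0))
        y = ce.default_initial_state(m).vector.copy()
        lam = m.growth_rate(y)
        assert lam < 0.9
        dy = m.rhs(0.0, y)
        assert dy[m.index("N")] < 0.0

    def test_antibiotic_pools_grow_under_treatment(self, model, single_cell_steady):
        y = single_cell_steady.state.vector
        m = model.with_params(k_rf=0.05, k_cm=0.05)
        dy = m.rhs(0.0, y)
        assert dy[m.index("Pab")] > 0.0
        assert dy[m.index("Rab")] > 0.0
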