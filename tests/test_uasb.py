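"""Sulfidogenic UASB engine tests: matrix validation, kinetics,
headspace transfer and tanks-in-series steady states."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from bioscrub.streams import LiquidStream
from bioscrub.uasb import (
    ReactionKinetics,
    StoichiometricModel,
    UASBConfig,
    default_glycerol_sulfate_model,
    headspace_transfer,
    reaction_rates,
    simulate_uasb,
)


@pytest.fixture(scope="module")
def model():
    return default_glycerol_sulfate_model()


def single_reaction_model(mu=2.0, ks=0.5, y=0.1, ki=None):
    species = ["glycerol", "acetate", "x_ferm", "sulfate", "sulfide", "ic"]
    inv = 1.0 / y
    row = np.zeros(len(species))
    row[0], row[1], row[2] = -inv, inv - 1.0, 1.0
    kin = [ReactionKinetics("g->a", "ferm", "glycerol", mu, ks, y, Ki_sulfide=ki)]
    return StoichiometricModel(species, row[None, :], kin)


class TestStoichiometricModel:
    def test_default_model_shape_and_groups(self, model):
        assert len(model.kinetics) == 15
        groups = [k.trophic_group for k in model.kinetics]
        assert groups.count("ferm") == 8
        assert groups.count("srb") == 5
        assert groups.count("met") == 2

    def test_default_model_balances_close(self, model):
        model.validate(rel_tol=1e-9)  # tighter than the load-time gate

    def test_cod_violation_rejected(self, model):
        bad = model.stoichiometry.copy()
        bad[0, model.index["pdo"]] *= 1.01
        with pytest.raises(ValueError, match="COD balance"):
            StoichiometricModel(model.species_names, bad, model.kinetics)

    def test_sulfur_violation_rejected(self, model):
        bad = model.stoichiometry.copy()
        j = next(i for i, k in enumerate(model.kinetics) if k.trophic_group == "srb")
        bad[j, model.index["sulfate"]] *= 1.05  # sulfate carries no COD
        with pytest.raises(ValueError, match="S balance"):
            StoichiometricModel(model.species_names, bad, model.kinetics)

    def test_shape_mismatch_rejected(self, model):
        with pytest.raises(ValueError, match="shape"):
            StoichiometricModel(model.species_names, model.stoichiometry[:, :-1], model.kinetics)


class TestReactionRates:
    def test_zero_substrate_zero_rate(self):
        m = single_reaction_model()
        rates = reaction_rates({"glycerol": 0.0, "x_ferm": 2.0}, m)
        assert rates[0] == 0.0

    def test_saturation_approaches_mu_max_x(self):
        m = single_reaction_model(mu=2.0, ks=0.5)
        rates = reaction_rates({"glycerol": 5e4, "x_ferm": 3.0}, m)
        assert rates[0] == pytest.approx(2.0 * 3.0, rel=1e-4)

    def test_noncompetitive_inhibition_halves_at_ki(self):
        ki = 0.25
        m = single_reaction_model(ki=ki)
        base = reaction_rates({"glycerol": 1.0, "x_ferm": 1.0, "sulfide": 0.0}, m)[0]
        inhib = reaction_rates({"glycerol": 1.0, "x_ferm": 1.0, "sulfide": ki}, m)[0]
        assert inhib == pytest.approx(base / 2.0, rel=1e-12)

    def test_negative_concentration_rejected(self):
        m = single_reaction_model()
        with pytest.raises(ValueError, match="glycerol"):
            reaction_rates({"glycerol": -0.1, "x_ferm": 1.0}, m)


class TestHeadspaceTransfer:
    def test_zero_at_saturation_and_zero_kla(self):
        assert headspace_transfer(0.3, 0.3, 200.0) == 0.0
        assert headspace_transfer(0.1, 0.5, 0.0) == 0.0

    def test_sign_moves_toward_equilibrium(self):
        assert headspace_transfer(0.1, 0.5, 200.0) > 0  # undersaturated: into liquid
        assert headspace_transfer(0.9, 0.5, 200.0) < 0

    def test_closed_batch_exponential_approach(self):
        """dC/dt = kLa (C_sat - C) has the analytic solution
        C_sat + (C0 - C_sat) exp(-kLa t); half-distance at ln2/kLa."""
        kla, sat, c0 = 200.0, 0.8, 0.1
        sol = solve_ivp(
            lambda t, c: headspace_transfer(c[0], sat, kla),
            (0.0, 0.05), [c0], rtol=1e-10, atol=1e-12, dense_output=True,
        )
        t_half = np.log(2.0) / kla
        got = sol.sol(t_half)[0]
        assert got == pytest.approx(sat + (c0 - sat) * 0.5, rel=1e-6)
        t = np.array([0.001, 0.01, 0.03])
        expected = sat + (c0 - sat) * np.exp(-kla * t)
        np.testing.assert_allclose(sol.sol(t)[0], expected, rtol=1e-6)


class TestSimulateUasb:
    def test_chemostat_matches_closed_form(self):
        """Suspended biomass, one Monod reaction, one tank: the washout
        equilibrium S* = Ks D / (mu_max - D)."""
        m = single_reaction_model(mu=2.0, ks=0.5, y=0.1)
        D = 0.5  # d-1
        volume = 100.0
        feed = LiquidStream(D * volume / 24.0, solutes={"glycerol": 5.0})
        cfg = UASBConfig(n_tanks=1, volume=volume, retention=0.0, biomass={"x_ferm": 0.1})
        res = simulate_uasb(feed, m, cfg, horizon=400.0)
        s_star = 0.5 * D / (2.0 - D)
        assert res.steady
        assert res.effluent.solutes["glycerol"] == pytest.approx(s_star, rel=1e-6)
        # biomass follows from the yield on consumed substrate
        x_star = 0.1 * (5.0 - s_star)
        assert res.effluent.solutes["x_ferm"] == pytest.approx(x_star, rel=1e-6)

    def test_sulfate_free_feed_is_inert_for_sulfur(self, model):
        feed = LiquidStream(50.0, solutes={"sulfide": 0.05})
        cfg = UASBConfig(n_tanks=3, volume=500.0, kla=0.0)  # closed liquid
        res = simulate_uasb(feed, model, cfg, carbon_dose=0.5, horizon=80.0)
        assert res.effluent.solutes["sulfide"] == pytest.approx(0.05, rel=1e-9)
        assert res.effluent.solutes["sulfate"] == pytest.approx(0.0, abs=1e-12)

    def test_more_tanks_approach_plug_flow(self):
        m = single_reaction_model(mu=2.0, ks=2.0, y=0.1)
        outs = []
        for n in (1, 2, 5, 10):
            cfg = UASBConfig(n_tanks=n, volume=50.0, biomass={"x_ferm": 1.0}, kla=0.0)
            feed = LiquidStream(25.0, solutes={"glycerol": 2.0})
            res = simulate_uasb(feed, m, cfg, horizon=30.0)
            outs.append(res.effluent.solutes["glycerol"])
        assert all(b <= a + 1e-12 for a, b in zip(outs, outs[1:]))

    def test_sulfur_and_cod_conservation_at_steady_state(self, model):
        """Feed S and COD either leave with the effluent, the biogas or
        the grown biomass (sludge); closure to 1e-6 relative."""
        feed = LiquidStream(
            100.0, solutes={"sulfate": 0.4, "sulfide": 0.01, "ic": 0.05}
        )
        cfg = UASBConfig(n_tanks=4, volume=600.0)
        dose = 2.5
        res = simulate_uasb(feed, model, cfg, carbon_dose=dose, horizon=80.0)
        assert res.steady
        q = feed.volumetric_flow * 24.0 * 1000.0  # L d-1
        e = res.effluent.solutes
        # --- sulfur ---
        s_in = (0.4 + 0.01) * q
        s_liq = (e["sulfate"] + e["sulfide"]) * q
        gas_mol_d = res.biogas.volumetric_flow * 24.0 / (24.45e-3)
        s_gas = gas_mol_d * res.biogas.composition.get("H2S", 0.0) * 1e-6 * 32.0
        assert (s_liq + s_gas) == pytest.approx(s_in, rel=1e-6)
        # --- COD ---
        cod_in = dose * 1.0 * q
        organics = ("glycerol", "pdo", "propionate", "butyrate", "acetate", "h2", "ch4")
        cod_liq = sum(e[sp] for sp in organics) * q
        cod_liq += 2.0 * e["sulfide"] * q - 2.0 * 0.01 * q  # sulfide carries 2 gCOD/gS
        cod_gas = gas_mol_d * (
            res.biogas.composition.get("CH4", 0.0) * 1e-6 * 64.0
            + res.biogas.composition.get("H2", 0.0) * 1e-6 * 16.0
            + res.biogas.composition.get("H2S", 0.0) * 1e-6 * 64.0
        )
        cod_sludge = res.sludge_production
        assert (cod_liq + cod_gas + cod_sludge) == pytest.approx(cod_in, rel=1e-6)

    def test_more_carbon_never_hurts_sulfate_removal(self, model):
        feed = LiquidStream(100.0, solutes={"sulfate": 0.4})
        cfg = UASBConfig(n_tanks=3, volume=400.0)
        residuals = []
        for dose in (0.6, 1.2, 2.4, 4.8):
            res = simulate_uasb(feed, model, cfg, carbon_dose=dose, horizon=60.0)
            residuals.append(res.effluent.solutes["sulfate"])
        assert all(b <= a + 1e-9 for a, b in zip(residuals, residuals[1:]))

    def test_zero_flow_rejected(self, model):
        with pytest.raises(ValueError, match="retention time|flow"):
            simulate_uasb(LiquidStream(0.0, solutes={}), model)
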