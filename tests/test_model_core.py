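"""Unit and property tests for the fruit growth simulator."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from fruitflux import synthetic_data as sd
from fruitflux.model_core import (
    CALIBRATION_BOUNDS,
    EnvSeries,
    FruitState,
    GenericParams,
    GenotypeParams,
    active_uptake,
    fruit_geometry,
    osmotic_pressure,
    reflection_coefficient,
    respiration_coupled,
    simulate,
    solve_turgor,
    soluble_sugar_fraction,
    step,
    stem_water_potential,
    sugar_flux,
    transpiration,
    turgor_residual,
    volume_balance_rate,
    water_fluxes,
)
from tests.conftest import mid_bounds_genotype, random_genotype_and_inputs


class TestSolubleSugarFraction:
    def test_intercept_at_zero(self):
        assert soluble_sugar_fraction(0.0, 0.002, 0.1) == pytest.approx(0.1)

    def test_linear_form(self):
        # 0.002 * 240/24 + 0.1
        assert soluble_sugar_fraction(240.0, 0.002, 0.1) == pytest.approx(0.12)

    def test_clipped_to_one(self):
        assert soluble_sugar_fraction(1e6, 0.002, 0.1) == 1.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            soluble_sugar_fraction(-1.0, 0.002, 0.1)


class TestReflectionCoefficient:
    def test_zero_at_t0(self):
        assert reflection_coefficient(0.0, 1.5e-5) == 0.0

    def test_closed_form(self):
        assert reflection_coefficient(300.0, 1.5e-5) == pytest.approx(
            1.0 - math.exp(-1.35), rel=1e-12)

    @given(t=st.floats(1.0, 2000.0), tau=st.floats(1e-6, 2e-5))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_taus_and_bounded(self, t, tau):
        a = reflection_coefficient(t, tau)
        b = reflection_coefficient(t, 2.0 * tau)
        assert 0.0 <= a <= 1.0
        # strictly increasing in tauS until float saturation at 1.0
        assert b > a or a == 1.0


class TestActiveUptake:
    def test_logistic_midpoint(self):
        got = active_uptake(t=500.0, Cp=0.2, nuM=0.1, tstar=500.0, tauA=50.0, Km=0.3)
        assert got == pytest.approx(0.5 * 0.1 * 0.2 / 0.5, rel=1e-12)

    def test_ten_time_scales_past_onset(self):
        got = active_uptake(t=500.0 + 10 * 40.0, Cp=0.2, nuM=0.1, tstar=500.0,
                            tauA=40.0, Km=0.3)
        expect = 0.1 / (1.0 + math.exp(10.0)) * 0.2 / 0.5
        assert got == pytest.approx(expect, rel=1e-9)

    def test_michaelis_menten_saturation(self):
        got = active_uptake(t=0.0, Cp=1e6, nuM=0.1, tstar=500.0, tauA=40.0, Km=0.3)
        assert got == pytest.approx(0.1, rel=1e-5)

    @given(t=st.floats(0, 1e7), tstar=st.floats(10, 900), tauA=st.floats(5, 900))
    @settings(max_examples=100, deadline=None)
    def test_overflow_safe_and_bounded(self, t, tstar, tauA):
        got = active_uptake(t, Cp=0.2, nuM=0.1, tstar=tstar, tauA=tauA, Km=0.0)
        assert 0.0 <= got <= 0.1 * (1.0 + 1e-12)


class TestFruitGeometry:
    def test_unit_sphere_identity(self):
        gamma = (36.0 * math.pi) ** (1.0 / 3.0)
        v, af = fruit_geometry(1.0, 1e-12, rhoS=1.6, gammaA=gamma)
        assert v == pytest.approx(1.0)
        assert af == pytest.approx(gamma, rel=1e-9)

    def test_two_thirds_power_scaling(self):
        _, af1 = fruit_geometry(1.0, 0.1, 1.6, 4.836)
        _, af8 = fruit_geometry(8.0, 0.8, 1.6, 4.836)
        assert af8 == pytest.approx(4.0 * af1, rel=1e-12)

    def test_hand_value(self):
        v, _ = fruit_geometry(8.0, 1.6, rhoS=1.6, gammaA=4.836)
        assert v == pytest.approx(9.0)


class TestOsmoticPressure:
    def test_no_sugar_term(self):
        got = osmotic_pressure(w=1.0, s=1e-300, t=100.0, T=20.0, piOther=2.0,
                               assrat=0.004, bssrat=0.1, Msugar=180.0)
        assert got == pytest.approx(2.0)

    def test_linearity_in_dry_mass(self):
        kw = dict(w=1.0, t=100.0, T=20.0, piOther=0.0, assrat=0.004,
                  bssrat=0.1, Msugar=180.0)
        assert osmotic_pressure(s=0.2, **kw) == pytest.approx(
            2.0 * osmotic_pressure(s=0.1, **kw), rel=1e-12)

    def test_van_t_hoff_hand_value(self):
        # 0.05 g sugar per g water at 20 C, hexose: c = 0.2778 mol/L,
        # pi = c R T = 0.2778 * 0.08314 * 293.15 = 6.77 bar
        got = osmotic_pressure(w=1.0, s=0.5, t=0.0, T=20.0, piOther=0.0,
                               assrat=0.0, bssrat=0.1, Msugar=180.0)
        expect = (0.05 * 1000.0 / 180.0) * 0.08314 * 293.15
        assert got == pytest.approx(expect, rel=1e-12)
        assert got == pytest.approx(6.7686, abs=2e-3)


class TestTranspiration:
    def test_vapour_equilibrium(self):
        assert transpiration(100.0, 25.0, 0.996, 50.0, Hf=0.996) == 0.0

    def test_no_condensation_gain(self):
        assert transpiration(100.0, 25.0, 1.0, 50.0, Hf=0.996) == 0.0

    def test_proportional_to_area(self):
        one = transpiration(100.0, 25.0, 0.6, 50.0, 0.996)
        two = transpiration(200.0, 25.0, 0.6, 50.0, 0.996)
        assert one > 0
        assert two == pytest.approx(2.0 * one, rel=1e-12)

    def test_increasing_in_temperature(self):
        cold = transpiration(100.0, 15.0, 0.6, 50.0, 0.996)
        warm = transpiration(100.0, 30.0, 0.6, 50.0, 0.996)
        assert warm > cold


class TestRespirationCoupled:
    def test_maintenance_consumes_uptake(self):
        qm20, q10 = 3e-4, 1.9
        s = 2.0
        us = qm20 * s  # T = 20 C
        dsdt, rf = respiration_coupled(us, s, 20.0, qg=0.2, qm20=qm20, Q10=q10)
        assert dsdt == pytest.approx(0.0, abs=1e-15)
        assert rf == pytest.approx(us)

    def test_no_growth_respiration(self):
        dsdt, _ = respiration_coupled(0.01, 1.0, 20.0, qg=0.0, qm20=3e-4, Q10=1.9)
        assert dsdt == pytest.approx(0.01 - 3e-4)

    def test_closed_form_hand_value(self):
        # qm*s = 0.002 at T=20 via qm20 = 0.002/s
        dsdt, rf = respiration_coupled(0.01, 1.0, 20.0, qg=0.2, qm20=0.002, Q10=1.9)
        assert dsdt == pytest.approx(0.008 / 1.2, rel=1e-12)
        assert rf == pytest.approx(0.01 - 0.008 / 1.2, rel=1e-12)


def _two_node_oracle(pathway, Pf, w, s, t, genotype, inputs, generic, T):
    """Independent flux via root-finding on the vasculature node potential."""
    _, af = fruit_geometry(w, s, generic.rhoS, generic.gammaA)
    pi_f = osmotic_pressure(w, s, t, T, inputs.piOther, inputs.assrat,
                            inputs.bssrat, generic.Msugar)
    pi_p = 0.08314 * (T + 273.15) * inputs.Cp * 1000.0 / generic.Msugar
    psi = stem_water_potential(t, inputs.psiStemPredawn, inputs.psiStemMidday)
    sig = reflection_coefficient(t, genotype.tauS)
    if pathway == "xylem":
        k_ped = genotype.lx1
        k_mem = generic.ax * af * genotype.lx

        def balance(node):
            return k_ped * (psi - node) - k_mem * (node - Pf + pi_f)
    else:
        k_ped = genotype.lp1
        k_mem = generic.ap * af * genotype.Lp

        def balance(node):
            return (k_ped * (psi + pi_p - node)
                    - k_mem * (node - Pf - sig * (pi_p - pi_f)))

    node = brentq(balance, -1e4, 1e4, xtol=1e-13, rtol=8.9e-16)
    return k_ped * ((psi - node) if pathway == "xylem" else (psi + pi_p - node))


class TestWaterFluxes:
    def test_zero_driving_force(self, generic, inputs_c):
        g = mid_bounds_genotype()
        w, s, t, T = 5.0, 0.4, 400.0, 22.0
        pi_f = osmotic_pressure(w, s, t, T, inputs_c.piOther, inputs_c.assrat,
                                inputs_c.bssrat, generic.Msugar)
        psi = stem_water_potential(t, inputs_c.psiStemPredawn, inputs_c.psiStemMidday)
        ux, _ = water_fluxes(psi + pi_f, w, s, t, g, inputs_c, generic, T)
        assert ux == pytest.approx(0.0, abs=1e-12)

    def test_membrane_limited_limit(self, generic, inputs_c):
        g = dataclasses.replace(mid_bounds_genotype(), lp1=1e12)
        w, s, t, T, pf = 5.0, 0.4, 400.0, 22.0, 3.0
        _, af = fruit_geometry(w, s, generic.rhoS, generic.gammaA)
        pi_f = osmotic_pressure(w, s, t, T, inputs_c.piOther, inputs_c.assrat,
                                inputs_c.bssrat, generic.Msugar)
        psi = stem_water_potential(t, inputs_c.psiStemPredawn, inputs_c.psiStemMidday)
        ux, _ = water_fluxes(pf, w, s, t, g, inputs_c, generic, T)
        expect = generic.ax * af * g.lx * (psi - pf + pi_f)
        assert ux == pytest.approx(expect, rel=1e-9)

    def test_series_conductance_arithmetic(self):
        # equal driving force, two conductances of 2 in series -> effective 1
        assert 1.0 / (1.0 / 2.0 + 1.0 / 2.0) == pytest.approx(1.0)

    def test_two_node_oracle_equivalence(self, generic, inputs_c, rng):
        for _ in range(100):
            g, inputs = random_genotype_and_inputs(rng, "C" if rng.random() < 0.5 else "WD")
            w = float(rng.uniform(0.5, 100.0))
            s = w * float(rng.uniform(0.03, 0.3))
            t = float(rng.uniform(192.0, 1400.0))
            T = float(rng.uniform(15.0, 32.0))
            pf = float(rng.uniform(0.0, 12.0))
            ux, up = water_fluxes(pf, w, s, t, g, inputs, generic, T)
            ox = _two_node_oracle("xylem", pf, w, s, t, g, inputs, generic, T)
            op = _two_node_oracle("phloem", pf, w, s, t, g, inputs, generic, T)
            assert ux == pytest.approx(ox, rel=1e-9, abs=1e-12)
            assert up == pytest.approx(op, rel=1e-9, abs=1e-12)

    def test_non_finite_rejected(self, generic, inputs_c):
        with pytest.raises(ValueError):
            water_fluxes(math.nan, 5.0, 0.4, 400.0, mid_bounds_genotype(),
                         inputs_c, generic, 22.0)


class TestSugarFlux:
    def test_no_gradient_no_diffusion(self, generic, inputs_c):
        g = mid_bounds_genotype()
        # choose s/w so that Cf == Cp
        t = 240.0
        ssr = soluble_sugar_fraction(t, inputs_c.assrat, inputs_c.bssrat)
        w = 5.0
        s = inputs_c.Cp * w / ssr
        _, _, ud, _ = sugar_flux(0.1, w, s, t, g, inputs_c, generic)
        assert ud == pytest.approx(0.0, abs=1e-12)

    def test_semipermeable_membrane_no_mass_flow(self, generic, inputs_c):
        g = dataclasses.replace(mid_bounds_genotype(), tauS=1.5e-5)
        _, um, _, _ = sugar_flux(0.5, 5.0, 0.4, 5e4, g, inputs_c, generic)
        assert um == pytest.approx(0.0, abs=1e-12)

    def test_no_solute_backflow(self, generic, inputs_c):
        g = mid_bounds_genotype()
        _, um, _, _ = sugar_flux(-0.5, 5.0, 0.4, 300.0, g, inputs_c, generic)
        assert um == 0.0

    def test_components_sum(self, generic, inputs_c):
        g = mid_bounds_genotype()
        ua, um, ud, us = sugar_flux(0.3, 5.0, 0.4, 300.0, g, inputs_c, generic)
        assert us == pytest.approx(ua + um + ud, rel=1e-12)


class TestSolveTurgor:
    def test_growing_root_matches_bisection_oracle(self, generic, inputs_c, rng):
        checked = 0
        for _ in range(200):
            g, inputs = random_genotype_and_inputs(rng)
            w = float(rng.uniform(1.0, 60.0))
            s = w * float(rng.uniform(0.05, 0.2))
            t = float(rng.uniform(192.0, 900.0))
            T, RH = 24.0, 0.65
            pf, regime = solve_turgor(w, s, t, g, inputs, generic, T, RH)
            if regime != "growing":
                continue
            checked += 1
            assert pf > generic.Y
            v, _ = fruit_geometry(w, s, generic.rhoS, generic.gammaA)
            phi = g.phiMax * math.exp(-t / generic.tauPhi)

            def defect(p):
                return (v * phi * (p - generic.Y)
                        - volume_balance_rate(p, w, s, t, g, inputs, generic, T, RH))

            oracle = brentq(defect, generic.Y, 200.0, xtol=1e-12)
            assert pf == pytest.approx(oracle, abs=1e-7)
            assert abs(defect(pf)) < 1e-8 * max(1.0, v)
            if checked >= 30:
                break
        assert checked >= 10

    def test_static_regime_balances_volume(self, generic, inputs_c, rng):
        found = 0
        for _ in range(400):
            g, inputs = random_genotype_and_inputs(rng)
            w = float(rng.uniform(1.0, 60.0))
            s = w * float(rng.uniform(0.05, 0.2))
            t = float(rng.uniform(1200.0, 1450.0))
            pf, regime = solve_turgor(w, s, t, g, inputs, generic, 24.0, 0.65)
            if regime != "static" or pf == 0.0:
                continue
            found += 1
            dv = volume_balance_rate(pf, w, s, t, g, inputs, generic, 24.0, 0.65)
            assert abs(dv) < 1e-8
            if found >= 10:
                break
        assert found >= 3

    def test_vanishing_extensibility_continuity(self, generic, inputs_c):
        g = mid_bounds_genotype()
        w, s, t = 10.0, 1.0, 800.0
        tiny = dataclasses.replace(g, phiMax=1e-12)
        pf_tiny, _ = solve_turgor(w, s, t, tiny, inputs_c, generic, 24.0, 0.65)
        frozen = dataclasses.replace(g, phiMax=1e-300)
        pf_static, regime = solve_turgor(w, s, t, frozen, inputs_c, generic, 24.0, 0.65)
        assert abs(pf_tiny - pf_static) < 1e-4

    def test_degenerate_no_flux_tie_break(self, generic, inputs_c):
        g = dataclasses.replace(mid_bounds_genotype(), lp1=0.0, nuM=0.0)
        gen = dataclasses.replace(generic, ps=0.0, qm20=0.0)
        inputs = dataclasses.replace(inputs_c, rhoSurf=1e-300)
        pf, regime = solve_turgor(5.0, 0.4, 400.0, g, inputs, gen, 24.0, 0.996)
        assert regime == "static"
        assert pf == 0.0

    def test_residual_helper_zero_for_solution(self, generic, inputs_c):
        g = mid_bounds_genotype()
        pf, regime = solve_turgor(5.0, 0.4, 300.0, g, inputs_c, generic, 24.0, 0.65)
        res = turgor_residual(pf, regime, 5.0, 0.4, 300.0, g, inputs_c,
                              generic, 24.0, 0.65)
        assert abs(res) < 1e-10


class TestStep:
    def test_fixed_point_when_all_fluxes_vanish(self, env):
        g = dataclasses.replace(mid_bounds_genotype(), lp1=0.0, nuM=0.0)
        gen = dataclasses.replace(GenericParams(), ps=0.0, qm20=0.0)
        inputs = dataclasses.replace(sd.default_base_inputs(), rhoSurf=1e-300)
        flat = EnvSeries(np.arange(0, 2000.0), np.full(2000, 24.0),
                         np.full(2000, gen.Hf))
        state = FruitState(t=400.0, w=5.0, s=0.4, Pf=0.0)
        nxt = step(state, 1.0, g, inputs, flat, gen)
        assert nxt.w == pytest.approx(state.w, rel=1e-12)
        assert nxt.s == pytest.approx(state.s, rel=1e-12)

    def test_respiratory_water_gain(self, generic, inputs_c):
        # with no water fluxes and no transpiration, dw/dt = (9/16) Rf
        from fruitflux import _kernel as K
        from fruitflux.model_core import build_constants
        g = dataclasses.replace(mid_bounds_genotype(), lp1=0.0)
        gen = dataclasses.replace(GenericParams(), ps=0.0)
        inputs = dataclasses.replace(inputs_c, rhoSurf=1e-300)
        pc = build_constants(gen, inputs, g)
        d = K.derivs(400.0, 5.0, 0.4, 24.0, gen.Hf, g.to_array(), pc)
        dwdt, rf = d[0], d[8]
        assert rf > 0
        assert dwdt == pytest.approx(9.0 / 16.0 * rf, rel=1e-12)

    def test_halving_dt_converges(self, env, generic, inputs_c, mid_genotype):
        coarse = simulate(mid_genotype, inputs_c, env, 192.0, 892.0,
                          generic=generic, dt=1.0)
        fine = simulate(mid_genotype, inputs_c, env, 192.0, 892.0,
                        generic=generic, dt=0.5)
        assert fine.w[-1] == pytest.approx(coarse.w[-1], rel=1e-3)
        assert fine.s[-1] == pytest.approx(coarse.s[-1], rel=1e-3)

    def test_dt_must_be_positive(self, env, generic, inputs_c, mid_genotype):
        state = FruitState(t=192.0, w=0.5, s=0.05, Pf=0.0)
        with pytest.raises(ValueError):
            step(state, 0.0, mid_genotype, inputs_c, env, generic)


class TestSimulate:
    def test_single_point_trajectory(self, env, generic, inputs_c, mid_genotype):
        traj = simulate(mid_genotype, inputs_c, env, 192.0, 192.0, generic=generic)
        assert traj.t.size == 1
        assert traj.w[0] == inputs_c.w0obs
        assert traj.s[0] == inputs_c.s0obs

    def test_deterministic(self, env, generic, inputs_c, mid_genotype):
        a = simulate(mid_genotype, inputs_c, env, 192.0, 1272.0, generic=generic)
        b = simulate(mid_genotype, inputs_c, env, 192.0, 1272.0, generic=generic)
        assert np.array_equal(a.w, b.w)
        assert np.array_equal(a.s, b.s)
        assert np.array_equal(a.Pf, b.Pf)

    def test_water_deficit_direction(self, env, generic, inputs_c, inputs_wd,
                                     mid_genotype):
        c = simulate(mid_genotype, inputs_c, env, 192.0, 1272.0, generic=generic)
        wd = simulate(mid_genotype, inputs_wd, env, 192.0, 1272.0, generic=generic)
        assert wd.final_state().fresh_mass < c.final_state().fresh_mass
        assert wd.final_state().dry_matter_content >= c.final_state().dry_matter_content

    def test_mid_bounds_ripe_mass_in_envelope(self, env, generic, inputs_c,
                                              mid_genotype):
        fm = simulate(mid_genotype, inputs_c, env, 192.0, 1272.0,
                      generic=generic).final_state().fresh_mass
        assert 5.0 <= fm <= 160.0

    def test_dry_matter_content_in_unit_interval(self, env, generic, rng):
        for _ in range(5):
            g, inputs = random_genotype_and_inputs(rng)
            traj = simulate(g, inputs, env, 192.0, 1272.0, generic=generic)
            dm = traj.dry_matter_content
            assert np.all(dm > 0.0) and np.all(dm < 1.0)

    def test_conservation_budgets(self, env, generic, rng):
        for _ in range(5):
            g, inputs = random_genotype_and_inputs(rng)
            traj = simulate(g, inputs, env, 192.0, 192.0 + 1200.0, generic=generic)
            dw = traj.w[-1] - traj.w[0]
            ds = traj.s[-1] - traj.s[0]
            iw = np.trapezoid(traj.Ux + traj.Up + generic.rw * traj.Rf - traj.Tf, traj.t)
            is_ = np.trapezoid(traj.Us - traj.Rf, traj.t)
            assert abs(iw - dw) <= 0.005 * max(abs(dw), 1e-6)
            assert abs(is_ - ds) <= 0.005 * max(abs(ds), 1e-6)

    def test_monotone_response_to_stem_potential(self, env, generic, rng):
        for _ in range(20):
            g, inputs = random_genotype_and_inputs(rng)
            relaxed = dataclasses.replace(
                inputs, psiStemPredawn=inputs.psiStemPredawn + 1.0,
                psiStemMidday=inputs.psiStemMidday + 1.0)
            f0 = simulate(g, inputs, env, 192.0, 1272.0,
                          generic=generic).final_state().fresh_mass
            f1 = simulate(g, relaxed, env, 192.0, 1272.0,
                          generic=generic).final_state().fresh_mass
            assert f1 >= f0 - 1e-9

    def test_trajectory_frame_schema(self, env, generic, inputs_c, mid_genotype):
        df = simulate(mid_genotype, inputs_c, env, 192.0, 292.0,
                      generic=generic).to_frame()
        assert list(df.columns) == ["t_h", "w_g", "s_g", "fm_g", "dm_frac",
                                    "Pf_bar", "Ux", "Up", "Us", "Tf", "Rf"]


class TestEnvSeries:
    def test_invalid_rh_rejected(self):
        with pytest.raises(ValueError):
            EnvSeries(np.arange(3.0), np.full(3, 20.0), np.array([0.5, 1.2, 0.5]))

    def test_non_increasing_time_rejected(self):
        with pytest.raises(ValueError):
            EnvSeries(np.array([0.0, 2.0, 1.0]), np.full(3, 20.0), np.full(3, 0.5))

    def test_hourly_resampling(self):
        coarse = EnvSeries(np.array([0.0, 2.0, 4.0]), np.array([20.0, 22.0, 24.0]),
                           np.array([0.5, 0.6, 0.7]))
        hourly = coarse.hourly()
        assert np.allclose(np.diff(hourly.t), 1.0)
        assert hourly.T[1] == pytest.approx(21.0)


class TestStemWaterPotential:
    def test_extremes_at_measurement_hours(self):
        assert stem_water_potential(5.0, -2.0, -6.0) == pytest.approx(-2.0)
        assert stem_water_potential(13.0, -2.0, -6.0) == pytest.approx(-6.0)

    def test_daily_periodicity(self):
        assert stem_water_potential(8.0, -2.0, -6.0) == pytest.approx(
            stem_water_potential(8.0 + 240.0, -2.0, -6.0))

    @given(t=st.floats(0.0, 2000.0))
    @settings(max_examples=100, deadline=None)
    def test_bounded_between_extremes(self, t):
        psi = stem_water_potential(t, -2.0, -6.0)
        assert -6.0 - 1e-12 <= psi <= -2.0 + 1e-12


class TestValidation:
    def test_genotype_bounds_enforced(self):
        g = mid_bounds_genotype()
        g.validate("calibration")
        bad = dataclasses.replace(g, phiMax=1.0)
        with pytest.raises(ValueError):
            bad.validate("calibration")

    def test_ideotype_mode_requires_extra_fields(self):
        with pytest.raises(ValueError):
            mid_bounds_genotype().validate("ideotype")

    def test_generic_rw_fixed(self):
        with pytest.raises(ValueError):
            dataclasses.replace(GenericParams(), rw=0.5).validate()

    def test_plant_inputs_ordering(self):
        bad = dataclasses.replace(sd.default_base_inputs(), psiStemMidday=-1.0)
        with pytest.raises(ValueError):
            bad.validate()

    def test_derived_xylem_conductances(self):
        g = mid_bounds_genotype()
        assert g.lx == pytest.approx(g.rxp * g.Lp)
        assert g.lx1 == pytest.approx(g.rxp * g.lp1)
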