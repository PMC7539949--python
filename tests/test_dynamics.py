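"""Pore-change factors, the ODE systems, steady states and integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from porespace import (InfeasibleSteadyStateError, NOT_REACHED,
                       PoreChangeFactors, PoreSpaceState, RootParams,
                       ShrinkageParams, WormParams,
                       bioturbation_volume_rates, integrate,
                       pore_change_step, porosities, solids_rate,
                       state_from_porosities, steady_flux_rates,
                       steady_state, surface_cast_fraction,
                       swell_shrink_step, table3_factors,
                       time_to_equilibrium, turnover_rate)

from conftest import SCENARIO


def scenario_initial(dz=1.0):
    """Compacted initial condition: no macropores, matrix only."""
    return state_from_porosities(0.32, 0.08, 0.0, SCENARIO["phi_min"],
                                 SCENARIO["f_t_mic"], dz=dz)


# ---------------------------------------------------------------------------
# Elementary rates


class TestSolidsRate:
    def test_steady_state_is_zero(self):
        roots = RootParams(B_r=0.002, tau_r=0.6)  # R_g = R_d by default
        worms = WormParams(tau_s=0.1, E_c=1.5, E_i=1.5)
        assert solids_rate(roots, worms, V_t=10.0, gamma_s=2.65) == 0.0

    def test_net_root_growth(self):
        roots = RootParams(gamma_r=1.2, R_g=0.0012, R_d=0.0)
        worms = WormParams(tau_s=0.0)
        assert solids_rate(roots, worms, 1.0, 2.65) == pytest.approx(0.001)

    def test_net_ingestion_shrinks_solids(self):
        roots = RootParams()
        worms = WormParams(tau_s=0.0, E_c=0.5, E_i=1.0)
        rate = solids_rate(roots, worms, 2.0, 2.5)
        assert rate == pytest.approx(2.0 * (0.5 - 1.0) / 2.5)
        assert rate < 0


class TestSwellShrink:
    @pytest.mark.parametrize("f,dvw,expected",
                             [(0.0, 5.0, 0.0), (1.0, -2.0, -2.0),
                              (0.5, 4.0, 2.0)])
    def test_slope_scaling(self, f, dvw, expected):
        assert swell_shrink_step(dvw, ShrinkageParams(f)) == expected

    def test_slope_bounds(self):
        with pytest.raises(ValueError):
            ShrinkageParams(1.5)


class TestTurnoverRate:
    def test_direct_substitution(self):
        assert turnover_rate(1000.0, 2e-4, 1.5) == pytest.approx(0.13333,
                                                                 abs=1e-4)

    def test_no_worms_no_turnover(self):
        assert turnover_rate(1000.0, 0.0, 1.5) == 0.0

    def test_linearity_in_ingestion(self):
        assert turnover_rate(2000.0, 2e-4, 1.5) == \
            pytest.approx(2 * turnover_rate(1000.0, 2e-4, 1.5))

    def test_zero_density_rejected(self):
        with pytest.raises(ValueError):
            turnover_rate(1.0, 1.0, 0.0)


class TestSurfaceCastFraction:
    @pytest.mark.parametrize("phi_mac,expected",
                             [(0.0, 1.0), (0.057, 0.0), (0.0285, 0.5),
                              (0.2, 0.0)])
    def test_threshold_function(self, phi_mac, expected):
        assert surface_cast_fraction(phi_mac, 0.057) == \
            pytest.approx(expected)

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            surface_cast_fraction(0.01, 0.0)


# ---------------------------------------------------------------------------
# Pore-change factors


class TestFactorTable:
    @settings(deadline=None, max_examples=100)
    @given(phi_s_mes=st.floats(0.0, 0.3), phi_s_mic=st.floats(0.0, 0.3),
           eps=st.floats(0.0, 1.5), eps_casts=st.floats(0.0, 1.5),
           f_cm=st.floats(0.0, 1.0), f_rc=st.floats(0.0, 1.0),
           f_t_mic=st.floats(0.0, 1.0))
    def test_each_process_conserves_volume(self, phi_s_mes, phi_s_mic, eps,
                                           eps_casts, f_cm, f_rc, f_t_mic):
        """All four factor triples sum to -1 exactly."""
        worms = WormParams(eps_casts=eps_casts, f_casts_mic=f_cm, tau_s=0.1)
        roots = RootParams(f_r_c=f_rc)
        f = table3_factors(phi_s_mes, phi_s_mic, eps, worms, roots, f_t_mic)
        for name, triple in f.as_dict().items():
            assert sum(triple) == pytest.approx(-1.0, abs=1e-12), name

    def test_root_decay_split(self):
        """A 20% coarse-root fraction opens macropores and mesopores 1:4."""
        f = table3_factors(0.1, 0.1, 0.5, WormParams(tau_s=0.1),
                           RootParams(f_r_c=0.2))
        assert f.root_decay == pytest.approx((-0.2, -0.8, 0.0))

    def test_symmetric_exchange_cancels(self):
        """When casts match the matrix (same void ratio, same micropore
        share) the casting and ingestion columns are identical, so their
        difference — which is what drives the porosity rates — vanishes
        termwise."""
        s_mic = 0.12 / (0.12 + 0.08)
        worms = WormParams(eps_casts=0.7, f_casts_mic=s_mic, tau_s=0.1)
        f = table3_factors(0.08, 0.12, 0.7, worms, RootParams())
        np.testing.assert_allclose(np.asarray(f.worm_casting),
                                   np.asarray(f.worm_ingestion),
                                   atol=1e-14)


class TestPoreChangeStep:
    @settings(deadline=None, max_examples=100)
    @given(data=st.data())
    def test_factor_sum_theorem(self, data):
        """Any factor set summing to -1 per agent leaves V_t unchanged."""
        tri = []
        for _ in range(4):
            a = data.draw(st.floats(-1.0, 2.0))
            b = data.draw(st.floats(-1.0, 2.0))
            tri.append((a, b, -1.0 - a - b))
        factors = PoreChangeFactors(root_growth=tri[0], root_decay=tri[1],
                                    worm_casting=tri[2],
                                    worm_ingestion=tri[3])
        dvs = {name: data.draw(st.floats(-2.0, 2.0))
               for name in ("root_growth", "root_decay", "worm_casting",
                            "worm_ingestion")}
        *_, dv_t = pore_change_step(dvs, factors)
        assert dv_t == pytest.approx(0.0, abs=1e-12)

    def test_som_aggregation_grows_soil(self):
        """Gaining OM with factors summing to 3 expands pores and volume."""
        factors = PoreChangeFactors(root_growth=(0, 0, 0),
                                    root_decay=(0, 0, 0),
                                    worm_casting=(0, 0, 0),
                                    worm_ingestion=(0, 0, 0),
                                    som_turnover=(0.0, 1.0, 2.0))
        dv_mic, dv_mes, dv_mac, dv_t = pore_change_step(
            {"som_turnover": 1.0}, factors)
        assert dv_mic + dv_mes + dv_mac == pytest.approx(3.0)
        assert dv_t == pytest.approx(4.0)

    def test_root_decay_creates_biopores(self):
        """Decay of 1 cm^3 of roots leaves 0.2 macro + 0.8 meso pore space.

        Oracle: the decayed root occupied pore space it once displaced;
        a coarse fraction f_rc reopens as macropores, the rest as
        mesopores — checked by moving the parcel by hand."""
        f = table3_factors(0.1, 0.1, 0.5, WormParams(tau_s=0.1),
                           RootParams(f_r_c=0.2))
        dv_mic, dv_mes, dv_mac, dv_t = pore_change_step(
            {"root_decay": -1.0}, f)
        assert (dv_mic, dv_mes, dv_mac) == pytest.approx((0.0, 0.8, 0.2))
        assert dv_t == pytest.approx(0.0, abs=1e-15)

    def test_unknown_agent_rejected(self):
        f = table3_factors(0.1, 0.1, 0.5, WormParams(tau_s=0.1),
                           RootParams())
        with pytest.raises(KeyError):
            pore_change_step({"tillage": 1.0}, f)


# ---------------------------------------------------------------------------
# Steady-flux system and closed-form steady state


def scenario_params(tau_s=0.12, R_g=0.0012, eps_casts=0.6, f_cm=0.8,
                    f_rc=0.2):
    roots = RootParams.from_production(R_g, gamma_r=SCENARIO["gamma_r"],
                                       f_r_c=f_rc)
    worms = WormParams(eps_casts=eps_casts, f_casts_mic=f_cm, tau_s=tau_s)
    return roots, worms


class TestSteadyFluxRates:
    def test_rates_sum_to_zero(self):
        roots, worms = scenario_params()
        prof = porosities(scenario_initial(), SCENARIO["gamma_s"])
        rates = steady_flux_rates(prof, roots, worms, SCENARIO["gamma_s"])
        assert sum(rates) == pytest.approx(0.0, abs=1e-15)

    def test_bare_soil_at_cast_void_ratio_is_stationary(self):
        """With B_r = 0 and eps = eps_casts the macropore rate vanishes."""
        roots, worms = scenario_params(R_g=0.0)
        # choose porosities with phi_mat/(1-phi) = eps_casts = 0.6
        phi = 0.4
        phi_mat = 0.6 * (1 - phi)
        prof = porosities(state_from_porosities(
            0.28, phi_mat - 0.28, phi - phi_mat, 0.3, 0.8, dz=1.0), 2.7)
        d_mac, _, _ = steady_flux_rates(prof, roots, worms, 2.7)
        assert d_mac == pytest.approx(0.0, abs=1e-15)

    def test_recovery_starts_from_compacted_state(self):
        """High/high scenario: macroporosity initially increases."""
        roots, worms = scenario_params()
        prof = porosities(scenario_initial(), SCENARIO["gamma_s"])
        d_mac, _, _ = steady_flux_rates(prof, roots, worms,
                                        SCENARIO["gamma_s"])
        assert d_mac > 0


class TestSteadyState:
    def test_bare_soil_matrix_void_ratio_equals_casts(self):
        """B_r = 0: the equilibrium matrix void ratio is eps_casts exactly,
        i.e. phi_mat = 0.36 and phi_mac = 0.04 at phi = 0.4."""
        roots, worms = scenario_params(R_g=0.0)
        ss = steady_state(roots, worms, phi=0.4, phi_min=0.3, f_t_mic=0.8,
                          gamma_s=2.7)
        assert ss.phi_mat == pytest.approx(0.36, abs=1e-12)
        assert ss.phi_mac == pytest.approx(0.04, abs=1e-12)
        assert ss.phi_mat / (1 - ss.phi) == pytest.approx(0.6, abs=1e-12)

    def test_high_high_scenario_macroporosity(self):
        """Equilibrium macroporosity of the high-roots/high-bioturbation
        scenario (frozen from the 500-year integration oracle below)."""
        roots, worms = scenario_params()
        ss = steady_state(roots, worms, **{k: SCENARIO[k] for k in
                                           ("phi", "phi_min", "f_t_mic",
                                            "gamma_s")})
        assert ss.phi_mac == pytest.approx(0.041667, abs=1e-5)

    def test_steady_state_is_fixed_point(self):
        roots, worms = scenario_params()
        ss = steady_state(roots, worms, phi=0.4, phi_min=0.3, f_t_mic=0.8,
                          gamma_s=2.7)
        rates = steady_flux_rates(ss, roots, worms, 2.7)
        assert np.max(np.abs(rates)) < 1e-10

    def test_infeasible_root_dominance_raises(self):
        """Huge root macropore production with almost no bioturbation
        pushes the implied matrix porosity negative."""
        roots, worms = scenario_params(R_g=0.05, tau_s=0.001)
        with pytest.raises(InfeasibleSteadyStateError):
            steady_state(roots, worms, phi=0.4, phi_min=0.3, f_t_mic=0.8,
                         gamma_s=2.7)

    def test_closed_form_matches_long_integration(self):
        """ODE state after 500 years equals the closed form to 1e-6
        across 20 random parameter draws within the scenario ranges."""
        rng = np.random.default_rng(2024)
        for _ in range(20):
            roots, worms = scenario_params(
                tau_s=rng.uniform(0.05, 0.15),
                R_g=rng.uniform(1e-4, 1.2e-3),
                # feasible band: phi_min/(1-phi) < eps_casts < phi/(1-phi)
                eps_casts=rng.uniform(0.56, 0.66),
                f_cm=rng.uniform(0.5, 0.95),
                f_rc=rng.uniform(0.1, 0.3))
            ss = steady_state(roots, worms, phi=0.4, phi_min=0.3,
                              f_t_mic=0.8, gamma_s=2.7)
            traj = integrate(scenario_initial(), roots, worms, 2.7,
                             t_end=500.0, mode="steady_flux", n_out=2,
                             max_step=np.inf)
            end = traj.profiles[-1]
            assert end.phi_mac == pytest.approx(ss.phi_mac, abs=1e-6)
            assert end.phi_mic == pytest.approx(ss.phi_mic, abs=1e-6)
            assert end.phi_mes == pytest.approx(ss.phi_mes, abs=1e-6)


# ---------------------------------------------------------------------------
# Surface-casting rates and the parcel-moving oracle


def recovery_worms(I_r_yr=1018.35, E_bio=2.1833e-4, eps_casts=0.714,
                   f_cm=0.845, phi_mac_c=0.057):
    return WormParams(eps_casts=eps_casts, f_casts_mic=f_cm, I_r=I_r_yr,
                      E_bio=E_bio, phi_mac_c=phi_mac_c)


def recovery_initial(dz=30.0):
    return state_from_porosities(0.345, 0.012, 0.005, 0.35, 0.966, dz=dz)


def parcel_tally(state, worms, gamma_s, dt, m_bio):
    """Independent bookkeeping oracle for one bioturbation step.

    Move the solids parcel ingested during dt by hand: excavating matrix
    removes (1+eps) times the parcel volume and leaves a macropore of
    that size; egested casts carry (1+eps_casts) times the parcel volume,
    of which the in-soil share refills macropores while the surface share
    adds new layer volume; cast pore space joins the meso/micro pools.
    The worm biomass ``m_bio`` [g] is conserved as the layer grows, so
    the ingested parcel is I_r * m_bio / gamma_s * dt regardless of V_t.
    """
    v_t = state.V_t
    eps = state.V_mat / state.V_s
    v = worms.I_r * m_bio / gamma_s * dt   # parcel volume [cm^3 solids]
    f_surf = surface_cast_fraction(state.V_mac / v_t, worms.phi_mac_c)
    tot = state.V_ps_mes + state.V_ps_mic
    s_mes, s_mic = state.V_ps_mes / tot, state.V_ps_mic / tot
    e_c, f_cm = worms.eps_casts, worms.f_casts_mic
    d_mac = (1 + eps) * v                      # void left by excavation
    d_mes = -s_mes * eps * v                   # matrix pores consumed
    d_mic = -s_mic * eps * v
    d_mac -= (1 - f_surf) * (1 + e_c) * v      # in-soil casts fill voids
    d_mes += (1 - f_cm) * e_c * v              # cast pore space created
    d_mic += f_cm * e_c * v
    d_t = f_surf * (1 + e_c) * v               # surface casts add volume
    return d_mac, d_mes, d_mic, d_t


class TestBioturbationRates:
    def test_internal_casting_conserves_volume(self):
        """f_surf = 0 (open macropores): total volume is constant."""
        worms = recovery_worms(phi_mac_c=None)
        *_, dv_t = bioturbation_volume_rates(recovery_initial(), worms, 2.56)
        assert dv_t == pytest.approx(0.0, abs=1e-15)

    def test_full_surface_casting_bookkeeping(self):
        """f_surf = 1 (no macropores): the pore-volume gain equals the
        total-volume gain, Q(1+eps_casts) — the oracle's tally."""
        state = state_from_porosities(0.345, 0.012, 0.0, 0.35, 0.966,
                                      dz=30.0)
        worms = recovery_worms()
        dv_mac, dv_mes, dv_mic, dv_t = bioturbation_volume_rates(
            state, worms, 2.56)
        q = state.V_t * worms.I_r * worms.E_bio / 2.56
        assert dv_t == pytest.approx(q * (1 + worms.eps_casts))
        assert dv_mac + dv_mes + dv_mic == pytest.approx(dv_t, rel=1e-12)

    def test_exchange_equilibrium(self):
        """eps = eps_casts, f_surf = 0, cast split matching the matrix
        split: ingestion and egestion cancel exactly."""
        state = state_from_porosities(0.30, 0.06, 0.04, 0.2, 0.8, dz=10.0)
        eps = state.V_mat / state.V_s
        s_mic = state.V_ps_mic / (state.V_ps_mic + state.V_ps_mes)
        worms = recovery_worms(eps_casts=eps, f_cm=s_mic, phi_mac_c=None)
        rates = bioturbation_volume_rates(state, worms, 2.56)
        assert np.max(np.abs(rates)) < 1e-12

    def test_rates_match_parcel_oracle_per_step(self):
        state = recovery_initial()
        worms = recovery_worms()
        dt = 1e-4
        m_bio = worms.E_bio * state.V_t
        rates = bioturbation_volume_rates(state, worms, 2.56)
        tally = parcel_tally(state, worms, 2.56, dt, m_bio)
        np.testing.assert_allclose(np.asarray(rates) * dt,
                                   np.asarray(tally), rtol=1e-12)

    def test_parcel_euler_matches_ode(self):
        """Euler stepping of the parcel oracle reproduces the adaptive ODE
        solution to < 1e-3 relative at dt = 1e-4 yr."""
        worms = recovery_worms()
        state = recovery_initial()
        m_bio = worms.E_bio * state.V_t
        dt, t_end = 1e-4, 0.5
        n = int(round(t_end / dt))
        for _ in range(n):
            d_mac, d_mes, d_mic, _ = parcel_tally(state, worms, 2.56, dt,
                                                  m_bio)
            state = state.copy(V_mac=state.V_mac + d_mac,
                               V_ps_mes=state.V_ps_mes + d_mes,
                               V_ps_mic=state.V_ps_mic + d_mic)
        traj = integrate(recovery_initial(), None, worms, 2.56,
                         t_end=t_end, mode="recovery", n_out=2)
        ode = traj.states[-1]
        for attr in ("V_mac", "V_ps_mes", "V_ps_mic"):
            assert getattr(state, attr) == pytest.approx(
                getattr(ode, attr), rel=1e-3)


# ---------------------------------------------------------------------------
# Integration and equilibration


class TestIntegrate:
    def test_no_biology_is_constant(self):
        roots = RootParams()
        worms = WormParams(tau_s=0.0)
        traj = integrate(scenario_initial(), roots, worms, 2.7, t_end=10.0,
                         mode="steady_flux", n_out=11)
        for p in traj.profiles:
            assert p.phi_mac == pytest.approx(0.0, abs=1e-12)
            assert p.phi_mic == pytest.approx(0.32, abs=1e-12)

    def test_total_porosity_conserved_along_trajectory(self):
        roots, worms = scenario_params()
        traj = integrate(scenario_initial(), roots, worms, 2.7, t_end=100.0,
                         mode="steady_flux")
        phis = np.array([p.phi for p in traj.profiles])
        assert np.max(np.abs(phis - 0.4)) < 1e-9

    @pytest.mark.parametrize("R_g", [0.0012, 0.00012])
    def test_high_bioturbation_equilibrates_within_30_years(self, R_g):
        """tau_s = 0.12 scenarios reach 95% of equilibrium macroporosity
        in under 30 years."""
        roots, worms = scenario_params(R_g=R_g)
        ss = steady_state(roots, worms, phi=0.4, phi_min=0.3, f_t_mic=0.8,
                          gamma_s=2.7)
        traj = integrate(scenario_initial(), roots, worms, 2.7, t_end=100.0,
                         mode="steady_flux", n_out=401)
        t_eq = time_to_equilibrium(traj, ss, rel_tol=0.05)
        assert t_eq <= 30.0

    def test_step_halving_converged(self):
        """Halving the step cap changes year-100 porosities by < 1e-6."""
        roots, worms = scenario_params()
        end = []
        for ms in (0.05, 0.025):
            traj = integrate(scenario_initial(), roots, worms, 2.7,
                             t_end=100.0, mode="steady_flux", n_out=2,
                             max_step=ms)
            p = traj.profiles[-1]
            end.append((p.phi_mac, p.phi_mes, p.phi_mic))
        np.testing.assert_allclose(end[0], end[1], atol=1e-6)

    def test_recovery_grows_layer_monotonically(self):
        """With f_surf > 0 throughout, thickness strictly increases and
        solids are untouched."""
        worms = recovery_worms()
        traj = integrate(recovery_initial(), None, worms, 2.56, t_end=2.0,
                         mode="recovery", n_out=41)
        thickness = np.array([p.layer_thickness for p in traj.profiles])
        assert np.all(traj.f_surf > 0)
        assert np.all(np.diff(thickness) > 0)
        solids = np.array([s.V_s for s in traj.states])
        assert np.max(np.abs(solids - solids[0])) < 1e-12

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            integrate(scenario_initial(), None, WormParams(tau_s=0.1), 2.7,
                      1.0, mode="warp")


class TestTimeToEquilibrium:
    def test_starting_at_target_is_zero(self):
        roots, worms = scenario_params(R_g=0.0)
        ss = steady_state(roots, worms, phi=0.4, phi_min=0.3, f_t_mic=0.8,
                          gamma_s=2.7)
        init = state_from_porosities(ss.phi_mic, ss.phi_mes, ss.phi_mac,
                                     0.3, 0.8, dz=1.0)
        traj = integrate(init, roots, worms, 2.7, t_end=5.0,
                         mode="steady_flux", n_out=6)
        assert time_to_equilibrium(traj, ss) == 0.0

    def test_never_reached_marker(self):
        roots, worms = scenario_params(tau_s=0.012)
        ss = steady_state(roots, worms, phi=0.4, phi_min=0.3, f_t_mic=0.8,
                          gamma_s=2.7)
        traj = integrate(scenario_initial(), roots, worms, 2.7, t_end=2.0,
                         mode="steady_flux", n_out=5)
        assert time_to_equilibrium(traj, ss) is NOT_REACHED
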