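import numpy as np
import pytest

from synergize.energy_model import RegressionLine, SpringParams
from synergize.pattern_dynamics import (
    CFLError,
    DynamicsParams,
    close_contact_patch_stats,
    dispersion_relation,
    instability_condition,
    kd_2d_from_enrichment,
    patternation_test,
    simulate_pde,
    sqre_margin,
    stability_curve,
    uniform_steady_states,
)
from synergize.synthetic_data import default_springs

SP = default_springs()
P_DEFAULT = DynamicsParams(springs=SP)
# a regime with three uniform states whose middle state patternates
P_THREE = DynamicsParams(springs=SP, kon=1e-4, koff0=0.1, I_tot=100.0, L_tot=1000.0)
# spatially unstable middle state, homogeneously stable
P_UNSTABLE = DynamicsParams(springs=SP, kon=1e-3, koff0=0.1, I_tot=100.0, L_tot=50.0)


def _uniform_init(state, shape, pert=0.0, seed=0):
    rng = np.random.default_rng(seed)
    init = {n: np.full(shape, getattr(state, n)) for n in "RLCI"}
    init["z"] = np.full(shape, state.z_star)
    if pert:
        init["z"] = init["z"] + pert * rng.standard_normal(shape)
    return init


class TestUniformSteadyStates:
    def test_no_long_ligand_pins_bond_length(self):
        states = uniform_steady_states(P_DEFAULT.with_(I_tot=0.0))
        assert len(states) == 1
        assert states[0].z_star == pytest.approx(SP.z_C, abs=1e-6)
        assert states[0].C > 0

    def test_no_receptor_ligand_pins_icam_length(self):
        states = uniform_steady_states(P_DEFAULT.with_(R_tot=0.0, L_tot=0.0))
        assert len(states) == 1
        assert states[0].z_star == pytest.approx(SP.z_I, abs=1e-6)

    def test_three_state_regime(self):
        states = uniform_steady_states(P_THREE)
        assert len(states) == 3
        lo, mid, hi = states
        assert lo.stable_homog and hi.stable_homog
        assert not mid.stable_homog           # positive homogeneous eigenvalue
        assert not mid.stable_spatial
        assert SP.z_C < mid.z_star < SP.z_I

    def test_state_count_one_or_three(self, rng):
        for _ in range(20):
            p = P_DEFAULT.with_(
                kon=10 ** rng.uniform(-4, -1), koff0=10 ** rng.uniform(-1, 1),
                R_tot=10 ** rng.uniform(1, 3), L_tot=10 ** rng.uniform(1, 3),
                I_tot=10 ** rng.uniform(1, 3))
            assert len(uniform_steady_states(p)) in (1, 3)

    def test_mass_action_and_force_balance_hold(self):
        for st in uniform_steady_states(P_THREE):
            koff = P_THREE.koff0 * np.exp(SP.lambda_C * (st.z_star - SP.z_C) ** 2)
            assert P_THREE.kon * st.R * st.L == pytest.approx(koff * st.C, rel=1e-6)
            f = (SP.lambda_C * st.C * (st.z_star - SP.z_C)
                 + SP.lambda_I * st.I * (st.z_star - SP.z_I))
            assert abs(f) < 1e-6 * SP.lambda_C * max(st.C, 1.0)


class TestStability:
    def test_sign_agreement_with_eigenvalue_oracle(self, rng):
        """Analytic margin sign vs numerical 5-variable linearisation."""
        kgrid = np.geomspace(0.05, 50, 30)
        agree = total = 0
        for _ in range(60):
            lam_C = 10 ** rng.uniform(-1.5, 0)
            p = DynamicsParams(
                springs=SpringParams(lam_C, lam_C * 10 ** rng.uniform(-1, 1), 13, 18),
                D_R=10 ** rng.uniform(-2, 0), D_L=10 ** rng.uniform(-2, 0),
                D_C=10 ** rng.uniform(-2, 0), D_I=10 ** rng.uniform(-2, 0),
                kon=10 ** rng.uniform(-3, 0), koff0=10 ** rng.uniform(-1, 1),
                R_tot=10 ** rng.uniform(1, 3), L_tot=10 ** rng.uniform(1, 3),
                I_tot=10 ** rng.uniform(1, 3), area_ratio=rng.uniform(0.05, 1),
                M=10 ** rng.uniform(4, 6))
            for st in uniform_steady_states(p):
                m = instability_condition(st, p, k=0.0)
                if abs(m) < 1e-6:
                    continue
                growth = max(dispersion_relation(st, p, k) for k in kgrid)
                total += 1
                agree += (m > 0) == (growth > 1e-12)
        assert total > 40
        assert agree / total >= 0.99

    def test_vanishing_springs_are_stable(self):
        sp = SpringParams(1e-9, 1e-9, 13, 18)
        p = P_DEFAULT.with_(springs=sp)
        st = uniform_steady_states(p)[0]
        assert instability_condition(st, p, k=0.0) <= 0
        for k in [0.1, 1.0, 10.0]:
            assert dispersion_relation(st, p, k) <= 1e-9

    def test_margin_nonincreasing_in_wavenumber(self):
        st = uniform_steady_states(P_UNSTABLE)[1]
        ks = np.linspace(0, 40, 60)
        margins = [instability_condition(st, P_UNSTABLE, k) for k in ks]
        assert np.all(np.diff(margins) <= 1e-12)

    def test_growth_negative_at_large_wavenumber(self):
        st = uniform_steady_states(P_UNSTABLE)[1]
        assert dispersion_relation(st, P_UNSTABLE, 500.0) < 0

    def test_non_steady_input_rejected(self):
        st = uniform_steady_states(P_DEFAULT)[0]
        import dataclasses

        fake = dataclasses.replace(st, z_star=st.z_star + 1.0)
        with pytest.raises(ValueError):
            dispersion_relation(fake, P_DEFAULT, 1.0)

    def test_growth_rate_matches_simulation(self):
        """Seeded cosine mode grows at the predicted linear rate (5%)."""
        st = uniform_steady_states(P_UNSTABLE)[1]
        nx, dx, m = 64, 0.06, 6
        k = np.pi * m / (nx * dx)
        g_pred = dispersion_relation(st, P_UNSTABLE, k)
        assert g_pred > 0
        x = (np.arange(nx) + 0.5) * dx
        init = _uniform_init(st, (1, nx))
        init["z"] = st.z_star + 1e-4 * np.cos(np.pi * m * x / (nx * dx))[None, :]
        traj = simulate_pde(P_UNSTABLE, init, dx=dx, t_end=1.0 / g_pred, n_save=9)
        from scipy.fft import dctn

        amps = np.array([dctn(z, type=2, norm="ortho")[0, m] for z in traj.z])
        sl = slice(len(traj.times) // 2, None)
        g_fit = np.polyfit(traj.times[sl], np.log(np.abs(amps[sl])), 1)[0]
        assert g_fit == pytest.approx(g_pred, rel=0.05)


class TestStabilityCurveAndPatternation:
    def test_curve_points_have_zero_margin(self):
        line = RegressionLine(alpha=1.6, beta=0.7)
        curve = stability_curve(line)
        np.testing.assert_allclose(sqre_margin(curve.e_C, curve.e_I, 0.7), 0,
                                   atol=1e-9)

    def test_curve_depends_only_on_spring_ratio(self):
        c1 = stability_curve(RegressionLine(alpha=1.0, beta=0.7))
        c2 = stability_curve(RegressionLine(alpha=2.5, beta=0.7))
        np.testing.assert_allclose(c1.e_I, c2.e_I, rtol=1e-12)

    def test_degenerate_beta_pushes_curve_out(self):
        c = stability_curve(RegressionLine(alpha=1.0, beta=1e-4), e_C_max=0.7)
        assert np.all(c.e_I > 50)   # no unstable states in the physical box

    def test_unstable_region_is_above_curve(self):
        line = RegressionLine(alpha=1.6, beta=0.7)
        curve = stability_curve(line)
        i = len(curve.e_C) // 2
        assert not curve.is_stable(curve.e_C[i], curve.e_I[i] + 0.5)
        assert curve.is_stable(curve.e_C[i], max(curve.e_I[i] - 0.5, 1e-3))

    def test_small_line_entirely_stable(self):
        res = patternation_test(RegressionLine(alpha=0.3, beta=0.7))
        assert not res.intersects
        assert res.crossings == ()

    def test_default_truth_line_intersects(self):
        res = patternation_test(RegressionLine(alpha=1.6, beta=0.7))
        assert res.intersects
        a, b = res.unstable_segments[0]
        # pure-species endpoints lie outside the unstable segment
        assert a > 0 and b < 1.6 / 0.7
        assert sqre_margin(0.0, 1.6, 0.7) < 0
        assert sqre_margin(1.6 / 0.7, 0.0, 0.7) < 0


class TestSimulatePde:
    def test_stable_uniform_state_is_stationary(self):
        st = uniform_steady_states(P_DEFAULT)[0]
        traj = simulate_pde(P_DEFAULT, _uniform_init(st, (16, 16)), dx=0.1,
                            t_end=0.5, n_save=3)
        assert np.abs(traj.z[-1] - traj.z[0]).max() < 1e-8
        assert np.abs(traj.C[-1] - traj.C[0]).max() < 1e-8

    def test_mass_conservation(self):
        st = uniform_steady_states(P_UNSTABLE)[1]
        init = _uniform_init(st, (24, 24), pert=0.05, seed=1)
        traj = simulate_pde(P_UNSTABLE, init, dx=0.06, t_end=1.0, n_save=4)
        t0 = traj.totals(0)
        t1 = traj.totals(-1)
        for a, b in zip(t0, t1):
            assert abs(a - b) <= 1e-6 * abs(a)

    def test_cfl_violation_refused_with_suggestion(self):
        st = uniform_steady_states(P_DEFAULT)[0]
        with pytest.raises(CFLError, match="use dt"):
            simulate_pde(P_DEFAULT, _uniform_init(st, (8, 8)), dx=0.05,
                         t_end=0.1, dt=10.0)

    def test_deterministic_given_seed_with_noise(self):
        st = uniform_steady_states(P_DEFAULT)[0]
        kw = dict(dx=0.1, t_end=0.2, n_save=3, seed=7, noise_amp=0.05)
        t1 = simulate_pde(P_DEFAULT, _uniform_init(st, (12, 12)), **kw)
        t2 = simulate_pde(P_DEFAULT, _uniform_init(st, (12, 12)), **kw)
        np.testing.assert_array_equal(t1.z[-1], t2.z[-1])


class TestPatchStats:
    def test_generous_threshold_covers_surface(self):
        st = close_contact_patch_stats(threshold=40.0, domain_size=1.0, n_rep=2,
                                       seed=0)
        assert st["area_fraction"] > 0.999

    def test_gaussian_tail_closed_form(self):
        st = close_contact_patch_stats(mean_sep=18, sd_sep=3, threshold=12,
                                       corr_len=30, domain_size=4.0, n_rep=6, seed=2)
        se = max(st["area_fraction_se"], 1e-5)
        assert abs(st["area_fraction"] - st["expected_area_fraction"]) < 3 * se

    def test_density_times_area_identity(self):
        st = close_contact_patch_stats(domain_size=4.0, n_rep=4, seed=3)
        prod = st["patch_density_um2"] * st["mean_patch_area_um2"]
        assert prod == pytest.approx(st["area_fraction"], rel=0.10)

    def test_grid_resolution_guard(self):
        with pytest.raises(ValueError):
            close_contact_patch_stats(corr_len=2.0, dx_nm=5.0)


class TestKd2d:
    def test_proportionality_and_trivial_case(self):
        assert kd_2d_from_enrichment(10.0, 50.0, 190.0)["K_d"] == pytest.approx(
            2 * kd_2d_from_enrichment(20.0, 50.0, 190.0)["K_d"])
        r = kd_2d_from_enrichment(B_opt=77.0, L_fs=77.0, R_density=190.0)
        assert r["K_d"] == pytest.approx(190.0)
        assert r["order_of_magnitude_only"]

    def test_matches_mass_action_ode_equilibrium(self):
        """Relax the binding ODE to equilibrium; K_d from the free densities."""
        from scipy.integrate import solve_ivp

        kon, koff = 0.02, 1.5
        R0, L0 = 190.0, 300.0
        sol = solve_ivp(lambda t, c: [kon * (R0 - c[0]) * (L0 - c[0]) - koff * c[0]],
                        (0, 500), [0.0], rtol=1e-10, atol=1e-12)
        C_eq = sol.y[0, -1]
        est = kd_2d_from_enrichment(C_eq, L0 - C_eq, R0 - C_eq)["K_d"]
        assert est == pytest.approx(koff / kon, rel=0.01)

    def test_zero_enrichment_is_error(self):
        with pytest.raises(ValueError):
            kd_2d_from_enrichment(0.0, 50.0, 190.0)
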