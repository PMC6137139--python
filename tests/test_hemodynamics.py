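"""Solver validation: rheology, Poiseuille benchmarks, pulsatile flow."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

from maflow.hemodynamics import (
    InletCondition,
    RheologyParams,
    SimulationError,
    carreau_yasuda_viscosity,
    run_pulsatile,
    run_steady,
    shear_rate_field,
    wall_shear_stress,
)
from maflow.synthetic_data import generate_waveform
from tests.conftest import BLOOD_ETA, CYL_LENGTH, CYL_RADIUS


class TestCarreauYasuda:
    def test_zero_shear_limit_is_eta0(self):
        p = RheologyParams()
        assert carreau_yasuda_viscosity(0.0, p) == pytest.approx(p.eta_0)

    def test_infinite_shear_limit_is_eta_inf(self):
        p = RheologyParams()
        assert carreau_yasuda_viscosity(1e6, p) == pytest.approx(p.eta_inf, rel=0.01)

    def test_matches_direct_formula_at_unit_shear(self):
        p = RheologyParams()
        expected = p.eta_inf + (p.eta_0 - p.eta_inf) * (
            1.0 + (p.lam * 1.0) ** p.a
        ) ** ((p.n - 1.0) / p.a)
        assert carreau_yasuda_viscosity(1.0, p) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.026, abs=0.002)  # blood at 1/s

    def test_monotonically_shear_thinning(self):
        p = RheologyParams()
        g = np.logspace(-2, 4, 50)
        eta = carreau_yasuda_viscosity(g, p)
        assert (np.diff(eta) < 0).all()

    def test_newtonian_limit_is_flat(self):
        p = RheologyParams.newtonian(0.004)
        assert carreau_yasuda_viscosity(123.0, p) == pytest.approx(0.004)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            RheologyParams(eta_inf=0.2, eta_0=0.1)
        with pytest.raises(ValueError):
            carreau_yasuda_viscosity(-1.0, RheologyParams())


def mid_section(dom, flow):
    i_mid = flow.shape[0] // 2
    sel = flow.idx[:, 0] == i_mid
    pos = dom.origin[None, :] + flow.idx[sel] * dom.spacing
    r = np.hypot(pos[:, 1], pos[:, 2])
    return sel, r


class TestPoiseuille:
    def test_velocity_profile_l2_error_below_2pc(self, cylinder_flow):
        dom, flow = cylinder_flow
        sel, r = mid_section(dom, flow)
        u = flow.velocity[sel, 0]
        u_peak = 2 * 1.69
        ana = u_peak * np.clip(1 - (r / CYL_RADIUS) ** 2, 0, None)
        l2 = np.sqrt(np.sum((u - ana) ** 2) / np.sum(ana**2))
        assert l2 < 0.02

    def test_wss_matches_4_eta_umean_over_R(self, cylinder_flow):
        dom, flow = cylinder_flow
        wall = wall_shear_stress(flow, dom)
        x = dom.origin[0] + wall.idx[:, 0] * dom.spacing
        mid = (x > CYL_LENGTH / 4) & (x < 3 * CYL_LENGTH / 4)
        measured = np.average(wall.wss[mid], weights=wall.area[mid])
        expected = 4 * BLOOD_ETA * 1.69e-3 / (CYL_RADIUS * 1e-6)
        assert measured == pytest.approx(expected, rel=0.05)

    def test_wss_circumferentially_uniform(self, cylinder_fine_flow):
        dom, flow = cylinder_fine_flow
        wall = wall_shear_stress(flow, dom)
        x = dom.origin[0] + wall.idx[:, 0] * dom.spacing
        mid = (x > CYL_LENGTH / 4) & (x < 3 * CYL_LENGTH / 4)
        y = dom.origin[1] + wall.idx[mid, 1] * dom.spacing
        z = dom.origin[2] + wall.idx[mid, 2] * dom.spacing
        theta = np.arctan2(y - 0.0, z - 0.0)
        sector = np.digitize(theta, np.linspace(-np.pi, np.pi, 17))
        means = [
            np.average(wall.wss[mid][sector == s], weights=wall.area[mid][sector == s])
            for s in range(1, 17)
        ]
        assert np.std(means) / np.mean(means) < 0.05

    def test_mass_conserved_across_sections(self, cylinder_flow):
        dom, flow = cylinder_flow
        nx = flow.shape[0]
        fluxes = []
        for i in range(3, nx - 3, 4):
            sel = flow.idx[:, 0] == i
            fluxes.append(flow.velocity[sel, 0].sum() * dom.spacing**2)
        fluxes = np.asarray(fluxes)
        assert np.abs(fluxes / fluxes.mean() - 1).max() < 0.005

    def test_grid_convergence_of_wall_stress(self, cylinder_flow, cylinder_fine_flow):
        def body_wss(pair):
            dom, flow = pair
            wall = wall_shear_stress(flow, dom)
            x = dom.origin[0] + wall.idx[:, 0] * dom.spacing
            mid = (x > CYL_LENGTH / 4) & (x < 3 * CYL_LENGTH / 4)
            return np.average(wall.wss[mid], weights=wall.area[mid])

        coarse, fine = body_wss(cylinder_flow), body_wss(cylinder_fine_flow)
        assert abs(fine - coarse) / fine < 0.05

    def test_stokes_linearity_under_inlet_rescaling(self, small_tube_domain):
        rheo = RheologyParams.newtonian(BLOOD_ETA)
        f1 = run_steady(small_tube_domain, InletCondition(2.0), rheo, tol=1e-7)
        f2 = run_steady(small_tube_domain, InletCondition(4.0), rheo, tol=1e-7)
        u1 = np.linalg.norm(f1.velocity, axis=1)
        u2 = np.linalg.norm(f2.velocity, axis=1) / 2.0
        scale = np.abs(u1).max()
        assert np.abs(u2 - u1).max() / scale < 0.02

    def test_mach_guard_raises_for_absurd_velocity(self, small_tube_domain):
        with pytest.raises(SimulationError, match="Mach"):
            run_steady(small_tube_domain, InletCondition(1e6),
                       RheologyParams.newtonian(BLOOD_ETA))


def generalized_poiseuille_ratio(rheology, radius_m, q_target):
    """Centerline-to-mean velocity ratio of a shear-thinning pipe flow.

    1-D quadrature oracle: for a pressure gradient G the local shear rate
    solves η(γ̇) γ̇ = G r / 2; the axial velocity is its inward integral.
    G is matched to the prescribed volumetric flow by bisection.
    """
    r = np.linspace(0, radius_m, 400)

    def profile(G):
        gdot = np.array([
            0.0 if ri == 0 else brentq(
                lambda g: carreau_yasuda_viscosity(g, rheology) * g - G * ri / 2,
                0, 1e7)
            for ri in r
        ])
        u = cumulative_trapezoid(gdot[::-1], r, initial=0)[::-1]
        q = np.trapezoid(u * 2 * np.pi * r, r)
        return u, q

    g_lo, g_hi = 1.0, 1e9
    G = brentq(lambda g: profile(g)[1] - q_target, g_lo, g_hi, rtol=1e-6)
    u, q = profile(G)
    u_mean = q / (np.pi * radius_m**2)
    return u[0] / u_mean


class TestShearThinning:
    def test_profile_blunter_than_newtonian(self, cylinder_cy_flow):
        dom, flow = cylinder_cy_flow
        sel, r = mid_section(dom, flow)
        u = flow.velocity[sel, 0]
        q = u.sum() * dom.spacing**2  # mm/s μm²
        u_mean = q / (np.pi * CYL_RADIUS**2)
        ratio = u.max() / u_mean
        assert ratio < 2.0

    def test_matches_quadrature_oracle(self, cylinder_cy_flow):
        dom, flow = cylinder_cy_flow
        sel, r = mid_section(dom, flow)
        u = flow.velocity[sel, 0]
        q_si = u.sum() * dom.spacing**2 * 1e-15  # mm/s μm² → m³/s
        expected = generalized_poiseuille_ratio(
            RheologyParams(), CYL_RADIUS * 1e-6, q_si
        )
        u_mean = u.sum() * dom.spacing**2 / (np.pi * CYL_RADIUS**2)
        assert u.max() / u_mean == pytest.approx(expected, rel=0.10)


class TestShearRate:
    def test_poiseuille_profile(self, cylinder_flow):
        dom, flow = cylinder_flow
        sel, r = mid_section(dom, flow)
        g = flow.shear_rate[sel]
        u_mean = 1.69e-3
        expected = 4 * u_mean * (r * 1e-6) / (CYL_RADIUS * 1e-6) ** 2
        bulk = (r > 2.0) & (r < 6.5)
        rel = np.abs(g[bulk] - expected[bulk]) / expected[bulk]
        assert np.median(rel) < 0.05

    def test_uniform_translation_has_zero_fd_shear(self, cylinder_flow):
        import dataclasses

        dom, flow = cylinder_flow
        uniform = dataclasses.replace(
            flow,
            velocity=np.tile([1.0, 0.0, 0.0], (len(flow.idx), 1)),
        )
        g = shear_rate_field(uniform, method="fd")
        interior = np.zeros(flow.shape, dtype=bool)
        interior[tuple(flow.idx.T)] = True
        # away from domain faces the gradient of a uniform field vanishes
        sel, r = mid_section(dom, flow)
        assert np.abs(g[sel][r < 6]).max() < 1e-9

    def test_noneq_and_fd_estimates_agree_in_bulk(self, cylinder_flow):
        dom, flow = cylinder_flow
        g_ne = shear_rate_field(flow, method="noneq")
        g_fd = shear_rate_field(flow, method="fd")
        sel, r = mid_section(dom, flow)
        bulk = sel & (np.hypot(
            dom.origin[1] + flow.idx[:, 1] * dom.spacing,
            dom.origin[2] + flow.idx[:, 2] * dom.spacing,
        ) < 0.6 * CYL_RADIUS) & (g_fd > 1)
        rel = np.abs(g_ne[bulk] - g_fd[bulk]) / g_fd[bulk]
        assert np.median(rel) < 0.10

    def test_unknown_method_rejected(self, cylinder_flow):
        with pytest.raises(ValueError):
            shear_rate_field(cylinder_flow[1], method="magic")


class TestPulsatile:
    def test_constant_waveform_reproduces_steady_state(self, small_tube_domain):
        rheo = RheologyParams.newtonian(BLOOD_ETA)
        wf = generate_waveform(pulsatility=0.0, n_points=32)
        inlet = InletCondition(2 * 1.69, mode="pulsatile", waveform=wf)
        series = run_pulsatile(small_tube_domain, inlet, rheo,
                               steps_per_cycle=3000, n_cycles=2, n_snapshots=4)
        steady = run_steady(small_tube_domain, InletCondition(2 * 1.69), rheo, tol=1e-7)
        for snap in series:
            diff = np.abs(snap.velocity - steady.velocity).max()
            assert diff / np.abs(steady.velocity).max() < 0.02

    def test_quasi_steady_snapshots_match_instantaneous_steady(self, pulsatile_tube):
        dom, inlet, series = pulsatile_tube
        rheo = RheologyParams.newtonian(BLOOD_ETA)
        wf = inlet.waveform
        for snap in (series[1], series[5]):
            scale = float(np.interp(snap.time, wf.time, wf.scale, period=wf.period))
            ref = run_steady(
                dom, InletCondition(inlet.peak_centerline_velocity * scale),
                rheo, tol=1e-7,
            )
            err = np.abs(snap.velocity - ref.velocity).max()
            assert err / np.abs(ref.velocity).max() < 0.05

    def test_systolic_snapshot_has_peak_velocity(self, pulsatile_tube):
        dom, inlet, series = pulsatile_tube
        peaks = np.array([np.abs(s.velocity).max() for s in series])
        wf = inlet.waveform
        scales = np.array(
            [np.interp(s.time, wf.time, wf.scale, period=wf.period) for s in series]
        )
        assert np.argmax(peaks) == np.argmax(scales)

    def test_requires_pulsatile_inlet_and_two_cycles(self, small_tube_domain):
        with pytest.raises(ValueError):
            run_pulsatile(small_tube_domain, InletCondition(1.0), RheologyParams())
        wf = generate_waveform()
        inlet = InletCondition(1.0, mode="pulsatile", waveform=wf)
        with pytest.raises(ValueError, match="cycle"):
            run_pulsatile(small_tube_domain, inlet, RheologyParams(), n_cycles=1)
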