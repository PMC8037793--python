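import numpy as np
import pytest

from porocoil.domain import DomainSpec, FLUID, POROUS, build_domain
from porocoil.metrics import wall_shear_stress
from porocoil.rheology import ergun_coefficients
from porocoil.solver import (
    InflowWaveform,
    ProjectionSolver,
    default_waveform,
    steady_waveform,
)

D = 3.0e-3
MU = 0.00345  # high-shear plateau, used as the constant test viscosity


def constant_mu_solver(domain, blood, cpd=0.0):
    solver = ProjectionSolver(domain, blood, ergun_coefficients(cpd, blood))
    f = solver.initial_field()
    f.mu[:] = MU
    return solver, f


class TestSteady:
    def test_poiseuille_profile_and_wss(self, poiseuille_field, channel_domain, blood):
        solver, f = poiseuille_field
        U, H = 0.2, D
        y = (np.arange(channel_domain.ny) + 0.5) * channel_domain.h
        analytic = 6 * U * (y / H) * (1 - y / H)
        i = channel_domain.nx // 2
        assert np.max(np.abs(f.u[i, :] - analytic)) / analytic.max() < 0.02
        _, tau = wall_shear_stress(f, channel_domain.wall_faces_artery, channel_domain, blood)
        tau_exact = 6 * MU * U / H
        assert np.max(np.abs(tau - tau_exact)) / tau_exact < 0.02

    def test_wss_error_halves_under_refinement(self, blood):
        errors = []
        for n in (16, 32):
            dom = build_domain(
                DomainSpec(D, 4 * D, 0.0, 0.0, D / n)
            )
            solver, f = constant_mu_solver(dom, blood)
            f = solver.solve_steady(0.2, tol=1e-6, max_iter=20000, init=f, freeze_viscosity=True)
            _, tau = wall_shear_stress(f, dom.wall_faces_artery, dom, blood)
            errors.append(abs(tau.mean() - 6 * MU * 0.2 / D))
        assert errors[1] < 0.7 * errors[0]

    def test_porous_plug_pressure_drop(self, blood):
        dom = build_domain(
            DomainSpec(D, 8 * D, 0.0, 0.0, D / 16, porous_channel=True)
        )
        por = ergun_coefficients(30.0, blood)
        solver, f = constant_mu_solver(dom, blood, cpd=30.0)
        U = 0.01
        f = solver.solve_steady(U, tol=1e-6, max_iter=8000, init=f, freeze_viscosity=True)
        jmid = dom.ny // 2
        i0, i1 = dom.nx // 4, 3 * dom.nx // 4
        dpdx = (f.p[i0, jmid] - f.p[i1, jmid]) / ((i1 - i0) * dom.h)
        predicted = (por.beta + por.alpha * U) * U
        assert dpdx == pytest.approx(predicted, rel=0.05)

    def test_zero_inflow_zero_field(self, channel_domain, blood):
        solver, f = constant_mu_solver(channel_domain, blood)
        g = solver.solve_steady(0.0, init=f)
        assert np.all(g.u == 0.0) and np.all(g.v == 0.0)
        assert np.ptp(g.p) == 0.0

    def test_mass_conservation_and_divergence(self, poiseuille_field, channel_domain):
        solver, f = poiseuille_field
        assert solver.mass_imbalance(f) < 1e-3
        div = solver.divergence(f)
        u_scale = np.abs(f.u).max() / channel_domain.h
        assert np.abs(div).max() / u_scale < 1e-3

    def test_no_slip_on_solid_faces(self, dome_domain, blood):
        solver, f = constant_mu_solver(dome_domain, blood)
        f = solver.solve_steady(0.2, tol=1e-5, max_iter=4000, init=f, freeze_viscosity=True)
        solid = ~dome_domain.active_mask
        # normal velocities on faces bordering solid cells vanish exactly
        u_into_solid = f.u[1:-1, :][solid[:-1, :] | solid[1:, :]]
        v_into_solid = f.v[:, 1:-1][solid[:, :-1] | solid[:, 1:]]
        assert np.all(u_into_solid == 0.0)
        assert np.all(v_into_solid == 0.0)

    def test_zero_cpd_dome_identical_to_fluid_cells(self, blood):
        spec = DomainSpec(D, 5 * D, 2.0e-3, 2.5e-3, D / 16)
        dom_porous = build_domain(spec)
        dom_fluid = build_domain(spec)
        dom_fluid.role[dom_fluid.role == POROUS] = FLUID

        fields = []
        for dom in (dom_porous, dom_fluid):
            solver, f = constant_mu_solver(dom, blood)
            f = solver.solve_steady(0.2, tol=1e-5, max_iter=4000, init=f, freeze_viscosity=True)
            fields.append(f)
        assert np.array_equal(fields[0].u, fields[1].u)
        assert np.array_equal(fields[0].v, fields[1].v)
        assert np.array_equal(fields[0].p, fields[1].p)


class TestWaveform:
    def test_default_waveform_mean_and_peak(self):
        wf = default_waveform(0.3, peak_to_mean=2.0)
        assert wf.mean_velocity == pytest.approx(0.3, rel=0.01)
        assert wf.peak_velocity == pytest.approx(0.6, rel=0.01)
        assert min(v for _, v in wf.samples) >= 0.0

    def test_aperiodic_waveform_rejected(self):
        with pytest.raises(ValueError, match="periodic"):
            InflowWaveform(period=1.0, samples=((0.0, 0.1), (1.0, 0.2)))

    def test_negative_velocity_rejected(self):
        with pytest.raises(ValueError):
            InflowWaveform(period=1.0, samples=((0.0, -0.1), (1.0, -0.1)))


class TestTransient:
    def test_cfl_violation_rejected_with_suggestion(self, short_dome_domain, blood):
        solver = ProjectionSolver(short_dome_domain, blood, ergun_coefficients(0.0, blood))
        wf = default_waveform(0.3, period=0.2, n_cycles=1)
        with pytest.raises(ValueError, match="dt <="):
            solver.solve_transient(wf, dt=1.0)

    def test_zero_amplitude_waveform_zero_field(self, short_dome_domain, blood):
        solver = ProjectionSolver(short_dome_domain, blood, ergun_coefficients(0.0, blood))
        wf = steady_waveform(0.0, period=0.1, n_cycles=1)
        res = solver.solve_transient(wf)
        assert np.all(res.fields[-1].u == 0.0)

    def test_steady_waveform_matches_steady_solver(self, short_dome_domain, blood):
        wf = steady_waveform(0.25, period=0.05, n_cycles=2)
        s1 = ProjectionSolver(short_dome_domain, blood, ergun_coefficients(0.0, blood))
        res = s1.solve_transient(wf, samples_per_cycle=8)
        f_t = res.fields[-1]
        s2 = ProjectionSolver(short_dome_domain, blood, ergun_coefficients(0.0, blood))
        f_s = s2.solve_steady(0.25, tol=2e-6, max_iter=8000)
        num = np.sqrt(np.mean((f_t.u - f_s.u) ** 2) + np.mean((f_t.v - f_s.v) ** 2))
        den = np.sqrt(np.mean(f_s.u**2) + np.mean(f_s.v**2))
        assert num / den < 0.01

    def test_packing_damps_pulsatile_dome_motion(self, short_dome_domain, blood):
        wf = default_waveform(0.3, period=0.1, n_cycles=3)
        peaks = {}
        for cpd in (0.0, 30.0):
            solver = ProjectionSolver(
                short_dome_domain, blood, ergun_coefficients(cpd, blood)
            )
            res = solver.solve_transient(wf, samples_per_cycle=16)
            peaks[cpd] = res.dome_mean_speed_series.max()
            assert res.cycle_periodicity_rel < 0.02
        assert peaks[30.0] < peaks[0.0]
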