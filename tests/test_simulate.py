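"""Integrators, Kuramoto ensembles, Ott–Antonsen reduction and fixtures."""

import numpy as np
import pytest

import hypernf as H
from hypernf.simulate import BlowUpError, Trajectory, default_ic


class TestStuartLandau:
    def test_uncoupled_radius_and_phase_slope(self):
        net = H.fixture("ring4", alpha=0.0)
        traj = H.simulate_network(net, T=800, dt=0.01, seed=0, save_dt=0.5)
        r = np.abs(traj.states[-200:])
        assert np.allclose(r, 0.1, rtol=0.01)  # √λ = 0.1
        th = np.unwrap(np.angle(traj.states), axis=0)
        slope = (th[-1] - th[-400]) / (traj.times[-1] - traj.times[-400])
        assert np.allclose(slope, net.omegas, atol=1e-6)

    def test_determinism_bit_identical(self, ring4):
        a = H.simulate_network(ring4, T=20, dt=0.01, seed=5)
        b = H.simulate_network(ring4, T=20, dt=0.01, seed=5)
        assert np.array_equal(a.states, b.states)

    def test_integrator_convergence(self, ring4):
        ic = default_ic(ring4, seed=2)
        t1 = H.simulate_network(ring4, T=30, method="rk45", rtol=1e-8, atol=1e-10, ic=ic)
        t2 = H.simulate_network(ring4, T=30, method="rk45", rtol=1e-11, atol=1e-13, ic=ic)
        assert np.max(np.abs(t1.states[-1] - t2.states[-1])) < 1e-6

    def test_blow_up_detected(self):
        dyn = [H.NodeDynamics(1.0, 1.0, beta=+1.0)]  # unstable cubic
        net = H.NetworkSpec(
            np.zeros((1, 1)), 0.0, dyn, H.CouplingFunction.from_string("z*conj(w)")
        )
        with pytest.raises(BlowUpError):
            H.simulate_network(net, T=100, dt=0.01, ic=np.array([0.5 + 0j]))

    def test_slow_modulation_structure(self):
        """With coupling, nodes' instantaneous frequencies acquire slow
        modulation at the triplet detuning scale; halving α roughly quarters
        the modulation amplitude (α² scaling)."""
        amps = []
        for a in (0.025, 0.05):
            net = H.fixture("ring4", alpha=a)
            traj = H.simulate_network(net, T=1200, dt=0.01, seed=1, save_dt=0.1)
            ps = H.extract_phases(traj)
            ps = H.smooth_frequency(ps, window=57.0, order=1, passes=3)
            d = ps.dtheta[1500:-1500, 1]
            amps.append(d.max() - d.min())
        ratio = amps[1] / amps[0]
        assert 2.5 < ratio < 6.0


class TestNormalFormSimulation:
    def test_slow_phase_model_pure_drift(self):
        from hypernf.hypernet import ResonanceCombo, SlowPhaseModel

        combos = [ResonanceCombo.make((1, -1), [1.0, 1.3], 1.0)]
        spm = SlowPhaseModel(combos, drift=np.array([-0.3]), a=np.zeros((1, 1)), b=np.zeros((1, 1)))
        tr = H.simulate_normal_form(spm, T=10, ic=np.array([0.5]), save_dt=0.5)
        assert np.allclose(tr.states[:, 0], 0.5 - 0.3 * tr.times, atol=1e-8)

    def test_phase_model_tracks_slow_modulation_of_full_network(self, ring4, ring4_nf):
        """Integrating the averaged phase model reproduces the slow drift of
        the triplet phase ϕ₁ extracted from the full network simulation."""
        hn = H.build_hypernetwork(ring4_nf)
        pm = H.phase_reduce(hn)
        full = H.simulate_network(ring4, T=600, dt=0.01, seed=4, save_dt=0.5)
        theta0 = np.angle(full.states[0])
        ptr = H.simulate_normal_form(pm, T=600, ic=theta0, save_dt=0.5, rtol=1e-10)
        C = np.array([1.0, -1.0, 1.0, 0.0])
        phi_full = np.unwrap(np.angle(full.states), axis=0) @ C
        phi_pm = ptr.states @ C
        # ϕ₁ spans ~18 rad over the run; the reduced model stays within a
        # small fraction of that
        drift = phi_full[-1] - phi_full[0]
        assert abs(drift) > 10
        assert np.max(np.abs(phi_pm - phi_full)) < 0.1 * abs(drift)

    def test_truncated_field_tracks_full_dynamics(self, ring4, ring4_nf):
        ic = default_ic(ring4, seed=3)
        full = H.simulate_network(ring4, T=40, method="rk45", rtol=1e-10, atol=1e-12, ic=ic, save_dt=0.5)
        U = H.transform_states(ring4_nf, full.states)
        red = H.simulate_normal_form(
            ring4_nf, T=40, method="rk45", rtol=1e-10, atol=1e-12, ic=U[0], save_dt=0.5
        )
        assert np.max(np.abs(red.states - U)) < 5e-5


class TestLorentzian:
    def test_quartile_values(self):
        got = H.sample_lorentzian(0.0, 1.0, 3, deterministic_quantiles=True)
        # mid-point quantiles p = 1/6, 1/2, 5/6 of the standard Cauchy
        assert got[1] == pytest.approx(0.0, abs=1e-12)
        assert got[2] == pytest.approx(np.tan(np.pi / 3))
        assert got[0] == pytest.approx(-np.tan(np.pi / 3))

    def test_sample_median_near_location(self):
        x = H.sample_lorentzian(3.0, 0.48, 20001, seed=4)
        assert np.median(x) == pytest.approx(3.0, abs=0.05)

    def test_seeded_reproducibility(self):
        a = H.sample_lorentzian(3.0, 0.48, 100, seed=7)
        b = H.sample_lorentzian(3.0, 0.48, 100, seed=7)
        assert np.array_equal(a, b)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            H.sample_lorentzian(0.0, 0.0, 5)


class TestKuramoto:
    def test_subcritical_incoherence(self):
        spec = H.fixture("kuramoto4", N=2000, alpha=0.0, mu=0.2)  # μ < σ
        traj, _ = H.simulate_kuramoto(spec, T=60, dt=0.01, save_dt=1.0)
        assert np.all(np.abs(traj.states[-20:]) < 0.1)

    def test_coherent_fixed_point_radius(self, kuramoto4_small):
        spec = H.fixture("kuramoto4", N=2000, alpha=0.0)
        traj, _ = H.simulate_kuramoto(spec, T=150, dt=0.01, save_dt=1.0)
        r = np.abs(traj.states[-50:]).mean(axis=0)
        assert np.allclose(r, spec.r_fixed_points(), rtol=0.05)

    def test_formula_vs_printed_value(self):
        # the coherent radius follows √((μ−σ)/μ) = 0.2 for μ=0.5, σ=0.48
        spec = H.fixture("kuramoto4")
        assert np.allclose(spec.r_fixed_points(), 0.2)

    def test_micro_vs_oa_gap_shrinks_with_N(self):
        gaps = []
        for N in (1000, 4000):
            spec = H.fixture("kuramoto4", N=N)
            _, psi = H.simulate_kuramoto(spec, T=150, dt=0.01, save_dt=1.0)
            m, _ = H.simulate_kuramoto(spec, T=30, dt=0.005, save_dt=0.25, ic=psi)
            net = H.kuramoto_to_network(spec)
            o = H.simulate_network(net, T=30, dt=0.005, ic=m.states[0], save_dt=0.25)
            gaps.append(np.abs(np.abs(o.states) - np.abs(m.states)).max())
        assert gaps[1] < gaps[0]
        assert gaps[1] < 0.06

    def test_oa_uncoupled_fixed_point(self):
        spec = H.fixture("kuramoto4", alpha=0.0)
        traj = H.simulate_oa(spec, T=400, dt=0.5)
        r = np.abs(traj.states[-100:])
        assert np.allclose(r, 0.2, rtol=0.01)
        th = np.unwrap(np.angle(traj.states), axis=0)
        slope = (th[-1] - th[-200]) / (traj.times[-1] - traj.times[-200])
        assert np.allclose(slope, spec.Omegas, atol=1e-4)

    def test_oa_pipeline_slow_phase_combos(self):
        """Feeding the mean-field network into the normal-form pipeline yields
        the slow phases θ₁−2θ₂+θ₃ and θ₂−2θ₁+θ₄ (canonical sign)."""
        spec = H.fixture("kuramoto4")
        net = H.kuramoto_to_network(spec)
        res = H.normal_form(net, degree_cut=5, filter_tol=1e-6)
        hn = H.build_hypernetwork(res, tol=1e-6)
        combos = {c.coeffs for c in hn.combos()}
        assert (1, -2, 1, 0) in combos
        assert (2, -1, 0, -1) in combos
        targets = {c.coeffs: set() for c in hn.combos()}
        for e in hn.hyperedges:
            if not e.combo.is_zero:
                targets[e.combo.coeffs].add(e.target)
        assert targets[(1, -2, 1, 0)] >= {0, 2}
        assert targets[(2, -1, 0, -1)] >= {1, 3}


class TestTrajectoryIO:
    def test_csv_round_trip_complex(self, tmp_path, ring4):
        traj = H.simulate_network(ring4, T=5, dt=0.01, seed=0)
        p = tmp_path / "traj.csv"
        traj.to_csv(p)
        back = Trajectory.from_csv(p)
        assert np.allclose(back.states, traj.states)
        assert np.allclose(back.times, traj.times)
        assert back.metadata["model"] == "network"

    def test_invalid_times_rejected(self):
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 0.0, 1.0]), np.zeros((3, 1)))
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 1.0]), np.array([[np.nan], [0.0]]))


class TestFixtures:
    def test_ring4_defaults(self, ring4):
        assert ring4.n == 4
        assert tuple(ring4.omegas) == (1.0, 2.53, 1.56, 2.53)
        assert ring4.alpha == 0.05
        assert ring4.dynamics[0].lambda_ == 0.01
        assert ring4.coupling.serialize().replace(" ", "") in (
            "z*conj(w)+z^2*conj(w)",
            "z^2*conj(w)+z*conj(w)",
        )
        # triplet detunings 0.03, pairwise exact
        w = ring4.omegas
        assert w[0] - w[1] + w[2] == pytest.approx(0.03)
        assert w[1] - w[3] == pytest.approx(0.0)

    def test_kuramoto4_printed_parameters(self):
        spec = H.fixture("kuramoto4")
        assert spec.Omegas == (2.0, 3.0, 4.0, 1.0)
        assert spec.mu == 0.5 and spec.alpha == 0.1
        assert spec.sigmas == (0.48,) * 4
        assert spec.N == 10_000

    def test_path3_shape(self, path3):
        assert path3.adjacency[0, 2] == 0
        assert path3.omegas[0] - path3.omegas[1] + path3.omegas[2] == pytest.approx(0.0)

    def test_unknown_fixture(self):
        with pytest.raises(ValueError, match="unknown fixture"):
            H.fixture("ring5")
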