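"""Neighbour search, force accumulation, integration and weak coupling."""
import numpy as np
import pytest

import elbamd
from elbamd.engine import neighbor_list
from elbamd.units import KB
from elbamd.verification import brute_force_energy


def _pair_set(pi, pj):
    return {(int(a), int(b)) for a, b in zip(pi, pj)}


class TestNeighborList:
    def test_matches_exhaustive_scan(self, ff, small_bilayer):
        st = small_bilayer
        sim = elbamd.Simulation(st, ff, elbamd.SimConfig())
        pi, pj = neighbor_list(st, sim.rcut, 0.2, sim.exclusions)
        got = _pair_set(pi, pj)
        # O(N^2) oracle
        expect = set()
        excl = {tuple(sorted((int(i), int(j)))) for i, j in sim.bond_ij}
        for i in range(st.n_sites - 1):
            d = st.pos[i + 1:] - st.pos[i]
            d -= np.rint(d / st.box) * st.box
            r = np.sqrt((d ** 2).sum(axis=1))
            thr = sim.rcut[st.typ[i], st.typ[i + 1:]] + 0.2
            for j in np.nonzero(r < thr)[0] + i + 1:
                if (i, int(j)) not in excl:
                    expect.add((i, int(j)))
        assert got == expect

    def test_distant_pair_absent_and_bonded_excluded(self, ff, small_bilayer):
        st = small_bilayer
        sim = elbamd.Simulation(st, ff, elbamd.SimConfig())
        pi, pj = neighbor_list(st, sim.rcut, 0.2, sim.exclusions)
        pairs = _pair_set(pi, pj)
        for i, j in sim.bond_ij:
            assert tuple(sorted((int(i), int(j)))) not in pairs

    def test_box_too_small_rejected(self, ff):
        st = elbamd.build_water_box(100, T=300, seed=0, ff=ff)
        st.box[:] = 1.5
        with pytest.raises(ValueError):
            neighbor_list(st, np.full((7, 7), 0.9), 0.2,
                          np.full((100, 4), -1, np.int64))


class TestForces:
    def test_energy_matches_bruteforce_oracle(self, ff, small_bilayer):
        sim = elbamd.Simulation(small_bilayer, ff, elbamd.SimConfig())
        rep = sim.compute_forces()
        oracle = brute_force_energy(small_bilayer, ff)
        for term in ("lj", "coulomb", "charge_dipole", "dipole_dipole",
                     "bond", "angle", "restraint"):
            assert getattr(rep, term) == pytest.approx(
                oracle[term], rel=1e-10, abs=1e-10)

    def test_newtons_third_law(self, ff, small_bilayer):
        sim = elbamd.Simulation(small_bilayer, ff, elbamd.SimConfig())
        sim.compute_forces()
        fsum = np.abs(sim.forces.sum(axis=0)).max()
        assert fsum < 1e-9 * np.abs(sim.forces).mean()

    def test_water_pair_beyond_short_cutoff_inert(self, ff):
        st = elbamd.build_water_box(100, T=300, seed=0, ff=ff)
        st.box[:] = 4.0
        st.pos[:] = 0.0
        st.pos[0] = [0.2, 0.2, 0.2]
        st.pos[1] = [0.2 + 0.95, 0.2, 0.2]     # beyond 0.9 nm
        st.pos[2:] = np.linspace(2.0, 2.9, 98)[:, None]
        sim = elbamd.Simulation(st, ff, elbamd.SimConfig())
        sim.compute_forces()
        assert np.allclose(sim.forces[0], 0.0, atol=1e-12)

    def test_overlap_is_fatal(self, ff):
        st = elbamd.build_water_box(100, T=300, seed=0, ff=ff)
        st.box[:] = 4.0
        st.pos[:] = np.linspace(0.3, 3.7, 100)[:, None]
        st.pos[1] = st.pos[0] + 1e-8
        sim = elbamd.Simulation(st, ff, elbamd.SimConfig())
        with pytest.raises(RuntimeError, match="overlap"):
            sim.compute_forces()

    def test_energy_report_sums(self, ff, small_bilayer):
        sim = elbamd.Simulation(small_bilayer, ff, elbamd.SimConfig())
        rep = sim.compute_forces()
        parts = (rep.lj + rep.coulomb + rep.charge_dipole
                 + rep.dipole_dipole + rep.bond + rep.angle + rep.restraint)
        assert rep.potential == pytest.approx(parts, rel=1e-14)
        assert rep.total == pytest.approx(
            rep.potential + rep.kinetic_trans + rep.kinetic_rot, rel=1e-14)


class TestIntegrator:
    def test_zero_force_straight_line_and_uniform_rotation(self, ff):
        st = elbamd.build_water_box(27, T=0.0, seed=0, ff=ff)
        st.box[:] = 50.0
        st.pos[:] = np.linspace(5, 45, 27)[:, None] * [1, 0, 0] + 25 * np.array([0, 1, 1])
        st.vel[:] = [0.1, 0.0, 0.0]
        st.u[:] = [0, 0, 1.0]
        st.omega[:] = [2.0, 0.0, 0.0]
        sim = elbamd.Simulation(
            st, ff, elbamd.SimConfig(thermostat=False, remove_com=False))
        x0 = st.pos[:, 0].copy()
        n = 200
        sim.run(n)
        t = n * sim.cfg.dt
        assert np.allclose(st.pos[:, 0], x0 + 0.1 * t, atol=1e-9)
        # axis precesses uniformly about omega: angle = |omega| t
        expected = np.array([0.0, -np.sin(2.0 * t), np.cos(2.0 * t)])
        assert np.allclose(st.u[0], expected, atol=1e-9)

    def test_dipole_norm_preserved(self, ff):
        st = elbamd.build_water_box(64, T=303.0, seed=3, ff=ff)
        st.box[:] = 10.0   # dilute: free rotors
        sim = elbamd.Simulation(st, ff, elbamd.SimConfig(thermostat=False))
        sim.run(10000)
        assert np.abs(np.linalg.norm(st.u, axis=1) - 1.0).max() < 1e-10

    def test_harmonic_dimer_period(self, ff):
        """A bonded dimer oscillates with T = 2 pi sqrt(m_red / k)."""
        st = elbamd.build_water_box(8, T=0.0, seed=0, ff=ff)
        st.box[:] = 30.0
        st.pos[:] = 3.0 * np.arange(8)[:, None] * [0, 0, 1] + 1.0
        st.vel[:] = 0.0
        st.omega[:] = 0.0
        sim = elbamd.Simulation(
            st, ff, elbamd.SimConfig(thermostat=False, remove_com=False))
        k, r0 = 1260.0, 0.4
        sim.bond_ij = np.array([[0, 1]], np.int64)
        sim.kb = np.array([k])
        sim.r0 = np.array([r0])
        sim.exclusions[0, 0] = 1
        sim.exclusions[1, 0] = 0
        sim._pairs = None
        st.pos[1] = st.pos[0] + [r0 + 0.02, 0, 0]   # small stretch
        m = ff.site("water").mass
        period = 2 * np.pi * np.sqrt(0.5 * m / k)
        dt = 0.002
        nsteps = int(round(5 * period / dt))
        xs = []
        sim.compute_forces()
        for _ in range(nsteps):
            sim.step(dt)
            xs.append(st.pos[1, 0] - st.pos[0, 0])
        xs = np.array(xs)
        # count the dominant frequency via zero crossings of (x - r0)
        sgn = np.sign(xs - r0)
        crossings = np.count_nonzero(np.diff(sgn))
        measured = 2 * nsteps * dt / crossings
        assert measured == pytest.approx(period, rel=5e-3)

    def test_same_seed_bit_identical_log(self, ff):
        def one():
            st = elbamd.build_water_box(125, T=303.0, seed=11, ff=ff)
            st.box[:] = 3.0
            st.pos *= 3.0 / st.pos.max()   # dilute, deterministic spread
            sim = elbamd.Simulation(st, ff,
                                    elbamd.SimConfig(thermostat=True, seed=11))
            return sim.run(300, log_stride=50)
        log1, log2 = one(), one()
        assert log1 == log2

    def test_observer_stride_honored(self, ff):
        st = elbamd.build_water_box(64, T=303.0, seed=1, ff=ff)
        st.box[:] = 10.0
        sim = elbamd.Simulation(st, ff, elbamd.SimConfig(thermostat=False))
        calls = []
        sim.run(100, observers=[(7, lambda s: calls.append(s.state.time))])
        assert len(calls) == 100 // 7

    def test_nonfinite_coordinates_fatal(self, ff):
        st = elbamd.build_water_box(64, T=303.0, seed=1, ff=ff)
        st.box[:] = 4.0
        st.pos[:] = np.linspace(0.3, 3.7, 64)[:, None]
        sim = elbamd.Simulation(st, ff, elbamd.SimConfig())
        sim.compute_forces()
        st.pos[0, 0] = np.nan
        with pytest.raises(RuntimeError, match="non-finite"):
            sim.step()


class TestWeakCoupling:
    def test_thermostat_noop_at_target(self, ff):
        st = elbamd.build_water_box(216, T=303.0, seed=2, ff=ff)
        st.box[:] = 8.0
        sim = elbamd.Simulation(st, ff, elbamd.SimConfig(temperature=303.0))
        # rescale exactly to target first
        for name, mask, dof, rot in sim._groups():
            vel = st.omega if rot else st.vel
            inert = sim.inertia if rot else sim.mass
            ke = 0.5 * np.sum(inert[mask] * np.sum(vel[mask] ** 2, axis=1))
            t = 2 * ke / (dof * KB)
            vel[mask] *= np.sqrt(303.0 / t)
        v0 = st.vel.copy()
        sim.apply_thermostat()
        assert np.allclose(st.vel, v0, rtol=1e-12)

    def test_berendsen_lambda_monotone_in_t(self):
        dt, tau, t0 = 0.015, 1.0, 303.0
        lam = lambda t: np.sqrt(1 + dt / tau * (t0 / t - 1))
        ts = np.linspace(150, 600, 40)
        lams = lam(ts)
        assert np.all(np.diff(lams) < 0)
        assert lam(t0) == pytest.approx(1.0)

    def test_mean_temperature_within_one_percent(self, water_npt):
        log = water_npt["log"]
        t = np.mean([row["water_trans"] for row in log[len(log) // 3:]])
        assert abs(t - 303.0) / 303.0 < 0.01

    def test_barostat_noop_at_target(self, ff):
        st = elbamd.build_water_box(216, T=303.0, seed=2, ff=ff)
        st.box[:] = 4.0
        st.pos *= 4.0 / st.pos.max()
        sim = elbamd.Simulation(st, ff, elbamd.SimConfig(barostat="iso",
                                                         pressure=1.0))
        sim.compute_forces()
        sim.report.pressure_tensor = np.eye(3) * 1.0
        box0 = st.box.copy()
        sim.apply_barostat()
        assert np.allclose(st.box, box0, rtol=1e-12)

    def test_semi_isotropic_keeps_square_interface(self, ff, small_bilayer):
        sim = elbamd.Simulation(small_bilayer.copy(), ff,
                                elbamd.SimConfig(barostat="semi"))
        sim.relax(300)
        for _ in range(50):
            sim.step()
        assert sim.state.box[0] == pytest.approx(sim.state.box[1], rel=1e-14)
        assert sim.state.box[2] != pytest.approx(sim.state.box[0])

    def test_remove_drift_zeroes_momentum_and_leaflet_lateral(self, ff,
                                                              small_bilayer):
        st = small_bilayer.copy()
        rng = np.random.default_rng(0)
        st.vel += rng.normal(0, 0.1, st.vel.shape)
        sim = elbamd.Simulation(st, ff,
                                elbamd.SimConfig(remove_leaflet_drift=True))
        vz_before = {leaf: st.vel[st.leaflet == leaf, 2].copy()
                     for leaf in (0, 1)}
        sim.remove_drift()
        p = (sim.mass[:, None] * st.vel).sum(axis=0)
        assert np.abs(p).max() < 1e-10
        for leaf in (0, 1):
            mask = st.leaflet == leaf
            m = sim.mass[mask]
            lat = (m[:, None] * st.vel[mask, :2]).sum(axis=0)
            assert np.abs(lat).max() < 1e-10
            # normal components shifted only by the global COM correction
            dz = st.vel[mask, 2] - vz_before[leaf]
            assert np.ptp(dz) < 1e-12
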