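"""Pair potentials, mixing rules and parameter-file contracts.

Frozen expected values come from an independent high-precision evaluation of
the closed-form expressions (mpmath, 30 digits)."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import elbamd
from elbamd.forcefield import (AngleParams, BondParams, PairParams,
                               cubic_switch)
from elbamd.units import DEBYE, KE

WATER_PAIR = PairParams(sigma_ij=0.3, epsilon_ij=1.95, cutoff=0.9,
                        switch_radius=0.81)
GENERIC = PairParams(sigma_ij=0.41, epsilon_ij=2.0, cutoff=1.2,
                     switch_radius=1.08)


# ---------------------------------------------------------------------------
# shifted-force Lennard-Jones
# ---------------------------------------------------------------------------

class TestLJ:
    def test_vanishes_at_cutoff(self):
        assert elbamd.lj_shifted_force(WATER_PAIR.cutoff, WATER_PAIR) == (0, 0)
        assert elbamd.lj_shifted_force(2.0, WATER_PAIR) == (0, 0)

    def test_frozen_value_at_sigma(self):
        e, _ = elbamd.lj_shifted_force(0.30, WATER_PAIR)
        assert e == pytest.approx(0.039138869601705551, rel=1e-12)

    @pytest.mark.parametrize("r,f_expected", [
        (0.3, 156.02371163183370), (0.5, -3.9199885603113001),
        (0.8, -0.098547651042713919)])
    def test_force_matches_central_difference(self, r, f_expected):
        _, f = elbamd.lj_shifted_force(r, WATER_PAIR)
        assert f == pytest.approx(f_expected, rel=1e-6)

    def test_continuity_at_cutoff(self):
        for h in (1e-4, 1e-6):
            e, f = elbamd.lj_shifted_force(WATER_PAIR.cutoff - h, WATER_PAIR)
            assert abs(e) < 1e-3 * h and abs(f) < 10 * h

    def test_domain_error(self):
        with pytest.raises(ValueError):
            elbamd.lj_shifted_force(0.0, WATER_PAIR)


# ---------------------------------------------------------------------------
# shifted-force Coulomb
# ---------------------------------------------------------------------------

class TestCoulomb:
    def test_vanishes_at_cutoff_and_zero_charge(self):
        assert elbamd.coulomb_shifted_force(1, -1, GENERIC.cutoff,
                                            GENERIC) == (0, 0)
        assert elbamd.coulomb_shifted_force(0, -1, 0.5, GENERIC) == (0, 0)

    def test_frozen_value(self):
        e, _ = elbamd.coulomb_shifted_force(1.0, -1.0, 0.5, GENERIC)
        assert e == pytest.approx(-94.553297805555556, rel=1e-12)

    def test_force_is_negative_gradient(self):
        h = 1e-6
        for r in (0.4, 0.8, 1.1):
            ep = elbamd.coulomb_shifted_force(1, -1, r + h, GENERIC)[0]
            em = elbamd.coulomb_shifted_force(1, -1, r - h, GENERIC)[0]
            f = elbamd.coulomb_shifted_force(1, -1, r, GENERIC)[1]
            assert f == pytest.approx(-(ep - em) / (2 * h), rel=1e-6)


# ---------------------------------------------------------------------------
# charge-dipole
# ---------------------------------------------------------------------------

class TestChargeDipole:
    def test_perpendicular_dipole_zero_energy(self):
        e, *_ = elbamd.charge_dipole(1.0, [0, 0.05, 0], [0.6, 0, 0], GENERIC)
        assert e == pytest.approx(0.0, abs=1e-14)

    def test_beyond_cutoff_zero(self):
        e, fq, fd, tq = elbamd.charge_dipole(1.0, [0, 0, 0.05],
                                             [1.3, 0, 0], GENERIC)
        assert e == 0 and not fq.any() and not fd.any() and not tq.any()

    def test_frozen_aligned_value(self):
        mu = 2.3 * DEBYE
        e, *_ = elbamd.charge_dipole(1.0, [mu, 0, 0], [0.6, 0, 0], GENERIC)
        assert e == pytest.approx(9.2401142831636716, rel=1e-12)

    def test_forces_and_torque_by_finite_difference(self):
        rng = np.random.default_rng(3)
        mu = 2.3 * DEBYE * rng.standard_normal(3)
        r = np.array([0.5, 0.2, -0.3])
        h = 1e-7
        e0, fq, fd, tq = elbamd.charge_dipole(0.7, mu, r, GENERIC)
        for ax in range(3):
            dr = np.zeros(3)
            dr[ax] = h
            ep = elbamd.charge_dipole(0.7, mu, r + dr, GENERIC)[0]
            em = elbamd.charge_dipole(0.7, mu, r - dr, GENERIC)[0]
            assert fq[ax] == pytest.approx(-(ep - em) / (2 * h), rel=1e-5)
        assert np.allclose(fq + fd, 0)
        # torque about an axis perpendicular to mu
        axis = np.cross(mu, [0, 0, 1.0])
        axis /= np.linalg.norm(axis)

        def rot(t):
            c, s = np.cos(t), np.sin(t)
            return (mu * c + np.cross(axis, mu) * s
                    + axis * (axis @ mu) * (1 - c))
        ep = elbamd.charge_dipole(0.7, rot(h), r, GENERIC)[0]
        em = elbamd.charge_dipole(0.7, rot(-h), r, GENERIC)[0]
        assert tq @ axis == pytest.approx(-(ep - em) / (2 * h), rel=1e-5)


# ---------------------------------------------------------------------------
# dipole-dipole
# ---------------------------------------------------------------------------

class TestDipoleDipole:
    MU = 2.3 * DEBYE

    def test_collinear_head_to_tail(self):
        mu = np.array([0, 0, self.MU])
        e, f, t1, t2 = elbamd.dipole_dipole([0, 0, 0.5], mu, mu, WATER_PAIR)
        assert e == pytest.approx(-5.0971400182822354, rel=1e-12)
        assert not t1.any() and not t2.any()

    def test_beyond_cutoff_zero(self):
        mu = np.array([0, 0, self.MU])
        e, f, t1, t2 = elbamd.dipole_dipole([1.0, 0, 0], mu, mu, WATER_PAIR)
        assert e == 0 and not f.any() and not t1.any() and not t2.any()

    def test_perpendicular_geometry_zero(self):
        e, *_ = elbamd.dipole_dipole([0.5, 0, 0], [self.MU, 0, 0],
                                     [0, self.MU, 0], WATER_PAIR)
        assert e == pytest.approx(0.0, abs=1e-14)

    def test_switch_region_force_includes_switch_derivative(self):
        mu = np.array([0, 0, self.MU])
        h = 1e-7
        for x in (0.5, 0.84, 0.88):   # inside and within switch window
            e0, f, *_ = elbamd.dipole_dipole([x, 0, 0.1], mu, mu, WATER_PAIR)
            ep = elbamd.dipole_dipole([x + h, 0, 0.1], mu, mu, WATER_PAIR)[0]
            em = elbamd.dipole_dipole([x - h, 0, 0.1], mu, mu, WATER_PAIR)[0]
            assert f[0] == pytest.approx(-(ep - em) / (2 * h), rel=1e-5)

    def test_pair_angular_momentum_closes(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            m1 = self.MU * rng.standard_normal(3)
            m2 = self.MU * rng.standard_normal(3)
            r = rng.uniform(0.3, 0.85, 3) * rng.choice([-1, 1], 3)
            e, f1, t1, t2 = elbamd.dipole_dipole(r, m1, m2, WATER_PAIR)
            total = np.cross(r, f1) + t1 + t2
            assert np.allclose(total, 0, atol=1e-12)


# ---------------------------------------------------------------------------
# bonded terms
# ---------------------------------------------------------------------------

class TestBonded:
    def test_bond_minimum_and_frozen_value(self):
        b = BondParams(k_b=1260.0, r0=0.38)
        assert elbamd.bond_energy(0.38, b) == (0.0, -0.0)
        e, _ = elbamd.bond_energy(0.43, b)
        assert e == pytest.approx(0.5 * 1260 * 0.05 ** 2, rel=1e-12)
        assert (elbamd.bond_energy(0.38 + 0.02, b)[0]
                == pytest.approx(elbamd.bond_energy(0.38 - 0.02, b)[0]))

    @pytest.mark.parametrize("form,expected", [
        # (k/2)(th - th0)^2 at 30 deg misalignment
        ("harmonic_theta", 15.0 * (np.pi / 6) ** 2),
        # (k/2)(cos th - cos th0)^2 frozen from the closed form
        ("cosine_harmonic", 0.26923788646684060)])
    def test_angle_minimum_and_frozen_value(self, form, expected):
        a = AngleParams(k_a=30.0, theta0=180.0, form=form)
        e, g = elbamd.angle_energy(180.0, a)
        assert e == 0 and g == pytest.approx(0.0, abs=1e-12)
        e, _ = elbamd.angle_energy(150.0, a)
        assert e == pytest.approx(expected, rel=1e-10)
        # symmetric displacements about theta0 give equal energies
        assert elbamd.angle_energy(160.0, a)[0] == pytest.approx(
            elbamd.angle_energy(200.0, a)[0])

    @pytest.mark.parametrize("form", ["harmonic_theta", "cosine_harmonic"])
    def test_angle_gradient_by_finite_difference(self, form):
        a = AngleParams(k_a=30.0, theta0=120.0, form=form)
        rng = np.random.default_rng(11)
        ri, rj, rk = rng.standard_normal((3, 3))
        e0, fi, fj, fk = elbamd.angle_gradient(ri, rj, rk, a)
        assert np.allclose(fi + fj + fk, 0, atol=1e-12)
        h = 1e-7
        for site, f in ((0, fi), (1, fj), (2, fk)):
            for ax in range(3):
                pts = [ri.copy(), rj.copy(), rk.copy()]
                pts[site][ax] += h
                ep = elbamd.angle_gradient(*pts, a)[0]
                pts[site][ax] -= 2 * h
                em = elbamd.angle_gradient(*pts, a)[0]
                assert f[ax] == pytest.approx(-(ep - em) / (2 * h),
                                              rel=1e-5, abs=1e-8)

    def test_angle_degenerate_bond_raises(self):
        a = AngleParams(k_a=30.0, theta0=180.0)
        with pytest.raises(ValueError):
            elbamd.angle_gradient([0, 0, 0], [0, 0, 0], [1, 0, 0], a)

    def test_restraint_aligned_and_quarter_turn(self):
        u = np.array([0, 0, 1.0])
        e, tq, *_ = elbamd.dipole_restraint(u, [0, 0, 2.0], 10.0)
        assert e == 0 and np.allclose(tq, 0)
        e, tq, f_to, f_from = elbamd.dipole_restraint(u, [1.0, 0, 0], 10.0)
        assert e == pytest.approx(10.0)
        assert np.linalg.norm(tq) == pytest.approx(10.0)
        # symmetric in the sign of the misalignment
        e2, *_ = elbamd.dipole_restraint([0, 0, -1.0], [1.0, 0, 0], 10.0)
        assert e2 == pytest.approx(e)

    def test_restraint_momentum_and_angular_momentum_close(self):
        rng = np.random.default_rng(7)
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        b = rng.standard_normal(3)
        e, tq, f_to, f_from = elbamd.dipole_restraint(u, b, 10.0)
        assert np.allclose(f_to + f_from, 0)
        assert np.allclose(np.cross(b, f_to) + tq, 0, atol=1e-12)

    def test_restraint_torque_matches_denergy_ddelta(self):
        kd, h = 10.0, 1e-7
        b = np.array([0, 0, 1.0])

        def u_at(delta):
            return np.array([np.sin(delta), 0, np.cos(delta)])
        d0 = np.radians(90.0)
        ep = elbamd.dipole_restraint(u_at(d0 + h), b, kd)[0]
        em = elbamd.dipole_restraint(u_at(d0 - h), b, kd)[0]
        tq = elbamd.dipole_restraint(u_at(d0), b, kd)[1]
        assert np.linalg.norm(tq) == pytest.approx((ep - em) / (2 * h),
                                                   rel=1e-6)


# ---------------------------------------------------------------------------
# mixing rules and the parameter file
# ---------------------------------------------------------------------------

class TestMixing:
    def test_lb_identity(self, ff):
        t = ff.site("tail")
        p = elbamd.mix_params(t, t)
        assert p.epsilon_ij == pytest.approx(t.epsilon)
        assert p.sigma_ij == pytest.approx(t.sigma)

    def test_choline_water_sigma(self, ff):
        p = ff.pair("choline", "water")
        assert p.sigma_ij == pytest.approx(0.41)

    def test_tail_water_epsilon(self, ff):
        p = ff.pair("tail", "water")
        assert p.epsilon_ij == pytest.approx(1.3964240043768941, rel=1e-12)
        assert p.s_ij == 1.0

    def test_hydrogen_bond_pairs_scaled(self, ff):
        hb = [("water", "phosphate"), ("water", "glycerol"),
              ("water", "ester"), ("amine", "phosphate"),
              ("amine", "glycerol"), ("amine", "ester"), ("amine", "water")]
        for a, b in hb:
            assert ff.pair(a, b).s_ij > 1.0
        assert ff.pair("water", "choline").s_ij == 1.0
        assert ff.pair("tail", "phosphate").s_ij == 1.0

    def test_water_water_cutoff_is_short(self, ff):
        assert ff.pair("water", "water").cutoff == pytest.approx(0.9)
        assert ff.pair("water", "tail").cutoff == pytest.approx(1.2)

    @given(st.sampled_from(["water", "choline", "amine", "phosphate",
                            "glycerol", "ester", "tail"]),
           st.sampled_from(["water", "choline", "amine", "phosphate",
                            "glycerol", "ester", "tail"]))
    @settings(max_examples=30, deadline=None)
    def test_mixing_symmetric(self, a, b):
        ff = elbamd.load_default()
        pab, pba = ff.pair(a, b), ff.pair(b, a)
        assert pab.sigma_ij == pba.sigma_ij
        assert pab.epsilon_ij == pba.epsilon_ij

    def test_unknown_type_raises(self, ff):
        with pytest.raises(KeyError):
            ff.site("cholesterol")


class TestReferenceBondLength:
    def test_equal_sigmas(self, ff):
        t = ff.site("tail")
        assert elbamd.reference_bond_length(t, t) == pytest.approx(t.sigma)

    def test_glycerol_phosphate_and_symmetry(self, ff):
        g, p = ff.site("glycerol"), ff.site("phosphate")
        assert elbamd.reference_bond_length(g, p) == pytest.approx(0.455)
        assert (elbamd.reference_bond_length(p, g)
                == elbamd.reference_bond_length(g, p))

    @given(st.floats(0.1, 1.0), st.floats(0.1, 1.0), st.floats(0.01, 0.5))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_either_sigma(self, s1, s2, ds):
        mk = lambda s: elbamd.SiteType(name="x", sigma=s, epsilon=1.0,
                                       mass=1.0)
        assert (elbamd.reference_bond_length(mk(s1 + ds), mk(s2))
                >= elbamd.reference_bond_length(mk(s1), mk(s2)))


def test_cubic_switch_is_c1():
    rs, rc = 0.81, 0.9
    assert cubic_switch(0.5, rs, rc) == (1.0, 0.0)
    assert cubic_switch(0.95, rs, rc) == (0.0, 0.0)
    s, sp = cubic_switch(rs + 1e-9, rs, rc)
    assert s == pytest.approx(1.0, abs=1e-12)
    assert sp == pytest.approx(0.0, abs=1e-6)
    s, sp = cubic_switch(rc - 1e-9, rs, rc)
    assert s == pytest.approx(0.0, abs=1e-12)
    assert sp == pytest.approx(0.0, abs=1e-6)


def test_site_type_invariants():
    with pytest.raises(ValueError):
        elbamd.SiteType(name="bad", sigma=-1, epsilon=1, mass=1)
    with pytest.raises(ValueError):
        elbamd.SiteType(name="bad", sigma=0.3, epsilon=1, mass=1,
                        dipole_mu=2.0, inertia=0.0)
    with pytest.raises(ValueError):
        PairParams(sigma_ij=0.3, epsilon_ij=1, s_ij=0.5)
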