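"""Independent oracles used to validate the engine.

The brute-force energy oracle sums every minimum-image pair with the pure
scalar/vector potential functions of :mod:`elbamd.forcefield`; it shares no
kernel code with the engine.  The finite-difference checker compares
analytic forces with central differences of the total potential energy and
analytic torques with derivatives under small rotations of each dipole axis
about two orthogonal axes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import forcefield as ffmod
from .forcefield import ForceField
from .topology import SystemState, make_template

__all__ = ["OracleReport", "brute_force_energy", "finite_difference_check",
           "synthetic_profile"]


@dataclass
class OracleReport:
    max_force_error: float
    max_torque_error: float
    energy_mismatch: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return (self.max_force_error < self.tolerance
                and self.max_torque_error < self.tolerance)


# ---------------------------------------------------------------------------
# brute-force energy oracle
# ---------------------------------------------------------------------------

def brute_force_energy(state: SystemState, ff: ForceField) -> dict:
    """O(N^2) minimum-image evaluation of every energy term.

    Intended for systems of a few hundred sites at most; returns a dict of
    per-term energies (kJ/mol) keyed like the engine's EnergyReport fields.
    """
    tab = ff.tables()
    typ = state.typ
    pos = state.pos
    box = state.box
    n = state.n_sites
    names = [ffmod.SITE_ORDER[t] for t in typ]
    mu_site = tab["mu"][typ][:, None] * state.u
    q_site = tab["charge"][typ]

    templates = {s: make_template(s, ff) for s in set(state.mol_species)}
    bonded_pairs = set()
    offset = 0
    bonds, angles, restraints = [], [], []
    for sp in state.mol_species:
        tpl = templates[sp]
        for i, j, bp in tpl.bonds:
            bonded_pairs.add((offset + i, offset + j))
            bonded_pairs.add((offset + j, offset + i))
            bonds.append((offset + i, offset + j, bp))
        for i, j, k, ap in tpl.angles:
            angles.append((offset + i, offset + j, offset + k, ap))
        for rp in tpl.restraints:
            restraints.append((offset + rp.dipole_site, offset + rp.ref_from,
                               offset + rp.ref_to, rp.k_d))
        offset += tpl.n_sites

    terms = {k: 0.0 for k in ("lj", "coulomb", "charge_dipole",
                              "dipole_dipole", "bond", "angle", "restraint")}

    def minimg(v):
        return v - np.rint(v / box) * box

    for i in range(n - 1):
        for j in range(i + 1, n):
            if (i, j) in bonded_pairs:
                continue
            d = minimg(pos[i] - pos[j])
            r = float(np.linalg.norm(d))
            p = ff.pair(names[i], names[j])
            if r >= p.cutoff:
                continue
            terms["lj"] += ffmod.lj_shifted_force(r, p)[0]
            if q_site[i] and q_site[j]:
                terms["coulomb"] += ffmod.coulomb_shifted_force(
                    q_site[i], q_site[j], r, p)[0]
            if q_site[i] and tab["mu"][typ[j]] > 0:
                terms["charge_dipole"] += ffmod.charge_dipole(
                    q_site[i], mu_site[j], d, p)[0]
            if q_site[j] and tab["mu"][typ[i]] > 0:
                terms["charge_dipole"] += ffmod.charge_dipole(
                    q_site[j], mu_site[i], -d, p)[0]
            if tab["mu"][typ[i]] > 0 and tab["mu"][typ[j]] > 0:
                terms["dipole_dipole"] += ffmod.dipole_dipole(
                    d, mu_site[i], mu_site[j], p)[0]

    for i, j, bp in bonds:
        r = float(np.linalg.norm(minimg(pos[i] - pos[j])))
        terms["bond"] += ffmod.bond_energy(r, bp)[0]
    for i, j, k, ap in angles:
        e, *_ = ffmod.angle_gradient(pos[j] + minimg(pos[i] - pos[j]), pos[j],
                                     pos[j] + minimg(pos[k] - pos[j]), ap)
        terms["angle"] += e
    for d_ix, a_ix, b_ix, kd in restraints:
        b = minimg(pos[b_ix] - pos[a_ix])
        terms["restraint"] += ffmod.dipole_restraint(state.u[d_ix], b, kd)[0]
    terms["potential"] = sum(terms.values())
    return terms


# ---------------------------------------------------------------------------
# finite differences
# ---------------------------------------------------------------------------

def finite_difference_check(sim, h: float = 1e-5,
                            tolerance: float = 1e-6,
                            max_sites: int = 30,
                            seed: int = 0) -> OracleReport:
    """Compare the engine's analytic forces and torques against central
    finite differences of its potential energy.

    ``h`` is the coordinate step in nm (and the rotation step in rad for
    torques).  A random subset of at most ``max_sites`` sites is probed.
    Errors are relative to the typical force/torque magnitude.
    """
    st = sim.state
    rng = np.random.default_rng(seed)
    sites = rng.choice(st.n_sites, size=min(max_sites, st.n_sites),
                       replace=False)
    rep = sim.compute_forces()
    f_ana = sim.forces.copy()
    t_ana = sim.torques.copy()
    scale_f = max(float(np.abs(f_ana).max()), 1.0)

    def potential():
        return sim.compute_forces().potential

    max_f_err = 0.0
    for i in sites:
        for ax in range(3):
            orig = st.pos[i, ax]
            st.pos[i, ax] = orig + h
            ep = potential()
            st.pos[i, ax] = orig - h
            em = potential()
            st.pos[i, ax] = orig
            f_num = -(ep - em) / (2 * h)
            max_f_err = max(max_f_err,
                            abs(f_num - f_ana[i, ax]) / scale_f)

    # torques: rotate each probed dipole about two axes orthogonal to u
    max_t_err = 0.0
    dip_sites = [i for i in sites if sim.is_dip[i]]
    scale_t = max(float(np.abs(t_ana).max()), 1.0)
    for i in dip_sites:
        u0 = st.u[i].copy()
        ref = np.array([1.0, 0.0, 0.0])
        if abs(u0 @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(u0, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u0, e1)
        for axis in (e1, e2):
            for sgn_t in (1.0,):
                c, s = np.cos(h), np.sin(h)
                def rot(th_s, th_c):
                    # Rodrigues rotation of u0 about `axis`
                    return (u0 * th_c + np.cross(axis, u0) * th_s
                            + axis * (axis @ u0) * (1 - th_c))
                st.u[i] = rot(s, c)
                ep = potential()
                st.u[i] = rot(-s, c)
                em = potential()
                st.u[i] = u0
                t_num = -(ep - em) / (2 * h)
                t_ana_axis = float(t_ana[i] @ axis)
                max_t_err = max(max_t_err,
                                abs(t_num - t_ana_axis) / scale_t)
    sim.compute_forces()
    eng = sim.report.potential
    oracle = brute_force_energy(st, sim.ff)["potential"]
    mismatch = abs(eng - oracle) / max(abs(oracle), 1.0)
    return OracleReport(max_force_error=max_f_err,
                        max_torque_error=max_t_err,
                        energy_mismatch=mismatch, tolerance=tolerance)


# ---------------------------------------------------------------------------
# synthetic profiles with closed-form observables
# ---------------------------------------------------------------------------

def synthetic_profile(kind: str, nslab: int = 200, lz: float = 10.0,
                      **params):
    """Slab arrays with known closed-form moments/potentials.

    kinds: ``zero``, ``constant`` (value, halfwidth), ``delta_pair``
    (weight, z1), ``capacitor`` (sigma_q, d), ``dipole_layer`` (areal_p,
    z1, width).  Returns ``(z_centres, values)`` with z centred on lz/2.
    """
    dz = lz / nslab
    z = (np.arange(nslab) + 0.5) * dz
    zc = z - lz / 2.0
    v = np.zeros(nslab)
    if kind == "zero":
        pass
    elif kind == "constant":
        hw = params.get("halfwidth", lz / 4)
        v[np.abs(zc) <= hw] = params.get("value", 1.0)
    elif kind == "delta_pair":
        w = params.get("weight", 1.0)
        z1 = params.get("z1", lz / 5)
        for target in (z1, -z1):
            i = int(np.argmin(np.abs(zc - target)))
            v[i] = w / dz
    elif kind == "capacitor":
        sq = params.get("sigma_q", 0.1)
        d = params.get("d", lz / 5)
        for target, sgn in ((-d, 1.0), (d, -1.0)):
            i = int(np.argmin(np.abs(zc - target)))
            v[i] = sgn * sq / dz
    elif kind == "dipole_layer":
        p = params.get("areal_p", 0.05)
        z1 = params.get("z1", 0.0)
        width = params.get("width", 5 * dz)
        mask = np.abs(zc - z1) <= width / 2
        v[mask] = p / (mask.sum() * dz)
    else:
        raise ValueError(f"unknown synthetic profile kind {kind!r}")
    return zc, v
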