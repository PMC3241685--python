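"""Molecular-dynamics propagation.

The engine advances translational and rotational (point-dipole) degrees of
freedom with a velocity-Verlet splitting: dipoles are linear rotors
represented by a unit axis and an angular velocity kept perpendicular to it,
rotated exactly about the instantaneous angular-velocity axis during the
drift substep.  Temperature and pressure are regulated by Berendsen
weak-coupling, with lipid and water groups (and translational/rotational
motion) coupled independently; pressure coupling supports isotropic,
semi-isotropic (membrane) and fully anisotropic box scaling.

Nonbonded interactions run over a Verlet pair list with per-pair cutoffs
(0.9 nm water-water, 1.2 nm otherwise), excluding directly bonded (1-2)
pairs.  The pair list is rebuilt on a maximum-displacement criterion.  The
virial is accumulated both as a full tensor (for the barostat) and per slab
along z with the Harasima convention (half of each pair's contribution to the
slab of each partner) to support lateral-pressure-profile analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .units import ATM_PER_KJMOLNM3, KB, KE
from .forcefield import ForceField
from .topology import SystemState, make_template

__all__ = ["SimConfig", "EnergyReport", "Simulation", "neighbor_list"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Run-control parameters (defaults follow the force field's protocol)."""
    dt: float = 0.015            # ps (15 fs)
    temperature: float = 303.0   # K
    tau_t: float = 1.0           # ps, thermostat time constant
    thermostat: bool = True
    pressure: float = 1.0        # atm
    tau_p: float = 5.0           # ps
    kappa: float = 4.6e-5        # 1/atm, isothermal compressibility
    barostat: str = "none"       # none | iso | semi | aniso
    skin: float = 0.2            # nm, pair-list skin
    remove_com: bool = True
    remove_leaflet_drift: bool = False
    nslab: int = 0               # per-slab virial accumulation (0 = off)
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0 or self.tau_t <= 0 or self.tau_p <= 0:
            raise ValueError("dt and coupling constants must be > 0")
        if self.barostat not in ("none", "iso", "semi", "aniso"):
            raise ValueError(f"unknown barostat mode {self.barostat!r}")


@dataclass
class EnergyReport:
    """Per-term potential energies, kinetic energies and pressure tensor."""
    lj: float = 0.0
    coulomb: float = 0.0
    charge_dipole: float = 0.0
    dipole_dipole: float = 0.0
    bond: float = 0.0
    angle: float = 0.0
    restraint: float = 0.0
    kinetic_trans: float = 0.0
    kinetic_rot: float = 0.0
    pressure_tensor: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))

    @property
    def potential(self) -> float:
        return (self.lj + self.coulomb + self.charge_dipole
                + self.dipole_dipole + self.bond + self.angle + self.restraint)

    @property
    def total(self) -> float:
        return self.potential + self.kinetic_trans + self.kinetic_rot

    @property
    def pressure(self) -> float:
        """Scalar pressure (atm)."""
        return float(np.trace(self.pressure_tensor)) / 3.0


# ---------------------------------------------------------------------------
# compiled kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _pair_scan(pos, box, typ, rlist2, excl, pi, pj, fill):
    n = pos.shape[0]
    cnt = 0
    for i in range(n - 1):
        ti = typ[i]
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box[0] * np.rint(dx / box[0])
            dy -= box[1] * np.rint(dy / box[1])
            dz -= box[2] * np.rint(dz / box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rlist2[ti, typ[j]]:
                skip = False
                for k in range(excl.shape[1]):
                    if excl[i, k] == j:
                        skip = True
                        break
                if not skip:
                    if fill:
                        pi[cnt] = i
                        pj[cnt] = j
                    cnt += 1
    return cnt


@njit(cache=True)
def _nonbonded_kernel(pos, box, typ, chg, mumag, u, pi, pj, sigma, eps,
                      rcut, rsw, F, TQ, eterms, W, slab_lat, slab_nrm):
    nslab = slab_lat.shape[0]
    min_r2 = 1.0e30
    for p in range(pi.shape[0]):
        i = pi[p]
        j = pj[p]
        ti = typ[i]
        tj = typ[j]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        rc = rcut[ti, tj]
        if r2 >= rc * rc:
            continue
        if r2 < min_r2:
            min_r2 = r2
        r = np.sqrt(r2)
        inv_r = 1.0 / r
        fx = 0.0
        fy = 0.0
        fz = 0.0
        # --- shifted-force Lennard-Jones ---
        sr2 = (sigma[ti, tj] * inv_r) ** 2
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        src2 = (sigma[ti, tj] / rc) ** 2
        src6 = src2 * src2 * src2
        src12 = src6 * src6
        quad = 6.0 * src12 - 3.0 * src6
        e4 = 4.0 * eps[ti, tj]
        eterms[0] += e4 * (sr12 - sr6 + quad * (r / rc) ** 2
                           - 7.0 * src12 + 4.0 * src6)
        fr = e4 * (12.0 * sr12 - 6.0 * sr6 - 2.0 * quad * r2 / (rc * rc)) / r2
        fx += fr * dx
        fy += fr * dy
        fz += fr * dz
        qi = chg[ti]
        qj = chg[tj]
        di = mumag[ti] > 0.0
        dj = mumag[tj] > 0.0
        # --- shifted-force Coulomb ---
        if qi != 0.0 and qj != 0.0:
            pref = KE * qi * qj
            eterms[1] += pref * (inv_r - 1.0 / rc + (r - rc) / (rc * rc))
            fr = pref * (inv_r * inv_r - 1.0 / (rc * rc)) * inv_r
            fx += fr * dx
            fy += fr * dy
            fz += fr * dz
        # --- shifted-force charge-dipole ---
        if (qi != 0.0 and dj) or (qj != 0.0 and di):
            g = inv_r * inv_r - 3.0 / (rc * rc) + 2.0 * r / rc ** 3
            gp = -2.0 * inv_r ** 3 + 2.0 / rc ** 3
            h = g * inv_r
            hp = gp * inv_r - g * inv_r * inv_r
            if qi != 0.0 and dj:
                # r_vec from dipole j to charge i is (dx,dy,dz)
                mx = mumag[tj] * u[j, 0]
                my = mumag[tj] * u[j, 1]
                mz = mumag[tj] * u[j, 2]
                mur = mx * dx + my * dy + mz * dz
                eterms[2] += KE * qi * mur * inv_r * g
                c1 = KE * qi
                gfx = c1 * (mx * h + mur * hp * dx * inv_r)
                gfy = c1 * (my * h + mur * hp * dy * inv_r)
                gfz = c1 * (mz * h + mur * hp * dz * inv_r)
                fx -= gfx
                fy -= gfy
                fz -= gfz
                # torque on dipole j: mu x E, E = -KE q g rhat
                ex = -c1 * g * dx * inv_r
                ey = -c1 * g * dy * inv_r
                ez = -c1 * g * dz * inv_r
                TQ[j, 0] += my * ez - mz * ey
                TQ[j, 1] += mz * ex - mx * ez
                TQ[j, 2] += mx * ey - my * ex
            if qj != 0.0 and di:
                # r_vec from dipole i to charge j is -(dx,dy,dz)
                mx = mumag[ti] * u[i, 0]
                my = mumag[ti] * u[i, 1]
                mz = mumag[ti] * u[i, 2]
                mur = -(mx * dx + my * dy + mz * dz)
                eterms[2] += KE * qj * mur * inv_r * g
                c1 = KE * qj
                # force on charge j along -rhat convention; accumulate on i
                gfx = c1 * (mx * h - mur * hp * dx * inv_r)
                gfy = c1 * (my * h - mur * hp * dy * inv_r)
                gfz = c1 * (mz * h - mur * hp * dz * inv_r)
                fx += gfx
                fy += gfy
                fz += gfz
                ex = c1 * g * dx * inv_r
                ey = c1 * g * dy * inv_r
                ez = c1 * g * dz * inv_r
                TQ[i, 0] += my * ez - mz * ey
                TQ[i, 1] += mz * ex - mx * ez
                TQ[i, 2] += mx * ey - my * ex
        # --- switched dipole-dipole ---
        if di and dj:
            rs = rsw[ti, tj]
            if r <= rs:
                s = 1.0
                sp = 0.0
            else:
                t = (r - rs) / (rc - rs)
                s = 1.0 - 3.0 * t * t + 2.0 * t ** 3
                sp = (-6.0 * t + 6.0 * t * t) / (rc - rs)
            mix = mumag[ti]
            mjx = mumag[tj]
            uix = mix * u[i, 0]
            uiy = mix * u[i, 1]
            uiz = mix * u[i, 2]
            ujx = mjx * u[j, 0]
            ujy = mjx * u[j, 1]
            ujz = mjx * u[j, 2]
            hx = dx * inv_r
            hy = dy * inv_r
            hz = dz * inv_r
            a1 = uix * ujx + uiy * ujy + uiz * ujz
            a2 = uix * hx + uiy * hy + uiz * hz
            a3 = ujx * hx + ujy * hy + ujz * hz
            inv_r3 = inv_r * inv_r * inv_r
            u0 = KE * (a1 - 3.0 * a2 * a3) * inv_r3
            eterms[3] += u0 * s
            c3 = 3.0 * KE * inv_r3 * inv_r
            ffx = c3 * ((a1 - 5.0 * a2 * a3) * hx + a3 * uix + a2 * ujx)
            ffy = c3 * ((a1 - 5.0 * a2 * a3) * hy + a3 * uiy + a2 * ujy)
            ffz = c3 * ((a1 - 5.0 * a2 * a3) * hz + a3 * uiz + a2 * ujz)
            fx += ffx * s - u0 * sp * hx
            fy += ffy * s - u0 * sp * hy
            fz += ffz * s - u0 * sp * hz
            cs = KE * inv_r3 * s
            eix = cs * (3.0 * a3 * hx - ujx)
            eiy = cs * (3.0 * a3 * hy - ujy)
            eiz = cs * (3.0 * a3 * hz - ujz)
            TQ[i, 0] += uiy * eiz - uiz * eiy
            TQ[i, 1] += uiz * eix - uix * eiz
            TQ[i, 2] += uix * eiy - uiy * eix
            ejx = cs * (3.0 * a2 * hx - uix)
            ejy = cs * (3.0 * a2 * hy - uiy)
            ejz = cs * (3.0 * a2 * hz - uiz)
            TQ[j, 0] += ujy * ejz - ujz * ejy
            TQ[j, 1] += ujz * ejx - ujx * ejz
            TQ[j, 2] += ujx * ejy - ujy * ejx
        # --- accumulate ---
        F[i, 0] += fx
        F[i, 1] += fy
        F[i, 2] += fz
        F[j, 0] -= fx
        F[j, 1] -= fy
        F[j, 2] -= fz
        W[0, 0] += dx * fx
        W[0, 1] += dx * fy
        W[0, 2] += dx * fz
        W[1, 0] += dy * fx
        W[1, 1] += dy * fy
        W[1, 2] += dy * fz
        W[2, 0] += dz * fx
        W[2, 1] += dz * fy
        W[2, 2] += dz * fz
        if nslab > 0:
            wl = 0.5 * (dx * fx + dy * fy)
            wn = dz * fz
            si = int(pos[i, 2] / box[2] * nslab) % nslab
            sj = int(pos[j, 2] / box[2] * nslab) % nslab
            slab_lat[si] += 0.5 * wl
            slab_lat[sj] += 0.5 * wl
            slab_nrm[si] += 0.5 * wn
            slab_nrm[sj] += 0.5 * wn
    return min_r2


@njit(cache=True)
def _bonded_kernel(pos, box, u, mumag, typ,
                   bond_ij, kb, r0, ang_ijk, ka, th0, angle_form,
                   res_idx, kd, F, TQ, eterms, W, slab_lat, slab_nrm):
    nslab = slab_lat.shape[0]
    # bonds
    for b in range(bond_ij.shape[0]):
        i = bond_ij[b, 0]
        j = bond_ij[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0[b]
        eterms[4] += 0.5 * kb[b] * dr * dr
        fr = -kb[b] * dr / r
        fx = fr * dx
        fy = fr * dy
        fz = fr * dz
        F[i, 0] += fx
        F[i, 1] += fy
        F[i, 2] += fz
        F[j, 0] -= fx
        F[j, 1] -= fy
        F[j, 2] -= fz
        W[0, 0] += dx * fx
        W[1, 1] += dy * fy
        W[2, 2] += dz * fz
        W[0, 1] += dx * fy
        W[0, 2] += dx * fz
        W[1, 0] += dy * fx
        W[1, 2] += dy * fz
        W[2, 0] += dz * fx
        W[2, 1] += dz * fy
        if nslab > 0:
            wl = 0.5 * (dx * fx + dy * fy)
            wn = dz * fz
            si = int(pos[i, 2] / box[2] * nslab) % nslab
            sj = int(pos[j, 2] / box[2] * nslab) % nslab
            slab_lat[si] += 0.5 * wl
            slab_lat[sj] += 0.5 * wl
            slab_nrm[si] += 0.5 * wn
            slab_nrm[sj] += 0.5 * wn
    # angles (cosine-harmonic, regular at collinearity)
    for a in range(ang_ijk.shape[0]):
        i = ang_ijk[a, 0]
        j = ang_ijk[a, 1]
        k = ang_ijk[a, 2]
        v1x = pos[i, 0] - pos[j, 0]
        v1y = pos[i, 1] - pos[j, 1]
        v1z = pos[i, 2] - pos[j, 2]
        v1x -= box[0] * np.rint(v1x / box[0])
        v1y -= box[1] * np.rint(v1y / box[1])
        v1z -= box[2] * np.rint(v1z / box[2])
        v2x = pos[k, 0] - pos[j, 0]
        v2y = pos[k, 1] - pos[j, 1]
        v2z = pos[k, 2] - pos[j, 2]
        v2x -= box[0] * np.rint(v2x / box[0])
        v2y -= box[1] * np.rint(v2y / box[1])
        v2z -= box[2] * np.rint(v2z / box[2])
        n1 = np.sqrt(v1x * v1x + v1y * v1y + v1z * v1z)
        n2 = np.sqrt(v2x * v2x + v2y * v2y + v2z * v2z)
        c = (v1x * v2x + v1y * v2y + v1z * v2z) / (n1 * n2)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        if angle_form == 1:
            # harmonic in theta; the 1/sin singularity at collinearity
            # cancels against the vanishing gradient of cos(theta)
            th = np.arccos(c)
            dth = th - th0[a]
            eterms[5] += 0.5 * ka[a] * dth * dth
            s_th = np.sqrt(1.0 - c * c)
            if s_th < 1.0e-6:
                s_th = 1.0e-6
            dudc = -ka[a] * dth / s_th
        else:
            dc = c - np.cos(th0[a])
            eterms[5] += 0.5 * ka[a] * dc * dc
            dudc = ka[a] * dc
        fi_x = -dudc * (v2x / (n1 * n2) - c * v1x / (n1 * n1))
        fi_y = -dudc * (v2y / (n1 * n2) - c * v1y / (n1 * n1))
        fi_z = -dudc * (v2z / (n1 * n2) - c * v1z / (n1 * n1))
        fk_x = -dudc * (v1x / (n1 * n2) - c * v2x / (n2 * n2))
        fk_y = -dudc * (v1y / (n1 * n2) - c * v2y / (n2 * n2))
        fk_z = -dudc * (v1z / (n1 * n2) - c * v2z / (n2 * n2))
        F[i, 0] += fi_x
        F[i, 1] += fi_y
        F[i, 2] += fi_z
        F[k, 0] += fk_x
        F[k, 1] += fk_y
        F[k, 2] += fk_z
        F[j, 0] -= fi_x + fk_x
        F[j, 1] -= fi_y + fk_y
        F[j, 2] -= fi_z + fk_z
        W[0, 0] += v1x * fi_x + v2x * fk_x
        W[1, 1] += v1y * fi_y + v2y * fk_y
        W[2, 2] += v1z * fi_z + v2z * fk_z
        W[0, 1] += v1x * fi_y + v2x * fk_y
        W[0, 2] += v1x * fi_z + v2x * fk_z
        W[1, 0] += v1y * fi_x + v2y * fk_x
        W[1, 2] += v1y * fi_z + v2y * fk_z
        W[2, 0] += v1z * fi_x + v2z * fk_x
        W[2, 1] += v1z * fi_y + v2z * fk_y
        if nslab > 0:
            sj = int(pos[j, 2] / box[2] * nslab) % nslab
            si = int(pos[i, 2] / box[2] * nslab) % nslab
            sk = int(pos[k, 2] / box[2] * nslab) % nslab
            wl1 = 0.5 * (v1x * fi_x + v1y * fi_y)
            wl2 = 0.5 * (v2x * fk_x + v2y * fk_y)
            slab_lat[si] += 0.5 * wl1
            slab_lat[sj] += 0.5 * (wl1 + wl2)
            slab_lat[sk] += 0.5 * wl2
            slab_nrm[si] += 0.5 * v1z * fi_z
            slab_nrm[sj] += 0.5 * (v1z * fi_z + v2z * fk_z)
            slab_nrm[sk] += 0.5 * v2z * fk_z
    # dipole orientation restraints
    for rr in range(res_idx.shape[0]):
        d = res_idx[rr, 0]
        ia = res_idx[rr, 1]
        ib = res_idx[rr, 2]
        bx = pos[ib, 0] - pos[ia, 0]
        by = pos[ib, 1] - pos[ia, 1]
        bz = pos[ib, 2] - pos[ia, 2]
        bx -= box[0] * np.rint(bx / box[0])
        by -= box[1] * np.rint(by / box[1])
        bz -= box[2] * np.rint(bz / box[2])
        nb = np.sqrt(bx * bx + by * by + bz * bz)
        hx = bx / nb
        hy = by / nb
        hz = bz / nb
        ux = u[d, 0]
        uy = u[d, 1]
        uz = u[d, 2]
        cosd = ux * hx + uy * hy + uz * hz
        eterms[6] += kd[rr] * (1.0 - cosd)
        TQ[d, 0] += kd[rr] * (uy * hz - uz * hy)
        TQ[d, 1] += kd[rr] * (uz * hx - ux * hz)
        TQ[d, 2] += kd[rr] * (ux * hy - uy * hx)
        fbx = kd[rr] * (ux - cosd * hx) / nb
        fby = kd[rr] * (uy - cosd * hy) / nb
        fbz = kd[rr] * (uz - cosd * hz) / nb
        F[ib, 0] += fbx
        F[ib, 1] += fby
        F[ib, 2] += fbz
        F[ia, 0] -= fbx
        F[ia, 1] -= fby
        F[ia, 2] -= fbz
        W[0, 0] += bx * fbx
        W[1, 1] += by * fby
        W[2, 2] += bz * fbz
        W[0, 1] += bx * fby
        W[0, 2] += bx * fbz
        W[1, 0] += by * fbx
        W[1, 2] += by * fbz
        W[2, 0] += bz * fbx
        W[2, 1] += bz * fby
        if nslab > 0:
            sa = int(pos[ia, 2] / box[2] * nslab) % nslab
            sb = int(pos[ib, 2] / box[2] * nslab) % nslab
            wl = 0.5 * (bx * fbx + by * fby)
            wn = bz * fbz
            slab_lat[sa] += 0.5 * wl
            slab_lat[sb] += 0.5 * wl
            slab_nrm[sa] += 0.5 * wn
            slab_nrm[sb] += 0.5 * wn


@njit(cache=True)
def _rotate_axes(u, omega, dt):
    """Rotate each unit axis about its angular-velocity vector (exact,
    norm-preserving Rodrigues rotation)."""
    for i in range(u.shape[0]):
        wx = omega[i, 0]
        wy = omega[i, 1]
        wz = omega[i, 2]
        w = np.sqrt(wx * wx + wy * wy + wz * wz)
        if w < 1.0e-14:
            continue
        ax = wx / w
        ay = wy / w
        az = wz / w
        th = w * dt
        c = np.cos(th)
        s = np.sin(th)
        ux = u[i, 0]
        uy = u[i, 1]
        uz = u[i, 2]
        dot = ax * ux + ay * uy + az * uz
        rx = ux * c + (ay * uz - az * uy) * s + ax * dot * (1.0 - c)
        ry = uy * c + (az * ux - ax * uz) * s + ay * dot * (1.0 - c)
        rz = uz * c + (ax * uy - ay * ux) * s + az * dot * (1.0 - c)
        norm = np.sqrt(rx * rx + ry * ry + rz * rz)
        u[i, 0] = rx / norm
        u[i, 1] = ry / norm
        u[i, 2] = rz / norm


# ---------------------------------------------------------------------------
# neighbour list (public, with brute-force-checkable contract)
# ---------------------------------------------------------------------------

def neighbor_list(state: SystemState, rcut_table: np.ndarray, skin: float,
                  exclusions: np.ndarray):
    """All pairs within ``cutoff + skin`` under minimum image, minus 1-2
    bonded exclusions.  Returns ``(i_array, j_array)`` with i < j."""
    present = np.unique(state.typ)
    rc_max = rcut_table[np.ix_(present, present)].max()
    if np.any(state.box <= 2.0 * (rc_max + skin)):
        raise ValueError("box too small for cutoff + skin under minimum image")
    rlist2 = (rcut_table + skin) ** 2
    dummy = np.empty(0, np.int64)
    n = _pair_scan(state.pos, state.box, state.typ, rlist2, exclusions,
                   dummy, dummy, False)
    pi = np.empty(n, np.int64)
    pj = np.empty(n, np.int64)
    _pair_scan(state.pos, state.box, state.typ, rlist2, exclusions,
               pi, pj, True)
    return pi, pj


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------

class Simulation:
    """Owns a state, its flattened topology and the propagation loop."""

    def __init__(self, state: SystemState, ff: ForceField, cfg: SimConfig):
        self.state = state
        self.ff = ff
        self.cfg = cfg
        tab = ff.tables()
        self.sigma = tab["sigma"]
        self.eps = tab["epsilon"]
        self.rcut = tab["rcut"]
        self.rsw = tab["rswitch"]
        self.chg = tab["charge"]
        self.mumag = tab["mu"]
        self.mass_t = tab["mass"]
        self.inertia_t = tab["inertia"]
        self.mass = self.mass_t[state.typ]
        self.inertia = self.inertia_t[state.typ]
        self.is_dip = self.mumag[state.typ] > 0
        self._flatten_topology()
        self._pairs = None
        self._pos_at_build = None
        self.forces = np.zeros_like(state.pos)
        self.torques = np.zeros_like(state.pos)
        self.report = EnergyReport()
        n = cfg.nslab
        self.slab_lat = np.zeros(max(n, 0))
        self.slab_nrm = np.zeros(max(n, 0))

    # -- topology flattening ------------------------------------------------
    def _flatten_topology(self):
        st = self.state
        templates = {s: make_template(s, self.ff)
                     for s in set(st.mol_species)}
        self.templates = templates
        bonds, kb, r0 = [], [], []
        angles, ka, th0 = [], [], []
        res, kd = [], []
        offset = 0
        for sp in st.mol_species:
            tpl = templates[sp]
            for i, j, bp in tpl.bonds:
                bonds.append((offset + i, offset + j))
                kb.append(bp.k_b)
                r0.append(bp.r0)
            for i, j, k, ap in tpl.angles:
                angles.append((offset + i, offset + j, offset + k))
                ka.append(ap.k_a)
                th0.append(np.radians(ap.theta0))
            for rp in tpl.restraints:
                res.append((offset + rp.dipole_site, offset + rp.ref_from,
                            offset + rp.ref_to))
                kd.append(rp.k_d)
            offset += tpl.n_sites
        if offset != st.n_sites:
            raise ValueError("molecule templates do not tile the system")
        self.bond_ij = np.array(bonds, np.int64).reshape(-1, 2)
        self.kb = np.array(kb)
        self.r0 = np.array(r0)
        self.ang_ijk = np.array(angles, np.int64).reshape(-1, 3)
        self.ka = np.array(ka)
        self.th0 = np.array(th0)
        self.angle_form = 1 if self.ff.angle_form == "harmonic_theta" else 0
        self.res_idx = np.array(res, np.int64).reshape(-1, 3)
        self.kd = np.array(kd)
        # 1-2 exclusions as a fixed-width neighbour table
        max_deg = 4
        excl = np.full((st.n_sites, max_deg), -1, np.int64)
        count = np.zeros(st.n_sites, np.int64)
        for i, j in self.bond_ij:
            excl[i, count[i]] = j
            count[i] += 1
            excl[j, count[j]] = i
            count[j] += 1
        self.exclusions = excl

    # -- pair list ----------------------------------------------------------
    def _ensure_pairs(self):
        st = self.state
        if self._pairs is not None:
            disp = st.pos - self._pos_at_build
            disp -= np.rint(disp / st.box) * st.box
            if np.max(np.sum(disp ** 2, axis=1)) < (0.5 * self.cfg.skin) ** 2 \
                    and \
                    self._box_at_build is not None and \
                    np.allclose(self._box_at_build, st.box):
                return
        self._pairs = neighbor_list(st, self.rcut, self.cfg.skin,
                                    self.exclusions)
        self._pos_at_build = st.pos.copy()
        self._box_at_build = st.box.copy()

    # -- forces -------------------------------------------------------------
    def compute_forces(self) -> EnergyReport:
        st = self.state
        self._ensure_pairs()
        self.forces[:] = 0.0
        self.torques[:] = 0.0
        eterms = np.zeros(7)
        W = np.zeros((3, 3))
        self.slab_lat[:] = 0.0
        self.slab_nrm[:] = 0.0
        pi, pj = self._pairs
        min_r2 = _nonbonded_kernel(
            st.pos, st.box, st.typ, self.chg, self.mumag, st.u, pi, pj,
            self.sigma, self.eps, self.rcut, self.rsw,
            self.forces, self.torques, eterms, W, self.slab_lat,
            self.slab_nrm)
        if min_r2 < 1.0e-12:
            raise RuntimeError(
                f"overlapping sites (r = {np.sqrt(min_r2):.2e} nm); "
                "the configuration is unphysical")
        _bonded_kernel(st.pos, st.box, st.u, self.mumag, st.typ,
                       self.bond_ij, self.kb, self.r0, self.ang_ijk, self.ka,
                       self.th0, self.angle_form, self.res_idx, self.kd,
                       self.forces, self.torques, eterms, W, self.slab_lat,
                       self.slab_nrm)
        rep = EnergyReport(lj=eterms[0], coulomb=eterms[1],
                           charge_dipole=eterms[2], dipole_dipole=eterms[3],
                           bond=eterms[4], angle=eterms[5],
                           restraint=eterms[6])
        self.report = rep
        self._virial = W
        self._refresh_kinetic()
        return rep

    def _refresh_kinetic(self):
        """(Re)compute kinetic energies and the pressure tensor from the
        current velocities.  Called again after the closing velocity kick of
        each step so that logged totals use synchronized velocities (the
        half-kicked ones would bias the reported temperature high)."""
        st = self.state
        rep = self.report
        rep.kinetic_trans = 0.5 * float(np.sum(self.mass *
                                               np.sum(st.vel ** 2, axis=1)))
        rep.kinetic_rot = 0.5 * float(np.sum(self.inertia *
                                             np.sum(st.omega ** 2, axis=1)))
        vol = float(np.prod(st.box))
        kin = (st.vel[:, :, None] * st.vel[:, None, :]
               * self.mass[:, None, None]).sum(axis=0)
        rep.pressure_tensor = (kin + self._virial) / vol * ATM_PER_KJMOLNM3

    # -- temperature bookkeeping --------------------------------------------
    def _groups(self):
        water = self.state.typ == 0
        out = []
        n = self.state.n_sites
        for name, mask in (("water", water), ("lipid", ~water)):
            if mask.any():
                dof_t = 3 * int(mask.sum()) - (3 if mask.all() else 0)
                out.append((name + "_trans", mask, dof_t, False))
                rot = mask & self.is_dip
                if rot.any():
                    out.append((name + "_rot", rot, 2 * int(rot.sum()), True))
        return out

    def temperatures(self) -> dict:
        st = self.state
        out = {}
        for name, mask, dof, rot in self._groups():
            if rot:
                ke = 0.5 * np.sum(self.inertia[mask]
                                  * np.sum(st.omega[mask] ** 2, axis=1))
            else:
                ke = 0.5 * np.sum(self.mass[mask]
                                  * np.sum(st.vel[mask] ** 2, axis=1))
            out[name] = 2.0 * float(ke) / (dof * KB)
        return out

    # -- coupling -----------------------------------------------------------
    def apply_thermostat(self, dt=None):
        """Berendsen weak coupling, each group scaled from its own kinetic
        temperature; lambda = sqrt(1 + dt/tau (T0/T - 1))."""
        dt = dt if dt is not None else self.cfg.dt
        t0 = self.cfg.temperature
        st = self.state
        for name, mask, dof, rot in self._groups():
            vel = st.omega if rot else st.vel
            inert = self.inertia if rot else self.mass
            ke = 0.5 * float(np.sum(inert[mask]
                                    * np.sum(vel[mask] ** 2, axis=1)))
            t_inst = 2.0 * ke / (dof * KB)
            if t_inst <= 0:
                continue
            lam = np.sqrt(max(1.0 + dt / self.cfg.tau_t
                              * (t0 / t_inst - 1.0), 0.0))
            vel[mask] *= min(max(lam, 0.8), 1.25)

    def apply_barostat(self, dt=None):
        """Berendsen weak coupling of the pressure; per-site coordinate
        scaling with mode-dependent box scaling."""
        mode = self.cfg.barostat
        if mode == "none":
            return
        dt = dt if dt is not None else self.cfg.dt
        p = self.report.pressure_tensor
        p0 = self.cfg.pressure
        pref = dt * self.cfg.kappa / (3.0 * self.cfg.tau_p)
        if mode == "iso":
            mu = (1.0 - pref * (p0 - np.trace(p) / 3.0)) ** (1.0 / 3.0)
            factors = np.array([mu, mu, mu])
        elif mode == "semi":
            plat = 0.5 * (p[0, 0] + p[1, 1])
            mul = (1.0 - pref * (p0 - plat)) ** (1.0 / 3.0)
            muz = (1.0 - pref * (p0 - p[2, 2])) ** (1.0 / 3.0)
            factors = np.array([mul, mul, muz])
        else:  # aniso
            factors = (1.0 - pref * (p0 - np.diag(p))) ** (1.0 / 3.0)
        factors = np.clip(factors, 0.98, 1.02)
        self.state.box *= factors
        self.state.pos *= factors[None, :]

    def remove_drift(self):
        """Zero the total momentum; for bilayers additionally zero the mean
        lateral velocity of each leaflet (normal components untouched)."""
        st = self.state
        if self.cfg.remove_com:
            pmean = (self.mass[:, None] * st.vel).sum(axis=0) / self.mass.sum()
            st.vel -= pmean[None, :]
        if self.cfg.remove_leaflet_drift:
            # zero the lateral mean of each leaflet and of the remaining
            # (solvent) group, so the total lateral momentum stays zero too
            for mask in (st.leaflet == 0, st.leaflet == 1, st.leaflet < 0):
                if mask.any():
                    m = self.mass[mask]
                    lat = (m[:, None] * st.vel[mask, :2]).sum(axis=0) / m.sum()
                    st.vel[mask, :2] -= lat[None, :]

    # -- integration --------------------------------------------------------
    def _kick(self, dt2):
        st = self.state
        st.vel += self.forces * (dt2 / self.mass[:, None])
        if self.is_dip.any():
            d = self.is_dip
            st.omega[d] += self.torques[d] * (dt2 / self.inertia[d][:, None])
            # linear-rotor contract: no spin about the dipole axis
            proj = np.sum(st.omega[d] * st.u[d], axis=1, keepdims=True)
            st.omega[d] -= proj * st.u[d]

    def _drift(self, dt):
        st = self.state
        st.pos += st.vel * dt
        shift = np.floor(st.pos / st.box)
        st.image += shift.astype(np.int64)
        st.pos -= shift * st.box
        if self.is_dip.any():
            _rotate_axes(st.u, st.omega, dt)
        st.time += dt

    def step(self, dt=None):
        """One velocity-Verlet step (forces must be current on entry)."""
        dt = dt if dt is not None else self.cfg.dt
        if not np.all(np.isfinite(self.state.pos)):
            raise RuntimeError("non-finite coordinates; simulation unstable")
        self._kick(0.5 * dt)
        self._drift(dt)
        self.compute_forces()
        self._kick(0.5 * dt)
        if self.cfg.thermostat:
            self.apply_thermostat(dt)
        self.remove_drift()
        self._refresh_kinetic()
        self.apply_barostat(dt)

    def run(self, n_steps: int, observers=(), log_stride: int = 0,
            dt=None):
        """Propagate ``n_steps``; observers are ``(stride, callable)`` pairs
        invoked with the simulation after every ``stride`` steps.  Returns the
        energy log as a list of dicts when ``log_stride`` > 0."""
        log = []
        self.compute_forces()
        for istep in range(n_steps):
            self.step(dt)
            if log_stride and (istep + 1) % log_stride == 0:
                rep = self.report
                row = {"time": self.state.time, "lj": rep.lj,
                       "coulomb": rep.coulomb,
                       "charge_dipole": rep.charge_dipole,
                       "dipole_dipole": rep.dipole_dipole,
                       "bond": rep.bond, "angle": rep.angle,
                       "restraint": rep.restraint,
                       "kinetic_trans": rep.kinetic_trans,
                       "kinetic_rot": rep.kinetic_rot,
                       "potential": rep.potential, "total": rep.total,
                       "pressure": rep.pressure,
                       "volume": float(np.prod(self.state.box))}
                row.update(self.temperatures())
                log.append(row)
            for stride, fn in observers:
                if (istep + 1) % stride == 0:
                    fn(self)
        return log

    def relax(self, n_steps: int = 2000, dt_start: float = 1.5e-5,
              dt_end: float = None, max_disp: float = 0.02):
        """Staged start-up relaxation with geometrically ramped timestep and a
        per-step displacement cap, removing initial-lattice strain."""
        dt_end = dt_end or self.cfg.dt
        dts = np.geomspace(dt_start, dt_end, n_steps)
        # no pressure coupling while initial overlaps unwind: the transient
        # virial would drive runaway box scaling
        mode = self.cfg.barostat
        self.cfg.barostat = "none"
        self.compute_forces()
        for dt in dts:
            speed = np.sqrt(np.sum(self.state.vel ** 2, axis=1))
            cap = max_disp / dt
            fast = speed > cap
            if fast.any():
                self.state.vel[fast] *= (cap / speed[fast])[:, None]
            self.step(float(dt))
        self.cfg.barostat = mode
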