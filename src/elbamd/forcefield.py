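"""ELBA interaction potentials, parameter mixing and the parameter file.

The force field represents every particle as a soft (Lennard-Jones) sphere;
water, glycerol and ester sites additionally carry an embedded point dipole,
and the two headgroup sites carry opposite point charges.  All truncated
interactions use shifted-force forms so that both the potential and its first
radial derivative vanish continuously at the cutoff; dipole-dipole
interactions instead use a C1 cubic switching function.  Electrostatics are
evaluated in vacuum (relative dielectric constant of unity).

Every function here is a plain scalar/vector reference implementation; the
simulation engine re-implements the same expressions in compiled kernels and
is validated against these functions (and against finite differences) by the
verification module.

Units: nm, kJ/mol, elementary charges, e*nm for dipole vectors (1 D =
:data:`elbamd.units.DEBYE` e*nm), degrees for angles at the API boundary.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .units import DEBYE, KE

__all__ = [
    "SiteType", "PairParams", "BondParams", "AngleParams", "RestraintParams",
    "ForceField", "load_default", "mix_params", "reference_bond_length",
    "lj_shifted_force", "coulomb_shifted_force", "charge_dipole",
    "dipole_dipole", "bond_energy", "angle_energy", "angle_gradient",
    "dipole_restraint", "cubic_switch",
]

# canonical site-type ordering used for engine array indices
SITE_ORDER = ("water", "choline", "amine", "phosphate", "glycerol", "ester",
              "tail")


@dataclass(frozen=True)
class SiteType:
    """Per-type nonbonded parameters and atomistic bookkeeping.

    ``dipole_mu`` is in Debye; ``inertia`` must be positive whenever
    ``dipole_mu`` is (a point dipole is a linear rotor and needs a principal
    moment of inertia for its rotational equation of motion).
    """
    name: str
    sigma: float          # nm
    epsilon: float        # kJ/mol
    mass: float           # amu
    charge: float = 0.0   # e
    dipole_mu: float = 0.0  # Debye
    inertia: float = 0.0  # amu nm^2
    electrons: int = 0
    atoms: int = 0

    def __post_init__(self):
        if self.sigma <= 0 or self.epsilon <= 0 or self.mass <= 0:
            raise ValueError(f"{self.name}: sigma, epsilon, mass must be > 0")
        if self.dipole_mu > 0 and self.inertia <= 0:
            raise ValueError(f"{self.name}: dipolar site needs inertia > 0")
        if self.electrons < 0:
            raise ValueError(f"{self.name}: electrons must be >= 0")


@dataclass(frozen=True)
class PairParams:
    """Mixed nonbonded parameters for one type pair."""
    sigma_ij: float       # nm
    epsilon_ij: float     # kJ/mol (hydrogen-bond scaling already applied)
    s_ij: float = 1.0
    cutoff: float = 1.2   # nm
    switch_radius: float = 1.08  # nm, dipole-dipole switching onset

    def __post_init__(self):
        if not (0.0 < self.switch_radius < self.cutoff):
            raise ValueError("need 0 < switch_radius < cutoff")
        if self.s_ij < 1.0:
            raise ValueError("hydrogen-bond scaling must be >= 1")


@dataclass(frozen=True)
class BondParams:
    k_b: float   # kJ/(mol nm^2)
    r0: float    # nm

    def __post_init__(self):
        if self.k_b <= 0 or self.r0 <= 0:
            raise ValueError("k_b and r0 must be > 0")


@dataclass(frozen=True)
class AngleParams:
    k_a: float      # kJ/mol (harmonic_theta: kJ/(mol rad^2))
    theta0: float   # degrees
    form: str = "harmonic_theta"   # or "cosine_harmonic"

    def __post_init__(self):
        if self.k_a <= 0 or not (0.0 < self.theta0 <= 180.0):
            raise ValueError("need k_a > 0 and 0 < theta0 <= 180")
        if self.form not in ("harmonic_theta", "cosine_harmonic"):
            raise ValueError(f"unknown angle form {self.form!r}")


@dataclass(frozen=True)
class RestraintParams:
    k_d: float          # kJ/mol
    dipole_site: int    # index within the molecule template
    ref_from: int       # bond site the reference vector starts at
    ref_to: int         # bond site it points to

    def __post_init__(self):
        if self.k_d <= 0:
            raise ValueError("k_d must be > 0")


# ---------------------------------------------------------------------------
# pair potentials
# ---------------------------------------------------------------------------

def lj_shifted_force(r: float, p: PairParams):
    """Stoddard-Ford shifted-force 12-6 Lennard-Jones.

    Returns ``(energy, radial_force)`` with ``force = -dU/dr``; both vanish
    continuously at the cutoff and are exactly zero beyond it.
    """
    if r <= 0:
        raise ValueError("r must be > 0")
    rc = p.cutoff
    if r >= rc:
        return 0.0, 0.0
    sr6 = (p.sigma_ij / r) ** 6
    sr12 = sr6 * sr6
    src6 = (p.sigma_ij / rc) ** 6
    src12 = src6 * src6
    quad = 6.0 * src12 - 3.0 * src6
    e = 4.0 * p.epsilon_ij * (sr12 - sr6 + quad * (r / rc) ** 2
                              - 7.0 * src12 + 4.0 * src6)
    f = 4.0 * p.epsilon_ij * (12.0 * sr12 / r - 6.0 * sr6 / r
                              - 2.0 * quad * r / rc ** 2)
    return e, f


def coulomb_shifted_force(q_i: float, q_j: float, r: float, p: PairParams):
    """Shifted-force Coulomb interaction between two point charges."""
    if r <= 0:
        raise ValueError("r must be > 0")
    rc = p.cutoff
    if r >= rc or q_i == 0.0 or q_j == 0.0:
        return 0.0, 0.0
    pref = KE * q_i * q_j
    e = pref * (1.0 / r - 1.0 / rc + (r - rc) / rc ** 2)
    f = pref * (1.0 / r ** 2 - 1.0 / rc ** 2)
    return e, f


def _cd_radial(r: float, rc: float):
    """Shifted radial factor g(r) of the charge-dipole interaction and g'(r).

    g replaces the bare 1/r^2 so that both g and g' vanish at the cutoff.
    """
    g = 1.0 / r ** 2 - 3.0 / rc ** 2 + 2.0 * r / rc ** 3
    gp = -2.0 / r ** 3 + 2.0 / rc ** 3
    return g, gp


def charge_dipole(q: float, mu: np.ndarray, r_vec: np.ndarray, p: PairParams):
    """Shifted-force charge - point-dipole interaction.

    ``r_vec`` points from the dipole site to the charge site; ``mu`` is the
    dipole vector in e*nm.  Returns ``(energy, force_on_charge,
    force_on_dipole, torque_on_dipole)``.
    """
    mu = np.asarray(mu, float)
    r_vec = np.asarray(r_vec, float)
    r = float(np.linalg.norm(r_vec))
    if r <= 0:
        raise ValueError("zero separation")
    z3 = np.zeros(3)
    if r >= p.cutoff or q == 0.0:
        return 0.0, z3, z3, z3
    rhat = r_vec / r
    g, gp = _cd_radial(r, p.cutoff)
    mur = float(mu @ rhat)
    e = KE * q * mur * g
    # U = KE q (mu.r_vec) g(r)/r ; grad wrt r_vec of (mu.r_vec) h(r), h=g/r
    h = g / r
    hp = gp / r - g / r ** 2
    f_charge = -KE * q * (mu * h + (mu @ r_vec) * hp * rhat)
    # shifted field of the charge at the dipole site
    efield = -KE * q * g * rhat
    torque = np.cross(mu, efield)
    return e, f_charge, -f_charge, torque


def cubic_switch(r: float, rs: float, rc: float):
    """C1 cubic switch: 1 below ``rs``, 0 at ``rc``, zero slope at both ends.

    Returns ``(S, dS/dr)``.
    """
    if r <= rs:
        return 1.0, 0.0
    if r >= rc:
        return 0.0, 0.0
    t = (r - rs) / (rc - rs)
    s = 1.0 - 3.0 * t * t + 2.0 * t ** 3
    sp = (-6.0 * t + 6.0 * t * t) / (rc - rs)
    return s, sp


def dipole_dipole(r_vec: np.ndarray, mu_i: np.ndarray, mu_j: np.ndarray,
                  p: PairParams):
    """Classical point-dipole pair interaction with a cubic switch.

    ``r_vec = r_i - r_j``; dipole vectors in e*nm.  Returns ``(energy,
    force_on_i, torque_on_i, torque_on_j)``.  The force includes the
    switch-derivative term; the torques are mu x (switched field).
    """
    r_vec = np.asarray(r_vec, float)
    mu_i = np.asarray(mu_i, float)
    mu_j = np.asarray(mu_j, float)
    r = float(np.linalg.norm(r_vec))
    if r <= 0:
        raise ValueError("zero separation")
    z3 = np.zeros(3)
    if r >= p.cutoff:
        return 0.0, z3, z3, z3
    rhat = r_vec / r
    a1 = float(mu_i @ mu_j)
    a2 = float(mu_i @ rhat)
    a3 = float(mu_j @ rhat)
    inv_r3 = 1.0 / r ** 3
    u0 = KE * (a1 - 3.0 * a2 * a3) * inv_r3
    f0 = (3.0 * KE / r ** 4) * ((a1 - 5.0 * a2 * a3) * rhat
                                + a3 * mu_i + a2 * mu_j)
    s, sp = cubic_switch(r, p.switch_radius, p.cutoff)
    e = u0 * s
    force_i = f0 * s - u0 * sp * rhat
    e_at_i = KE * (3.0 * a3 * rhat - mu_j) * inv_r3 * s
    e_at_j = KE * (3.0 * a2 * rhat - mu_i) * inv_r3 * s
    torque_i = np.cross(mu_i, e_at_i)
    torque_j = np.cross(mu_j, e_at_j)
    return e, force_i, torque_i, torque_j


# ---------------------------------------------------------------------------
# bonded terms
# ---------------------------------------------------------------------------

def bond_energy(r: float, b: BondParams):
    """Harmonic bond: U = (k_b/2)(r - r0)^2, radial force -dU/dr."""
    if r <= 0:
        raise ValueError("r must be > 0")
    dr = r - b.r0
    return 0.5 * b.k_b * dr * dr, -b.k_b * dr


def angle_energy(theta: float, a: AngleParams):
    """Bending energy of one angle (``theta`` in degrees).

    ``harmonic_theta``: U = (k_a/2)(theta - theta0)^2 — quadratic stiffness
    everywhere, including at straight (180 deg) reference angles, which a
    cosine-based form loses; this is what keeps solid-ordered (gel) chains
    extended.  ``cosine_harmonic``: U = (k_a/2)(cos t - cos t0)^2.
    Returns ``(energy, dU/dtheta)`` with the derivative per radian.
    """
    th = np.radians(theta)
    th0 = np.radians(a.theta0)
    if a.form == "harmonic_theta":
        return (float(0.5 * a.k_a * (th - th0) ** 2),
                float(a.k_a * (th - th0)))
    c, c0 = np.cos(th), np.cos(th0)
    e = 0.5 * a.k_a * (c - c0) ** 2
    return float(e), float(-a.k_a * (c - c0) * np.sin(th))


def angle_gradient(r_i, r_j, r_k, a: AngleParams):
    """Energy and forces of the angle i-j-k (j is the vertex).

    Returns ``(energy, f_i, f_j, f_k)``.  Uses the cosine-based formulation,
    which needs no division by sin(theta) and is therefore well defined at
    collinear geometries.
    """
    v1 = np.asarray(r_i, float) - np.asarray(r_j, float)
    v2 = np.asarray(r_k, float) - np.asarray(r_j, float)
    n1 = float(np.linalg.norm(v1))
    n2 = float(np.linalg.norm(v2))
    if n1 <= 0 or n2 <= 0:
        raise ValueError("degenerate (zero-length) bond vector in angle")
    c = float(v1 @ v2) / (n1 * n2)
    c = max(-1.0, min(1.0, c))
    th0 = np.radians(a.theta0)
    if a.form == "harmonic_theta":
        th = np.arccos(c)
        # dU/dcos = -k (th - th0)/sin th; the sin cancels against |grad cos|
        s_th = max(np.sqrt(1.0 - c * c), 1e-6)
        dudc = -a.k_a * (th - th0) / s_th
        e = 0.5 * a.k_a * (th - th0) ** 2
    else:
        c0 = np.cos(th0)
        dudc = a.k_a * (c - c0)
        e = 0.5 * a.k_a * (c - c0) ** 2
    dc_di = v2 / (n1 * n2) - c * v1 / n1 ** 2
    dc_dk = v1 / (n1 * n2) - c * v2 / n2 ** 2
    f_i = -dudc * dc_di
    f_k = -dudc * dc_dk
    return float(e), f_i, -(f_i + f_k), f_k


def dipole_restraint(u: np.ndarray, ref_bond: np.ndarray, k_d: float):
    """Orientation restraint U = k_d (1 - cos delta) of a dipole axis.

    ``u`` is the unit dipole axis, ``ref_bond`` the reference bond vector the
    dipole is restrained to lie along.  Returns ``(energy, torque_on_dipole,
    force_on_ref_to, force_on_ref_from)``; the reaction forces act on the two
    sites defining the bond and close both linear and angular momentum.
    """
    u = np.asarray(u, float)
    b = np.asarray(ref_bond, float)
    nb = float(np.linalg.norm(b))
    if nb <= 0:
        raise ValueError("zero reference bond vector")
    bhat = b / nb
    cosd = float(u @ bhat)
    e = k_d * (1.0 - cosd)
    torque = k_d * np.cross(u, bhat)
    f_to = k_d * (u - cosd * bhat) / nb
    return e, torque, f_to, -f_to


# ---------------------------------------------------------------------------
# mixing rules
# ---------------------------------------------------------------------------

def reference_bond_length(t_i: SiteType, t_j: SiteType) -> float:
    """Reference bond length from the Lennard-Jones diameters of the two
    bonded sites (arithmetic mean)."""
    return 0.5 * (t_i.sigma + t_j.sigma)


def mix_params(t_i: SiteType, t_j: SiteType, hb_table=None, *,
               cutoff: float = 1.2, switch_fraction: float = 0.9
               ) -> PairParams:
    """Lorentz-Berthelot mixing with hydrogen-bond epsilon scaling.

    sigma by arithmetic mean, epsilon by geometric mean multiplied by the
    pair's s_ij (1 unless the pair is listed as hydrogen-bonding).
    Symmetric in (i, j).
    """
    hb_table = hb_table or {}
    s = float(hb_table.get(frozenset((t_i.name, t_j.name)), 1.0))
    return PairParams(
        sigma_ij=0.5 * (t_i.sigma + t_j.sigma),
        epsilon_ij=s * float(np.sqrt(t_i.epsilon * t_j.epsilon)),
        s_ij=s,
        cutoff=cutoff,
        switch_radius=switch_fraction * cutoff,
    )


# ---------------------------------------------------------------------------
# parameter file
# ---------------------------------------------------------------------------

@dataclass
class ForceField:
    """A parsed force-field parameter set.

    All numeric values live in the plain-text parameter file (see
    ``elbamd/data/elba.ff``); this class only holds and mixes them.
    """
    sites: dict = field(default_factory=dict)
    hbond: dict = field(default_factory=dict)
    k_bond: float = 0.0
    k_angle: float = 0.0
    k_restraint: float = 0.0
    angle_form: str = "harmonic_theta"
    theta_saturated: float = 180.0
    theta_unsaturated: float = 120.0
    theta_backbone: float = 120.0
    theta_head: float = 90.0
    cutoff_ww: float = 0.9
    cutoff_general: float = 1.2
    switch_fraction: float = 0.9
    checksum: str = ""

    # -- parsing ------------------------------------------------------------
    @classmethod
    def from_file(cls, path=None) -> "ForceField":
        if path is None:
            text = (resources.files("elbamd") / "data/elba.ff").read_text()
        else:
            text = Path(path).read_text()
        ff = cls(checksum=hashlib.sha256(text.encode()).hexdigest()[:16])
        section = None
        scalars = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("["):
                section = line.strip("[]")
                continue
            parts = line.split()
            if section == "sites":
                name, sig, eps, m, q, mu, inert, ne, na = parts
                ff.sites[name] = SiteType(
                    name=name, sigma=float(sig), epsilon=float(eps),
                    mass=float(m), charge=float(q), dipole_mu=float(mu),
                    inertia=float(inert), electrons=int(ne), atoms=int(na))
            elif section == "hbond_scaling":
                a, b, s = parts
                ff.hbond[frozenset((a, b))] = float(s)
            elif parts[0] == "angle_form":
                ff.angle_form = parts[1]
            else:
                scalars[parts[0]] = float(parts[1])
        ff.k_bond = scalars["k_bond"]
        ff.k_angle = scalars["k_angle"]
        ff.k_restraint = scalars["k_restraint"]
        ff.theta_saturated = scalars["theta_saturated"]
        ff.theta_unsaturated = scalars["theta_unsaturated"]
        ff.theta_backbone = scalars["theta_backbone"]
        ff.theta_head = scalars.get("theta_head", 90.0)
        ff.cutoff_ww = scalars["cutoff_water_water"]
        ff.cutoff_general = scalars["cutoff_general"]
        ff.switch_fraction = scalars["switch_fraction"]
        for s in ff.hbond.values():
            if s < 1.0:
                raise ValueError("hydrogen-bond scaling must be >= 1")
        return ff

    # -- lookups ------------------------------------------------------------
    def site(self, name: str) -> SiteType:
        try:
            return self.sites[name]
        except KeyError:
            raise KeyError(f"unknown site type {name!r}") from None

    def pair_cutoff(self, name_i: str, name_j: str) -> float:
        if name_i == "water" and name_j == "water":
            return self.cutoff_ww
        return self.cutoff_general

    def pair(self, name_i: str, name_j: str) -> PairParams:
        return mix_params(self.site(name_i), self.site(name_j), self.hbond,
                          cutoff=self.pair_cutoff(name_i, name_j),
                          switch_fraction=self.switch_fraction)

    # -- engine tables ------------------------------------------------------
    def tables(self):
        """Dense per-type arrays consumed by the compiled engine kernels.

        Returns a dict of numpy arrays indexed by the canonical type order
        (:data:`SITE_ORDER`).  Dipole moments are converted to e*nm.
        """
        nt = len(SITE_ORDER)
        sigma = np.zeros((nt, nt))
        eps = np.zeros((nt, nt))
        rcut = np.zeros((nt, nt))
        rswitch = np.zeros((nt, nt))
        for i, ni in enumerate(SITE_ORDER):
            for j, nj in enumerate(SITE_ORDER):
                p = self.pair(ni, nj)
                sigma[i, j] = p.sigma_ij
                eps[i, j] = p.epsilon_ij
                rcut[i, j] = p.cutoff
                rswitch[i, j] = p.switch_radius
        get = lambda attr: np.array(
            [getattr(self.sites[n], attr) for n in SITE_ORDER], float)
        return {
            "sigma": sigma, "epsilon": eps, "rcut": rcut, "rswitch": rswitch,
            "charge": get("charge"),
            "mu": get("dipole_mu") * DEBYE,
            "mass": get("mass"),
            "inertia": get("inertia"),
            "electrons": get("electrons"),
        }

    def type_index(self, name: str) -> int:
        return SITE_ORDER.index(name)


def load_default() -> ForceField:
    """Load the packaged ELBA parameter file."""
    return ForceField.from_file()
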