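"""Molecule templates and system construction.

Each lipid (DOPC, DSPC, DOPE) is a 15-site molecule: two headgroup sites
carrying opposite point charges, one glycerol and two ester sites carrying
restrained point dipoles, and two five-site hydrocarbon tails.  Water is a
single Lennard-Jones site with an embedded free point dipole.

Site order within a lipid template::

    0 head (choline or amine)   +q
    1 phosphate                 -q
    2 glycerol                  dipole, restrained along bond 2->1
    3 ester (sn-1)              dipole, restrained along bond 3->4
    4-8 tail sites (sn-1)
    9 ester (sn-2)              dipole, restrained along bond 9->10
    10-14 tail sites (sn-2)

Electron and atom counts are assigned per site so that molecular totals match
the parent molecules exactly (DOPC C44H84NO8P: 138 atoms / 434 electrons,
DSPC 438 e-, DOPE 410 e-); the tails are split into consecutive carbon
triplets with their hydrogens.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import KB, GCM3_PER_AMUNM3, WATER_MOLAR_MASS
from .forcefield import (AngleParams, BondParams, ForceField, RestraintParams,
                         SITE_ORDER, reference_bond_length)

__all__ = ["MoleculeTemplate", "BuildSpec", "SystemState", "make_template",
           "build_water_box", "build_bilayer", "build_random_dispersion"]

LIPID_SPECIES = ("DOPC", "DSPC", "DOPE")

# per-site (electrons, atoms) partitions; tails listed top-to-bottom
_HEAD_ELECTRONS = {"choline": (50, 19), "amine": (26, 10)}
_TAIL_ELECTRONS = {
    # oleoyl: cis double bond inside the 3rd/4th triplet
    "unsaturated": [(24, 9), (24, 9), (23, 8), (23, 8), (25, 10)],
    # stearoyl: fully saturated
    "saturated": [(24, 9), (24, 9), (24, 9), (24, 9), (25, 10)],
}
_ESTER_ELECTRONS = (30, 8)
_PHOSPHATE_ELECTRONS = (47, 5)
_GLYCEROL_ELECTRONS = (39, 10)


@dataclass
class MoleculeTemplate:
    """Bonded graph plus per-site bookkeeping for one molecular species."""
    species: str
    site_types: list                      # type names, in site order
    type_index: np.ndarray                # canonical type ids
    bonds: list = field(default_factory=list)      # (i, j, BondParams)
    angles: list = field(default_factory=list)     # (i, j, k, AngleParams)
    restraints: list = field(default_factory=list)  # RestraintParams
    electrons: np.ndarray = None
    atoms: np.ndarray = None

    @property
    def n_sites(self) -> int:
        return len(self.site_types)

    @property
    def total_electrons(self) -> int:
        return int(self.electrons.sum())

    @property
    def total_atoms(self) -> int:
        return int(self.atoms.sum())

    def tail_bonds(self):
        """The four bonds along each tail (used for the order parameter)."""
        if self.species == "water":
            return []
        return [(4, 5), (5, 6), (6, 7), (7, 8),
                (10, 11), (11, 12), (12, 13), (13, 14)]


def make_template(species: str, ff: ForceField) -> MoleculeTemplate:
    """Build the molecule template for one species.

    DOPC/DOPE carry the cis-kink reference angle on the tail triplet centred
    on the second tail site of each tail; DSPC is the same molecule with all
    tail angles saturated; DOPE replaces the choline site by the amine type.
    """
    if species == "water":
        t = MoleculeTemplate(
            species="water", site_types=["water"],
            type_index=np.array([SITE_ORDER.index("water")]),
            electrons=np.array([10]), atoms=np.array([3]))
        return t
    if species not in LIPID_SPECIES:
        raise ValueError(f"unknown species {species!r}")

    head = "amine" if species == "DOPE" else "choline"
    sat = "saturated" if species == "DSPC" else "unsaturated"
    types = ([head, "phosphate", "glycerol", "ester"] + ["tail"] * 5
             + ["ester"] + ["tail"] * 5)
    elec = [_HEAD_ELECTRONS[head][0], _PHOSPHATE_ELECTRONS[0],
            _GLYCEROL_ELECTRONS[0]]
    atoms = [_HEAD_ELECTRONS[head][1], _PHOSPHATE_ELECTRONS[1],
             _GLYCEROL_ELECTRONS[1]]
    for _ in range(2):
        elec.append(_ESTER_ELECTRONS[0])
        atoms.append(_ESTER_ELECTRONS[1])
        elec.extend(e for e, _ in _TAIL_ELECTRONS[sat])
        atoms.extend(a for _, a in _TAIL_ELECTRONS[sat])

    tpl = MoleculeTemplate(
        species=species, site_types=types,
        type_index=np.array([SITE_ORDER.index(t) for t in types]),
        electrons=np.array(elec), atoms=np.array(atoms))

    bond_pairs = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7),
                  (7, 8), (2, 9), (9, 10), (10, 11), (11, 12), (12, 13),
                  (13, 14)]
    for i, j in bond_pairs:
        r0 = reference_bond_length(ff.site(types[i]), ff.site(types[j]))
        tpl.bonds.append((i, j, BondParams(k_b=ff.k_bond, r0=r0)))

    # consecutive triplets along the two chains head->tail plus the two
    # phosphate-glycerol-ester branches
    angle_triplets = [(0, 1, 2), (1, 2, 3), (1, 2, 9),
                      (2, 3, 4), (3, 4, 5), (4, 5, 6), (5, 6, 7), (6, 7, 8),
                      (2, 9, 10), (9, 10, 11), (10, 11, 12), (11, 12, 13),
                      (12, 13, 14)]
    kink = {(4, 5, 6), (10, 11, 12)}  # centred on the 2nd tail site
    for trip in angle_triplets:
        if trip in kink and sat == "unsaturated":
            theta0 = ff.theta_unsaturated
        elif trip == (0, 1, 2):
            # headgroup reference ~perpendicular to the backbone keeps the
            # P->N dipole close to the membrane plane
            theta0 = ff.theta_head
        elif set(trip) <= {0, 1, 2, 3, 9}:
            theta0 = ff.theta_backbone
        else:
            theta0 = ff.theta_saturated
        tpl.angles.append((*trip, AngleParams(k_a=ff.k_angle, theta0=theta0,
                                      form=ff.angle_form)))

    # glycerol dipole along glycerol->phosphate; ester dipoles along
    # ester->first tail site of the same chain
    tpl.restraints = [
        RestraintParams(k_d=ff.k_restraint, dipole_site=2, ref_from=2, ref_to=1),
        RestraintParams(k_d=ff.k_restraint, dipole_site=3, ref_from=3, ref_to=4),
        RestraintParams(k_d=ff.k_restraint, dipole_site=9, ref_from=9, ref_to=10),
    ]
    return tpl


@dataclass
class BuildSpec:
    """System-build specification."""
    species: str = "DOPC"
    n_lipids: int = 128
    hydration: float = 33.06        # waters per lipid
    area_per_lipid: float = 0.67    # nm^2, initial lattice target
    temperature: float = 303.0      # K
    water_density: float = 33.3     # bulk water sites per nm^3

    def __post_init__(self):
        if self.n_lipids <= 0 or self.hydration < 0:
            raise ValueError("need n_lipids > 0 and hydration >= 0")


@dataclass
class SystemState:
    """Full dynamic state of a simulated system.

    Positions are wrapped into the orthorhombic box; ``image`` holds the
    periodic image counts so unwrapped trajectories (for diffusion) can be
    reconstructed.  ``u`` holds unit dipole orientations (zero rows for
    non-dipolar sites) and ``omega`` the angular velocities, kept
    perpendicular to ``u`` (linear-rotor contract).
    """
    pos: np.ndarray
    vel: np.ndarray
    u: np.ndarray
    omega: np.ndarray
    typ: np.ndarray          # canonical type index per site
    mol: np.ndarray          # molecule id per site
    leaflet: np.ndarray      # 0/1 for lipid leaflets, -1 otherwise
    box: np.ndarray          # (3,) box lengths, nm
    time: float = 0.0
    mol_species: list = field(default_factory=list)
    image: np.ndarray = None

    def __post_init__(self):
        if self.image is None:
            self.image = np.zeros_like(self.pos, dtype=np.int64)

    @property
    def n_sites(self) -> int:
        return self.pos.shape[0]

    @property
    def n_molecules(self) -> int:
        return len(self.mol_species)

    def unwrapped(self) -> np.ndarray:
        return self.pos + self.image * self.box

    def copy(self) -> "SystemState":
        return SystemState(
            pos=self.pos.copy(), vel=self.vel.copy(), u=self.u.copy(),
            omega=self.omega.copy(), typ=self.typ.copy(), mol=self.mol.copy(),
            leaflet=self.leaflet.copy(), box=self.box.copy(), time=self.time,
            mol_species=list(self.mol_species), image=self.image.copy())


# ---------------------------------------------------------------------------
# velocity / orientation initialisation
# ---------------------------------------------------------------------------

def _maxwell_velocities(masses, T, rng):
    v = rng.standard_normal((len(masses), 3)) * np.sqrt(
        KB * T / masses)[:, None]
    # zero net momentum
    p = (masses[:, None] * v).sum(axis=0) / masses.sum()
    return v - p[None, :]


def _random_units(n, rng):
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _thermal_omegas(u, inertia, T, rng):
    """Angular velocities perpendicular to each axis, two thermal DOF."""
    omega = np.zeros_like(u)
    ok = inertia > 0
    w = rng.standard_normal((ok.sum(), 3)) * np.sqrt(KB * T / inertia[ok])[:, None]
    uu = u[ok]
    w -= (np.sum(w * uu, axis=1, keepdims=True)) * uu
    omega[ok] = w
    return omega


def _finalize(state: SystemState, ff: ForceField, T, rng):
    tab = ff.tables()
    masses = tab["mass"][state.typ]
    state.vel = _maxwell_velocities(masses, T, rng)
    inertia = tab["inertia"][state.typ]
    state.omega = _thermal_omegas(state.u, inertia, T, rng)
    return state


# ---------------------------------------------------------------------------
# straight-chain lipid geometry used by the builders
# ---------------------------------------------------------------------------

def _lipid_offsets(tpl: MoleculeTemplate, ff: ForceField) -> np.ndarray:
    """Site offsets (nm) of an extended lipid with the head at +z and the
    tails pointing toward -z; the two chains are splayed in x."""
    r0 = {(i, j): b.r0 for i, j, b in tpl.bonds}
    r0.update({(j, i): v for (i, j), v in list(r0.items())})
    xyz = np.zeros((15, 3))
    xyz[2] = (0.0, 0.0, 0.0)                      # glycerol
    xyz[1] = (0.0, 0.0, r0[(1, 2)])               # phosphate
    xyz[0] = (0.0, 0.0, xyz[1][2] + r0[(0, 1)])   # head
    for chain, (e, sgn) in enumerate(((3, -1.0), (9, 1.0))):
        dx = 0.16 * sgn
        ze = -np.sqrt(max(r0[(2, e)] ** 2 - dx ** 2, 0.01))
        xyz[e] = (dx, 0.0, ze)
        z = ze
        prev = e
        for k in range(5):
            s = e + 1 + k
            z -= r0[(prev, s)]
            xyz[s] = (dx, 0.0, z)
            prev = s
    return xyz


def _orient_dipoles(tpl, xyz):
    """Unit dipole axes aligned with their reference bonds."""
    u = np.zeros((tpl.n_sites, 3))
    for r in tpl.restraints:
        b = xyz[r.ref_to] - xyz[r.ref_from]
        u[r.dipole_site] = b / np.linalg.norm(b)
    return u


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_water_box(n: int, density_guess: float = 0.996,
                    T: float = 303.0, seed: int = 0,
                    ff: ForceField | None = None) -> SystemState:
    """Cubic lattice of water sites at a requested mass density (g/cm^3)
    with random dipole orientations and Maxwell-Boltzmann velocities."""
    if n < 8:
        raise ValueError("need at least 8 water sites")
    ff = ff or ForceField.from_file()
    rng = np.random.default_rng(seed)
    # each site represents one water molecule; physical density uses the
    # molecular mass, not the site's dynamical mass
    vol = n * WATER_MOLAR_MASS * GCM3_PER_AMUNM3 / density_guess   # nm^3
    L = vol ** (1.0 / 3.0)
    ncell = int(np.ceil(n ** (1.0 / 3.0)))
    a = L / ncell
    grid = [(i, j, k) for i in range(ncell) for j in range(ncell)
            for k in range(ncell)]
    pos = (np.array(grid[:n], float) + 0.5) * a
    wtype = SITE_ORDER.index("water")
    state = SystemState(
        pos=pos, vel=np.zeros((n, 3)), u=_random_units(n, rng),
        omega=np.zeros((n, 3)), typ=np.full(n, wtype),
        mol=np.arange(n), leaflet=np.full(n, -1, np.int8),
        box=np.array([L, L, L]), mol_species=["water"] * n)
    return _finalize(state, ff, T, rng)


def _append_molecule(buffers, tpl, xyz, u0, leaflet):
    pos, uvec, typ, mol, leaf, species = buffers
    mid = len(species)
    pos.append(xyz)
    uvec.append(u0)
    typ.append(tpl.type_index)
    mol.append(np.full(tpl.n_sites, mid))
    leaf.append(np.full(tpl.n_sites, leaflet, np.int8))
    species.append(tpl.species)


def _stack_state(buffers, box) -> SystemState:
    pos, uvec, typ, mol, leaf, species = buffers
    pos = np.concatenate(pos)
    return SystemState(
        pos=pos, vel=np.zeros_like(pos), u=np.concatenate(uvec),
        omega=np.zeros_like(pos), typ=np.concatenate(typ),
        mol=np.concatenate(mol), leaflet=np.concatenate(leaf),
        box=np.asarray(box, float), mol_species=species)


def build_bilayer(spec: BuildSpec, seed: int = 0,
                  ff: ForceField | None = None,
                  disorder: bool = False) -> SystemState:
    """Pre-assembled bilayer: two opposed leaflets on square lattices normal
    to z, tails inward, with water slabs on both sides.

    ``disorder=True`` perturbs lipid placement (random azimuth, tilt and
    in-plane jitter) to provide a disordered, fluid-like starting point.
    """
    if spec.n_lipids % 2:
        raise ValueError("lipid count must be even (two equal leaflets)")
    ff = ff or ForceField.from_file()
    rng = np.random.default_rng(seed)
    tpl = make_template(spec.species, ff)
    wat = make_template("water", ff)
    offs = _lipid_offsets(tpl, ff)
    udip = _orient_dipoles(tpl, offs)

    n_leaf = spec.n_lipids // 2
    area = n_leaf * spec.area_per_lipid
    Lx = Ly = np.sqrt(area)
    m = int(np.ceil(np.sqrt(n_leaf)))
    a = Lx / m
    z_top = offs[:, 2].max()       # head height above glycerol
    z_bot = offs[:, 2].min()       # deepest tail site (negative)
    half = abs(z_bot) + 0.15       # glycerol plane of the upper leaflet
    head_z = half + z_top          # |z| of the outermost head sites

    n_w = int(round(spec.hydration * spec.n_lipids))
    water_thick = (n_w / (spec.water_density * Lx * Ly)) if n_w else 0.0
    Lz = 2.0 * (head_z + 0.3) + water_thick
    zmid = Lz / 2.0

    buffers = ([], [], [], [], [], [])
    for leaflet, zsign in ((0, 1.0), (1, -1.0)):
        for idx in range(n_leaf):
            ix, iy = idx % m, idx // m
            base = np.array([(ix + 0.5) * a, (iy + 0.5) * a,
                             zmid + zsign * half])
            xyz = offs.copy()
            xyz[:, 2] *= zsign
            udz = udip.copy()
            udz[:, 2] *= zsign
            ang = rng.uniform(0, 2 * np.pi)
            c, s = np.cos(ang), np.sin(ang)
            R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
            if disorder:
                tilt = rng.uniform(0, np.radians(40.0))
                ct, st = np.cos(tilt), np.sin(tilt)
                Rt = np.array([[ct, 0, st], [0, 1, 0], [-st, 0, ct]])
                R = R @ Rt
                base[:2] += rng.normal(0, 0.08, 2)
            xyz = xyz @ R.T + base
            udz = udz @ R.T
            xyz += rng.normal(0.0, 0.01, xyz.shape)
            _append_molecule(buffers, tpl, xyz, udz, leaflet)

    # water slabs above and below the bilayer
    if n_w:
        per_slab = [n_w // 2 + n_w % 2, n_w // 2]
        spacing = spec.water_density ** (-1.0 / 3.0)
        nz = max(1, int(np.ceil(water_thick / 2.0 / spacing)))
        nx = int(np.ceil(Lx / spacing))
        placed = 0
        for slab, count in enumerate(per_slab):
            z0 = zmid + head_z + 0.3 if slab == 0 else 0.12
            pts = []
            for k in range(nz + 2):
                for j in range(nx):
                    for i in range(nx):
                        if len(pts) >= count:
                            break
                        pts.append(((i + 0.5) * Lx / nx, (j + 0.5) * Ly / nx,
                                    z0 + (k + 0.5) * spacing))
            if len(pts) < count:
                raise ValueError("water slab does not fit the box")
            for ptn in pts[:count]:
                _append_molecule(buffers, wat, np.array([ptn]),
                                 _random_units(1, rng), -1)
            placed += count

    state = _stack_state(buffers, [Lx, Ly, Lz])
    state.pos %= state.box
    return _finalize(state, ff, spec.temperature, rng)


def build_random_dispersion(spec: BuildSpec, seed: int = 0,
                            ff: ForceField | None = None,
                            overlap_factor: float = 0.8) -> SystemState:
    """Random lipid/water mixture for self-assembly runs.

    Lipids are inserted with random positions and orientations, rejected when
    any site comes within ``overlap_factor * sigma_ij`` of an already placed
    site; water fills the remaining space on a lattice with the same
    minimum-distance criterion.
    """
    ff = ff or ForceField.from_file()
    rng = np.random.default_rng(seed)
    tpl = make_template(spec.species, ff)
    wat = make_template("water", ff)
    tab = ff.tables()
    sig = tab["sigma"]
    # compress the extended conformation along its axis: long rigid rods jam
    # random sequential insertion, and the ramped-timestep relaxation
    # releases the residual bond strain immediately
    offs = _lipid_offsets(tpl, ff)
    offs = offs.copy()
    offs[:, 2] *= 0.55
    udip = _orient_dipoles(tpl, offs)

    n_w = int(round(spec.hydration * spec.n_lipids))
    # generous initial volume: random packing needs slack, and the barostat
    # compresses the box during equilibration anyway
    vol = spec.n_lipids * 2.1 + 1.35 * n_w / spec.water_density
    # the box must comfortably hold an extended lipid in any orientation
    extent = float(offs[:, 2].max() - offs[:, 2].min())
    L = max(vol ** (1.0 / 3.0), extent + 0.6)
    box = np.array([L, L, L])

    placed_pos = np.empty((0, 3))
    placed_typ = np.empty(0, int)

    def clashes(xyz, tidx):
        if placed_pos.shape[0] == 0:
            return False
        for p, t in zip(xyz, tidx):
            d = placed_pos - p
            d -= np.round(d / box) * box
            r2 = (d ** 2).sum(axis=1)
            thr = (overlap_factor * sig[t, placed_typ]) ** 2
            if np.any(r2 < thr):
                return True
        return False

    buffers = ([], [], [], [], [], [])
    for _ in range(spec.n_lipids):
        for _attempt in range(4000):
            # random rotation from a random quaternion
            q = rng.standard_normal(4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            R = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
            xyz = (offs @ R.T + rng.uniform(0, L, 3)) % box
            if not clashes(xyz, tpl.type_index):
                break
        else:
            raise RuntimeError("could not place lipid without overlap")
        _append_molecule(buffers, tpl, xyz, udip @ R.T, -1)
        placed_pos = np.vstack([placed_pos, xyz])
        placed_typ = np.concatenate([placed_typ, tpl.type_index])

    spacing = 0.8 * spec.water_density ** (-1.0 / 3.0)
    ncell = int(np.ceil(L / spacing))
    wtype = SITE_ORDER.index("water")
    n_placed = 0
    for k in range(ncell):
        for j in range(ncell):
            for i in range(ncell):
                if n_placed >= n_w:
                    break
                p = (np.array([i, j, k]) + 0.5) * L / ncell
                if not clashes(p[None, :], np.array([wtype])):
                    _append_molecule(buffers, wat, p[None, :],
                                     _random_units(1, rng), -1)
                    placed_pos = np.vstack([placed_pos, p[None, :]])
                    placed_typ = np.concatenate([placed_typ, [wtype]])
                    n_placed += 1
    if n_placed < n_w:
        raise RuntimeError("could not place all waters without overlap")

    state = _stack_state(buffers, box)
    return _finalize(state, ff, spec.temperature, rng)
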