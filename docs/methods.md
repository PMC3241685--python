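# Methods

`elbamd` implements an electrostatics-based coarse-grain (CG) force field
for lipid membranes together with the molecular-dynamics machinery and the
membrane observables needed to use it.  This note records the model, the
numerical choices, and what the desk-scale validation runs do and do not
demonstrate.

## The model

**Water.** Each water site represents one water molecule as a Stockmayer
particle: a 12-6 Lennard-Jones sphere (σ = 0.30 nm, ε = 1.95 kJ/mol) with an
embedded point dipole of fixed magnitude μ = 2.3 D.  The site's dynamical
mass is 40 amu and its principal moment of inertia 1 amu nm²; these inertial
parameters tune the translational and rotational diffusion of the model and
have no effect on thermodynamic averages, so *physical* mass densities are
reported with the represented molecule's mass (18.015 amu per site).  At the
parametrization state point (303 K, 1 atm) the model is a dense dipolar
liquid at ≈ 33.3 sites/nm³ (0.996 g/cm³).

**Lipids.** DOPC, DSPC and DOPE are 15-site molecules: a 2-site zwitterionic
headgroup (+0.7 e on the choline/amine site, −0.7 e on the phosphate), one
glycerol site and two ester sites carrying restrained point dipoles, and two
5-site hydrocarbon tails (one site per 3 carbons).  DSPC is the DOPC
template with the cis-kink tail reference angle (120°) reset to the
saturated value (180°); backbone reference angles are 120° and the
headgroup (choline–phosphate–glycerol) reference 90°, which lets the P→N
dipole lie close to the membrane plane as observed experimentally.  DOPE
replaces choline with a smaller amine site that reuses the tail
Lennard-Jones size and carries its own hydrogen-bond scalings.  Per-site electron and atom assignments reproduce the parent
molecules exactly (434 e⁻/138 atoms for DOPC, 438 e⁻ for DSPC, 410 e⁻ for
DOPE), which anchors the electron-density profiles.

**Interactions.** All pair interactions are truncated with shifted-force
forms (energy and radial derivative both vanish continuously at the cutoff):
Stoddard–Ford Lennard-Jones, shifted-force Coulomb, and a shifted-force
charge–dipole term whose radial scalar is modified so that both the energy
and its radial derivative vanish at the cutoff while the angular structure
is untouched.  Dipole–dipole interactions use the classical point-dipole
energy multiplied by a C¹ cubic switch, equal to 1 below r_s = 0.9 r_c and 0
at r_c; the force includes the switch-derivative term, and torques are
μ × E with the switched field.  All electrostatics use a relative dielectric
constant of 1.  Cutoffs: 0.9 nm for water–water (all terms), 1.2 nm for
every other pair.  Unlike sigma/epsilon pairs follow Lorentz–Berthelot
mixing, with the mixed epsilon multiplied by a hydrogen-bond factor
s_ij ≥ 1 for the donor–acceptor pairs (water with phosphate/glycerol/ester;
amine with phosphate/glycerol/ester/water).  1–2 bonded pairs are excluded
from nonbonded evaluation; 1–3 pairs interact normally.

**Bonded terms.** Bonds are harmonic, U = (k_b/2)(r − r₀)² with
k_b = 1260 kJ/(mol nm²) and r₀ the arithmetic mean of the two sites'
Lennard-Jones diameters.  Angles default to the angle-harmonic form
U = (k_a/2)(θ − θ₀)², k_a = 30 kJ/mol; a cosine-harmonic alternative
U = (k_a/2)(cos θ − cos θ₀)² is selectable in the parameter file
(`angle_form`).  The angle-harmonic default is deliberate: at straight
reference angles (θ₀ = 180°) the cosine form has a *quartic* minimum — zero
harmonic stiffness — and chains built with it are too floppy to sustain a
solid-ordered (gel) phase; with the angle-harmonic form a 64-lipid DSPC
bilayer at 303 K holds a global tail order of S ≈ 0.7 while melting
correctly at 333 K.  The glycerol and ester dipoles are restrained to their
reference bond directions (glycerol→phosphate; ester→first tail site) by
U = k_d(1 − cos δ), k_d = 10 kJ/mol, a bounded form with restoring torque
∝ sin δ; the reaction forces on the two bond sites close linear and angular
momentum exactly.

**Unverifiable constants.** The parameter file
(`src/elbamd/data/elba.ff`) is the single versioned source of every numeric
constant.  Hydrogen-bond factors (water: phosphate 1.4 > ester 1.3 >
glycerol 1.1; amine: phosphate/ester 1.7 > water 1.4 > glycerol 1.3) follow
the known relative hydrogen-bond strengths from atomistic simulation.  The
glycerol/ester dipole magnitudes (0.5 D / 3.5 D) were calibrated, as this
model family prescribes, against the membrane dipole potential: the
carbonyl-bearing ester layer must dominate the decomposition and make the
hydrocarbon core positive with respect to water despite the residual
potential of the zwitterionic headgroup charge layer.  The dipole–dipole
switch onset 0.9 r_c was confirmed by a sensitivity scan against the water
parametrization target (equation-of-state density).

## Dynamics

Translation uses velocity Verlet.  A point dipole is a linear rotor: it is
represented by a unit axis u and an angular velocity ω kept perpendicular to
u (spin about the axis is unphysical), and integrated by a kick–drift–kick
scheme in which the drift rotates u exactly about the instantaneous ω
(Rodrigues rotation), preserving |u| to round-off.  Quaternions are
deliberately avoided.  The default timestep is 15 fs; NVE total-energy drift
of a 400-site water box is < 10⁻³ (relative) over 10⁴ steps and grows
roughly quadratically in the timestep over 5–20 fs.

Temperature and pressure use Berendsen weak coupling.  Lipid and water
groups are thermostatted separately, and translational and rotational
kinetic energies independently (four groups in a membrane system), each with
τ_T = 1 ps.  The barostat (τ_P = 5 ps, compressibility 4.6×10⁻⁵ atm⁻¹)
scales per-site coordinates and supports isotropic (bulk water),
semi-isotropic (membranes: z from P_zz, the x–y area jointly from
(P_xx+P_yy)/2 with a square interface) and fully anisotropic
(self-assembly) modes.  Per-step scale factors are clamped to [0.98, 1.02],
and pressure coupling is disabled during start-up relaxation — the transient
virial of an unrelaxed lattice would otherwise drive runaway box scaling.
The net system momentum is removed every step; for bilayers the mean
lateral velocity of each leaflet is removed as well (this matters for lipid
diffusion estimates).  Start-up relaxation ramps the timestep geometrically
from 1.5×10⁻⁵ fs-scale values to the production step with a per-step
displacement cap.

Nonbonded interactions run over a Verlet pair list with 0.2 nm skin,
rebuilt when any site has moved more than half the skin; the box must
exceed twice (cutoff + skin) in every direction (minimum image).  The
virial is accumulated as a full tensor (barostat) and per z-slab with the
Harasima convention: half of each pair's lateral and normal virial to the
slab of each partner, three-body (angle) terms split per leg.

## Observables

Profiles share one slab geometry: ~0.1 nm target slab thickness, the count
fixed at setup and the physical thickness recomputed per frame as the box
fluctuates.  Profiles are *not* symmetrized over the monolayers; mid-plane
symmetry is a statistical check.

- **Electron density**: all electrons of the mapped atom group at each
  site's position; the profile integral conserves the total electron count.
  The bilayer thickness D_HH is the distance between the two headgroup
  maxima.
- **Lateral pressure profile**: π(z) = P_T(z) − P_N(z) from kinetic +
  Harasima virial slab sums, in atm.  For a tensionless bilayer ∫π dz ≈ 0.
- **Curvature elastics**: per-monolayer integral moments
  M1 = ∫ z π dz and M2 = ∫ z² π dz with z measured outward from the bilayer
  centre, averaged over the two monolayers.  Monolayer bending modulus
  κ_m = κ_bilayer/2; spontaneous curvature c0 = −M1/κ_m (negative = bends
  toward water); pivotal distance δ = half-distance between the two global
  minima of π(z); Gaussian modulus κ_G = M2 − 2δM1, the second moment about
  the pivotal plane of a tension-free monolayer.  The sign of c0 depends
  jointly on the z-origin and integration direction; the convention here
  (origin at the bilayer centre, z increasing toward water) is exposed via
  the `z0` argument so the opposite convention is one sign flip away.
- **Electrostatic potential**: ψ(z) from −(1/ε₀)[double integral of the
  headgroup charge density − single integral of the z-projected dipole
  density (water + glycerol + ester)], referenced to bulk water;
  Δψ = ψ(core) − ψ(water), with per-species decomposition.
- **Order parameter**: S = ⟨(3cos²θ − 1)/2⟩ of tail bonds against the
  normal, averaged over the four bonds per tail, all lipids, all frames.
- **Structural summary**: A_L = 2⟨L_xL_y⟩/N; V_L = (⟨V⟩ − N_w v_w)/N with
  v_w = 1/33.3 nm³ from the bulk water run; K_A = k_BT⟨A⟩/var(A) (infinite
  variance-free input is flagged, not silently propagated); k_c from the
  polymer-brush relation k_c = K_A (D_HH − h₀)²/24 with h₀ = 1 nm
  (configurable).
- **Lateral diffusion**: 2-D Einstein relation
  D = ⟨Σ|Δr|²⟩/(4Nt) averaged over 26 time origins by default.
- **Permeability**: P = (N_cross/2)/(t·A·Δc) with Δc = 33.4 nm⁻³ and
  crossings counted with hysteresis planes at the mean ester positions
  ± 0.3 nm — a crossing requires passage from one bulk region through the
  core to the other; periodic-boundary jumps between the bulk regions do
  not count.
- **Aggregation diagnostics** (self-assembly): fraction of tail sites in
  the largest periodic distance-linked cluster, and detection of a
  contiguous water-free tail slab along a box axis.

Slab profiles assume a flat bilayer.  Systems beyond ~256 lipids undulate
visibly, which blurs profiles and shrinks projected areas; the analysis
warns in that regime rather than correcting for it (no undulation-corrected
frames, by design).

## Desk-scale validation sizes

All validation runs are sized for a single CPU: bulk water 512 sites
(165 ps NPT production; 300 ps for self-diffusion), NVE conservation 400
sites (10⁴ steps), gel/fluid DSPC 64 lipids at 8 waters/lipid (~150–180 ps
production each; the gel keeps its ordered 303 K start, the fluid state is
produced by melting the same ordered start at 333 K), self-assembly
32 DOPC at 10 waters/lipid (~0.85 ns, anisotropic coupling).  At these sizes
the water equation of state (0.996 ± 0.01 g/cm³) and self-diffusion
(2.6×10⁻⁹ m²/s ± 15%) are quantitative; membrane structure/elasticity/
transport checks are *ordinal only* (gel more ordered, thicker, slower than
fluid; dipole potential positive and ester-dominated; dispersions aggregate
into one lamellar cluster).  Long-timescale quantities — converged areas
and moduli, lateral diffusion coefficients, permeability statistics —
require the orders-of-magnitude longer runs of production studies and are
not asserted quantitatively here.

## Known limitations

- Cutoff electrostatics only (no Ewald/reaction field): intentional for
  this model family; dielectric constants of the bulk water model are not
  measurable in this scheme.
- The synthetic starting configurations (lattice bilayers, random
  dispersions) are idealized; they exercise the physics but not the
  structural diversity of experimentally derived configurations.
- Single-species membranes only; orthorhombic boxes only.
- Berendsen coupling does not sample a rigorous NPT ensemble; fluctuation
  observables (K_A) are computed from it anyway, as is common practice for
  weak coupling with gentle time constants, and should be read as
  approximate at desk scale.
- At the 15 fs production timestep the weak-coupling group temperatures
  settle within about 1% of their targets (discretization of the kinetic
  estimator); quantities with strong temperature dependence inherit a
  corresponding percent-level bias.
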