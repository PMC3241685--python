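# ELBA coarse-grain force field parameter file, version 1.
#
# Units are fixed package-wide: nm, kJ/mol, amu, Debye, elementary charge,
# degrees, amu nm^2 (moments of inertia), ps.
#
# Conventions encoded by this file (flippable here, not in code):
#   bond potential      U = (k_b/2) (r - r0)^2
#   angle potential     set by angle_form below:
#                         harmonic_theta:   U = (k_a/2) (theta - theta0)^2
#                         cosine_harmonic:  U = (k_a/2) (cos th - cos th0)^2
#     (harmonic_theta keeps quadratic stiffness at straight reference
#      angles, which the cosine form loses; needed for solid-ordered
#      gel-phase chains)
#   dipole restraint    U = k_d (1 - cos(delta))
#   reference bond      r0 = (sigma_i + sigma_j) / 2
#   dipole switch       r_s = switch_fraction * r_c
#
# Site types. Columns:
# name      sigma   epsilon  mass   charge  dipole  inertia  electrons  atoms
# (nm)      (kJ/mol) (amu)   (e)    (D)     (amu nm^2)
[sites]
water      0.30    1.95     40.0    0.0     2.3     1.0      10         3
choline    0.52    6.0      90.0    0.7     0.0     0.0      50         19
amine      0.45    1.0      42.0    0.7     0.0     0.0      26         10
phosphate  0.46    4.0      90.0   -0.7     0.0     0.0      47         5
glycerol   0.45    3.5      62.0    0.0     0.5    10.0      39         10
ester      0.45    3.5      62.0    0.0     3.5    10.0      30         8
tail       0.45    1.0      42.0    0.0     0.0     0.0      24         9

# Hydrogen-bond epsilon scaling factors s_ij (dimensionless, >= 1).
# Pairs not listed use s_ij = 1 (plain Lorentz-Berthelot).
[hbond_scaling]
water      phosphate  1.4
water      ester      1.3
water      glycerol   1.1
amine      phosphate  1.7
amine      ester      1.7
amine      glycerol   1.3
amine      water      1.4

# Bonded interaction constants (shared by all bonds / angles / restraints).
[bonded]
k_bond       1260.0     # kJ/(mol nm^2)
k_angle      30.0       # kJ/mol
k_restraint  10.0       # kJ/mol
angle_form   harmonic_theta

# Reference angles (degrees).
[angles]
theta_saturated    180.0
theta_unsaturated  120.0
theta_backbone     120.0
theta_head          90.0

# Nonbonded cutoffs (nm). Water-water interactions use the shorter cutoff;
# every other pair uses the general one.  The dipole-dipole cubic switching
# function starts at switch_fraction * cutoff.
[cutoffs]
cutoff_water_water  0.9
cutoff_general      1.2
switch_fraction     0.9
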