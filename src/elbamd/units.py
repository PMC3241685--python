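"""Physical constants and unit conversions.

Internal unit system (GROMACS-like, self-consistent):

==========  ==============
length      nm
time        ps
mass        amu
energy      kJ/mol
charge      e
velocity    nm/ps
==========  ==============

In this system ``1 amu nm^2 / ps^2 == 1 kJ/mol`` exactly, so no conversion
factor is needed between kinetic and potential energy.  Dipole moments are
given in Debye at the I/O boundary and stored internally as e*nm.
Conversions to reporting units (atm, g/cm^3, dyn/cm, Angstrom^2, V) happen
only in analysis/reporting code.
"""

# Boltzmann constant [kJ/(mol K)]
KB = 8.314462618e-3

# Coulomb prefactor 1/(4 pi eps0) [kJ/mol nm / e^2] (vacuum permittivity,
# relative dielectric constant of unity throughout the force field)
KE = 138.935458

# 1 Debye in e*nm
DEBYE = 0.0208194334

# pressure: 1 kJ/(mol nm^3) in bar and atm
BAR_PER_KJMOLNM3 = 16.6054
ATM_PER_KJMOLNM3 = BAR_PER_KJMOLNM3 / 1.01325

# mass density: amu/nm^3 -> g/cm^3
GCM3_PER_AMUNM3 = 1.66053907e-3

# molar mass of the water molecule each water site represents (amu).
# The site's dynamical mass (40 amu) is an inertial device that does not
# affect thermodynamic averages; physical densities are reported with the
# represented molecule's mass.
WATER_MOLAR_MASS = 18.01528

# electrostatic potential: (e/nm) / eps0 -> Volt.
# eps0 = 8.8541878128e-12 F/m; (1 e / 1 nm) / eps0 = 1.602176634e-19 /
# (8.8541878128e-12 * 1e-9) V
VOLT_PER_E_PER_NM = 18.0951262

# diffusion: nm^2/ps -> m^2/s
M2S_PER_NM2PS = 1e-6

# k_B T at T in Kelvin, in kJ/mol
def kbt(temperature: float) -> float:
    return KB * temperature
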