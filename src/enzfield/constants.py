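"""Physical constants and unit conversions.

Internal units are fixed package-wide: coordinates in Angstrom, charges in
elementary charges e, energies in kcal/mol, electrostatic potential in
kcal/(mol e) and electric field in kcal/(mol e A). Converters live only at
the I/O and reporting boundaries.

The Coulomb prefactor and Boltzmann constant are pinned to the Amber
molecular-mechanics convention so that results are bit-stable across scipy
releases; the remaining conversions are derived from CODATA values at import.
"""

from scipy import constants as _c

#: Coulomb prefactor k in kcal A / (mol e^2)  (Amber convention).
COULOMB_K = 332.0637

#: Boltzmann constant in kcal/(mol K) (Amber convention).
KB_KCAL_MOL_K = 0.0019872041

#: 1 hartree in eV (CODATA).
HARTREE_TO_EV = _c.physical_constants["Hartree energy in eV"][0]

# 1 kcal/(mol e A)  ->  MV/cm:
#   kcal/mol -> J per particle: calorie*1000 / N_A
#   per elementary charge -> volts: / e
#   per Angstrom -> V/m: / 1e-10 ; V/m -> MV/cm: * 1e-8
#: Field-unit conversion factor, ~4.336 MV/cm per kcal/(mol e A).
KCAL_MOL_E_A_TO_MV_CM = (
    _c.calorie * 1000.0 / (_c.N_A * _c.e) / _c.angstrom * 1e-8
)
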