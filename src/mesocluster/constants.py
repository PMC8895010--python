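"""Physical constants and default parameter values.

All constants are CODATA values re-exported from :mod:`scipy.constants`.
The defaults collect the experimentally determined quantities for the
reference system — 2-cyano-4'-methylbiphenyl (OTBN) in methanol — that
the documentation examples and the derived-constant chain use.
"""

from scipy.constants import Avogadro as N_A
from scipy.constants import Boltzmann as K_B
from scipy.constants import R as GAS_CONSTANT

#: Molar mass of the reference solute, 2-cyano-4'-methylbiphenyl (C14H11N) [g mol⁻¹].
DEFAULT_MOLAR_MASS = 193.25

#: Solvent (methanol) refractive index at the scattering wavelength.
DEFAULT_REFRACTIVE_INDEX = 1.325

#: Refractive-index increment dn/dc of the solute in methanol [ml g⁻¹].
DEFAULT_DNDC = 0.275

#: Laser wavelength of the light-scattering instrument [m].
DEFAULT_WAVELENGTH = 633e-9

#: Temperature of the NMR and scattering experiments [K].
DEFAULT_TEMPERATURE = 298.15

#: Methanol viscosity at 298 K [Pa s].
DEFAULT_VISCOSITY = 5.44e-4

#: Monomer diffusion coefficient from dilute-solution DOSY [m² s⁻¹].
DEFAULT_D1 = 4.0e-11

#: Monomer hydrodynamic radius (cylindrical-model fit) [m].
DEFAULT_R1 = 3.72e-10

#: Dimer hydrodynamic radius (cylindrical-model fit) [m].
DEFAULT_R2 = 4.65e-10

#: Dimerization constant [D]/[M]² in methanol [M⁻¹].
DEFAULT_KD = 1.147

#: Mean cluster diameter from dynamic light scattering [m].
DEFAULT_CLUSTER_DIAMETER = 3.2e-8

__all__ = [
    "N_A",
    "K_B",
    "GAS_CONSTANT",
    "DEFAULT_MOLAR_MASS",
    "DEFAULT_REFRACTIVE_INDEX",
    "DEFAULT_DNDC",
    "DEFAULT_WAVELENGTH",
    "DEFAULT_TEMPERATURE",
    "DEFAULT_VISCOSITY",
    "DEFAULT_D1",
    "DEFAULT_R1",
    "DEFAULT_R2",
    "DEFAULT_KD",
    "DEFAULT_CLUSTER_DIAMETER",
]
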