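"""Physical constants and unit conversions used throughout the package.

Unit conventions (fixed package-wide):

* lag times in seconds
* diffusion coefficients in µm²/s
* beam radii in µm, effective volumes in fL (1 µm³ = 1 fL)
* hydrodynamic radii and semi-axes in Å, volumes in ų
* temperature in K, viscosity in cP (1 cP = 1e-3 Pa·s)
* trajectory coordinates in nm, frame times in ps
"""

from scipy.constants import Avogadro as N_AVOGADRO
from scipy.constants import Boltzmann as K_BOLTZMANN  # J/K

CP_TO_PA_S = 1e-3
M_TO_ANGSTROM = 1e10
UM2_TO_M2 = 1e-12
FL_TO_L = 1e-15

#: nm²/ps -> µm²/s  (1 nm² = 1e-6 µm², 1 ps = 1e-12 s)
NM2_PER_PS_TO_UM2_PER_S = 1e6
UM2_PER_S_TO_NM2_PER_PS = 1e-6


def thermal_mobility_um3_per_s(temperature_K: float, viscosity_cP: float) -> float:
    """Return kT/(6πη) expressed in µm³/s.

    This is the product D·R of the Stokes–Einstein relation, so dividing by a
    radius in µm gives D in µm²/s.
    """
    eta_pa_s = viscosity_cP * CP_TO_PA_S
    kt_over_6pi_eta_m3_s = K_BOLTZMANN * temperature_K / (6.0 * 3.141592653589793 * eta_pa_s)
    return kt_over_6pi_eta_m3_s * 1e18  # m³ -> µm³
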