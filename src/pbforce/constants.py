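"""Physical constants and unit conventions.

All lengths are in ångström, charges in units of the elementary charge e,
energies in kT at the reference temperature (298.15 K), potentials in kT/e
and forces in kT/Å.
"""

from scipy import constants as _sc

#: Reference temperature (K) for the kT energy scale.
TEMPERATURE = 298.15

#: Coulomb constant C = e^2 / (4 pi eps0 * kT * 1 Å), in kT·Å/e².
#:
#: Two unit charges 1 Å apart in vacuum interact with energy C kT; in a
#: uniform dielectric eps the screened pair energy is C/(eps * r) kT.
COULOMB_KT_ANGSTROM = _sc.e**2 / (
    4.0 * _sc.pi * _sc.epsilon_0 * _sc.k * TEMPERATURE * 1.0e-10
)

#: 4*pi*C — the source prefactor of the gridded Poisson equation
#: div(eps grad phi) = -4 pi C rho  (phi in kT/e, rho in e/Å³).
FOUR_PI_C = 4.0 * _sc.pi * COULOMB_KT_ANGSTROM
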