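"""Internal unit system and physical constants.

The package works in the molecular-mechanics unit system
(Å, fs, amu, kcal/mol); every conversion to/from SI lives here so the
convention is stated in exactly one place.

Derived consequences of that choice:

* a force of 1 kcal mol⁻¹ Å⁻¹ acting on 1 amu gives an acceleration of
  ``ACCEL_CONV`` Å fs⁻²;
* 1 kcal mol⁻¹ Å⁻¹ equals ``KCAL_PER_MOL_ANG_TO_PN`` pN;
* shear rates quoted in s⁻¹ are multiplied by ``PER_S_TO_PER_FS`` before
  entering the integrator.
"""

from __future__ import annotations

#: Boltzmann constant, kcal mol⁻¹ K⁻¹.
KB_KCAL_MOL_K: float = 0.0019872041

#: Acceleration conversion: (kcal mol⁻¹ Å⁻¹) / amu -> Å fs⁻².
#: 4184 J/mol / 1e-10 m / (1e-3 kg/mol) expressed in Å fs⁻².
ACCEL_CONV: float = 4.184e-4

#: Force conversion: 1 kcal mol⁻¹ Å⁻¹ in piconewton.
KCAL_PER_MOL_ANG_TO_PN: float = 69.4786

#: Shear-rate conversion s⁻¹ -> fs⁻¹.
PER_S_TO_PER_FS: float = 1.0e-15

#: Time conversions.
FS_PER_NS: float = 1.0e6
NS_PER_FS: float = 1.0e-6


def force_pn_to_internal(force_pn: float) -> float:
    """Convert a force in pN to kcal mol⁻¹ Å⁻¹."""
    return force_pn / KCAL_PER_MOL_ANG_TO_PN


def force_internal_to_pn(force_kcal_mol_ang: float) -> float:
    """Convert a force in kcal mol⁻¹ Å⁻¹ to pN."""
    return force_kcal_mol_ang * KCAL_PER_MOL_ANG_TO_PN


def shear_rate_si_to_internal(gamma_dot_per_s: float) -> float:
    """Convert a shear rate in s⁻¹ to fs⁻¹."""
    return gamma_dot_per_s * PER_S_TO_PER_FS
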