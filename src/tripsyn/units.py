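"""Physical constants and unit conversions.

Internal unit convention (used consistently across the package):

==============  ===========
quantity        unit
==============  ===========
time            ms
length          um
concentration   mM
conductance     pS
voltage         mV
current         pA
==============  ===========

With these units, conductance x voltage gives femtoamperes, hence the
``PS_MV_TO_PA`` factor in the current equations.
"""

from __future__ import annotations

#: Avogadro's number, molecules per mole.
N_AVOGADRO = 6.02214076e23

#: 1 molecule/um^3 expressed in mM.
#: molecules/um^3 -> mol/L: multiply by 1e15 (um^3 per L) / N_A; -> mM: x 1e3.
MM_PER_MOLECULE_PER_UM3 = 1.0e18 / N_AVOGADRO

#: pS * mV = 1e-12 S * 1e-3 V = 1e-15 A = 1e-3 pA.
PS_MV_TO_PA = 1.0e-3

#: Molar gas constant, J mol^-1 K^-1.
R_GAS = 8.31434

#: Faraday constant, C mol^-1.
F_FARADAY = 9.64867e4


def molecules_per_um3_to_mM(n: float) -> float:
    """Convert a number density (molecules per um^3) to millimolar."""
    return n * MM_PER_MOLECULE_PER_UM3


def mM_to_molecules_per_um3(c: float) -> float:
    """Convert millimolar to molecules per um^3 (inverse of the above)."""
    return c / MM_PER_MOLECULE_PER_UM3
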