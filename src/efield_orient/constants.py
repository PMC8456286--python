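"""Physical constants and unit conversions.

Public interfaces use a fixed unit system: time in ns, length in nm,
field strength in V/nm, charge in e, mass in amu, energy in eV,
force in eV/Å. No unit autodetection happens anywhere.
"""

#: 1 e·nm expressed in Debye.
DEBYE_PER_E_NM = 48.0321

#: Boltzmann constant, eV/K.
KB_EV_PER_K = 8.617333262e-5

#: 1 eV expressed in amu·nm²/ns² (the natural energy unit of the
#: rotor integrator's internal state). Numerically equal to the Faraday
#: constant × 10³ because e·V / (amu·nm²/ns²) = (e/amu) · V·s²/m² scaled.
AMU_NM2_NS2_PER_EV = 9.648533212e7

#: PDB files store Å; all package interfaces use nm.
NM_PER_ANGSTROM = 0.1

#: Cα RMSD below which a protein structure counts as preserved, nm.
PRESERVATION_THRESHOLD_NM = 0.5

#: Lower-estimate bond dissociation force threshold, eV/Å.
BDF_THRESHOLD_EV_PER_A = 1.0

#: Fraction of initial orientation lost at the orientation time tau.
ORIENTATION_LOSS_FRACTION = 0.9
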