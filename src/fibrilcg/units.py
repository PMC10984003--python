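"""Unit system and physical constants.

The package works in LAMMPS-style "real" units throughout:
energy kcal/mol, length Angstrom, time fs, mass amu (g/mol).
Derived force unit: kcal/mol/A.  All conversions live here and
nowhere else.
"""

# thermochemical calorie
_J_PER_KCAL = 4184.0
_AVOGADRO = 6.02214076e23

#: Boltzmann constant, kcal/mol/K
KB = 0.001987204259

#: kinetic-energy conversion: 1 amu * (A/fs)^2 = MVV2E kcal/mol
#: (1e-3 kg/mol * 1e-20 m^2 / 1e-30 s^2 = 1e7 J/mol)
MVV2E = 1.0e7 / _J_PER_KCAL  # 2390.057...

#: force-to-acceleration: a [A/fs^2] = FTM2V * F [kcal/mol/A] / m [amu]
FTM2V = 1.0 / MVV2E

#: pressure conversion: 1 kcal/mol/A^3 in MPa
#: 4184 J/mol / Avogadro / 1e-30 m^3 = 6.9477e9 Pa
KCAL_PER_MOL_A3_IN_MPA = _J_PER_KCAL / _AVOGADRO / 1.0e-30 / 1.0e6

#: same, in GPa
KCAL_PER_MOL_A3_IN_GPA = KCAL_PER_MOL_A3_IN_MPA / 1.0e3
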