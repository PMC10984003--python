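# Default coarse-grained force field for the mineralized collagen fibril model.
# Units: kcal/mol, Angstrom, amu.  Loaded and schema-validated by
# fibrilcg.parameters.load_forcefield.
bonds:
  collagen:
    r0: 14.00        # equilibrium particle distance
    r1: 18.20        # critical hyperelastic distance
    rbreak: 21.00    # bond breaking distance
    k0: 17.13        # tensile stiffness, first regime (kcal/mol/A^2)
    k1: 97.66        # tensile stiffness, second regime (kcal/mol/A^2)
    z: 0.05          # regularization factor; ramp width a = z*(rbreak - r1)
  end:
    # particles at the ends of the TC molecules: same as collagen
    # except the bond breaking distance
    r0: 14.00
    r1: 18.20
    rbreak: 70.00
    k0: 17.13
    k1: 97.66
    z: 0.05
  age:
    # glucosepane-like AGE cross-link; k1 may be scaled x2 at insertion
    r0: 18.52
    r1: 22.72
    rbreak: 31.72
    k0: 0.1
    k1: 8.00
    z: 0.05
angle:
  kb: 14.98          # bending stiffness (kcal/mol/rad^2)
  phi0_range: [170.0, 180.0]   # equilibrium angles, read from initial geometry
pairs:
  col_col:
    epsilon: 6.87
    sigma: 14.72
    lam: 0.9
    cutoff: 36.80    # 2.5*sigma; not tabulated, package default
  hap_hap:
    epsilon: 106.7
    sigma: 10.28
    lam: 0.9
    cutoff: 13.85
  col_hap:
    epsilon: 137.1
    sigma: 9.88
    lam: 0.9
    cutoff: 20.00
masses:
  collagen: 1548.0
  mineral: 1324.0
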