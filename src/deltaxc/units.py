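"""Physical constants and unit conversions.

All internal quantities are in Hartree atomic units (Bohr, Hartree, electron
charge). Conversions are applied only at I/O boundaries (XYZ files are in
Angstrom, dipoles are reported in Debye, CLI energy reports in eV).
"""

BOHR_PER_ANGSTROM = 1.8897259886
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM

HARTREE_PER_EV = 1.0 / 27.211386245988
EV_PER_HARTREE = 27.211386245988

#: 1 e*Bohr in Debye
DEBYE_PER_EBOHR = 2.541746473

#: 1 e*Bohr^2 in Debye*Angstrom (quadrupole / spread unit)
DEBYE_ANGSTROM_PER_EBOHR2 = DEBYE_PER_EBOHR * ANGSTROM_PER_BOHR
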