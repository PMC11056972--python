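"""Physical constants and unit conversions (CODATA 2018).

All internal math is in Hartree atomic units; file I/O uses Angstrom.
"""

BOHR_PER_ANGSTROM = 1.8897259886
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM

#: proton mass in electron-mass units
PROTON_MASS = 1836.15267343

HARTREE_TO_KCALMOL = 627.509474
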