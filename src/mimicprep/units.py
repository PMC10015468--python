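"""Length-unit conversion constants.

All coordinates inside the package are stored in nanometers (the GROMACS
convention).  CPMD files use Bohr, PDB/XYZ use Angstrom.
"""

#: One Bohr (atomic unit of length) in nanometers (CODATA 2018).
BOHR_TO_NM = 0.0529177210903

#: Nanometers to Bohr.
NM_TO_BOHR = 1.0 / BOHR_TO_NM

#: Angstrom to nanometers.
ANGSTROM_TO_NM = 0.1

#: Nanometers to Angstrom.
NM_TO_ANGSTROM = 10.0
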