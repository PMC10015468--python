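"""Atomic-species inference from force-field metadata.

Force-field topologies frequently omit the chemical element of an atom
type (nonstandard ligands, custom residues).  The QM engine, however,
needs it to pick pseudopotentials.  This module infers elements from, in
order of preference:

1. an explicit user table mapping atom-type names to elements,
2. the atomic mass (nearest standard atomic weight within +/-0.5 amu,
   elements Z=1..86; anything lighter than 3.5 amu is hydrogen so that
   deuterium-like force-field masses resolve correctly),
3. the leading alphabetic characters of the atom name (two-letter symbol
   tried before one-letter),
4. the same rule applied to the atom-type name.

Standard atomic weights are taken from Biopython's IUPAC data tables.
"""

from __future__ import annotations

import re

import numpy as np
from Bio.Data.IUPACData import atom_weights

#: Element symbols ordered by atomic number, Z = 1..86 (H..Rn).
SYMBOLS: tuple[str, ...] = (
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn",
)

_SYMBOL_SET = frozenset(SYMBOLS)
_Z = {sym: i + 1 for i, sym in enumerate(SYMBOLS)}
_WEIGHTS = np.array([atom_weights[s] for s in SYMBOLS])

#: Mass below which an atom is assumed to be (an isotope of) hydrogen.
HYDROGEN_MASS_CEILING = 3.5

#: Maximum |mass - standard weight| for the mass rule to accept a match.
MASS_TOLERANCE = 0.5


def atomic_number(symbol: str) -> int:
    """Atomic number Z of an element symbol (IUPAC capitalization)."""
    return _Z[symbol]


def standard_weight(symbol: str) -> float:
    """Standard atomic weight in amu."""
    return float(atom_weights[symbol])


def normalize_symbol(symbol: str) -> str | None:
    """Return the IUPAC-capitalized form of ``symbol`` if it names an
    element with Z <= 86, else None."""
    s = symbol.strip().capitalize()
    return s if s in _SYMBOL_SET else None


def element_from_mass(mass: float | None) -> str | None:
    """Map an atomic mass to an element symbol, or None if no standard
    weight lies within the tolerance.  Non-positive/missing masses never
    match (virtual sites carry mass 0)."""
    if mass is None or mass <= 0.0:
        return None
    if mass < HYDROGEN_MASS_CEILING:
        return "H"
    diffs = np.abs(_WEIGHTS - mass)
    best = int(np.argmin(diffs))  # argmin takes the lowest Z on a tie
    if diffs[best] <= MASS_TOLERANCE:
        return SYMBOLS[best]
    return None


def element_from_label(label: str) -> str | None:
    """Infer an element from an atom or type name: take the leading
    alphabetic characters and try them as a two-letter, then one-letter,
    element symbol (case-insensitive)."""
    m = re.match(r"[A-Za-z]+", label.strip())
    if not m:
        return None
    alpha = m.group(0)
    if len(alpha) >= 2:
        two = normalize_symbol(alpha[:2])
        if two is not None:
            return two
    return normalize_symbol(alpha[:1])
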