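"""Deterministic generators of small synthetic test systems.

Two study systems are produced, each written as standard GROMACS
``.top``/``.itp``/``.gro`` files plus the auxiliary inputs a preparation
run needs (CPMD template, pseudopotential table, mdp file), together with
ground-truth annotations so tests can assert against the construction:

* a solvated small molecule: one 10-atom acetone-like solute whose atom
  types deliberately carry **no** element information (the nonstandard-
  ligand situation), in a bath of 3-site waters constrained via
  ``[ settles ]`` inside an ``#ifdef FLEXIBLE`` block;
* a linear toy peptide chain with 4-atom backbones, 2-atom side chains
  and explicit peptide bonds, for exercising covalent QM/MM boundary
  cuts.

Geometries are placeholders, not physical: coordinates are laid out on
jittered grids/lines and quantized to 3 decimals (nm) so gro round-trips
are bit-exact.  Generation is a pure function of the arguments and the
seed: identical calls produce byte-identical files.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: atom-type -> true element for every type used by the generators
TRUE_ELEMENTS = {
    "c_me": "C", "c_ke": "C", "o_ke": "O", "h_me": "H",   # solute
    "ow_t": "O", "hw_t": "H",                             # water
    "n_bb": "N", "c_al": "C", "c_bb": "C", "o_bb": "O",   # peptide backbone
    "c_sd": "C", "o_sd": "O",                             # peptide side chain
}


@dataclass
class FixtureSystem:
    """A generated system plus its ground truth."""

    directory: Path
    top_path: Path
    gro_path: Path
    template_path: Path
    pp_info_path: Path
    mdp_path: Path
    seed: int
    n_atoms: int
    true_elements: dict[str, str]
    #: named selection -> expected global atom ids (ascending)
    expected_selections: dict[str, list[int]] = field(default_factory=dict)
    #: named selection -> expected boundary atom ids for that region
    expected_boundary: dict[str, list[int]] = field(default_factory=dict)
    #: molecule name -> per-copy charge sum (e)
    charge_sums: dict[str, float] = field(default_factory=dict)
    #: molecule name -> copy count
    molecule_counts: dict[str, int] = field(default_factory=dict)


def _q(values) -> np.ndarray:
    """Quantize nm coordinates to the gro precision (3 decimals)."""
    return np.round(np.asarray(values, dtype=float), 3)


_TEMPLATE_INP = """\
&INFO
annealing run for a solvated solute
&END

&CPMD
ANNEAL IONS
TIMESTEP
 5.0
MAXSTEP
 1000
&END

&DFT
FUNCTIONAL BLYP
&END
"""

_PP_INFO = """\
# element  pp-filename  LMAX=<l> [LOC=<l>] [boundary-pp-filename]
H   H_MT_BLYP.psp  LMAX=S LOC=S  H_GIA_BLYP.psp
C   C_MT_BLYP.psp  LMAX=P LOC=P  C_GIA_BLYP.psp
N   N_MT_BLYP.psp  LMAX=P LOC=P  N_GIA_BLYP.psp
O   O_MT_BLYP.psp  LMAX=P LOC=P  O_GIA_BLYP.psp
"""

_MDP = """\
; generic MD parameters for a coupled run
integrator               = md
dt                       = 0.0002
nsteps                   = 1000
cutoff-scheme            = Verlet
rlist                    = 1.0
coulombtype              = PME
"""


def _write_common(directory: Path) -> tuple[Path, Path, Path]:
    template = directory / "template.inp"
    template.write_text(_TEMPLATE_INP)
    pp = directory / "pp_info.dat"
    pp.write_text(_PP_INFO)
    mdp = directory / "mimic.mdp"
    mdp.write_text(_MDP)
    return template, pp, mdp


def _write_gro(path: Path, rows, box) -> None:
    """rows: (resid, resname, name, x, y, z); serials are sequential."""
    lines = ["synthetic fixture", f"{len(rows):5d}"]
    for serial, (resid, resname, name, x, y, z) in enumerate(rows, start=1):
        lines.append(f"{resid:>5d}{resname:<5s}{name:>5s}{serial:>5d}"
                     f"{x:8.3f}{y:8.3f}{z:8.3f}")
    lines.append("{:10.5f}{:10.5f}{:10.5f}".format(*box))
    path.write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Solvated small molecule (acetone-like solute + waters)

#: solute atoms: (name, type, charge); masses come from the type table
_SOLUTE_ATOMS = [
    ("C1", "c_me", -0.30), ("C2", "c_ke", 0.55), ("O1", "o_ke", -0.55),
    ("C3", "c_me", -0.30),
    ("H1", "h_me", 0.10), ("H2", "h_me", 0.10), ("H3", "h_me", 0.10),
    ("H4", "h_me", 0.10), ("H5", "h_me", 0.10), ("H6", "h_me", 0.10),
]
_SOLUTE_BONDS = [(1, 2), (2, 3), (2, 4), (1, 5), (1, 6), (1, 7),
                 (4, 8), (4, 9), (4, 10)]
#: idealized local geometry (nm, relative to the solute anchor)
_SOLUTE_GEOM = np.array([
    [-0.128, 0.069, 0.000], [0.000, 0.000, 0.000], [0.000, -0.122, 0.000],
    [0.128, 0.069, 0.000],
    [-0.131, 0.178, 0.002], [-0.216, 0.020, 0.041], [-0.118, 0.105, -0.104],
    [0.131, 0.178, 0.002], [0.216, 0.020, 0.041], [0.118, 0.105, -0.104],
])

_TYPE_MASSES = {"c_me": 12.011, "c_ke": 12.011, "o_ke": 15.9994,
                "h_me": 1.008, "ow_t": 15.9994, "hw_t": 1.008,
                "n_bb": 14.007, "c_al": 12.011, "c_bb": 12.011,
                "o_bb": 15.9994, "c_sd": 12.011, "o_sd": 15.9994}

_FF_HEADER = "; synthetic force field: atom types carry no element column\n"


def _atomtypes_itp(types: list[str]) -> str:
    lines = ["[ atomtypes ]",
             "; name       mass    charge  ptype    sigma   epsilon"]
    for t in types:
        lines.append(f"{t:<8s} {_TYPE_MASSES[t]:9.4f}   0.000  A   "
                     f"0.30000  0.50000")
    return _FF_HEADER + "\n".join(lines) + "\n"


def make_solvated_small_molecule(n_waters: int, seed: int,
                                 out_dir=None) -> FixtureSystem:
    """Acetone-like solute (residue ACT, 10 atoms, zero net charge) plus
    ``n_waters`` rigid 3-site waters (residue SOL) on a jittered grid."""
    if n_waters < 0:
        raise ValueError("n_waters must be >= 0")
    directory = Path(out_dir) if out_dir is not None else \
        Path(tempfile.mkdtemp(prefix="mimicprep_solvated_"))
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "ffdir").mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)

    (directory / "ffdir" / "ffnonbonded.itp").write_text(
        _atomtypes_itp(["c_me", "c_ke", "o_ke", "h_me", "ow_t", "hw_t"]))

    solute_lines = ["[ moleculetype ]", "ACT   3", "", "[ atoms ]",
                    ";  nr  type  resnr  residue  atom  cgnr  charge  mass"]
    for i, (name, typ, charge) in enumerate(_SOLUTE_ATOMS, start=1):
        solute_lines.append(f"{i:5d}  {typ:<6s} 1  ACT  {name:<4s} 1 "
                            f"{charge:8.3f} {_TYPE_MASSES[typ]:9.4f}")
    solute_lines += ["", "[ bonds ]"]
    solute_lines += [f"{a:5d} {b:5d}  1" for a, b in _SOLUTE_BONDS]
    (directory / "solute.itp").write_text("\n".join(solute_lines) + "\n")

    water = """\
[ moleculetype ]
SOL   2

[ atoms ]
;  nr  type  resnr  residue  atom  cgnr  charge  mass
   1   ow_t  1  SOL  OW   1  -0.834  15.9994
   2   hw_t  1  SOL  HW1  1   0.417   1.0080
   3   hw_t  1  SOL  HW2  1   0.417   1.0080

#ifdef FLEXIBLE
[ bonds ]
1 2 1
1 3 1
#else
[ settles ]
1  1  0.09572  0.15139
#endif
"""
    (directory / "water.itp").write_text(water)

    top = f"""\
; synthetic solvated small-molecule system
#include "ffdir/ffnonbonded.itp"
#include "solute.itp"
#include "water.itp"

[ system ]
acetone-like solute in water

[ molecules ]
ACT  1
SOL  {n_waters}
"""
    top_path = directory / "topol.top"
    top_path.write_text(top)

    # coordinates: solute near one corner region, waters on a grid
    grid = max(1, int(np.ceil(n_waters ** (1 / 3)))) if n_waters else 1
    spacing = 0.31
    box = _q([grid * spacing + 1.2] * 3)
    anchor = np.array([0.6, 0.6, 0.6])
    rows = []
    solute_xyz = _q(anchor + _SOLUTE_GEOM)
    for (name, _, _), (x, y, z) in zip(_SOLUTE_ATOMS, solute_xyz):
        rows.append((1, "ACT", name, x, y, z))
    placed = 0
    for ix in range(grid):
        for iy in range(grid):
            for iz in range(grid):
                if placed >= n_waters:
                    break
                placed += 1
                base = np.array([1.0 + ix * spacing, 1.0 + iy * spacing,
                                 1.0 + iz * spacing])
                jitter = rng.uniform(-0.02, 0.02, size=3)
                o = _q(base + jitter)
                h1 = _q(o + [0.076, 0.059, 0.0])
                h2 = _q(o + [-0.076, 0.059, 0.0])
                resid = 1 + placed
                for name, p in (("OW", o), ("HW1", h1), ("HW2", h2)):
                    rows.append((resid, "SOL", name, p[0], p[1], p[2]))
    gro_path = directory / "conf.gro"
    _write_gro(gro_path, rows, box)

    template, pp, mdp = _write_common(directory)
    n_atoms = 10 + 3 * n_waters
    return FixtureSystem(
        directory=directory, top_path=top_path, gro_path=gro_path,
        template_path=template, pp_info_path=pp, mdp_path=mdp, seed=seed,
        n_atoms=n_atoms, true_elements=dict(TRUE_ELEMENTS),
        expected_selections={
            "solute": list(range(1, 11)),
            "water": list(range(11, n_atoms + 1)),
        },
        expected_boundary={"solute": []},
        charge_sums={"ACT": 0.0, "SOL": 0.0},
        molecule_counts={"ACT": 1, "SOL": n_waters},
    )


# --------------------------------------------------------------------------
# Toy peptide chain

#: per-residue atoms: (name, type, charge); neutral side chain
_RESIDUE_ATOMS = [
    ("N", "n_bb", -0.40), ("CA", "c_al", 0.30), ("C", "c_bb", 0.50),
    ("O", "o_bb", -0.50), ("CB", "c_sd", 0.35), ("OG", "o_sd", -0.25),
]
#: extra charge put on OG of a "charged" residue (net +1)
_CHARGED_EXTRA = 1.00
#: intra-residue bonds (1-based within the residue)
_RESIDUE_BONDS = [(1, 2), (2, 3), (3, 4), (2, 5), (5, 6)]


def make_peptide_chain(n_residues: int, seed: int, out_dir=None,
                       charged_residues=()) -> FixtureSystem:
    """Linear toy peptide: backbone N-CA-C(=O) plus a CB-OG side chain per
    residue, peptide bonds C(i)-N(i+1).  Residues listed in
    ``charged_residues`` carry a net +1 charge on the side chain."""
    if n_residues < 2:
        raise ValueError("a chain needs at least 2 residues")
    charged = set(int(r) for r in charged_residues)
    directory = Path(out_dir) if out_dir is not None else \
        Path(tempfile.mkdtemp(prefix="mimicprep_peptide_"))
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "ffdir").mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)

    (directory / "ffdir" / "ffnonbonded.itp").write_text(
        _atomtypes_itp(["n_bb", "c_al", "c_bb", "o_bb", "c_sd", "o_sd"]))

    lines = ["[ moleculetype ]", "PEP   3", "", "[ atoms ]",
             ";  nr  type  resnr  residue  atom  cgnr  charge  mass"]
    nr = 0
    for r in range(1, n_residues + 1):
        for name, typ, charge in _RESIDUE_ATOMS:
            nr += 1
            if name == "OG" and r in charged:
                charge += _CHARGED_EXTRA
            lines.append(f"{nr:5d}  {typ:<6s} {r:3d}  RES  {name:<4s} {r:3d} "
                         f"{charge:8.3f} {_TYPE_MASSES[typ]:9.4f}")
    lines += ["", "[ bonds ]"]
    bonds = []
    for r in range(n_residues):
        base = 6 * r
        bonds.extend((base + a, base + b) for a, b in _RESIDUE_BONDS)
    for r in range(n_residues - 1):
        bonds.append((6 * r + 3, 6 * r + 7))  # peptide bond C(i)-N(i+1)
    lines += [f"{a:5d} {b:5d}  1" for a, b in bonds]
    (directory / "peptide.itp").write_text("\n".join(lines) + "\n")

    top_path = directory / "topol.top"
    top_path.write_text(f"""\
; synthetic toy peptide
#include "ffdir/ffnonbonded.itp"
#include "peptide.itp"

[ system ]
toy peptide chain

[ molecules ]
PEP  1
""")

    offsets = np.array([
        [0.00, 0.00, 0.00], [0.12, 0.08, 0.00], [0.26, 0.02, 0.00],
        [0.28, -0.10, 0.00], [0.12, 0.18, 0.12], [0.20, 0.28, 0.18],
    ])
    rows = []
    for r in range(1, n_residues + 1):
        start = np.array([0.5 + 0.38 * (r - 1), 1.0, 1.0])
        jitter = rng.uniform(-0.01, 0.01, size=3)
        for (name, _, _), off in zip(_RESIDUE_ATOMS, offsets):
            x, y, z = _q(start + off + jitter)
            rows.append((r, "RES", name, x, y, z))
    box = _q([0.38 * n_residues + 1.5, 2.5, 2.5])
    gro_path = directory / "conf.gro"
    _write_gro(gro_path, rows, box)

    template, pp, mdp = _write_common(directory)

    expected_selections = {}
    expected_boundary = {}
    for r in range(1, n_residues + 1):
        base = 6 * (r - 1)
        side = [base + 5, base + 6]          # CB, OG
        expected_selections[f"sidechain_{r}"] = side
        expected_boundary[f"sidechain_{r}"] = [base + 5]   # CB cut from CA
        full = list(range(base + 1, base + 7))
        expected_selections[f"residue_{r}"] = full
        cut = []
        if r > 1:
            cut.append(base + 1)             # N bonded to previous C
        if r < n_residues:
            cut.append(base + 3)             # C bonded to next N
        expected_boundary[f"residue_{r}"] = cut
    expected_selections["all"] = list(range(1, 6 * n_residues + 1))
    expected_boundary["all"] = []

    return FixtureSystem(
        directory=directory, top_path=top_path, gro_path=gro_path,
        template_path=template, pp_info_path=pp, mdp_path=mdp, seed=seed,
        n_atoms=6 * n_residues, true_elements=dict(TRUE_ELEMENTS),
        expected_selections=expected_selections,
        expected_boundary=expected_boundary,
        charge_sums={"PEP": float(len(charged))},
        molecule_counts={"PEP": 1},
    )
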