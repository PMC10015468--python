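"""QM-region preparation: the central engine that holds the selection,
computes the QM cell and charge, detects open-valence (boundary) atoms,
and emits the MiMiC-compliant CPMD input plus the GROMACS index file.

Conventions
-----------
* The QM cell per axis is ``extent + 2 * padding`` (nm, converted to
  Bohr).  The default padding of 0.35 nm gives the isolated-system
  Poisson solver (Martyna-Tuckerman) its required vacuum margin; larger
  systems usually need more.
* &ATOMS coordinates are absolute Bohr, translated so the region's
  minimum corner sits at (padding, padding, padding) — the molecule is
  centered in the minimal cell.
* Species blocks are ordered by ascending atomic number with boundary
  blocks last; within a block atoms keep ascending GROMACS index.  This
  fixed order is shared with :mod:`mimicprep.index_mapping` (single
  source of truth for the GROMACS->CPMD numbering).
* External executables are never invoked: when an mdp file is supplied
  the patched mdp is returned together with the ready-to-run
  ``gmx grompp`` / ``gmx mdrun`` / ``cpmd.x`` command lines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import PurePosixPath

import numpy as np

from . import elements as el
from .coords import CoordinateSet
from .errors import (ChemistryError, NonIntegralChargeWarning, UsageError)
from .scripts import (CpmdScript, CpmdSection, MdpFile, NdxFile, PpInfoTable,
                      patch_mdp)
from .selection import evaluate, parse_query
from .topology import Topology, guess_elements
from .units import NM_TO_BOHR

#: Default vacuum margin between the QM atoms and the QM cell faces (nm).
DEFAULT_BOX_PADDING = 0.35

#: Default name of the QM-atom index group.
DEFAULT_NDX_GROUP = "QMatoms"


@dataclass
class QmBox:
    """Orthorhombic QM cell: lengths in Bohr plus the padding used."""

    lengths_bohr: np.ndarray
    padding_nm: float


@dataclass
class MimicInput:
    """Bundle returned by input generation."""

    cpmd: CpmdScript
    ndx: NdxFile
    mdp: MdpFile | None
    commands: list[str] = field(default_factory=list)


def compute_qm_box(positions_nm: np.ndarray, padding_nm: float) -> QmBox:
    """QM cell lengths: per axis, coordinate extent plus twice the
    padding, in Bohr.  A degenerate axis with zero padding is an error
    (zero-volume cell)."""
    positions_nm = np.asarray(positions_nm, dtype=float)
    if positions_nm.size == 0:
        raise UsageError("cannot size a QM box for an empty region")
    if padding_nm < 0:
        raise UsageError("box padding must be non-negative")
    extent = positions_nm.max(axis=0) - positions_nm.min(axis=0)
    lengths_nm = extent + 2.0 * padding_nm
    if np.any(lengths_nm <= 0):
        raise UsageError("QM cell has zero volume: degenerate coordinate "
                         "extent with zero padding")
    return QmBox(lengths_bohr=lengths_nm * NM_TO_BOHR, padding_nm=padding_nm)


def compute_qm_charge(top: Topology, region: list[int]) -> tuple[float, int]:
    """Summed partial charge of the region and the declared (nearest
    integer) total.  Warns when the sum is further than 0.01 e from an
    integer — the typical signature of a bond-severing selection."""
    charges = top.global_atoms.set_index("id").loc[list(region), "charge"]
    raw = float(charges.sum())
    declared = int(math.floor(raw + 0.5)) if raw >= 0 else \
        -int(math.floor(-raw + 0.5))
    if abs(raw - declared) > 0.01:
        warnings.warn(
            f"QM region charge {raw:.4f} e is not close to an integer "
            f"(declared {declared}); the selection may sever a charge group",
            NonIntegralChargeWarning)
    return raw, declared


def detect_boundary_atoms(top: Topology, region) -> list[int]:
    """QM atoms with at least one bonded neighbour outside the region
    (open valences), ascending."""
    region_set = set(int(i) for i in region)
    boundary = set()
    for a, b in top.global_bonds():
        if (a in region_set) != (b in region_set):
            boundary.add(a if a in region_set else b)
    return sorted(boundary)


def qm_emission_order(top: Topology, region, boundary) -> list[tuple[str, bool, list[int]]]:
    """Species blocks of the &ATOMS section: ``(element, is_boundary,
    gromacs ids)`` — ascending atomic number, boundary blocks last,
    ascending GROMACS index within each block.  The blocks partition the
    region."""
    boundary_set = set(int(i) for i in boundary)
    elem = top.global_atoms.set_index("id")["element"]
    blocks: dict[tuple[bool, int], list[int]] = {}
    for gid in sorted(int(i) for i in region):
        sym = elem.loc[gid]
        if sym is None or (isinstance(sym, float) and np.isnan(sym)):
            raise ChemistryError(f"atom {gid} has no resolved element")
        key = (gid in boundary_set, el.atomic_number(sym))
        blocks.setdefault(key, []).append(gid)
    out = []
    for (is_boundary, z) in sorted(blocks):
        out.append((el.SYMBOLS[z - 1], is_boundary, blocks[(is_boundary, z)]))
    return out


def _fill_region_elements(top: Topology, region, nsa_table, guess: bool):
    """Resolve elements for the QM atoms only (MM atoms are the topology
    repair tool's job)."""
    df = top.global_atoms
    missing = df["element"].isna() & df["id"].isin(list(region))
    if not missing.any():
        return
    probe = Topology(moleculetypes=top.moleculetypes,
                     molecule_order=top.molecule_order,
                     atom_types=top.atom_types,
                     global_atoms=df.loc[df["id"].isin(list(region))].copy(),
                     system_name=top.system_name)
    guess_elements(probe, nsa_table=nsa_table, guess=guess)
    df.loc[probe.global_atoms.index, "element"] = \
        probe.global_atoms["element"]


# --------------------------------------------------------------------------
# MiMiC / CPMD serializers (the only place that knows the line syntax)

def _mimic_section(mm_box_nm, tpr_path: str, pairs) -> CpmdSection:
    """&MIMIC: PATHS (one GROMACS working directory), BOX (MM box, Bohr)
    and OVERLAPS (one ``2 <gromacs id> 1 <cpmd id>`` line per QM atom)."""
    tpr_dir = str(PurePosixPath(tpr_path).parent) or "."
    box = np.asarray(mm_box_nm, dtype=float) * NM_TO_BOHR
    lines = ["PATHS", "1", tpr_dir,
             "BOX",
             "  {:.6f} {:.6f} {:.6f}".format(*box),
             "OVERLAPS",
             str(len(pairs))]
    lines += [f"2 {gmx} 1 {cpmd}" for gmx, cpmd in pairs]
    return CpmdSection("MIMIC", lines)


def _atoms_section(blocks, coords_bohr: dict[int, np.ndarray],
                   pp: PpInfoTable) -> CpmdSection:
    lines = []
    for element, is_boundary, gids in blocks:
        entry = pp.require(element, boundary=is_boundary)
        filename = entry.boundary_filename if is_boundary \
            else entry.pseudopotential_filename
        lines.append(f"*{filename}")
        lmax = f" LMAX={entry.lmax}"
        if entry.loc is not None:
            lmax += f" LOC={entry.loc}"
        lines.append(lmax)
        lines.append(f" {len(gids)}")
        for gid in gids:
            x, y, z = coords_bohr[gid]
            lines.append(f"  {x:14.6f} {y:14.6f} {z:14.6f}")
    return CpmdSection("ATOMS", lines)


def _system_section(box: QmBox, declared_charge: int) -> CpmdSection:
    a, b, c = box.lengths_bohr
    return CpmdSection("SYSTEM", [
        "CELL ABSOLUTE",
        f"  {a:.6f} {b:.6f} {c:.6f}  0.0 0.0 0.0",
        "CHARGE",
        f"  {declared_charge}",
    ])


def generate_mimic_input(top: Topology, coords: CoordinateSet, region,
                         template: CpmdScript | None = None,
                         pp: PpInfoTable | None = None,
                         tpr_path: str = "mimic.tpr",
                         padding_nm: float = DEFAULT_BOX_PADDING,
                         boundary: bool = False,
                         mdp: MdpFile | None = None,
                         ndx_group: str = DEFAULT_NDX_GROUP,
                         mdp_out: str = "mimic.mdp",
                         coords_path: str = "coords.gro",
                         top_path: str = "topol.top",
                         ndx_path: str = "index.ndx") -> MimicInput:
    """Emit the CPMD input, index file and (optionally) patched mdp for a
    QM region.

    The template's sections are preserved verbatim except &MIMIC, &SYSTEM
    and &ATOMS, which are generated.  Deterministic: identical inputs give
    byte-identical outputs.
    """
    region = sorted(int(i) for i in region)
    if not region:
        raise UsageError("no atoms selected: the QM region is empty")
    if pp is None:
        raise UsageError("a pseudopotential-information table is required")
    if coords.box is None:
        raise UsageError("the MM coordinate file carries no box; one is "
                         "required for the &MIMIC BOX record")
    if len(coords) != top.n_atoms:
        raise UsageError(f"coordinate file has {len(coords)} atoms but the "
                         f"topology defines {top.n_atoms}")

    boundary_ids = detect_boundary_atoms(top, region)
    if boundary_ids and not boundary:
        raise ChemistryError(
            f"{len(boundary_ids)} QM atom(s) have bonds crossing the QM-MM "
            "boundary, leaving open valences; enable boundary-atom "
            "treatment (-bound) to assign monovalent boundary "
            "pseudopotentials")
    if not boundary:
        boundary_ids = []

    blocks = qm_emission_order(top, region, boundary_ids)
    missing = sorted({e for e, b, _ in blocks
                      if (pp.entries.get(e) is None)
                      or (b and pp.entries[e].boundary_filename is None)})
    if missing:
        raise ChemistryError("missing pseudopotential entries for "
                             "element(s): " + ", ".join(missing))

    pos = coords.positions
    region_xyz = pos[[gid - 1 for gid in region]]
    box = compute_qm_box(region_xyz, padding_nm)
    shift = padding_nm - region_xyz.min(axis=0)
    coords_bohr = {gid: (pos[gid - 1] + shift) * NM_TO_BOHR
                   for gid in region}

    emission = [gid for _, _, gids in blocks for gid in gids]
    pairs = [(gid, cpmd_id) for cpmd_id, gid in enumerate(emission, start=1)]
    pairs.sort()  # ascending GROMACS index for readability

    raw, declared = compute_qm_charge(top, region)

    out = CpmdScript()
    out.add_section(_mimic_section(coords.box, tpr_path, pairs))
    if template is not None:
        for section in template.sections.values():
            if section.name not in ("MIMIC", "SYSTEM", "ATOMS"):
                out.add_section(CpmdSection(section.name,
                                            list(section.lines)))
    out.add_section(_system_section(box, declared))
    out.add_section(_atoms_section(blocks, coords_bohr, pp))

    ndx = NdxFile()
    ndx.add_group(ndx_group, region)

    commands = []
    patched = None
    if mdp is not None:
        patched = patch_mdp(mdp, {"integrator": "mimic",
                                  "QMMM-grps": ndx_group})
        commands.append(
            f"gmx grompp -f {mdp_out} -c {coords_path} -p {top_path} "
            f"-n {ndx_path} -o {tpr_path}")
        commands.append(f"gmx mdrun -deffnm {PurePosixPath(tpr_path).stem}")
        commands.append("cpmd.x cpmd.inp > cpmd.out")
    return MimicInput(cpmd=out, ndx=ndx, mdp=patched, commands=commands)


# --------------------------------------------------------------------------
# Selection-holding front end

class Preparation:
    """Holds the selected QM region and generates the MiMiC input files.

    Queries may be passed as strings or pre-parsed ASTs; ``add`` unions
    the matching atoms into the region, ``delete`` removes them.  Both
    are idempotent.
    """

    def __init__(self, top: Topology, coords: CoordinateSet):
        if len(coords) != top.n_atoms:
            raise UsageError(
                f"coordinate file has {len(coords)} atoms but the topology "
                f"defines {top.n_atoms}; pass matching files")
        self.top = top
        self.coords = coords
        self._region: set[int] = set()

    @property
    def region(self) -> list[int]:
        """Selected global atom ids, ascending."""
        return sorted(self._region)

    def _evaluate(self, query) -> list[int]:
        ast = parse_query(query) if isinstance(query, str) else query
        return evaluate(ast, self.top)

    def add(self, query) -> list[int]:
        """Add matching atoms; returns the new region."""
        self._region.update(self._evaluate(query))
        return self.region

    def delete(self, query) -> list[int]:
        """Remove matching atoms; atoms not in the region are counted and
        warned about, not an error."""
        hits = set(self._evaluate(query))
        absent = len(hits - self._region)
        if absent:
            warnings.warn(f"{absent} matching atom(s) were not in the QM "
                          "region")
        self._region -= hits
        return self.region

    def clear(self) -> None:
        self._region.clear()

    def view(self):
        """DataFrame of the selected atoms (global table rows)."""
        df = self.top.global_atoms
        return df[df["id"].isin(self._region)]

    def get_mimic_input(self, template=None, pp=None,
                        tpr_path: str = "mimic.tpr",
                        padding_nm: float = DEFAULT_BOX_PADDING,
                        boundary: bool = False, mdp=None,
                        guess: bool = True, nsa_table=None,
                        ndx_group: str = DEFAULT_NDX_GROUP,
                        **paths) -> MimicInput:
        if not self._region:
            raise UsageError("no atoms selected: the QM region is empty")
        _fill_region_elements(self.top, self.region, nsa_table, guess)
        return generate_mimic_input(
            self.top, self.coords, self.region, template=template, pp=pp,
            tpr_path=tpr_path, padding_nm=padding_nm, boundary=boundary,
            mdp=mdp, ndx_group=ndx_group, **paths)
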