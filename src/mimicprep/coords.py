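"""Coordinate-file adapter: one tabular, unit-normalized representation
for the four supported formats (GROMACS gro, PDB, XYZ, CPMD GEOMETRY).

Each format has a dedicated parser/writer pair; :func:`read_coordinates`
and :func:`write_coordinates` dispatch on an explicit format or the file
extension.  All coordinates are stored in **nanometers** regardless of the
native unit (gro: nm; pdb/xyz: Angstrom; GEOMETRY: Bohr).

Dialect decisions
-----------------
* gro lines are parsed strictly fixed-width (names may abut digits);
  velocity columns are ignored on read and omitted on write.
* The PDB reader accepts ATOM and HETATM and ignores every other record;
  occupancy/B-factor are written as 1.00/0.00.
* XYZ stores the element symbol in ``atom_name``; residue name/id are
  "MOL"/1.
* CPMD GEOMETRY carries no atom names: one line per atom, the first three
  whitespace-separated floats are Bohr positions; further columns
  (velocities) are ignored on read and written as zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, UsageError
from .units import ANGSTROM_TO_NM, BOHR_TO_NM, NM_TO_ANGSTROM, NM_TO_BOHR

FORMATS = ("gro", "pdb", "xyz", "cpmd_geometry")

ATOM_COLUMNS = ["serial", "atom_name", "residue_name", "residue_id",
                "chain_or_mol", "x", "y", "z"]


@dataclass
class CoordinateSet:
    """Per-atom coordinates plus the periodic box, in nanometers.

    ``atoms`` is a DataFrame with columns ``serial`` (1-based, strictly
    increasing), ``atom_name``, ``residue_name``, ``residue_id``,
    ``chain_or_mol`` and Cartesian ``x, y, z`` in nm.  ``box`` is a
    3-vector of box lengths in nm, or None when the source format carries
    no box.
    """

    atoms: pd.DataFrame
    box: np.ndarray | None = None
    source_format: str = "gro"

    def __post_init__(self):
        self.validate()

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) array of coordinates in nm."""
        return self.atoms[["x", "y", "z"]].to_numpy(dtype=float)

    def validate(self) -> None:
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise UsageError(f"coordinate table lacks columns {missing}")
        serial = self.atoms["serial"].to_numpy()
        if len(serial) and not np.all(np.diff(serial) > 0):
            raise UsageError("atom serials must be strictly increasing")
        xyz = self.atoms[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xyz)):
            raise UsageError("coordinates must be finite")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or not np.all(self.box > 0):
                raise UsageError("box must have three strictly positive lengths")


def _make_atoms(records: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=ATOM_COLUMNS)
    df["serial"] = df["serial"].astype(int)
    df["residue_id"] = df["residue_id"].astype(int)
    for c in ("x", "y", "z"):
        df[c] = df[c].astype(float)
    return df


def infer_format(path: Path) -> str:
    """Infer a coordinate format from a file name.

    ``.gro``/``.pdb``/``.xyz`` map to the respective formats; a file named
    GEOMETRY (any case) or lacking an extension is treated as CPMD
    GEOMETRY.
    """
    suffix = path.suffix.lower()
    if suffix == ".gro":
        return "gro"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix == ".xyz":
        return "xyz"
    if suffix == "" or "geometry" in path.name.lower():
        return "cpmd_geometry"
    raise UsageError(
        f"cannot infer coordinate format from {path.name!r}; pass one of {FORMATS}")


def read_coordinates(path, fmt: str | None = None) -> CoordinateSet:
    """Read a coordinate file into a :class:`CoordinateSet` (nm)."""
    path = Path(path)
    if fmt is None:
        fmt = infer_format(path)
    if fmt not in FORMATS:
        raise UsageError(f"unknown coordinate format {fmt!r}")
    try:
        text = path.read_text()
    except OSError as exc:
        raise UsageError(f"cannot read {path}: {exc}") from exc
    reader = {"gro": _read_gro, "pdb": _read_pdb, "xyz": _read_xyz,
              "cpmd_geometry": _read_geometry}[fmt]
    return reader(text, path)


def write_coordinates(cs: CoordinateSet, path, fmt: str | None = None) -> None:
    """Write a :class:`CoordinateSet` in the requested format."""
    path = Path(path)
    if fmt is None:
        fmt = infer_format(path)
    if fmt not in FORMATS:
        raise UsageError(f"unknown coordinate format {fmt!r}")
    if len(cs) == 0:
        raise UsageError("refusing to write an empty coordinate set")
    writer = {"gro": _write_gro, "pdb": _write_pdb, "xyz": _write_xyz,
              "cpmd_geometry": _write_geometry}[fmt]
    path.write_text(writer(cs))


# --------------------------------------------------------------------------
# GROMACS gro (fixed width, nm)

_GRO_BODY = "{:>5d}{:<5s}{:>5s}{:>5d}{:8.3f}{:8.3f}{:8.3f}\n"


def _read_gro(text: str, path: Path) -> CoordinateSet:
    lines = text.splitlines()
    if len(lines) < 3:
        raise ParseError("gro file needs title, atom count and box lines",
                         path=path, line=len(lines))
    try:
        natoms = int(lines[1].strip())
    except ValueError:
        raise ParseError("invalid atom count", path=path, line=2)
    if len(lines) < natoms + 3:
        raise ParseError(f"expected {natoms} atom lines", path=path,
                         line=len(lines))
    records = []
    for i in range(natoms):
        lineno = i + 3
        line = lines[2 + i]
        if len(line) < 44:
            raise ParseError("gro atom line shorter than 44 columns",
                             path=path, line=lineno)
        try:
            records.append(dict(
                serial=int(line[15:20]),
                atom_name=line[10:15].strip(),
                residue_name=line[5:10].strip(),
                residue_id=int(line[0:5]),
                chain_or_mol="",
                x=float(line[20:28]), y=float(line[28:36]), z=float(line[36:44]),
            ))
        except ValueError as exc:
            raise ParseError(f"malformed gro atom line: {exc}", path=path,
                             line=lineno) from exc
    serials = [r["serial"] for r in records]
    if any(b <= a for a, b in zip(serials, serials[1:])):
        # gro serials wrap at 99999; renumber to keep the invariant
        for i, r in enumerate(records, start=1):
            r["serial"] = i
    box_line = lines[2 + natoms].split()
    try:
        box = np.array([float(v) for v in box_line[:3]])
    except (ValueError, IndexError) as exc:
        raise ParseError("malformed gro box line", path=path,
                         line=natoms + 3) from exc
    return CoordinateSet(_make_atoms(records), box=box, source_format="gro")


def _synthesized_box(cs: CoordinateSet) -> np.ndarray:
    pos = cs.positions
    extent = pos.max(axis=0) - pos.min(axis=0)
    warnings.warn("no box present; synthesizing one from the coordinate "
                  "extent plus a 0.1 nm margin per side")
    return extent + 0.2


def _write_gro(cs: CoordinateSet) -> str:
    box = cs.box if cs.box is not None else _synthesized_box(cs)
    n = len(cs)
    if n > 99999:
        warnings.warn("more than 99999 atoms: gro serial/resid fields wrap "
                      "modulo 100000")
    out = ["Written by mimicprep\n", f"{n:5d}\n"]
    for row in cs.atoms.itertuples(index=False):
        out.append(_GRO_BODY.format(
            row.residue_id % 100000, str(row.residue_name)[:5],
            str(row.atom_name)[:5], row.serial % 100000,
            row.x, row.y, row.z))
    out.append(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}\n")
    return "".join(out)


# --------------------------------------------------------------------------
# PDB (ATOM/HETATM records, Angstrom)

def _read_pdb(text: str, path: Path) -> CoordinateSet:
    records = []
    box = None
    serial_fallback = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip().upper()
        if rec == "CRYST1":
            try:
                box = np.array([float(line[6:15]), float(line[15:24]),
                                float(line[24:33])]) * ANGSTROM_TO_NM
            except ValueError as exc:
                raise ParseError("malformed CRYST1 record", path=path,
                                 line=lineno) from exc
        elif rec in ("ATOM", "HETATM"):
            serial_fallback += 1
            try:
                serial = int(line[6:11])
            except ValueError:
                serial = serial_fallback
            try:
                records.append(dict(
                    serial=serial,
                    atom_name=line[12:16].strip(),
                    residue_name=line[17:20].strip(),
                    residue_id=int(line[22:26]),
                    chain_or_mol=line[21].strip(),
                    x=float(line[30:38]) * ANGSTROM_TO_NM,
                    y=float(line[38:46]) * ANGSTROM_TO_NM,
                    z=float(line[46:54]) * ANGSTROM_TO_NM,
                ))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"malformed {rec} record: {exc}", path=path,
                                 line=lineno) from exc
    serials = [r["serial"] for r in records]
    if any(b <= a for a, b in zip(serials, serials[1:])):
        for i, r in enumerate(records, start=1):
            r["serial"] = i
    return CoordinateSet(_make_atoms(records), box=box, source_format="pdb")


def _pdb_atom_name(name: str) -> str:
    # PDB convention: names shorter than 4 characters start in column 14
    name = name[:4]
    return f" {name:<3s}" if len(name) < 4 else name


def _write_pdb(cs: CoordinateSet) -> str:
    from .elements import element_from_label

    out = []
    if cs.box is not None:
        a, b, c = cs.box * NM_TO_ANGSTROM
        out.append(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}"
                   f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")
    if len(cs) > 99999:
        warnings.warn("more than 99999 atoms: pdb serial field wraps "
                      "modulo 100000")
    for row in cs.atoms.itertuples(index=False):
        elem = element_from_label(str(row.atom_name)) or ""
        chain = (str(row.chain_or_mol)[:1] or " ")
        out.append(
            "ATOM  {:>5d} {:4s} {:<4s}{:1s}{:>4d}    "
            "{:8.3f}{:8.3f}{:8.3f}{:6.2f}{:6.2f}          {:>2s}\n".format(
                row.serial % 100000, _pdb_atom_name(str(row.atom_name)),
                str(row.residue_name)[:4], chain, row.residue_id % 10000,
                row.x * NM_TO_ANGSTROM, row.y * NM_TO_ANGSTROM,
                row.z * NM_TO_ANGSTROM, 1.0, 0.0, elem))
    out.append("END\n")
    return "".join(out)


# --------------------------------------------------------------------------
# XYZ (count + comment header, Angstrom)

def _read_xyz(text: str, path: Path) -> CoordinateSet:
    lines = text.splitlines()
    body = lines
    start = 1
    # A count header is standard but a bare list of "El x y z" lines is
    # tolerated (the single-line example form).
    try:
        natoms = int(lines[0].split()[0])
        body = lines[2:2 + natoms]
        start = 3
        if len(body) < natoms:
            raise ParseError(f"expected {natoms} atom lines", path=path,
                             line=len(lines))
    except (ValueError, IndexError):
        body = [ln for ln in lines if ln.strip()]
        start = 1
    records = []
    for i, line in enumerate(body):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError("xyz atom line needs 'element x y z'",
                             path=path, line=start + i)
        try:
            x, y, z = (float(v) * ANGSTROM_TO_NM for v in parts[1:4])
        except ValueError as exc:
            raise ParseError(f"non-numeric xyz coordinate: {exc}", path=path,
                             line=start + i) from exc
        records.append(dict(serial=i + 1, atom_name=parts[0],
                            residue_name="MOL", residue_id=1,
                            chain_or_mol="", x=x, y=y, z=z))
    return CoordinateSet(_make_atoms(records), box=None, source_format="xyz")


def _write_xyz(cs: CoordinateSet) -> str:
    out = [f"{len(cs)}\n", "Written by mimicprep\n"]
    for row in cs.atoms.itertuples(index=False):
        out.append("{:<4s} {:14.6f} {:14.6f} {:14.6f}\n".format(
            str(row.atom_name), row.x * NM_TO_ANGSTROM,
            row.y * NM_TO_ANGSTROM, row.z * NM_TO_ANGSTROM))
    return "".join(out)


# --------------------------------------------------------------------------
# CPMD GEOMETRY (Bohr; trailing velocity columns ignored)

def _read_geometry(text: str, path: Path) -> CoordinateSet:
    records = []
    i = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ParseError("GEOMETRY line needs at least three floats",
                             path=path, line=lineno)
        try:
            x, y, z = (float(v) * BOHR_TO_NM for v in parts[:3])
        except ValueError as exc:
            raise ParseError(f"non-numeric GEOMETRY coordinate: {exc}",
                             path=path, line=lineno) from exc
        i += 1
        records.append(dict(serial=i, atom_name="X", residue_name="MOL",
                            residue_id=1, chain_or_mol="", x=x, y=y, z=z))
    return CoordinateSet(_make_atoms(records), box=None,
                         source_format="cpmd_geometry")


def _write_geometry(cs: CoordinateSet) -> str:
    out = []
    for row in cs.atoms.itertuples(index=False):
        out.append("{:18.8f} {:18.8f} {:18.8f} {:18.8f} {:18.8f} {:18.8f}\n"
                   .format(row.x * NM_TO_BOHR, row.y * NM_TO_BOHR,
                           row.z * NM_TO_BOHR, 0.0, 0.0, 0.0))
    return "".join(out)
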