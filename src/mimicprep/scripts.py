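"""Structured document models for the plain-text formats the toolkit
emits and consumes: CPMD input scripts (&SECTION ... &END), GROMACS index
(.ndx) and run-parameter (.mdp) files, and the pseudopotential-information
table.

All models round-trip: parse -> serialize -> parse is the identity on the
structure, with section order (CPMD), group order (ndx) and comments/order
(mdp) preserved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from .errors import ChemistryError, ParseError, UsageError


# --------------------------------------------------------------------------
# CPMD input scripts

def _numeric_line(line: str) -> bool:
    toks = line.split()
    if not toks:
        return False
    for t in toks:
        try:
            float(t)
        except ValueError:
            return False
    return True


class CpmdSection:
    """One &NAME ... &END section, stored as verbatim lines.

    Keyword access follows the CPMD convention that a keyword's value may
    sit either on the same line (``FUNCTIONAL BLYP``) or on the following
    line (``CHARGE`` / ``0``).
    """

    def __init__(self, name: str, lines: list[str] | None = None):
        object.__setattr__(self, "name", name.upper())
        object.__setattr__(self, "lines", list(lines or []))

    def __eq__(self, other):
        return (isinstance(other, CpmdSection) and self.name == other.name
                and self.lines == other.lines)

    def __repr__(self):
        return f"CpmdSection({self.name!r}, {len(self.lines)} lines)"

    def _find(self, keyword: str) -> int | None:
        kw = keyword.upper()
        for i, line in enumerate(self.lines):
            toks = line.split()
            if toks and toks[0].upper() == kw:
                return i
        return None

    def get(self, keyword: str):
        """Value of a keyword: trailing tokens on its line, or the next
        line when the keyword stands alone.  Numeric values are returned
        as int/float."""
        i = self._find(keyword)
        if i is None:
            raise KeyError(keyword)
        toks = self.lines[i].split()
        if len(toks) > 1:
            value = " ".join(toks[1:])
        elif i + 1 < len(self.lines):
            value = self.lines[i + 1].strip()
        else:
            return ""
        for conv in (int, float):
            try:
                return conv(value)
            except ValueError:
                pass
        return value

    def set(self, keyword: str, value=None) -> None:
        """Set a keyword, replacing any existing occurrence.  A non-None
        value is written on the following line (CPMD convention)."""
        i = self._find(keyword)
        if i is not None:
            end = i + 1
            if len(self.lines[i].split()) == 1:
                while end < len(self.lines) and _numeric_line(self.lines[end]):
                    end += 1
            del self.lines[i:end]
        else:
            i = len(self.lines)
        new = [keyword.upper()]
        if value is not None:
            new.append(str(value))
        self.lines[i:i] = new

    def __getattr__(self, keyword: str):
        if keyword.startswith("_"):
            raise AttributeError(keyword)
        try:
            return self.get(keyword)
        except KeyError:
            raise AttributeError(f"section &{self.name} has no keyword "
                                 f"{keyword!r}")

    def __setattr__(self, keyword: str, value):
        self.set(keyword, value)


class CpmdScript:
    """Ordered collection of &SECTION blocks with dot access
    (``script.SYSTEM.CHARGE``)."""

    def __init__(self, sections: list[CpmdSection] | None = None):
        object.__setattr__(self, "sections", {})
        for s in sections or []:
            self.add_section(s)

    def add_section(self, section: CpmdSection, replace: bool = True) -> None:
        if not replace and section.name in self.sections:
            raise UsageError(f"duplicate section &{section.name}")
        self.sections[section.name] = section

    def has_section(self, name: str) -> bool:
        return name.upper() in self.sections

    def __getattr__(self, name: str):
        if name.startswith("_"):
            raise AttributeError(name)
        try:
            return self.sections[name.upper()]
        except KeyError:
            raise AttributeError(f"no section &{name.upper()}")

    def __eq__(self, other):
        return (isinstance(other, CpmdScript)
                and list(self.sections.values())
                == list(other.sections.values()))


def parse_cpmd(text: str, path=None) -> CpmdScript:
    """Parse a CPMD input script.  Unknown sections are preserved
    verbatim; an unterminated section is a parse error naming it."""
    script = CpmdScript()
    current: CpmdSection | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        stripped = raw.strip()
        if current is None:
            if not stripped:
                continue
            if stripped.startswith("&"):
                current = CpmdSection(stripped[1:].strip())
            # stray text outside any section is ignored
        else:
            if stripped.upper() == "&END":
                script.add_section(current)
                current = None
            elif stripped.startswith("&"):
                raise ParseError(f"section &{current.name} not terminated "
                                 f"before &{stripped[1:]}", path=path,
                                 line=lineno)
            else:
                current.lines.append(raw.rstrip("\n"))
    if current is not None:
        raise ParseError(f"unterminated section &{current.name}", path=path)
    return script


def serialize_cpmd(script: CpmdScript) -> str:
    out = []
    for section in script.sections.values():
        out.append(f"&{section.name}")
        out.extend(section.lines)
        out.append("&END")
        out.append("")
    return "\n".join(out).rstrip("\n") + "\n"


def read_cpmd(path) -> CpmdScript:
    path = Path(path)
    return parse_cpmd(path.read_text(), path=path)


def write_cpmd(script: CpmdScript, path) -> None:
    Path(path).write_text(serialize_cpmd(script))


# --------------------------------------------------------------------------
# GROMACS index files

#: ndx lines wrap after this many indices
NDX_WRAP = 15


@dataclass
class NdxFile:
    """Ordered named groups of 1-based atom indices."""

    groups: dict[str, list[int]] = dc_field(default_factory=dict)

    def add_group(self, name: str, indices) -> None:
        indices = [int(i) for i in indices]
        if not indices:
            raise UsageError("no atoms selected: refusing to create an "
                             "empty index group")
        if any(i <= 0 for i in indices):
            raise UsageError("ndx indices must be positive")
        self.groups[name] = indices


def serialize_ndx(ndx: NdxFile) -> str:
    out = []
    for name, indices in ndx.groups.items():
        out.append(f"[ {name} ]")
        for start in range(0, len(indices), NDX_WRAP):
            chunk = indices[start:start + NDX_WRAP]
            out.append(" ".join(str(i) for i in chunk))
    return "\n".join(out) + "\n"


def parse_ndx(text: str) -> NdxFile:
    ndx = NdxFile()
    current = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        m = re.match(r"\[\s*(.+?)\s*\]", line)
        if m:
            current = m.group(1)
            ndx.groups[current] = []
        elif current is not None:
            ndx.groups[current].extend(int(t) for t in line.split())
    return ndx


def write_ndx(ndx: NdxFile, path) -> None:
    if not ndx.groups or not any(ndx.groups.values()):
        raise UsageError("no atoms selected")
    Path(path).write_text(serialize_ndx(ndx))


# --------------------------------------------------------------------------
# GROMACS mdp files

def _norm_mdp_key(key: str) -> str:
    return key.strip().lower().replace("-", "_")


@dataclass
class MdpFile:
    """GROMACS run-parameter file, order and comments preserved."""

    lines: list[str] = dc_field(default_factory=list)
    #: normalized key -> line index
    _index: dict[str, int] = dc_field(default_factory=dict)

    def keys(self):
        return list(self._index)

    def get(self, key: str) -> str:
        i = self._index[_norm_mdp_key(key)]
        value = self.lines[i].split("=", 1)[1]
        return value.split(";", 1)[0].strip()

    def set(self, key: str, value: str) -> None:
        norm = _norm_mdp_key(key)
        if norm in self._index:
            i = self._index[norm]
            display = self.lines[i].split("=", 1)[0].strip()
            self.lines[i] = f"{display} = {value}"
        else:
            self._index[norm] = len(self.lines)
            self.lines.append(f"{key} = {value}")

    def as_dict(self) -> dict[str, str]:
        return {k: self.get(k) for k in self._index}

    def copy(self) -> "MdpFile":
        return MdpFile(lines=list(self.lines), _index=dict(self._index))


def parse_mdp(text: str) -> MdpFile:
    mdp = MdpFile()
    for raw in text.splitlines():
        line = raw.rstrip("\n")
        content = line.split(";", 1)[0]
        if "=" in content:
            key = content.split("=", 1)[0]
            mdp._index[_norm_mdp_key(key)] = len(mdp.lines)
        mdp.lines.append(line)
    return mdp


def serialize_mdp(mdp: MdpFile) -> str:
    return "\n".join(mdp.lines) + "\n"


def patch_mdp(mdp: MdpFile, required: dict[str, str]) -> MdpFile:
    """Return a copy of ``mdp`` with the given keys set (existing keys
    overwritten in place, missing keys appended); all other lines are
    preserved verbatim."""
    out = mdp.copy()
    for key, value in required.items():
        out.set(key, value)
    return out


def read_mdp(path) -> MdpFile:
    return parse_mdp(Path(path).read_text())


def write_mdp(mdp: MdpFile, path) -> None:
    Path(path).write_text(serialize_mdp(mdp))


# --------------------------------------------------------------------------
# Pseudopotential information table

@dataclass(frozen=True)
class PpEntry:
    pseudopotential_filename: str
    lmax: str
    loc: str | None = None
    boundary_filename: str | None = None


@dataclass
class PpInfoTable:
    """Per-element pseudopotential details.

    File syntax: one record per element, whitespace-separated ::

        <element> <pp filename> LMAX=<l> [LOC=<l>] [<boundary pp filename>]

    with ``#`` comments.
    """

    entries: dict[str, PpEntry] = dc_field(default_factory=dict)

    def require(self, element: str, boundary: bool = False) -> PpEntry:
        entry = self.entries.get(element)
        if entry is None:
            raise ChemistryError(f"no pseudopotential entry for element "
                                 f"{element}")
        if boundary and entry.boundary_filename is None:
            raise ChemistryError(f"no boundary pseudopotential for element "
                                 f"{element}")
        return entry


def parse_pp_info(text: str, path=None) -> PpInfoTable:
    table = PpInfoTable()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        toks = line.split()
        if len(toks) < 3:
            raise ParseError("pseudopotential record needs at least "
                             "'<element> <filename> LMAX=<l>'", path=path,
                             line=lineno)
        element, filename = toks[0], toks[1]
        lmax = loc = boundary = None
        for tok in toks[2:]:
            up = tok.upper()
            if up.startswith("LMAX="):
                lmax = tok.split("=", 1)[1]
            elif up.startswith("LOC="):
                loc = tok.split("=", 1)[1]
            else:
                boundary = tok
        if lmax is None:
            raise ParseError(f"missing LMAX= for element {element}",
                             path=path, line=lineno)
        table.entries[element] = PpEntry(filename, lmax, loc, boundary)
    return table


def serialize_pp_info(table: PpInfoTable) -> str:
    out = ["# element  pp-filename  LMAX=<l> [LOC=<l>] [boundary-pp-filename]"]
    for element, e in table.entries.items():
        toks = [element, e.pseudopotential_filename, f"LMAX={e.lmax}"]
        if e.loc is not None:
            toks.append(f"LOC={e.loc}")
        if e.boundary_filename is not None:
            toks.append(e.boundary_filename)
        out.append("  ".join(toks))
    return "\n".join(out) + "\n"


def read_pp_info(path) -> PpInfoTable:
    path = Path(path)
    return parse_pp_info(path.read_text(), path=path)
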