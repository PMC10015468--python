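"""GROMACS -> CPMD atom index translation.

When a coupled simulation transfers the system to the QM engine, atoms
are renumbered: the QM atoms come first, in the &ATOMS emission order,
and the MM atoms follow, regrouped by chemical species.  That reordering
is opaque to the user, which makes it hard to reference MM atoms (e.g. in
a CONSTRAINTS block) by their CPMD index.  This module reproduces the
numbering so any GROMACS index can be translated.

The MM grouping rule used here — ascending atomic number, ascending
GROMACS index within a species — is this package's deterministic
rendering of the engine's reordering.  It is deliberately centralized in
:func:`build_index_map` so it can be swapped out if the engine's actual
rule is found to differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import elements as el
from .errors import ChemistryError, UsageError
from .preparation import detect_boundary_atoms, qm_emission_order
from .topology import Topology

log = logging.getLogger(__name__)

FORMAT_STYLES = ("table", "list", "range")


@dataclass
class IndexMap:
    """Bijection between GROMACS ids and CPMD ids over all N atoms.

    ``atoms`` is indexed by GROMACS id with columns ``cpmd_id``,
    ``partition`` ("qm"/"mm"), ``species``, ``name``, ``resid``.
    """

    atoms: pd.DataFrame
    n_qm: int

    def cpmd_id(self, gmx_id: int) -> int:
        return int(self.atoms.loc[gmx_id, "cpmd_id"])

    def gmx_id(self, cpmd_id: int) -> int:
        hits = self.atoms.index[self.atoms["cpmd_id"] == cpmd_id]
        if len(hits) != 1:
            raise UsageError(f"no atom with CPMD id {cpmd_id}")
        return int(hits[0])

    def pairs(self) -> list[tuple[int, int]]:
        """(gromacs id, cpmd id) for the QM atoms, ascending GROMACS id."""
        qm = self.atoms[self.atoms["partition"] == "qm"]
        return [(int(g), int(c)) for g, c in qm["cpmd_id"].items()]


def build_index_map(top: Topology, region,
                    boundary=None) -> IndexMap:
    """Build the full GROMACS<->CPMD index bijection.

    QM atoms get CPMD ids 1..|QM| in &ATOMS emission order (ascending
    atomic number, boundary species last, ascending GROMACS index within
    a block); MM atoms get |QM|+1..N grouped by species in ascending
    atomic number, ascending GROMACS index within a species.

    Requires every atom's element to be resolved (MM included): run the
    topology repair tool (fix_top) first if the topology lacks species
    information.
    """
    df = top.global_atoms
    region = sorted(int(i) for i in region)
    region_set = set(region)
    if boundary is None:
        boundary = [b for b in detect_boundary_atoms(top, region)]

    mm = df[~df["id"].isin(region_set)]
    unresolved = mm.loc[mm["element"].isna(), "type"].unique()
    if len(unresolved):
        raise ChemistryError(
            "MM atom type(s) without a resolved element: "
            + ", ".join(sorted(map(str, unresolved)))
            + "; repair the topology with fix_top before index mapping")
    if df["element"].isna().any():
        raise ChemistryError("QM atoms with unresolved elements; resolve "
                             "species before index mapping")

    order: list[int] = []
    for _, _, gids in qm_emission_order(top, region, boundary):
        order.extend(gids)
    mm_ids = sorted((int(i) for i in mm["id"]),
                    key=lambda g: (el.atomic_number(df.at[g - 1, "element"]),
                                   g))
    order.extend(mm_ids)

    cpmd_of = {g: i for i, g in enumerate(order, start=1)}
    out = pd.DataFrame({
        "cpmd_id": [cpmd_of[int(g)] for g in df["id"]],
        "partition": ["qm" if int(g) in region_set else "mm"
                      for g in df["id"]],
        "species": df["element"].tolist(),
        "name": df["name"].tolist(),
        "resid": df["resid"].tolist(),
    }, index=pd.Index(df["id"], name="gmx_id"))
    return IndexMap(atoms=out, n_qm=len(region))


def _ranges(ids: list[int]) -> str:
    """Maximal runs of consecutive integers as "a-b", comma-joined."""
    if not ids:
        return ""
    runs = []
    start = prev = ids[0]
    for v in ids[1:]:
        if v == prev + 1:
            prev = v
            continue
        runs.append((start, prev))
        start = prev = v
    runs.append((start, prev))
    return ",".join(f"{a}-{b}" if a != b else f"{a}" for a, b in runs)


def format_indices(imap: IndexMap, gmx_ids, style: str = "table") -> str:
    """Render the CPMD indices of the given GROMACS atoms.

    ``table``: one row per atom (gromacs id, cpmd id, name, resid,
    species); ``list``: space-separated CPMD ids; ``range``: maximal runs
    of consecutive CPMD ids like ``3-5,9``.
    """
    if style not in FORMAT_STYLES:
        raise UsageError(f"unknown print style {style!r}; choose from "
                         f"{FORMAT_STYLES}")
    gmx_ids = sorted(int(i) for i in gmx_ids)
    if not gmx_ids:
        log.warning("empty selection: nothing to print")
        return ""
    sub = imap.atoms.loc[gmx_ids]
    cpmd_ids = sorted(int(c) for c in sub["cpmd_id"])
    if style == "list":
        return " ".join(str(c) for c in cpmd_ids)
    if style == "range":
        return _ranges(cpmd_ids)
    table = sub.reset_index()[["gmx_id", "cpmd_id", "name", "resid",
                               "species"]]
    table = table.rename(columns={"gmx_id": "gromacs_id"})
    return table.to_string(index=False)
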