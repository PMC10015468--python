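"""Shared fixtures and independent oracles.

The brute-force selection oracle and the random query generator live
here: they evaluate queries row by row with plain Python, independently
of the vectorized evaluator they are used to check.
"""

from __future__ import annotations

import numpy as np
import pytest

from mimicprep import read_coordinates, read_topology
from mimicprep.fixtures import (make_peptide_chain,
                                make_solvated_small_molecule)
from mimicprep.selection import And, Comparison, Not, Or

# --------------------------------------------------------------------------
# Study systems


@pytest.fixture(scope="session")
def solvated(tmp_path_factory):
    return make_solvated_small_molecule(
        5, seed=7, out_dir=tmp_path_factory.mktemp("solvated"))


@pytest.fixture(scope="session")
def solvated_top(solvated):
    return read_topology(solvated.top_path)


@pytest.fixture(scope="session")
def solvated_coords(solvated):
    return read_coordinates(solvated.gro_path)


@pytest.fixture(scope="session")
def peptide(tmp_path_factory):
    return make_peptide_chain(
        4, seed=3, out_dir=tmp_path_factory.mktemp("peptide"))


@pytest.fixture(scope="session")
def peptide_top(peptide):
    return read_topology(peptide.top_path)


# --------------------------------------------------------------------------
# Brute-force selection oracle

_FIELD = {"resname": "resname", "resid": "resid", "name": "name",
          "type": "type", "id": "id", "mol": "mol_name"}


def row_matches(node, row) -> bool:
    """Evaluate a query AST on a single atom row (plain Python)."""
    if isinstance(node, Comparison):
        value = row[_FIELD[node.keyword]]
        if node.keyword in ("resid", "id"):
            value = int(value)
        op = node.operator
        if op == "is":
            return value == node.literal
        if op == "not":
            return value != node.literal
        if op == ">":
            return value > node.literal
        if op == "<":
            return value < node.literal
        if op == ">=":
            return value >= node.literal
        return value <= node.literal
    if isinstance(node, And):
        return row_matches(node.left, row) and row_matches(node.right, row)
    if isinstance(node, Or):
        return row_matches(node.left, row) or row_matches(node.right, row)
    if isinstance(node, Not):
        return not row_matches(node.operand, row)
    raise TypeError(node)


def brute_force_ids(ast, top) -> list[int]:
    """Row-by-row reference evaluation over the global atom table."""
    df = top.global_atoms
    return [int(row["id"]) for _, row in df.iterrows()
            if row_matches(ast, row)]


def random_ast(rng: np.random.Generator, top, depth: int = 4):
    """Random query tree of at most the given depth, with literals drawn
    half from values present in the table, half arbitrary."""
    df = top.global_atoms
    kind = rng.choice(["cmp", "and", "or", "not"]) if depth > 0 else "cmp"
    if kind == "cmp":
        keyword = str(rng.choice(["resname", "resid", "name", "type", "id",
                                  "mol"]))
        if keyword in ("resid", "id"):
            operator = str(rng.choice(["is", "not", ">", "<", ">=", "<="]))
            hi = int(df[_FIELD[keyword]].max())
            literal = int(rng.integers(0, hi + 2))
        else:
            operator = str(rng.choice(["is", "not"]))
            if rng.random() < 0.5:
                literal = str(rng.choice(df[_FIELD[keyword]].unique()))
            else:
                literal = str(rng.choice(["XX", "C1", "SOL", "none"]))
        return Comparison(keyword, operator, literal)
    if kind == "not":
        return Not(random_ast(rng, top, depth - 1))
    cls = And if kind == "and" else Or
    return cls(random_ast(rng, top, depth - 1),
               random_ast(rng, top, depth - 1))
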