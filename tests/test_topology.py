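"""Topology parsing, element inference, and repair."""

import warnings

import numpy as np
import pytest

from mimicprep import (ChemistryError, ParseError, UsageError,
                       guess_elements, read_topology)
from mimicprep.topology import fix_top


def write_minimal(tmp_path, atoms_extra="", atomtypes=None, name="t.top"):
    atomtypes = atomtypes if atomtypes is not None else (
        "[ atomtypes ]\n"
        "ca  12.011  -0.10  A  0.3  0.4\n"
        "ha   1.008   0.10  A  0.2  0.1\n")
    text = (atomtypes +
            "\n[ moleculetype ]\nMOL 3\n"
            "[ atoms ]\n"
            f"1 ca 1 MOL C1 1 {atoms_extra}\n"
            f"2 ha 1 MOL H1 1 {atoms_extra}\n"
            "[ bonds ]\n1 2 1\n"
            "\n[ system ]\ntest\n[ molecules ]\nMOL 2\n")
    p = tmp_path / name
    p.write_text(text)
    return p


class TestParsing:
    def test_molecule_block_flattening(self, solvated, solvated_top):
        """ACT(10 atoms) x1 then SOL(3) x5 gives 25 global atoms in
        GROMACS order with contiguous 1-based ids."""
        df = solvated_top.global_atoms
        assert len(df) == 25
        assert list(df["id"]) == list(range(1, 26))
        assert set(df.loc[:9, "mol_name"]) == {"ACT"}
        assert set(df.loc[10:, "mol_name"]) == {"SOL"}

    def test_charge_fallback_to_registry_then_zero(self, tmp_path):
        """Atoms without a charge column inherit the registry charge; a
        registry without charges means 0.0 with a warning."""
        p = write_minimal(tmp_path)  # no charge column in [ atoms ]
        top = read_topology(p)
        assert np.allclose(top.global_atoms["charge"], [-0.1, 0.1] * 2)

        r = tmp_path / "zero.top"  # type absent from the registry
        r.write_text("[ moleculetype ]\nMOL 3\n[ atoms ]\n"
                     "1 zz 1 MOL Q1 1\n\n[ system ]\nx\n"
                     "[ molecules ]\nMOL 1\n")
        with pytest.warns(UserWarning, match="assuming 0.0"):
            top0 = read_topology(r)
        assert top0.global_atoms["charge"].iloc[0] == 0.0

    def test_global_charge_sum_matches_hand_sum(self, solvated,
                                                solvated_top):
        """Total charge equals sum over molecules of per-copy sum x count
        (independent summation over the fixture definition)."""
        expected = sum(fx_sum * solvated.molecule_counts[mol]
                       for mol, fx_sum in solvated.charge_sums.items())
        assert solvated_top.global_atoms["charge"].sum() == \
            pytest.approx(expected, abs=1e-9)

    def test_comments_and_whitespace_insensitive(self, tmp_path):
        p = write_minimal(tmp_path)
        ref = read_topology(p).global_atoms
        noisy = []
        for line in p.read_text().splitlines():
            noisy.append("  " + line.replace(" ", "   ") + " ; trailing")
            noisy.append("; a full-line comment")
            noisy.append("")
        q = tmp_path / "noisy.top"
        q.write_text("\n".join(noisy) + "\n")
        assert read_topology(q).global_atoms.equals(ref)

    def test_missing_include_names_chain(self, tmp_path):
        p = tmp_path / "a.top"
        p.write_text('#include "missing.itp"\n')
        with pytest.raises(UsageError, match="missing.itp"):
            read_topology(p)

    def test_undefined_moleculetype_in_molecules(self, tmp_path):
        p = tmp_path / "b.top"
        p.write_text("[ system ]\nx\n[ molecules ]\nGHOST 1\n")
        with pytest.raises(ParseError, match="GHOST"):
            read_topology(p)

    def test_duplicate_moleculetype_rejected(self, tmp_path):
        p = tmp_path / "c.top"
        p.write_text("[ moleculetype ]\nM 3\n[ atoms ]\n1 ca 1 M C1 1 0 12\n"
                     "[ moleculetype ]\nM 3\n[ atoms ]\n1 ca 1 M C1 1 0 12\n"
                     "[ system ]\nx\n[ molecules ]\nM 1\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_topology(p)

    def test_settles_become_oh_bonds(self, solvated_top):
        """Rigid-water settles are translated into O-H bonds so boundary
        detection sees water connectivity."""
        bonds = set(map(frozenset, solvated_top.global_bonds()))
        # first water is atoms 11,12,13
        assert frozenset((11, 12)) in bonds and frozenset((11, 13)) in bonds

    def test_ifdef_flexible_branch(self, solvated):
        """Defining FLEXIBLE picks the explicit-bond branch instead."""
        rigid = read_topology(solvated.top_path)
        flexible = read_topology(solvated.top_path, defines=("FLEXIBLE",))
        # both see the same water connectivity, via settles vs bonds
        assert sorted(map(tuple, map(sorted, rigid.global_bonds()))) == \
            sorted(map(tuple, map(sorted, flexible.global_bonds())))


class TestElementInference:
    def test_mass_rule(self, tmp_path):
        top = read_topology(write_minimal(tmp_path))
        guess_elements(top)
        assert list(top.global_atoms["element"][:2]) == ["C", "H"]

    def test_two_letter_symbol_precedes_one_letter(self, tmp_path):
        p = tmp_path / "cl.top"
        p.write_text("[ moleculetype ]\nM 3\n[ atoms ]\n"
                     "1 qq 1 M CL1 1 0.0\n[ system ]\nx\n"
                     "[ molecules ]\nM 1\n")
        top = read_topology(p)   # type qq unknown, no mass
        guess_elements(top)
        assert top.global_atoms["element"].iloc[0] == "Cl"

    def test_nsa_table_takes_precedence(self, tmp_path):
        top = read_topology(write_minimal(tmp_path))
        guess_elements(top, nsa_table={"ca": "Ca"})
        assert top.global_atoms["element"].iloc[0] == "Ca"

    def test_guessing_disabled_errors_on_unresolved(self, solvated):
        top = read_topology(solvated.top_path)
        with pytest.raises(ChemistryError, match="disabled"):
            guess_elements(top, guess=False)

    def test_idempotent(self, solvated):
        top = read_topology(solvated.top_path)
        guess_elements(top)
        first = list(top.global_atoms["element"])
        guess_elements(top)
        assert list(top.global_atoms["element"]) == first

    def test_scrambled_names_recovered_by_mass(self, tmp_path):
        """With meaningless names but correct masses, the mass rule
        recovers every ground-truth element."""
        truth = {"qx": ("N", 14.007), "qy": ("O", 15.9994),
                 "qz": ("S", 32.06), "qw": ("Fe", 55.845),
                 "qv": ("H", 2.014)}  # deuterium-like mass -> H
        lines = ["[ moleculetype ]", "M 3", "[ atoms ]"]
        for i, (typ, (_, mass)) in enumerate(truth.items(), start=1):
            lines.append(f"{i} {typ} 1 M ZZ{i} 1 0.0 {mass}")
        lines += ["[ system ]", "x", "[ molecules ]", "M 1"]
        p = tmp_path / "scrambled.top"
        p.write_text("\n".join(lines) + "\n")
        top = read_topology(p)
        guess_elements(top)
        assert list(top.global_atoms["element"]) == \
            [e for e, _ in truth.values()]

    def test_fixture_ground_truth_recovered(self, solvated, solvated_top):
        top = read_topology(solvated.top_path)
        guess_elements(top)
        for row in top.global_atoms.itertuples(index=False):
            assert row.element == solvated.true_elements[row.type], row


class TestFixTop:
    def test_output_resolves_without_guessing(self, peptide, tmp_path):
        out_top = fix_top(peptide.top_path, tmp_path / "fixed")
        fixed = read_topology(out_top)
        guess_elements(fixed, guess=False)  # must not raise
        truth = peptide.true_elements
        for row in fixed.global_atoms.itertuples(index=False):
            assert row.element == truth[row.type]

    def test_idempotent(self, peptide, tmp_path):
        out1 = fix_top(peptide.top_path, tmp_path / "f1", clear_sections=True)
        out2 = fix_top(out1, tmp_path / "f2", clear_sections=True)
        d1, d2 = out1.parent, out2.parent
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*")
                        if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*")
                        if p.is_file())
        assert files1 == files2
        for f in files1:
            assert (d1 / f).read_text() == (d2 / f).read_text(), f

    def test_clear_sections_flag_semantics(self, tmp_path, peptide):
        """With the flag unset, non-target [ atomtypes ] sections are
        preserved verbatim; with it set they are removed."""
        extra = "[ atomtypes ]\nzz_extra  1.008  0.0  A  0.1  0.1\n"
        src = tmp_path / "src"
        src.mkdir()
        import shutil
        shutil.copytree(peptide.directory / "ffdir", src / "ffdir")
        shutil.copy(peptide.directory / "peptide.itp", src)
        top_text = (peptide.top_path.read_text()
                    .replace("[ system ]", extra + "\n[ system ]"))
        (src / "topol.top").write_text(top_text)

        keep = fix_top(src / "topol.top", tmp_path / "keep")
        assert "zz_extra" in keep.read_text()
        cleared = fix_top(src / "topol.top", tmp_path / "cls",
                          clear_sections=True)
        assert "zz_extra" not in cleared.read_text()
        # but the consolidated section still carries the type
        assert "zz_extra" in \
            (tmp_path / "cls" / "ffdir" / "ffnonbonded.itp").read_text()

    def test_unresolvable_type_errors_before_writing(self, tmp_path):
        p = tmp_path / "bad.top"
        p.write_text("[ atomtypes ]\nzq  999.0  0.0  A  0.1  0.1\n"
                     "[ moleculetype ]\nM 3\n[ atoms ]\n1 zq 1 M QQQ 1 0\n"
                     "[ system ]\nx\n[ molecules ]\nM 1\n")
        out = tmp_path / "out"
        with pytest.raises(ChemistryError):
            fix_top(p, out)
        assert not out.exists()

    def test_without_nonbonded_include_writes_fixed_itp(self, tmp_path):
        p = write_minimal(tmp_path)
        out_top = fix_top(p, tmp_path / "noff")
        assert (tmp_path / "noff" / "atomtypes_fixed.itp").exists()
        fixed = read_topology(out_top)
        guess_elements(fixed, guess=False)
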