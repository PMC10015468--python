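"""QM-region engine: box, charge, boundary detection, input generation."""

import numpy as np
import pytest

from mimicprep import (ChemistryError, NonIntegralChargeWarning,
                       Preparation, UsageError, compute_qm_box,
                       compute_qm_charge, detect_boundary_atoms,
                       read_cpmd, read_coordinates, read_mdp, read_pp_info,
                       read_topology, serialize_cpmd, serialize_ndx)
from mimicprep.units import NM_TO_BOHR


@pytest.fixture()
def solvated_prep(solvated, solvated_top, solvated_coords):
    prep = Preparation(read_topology(solvated.top_path), solvated_coords)
    return prep, solvated


def generate(prep, fx, **kw):
    return prep.get_mimic_input(template=read_cpmd(fx.template_path),
                                pp=read_pp_info(fx.pp_info_path), **kw)


class TestRegionEditing:
    def test_add_selects_the_solute(self, solvated_prep):
        prep, fx = solvated_prep
        prep.add("resname is ACT")
        assert prep.region == fx.expected_selections["solute"]

    def test_add_is_idempotent(self, solvated_prep):
        prep, _ = solvated_prep
        once = list(prep.add("resname is ACT"))
        twice = list(prep.add("resname is ACT"))
        assert once == twice

    def test_delete_inverts_add(self, solvated_prep):
        prep, _ = solvated_prep
        prep.add("resname is ACT")
        prep.delete("resname is ACT")
        assert prep.region == []

    def test_delete_outside_region_warns(self, solvated_prep):
        prep, _ = solvated_prep
        prep.add("resname is ACT")
        with pytest.warns(UserWarning, match="not in the QM region"):
            prep.delete("resname is SOL")
        assert len(prep.region) == 10


class TestQmBox:
    def test_stated_rule_with_default_padding(self):
        """Two atoms 1 nm apart, 0.35 nm pad: cell edge 1.7 nm = 32.125
        Bohr."""
        box = compute_qm_box(np.array([[0.0, 0.0, 0.0], [1.0, 0.1, 0.1]]),
                             0.35)
        assert round(box.lengths_bohr[0], 3) == 32.125

    def test_degenerate_axis_with_zero_padding_errors(self):
        with pytest.raises(UsageError, match="zero volume"):
            compute_qm_box(np.array([[1.0, 1.0, 1.0]]), 0.0)

    def test_extent_plus_twice_padding_property(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            cloud = rng.uniform(-2, 5, size=(100, 3))
            pad = float(rng.uniform(0, 1))
            box = compute_qm_box(cloud, pad)
            extent = cloud.max(axis=0) - cloud.min(axis=0)
            expected = (extent + 2 * pad) * NM_TO_BOHR
            assert np.abs(box.lengths_bohr - expected).max() < 1e-9 * NM_TO_BOHR


class TestQmCharge:
    def test_neutral_solute(self, solvated_top):
        raw, declared = compute_qm_charge(solvated_top, range(1, 11))
        assert declared == 0
        assert raw == pytest.approx(0.0, abs=1e-9)

    def test_two_charged_residues_sum(self, tmp_path):
        from mimicprep.fixtures import make_peptide_chain
        fx = make_peptide_chain(4, seed=3, out_dir=tmp_path,
                                charged_residues=(2, 3))
        top = read_topology(fx.top_path)
        region = (fx.expected_selections["residue_2"]
                  + fx.expected_selections["residue_3"])
        _, declared = compute_qm_charge(top, region)
        assert declared == 2

    def test_bond_severing_selection_warns(self, solvated_top):
        # solute minus one methyl hydrogen: -0.1 e, not integral
        with pytest.warns(NonIntegralChargeWarning):
            raw, declared = compute_qm_charge(solvated_top, range(1, 10))
        assert declared == 0
        assert raw == pytest.approx(-0.1)


class TestBoundaryDetection:
    def test_fully_contained_molecule(self, solvated_top):
        assert detect_boundary_atoms(solvated_top, range(1, 11)) == []

    def test_whole_system_has_no_boundary(self, solvated_top):
        assert detect_boundary_atoms(
            solvated_top, range(1, solvated_top.n_atoms + 1)) == []

    def test_side_chains_cut_at_the_alpha_carbon(self, peptide, peptide_top):
        region = (peptide.expected_selections["sidechain_1"]
                  + peptide.expected_selections["sidechain_3"])
        expected = (peptide.expected_boundary["sidechain_1"]
                    + peptide.expected_boundary["sidechain_3"])
        assert detect_boundary_atoms(peptide_top, region) == sorted(expected)

    def test_interior_residue_cuts_two_peptide_bonds(self, peptide,
                                                     peptide_top):
        region = peptide.expected_selections["residue_2"]
        assert detect_boundary_atoms(peptide_top, region) == \
            sorted(peptide.expected_boundary["residue_2"])

    def test_matches_brute_force_on_random_regions(self, peptide_top):
        bonds = peptide_top.global_bonds()
        rng = np.random.default_rng(12)
        n = peptide_top.n_atoms
        for _ in range(25):
            region = set(int(i) for i in
                         rng.choice(np.arange(1, n + 1),
                                    size=rng.integers(1, n), replace=False))
            expected = sorted({a for a, b in ((x, y) for x, y in bonds)
                               if (a in region) != (b in region)
                               and a in region}
                              | {b for a, b in bonds
                                 if (a in region) != (b in region)
                                 and b in region})
            assert detect_boundary_atoms(peptide_top, region) == expected


class TestGeneration:
    def test_species_blocks_partition_the_region(self, solvated_prep):
        prep, fx = solvated_prep
        prep.add("resname is ACT")
        result = generate(prep, fx)
        atoms = result.cpmd.ATOMS.lines
        counts = [int(atoms[i + 1].split()[0]) for i, ln in enumerate(atoms)
                  if ln.strip().upper().startswith("LMAX")]
        assert sum(counts) == 10
        overlaps = result.cpmd.MIMIC.get("OVERLAPS")
        assert overlaps == 10

    def test_template_cpmd_dft_preserved_bytewise(self, solvated_prep):
        prep, fx = solvated_prep
        prep.add("resname is ACT")
        result = generate(prep, fx)
        template = read_cpmd(fx.template_path)
        assert result.cpmd.CPMD.lines == template.CPMD.lines
        assert result.cpmd.DFT.lines == template.DFT.lines
        for name in ("MIMIC", "SYSTEM", "ATOMS"):
            assert result.cpmd.has_section(name)

    def test_declared_charge_in_system_section(self, solvated_prep):
        prep, fx = solvated_prep
        prep.add("resname is ACT")
        result = generate(prep, fx)
        assert result.cpmd.SYSTEM.CHARGE == 0

    def test_ndx_group_ascending(self, solvated_prep):
        prep, fx = solvated_prep
        prep.add("resname is ACT")
        result = generate(prep, fx)
        assert result.ndx.groups["QMatoms"] == list(range(1, 11))

    def test_boundary_atoms_form_their_own_block(self, peptide):
        top = read_topology(peptide.top_path)
        coords = read_coordinates(peptide.gro_path)
        prep = Preparation(top, coords)
        prep.add("(resid is 1 or resid is 3) and "
                 "(name is CB or name is OG)")
        result = generate(prep, peptide, boundary=True)
        text = serialize_cpmd(result.cpmd)
        # boundary CB atoms use the boundary pseudopotential file
        assert "C_GIA_BLYP.psp" in text
        atoms = result.cpmd.ATOMS.lines
        counts = [int(atoms[i + 1].split()[0]) for i, ln in enumerate(atoms)
                  if ln.strip().upper().startswith("LMAX")]
        assert sum(counts) == 4  # every region atom in exactly one block

    def test_boundary_without_flag_is_an_error(self, peptide):
        top = read_topology(peptide.top_path)
        prep = Preparation(top, read_coordinates(peptide.gro_path))
        prep.add("resid is 2 and (name is CB or name is OG)")
        with pytest.raises(ChemistryError, match="open valence"):
            generate(prep, peptide)

    def test_missing_pp_entry_lists_elements(self, solvated_prep):
        from mimicprep import parse_pp_info
        prep, fx = solvated_prep
        prep.add("resname is ACT")
        tiny = parse_pp_info("C C.psp LMAX=P\n")
        with pytest.raises(ChemistryError, match="H"):
            prep.get_mimic_input(pp=tiny)

    def test_empty_region_is_an_error(self, solvated_prep):
        prep, fx = solvated_prep
        with pytest.raises(UsageError, match="empty"):
            generate(prep, fx)

    def test_generation_deterministic(self, solvated, solvated_top):
        outs = []
        for _ in range(2):
            top = read_topology(solvated.top_path)
            prep = Preparation(top, read_coordinates(solvated.gro_path))
            prep.add("resname is ACT")
            result = generate(prep, solvated,
                              mdp=read_mdp(solvated.mdp_path))
            outs.append((serialize_cpmd(result.cpmd),
                         serialize_ndx(result.ndx)))
        assert outs[0] == outs[1]

    def test_mdp_patching_and_commands(self, solvated_prep):
        prep, fx = solvated_prep
        prep.add("resname is ACT")
        result = generate(prep, fx, mdp=read_mdp(fx.mdp_path))
        assert result.mdp.get("integrator") == "mimic"
        assert result.mdp.get("qmmm_grps") == "QMatoms"
        assert any(cmd.startswith("gmx grompp") for cmd in result.commands)

    def test_atom_count_mismatch_rejected(self, solvated, peptide):
        top = read_topology(solvated.top_path)
        coords = read_coordinates(peptide.gro_path)
        with pytest.raises(UsageError, match="atoms"):
            Preparation(top, coords)
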