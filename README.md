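# mimicprep

Tools for preparing the input files of a MiMiC-based QM/MM simulation,
in which CPMD treats a small quantum-mechanical (QM) region and GROMACS
treats the classical (MM) remainder. Such a run needs two coordinated
inputs — a CPMD input file whose `&MIMIC`, `&ATOMS` and `&SYSTEM`
sections describe the QM subsystem, and a GROMACS index file naming the
same atoms — and writing them by hand is tedious and error-prone,
especially for large QM regions with covalent cuts. `mimicprep`
automates the whole workflow for computational chemists setting up such
simulations:

* **coordinate I/O** for GROMACS `.gro` (nm), PDB (Å), XYZ (Å) and CPMD
  `GEOMETRY` (Bohr) files, normalized to one tabular representation in nm;
* **topology parsing** of GROMACS `.top`/`.itp` files (recursive
  `#include`, `[ atomtypes ]`, molecules, bonds, settles) into a global
  atom table;
* **element inference** for nonstandard atom types from mass, name and
  type (nearest standard atomic weight within ±0.5 amu; masses below
  3.5 amu are hydrogen), plus `fixtop` to repair a topology in place so
  the QM engine gets every species;
* a human-readable **selection language**
  (`resname/resid/name/type/id/mol` with `is/not/>/</≥/≤`, `and`/`or`,
  brackets) for choosing the QM region interactively or in scripts;
* the **preparation engine**: QM cell sizing (coordinate extent plus
  twice a padding, default 0.35 nm, for the isolated-system
  Martyna–Tuckerman Poisson solver), total-charge bookkeeping,
  open-valence (boundary) atom detection for bonds that cross the QM/MM
  boundary, and deterministic emission of `cpmd.inp` + `index.ndx`;
* **index translation** (`cpmdid`): reproduces the GROMACS→CPMD atom
  renumbering (QM atoms first in species-block order, MM atoms regrouped
  by species) so any atom can be referenced in CPMD, e.g. in a
  `CONSTRAINTS` block.

External engines are never executed: when an `.mdp` file is supplied the
patched parameters are written and the exact `gmx grompp` command line is
printed for the user to run.

## Worked example

The package ships a deterministic generator of synthetic study systems.
Build an acetone-like solute (residue `ACT`, 10 atoms, net charge 0) in
a bath of 5 rigid waters, then prepare the MiMiC inputs with the solute
as the QM region:

```sh
python - <<'EOF'
from mimicprep.fixtures import make_solvated_small_molecule
fx = make_solvated_small_molecule(5, seed=7, out_dir="solv")
EOF
printf 'add resname is ACT\nq\n' | \
  mimicprep prepqm -top solv/topol.top -coords solv/conf.gro \
      -inp solv/template.inp -pp solv/pp_info.dat -mdp solv/mimic.mdp \
      -path run/mimic.tpr
```

which prints

```
selected 10 atom(s)
QM region: 10 atom(s), declared charge 0
wrote: cpmd.inp, index.ndx, mimic_patched.mdp
run: gmx grompp -f mimic_patched.mdp -c solv/conf.gro -p solv/topol.top -n index.ndx -o run/mimic.tpr
run: gmx mdrun -deffnm mimic
run: cpmd.x cpmd.inp > cpmd.out
```

The selection matched the 10 solute atoms; their partial charges sum to
0, so `CHARGE 0` is declared in `&SYSTEM`. `cpmd.inp` now contains the
template's `&CPMD`/`&DFT` sections verbatim plus generated sections: in
`&MIMIC`, the `OVERLAPS` block pairs each GROMACS index with its CPMD
index (`2 <gromacs id> 1 <cpmd id>`); `&ATOMS` holds one block per
element (here H, C, O — 6 + 3 + 1 atoms, in Bohr) with the
pseudopotential details from `pp_info.dat`; `&SYSTEM` carries the cell
sized to the solute extent plus 2 × 0.35 nm. `index.ndx` defines the
`QMatoms` group used by the printed `gmx grompp` command.

The same objects are available as a library:

```python
import mimicprep as mp

top = mp.read_topology("solv/topol.top")
prep = mp.Preparation(top, mp.read_coordinates("solv/conf.gro"))
prep.add("resname is ACT")
out = prep.get_mimic_input(pp=mp.read_pp_info("solv/pp_info.dat"))
print(out.cpmd.SYSTEM.CHARGE)   # -> 0
```

For QM regions that sever covalent bonds (e.g. amino-acid side chains),
pass `-bound`: the atoms with open valences are detected from the bond
list and emitted as a separate species block using each element's
boundary (monovalent) pseudopotential.

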