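# Methods

This note documents the models, rules and design choices behind
`mimicprep`, in the spirit of a methods section: what the package
computes, under which assumptions, and where genuine choices were made.

## The preparation problem

A loosely coupled QM/MM run pairs CPMD (QM) with GROMACS (MM). The MM
side is fully described by the topology, coordinates and run parameters;
the QM side needs a CPMD input whose `&MIMIC` section ties the two
together (paths, MM box, and the mapping between GROMACS and CPMD atom
indices), whose `&ATOMS` section lists the QM atoms per chemical species
with pseudopotential assignments, and whose `&SYSTEM` section declares
the QM cell and total charge. `mimicprep` derives all of this from the
GROMACS inputs plus a user selection of the QM region.

## Units and formats

All coordinates are held internally in nanometers. Conversions:
1 Å = 0.1 nm; 1 Bohr = 0.0529177210903 nm (CODATA 2018). The `.gro`
parser is strictly fixed-width (names can abut digits, so whitespace
splitting is unsafe); PDB reads `ATOM`/`HETATM` only and writes
occupancy/B-factor as 1.00/0.00; XYZ keeps the element symbol as the
atom name; the CPMD `GEOMETRY` dialect is one line per atom with the
first three floats as Bohr positions, trailing velocity columns ignored
on read and written as zeros. Writers always end files with a newline.
Printed precisions (gro: 3 decimals in nm; PDB: 3 decimals in Å; XYZ:
6 decimals in Å; GEOMETRY: 8 decimals in Bohr) bound the round-trip
error of each dialect; the tests assert identity within those bounds
and byte-stability from the second write on.

## Topology model

The parser resolves `#include` recursively (quoted paths relative to the
including file first, then user-supplied include directories) and builds
a flat *global atom table*: molecule blocks of `[ molecules ]` repeated
by their counts, ids 1..N in GROMACS order. Only the sections needed for
QM-region preparation are interpreted; `[ pairs ]`, `[ angles ]`,
`[ dihedrals ]` and friends are skipped with a debug log.
`[ settles ]` water constraints are translated into O–H bonds so that
boundary detection sees water connectivity. Preprocessor handling is
deliberately minimal — `#define` plus `#ifdef`/`#ifndef`/`#else`/
`#endif` with a caller-supplied symbol set, defaulting to the rigid
(`#else`) branch of the common `#ifdef FLEXIBLE` water block; full cpp
semantics is out of scope. Missing per-atom charges fall back to the
atom-type registry, then to 0.0 with a warning.

`[ atomtypes ]` lines are parsed by anchoring on the particle-type
column (`A`/`S`/`V`/`D`): the two preceding tokens are mass and charge,
and an integer token between the name and the mass is the atomic number.
When a type is redefined, the later definition wins but never loses
species information the earlier one carried — this makes a consolidated
section coexist safely with legacy element-less ones.

## Element inference

Per atom, in order: (1) an explicit user table mapping atom types to
elements; (2) the element recorded in the atom-type registry (atomic
number column); (3) the mass rule — nearest standard atomic weight
(Biopython's IUPAC table, Z = 1..86) within ±0.5 amu, with anything
below 3.5 amu taken as hydrogen so deuterated force-field masses resolve
correctly, and non-positive masses (virtual sites) never matching;
(4) the leading alphabetic characters of the atom name as a two-letter,
then one-letter symbol; (5) the same rule on the type name. The ±0.5 amu
tolerance reflects that force-field masses deviate from standard weights
by rounding only. The precedence mass → name → type is this package's
choice; the alternatives are defensible, but mass is the least ambiguous
signal (names like `CA` collide with calcium). With guessing disabled,
only sources (1) and (2) apply and unresolved types are a hard error
listing them.

`fix_top` repairs a topology so resolution succeeds without guessing: it
copies the include closure (relative layout preserved, include lines
repointed), and rewrites the `[ atomtypes ]` body of the deepest
included file whose name contains "nonbonded" — matching the
`ffnonbonded.itp` layout of the stock force fields — with every type's
atomic number and mass filled. If no such file exists, a new
`atomtypes_fixed.itp` is created and included; on a second run that file
is recognized as the consolidation target, which makes the operation
idempotent (byte-identical output). The `clear_sections` flag removes
`[ atomtypes ]` sections from all other files. Nothing is written if any
type remains unresolved.

## Selection language

Grammar: `expr := term ("or" term)*`, `term := factor ("and" factor)*`,
`factor := "not" factor | "(" expr ")" | keyword op literal`, with
keywords `resname resid name type id mol` and operators
`is not > < ≥ ≤` (ASCII `>=`/`<=` accepted). Ordering operators apply
only to the integer fields `resid`/`id`; applying them to string fields
is a parse error rather than a silent lexicographic comparison. `not`
serves both as a comparison operator (`name not CA`) and as a unary
prefix, disambiguated purely by position (after a keyword it is the
operator). `mol` matches the moleculetype name of the flattened table.
The parser is a small hand-written recursive-descent parser; errors
carry the character position. Evaluation is vectorized over the global
atom table and returns ascending ids; `and`/`or`/`not` are set
intersection/union/complement, verified property-based against a
row-by-row predicate oracle.

## QM cell, charge, boundary atoms

* **Cell**: per axis, `extent + 2 × padding`, converted to Bohr. Default
  padding 0.35 nm — the vacuum margin the Martyna–Tuckerman
  isolated-system Poisson solver needs; larger regions generally require
  more, and the value is a first-class parameter (`-pad` /
  `padding_nm`). A degenerate extent with zero padding (zero-volume
  cell) is rejected.
* **Charge**: the declared `CHARGE` is the summed partial charge of the
  region rounded to the nearest integer (half away from zero). A
  deviation above 0.01 e raises a dedicated warning: it almost always
  means the selection cut through a charge group.
* **Boundary atoms**: QM atoms with at least one bonded neighbour
  outside the region, found by scanning the global bond list. They must
  be treated with monovalent boundary pseudopotentials; generating an
  input with open valences and the boundary flag off is an error rather
  than a warning, because the resulting simulation would be silently
  wrong. Charge-redistribution or link-atom capping schemes beyond the
  boundary-pseudopotential flagging are out of scope.

## Emission and index mapping

`&ATOMS` blocks are ordered by ascending atomic number with boundary
blocks last; within a block atoms keep ascending GROMACS index. The
order is arbitrary in principle — the engine fixes no order — so a
deterministic, reproducible one was chosen and centralized in a single
function used by both the emitter and the index mapper, making the
`OVERLAPS` records and `cpmdid` answers consistent by construction. The
MM part of the index map (ids |QM|+1..N) groups atoms by species in
ascending atomic number, ascending GROMACS index within a species; this
is the package's explicit rendering of the engine's undocumented
reshuffling and is deliberately isolated so it can be swapped if the
real rule is found to differ.

`&ATOMS` coordinates are absolute Bohr translated so the region's
minimum corner sits at (padding, padding, padding), i.e. the molecule is
centered in the minimal cell the isolated-system solver requires. The
inverse converter (`cpmd2coords`) therefore recovers the QM geometry
exactly up to that uniform, documented translation; the tests verify
recovery after aligning it and check that the shift equals
`padding − min corner`.

The `OVERLAPS` line syntax (`2 <gromacs id> 1 <cpmd id>`) and the
`PATHS` block follow the MiMiC convention and are produced by one
serializer function, so a dialect correction would touch no logic.

## Synthetic study systems

The fixtures module generates two systems entirely in code:

* **Solvated solute** — a 10-atom acetone-like molecule (residue `ACT`,
  zero net charge, realistic masses, atom types that deliberately carry
  no element information) plus n rigid 3-site waters with
  `[ settles ]` constraints inside an `#ifdef FLEXIBLE` block, on a
  jittered grid in a cubic box. Defaults in the tests use 5 waters
  (25 atoms): large enough to exercise every code path, small enough
  that the whole suite runs in seconds.
* **Toy peptide** — a linear chain of residues with an N–CA–C(=O)
  backbone and a CB–OG side chain, explicit peptide bonds, and optional
  +1-charged side chains; every named selection's expected atoms and
  expected boundary atoms are recorded at construction.

Geometries are placeholders: jittered grids and lines quantized to the
gro precision (3 decimals, nm) so golden-file comparisons are exact and
generation is byte-identical for a given seed. The generators emulate
the *bookkeeping* structure of real systems (includes, nonstandard
types, settles, charge groups, cut bonds) but none of their physics —
no force-field realism, no condensed-phase packing, no protein
stereochemistry. Passing tests therefore demonstrate correct parsing,
selection, accounting and emission on well-formed inputs; they say
nothing about tolerance to the malformed topologies found in the wild.

## Numerical and interface choices

* Rounding: gro/PDB writers print at fixed precision; serial/resid
  fields wrap modulo their width above 99 999 atoms, with a warning.
* A gro written without a box synthesizes one from the coordinate
  extent plus a 0.1 nm margin per side, with a warning.
* Determinism: generation has no hidden state; identical inputs yield
  byte-identical outputs (asserted by tests).
* The CLI is a thin layer over the library. The interactive session
  reads `add`/`delete`/`view`/`clear`/`q` lines from stdin or a `-sele`
  file, so workflows need no TTY; query errors re-prompt instead of
  aborting. Exit codes: 0 success, 2 usage, 3 parse, 4 chemistry.
* External binaries (`gmx grompp`, `gmx mdrun`, `cpmd.x`) are never
  invoked; the exact command lines are printed instead.

## Known limitations

* Preprocessor support is not full cpp (`#if`, macro expansion and
  nested arithmetic conditions are unsupported).
* Only orthorhombic boxes are handled; triclinic gro box lines are read
  as their first three components.
* Multi-model PDB, CONECT records, and trajectory formats are out of
  scope.
* The MM index-grouping rule is an assumption (see above) and should be
  validated against the engine before relying on MM ids in production
  constraint blocks.
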