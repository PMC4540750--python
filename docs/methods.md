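# Methods

This note records the models implemented in `atomenv`, the parameters that
matter, and the design choices made where the design was genuinely open.

## Molecular graph and preprocessing

A structure record is a simple labeled graph (`MolGraph`): at most one bond
per atom pair, no self-loops, stable atom indices. Bonds carry a *class*;
only covalent bonds enter degree, valence, ring perception and environment
growth. Ionic, complex and dative bonds are stored but ignored everywhere
else. Isotope labels and stereo annotations are discarded at parse time;
radical annotations are not represented (radical character shows up only
through the implicit hydrogen count).

**Hydrogen suppression.** Every neutral explicit hydrogen bonded by one
single covalent bond to one heavy atom is deleted and folded into the
neighbor's implicit count. Hydrogens without a heavy neighbor (H2, hydride,
a lone H atom) are retained as explicit atoms and typed like any other
atom. Total hydrogen count is conserved.

**Implicit hydrogen assignment.** Atoms whose input carried an explicit
hydrogen count (bracket SMILES atoms) keep it. For all others the count is
topped up to the smallest allowed default valence `v* >= s`, where `s` is
the sigma/pi bond-order sum including hydrogens already folded in by
suppression. If no default reaches `s`, the atom stays hypervalent with no
added hydrogens — this is what makes the pentavalent nitro nitrogen of
`*N(=O)=O` representable and detectable. The shipped defaults follow MDL
conventions: H 1, C 4, N 3, O 2, F 1, P 3/5, S 2/4/6, Cl/Br/I 1 at charge
0, N+/P+ 4, O−/S− reduced by one; any other (element, charge) pair adds
nothing. The table is overridable from a YAML/JSON file of
`{element, charge, valences}` entries.

**Kekulé resolution and valence arithmetic.** Input written in aromatic
(lowercase / bond-type-4) form is resolved to an alternating single/double
assignment at parse time via RDKit; the provisional aromatic flags are kept
until perception overwrites them. Valence is then always the sum of
implicit hydrogens and integer bond orders. The Kekulé-based valence is
invariant under the choice of Kekulé structure (every aromatic atom has a
fixed number of double bonds across assignments) and gives the chemically
expected values — benzene C 4, pyridine N 3, pyrrole N 3, furan O 2. Only
when no Kekulé form exists (unkekulizable deposited aromatics) does a bond
count 1.5 with the total rounded. This matches RDKit's own aromatic valence
accounting, which keeps the SMARTS self-match guarantee intact.

**Ring annotation.** A bond is `in_ring` iff it is not a bridge of the
covalent graph (networkx bridge detection; verified in the tests against a
remove-edge/connectivity oracle).

**Aromaticity models.** Two models are provided; exactly one is active per
run.

* `simple_sixring`: a six-membered cycle is aromatic iff all members are C
  or N, no member has a triple bond or degree > 3, every member carries
  exactly one double bond, and the in-ring π count is 6 (i.e., three
  alternating ring doubles). This reproduces the restrictive MDL-style
  model used for comparisons against historical augmented-atom statistics:
  furan, pyrrole and thiophene are *not* aromatic under it.
* `general_huckel`: simple cycles of size 5-7 with members in {C, N, O, S},
  no triples, degree ≤ 3. π contributions: in-ring double 1; exocyclic
  double 0; N/O/S with no double (lone pair) 2; C− 2; C+ 0; a saturated
  neutral carbon disqualifies the ring. A ring qualifies when the total
  satisfies 4n+2. Fused systems are handled by iterating to a fixed point:
  an atom whose double bond was consumed by an already-aromatic ring
  contributes one electron, which aromatizes the second naphthalene ring on
  the second pass. This is an approximation of toolkit-specific "general"
  models; exotic ring systems (e.g. charged three-membered rings, azulene's
  5-7 pairing) may be classified differently than by other software, which
  is a known limitation.

Perception always starts from cleared flags and depends only on Kekulé
orders, so it is idempotent. Passing `aromaticity=None` clears all flags
and leaves the Kekulé form — that is the "no perception" pipeline used to
demonstrate why perception matters.

## Typing and encoding

Six-property atom keys are `(Z, charge, h, D, v, aromatic)`; element-only
keys are `(Z,)`. Primitive concatenation order inside the bracket is fixed
— element, charge, `h`, `D`, `v` — for byte-exact output; charge is always
signed (`+0`). Retained hydrogen atoms are encoded as `[#1...]` rather than
by symbol because the SMARTS grammar reserves bracketed `H` for hydrogen
counts; all other elements use their symbol, lowercased when aromatic.
Under the four-type bond scheme an aromatic `:` between two aromatic atom
primitives is elided (implied), and a non-aromatic bond between aromatic
atoms is always written explicitly; the augmented scheme writes every bond
primitive (`-@`, `-!@`, …, `:`).

## Environments and canonicalization

An environment of radius `r` contains all atoms at BFS distance ≤ r over
covalent bonds and **all** covalent bonds with both endpoints included; the
all-bonds rule closes rings that fall inside the environment (the
perhydrobenzimidazole fusion-carbon case), which a BFS-tree variant cannot
distinguish from branching. Environments never cross disconnected
components. Atom and bond primitives are computed in the context of the
*full* molecule, not the clipped fragment.

At `r` > 0, terminal atoms (degree 1) are not centers unless the scheme
allows them, and records with at most two atoms yield no environments; at
`r` = 0 every atom is a center.

Fragment identity is the canonical string of the labeled environment graph.
The center is not specially marked in the string — identity is graph
identity, which is what lets an `r` = 1 environment around one atom
coincide with an `r` = 2 environment around another (the
dispiro(2.0.2.4)deca-1,5-diene spiro centers) and what makes
whole-structure environments saturate across radii. Canonicalization:

1. seed a coloring with the atom primitive strings;
2. refine by iterated neighborhood signatures (bond primitive + neighbor
   color multisets) until the partition stabilizes;
3. if cells remain non-singleton, branch on every member of the first
   non-singleton cell (individualize, re-refine, recurse) and keep the
   lexicographically smallest emitted string.

Branching makes the procedure exact on symmetric graphs (the
tetra-*tert*-butylmethane r=2 environment is the stress case) at a cost
that is negligible for circular fragments of radius ≤ 3. Emission is
depth-first from the rank-0 atom, children in rank order, branches
parenthesized, ring-closure digits assigned in order of first appearance
starting at 1 (`%nn` beyond 9), with the closure bond symbol written at
both ends.

Determinism and soundness are enforced by the test suite: identical keys
under 50 random atom permutations of 100 generated molecules, and key
equality coinciding with exact labeled-graph isomorphism (networkx VF2) on
all small fixture molecules.

## Census

Per record, each unique key increments incidence once and every center
increments occurrence, giving the conservation law Σ occurrence(r) =
Σ |eligible centers(r)| over processed records. Rejected records
(pseudo-atoms, parse failures, and — under the element-only scheme — the
size/degree pre-filter of at most 100 heavy atoms with degrees 1-4) are
tallied but not fragmented, and excluded from incidence denominators.
Censusing in batches and merging equals censusing at once; tables and the
TSV export are independent of record order.

Cross-radius overlap compares canonical strings while ignoring the radius
tag; the exclusive (r1 ∩ r3) \ r2 region is provably empty, and the tests
assert it on every corpus. The element census counts non-hydrogen atoms
for occurrence (retained explicit hydrogens are excluded from the
denominator; an all-atoms denominator can be derived from the r=0 table if
needed) and records for incidence.

Valence screening checks each atom's (element, charge, valence) against an
allowed-valence table generated from the same valence defaults (config
overridable); `organic_only` restricts to organic atoms bonded only to
organic atoms, excluding violations that stem from metal coordination drawn
as covalent bonds. Environment filters are exact-canonical-key matches at
the filter's radius — filters are themselves environments, and key equality
is the defined identity — not general substructure searches.

Incidence histograms use logarithmic decade bins from 1e-7 % to 10 % and
linear ten-percent bins above, minima inclusive, maxima exclusive, top bin
closed.

## Synthetic data generator

`fixtures.generate` emulates small drug-like organic molecules: element
alphabet C/N/O/S with weights 0.70/0.12/0.14/0.04, 4-14 heavy atoms,
maximum degree 4, double/triple bond probabilities 0.15/0.03, one extra
ring-closure attempt in 30 % of molecules, and a planted Kekulé benzene
ring in 25 %. Connectivity is guaranteed by growing a random spanning tree;
degree and default-valence caps are enforced during construction, so every
generated molecule passes valence validation after preprocessing. The
generator is deterministic per seed.

What it does *not* emulate: realistic functional-group frequencies, the
element and size distributions of real registries, charges, multiple
components (salts), deposition errors, or non-covalent bond classes.
Passing tests on generated corpora therefore demonstrate the combinatorial
and algebraic properties of the pipeline (canonicalization soundness,
conservation laws, scheme behavior), not fidelity to any real database's
fragment statistics.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so a
full run takes a few minutes on one CPU: 100 molecules × 50 permutations
(≈ 88,000 keys) for invariance, ≈ 1,900 emitted patterns for SMARTS
validity/self-match, and a census of the ≈ 30 fixture molecules plus 200
generated records at radii 0-3. Corpus-scale surveys of real databases are
out of scope for the bundled data but supported by the same API and CLI,
which stream records and merge batch censuses.

## Known limitations

* The general Hückel model approximates proprietary toolkit models; fragment
  strings for unusual ring systems may not agree with other software.
* SDF support is V2000 only; V3000 records are rejected with a clear error.
* No tautomer/charge normalization, no structure rewriting: deposited
  variants (e.g. both nitro representations) are detected and counted, never
  corrected.
* Stereochemistry and isotopes are deliberately discarded; fragments carry
  no such information.
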