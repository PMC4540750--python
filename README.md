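# atomenv

Circular atom-environment fragmentation and fragment census for
small-molecule collections.

Large chemical registries accumulate millions of deposited structures of
very uneven quality. A simple but powerful way to characterize such a
collection — and to find chemistry in it that is formally "valid" but
implausible or outright wrong — is to fragment every structure into
*circular atom environments*: for each atom (the *center*), the fragment of
radius *r* containing every atom within topological distance *r* and **all**
bonds between the included atoms. These are the same fragments that underlie
extended-connectivity (ECFP/Morgan) fingerprints; *r* = 3 environments
correspond to ECFP_6 features. `atomenv` implements the fragmentation, a
canonical SMARTS encoding of each fragment, and the corpus-level census
machinery on top, as a reusable library plus CLI for cheminformaticians and
database curators.

## The model

**Typing.** Two atom typing schemes define fragment identity. Under
*six-property* typing an atom is characterized by atomic number, formal
charge, implicit hydrogen count *h*, explicit degree *D*, valence *v*
(sum of incident σ and π bonds, implicit hydrogens included), and aromatic
membership, encoded as a SMARTS primitive such as `[c+0h1D2v4]` (a benzene
CH). Under *element-only* typing (`[#6]`) the atomic number is the sole
feature — the typing used by the classic 1970s "augmented atom" studies.
Bonds are typed either as single/double/triple/aromatic (`-`, `=`, `#`,
`:`, the aromatic flag winning) or, in the augmented scheme, by order plus
ring/chain membership (`-@`, `-!@`, …).

**Preprocessing.** Explicit hydrogens are folded into implicit counts
(isotope labels discarded; hydrogen species without a heavy neighbor such
as H2 or hydride stay explicit), unspecified valences are completed under
an MDL-style standard valence model, ring bonds are annotated, and
aromaticity is perceived under either a general Hückel 4n+2 model for 5-7
membered C/N/O/S rings and their fused systems, or a restrictive model that
aromatizes only six-membered C/N rings.

**Environments.** For radius *r* > 0, terminal atoms are not used as
centers (they are covered by their neighbor's environment), so mono- and
di-atomic structures contribute atom types only. Every environment is
rendered as a canonical SMARTS string by iterative neighborhood refinement
with full tie-breaking, so key equality is exactly labeled-graph
isomorphism — independent of input atom order, and able to recognize that
an *r* = 1 environment around one atom can equal an *r* = 2 environment
around another.

**Census.** Fragment frequencies are reported as *incidence* (number of
records containing a fragment at least once) and *occurrence* (total count
with multiplicity); fragments with incidence 1 are *singletons*. The census
layer also computes cross-radius set overlap (a whole-structure *r* = 1
environment necessarily reappears at *r* = 2 and *r* = 3), per-element
composition tables, allowed-valence screening (the pentavalent nitro
nitrogen of `*N(=O)=O` is the canonical offender), and exact-key
environment filters for implausible structures such as
tetra-*tert*-butylmethane.

## Worked example

```python
from atomenv import Scheme, parse_smiles, preprocess, run_census, singleton_stats
from atomenv.environment import fragment_record

scheme = Scheme.default()          # six-property atoms, four bond types
aniline = preprocess(parse_smiles("Nc1ccccc1 aniline"))
for key, mult in sorted(fragment_record(aniline, [1], scheme)[1].items(),
                        key=lambda kv: kv[0].canonical_smarts):
    print(f"{mult}x  {key.canonical_smarts}")
```

```
1x  [N+0h2D1v3]-[c+0h0D3v4]([c+0h1D2v4])[c+0h1D2v4]
2x  [c+0h0D3v4][c+0h1D2v4][c+0h1D2v4]
3x  [c+0h1D2v4][c+0h1D2v4][c+0h1D2v4]
```

Aniline has six eligible *r* = 1 centers (the NH2 nitrogen is terminal).
The ipso carbon is unique; the two ortho carbons share one key *because*
aromaticity was perceived — on the raw Kekulé form they would differ; and
the meta and para carbons are indistinguishable at this radius (multiplicity
3). Aromatic bonds between aromatic atoms are implied and need no `:`.

A three-record census:

```python
corpus = [preprocess(parse_smiles(s))
          for s in ["c1ccccc1 benzene", "Cc1ccccc1 toluene", "CCO ethanol"]]
census = run_census(corpus, [0, 1], scheme)
for r in (0, 1):
    count, frac = singleton_stats(census, r)
    print(f"r={r}: unique={census.unique_at(r)} "
          f"occurrences={census.occurrence_total(r)} singletons={count}")
print(census.counts_at(0)["[c+0h1D2v4]"])
```

```
r=0: unique=5 occurrences=16 singletons=3
r=1: unique=4 occurrences=13 singletons=3
(2, 11)
```

The aromatic CH atom type occurs 11 times (6 in benzene, 5 in toluene)
across 2 of the 3 records — occurrence 11, incidence 2.

The same operations are available from the shell:

```sh
atomenv fixtures emit aniline -o aniline.smi
atomenv fragment aniline.smi --radii 1
atomenv census aniline.smi -o out/        # fragments.tsv + summary.json
atomenv validate aniline.smi --organic-only
```

## Layout

| module | contents |
| --- | --- |
| `atomenv.graph` | `MolGraph`/`AtomNode`/`BondEdge`, RDKit/networkx export |
| `atomenv.io` | SMILES and SDF V2000 readers, TSV fragment tables |
| `atomenv.preprocess` | hydrogen suppression, valence model, ring and aromaticity perception |
| `atomenv.typing` | atom/bond type keys and SMARTS primitives |
| `atomenv.environment` | extraction, canonicalization, per-record fragmentation |
| `atomenv.census` | incidence/occurrence tables, overlap, element census, valence screen, filters |
| `atomenv.fixtures` | worked-example molecules, seeded random generator |
| `atomenv.cli` | `atomenv` command group |

See `docs/methods.md` for the full account of the models, parameters and
numerical choices.
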