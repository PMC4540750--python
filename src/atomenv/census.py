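"""Corpus-level fragment statistics.

Frequencies follow the incidence/occurrence distinction used in large
chemical-database surveys: *incidence* counts the records that contain a
fragment at least once; *occurrence* counts every instance with
multiplicity.  A fragment with incidence 1 is a *singleton*.

The module also provides the corpus-level operations built on fragment
keys: cross-radius set overlap, per-element composition, valence-list
validation of atom types, exact-key environment filters, and incidence
histograms.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem

from .environment import (
    FragmentKey,
    augmented_prefilter,
    eligible_centers,
    enumerate_environments,
)
from .graph import MolGraph
from .preprocess import ORGANIC_ELEMENTS, ValenceDefaults
from .typing import ELEMENT_ONLY, Scheme, valence

_PERIODIC = Chem.GetPeriodicTable()


@dataclass
class CensusTable:
    """Incidence/occurrence counters per (radius, canonical key)."""

    scheme_tag: str = ""
    records_processed: int = 0
    records_rejected: int = 0
    # radius -> smarts -> [incidence, occurrence]
    _counts: dict[int, dict[str, list[int]]] = field(default_factory=dict)
    whole_structure_counts: dict[int, int] = field(default_factory=dict)

    def radii(self) -> list[int]:
        return sorted(self._counts)

    def counts_at(self, radius: int) -> dict[str, tuple[int, int]]:
        if radius not in self._counts:
            raise KeyError(f"radius {radius} not in census")
        return {s: (c[0], c[1]) for s, c in self._counts[radius].items()}

    def unique_at(self, radius: int) -> int:
        return len(self._counts.get(radius, {}))

    def occurrence_total(self, radius: int) -> int:
        return sum(c[1] for c in self._counts.get(radius, {}).values())

    def _add_record(self, per_radius: dict[int, Counter]) -> None:
        for radius, keys in per_radius.items():
            table = self._counts.setdefault(radius, {})
            for key, mult in keys.items():
                smarts = key.canonical_smarts if isinstance(key, FragmentKey) else key
                entry = table.setdefault(smarts, [0, 0])
                entry[0] += 1
                entry[1] += mult

    def merge(self, other: "CensusTable") -> "CensusTable":
        """Combine two censuses over disjoint record batches."""
        if self.scheme_tag != other.scheme_tag:
            raise ValueError("cannot merge censuses under different schemes")
        out = CensusTable(scheme_tag=self.scheme_tag)
        out.records_processed = self.records_processed + other.records_processed
        out.records_rejected = self.records_rejected + other.records_rejected
        for src in (self, other):
            for radius, table in src._counts.items():
                dst = out._counts.setdefault(radius, {})
                for smarts, (inc, occ) in (
                    (s, (c[0], c[1])) for s, c in table.items()
                ):
                    entry = dst.setdefault(smarts, [0, 0])
                    entry[0] += inc
                    entry[1] += occ
            for radius, count in src.whole_structure_counts.items():
                out.whole_structure_counts[radius] = (
                    out.whole_structure_counts.get(radius, 0) + count
                )
        return out

    def summary(self) -> dict:
        """JSON-ready summary of the census."""
        per_radius = {}
        for r in self.radii():
            count, fraction = singleton_stats(self, r)
            per_radius[str(r)] = {
                "unique": self.unique_at(r),
                "occurrences": self.occurrence_total(r),
                "singletons": count,
                "singleton_fraction": fraction,
                "whole_structure_count": self.whole_structure_counts.get(r, 0),
            }
        out = {
            "scheme": self.scheme_tag,
            "records_processed": self.records_processed,
            "records_rejected": self.records_rejected,
            "radii": per_radius,
        }
        if len(self.radii()) >= 2:
            out["overlap"] = {
                "+".join(f"r{r}" for r in region): n
                for region, n in radius_overlap(self, self.radii()).items()
            }
        return out


def run_census(
    records: Iterable[MolGraph],
    radii: Sequence[int],
    scheme: Scheme,
    apply_prefilter: bool | None = None,
) -> CensusTable:
    """Census a corpus of preprocessed records.

    Rejected records (pseudo-atoms, parse failures, and — when the
    element-only/augmented configuration is active or ``apply_prefilter`` is
    forced on — records failing the size/degree pre-filter) are tallied but
    not fragmented.  Per-record key multiplicities feed occurrence counts;
    unique keys feed incidence.
    """
    if apply_prefilter is None:
        apply_prefilter = scheme.atom_scheme == ELEMENT_ONLY
    census = CensusTable(scheme_tag=scheme.tag)
    radii = list(radii)
    for mol in records:
        if mol.rejected or (apply_prefilter and not augmented_prefilter(mol)):
            census.records_rejected += 1
            continue
        census.records_processed += 1
        per_radius: dict[int, Counter] = {r: Counter() for r in radii}
        for r, _center, env, key in enumerate_environments(mol, radii, scheme):
            per_radius[r][key] += 1
            if env.covers_whole and r > 0:
                census.whole_structure_counts[r] = (
                    census.whole_structure_counts.get(r, 0) + 1
                )
        census._add_record(per_radius)
    for r in radii:
        census._counts.setdefault(r, {})
    return census


def singleton_stats(census: CensusTable, radius: int) -> tuple[int, float]:
    """Count and fraction of keys occurring in exactly one record."""
    table = census.counts_at(radius)
    count = sum(1 for inc, _ in table.values() if inc == 1)
    fraction = count / len(table) if table else 0.0
    return count, fraction


def radius_overlap(
    census: CensusTable, radii: Sequence[int]
) -> dict[tuple[int, ...], int]:
    """Venn-region counts of unique key strings across radius sets.

    Keys are compared as canonical strings, ignoring the radius they were
    extracted at.  Returns ``{(r, ...): count}`` for every non-empty subset
    of ``radii``, counting keys present in exactly those radius sets.
    """
    radii = sorted(radii)
    if len(radii) < 2:
        raise ValueError("overlap needs at least two radii")
    sets = {r: set(census.counts_at(r)) for r in radii}
    regions: dict[tuple[int, ...], int] = {}
    for k in range(1, len(radii) + 1):
        for combo in itertools.combinations(radii, k):
            inside = set.intersection(*(sets[r] for r in combo))
            for r in radii:
                if r not in combo:
                    inside -= sets[r]
            regions[combo] = len(inside)
    return regions


def element_census(records: Iterable[MolGraph]) -> pd.DataFrame:
    """Per-element heavy-atom occurrence % and record incidence %.

    Occurrence is computed over non-hydrogen atoms (retained explicit
    hydrogens are excluded from the denominator); incidence over processed
    records.  Returns a DataFrame indexed by element symbol with columns
    ``occurrence_pct`` and ``incidence_pct``, sorted by occurrence.
    """
    atom_counts: Counter = Counter()
    record_counts: Counter = Counter()
    n_records = 0
    for mol in records:
        if mol.rejected:
            continue
        n_records += 1
        elements = {a.atomic_number for a in mol.atoms if a.atomic_number > 1}
        for a in mol.atoms:
            if a.atomic_number > 1:
                atom_counts[a.atomic_number] += 1
        for z in elements:
            record_counts[z] += 1
    total = sum(atom_counts.values())
    rows = []
    for z in sorted(atom_counts):
        rows.append(
            {
                "element": _PERIODIC.GetElementSymbol(z),
                "atomic_number": z,
                "occurrence_pct": 100.0 * atom_counts[z] / total if total else 0.0,
                "incidence_pct": 100.0 * record_counts[z] / n_records
                if n_records
                else 0.0,
            }
        )
    df = pd.DataFrame(
        rows, columns=["element", "atomic_number", "occurrence_pct", "incidence_pct"]
    )
    return df.sort_values(
        ["occurrence_pct", "atomic_number"], ascending=[False, True]
    ).reset_index(drop=True)


class ValenceRuleTable:
    """Allowed (element, charge, valence) combinations for validity checks.

    Lookup is total: combinations absent from the table are not allowed.
    The default table is generated from the standard valence defaults.
    """

    def __init__(self, allowed: set[tuple[int, int, int]]):
        self._allowed = set(allowed)

    @classmethod
    def from_defaults(cls, defaults: ValenceDefaults | None = None) -> "ValenceRuleTable":
        defaults = defaults or ValenceDefaults.default()
        allowed = {
            (z, charge, v)
            for (z, charge), valences in defaults.items()
            for v in valences
        }
        return cls(allowed)

    @classmethod
    def from_file(cls, path) -> "ValenceRuleTable":
        return cls.from_defaults(ValenceDefaults.from_file(path))

    def allows(self, atomic_number: int, charge: int, val: int) -> bool:
        return (atomic_number, charge, val) in self._allowed


@dataclass(frozen=True)
class ValenceFlag:
    atom_index: int
    atomic_number: int
    formal_charge: int
    valence: int


def validate_valences(
    mol: MolGraph,
    rules: ValenceRuleTable | None = None,
    organic_only: bool = False,
) -> list[ValenceFlag]:
    """Flag atoms whose (element, charge, valence) is not in the rule table.

    With ``organic_only``, only organic atoms (H, C, N, O, F, P, S, Cl, Br,
    I) connected exclusively to other organic atoms are examined — this
    excludes apparent violations that stem from organic/metal interactions
    drawn as covalent bonds.
    """
    rules = rules or ValenceRuleTable.from_defaults()
    adj = mol.covalent_adjacency()
    flags = []
    for idx, atom in enumerate(mol.atoms):
        if organic_only:
            if atom.atomic_number not in ORGANIC_ELEMENTS:
                continue
            if any(
                mol.atoms[nbr].atomic_number not in ORGANIC_ELEMENTS
                for nbr, _ in adj[idx]
            ):
                continue
        v = valence(mol, idx)
        if not rules.allows(atom.atomic_number, atom.formal_charge, v):
            flags.append(
                ValenceFlag(idx, atom.atomic_number, atom.formal_charge, v)
            )
    return flags


def match_environment_filter(
    mol: MolGraph, filter_key: FragmentKey, scheme: Scheme
) -> bool:
    """True iff some eligible center's environment at the filter's radius
    has exactly the filter's canonical key (exact-key matching, not general
    substructure search)."""
    if filter_key.scheme_tag and filter_key.scheme_tag != scheme.tag:
        raise ValueError(
            f"filter was built under scheme {filter_key.scheme_tag!r}, "
            f"matching under {scheme.tag!r}"
        )
    return any(
        key.canonical_smarts == filter_key.canonical_smarts
        for _r, _c, _e, key in enumerate_environments(
            mol, [filter_key.radius], scheme
        )
    )


def incidence_histogram(
    census: CensusTable, radius: int
) -> list[tuple[float, float, int]]:
    """Bin incidence percentages: log-decade bins from 1e-7 to 10, then
    linear 10-percent bins up to 100.

    Bin minima are inclusive, maxima exclusive; the top bin is closed.
    Returns ``(low, high, count)`` triples covering all keys at ``radius``.
    """
    if census.records_processed <= 0:
        raise ValueError("census has no processed records")
    edges = [10.0 ** e for e in range(-7, 2)] + [
        float(x) for x in range(20, 101, 10)
    ]
    lows = [0.0] + edges[:-1]
    counts = [0] * len(lows)
    for inc, _ in census.counts_at(radius).values():
        pct = 100.0 * inc / census.records_processed
        for k in range(len(lows) - 1, -1, -1):
            if pct >= lows[k] or k == 0:
                counts[k] += 1
                break
    return [(lows[k], edges[k], counts[k]) for k in range(len(lows))]
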