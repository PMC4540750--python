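import random

import pytest

from atomenv import (
    Scheme,
    ValenceRuleTable,
    element_census,
    incidence_histogram,
    match_environment_filter,
    preprocess,
    radius_overlap,
    run_census,
    singleton_stats,
    validate_valences,
)
from atomenv.environment import canonical_smarts, eligible_centers, extract_environment
from atomenv.fixtures import GeneratorParams, builtin, generate


def corpus(prep, names):
    return [prep(n) for n in names]


class TestRunCensus:
    def test_atom_type_census_matches_hand_count(self, prep, scheme):
        """benzene+toluene+ethanol at r=0: the aromatic CH type appears in
        two records, 6+5 = 11 times in total."""
        census = run_census(
            corpus(prep, ["benzene", "toluene", "ethanol"]), [0], scheme
        )
        table = census.counts_at(0)
        assert table["[c+0h1D2v4]"] == (2, 11)
        # ethanol contributes CH3, CH2, OH
        assert table["[C+0h3D1v4]"] == (2, 2)  # toluene methyl + ethanol methyl
        assert table["[O+0h1D1v2]"] == (1, 1)

    def test_single_benzene(self, prep, scheme):
        census = run_census([prep("benzene")], [1], scheme)
        assert census.counts_at(1) == {
            "[c+0h1D2v4][c+0h1D2v4][c+0h1D2v4]": (1, 6)
        }

    def test_empty_corpus(self, scheme):
        census = run_census([], [0, 1], scheme)
        assert census.records_processed == 0
        assert census.unique_at(0) == 0

    def test_rejected_records_counted_not_fragmented(self, prep, scheme):
        from atomenv.graph import MolGraph

        bad = MolGraph(record_id="bad", rejected=True, reject_reason="pseudo-atom")
        census = run_census([prep("benzene"), bad], [0], scheme)
        assert census.records_processed == 1
        assert census.records_rejected == 1

    def test_augmented_scheme_applies_prefilter(self, prep):
        aug = Scheme.augmented()
        records = [
            prep("benzene", "simple_sixring"),
            prep("phosphorus_pentachloride", "simple_sixring"),
        ]
        census = run_census(records, [1], aug)
        assert census.records_processed == 1
        assert census.records_rejected == 1

    def test_occurrence_conservation(self, prep, scheme):
        """Sum of occurrences at radius r equals the eligible-center count."""
        records = corpus(
            prep, ["benzene", "toluene", "promazine", "neopentane", "methane"]
        )
        census = run_census(records, [0, 1, 2, 3], scheme)
        for r in (0, 1, 2, 3):
            expected = sum(len(eligible_centers(m, r, scheme)) for m in records)
            assert census.occurrence_total(r) == expected

    def test_order_independence_and_merge(self, prep, scheme):
        records = corpus(prep, ["benzene", "toluene", "ethanol", "aniline", "furan"])
        base = run_census(records, [0, 1, 2], scheme)
        shuffled = list(records)
        random.Random(7).shuffle(shuffled)
        assert run_census(shuffled, [0, 1, 2], scheme)._counts == base._counts
        merged = run_census(records[:2], [0, 1, 2], scheme).merge(
            run_census(records[2:], [0, 1, 2], scheme)
        )
        assert merged._counts == base._counts
        assert merged.records_processed == base.records_processed


class TestSingletons:
    def test_benzene_toluene(self, prep, scheme):
        census = run_census(corpus(prep, ["benzene", "toluene"]), [1], scheme)
        count, fraction = singleton_stats(census, 1)
        # every toluene-specific environment is a singleton; the shared
        # aromatic CH(-CH)(-CH) environment is not
        table = census.counts_at(1)
        assert count == sum(1 for inc, _ in table.values() if inc == 1)
        assert count >= 1
        assert fraction == count / len(table)

    def test_duplicate_records_no_singletons(self, prep, scheme):
        census = run_census([prep("benzene"), prep("benzene")], [1], scheme)
        assert singleton_stats(census, 1) == (0, 0.0)

    def test_single_record_all_singletons(self, prep, scheme):
        census = run_census([prep("toluene")], [1], scheme)
        assert singleton_stats(census, 1)[1] == 1.0

    def test_missing_radius_errors(self, prep, scheme):
        census = run_census([prep("benzene")], [1], scheme)
        with pytest.raises(KeyError):
            singleton_stats(census, 3)


class TestRadiusOverlap:
    def test_propane_whole_structure_in_triple_intersection(self, prep, scheme):
        census = run_census([prep("propane")], [1, 2, 3], scheme)
        regions = radius_overlap(census, [1, 2, 3])
        assert regions[(1, 2, 3)] == 1

    def test_benzene_radii_disjoint(self, prep, scheme):
        census = run_census([prep("benzene")], [1, 2], scheme)
        regions = radius_overlap(census, [1, 2])
        assert regions[(1, 2)] == 0
        assert regions[(1,)] == 1
        assert regions[(2,)] == 1

    def test_no_exclusive_r1_r3_overlap(self, prep, scheme):
        """A whole-structure r=1 environment is necessarily also an r=2
        environment, so the exclusive (r1 ∩ r3) \\ r2 region is empty."""
        records = corpus(
            prep,
            ["benzene", "toluene", "propane", "neopentane", "dispiro_deca_diene"],
        ) + [preprocess(m) for m in generate(GeneratorParams(n_molecules=30, seed=11))]
        census = run_census(records, [1, 2, 3], scheme)
        assert radius_overlap(census, [1, 2, 3])[(1, 3)] == 0


class TestElementCensus:
    def test_hand_counted_composition(self, prep):
        df = element_census(corpus(prep, ["benzene", "ethanol", "aniline"]))
        row = df.set_index("element")
        assert row.loc["C", "occurrence_pct"] == pytest.approx(100 * 14 / 16)
        assert row.loc["C", "incidence_pct"] == pytest.approx(100.0)
        assert row.loc["N", "occurrence_pct"] == pytest.approx(100 / 16)
        assert row.loc["N", "incidence_pct"] == pytest.approx(100 / 3)

    def test_single_element(self, prep):
        df = element_census([prep("propane")])
        assert df.iloc[0]["occurrence_pct"] == 100.0
        assert df.iloc[0]["incidence_pct"] == 100.0

    def test_empty_corpus(self):
        assert element_census([]).empty

    def test_retained_hydrogen_excluded_from_denominator(self, prep):
        df = element_census([prep("ethanol"), prep("dihydrogen")])
        row = df.set_index("element")
        assert row.loc["C", "occurrence_pct"] == pytest.approx(100 * 2 / 3)


class TestValenceValidation:
    def test_pentavalent_nitro_flagged(self, prep):
        flags = validate_valences(prep("nitro_pentavalent"))
        assert [(f.atomic_number, f.valence) for f in flags] == [(7, 5)]

    def test_charge_separated_nitro_clean(self, prep):
        assert validate_valences(prep("nitro_charge_separated")) == []

    def test_pentavalent_carbon_flagged(self, prep):
        flags = validate_valences(prep("pentavalent_carbon"))
        assert [(f.atomic_number, f.valence) for f in flags] == [(6, 5)]

    def test_organic_only_hides_metal_bonded(self):
        mol = preprocess(builtin("ethanol")).copy()
        mol.atoms[2].atomic_number = 26  # turn the O into Fe: C-C-Fe
        all_flags = validate_valences(mol)
        organic = validate_valences(mol, organic_only=True)
        flagged_all = {f.atom_index for f in all_flags}
        assert 2 in flagged_all  # Fe has no allowed valences
        # the carbon bonded to Fe and Fe itself are excluded from organic-only
        assert {f.atom_index for f in organic} <= {0}

    def test_custom_rule_table(self, prep):
        permissive = ValenceRuleTable({(7, 0, 5)})
        assert validate_valences(prep("nitro_pentavalent"), permissive) != []
        n_flags = [
            f
            for f in validate_valences(prep("nitro_pentavalent"), permissive)
            if f.atomic_number == 7
        ]
        assert n_flags == []


class TestEnvironmentFilter:
    def test_implausible_center_matches_itself(self, prep, scheme):
        mol = prep("tetra_tert_butylmethane")
        central = next(
            i
            for i in range(len(mol.atoms))
            if mol.covalent_degree(i) == 4
            and all(
                mol.covalent_degree(n) == 4
                for n, _ in mol.covalent_adjacency()[i]
            )
        )
        for r in (1, 2):
            key = canonical_smarts(extract_environment(mol, central, r), mol, scheme)
            assert match_environment_filter(mol, key, scheme)

    def test_neopentane_does_not_match_quaternary_filter(self, prep, scheme):
        ttbm = prep("tetra_tert_butylmethane")
        central = next(
            i
            for i in range(len(ttbm.atoms))
            if ttbm.covalent_degree(i) == 4
            and all(
                ttbm.covalent_degree(n) == 4
                for n, _ in ttbm.covalent_adjacency()[i]
            )
        )
        key = canonical_smarts(extract_environment(ttbm, central, 2), ttbm, scheme)
        assert not match_environment_filter(prep("neopentane"), key, scheme)

    def test_scheme_mismatch_errors(self, prep, scheme):
        mol = prep("benzene")
        key = canonical_smarts(extract_environment(mol, 0, 1), mol, scheme)
        with pytest.raises(ValueError, match="scheme"):
            match_environment_filter(mol, key, Scheme.augmented())


class TestIncidenceHistogram:
    def test_partition_and_bins(self, prep, scheme):
        records = corpus(prep, ["benzene", "toluene", "ethanol", "aniline"])
        census = run_census(records, [1], scheme)
        bins = incidence_histogram(census, 1)
        assert sum(c for _, _, c in bins) == census.unique_at(1)
        # incidence 1/4 records = 25% lands in the [20, 30) bin
        by_low = {low: c for low, _, c in bins}
        table = census.counts_at(1)
        n25 = sum(1 for inc, _ in table.values() if inc == 1)
        assert by_low[20.0] == n25

    def test_full_incidence_in_top_bin(self, prep, scheme):
        census = run_census([prep("benzene"), prep("toluene")], [0], scheme)
        bins = incidence_histogram(census, 0)
        top = bins[-1]
        assert top[0] == 90.0 and top[1] == 100.0
        assert top[2] == 1  # the aromatic CH type occurs in both records

    def test_empty_census_errors(self, scheme):
        with pytest.raises(ValueError):
            incidence_histogram(run_census([], [0], scheme), 0)
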