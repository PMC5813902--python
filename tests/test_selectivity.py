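"""Gland/labor selectivity calls, reference CYP flags, and Venn partitions."""

import itertools

import numpy as np
import pytest

from glandprot import (
    CriteriaConfig,
    SpectralCountTable,
    labor_selective_proteins,
    merge_labor,
    selective_proteins,
    specific_proteins,
    venn_partition,
)
from glandprot.refdata import cyp_frame, cyp_table, lipid_metabolism_table, vatpase_table
from glandprot.samples import Gland, merged_name
from glandprot.selectivity import FOLD_EXCESS, UNIQUE_DETECTION, gland_groups

from conftest import random_count_table

EQUAL_TOTALS = CriteriaConfig(assume_equal_totals=True)
MERGED_GROUPS = {g.value: [merged_name(g)] for g in Gland}


def three_group_table(counts_by_acc):
    """Tiny one-column-per-group table: {acc: (PcG, TG, MG)}."""
    accs = list(counts_by_acc)
    cols = {
        merged_name(g): [counts_by_acc[a][i] for a in accs]
        for i, g in enumerate(Gland)
    }
    return SpectralCountTable.from_records(accs, cols)


class TestSpecificProteins:
    def test_alkyl_dhap_synthase_is_pcg_specific(self):
        """(470, 0, 0) across pooled glands -> detected in PcG only."""
        table = lipid_metabolism_table()
        sets = specific_proteins(table, MERGED_GROUPS, unique_min=2)
        assert "gi|328777397" in sets["PcG"]
        assert all("gi|328777397" not in sets[g] for g in ("TG", "MG"))

    def test_cyp305d1_is_mg_specific(self):
        sets = specific_proteins(merge_labor(cyp_table()), MERGED_GROUPS, unique_min=2)
        assert "gi|66512130" in sets["MG"]

    def test_unique_min_boundary_both_readings(self):
        t = three_group_table({"A": (2, 0, 0)})
        assert "A" in specific_proteins(t, MERGED_GROUPS, unique_min=2)["PcG"]
        assert "A" not in specific_proteins(t, MERGED_GROUPS, unique_min=3)["PcG"]

    def test_overlapping_groups_rejected(self, six_sample_table):
        groups = {"a": ["nPcG", "fPcG"], "b": ["fPcG", "nTG"]}
        with pytest.raises(ValueError, match="overlap"):
            specific_proteins(six_sample_table, groups)


class TestSelectiveProteins:
    def test_glucosylceramidase_mg_selective_by_fold(self):
        """(4, 0, 480): 120-fold over the strongest competitor under equal totals."""
        calls = selective_proteins(lipid_metabolism_table(), MERGED_GROUPS, EQUAL_TOTALS)
        call = {c.entry.accession: c for c in calls["MG"]}["gi|66511554"]
        assert call.basis == FOLD_EXCESS
        assert call.fold == pytest.approx(120.0)

    def test_cyp6as7_selective_nowhere(self):
        """Pooled counts (9, 16, 9): max fold 16/9 stays below 5."""
        calls = selective_proteins(merge_labor(cyp_table()), gland_groups(), EQUAL_TOTALS)
        assert all("gi|66522973" not in {c.entry.accession for c in calls[g]} for g in calls)

    def test_forced_tenfold_ratio(self):
        t = three_group_table({"A": (50, 5, 5)})
        calls = selective_proteins(t, MERGED_GROUPS, EQUAL_TOTALS)
        (call,) = calls["PcG"]
        assert call.basis == FOLD_EXCESS and call.fold == pytest.approx(10.0)
        assert not calls["TG"] and not calls["MG"]

    def test_reference_cyp_flags_reproduced(self):
        """The curated S flags: exactly 8 MG-selective CYPs of 14 identified."""
        table = merge_labor(cyp_table())
        flags = cyp_frame().set_index("accession")["mg_selective"]
        calls = selective_proteins(table, gland_groups(), EQUAL_TOTALS)
        mg = {c.entry.accession for c in calls["MG"]}
        assert mg == set(flags[flags == "S"].index)
        assert len(mg) == 8 and len(table) == 14

    def test_reference_cyp_abundance_flags(self):
        """The curated A flags: the 3 MG-selective CYPs that are also frequent."""
        table = merge_labor(cyp_table())
        flags = cyp_frame().set_index("accession")["abundance"]
        frequent = set(table.df.index[table.df[merged_name(Gland.MG)] > 100])
        assert frequent == set(flags[flags == "A"].index)

    def test_detection_below_unique_min_with_zero_competitors_not_called(self):
        t = three_group_table({"A": (1, 0, 0)})
        calls = selective_proteins(t, MERGED_GROUPS, EQUAL_TOTALS)
        assert not any(calls.values())

    def test_monotone_in_thresholds(self, rng):
        for _ in range(20):
            t = random_count_table(rng, 30)
            groups = gland_groups()
            loose = selective_proteins(t, groups, EQUAL_TOTALS)
            for crit in (EQUAL_TOTALS.replace(fold_min=10.0), EQUAL_TOTALS.replace(unique_min=5)):
                tight = selective_proteins(t, groups, crit)
                for g in groups:
                    assert {c.entry.accession for c in tight[g]} <= {
                        c.entry.accession for c in loose[g]
                    }

    def test_selective_for_at_most_one_group(self, rng):
        for _ in range(20):
            t = random_count_table(rng, 30)
            calls = selective_proteins(t, gland_groups(), EQUAL_TOTALS)
            seen = list(
                itertools.chain.from_iterable(
                    (c.entry.accession for c in cs) for cs in calls.values()
                )
            )
            assert len(seen) == len(set(seen))

    def test_unique_detection_invariant_to_totals(self, rng):
        t = random_count_table(rng, 30)
        groups = gland_groups()
        override = {s: float(v) for s, v in zip(t.samples, rng.uniform(1e3, 1e5, 6))}
        with_tot = selective_proteins(t, groups, CriteriaConfig(), override)
        equal = selective_proteins(t, groups, EQUAL_TOTALS)
        for g in groups:
            u1 = {c.entry.accession for c in with_tot[g] if c.basis == UNIQUE_DETECTION}
            u2 = {c.entry.accession for c in equal[g] if c.basis == UNIQUE_DETECTION}
            assert u1 == u2

    def test_equal_totals_equals_raw_count_rule(self, rng):
        """With equal totals, fold calls agree with the plain raw-count 5x rule."""
        t = random_count_table(rng, 40)
        calls = selective_proteins(t, gland_groups(), EQUAL_TOTALS)
        raw = {g.value: t.counts[[f"n{g.value}", f"f{g.value}"]].sum(axis=1) for g in Gland}
        for g, cs in calls.items():
            others = [raw[h] for h in raw if h != g]
            for c in cs:
                if c.basis == FOLD_EXCESS:
                    own = raw[g][c.entry.accession]
                    assert own > 5 * max(o[c.entry.accession] for o in others)


class TestLaborSelective:
    def test_vatpase_h1_is_nurse_selective_in_tg(self):
        """Subunit H isoform 1: nTG 284, fTG 0 -> unique detection for nurses."""
        calls = labor_selective_proteins(vatpase_table(), Gland.TG, EQUAL_TOTALS)
        ntg = {c.entry.accession: c for c in calls["nTG"]}
        assert ntg["gi|328792071"].basis == UNIQUE_DETECTION
        assert "gi|328792071" not in {c.entry.accession for c in calls["fTG"]}

    def test_acyl_coa_synthetase_partial_nurse_selective_in_mg(self):
        from glandprot.refdata import top30_table

        calls = labor_selective_proteins(top30_table(Gland.MG), Gland.MG, EQUAL_TOTALS)
        assert "gi|66548355" in {c.entry.accession for c in calls["nMG"]}  # 535 vs 0

    def test_symmetric_counts_selective_for_neither(self):
        t = SpectralCountTable.from_records(["A"], {"nMG": [10], "fMG": [10]})
        calls = labor_selective_proteins(t, Gland.MG, EQUAL_TOTALS)
        assert not calls["nMG"] and not calls["fMG"]


class TestVennPartition:
    def test_two_set_example(self):
        regions = venn_partition({"A": {"x", "y"}, "B": {"y", "z"}})
        assert regions == {
            frozenset({"A"}): 1,
            frozenset({"B"}): 1,
            frozenset({"A", "B"}): 1,
        }

    def test_disjoint_sets(self):
        regions = venn_partition({"A": {1}, "B": {2}, "C": {3}})
        assert all(v == 0 for k, v in regions.items() if len(k) > 1)

    def test_matches_powerset_oracle_and_sums_to_union(self, rng):
        for _ in range(30):
            sets = {
                name: set(rng.integers(0, 25, size=rng.integers(0, 15)).tolist())
                for name in "ABC"
            }
            regions = venn_partition(sets)
            union = set().union(*sets.values())
            assert sum(regions.values()) == len(union)
            for members, count in regions.items():
                expected = sum(
                    1
                    for x in union
                    if {n for n in sets if x in sets[n]} == set(members)
                )
                assert count == expected

    def test_more_than_three_sets_unsupported(self):
        with pytest.raises(ValueError):
            venn_partition({n: set() for n in "ABCD"})
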