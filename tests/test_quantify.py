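"""Labor merging, normalization, frequent calling, ranking, folds."""

import math

import numpy as np
import pandas as pd
import pytest

from glandprot import (
    DegenerateInputError,
    find_frequent,
    fold_change,
    merge_labor,
    normalize,
    rank_proteins,
    relative_to_reference,
)
from glandprot.refdata import top30_table, vatpase_table
from glandprot.samples import Gland, merged_name

from conftest import random_count_table


class TestMergeLabor:
    @pytest.mark.parametrize(
        "gland,accession,expected",
        [
            (Gland.MG, "gi|328787941", 6381),   # fatty acid synthase-like: 2118 + 4263
            (Gland.PcG, "gi|328789361", 4291),  # transketolase isoform 1: 2207 + 2084
            (Gland.TG, "gi|66531434", 2846),    # V-ATPase subunit B-like: 1329 + 1517
        ],
    )
    def test_pooled_counts_match_reference(self, gland, accession, expected):
        merged = merge_labor(top30_table(gland), glands=[gland])
        assert merged.count(accession, merged_name(gland)) == expected

    def test_all_zero_row_merges_to_zero(self, six_sample_table):
        merged = merge_labor(six_sample_table)
        assert merged.count("D", "(n+f)PcG") == 0

    def test_conserves_totals(self, rng):
        t = random_count_table(rng)
        merged = merge_labor(t)
        for g in Gland:
            n, f = f"n{g.value}", f"f{g.value}"
            assert (
                merged.column_totals()[merged_name(g)]
                == t.column_totals()[n] + t.column_totals()[f]
            )

    def test_missing_labor_column_rejected(self, rng):
        t = random_count_table(rng).subset(["prot|0000"])
        broken = t.df.drop(columns=["fMG"])
        from glandprot import SpectralCountTable

        with pytest.raises(ValueError, match="fMG"):
            merge_labor(SpectralCountTable(broken))


class TestNormalize:
    def test_simple_ratio(self):
        from glandprot import SpectralCountTable

        t = SpectralCountTable.from_records(["A", "B"], {"s": [400, 39600]})
        assert normalize(t).value("A", "s") == pytest.approx(0.01)

    def test_columns_sum_to_one(self, rng):
        t = random_count_table(rng, 40)
        norm = normalize(t)
        sums = norm.values.sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_zero_iff_zero_count(self, rng):
        t = random_count_table(rng, 40)
        norm = normalize(t)
        assert ((norm.values.to_numpy() == 0) == (t.counts.to_numpy() == 0)).all()

    def test_zero_total_needs_override(self):
        from glandprot import SpectralCountTable

        t = SpectralCountTable.from_records(["A"], {"s1": [5], "s2": [0]})
        with pytest.raises(DegenerateInputError, match="s2"):
            normalize(t)
        norm = normalize(t, totals_override={"s2": 40000.0})
        assert norm.value("A", "s2") == 0.0

    def test_equal_totals_override_preserves_count_ratios(self, six_sample_table):
        norm = normalize(six_sample_table, {s: 1000.0 for s in six_sample_table.samples})
        assert norm.value("A", "fPcG") / norm.value("A", "nPcG") == pytest.approx(2.0)


class TestFindFrequent:
    def test_eleven_frequent_vatpases_in_tg(self):
        merged = merge_labor(vatpase_table())
        calls = find_frequent(merged, 100)[Gland.TG]
        assert sum(c.is_frequent for c in calls) == 11

    def test_vatpase_subunit_c_like_not_frequent(self):
        """Pooled TG count 28+21=49 stays below the 100-count threshold."""
        merged = merge_labor(vatpase_table())
        call = {c.entry.accession: c for c in find_frequent(merged, 100)[Gland.TG]}["gi|328781786"]
        assert call.merged_count == 49 and not call.is_frequent

    def test_threshold_is_strict(self):
        from glandprot import SpectralCountTable

        t = SpectralCountTable.from_records(
            ["A", "B"], {"nMG": [50, 51], "fMG": [50, 50]}
        )
        merged = merge_labor(t, [Gland.MG])
        calls = {c.entry.accession: c.is_frequent for c in find_frequent(merged, 100, glands=[Gland.MG])[Gland.MG]}
        assert calls == {"A": False, "B": True}

    def test_monotone_in_threshold(self, rng):
        merged = merge_labor(random_count_table(rng, 50))
        freq = lambda m: {c.entry.accession for c in find_frequent(merged, m)[Gland.PcG] if c.is_frequent}
        assert freq(200) <= freq(100) <= freq(10)

    def test_requires_merged_columns(self, six_sample_table):
        with pytest.raises(ValueError, match="merge_labor"):
            find_frequent(six_sample_table, 100)


class TestRankProteins:
    @pytest.mark.parametrize(
        "gland,top_accession",
        [(Gland.MG, "gi|328787941"), (Gland.TG, "gi|66531434")],
    )
    def test_reference_top_ranks(self, gland, top_accession):
        merged = merge_labor(top30_table(gland), glands=[gland])
        ranking = rank_proteins(merged, gland)
        assert ranking.index[0] == top_accession

    def test_ranking_is_permutation_with_nonincreasing_counts(self, rng):
        merged = merge_labor(random_count_table(rng, 40))
        ranking = rank_proteins(merged, Gland.MG)
        assert sorted(ranking.index) == sorted(merged.accessions)
        counts = ranking[merged_name(Gland.MG)].tolist()
        assert counts == sorted(counts, reverse=True)

    def test_ties_keep_input_order(self):
        from glandprot import SpectralCountTable

        t = SpectralCountTable.from_records(
            ["first", "second"], {"nTG": [5, 5], "fTG": [5, 5]}
        )
        ranking = rank_proteins(merge_labor(t, [Gland.TG]), Gland.TG)
        assert list(ranking.index) == ["first", "second"]


class TestFoldChange:
    def test_far_forager_over_nurse(self):
        """Fatty acyl-CoA reductase 1: 380/151 = 2.52, i.e. 2.5 at one decimal."""
        fold = fold_change(top30_table(Gland.PcG), "gi|300807169", "fPcG", "nPcG")
        assert fold == pytest.approx(380 / 151)
        assert round(fold, 1) == 2.5

    def test_zero_numerator(self, six_sample_table):
        assert fold_change(six_sample_table, "B", "nPcG", "nTG") == 0.0

    def test_zero_denominator_is_infinite(self, six_sample_table):
        assert math.isinf(fold_change(six_sample_table, "B", "nTG", "nPcG"))

    def test_zero_over_zero_is_undefined(self, six_sample_table):
        assert math.isnan(fold_change(six_sample_table, "D", "nPcG", "fPcG"))

    def test_missing_entry_raises(self, six_sample_table):
        with pytest.raises(KeyError):
            fold_change(six_sample_table, "ZZZ", "nPcG", "fPcG")


class TestRelativeToReference:
    def test_identity(self, six_sample_table):
        series = relative_to_reference(six_sample_table, "C", "C")
        assert (series == 1.0).all()

    def test_simple_ratio(self):
        from glandprot import SpectralCountTable

        t = SpectralCountTable.from_records(["tgt", "actin"], {"s": [30, 10]})
        assert relative_to_reference(t, "tgt", "actin")["s"] == 3.0

    def test_matches_elementwise_division(self, rng):
        t = random_count_table(rng, 10)
        df = t.counts + 1  # ensure a never-zero reference
        from glandprot import SpectralCountTable

        t2 = SpectralCountTable(pd.concat([t.df[["description"]], df], axis=1))
        series = relative_to_reference(t2, "prot|0003", "prot|0007")
        expected = df.loc["prot|0003"] / df.loc["prot|0007"]
        assert np.allclose(series, expected)

    def test_zero_reference_names_sample(self, six_sample_table):
        with pytest.raises(DegenerateInputError, match="nMG"):
            relative_to_reference(six_sample_table, "A", "B")
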