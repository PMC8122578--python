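import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tnt1map import (
    GeneModel,
    InsertionSite,
    ReferenceGenome,
    assign_to_genes,
    bin_landscape,
    chromosome_table,
    frequency_classes,
    select_frequent_genes,
    synteny_tally,
)
from tnt1map.landscape import GeneTally, sites_to_chrom_counts
from tnt1map.rounding import percent_of


def _site(chrom, pos, name="f1"):
    return InsertionSite(fst_id=name, line_id=name, chrom=chrom, position=pos, strand="+")


class TestAssignToGenes:
    GENES = [GeneModel("A", "c1", 10, 100), GeneModel("B", "c1", 200, 300)]

    def test_containment(self):
        tallies, zero = assign_to_genes([_site("c1", 50)], self.GENES)
        assert [(t.gene_id, t.insertion_count) for t in tallies] == [("A", 1)]
        assert zero == ["B"]

    def test_inclusive_end_boundary(self):
        tallies, _ = assign_to_genes([_site("c1", 100)], self.GENES)
        assert tallies and tallies[0].gene_id == "A"
        tallies, _ = assign_to_genes([_site("c1", 101)], self.GENES)
        assert tallies == []

    def test_counts_and_zero_list(self):
        sites = [_site("c1", p, f"f{i}") for i, p in enumerate((20, 30, 40))]
        tallies, zero = assign_to_genes(sites, self.GENES)
        assert tallies[0].insertion_count == 3 and len(tallies[0].fst_ids) == 3
        assert zero == ["B"]

    def test_overlapping_genes_both_counted(self):
        genes = [GeneModel("A", "c1", 10, 100), GeneModel("B", "c1", 50, 150)]
        tallies, _ = assign_to_genes([_site("c1", 75)], genes)
        assert {t.gene_id for t in tallies} == {"A", "B"}

    @given(
        st.lists(st.integers(min_value=1, max_value=500), min_size=0, max_size=40),
        st.lists(
            st.tuples(st.integers(min_value=1, max_value=480), st.integers(min_value=1, max_value=40)),
            min_size=1,
            max_size=10,
        ),
    )
    def test_matches_brute_force_containment(self, positions, gene_spans):
        genes = [
            GeneModel(f"g{i}", "c1", start, start + span)
            for i, (start, span) in enumerate(gene_spans)
        ]
        sites = [_site("c1", p, f"f{i}") for i, p in enumerate(positions)]
        tallies, zero = assign_to_genes(sites, genes)
        got = {t.gene_id: t.insertion_count for t in tallies}
        for g in genes:
            expected = sum(1 for p in positions if g.start <= p <= g.end)
            assert got.get(g.gene_id, 0) == expected
        assert set(zero) == {g.gene_id for g in genes if got.get(g.gene_id, 0) == 0}


class TestChromosomeTable:
    def test_exact_fractions(self):
        df = chromosome_table({"c1": 3, "c2": 1}, 8, ["c1", "c2"])
        by_cat = df.set_index("category")
        assert by_cat.loc["FSTs mapped to c1", "percent_of_total"] == 37.50
        assert by_cat.loc["FSTs mapped to c2", "percent_of_total"] == 12.50

    def test_published_row_arithmetic(self):
        df = chromosome_table({"Chromosome 1": 27_902}, 221_275, ["Chromosome 1"])
        assert df.iloc[0]["percent_of_total"] == 12.61

    def test_mean_per_chromosome(self):
        counts = {f"c{i}": 0 for i in range(1, 9)}
        counts["c1"] = 201_427  # total over 8 chromosomes
        df = chromosome_table(counts, 221_275, list(counts))
        mean_row = df[df["category"] == "Mean per chromosome"].iloc[0]
        assert mean_row["fst_count"] == 25_178

    def test_unknown_chromosome_counted_unanchored(self):
        df = chromosome_table({"c1": 3, "scaf9": 2}, 10, ["c1"])
        un = df[df["category"] == "Total mapped to unanchored scaffolds"].iloc[0]
        assert un["fst_count"] == 2

    def test_conservation_of_counts(self, small_dataset, small_qc):
        from tnt1map import map_batch

        sites, summary = map_batch(
            small_qc["passed"], small_dataset.genome, qc_outcomes=small_qc["outcomes"]
        )
        counts = sites_to_chrom_counts(sites)
        df = chromosome_table(counts, summary.n_input, small_dataset.genome.names)
        anchored = df[df["category"].str.startswith("FSTs mapped")]["fst_count"].sum()
        un = df[df["category"] == "Total mapped to unanchored scaffolds"]["fst_count"].iloc[0]
        assert anchored + un == summary.n_mapped


class TestFrequencyClasses:
    def test_enumerated_fixture(self):
        tallies = [GeneTally("A", 1), GeneTally("B", 2), GeneTally("C", 5)]
        s = frequency_classes(tallies, 10)
        assert (s.n_genes_ge1, s.n_genes_gt1, s.n_genes_ge4) == (3, 2, 1)
        assert s.mean_per_inserted_gene == pytest.approx(8 / 3)

    def test_empty_tallies(self):
        s = frequency_classes([], 10)
        assert (s.n_genes_ge1, s.n_genes_gt1, s.n_genes_ge4) == (0, 0, 0)
        assert s.mean_per_inserted_gene == 0.0

    def test_published_percent(self):
        assert percent_of(19_008, 39_027, 1) == 48.7

    def test_nesting_invariant(self, small_dataset, small_qc):
        from tnt1map import map_batch

        sites, _ = map_batch(
            small_qc["passed"], small_dataset.genome, qc_outcomes=small_qc["outcomes"]
        )
        tallies, _ = assign_to_genes(sites, small_dataset.genes)
        s = frequency_classes(tallies, len(small_dataset.genes))
        assert s.n_genes_ge4 <= s.n_genes_gt1 <= s.n_genes_ge1 <= s.n_annotated_genes


class TestSelectFrequentGenes:
    TALLIES = [GeneTally("A", 5), GeneTally("B", 4), GeneTally("C", 3)]

    def test_strict_inequality_at_threshold(self):
        assert [t.gene_id for t in select_frequent_genes(self.TALLIES, 4.33)] == ["A"]

    def test_zero_threshold_selects_all(self):
        assert len(select_frequent_genes(self.TALLIES, 0)) == 3

    def test_sorted_by_count_then_id(self):
        tallies = [GeneTally("B", 9), GeneTally("A", 9), GeneTally("C", 12)]
        assert [t.gene_id for t in select_frequent_genes(tallies, 0)] == ["C", "A", "B"]


class TestBinLandscape:
    def test_tiling_arithmetic(self):
        genome = ReferenceGenome({"c1": "A" * 1_200_000})
        bins = bin_landscape([], genome, 500_000)
        assert [(b.bin_start, b.bin_end) for b in bins] == [
            (1, 500_000),
            (500_001, 1_000_000),
            (1_000_001, 1_200_000),
        ]

    def test_boundary_site_assignment(self):
        genome = ReferenceGenome({"c1": "A" * 1_200_000})
        bins = bin_landscape([_site("c1", 500_000), _site("c1", 500_001, "f2")], genome, 500_000)
        assert bins[0].insertion_count == 1 and bins[1].insertion_count == 1

    def test_gc_extremes(self):
        genome = ReferenceGenome({"c1": "GGCC" * 25})
        bins = bin_landscape([], genome, 100)
        assert bins[0].gc_fraction == 1.0

    def test_all_n_bin_flagged(self):
        genome = ReferenceGenome({"c1": "N" * 100 + "ACGT" * 25})
        bins = bin_landscape([], genome, 100)
        assert bins[0].all_n and bins[0].gc_fraction == 0.0
        assert not bins[1].all_n and bins[1].gc_fraction == 0.5

    @given(
        st.integers(min_value=1, max_value=5000),
        st.integers(min_value=1, max_value=1500),
        st.lists(st.integers(min_value=1, max_value=5000), max_size=50),
    )
    def test_tiling_covers_every_base_once_and_counts_conserve(
        self, chrom_len, width, raw_positions
    ):
        genome = ReferenceGenome({"c1": "ACGT" * (chrom_len // 4 + 1)})
        genome.sequences["c1"] = genome.sequences["c1"][:chrom_len]
        positions = [p for p in raw_positions if p <= chrom_len]
        sites = [_site("c1", p, f"f{i}") for i, p in enumerate(positions)]
        bins = bin_landscape(sites, genome, width)
        assert bins[0].bin_start == 1 and bins[-1].bin_end == chrom_len
        for a, b in zip(bins, bins[1:]):
            assert b.bin_start == a.bin_end + 1
        assert all(b.bin_end - b.bin_start + 1 == width for b in bins[:-1])
        assert sum(b.insertion_count for b in bins) == len(sites)


class TestSyntenyTally:
    def test_constructed_block(self):
        df = synteny_tally([GeneTally("A", 2)], {"b1": ["A", "B"]})
        row = df.iloc[0]
        assert (row["n_genes"], row["genes_with_insertions"], row["total_insertions"]) == (2, 1, 2)

    def test_gene_in_two_blocks_counted_in_both(self):
        df = synteny_tally([GeneTally("A", 1)], {"b1": ["A"], "b2": ["A"]})
        assert list(df["genes_with_insertions"]) == [1, 1]

    def test_block_without_insertions(self):
        df = synteny_tally([], {"b1": ["A"]})
        assert df.iloc[0]["genes_with_insertions"] == 0

    def test_empty_block_table_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            synteny_tally([], {})

    def test_sorted_by_genes_with_insertions(self):
        tallies = [GeneTally("A", 1), GeneTally("B", 1), GeneTally("C", 1)]
        df = synteny_tally(tallies, {"small": ["A"], "big": ["B", "C"]})
        assert list(df["block_id"]) == ["big", "small"]
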