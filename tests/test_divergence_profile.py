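import numpy as np
import pytest

from barcodegap.distance import distance_matrix
from barcodegap.divergence_profile import (
    WITHIN_FAMILY, WITHIN_GENUS, WITHIN_SPECIES, divergence_histogram,
    partition_pairs_by_level, per_group_summaries, summarize_levels,
)
from barcodegap.sequence_io import Alignment, BarcodeRecord
from barcodegap.synthetic_data import ComplexConfig, simulate_complex


def _aln(rows):
    return Alignment(records=tuple(
        BarcodeRecord(id=i, sequence=s, species=sp, genus=ge, family=fa)
        for i, s, sp, ge, fa in rows
    ))


@pytest.fixture
def four_taxon_matrix():
    # A1,A2 conspecific; B1 congeneric with them; C1 confamilial
    aln = _aln([
        ("A1", "ACGTACGTACGTACGTACGT", "X", "G", "F"),
        ("A2", "ACGTACGTACGTACGTACGA", "X", "G", "F"),
        ("B1", "ACGTACGAACGAACGTACGT", "Y", "G", "F"),
        ("C1", "TCGATCGAACGAACTTACGT", "Z", "H", "F"),
    ])
    return distance_matrix(aln, "p"), {r.id: r for r in aln.records}


class TestPartition:
    def test_level_enumeration(self, four_taxon_matrix):
        m, tax = four_taxon_matrix
        part = partition_pairs_by_level(m, tax)
        assert len(part.distances[WITHIN_SPECIES]) == 1      # A1-A2
        assert len(part.distances[WITHIN_GENUS]) == 2        # A*-B1
        assert len(part.distances[WITHIN_FAMILY]) == 3       # *-C1
        assert part.n_assigned + part.n_skipped + part.n_excluded == m.n_pairs

    def test_cross_family_excluded(self):
        aln = _aln([
            ("a", "ACGT", "X", "G", "F1"),
            ("b", "ACGA", "Y", "H", "F2"),
        ])
        m = distance_matrix(aln, "p")
        part = partition_pairs_by_level(m, {r.id: r for r in aln.records})
        assert part.n_assigned == 0 and part.n_excluded == 1

    def test_missing_labels_skipped_and_counted(self):
        aln = _aln([
            ("a", "ACGT", "X", "G", "F"),
            ("b", "ACGA", None, "G", "F"),
        ])
        m = distance_matrix(aln, "p")
        part = partition_pairs_by_level(m, {r.id: r for r in aln.records})
        assert part.n_skipped == 1 and part.n_assigned == 0

    def test_levels_are_exclusive_and_conserve_pairs(self):
        aln, _ = simulate_complex(ComplexConfig(
            n_species=5, members_per_species=3, seq_length=200, seed=11))
        m = distance_matrix(aln)
        part = partition_pairs_by_level(m, {r.id: r for r in aln.records})
        assert part.n_assigned + part.n_skipped + part.n_excluded == m.n_pairs

    def test_nested_counting_is_cumulative(self, four_taxon_matrix):
        m, tax = four_taxon_matrix
        nested = partition_pairs_by_level(m, tax, nested=True)
        # every confamilial-or-closer pair reaches the family level
        assert len(nested.distances[WITHIN_FAMILY]) == 6
        assert len(nested.distances[WITHIN_GENUS]) == 3

    def test_ordering_on_separated_synthetic_data(self):
        # within-species average below congeneric average by construction
        aln, _ = simulate_complex(ComplexConfig(
            n_species=6, members_per_species=4, seq_length=400,
            d_intra=0.01, d_inter=0.15, seed=3))
        m = distance_matrix(aln)
        part = partition_pairs_by_level(m, {r.id: r for r in aln.records})
        summaries = {s.level: s for s in summarize_levels(part)}
        assert summaries[WITHIN_SPECIES].avg < summaries[WITHIN_GENUS].avg


class TestSummaries:
    def test_direct_arithmetic(self):
        from barcodegap.divergence_profile import LevelPartition
        part = LevelPartition()
        part.distances[WITHIN_SPECIES] = [0.01, 0.03]
        (s,) = summarize_levels(part)
        assert (s.avg, s.min, s.max, s.n_comparisons) == (2.0, 1.0, 3.0, 2)

    def test_single_pair_collapses(self):
        from barcodegap.divergence_profile import LevelPartition
        part = LevelPartition()
        part.distances[WITHIN_GENUS] = [0.05]
        (s,) = summarize_levels(part)
        assert s.avg == s.min == s.max == pytest.approx(5.0)

    def test_undefined_excluded_but_counted(self):
        from barcodegap.divergence_profile import LevelPartition
        part = LevelPartition()
        part.distances[WITHIN_SPECIES] = [0.02, float("nan")]
        (s,) = summarize_levels(part)
        assert s.n_comparisons == 1 and s.n_undefined == 1
        assert s.avg == pytest.approx(2.0)


class TestHistogram:
    def test_small_example(self):
        edges, counts = divergence_histogram([0.001, 0.006], bin_width=0.5)
        assert counts.tolist() == [1, 1]
        assert edges.tolist() == [0.0, 0.5, 1.0]

    def test_boundary_goes_to_upper_bin(self):
        _, counts = divergence_histogram([0.005], bin_width=0.5)
        assert counts.tolist() == [0, 1]  # 0.5% sits in [0.5, 1.0)

    def test_conservation_and_order_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 0.25, size=500)
        edges, counts = divergence_histogram(vals, 0.5)
        assert counts.sum() == 500
        _, shuffled = divergence_histogram(vals[::-1], 0.5)
        assert (counts == shuffled).all()

    def test_empty_input(self):
        edges, counts = divergence_histogram([])
        assert len(edges) == 0 and len(counts) == 0


class TestPerGroup:
    @pytest.fixture
    def grouped_matrix(self):
        aln = _aln([
            ("a1", "ACGTACGTACGTACGTACGT", "A", "G", "F"),
            ("a2", "ACGTACGTACGTACGTACGA", "A", "G", "F"),
            ("b1", "ACGAACGAACGTACGTACGT", "B", "G", "F"),
            ("c1", "TCGATCGTACGTACGTACGT", "C", "G", "F"),
        ])
        m = distance_matrix(aln, "p")
        return m, {r.id: r.species for r in aln.records}

    def test_intra_summary_and_singleton_skipped(self, grouped_matrix):
        m, groups = grouped_matrix
        summaries, skipped = per_group_summaries(m, groups, mode="intra")
        assert [s.name for s in summaries] == ["A"]
        assert summaries[0].avg == pytest.approx(5.0)  # 1/20 difference
        assert sorted(skipped) == ["B", "C"]

    def test_inter_pairs_enumerated(self, grouped_matrix):
        m, groups = grouped_matrix
        summaries, _ = per_group_summaries(
            m, groups, mode="inter", pair_list=[("A", "B")])
        (s,) = summaries
        assert s.n_comparisons == 2  # a1-b1, a2-b1

    def test_unknown_group_in_pair_list(self, grouped_matrix):
        m, groups = grouped_matrix
        with pytest.raises(ValueError, match="nope"):
            per_group_summaries(m, groups, mode="inter",
                                pair_list=[("A", "nope")])
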