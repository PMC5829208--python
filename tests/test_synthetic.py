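"""Ground-truth behavior of the synthetic-data generators."""

import numpy as np
import pytest

from ploidyshift import (
    HaplotypeSimConfig,
    OUSimConfig,
    SimConfig,
    count_haplotypes,
    edge_table,
    filter_reads,
    ou_design,
    simulate_contig_alignments,
    simulate_ou_traits,
    simulate_read_ratio_dataset,
)
from ploidyshift.synthetic import balanced_tree, simulate_coalescent_tree


class TestSimConfigValidation:
    def test_rejects_bad_ploidy(self):
        with pytest.raises(ValueError, match="ploidy"):
            SimConfig(ploidy=5, n_snps=10)

    def test_rejects_wrong_dosage_length(self):
        with pytest.raises(ValueError, match="dosage_weights"):
            SimConfig(ploidy=2, n_snps=10, dosage_weights=(0.5, 0.5))

    def test_rejects_unnormalized_dosage(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(ploidy=3, n_snps=10, dosage_weights=(0.6, 0.6))

    def test_rejects_high_error(self):
        with pytest.raises(ValueError, match="error_rate"):
            SimConfig(ploidy=2, n_snps=10, error_rate=0.5)


class TestReadRatioSimulator:
    def test_diploid_grand_mean_half(self):
        reps = simulate_read_ratio_dataset(
            SimConfig(ploidy=2, n_snps=100_000, depth_mean=30, error_rate=0.0, seed=1)
        )
        ratios = np.array([r.ref_count / r.total for r in reps[0]])
        assert abs(ratios.mean() - 0.5) < 0.01

    def test_triploid_dosage_two_gives_one_to_two(self):
        reps = simulate_read_ratio_dataset(
            SimConfig(ploidy=3, n_snps=30_000, dosage_weights=(0.0, 1.0), error_rate=0.0, seed=2)
        )
        ref = sum(r.ref_count for r in reps[0])
        alt = sum(r.alt_count for r in reps[0])
        assert alt / ref == pytest.approx(2.0, rel=0.05)

    def test_same_seed_byte_identical(self):
        cfg = SimConfig(ploidy=4, n_snps=500, depth_law="poisson", error_rate=0.01, seed=7)
        assert simulate_read_ratio_dataset(cfg) == simulate_read_ratio_dataset(cfg)

    def test_counts_sum_to_fixed_depth(self):
        reps = simulate_read_ratio_dataset(SimConfig(ploidy=2, n_snps=200, depth_mean=30, seed=3))
        assert all(r.total == 30 for rep in reps for r in rep)

    def test_poisson_depths_positive(self):
        reps = simulate_read_ratio_dataset(
            SimConfig(ploidy=2, n_snps=2000, depth_mean=2.0, depth_law="poisson", seed=4)
        )
        assert all(r.total >= 1 for r in reps[0])

    def test_tetraploid_histogram_modes(self):
        """Dosage weights (1/4, 1/2, 1/4) put local modes near 0.25/0.5/0.75."""
        reps = simulate_read_ratio_dataset(
            SimConfig(ploidy=4, n_snps=20_000, depth_mean=30, dosage_weights=(0.25, 0.5, 0.25), seed=5)
        )
        ratios = np.array([r.ref_count / r.total for r in reps[0]])
        hist, edges = np.histogram(ratios, bins=50, range=(0, 1))
        centers = (edges[:-1] + edges[1:]) / 2
        for target in (0.25, 0.5, 0.75):
            window = (centers > target - 0.08) & (centers < target + 0.08)
            local_mode = centers[window][hist[window].argmax()]
            assert abs(local_mode - target) <= 0.03

    def test_paralog_sites_add_outer_mass_in_diploids(self):
        clean = simulate_read_ratio_dataset(
            SimConfig(ploidy=2, n_snps=20_000, depth_mean=60, seed=6)
        )
        contaminated = simulate_read_ratio_dataset(
            SimConfig(ploidy=2, n_snps=20_000, depth_mean=60, paralog_fraction=0.3, seed=6)
        )
        def outer_frac(rep):
            r = np.array([x.ref_count / x.total for x in rep])
            return np.mean((r < 0.35) | (r > 0.65))
        assert outer_frac(contaminated[0]) > outer_frac(clean[0]) + 0.1


class TestContigSimulator:
    def test_single_haplotype_reads_identical(self):
        alns, truth = simulate_contig_alignments(
            HaplotypeSimConfig(n_contigs=5, true_haplotypes_per_contig={1: 1.0}, seed=1)
        )
        assert set(truth.values()) == {1}
        for aln in alns:
            base_by_col = {}
            for read in aln.reads:
                for pos, base in read.bases.items():
                    assert base_by_col.setdefault(pos, base) == base

    def test_two_haplotypes_fully_recoverable(self):
        alns, _ = simulate_contig_alignments(
            HaplotypeSimConfig(
                n_contigs=10, true_haplotypes_per_contig={2: 1.0}, reads_per_contig=50,
                haplotype_divergence=1.0, seed=2,
            )
        )
        assert all(count_haplotypes(filter_reads(a)) == 2 for a in alns)

    def test_undersupported_contigs_score_zero(self):
        """Below 20 reads per haplotype the support filter wipes the contig."""
        alns, _ = simulate_contig_alignments(
            HaplotypeSimConfig(
                n_contigs=5, true_haplotypes_per_contig={2: 1.0}, reads_per_contig=30, seed=3
            )
        )
        assert all(count_haplotypes(filter_reads(a), min_reads_per_hap=20) == 0 for a in alns)

    def test_seed_determinism(self):
        cfg = HaplotypeSimConfig(n_contigs=4, seed=11)
        a1, t1 = simulate_contig_alignments(cfg)
        a2, t2 = simulate_contig_alignments(cfg)
        assert a1 == a2 and t1 == t2


class TestOUSimulator:
    def test_zero_noise_returns_expectations(self, tree32):
        table = edge_table(tree32)
        cfg = OUSimConfig(tree=tree32, shift_edges=(0,), shift_offsets=(2.0,), alpha=2.0, sigma2=0.0, seed=1)
        traits = simulate_ou_traits(cfg)
        design, _ = ou_design(tree32, 2.0)
        expected = 2.0 * design[:, 0]
        got = np.array([traits[t] for t in table.tip_labels])
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_same_seed_identical(self, tree32):
        cfg = OUSimConfig(tree=tree32, alpha=1.0, sigma2=1.0, seed=5)
        assert simulate_ou_traits(cfg) == simulate_ou_traits(cfg)

    def test_non_ultrametric_tree_names_tip(self):
        import dendropy

        bad = dendropy.Tree.get(data="((A:1.0,B:2.0):1.0,C:2.0);", schema="newick")
        with pytest.raises(ValueError, match="tip 'A'"):  # A is 1 below the height
            simulate_ou_traits(OUSimConfig(tree=bad, alpha=1.0, sigma2=1.0, seed=0))

    def test_brownian_limit_covariance(self, tree4):
        """As alpha -> 0 the sample covariance approaches sigma2 x shared path."""
        table = edge_table(tree4)
        n_rep = 10_000
        draws = np.empty((n_rep, 4))
        for i in range(n_rep):
            traits = simulate_ou_traits(
                OUSimConfig(tree=tree4, alpha=1e-8, sigma2=1.0, seed=1000 + i)
            )
            draws[i] = [traits[t] for t in table.tip_labels]
        sample_cov = np.cov(draws.T)
        # independent analytic BM covariance: sigma2 * shared path length
        from ploidyshift.ou_shift import _shared_time_matrix

        bm_cov = _shared_time_matrix(tree4, table)
        np.testing.assert_allclose(sample_cov, bm_cov, atol=4 * 1.0 / np.sqrt(n_rep) + 0.02)

    def test_ou_covariance_spd(self, tree32):
        _, cov = ou_design(tree32, alpha=3.0, sigma2=2.0)
        np.testing.assert_allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) > 0)


def test_coalescent_tree_is_ultrametric_unit_height():
    from ploidyshift import check_ultrametric

    tree = simulate_coalescent_tree(20, seed=3)
    assert check_ultrametric(tree) == pytest.approx(1.0)
    table = edge_table(tree)
    assert len(table.tip_labels) == 20
    assert np.all(table.t_end - table.t_start > 0)


def test_balanced_tree_structure():
    tree = balanced_tree(4)
    table = edge_table(tree)
    assert len(table.tip_labels) == 16
    sizes = table.tip_indicator.sum(axis=0)
    assert sorted(sizes)[-2:] == [8.0, 8.0]  # two root children cover half each
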