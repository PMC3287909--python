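"""Unit and property tests for the burden statistic and its plumbing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from geneburden.core import (
    GeneBurden,
    GeneRegion,
    GenotypeMatrix,
    PhenotypeVector,
    VariantRecord,
    assign_variants_to_genes,
    burden_counts,
    compute_maf,
    pooled_variance,
    scan_genes,
    select_rare,
    t_g_from_counts,
    t_g_statistic,
    total_variance,
)


def make_burden(p, q):
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    n = p.size + q.size
    return GeneBurden(
        gene="g", case_counts=p, control_counts=q,
        case_mean=float(p.mean()), control_mean=float(q.mean()),
        grand_mean=float(np.concatenate([p, q]).mean()),
        pooled_variance=pooled_variance(p, q),
        n_case=p.size, n_control=q.size, n_total=n,
    )


class TestComputeMaf:
    @pytest.mark.parametrize(
        "dosages, expected",
        [
            ([0] * 100, 0.0),
            ([1, 1, 1] + [0] * 197, 3 / 400),  # three hets among 200 typed
            ([2] * 198 + [1] * 2, 0.005),  # alt frequency 0.995 folds to 0.005
            ([0, 1, float("nan"), 1], 1 / 3),  # missing excluded from denominator
        ],
    )
    def test_folded_frequency(self, dosages, expected):
        assert compute_maf(dosages) == pytest.approx(expected, abs=1e-12)

    def test_all_missing_is_an_error(self):
        with pytest.raises(ValueError, match="no typed"):
            compute_maf([float("nan")] * 4)


class TestSelectRare:
    def test_threshold_is_strict(self):
        mk = lambda i, maf: VariantRecord(f"v{i}", "chr1", 100 + i, maf=maf)
        variants = [mk(1, 0.0075), mk(2, 0.01), mk(3, 0.5), mk(4, 0.0)]
        kept = {v.variant_id for v in select_rare(variants, 0.01)}
        assert kept == {"v1", "v4"}

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            select_rare([], -0.01)


class TestGeneAssignment:
    def test_inclusive_bounds_and_chromosome_match(self):
        gene = GeneRegion("G", "chr1", 100, 200)
        variants = [
            VariantRecord("at_start", "chr1", 100),
            VariantRecord("at_end", "chr1", 200),
            VariantRecord("past_end", "chr1", 201),
            VariantRecord("before", "chr1", 99),
            VariantRecord("wrong_chrom", "chr2", 150),
        ]
        mapping = assign_variants_to_genes(variants, [gene])
        assert mapping["G"] == ["at_start", "at_end"]

    def test_overlapping_genes_both_get_the_variant(self):
        genes = [GeneRegion("A", "chr1", 100, 300), GeneRegion("B", "chr1", 250, 400)]
        v = [VariantRecord("v", "chr1", 275)]
        mapping = assign_variants_to_genes(v, genes)
        assert mapping == {"A": ["v"], "B": ["v"]}

    def test_empty_inputs(self):
        assert assign_variants_to_genes([], []) == {}
        assert assign_variants_to_genes([], [GeneRegion("G", "chr1", 1, 10)]) == {"G": []}


class TestBurdenCounts:
    def test_counts_and_group_summaries(self, small_dataset):
        variants, genes, genotypes, phenotype = small_dataset
        b = burden_counts(genes[0], ["v1", "v2", "v3"], genotypes, phenotype)
        assert b.case_counts.tolist() == [2.0, 0.0]
        assert b.control_counts.tolist() == [1.0, 3.0]
        assert b.case_mean == 1.0
        assert b.control_mean == 2.0
        assert b.grand_mean == 1.5
        assert b.n_total == b.n_case + b.n_control == 4

    def test_het_plus_rare_homozygote_counts_dosage(self, small_dataset):
        variants, genes, genotypes, phenotype = small_dataset
        b = burden_counts(genes[0], ["v1", "v2", "v3"], genotypes, phenotype)
        # s4 is het at v1 and rare-homozygous at v3: 1 + 2
        assert b.control_counts[1] == 3.0

    def test_carrier_mode_caps_per_site_contribution(self, small_dataset):
        variants, genes, genotypes, phenotype = small_dataset
        b = burden_counts(
            genes[0], ["v1", "v2", "v3"], genotypes, phenotype, count_mode="carrier"
        )
        assert b.control_counts.tolist() == [1.0, 2.0]

    def test_zero_rare_variants_gives_all_zero_counts(self, small_dataset):
        variants, genes, genotypes, phenotype = small_dataset
        b = burden_counts(genes[0], [], genotypes, phenotype)
        assert b.case_counts.tolist() == [0.0, 0.0]
        assert b.pooled_variance == 0.0

    def test_common_alt_column_is_folded_to_minor(self):
        # alt frequency 0.75: minor allele is REF, dosages flip 2 - d
        geno = GenotypeMatrix(["a", "b"], ["v"], np.array([[2.0], [1.0]]))
        phen = PhenotypeVector(["a", "b"], np.array([1, 0], bool))
        b = burden_counts(GeneRegion("G", "chr1", 1, 10), ["v"], geno, phen)
        assert b.case_counts.tolist() == [0.0]
        assert b.control_counts.tolist() == [1.0]


class TestPooledVariance:
    @pytest.mark.parametrize(
        "p, q, expected",
        [
            ([1, 1], [1, 1], 0.0),
            ([2, 0, 1, 1], [0, 0, 1, 0], (2 + 0.75) / 6),
            ([0, 2], [1, 3], 2.0),
        ],
    )
    def test_against_sum_of_squares(self, p, q, expected):
        assert pooled_variance(p, q) == pytest.approx(expected, rel=1e-12)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="N >= 3"):
            pooled_variance([1], [2])

    def test_total_variance_uses_grand_mean(self):
        p, q = [0, 2], [1, 3]
        assert total_variance(p, q) == pytest.approx(np.var([0, 2, 1, 3], ddof=1))


class TestTgStatistic:
    def test_worked_micro_example(self):
        res = t_g_statistic(make_burden([2, 0, 1, 1], [0, 0, 1, 0]))
        assert res.t_g == pytest.approx(2.4545454545, rel=1e-9)
        assert res.p_value == pytest.approx(0.117, abs=5e-4)
        assert not res.degenerate

    def test_equal_means_give_zero_statistic(self):
        res = t_g_statistic(make_burden([0, 2], [1, 1]))
        assert res.t_g == 0.0
        assert res.p_value == 1.0

    def test_monomorphic_gene_is_degenerate_with_p_one(self):
        res = t_g_statistic(make_burden([0, 0], [0, 0]))
        assert res.degenerate
        assert math.isnan(res.t_g)
        assert res.p_value == 1.0

    def test_zero_variance_unequal_means_has_undefined_p(self):
        res = t_g_statistic(make_burden([1, 1], [0, 0]))
        assert res.degenerate
        assert math.isnan(res.p_value)

    def test_label_symmetry(self):
        a = t_g_statistic(make_burden([2, 0, 1, 1], [0, 0, 1, 0]))
        b = t_g_statistic(make_burden([0, 0, 1, 0], [2, 0, 1, 1]))
        assert a.t_g == pytest.approx(b.t_g, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    @pytest.mark.parametrize("shift, scale", [(3, 1.0), (0, 2.5), (7, 0.5)])
    def test_location_and_scale_invariance(self, shift, scale):
        p, q = np.array([2.0, 0, 1, 1, 4]), np.array([0.0, 0, 1, 0])
        base = t_g_statistic(make_burden(p, q)).t_g
        moved = t_g_statistic(make_burden(scale * (p + shift), scale * (q + shift))).t_g
        assert moved == pytest.approx(base, rel=1e-10)

    def test_p_value_decreases_with_t(self):
        t = np.linspace(0.1, 30, 50)
        p = stats.chi2.sf(t, 1)
        assert np.all(np.diff(p) < 0)

    @given(
        p=st.lists(st.integers(0, 10), min_size=2, max_size=40),
        q=st.lists(st.integers(0, 10), min_size=2, max_size=40),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_matches_squared_pooled_t_oracle(self, p, q):
        """T_G equals the square of the classical equal-variance two-sample t."""
        res = t_g_statistic(make_burden(p, q))
        t, _ = stats.ttest_ind(p, q, equal_var=True)
        if res.degenerate:
            assert np.isnan(t) or pooled_variance(p, q) == 0.0
        else:
            assert res.t_g == pytest.approx(t**2, rel=1e-10)
            assert res.t_g >= 0


class TestVectorizedTg:
    def test_agrees_with_scalar_path(self):
        rng = np.random.default_rng(11)
        case = rng.poisson(1.2, size=(50, 30))
        ctrl = rng.poisson(0.8, size=(50, 25))
        t, p = t_g_from_counts(case, ctrl)
        for i in range(50):
            res = t_g_statistic(make_burden(case[i], ctrl[i]))
            if res.degenerate:
                assert math.isnan(t[i])
            else:
                assert t[i] == pytest.approx(res.t_g, rel=1e-12)
                assert p[i] == pytest.approx(res.p_value, rel=1e-12)

    def test_degenerate_rows_flagged(self):
        t, p = t_g_from_counts(np.array([[1, 1], [0, 0]]), np.array([[1, 1], [1, 1]]))
        assert np.isnan(t).all()
        assert p[0] == 1.0 and math.isnan(p[1])


class TestScanGenes:
    def test_one_result_per_gene_in_input_order(self, small_dataset):
        variants, genes, genotypes, phenotype = small_dataset
        genes = genes + [GeneRegion("EMPTY", "chr9", 1, 100)]
        results = scan_genes(genotypes, variants, genes, phenotype)
        assert [r.gene for r in results] == ["G1", "EMPTY"]
        assert results[1].degenerate and results[1].n_rare_snps == 0

    def test_common_variants_excluded_from_burden(self, small_dataset):
        variants, genes, genotypes, phenotype = small_dataset
        # recompute MAFs from the sample: all are large, so a strict
        # threshold of 0.01 keeps nothing
        unset = [VariantRecord(v.variant_id, v.chrom, v.pos) for v in variants]
        results = scan_genes(genotypes, unset, genes, phenotype, maf_threshold=0.01)
        assert results[0].n_rare_snps == 0 and results[0].degenerate

    def test_external_mafs_override_sample_estimates(self, small_dataset):
        variants, genes, genotypes, phenotype = small_dataset
        ext = {"v1": 0.001, "v2": 0.001, "v3": 0.001}
        results = scan_genes(
            genotypes, variants, genes, phenotype, external_mafs=ext
        )
        assert results[0].n_rare_snps == 3
        assert not results[0].degenerate

    def test_sample_permutation_invariance(self, small_dataset):
        variants, genes, genotypes, phenotype = small_dataset
        perm = [3, 1, 0, 2]
        geno2 = GenotypeMatrix(
            [genotypes.sample_ids[i] for i in perm],
            list(genotypes.variant_ids),
            genotypes.dosage[perm],
        )
        phen2 = PhenotypeVector(
            [phenotype.sample_ids[i] for i in perm], phenotype.is_case[perm]
        )
        ext = {"v1": 0.001, "v2": 0.001, "v3": 0.001}
        r1 = scan_genes(genotypes, variants, genes, phenotype, external_mafs=ext)
        r2 = scan_genes(geno2, variants, genes, phen2, external_mafs=ext)
        assert r1[0].t_g == pytest.approx(r2[0].t_g, rel=1e-14)

    def test_sample_mismatch_reports_offending_ids(self, small_dataset):
        variants, genes, genotypes, phenotype = small_dataset
        bad = PhenotypeVector(["s1", "s2", "s3", "sX"], phenotype.is_case)
        with pytest.raises(ValueError, match="sX"):
            scan_genes(genotypes, variants, genes, bad)
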