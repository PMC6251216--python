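"""Association scan: QC filter, contingency/GLM tests, interval, arithmetic."""

import numpy as np
import pytest
from scipy import stats

from bsamap.association import (
    associate,
    define_interval,
    fold_coverage_per_sample,
    qc_filter,
    raw_gb_to_coverage,
)
from bsamap.simulate import CrossDesign, phenotype_to_binary, simulate_f2
from bsamap.variants import GenotypeMatrix, VariantRecord, marker_distance


def _matrix(codes, chrom="C1"):
    codes = np.asarray(codes, dtype=np.int8)
    variants = [VariantRecord(chrom, 100 * (j + 1), "A", "T") for j in range(codes.shape[1])]
    samples = [f"s{i}" for i in range(codes.shape[0])]
    return GenotypeMatrix(samples, variants, codes)


def _random_matrix(rng, n, m, missing_rate=0.1):
    codes = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    codes[rng.random((n, m)) < missing_rate] = -1
    return _matrix(codes)


class TestQcFilter:
    def test_call_count_boundary_is_inclusive(self):
        codes = np.ones((130, 2), dtype=np.int8)
        codes[: 130 - 99, 0] = -1  # 99 calls: below threshold
        codes[60:130, 1] = 0  # 130 calls, MAF ~0.46
        kept = qc_filter(_matrix(codes), min_count=100, min_freq=0.1)
        assert kept.variant_ids() == ["C1_200"]

    def test_maf_boundary_is_inclusive(self):
        # 10 samples, one hom-alt => alt freq 0.10 exactly
        codes = np.zeros((10, 1), dtype=np.int8)
        codes[0, 0] = 2
        assert qc_filter(_matrix(codes), min_count=1, min_freq=0.1).n_variants == 1
        codes[0, 0] = 1  # alt freq 0.05
        assert qc_filter(_matrix(codes), min_count=1, min_freq=0.1).n_variants == 0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(12)
        gm = _random_matrix(rng, 60, 200, missing_rate=0.3)
        kept = qc_filter(gm, min_count=40, min_freq=0.2)
        expected = []
        for j, v in enumerate(gm.variants):
            col = gm.codes[:, j]
            called = col[col >= 0]
            if len(called) < 40:
                continue
            f = (called == 1).sum() / (2 * len(called)) + (called == 2).sum() / len(called)
            if min(f, 1 - f) >= 0.2:
                expected.append(v.id)
        assert kept.variant_ids() == expected


class TestAssociate:
    def test_deterministic_phenotype_gives_chi2_equal_to_n(self):
        """(33,65,32) genotype classes with phenotype = hom-alt: chi2 = N."""
        codes = np.array([[0] * 33 + [1] * 65 + [2] * 32]).T
        phen = np.array([0] * 98 + [1] * 32)
        (res,) = associate(_matrix(codes), phen)
        assert res.statistic == pytest.approx(130.0, abs=1e-9)
        assert res.df == 2
        assert res.p_value == pytest.approx(stats.chi2.sf(130, 2))

    def test_chi2_equals_n_over_random_class_splits(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(30, 300))
            codes = rng.integers(0, 3, size=(n, 1)).astype(np.int8)
            if len(np.unique(codes)) < 2 or not (codes == 2).any() or (codes == 2).all():
                continue
            phen = (codes[:, 0] == 2).astype(int)
            (res,) = associate(_matrix(codes), phen)
            assert res.statistic == pytest.approx(n, rel=1e-12)

    def test_identical_class_proportions_give_zero(self):
        codes = np.array([[0, 0, 1, 1, 2, 2, 0, 0, 1, 1, 2, 2]]).T
        phen = np.array([0, 1] * 6)
        (res,) = associate(_matrix(codes), phen)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_contingency_implementation(self):
        """Both routes agree with scipy oracles on random genotype data."""
        rng = np.random.default_rng(7)
        gm = _random_matrix(rng, 80, 150, missing_rate=0.15)
        phen = rng.integers(0, 2, size=80)
        for res in associate(gm, phen, method="chi2_genotypic"):
            j = gm.variant_ids().index(res.variant_id)
            col = gm.codes[:, j]
            ok = col >= 0
            table = [
                [((col == g) & ok & (phen == p)).sum() for g in (0, 1, 2)]
                for p in (0, 1)
            ]
            table = np.array(table)[:, np.array(table).sum(axis=0) > 0]
            if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
                continue
            ref = stats.chi2_contingency(table, correction=False)
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)
        for res in associate(gm, phen, method="glm_dosage_F"):
            j = gm.variant_ids().index(res.variant_id)
            col = gm.codes[:, j]
            groups = [phen[(col == g)] for g in (0, 1, 2) if (col == g).sum() > 0]
            if len(groups) < 2 or res.p_value <= 1e-290:
                continue
            ref = stats.f_oneway(*groups)
            if np.isnan(ref.statistic):
                continue
            assert res.statistic == pytest.approx(ref.statistic, rel=1e-8)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_monomorphic_variant_reports_p_one(self):
        codes = np.zeros((20, 1), dtype=np.int8)
        phen = np.array([0, 1] * 10)
        (res,) = associate(_matrix(codes), phen)
        assert res.p_value == 1.0 and res.statistic == 0.0

    def test_uniform_phenotype_is_an_error(self):
        codes = np.array([[0, 1, 2, 1]]).T
        with pytest.raises(ValueError, match="one phenotype"):
            associate(_matrix(codes), np.array([1, 1, 1, 1]))

    def test_both_methods_rank_perfectly_linked_variant_first(self):
        hits = 0
        for seed in range(20):
            design = CrossDesign(
                n_f2=130, n_chromosomes=2, chrom_length_bp=1_000_000,
                variants_per_chrom=40, causal_chrom=1, causal_pos=500_000, seed=seed,
            )
            gm, phen, variants = simulate_f2(design)
            y = phenotype_to_binary(phen)
            for method in ("chi2_genotypic", "glm_dosage_F"):
                results = associate(gm, y, method=method)
                best = min(results, key=lambda r: r.p_value)
                hits += best.statistic == max(r.statistic for r in results) and (
                    abs(best.variant.pos - 500_000) < 100_000
                )
        assert hits >= 38  # ties with perfectly co-segregating neighbours allowed


class TestInterval:
    def _results(self, positions, pvals, chrom="C29"):
        out = []
        for pos, p in zip(positions, pvals):
            v = VariantRecord(chrom, pos, "A", "T")
            from bsamap.association import AssociationResult

            out.append(AssociationResult(v, 10.0, 1, p, "chi2_genotypic"))
        return out

    def test_bounds_are_outermost_markers_within_flank(self):
        positions = [6_510_000, 6_522_236, 6_600_000, 6_721_563, 6_918_901, 6_930_000]
        pvals = [0.5, 0.1, 0.2, 1e-30, 0.3, 0.4]
        interval = define_interval(self._results(positions, pvals), flank_bp=200_000)
        assert interval.peak_variant.pos == 6_721_563
        assert (interval.start, interval.end) == (6_522_236, 6_918_901)
        assert [v.pos for v in interval.member_variants] == positions[1:5]
        assert interval.span_bp <= 2 * 200_000

    def test_single_variant_gives_degenerate_interval(self):
        interval = define_interval(self._results([123], [0.01]))
        assert interval.start == interval.end == 123

    def test_ties_break_to_lowest_chromosome_then_position(self):
        a = self._results([500], [1e-5], chrom="C2")
        b = self._results([400], [1e-5], chrom="C10")
        interval = define_interval(a + b)
        assert interval.peak_variant.chrom == "C2"

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            define_interval([])

    def test_causal_variant_lands_in_interval_across_seeds(self):
        hits = 0
        for seed in range(30):
            design = CrossDesign(
                n_f2=130, n_chromosomes=3, chrom_length_bp=2_000_000,
                variants_per_chrom=100, causal_chrom=2, causal_pos=1_000_000, seed=seed,
            )
            gm, phen, variants = simulate_f2(design)
            results = associate(gm, phenotype_to_binary(phen))
            interval = define_interval(results, flank_bp=200_000)
            hits += interval.contains("C2", 1_000_000)
        assert hits >= 29


class TestMarkerArithmetic:
    def test_printed_marker_distances(self):
        assert marker_distance("C29_6721553", "C29_6912561") == 191_008
        assert marker_distance("C29_5", "C29_5") == 0
        assert marker_distance("C29_6522236", "C29_6918901") == 396_665

    def test_cross_scaffold_and_malformed_ids_rejected(self):
        with pytest.raises(ValueError, match="different scaffolds"):
            marker_distance("C29_100", "C30_100")
        with pytest.raises(ValueError, match="malformed"):
            marker_distance("chr29:100", "C29_100")

    def test_coverage_quotients(self):
        assert round(fold_coverage_per_sample(2347.32, 130), 2) == 18.06
        assert round(raw_gb_to_coverage(847.46, 354, 132), 1) == 18.1
        assert fold_coverage_per_sample(0, 10) == 0
        with pytest.raises(ValueError):
            fold_coverage_per_sample(100, 0)
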