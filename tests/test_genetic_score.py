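"""Genetic summaries: allele counts, weighted score, gamma_G and pRR."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chdrisk import (
    GenotypeMatrix,
    ValidationError,
    allele_count_score,
    combined_prr,
    compute_scores,
    gamma_g,
    per_snp_prr,
    population_average_risk,
    prr_offset,
    simulate_genotypes,
    weighted_score,
)


class TestAlleleCount:
    def test_hand_sum(self):
        assert allele_count_score(np.array([[0.0, 1.0, 2.0]]))[0] == 3.0

    @pytest.mark.parametrize("fill,expected", [(0.0, 0.0), (2.0, 22.0)])
    def test_extremes_over_11_snps(self, fill, expected):
        assert allele_count_score(np.full((1, 11), fill))[0] == expected

    def test_missing_is_hard_error_by_default(self):
        counts = np.array([[1.0, np.nan]])
        with pytest.raises(ValidationError, match="missing"):
            allele_count_score(counts)

    def test_mean_imputation_uses_2p(self):
        counts = np.array([[1.0, np.nan]])
        got = allele_count_score(counts, rafs=np.array([0.5, 0.25]), impute_missing=True)
        assert got[0] == pytest.approx(1.0 + 0.5)


class TestWeightedScore:
    def test_equal_weights_reduce_to_allele_count(self):
        counts = np.array([[0.0, 1.0, 2.0], [2.0, 2.0, 1.0]])
        w = np.full(3, 0.37)
        assert np.allclose(weighted_score(counts, w), allele_count_score(counts))

    def test_hand_algebra(self):
        # k=2, w=(ln2, ln4), n=(2,0): (2 / (3 ln 2)) * 2 ln 2 = 4/3
        got = weighted_score(np.array([[2.0, 0.0]]), np.log([2.0, 4.0]))
        assert got[0] == pytest.approx(4.0 / 3.0, rel=1e-12)

    def test_constant_genotype_factorizes(self):
        w = np.array([0.1, 0.9, 0.4])
        got = weighted_score(np.full((1, 3), 2.0), w)
        assert got[0] == pytest.approx(3 * 2.0, rel=1e-12)

    def test_nonpositive_weight_sum_rejected(self):
        with pytest.raises(ValidationError, match="positive"):
            weighted_score(np.array([[1.0]]), np.array([0.0]))

    def test_range_is_0_to_2k(self, panel):
        g = simulate_genotypes(panel, 2000, 21)
        s = weighted_score(g, panel.log_weights(), k=panel.k)
        assert np.all(s >= 0) and np.all(s <= 2 * panel.k)


class TestGammaG:
    def test_centered_dosage_gives_zero(self):
        p = np.array([0.2, 0.7])
        counts = (2 * p)[None, :]
        assert gamma_g(counts, np.array([0.3, 0.5]), p)[0] == pytest.approx(0.0)

    def test_single_snp_hand_value(self):
        # n=2, p=0.5, OR=e: (2 - 1) * ln e = 1
        got = gamma_g(np.array([[2.0]]), np.array([1.0]), np.array([0.5]))
        assert got[0] == pytest.approx(1.0, rel=1e-12)

    def test_zero_genotype_panel_value(self, panel):
        # independent oracle: -2 * sum p_i ln(OR_i) over the usable loci
        expected = -2 * sum(
            s.raf_observed * math.log(s.or_point) for s in panel.usable_snps
        )
        got = gamma_g(np.zeros((1, panel.k)), panel.log_weights(), panel.rafs())
        assert got[0] == pytest.approx(expected, rel=1e-12)
        assert got[0] == pytest.approx(-2.066, abs=5e-4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            gamma_g(np.zeros((1, 2)), np.array([0.1]), np.array([0.5, 0.5]))


class TestPopulationRisk:
    def test_null_effect_and_absent_allele(self):
        assert population_average_risk(0.0, 0.7) == pytest.approx(1.0)
        assert population_average_risk(0.9, 0.0) == pytest.approx(1.0)

    def test_hand_value(self):
        # p=0.5, w=1: (e^2 + 2e + 1)/4 = ((e+1)/2)^2
        assert population_average_risk(1.0, 0.5) == pytest.approx(
            ((math.e + 1) / 2) ** 2, rel=1e-12
        )

    def test_at_least_one_for_positive_weights(self, panel):
        r = population_average_risk(panel.log_weights(), panel.rafs())
        assert np.all(r >= 1.0)


class TestPerSnpPrr:
    def test_zero_copies_is_inverse_population_risk(self):
        w, p = 0.4, 0.3
        assert per_snp_prr(0, w, p) == pytest.approx(1 / population_average_risk(w, p))

    def test_null_or_is_unity_for_all_genotypes(self):
        for n in (0, 0.5, 1, 2):
            assert per_snp_prr(n, 0.0, 0.4) == pytest.approx(1.0)

    def test_hand_value(self):
        got = per_snp_prr(2, 1.0, 0.5)
        assert got == pytest.approx(math.e**2 / ((math.e + 1) / 2) ** 2, rel=1e-12)
        assert got == pytest.approx(2.138, abs=5e-4)

    def test_mean_prr_is_one_under_hwe(self, panel):
        n = 50_000
        g = simulate_genotypes(panel, n, 23)
        w, p = panel.log_weights(), panel.rafs()
        for j in range(panel.k):
            vals = per_snp_prr(g.counts[:, j], w[j], p[j])
            se = vals.std(ddof=1) / np.sqrt(n)
            assert abs(vals.mean() - 1.0) < 3 * se


class TestCombinedPrr:
    def test_single_snp_zero_copies(self):
        w = np.array([0.4])
        p = np.array([0.3])
        got = combined_prr(np.array([[0.0]]), w, p)
        assert got[0] == pytest.approx(1 / population_average_risk(0.4, 0.3))

    def test_null_panel_is_unity(self):
        got = combined_prr(np.array([[1.0, 2.0]]), np.zeros(2), np.array([0.3, 0.6]))
        assert got[0] == pytest.approx(1.0)

    def test_log_offset_identity(self, panel):
        """ln pRR - gamma_G is the same panel constant for every individual."""
        g = simulate_genotypes(panel, 500, 29)
        w, p = panel.log_weights(), panel.rafs()
        diff = combined_prr(g, w, p, log=True) - gamma_g(g, w, p)
        assert np.ptp(diff) < 1e-10
        assert diff[0] == pytest.approx(prr_offset(w, p), abs=1e-10)


class TestComputeScores:
    def test_columns_and_consistency(self, panel):
        g = simulate_genotypes(panel, 300, 31)
        df = compute_scores(g, panel)
        assert list(df.columns) == [
            "id", "grs_count", "grs_weighted", "gamma_g", "combined_or", "prr",
        ]
        assert np.allclose(df["combined_or"], np.exp(df["gamma_g"]))
        assert df["grs_count"].between(0, 2 * panel.k).all()

    def test_count_weighted_correlation_near_096(self, panel):
        g = simulate_genotypes(panel, 100_000, 37)
        df = compute_scores(g, panel)
        r = np.corrcoef(df["grs_count"], df["grs_weighted"])[0, 1]
        # closed form sum(w v)/sqrt(sum v * sum w^2 v), v = 2p(1-p)
        w, p = panel.log_weights(), panel.rafs()
        v = 2 * p * (1 - p)
        r_exact = np.sum(w * v) / np.sqrt(np.sum(v) * np.sum(w**2 * v))
        assert r == pytest.approx(r_exact, abs=0.01)
        assert round(r, 2) == 0.96

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(0, 10), st.integers(0, 10))
    def test_scores_monotone_in_each_genotype(self, i, j):
        """Raising any allele count never lowers any score (w >= 0)."""
        rng = np.random.default_rng(101)
        k = 11
        w = rng.uniform(0.05, 0.3, size=k)
        p = rng.uniform(0.1, 0.9, size=k)
        base = rng.integers(0, 2, size=(1, k)).astype(float)
        bumped = base.copy()
        col = (i + j) % k
        bumped[0, col] = min(2.0, bumped[0, col] + 1)
        for fn in (
            lambda c: allele_count_score(c)[0],
            lambda c: weighted_score(c, w)[0],
            lambda c: gamma_g(c, w, p)[0],
            lambda c: combined_prr(c, w, p)[0],
        ):
            assert fn(bumped) >= fn(base) - 1e-12
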