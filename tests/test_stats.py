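"""Library statistics: bin distributions, intensity estimates, normalization,
fold changes, correlations, Fisher association, co-integrand model."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from castling import stats as St


@pytest.fixture
def worked_example():
    """Three-bin worked case: r_g=(10,10,0), bin totals (100,50,50),
    p=(0.5,0.3,0.2) -> C~=(0.05,0.06,0), estimate 0.17/0.11."""
    counts = pd.DataFrame(
        {
            "bin1": [10, 90],
            "bin2": [10, 40],
            "bin3": [0, 50],
        },
        index=["g", "rest"],
    )
    profile = St.BinProfile((0.5, 0.3, 0.2))
    return counts, profile


class TestBinDistribution:
    def test_worked_example_exact(self, worked_example):
        counts, profile = worked_example
        c = St.bin_distribution(counts, profile)
        assert np.allclose(c.loc["g"], [0.05, 0.06, 0.0], atol=1e-12)

    def test_single_genotype_recovers_p_b(self):
        counts = pd.DataFrame({"bin1": [7], "bin2": [3], "bin3": [99]}, index=["g"])
        profile = St.BinProfile((0.5, 0.3, 0.2))
        c = St.bin_distribution(counts, profile)
        assert np.allclose(c.loc["g"], profile.p_b)

    def test_scale_invariance(self, worked_example):
        counts, profile = worked_example
        c1 = St.bin_distribution(counts, profile)
        c2 = St.bin_distribution(counts * 2, profile)
        assert np.allclose(c1, c2, atol=1e-15)

    def test_zero_total_bin_dropped_with_warning(self, worked_example):
        counts, profile = worked_example
        counts = counts.copy()
        counts["bin3"] = 0
        with pytest.warns(UserWarning, match="zero total"):
            c = St.bin_distribution(counts, profile)
        assert list(c.columns) == ["bin1", "bin2"]


class TestIntensityEstimate:
    def test_point_mass_returns_bin_index(self):
        c = pd.DataFrame(
            [[0, 0, 0, 0, 0.2, 0, 0, 0]],
            columns=[f"bin{i}" for i in range(1, 9)],
            index=["g"],
        )
        assert St.intensity_estimate(c).loc["g"] == pytest.approx(5.0)

    def test_worked_example_value(self, worked_example):
        counts, profile = worked_example
        est = St.intensity_estimate(St.bin_distribution(counts, profile))
        assert est.loc["g"] == pytest.approx(0.17 / 0.11, abs=1e-12)

    def test_invariant_under_global_rescaling(self, worked_example):
        counts, profile = worked_example
        c = St.bin_distribution(counts, profile)
        assert np.allclose(
            St.intensity_estimate(c), St.intensity_estimate(c * 37.5), atol=1e-12
        )

    def test_all_zero_distribution_flagged_nan(self):
        c = pd.DataFrame([[0.0, 0.0]], columns=["bin1", "bin2"], index=["g"])
        assert St.intensity_estimate(c).isna().all()

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_shifting_reads_to_higher_bins_never_decreases(self, seed):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(
            rng.integers(1, 100, size=(3, 5)), columns=[f"bin{i}" for i in range(1, 6)]
        )
        profile = St.BinProfile(tuple(rng.uniform(0.05, 0.3, size=5)))
        base = St.intensity_estimate(St.bin_distribution(counts, profile))
        moved = counts.copy()
        # move reads of genotype 0 from a lower to a higher bin
        lo, hi = 1, 3
        k = int(moved.iloc[0, lo])
        moved.iloc[0, lo] = 0
        moved.iloc[0, hi] += k
        shifted = St.intensity_estimate(St.bin_distribution(moved, profile))
        assert shifted.iloc[0] >= base.iloc[0] - 1e-12

    def test_agrees_with_spreadsheet_recomputation(self):
        """Eq. 1/2 chain vs an independent elementwise recomputation."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            G, B = int(rng.integers(2, 6)), int(rng.integers(2, 7))
            counts = pd.DataFrame(
                rng.integers(0, 50, size=(G, B)),
                columns=[f"bin{i}" for i in range(1, B + 1)],
            )
            counts.iloc[0] += 1  # keep at least one bin total nonzero
            totals = counts.sum(axis=0)
            keep = totals > 0
            p = rng.uniform(0.01, 0.4, size=B)
            p = p / p.sum()
            profile = St.BinProfile(tuple(p))
            c = St.bin_distribution(counts, profile)
            # manual: C~ = r/total * p, est = sum(b*C~)/sum(C~)
            for gi in range(G):
                manual = []
                for bi in range(B):
                    if not keep.iloc[bi]:
                        continue
                    manual.append(counts.iloc[gi, bi] / totals.iloc[bi] * p[bi])
                manual = np.array(manual)
                assert np.allclose(c.iloc[gi], manual, atol=1e-12)
                if manual.sum() > 0:
                    b_idx = np.arange(1, len(manual) + 1)
                    est = (b_idx * manual).sum() / manual.sum()
                    got = St.intensity_estimate(c).iloc[gi]
                    assert got == pytest.approx(est, abs=1e-12)


class TestNormalization:
    def test_worked_arithmetic(self):
        s = pd.Series([1, 2, 3, 4, 5], dtype=float)
        assert np.allclose(St.normalize_counts(s), [1 / 3, 2 / 3, 1, 4 / 3, 5 / 3])

    def test_constant_counts_all_one(self):
        s = pd.Series([7.0] * 5)
        assert (St.normalize_counts(s) == 1).all()

    def test_median_of_normalized_is_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            s = pd.Series(rng.lognormal(0, 1, size=31))
            assert St.normalize_counts(s).median() == pytest.approx(1.0)


class TestFoldChanges:
    def test_identical_samples_give_unit_fold_changes(self):
        s = pd.Series([5.0, 10.0, 1.0, 3.0], index=list("abcd"))
        fc, summary = St.rca_fold_changes(s, s)
        assert np.allclose(fc, 1.0)
        assert summary["fraction_beyond_threshold"] == 0.0

    def test_hand_built_table(self):
        pcr = pd.Series([4, 4, 4, 4, 4, 4], index=list("abcdef"), dtype=float)
        rca = pd.Series([4, 8, 2, 40, 1, 4], index=list("abcdef"), dtype=float)
        # medians: pcr 4, rca 4 -> normalized fc = rca/4 / (pcr/4) = rca/pcr
        fc, summary = St.rca_fold_changes(rca, pcr)
        assert np.allclose(fc[list("abcdef")], [1, 2, 0.5, 10, 0.25, 1])
        assert summary["fraction_beyond_threshold"] == pytest.approx(2 / 6)

    def test_absent_designs_reported_lost(self):
        pcr = pd.Series({"a": 3.0, "b": 6.0, "c": 9.0})
        rca = pd.Series({"a": 3.0, "b": 6.0})
        _, summary = St.rca_fold_changes(rca, pcr)
        assert summary["lost"] == ["c"]


class TestCoverageAndCorrelation:
    def test_set_algebra(self):
        d2o = {f"d{i}": f"o{i % 4}" for i in range(8)}
        libs = {
            "A": {"d0", "d1", "d2"},
            "B": {"d2", "d3"},
            "C": {"d7"},
        }
        res = St.coverage_overlap(libs, d2o)
        assert res["designs_detected"] == {"A": 3, "B": 2, "C": 1}
        assert res["orfs_covered"] == {"A": 3, "B": 2, "C": 1}
        assert res["pairwise_orf_overlap"][("A", "B")] == 1  # only o2 shared
        assert res["pairwise_orf_overlap"][("A", "C")] == 0  # disjoint
        assert res["threeway_orf_overlap"] == 0

    def test_self_correlation_is_one(self):
        s = pd.Series([1.0, 5.0, 2.0, 8.0], index=list("abcd"))
        assert St.replicate_correlation(s, s) == pytest.approx(1.0)

    def test_hand_five_point_pearson(self):
        a = pd.Series([1, 2, 3, 4, 5], dtype=float)
        b = pd.Series([2, 1, 4, 3, 7], dtype=float)
        # textbook formula
        r = ((a - a.mean()) * (b - b.mean())).sum() / np.sqrt(
            ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()
        )
        assert St.replicate_correlation(a, b) == pytest.approx(r)

    def test_independent_samples_near_zero(self):
        rng = np.random.default_rng(4)
        a = pd.Series(rng.lognormal(0, 1, 500))
        b = pd.Series(rng.lognormal(0, 1, 500))
        assert abs(St.replicate_correlation(a, b)) < 3 / np.sqrt(500)

    def test_too_few_points_raise(self):
        a = pd.Series([1.0, 2.0])
        with pytest.raises(ValueError, match="at least 3"):
            St.replicate_correlation(a, a)


class TestEnrichment:
    def test_equal_frequencies_unit_enrichment(self):
        pre = pd.Series({"a": 10, "b": 20})
        res = St.enrichment(pre, pre)
        assert np.allclose(res.fold_enrichment, 1.0)

    def test_absent_post_is_depleted(self):
        pre = pd.Series({"a": 10, "b": 20})
        post = pd.Series({"a": 30})
        res = St.enrichment(pre, post)
        assert res.loc["b", "call"] == "depleted"

    def test_rank_recovery_under_selection(self):
        rng = np.random.default_rng(5)
        n = 200
        sel = rng.normal(0, 1, n)  # selection coefficients
        pre = rng.multinomial(200_000, np.ones(n) / n).astype(float)
        w = pre * np.exp(sel)
        post = rng.multinomial(200_000, w / w.sum()).astype(float)
        res = St.enrichment(pd.Series(pre), pd.Series(post))
        from scipy.stats import spearmanr

        rho = spearmanr(sel, np.log(res.fold_enrichment)).statistic
        assert rho > 0.9


def fisher_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration of the two-sided p-value."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestFeatureAssociation:
    def test_flat_table_p_one(self):
        p, orat = St.fisher_exact_2x2([[1, 1], [1, 1]])
        assert p == pytest.approx(1.0)
        assert orat == pytest.approx(1.0)

    def test_example_against_enumeration(self):
        p, _ = St.fisher_exact_2x2([[8, 2], [1, 5]])
        assert p == pytest.approx(fisher_oracle(8, 2, 1, 5), abs=1e-12)

    def test_all_small_tables_match_enumeration(self):
        """Implementation equals brute-force enumeration for margins <= 12."""
        for a, b, c, d in itertools.product(range(0, 7), repeat=4):
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            p, _ = St.fisher_exact_2x2([[a, b], [c, d]])
            assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-9), (a, b, c, d)

    def test_haldane_correction_on_zero_cell(self):
        _, orat = St.fisher_exact_2x2([[5, 0], [2, 3]])
        assert orat == pytest.approx((5.5 * 3.5) / (0.5 * 2.5))

    def test_degenerate_margins_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            St.fisher_exact_2x2([[0, 0], [3, 4]])

    def test_destroyed_flag_association_detected_in_simulation(self):
        """Clones generated under the multiplicative score weights show a
        significant success/destroyed association at n = 2000."""
        rng = np.random.default_rng(6)
        n = 2000
        destroyed = rng.random(n) < 0.5
        base = 0.2
        p_succ = np.where(destroyed, np.minimum(base * 3.5, 0.95), base)
        success = rng.random(n) < p_succ
        df = pd.DataFrame({"success": success, "destroyed": destroyed})
        res = St.feature_association(df, feature_cols=["destroyed"])
        assert res.p_value.iloc[0] < 0.05
        assert res.odds_ratio.iloc[0] > 1


class TestCointegration:
    def test_equimolar_gives_half(self):
        res = St.cointegration_model(0.5, n_draws=100_000, seed=7)
        assert res["closed_form"] == pytest.approx(0.5)
        assert res["heterozygous_fraction"] == pytest.approx(0.5, abs=0.005)

    def test_skewed_ratio_closed_form(self):
        res = St.cointegration_model(0.3, n_draws=100_000, seed=8)
        se = np.sqrt(0.42 * 0.58 / 100_000)
        assert abs(res["heterozygous_fraction"] - 0.42) < 3 * se

    def test_limit_toward_pure_uptake(self):
        res = St.cointegration_model(0.999, n_draws=50_000, seed=9)
        assert res["heterozygous_fraction"] < 0.01

    def test_estimator_doubles_heterozygote_count(self):
        res = St.cointegration_model(0.5, n_draws=1000, seed=10)
        assert res["estimated_total_cointegrands"] == 2 * res["heterozygous_count"]

    def test_invalid_ratio_raises(self):
        with pytest.raises(ValueError):
            St.cointegration_model(1.5)
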