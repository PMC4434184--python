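"""Tests for per-feature occupancy means, family Spearman stats, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oracle
from nucbend import (
    CohortSummary,
    Feature,
    OccupancyTrack,
    family_correlations,
    group_anova,
    mean_feature_occupancy,
    summarize_cohort,
)
from nucbend.family_stats import _spearman


def track_of(values, origin=0, seq_id="chr1"):
    return OccupancyTrack(seq_id, origin, np.asarray(values, dtype=float), "occupancy")


class TestMeanFeatureOccupancy:
    def test_constant_track(self):
        f = Feature("chr1", 10, 200, "a", "+")
        assert mean_feature_occupancy(track_of(np.full(500, 0.6)), f) == pytest.approx(0.6)

    def test_short_feature_excluded_for_predicted_kind(self):
        f = Feature("chr1", 0, 120, "a", "+")
        out = mean_feature_occupancy(track_of(np.ones(500)), f, min_length=129)
        assert np.isnan(out)

    def test_mean_over_defined_only(self):
        vals = np.full(100, 0.3)
        vals[:50] = np.nan
        f = Feature("chr1", 0, 100, "a", "+")
        assert mean_feature_occupancy(track_of(vals), f) == pytest.approx(0.3)

    def test_all_missing_gives_nan(self):
        f = Feature("chr1", 0, 10, "a", "+")
        assert np.isnan(mean_feature_occupancy(track_of(np.full(50, np.nan)), f))


class TestSpearman:
    def test_agrees_with_rank_then_pearson(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 40))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            # inject ties sometimes
            if rng.random() < 0.5:
                x = np.round(x, 1)
            rho, _ = _spearman(x, y, "t", None)
            assert rho == pytest.approx(oracle.spearman_rank_pearson(x, y), abs=1e-12)

    def test_permutation_p_exact_small_n(self, rng):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        rho_t, p_t = _spearman(x, y, "t", rng)
        rho_p, p_p = _spearman(x, y, "permutation", rng)
        assert rho_p == pytest.approx(rho_t)
        # exact enumeration: p is the fraction of the 720 pairings at least
        # as extreme; must be a multiple of 1/720
        assert (p_p * 720) == pytest.approx(round(p_p * 720), abs=1e-9)


class TestFamilyCorrelations:
    def make_data(self):
        rows = []
        for fam in range(3):
            for j in range(10):
                gc = 0.3 + 0.04 * j
                rows.append(
                    {
                        "family_id": f"fam{fam}",
                        "gc_content": gc,
                        "identity": 1.0 - 0.05 * j,
                        "divergence": 0.05 * j,
                        "occ_predicted": 0.1 + gc,  # strictly increasing in GC
                    }
                )
        return pd.DataFrame(rows)

    def test_perfect_monotone_association(self):
        summaries = family_correlations(self.make_data())
        for s in summaries:
            res = s.results[("gc_content", "predicted")]
            assert res.rho == pytest.approx(1.0)
            assert res.significant and res.sign == 1
            # occupancy increases with GC but identity falls with it
            assert s.results[("identity", "predicted")].rho == pytest.approx(-1.0)

    def test_small_families_reported_untested(self):
        df = self.make_data().groupby("family_id").head(3)
        summaries = family_correlations(df, min_family_size=5)
        for s in summaries:
            res = s.results[("gc_content", "predicted")]
            assert not res.tested and not res.significant
            assert res.n_pairs == 3

    def test_zero_variance_correlate_untested(self):
        df = self.make_data()
        df["divergence"] = 0.2
        summaries = family_correlations(df)
        for s in summaries:
            assert not s.results[("divergence", "predicted")].tested

    def test_missing_values_dropped_pairwise(self):
        df = self.make_data()
        df.loc[df.index[:3], "occ_predicted"] = np.nan
        summaries = family_correlations(df)
        assert summaries[0].results[("gc_content", "predicted")].n_pairs == 7

    def test_null_significant_fraction_near_alpha(self, rng):
        """Independent occupancy and correlate: ~alpha of families significant."""
        rows = []
        for fam in range(100):
            for _ in range(30):
                rows.append(
                    {
                        "family_id": f"f{fam:03d}",
                        "gc_content": rng.uniform(0.3, 0.7),
                        "identity": rng.uniform(0.6, 1.0),
                        "divergence": rng.uniform(0.0, 0.5),
                        "occ_predicted": rng.uniform(0.1, 0.9),
                    }
                )
        summaries = family_correlations(pd.DataFrame(rows), alpha=0.05)
        c = summarize_cohort(summaries, "gc_content", "predicted")
        assert c.n_families_tested == 100
        # 99% binomial band around 0.05 for 100 trials
        band = 3 * np.sqrt(0.05 * 0.95 / 100)
        assert c.n_significant / 100 <= 0.05 + band + 1e-12


class TestSummarizeCohort:
    def make_summaries(self, rhos_sig):
        from nucbend.family_stats import CorrelationResult, FamilySummary

        out = []
        for k, (rho, sig) in enumerate(rhos_sig):
            s = FamilySummary(family_id=f"f{k}", n_members=10)
            s.results[("gc_content", "predicted")] = CorrelationResult(
                rho=rho, p_value=0.01 if sig else 0.5, n_pairs=10, tested=True, significant=sig
            )
            out.append(s)
        return out

    def test_counts_and_mean_on_stated_input(self):
        summaries = self.make_summaries([(0.9, True), (-0.5, True), (0.2, False)])
        c = summarize_cohort(summaries, "gc_content", "predicted")
        assert (c.n_families_tested, c.n_significant, c.n_significant_positive) == (3, 2, 1)
        assert c.mean_significant_rho == pytest.approx(0.2)

    def test_no_significant_mean_undefined(self):
        c = summarize_cohort(self.make_summaries([(0.3, False)]), "gc_content", "predicted")
        assert c.n_significant == 0
        assert np.isnan(c.mean_significant_rho)

    def test_all_significant_positive(self):
        c = summarize_cohort(
            self.make_summaries([(0.8, True), (0.9, True)]), "gc_content", "predicted"
        )
        assert c.n_significant_positive == c.n_significant == c.n_families_tested == 2

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            CohortSummary("gc", "predicted", 1, 2, 0, 0.5)


class TestGroupAnova:
    def test_overwhelming_offset_significant(self, rng):
        a = rng.normal(0.0, 1.0, size=100)
        b = rng.normal(3.0, 1.0, size=100)  # 3 pooled SDs apart
        F, p = group_anova(np.concatenate([a, b]), ["t"] * 100 + ["n"] * 100)
        assert p < 0.001

    def test_identical_constant_groups(self):
        F, p = group_anova([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])
        assert F == 0.0 and p == 1.0

    def test_type_one_error_calibration(self, rng):
        rejections = 0
        reps = 200
        for _ in range(reps):
            vals = rng.normal(size=120)
            _, p = group_anova(vals, ["a"] * 60 + ["b"] * 60)
            rejections += p < 0.05
        rate = rejections / reps
        band = 3 * np.sqrt(0.05 * 0.95 / reps)
        assert rate <= 0.05 + band

    def test_matches_scipy_directly(self, rng):
        vals = rng.normal(size=60)
        groups = ["a"] * 30 + ["b"] * 30
        F, p = group_anova(vals, groups)
        F2, p2 = stats.f_oneway(vals[:30], vals[30:])
        assert F == pytest.approx(F2) and p == pytest.approx(p2)

    def test_degenerate_grouping_rejected(self):
        with pytest.raises(ValueError):
            group_anova([1.0, 2.0, 3.0], ["a", "a", "a"])
        with pytest.raises(ValueError):
            group_anova([1.0, 2.0, 3.0], ["a", "a", "b"])
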