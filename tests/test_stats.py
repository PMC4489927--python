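"""Comparative statistics: t-tests, regressions, Steiger Z, proportions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from lincsynteny.errors import InvalidInputError, UndefinedStatisticError
from lincsynteny.stats import (
    ScoreTrack,
    aggregate_track,
    compare_dependent_correlations,
    r_squared,
    rate_confound_regression,
    replicate_fig3,
    two_proportion_z,
    two_sample_t,
)


def _track(values_by_linc, tf):
    return ScoreTrack(
        {
            k: {"phastcons": np.clip(v, 0, 1), "phylop": np.asarray(v) * 2}
            for k, v in values_by_linc.items()
        },
        tf,
    )


class TestAggregateTrack:
    def test_constant_track(self):
        t = _track({"l1": np.full(50, 0.4)}, set())
        agg = aggregate_track(t)
        assert agg.loc["l1", "mean_phastcons"] == pytest.approx(0.4)
        assert agg.loc["l1", "median_phastcons"] == pytest.approx(0.4)

    def test_binary_values(self):
        t = _track({"l1": np.array([0.0, 1.0] * 25)}, set())
        agg = aggregate_track(t)
        assert agg.loc["l1", "mean_phastcons"] == 0.5
        assert agg.loc["l1", "median_phastcons"] == 0.5

    def test_matches_sort_based_median_oracle(self):
        rng = np.random.default_rng(31)
        vals = rng.random(201)
        t = _track({"l1": vals}, set())
        agg = aggregate_track(t)
        srt = np.sort(np.clip(vals, 0, 1))
        assert agg.loc["l1", "median_phastcons"] == srt[100]

    def test_empty_interval_rejected(self):
        with pytest.raises(InvalidInputError):
            ScoreTrack({"l1": {"phastcons": np.array([]), "phylop": np.array([])}}, set())

    def test_bedgraph_round_trip(self, tmp_path):
        rng = np.random.default_rng(32)
        t = _track({"l1": rng.random(20), "l2": rng.random(30)}, {"l2"})
        t.to_bedgraph(tmp_path / "pc.bg", tmp_path / "pp.bg", tmp_path / "labels.bed")
        back = ScoreTrack.from_bedgraph(
            tmp_path / "pc.bg", tmp_path / "pp.bg", tmp_path / "labels.bed"
        )
        assert back.tf_adjacent == {"l2"}
        for linc in ("l1", "l2"):
            for stype in ("phastcons", "phylop"):
                assert np.allclose(
                    back.values[linc][stype], t.values[linc][stype], atol=1e-6
                )


class TestTwoSampleT:
    def test_identical_groups_give_zero(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0

    def test_pooled_variance_formula_oracle(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        res = two_sample_t(a, b)
        sp2 = (2 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 4
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert res.statistic == pytest.approx(t_hand)
        assert res.pvalue == pytest.approx(2 * sps.t.sf(abs(t_hand), 4))

    def test_degenerate_equal_constant_groups(self):
        res = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_antisymmetric_under_group_swap(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1.5, 9)
        r1 = two_sample_t(a, b)
        r2 = two_sample_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.pvalue == pytest.approx(r2.pvalue)


class TestRSquared:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        res = r_squared(x, 2 * x)
        assert res.statistic == pytest.approx(1.0)

    def test_null_relation_is_near_zero(self):
        rng = np.random.default_rng(41)
        res = r_squared(rng.normal(0, 1, 10_000), rng.normal(0, 1, 10_000))
        assert res.statistic < 0.001

    def test_calibrated_at_half(self):
        """y = x + noise with Var(noise)=Var(x): true R^2 = 0.5."""
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, 1000)
        y = x + rng.normal(0, 1, 1000)
        res = r_squared(x, y)
        assert res.statistic == pytest.approx(0.5, abs=0.05)

    def test_affine_invariance(self):
        rng = np.random.default_rng(43)
        x = rng.normal(0, 1, 50)
        y = 2 * x + rng.normal(0, 1, 50)
        r1 = r_squared(x, y)
        r2 = r_squared(3 * x - 7, -0.5 * y + 11)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.pvalue == pytest.approx(r2.pvalue)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSteigerZ:
    def test_equal_correlations_give_zero(self):
        for r12 in (-0.5, 0.0, 0.7):
            res = compare_dependent_correlations(0.6, 0.6, r12, 30)
            assert res.statistic == 0.0
            assert res.pvalue == 0.5

    def test_published_formula_oracle(self):
        r1, r2, r12, n = 0.825, 0.625, 0.6, 29
        res = compare_dependent_correlations(r1, r2, r12, n)
        # independent step-by-step evaluation of Steiger's pooled-estimate Z
        z1, z2 = np.arctanh(r1), np.arctanh(r2)
        rbar = (r1 + r2) / 2
        psi = r12 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r12**2)
        c = psi / (1 - rbar**2) ** 2
        z = (z1 - z2) * np.sqrt((n - 3) / (2 - 2 * c))
        assert res.statistic == pytest.approx(z, rel=1e-12)
        assert res.pvalue == pytest.approx(sps.norm.sf(z), rel=1e-12)

    def test_type_i_error_under_null(self):
        """Equal population correlations: one-tailed rejection rate at 0.05
        within 3 SE over 2,000 simulated samples of n=30."""
        rng = np.random.default_rng(55)
        rho, r12 = 0.5, 0.5
        cov = np.array([[1, rho, rho], [rho, 1, r12], [rho, r12, 1]])
        L = np.linalg.cholesky(cov)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            x = (L @ rng.standard_normal((3, 30))).T
            r = np.corrcoef(x, rowvar=False)
            res = compare_dependent_correlations(r[0, 1], r[0, 2], r[1, 2], 30)
            rejections += res.pvalue < 0.05
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rejections / n_sim - 0.05) <= 3 * se

    def test_out_of_range_correlation_rejected(self):
        with pytest.raises(InvalidInputError):
            compare_dependent_correlations(1.0, 0.5, 0.5, 30)


class TestTwoProportionZ:
    def test_equal_proportions_give_zero(self):
        res = two_proportion_z(10, 100, 10, 100)
        assert res.statistic == 0.0

    def test_hand_formula_oracle(self):
        res = two_proportion_z(30, 100, 10, 100)
        pooled = 0.2
        se = np.sqrt(pooled * 0.8 * (1 / 100 + 1 / 100))
        z = (0.3 - 0.1) / se
        assert res.statistic == pytest.approx(z)
        assert res.pvalue == pytest.approx(sps.norm.sf(z))

    def test_degenerate_saturated_groups(self):
        res = two_proportion_z(50, 50, 30, 30)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            two_proportion_z(11, 10, 5, 10)


class TestRateConfound:
    def test_perfectly_collinear_adjusted_r2_is_one(self):
        idx = [f"s{i}" for i in range(6)]
        rates = pd.Series(np.arange(6.0), index=idx)
        cons = 2 * rates + 1
        cls = pd.Series(["high"] * 6, index=idx)
        out = rate_confound_regression(cons, rates, cls)
        assert out["high"].statistic == pytest.approx(1.0)

    def test_pure_noise_adjusted_r2_near_zero_possibly_negative(self):
        rng = np.random.default_rng(60)
        idx = [f"s{i}" for i in range(50)]
        cons = pd.Series(rng.normal(0, 1, 50), index=idx)
        rates = pd.Series(rng.normal(0, 1, 50), index=idx)
        cls = pd.Series(["low"] * 50, index=idx)
        out = rate_confound_regression(cons, rates, cls)
        assert abs(out["low"].statistic) < 0.15

    def test_matches_adjusted_r2_formula(self):
        rng = np.random.default_rng(61)
        idx = [f"s{i}" for i in range(20)]
        rates = pd.Series(rng.normal(0, 1, 20), index=idx)
        cons = pd.Series(0.5 * rates + rng.normal(0, 1, 20), index=idx)
        cls = pd.Series(["high"] * 20, index=idx)
        out = rate_confound_regression(cons, rates, cls)
        r = np.corrcoef(rates, cons)[0, 1]
        adj = 1 - (1 - r**2) * 19 / 18
        assert out["high"].statistic == pytest.approx(adj, rel=1e-10)

    def test_small_class_skipped_with_warning(self):
        idx = ["a", "b", "c", "d", "e"]
        cons = pd.Series(np.arange(5.0), index=idx)
        rates = pd.Series(np.arange(5.0) ** 2, index=idx)
        cls = pd.Series(["high", "high", "high", "low", "low"], index=idx)
        with pytest.warns(RuntimeWarning):
            out = rate_confound_regression(cons, rates, cls)
        assert "low" not in out and "high" in out


class TestReplicationTable:
    def test_fig3_style_tests_on_synthetic_stand_in(self, tmp_path):
        """The replication reader computes the same four t-tests as running
        two_sample_t on the table's columns directly (synthetic stand-in
        table; the study's real S3 supplement is not redistributable)."""
        rng = np.random.default_rng(71)
        n = 62
        tf = rng.random(n) < 0.5
        df = pd.DataFrame(
            {
                "lincRNA": [f"XLOC_{i:06d}" for i in range(n)],
                "tf_adjacent": tf.astype(int),
                "mean_phastcons": rng.normal(0.4 + 0.1 * tf, 0.1),
                "median_phastcons": rng.normal(0.35 + 0.1 * tf, 0.1),
                "mean_phylop": rng.normal(0.5 + 0.3 * tf, 0.4),
                "median_phylop": rng.normal(0.45 + 0.3 * tf, 0.4),
            }
        )
        path = tmp_path / "s3_synthetic.csv"
        df.to_csv(path, index=False)
        out = replicate_fig3(path)
        assert set(out) == {
            "mean_phastcons", "median_phastcons", "mean_phylop", "median_phylop"
        }
        direct = two_sample_t(
            df.loc[~tf, "mean_phylop"], df.loc[tf, "mean_phylop"]
        )
        assert out["mean_phylop"].statistic == pytest.approx(direct.statistic)
        # TF-adjacent lincRNAs are more conserved, so without-minus-with is negative
        assert out["mean_phylop"].statistic < 0
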