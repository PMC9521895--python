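"""Per-participant quadratic fits, classification, peaks, group curve."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from sweetspot import (
    CohortConfig,
    LikingMatrix,
    WundtModel,
    classify_wundt,
    fit_group_curve,
    fit_participant_curve,
    generate_cohort,
    preferred_level,
)
from sweetspot.wundt import WundtFit, liking_variance, screen_response_quality

RANGE = (2.625, 8.625)


def normal_equations(x, y):
    """Independent closed-form OLS oracle: solve X'X b = X'y directly."""
    X = np.column_stack([np.ones_like(x), x, x * x])
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestParticipantFit:
    def test_exact_parabola_on_stimulus_complexities(self, table1):
        x = table1.complexity.to_numpy()
        y = -((x - 5.0) ** 2) + 80.0
        fit = fit_participant_curve(x, y)
        assert fit.b2 == pytest.approx(-1.0, abs=1e-10)
        assert fit.b1 == pytest.approx(10.0, abs=1e-9)
        assert fit.b0 == pytest.approx(55.0, abs=1e-8)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_average_liking_column_matches_normal_equations(self, table1):
        x = table1.complexity.to_numpy()
        y = table1.df["avg_liking"].to_numpy(float)
        fit = fit_participant_curve(x, y)
        b = normal_equations(x, y)
        np.testing.assert_allclose([fit.b0, fit.b1, fit.b2], b, atol=1e-8)
        # the sample-average liking curve is itself concave
        assert fit.b2 < -0.1

    def test_constant_response(self, table1):
        x = table1.complexity.to_numpy()
        fit = fit_participant_curve(x, np.full_like(x, 50.0))
        assert fit.b1 == pytest.approx(0.0, abs=1e-10)
        assert fit.b2 == pytest.approx(0.0, abs=1e-10)
        assert fit.r2 == 0.0

    def test_random_instances_match_oracle(self, rng):
        for _ in range(100):
            n = rng.integers(5, 40)
            x = rng.uniform(1, 10, n)
            while np.unique(x).size < 3:
                x = rng.uniform(1, 10, n)
            y = rng.uniform(0, 100, n)
            fit = fit_participant_curve(x, y)
            b = normal_equations(x, y)
            np.testing.assert_allclose([fit.b0, fit.b1, fit.b2], b, atol=1e-8)

    def test_pairwise_deletion_of_missing_ratings(self, table1):
        x = table1.complexity.to_numpy()
        y = 70 - (x - 5) ** 2 + 0.1 * np.sin(x)
        y_missing = y.copy()
        y_missing[[3, 10, 20]] = np.nan
        fit = fit_participant_curve(x, y_missing)
        keep = np.delete(np.arange(x.size), [3, 10, 20])
        ref = fit_participant_curve(x[keep], y[keep])
        assert fit.b2 == pytest.approx(ref.b2, abs=1e-12)
        assert fit.n_obs == 26

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match=">= 4"):
            fit_participant_curve([1, 2, 3], [1, 2, 3])

    def test_rank_deficient_design(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_participant_curve([2.0, 2.0, 2.0, 2.0], [1, 2, 3, 4])


class TestClassification:
    @pytest.mark.parametrize(
        "b2,expected",
        [(-1.56, "wundt"), (0.78, "non_wundt"), (-0.1, "wundt"), (-0.0999, "non_undt"[:3] + "_wundt")],
    )
    def test_threshold_rule(self, b2, expected):
        assert classify_wundt(b2) == expected


class TestPreferredLevel:
    def test_interior_vertex(self):
        fit = WundtFit(b0=55, b1=10, b2=-1, r2=1, n_obs=29)
        assert preferred_level(fit, RANGE) == (pytest.approx(5.0), "interior_vertex")

    def test_vertex_below_range_is_clipped(self):
        fit = WundtFit(b0=60, b1=2, b2=-1, r2=1, n_obs=29)  # vertex at 1.0
        peak, kind = preferred_level(fit, RANGE)
        assert (peak, kind) == (2.625, "clipped_vertex")

    def test_bounded_maximum_takes_better_endpoint(self):
        fit = WundtFit(b0=70, b1=-8, b2=0.78, r2=0.5, n_obs=29)
        peak, kind = preferred_level(fit, RANGE)
        f = lambda x: fit.b0 + fit.b1 * x + fit.b2 * x * x
        lo, hi = RANGE
        assert kind == "bounded_maximum"
        assert peak == (lo if f(lo) >= f(hi) else hi)

    def test_monotone_linear_takes_rising_endpoint(self):
        fit = WundtFit(b0=10, b1=3, b2=0.0, r2=0.5, n_obs=29)
        assert preferred_level(fit, RANGE) == (8.625, "bounded_maximum")

    def test_flat_fit_is_undefined(self):
        fit = WundtFit(b0=50, b1=0.0, b2=0.0, r2=0.0, n_obs=29)
        peak, kind = preferred_level(fit, RANGE)
        assert np.isnan(peak) and kind == "undefined"

    def test_peak_containment_on_random_cohorts(self, table1):
        cfg = CohortConfig(n_participants=150, frac_nonwundt=0.4, noise_sd=15, seed=21)
        liking, _, _ = generate_cohort(cfg)
        res = WundtModel(liking, table1).fit(group_curve=False)
        defined = res.fits["peak_type"] != "undefined"
        lo, hi = table1.complexity_range
        assert res.fits.loc[defined, "peak"].between(lo, hi).all()


class TestClassificationRecovery:
    def test_noise_free_classification_matches_truth(self, table1):
        cfg = CohortConfig(
            n_participants=200, frac_nonwundt=0.4, noise_sd=0.0, seed=13
        )
        liking, _, truth = generate_cohort(cfg)
        res = WundtModel(liking, table1).fit(group_curve=False)
        got = res.fits["classification"] == "wundt"
        want = truth.classes == "wundt"
        assert (got == want).all()

    def test_noisy_classification_agreement_matches_normal_theory(self, table1):
        # all-Wundt cohorts, sharpness -1, rating noise SD 10, 29 stimuli:
        # the agreement rate is P(b2_hat <= -0.1 | b2 = -1), which normal
        # theory puts at Phi((b2 - threshold) / SE(b2)) from the design
        from scipy.stats import norm

        x = table1.complexity.to_numpy()
        X = np.column_stack([np.ones_like(x), x, x * x])
        se_b2 = 10.0 * np.sqrt(np.linalg.inv(X.T @ X)[2, 2])
        predicted = norm.cdf((-0.1 - -1.0) / se_b2)
        agree = total = 0
        for seed in range(500):
            cfg = CohortConfig(
                n_participants=8,
                frac_nonwundt=0.0,
                noise_sd=10.0,
                sharpness_mean=-1.0,
                sharpness_sd=0.0,
                seed=3000 + seed,
            )
            liking, _, truth = generate_cohort(cfg)
            res = WundtModel(liking, table1).fit(group_curve=False)
            agree += (res.fits["classification"] == "wundt").sum()
            total += len(res.fits)
        rate = agree / total
        margin = 3 * np.sqrt(predicted * (1 - predicted) / total)
        assert abs(rate - predicted) < margin
        assert rate > 0.9


class TestGroupCurve:
    def test_noiseless_shared_parabola_recovered(self, table1):
        x = table1.complexity.to_numpy()
        rng = np.random.default_rng(0)
        offsets = rng.uniform(-10, 10, 12)
        Y = 60.0 + offsets[:, None] + 8.0 * x - 0.9 * x**2
        liking = LikingMatrix(
            pd.DataFrame(
                np.clip(Y, 0, 100),
                index=[f"p{i}" for i in range(12)],
                columns=table1.excerpt_ids,
            ),
            table1,
        )
        g = fit_group_curve(liking, table1)
        assert g.beta_lin == pytest.approx(8.0, abs=1e-6)
        assert g.beta_quad == pytest.approx(-0.9, abs=1e-6)

    def test_balanced_design_equals_pooled_ols(self, table1, rng):
        cfg = CohortConfig(n_participants=25, noise_sd=12.0, seed=17)
        liking, _, _ = generate_cohort(cfg)
        g = fit_group_curve(liking, table1)
        x = table1.complexity.to_numpy()
        Y = liking.values
        X = np.column_stack([np.ones_like(x), x, x * x])
        Xs = np.tile(X, (Y.shape[0], 1))
        beta = np.linalg.lstsq(Xs, Y.ravel(), rcond=None)[0]
        assert g.beta_lin == pytest.approx(beta[1], abs=1e-6)
        assert g.beta_quad == pytest.approx(beta[2], abs=1e-6)

    def test_wundt_cohort_sign_pattern(self, table1):
        cfg = CohortConfig(n_participants=120, frac_nonwundt=0.0, seed=29)
        liking, _, _ = generate_cohort(cfg)
        g = fit_group_curve(liking, table1)
        assert g.beta_quad < 0 and g.beta_lin > 0
        assert g.p_quad < 0.001

    def test_requires_two_participants(self, table1):
        liking = LikingMatrix(
            pd.DataFrame(
                [np.full(29, 50.0)], index=["p0"], columns=table1.excerpt_ids
            ),
            table1,
        )
        with pytest.raises(ValueError, match=">= 2"):
            fit_group_curve(liking, table1)


class TestScreening:
    def _matrix(self, rows, table1):
        return LikingMatrix(
            pd.DataFrame(
                rows,
                index=[f"p{i}" for i in range(len(rows))],
                columns=table1.excerpt_ids,
            ),
            table1,
        )

    def test_midpoint_majority_flagged(self, table1):
        row = np.concatenate([np.full(20, 50.0), np.linspace(0, 40, 9)])
        report = screen_response_quality(self._matrix([row], table1))
        assert list(report["participant_id"]) == ["p0"]
        assert report["statistic"].iloc[0] == pytest.approx(20 / 29)

    def test_distinct_ratings_not_flagged(self, table1):
        row = np.linspace(0, 100, 29)
        report = screen_response_quality(self._matrix([row], table1))
        assert report.empty


class TestLikingVariance:
    def test_closed_forms(self, table1):
        rows = [np.full(29, 42.0), np.r_[0.0, 100.0, np.full(27, np.nan)]]
        m = LikingMatrix(
            pd.DataFrame(rows, index=["const", "extreme"], columns=table1.excerpt_ids),
            table1,
        )
        v = liking_variance(m)
        assert v["const"] == pytest.approx(0.0)
        assert v["extreme"] == pytest.approx(5000.0)

    def test_two_pass_oracle(self, rng, table1):
        Y = rng.uniform(0, 100, (30, 29))
        m = LikingMatrix(
            pd.DataFrame(Y, index=[f"p{i}" for i in range(30)], columns=table1.excerpt_ids),
            table1,
        )
        v = liking_variance(m).to_numpy()
        oracle = np.array([np.sum((y - y.mean()) ** 2) / (y.size - 1) for y in Y])
        np.testing.assert_allclose(v, oracle, atol=1e-10)

    def test_single_rating_undefined(self, table1):
        row = np.r_[50.0, np.full(28, np.nan)]
        m = LikingMatrix(
            pd.DataFrame([row], index=["p0"], columns=table1.excerpt_ids), table1
        )
        assert np.isnan(liking_variance(m)["p0"])


class TestResultsSurface:
    def test_summary_and_fits_schema(self, table1):
        cfg = CohortConfig(n_participants=30, seed=1)
        liking, _, _ = generate_cohort(cfg)
        res = WundtModel(liking, table1).fit()
        assert {"b0", "b1", "b2", "r2", "classification", "peak_raw", "peak",
                "peak_type", "n_obs"} <= set(res.fits.columns)
        text = res.summary()
        assert "wundt responders" in text and "group curve" in text

    def test_unclipped_variant_keeps_raw_vertex(self, table1):
        cfg = CohortConfig(n_participants=80, noise_sd=15.0, seed=31)
        liking, _, _ = generate_cohort(cfg)
        clipped = WundtModel(liking, table1).fit(group_curve=False)
        raw = WundtModel(liking, table1, clip_vertices=False).fit(group_curve=False)
        was_clipped = clipped.fits["peak_type"] == "clipped_vertex"
        assert was_clipped.any()
        pd.testing.assert_series_equal(
            raw.fits.loc[was_clipped, "peak"],
            clipped.fits.loc[was_clipped, "peak_raw"],
            check_names=False,
        )
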