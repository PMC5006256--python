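import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from hextma import (
    SamplingConfig,
    ce_by_nuclei,
    coefficient_of_error,
    cohort_mean_ce,
    draw_subset_estimates,
    estimate_li,
    run_error_analysis,
    single_subsample,
)
from hextma.sampler import _draw_without_replacement

from conftest import make_tiling


class TestEstimateLI:
    def test_equal_denominators_sum_equals_mean(self):
        n_pos, n_neg = np.array([10, 30]), np.array([90, 70])
        assert estimate_li(n_pos, n_neg, "sum") == pytest.approx(0.20)
        assert estimate_li(n_pos, n_neg, "mean") == pytest.approx(0.20)

    def test_unequal_denominators_expose_weighting_bias(self):
        # pooled 100/400 = 0.25 but the unweighted mean of (0.1, 0.3) is 0.2
        n_pos, n_neg = np.array([10, 90]), np.array([90, 210])
        assert estimate_li(n_pos, n_neg, "sum") == pytest.approx(0.25)
        assert estimate_li(n_pos, n_neg, "mean") == pytest.approx(0.20)

    def test_single_tile_all_estimators_agree(self):
        for est in ("sum", "mean", "median"):
            assert estimate_li([37], [63], est) == pytest.approx(0.37)

    def test_median_midpoint_for_even_subsets(self):
        n_pos = np.array([10, 20, 60, 80])
        n_neg = 100 - n_pos
        assert estimate_li(n_pos, n_neg, "median") == pytest.approx(0.40)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            estimate_li([], [], "sum")


class TestCoefficientOfError:
    def test_zero_iff_exact(self):
        assert coefficient_of_error(0.3, 0.0, 0.3) == 0.0
        assert coefficient_of_error(0.3, 0.01, 0.3) > 0.0
        assert coefficient_of_error(0.31, 0.0, 0.3) > 0.0

    def test_formula(self):
        assert coefficient_of_error(0.25, 0.05, 0.2) == pytest.approx(
            np.sqrt(0.05**2 + 0.05**2) / 0.2
        )

    def test_undefined_for_zero_reference(self):
        with pytest.raises(ValueError):
            coefficient_of_error(0.1, 0.1, 0.0)


def _toy_pool():
    # 3 informative tiles, distinct LI and sizes
    return make_tiling(
        [(0, 0, 10, 90), (1, 0, 60, 140), (0, 1, 90, 210)],
        min_informative_tiles=1,
    )


class TestMonteCarlo:
    def test_exhaustive_subset_zero_sigma(self):
        t = _toy_pool()
        cfg = SamplingConfig(hexn_values=(3,), iterations=500,
                             estimators=("sum",), seed=0)
        out = run_error_analysis(t, cfg)
        assert out["sigma"].iloc[0] == 0.0
        assert out["mu"].iloc[0] == pytest.approx(160 / 600)

    @pytest.mark.parametrize("hexn", [1, 2])
    @pytest.mark.parametrize("estimator", ["sum", "mean", "median"])
    def test_matches_exhaustive_enumeration(self, hexn, estimator):
        """Monte-Carlo mu/sigma agree with enumeration over all C(3, k)
        subsets within 3 standard errors."""
        t = _toy_pool()
        pool = t.informative
        vals = [
            estimate_li(pool["n_pos"].to_numpy()[list(c)],
                        pool["n_neg"].to_numpy()[list(c)], estimator)
            for c in itertools.combinations(range(3), hexn)
        ]
        mu_exact, sigma_exact = np.mean(vals), np.std(vals)
        iters = 8000
        cfg = SamplingConfig(hexn_values=(hexn,), iterations=iters,
                             estimators=(estimator,), seed=5)
        out = run_error_analysis(t, cfg).iloc[0]
        se_mu = sigma_exact / np.sqrt(iters)
        se_sigma = sigma_exact / np.sqrt(2 * iters)
        assert abs(out["mu"] - mu_exact) <= 3 * se_mu + 1e-12
        assert abs(out["sigma"] - sigma_exact) <= 3 * se_sigma + 1e-12

    def test_subsets_have_distinct_tiles(self):
        rng = np.random.default_rng(0)
        idx = _draw_without_replacement(rng, pool=7, k=4, n_subsets=200)
        assert idx.shape == (200, 4)
        for row in idx:
            assert len(set(row)) == 4

    def test_reproducible_from_seed(self):
        t = _toy_pool()
        cfg = SamplingConfig(hexn_values=(1, 2), iterations=300, seed=11)
        a = draw_subset_estimates(t, cfg)
        b = draw_subset_estimates(t, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_oversized_hexn_skipped_with_warning(self):
        t = _toy_pool()
        cfg = SamplingConfig(hexn_values=(2, 9), iterations=50, seed=1)
        with pytest.warns(UserWarning, match="exceeds informative pool"):
            df = draw_subset_estimates(t, cfg)
        assert set(df["hexn"]) == {2}

    def test_uniform_tile_field_pure_bias(self):
        # all tiles identical: sigma = 0 and mu equals the common local LI
        t = make_tiling([(q, 0, 30, 70) for q in range(4)],
                        min_informative_tiles=1)
        cfg = SamplingConfig(hexn_values=(2,), iterations=200,
                             estimators=("sum",), seed=2)
        out = run_error_analysis(t, cfg).iloc[0]
        assert out["sigma"] == 0.0
        assert out["ce"] == pytest.approx(abs(out["mu"] - t.T) / t.T)


class TestCeByNuclei:
    def test_half_open_bin_edges(self):
        est = pd.DataFrame(
            {
                "hexn": 1,
                "estimator": "sum",
                "li_hat": [0.3, 0.3, 0.3],
                "total_nuclei": [100, 249, 250],
            }
        )
        out = ce_by_nuclei(est, T=0.3, bin_width=250)
        assert dict(zip(out["bin_low"], out["n_subsets"])) == {0: 2, 250: 1}

    def test_exact_estimates_zero_ce(self):
        est = pd.DataFrame(
            {
                "hexn": [1] * 6,
                "estimator": "sum",
                "li_hat": [0.4] * 6,
                "total_nuclei": [100, 120, 300, 310, 500, 505],
            }
        )
        out = ce_by_nuclei(est, T=0.4, bin_width=250)
        assert (out["ce"] == 0).all()
        assert not out["unstable"].any()

    def test_singleton_bins_flagged_unstable(self):
        est = pd.DataFrame(
            {"hexn": [1], "estimator": "sum", "li_hat": [0.4],
             "total_nuclei": [90]}
        )
        out = ce_by_nuclei(est, T=0.4)
        assert out["unstable"].all()


class TestSingleSubsample:
    def test_full_pool_sum_is_exact(self):
        t = _toy_pool()
        out = single_subsample([t], hexn=3, estimator="sum", seed=0)
        assert out["li_hat"].iloc[0] == pytest.approx(160 / 600)

    def test_same_seed_identical(self):
        t = _toy_pool()
        a = single_subsample([t], 2, "mean", seed=9)
        b = single_subsample([t], 2, "mean", seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_ineligible_cases_excluded(self):
        good = _toy_pool()
        bad = make_tiling([(0, 0, 5, 5)], case_id="BAD", min_informative_tiles=1)
        with pytest.warns(UserWarning, match="excluded"):
            out = single_subsample([good, bad], hexn=2, seed=0)
        assert list(out["case_id"]) == ["TOY"]


class TestCohortMeanCE:
    def _summaries(self):
        return pd.DataFrame(
            {
                "case_id": ["A", "A", "B", "B"],
                "estimator": "sum",
                "hexn": [8, 9, 8, 9],
                "ce": [0.08, 0.07, 0.12, 0.10],
            }
        )

    def test_single_case_curve_is_its_ce(self):
        s = self._summaries()
        out = cohort_mean_ce(s[s.case_id == "A"])
        assert dict(zip(out["hexn"], out["mean_ce"])) == {8: 0.08, 9: 0.07}

    def test_unweighted_mean_over_cases(self):
        out = cohort_mean_ce(self._summaries())
        assert out.loc[out.hexn == 8, "mean_ce"].iloc[0] == pytest.approx(0.10)

    def test_empty_group_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            out = cohort_mean_ce(self._summaries(),
                                 {"A": "homogeneous", "B": "homogeneous",
                                  "C": "heterogeneous"})
        assert set(out["group"]) == {"all", "homogeneous"}


class TestSamplingConfig:
    def test_rejects_non_increasing_hexn(self):
        with pytest.raises(ValueError):
            SamplingConfig(hexn_values=(1, 3, 2))

    def test_rejects_unknown_estimator(self):
        with pytest.raises(ValueError):
            SamplingConfig(estimators=("sum", "mode"))

    def test_defaults_match_protocol(self):
        cfg = SamplingConfig()
        assert cfg.hexn_values == tuple(range(1, 16))
        assert cfg.iterations == 50_000
        assert cfg.nuclei_bin_width == 250
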