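"""Synthetic cohort generation, calibration, and outlier implantation."""

import dataclasses

import numpy as np
import pytest

from cdintake.intake import read_subject_table, write_subject_table
from cdintake.montecarlo import fit_lognormal_mle
from cdintake.stats import grubbs_iterative
from cdintake.synthetic import (
    SyntheticError,
    TruncNormal,
    calibrate_nonrice_component,
    cohort_weekly,
    generate_cohort,
    implant_outliers,
    load_preset,
    _closed_form_weekly,
)


class TestGeneration:
    def test_same_seed_identical_cohort(self, area_b_params):
        a = generate_cohort(area_b_params, seed=4)
        b = generate_cohort(area_b_params, seed=4)
        assert a == b
        c = generate_cohort(area_b_params, seed=5)
        assert a != c

    def test_single_subject(self, area_b_params):
        p = dataclasses.replace(area_b_params, n=1, n_missing_rice=0)
        (s,) = generate_cohort(p, seed=2)
        assert s.weight > 0 and s.intakes["rice"] > 0
        assert generate_cohort(p, seed=2) == [s]

    def test_area_a_anthropometrics_match_published_means(self, area_a_params, table):
        cohort = generate_cohort(area_a_params, seed=10, table=table)
        weights = np.array([s.weight for s in cohort])
        rice = np.array([s.intakes["rice"] for s in cohort])
        # 3-SE bands around the published means
        assert abs(weights.mean() - 54.5) < 3 * 8.0 / np.sqrt(712)
        assert abs(rice.mean() - 371.8) < 15.0

    def test_area_b_rice_gm_within_10_percent(self, area_b_cohort):
        rice_cd = np.array([s.rice_cd for s in area_b_cohort if s.rice_cd is not None])
        gm = np.exp(np.mean(np.log(rice_cd)))
        assert abs(gm - 0.109) / 0.109 < 0.10

    def test_missing_rice_count(self, area_a_params, table):
        cohort = generate_cohort(area_a_params, seed=3, table=table)
        assert sum(s.rice_cd is None for s in cohort) == area_a_params.n_missing_rice

    def test_invalid_params_rejected_before_sampling(self, area_b_params):
        with pytest.raises(SyntheticError):
            dataclasses.replace(area_b_params, n=0)
        with pytest.raises(SyntheticError):
            dataclasses.replace(area_b_params, nonrice_sigma=0.0)
        with pytest.raises(SyntheticError):
            TruncNormal(mean=1.0, sd=1.0, lo=5.0, hi=2.0)

    def test_round_trip_through_subject_csv(self, tmp_path, area_b_cohort):
        path = tmp_path / "cohort.csv"
        write_subject_table(area_b_cohort, path)
        assert read_subject_table(path) == area_b_cohort


class TestEngineConsistency:
    def test_engine_weekly_equals_closed_form(self, area_b_params, table):
        cohort = generate_cohort(area_b_params, seed=6, table=table)
        engine = cohort_weekly(cohort, area_b_params, table=table)
        closed = _closed_form_weekly(
            area_b_params, 6, area_b_params.n, table.rice_gm("B")
        )
        np.testing.assert_allclose(engine, closed, rtol=1e-12)


class TestCalibration:
    def test_packaged_area_b_preset_hits_weekly_median(self, area_b_params, table):
        cohort = generate_cohort(area_b_params, seed=1, table=table)
        weekly = cohort_weekly(cohort, area_b_params, table=table)
        assert np.median(weekly) == pytest.approx(6.0, abs=0.2)

    def test_packaged_area_a_preset_exceedance(self, area_a_params, table):
        cohort = generate_cohort(area_a_params, seed=1, table=table)
        weekly = cohort_weekly(cohort, area_a_params, table=table)
        assert 100 * np.mean(weekly >= 7.0) == pytest.approx(51.7, abs=3.0)

    def test_calibration_recovers_perturbed_component(self, area_b_params):
        start = dataclasses.replace(
            area_b_params, nonrice_mu=area_b_params.nonrice_mu + 0.4,
            nonrice_sigma=0.6,
        )
        cal = calibrate_nonrice_component(
            4.4, 6.0, 8.5, start, seed=77, calib_n=20_000
        )
        weekly = _closed_form_weekly(cal, 555, 50_000, 0.109)
        q25, med, q75 = np.percentile(weekly, [25, 50, 75])
        assert med == pytest.approx(6.0, rel=0.02)
        assert q25 == pytest.approx(4.4, rel=0.05)
        assert q75 == pytest.approx(8.5, rel=0.05)

    def test_degenerate_targets_rejected(self, area_b_params):
        with pytest.raises(SyntheticError):
            calibrate_nonrice_component(6.0, 6.0, 6.0, area_b_params)


class TestOutlierImplantation:
    def test_identity_when_k_zero(self, area_b_cohort):
        out, idx = implant_outliers(area_b_cohort, np.ones(len(area_b_cohort)), k=0)
        assert out == list(area_b_cohort)
        assert idx == []

    def test_k_larger_than_n_rejected(self, area_b_cohort):
        with pytest.raises(SyntheticError):
            implant_outliers(area_b_cohort, np.ones(len(area_b_cohort)), k=len(area_b_cohort) + 1)

    def test_grubbs_removes_exactly_the_implanted_pair(self, area_b_params, table):
        cohort = generate_cohort(area_b_params, seed=9, table=table)
        weekly = cohort_weekly(cohort, area_b_params, table=table)
        spiked, idx = implant_outliers(cohort, weekly, k=2, multiplier=5.0, seed=1)
        weekly_spiked = cohort_weekly(spiked, area_b_params, table=table)
        outcome = grubbs_iterative(np.log(weekly_spiked))
        assert sorted(outcome.outlier_indices) == idx

    def test_fit_robust_to_implant_then_screen(self, area_b_params, table):
        cohort = generate_cohort(area_b_params, seed=9, table=table)
        weekly = cohort_weekly(cohort, area_b_params, table=table)
        clean_fit = fit_lognormal_mle(weekly)
        spiked, _ = implant_outliers(cohort, weekly, k=2, multiplier=5.0, seed=1)
        weekly_spiked = cohort_weekly(spiked, area_b_params, table=table)
        outcome = grubbs_iterative(np.log(weekly_spiked))
        screened = np.delete(weekly_spiked, outcome.outlier_indices)
        fit = fit_lognormal_mle(screened)
        assert fit.median == pytest.approx(clean_fit.median, rel=0.03)


def test_mle_stability_across_cohort_sizes(area_b_params, table):
    # the weekly-intake fit from one study-sized cohort agrees with the fit
    # from a much larger cohort of the same process within 3 SE
    small = fit_lognormal_mle(
        cohort_weekly(generate_cohort(area_b_params, seed=2, table=table), area_b_params, table)
    )
    big = fit_lognormal_mle(
        _closed_form_weekly(area_b_params, 1234, 100_000, table.rice_gm("B"))
    )
    se_mu = big.sigma / np.sqrt(area_b_params.n)
    assert abs(small.mu - big.mu) < 3 * se_mu
    se_sigma = big.sigma / np.sqrt(2 * (area_b_params.n - 1))
    assert abs(small.sigma - big.sigma) < 3 * se_sigma
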