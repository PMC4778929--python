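import io

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from tkrcea import config as cfg
from tkrcea.config import GeneratorConfig, two_piece_rates
from tkrcea.synthetic import (generate_proms_cohort, generate_rerevision,
                              generate_revision_survival, inject_missingness,
                              latent_mean_for_censored_target)


def test_config_validation_errors():
    with pytest.raises(ValueError):
        GeneratorConfig(n_patients=0)
    shares = {b: 0.1 for b in cfg.BRANDS}
    with pytest.raises(ValueError):
        GeneratorConfig(brand_shares=shares)
    with pytest.raises(ValueError):
        GeneratorConfig(missing_postop_rate=1.2)
    bad = dict(cfg.REVISION_TARGETS)
    bad[("Nexgen", "M")] = (0.05, 0.02)  # 10-y below 5-y
    with pytest.raises(ValueError):
        GeneratorConfig(brand_hazard_targets=bad)


def test_case_mix_marginals_match_registry_targets(small_data):
    """Per-brand means track the configured case-mix table."""
    df = small_data.proms
    for b in cfg.BRANDS:
        sub = df[df["brand"] == b]
        n = len(sub)
        assert n > 500
        assert sub["age"].mean() == pytest.approx(cfg.BRAND_MEAN_AGE[b], abs=0.5)
        assert sub["bmi"].mean() == pytest.approx(cfg.BRAND_MEAN_BMI[b], abs=0.4)
        assert (sub["sex"] == "M").mean() == pytest.approx(
            cfg.BRAND_MALE_SHARE[b], abs=0.04)
        assert (sub["comorbidity_count"] >= 2).mean() == pytest.approx(
            cfg.BRAND_COMORBID2[b], abs=0.04)
    assert df["age"].between(55, 84).all()
    assert df["preop_oks"].between(0, 48).all()
    assert df["preop_eq5d"].le(1.0).all()
    assert df["postop_eq5d"].dropna().le(1.0).all()
    # overall age/BMI/male-share in the printed ranges
    assert 69.7 <= df["age"].mean() <= 70.6
    assert 30.8 <= df["bmi"].mean() <= 31.6
    assert 0.42 <= (df["sex"] == "M").mean() <= 0.46


def test_provider_mix_differs_by_brand(small_data):
    """Treatment-centre use concentrates in the brands configured with
    independent-sector providers (confounding-by-provider structure)."""
    df = small_data.proms
    tc = df.groupby("brand")["treatment_centre"].mean()
    assert tc["PFC Sigma"] > 0.05
    assert tc["Triathlon"] > 0.07
    assert tc["Nexgen"] < 0.03


def test_same_seed_reproduces_identical_records(small_config):
    a, _ = generate_proms_cohort(small_config)
    b, _ = generate_proms_cohort(small_config)
    pd.testing.assert_frame_equal(a, b)


def test_round_trip_through_csv(small_data):
    buf = io.StringIO()
    small_data.proms.to_csv(buf, index=False)
    buf.seek(0)
    back = pd.read_csv(buf)
    for c in small_data.proms.columns:
        orig = small_data.proms[c]
        if orig.dtype == object:
            assert (back[c] == orig).all()
        else:
            assert np.allclose(back[c].to_numpy(dtype=float),
                               orig.to_numpy(dtype=float), equal_nan=True)


def test_zero_offsets_zero_noise_gives_equal_brand_means():
    config = GeneratorConfig(
        n_patients=20_000, seed=3,
        brand_utility_effects={b: 0.0 for b in cfg.BRANDS},
        postop_eq5d_sd=0.0, missing_postop_rate=0.0)
    df, _ = generate_proms_cohort(config, uniform_case_mix=True)
    means = df.groupby("brand")["postop_eq5d"].mean()
    assert means.max() - means.min() < 0.012


def test_censored_target_calibration():
    """The latent-mean correction makes the ceiling-censored mean match the
    observed-scale target."""
    rng = np.random.default_rng(0)
    for target, sd in [(0.74, 0.25), (0.62, 0.27), (0.2, 0.3)]:
        mu = latent_mean_for_censored_target(target, sd)
        x = np.minimum(rng.normal(mu, sd, 400_000), 1.0)
        assert x.mean() == pytest.approx(target, abs=0.002)
    assert latent_mean_for_censored_target(0.5, 0.0) == 0.5


class TestMissingness:
    def test_zero_rate_no_missing(self, small_data):
        df = inject_missingness(small_data.proms.dropna(), 0.0, "MCAR")
        assert not df["postop_eq5d"].isna().any()

    def test_rate_within_binomial_error(self):
        config = GeneratorConfig(n_patients=53_126, seed=11,
                                 missing_postop_rate=0.0)
        df, _ = generate_proms_cohort(config)
        out = inject_missingness(df, 0.17, "MCAR", seed=1)
        n_missing = out["postop_eq5d"].isna().sum()
        expected = 0.17 * len(df)          # ~9 031 of 53 126
        sd = np.sqrt(len(df) * 0.17 * 0.83)
        assert abs(n_missing - expected) < 3 * sd

    def test_mar_depends_on_age_not_outcome_residual(self):
        config = GeneratorConfig(n_patients=30_000, seed=5,
                                 missing_postop_rate=0.0)
        df, truth = generate_proms_cohort(config)
        out = inject_missingness(df, 0.17, "MAR", seed=2)
        miss = out["postop_eq5d"].isna().astype(float)
        # age association present
        X = sm.add_constant((df["age"] - df["age"].mean()).to_numpy())
        fit = sm.Logit(miss, X).fit(disp=0)
        assert fit.params.iloc[1] / fit.bse.iloc[1] > 3
        # no association with the unobserved outcome residual given covariates
        resid = df["postop_eq5d"] - df.groupby(["brand", "sex"])[
            "postop_eq5d"].transform("mean")
        X2 = sm.add_constant(np.column_stack(
            [(df["age"] - df["age"].mean()),
             (df["imd_quintile"] - df["imd_quintile"].mean()),
             (df["preop_eq5d"] - df["preop_eq5d"].mean()), resid]))
        fit2 = sm.Logit(miss, X2).fit(disp=0)
        assert abs(fit2.params.iloc[-1] / fit2.bse.iloc[-1]) < 3

    def test_unknown_mechanism_rejected(self, small_data):
        with pytest.raises(ValueError):
            inject_missingness(small_data.proms, 0.1, "MNAR")


class TestRevisionSurvival:
    def test_two_piece_solver_exact(self):
        h1, h2 = two_piece_rates(0.016, 0.025)
        assert 1 - np.exp(-(h1 + 4 * h2)) == pytest.approx(0.016, abs=1e-12)
        assert 1 - np.exp(-(h1 + 9 * h2)) == pytest.approx(0.025, abs=1e-12)
        assert h1 > h2 > 0  # early-failure excess
        with pytest.raises(ValueError):
            two_piece_rates(0.05, 0.02)

    def test_zero_hazard_all_censored(self):
        targets = {(b, s): (0.0, 0.0) for b in cfg.BRANDS for s in ("M", "F")}
        config = GeneratorConfig(n_patients=100, n_revision_cohort=5_000,
                                 brand_hazard_targets=targets, seed=2)
        df, _ = generate_revision_survival(config)
        assert (df["event"] == 0).all()
        assert (df["time_to_event"] > 0).all()

    def test_constant_hazard_closed_form(self):
        # equal H increments over (0,5] and (5,10] => constant hazard h
        h = 0.005
        p5, p10 = 1 - np.exp(-5 * h), 1 - np.exp(-10 * h)
        targets = {(b, s): (p5, p10) for b in cfg.BRANDS for s in ("M", "F")}
        config = GeneratorConfig(n_patients=100, n_revision_cohort=150_000,
                                 brand_hazard_targets=targets, seed=4)
        df, _ = generate_revision_survival(config)
        from lifelines import KaplanMeierFitter
        km = KaplanMeierFitter().fit(df["time_to_event"], df["event"])
        for t in (2.0, 5.0):
            expect = 1 - np.exp(-h * t)
            assert 1 - km.predict(t) == pytest.approx(expect, abs=0.002)

    def test_censoring_respects_brand_max_followup(self, small_data):
        df = small_data.revisions
        for b in cfg.BRANDS:
            assert df.loc[df["brand"] == b, "time_to_event"].max() <= \
                cfg.MAX_FOLLOWUP[b] + 1e-9


class TestRerevision:
    def test_first_year_cumulative_incidence_closed_form(self):
        config = GeneratorConfig(n_patients=100, n_rerevision_cohort=200_000,
                                 rerevision_rates=(0.04, 0.015), seed=6)
        df, _ = generate_rerevision(config)
        # uniform censoring over (0, 15]: at-risk-adjusted 1-year incidence
        from lifelines import KaplanMeierFitter
        km = KaplanMeierFitter().fit(df["time_to_event"], df["event"])
        assert 1 - km.predict(1.0) == pytest.approx(1 - np.exp(-0.04),
                                                    rel=0.05)

    def test_equal_pieces_reduce_to_exponential(self):
        config = GeneratorConfig(n_patients=100, n_rerevision_cohort=100_000,
                                 rerevision_rates=(0.02, 0.02), seed=8)
        df, _ = generate_rerevision(config)
        from lifelines import KaplanMeierFitter
        km = KaplanMeierFitter().fit(df["time_to_event"], df["event"])
        for t in (1.0, 4.0, 8.0):
            assert 1 - km.predict(t) == pytest.approx(1 - np.exp(-0.02 * t),
                                                      rel=0.08)
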