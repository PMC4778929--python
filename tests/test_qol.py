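import numpy as np
import pandas as pd
import pytest

from tkrcea import config as cfg
from tkrcea.config import GeneratorConfig
from tkrcea.qol import (DEFAULT_COVARIATES, FractionalPolynomialSelector,
                        QOLRegression, StateQOLModel, aging_decline,
                        apply_aging_decline, fit_postop_qol, fit_state_qol,
                        pool_rubin)
from tkrcea.synthetic import generate_proms_cohort


def _balanced_frame(k: int = 40) -> pd.DataFrame:
    """Each x value replicated across every brand x sex cell, so the single
    covariate is exactly orthogonal to the factor dummies."""
    xs = np.linspace(0.0, 1.0, k)
    rows = []
    for b in cfg.BRANDS:
        for s in ("M", "F"):
            for x in xs:
                rows.append({"brand": b, "sex": s, "preop_eq5d": x})
    df = pd.DataFrame(rows)
    df["postop_eq5d"] = 0.2 + 0.5 * df["preop_eq5d"] \
        + 0.01 * np.sin(997 * df["preop_eq5d"])  # deterministic 'noise'
    return df


def test_single_covariate_fit_equals_closed_form_slope():
    df = _balanced_frame()
    m = QOLRegression(covariates=("sex", "preop_eq5d"), fp_covariates=()).fit(df)
    x, y = df["preop_eq5d"].to_numpy(), df["postop_eq5d"].to_numpy()
    slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    assert m.params_["preop_eq5d"] == pytest.approx(slope, abs=1e-10)


def test_collinear_design_reports_offending_terms():
    df = _balanced_frame()
    df["bmi"] = 31.0  # constant column, collinear with the intercept
    with pytest.raises(ValueError, match="collinear"):
        QOLRegression(covariates=("sex", "preop_eq5d", "bmi"),
                      fp_covariates=()).fit(df)


def test_null_brand_effects_give_null_contrasts():
    config = GeneratorConfig(
        n_patients=20_000, seed=21, missing_postop_rate=0.0,
        brand_utility_effects={b: 0.0 for b in cfg.BRANDS})
    df, _ = generate_proms_cohort(config)
    m = fit_postop_qol(df)
    for b in cfg.BRANDS:
        est, se = m.brand_contrast(b)
        if b != cfg.REFERENCE_BRAND:
            assert abs(est) < 3 * se


def test_brand_offset_parameter_recovery():
    """At n = 50 000 the adjusted Nexgen-vs-reference contrast recovers the
    generating offset within 3 SE."""
    config = GeneratorConfig(n_patients=50_000, seed=22,
                             missing_postop_rate=0.0)
    df, truth = generate_proms_cohort(config)
    m = fit_postop_qol(df)
    for b in ("Nexgen", "Genesis 2", "PFC Sigma"):
        est, se = m.brand_contrast(b)
        assert abs(est - truth.brand_utility_effects[b]) < 3 * se


def test_provider_adjustment_moves_contrast_toward_truth():
    """With brand chosen by providers that also affect outcomes, the contrast
    estimated without provider covariates is confounded; adding them removes
    the bias (checked at low noise so the bias is resolvable)."""
    config = GeneratorConfig(
        n_patients=20_000, seed=23, missing_postop_rate=0.0,
        postop_eq5d_sd=0.02,
        brand_utility_effects={b: 0.0 for b in cfg.BRANDS})
    df, _ = generate_proms_cohort(config)
    no_prov = tuple(c for c in DEFAULT_COVARIATES
                    if c not in ("senior_surgeon", "treatment_centre"))
    biased = fit_postop_qol(df, covariates=no_prov, fp_covariates=())
    full = fit_postop_qol(df, fp_covariates=())
    # PFC Sigma uses treatment centres / consultants most; truth offset is 0
    assert abs(full.brand_contrast("PFC Sigma")[0]) < \
        abs(biased.brand_contrast("PFC Sigma")[0])
    assert abs(full.brand_contrast("PFC Sigma")[0]) < 0.002


def test_predictions_invariant_to_affine_covariate_recoding():
    config = GeneratorConfig(n_patients=8_000, seed=24, missing_postop_rate=0.0)
    df, _ = generate_proms_cohort(config)
    m1 = fit_postop_qol(df, fp_covariates=())
    df2 = df.copy()
    df2["bmi"] = 2.0 * df2["bmi"] + 5.0
    m2 = fit_postop_qol(df2, fp_covariates=())
    for b in ("Nexgen", "AGC Biomet"):
        p1, se1 = m1.predict_subgroup(b, "M", 70)
        p2, se2 = m2.predict_subgroup(b, "M", 70)
        assert p1 == pytest.approx(p2, abs=1e-8)
        assert se1 == pytest.approx(se2, abs=1e-8)


def test_null_effect_fit_predicts_identically_across_brands():
    config = GeneratorConfig(n_patients=5_000, seed=25, missing_postop_rate=0.0)
    df, _ = generate_proms_cohort(config)
    m = fit_postop_qol(df, fp_covariates=())
    params = m.params_.copy()
    params[[t for t in params.index if t.startswith("brand[")]] = 0.0
    preds = {b: m.predict_subgroup(b, "F", 70, params=params, cov=m.cov_)[0]
             for b in cfg.BRANDS}
    assert max(preds.values()) - min(preds.values()) < 1e-12


class TestFractionalPolynomials:
    def _select(self, y, age):
        sel = FractionalPolynomialSelector()
        return sel.fit(age, y, name="age").selection_

    def test_linear_outcome_selects_linear(self, rng):
        age = rng.uniform(55, 84, 20_000)
        y = 0.5 - 0.004 * age + rng.normal(0, 0.2, age.size)
        assert self._select(y, age).kind == "linear"

    def test_inverse_square_outcome_selects_fp1_power_minus2(self, rng):
        age = rng.uniform(55, 84, 20_000)
        z = age / 10.0
        y = 5.0 * z ** -2 + rng.normal(0, 0.05, age.size)
        sel = self._select(y, age)
        assert sel.kind == "fp1"
        assert sel.powers == (-2.0,)

    def test_quadratic_outcome_retains_quadratic(self, rng):
        age = rng.uniform(55, 84, 20_000)
        z = (age - 70) / 10.0
        y = 0.7 - 0.05 * z ** 2 + rng.normal(0, 0.1, age.size)
        sel = self._select(y, age)
        # FP cannot beat the quadratic by the threshold here
        assert sel.kind == "quadratic"

    def test_constant_covariate_flagged_omit(self):
        sel = FractionalPolynomialSelector()
        with pytest.warns(UserWarning, match="constant"):
            sel.fit(np.full(100, 3.0), np.random.default_rng(0).normal(size=100))
        assert sel.selection_.kind == "omit"


class TestRubin:
    def test_hand_computed_example(self):
        pooled, total = pool_rubin([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert pooled == pytest.approx(2.0)
        assert total == pytest.approx(1.0 + (1 + 1 / 3) * 1.0)  # 2.333...

    def test_identical_estimates_have_zero_between_variance(self):
        pooled, total = pool_rubin([1.7, 1.7, 1.7, 1.7], [0.3, 0.3, 0.3, 0.3])
        assert pooled == pytest.approx(1.7)
        assert total == pytest.approx(0.3)

    def test_total_variance_at_least_mean_within(self, rng):
        est = rng.normal(size=(5, 4))
        var = rng.uniform(0.1, 1.0, size=(5, 4))
        _, total = pool_rubin(est, var)
        assert np.all(total >= var.mean(axis=0) - 1e-12)

    def test_requires_two_imputations(self):
        with pytest.raises(ValueError):
            pool_rubin([1.0], [1.0])


class TestStateQOL:
    def _records(self, female_effect: float, n=6_000, seed=31):
        rng = np.random.default_rng(seed)
        age = rng.uniform(55, 90, n)
        female = rng.random(n) < 0.5
        pre = 0.45 - 0.003 * (age - 70) + female_effect * female \
            + rng.normal(0, 0.3, n)
        post = 0.62 - 0.003 * (age - 70) + female_effect * female \
            + rng.normal(0, 0.27, n)
        return pd.DataFrame({"age": age, "sex": np.where(female, "F", "M"),
                             "preop_eq5d": pre, "postop_eq5d": post})

    def test_recovery_of_state_utilities(self, small_data):
        truth = small_data.truth.state_qol
        pre = fit_state_qol(small_data.revision_proms, "pre_revision")
        post = fit_state_qol(small_data.revision_proms, "post_revision")
        mu, se = pre.predict(70, "M")
        assert abs(mu - truth["revision_year"]["at70"]) < 3 * se + 0.005
        mu, se = post.predict(70, "M")
        assert abs(mu - truth["post_revision"]["at70"]) < 3 * se + 0.01
        assert pre.predict(70, "M")[0] < post.predict(70, "M")[0]

    def test_null_sex_effect_recovered(self):
        m = fit_state_qol(self._records(0.0), "pre_revision")
        assert abs(m.params_["female"]) < 3 * np.sqrt(m.cov_.loc["female",
                                                                 "female"])

    def test_minimum_records_enforced(self):
        with pytest.raises(ValueError):
            StateQOLModel(min_records=50).fit(self._records(0.0, n=10))

    def test_unknown_timing_rejected(self):
        with pytest.raises(ValueError):
            fit_state_qol(self._records(0.0), "mid_revision")


class TestAgingDecline:
    def test_anchor_values(self):
        assert aging_decline(70) == pytest.approx(0.004)
        assert aging_decline(0) == 0.0
        assert aging_decline(80) == pytest.approx(0.004 * (80 / 70) ** 2,
                                                  rel=1e-9)  # ~0.00522

    def test_floor_clamps_at_instrument_minimum(self):
        assert apply_aging_decline(-0.594, 90) == pytest.approx(-0.594)
        assert apply_aging_decline(0.7, 70) == pytest.approx(0.696)


def test_pooled_model_matches_single_fit_when_duplicated():
    config = GeneratorConfig(n_patients=4_000, seed=26, missing_postop_rate=0.0)
    df, _ = generate_proms_cohort(config)
    single = fit_postop_qol(df, fp_covariates=())
    pooled = fit_postop_qol([df, df.copy()], fp_covariates=())
    assert np.allclose(pooled.params_.to_numpy(),
                       single.params_.to_numpy(), atol=1e-10)
    # duplicated datasets: zero between-imputation variance
    assert np.allclose(pooled.cov_.to_numpy(), single.cov_.to_numpy(),
                       atol=1e-10)
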