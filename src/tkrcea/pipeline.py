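"""End-to-end pipeline: simulate -> fit -> assemble Markov inputs.

This module glues the synthetic registry, the QOL and survival estimators and
the mortality model into the parameter sets consumed by the Markov engine and
the cost-effectiveness layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import config as cfg
from .config import GeneratorConfig, RunConfig
from .impute import impute_chained
from .markov import ModelInputs, mortality_schedule
from .mortality import LifeTable, HealthyPatientEffect
from .qol import (PooledQOLModel, StateQOLModel, fit_postop_qol, fit_state_qol)
from .survival import PiecewiseExponential, SplineSurvival
from .synthetic import (SyntheticTruth, generate_proms_cohort,
                        generate_rerevision, generate_revision_proms,
                        generate_revision_survival, inject_missingness)

log = logging.getLogger(__name__)

SURVIVAL_COVARIATES = ("age", "female", "asa3", "bmi", "patella_replaced",
                       "antibiotic_cement", "senior_surgeon", "treatment_centre")


@dataclass
class SimulatedData:
    """One linked synthetic dataset bundle."""

    proms: pd.DataFrame
    revisions: pd.DataFrame
    rerevisions: pd.DataFrame
    revision_proms: pd.DataFrame
    truth: SyntheticTruth


def simulate(config: GeneratorConfig | None = None) -> SimulatedData:
    config = config or GeneratorConfig()
    proms, truth = generate_proms_cohort(config)
    proms = inject_missingness(proms, config.missing_postop_rate,
                               config.missing_mechanism, seed=config.seed + 7)
    revisions, truth = generate_revision_survival(config, truth)
    rerevisions, _ = generate_rerevision(config)
    revision_proms = generate_revision_proms(config)
    return SimulatedData(proms, revisions, rerevisions, revision_proms, truth)


@dataclass
class FittedModels:
    """Every fitted input model for the decision model."""

    qol: PooledQOLModel
    oks: PooledQOLModel | None
    state_pre: StateQOLModel
    state_post: StateQOLModel
    revision: dict[str, SplineSurvival]
    rerevision: PiecewiseExponential
    los: dict[tuple[str, str], tuple[float, float]]  # (brand, sex) -> (mean, se)
    revision_piecewise: dict[str, PiecewiseExponential] = field(default_factory=dict)
    qol_interactions: PooledQOLModel | None = None
    qol_categorical: PooledQOLModel | None = None


def _with_survival_columns(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["female"] = (out["sex"] == "F").astype(float)
    out["asa3"] = (out["asa_grade"] == 3).astype(float)
    return out


def fit_survival_models(revisions: pd.DataFrame, n_knots: int = 3,
                        ) -> dict[str, SplineSurvival]:
    """Brand-stratified flexible parametric revision models with case-mix
    adjustment."""
    data = _with_survival_columns(revisions)
    models = {}
    for b in cfg.BRANDS:
        sub = data[data["brand"] == b]
        m = SplineSurvival(n_knots=n_knots, covariates=SURVIVAL_COVARIATES)
        m.fit(sub)
        models[b] = m
        log.info("revision model %s: %d records, %d events, loglik %.1f",
                 b, len(sub), m.n_events_, m.loglik_)
    return models


def fit_piecewise_revision_models(revisions: pd.DataFrame,
                                  ) -> dict[str, PiecewiseExponential]:
    """Scenario alternative: piecewise-constant revision hazard with yearly
    cuts up to the brand's maximum follow-up."""
    models = {}
    for b in cfg.BRANDS:
        sub = revisions[revisions["brand"] == b]
        cuts = tuple(float(c) for c in range(1, int(cfg.MAX_FOLLOWUP[b])))
        models[b] = PiecewiseExponential(cuts=cuts).fit(sub)
    return models


def fit_los(proms: pd.DataFrame) -> dict[tuple[str, str], tuple[float, float]]:
    out = {}
    for (b, s), grp in proms.groupby(["brand", "sex"]):
        x = grp["los_days"].to_numpy(dtype=float)
        out[(b, s)] = (float(x.mean()), float(x.std(ddof=1) / np.sqrt(len(x))))
    return out


def fit_all(data: SimulatedData, run: RunConfig | None = None,
            fit_scenario_variants: bool = False) -> FittedModels:
    run = run or RunConfig()
    if data.proms["postop_eq5d"].isna().any():
        imputed = impute_chained(data.proms, m=run.m_imputations,
                                 seed=run.seed + 11, n_iter=run.mice_iterations)
        datasets = list(imputed)
    else:
        log.info("no missing post-operative outcomes; imputation skipped")
        datasets = [data.proms]

    qol = fit_postop_qol(datasets)
    oks = fit_postop_qol(datasets, outcome="postop_oks")
    models = FittedModels(
        qol=qol,
        oks=oks,
        state_pre=fit_state_qol(data.revision_proms, "pre_revision"),
        state_post=fit_state_qol(data.revision_proms, "post_revision"),
        revision=fit_survival_models(data.revisions),
        rerevision=PiecewiseExponential(cuts=(1.0,)).fit(data.rerevisions),
        los=fit_los(data.proms),
    )
    if fit_scenario_variants:
        models.revision_piecewise = fit_piecewise_revision_models(data.revisions)
        models.qol_interactions = fit_postop_qol(datasets, brand_interactions=True)
        models.qol_categorical = fit_postop_qol(
            datasets, preop_categorical=True,
            fp_covariates=("age", "bmi", "preop_oks"))
    return models


# ---------------------------------------------------------------------------
# Markov input assembly
# ---------------------------------------------------------------------------

def _survival_profile(sex: str, age: float) -> dict:
    return {"age": float(age), "female": 1.0 if sex == "F" else 0.0}


def build_point_inputs(models: FittedModels, brand: str, sex: str, age: int,
                       run: RunConfig | None = None,
                       life_table: LifeTable | None = None,
                       price_override: float | None = None,
                       use_piecewise_revision: bool = False) -> ModelInputs:
    """Point-estimate Markov inputs for one brand x subgroup."""
    run = run or RunConfig()
    u_pri, _ = models.qol.predict_subgroup(brand, sex, age)
    u_rev, _ = models.state_pre.predict(age, sex)
    u_post, _ = models.state_post.predict(age, sex)
    if use_piecewise_revision:
        p_rev = models.revision_piecewise[brand].annual_transition_probs(
            horizon=cfg.N_CYCLES)
    else:
        p_rev = models.revision[brand].annual_transition_probs(
            _survival_profile(sex, age), horizon=cfg.N_CYCLES)
    r1, r2 = models.rerevision.rates_
    price = (cfg.PROSTHESIS_PRICE[brand] if price_override is None
             else price_override)
    return ModelInputs(
        brand=brand, sex=sex, age_at_surgery=age,
        utility_primary=min(u_pri, 1.0),
        utility_revision_year=min(u_rev, 1.0),
        utility_post_revision=min(u_post, 1.0),
        p_revision=p_rev,
        p_rerevision_year1=1.0 - np.exp(-r1),
        p_rerevision_later=1.0 - np.exp(-r2),
        mortality=mortality_schedule(age, sex, life_table),
        operative_mortality=run.operative_mortality,
        prosthesis_price=price,
        los_days=models.los[(brand, sex)][0],
        discount_rate=run.discount_rate,
    )


def build_draw_inputs(models: FittedModels, sex: str, age: int, n_sims: int,
                      rng: np.random.Generator,
                      run: RunConfig | None = None,
                      life_table: LifeTable | None = None,
                      price_override: float | None = None,
                      qol_model: PooledQOLModel | None = None,
                      use_piecewise_revision: bool = False,
                      ) -> dict[str, ModelInputs]:
    """Sampled Markov inputs for every brand, sharing parameter draws within
    a simulation so per-draw brand comparisons are coherent.

    Regression and spline coefficient vectors are drawn multivariate normal
    from their fitted covariances; re-revision rates log-normal; unit costs
    and prices are contract values and stay fixed.
    """
    run = run or RunConfig()
    qol = qol_model or models.qol
    beta = qol.sample_params(n_sims, rng)
    state_draws = {
        "pre": models.state_pre.sample_predictions(age, sex, n_sims, rng),
        "post": models.state_post.sample_predictions(age, sex, n_sims, rng),
    }
    rr = models.rerevision.sample_rates(n_sims, rng)
    mort = mortality_schedule(age, sex, life_table)

    out = {}
    for brand in cfg.BRANDS:
        x = qol.subgroup_row(brand, sex, age)
        u_pri = np.minimum(beta @ x, 1.0)
        if use_piecewise_revision:
            pw = models.revision_piecewise[brand]
            rate_draws = pw.sample_rates(n_sims, rng)
            edges = np.concatenate([[0.0], np.asarray(pw.cuts), [np.inf]])
            ts = np.arange(0, cfg.N_CYCLES + 1, dtype=float)
            expo = np.stack([np.clip(np.minimum(ts, hi) - lo, 0.0, None)
                             for lo, hi in zip(edges[:-1], edges[1:])])
            H = rate_draws @ expo
            S = np.exp(-H)
            p_rev = np.clip((S[:, :-1] - S[:, 1:]) / S[:, :-1], 0.0, 1.0)
        else:
            m = models.revision[brand]
            draws = m.sample_coefficients(n_sims, rng)
            p_rev = m.annual_probs_from_draws(
                draws, _survival_profile(sex, age), horizon=cfg.N_CYCLES)
        los_mean, los_se = models.los[(brand, sex)]
        price = (cfg.PROSTHESIS_PRICE[brand] if price_override is None
                 else price_override)
        out[brand] = ModelInputs(
            brand=brand, sex=sex, age_at_surgery=age,
            utility_primary=u_pri,
            utility_revision_year=state_draws["pre"],
            utility_post_revision=state_draws["post"],
            p_revision=p_rev,
            p_rerevision_year1=1.0 - np.exp(-rr[:, 0]),
            p_rerevision_later=1.0 - np.exp(-rr[:, 1]),
            mortality=mort,
            operative_mortality=run.operative_mortality,
            prosthesis_price=price,
            los_days=np.maximum(rng.normal(los_mean, los_se, n_sims), 0.0),
            discount_rate=run.discount_rate,
        )
    return out


def subgroup_qol_table(models: FittedModels,
                       ages=(70,), sexes=("M", "F")) -> pd.DataFrame:
    """Adjusted post-operative EQ-5D and OKS by brand and subgroup."""
    rows = []
    for sex in sexes:
        for age in ages:
            for b in cfg.BRANDS:
                eq, eq_se = models.qol.predict_subgroup(b, sex, age)
                row = {"brand": b, "sex": sex, "age": age,
                       "postop_eq5d": eq, "postop_eq5d_se": eq_se}
                if models.oks is not None:
                    oks, oks_se = models.oks.predict_subgroup(b, sex, age)
                    row["postop_oks"] = oks
                    row["postop_oks_se"] = oks_se
                los_mean, _ = models.los[(b, sex)]
                row["initial_cost"] = (cfg.PROSTHESIS_PRICE[b] + cfg.THEATRE_COST
                                       + cfg.BED_DAY_COST * los_mean)
                m = models.revision[b]
                prof = _survival_profile(sex, age)
                row["revision_5y"] = m.predict_cumulative_incidence(5.0, prof)
                row["revision_10y"] = m.predict_cumulative_incidence(10.0, prof)
                rows.append(row)
    return pd.DataFrame(rows)
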