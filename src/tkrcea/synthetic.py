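"""Synthetic registry generator.

Emulates the linked data structure the analysis assumes: a national
PROMs-style cohort (pre/post EQ-5D and OKS, case mix, provider flags, length
of stay), a registry-scale revision-survival cohort, a re-revision cohort,
and revision-episode QOL records. Every dataset is generated from an explicit
ground truth (`SyntheticTruth`) that is serialized alongside it, enabling
parameter-recovery tests of each downstream estimator.

Key structural features reproduced:

* five brand groups with near-identical case mix but brand-specific provider
  mix (treatment-centre and senior-surgeon rates), generated through a
  hospital layer in which most hospitals use a single brand;
* brand effects on 6-month EQ-5D of order 0.01-0.04 on top of a case-mix
  linear predictor with Gaussian noise;
* two-piece revision hazards (elevated first-year early-failure rate, then
  constant) solved exactly to the target 5- and 10-year cumulative revision
  probabilities per brand and sex, with proportional covariate effects;
* 17% missing post-operative outcomes, MCAR or MAR-on-covariates;
* uniform accrual with administrative censoring at brand-specific maximum
  follow-up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm, truncnorm

from . import config as cfg
from .config import GeneratorConfig, two_piece_rates

SEXES = ("M", "F")


def latent_mean_for_censored_target(target: float, sd: float,
                                    ceiling: float = 1.0) -> float:
    """Latent normal mean whose ceiling-censored expectation equals ``target``.

    The EQ-5D index is capped at 1 (perfect health), so adding Gaussian noise
    and truncating shifts the observed mean below the latent one. Solving
    E[min(N(mu, sd), ceiling)] = target keeps the *observed* adjusted means on
    the calibrated scale. E[min(X, c)] = c - (c - mu) Phi(a) - sd phi(a) with
    a = (c - mu)/sd.
    """
    if sd <= 0 or target <= ceiling - 6 * sd:
        return target

    def censored_mean(mu: float) -> float:
        a = (ceiling - mu) / sd
        return ceiling - (ceiling - mu) * norm.cdf(a) - sd * norm.pdf(a)

    return brentq(lambda mu: censored_mean(mu) - target,
                  target, target + 6 * sd)


@dataclass
class SyntheticTruth:
    """Ground truth underlying one generated dataset bundle."""

    brand_utility_effects: dict[str, float]
    qol_intercept: float
    qol_female_effect: float
    qol_coef: dict[str, float]
    qol_noise_sd: float
    covariate_means: dict[str, float]
    oks_offsets: dict[str, float]
    hazard_params: dict[str, tuple[float, float]]  # "brand|sex" -> (h1, h2)
    hazard_coef: dict[str, float]
    hazard_covariate_means: dict[str, float]
    max_followup: dict[str, float]
    rerevision_rates: tuple[float, float]
    state_qol: dict[str, dict[str, float]]
    los_mean: dict[str, float]                      # "brand|sex" -> days
    missing_rate: float
    missing_mechanism: str
    seed: int
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=list)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path) as fh:
            raw = json.load(fh)
        raw["rerevision_rates"] = tuple(raw["rerevision_rates"])
        raw["hazard_params"] = {k: tuple(v) for k, v in raw["hazard_params"].items()}
        return cls(**raw)

    def cumulative_revision(self, brand: str, sex: str, t: float) -> float:
        """True cumulative revision probability at the calibration profile."""
        h1, h2 = self.hazard_params[f"{brand}|{sex}"]
        h = h1 * min(t, 1.0) + h2 * max(t - 1.0, 0.0)
        return 1.0 - np.exp(-h)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                         random_state=rng)


def _draw_case_mix(rng: np.random.Generator, brands: np.ndarray,
                   uniform_case_mix: bool) -> pd.DataFrame:
    """Patient covariates given brand assignment (Table-1-style marginals)."""
    n = brands.size

    def per_brand(d: dict[str, float]) -> np.ndarray:
        if uniform_case_mix:
            m = float(np.mean(list(d.values())))
            return np.full(n, m)
        return np.array([d[b] for b in brands])

    age = np.empty(n)
    bmi = np.empty(n)
    for b in cfg.BRANDS:
        mask = brands == b
        k = int(mask.sum())
        if k == 0:
            continue
        mean_age = (np.mean(list(cfg.BRAND_MEAN_AGE.values()))
                    if uniform_case_mix else cfg.BRAND_MEAN_AGE[b])
        mean_bmi = (np.mean(list(cfg.BRAND_MEAN_BMI.values()))
                    if uniform_case_mix else cfg.BRAND_MEAN_BMI[b])
        age[mask] = _truncated_normal(rng, mean_age, cfg.AGE_SD, *cfg.AGE_RANGE, k)
        bmi[mask] = np.clip(rng.normal(mean_bmi, cfg.BMI_SD, k), 15.0, 60.0)

    male = rng.random(n) < per_brand(cfg.BRAND_MALE_SHARE)
    sex = np.where(male, "M", "F")

    # comorbidity count: Poisson with mean solved so P(X >= 2) matches target
    p2 = per_brand(cfg.BRAND_COMORBID2)
    lam = np.array([brentq(lambda l: 1 - np.exp(-l) * (1 + l) - p, 1e-6, 10.0)
                    for p in np.unique(p2)])
    lam_map = dict(zip(np.unique(p2), lam))
    comorb = rng.poisson(np.array([lam_map[p] for p in p2]))

    asa3 = rng.random(n) < per_brand(cfg.BRAND_ASA3_SHARE)
    asa = np.where(asa3, 3, np.where(rng.random(n) < cfg.ASA1_SHARE / (1 - per_brand(cfg.BRAND_ASA3_SHARE)), 1, 2))

    # IMD: most-deprived fifth at the brand target, remainder uniform over 2-5
    p_dep = per_brand(cfg.BRAND_MOST_DEPRIVED)
    u = rng.random(n)
    imd = np.where(u < p_dep, 1, rng.integers(2, 6, n))

    preop_eq5d = _truncated_normal(
        rng, 0.0, cfg.PREOP_EQ5D_SD, *cfg.EQ5D_RANGE, n) + per_brand(cfg.BRAND_PREOP_EQ5D)
    preop_eq5d = np.clip(preop_eq5d, *cfg.EQ5D_RANGE)
    preop_oks = np.clip(
        rng.normal(per_brand(cfg.BRAND_PREOP_OKS), cfg.PREOP_OKS_SD), *cfg.OKS_RANGE)

    return pd.DataFrame({
        "brand": brands, "age": age, "sex": sex,
        "comorbidity_count": comorb, "asa_grade": asa, "bmi": bmi,
        "imd_quintile": imd,
        "patella_replaced": (rng.random(n) < cfg.PATELLA_SHARE).astype(int),
        "disability": (rng.random(n) < cfg.DISABILITY_SHARE).astype(int),
        "surgical_position": (rng.random(n) < cfg.SURGICAL_POSITION_SHARE).astype(int),
        "preop_eq5d": preop_eq5d, "preop_oks": preop_oks,
    })


def _assign_providers(rng: np.random.Generator, config: GeneratorConfig,
                      uniform_case_mix: bool = False):
    """Hospital layer: most hospitals use a single brand; provider flags follow
    the hospital's dominant brand, so brand is correlated with provider
    characteristics but independent of patient covariates given provider."""
    brands = np.array(cfg.BRANDS)
    shares = np.array([config.brand_shares[b] for b in cfg.BRANDS])
    nh = config.n_hospitals
    hosp_brand = rng.choice(brands, size=nh, p=shares)

    def rate(d, b):
        if uniform_case_mix:
            return float(np.mean(list(d.values())))
        return d[b]

    hosp_tc = np.array([rng.random() < rate(cfg.BRAND_TREATMENT_CENTRE, b)
                        for b in hosp_brand])
    hosp_senior = np.array([rate(cfg.BRAND_SENIOR_SURGEON, b) for b in hosp_brand])

    n = config.n_patients
    hospital = rng.integers(0, nh, n)
    # 90% of patients receive the hospital's dominant brand
    own = rng.random(n) < 0.9
    brand = np.where(own, hosp_brand[hospital], rng.choice(brands, size=n, p=shares))
    treatment_centre = hosp_tc[hospital].astype(int)
    senior = (rng.random(n) < hosp_senior[hospital]).astype(int)
    return hospital, brand, treatment_centre, senior


def generate_proms_cohort(config: GeneratorConfig | None = None, *,
                          uniform_case_mix: bool = False,
                          ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate the PROMs-style QOL cohort plus its ground truth.

    The 6-month EQ-5D index is a linear predictor in centred case-mix and
    provider covariates plus the brand offset and Gaussian noise, truncated to
    the instrument support [-0.594, 1].
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    hospital, brands, tc, senior = _assign_providers(rng, config, uniform_case_mix)
    df = _draw_case_mix(rng, brands, uniform_case_mix)
    df.insert(0, "patient_id", np.arange(len(df)))
    df["treatment_centre"] = tc
    df["senior_surgeon"] = senior
    df["hospital"] = hospital

    female = (df["sex"] == "F").astype(float)
    coef = dict(cfg.QOL_TRUTH_COEF)
    means = {
        "age": 70.0, "bmi": float(df["bmi"].mean()),
        "comorbidity_count": float(df["comorbidity_count"].mean()),
        "asa3": float((df["asa_grade"] == 3).mean()),
        "imd_quintile": float(df["imd_quintile"].mean()),
        "disability": float(df["disability"].mean()),
        "patella_replaced": float(df["patella_replaced"].mean()),
        "surgical_position": float(df["surgical_position"].mean()),
        "preop_eq5d": float(df["preop_eq5d"].mean()),
        "preop_oks": float(df["preop_oks"].mean()),
        "senior_surgeon": float(df["senior_surgeon"].mean()),
        "treatment_centre": float(df["treatment_centre"].mean()),
    }

    def centred(name):
        if name == "asa3":
            x = (df["asa_grade"] == 3).astype(float)
        else:
            x = df[name].astype(float)
        return x - means[name]

    # Observed-scale targets per brand x sex; the latent mean compensates for
    # ceiling censoring of the index at 1 so the *observed* adjusted means sit
    # on the calibrated scale.
    latent_base = {
        (b, s): latent_mean_for_censored_target(
            cfg.POSTOP_EQ5D_MEN70 + config.brand_utility_effects[b]
            + (cfg.POSTOP_EQ5D_FEMALE if s == "F" else 0.0),
            config.postop_eq5d_sd)
        for b in cfg.BRANDS for s in SEXES}
    lp = pd.Series([latent_base[(b, s)] for b, s in zip(df["brand"], df["sex"])],
                   index=df.index)
    for name, c in coef.items():
        lp = lp + c * centred(name)
    noise = rng.normal(0.0, config.postop_eq5d_sd, len(df))
    df["postop_eq5d"] = np.clip(lp + noise, *cfg.EQ5D_RANGE)

    # OKS modelled in parallel (reporting only)
    oks = (cfg.POSTOP_OKS_MEN70 + df["brand"].map(cfg.BRAND_OKS_OFFSET)
           + cfg.POSTOP_OKS_FEMALE * female
           + 0.8 * centred("preop_oks") * 0.5
           + rng.normal(0.0, cfg.POSTOP_OKS_SD, len(df)))
    df["postop_oks"] = np.clip(oks, *cfg.OKS_RANGE)

    los_mu = np.array([cfg.LOS_MEAN[(b, s)] for b, s in zip(df["brand"], df["sex"])])
    shape = (los_mu / cfg.LOS_SD) ** 2
    df["los_days"] = rng.gamma(shape, los_mu / shape)

    truth = SyntheticTruth(
        brand_utility_effects=dict(config.brand_utility_effects),
        qol_intercept=cfg.POSTOP_EQ5D_MEN70,
        qol_female_effect=cfg.POSTOP_EQ5D_FEMALE,
        qol_coef=coef,
        qol_noise_sd=config.postop_eq5d_sd,
        covariate_means=means,
        oks_offsets=dict(cfg.BRAND_OKS_OFFSET),
        hazard_params={f"{b}|{s}": two_piece_rates(*config.brand_hazard_targets[(b, s)])
                       for b in cfg.BRANDS for s in SEXES},
        hazard_coef=dict(cfg.REVISION_TRUTH_COEF),
        hazard_covariate_means={},
        max_followup=dict(cfg.MAX_FOLLOWUP),
        rerevision_rates=tuple(config.rerevision_rates),
        state_qol={k: dict(v) for k, v in cfg.STATE_QOL_TRUTH.items()},
        los_mean={f"{b}|{s}": cfg.LOS_MEAN[(b, s)] for b in cfg.BRANDS for s in SEXES},
        missing_rate=config.missing_postop_rate,
        missing_mechanism=config.missing_mechanism,
        seed=config.seed,
    )
    return df, truth


def inject_missingness(records: pd.DataFrame, rate: float,
                       mechanism: str = "MCAR", seed: int = 0) -> pd.DataFrame:
    """Blank post-operative outcomes (EQ-5D and OKS jointly: questionnaire
    non-response) at the given rate.

    MCAR: uniform. MAR: log-odds of missingness increase with age and
    deprivation and decrease with pre-operative QOL; the intercept is solved
    so the expected missing fraction equals ``rate`` in this sample.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if mechanism not in ("MCAR", "MAR"):
        raise ValueError(f"unknown missingness mechanism: {mechanism!r}")
    out = records.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    n = len(out)
    if mechanism == "MCAR":
        p = np.full(n, rate)
    else:
        z = (0.04 * (out["age"] - out["age"].mean())
             + 0.10 * (out["imd_quintile"] - out["imd_quintile"].mean())
             - 0.8 * (out["preop_eq5d"] - out["preop_eq5d"].mean())).to_numpy()

        def mean_p(a):
            return 1.0 / (1.0 + np.exp(-(a + z))).mean() - rate

        a = brentq(mean_p, -20.0, 20.0)
        p = 1.0 / (1.0 + np.exp(-(a + z)))
    miss = rng.random(n) < p
    out.loc[miss, ["postop_eq5d", "postop_oks"]] = np.nan
    return out


def generate_revision_survival(config: GeneratorConfig | None = None,
                               truth: SyntheticTruth | None = None,
                               ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Registry-scale time-to-first-revision cohort.

    Event times are drawn from the two-piece hazard calibrated per brand and
    sex, scaled by proportional effects of centred case-mix covariates, with
    uniform accrual and administrative censoring at the brand's maximum
    observation period.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_revision_cohort

    brands = rng.choice(np.array(cfg.BRANDS), size=n,
                        p=[config.brand_shares[b] for b in cfg.BRANDS])
    df = _draw_case_mix(rng, brands, uniform_case_mix=False)
    df.insert(0, "patient_id", np.arange(n))
    df["antibiotic_cement"] = (rng.random(n) < cfg.ANTIBIOTIC_CEMENT_SHARE).astype(int)
    df["senior_surgeon"] = (rng.random(n) < np.array(
        [cfg.BRAND_SENIOR_SURGEON[b] for b in brands])).astype(int)
    df["treatment_centre"] = (rng.random(n) < np.array(
        [cfg.BRAND_TREATMENT_CENTRE[b] for b in brands])).astype(int)

    coef = dict(cfg.REVISION_TRUTH_COEF)
    means = {
        "age": 70.0, "bmi": float(df["bmi"].mean()),
        "asa3": float((df["asa_grade"] == 3).mean()),
        "patella_replaced": float(df["patella_replaced"].mean()),
        "antibiotic_cement": float(df["antibiotic_cement"].mean()),
        "senior_surgeon": float(df["senior_surgeon"].mean()),
        "treatment_centre": float(df["treatment_centre"].mean()),
    }
    lp = np.zeros(n)
    for name, c in coef.items():
        x = (df["asa_grade"] == 3).astype(float) if name == "asa3" else df[name].astype(float)
        lp += c * (x.to_numpy() - means[name])
    mult = np.exp(lp)

    params = {(b, s): two_piece_rates(*config.brand_hazard_targets[(b, s)])
              for b in cfg.BRANDS for s in SEXES}
    h1 = np.array([params[(b, s)][0] for b, s in zip(df["brand"], df["sex"])]) * mult
    h2 = np.array([params[(b, s)][1] for b, s in zip(df["brand"], df["sex"])]) * mult

    # inverse-transform sampling of the two-piece cumulative hazard
    target = rng.exponential(1.0, n)
    event_time = np.where(target < h1, target / np.maximum(h1, 1e-300),
                          1.0 + (target - h1) / np.maximum(h2, 1e-300))
    max_fu = np.array([cfg.MAX_FOLLOWUP[b] for b in df["brand"]])
    censor = rng.uniform(0.0, max_fu)            # uniform accrual
    censor = np.maximum(censor, 1.0 / 365.0)
    event = event_time <= censor
    df["time_to_event"] = np.where(event, event_time, censor)
    df["event"] = event.astype(int)

    if truth is None:
        _, truth = generate_proms_cohort(
            GeneratorConfig(n_patients=100, seed=config.seed))
    truth.hazard_covariate_means = means
    return df, truth


def generate_rerevision(config: GeneratorConfig | None = None,
                        ) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Time from first revision to re-revision, drawn from a two-piece
    hazard (first year vs later) with uniform administrative censoring."""
    config = config or GeneratorConfig()
    r1, r2 = config.rerevision_rates
    if r1 < 0 or r2 < 0:
        raise ValueError("re-revision rates must be non-negative")
    rng = np.random.default_rng(config.seed + 2)
    n = config.n_rerevision_cohort
    target = rng.exponential(1.0, n)
    with np.errstate(divide="ignore", invalid="ignore"):
        event_time = np.where(
            target < r1, target / max(r1, 1e-300),
            1.0 + (target - r1) / max(r2, 1e-300))
    censor = rng.uniform(1.0 / 365.0, cfg.REREVISION_MAX_FOLLOWUP, n)
    event = event_time <= censor
    df = pd.DataFrame({
        "patient_id": np.arange(n),
        "time_to_event": np.where(event, event_time, censor),
        "event": event.astype(int),
    })
    return df, (r1, r2)


def generate_revision_proms(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """QOL records around revision episodes: pre-operative QOL of revision
    patients (the revision-year state) and 6-month post-revision QOL for the
    subset who responded (the revised-TKR state)."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed + 3)
    n = cfg.N_REVISION_PROMS
    age = _truncated_normal(rng, 71.0, 7.5, 55.0, 90.0, n)
    female = rng.random(n) < 0.57
    rows = {"patient_id": np.arange(n), "age": age,
            "sex": np.where(female, "F", "M")}
    for col, key in (("preop_eq5d", "revision_year"),
                     ("postop_eq5d", "post_revision")):
        p = cfg.STATE_QOL_TRUTH[key]
        # anchor the censoring correction per sex at age 70
        base = {s: latent_mean_for_censored_target(
            p["at70"] + (p["female"] if s == "F" else 0.0), p["sd"])
            for s in SEXES}
        val = (np.where(female, base["F"], base["M"])
               + p["age_slope"] * (age - 70.0) + rng.normal(0.0, p["sd"], n))
        rows[col] = np.clip(val, *cfg.EQ5D_RANGE)
    df = pd.DataFrame(rows)
    responded = rng.permutation(n) < cfg.N_REVISION_PROMS_POSTOP
    df.loc[~responded, "postop_eq5d"] = np.nan
    return df
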