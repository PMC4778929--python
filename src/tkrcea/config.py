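"""Default parameter set and run configuration.

Every calibrated constant of the analysis lives here so the full set of
modelling choices is inspectable (and overridable) in one place: brand
definitions and unit costs, the synthetic-registry generator targets, the
mortality model, and cost-effectiveness settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

# ---------------------------------------------------------------------------
# Brands and unit costs (2011-12 GBP)
# ---------------------------------------------------------------------------

BRANDS: tuple[str, ...] = (
    "PFC Sigma",
    "AGC Biomet",
    "Nexgen",
    "Genesis 2",
    "Triathlon",
)

#: Reference brand for regression contrasts and the ICER ladder base
#: (cheapest prosthesis).
REFERENCE_BRAND = "AGC Biomet"

#: Average prices paid by a mid-size NHS provider, incl. components and
#: instrumentation.
PROSTHESIS_PRICE = {
    "PFC Sigma": 1835.0,
    "AGC Biomet": 1150.0,
    "Nexgen": 1676.0,
    "Genesis 2": 1294.0,
    "Triathlon": 1325.0,
}

THEATRE_COST = 2022.0        # operating theatre, primary TKR
BED_DAY_COST = 332.0         # one hospital bed day
REVISION_EPISODE_COST = 8429.0
DISCOUNT_RATE = 0.035
N_CYCLES = 45

# ---------------------------------------------------------------------------
# Registry-scale case-mix targets (five-brand QOL cohort)
# ---------------------------------------------------------------------------

#: Patient counts per brand in the five-brand QOL sample; shares are taken
#: proportional to these.
BRAND_COUNTS = {
    "PFC Sigma": 13635,
    "AGC Biomet": 5005,
    "Nexgen": 3364,
    "Genesis 2": 4187,
    "Triathlon": 3585,
}

#: Mean age per brand (SD 7.3 for all), truncated to the 55-84 inclusion window.
BRAND_MEAN_AGE = {
    "PFC Sigma": 69.9,
    "AGC Biomet": 70.5,
    "Nexgen": 69.8,
    "Genesis 2": 70.1,
    "Triathlon": 69.9,
}
AGE_SD = 7.3
AGE_RANGE = (55.0, 84.0)

BRAND_MALE_SHARE = {
    "PFC Sigma": 0.45,
    "AGC Biomet": 0.44,
    "Nexgen": 0.45,
    "Genesis 2": 0.44,
    "Triathlon": 0.43,
}

BRAND_MEAN_BMI = {
    "PFC Sigma": 31.3,
    "AGC Biomet": 31.4,
    "Nexgen": 31.4,
    "Genesis 2": 31.3,
    "Triathlon": 31.0,
}
BMI_SD = 5.6

#: Probability of ASA grade 3 (grades 1/2 fill the remainder as 0.13 / rest).
BRAND_ASA3_SHARE = {
    "PFC Sigma": 0.16,
    "AGC Biomet": 0.17,
    "Nexgen": 0.18,
    "Genesis 2": 0.16,
    "Triathlon": 0.18,
}
ASA1_SHARE = 0.13

#: Share in the most-deprived IMD fifth; remaining quintiles uniform.
BRAND_MOST_DEPRIVED = {
    "PFC Sigma": 0.20,
    "AGC Biomet": 0.16,
    "Nexgen": 0.21,
    "Genesis 2": 0.22,
    "Triathlon": 0.23,
}

#: Share with two or more patient-reported comorbidities (comorbidity count
#: drawn Poisson with brand-specific mean matching this tail probability).
BRAND_COMORBID2 = {
    "PFC Sigma": 0.30,
    "AGC Biomet": 0.29,
    "Nexgen": 0.30,
    "Genesis 2": 0.29,
    "Triathlon": 0.28,
}

#: Provider mix: operation at an independent-sector treatment centre and by a
#: senior (consultant) surgeon, by brand.
BRAND_TREATMENT_CENTRE = {
    "PFC Sigma": 0.10,
    "AGC Biomet": 0.02,
    "Nexgen": 0.00,
    "Genesis 2": 0.01,
    "Triathlon": 0.14,
}
BRAND_SENIOR_SURGEON = {
    "PFC Sigma": 0.84,
    "AGC Biomet": 0.79,
    "Nexgen": 0.76,
    "Genesis 2": 0.77,
    "Triathlon": 0.82,
}

BRAND_PREOP_OKS = {
    "PFC Sigma": 18.5,
    "AGC Biomet": 19.0,
    "Nexgen": 18.6,
    "Genesis 2": 19.0,
    "Triathlon": 18.8,
}
PREOP_OKS_SD = 7.6
OKS_RANGE = (0.0, 48.0)

BRAND_PREOP_EQ5D = {
    "PFC Sigma": 0.38,
    "AGC Biomet": 0.41,
    "Nexgen": 0.39,
    "Genesis 2": 0.41,
    "Triathlon": 0.40,
}
PREOP_EQ5D_SD = 0.31
EQ5D_RANGE = (-0.594, 1.0)

PATELLA_SHARE = 0.33
DISABILITY_SHARE = 0.20
SURGICAL_POSITION_SHARE = 0.15
ANTIBIOTIC_CEMENT_SHARE = 0.90

# ---------------------------------------------------------------------------
# Outcome truth: case-mix-adjusted 6-month EQ-5D / OKS and length of stay
# ---------------------------------------------------------------------------

#: Brand effects on 6-month EQ-5D index relative to the AGC Biomet reference;
#: with all other covariates at subgroup means these reproduce the adjusted
#: brand means for men aged 70 (0.73/0.72/0.74/0.71/0.72).
BRAND_EQ5D_OFFSET = {
    "PFC Sigma": 0.01,
    "AGC Biomet": 0.00,
    "Nexgen": 0.02,
    "Genesis 2": -0.01,
    "Triathlon": 0.00,
}
POSTOP_EQ5D_MEN70 = 0.72          # AGC Biomet, men aged 70
POSTOP_EQ5D_FEMALE = -0.01        # additive female effect

BRAND_OKS_OFFSET = {
    "PFC Sigma": 0.0,
    "AGC Biomet": 0.0,
    "Nexgen": 0.6,
    "Genesis 2": -1.2,
    "Triathlon": -0.1,
}
POSTOP_OKS_MEN70 = 35.4
POSTOP_OKS_FEMALE = -1.6
POSTOP_OKS_SD = 8.0

#: Residual SD of the 6-month EQ-5D index after case-mix adjustment.
#: Calibrated so the OLS brand-contrast SE at registry scale (n = 53 126,
#: Table-1 brand shares) is ~0.004-0.005, matching the precision a national
#: PROMs sample yields.
POSTOP_EQ5D_SD = 0.25

#: Covariate effects in the outcome-generating linear predictor (all covariates
#: centred at population means, so subgroup means above are exact at the means).
QOL_TRUTH_COEF = {
    "age": -0.0015,        # per year from 70
    "bmi": -0.002,         # per kg/m^2 from mean
    "comorbidity_count": -0.02,
    "asa3": -0.03,
    "imd_quintile": -0.005,  # per quintile from mean
    "disability": -0.05,
    "patella_replaced": 0.0,
    "surgical_position": 0.0,
    "preop_eq5d": 0.25,    # per index unit from mean
    "preop_oks": 0.003,    # per point from mean
    "senior_surgeon": 0.01,
    "treatment_centre": 0.02,
}

#: Mean length of stay (days) by brand and sex. Back-computed from the printed
#: mean primary-episode costs: LOS = (cost - price - theatre) / bed-day.
LOS_MEAN = {
    ("PFC Sigma", "M"): 4.690, ("PFC Sigma", "F"): 4.922,
    ("AGC Biomet", "M"): 4.223, ("AGC Biomet", "F"): 4.455,
    ("Nexgen", "M"): 4.623, ("Nexgen", "F"): 4.858,
    ("Genesis 2", "M"): 5.762, ("Genesis 2", "F"): 5.994,
    ("Triathlon", "M"): 5.232, ("Triathlon", "F"): 5.232,
}
LOS_SD = 2.5

#: Health-state utilities around a revision episode (age 70; linear in age,
#: additive female effect).
STATE_QOL_TRUTH = {
    "revision_year": {"at70": 0.45, "age_slope": -0.003, "female": -0.01, "sd": 0.30},
    "post_revision": {"at70": 0.62, "age_slope": -0.003, "female": -0.01, "sd": 0.27},
}
N_REVISION_PROMS = 6128       # revision episodes with pre-operative QOL
N_REVISION_PROMS_POSTOP = 3912  # of which responded six months after revision

MISSING_POSTOP_RATE = 0.17

# ---------------------------------------------------------------------------
# Revision survival truth
# ---------------------------------------------------------------------------

#: Adjusted cumulative revision probabilities at 5 and 10 years by brand and
#: sex (age 70, other covariates at means). The generating hazard is two-piece
#: (year 1 vs later) solved exactly to these targets.
REVISION_TARGETS = {
    ("PFC Sigma", "M"): (0.021, 0.031), ("PFC Sigma", "F"): (0.016, 0.025),
    ("AGC Biomet", "M"): (0.028, 0.042), ("AGC Biomet", "F"): (0.022, 0.033),
    ("Nexgen", "M"): (0.021, 0.031), ("Nexgen", "F"): (0.016, 0.025),
    ("Genesis 2", "M"): (0.024, 0.037), ("Genesis 2", "F"): (0.019, 0.029),
    ("Triathlon", "M"): (0.025, 0.038), ("Triathlon", "F"): (0.020, 0.030),
}

#: Maximum observation period (years) by brand. The extremes are known
#: (PFC Sigma longest at 11.1 y, Triathlon shortest at 6.7 y); the middle
#: brands are interpolated package defaults.
MAX_FOLLOWUP = {
    "PFC Sigma": 11.1,
    "AGC Biomet": 10.5,
    "Nexgen": 9.5,
    "Genesis 2": 8.5,
    "Triathlon": 6.7,
}

#: Covariate log-hazard-ratios in the revision truth (covariates centred, so
#: the brand x sex calibration above is exact at age 70 / covariate means).
REVISION_TRUTH_COEF = {
    "age": 0.02,          # per year from 70
    "bmi": 0.01,          # per kg/m^2 from mean
    "asa3": 0.30,
    "patella_replaced": 0.0,
    "antibiotic_cement": -0.10,
    "senior_surgeon": 0.0,
    "treatment_centre": 0.0,
}

N_REVISION_COHORT = 239_945

#: Re-revision hazard truth: rate in the first year after revision vs all
#: subsequent years (per person-year).
REREVISION_RATES = (0.04, 0.015)
N_REREVISION_COHORT = 54_134
REREVISION_MAX_FOLLOWUP = 15.0

# ---------------------------------------------------------------------------
# Mortality
# ---------------------------------------------------------------------------

OPERATIVE_MORTALITY = 0.002   # brand-independent

#: Gompertz life-table parameters q(a) = 1 - exp(-B e^(theta a)), calibrated so
#: remaining life expectancy at 70 is 14 y (men) / 16 y (women).
GOMPERTZ_THETA = 0.095
GOMPERTZ_B = {"M": 3.278301e-05, "F": 2.483900e-05}
LIFETABLE_MAX_AGE = 110

#: Healthy-patient effect: initial relative risk RR0(a) = 1 - 0.7 (a-40)/40,
#: clamped to [0.3, 1] (RR0(80) = 0.3); decays as
#: RR(t) = 1 - (1-RR0) exp(-t/tau) with tau chosen so RR(10) >= 0.99.
HEALTHY_PATIENT_TAU = 2.35

#: Annual quality-of-life decline from aging: 0.004 at age 70, growing as age^2.
AGING_DECLINE_KAPPA = 0.004 / 70.0**2

# ---------------------------------------------------------------------------
# CEA settings
# ---------------------------------------------------------------------------

N_PSA = 1000
WTP_GRID = tuple(float(x) for x in range(0, 50_001, 500))
WTP_REFERENCE = 20_000.0
SUBGROUP_AGES = (60, 70, 80)
SEXES = ("M", "F")
MEAN_PROSTHESIS_PRICE = round(sum(PROSTHESIS_PRICE.values()) / 5.0)  # scenario 5


def brand_shares() -> dict[str, float]:
    total = sum(BRAND_COUNTS.values())
    return {b: BRAND_COUNTS[b] / total for b in BRANDS}


@dataclass
class GeneratorConfig:
    """Configuration for the synthetic registry generator.

    Defaults reproduce the registry-scale study conditions: five brand groups
    with near-identical case mix, brand effects on 6-month EQ-5D of order
    0.01-0.04, brand-specific revision hazards hitting the printed 5- and
    10-year cumulative rates, and 17% missing post-operative outcomes.
    """

    n_patients: int = 53_126
    brand_shares: dict[str, float] = field(default_factory=brand_shares)
    brand_utility_effects: dict[str, float] = field(
        default_factory=lambda: dict(BRAND_EQ5D_OFFSET))
    brand_hazard_targets: dict = field(
        default_factory=lambda: dict(REVISION_TARGETS))
    missing_postop_rate: float = MISSING_POSTOP_RATE
    missing_mechanism: str = "MAR"
    postop_eq5d_sd: float = POSTOP_EQ5D_SD
    n_revision_cohort: int = N_REVISION_COHORT
    n_rerevision_cohort: int = N_REREVISION_COHORT
    rerevision_rates: tuple[float, float] = REREVISION_RATES
    n_hospitals: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        total = sum(self.brand_shares.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"brand shares sum to {total}, expected 1")
        if not 0.0 <= self.missing_postop_rate <= 1.0:
            raise ValueError("missing_postop_rate must be in [0, 1]")
        for b, off in self.brand_utility_effects.items():
            if not -1.0 <= off <= 1.0:
                raise ValueError(f"utility offset for {b} outside [-1, 1]")
        for key, (p5, p10) in self.brand_hazard_targets.items():
            if p10 >= 1.0 or p5 >= 1.0:
                raise ValueError(f"cumulative incidence target >= 1 for {key}")
            if p10 < p5:
                raise ValueError(f"10-y target below 5-y target for {key}")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (simulate -> fit -> evaluate)."""

    outdir: str = "results"
    seed: int = 0
    n_psa: int = N_PSA
    subgroup_ages: Sequence[int] = SUBGROUP_AGES
    sexes: Sequence[str] = SEXES
    scenario: int | None = None          # None = base case; 1..5 otherwise
    wtp_reference: float = WTP_REFERENCE
    m_imputations: int = 20
    mice_iterations: int = 10
    discount_rate: float = DISCOUNT_RATE
    operative_mortality: float = OPERATIVE_MORTALITY
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        gen = raw.pop("generator", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "generator"})
        if gen:
            gkwargs = {**asdict(cfg.generator), **gen}
            # tuples serialize as lists in YAML
            if "rerevision_rates" in gkwargs:
                gkwargs["rerevision_rates"] = tuple(gkwargs["rerevision_rates"])
            if "brand_hazard_targets" in gkwargs:
                gkwargs["brand_hazard_targets"] = {
                    k if isinstance(k, tuple) else tuple(k): tuple(v)
                    for k, v in gkwargs["brand_hazard_targets"].items()
                }
            cfg.generator = GeneratorConfig(**gkwargs)
        if cfg.scenario is not None and cfg.scenario not in (1, 2, 3, 4, 5):
            raise ValueError(f"unknown scenario id: {cfg.scenario}")
        cfg.generator.seed = cfg.seed
        return cfg

    def to_manifest(self) -> dict:
        """Serializable record of every parameter for the run manifest."""
        d = asdict(self)
        gen = d["generator"]
        gen["brand_hazard_targets"] = {
            "|".join(k): list(v) for k, v in gen["brand_hazard_targets"].items()
        }
        return d


def two_piece_rates(p5: float, p10: float) -> tuple[float, float]:
    """Solve the two-piece hazard (year 1 vs later) hitting cumulative
    incidence ``p5`` at 5 years and ``p10`` at 10 years exactly.

    H(t) = h1 min(t,1) + h2 max(t-1, 0); CI(t) = 1 - exp(-H(t)).
    """
    if not 0.0 <= p5 <= p10 < 1.0:
        raise ValueError("targets must satisfy 0 <= p5 <= p10 < 1")
    h5 = -np.log1p(-p5)
    h10 = -np.log1p(-p10)
    h2 = (h10 - h5) / 5.0
    h1 = h5 - 4.0 * h2
    if h1 < 0:
        raise ValueError("targets imply a negative first-year rate")
    return float(h1), float(h2)
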