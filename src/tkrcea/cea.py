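"""Cost-effectiveness layer: PSA, dominance ladder, NMB, frontiers, scenarios.

Probabilistic sensitivity analysis propagates parameter-sampling uncertainty
(multivariate-normal coefficient draws, log-normal rates) through the Markov
engine for every brand, sharing draws within a simulation. Mean lifetime
costs and QALYs feed the incremental cost-effectiveness ladder (with simple
and extended dominance); net monetary benefit across willingness-to-pay
values yields the acceptability frontier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import config as cfg
from .config import RunConfig
from .markov import run_cohort
from .pipeline import (FittedModels, SimulatedData, build_draw_inputs,
                       build_point_inputs, fit_piecewise_revision_models)
from .qol import fit_postop_qol

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Net monetary benefit
# ---------------------------------------------------------------------------

def nmb(qalys, cost, wtp):
    """Net monetary benefit: wtp x QALYs - cost."""
    if np.any(np.asarray(wtp) < 0):
        raise ValueError("willingness-to-pay must be non-negative")
    return np.asarray(wtp, dtype=float) * np.asarray(qalys, dtype=float) \
        - np.asarray(cost, dtype=float)


# ---------------------------------------------------------------------------
# PSA
# ---------------------------------------------------------------------------

@dataclass
class PSAResult:
    """Per-draw lifetime results for every brand in one subgroup."""

    sex: str
    age: int
    qalys: pd.DataFrame        # n_sims x brands
    costs: pd.DataFrame
    proportion_revised: pd.DataFrame

    @property
    def n_sims(self) -> int:
        return len(self.qalys)

    def mean_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "brand": list(self.qalys.columns),
            "qalys": self.qalys.mean().to_numpy(),
            "cost": self.costs.mean().to_numpy(),
            "proportion_revised": self.proportion_revised.mean().to_numpy(),
        })

    def probability_highest_nmb(self, wtp: float) -> pd.Series:
        """Fraction of draws in which each brand attains the maximal NMB
        (ties resolved to the first brand in column order)."""
        b = nmb(self.qalys.to_numpy(), self.costs.to_numpy(), wtp)
        winners = np.argmax(b, axis=1)
        counts = np.bincount(winners, minlength=b.shape[1])
        return pd.Series(counts / b.shape[0], index=self.qalys.columns)


def run_psa(models: FittedModels, sex: str, age: int,
            n_sims: int = cfg.N_PSA, seed: int | np.random.Generator = 0,
            run: RunConfig | None = None, **build_kwargs) -> PSAResult:
    """Sample every uncertain parameter and propagate each draw through the
    cohort model for all brands."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    inputs = build_draw_inputs(models, sex, age, n_sims, rng, run=run,
                               **build_kwargs)
    qalys, costs, prev = {}, {}, {}
    for brand, inp in inputs.items():
        _, res = run_cohort(inp)
        qalys[brand] = res.qalys
        costs[brand] = res.cost
        prev[brand] = res.proportion_revised
    return PSAResult(sex, age,
                     pd.DataFrame(qalys, columns=list(cfg.BRANDS)),
                     pd.DataFrame(costs, columns=list(cfg.BRANDS)),
                     pd.DataFrame(prev, columns=list(cfg.BRANDS)))


# ---------------------------------------------------------------------------
# ICER ladder with simple and extended dominance
# ---------------------------------------------------------------------------

def icer_ladder(means: pd.DataFrame, wtp: float = cfg.WTP_REFERENCE
                ) -> pd.DataFrame:
    """Rank brands by mean cost and compute the incremental ladder.

    A brand is (simply) dominated if another option has no higher cost and no
    fewer QALYs; extendedly dominated if excluded by the convex frontier.
    ICERs are reported between successive frontier members; the cheapest
    non-dominated brand is the base. Ties in both cost and QALYs are broken
    by brand name order (logged).
    """
    req = {"brand", "cost", "qalys"}
    if not req <= set(means.columns) or len(means) < 2:
        raise ValueError("need >= 2 brands with columns brand, cost, qalys")
    df = means.copy()
    dup = df.duplicated(subset=["cost", "qalys"], keep=False)
    if dup.any():
        log.info("cost/QALY ties broken by brand name order: %s",
                 sorted(df.loc[dup, "brand"]))
    df = df.sort_values(["cost", "qalys", "brand"],
                        ascending=[True, False, True]).reset_index(drop=True)

    status = {}
    for i, row in df.iterrows():
        dominated = ((df["cost"] <= row["cost"]) & (df["qalys"] >= row["qalys"])
                     & ((df["cost"] < row["cost"]) | (df["qalys"] > row["qalys"])))
        # exact cost/QALY ties: keep the first brand by name order
        tied = ((df["cost"] == row["cost"]) & (df["qalys"] == row["qalys"])
                & (df["brand"] < row["brand"]))
        status[row["brand"]] = "dominated" if (dominated | tied).any() else None

    frontier = [b for b in df["brand"] if status[b] is None]
    # extended dominance: prune until ICERs increase along the frontier
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        sub = df[df["brand"].isin(frontier)].reset_index(drop=True)
        icers = (sub["cost"].diff() / sub["qalys"].diff()).to_numpy()
        for i in range(1, len(sub) - 1):
            if icers[i + 1] < icers[i]:
                status[sub.loc[i, "brand"]] = "extendedly dominated"
                frontier.remove(sub.loc[i, "brand"])
                changed = True
                break

    icer_map = {frontier[0]: "base"}
    sub = df[df["brand"].isin(frontier)].reset_index(drop=True)
    for i in range(1, len(sub)):
        d_c = sub.loc[i, "cost"] - sub.loc[i - 1, "cost"]
        d_q = sub.loc[i, "qalys"] - sub.loc[i - 1, "qalys"]
        icer_map[sub.loc[i, "brand"]] = d_c / d_q

    df["nmb"] = nmb(df["qalys"].to_numpy(), df["cost"].to_numpy(), wtp)
    df["status"] = [status[b] or ("base" if icer_map.get(b) == "base"
                                  else "nondominated") for b in df["brand"]]
    df["icer"] = [icer_map.get(b, np.nan) if status[b] is None else np.nan
                  for b in df["brand"]]
    df.loc[df["status"] == "base", "icer"] = np.nan
    return df


# ---------------------------------------------------------------------------
# Acceptability frontier
# ---------------------------------------------------------------------------

def acceptability_frontier(psa: PSAResult,
                           wtp_grid=cfg.WTP_GRID) -> pd.DataFrame:
    """For each willingness-to-pay value: the brand with the highest mean NMB
    and the proportion of simulations in which that brand's NMB is maximal."""
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    Q = psa.qalys.to_numpy()
    C = psa.costs.to_numpy()
    brands = list(psa.qalys.columns)
    rows = []
    for lam in wtp_grid:
        b = lam * Q - C
        mean_b = b.mean(axis=0)
        j = int(np.argmax(mean_b))
        winners = np.argmax(b, axis=1)
        rows.append({"wtp": lam, "brand": brands[j],
                     "mean_nmb": mean_b[j],
                     "probability": float(np.mean(winners == j))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Subgroup evaluation and scenarios
# ---------------------------------------------------------------------------

@dataclass
class SubgroupResult:
    sex: str
    age: int
    point_table: pd.DataFrame      # deterministic ladder from point estimates
    psa_table: pd.DataFrame        # ladder on PSA means
    frontier: pd.DataFrame
    p_best: pd.Series              # P(highest NMB) at the reference threshold
    psa: PSAResult


def evaluate_subgroup(models: FittedModels, sex: str, age: int,
                      run: RunConfig | None = None,
                      seed: int | np.random.Generator = 0,
                      **build_kwargs) -> SubgroupResult:
    run = run or RunConfig()
    point = []
    for b in cfg.BRANDS:
        inp = build_point_inputs(
            models, b, sex, age, run=run,
            price_override=build_kwargs.get("price_override"),
            use_piecewise_revision=build_kwargs.get("use_piecewise_revision",
                                                    False))
        _, res = run_cohort(inp)
        point.append({"brand": b, "cost": res.cost, "qalys": res.qalys,
                      "proportion_revised": res.proportion_revised})
    point_table = icer_ladder(pd.DataFrame(point), wtp=run.wtp_reference)

    psa = run_psa(models, sex, age, n_sims=run.n_psa, seed=seed, run=run,
                  **build_kwargs)
    psa_table = icer_ladder(psa.mean_table(), wtp=run.wtp_reference)
    frontier = acceptability_frontier(psa)
    p_best = psa.probability_highest_nmb(run.wtp_reference)
    return SubgroupResult(sex, age, point_table, psa_table, frontier,
                          p_best, psa)


def run_scenario(scenario_id: int, data: SimulatedData, models: FittedModels,
                 sex: str, age: int, run: RunConfig | None = None,
                 seed: int | np.random.Generator = 0) -> SubgroupResult:
    """Re-run one subgroup under a sensitivity-analysis assumption.

    1. brand differences in post-operative QOL last one year only;
    2. brand x age and brand x sex interactions in the QOL regression;
    3. pre-operative QOL entered as categorical bins instead of linearly;
    4. piecewise-constant revision hazard instead of the spline;
    5. the same (average) prosthesis price for every brand.
    """
    run = run or RunConfig()
    kw: dict = {}
    if scenario_id == 1:
        kw["equalize_qol_after_year1"] = True
    elif scenario_id == 2:
        if models.qol_interactions is None:
            datasets = _imputed_datasets(data, run)
            models.qol_interactions = fit_postop_qol(
                datasets, brand_interactions=True)
        kw["qol_model"] = models.qol_interactions
    elif scenario_id == 3:
        if models.qol_categorical is None:
            datasets = _imputed_datasets(data, run)
            models.qol_categorical = fit_postop_qol(
                datasets, preop_categorical=True,
                fp_covariates=("age", "bmi", "preop_oks"))
        kw["qol_model"] = models.qol_categorical
    elif scenario_id == 4:
        if not models.revision_piecewise:
            models.revision_piecewise = fit_piecewise_revision_models(
                data.revisions)
        kw["use_piecewise_revision"] = True
    elif scenario_id == 5:
        kw["price_override"] = float(cfg.MEAN_PROSTHESIS_PRICE)
    else:
        raise ValueError(f"unknown scenario id: {scenario_id}")

    equalize = kw.pop("equalize_qol_after_year1", False)
    if not equalize:
        return evaluate_subgroup(models, sex, age, run=run, seed=seed, **kw)
    return _evaluate_equalized_qol(models, sex, age, run, seed, **kw)


def _imputed_datasets(data: SimulatedData, run: RunConfig):
    from .impute import impute_chained
    if data.proms["postop_eq5d"].isna().any():
        return list(impute_chained(data.proms, m=run.m_imputations,
                                   seed=run.seed + 11,
                                   n_iter=run.mice_iterations))
    return [data.proms]


def _evaluate_equalized_qol(models: FittedModels, sex: str, age: int,
                            run: RunConfig, seed, **kw) -> SubgroupResult:
    """Scenario 1: brand-specific primary utility in the surgery year only;
    from cycle 1 on, every brand uses the across-brand mean utility."""
    from .markov import run_cohort as _run

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    # Point estimates
    point_inputs = {b: build_point_inputs(models, b, sex, age, run=run)
                    for b in cfg.BRANDS}
    mean_u = float(np.mean([i.utility_primary for i in point_inputs.values()]))
    point = []
    for b, inp in point_inputs.items():
        inp.utility_primary_later = mean_u
        _, res = _run(inp)
        point.append({"brand": b, "cost": res.cost, "qalys": res.qalys,
                      "proportion_revised": res.proportion_revised})
    point_table = icer_ladder(pd.DataFrame(point), wtp=run.wtp_reference)

    from .pipeline import build_draw_inputs as _bdi
    inputs = _bdi(models, sex, age, run.n_psa, rng, run=run, **kw)
    mean_u_draws = np.mean([inputs[b].utility_primary for b in cfg.BRANDS],
                           axis=0)
    qalys, costs, prev = {}, {}, {}
    for b, inp in inputs.items():
        inp.utility_primary_later = mean_u_draws
        _, res = _run(inp)
        qalys[b], costs[b], prev[b] = res.qalys, res.cost, res.proportion_revised
    psa = PSAResult(sex, age, pd.DataFrame(qalys, columns=list(cfg.BRANDS)),
                    pd.DataFrame(costs, columns=list(cfg.BRANDS)),
                    pd.DataFrame(prev, columns=list(cfg.BRANDS)))
    psa_table = icer_ladder(psa.mean_table(), wtp=run.wtp_reference)
    return SubgroupResult(sex, age, point_table, psa_table,
                          acceptability_frontier(psa),
                          psa.probability_highest_nmb(run.wtp_reference), psa)
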