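"""Four-state annual-cycle Markov cohort engine.

States: intact primary prosthesis (PostTKR), the year in which a revision is
performed (RevisionYear, occupied for exactly one cycle), the revised
prosthesis (PostRevision, from which re-revision returns the patient to
RevisionYear), and Dead (absorbing). The cohort enters at surgery, faces
operative mortality in cycle 0, then 44 further annual cycles applying, in
order, background mortality (healthy-patient-adjusted) and revision
transitions among survivors. QALYs apply each state's utility (reduced by the
aging decline) and both QALYs and costs are discounted at 3.5% a year. No
half-cycle correction is applied, so the arithmetic is reproducible exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import config as cfg
from .mortality import LifeTable, HealthyPatientEffect, adjusted_mortality
from .qol import aging_decline

POSTTKR, REVISION, POSTREV, DEAD = 0, 1, 2, 3
STATE_NAMES = ("PostTKR", "RevisionYear", "PostRevision", "Dead")


def mortality_schedule(age_at_surgery: float, sex: str,
                       life_table: LifeTable | None = None,
                       effect: HealthyPatientEffect | None = None,
                       n_cycles: int = cfg.N_CYCLES) -> np.ndarray:
    """Adjusted annual death probability at each cycle 1..n_cycles-1."""
    lt = life_table or LifeTable()
    eff = effect or HealthyPatientEffect()
    return np.array([adjusted_mortality(lt, eff, age_at_surgery, sex, t)
                     for t in range(1, n_cycles)])


@dataclass
class ModelInputs:
    """Complete parameter set for one brand x subgroup cohort run.

    Probability inputs may carry a leading draw dimension (probabilistic
    analysis); the engine broadcasts.
    """

    brand: str
    sex: str
    age_at_surgery: float
    utility_primary: float | np.ndarray
    utility_revision_year: float | np.ndarray
    utility_post_revision: float | np.ndarray
    p_revision: np.ndarray              # (45,) or (ndraws, 45)
    p_rerevision_year1: float | np.ndarray
    p_rerevision_later: float | np.ndarray
    mortality: np.ndarray               # (44,) adjusted q for cycles 1..44
    operative_mortality: float = cfg.OPERATIVE_MORTALITY
    prosthesis_price: float = 0.0
    theatre_cost: float = cfg.THEATRE_COST
    bed_day_cost: float = cfg.BED_DAY_COST
    los_days: float | np.ndarray = 0.0
    revision_cost: float = cfg.REVISION_EPISODE_COST
    discount_rate: float = cfg.DISCOUNT_RATE
    n_cycles: int = cfg.N_CYCLES
    aging_kappa: float = cfg.AGING_DECLINE_KAPPA
    utility_floor: float = cfg.EQ5D_RANGE[0]
    #: Primary-state utility from cycle 1 onward; None means the brand's own
    #: utility persists (scenario analysis can set the across-brand mean here).
    utility_primary_later: float | np.ndarray | None = None

    def validate(self) -> None:
        for name in ("utility_primary", "utility_revision_year",
                     "utility_post_revision"):
            if np.any(np.asarray(getattr(self, name)) > 1.0):
                raise ValueError(f"{name} exceeds 1")
        for name in ("p_revision", "p_rerevision_year1", "p_rerevision_later",
                     "mortality"):
            v = np.asarray(getattr(self, name))
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{name} outside [0, 1]")
        if not 0.0 <= self.operative_mortality <= 1.0:
            raise ValueError("operative mortality outside [0, 1]")
        if np.any(np.asarray(self.los_days) < 0):
            raise ValueError("negative length of stay")
        for name in ("prosthesis_price", "theatre_cost", "bed_day_cost",
                     "revision_cost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} is negative")


@dataclass
class CohortTrace:
    """State occupancy and discounted increments per cycle."""

    occupancy: np.ndarray          # (..., n_cycles, 4); sums to 1 per cycle
    qaly_increments: np.ndarray    # (..., n_cycles)
    cost_increments: np.ndarray    # (..., n_cycles)
    first_revision_inflow: np.ndarray  # (..., n_cycles) mass newly revised from PostTKR
    states: tuple[str, ...] = STATE_NAMES


@dataclass
class LifetimeResult:
    qalys: float | np.ndarray
    cost: float | np.ndarray
    proportion_revised: float | np.ndarray


def initial_cost(inputs: ModelInputs) -> float | np.ndarray:
    """Primary episode cost: prosthesis price + theatre + LOS x bed-day."""
    if np.any(np.asarray(inputs.los_days) < 0):
        raise ValueError("negative length of stay")
    return (inputs.prosthesis_price + inputs.theatre_cost
            + np.asarray(inputs.los_days, dtype=float) * inputs.bed_day_cost)


def run_cohort(inputs: ModelInputs) -> tuple[CohortTrace, LifetimeResult]:
    """Propagate the cohort over ``n_cycles`` annual cycles (t = 0 .. n-1).

    Cycle 0 applies operative mortality and the initial cost. Each later
    cycle applies death first, then revision transitions among survivors:
    PostTKR -> RevisionYear with the year-t first-revision probability;
    RevisionYear occupants either suffer an early re-revision (year-1
    piecewise probability, staying in RevisionYear) or move to PostRevision;
    PostRevision returns to RevisionYear with the later re-revision
    probability. Each entry to RevisionYear incurs the revision episode cost.
    """
    inputs.validate()
    n = inputs.n_cycles
    p_rev = np.asarray(inputs.p_revision, dtype=float)
    if p_rev.shape[-1] < n - 1:
        raise ValueError("p_revision must cover n_cycles - 1 transitions")
    batch = np.broadcast_shapes(
        p_rev.shape[:-1],
        np.shape(inputs.utility_primary),
        np.shape(inputs.p_rerevision_year1),
        np.shape(inputs.p_rerevision_later),
        np.shape(inputs.los_days),
    )

    u_pri = np.broadcast_to(np.asarray(inputs.utility_primary, float), batch).copy()
    u_pri_later = u_pri if inputs.utility_primary_later is None else \
        np.broadcast_to(np.asarray(inputs.utility_primary_later, float), batch).copy()
    u_rev = np.broadcast_to(np.asarray(inputs.utility_revision_year, float), batch).copy()
    u_post = np.broadcast_to(np.asarray(inputs.utility_post_revision, float), batch).copy()
    r1 = np.broadcast_to(np.asarray(inputs.p_rerevision_year1, float), batch)
    r2 = np.broadcast_to(np.asarray(inputs.p_rerevision_later, float), batch)

    occ = np.zeros(batch + (n, 4))
    qaly = np.zeros(batch + (n,))
    cost = np.zeros(batch + (n,))
    first_inflow = np.zeros(batch + (n,))

    om = inputs.operative_mortality
    s0 = np.full(batch, 1.0 - om)
    s1 = np.zeros(batch)
    s2 = np.zeros(batch)
    dead = np.full(batch, om)

    floor = inputs.utility_floor
    disc = 1.0 + inputs.discount_rate

    occ[..., 0, POSTTKR] = s0
    occ[..., 0, DEAD] = dead
    qaly[..., 0] = s0 * np.maximum(u_pri, floor)
    cost[..., 0] = np.broadcast_to(initial_cost(inputs), batch)

    decline = 0.0
    age0 = inputs.age_at_surgery
    for t in range(1, n):
        q = inputs.mortality[t - 1]
        s0, s1, s2 = s0 * (1 - q), s1 * (1 - q), s2 * (1 - q)
        dead = 1.0 - s0 - s1 - s2

        new_first = s0 * p_rev[..., t - 1]
        re_early = s1 * r1
        re_late = s2 * r2
        new_rev = new_first + re_early + re_late
        s2 = s2 - re_late + (s1 - re_early)
        s0 = s0 - new_first
        s1 = new_rev

        decline += aging_decline(age0 + t, inputs.aging_kappa)
        df = disc ** (-t)
        occ[..., t, POSTTKR] = s0
        occ[..., t, REVISION] = s1
        occ[..., t, POSTREV] = s2
        occ[..., t, DEAD] = dead
        first_inflow[..., t] = new_first
        qaly[..., t] = df * (
            s0 * np.maximum(u_pri_later - decline, floor)
            + s1 * np.maximum(u_rev - decline, floor)
            + s2 * np.maximum(u_post - decline, floor))
        cost[..., t] = df * inputs.revision_cost * new_rev

    trace = CohortTrace(occ, qaly, cost, first_inflow)
    result = LifetimeResult(
        qalys=qaly.sum(axis=-1) if batch else float(qaly.sum()),
        cost=cost.sum(axis=-1) if batch else float(cost.sum()),
        proportion_revised=(first_inflow.sum(axis=-1) if batch
                            else float(first_inflow.sum())),
    )
    return trace, result


def lifetime_proportion_revised(trace: CohortTrace) -> float | np.ndarray:
    """Cumulative cohort mass ever entering RevisionYear from PostTKR."""
    s = trace.first_revision_inflow.sum(axis=-1)
    return float(s) if np.ndim(s) == 0 else s
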