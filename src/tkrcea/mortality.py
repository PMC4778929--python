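"""Mortality inputs for the cohort model.

Background mortality comes from a sex-specific life table (a calibrated
Gompertz law by default, or any CSV table with columns age, sex, qx), and is
adjusted for the healthy-patient effect: patients fit for elective joint
replacement die at a lower rate than the general population immediately after
surgery, an advantage that decays exponentially over about a decade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import config as cfg


class LifeTable:
    """Annual death probability q(age, sex) for ages 55-110.

    The default is the Gompertz law q(a) = 1 - exp(-B e^(theta a)) with
    sex-specific B calibrated so remaining life expectancy at 70 is about
    14 years for men and 16 for women. q at the terminal age (110) is 1.
    """

    def __init__(self, table: pd.DataFrame | None = None):
        if table is None:
            ages = np.arange(55, cfg.LIFETABLE_MAX_AGE + 1)
            rows = []
            for sex in ("M", "F"):
                q = 1.0 - np.exp(-cfg.GOMPERTZ_B[sex]
                                 * np.exp(cfg.GOMPERTZ_THETA * ages))
                rows.append(pd.DataFrame({"age": ages, "sex": sex, "qx": q}))
            table = pd.concat(rows, ignore_index=True)
        table = table.copy()
        if not {"age", "sex", "qx"} <= set(table.columns):
            raise ValueError("life table needs columns age, sex, qx")
        if ((table["qx"] < 0) | (table["qx"] > 1)).any():
            raise ValueError("qx outside [0, 1]")
        table.loc[table["age"] >= cfg.LIFETABLE_MAX_AGE, "qx"] = 1.0
        self._q = {(int(a), s): float(q) for a, s, q in
                   zip(table["age"], table["sex"], table["qx"])}
        self.min_age = int(table["age"].min())

    @classmethod
    def from_csv(cls, path: str) -> "LifeTable":
        return cls(pd.read_csv(path))

    def q(self, age: float, sex: str) -> float:
        a = int(round(age))
        if a >= cfg.LIFETABLE_MAX_AGE:
            return 1.0
        if a < self.min_age:
            raise ValueError(f"age {a} below life-table start ({self.min_age})")
        return self._q[(a, sex)]

    def life_expectancy(self, age: int, sex: str) -> float:
        """Expected remaining years (half-year convention)."""
        ages = np.arange(age, cfg.LIFETABLE_MAX_AGE + 1)
        q = np.array([self.q(a, sex) for a in ages])
        return float(np.cumprod(1.0 - q).sum()) + 0.5


@dataclass
class HealthyPatientEffect:
    """Initial relative risk of death and its exponential decay to 1.

    RR0(a) = 1 - slope (a - 40)/40 clamped to [rr_floor, 1] — anchored so a
    man aged 80 has RR0 = 0.3 in the year after surgery — and
    RR(t) = 1 - (1 - RR0) exp(-t / tau), reaching ~1 within a decade.
    """

    tau: float = cfg.HEALTHY_PATIENT_TAU
    slope: float = 0.7
    rr_floor: float = 0.3

    def rr0(self, age_at_surgery: float) -> float:
        rr = 1.0 - self.slope * (age_at_surgery - 40.0) / 40.0
        return float(np.clip(rr, self.rr_floor, 1.0))

    def rr(self, years_since_surgery, age_at_surgery: float):
        t = np.asarray(years_since_surgery, dtype=float)
        out = 1.0 - (1.0 - self.rr0(age_at_surgery)) * np.exp(-t / self.tau)
        return out if out.ndim else float(out)


def adjusted_mortality(life_table: LifeTable, effect: HealthyPatientEffect,
                       age_at_surgery: float, sex: str,
                       years_since_surgery: float) -> float:
    """q(age_at_surgery + t, sex) x RR(t), capped to [0, 1]."""
    t = years_since_surgery
    q = life_table.q(age_at_surgery + t, sex)
    return float(np.clip(q * effect.rr(t, age_at_surgery), 0.0, 1.0))


def operative_mortality(brand: str | None = None,
                        value: float = cfg.OPERATIVE_MORTALITY) -> float:
    """Immediate post-operative death probability; identical for every brand
    (no across-brand difference is modelled)."""
    if not 0.0 <= value <= 1.0:
        raise ValueError("operative mortality must be a probability")
    return value
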