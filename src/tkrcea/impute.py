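"""Multiple imputation by chained equations.

Missing pre- and post-operative responses are imputed with chained equations
(predictive mean matching within `statsmodels`' MICE machinery) on a numeric
encoding of the cohort; twenty completed datasets are produced by default and
downstream estimates are pooled with Rubin's rules (`tkrcea.qol.pool_rubin`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.imputation.mice import MICEData

from . import config as cfg

log = logging.getLogger(__name__)

#: Predictors entering every imputation model (numeric encoding).
_PREDICTORS = (
    "age", "bmi", "comorbidity_count", "imd_quintile", "preop_eq5d",
    "preop_oks", "patella_replaced", "disability", "surgical_position",
    "senior_surgeon", "treatment_centre",
)


@dataclass
class ImputationSet:
    """m completed datasets plus bookkeeping."""

    datasets: list[pd.DataFrame]

    @property
    def m(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)


class ChainedEquationsImputer:
    """Chained-equations imputation of incomplete cohort columns.

    Parameters
    ----------
    m : number of completed datasets (default 20).
    n_iter : chained-equation cycles between saved datasets (default 10).
    seed : RNG seed (the imputation draws are derandomised through numpy's
        global state, which statsmodels' MICE uses internally).
    """

    def __init__(self, m: int = 20, n_iter: int = 10, seed: int = 0):
        self.m = m
        self.n_iter = n_iter
        self.seed = seed

    def fit_transform(self, df: pd.DataFrame,
                      columns: list[str] | None = None) -> ImputationSet:
        if columns is None:
            columns = [c for c in df.columns
                       if df[c].isna().any() and c not in ("brand", "sex")]
        for c in columns:
            if df[c].isna().all():
                raise ValueError(f"column {c!r} is 100% missing; cannot impute")
        if not columns or not df[columns].isna().any().any():
            log.info("no missing values; imputation skipped, returning %d "
                     "copies of the input", self.m)
            return ImputationSet([df.copy() for _ in range(self.m)])

        num = pd.DataFrame(index=df.index)
        for b in cfg.BRANDS[1:]:
            num[f"b{cfg.BRANDS.index(b)}"] = (df["brand"] == b).astype(float)
        num["female"] = (df["sex"] == "F").astype(float)
        num["asa3"] = (df["asa_grade"] == 3).astype(float)
        for c in _PREDICTORS:
            if c in df.columns:
                num[c] = df[c].astype(float)
        for c in columns:
            if c not in num.columns:
                num[c] = df[c].astype(float)

        rename = {c: c.replace("[", "_").replace("]", "_") for c in num.columns}
        num = num.rename(columns=rename)

        np.random.seed(self.seed % (2**32))
        md = MICEData(num)
        datasets = []
        for _ in range(self.m):
            md.update_all(self.n_iter)
            completed = md.data
            out = df.copy()
            for c in columns:
                out[c] = completed[rename.get(c, c)].to_numpy()
            datasets.append(out)
        log.info("produced %d imputations (%d cycles each) for columns %s",
                 self.m, self.n_iter, columns)
        return ImputationSet(datasets)


def impute_chained(records: pd.DataFrame, m: int = 20, seed: int = 0,
                   n_iter: int = 10,
                   columns: list[str] | None = None) -> ImputationSet:
    """Functional wrapper over `ChainedEquationsImputer`."""
    return ChainedEquationsImputer(m=m, n_iter=n_iter, seed=seed
                                   ).fit_transform(records, columns=columns)
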