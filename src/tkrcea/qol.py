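"""Case-mix-adjusted quality-of-life models.

The 6-month EQ-5D index (and, for reporting, the Oxford Knee Score) is
regressed on prosthesis brand plus patient and provider characteristics by
ordinary least squares, with fractional-polynomial transformations of
continuous covariates where they improve fit. Estimates from multiply-imputed
datasets are combined by Rubin's rules. Subgroup predictions (brand x sex x
age 60/70/80, other covariates at sample means) feed the Markov model, as do
the revision-year and post-revision state utilities regressed on age and sex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import config as cfg

try:  # pragma: no cover
    from sklearn.base import BaseEstimator
except Exception:  # pragma: no cover
    class BaseEstimator:  # type: ignore
        pass

#: Candidate fractional-polynomial powers; 0 denotes the logarithm.
FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

DEFAULT_COVARIATES = (
    "age", "sex", "comorbidity_count", "bmi", "disability", "asa_grade",
    "imd_quintile", "patella_replaced", "surgical_position", "preop_eq5d",
    "preop_oks", "senior_surgeon", "treatment_centre",
)

CONTINUOUS = ("age", "bmi", "preop_eq5d", "preop_oks")


# ---------------------------------------------------------------------------
# Fractional polynomials
# ---------------------------------------------------------------------------

def _fp_columns(z: np.ndarray, powers: tuple[float, ...]) -> np.ndarray:
    """FP basis columns for strictly positive z; repeated powers follow the
    usual convention (z^p, z^p log z)."""
    cols = []
    prev = None
    for p in powers:
        base = np.log(z) if p == 0.0 else z ** p
        if prev is not None and p == prev:
            base = cols[-1] * np.log(z)
        cols.append(base)
        prev = p
    return np.column_stack(cols)


@dataclass
class FPSelection:
    """Chosen functional form for one continuous covariate."""

    covariate: str
    kind: str                      # 'linear' | 'quadratic' | 'fp1' | 'fp2' | 'omit'
    powers: tuple[float, ...] = ()
    shift: float = 0.0             # applied before powers so z > 0
    scale: float = 1.0
    deviances: dict = field(default_factory=dict)

    def transform(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) + self.shift) / self.scale
        if self.kind == "linear":
            return z[:, None]
        if self.kind == "quadratic":
            return np.column_stack([z, z ** 2])
        if self.kind in ("fp1", "fp2"):
            return _fp_columns(z, self.powers)
        raise ValueError(f"cannot transform with kind={self.kind!r}")

    @property
    def n_columns(self) -> int:
        return {"linear": 1, "quadratic": 2, "fp1": 1, "fp2": 2}[self.kind]


class FractionalPolynomialSelector(BaseEstimator):
    """Select linear vs quadratic vs FP1 vs FP2 for a single covariate.

    A fractional polynomial is adopted only when its deviance improves on both
    the linear and the quadratic fit by more than ``threshold`` (chi-squared
    scale; default 4.605, the 10% point on 2 df). The quadratic replaces the
    linear when it improves deviance by more than 3.84 (5% on 1 df), and FP2
    replaces FP1 under the same 4.605 rule.
    """

    def __init__(self, threshold: float = 4.605, quad_threshold: float = 3.84):
        self.threshold = threshold
        self.quad_threshold = quad_threshold

    def fit(self, x: np.ndarray, y: np.ndarray,
            adjust: np.ndarray | None = None,
            name: str = "x") -> "FractionalPolynomialSelector":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.ptp(x) == 0.0:
            warnings.warn(f"covariate {name!r} is constant; omitted")
            self.selection_ = FPSelection(name, "omit")
            return self

        shift = 0.0
        if x.min() <= 0:
            shift = -x.min() + np.ptp(x) / 100.0
        scale = 10.0 ** np.round(np.log10(np.ptp(x)))
        z = (x + shift) / scale
        n = y.size

        base = np.ones((n, 1)) if adjust is None else np.column_stack(
            [np.ones(n), adjust])

        def deviance(cols: np.ndarray) -> float:
            X = np.column_stack([base, cols])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((y - X @ beta) ** 2))
            return n * np.log(rss / n)

        dev = {"linear": deviance(z[:, None]),
               "quadratic": deviance(np.column_stack([z, z ** 2]))}

        best_fp1, best_fp2 = None, None
        for p in FP_POWERS:
            d = deviance(_fp_columns(z, (p,)))
            if best_fp1 is None or d < best_fp1[1]:
                best_fp1 = ((p,), d)
        for i, p1 in enumerate(FP_POWERS):
            for p2 in FP_POWERS[i:]:
                d = deviance(_fp_columns(z, (p1, p2)))
                if best_fp2 is None or d < best_fp2[1]:
                    best_fp2 = ((p1, p2), d)
        dev["fp1"] = best_fp1[1]
        dev["fp2"] = best_fp2[1]

        conventional = "quadratic" if (
            dev["linear"] - dev["quadratic"] > self.quad_threshold) else "linear"
        fp_kind = "fp2" if (dev["fp1"] - dev["fp2"] > self.threshold) else "fp1"
        fp_dev = dev[fp_kind]

        if (dev["linear"] - fp_dev > self.threshold
                and dev["quadratic"] - fp_dev > self.threshold):
            kind, powers = fp_kind, (best_fp2[0] if fp_kind == "fp2" else best_fp1[0])
        else:
            kind, powers = conventional, ()
        self.selection_ = FPSelection(name, kind, powers, shift, scale, dev)
        return self


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

def pool_rubin(estimates, variances) -> tuple[np.ndarray, np.ndarray]:
    """Combine estimates across m imputations.

    pooled = mean(estimates); total variance = mean within-variance +
    (1 + 1/m) between-imputation variance. Works elementwise on vectors and,
    when ``variances`` are matrices, pools the full covariance.
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    m = est.shape[0]
    if m < 2:
        raise ValueError("Rubin's rules need at least m=2 imputations")
    if var.shape[0] != m:
        raise ValueError("estimates and variances must have equal length")
    pooled = est.mean(axis=0)
    dev = est - pooled
    if var.ndim == est.ndim + 1:  # full covariance matrices
        between = np.einsum("mi,mj->ij", dev, dev) / (m - 1)
    else:
        between = (dev ** 2).sum(axis=0) / (m - 1)
    total = var.mean(axis=0) + (1.0 + 1.0 / m) * between
    return pooled, total


# ---------------------------------------------------------------------------
# Post-operative QOL regression
# ---------------------------------------------------------------------------

class QOLRegression(BaseEstimator):
    """OLS model of a post-operative outcome on brand plus case mix.

    Brand is coded with treatment contrasts against ``reference_brand``.
    Continuous covariates in ``fp_covariates`` go through fractional-
    polynomial selection. ``brand_interactions`` adds brand x age and
    brand x sex terms (scenario analysis); ``preop_categorical`` replaces the
    continuous pre-operative EQ-5D with quintile-bin indicators.

    Fitted attributes: ``params_`` (Series), ``cov_`` (DataFrame),
    ``resid_var_``, ``terms_``, ``fp_selections_``, ``covariate_means_``.
    """

    def __init__(self, outcome: str = "postop_eq5d",
                 reference_brand: str = cfg.REFERENCE_BRAND,
                 covariates: tuple[str, ...] = DEFAULT_COVARIATES,
                 fp_covariates: tuple[str, ...] = ("age", "bmi", "preop_oks"),
                 fp_threshold: float = 4.605,
                 brand_interactions: bool = False,
                 preop_categorical: bool = False):
        self.outcome = outcome
        self.reference_brand = reference_brand
        self.covariates = tuple(covariates)
        self.fp_covariates = tuple(fp_covariates)
        self.fp_threshold = fp_threshold
        self.brand_interactions = brand_interactions
        self.preop_categorical = preop_categorical

    # -- design ------------------------------------------------------------

    def _brand_levels(self):
        return [b for b in cfg.BRANDS if b != self.reference_brand]

    def _design(self, df: pd.DataFrame, fit: bool) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"const": np.ones(len(df))}
        for b in self._brand_levels():
            cols[f"brand[{b}]"] = (df["brand"] == b).astype(float).to_numpy()
        female = (df["sex"] == "F").astype(float).to_numpy()

        for c in self.covariates:
            if c == "sex":
                cols["female"] = female
            elif c == "asa_grade":
                for g in (1, 3):  # reference: grade 2
                    cols[f"asa[{g}]"] = (df["asa_grade"] == g).astype(float).to_numpy()
            elif c == "preop_eq5d" and self.preop_categorical:
                if fit:
                    self._preop_bins_ = np.unique(np.quantile(
                        df["preop_eq5d"].to_numpy(), [0.2, 0.4, 0.6, 0.8]))
                idx = np.digitize(df["preop_eq5d"].to_numpy(), self._preop_bins_)
                for q in range(1, len(self._preop_bins_) + 1):
                    cols[f"preop_eq5d_bin[{q}]"] = (idx == q).astype(float)
            elif c in self.fp_selections_:
                sel = self.fp_selections_[c]
                if sel.kind == "omit":
                    continue
                tr = sel.transform(df[c].to_numpy())
                for j in range(tr.shape[1]):
                    cols[f"{c}_t{j}"] = tr[:, j]
            else:
                cols[c] = df[c].astype(float).to_numpy()

        if self.brand_interactions:
            age_c = df["age"].astype(float).to_numpy() - 70.0
            for b in self._brand_levels():
                dummy = cols[f"brand[{b}]"]
                cols[f"brand[{b}]:age"] = dummy * age_c
                cols[f"brand[{b}]:female"] = dummy * female
        return pd.DataFrame(cols, index=df.index)

    # -- fitting -----------------------------------------------------------

    def fit(self, df: pd.DataFrame,
            fp_selections: dict[str, FPSelection] | None = None
            ) -> "QOLRegression":
        """Fit by OLS. ``fp_selections`` fixes the functional forms up front
        (used to keep the design identical across multiply-imputed datasets);
        otherwise they are selected on this dataset."""
        data = df.dropna(subset=[self.outcome])
        if data[list(self.covariates) + ["brand"]].isna().any().any():
            raise ValueError("missing covariate values: impute before fitting")
        y = data[self.outcome].to_numpy(dtype=float)

        if fp_selections is not None:
            self.fp_selections_ = dict(fp_selections)
            return self._fit_design(data, y)
        self.fp_selections_ = {}
        for c in self.fp_covariates:
            if c not in self.covariates or (
                    c == "preop_eq5d" and self.preop_categorical):
                continue
            adjust = np.column_stack(
                [(data["brand"] == b).astype(float) for b in self._brand_levels()]
                + [(data["sex"] == "F").astype(float)])
            sel = FractionalPolynomialSelector(threshold=self.fp_threshold)
            sel.fit(data[c].to_numpy(dtype=float), y, adjust=adjust, name=c)
            self.fp_selections_[c] = sel.selection_
        return self._fit_design(data, y)

    def _fit_design(self, data: pd.DataFrame, y: np.ndarray) -> "QOLRegression":
        X = self._design(data, fit=True)
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            # report the offending terms
            _, r = np.linalg.qr(X.to_numpy())
            bad = [X.columns[i] for i in range(X.shape[1])
                   if abs(r[min(i, r.shape[0] - 1), i]) < 1e-8]
            raise ValueError(f"rank-deficient design; collinear terms: {bad}")

        res = sm.OLS(y, X).fit()
        self.params_ = res.params
        self.cov_ = pd.DataFrame(res.cov_params(), index=X.columns,
                                 columns=X.columns)
        self.resid_var_ = float(res.mse_resid)
        self.terms_ = list(X.columns)
        self.nobs_ = int(res.nobs)
        self.covariate_means_ = {
            c: float(data[c].mean()) for c in self.covariates
            if c not in ("sex", "asa_grade")}
        if "sex" in self.covariates:
            self.covariate_means_["female"] = float((data["sex"] == "F").mean())
        if "asa_grade" in self.covariates:
            self.covariate_means_["asa1"] = float((data["asa_grade"] == 1).mean())
            self.covariate_means_["asa3"] = float((data["asa_grade"] == 3).mean())
        if self.preop_categorical:
            idx = np.digitize(data["preop_eq5d"].to_numpy(), self._preop_bins_)
            self._preop_bin_means_ = {
                q: float((idx == q).mean())
                for q in range(1, len(self._preop_bins_) + 1)}
        return self

    # -- prediction --------------------------------------------------------

    def _subgroup_row(self, brand: str, sex: str, age: float) -> np.ndarray:
        """Design row for a subgroup: brand/sex/age set, all other covariates
        at their training means (categorical ones at observed shares)."""
        m = self.covariate_means_
        female = 1.0 if sex == "F" else 0.0
        row = {"const": 1.0}
        for b in self._brand_levels():
            row[f"brand[{b}]"] = 1.0 if brand == b else 0.0
        for c in self.covariates:
            if c == "sex":
                row["female"] = female
            elif c == "asa_grade":
                row["asa[1]"] = m["asa1"]
                row["asa[3]"] = m["asa3"]
            elif c == "preop_eq5d" and self.preop_categorical:
                for q, share in self._preop_bin_means_.items():
                    row[f"preop_eq5d_bin[{q}]"] = share
            elif c in self.fp_selections_:
                sel = self.fp_selections_[c]
                if sel.kind == "omit":
                    continue
                val = age if c == "age" else m[c]
                tr = sel.transform(np.array([val]))
                for j in range(tr.shape[1]):
                    row[f"{c}_t{j}"] = tr[0, j]
            elif c == "age":
                row["age"] = age
            else:
                row[c] = m[c]
        if self.brand_interactions:
            for b in self._brand_levels():
                d = row[f"brand[{b}]"]
                row[f"brand[{b}]:age"] = d * (age - 70.0)
                row[f"brand[{b}]:female"] = d * female
        return np.array([row[t] for t in self.terms_])

    def predict_subgroup(self, brand: str, sex: str, age: float,
                         params: pd.Series | None = None,
                         cov: pd.DataFrame | None = None
                         ) -> tuple[float, float]:
        """Point prediction and SE for a brand x sex x age subgroup."""
        if age not in (60, 70, 80):
            warnings.warn(f"age {age} outside the reporting set {{60, 70, 80}}")
        x = self._subgroup_row(brand, sex, age)
        p = (self.params_ if params is None else params).to_numpy()
        V = (self.cov_ if cov is None else cov).to_numpy()
        return float(x @ p), float(np.sqrt(x @ V @ x))

    def brand_contrast(self, brand: str,
                       params: pd.Series | None = None,
                       cov: pd.DataFrame | None = None) -> tuple[float, float]:
        """Adjusted contrast of ``brand`` against the reference brand."""
        if brand == self.reference_brand:
            return 0.0, 0.0
        term = f"brand[{brand}]"
        p = self.params_ if params is None else params
        V = self.cov_ if cov is None else cov
        return float(p[term]), float(np.sqrt(V.loc[term, term]))


@dataclass
class PooledQOLModel:
    """Rubin-pooled coefficients bound to a reference design."""

    ref: QOLRegression
    params_: pd.Series
    cov_: pd.DataFrame
    m: int

    def predict_subgroup(self, brand, sex, age):
        return self.ref.predict_subgroup(brand, sex, age,
                                         params=self.params_, cov=self.cov_)

    def brand_contrast(self, brand):
        return self.ref.brand_contrast(brand, params=self.params_, cov=self.cov_)

    def sample_params(self, n: int, rng: np.random.Generator) -> np.ndarray:
        cov = 0.5 * (self.cov_.to_numpy() + self.cov_.to_numpy().T)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            w, V = np.linalg.eigh(cov)
            L = V @ np.diag(np.sqrt(np.maximum(w, 1e-14)))
        z = rng.standard_normal((n, len(self.params_)))
        return self.params_.to_numpy() + z @ L.T

    def subgroup_row(self, brand, sex, age) -> np.ndarray:
        return self.ref._subgroup_row(brand, sex, age)


def fit_postop_qol(datasets, **kwargs) -> PooledQOLModel | QOLRegression:
    """Fit the post-operative QOL regression.

    ``datasets`` may be a single complete DataFrame (returns the fitted
    `QOLRegression`) or a list of multiply-imputed DataFrames, in which case
    per-imputation estimates are combined by Rubin's rules into a
    `PooledQOLModel` (full-covariance pooling).
    """
    if isinstance(datasets, pd.DataFrame):
        return QOLRegression(**kwargs).fit(datasets)
    first = QOLRegression(**kwargs).fit(datasets[0])
    models = [first] + [
        QOLRegression(**kwargs).fit(d, fp_selections=first.fp_selections_)
        for d in datasets[1:]]
    if len(models) == 1:
        m = models[0]
        return PooledQOLModel(m, m.params_, m.cov_, 1)
    ests = np.array([m.params_.to_numpy() for m in models])
    covs = np.array([m.cov_.to_numpy() for m in models])
    pooled, total = pool_rubin(ests, covs)
    ref = models[0]
    return PooledQOLModel(
        ref,
        pd.Series(pooled, index=ref.terms_),
        pd.DataFrame(total, index=ref.terms_, columns=ref.terms_),
        len(models),
    )


# ---------------------------------------------------------------------------
# Health-state QOL around revision
# ---------------------------------------------------------------------------

class StateQOLModel(BaseEstimator):
    """Linear model of a revision-episode utility on age and sex.

    ``timing='pre_revision'`` uses the pre-operative utility of revision
    patients (the revision-year state); ``'post_revision'`` the 6-month
    post-revision utility (the revised-TKR state).
    """

    def __init__(self, timing: str = "pre_revision", min_records: int = 30):
        self.timing = timing
        self.min_records = min_records

    def fit(self, revision_records: pd.DataFrame) -> "StateQOLModel":
        col = {"pre_revision": "preop_eq5d",
               "post_revision": "postop_eq5d"}.get(self.timing)
        if col is None:
            raise ValueError(f"unknown timing: {self.timing!r}")
        data = revision_records.dropna(subset=[col])
        if len(data) < self.min_records:
            raise ValueError(
                f"only {len(data)} records with {col}; need {self.min_records}")
        X = pd.DataFrame({
            "const": 1.0,
            "age": data["age"].astype(float) - 70.0,
            "female": (data["sex"] == "F").astype(float),
        })
        res = sm.OLS(data[col].to_numpy(dtype=float), X).fit()
        self.params_ = res.params
        self.cov_ = pd.DataFrame(res.cov_params(), index=X.columns,
                                 columns=X.columns)
        self.nobs_ = int(res.nobs)
        return self

    def predict(self, age: float, sex: str) -> tuple[float, float]:
        x = np.array([1.0, age - 70.0, 1.0 if sex == "F" else 0.0])
        return (float(x @ self.params_.to_numpy()),
                float(np.sqrt(x @ self.cov_.to_numpy() @ x)))

    def sample_predictions(self, age: float, sex: str, n: int,
                           rng: np.random.Generator) -> np.ndarray:
        mu, se = self.predict(age, sex)
        return np.minimum(rng.normal(mu, se, n), 1.0)


def fit_state_qol(revision_records: pd.DataFrame,
                  timing: str = "pre_revision") -> StateQOLModel:
    return StateQOLModel(timing=timing).fit(revision_records)


# ---------------------------------------------------------------------------
# Aging decline
# ---------------------------------------------------------------------------

def aging_decline(age: float, kappa: float = cfg.AGING_DECLINE_KAPPA) -> float:
    """Annual utility reduction from aging: kappa age^2, anchored so the
    reduction is 0.004 at age 70 and growing curvilinearly with age."""
    return kappa * float(age) ** 2


def apply_aging_decline(utility, age: float,
                        kappa: float = cfg.AGING_DECLINE_KAPPA):
    """Utility for the next cycle after one year of aging at ``age``,
    floored at the EQ-5D-3L minimum."""
    return np.maximum(np.asarray(utility, dtype=float) - aging_decline(age, kappa),
                      cfg.EQ5D_RANGE[0])
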