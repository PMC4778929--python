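"""Revision and re-revision survival models.

`SplineSurvival` is a flexible parametric survival model: the log cumulative
hazard is a restricted cubic spline in log time plus linear covariate effects,

    log H(t | x) = s(log t; gamma) + x' beta,

fitted by maximum likelihood. Because the restricted spline is linear in log
time beyond the boundary knots, predictions beyond the observed follow-up
extrapolate the log-cumulative-hazard trend — the property the Markov model
relies on for lifetime projection.

`PiecewiseExponential` is the piecewise-constant-hazard model used for
re-revision rates (first year vs all subsequent years) and, with yearly cuts,
as the alternative revision-rate model in scenario analysis.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .splines import rcs_basis, rcs_basis_deriv, default_knots

log = logging.getLogger(__name__)

try:  # pragma: no cover - import convenience
    from sklearn.base import BaseEstimator
except Exception:  # pragma: no cover
    class BaseEstimator:  # type: ignore
        pass


class ConvergenceError(RuntimeError):
    pass


class SplineSurvival(BaseEstimator):
    """Restricted-cubic-spline model on the log-cumulative-hazard scale.

    Parameters
    ----------
    n_knots : number of internal knots (default 3, placed at the 10th/50th/
        90th percentiles of uncensored log event times; boundary knots at the
        extremes).
    covariates : column names entering linearly on the log-hazard-ratio
        scale. Centred at their training means for numerical stability;
        predictions with covariates at the training means therefore use the
        baseline spline alone.
    max_iter, tol : optimizer settings.

    Attributes
    ----------
    knots_ : knot locations on log time.
    coef_ : concatenated (gamma, beta).
    cov_ : asymptotic covariance of coef_ (inverse observed information).
    loglik_, deviance_ : fit quality.
    max_time_ : largest observed time (extrapolation starts beyond this).
    """

    def __init__(self, n_knots: int = 3, covariates: tuple[str, ...] = (),
                 max_iter: int = 500, tol: float = 1e-9):
        self.n_knots = n_knots
        self.covariates = tuple(covariates)
        self.max_iter = max_iter
        self.tol = tol

    # -- fitting -----------------------------------------------------------

    def fit(self, data: pd.DataFrame, time_col: str = "time_to_event",
            event_col: str = "event") -> "SplineSurvival":
        t = np.asarray(data[time_col], dtype=float)
        d = np.asarray(data[event_col], dtype=float)
        if np.any(t <= 0):
            raise ValueError("event/censoring times must be positive")
        n_events = int(d.sum())
        if n_events < self.n_knots + 2:
            raise ValueError("too few uncensored times for the knot count")

        u = np.log(t)
        self.knots_ = default_knots(u[d == 1], self.n_knots)
        # Orthonormalize the spline block (QR) for optimizer conditioning;
        # the transform is carried into every later basis evaluation.
        raw = rcs_basis(u, self.knots_)
        try:
            _, R = np.linalg.qr(raw)
            self.basis_transform_ = np.linalg.inv(R) * np.sqrt(len(t))
        except np.linalg.LinAlgError:
            self.basis_transform_ = np.eye(raw.shape[1])
        B = raw @ self.basis_transform_
        Bd = rcs_basis_deriv(u, self.knots_) @ self.basis_transform_

        X = np.empty((len(t), len(self.covariates)))
        self.covariate_means_ = {}
        for j, c in enumerate(self.covariates):
            col = np.asarray(data[c], dtype=float)
            self.covariate_means_[c] = float(col.mean())
            X[:, j] = col - self.covariate_means_[c]

        k = B.shape[1]
        p = X.shape[1]

        def split(theta):
            return theta[:k], theta[k:]

        def negloglik(theta):
            g, b = split(theta)
            sp = Bd @ g
            if np.any(sp[d == 1] <= 0):
                return np.inf
            eta = B @ g + (X @ b if p else 0.0)
            eta = np.clip(eta, -200, 30)
            ll = np.sum(d * (np.log(np.where(sp > 0, sp, 1.0)) + eta - u)) \
                - np.sum(np.exp(eta))
            return -ll

        def grad(theta):
            g, b = split(theta)
            sp = Bd @ g
            eta = np.clip(B @ g + (X @ b if p else 0.0), -200, 30)
            H = np.exp(eta)
            w = d - H
            gg = Bd.T @ (d / np.where(sp > 0, sp, 1.0)) + B.T @ w
            if p:
                gb = X.T @ w
                return -np.concatenate([gg, gb])
            return -gg

        # initialize from the exponential fit: H(t) = r t  =>  log H = log r + u
        r0 = n_events / t.sum()
        g_raw = np.zeros(k)
        g_raw[0] = np.log(r0)
        g_raw[1] = 1.0
        theta0 = np.zeros(k + p)
        theta0[:k] = np.linalg.solve(self.basis_transform_, g_raw)

        res = minimize(negloglik, theta0, jac=grad, method="BFGS",
                       options={"maxiter": self.max_iter, "gtol": self.tol * 1e3})
        if not np.isfinite(res.fun):
            raise ConvergenceError("spline survival fit did not converge")
        if not res.success and np.linalg.norm(res.jac) > 1e-2 * max(1, n_events) ** 0.5:
            warnings.warn(f"spline survival fit: {res.message}")

        self.coef_ = res.x
        self.loglik_ = -res.fun
        self.deviance_ = 2.0 * res.fun
        self.cov_ = self._information_inverse(grad, res.x)
        self.max_time_ = float(t.max())
        self.n_events_ = n_events
        self._check_monotone()
        return self

    def _information_inverse(self, grad, theta):
        k = theta.size
        h = 1e-5 * np.maximum(np.abs(theta), 1.0)
        H = np.empty((k, k))
        for i in range(k):
            e = np.zeros(k)
            e[i] = h[i]
            H[:, i] = (grad(theta + e) - grad(theta - e)) / (2 * h[i])
        H = 0.5 * (H + H.T)
        try:
            return np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(H)

    def _check_monotone(self):
        k = self.knots_.size
        grid = np.linspace(self.knots_[0], self.knots_[-1], 200)
        sp = (rcs_basis_deriv(grid, self.knots_)
              @ self.basis_transform_) @ self.coef_[:k]
        if np.any(sp <= 0):
            warnings.warn("fitted log cumulative hazard is not monotone "
                          "within the observed range")

    # -- prediction --------------------------------------------------------

    @property
    def gamma_raw_(self) -> np.ndarray:
        """Spline coefficients on the untransformed basis [1, log t, v_j]."""
        return self.basis_transform_ @ self.coef_[:self.knots_.size]

    def _xbeta(self, covariates: dict | None) -> float:
        covariates = covariates or {}
        xb = 0.0
        beta = self.coef_[self.knots_.size:]  # after the gamma block
        for j, c in enumerate(self.covariates):
            xb += beta[j] * (covariates.get(c, self.covariate_means_[c])
                             - self.covariate_means_[c])
        return xb

    def cumulative_hazard(self, t, covariates: dict | None = None) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t <= 0):
            raise ValueError("t must be positive")
        k = self.knots_.size
        eta = (rcs_basis(np.log(t), self.knots_) @ self.basis_transform_
               ) @ self.coef_[:k] + self._xbeta(covariates)
        return np.exp(np.clip(eta, -200, 30))

    def survival_function(self, t, covariates: dict | None = None) -> np.ndarray:
        return np.exp(-self.cumulative_hazard(t, covariates))

    def predict_cumulative_incidence(self, t, covariates: dict | None = None):
        """P(revision by t | x) = 1 - exp(-H(t|x)); scalar in, scalar out."""
        out = 1.0 - self.survival_function(t, covariates)
        return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out

    def annual_transition_probs(self, covariates: dict | None = None,
                                horizon: int = 45) -> np.ndarray:
        """Per-cycle conditional revision probabilities
        p_t = [S(t-1) - S(t)] / S(t-1), t = 1..horizon (S(0) = 1)."""
        ts = np.arange(1, horizon + 1, dtype=float)
        S = self.survival_function(ts, covariates)
        S = np.concatenate([[1.0], S])
        prev = S[:-1]
        p = np.divide(prev - S[1:], prev, out=np.ones_like(prev),
                      where=prev > 0)
        return np.clip(p, 0.0, 1.0)

    def sample_coefficients(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Multivariate-normal parameter draws for probabilistic analysis;
        non-positive-definite covariances are repaired by eigenvalue flooring."""
        cov = 0.5 * (self.cov_ + self.cov_.T)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            log.info("coefficient covariance not positive definite; "
                     "flooring eigenvalues")
            w, V = np.linalg.eigh(cov)
            L = V @ np.diag(np.sqrt(np.maximum(w, 1e-12)))
        z = rng.standard_normal((n, self.coef_.size))
        return self.coef_ + z @ L.T

    def annual_probs_from_draws(self, draws: np.ndarray,
                                covariates: dict | None = None,
                                horizon: int = 45) -> np.ndarray:
        """Vectorized annual probabilities, one row per coefficient draw."""
        ts = np.arange(1, horizon + 1, dtype=float)
        k = self.knots_.size
        B = rcs_basis(np.log(ts), self.knots_) @ self.basis_transform_
        xb = np.zeros(draws.shape[0])
        for j, c in enumerate(self.covariates):
            xb += draws[:, k + j] * ((covariates or {}).get(c, self.covariate_means_[c])
                                     - self.covariate_means_[c])
        eta = draws[:, :k] @ B.T + xb[:, None]
        S = np.exp(-np.exp(np.clip(eta, -200, 30)))
        S = np.concatenate([np.ones((S.shape[0], 1)), S], axis=1)
        prev = S[:, :-1]
        p = np.divide(prev - S[:, 1:], prev, out=np.ones_like(prev),
                      where=prev > 0)
        return np.clip(p, 0.0, 1.0)

    def to_dict(self) -> dict:
        return {
            "model": "spline_survival",
            "n_knots": self.n_knots,
            "covariates": list(self.covariates),
            "knots": self.knots_.tolist(),
            "coef": self.coef_.tolist(),
            "cov": self.cov_.tolist(),
            "covariate_means": self.covariate_means_,
            "basis_transform": self.basis_transform_.tolist(),
            "max_time": self.max_time_,
            "loglik": self.loglik_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSurvival":
        m = cls(n_knots=d["n_knots"], covariates=tuple(d["covariates"]))
        m.knots_ = np.array(d["knots"])
        m.coef_ = np.array(d["coef"])
        m.cov_ = np.array(d["cov"])
        m.covariate_means_ = dict(d["covariate_means"])
        m.basis_transform_ = np.array(d["basis_transform"])
        m.max_time_ = d["max_time"]
        m.loglik_ = d["loglik"]
        return m


class PiecewiseExponential(BaseEstimator):
    """Piecewise-constant hazard estimated as events / person-years per piece.

    Default cuts (1.0,) differentiate the first year after (re)entry from all
    subsequent years. With no events in a piece the rate is 0 (warned).
    """

    def __init__(self, cuts: tuple[float, ...] = (1.0,)):
        self.cuts = tuple(cuts)

    def fit(self, data: pd.DataFrame, time_col: str = "time_to_event",
            event_col: str = "event") -> "PiecewiseExponential":
        t = np.asarray(data[time_col], dtype=float)
        d = np.asarray(data[event_col], dtype=float)
        if np.any(t <= 0):
            raise ValueError("times must be positive")
        edges = np.concatenate([[0.0], np.asarray(self.cuts, float), [np.inf]])
        rates, py, ev = [], [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            exposure = np.clip(np.minimum(t, hi) - lo, 0.0, None)
            events = float(d[(t > lo) & (t <= hi)].sum())
            persontime = float(exposure.sum())
            if persontime <= 0:
                raise ValueError(f"zero person-years in piece ({lo}, {hi}]")
            if events == 0:
                warnings.warn(f"no events in piece ({lo}, {hi}]; rate set to 0")
            rates.append(events / persontime)
            py.append(persontime)
            ev.append(events)
        self.rates_ = np.array(rates)
        self.person_years_ = np.array(py)
        self.events_ = np.array(ev)
        # Poisson MLE: SE of log rate = 1 / sqrt(events)
        with np.errstate(divide="ignore"):
            self.log_rate_se_ = np.where(self.events_ > 0,
                                         1.0 / np.sqrt(np.maximum(self.events_, 1e-12)),
                                         np.inf)
        ll = np.sum(self.events_ * np.log(np.where(self.rates_ > 0, self.rates_, 1.0))
                    - self.rates_ * self.person_years_)
        self.loglik_ = float(ll)
        return self

    def cumulative_hazard(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        edges = np.concatenate([[0.0], np.asarray(self.cuts, float), [np.inf]])
        H = np.zeros_like(t)
        for r, lo, hi in zip(self.rates_, edges[:-1], edges[1:]):
            H += r * np.clip(np.minimum(t, hi) - lo, 0.0, None)
        return H

    def predict_cumulative_incidence(self, t):
        out = 1.0 - np.exp(-self.cumulative_hazard(t))
        return float(out[0]) if np.ndim(t) == 0 else out

    def annual_transition_probs(self, horizon: int = 45) -> np.ndarray:
        ts = np.arange(0, horizon + 1, dtype=float)
        S = np.exp(-self.cumulative_hazard(ts))
        p = (S[:-1] - S[1:]) / S[:-1]
        return np.clip(p, 0.0, 1.0)

    def sample_rates(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Log-normal draws of each piece's rate (zero rates stay zero)."""
        out = np.zeros((n, self.rates_.size))
        for j, (r, se) in enumerate(zip(self.rates_, self.log_rate_se_)):
            if r > 0 and np.isfinite(se):
                out[:, j] = np.exp(rng.normal(np.log(r), se, n))
        return out

    def to_dict(self) -> dict:
        return {"model": "piecewise_exponential", "cuts": list(self.cuts),
                "rates": self.rates_.tolist(),
                "person_years": self.person_years_.tolist(),
                "events": self.events_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "PiecewiseExponential":
        m = cls(cuts=tuple(d["cuts"]))
        m.rates_ = np.array(d["rates"])
        m.person_years_ = np.array(d["person_years"])
        m.events_ = np.array(d["events"])
        with np.errstate(divide="ignore"):
            m.log_rate_se_ = np.where(m.events_ > 0,
                                      1.0 / np.sqrt(np.maximum(m.events_, 1e-12)),
                                      np.inf)
        return m
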