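"""Multiplicative stand-production model and its fitting machinery.

The model relates a positive plot-level response (basal-area increment dG,
volume increment dV, light interception efficiency LIE or light use
efficiency LUE) to stand structure and climate:

    y = exp(α0 + α1·WB + α2·SGDD) · G^β · exp(γ·Dq) · exp(δ·Gini) · exp(ε)

Taking logs yields a linear model in (log G, Dq, Gini, WB, SGDD) with
Normal error, fitted by ordinary least squares (the multiplicative-error
route); the same mean function can instead be fitted on the natural scale
with additive error by iterative least squares.  δ — the coefficient on
the Gini index of tree basal areas — is the quantity of interest: it
measures the effect of tree size inequality on production, all else equal.

Two sklearn-style estimators (`ProductionModel`, `NonlinearProductionModel`)
carry the fits; module-level functions mirror them for script use and add
likelihood-ratio tests, AIC comparison and backward selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "ALL_COVARIATES",
    "ModelSpec",
    "FitResult",
    "LRTResult",
    "ProductionModel",
    "NonlinearProductionModel",
    "fit_log_linear",
    "fit_nonlinear",
    "likelihood_ratio_test",
    "compare_aic",
    "backward_select",
    "predict_response",
]

#: Canonical covariate order: regressors as they enter the linear predictor.
ALL_COVARIATES = ("logG", "Dq", "gini", "WB", "SGDD")

#: Map from covariate name to the raw column it is built from.
_SOURCE_COLUMNS = {
    "logG": ("G",),
    "Dq": ("Dq",),
    "gini": ("gini",),
    "WB": ("wb_mm", "WB", "wb"),
    "SGDD": ("sgdd", "SGDD"),
}

#: Coefficient names used in reports, keyed by covariate.
COEF_NAMES = {
    "const": "alpha0",
    "logG": "beta",
    "Dq": "gamma",
    "gini": "delta",
    "WB": "alpha1",
    "SGDD": "alpha2",
}


@dataclass(frozen=True)
class ModelSpec:
    """Which response and covariates enter the fit."""

    response: str = "dG"
    covariates: tuple[str, ...] = ALL_COVARIATES
    standardize: bool = False

    def __post_init__(self):
        unknown = set(self.covariates) - set(ALL_COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")

    def drop(self, covariate: str) -> "ModelSpec":
        return ModelSpec(
            self.response,
            tuple(c for c in self.covariates if c != covariate),
            self.standardize,
        )


@dataclass
class FitResult:
    """Estimates and inference for one fit of the production model.

    ``params``/``bse``/``pvalues`` are keyed by covariate name (plus
    ``const``); when the fit was standardized, they refer to the
    standardized regressors and ``scaling`` holds the means/SDs needed to
    recover natural-scale coefficients (see :meth:`natural_params`).
    ``loglik`` is the Gaussian log-likelihood on the scale the model was
    fitted on, with the ML variance estimate; AIC counts the variance as
    a parameter.
    """

    spec: ModelSpec
    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    loglik: float
    aic: float
    sigma: float
    n: int
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)
    scale: str = "log"              # "log" (multiplicative) or "natural"
    sum_log_response: float = 0.0   # Jacobian term for cross-scale AIC

    @property
    def k(self) -> int:
        """Number of fitted parameters, counting the error variance."""
        return len(self.params) + 1

    def natural_params(self) -> dict[str, float]:
        """Coefficients on the natural (unstandardized) regressor scale."""
        if not self.scaling:
            return dict(self.params)
        out = {}
        const = self.params["const"]
        for name, value in self.params.items():
            if name == "const":
                continue
            mu, sd = self.scaling[name]
            out[name] = value / sd
            const -= value * mu / sd
        out["const"] = const
        return out

    def loglik_natural_scale(self) -> float:
        """Log-likelihood expressed on the natural response scale.

        For a log-scale fit the change of variables contributes
        −Σ log(y), making the value comparable with natural-scale fits.
        """
        if self.scale == "log":
            return self.loglik - self.sum_log_response
        return self.loglik

    def aic_natural_scale(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik_natural_scale()

    def delta_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Wald confidence interval for δ (the Gini coefficient effect)."""
        if "gini" not in self.params:
            raise ValueError("fit has no Gini term")
        z = stats.norm.ppf(0.5 + level / 2.0)
        est, se = self.params["gini"], self.bse["gini"]
        return est - z * se, est + z * se

    def report(self) -> dict:
        """JSON-ready summary with field-standard coefficient names."""
        return {
            "response": self.spec.response,
            "covariates": list(self.spec.covariates),
            "standardized": self.spec.standardize,
            "n": self.n,
            "coefficients": {
                COEF_NAMES.get(k, k): {
                    "estimate": self.params[k],
                    "se": self.bse[k],
                    "p": self.pvalues[k],
                }
                for k in self.params
            },
            "sigma": self.sigma,
            "loglik": self.loglik,
            "aic": self.aic,
        }


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    pvalue: float


def _resolve_column(table: pd.DataFrame, covariate: str) -> pd.Series:
    for col in _SOURCE_COLUMNS[covariate]:
        if col in table.columns:
            return table[col].astype(float)
    raise ValueError(
        f"covariate {covariate!r} needs one of columns "
        f"{_SOURCE_COLUMNS[covariate]}"
    )


def build_design(
    table: pd.DataFrame, covariates: tuple[str, ...]
) -> pd.DataFrame:
    """Regressor matrix (without intercept) from a per-plot metrics table."""
    cols = {}
    for cov in covariates:
        x = _resolve_column(table, cov)
        if cov == "logG":
            if (x <= 0).any():
                bad = table.index[x <= 0].tolist()
                raise ValueError(f"G must be > 0 for logG; offending rows {bad}")
            x = np.log(x)
        cols[cov] = np.asarray(x, dtype=float)
    return pd.DataFrame(cols, index=table.index)


class ProductionModel(RegressorMixin, BaseEstimator):
    """Multiplicative production model fitted by OLS on the log scale.

    Parameters
    ----------
    response : str
        Column of the fitted table holding the (strictly positive)
        response when ``fit`` is called with a single table.
    covariates : tuple of str
        Subset of ``("logG", "Dq", "gini", "WB", "SGDD")``.
    standardize : bool
        Centre and scale the regressors before fitting.  Predictions and
        log-likelihood are invariant to this; it only changes the scale
        on which coefficients are reported.
    bias_correction : bool
        Apply the log-normal mean correction exp(σ²/2) in ``predict``.
        Off by default.

    Attributes
    ----------
    result_ : FitResult
    params_, bse_, pvalues_ : dict
    loglik_, aic_, sigma_ : float
    """

    def __init__(
        self,
        response: str = "dG",
        covariates: tuple[str, ...] = ALL_COVARIATES,
        standardize: bool = False,
        bias_correction: bool = False,
    ):
        self.response = response
        self.covariates = covariates
        self.standardize = standardize
        self.bias_correction = bias_correction

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(self.response, tuple(self.covariates), self.standardize)

    def _design(self, X: pd.DataFrame) -> pd.DataFrame:
        return build_design(X, tuple(self.covariates))

    def fit(self, X: pd.DataFrame, y=None) -> "ProductionModel":
        """Fit on a per-plot table; ``y`` defaults to ``X[self.response]``."""
        if y is None:
            if self.response not in X.columns:
                raise ValueError(f"response column {self.response!r} not in table")
            y = X[self.response]
        y = np.asarray(y, dtype=float)
        if np.any(y <= 0):
            bad = np.flatnonzero(y <= 0).tolist()
            raise ValueError(
                f"response must be > 0 for the log transform; offending rows {bad}"
            )
        design = self._design(X)
        k = design.shape[1] + 1
        if len(y) <= k + 2:
            raise ValueError(f"need n > {k + 2} rows, got {len(y)}")

        self.scaling_ = {}
        Z = design.copy()
        if self.standardize:
            for col in Z.columns:
                mu, sd = float(Z[col].mean()), float(Z[col].std(ddof=0))
                if sd == 0:
                    raise ValueError(f"covariate {col} is constant; cannot standardize")
                Z[col] = (Z[col] - mu) / sd
                self.scaling_[col] = (mu, sd)

        exog = sm.add_constant(Z, has_constant="add")
        rank = np.linalg.matrix_rank(exog.to_numpy())
        if rank < exog.shape[1]:
            raise ValueError(
                f"rank-deficient design (rank {rank} < {exog.shape[1]}); "
                f"collinear covariates among {list(Z.columns)}"
            )
        ols = sm.OLS(np.log(y), exog).fit()

        self.params_ = {name: float(v) for name, v in ols.params.items()}
        self.bse_ = {name: float(v) for name, v in ols.bse.items()}
        self.pvalues_ = {name: float(v) for name, v in ols.pvalues.items()}
        self.loglik_ = float(ols.llf)  # OLS llf uses the ML variance
        self.sigma_ = float(np.sqrt(ols.ssr / len(y)))
        self.n_ = int(len(y))
        self.aic_ = 2.0 * (len(self.params_) + 1) - 2.0 * self.loglik_
        self.result_ = FitResult(
            spec=self.spec,
            params=self.params_,
            bse=self.bse_,
            pvalues=self.pvalues_,
            loglik=self.loglik_,
            aic=self.aic_,
            sigma=self.sigma_,
            n=self.n_,
            scaling=dict(self.scaling_),
            scale="log",
            sum_log_response=float(np.sum(np.log(y))),
        )
        return self

    def _linpred(self, X: pd.DataFrame) -> np.ndarray:
        design = self._design(X)
        eta = np.full(len(design), self.params_["const"])
        for col in design.columns:
            x = design[col].to_numpy()
            if col in self.scaling_:
                mu, sd = self.scaling_[col]
                x = (x - mu) / sd
            eta += self.params_[col] * x
        return eta

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Natural-scale prediction exp(linear predictor)."""
        eta = self._linpred(X)
        if self.bias_correction:
            eta = eta + 0.5 * self.sigma_**2
        return np.exp(eta)


class NonlinearProductionModel(BaseEstimator):
    """Same mean function, fitted on the natural scale with additive error.

    Minimises Σ (y − exp(η(x)))² by trust-region least squares, started
    from the log-scale OLS solution.  AIC is comparable with the
    log-scale fit only through ``FitResult.aic_natural_scale``.
    """

    def __init__(
        self,
        response: str = "dG",
        covariates: tuple[str, ...] = ALL_COVARIATES,
        max_iter: int = 200,
    ):
        self.response = response
        self.covariates = covariates
        self.max_iter = max_iter

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(self.response, tuple(self.covariates), False)

    def fit(self, X: pd.DataFrame, y=None) -> "NonlinearProductionModel":
        if y is None:
            y = X[self.response]
        y = np.asarray(y, dtype=float)
        design = build_design(X, tuple(self.covariates))
        # initialise from the log fit on the positive rows
        pos = y > 0
        if pos.sum() <= design.shape[1] + 3:
            raise ValueError("too few positive rows to initialise")
        init = ProductionModel(self.response, tuple(self.covariates)).fit(
            X[pos], y[pos]
        )
        names = ["const", *design.columns]
        theta0 = np.array([init.params_[n] for n in names])
        A = np.column_stack([np.ones(len(design)), design.to_numpy()])

        def resid(theta):
            return np.exp(A @ theta) - y

        sol = optimize.least_squares(
            resid, theta0, method="trf", max_nfev=self.max_iter * len(theta0)
        )
        if not sol.success:
            raise RuntimeError(f"nonlinear fit did not converge: {sol.message}")
        n = len(y)
        ssr = float(np.sum(sol.fun**2))
        sigma2 = ssr / n
        loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
        # Wald SEs from the Gauss-Newton approximation of the Hessian
        J = sol.jac
        try:
            cov = sigma2 * np.linalg.inv(J.T @ J) * n / max(n - len(theta0), 1)
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            se = np.full(len(theta0), np.nan)
        z = sol.x / se
        pvals = 2.0 * stats.norm.sf(np.abs(z))

        self.params_ = dict(zip(names, map(float, sol.x)))
        self.bse_ = dict(zip(names, map(float, se)))
        self.pvalues_ = dict(zip(names, map(float, pvals)))
        self.loglik_ = float(loglik)
        self.sigma_ = float(np.sqrt(sigma2))
        self.n_ = n
        self.aic_ = 2.0 * (len(names) + 1) - 2.0 * self.loglik_
        self.result_ = FitResult(
            spec=self.spec,
            params=self.params_,
            bse=self.bse_,
            pvalues=self.pvalues_,
            loglik=self.loglik_,
            aic=self.aic_,
            sigma=self.sigma_,
            n=n,
            scale="natural",
        )
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        design = build_design(X, tuple(self.covariates))
        A = np.column_stack([np.ones(len(design)), design.to_numpy()])
        theta = np.array([self.params_[n] for n in ["const", *design.columns]])
        return np.exp(A @ theta)


def fit_log_linear(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """OLS fit of the log-transformed model (multiplicative error)."""
    est = ProductionModel(spec.response, spec.covariates, spec.standardize)
    return est.fit(table).result_


def fit_nonlinear(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Least-squares fit of the untransformed model (additive error)."""
    est = NonlinearProductionModel(spec.response, spec.covariates)
    return est.fit(table).result_


def likelihood_ratio_test(full: FitResult, reduced: FitResult) -> LRTResult:
    """Chi-square LRT between two nested fits on the same rows."""
    if full.n != reduced.n:
        raise ValueError(f"fits use different n ({full.n} vs {reduced.n})")
    if full.scale != reduced.scale:
        raise ValueError("cannot compare fits on different scales")
    if not set(reduced.spec.covariates) <= set(full.spec.covariates):
        raise ValueError("models are not nested")
    df = len(full.params) - len(reduced.params)
    if df < 0:
        raise ValueError("reduced model has more parameters than the full one")
    statistic = 2.0 * (full.loglik - reduced.loglik)
    pvalue = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    if df == 0:
        statistic = 0.0
    return LRTResult(float(statistic), int(df), float(pvalue))


def compare_aic(with_gini: FitResult, without: FitResult) -> float:
    """ΔAIC = AIC(without Gini) − AIC(with Gini); positive favours Gini."""
    if with_gini.n != without.n:
        raise ValueError("fits use different numbers of rows")
    if with_gini.spec.response != without.spec.response:
        raise ValueError("fits use different responses")
    return float(without.aic - with_gini.aic)


def backward_select(
    table: pd.DataFrame, full_spec: ModelSpec, alpha: float = 0.05
) -> ModelSpec:
    """Drop covariates with p ≥ alpha one at a time until all are significant.

    At each step the covariate with the largest p-value is removed (ties
    broken lexicographically) and the model refitted.  Deterministic.
    """
    spec = full_spec
    while spec.covariates:
        fit = fit_log_linear(table, spec)
        candidates = [
            (fit.pvalues[c], c) for c in spec.covariates if fit.pvalues[c] >= alpha
        ]
        if not candidates:
            return spec
        candidates.sort(key=lambda t: (-t[0], t[1]))
        spec = spec.drop(candidates[0][1])
    return spec


def predict_response(fit: FitResult, covariates: pd.DataFrame) -> np.ndarray:
    """Natural-scale prediction from a FitResult and a covariate table."""
    design = build_design(covariates, fit.spec.covariates)
    eta = np.full(len(design), fit.params["const"])
    for col in design.columns:
        x = design[col].to_numpy()
        if col in fit.scaling:
            mu, sd = fit.scaling[col]
            x = (x - mu) / sd
        eta += fit.params[col] * x
    return np.exp(eta)
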