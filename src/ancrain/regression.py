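"""Log-linear panel regression: OLS fit, backward stepwise AIC, LR test.

Two models underpin the attribution: M0 regresses log(ANC count + eps) on
calendar and facility covariates only; M1 adds precipitation index terms.
Backward stepwise selection over the precipitation candidates minimises AIC
(k counts the intercept, the slopes and the Gaussian error variance, so
AIC = 2k - 2 loglik); the two fitted models are compared with a likelihood
ratio test against the chi-squared upper tail.

Estimators follow the scikit-learn protocol (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) and
accept term-named pandas DataFrames so fitted coefficients stay named.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def _rank_check(X: pd.DataFrame) -> None:
    """Reject rank-deficient designs, naming the dependent columns.

    Columns are centred and scaled first so the check is invariant to units
    (metres vs millimetres) and to an intercept shift.
    """
    arr = X.to_numpy(dtype=float)
    centred = arr - arr.mean(axis=0)
    norms = np.linalg.norm(centred, axis=0)
    constant = norms < 1e-12  # collinear with the intercept
    scaled = np.where(constant, 1.0, norms)
    std = centred / scaled
    rank = np.linalg.matrix_rank(std, tol=1e-8)
    if constant.any() or rank < arr.shape[1]:
        _, r = np.linalg.qr(std)
        diag = np.abs(np.diag(r))
        bad = sorted(
            set(X.columns[constant])
            | {X.columns[i] for i in range(arr.shape[1]) if diag[i] < 1e-8}
        )
        raise ValueError(f"design is rank deficient; dependent columns: {bad}")


class LogLinearRegression(RegressorMixin, BaseEstimator):
    """OLS on a log(count + eps) response with named terms.

    Parameters
    ----------
    eps : float
        The offset of the log transform; used by :meth:`predict_count` to
        back-transform the linear predictor to the count scale.

    Attributes
    ----------
    terms_ : list of str
        Fitted term names (intercept excluded).
    coef_ : pd.Series
        Coefficients indexed by term name, including ``intercept``.
    bse_, pvalues_ : pd.Series
        Standard errors and two-sided t-test p-values per coefficient.
    loglik_, aic_ : float
        Gaussian log-likelihood and AIC = 2k - 2 loglik with k counting the
        intercept, slopes and error variance.
    nobs_ : int
    rsquared_adj_ : float
    """

    def __init__(self, eps: float = 1.0):
        self.eps = eps

    def fit(self, X, y):
        X = _as_frame(X)
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        k_params = X.shape[1] + 2  # slopes + intercept + error variance
        if len(X) <= k_params:
            raise ValueError("not enough observations for the parameter count")
        _rank_check(X)
        exog = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
        res = sm.OLS(y, exog).fit()
        names = ["intercept"] + list(X.columns)
        self.terms_ = list(X.columns)
        self.coef_ = pd.Series(res.params, index=names)
        self.bse_ = pd.Series(res.bse, index=names)
        self.pvalues_ = pd.Series(res.pvalues, index=names)
        self.loglik_ = float(res.llf)
        self.aic_ = 2.0 * k_params - 2.0 * self.loglik_
        self.nobs_ = int(res.nobs)
        self.rsquared_adj_ = float(res.rsquared_adj)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        """Linear predictor on the log(count + eps) scale."""
        check_is_fitted(self, "coef_")
        X = _as_frame(X)
        missing = [t for t in self.terms_ if t not in X.columns]
        if missing:
            raise KeyError(f"design lacks fitted model terms: {missing}")
        # column-wise accumulation in term order: a zero coefficient adds an
        # exact 0, so nested models with zeroed extra terms predict
        # bit-identically to the reduced model
        lp = np.full(len(X), float(self.coef_["intercept"]))
        for term in self.terms_:
            lp += float(self.coef_[term]) * X[term].to_numpy(dtype=float)
        return lp

    def predict_count(self, X) -> np.ndarray:
        """Back-transformed count prediction, exp(linear predictor) - eps,
        floored at zero (no smearing correction; see the methods note)."""
        return np.maximum(np.exp(self.predict(X)) - self.eps, 0.0)

    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "eps": self.eps,
            "terms": self.terms_,
            "coef": self.coef_.to_dict(),
            "bse": self.bse_.to_dict(),
            "pvalues": self.pvalues_.to_dict(),
            "loglik": self.loglik_,
            "aic": self.aic_,
            "nobs": self.nobs_,
            "rsquared_adj": self.rsquared_adj_,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "LogLinearRegression":
        model = cls(eps=payload["eps"])
        model.terms_ = list(payload["terms"])
        names = ["intercept"] + model.terms_
        model.coef_ = pd.Series(payload["coef"]).reindex(names)
        model.bse_ = pd.Series(payload["bse"]).reindex(names)
        model.pvalues_ = pd.Series(payload["pvalues"]).reindex(names)
        model.loglik_ = payload["loglik"]
        model.aic_ = payload["aic"]
        model.nobs_ = payload["nobs"]
        model.rsquared_adj_ = payload["rsquared_adj"]
        model.n_features_in_ = len(model.terms_)
        return model


class BackwardStepwiseSelector(RegressorMixin, BaseEstimator):
    """Backward stepwise AIC elimination over candidate terms.

    Starting from fixed + candidate terms, repeatedly removes the single
    candidate whose removal most decreases AIC, until no removal decreases
    it. Ties in AIC improvement are broken by removing the term with the
    larger coefficient p-value.

    Attributes
    ----------
    model_ : LogLinearRegression
        The final refitted model.
    selected_terms_ : list of str
        Terms retained (fixed terms plus surviving candidates).
    removal_path_ : list of tuple
        (removed term, AIC after removal), in removal order.
    aic_path_ : list of float
        AIC from the full model through each removal (non-increasing).
    """

    def __init__(self, fixed_terms: list[str] | None = None,
                 candidate_terms: list[str] | None = None, eps: float = 1.0):
        self.fixed_terms = fixed_terms
        self.candidate_terms = candidate_terms
        self.eps = eps

    def fit(self, X, y):
        X = _as_frame(X)
        fixed = list(self.fixed_terms or [])
        candidates = list(self.candidate_terms or [])
        unknown = [t for t in fixed + candidates if t not in X.columns]
        if unknown:
            raise KeyError(f"terms not in design: {unknown}")

        current = fixed + [t for t in candidates if t not in fixed]
        model = LogLinearRegression(eps=self.eps).fit(X[current], y)
        path: list[tuple[str, float]] = []
        aics = [model.aic_]
        active = [t for t in candidates if t not in fixed]
        while active:
            trials = []
            for term in active:
                reduced = [t for t in current if t != term]
                trial = LogLinearRegression(eps=self.eps).fit(X[reduced], y)
                trials.append((trial.aic_, -model.pvalues_[term], term, trial))
            best_aic, _, best_term, best_model = min(trials)
            if best_aic >= model.aic_:
                break
            current = [t for t in current if t != best_term]
            active.remove(best_term)
            model = best_model
            path.append((best_term, best_aic))
            aics.append(best_aic)

        self.model_ = model
        self.selected_terms_ = current
        self.removal_path_ = path
        self.aic_path_ = aics
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(X)

    def predict_count(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_count(X)


@dataclass
class LRTestResult:
    statistic: float
    df: int
    pvalue: float


def lr_pvalue(statistic: float, df: int) -> float:
    """Upper-tail chi-squared probability of a likelihood-ratio statistic."""
    return float(chi2.sf(statistic, df))


def likelihood_ratio_test(
    m0: LogLinearRegression, m1: LogLinearRegression
) -> LRTestResult:
    """LR test of nested fits: stat = 2(loglik1 - loglik0) ~ chi2(k1 - k0)."""
    if not set(m0.terms_) <= set(m1.terms_):
        raise ValueError("m0 is not nested in m1 (terms are not a subset)")
    if m0.nobs_ != m1.nobs_:
        raise ValueError(
            f"models fitted on different samples (n={m0.nobs_} vs {m1.nobs_})"
        )
    stat = 2.0 * (m1.loglik_ - m0.loglik_)
    df = len(m1.terms_) - len(m0.terms_)
    if df <= 0:
        raise ValueError("m1 has no extra parameters over m0")
    return LRTestResult(statistic=stat, df=df, pvalue=lr_pvalue(stat, df))


def coefficient_report(m0: LogLinearRegression,
                       m1: LogLinearRegression) -> str:
    """Human-readable side-by-side coefficient table for the two models."""
    rows = ["intercept"] + sorted(
        set(m0.terms_) | set(m1.terms_),
        key=lambda t: (t not in m0.terms_, t),
    )
    width = max(len(r) for r in rows) + 2
    lines = [
        f"{'term':<{width}}{'M0':>12}{'p':>9}{'M1':>12}{'p':>9}",
        "-" * (width + 42),
    ]
    for term in rows:
        cells = []
        for m in (m0, m1):
            if term in m.coef_.index:
                cells.append(f"{m.coef_[term]:>12.4f}{m.pvalues_[term]:>9.4f}")
            else:
                cells.append(f"{'—':>12}{'':>9}")
        lines.append(f"{term:<{width}}" + "".join(cells))
    lines.append("-" * (width + 42))
    lines.append(
        f"{'AIC':<{width}}{m0.aic_:>12.1f}{'':>9}{m1.aic_:>12.1f}{'':>9}"
    )
    lines.append(
        f"{'adj R2':<{width}}{m0.rsquared_adj_:>12.4f}{'':>9}"
        f"{m1.rsquared_adj_:>12.4f}{'':>9}"
    )
    return "\n".join(lines)
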