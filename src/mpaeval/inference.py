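"""Causal-inference engine: BACI difference-in-differences and before-after fits.

The biological model regresses a per-transect indicator value
:math:`I_{i,t,z}` on year factors (first survey year as reference), a
zone dummy Z (control = 0, reserve = 1), the interaction of Z with a
post-implementation dummy P (before = 0, after = 1), and the
environmental covariates temperature, visibility and depth:

.. math::

    I_{i,t,z} = \\beta_0 + \\sum_{t=2}^{T}\\gamma_t Y_t + \\beta_1 Z
                + \\beta_2 P \\times Z + \\beta_3 T + \\beta_4 V
                + \\beta_5 D + \\epsilon

There is no standalone P main effect: the year factors span it.  The
interaction coefficient :math:`\\beta_2` is the difference-in-
differences estimate of the reserve effect — the difference between
the temporal trends of reserve and control.  With exactly two periods,
two zones and no covariates it reduces to the textbook difference of
group-mean differences.

Economic series lack a control site and use the simplified before-after
model :math:`I_t = \\beta_0 + \\beta_1 P_t + \\epsilon_t`, whose slope is
algebraically the difference of period means; it measures change but
does not support causal attribution.

Both models are fit by OLS; inference uses heteroskedasticity-robust
(sandwich) standard errors (HC0-HC3, default HC1) and Student-t tests
with df = n - rank(X).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .errors import DesignError, ValidationError
from .surveys import COVARIATE_COLUMNS, _post_boundary

logger = logging.getLogger(__name__)

HC_FLAVORS = ("HC0", "HC1", "HC2", "HC3")


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """OLS fit with heteroskedasticity-robust inference."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    cov: pd.DataFrame
    resid: np.ndarray
    nobs: int
    df_resid: int
    rsquared: float
    cov_type: str
    n_dropped: int = 0
    used_covariates: tuple[str, ...] = ()

    def coef_table(self) -> pd.DataFrame:
        """Tidy coefficient table (term, estimate, robust_se, t, p)."""
        return pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": self.params.values,
                "robust_se": self.bse.values,
                "t": self.tvalues.values,
                "p": self.pvalues.values,
            }
        )


@dataclass
class EffectEstimate:
    """The headline reserve-effect coefficient for one indicator."""

    indicator: str
    community: str
    scope: str
    beta: float
    se: float
    t: float
    p: float
    model: str  # "did" | "before_after"
    n: int
    causal: bool
    fit: FitResult | None = field(default=None, repr=False)

    @property
    def category(self) -> str:
        return "biological" if self.indicator.startswith("B") else "socioeconomic"


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def build_design_matrix(
    table: pd.DataFrame,
    implementation_year: int,
    post_from: str = "impl-year",
    covariates: tuple[str, ...] = COVARIATE_COLUMNS,
    fallback_drop_threshold: float = 0.5,
) -> tuple[pd.Series, pd.DataFrame, dict]:
    """Build the BACI design matrix from a tidy indicator table.

    Columns, in order: intercept, one dummy per survey year except the
    earliest (reference level), zone dummy Z, interaction P x Z, then
    the covariates.  Rows with a missing response are dropped; rows
    with missing covariates are dropped listwise unless that would
    remove more than ``fallback_drop_threshold`` of the data, in which
    case the model falls back to the covariate-free specification
    (logged).

    Returns ``(y, X, info)`` where ``info`` records dropped-row counts
    and the covariates actually used.
    """
    required = {"zone", "year", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"indicator table lacks column(s) {sorted(missing)}")

    d = table[table["value"].notna()].copy()
    n_undefined = len(table) - len(d)
    if d.empty:
        raise DesignError("no defined indicator values to fit")

    zones = sorted(set(d["zone"]))
    years = sorted(set(d["year"]))
    if len(zones) < 2:
        raise DesignError(
            f"single zone {zones}: both reserve and control are required"
        )
    if len(years) < 2:
        raise DesignError(f"single survey year {years}: at least two required")
    boundary = _post_boundary(implementation_year, post_from)
    if not any(y < boundary for y in years):
        raise DesignError("no pre-implementation years: interaction unidentified")
    if not any(y >= boundary for y in years):
        raise DesignError("no post-implementation years: interaction unidentified")

    use_cov = [c for c in covariates if c in d.columns]
    n_rows = len(d)
    if use_cov:
        complete = d[use_cov].notna().all(axis=1)
        frac_drop = 1.0 - complete.mean()
        if frac_drop > fallback_drop_threshold:
            logger.warning(
                "covariates missing on %.0f%% of rows; falling back to the "
                "covariate-free model", 100 * frac_drop,
            )
            use_cov = []
        elif frac_drop > 0:
            logger.info(
                "dropping %d/%d rows with missing covariates",
                int((~complete).sum()), n_rows,
            )
            d = d[complete]
    n_dropped_cov = n_rows - len(d)

    X = pd.DataFrame(index=d.index)
    X["const"] = 1.0
    for y in years[1:]:
        X[f"year_{y}"] = (d["year"] == y).astype(float)
    X["zone"] = (d["zone"] == "reserve").astype(float)
    post = (d["year"] >= boundary).astype(float)
    X["post_x_zone"] = post * X["zone"]
    for c in use_cov:
        X[c] = d[c].astype(float)

    _check_rank(X)
    info = {
        "n_undefined": n_undefined,
        "n_dropped_covariates": n_dropped_cov,
        "used_covariates": tuple(use_cov),
        "post_boundary": boundary,
    }
    return d["value"].astype(float), X, info


def _check_rank(X: pd.DataFrame) -> None:
    """Raise a DesignError naming collinear columns if X is rank-deficient."""
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank == X.shape[1]:
        return
    # identify offending columns via pivoted QR
    _, r, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps
    bad = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    bad += [X.columns[j] for j in piv[len(diag):]]
    raise DesignError(
        f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
        f"collinear column(s): {bad}"
    )


# ---------------------------------------------------------------------------
# OLS + sandwich machinery
# ---------------------------------------------------------------------------

def ols_fit(y, X: pd.DataFrame, cov_type: str = "HC1") -> FitResult:
    """Fit OLS and return robust (sandwich) inference.

    ``cov_type`` is one of HC0-HC3 (or ``"nonrobust"`` for classical
    SEs).  p-values come from a two-sided Student-t test with
    df = n - rank(X).
    """
    if cov_type not in HC_FLAVORS + ("nonrobust",):
        raise ValidationError(
            f"unknown robust flavor {cov_type!r}; expected one of {HC_FLAVORS}"
        )
    _check_rank(X)
    if len(X) <= X.shape[1]:
        raise DesignError(
            f"n = {len(X)} observations with {X.shape[1]} parameters: "
            "no residual degrees of freedom"
        )
    model = sm.OLS(np.asarray(y, dtype=float), X.astype(float))
    # use_t: the t test with df = n - rank, rather than the normal
    # approximation statsmodels defaults to under robust covariances.
    res = model.fit(cov_type=cov_type, use_t=True)
    return FitResult(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        resid=np.asarray(res.resid),
        nobs=int(res.nobs),
        df_resid=int(res.df_resid),
        rsquared=float(res.rsquared),
        cov_type=cov_type,
    )


def robust_vcov(X, resid, flavor: str = "HC1") -> np.ndarray:
    """Heteroskedasticity-consistent sandwich covariance of the OLS estimator.

    (X'X)^-1 X' diag(w_i e_i^2) X (X'X)^-1 with weights

    - HC0: w_i = 1
    - HC1: w_i = n / (n - k)
    - HC2: w_i = 1 / (1 - h_i)
    - HC3: w_i = 1 / (1 - h_i)^2

    where h_i is the i-th leverage (hat-matrix diagonal).
    """
    if flavor not in HC_FLAVORS:
        raise ValidationError(
            f"unknown robust flavor {flavor!r}; expected one of {HC_FLAVORS}"
        )
    Xa = np.asarray(X, dtype=float)
    e = np.asarray(resid, dtype=float)
    n, k = Xa.shape
    xtx_inv = np.linalg.inv(Xa.T @ Xa)
    if flavor == "HC0":
        w = np.ones(n)
    elif flavor == "HC1":
        w = np.full(n, n / (n - k))
    else:
        h = np.einsum("ij,jk,ik->i", Xa, xtx_inv, Xa)
        w = 1.0 / (1.0 - h) if flavor == "HC2" else 1.0 / (1.0 - h) ** 2
    meat = (Xa * (w * e**2)[:, None]).T @ Xa
    return xtx_inv @ meat @ xtx_inv


def t_and_p(estimate: float, se: float, df: int) -> tuple[float, float]:
    """Two-sided Student-t test of H0: coefficient = 0.

    A zero standard error (perfect fit) returns an infinite t with
    p = 0.
    """
    if se < 0:
        raise ValidationError("standard error must be non-negative")
    if se == 0:
        return float(np.copysign(np.inf, estimate)) if estimate else 0.0, \
            (0.0 if estimate else 1.0)
    t = estimate / se
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class DifferenceInDifferencesRegressor(BaseEstimator):
    """BACI difference-in-differences regression for one indicator.

    scikit-learn style estimator: hyper-parameters in ``__init__``,
    data in :meth:`fit`, fitted attributes with trailing underscores.

    Parameters
    ----------
    implementation_year : int
        Year the reserve was implemented.
    cov_type : {"HC0", "HC1", "HC2", "HC3"}, default "HC1"
        Heteroskedasticity-robust covariance flavor.
    post_from : {"impl-year", "impl-year+1"}, default "impl-year"
        Whether the implementation year itself counts as "after".
    covariates : tuple of str
        Environmental covariate columns to adjust for.
    fallback_drop_threshold : float, default 0.5
        If listwise deletion of missing covariates would drop more than
        this fraction of rows, refit without covariates instead.

    Attributes
    ----------
    coef_, bse_, tvalues_, pvalues_ : pandas.Series
    cov_ : pandas.DataFrame
    effect_, effect_se_, effect_t_, effect_p_ : float
        The interaction (reserve-effect) coefficient and its inference.
    nobs_, df_resid_ : int
    rsquared_ : float
    design_columns_ : list of str

    Examples
    --------
    >>> est = DifferenceInDifferencesRegressor(implementation_year=2006)
    >>> est.fit(indicator_table)             # doctest: +SKIP
    >>> est.effect_, est.effect_p_           # doctest: +SKIP
    """

    def __init__(
        self,
        implementation_year: int | None = None,
        cov_type: str = "HC1",
        post_from: str = "impl-year",
        covariates: tuple[str, ...] = COVARIATE_COLUMNS,
        fallback_drop_threshold: float = 0.5,
    ):
        self.implementation_year = implementation_year
        self.cov_type = cov_type
        self.post_from = post_from
        self.covariates = covariates
        self.fallback_drop_threshold = fallback_drop_threshold

    def fit(self, table: pd.DataFrame, y=None):
        """Fit the model on a tidy per-transect indicator table.

        ``table`` needs columns ``zone``, ``year``, ``value`` and
        optionally the covariates; ``y`` is ignored (the response is
        the ``value`` column) and accepted only for sklearn API
        compatibility.
        """
        if self.implementation_year is None:
            raise ValidationError("implementation_year must be set before fit")
        if not isinstance(table, pd.DataFrame):
            raise ValidationError("fit expects a tidy pandas DataFrame")
        resp, X, info = build_design_matrix(
            table,
            implementation_year=self.implementation_year,
            post_from=self.post_from,
            covariates=tuple(self.covariates),
            fallback_drop_threshold=self.fallback_drop_threshold,
        )
        fr = ols_fit(resp, X, cov_type=self.cov_type)
        fr.n_dropped = info["n_dropped_covariates"]
        fr.used_covariates = info["used_covariates"]
        self.result_ = fr
        self.coef_ = fr.params
        self.bse_ = fr.bse
        self.tvalues_ = fr.tvalues
        self.pvalues_ = fr.pvalues
        self.cov_ = fr.cov
        self.nobs_ = fr.nobs
        self.df_resid_ = fr.df_resid
        self.rsquared_ = fr.rsquared
        self.design_columns_ = list(X.columns)
        self.effect_ = float(fr.params["post_x_zone"])
        self.effect_se_ = float(fr.bse["post_x_zone"])
        self.effect_t_ = float(fr.tvalues["post_x_zone"])
        self.effect_p_ = float(fr.pvalues["post_x_zone"])
        return self

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Model-implied indicator values for the rows of ``table``."""
        if not hasattr(self, "result_"):
            raise ValidationError("estimator is not fitted")
        _, X, _ = build_design_matrix(
            table,
            implementation_year=self.implementation_year,
            post_from=self.post_from,
            covariates=tuple(self.result_.used_covariates),
        )
        X = X.reindex(columns=self.design_columns_, fill_value=0.0)
        return X.to_numpy() @ self.coef_.to_numpy()

    def effect_estimate(
        self, indicator: str = "", community: str = "", scope: str = "all"
    ) -> EffectEstimate:
        """Package the interaction coefficient as an :class:`EffectEstimate`."""
        if not hasattr(self, "result_"):
            raise ValidationError("estimator is not fitted")
        return EffectEstimate(
            indicator=indicator,
            community=community,
            scope=scope,
            beta=self.effect_,
            se=self.effect_se_,
            t=self.effect_t_,
            p=self.effect_p_,
            model="did",
            n=self.nobs_,
            causal=True,
            fit=self.result_,
        )


class BeforeAfterEstimator(BaseEstimator):
    """Before-after mean-shift model for annual economic series.

    Fits ``value = b0 + b1 * P`` by OLS on the post-period dummy;
    ``b1`` is algebraically the difference between the post- and
    pre-period means.  Robust SEs keep inference consistent with the
    BACI model, but without a control site the estimate is flagged
    non-causal.
    """

    def __init__(
        self,
        implementation_year: int | None = None,
        cov_type: str = "HC1",
        post_from: str = "impl-year",
    ):
        self.implementation_year = implementation_year
        self.cov_type = cov_type
        self.post_from = post_from

    def fit(self, series: pd.Series, y=None):
        """Fit on a pandas Series indexed by year (or a year->value dict)."""
        if self.implementation_year is None:
            raise ValidationError("implementation_year must be set before fit")
        if isinstance(series, dict):
            series = pd.Series(series)
        if not isinstance(series, pd.Series):
            raise ValidationError("fit expects a year-indexed pandas Series")
        series = series.dropna().sort_index()
        years = series.index.astype(int)
        boundary = _post_boundary(self.implementation_year, self.post_from)
        post = (years >= boundary).astype(float)
        if post.min() == post.max():
            raise DesignError(
                "before-after model needs at least one year on each side of "
                f"the implementation boundary {boundary}; got years "
                f"{list(years)}"
            )
        X = pd.DataFrame({"const": 1.0, "post": post}, index=series.index)
        fr = ols_fit(series, X, cov_type=self.cov_type)
        self.result_ = fr
        self.coef_ = fr.params
        self.nobs_ = fr.nobs
        self.df_resid_ = fr.df_resid
        self.rsquared_ = fr.rsquared
        self.effect_ = float(fr.params["post"])
        self.effect_se_ = float(fr.bse["post"])
        self.effect_t_ = float(fr.tvalues["post"])
        self.effect_p_ = float(fr.pvalues["post"])
        return self

    def effect_estimate(
        self, indicator: str = "", scope: str = "all"
    ) -> EffectEstimate:
        if not hasattr(self, "result_"):
            raise ValidationError("estimator is not fitted")
        return EffectEstimate(
            indicator=indicator,
            community="",
            scope=scope,
            beta=self.effect_,
            se=self.effect_se_,
            t=self.effect_t_,
            p=self.effect_p_,
            model="before_after",
            n=self.nobs_,
            causal=False,
            fit=self.result_,
        )


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def did_effect(
    table: pd.DataFrame,
    implementation_year: int,
    cov_type: str = "HC1",
    post_from: str = "impl-year",
    indicator: str = "",
    community: str = "",
    scope: str = "all",
) -> EffectEstimate:
    """Fit the BACI difference-in-differences model; return the effect."""
    est = DifferenceInDifferencesRegressor(
        implementation_year=implementation_year,
        cov_type=cov_type,
        post_from=post_from,
    ).fit(table)
    return est.effect_estimate(indicator=indicator, community=community,
                               scope=scope)


def before_after_effect(
    series,
    implementation_year: int,
    cov_type: str = "HC1",
    post_from: str = "impl-year",
    indicator: str = "",
    scope: str = "all",
) -> EffectEstimate:
    """Fit the before-after mean-shift model; return the (non-causal) effect."""
    est = BeforeAfterEstimator(
        implementation_year=implementation_year,
        cov_type=cov_type,
        post_from=post_from,
    ).fit(series)
    return est.effect_estimate(indicator=indicator, scope=scope)
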