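"""Proportional-odds diagnostic models and nested-model comparison.

The consciousness outcome is an ordered three-level variable
(UWS < MCS < EMCS).  The cumulative-logit (proportional-odds) model is

    P(Y <= k | x) = logistic(theta_k - x' beta),   theta_1 < ... < theta_{K-1}

so a positive coefficient means higher odds of a *higher* consciousness
level.  Fitting is maximum likelihood via statsmodels' ordinal model; this
module adds the comparison machinery used to judge whether ECG-derived
respiration complexity (ApEn) improves the EEG-descriptor model: Wilks
likelihood-ratio tests between nested fits, Nagelkerke pseudo-R², and the
full model battery (ApEn only / descriptors only / combined / drop-one
reductions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as st

from .errors import InvalidArgumentError
from .groupstats import TestResult

__all__ = [
    "OrdinalFit",
    "ModelComparison",
    "fit_proportional_odds",
    "null_minus2ll",
    "nagelkerke_r2",
    "likelihood_ratio_test",
    "compare_models",
]

DESCRIPTOR_COLUMNS = ("frequency_theta", "apg", "reactivity")


@dataclass
class OrdinalFit:
    """A fitted proportional-odds model."""

    predictors: tuple[str, ...]
    thresholds: np.ndarray
    coefficients: pd.DataFrame  # index: predictor; columns: beta, se, ci_low, ci_high, p
    minus2ll: float
    n: int
    converged: bool
    outcome_levels: tuple[str, ...]
    warnings_: list[str] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return len(self.thresholds) + len(self.predictors)

    def coef(self, name: str) -> float:
        return float(self.coefficients.loc[name, "beta"])


def _validate_design(X: pd.DataFrame, y: pd.Series) -> None:
    if y.nunique() < 2:
        raise InvalidArgumentError("outcome must have at least 2 observed levels")
    for col in X.columns:
        if np.ptp(X[col].to_numpy(dtype=float)) == 0:
            raise InvalidArgumentError(f"predictor {col!r} is constant")


def _detect_separation(X: pd.DataFrame, coefs: np.ndarray, se: np.ndarray) -> bool:
    # crude but effective: exploding coefficients with huge standard errors
    return bool(np.any(np.abs(coefs) > 15) or np.any(se > 50))


def fit_proportional_odds(
    data: pd.DataFrame,
    predictors: tuple[str, ...] | list[str],
    outcome: str = "group",
    outcome_order: tuple[str, ...] = ("UWS", "MCS", "EMCS"),
) -> OrdinalFit:
    """Fit a cumulative-logit model of the ordered outcome on the predictors.

    Sign convention: positive beta raises the odds of a higher outcome
    level.  Wald 95% confidence intervals and p-values per coefficient.
    Non-convergence and (quasi-)complete separation are flagged on the
    returned fit rather than raised, so the model battery can report them.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    predictors = tuple(predictors)
    if not predictors:
        raise InvalidArgumentError("need at least one predictor; use null_minus2ll for the thresholds-only model")
    present = [lv for lv in outcome_order if lv in set(data[outcome].astype(str))]
    y = pd.Series(
        pd.Categorical(data[outcome].astype(str), categories=present, ordered=True),
        index=data.index,
        name=outcome,
    )
    X = data.loc[:, list(predictors)].astype(float)
    _validate_design(X, pd.Series(y))

    model = OrderedModel(y, X, distr="logit")
    fit_warnings: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="bfgs", maxiter=500, disp=False)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception as exc:  # pragma: no cover - defensive
            raise InvalidArgumentError(f"ordinal fit failed: {exc}") from exc
    if not converged:
        fit_warnings.append("optimizer did not report convergence")

    k_pred = len(predictors)
    params = np.asarray(res.params)
    betas = params[:k_pred]
    se_all = np.asarray(res.bse)
    se = se_all[:k_pred]
    # statsmodels parameterizes thresholds as (theta_1, log increments)
    thresholds = model.transform_threshold_params(params)[1:-1]
    z = st.norm.ppf(0.975)
    coef_table = pd.DataFrame(
        {
            "beta": betas,
            "se": se,
            "ci_low": betas - z * se,
            "ci_high": betas + z * se,
            "p": 2 * st.norm.sf(np.abs(betas) / np.where(se > 0, se, np.inf)),
        },
        index=list(predictors),
    )
    if _detect_separation(X, betas, se):
        fit_warnings.append("possible complete or quasi-complete separation")
    return OrdinalFit(
        predictors=predictors,
        thresholds=np.asarray(thresholds, dtype=float),
        coefficients=coef_table,
        minus2ll=float(-2.0 * res.llf),
        n=int(len(y)),
        converged=converged,
        outcome_levels=tuple(present),
        warnings_=fit_warnings,
    )


def null_minus2ll(data: pd.DataFrame, outcome: str = "group") -> float:
    """-2 log-likelihood of the thresholds-only (intercept) ordinal model.

    With no predictors the MLE fitted probabilities are the observed class
    proportions, so the maximized log-likelihood is sum(n_k log(n_k/n)) in
    closed form.
    """
    counts = data[outcome].astype(str).value_counts().to_numpy(dtype=float)
    n = counts.sum()
    return float(-2.0 * np.sum(counts * np.log(counts / n)))


def nagelkerke_r2(fit: OrdinalFit | float, null_m2ll: float, n: int | None = None) -> float:
    """Nagelkerke pseudo-R² of a fit against the thresholds-only model.

    R²_CS = 1 - exp((m2ll_full - m2ll_null)/n);  R²_N = R²_CS / (1 - exp(-m2ll_null/n)).
    Accepts either an :class:`OrdinalFit` or a raw -2LL value (then `n` is
    required).  Values are clipped into [0, 1] against floating-point noise.
    """
    if isinstance(fit, OrdinalFit):
        m2ll, n_obs = fit.minus2ll, fit.n
    else:
        if n is None:
            raise InvalidArgumentError("n is required when passing a raw -2LL")
        m2ll, n_obs = float(fit), int(n)
    cox_snell = 1.0 - np.exp((m2ll - null_m2ll) / n_obs)
    max_cs = 1.0 - np.exp(-null_m2ll / n_obs)
    if max_cs <= 0:
        return 0.0
    return float(np.clip(cox_snell / max_cs, 0.0, 1.0))


def likelihood_ratio_test(full: OrdinalFit, reduced: OrdinalFit | float, df: int | None = None) -> TestResult:
    """Wilks likelihood-ratio test of a reduced model nested in the full one.

    Delta = m2ll_reduced - m2ll_full, chi-square on the parameter-count
    difference.  The reduced model may be passed as a raw -2LL (the
    thresholds-only null), in which case `df` must be given.
    """
    if isinstance(reduced, OrdinalFit):
        if reduced.n != full.n:
            raise InvalidArgumentError("nested models must be fitted on the same data")
        if not set(reduced.predictors) <= set(full.predictors):
            raise InvalidArgumentError("reduced model is not nested in the full model")
        delta_df = full.n_params - reduced.n_params
        reduced_m2ll = reduced.minus2ll
    else:
        if df is None:
            raise InvalidArgumentError("df required when the reduced model is a raw -2LL")
        delta_df = df
        reduced_m2ll = float(reduced)
    delta = reduced_m2ll - full.minus2ll
    if delta < 0:
        # numerically the full model can sit a hair below; treat tiny negatives as 0
        if delta < -1e-6 * max(1.0, abs(full.minus2ll)):
            raise InvalidArgumentError(
                f"reduced model fits better than the full model (delta={delta:.6f}); models are not nested on the same data"
            )
        delta = 0.0
    p = float(st.chi2.sf(delta, delta_df)) if delta_df > 0 else 1.0
    return TestResult(
        statistic=float(delta),
        df=delta_df,
        p_value=p if delta > 0 else 1.0,
        method="likelihood-ratio (Wilks)",
    )


@dataclass
class ModelComparison:
    """The model battery: ApEn-only (A), descriptors-only (B), combined (C),
    plus the drop-one reductions of C, with LRTs and Nagelkerke R²."""

    fits: dict  # name -> OrdinalFit
    null_m2ll: float
    r2: dict  # name -> Nagelkerke R²
    lrt: pd.DataFrame  # comparison, delta_m2ll, df, p

    def fit(self, name: str) -> OrdinalFit:
        return self.fits[name]


def compare_models(
    cohort: pd.DataFrame,
    apen_col: str = "apen",
    descriptor_cols: tuple[str, ...] = DESCRIPTOR_COLUMNS,
    outcome: str = "group",
) -> ModelComparison:
    """Fit the competing ordinal diagnostic models and their comparisons.

    Models: ``A`` (ApEn only), ``B`` (EEG descriptors only), ``C`` (both),
    and ``C_drop_<predictor>`` for each predictor of C.  Reports Nagelkerke
    R² per model and Wilks LRTs of C against B (does ApEn add information?)
    and against each drop-one reduction.  The nesting inequality
    m2ll(C) <= m2ll(reduced) is verified on every run.
    """
    for col in (apen_col, *descriptor_cols, outcome):
        if col not in cohort.columns:
            raise InvalidArgumentError(f"cohort table is missing column {col!r}")
    full_preds = (apen_col, *descriptor_cols)
    fits: dict[str, OrdinalFit] = {}
    fits["A"] = fit_proportional_odds(cohort, (apen_col,), outcome=outcome)
    fits["B"] = fit_proportional_odds(cohort, descriptor_cols, outcome=outcome)
    fits["C"] = fit_proportional_odds(cohort, full_preds, outcome=outcome)
    for drop in full_preds:
        kept = tuple(p for p in full_preds if p != drop)
        fits[f"C_drop_{drop}"] = fit_proportional_odds(cohort, kept, outcome=outcome)

    null_m2ll = null_minus2ll(cohort, outcome=outcome)
    r2 = {name: nagelkerke_r2(f, null_m2ll) for name, f in fits.items()}

    rows = []
    for name, f in fits.items():
        if name == "C":
            continue
        if set(f.predictors) <= set(full_preds):
            slack = 1e-6 * max(1.0, abs(fits["C"].minus2ll))
            if fits["C"].minus2ll > f.minus2ll + slack:
                raise InvalidArgumentError(
                    f"nesting violated: -2LL(C)={fits['C'].minus2ll:.3f} > -2LL({name})={f.minus2ll:.3f}"
                )
            res = likelihood_ratio_test(fits["C"], f)
            rows.append(
                {
                    "comparison": f"C vs {name}",
                    "delta_minus2ll": res.statistic,
                    "df": res.df,
                    "p": res.p_value,
                }
            )
    return ModelComparison(
        fits=fits, null_m2ll=null_m2ll, r2=r2, lrt=pd.DataFrame(rows)
    )
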