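"""Phenomenological classification of functional-response shape.

Before fitting a mechanistic curve, the shape of the response is diagnosed
from the proportion of prey killed (partially and completely eaten prey both
count as killed).  A binomial GLM with logit link regresses kills out of
initial density on a polynomial in density:

    logit(Ne / N0) = b0 + b1 * N0 + b2 * N0^2

A significant negative first-order term indicates a Type II response
(proportion killed declines from low density upward); a significant positive
first-order term followed by a significant negative second-order term
indicates Type III (the proportion peaks at intermediate density).  Anything
else is inconclusive, in which case single-curve Type I / II / III fits are
compared by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .fit import fit_variant

__all__ = [
    "LogisticPolyFit",
    "TypeTestResult",
    "fit_logistic_poly",
    "classify_response",
    "aic_model_comparison",
    "classify_module",
]


@dataclass
class LogisticPolyFit:
    """Binomial GLM of proportion killed against a density polynomial."""

    coef: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    converged: bool
    degree: int
    n: int


@dataclass
class TypeTestResult:
    logistic: LogisticPolyFit | None
    classification: str  # "TypeII", "TypeIII", or "inconclusive"
    aic_table: pd.DataFrame | None = field(default=None)
    selected_variant: str | None = None

    @property
    def resolved_type(self) -> str:
        """Sign-rule classification, falling back on the AIC winner."""
        if self.classification != "inconclusive":
            return self.classification
        if self.selected_variant is not None:
            return {"I": "TypeI", "II": "TypeII", "III": "TypeIII"}[self.selected_variant]
        return "inconclusive"


def fit_logistic_poly(records: pd.DataFrame, degree: int = 2) -> LogisticPolyFit:
    """Fit the logit-link binomial GLM of kills/density on density powers.

    Density enters untransformed and uncentred so the sign rules apply to the
    raw first- and second-order coefficients.  Estimation is IRLS; complete
    separation (or any IRLS failure) is returned as a non-converged result
    with NaN statistics rather than raising.
    """
    if records["density"].nunique() < 3:
        raise ValueError("type test requires at least 3 distinct prey densities")
    n0 = records["density"].to_numpy(dtype=float)
    killed = records["killed"].to_numpy(dtype=float)
    if np.any(killed > n0):
        raise ValueError("killed counts exceed initial densities")
    exog = np.column_stack([n0**d for d in range(degree + 1)])
    endog = np.column_stack([killed, n0 - killed])
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(endog, exog, family=sm.families.Binomial())
            res = model.fit(maxiter=100)
        converged = bool(getattr(res, "converged", True)) and np.all(
            np.isfinite(res.bse)
        )
        return LogisticPolyFit(
            coef=np.asarray(res.params),
            se=np.asarray(res.bse),
            pvalues=np.asarray(res.pvalues),
            converged=converged,
            degree=degree,
            n=len(records),
        )
    except Exception:
        nan = np.full(degree + 1, np.nan)
        return LogisticPolyFit(
            coef=nan, se=nan.copy(), pvalues=nan.copy(), converged=False,
            degree=degree, n=len(records),
        )


def classify_response(fit: LogisticPolyFit, alpha: float = 0.05) -> str:
    """Apply the sign/significance rules to a fitted density polynomial."""
    if not fit.converged or fit.degree < 1:
        return "inconclusive"
    b1, p1 = fit.coef[1], fit.pvalues[1]
    if p1 < alpha and b1 < 0:
        return "TypeII"
    if fit.degree >= 2:
        b2, p2 = fit.coef[2], fit.pvalues[2]
        if p1 < alpha and b1 > 0 and p2 < alpha and b2 < 0:
            return "TypeIII"
    return "inconclusive"


def aic_model_comparison(records: pd.DataFrame, t: float = 1.0) -> tuple:
    """Single-curve Type I / II / III fits compared by AIC (= 2k - 2 logLik).

    Returns ``(aic_table, selected_variant)``; variants that fail to converge
    appear with NaN statistics and are excluded from selection.
    """
    rows = []
    for variant in ("I", "II", "III"):
        try:
            res = fit_variant(records, variant, t=t)
            ok = res.converged or (res.se_available and not res.boundary)
            rows.append(
                {
                    "variant": variant,
                    "logLik": res.loglik if ok else np.nan,
                    "k": res.n_params,
                    "AIC": res.aic if ok else np.nan,
                    "converged": ok,
                }
            )
        except Exception:
            rows.append(
                {"variant": variant, "logLik": np.nan, "k": np.nan, "AIC": np.nan,
                 "converged": False}
            )
    table = pd.DataFrame(rows)
    usable = table.dropna(subset=["AIC"])
    selected = None if usable.empty else str(usable.loc[usable["AIC"].idxmin(), "variant"])
    return table, selected


def classify_module(
    records: pd.DataFrame, alpha: float = 0.05, degree: int = 2, t: float = 1.0
) -> TypeTestResult:
    """Full workflow for one community module: sign rules, then AIC fallback."""
    logistic = fit_logistic_poly(records, degree=degree)
    classification = classify_response(logistic, alpha=alpha)
    aic_table = None
    selected = None
    if classification == "inconclusive":
        aic_table, selected = aic_model_comparison(records, t=t)
    return TypeTestResult(
        logistic=logistic,
        classification=classification,
        aic_table=aic_table,
        selected_variant=selected,
    )
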