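"""Additive gene-lifestyle interaction via RERI.

Both summary exposures are dichotomised — lifestyle risk = intermediate or
unhealthful group (vs healthful), genetic risk = GRS at or above the cohort
median — and entered with their product term. For the binary outcome,

    RERI = OR11 - OR10 - OR01 + 1,

with odds ratios standing in for risk ratios; RERI > 0 indicates risks more
than additive, 0 exact additivity. Confidence intervals come from the delta
method on (betaA, betaB, betaAB) by default, or from seeded subject
bootstrap. For continuous blood pressure the additive-interaction contrast
of adjusted means equals the product-term coefficient itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .models import (
    FitError,
    ModelFit,
    Z95,
    _covs_for,
    covariate_design,
    fit_linear,
    fit_logistic,
)

_OUTCOME_COLUMN = {"hypertension": "hypertension", "sbp": "followup_sbp", "dbp": "followup_dbp"}


@dataclass
class ReriResult:
    outcome: str
    estimate: float
    ci_low: float
    ci_high: float
    method: str
    lifestyle_split: str = "healthful vs intermediate+unhealthful"
    grs_split: str = "upper vs lower half (median inclusive above)"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")


def dichotomize_for_reri(scored: pd.DataFrame) -> pd.DataFrame:
    """Binary exposures for the RERI models.

    lifestyle_risk = 1 unless the subject is in the healthful group;
    genetic_risk = 1 iff the GRS is in the upper half (values exactly at
    the median count as upper).
    """
    data = scored[scored["grs"].notna()]
    median = float(np.median(data["grs"].to_numpy(dtype=float)))
    return pd.DataFrame(
        {
            "lifestyle_risk": (data["lifestyle_group"] != "healthful").astype(float),
            "genetic_risk": (data["grs"] >= median).astype(float),
        },
        index=data.index,
    )


def _reri_from_params(fit: ModelFit, a: str, b: str, ab: str) -> tuple[float, float]:
    """Point estimate and delta-method SE of RERI from a logistic fit."""
    for name in (a, b, ab):
        if name not in fit.coefficients.index:
            raise FitError(f"fit lacks required coefficient {name!r} (product term?)")
    ba, bb, bab = (float(fit.coefficients[k]) for k in (a, b, ab))
    or11 = np.exp(ba + bb + bab)
    reri = or11 - np.exp(ba) - np.exp(bb) + 1.0
    grad = pd.Series(
        {a: or11 - np.exp(ba), b: or11 - np.exp(bb), ab: or11}
    )
    cov = fit.covariance.loc[grad.index, grad.index].to_numpy(dtype=float)
    var = float(grad.to_numpy() @ cov @ grad.to_numpy())
    return float(reri), float(np.sqrt(max(var, 0.0)))


def reri_binary(fit: ModelFit, a: str = "lifestyle_risk", b: str = "genetic_risk",
                ab: str = "interaction") -> ReriResult:
    """RERI with a delta-method 95% CI from a fitted logistic model."""
    reri, se = _reri_from_params(fit, a, b, ab)
    return ReriResult(
        outcome=fit.outcome,
        estimate=reri,
        ci_low=reri - Z95 * se,
        ci_high=reri + Z95 * se,
        method="delta",
    )


def reri_continuous(fit: ModelFit, ab: str = "interaction") -> ReriResult:
    """Additive-interaction contrast for a continuous outcome.

    On the mean-difference scale the excess beyond additivity,
    beta11 - beta10 - beta01, is exactly the product-term coefficient, so
    the estimate and its Wald CI are read off the fit directly.
    """
    if ab not in fit.coefficients.index:
        raise FitError(f"fit lacks required coefficient {ab!r} (product term?)")
    est, lo, hi = fit.wald_ci(ab)
    return ReriResult(
        outcome=fit.outcome, estimate=est, ci_low=lo, ci_high=hi, method="delta"
    )


def _build_design(
    scored: pd.DataFrame, config: AnalysisConfig, adjusted: bool
) -> tuple[pd.DataFrame, pd.DataFrame]:
    expo = dichotomize_for_reri(scored)
    expo["interaction"] = expo["lifestyle_risk"] * expo["genetic_risk"]
    data = scored.loc[expo.index]
    design = (
        pd.concat([expo, covariate_design(data, config.covariate_set)], axis=1)
        if adjusted
        else expo
    )
    return data, design


def reri_panel(
    scored: pd.DataFrame,
    config: AnalysisConfig | None = None,
    adjusted: bool = True,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Three-row RERI table: hypertension, SBP and DBP.

    Delta-method intervals by default; ``config.reri_ci_method='bootstrap'``
    resamples subjects (``config.bootstrap_reps`` times, seeded) instead.
    """
    config = config or AnalysisConfig()
    data, design = _build_design(scored, config, adjusted)
    rows = []
    for outcome in ("hypertension", "sbp", "dbp"):
        y = data[_OUTCOME_COLUMN[outcome]]
        X = _covs_for(design, outcome)
        if outcome == "hypertension":
            fit = fit_logistic(y, X, outcome_name=outcome)
            res = reri_binary(fit)
        else:
            fit = fit_linear(y, X, outcome_name=outcome)
            res = reri_continuous(fit)
        if config.reri_ci_method == "bootstrap":
            res = _bootstrap_reri(data, config, adjusted, outcome, res, rng)
        rows.append(
            {
                "outcome": outcome,
                "reri": res.estimate,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)


def _bootstrap_reri(
    data: pd.DataFrame,
    config: AnalysisConfig,
    adjusted: bool,
    outcome: str,
    point: ReriResult,
    rng: np.random.Generator | None,
) -> ReriResult:
    rng = rng or np.random.default_rng(config.seed)
    n = len(data)
    stats = []
    for _ in range(config.bootstrap_reps):
        idx = rng.integers(0, n, size=n)
        sample = data.iloc[idx].reset_index(drop=True)
        try:
            sub, design = _build_design(sample, config, adjusted)
            y = sub[_OUTCOME_COLUMN[outcome]]
            X = _covs_for(design, outcome)
            if outcome == "hypertension":
                fit = fit_logistic(y, X, outcome_name=outcome)
                stats.append(reri_binary(fit).estimate)
            else:
                fit = fit_linear(y, X, outcome_name=outcome)
                stats.append(reri_continuous(fit).estimate)
        except FitError:
            continue
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return ReriResult(
        outcome=outcome,
        estimate=point.estimate,
        ci_low=float(min(lo, point.estimate)),
        ci_high=float(max(hi, point.estimate)),
        method="bootstrap",
    )
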