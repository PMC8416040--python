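"""Association models for incident hypertension and blood pressure.

Logistic regression for the binary 3-year hypertension outcome and
ordinary (identity-link Gaussian) linear models for follow-up SBP/DBP,
with three adjustment tiers:

* model1 - unadjusted;
* model2 - adjusted for age, sex, antihypertensive medication, family
  history of hypertension, education, marriage, income, and baseline
  SBP and DBP;
* model3 - model2 plus mutual adjustment (lifestyle and GRS groups in the
  same model).

The joint grid crosses GRS tertiles with lifestyle groups in a single
9-cell model against the low-GRS / healthful-lifestyle reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import AnalysisConfig, DEFAULT_COVARIATES
from .scoring import GRS_GROUPS, LIFESTYLE_GROUPS

Z95 = 1.959963984540054  # two-sided 95% normal quantile

OUTCOMES = {"hypertension": "logistic", "sbp": "linear", "dbp": "linear"}
_OUTCOME_COLUMN = {"hypertension": "hypertension", "sbp": "followup_sbp", "dbp": "followup_dbp"}


class FitError(RuntimeError):
    """A regression could not be fitted (rank deficiency, separation, n<=p)."""


@dataclass
class ModelFit:
    """One fitted regression with named coefficients and Wald inference."""

    coefficients: pd.Series
    covariance: pd.DataFrame
    outcome: str
    kind: str  # "logistic" | "linear"
    n_used: int
    model_tag: str = ""
    effect_estimates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def wald_ci(self, name: str) -> tuple[float, float, float]:
        """(point, lo, hi) on the coefficient scale."""
        beta = float(self.coefficients[name])
        se = float(np.sqrt(self.covariance.loc[name, name]))
        return beta, beta - Z95 * se, beta + Z95 * se

    def effect(self, name: str) -> tuple[float, float, float]:
        """OR (logistic) or beta in mmHg (linear) with its 95% CI."""
        beta, lo, hi = self.wald_ci(name)
        if self.kind == "logistic":
            return float(np.exp(beta)), float(np.exp(lo)), float(np.exp(hi))
        return beta, lo, hi


def _check_design(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy QR-style elimination
        bad = []
        cols: list[int] = []
        for j in range(X.shape[1]):
            trial = cols + [j]
            if np.linalg.matrix_rank(X[:, trial]) < len(trial):
                bad.append(design.columns[j])
            else:
                cols = trial
        raise FitError(f"design is rank deficient; collinear column(s): {bad}")


def fit_logistic(
    outcome: np.ndarray | pd.Series,
    design: pd.DataFrame,
    outcome_name: str = "hypertension",
    model_tag: str = "",
    add_intercept: bool = True,
) -> ModelFit:
    """Maximum-likelihood logistic regression with Wald 95% intervals.

    ``design`` holds the exposure dummies and covariates (no intercept
    column; one is added unless ``add_intercept`` is False). Separation is
    reported as a :class:`FitError` naming the runaway column.
    """
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise FitError("outcome has a single class; logistic model undefined")
    X = design.copy()
    if add_intercept:
        X.insert(0, "intercept", 1.0)
    _check_design(X)
    if len(y) <= X.shape[1]:
        raise FitError(f"n={len(y)} too small for p={X.shape[1]} parameters")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, X.to_numpy(dtype=float), family=sm.families.Binomial()).fit(
            maxiter=100, tol=1e-10
        )
    params = pd.Series(fit.params, index=X.columns)
    bse = pd.Series(fit.bse, index=X.columns)
    runaway = bse.index[(bse > 100) | (params.abs() > 30)]
    if len(runaway):
        raise FitError(f"separation suspected; runaway column(s): {list(runaway)}")
    cov = pd.DataFrame(fit.cov_params(), index=X.columns, columns=X.columns)
    return ModelFit(
        coefficients=params,
        covariance=cov,
        outcome=outcome_name,
        kind="logistic",
        n_used=len(y),
        model_tag=model_tag,
    )


def fit_linear(
    outcome: np.ndarray | pd.Series,
    design: pd.DataFrame,
    outcome_name: str = "sbp",
    model_tag: str = "",
    add_intercept: bool = True,
) -> ModelFit:
    """Ordinary least squares (identity-link Gaussian) with Wald 95% CIs."""
    y = np.asarray(outcome, dtype=float)
    X = design.copy()
    if add_intercept:
        X.insert(0, "intercept", 1.0)
    _check_design(X)
    if len(y) <= X.shape[1]:
        raise FitError(f"n={len(y)} too small for p={X.shape[1]} parameters")
    fit = sm.OLS(y, X.to_numpy(dtype=float)).fit()
    params = pd.Series(fit.params, index=X.columns)
    cov = pd.DataFrame(
        fit.normalized_cov_params * fit.scale, index=X.columns, columns=X.columns
    )
    return ModelFit(
        coefficients=params,
        covariance=cov,
        outcome=outcome_name,
        kind="linear",
        n_used=len(y),
        model_tag=model_tag,
    )


def covariate_design(scored: pd.DataFrame, covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
    """Dummy-code the adjustment covariates.

    Continuous covariates pass through; categorical ones are expanded to
    treatment dummies against their first level.
    """
    cols = {}
    for cov in covariates:
        if cov in ("age", "baseline_sbp", "baseline_dbp"):
            cols[cov] = scored[cov].astype(float)
        elif cov in ("antihypertensive_med", "family_history_htn"):
            cols[cov] = scored[cov].astype(float)
        elif cov == "sex":
            cols["sex_male"] = (scored["sex"] == "male").astype(float)
        elif cov == "education":
            cols["education_junior"] = (scored["education"] == "junior").astype(float)
            cols["education_senior_or_above"] = (
                scored["education"] == "senior_or_above"
            ).astype(float)
        elif cov == "marital":
            cols["marital_other"] = (scored["marital"] == "other").astype(float)
        elif cov == "income":
            cols["income_1000to2999"] = (scored["income"] == "1000to2999").astype(float)
            cols["income_ge3000"] = (scored["income"] == "ge3000").astype(float)
        else:
            raise FitError(f"unknown covariate {cov!r}")
    return pd.DataFrame(cols, index=scored.index)


def _covs_for(covs: pd.DataFrame, outcome: str) -> pd.DataFrame:
    # antihypertensive medication is part of the hypertension outcome
    # definition (medication implies a case), so conditioning on it in the
    # logistic model is degenerate by construction; it stays a covariate for
    # the continuous blood-pressure outcomes only.
    if outcome == "hypertension" and "antihypertensive_med" in covs.columns:
        return covs.drop(columns=["antihypertensive_med"])
    return covs


def _group_dummies(series: pd.Series, levels, prefix: str) -> pd.DataFrame:
    # first level is the reference
    return pd.DataFrame(
        {f"{prefix}_{lvl}": (series == lvl).astype(float) for lvl in levels[1:]},
        index=series.index,
    )


def _effect_table(fit: ModelFit, exposure_cols: dict[str, str], reference: str) -> pd.DataFrame:
    rows = [
        {
            "level": reference,
            "estimate": 1.0 if fit.kind == "logistic" else 0.0,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "reference": True,
        }
    ]
    for col, level in exposure_cols.items():
        est, lo, hi = fit.effect(col)
        rows.append(
            {"level": level, "estimate": est, "ci_low": lo, "ci_high": hi, "reference": False}
        )
    return pd.DataFrame(rows)


def separate_associations(
    scored: pd.DataFrame, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Separate lifestyle-group and GRS-group associations, Models 1-3.

    Returns a long table with one row per (exposure, level, outcome, model),
    holding OR (hypertension) or beta in mmHg (SBP/DBP) with 95% CIs.
    References: unhealthful lifestyle and low-risk GRS. Levels absent from
    the data are flagged rather than fitted.
    """
    config = config or AnalysisConfig()
    covs = covariate_design(scored, config.covariate_set)
    ls = _group_dummies(scored["lifestyle_group"], LIFESTYLE_GROUPS, "lifestyle")
    has_grs = scored["grs"].notna()
    results = []

    for exposure, dummies, ref, mask in (
        ("lifestyle", ls, "unhealthful", pd.Series(True, index=scored.index)),
        (
            "grs",
            _group_dummies(scored["grs_group"].astype(str), GRS_GROUPS, "grs"),
            "low",
            has_grs,
        ),
    ):
        present = [c for c in dummies.columns if dummies.loc[mask, c].sum() > 0]
        absent = [c for c in dummies.columns if c not in present]
        mutual = ls if exposure == "grs" else _group_dummies(
            scored["grs_group"].astype(str), GRS_GROUPS, "grs"
        )
        for tag in ("model1", "model2", "model3"):
            m = mask & has_grs if tag == "model3" else mask
            for outcome, kind in OUTCOMES.items():
                if tag == "model1":
                    design = dummies[present]
                elif tag == "model2":
                    design = pd.concat([dummies[present], _covs_for(covs, outcome)], axis=1)
                else:
                    mut_present = [c for c in mutual.columns if mutual.loc[m, c].sum() > 0]
                    design = pd.concat(
                        [dummies[present], mutual[mut_present], _covs_for(covs, outcome)],
                        axis=1,
                    )
                y = scored.loc[m, _OUTCOME_COLUMN[outcome]]
                fitter = fit_logistic if kind == "logistic" else fit_linear
                fit = fitter(y, design.loc[m], outcome_name=outcome, model_tag=tag)
                table = _effect_table(
                    fit,
                    {c: c.split("_", 1)[1] for c in present},
                    ref,
                )
                table.insert(0, "exposure", exposure)
                table.insert(1, "outcome", outcome)
                table.insert(2, "model", tag)
                for c in absent:
                    table.loc[len(table)] = {
                        "exposure": exposure,
                        "outcome": outcome,
                        "model": tag,
                        "level": c.split("_", 1)[1],
                        "estimate": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "reference": False,
                    }
                results.append(table)
    return pd.concat(results, ignore_index=True)


def joint_effect_grid(
    scored: pd.DataFrame, config: AnalysisConfig | None = None, adjusted: bool = True
) -> pd.DataFrame:
    """3x3 GRS-group x lifestyle-group joint-effect grid.

    One model per outcome with 8 dummies for the non-reference cells (the
    low-GRS / healthful-lifestyle cell is the reference) plus the covariate
    set when ``adjusted``. Returns one row per cell and outcome with the
    cell count, OR or beta and 95% CI; cells with no subjects (or no
    outcome variation) are flagged sparse.
    """
    config = config or AnalysisConfig()
    data = scored[scored["grs"].notna()].copy()
    cell = data["grs_group"].astype(str) + ":" + data["lifestyle_group"].astype(str)
    ref = "low:healthful"
    all_cells = [f"{g}:{l}" for g in GRS_GROUPS for l in LIFESTYLE_GROUPS]
    counts = cell.value_counts()
    present = [c for c in all_cells if c != ref and counts.get(c, 0) > 0]
    dummies = pd.DataFrame(
        {f"cell_{c}": (cell == c).astype(float) for c in present}, index=data.index
    )
    covs = covariate_design(data, config.covariate_set) if adjusted else None
    rows = []
    for outcome, kind in OUTCOMES.items():
        design = (
            pd.concat([dummies, _covs_for(covs, outcome)], axis=1)
            if adjusted
            else dummies
        )
        fitter = fit_logistic if kind == "logistic" else fit_linear
        fit = fitter(data[_OUTCOME_COLUMN[outcome]], design, outcome_name=outcome)
        for c in all_cells:
            g, l = c.split(":")
            row = {
                "grs_group": g,
                "lifestyle_group": l,
                "outcome": outcome,
                "n": int(counts.get(c, 0)),
                "events": int(data.loc[cell == c, "hypertension"].sum()),
            }
            if c == ref:
                row.update(
                    estimate=1.0 if kind == "logistic" else 0.0,
                    ci_low=np.nan,
                    ci_high=np.nan,
                    reference=True,
                    sparse=counts.get(c, 0) == 0,
                )
            elif c in present:
                est, lo, hi = fit.effect(f"cell_{c}")
                row.update(
                    estimate=est, ci_low=lo, ci_high=hi, reference=False, sparse=False
                )
            else:
                row.update(
                    estimate=np.nan, ci_low=np.nan, ci_high=np.nan,
                    reference=False, sparse=True,
                )
            rows.append(row)
    return pd.DataFrame(rows)
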