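"""Lifestyle and genetic risk scores.

Two summary exposures drive the whole analysis:

* a five-factor healthy-lifestyle score (0-5): diet quality (a 9-item
  food-frequency CHEI sub-score), body-mass index, smoking status, physical
  activity, and drinking frequency, each dichotomised healthful/unhealthful
  and summed, then grouped 0-1 / 2-3 / 4-5;
* a 13-SNP genetic risk score (GRS): each locus contributes the in-sample
  regression effect value of the subject's genotype dummy (reference =
  non-risk homozygote, contributing 0), summed across loci and grouped into
  tertiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import (
    AnalysisConfig,
    FOOD_ITEMS,
    FREQ_LEVELS,
    IPAQ_LEVELS,
    SMOKING_LEVELS,
    SNP_IDS,
)

log = logging.getLogger(__name__)

#: Frequency -> points for the 8 beneficial foods (daily best).
_BENEFICIAL_POINTS = {lvl: i for i, lvl in enumerate(FREQ_LEVELS)}
#: Red meat is reverse-scored (never best).
_RED_MEAT_POINTS = {lvl: 4 - i for i, lvl in enumerate(FREQ_LEVELS)}

CHEI_MAX = 4 * len(FOOD_ITEMS)  # 36

LIFESTYLE_GROUPS = ("unhealthful", "intermediate", "healthful")
GRS_GROUPS = ("low", "intermediate", "high")


def chei_diet_score(food_freq: dict[str, str]) -> int:
    """Diet-quality sub-score over the nine food-frequency items.

    The eight beneficial foods score daily=4 ... never=0; red meat is
    reverse-scored daily=0 ... never=4. Theoretical range 0-36 (the observed
    cohort range is narrower).
    """
    missing = [item for item in FOOD_ITEMS if item not in food_freq]
    if missing:
        raise ValueError(f"missing food-frequency item(s): {missing}")
    total = 0
    for item in FOOD_ITEMS:
        freq = food_freq[item]
        if freq not in _BENEFICIAL_POINTS:
            raise ValueError(f"unknown frequency label {freq!r} for {item}")
        points = _RED_MEAT_POINTS if item == "red_meat" else _BENEFICIAL_POINTS
        total += points[freq]
    return total


def classify_diet(
    chei: int,
    cohort_cheis: np.ndarray | None = None,
    config: AnalysisConfig | None = None,
) -> bool:
    """Healthful diet = top 40% of the CHEI distribution.

    In ``fixed_threshold`` mode (default) that is operationalised as
    CHEI >= 17, the published cutoff; ``empirical_top40pct`` recomputes the
    60th-percentile cutoff from the cohort's own CHEI values.
    """
    config = config or AnalysisConfig()
    if config.chei_cutoff_mode == "fixed_threshold":
        return chei >= config.chei_fixed_threshold
    if cohort_cheis is None or len(cohort_cheis) == 0:
        raise ValueError("empirical CHEI cutoff requires a nonempty cohort CHEI list")
    cutoff = float(np.quantile(np.asarray(cohort_cheis, dtype=float), 0.6))
    return chei >= cutoff


def classify_bmi(bmi: float, config: AnalysisConfig | None = None) -> bool:
    """Healthful BMI band: 18.5 <= BMI < 24 kg/m^2 (25 in sensitivity mode)."""
    if bmi <= 0:
        raise ValueError("BMI must be positive")
    upper = 25.0 if (config or AnalysisConfig()).bmi_rule == "sensitivity25" else 24.0
    return 18.5 <= bmi < upper


def classify_smoking(status: str, years_since_quit: float | None = None) -> bool:
    """Healthful = never smoked, or quit at least 30 years ago."""
    if status not in SMOKING_LEVELS:
        raise ValueError(f"unknown smoking status {status!r}")
    if status == "never":
        return True
    if status == "current":
        return False
    if years_since_quit is None or (
        isinstance(years_since_quit, float) and np.isnan(years_since_quit)
    ):
        raise ValueError("years_since_quit required for former smokers")
    return years_since_quit >= 30


def classify_activity(ipaq_level: str) -> bool:
    """Healthful = moderate or high IPAQ physical-activity category."""
    if ipaq_level not in IPAQ_LEVELS:
        raise ValueError(f"unknown IPAQ level {ipaq_level!r}")
    return ipaq_level in ("moderate", "high")


def classify_drinking(drinks_per_year: float) -> bool:
    """Healthful = not a current drinker (at most 12 drinks in the last year)."""
    if drinks_per_year < 0:
        raise ValueError("drinks_per_year must be non-negative")
    return drinks_per_year <= 12


def lifestyle_group(score: int) -> str:
    if score in (0, 1):
        return "unhealthful"
    if score in (2, 3):
        return "intermediate"
    if score in (4, 5):
        return "healthful"
    raise ValueError(f"lifestyle score out of range: {score}")


def score_lifestyle(
    cohort: pd.DataFrame, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Per-subject lifestyle profile for a whole cohort.

    Returns a frame indexed like ``cohort`` with the CHEI, the five factor
    booleans, the 0-5 ``lifestyle_score`` and the 3-level ``lifestyle_group``.
    """
    config = config or AnalysisConfig()
    chei = np.zeros(len(cohort), dtype=int)
    for item in FOOD_ITEMS:
        points = _RED_MEAT_POINTS if item == "red_meat" else _BENEFICIAL_POINTS
        col = cohort[f"ff_{item}"].map(points)
        if col.isna().any():
            bad = cohort.loc[col.isna(), f"ff_{item}"].iloc[0]
            raise ValueError(f"unknown frequency label {bad!r} in ff_{item}")
        chei += col.to_numpy(dtype=int)

    if config.chei_cutoff_mode == "fixed_threshold":
        diet_ok = chei >= config.chei_fixed_threshold
    else:
        if len(chei) == 0:
            raise ValueError("empirical CHEI cutoff requires a nonempty cohort")
        diet_ok = chei >= np.quantile(chei.astype(float), 0.6)

    upper = 25.0 if config.bmi_rule == "sensitivity25" else 24.0
    bmi = cohort["bmi"].to_numpy(dtype=float)
    if np.any(bmi <= 0):
        raise ValueError("BMI must be positive")
    bmi_ok = (bmi >= 18.5) & (bmi < upper)

    status = cohort["smoking"]
    quit_years = pd.to_numeric(cohort["years_since_quit"], errors="coerce")
    former = status == "former"
    if (former & quit_years.isna()).any():
        raise ValueError("years_since_quit required for former smokers")
    smoke_ok = (status == "never").to_numpy() | (
        former.to_numpy() & (quit_years.fillna(-1).to_numpy() >= 30)
    )

    act_ok = cohort["ipaq_level"].isin(("moderate", "high")).to_numpy()
    drinks = cohort["drinks_per_year"].to_numpy(dtype=float)
    if np.any(drinks < 0):
        raise ValueError("drinks_per_year must be non-negative")
    drink_ok = drinks <= 12

    score = (
        diet_ok.astype(int)
        + bmi_ok.astype(int)
        + smoke_ok.astype(int)
        + act_ok.astype(int)
        + drink_ok.astype(int)
    )
    group = pd.cut(
        score,
        bins=[-0.5, 1.5, 3.5, 5.5],
        labels=LIFESTYLE_GROUPS,
    ).astype(str)
    return pd.DataFrame(
        {
            "chei": chei,
            "diet_healthful": diet_ok,
            "bmi_healthful": bmi_ok,
            "smoking_healthful": smoke_ok,
            "activity_healthful": act_ok,
            "drinking_healthful": drink_ok,
            "lifestyle_score": score,
            "lifestyle_group": group,
        },
        index=cohort.index,
    )


# ---------------------------------------------------------------------------
# Genetic risk score
# ---------------------------------------------------------------------------


@dataclass
class GrsModel:
    """Per-genotype effect values for the 13 loci.

    ``effects[snp]`` maps each observed genotype label to its effect value;
    the reference genotype (non-risk homozygote) maps to 0. ``meta`` records
    how the effects were obtained (outcome, cohort size, warnings).
    """

    effects: dict[str, dict[str, float]]
    reference: dict[str, str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for snp, eff in self.effects.items():
            for label, value in eff.items():
                if not np.isfinite(value):
                    raise ValueError(f"non-finite effect for {snp} {label}")

    @classmethod
    def from_effects(
        cls, effects: dict[str, dict[str, float]], reference: dict[str, str]
    ) -> "GrsModel":
        """Build a model from user-supplied weights (e.g. published betas)."""
        return cls(effects=effects, reference=reference, meta={"source": "supplied"})


def _genotype_dummies(genos: pd.Series, reference: str) -> tuple[pd.DataFrame, list[str]]:
    labels = sorted(set(genos.dropna()) - {reference})
    X = pd.DataFrame({lab: (genos == lab).astype(float) for lab in labels})
    return X, labels


def infer_reference_genotypes(cohort: pd.DataFrame) -> dict[str, str]:
    """Default reference per SNP: the most frequent homozygote genotype."""
    ref = {}
    for snp in SNP_IDS:
        counts = cohort[snp].dropna().value_counts()
        homs = [g for g in counts.index if len(set(g)) == 1]
        if homs:
            ref[snp] = max(homs, key=lambda g: counts[g])
        elif len(counts):
            ref[snp] = counts.index[0]
        else:
            ref[snp] = ""
    return ref


def estimate_genotype_effects(
    cohort: pd.DataFrame,
    config: AnalysisConfig | None = None,
    reference: dict[str, str] | None = None,
) -> GrsModel:
    """Estimate per-genotype effect values in the study population.

    For each locus independently, the configured outcome (default: logistic
    regression on incident hypertension; alternatively linear regression on
    follow-up SBP) is regressed on the two genotype dummies with the
    non-risk homozygote as reference. The fitted coefficient of each dummy
    is that genotype's effect value. Degenerate loci (monomorphic, empty
    cells, separation) get zero effects with a logged warning.
    """
    config = config or AnalysisConfig()
    reference = reference or infer_reference_genotypes(cohort)
    logistic = config.grs_effect_outcome == "hypertension_logistic"
    y = (
        cohort["hypertension"].astype(float)
        if logistic
        else cohort["followup_sbp"].astype(float)
    )

    effects: dict[str, dict[str, float]] = {}
    warnings_log: list[str] = []
    for snp in SNP_IDS:
        genos = cohort[snp]
        ok = genos.notna()
        X, labels = _genotype_dummies(genos[ok], reference[snp])
        eff = {reference[snp]: 0.0}
        if not labels:
            warnings_log.append(f"{snp}: monomorphic, effects set to 0")
            effects[snp] = eff
            continue
        Xc = sm.add_constant(X.to_numpy(), has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if logistic:
                    fit = sm.GLM(y[ok].to_numpy(), Xc, family=sm.families.Binomial()).fit()
                else:
                    fit = sm.OLS(y[ok].to_numpy(), Xc).fit()
            params = fit.params[1:]
            bse = fit.bse[1:]
            for lab, beta, se in zip(labels, params, bse):
                if not np.isfinite(beta) or (logistic and (se > 50 or abs(beta) > 20)):
                    warnings_log.append(
                        f"{snp} {lab}: unstable estimate (separation/empty cell), set to 0"
                    )
                    eff[lab] = 0.0
                else:
                    eff[lab] = float(beta)
        except Exception as exc:  # pragma: no cover - statsmodels failures
            warnings_log.append(f"{snp}: fit failed ({exc}); effects set to 0")
            for lab in labels:
                eff[lab] = 0.0
        effects[snp] = eff

    for msg in warnings_log:
        log.warning(msg)
    return GrsModel(
        effects=effects,
        reference=reference,
        meta={
            "outcome": config.grs_effect_outcome,
            "n": int(len(cohort)),
            "warnings": warnings_log,
        },
    )


def compute_grs(genotypes: pd.DataFrame | dict, model: GrsModel) -> np.ndarray:
    """Sum of per-locus effect values of each subject's genotypes.

    The reference genotype contributes 0; an unknown genotype label is a
    domain error.
    """
    if isinstance(genotypes, dict):
        genotypes = pd.DataFrame({k: [v] for k, v in genotypes.items()})
        squeeze = True
    else:
        squeeze = False
    grs = np.zeros(len(genotypes), dtype=float)
    for snp in SNP_IDS:
        eff = model.effects[snp]
        genos = genotypes[snp]
        mapped = genos.map(eff)
        unknown = mapped.isna() & genos.notna()
        if unknown.any():
            bad = genos[unknown].iloc[0]
            raise ValueError(f"unknown genotype label {bad!r} for {snp}")
        if mapped.isna().any():
            raise ValueError(f"missing genotype for {snp}; filter incomplete subjects first")
        grs += mapped.to_numpy(dtype=float)
    return grs[0] if squeeze else grs


def assign_grs_groups(
    grs_values: np.ndarray, config: AnalysisConfig | None = None
) -> pd.Series:
    """Partition subjects into low/intermediate/high GRS risk groups.

    Cutpoints sit at the empirical 1/3 and 2/3 quantiles (or the configured
    percentiles); ties at a cutpoint are broken by stable subject order so
    group sizes are as equal as possible. If every GRS is identical the
    partition is undefined and all subjects are assigned ``low`` with a
    warning.
    """
    config = config or AnalysisConfig()
    values = np.asarray(grs_values, dtype=float)
    n = len(values)
    if n == 0:
        raise ValueError("cannot assign groups to an empty GRS list")
    if np.all(values == values[0]):
        log.warning("all GRS values identical; assigning every subject to 'low'")
        return pd.Series(["low"] * n, dtype=str)
    if config.grs_group_mode == "tertile":
        percentiles = (1 / 3, 2 / 3)
    else:
        percentiles = config.grs_percentiles
    order = np.argsort(values, kind="stable")
    cuts = [int(round(p * n)) for p in percentiles]
    names = GRS_GROUPS if len(percentiles) == 2 else [f"q{i}" for i in range(len(cuts) + 1)]
    groups = np.empty(n, dtype=object)
    bounds = [0] + cuts + [n]
    for gi, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        groups[order[lo:hi]] = names[gi]
    return pd.Series(groups, dtype=str)


def score_cohort(
    cohort: pd.DataFrame,
    config: AnalysisConfig | None = None,
    grs_model: GrsModel | None = None,
) -> tuple[pd.DataFrame, GrsModel]:
    """Append lifestyle and GRS scores to a cohort table.

    Subjects with incomplete genotypes keep their lifestyle scores but get
    missing GRS/GRS-group entries. Returns the scored table and the
    :class:`GrsModel` used (estimated in-sample unless one is supplied).
    """
    from .cohort import split_by_genotype_completeness

    config = config or AnalysisConfig()
    scored = pd.concat([cohort, score_lifestyle(cohort, config)], axis=1)

    gsplit = split_by_genotype_completeness(cohort)
    if gsplit.n_excluded:
        log.info(
            "%d subject(s) with incomplete genotypes excluded from GRS analyses",
            gsplit.n_excluded,
        )
    complete = gsplit.complete
    if grs_model is None:
        grs_model = estimate_genotype_effects(complete, config)
    scored["grs"] = np.nan
    scored["grs_group"] = pd.Series([None] * len(scored), index=scored.index, dtype=object)
    if len(complete):
        grs = compute_grs(complete[list(SNP_IDS)], grs_model)
        groups = assign_grs_groups(grs, config)
        scored.loc[complete.index, "grs"] = grs
        scored.loc[complete.index, "grs_group"] = groups.to_numpy()
    return scored, grs_model
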