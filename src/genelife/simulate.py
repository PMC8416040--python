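"""Seeded synthetic cohort generator.

Emulates a rural-cohort hypertension study table: genotypes at 13 loci
drawn under Hardy-Weinberg equilibrium, raw lifestyle variables drawn so
the scoring rules reproduce configured unhealthful-state prevalences,
incident hypertension from a logistic model over the configured genetic and
lifestyle effects (intercept calibrated to the target incidence), and
baseline/follow-up blood pressure from a linear model reconciled with the
outcome flag through the medication indicator.

All randomness flows from one ``numpy.random.Generator`` seeded by the
configuration; identical (config, seed) gives identical tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .cohort import FOOD_COLUMNS, REQUIRED_COLUMNS, validate_cohort
from .config import (
    EDUCATION_LEVELS,
    FOOD_ITEMS,
    FREQ_LEVELS,
    INCOME_LEVELS,
    LIFESTYLE_FACTORS,
    SNP_IDS,
    SimulationConfig,
)

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]

#: non-risk/risk allele letters per SNP (fixed, arbitrary but stable)
SNP_ALLELES = {snp: _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i, snp in enumerate(SNP_IDS)}


class CalibrationError(RuntimeError):
    """The target incidence (or interaction) is unreachable under the config."""


def genotype_labels(snp: str) -> tuple[str, str, str]:
    """(reference homozygote, heterozygote, risk homozygote) labels."""
    a, b = SNP_ALLELES[snp]
    return a + a, "".join(sorted((a, b))), b + b


def reference_genotypes() -> dict[str, str]:
    """Non-risk homozygote label per SNP (the GRS reference category)."""
    return {snp: genotype_labels(snp)[0] for snp in SNP_IDS}


def true_grs_model():
    """GRS weights implied by the configured per-genotype odds ratios."""
    from .scoring import GrsModel

    def build(config: SimulationConfig) -> GrsModel:
        effects = {}
        for snp in SNP_IDS:
            g0, g1, g2 = genotype_labels(snp)
            o1, o2 = config.genotype_ors[snp]
            effects[snp] = {g0: 0.0, g1: float(np.log(o1)), g2: float(np.log(o2))}
        return GrsModel(effects=effects, reference=reference_genotypes(),
                        meta={"source": "configured"})

    return build


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _truncated_normal_matching_mean(rng, target_mean, sd, lo, hi, size):
    """Truncated normal whose post-truncation mean equals ``target_mean``.

    The configured baseline-BP means describe the analysis cohort, i.e.
    after baseline hypertensives are excluded, so the underlying location
    is solved to offset the truncation shift.
    """

    def shifted_mean(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(truncnorm.mean(a, b, loc=loc, scale=sd)) - target_mean

    loc = brentq(shifted_mean, lo, hi, xtol=1e-10)
    return _truncated_normal(rng, loc, sd, lo, hi, size)


def _compose_item_scores(rng: np.random.Generator, targets: np.ndarray) -> np.ndarray:
    """Random 9 x n item scores in 0..4 summing exactly to each target."""
    n = len(targets)
    remaining = targets.astype(int).copy()
    scores = np.zeros((len(FOOD_ITEMS), n), dtype=int)
    for j in range(len(FOOD_ITEMS)):
        items_left = len(FOOD_ITEMS) - j
        lo = np.maximum(0, remaining - 4 * (items_left - 1))
        hi = np.minimum(4, remaining)
        draw = rng.integers(lo, hi + 1) if n else np.zeros(0, dtype=int)
        scores[j] = draw
        remaining -= draw
    assert not np.any(remaining)
    return scores


def _solve_intercept(lp: np.ndarray, target: float) -> float:
    def f(b0):
        return float(np.mean(expit(b0 + lp))) - target

    try:
        return float(brentq(f, -30.0, 30.0, xtol=1e-12))
    except ValueError as exc:  # no sign change
        raise CalibrationError(
            f"target incidence {target} unreachable under configured effects"
        ) from exc


def generate_cohort(config: SimulationConfig | None = None) -> pd.DataFrame:
    """Draw one synthetic cohort table under the configured world."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    if n == 0:
        empty = pd.DataFrame({c: pd.Series(dtype=object) for c in REQUIRED_COLUMNS})
        validate_cohort(empty)
        return empty

    cov = config.covariates

    # --- demographics / covariates (independent of exposures by default)
    age = np.clip(rng.normal(cov.age_mean, cov.age_sd, n), 18, 79).round(1)
    sex = np.where(rng.random(n) < cov.male_prop, "male", "female")
    education = rng.choice(EDUCATION_LEVELS, size=n, p=cov.education_probs)
    marital = np.where(rng.random(n) < cov.married_prop, "married_cohabit", "other")
    income = rng.choice(INCOME_LEVELS, size=n, p=cov.income_probs)
    famhist = rng.random(n) < cov.family_history_prop

    baseline_sbp = _truncated_normal_matching_mean(
        rng, cov.baseline_sbp_mean, cov.baseline_sbp_sd, 85.0, 139.9, n
    )
    baseline_dbp = _truncated_normal_matching_mean(
        rng, cov.baseline_dbp_mean, cov.baseline_dbp_sd, 45.0, 89.9, n
    )
    baseline_dbp = np.minimum(baseline_dbp, baseline_sbp - 5.0)

    # --- genotypes under Hardy-Weinberg equilibrium
    geno_codes = {}
    geno_labels = {}
    for snp in SNP_IDS:
        p = config.allele_freqs[snp]
        probs = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
        codes = rng.choice(3, size=n, p=probs)
        geno_codes[snp] = codes
        labels = np.array(genotype_labels(snp), dtype=object)
        geno_labels[snp] = labels[codes]

    # --- unhealthful lifestyle states, then raw variables consistent with them
    unhealthful = {
        fac: rng.random(n) < config.lifestyle_prevalence[fac]
        for fac in LIFESTYLE_FACTORS
    }

    # diet: CHEI target below/at-or-above the fixed cutoff 17 (observed range 3-28)
    chei_target = np.where(
        unhealthful["diet"], rng.integers(3, 17, size=n), rng.integers(17, 29, size=n)
    )
    item_scores = _compose_item_scores(rng, chei_target)
    freq_arr = np.array(FREQ_LEVELS, dtype=object)
    food_cols = {}
    for j, item in enumerate(FOOD_ITEMS):
        pts = item_scores[j]
        # beneficial foods: points == frequency index; red meat reversed
        idx = (4 - pts) if item == "red_meat" else pts
        food_cols[f"ff_{item}"] = freq_arr[idx]

    # BMI: healthy band vs an over/underweight mixture
    bmi = np.where(
        unhealthful["bmi"],
        np.where(
            rng.random(n) < 0.90,
            _truncated_normal(rng, 26.5, 2.0, 24.0, 40.0, n),
            _truncated_normal(rng, 17.5, 0.8, 14.0, 18.49, n),
        ),
        _truncated_normal(rng, 21.3, 1.6, 18.5, 23.99, n),
    ).round(2)

    # smoking: unhealthful = current or quit < 30y; healthful = never or quit >= 30y
    u_smoke = rng.random(n)
    smoking = np.where(
        unhealthful["smoking"],
        np.where(u_smoke < 0.85, "current", "former"),
        np.where(u_smoke < 0.92, "never", "former"),
    )
    years_since_quit = np.full(n, np.nan)
    former = smoking == "former"
    quit_short = rng.integers(0, 30, size=n)
    quit_long = rng.integers(30, 51, size=n)
    years_since_quit[former & unhealthful["smoking"]] = quit_short[
        former & unhealthful["smoking"]
    ]
    years_since_quit[former & ~unhealthful["smoking"]] = quit_long[
        former & ~unhealthful["smoking"]
    ]

    ipaq = np.where(
        unhealthful["activity"],
        "low",
        np.where(rng.random(n) < 0.5, "moderate", "high"),
    )

    drinks = np.where(
        unhealthful["drinking"],
        13 + rng.poisson(90, size=n),
        np.where(rng.random(n) < 0.8, 0, rng.integers(1, 13, size=n)),
    )

    # --- lifestyle score implied by the drawn states
    n_unhealthful = np.sum([unhealthful[f] for f in LIFESTYLE_FACTORS], axis=0)
    score = 5 - n_unhealthful

    # --- linear predictor for incident hypertension
    true_grs = np.zeros(n)
    for snp in SNP_IDS:
        o1, o2 = config.genotype_ors[snp]
        per_geno = np.array([0.0, np.log(o1), np.log(o2)])
        true_grs += per_geno[geno_codes[snp]]

    if config.effect_mode == "per_factor":
        lp = true_grs.copy()
        for fac in LIFESTYLE_FACTORS:
            lp += unhealthful[fac] * np.log(config.lifestyle_ors[fac])
    else:  # group_level
        from .scoring import assign_grs_groups

        groups = assign_grs_groups(true_grs).to_numpy()
        o_int, o_high = config.grs_group_ors
        lp = np.where(
            groups == "high", np.log(o_high), np.where(groups == "intermediate", np.log(o_int), 0.0)
        )
        l_int, l_heal = config.lifestyle_group_ors
        lp += np.where(
            score >= 4, np.log(l_heal), np.where(score >= 2, np.log(l_int), 0.0)
        )

    # optional product term calibrated so the population RERI (on the odds
    # scale, over the two dichotomized summary exposures) hits the target
    if config.interaction_reri_target != 0.0:
        a_risk = score <= 3
        b_risk = true_grs >= np.median(true_grs)
        b0 = _solve_intercept(lp, config.baseline_prevalence)
        p = expit(b0 + lp)

        def cell_odds(mask):
            if not mask.any():
                raise CalibrationError("empty exposure cell during calibration")
            m = float(np.mean(p[mask]))
            return m / (1 - m)

        o00 = cell_odds(~a_risk & ~b_risk)
        or10 = cell_odds(a_risk & ~b_risk) / o00
        or01 = cell_odds(~a_risk & b_risk) / o00
        arg = config.interaction_reri_target + or10 + or01 - 1.0
        if arg <= 0:
            raise CalibrationError(
                f"RERI target {config.interaction_reri_target} infeasible "
                f"(OR10={or10:.3f}, OR01={or01:.3f})"
            )
        lp = lp + (np.log(arg) - np.log(or10) - np.log(or01)) * (a_risk & b_risk)

    b0 = _solve_intercept(lp, config.baseline_prevalence)
    hypertension = rng.random(n) < expit(b0 + lp)

    # --- follow-up blood pressure, reconciled with the outcome flag
    bp = config.bp_model
    shift_sbp = bp.sbp_per_grs * true_grs + bp.sbp_per_unhealthful_factor * n_unhealthful
    shift_dbp = bp.dbp_per_grs * true_grs + bp.dbp_per_unhealthful_factor * n_unhealthful
    fu_sbp = (
        bp.sbp_intercept
        + bp.carryover * (baseline_sbp - cov.baseline_sbp_mean)
        + shift_sbp
        + rng.normal(0, bp.sbp_resid_sd, n)
    )
    fu_dbp = (
        bp.dbp_intercept
        + bp.carryover * (baseline_dbp - cov.baseline_dbp_mean)
        + shift_dbp
        + rng.normal(0, bp.dbp_resid_sd, n)
    )
    fu_sbp = np.maximum(fu_sbp, fu_dbp + 5.0)  # pulse pressure stays positive

    # non-cases must sit below both cutoffs with no medication
    noncase = ~hypertension
    clip_s = 139.9 - rng.uniform(0.0, 6.0, n)
    clip_d = 89.9 - rng.uniform(0.0, 6.0, n)
    fu_sbp = np.where(noncase, np.minimum(fu_sbp, clip_s), fu_sbp)
    fu_dbp = np.where(noncase, np.minimum(fu_dbp, clip_d), fu_dbp)
    fu_sbp = np.maximum(fu_sbp, fu_dbp + 5.0)
    fu_sbp = np.where(noncase, np.minimum(fu_sbp, 139.9), fu_sbp)

    # cases whose sampled pressure is below the cutoffs are treated patients
    med = hypertension & (fu_sbp < 140.0) & (fu_dbp < 90.0)

    table = pd.DataFrame(
        {
            "subject_id": [f"S{i:06d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "education": education,
            "marital": marital,
            "income": income,
            "family_history_htn": famhist,
            "antihypertensive_med": med,
            "baseline_sbp": baseline_sbp.round(1),
            "baseline_dbp": baseline_dbp.round(1),
            "followup_sbp": fu_sbp.round(1),
            "followup_dbp": fu_dbp.round(1),
            "hypertension": hypertension,
            **food_cols,
            "bmi": bmi,
            "smoking": smoking,
            "years_since_quit": years_since_quit,
            "ipaq_level": ipaq,
            "drinks_per_year": drinks,
            **{snp: geno_labels[snp] for snp in SNP_IDS},
        }
    )

    if config.missing_genotype_rate > 0:
        for snp in SNP_IDS:
            mask = rng.random(n) < config.missing_genotype_rate
            table.loc[mask, snp] = np.nan

    validate_cohort(table)
    return table[list(REQUIRED_COLUMNS)]


def marginal_report(cohort: pd.DataFrame) -> dict:
    """Realized marginal distributions of a cohort.

    Per-factor unhealthful prevalence (under the primary scoring rules),
    genotype frequencies, incidence, and blood-pressure means/SDs.
    """
    if cohort.empty:
        raise ValueError("marginal report requires a nonempty cohort")
    from .scoring import score_lifestyle

    profile = score_lifestyle(cohort)
    report: dict = {
        "n": int(len(cohort)),
        "incidence": float(cohort["hypertension"].mean()),
        "unhealthful_prevalence": {
            fac: float(1.0 - profile[f"{fac}_healthful"].mean())
            for fac in LIFESTYLE_FACTORS
        },
        "lifestyle_score_mean": float(profile["lifestyle_score"].mean()),
        "baseline_sbp_mean": float(cohort["baseline_sbp"].mean()),
        "baseline_sbp_sd": float(cohort["baseline_sbp"].std()),
        "baseline_dbp_mean": float(cohort["baseline_dbp"].mean()),
        "baseline_dbp_sd": float(cohort["baseline_dbp"].std()),
        "followup_sbp_mean": float(cohort["followup_sbp"].mean()),
        "followup_dbp_mean": float(cohort["followup_dbp"].mean()),
        "genotype_freqs": {
            snp: cohort[snp].value_counts(normalize=True, dropna=True).to_dict()
            for snp in SNP_IDS
        },
    }
    return report


def simulate_two_exposures(
    n: int,
    risks: tuple[float, float, float, float],
    prev_a: float = 0.5,
    prev_b: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Minimal two-binary-exposure outcome simulator for interaction checks.

    ``risks`` = (p00, p10, p01, p11): outcome probability per exposure cell
    (A, B) in {(0,0), (1,0), (0,1), (1,1)}. Exposures are independent
    Bernoulli draws with prevalences ``prev_a``/``prev_b``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    a = (rng.random(n) < prev_a).astype(int)
    b = (rng.random(n) < prev_b).astype(int)
    p00, p10, p01, p11 = risks
    p = np.select(
        [(a == 0) & (b == 0), (a == 1) & (b == 0), (a == 0) & (b == 1)],
        [p00, p10, p01],
        default=p11,
    )
    y = (rng.random(n) < p).astype(int)
    return pd.DataFrame({"A": a, "B": b, "y": y})
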