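"""Lifestyle score (CHEI + five factors) and genetic risk score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genelife.config import FOOD_ITEMS, FREQ_LEVELS, SNP_IDS, AnalysisConfig
from genelife.scoring import (
    GrsModel,
    assign_grs_groups,
    chei_diet_score,
    classify_activity,
    classify_bmi,
    classify_diet,
    classify_drinking,
    classify_smoking,
    compute_grs,
    estimate_genotype_effects,
    lifestyle_group,
    score_lifestyle,
)
from genelife.simulate import genotype_labels, reference_genotypes

from conftest import make_cohort, make_subject

BENEFICIAL = [item for item in FOOD_ITEMS if item != "red_meat"]


# ---------------------------------------------------------------------------
# CHEI diet sub-score
# ---------------------------------------------------------------------------


def test_chei_extremes_and_hand_sum():
    best = {item: "daily" for item in BENEFICIAL} | {"red_meat": "never"}
    worst = {item: "never" for item in BENEFICIAL} | {"red_meat": "daily"}
    assert chei_diet_score(best) == 36
    assert chei_diet_score(worst) == 0
    # 8 beneficial weekly (8*3) + red meat weekly (reverse-scored 1) = 25
    all_weekly = {item: "weekly" for item in FOOD_ITEMS}
    assert chei_diet_score(all_weekly) == 8 * 3 + 1


def test_chei_rejects_unknown_label():
    freq = {item: "weekly" for item in FOOD_ITEMS} | {"fish": "fortnightly"}
    with pytest.raises(ValueError, match="fortnightly"):
        chei_diet_score(freq)


freq_strategy = st.sampled_from(FREQ_LEVELS)


@settings(deadline=None, derandomize=True)
@given(st.lists(freq_strategy, min_size=9, max_size=9))
def test_chei_bounds_and_permutation_invariance(freqs):
    base = dict(zip(FOOD_ITEMS, freqs))
    score = chei_diet_score(base)
    assert 0 <= score <= 36
    # permuting the 8 beneficial foods leaves the score unchanged
    rotated = dict(zip(BENEFICIAL, [base[i] for i in BENEFICIAL[1:] + BENEFICIAL[:1]]))
    rotated["red_meat"] = base["red_meat"]
    assert chei_diet_score(rotated) == score


@settings(deadline=None, derandomize=True)
@given(
    st.lists(freq_strategy, min_size=9, max_size=9),
    st.sampled_from(BENEFICIAL),
)
def test_chei_monotone(freqs, item):
    base = dict(zip(FOOD_ITEMS, freqs))
    idx = FREQ_LEVELS.index(base[item])
    if idx < len(FREQ_LEVELS) - 1:
        more = base | {item: FREQ_LEVELS[idx + 1]}
        assert chei_diet_score(more) >= chei_diet_score(base)
    idx_rm = FREQ_LEVELS.index(base["red_meat"])
    if idx_rm < len(FREQ_LEVELS) - 1:
        more_meat = base | {"red_meat": FREQ_LEVELS[idx_rm + 1]}
        assert chei_diet_score(more_meat) <= chei_diet_score(base)


# ---------------------------------------------------------------------------
# Factor classifiers
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("chei,expected", [(17, True), (16, False), (28, True), (3, False)])
def test_diet_fixed_threshold(chei, expected):
    assert classify_diet(chei) is expected


def test_diet_empirical_cutoff():
    cheis = np.arange(10, 20)  # one each of 10..19; 60th percentile = 15.4
    cfg = AnalysisConfig(chei_cutoff_mode="empirical_top40pct")
    assert classify_diet(17, cheis, cfg) is True
    assert classify_diet(15, cheis, cfg) is False
    with pytest.raises(ValueError):
        classify_diet(17, np.array([]), cfg)


@pytest.mark.parametrize(
    "bmi,rule,expected",
    [
        (18.5, "primary", True),
        (18.4, "primary", False),
        (23.9, "primary", True),
        (24.5, "primary", False),
        (24.5, "sensitivity25", True),
        (25.0, "sensitivity25", False),
    ],
)
def test_bmi_band(bmi, rule, expected):
    assert classify_bmi(bmi, AnalysisConfig(bmi_rule=rule)) is expected


def test_bmi_rejects_nonpositive():
    with pytest.raises(ValueError):
        classify_bmi(0.0)


@pytest.mark.parametrize(
    "status,quit,expected",
    [("never", None, True), ("former", 30, True), ("former", 29, False), ("current", None, False)],
)
def test_smoking_rule(status, quit, expected):
    assert classify_smoking(status, quit) is expected


def test_smoking_former_requires_quit_years():
    with pytest.raises(ValueError):
        classify_smoking("former", None)


@pytest.mark.parametrize("level,expected", [("low", False), ("moderate", True), ("high", True)])
def test_activity_rule(level, expected):
    assert classify_activity(level) is expected


@pytest.mark.parametrize("drinks,expected", [(0, True), (12, True), (13, False)])
def test_drinking_rule(drinks, expected):
    assert classify_drinking(drinks) is expected


# ---------------------------------------------------------------------------
# Lifestyle score and grouping
# ---------------------------------------------------------------------------


def test_lifestyle_profile_examples():
    # all five healthful
    best = make_subject("A")
    # diet + BMI healthful only
    two = make_subject(
        "B", smoking="current", ipaq_level="low", drinks_per_year=50
    )
    # none healthful
    none = make_subject(
        "C",
        **{f"ff_{i}": "never" for i in BENEFICIAL},
        ff_red_meat="daily",
        bmi=30.0,
        smoking="current",
        ipaq_level="low",
        drinks_per_year=100,
    )
    prof = score_lifestyle(make_cohort([best, two, none]))
    assert list(prof["lifestyle_score"]) == [5, 2, 0]
    assert list(prof["lifestyle_group"]) == ["healthful", "intermediate", "unhealthful"]


@settings(deadline=None, derandomize=True)
@given(st.integers(0, 5))
def test_group_bins(score):
    expected = "unhealthful" if score <= 1 else "intermediate" if score <= 3 else "healthful"
    assert lifestyle_group(score) == expected


def test_score_equals_sum_of_indicators(sim_cohort):
    prof = score_lifestyle(sim_cohort)
    indicators = prof[
        [f"{f}_healthful" for f in ("diet", "bmi", "smoking", "activity", "drinking")]
    ].sum(axis=1)
    assert (prof["lifestyle_score"] == indicators).all()
    assert prof["lifestyle_score"].between(0, 5).all()


# ---------------------------------------------------------------------------
# Genetic risk score
# ---------------------------------------------------------------------------


def _model_with_effects(values):
    """GrsModel with hand-listed effects for the 13 loci."""
    effects, ref = {}, reference_genotypes()
    for snp, (e1, e2) in zip(SNP_IDS, values):
        g0, g1, g2 = genotype_labels(snp)
        effects[snp] = {g0: 0.0, g1: e1, g2: e2}
    return GrsModel(effects=effects, reference=ref)


def test_grs_sum_examples():
    rng = np.random.default_rng(7)
    values = [(round(a, 3), round(b, 3)) for a, b in rng.normal(0.2, 0.1, (13, 2))]
    model = _model_with_effects(values)

    ref_row = {snp: genotype_labels(snp)[0] for snp in SNP_IDS}
    assert compute_grs(ref_row, model) == 0.0

    one = dict(ref_row)
    one[SNP_IDS[4]] = genotype_labels(SNP_IDS[4])[1]
    assert compute_grs(one, model) == pytest.approx(values[4][0])

    # all heterozygote: brute-force hand sum of the first effect column
    het = {snp: genotype_labels(snp)[1] for snp in SNP_IDS}
    assert compute_grs(het, model) == pytest.approx(sum(v[0] for v in values))


def test_grs_additivity(sim_cohort, scored_cohort):
    _, model = scored_cohort
    genos = sim_cohort[list(SNP_IDS)].head(5).copy()
    base = compute_grs(genos, model)
    snp = SNP_IDS[0]
    g0, g1, g2 = genotype_labels(snp)
    flipped = genos.copy()
    flipped[snp] = g2
    delta = compute_grs(flipped, model) - base
    expected = np.array([model.effects[snp][g2] - model.effects[snp][g] for g in genos[snp]])
    np.testing.assert_allclose(delta, expected, atol=1e-12)


def test_grs_unknown_genotype_rejected(scored_cohort):
    _, model = scored_cohort
    row = {snp: genotype_labels(snp)[0] for snp in SNP_IDS}
    row[SNP_IDS[0]] = "XX"
    with pytest.raises(ValueError, match="XX"):
        compute_grs(row, model)


def test_genotype_effects_match_contingency_table():
    """Single-SNP saturated logistic = closed-form 2x3 table odds ratios."""
    snp = SNP_IDS[0]
    g0, g1, g2 = genotype_labels(snp)
    # genotype: (events, non-events) -- closed-form saturated model
    cells = {g0: (30, 170), g1: (45, 155), g2: (40, 60)}
    rows = []
    i = 0
    for geno, (ev, nonev) in cells.items():
        for k in range(ev + nonev):
            rows.append(
                make_subject(
                    f"S{i}",
                    **{snp: geno},
                    hypertension=k < ev,
                    followup_sbp=145.0 if k < ev else 120.0,
                    followup_dbp=85.0 if k < ev else 75.0,
                )
            )
            i += 1
    cohort = make_cohort(rows)
    model = estimate_genotype_effects(cohort, reference=reference_genotypes())

    def log_or(ev, nonev):
        return np.log((ev * cells[g0][1]) / (nonev * cells[g0][0]))

    assert model.effects[snp][g0] == 0.0
    assert model.effects[snp][g1] == pytest.approx(log_or(45, 155), rel=1e-6)
    assert model.effects[snp][g2] == pytest.approx(log_or(40, 60), rel=1e-6)


def test_monomorphic_snp_gets_zero_effects():
    rows = [
        make_subject(f"S{i}", hypertension=i < 3, followup_sbp=145.0 if i < 3 else 120.0)
        for i in range(10)
    ]
    cohort = make_cohort(rows)  # every genotype is the reference homozygote
    model = estimate_genotype_effects(cohort)
    assert all(set(model.effects[snp].values()) == {0.0} for snp in SNP_IDS)
    assert any("monomorphic" in w for w in model.meta["warnings"])


def test_tertile_assignment_oracle():
    groups = assign_grs_groups(np.arange(1.0, 10.0))
    assert list(groups) == ["low"] * 3 + ["intermediate"] * 3 + ["high"] * 3

    two = assign_grs_groups(np.array([0.2, 0.9]))
    assert list(two) == ["low", "high"]

    same = assign_grs_groups(np.full(5, 1.3))  # degenerate: warns, all low
    assert list(same) == ["low"] * 5


def test_tertile_balance_with_ties(scored_cohort):
    scored, _ = scored_cohort
    grs = scored["grs"].dropna().to_numpy()
    groups = assign_grs_groups(grs)
    sizes = groups.value_counts()
    assert sizes.max() - sizes.min() <= 2
    means = pd.Series(grs).groupby(groups.to_numpy()).mean()
    assert means["low"] <= means["intermediate"] <= means["high"]
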