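"""Population-impact indicator panel: RR, AR, PAR, PAR%, PFP, averted cases."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genelife.epi import (
    DegenerateGroupError,
    ExposureCounts,
    compute_indicators,
    indicator_table,
    tabulate_exposure,
)

from conftest import make_cohort, make_subject


def test_published_overall_counts_reproduce_printed_panel():
    """636/3046 exposed, 232/1546 unexposed, 868/4592 total -> printed row."""
    counts = ExposureCounts(636, 3046, 232, 1546)
    panel = compute_indicators(counts, 4592, 868)
    r = panel.rounded(2)
    assert r["rr"] == 1.39
    assert r["ar"] == 5.87
    assert r["par"] == 0.04
    assert r["par_pct"] == 20.61
    assert r["pfp"] == 9.47
    assert r["morbidities_averted"] == 90.80


def test_hand_arithmetic_oracle():
    panel = compute_indicators(ExposureCounts(20, 100, 10, 100), 200, 30)
    assert panel.rr == pytest.approx(2.0)
    assert panel.ar == pytest.approx(10.0)
    assert panel.par_pct == pytest.approx((0.15 - 0.10) / 0.15 * 100)
    assert panel.morbidities_averted == pytest.approx(200 * (0.20 - 0.15))


def test_no_effect_identity():
    panel = compute_indicators(ExposureCounts(10, 100, 10, 100), 200, 20)
    assert panel.rr == pytest.approx(1.0)
    assert panel.ar == pytest.approx(0.0)
    assert panel.par == pytest.approx(0.0)
    assert panel.pfp == pytest.approx(0.0)
    assert panel.morbidities_averted == pytest.approx(0.0)


counts_strategy = st.tuples(
    st.integers(1, 500), st.integers(1, 500), st.integers(1, 500), st.integers(1, 500)
).map(lambda t: ExposureCounts(min(t[0], t[1]), t[0] + t[1], min(t[2], t[3]), t[2] + t[3]))


@settings(deadline=None, derandomize=True, max_examples=200)
@given(counts_strategy)
def test_algebraic_identities(counts):
    """PAR% = PAR/It*100, AR = (RR-1)*Iu*100, averted = events*PFP/(100-PFP)."""
    total = counts.exposed_total + counts.unexposed_total
    events = counts.exposed_events + counts.unexposed_events
    panel = compute_indicators(counts, total, events)
    assert panel.par_pct == pytest.approx(panel.par / panel.incidence_total * 100, abs=1e-12)
    assert panel.ar == pytest.approx(
        (panel.rr - 1) * panel.incidence_unexposed * 100, abs=1e-9
    )
    assert panel.morbidities_averted == pytest.approx(
        events * panel.pfp / (100 - panel.pfp), abs=1e-9
    )
    assert 0 <= panel.incidence_total <= 1


def test_monotone_in_exposed_incidence():
    fixed = dict(unexposed_events=10, unexposed_total=100)
    panels = [
        compute_indicators(
            ExposureCounts(ev, 100, **fixed), population_total=200, population_events=ev + 10
        )
        for ev in (15, 25, 40)
    ]
    for a, b in zip(panels, panels[1:]):
        assert b.rr > a.rr and b.ar > a.ar and b.pfp > a.pfp


def test_degenerate_groups_raise():
    with pytest.raises(DegenerateGroupError, match="unexposed"):
        compute_indicators(ExposureCounts(5, 10, 0, 0), 10, 5)
    with pytest.raises(DegenerateGroupError, match="exposed"):
        compute_indicators(ExposureCounts(0, 0, 5, 10), 10, 5)
    with pytest.raises(DegenerateGroupError, match="RR undefined"):
        compute_indicators(ExposureCounts(5, 10, 0, 10), 20, 5)


def test_tabulate_exposure_hand_counts():
    rows = []
    # scores: 5,5,2,0,4,3  events: F,T,T,F,T,F  (hand-countable)
    cases = [
        (5, False), (5, True), (2, True), (0, False), (4, True), (3, False),
    ]
    for i, (score, event) in enumerate(cases):
        over = {}
        if score < 5:
            over["drinks_per_year"] = 50          # drop drinking factor
        if score < 4:
            over["ipaq_level"] = "low"            # drop activity
        if score < 3:
            over["smoking"] = "current"           # drop smoking
        if score < 2:
            over["bmi"] = 30.0                    # drop BMI
        if score < 1:
            over["ff_red_meat"] = "daily"
            over.update({f"ff_{x}": "never" for x in (
                "whole_grains", "fish", "eggs", "dairy", "vegetables",
                "fruits", "bean_products", "nuts")})
        if event:
            over.update(followup_sbp=150.0, followup_dbp=92.0, hypertension=True)
        rows.append(make_subject(f"S{i}", **over))
    cohort = make_cohort(rows)
    from genelife.scoring import score_lifestyle

    scored = pd.concat([cohort, score_lifestyle(cohort)], axis=1)
    assert list(scored["lifestyle_score"]) == [s for s, _ in cases]
    counts = tabulate_exposure(scored)
    assert counts == ExposureCounts(
        exposed_events=1, exposed_total=3, unexposed_events=2, unexposed_total=3
    )


def test_tabulate_all_unexposed():
    cohort = make_cohort([make_subject("S1"), make_subject("S2")])
    from genelife.scoring import score_lifestyle

    scored = pd.concat([cohort, score_lifestyle(cohort)], axis=1)
    counts = tabulate_exposure(scored)
    assert counts.exposed_total == 0
    with pytest.raises(DegenerateGroupError):
        compute_indicators(counts, 2, 0)


def test_indicator_table_consistency(scored_cohort):
    """Overall column equals compute_indicators on pooled counts; strata stack."""
    scored, _ = scored_cohort
    table = indicator_table(scored)
    assert list(table["stratum"]) == ["overall", "low", "intermediate", "high"]
    overall = table.iloc[0]
    counts = tabulate_exposure(scored)
    panel = compute_indicators(counts, len(scored), int(scored["hypertension"].sum()))
    assert overall["rr"] == pytest.approx(panel.rr)
    assert overall["morbidities_averted"] == pytest.approx(panel.morbidities_averted)
    # stratum populations partition the cohort
    assert table.iloc[1:]["n"].sum() == scored["grs"].notna().sum()
    # pooled vs summed-stratum averted are reported side by side
    assert "sum_stratum_averted" in table.attrs


def test_indicator_table_flags_degenerate_stratum(scored_cohort):
    scored, _ = scored_cohort
    capped = scored.copy()
    mask = capped["grs_group"] == "high"
    capped.loc[mask, "lifestyle_score"] = 2  # no unexposed subjects in stratum
    table = indicator_table(capped).set_index("stratum")
    assert "unexposed" in table.loc["high", "note"]
    assert np.isnan(table.loc["high", "rr"])
    assert table.loc["overall", "note"] == ""


def test_brute_force_equivalence_on_small_random_cohorts(scored_cohort):
    """Indicators match direct per-subject counting on random subsets."""
    scored, _ = scored_cohort
    rng = np.random.default_rng(0)
    for _ in range(5):
        sub = scored.sample(n=150, random_state=rng.integers(2**31 - 1))
        exposed = sub["lifestyle_score"] <= 3
        if exposed.all() or (~exposed).all():
            continue
        counts = tabulate_exposure(sub)
        panel = compute_indicators(counts, len(sub), int(sub["hypertension"].sum()))
        ie = sub.loc[exposed, "hypertension"].mean()
        iu = sub.loc[~exposed, "hypertension"].mean()
        assert panel.rr == pytest.approx(ie / iu)
        assert panel.ar == pytest.approx((ie - iu) * 100)
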