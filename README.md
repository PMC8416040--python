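# genelife

Joint-effect analysis of genetic risk and healthy-lifestyle adherence on
incident hypertension, for epidemiologists working with short-follow-up
cohort tables (demographics, food-frequency items, anthropometry, smoking,
activity, drinking, 13 blood-pressure SNP genotypes, baseline/follow-up
blood pressure).

The package builds the two summary exposures and runs the full analysis:

- **Lifestyle score** `LS ∈ {0..5}`: one point per healthful factor —
  diet (9-item CHEI food-frequency sub-score ≥ 17), BMI (18.5 ≤ BMI < 24),
  smoking (never or quit ≥ 30 y), physical activity (IPAQ moderate/high),
  drinking (≤ 12 drinks/year) — grouped 0–1 / 2–3 / 4–5.
- **Genetic risk score** `GRS = Σⱼ βⱼ(gⱼ)`: the sum over 13 loci of
  in-sample per-genotype regression effect values (non-risk homozygote =
  reference), grouped into tertiles.
- **Models**: logistic regression for 3-year incident hypertension
  (SBP ≥ 140 or DBP ≥ 90 mmHg or antihypertensive medication), linear
  models for follow-up SBP/DBP; unadjusted, covariate-adjusted and
  mutually adjusted tiers, plus a 3×3 GRS-by-lifestyle joint grid against
  the low-GRS/healthful reference.
- **Additive interaction**: `RERI = OR₁₁ − OR₁₀ − OR₀₁ + 1` over the
  dichotomized exposures, delta-method or bootstrap CIs.
- **Population impact**: `RR = Iₑ/Iᵤ`, `AR = Iₑ − Iᵤ`, `PAR = Iₜ − Iᵤ`,
  `PAR% = PAR/Iₜ`, `PFP = (Iₑ − Iₜ)/Iₑ`, morbidities averted
  `N·(Iₑ − Iₜ)`, overall and per GRS tertile.

Because no individual-level data are deposited, a seeded synthetic cohort
generator (`genelife.simulate`) reproduces the published marginal
distributions and configurable effect sizes, so every stage is testable
end to end. See `docs/methods.md` for the model details and what the
synthetic world does and does not establish.

## Worked example

```sh
python analysis/01_simulate.py --seed 1     # draw the n=4,592 cohort
python analysis/02_score.py --seed 1        # CHEI, lifestyle score, GRS
python analysis/03_associations.py --seed 1 # Models 1-3 + joint grid
python analysis/04_interaction.py --seed 1  # RERI panel
python analysis/05_indicators.py            # RR/AR/PAR/PFP panel
```

Step 05 prints (seed 1):

```
     stratum    n  events  incidence_pct   rr   ar  par  par_pct  pfp  morbidities_averted
     overall 4592     882          19.21 1.31 4.95 0.03    17.57 7.56                72.16
         low 1531     208          13.59 1.26 2.99 0.02    14.90 6.61                14.72
intermediate 1530     293          19.15 1.35 5.42 0.04    19.10 8.42                26.92
        high 1531     381          24.89 1.29 6.06 0.04    16.89 6.94                28.42
```

Reading the overall row: subjects with an unfavorable lifestyle (score
0–3) develop hypertension 1.31 times as often as those with a favorable
one (score 4–5); the unfavorable lifestyle adds 4.95 percentage points of
incidence among the exposed; 17.57% of all incident cases are attributable
to it; and the current prevalence of the favorable lifestyle already
reduces population incidence by 7.56%, i.e. about 72 cases averted in this
cohort. The same drivers print the mutually adjusted ORs (e.g. high- vs
low-GRS OR ≈ 2.1 under the default simulated effect sizes) and the RERI
panel with its additive-interaction verdicts.

The equivalent shell interface: `genelife simulate|score|fit|indicators|run`,
each taking `--seed`, `--config` (YAML) and `--out`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the published cohort's lifestyle-score margins (exposed
636/3,046, unexposed 232/1,546, total 868/4,592), the overall
epidemiological-indicator row — RR, AR, PAR, PAR%, PFP, morbidities
averted — and the overall incidence, writing them as JSON; it also runs
the full pipeline on a synthetic cohort of the same size as a smoke check.
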