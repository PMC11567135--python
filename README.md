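# dlwater

Doubly-labelled-water (DLW) energetics for field physiology: from raw
isotope washout curves to total energy expenditure, water turnover and
body composition, with the cohort-level statistics and accelerometry
summaries that a human-energetics study needs around them.

The package was built around a reference cohort of 34 Daasanach adults —
semi-nomadic pastoralists from three communities (Illeret, El Bokoch,
Roto) in the hot, arid Turkana Basin of northern Kenya — whose published
measurement table ships with the package and serves as its golden test
surface. It is aimed at researchers in human energetics, biological
anthropology and nutrition who run DLW field studies.

## The method

After an oral dose of water labelled with deuterium and oxygen-18, both
tracers wash out of body water mono-exponentially. ²H leaves only as
water; ¹⁸O leaves as water *and* as CO₂. The washout slope-intercept fit
gives each tracer's elimination rate (k_D, k_O; day⁻¹) and dilution space
(N_D, N_O; mol), and the rate difference isolates CO₂ production:

    N_corr = (N_D/1.043 + N_O/1.007) / 2
    Δ      = 1.007·k_O − 1.043·k_D
    rCO₂   = (N_corr/2.078)·Δ − 0.0246·(1.05·N_corr·Δ)     [mol/day]
    TEE    = 22.26·rCO₂ · (1.106 + 3.94/FQ)                [kcal/day]

with FQ the food quotient (default 0.86). The dilution space also yields
body composition — TBW = N_corr·0.01802 kg, FFM = TBW/0.732 — and the
deuterium kinetics alone give water turnover,
WT = 0.01802·1.043·k_D·N_D/0.99 litres/day.

On top of the per-participant chain the package provides the study-level
statistics: ln-transformed allometric OLS models (lnTEE ~ lnFFM + lnFM +
sex, and nested variants), residual-adjusted one-way ANOVA between
communities, Kruskal–Wallis tests, group summaries, and screening of
individuals against an external reference regression via 95% prediction
intervals. An accelerometry module converts 10-s triaxial count streams
to daily steps and sedentary+nonwear / light / MVPA minutes using
per-minute vector-magnitude cut points (200 and 2690 counts/min) and
Choi-style non-wear marking. A synthetic-data module generates cohorts,
washout curves and count streams with exact ground truth, by inverting
the equations above.

## Worked example

```python
import dlwater as dw

participants, isotopes = dw.load_reference_cohort()
derived = dw.process_cohort(participants, isotopes)

row = derived.set_index("participant_id").loc["D34"]   # a 22-y Roto man, 52 kg
print(row[["FFM_kg", "fat_pct", "rCO2_L_day", "TEE_kcal_day", "WT_L_day"]]
      .astype(float).round(2))

res = dw.fit_model(dw.ModelSpec("lnTEE", ("lnFFM", "lnFM", "sex")), derived)
print(res.summary())
```

```
FFM_kg            47.65
fat_pct            8.37
rCO2_L_day       733.35
TEE_kcal_day    4170.83
WT_L_day           7.83

lnTEE ~ lnFFM + lnFM + sex
------------------------------------------------
intercept                    3.3813 (0.8877)  p=0.0006436
lnFFM                        1.3207 (0.2250)  p=2.011e-06
lnFM                        -0.1656 (0.0713)  p=0.02721
sex[M]                      -0.2205 (0.0707)  p=0.004005
------------------------------------------------
n = 34   R^2 = 0.6781   adj. R^2 = 0.6459
```

From the printed kinetics of this participant the pipeline recovers a
fat-free mass of 47.7 kg, a TEE of ~4171 kcal/day (the cohort maximum)
and a water turnover of 7.83 L/day. The cohort model says TEE scales
with fat-free mass with an exponent of ~1.32, and that women expend
~22% more than men at equal composition (the negative male dummy on the
log scale); composition and sex together explain about two thirds of the
variance in ln TEE.

The same operations are available from a shell:

```
dlw compute participants.csv isotopes.csv -o derived.csv
dlw stats derived.csv --spec model.yaml -o coefficients.csv
dlw accel counts.csv -o day_summary.csv
dlw simulate cohort -o fixtures/ --n 100 --seed 1
```

Every command writes a `.provenance.json` sidecar recording the package
version, the complete constant set and SHA-256 hashes of its inputs.

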