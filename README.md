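# aquarisk

Non-carcinogenic health-risk assessment for contaminants in drinking water,
built around per-brand concentration surveys of bottled water. The package
computes chronic intake and hazard screening numbers the way regulatory
exposure assessments do, then replaces the single-point answer with a full
Monte Carlo distribution and says which input drives it.

It is aimed at environmental-health researchers and water-quality analysts
who have a table of measured concentrations (one row per brand or source,
optionally with the bottle's declared value) and want, per receptor group:

- **EDI**, the estimated daily intake: `EDI = C·IR·EF·ED / (BW·AT)`
  in mg/kg/day, where `C` is the concentration in water (mg/L), `IR` the
  ingestion rate (L/day), `EF` the exposure frequency (days/year), `ED` the
  exposure duration (years), `BW` body weight (kg) and `AT` the averaging
  time (days);
- **HQ**, the hazard quotient `HQ = EDI / RfD` against the contaminant's
  chronic oral reference dose, with `HQ > 1` flagging potential
  non-carcinogenic concern;
- **HI**, the hazard index `HI = Σ HQ` summed over co-occurring contaminants
  within the same brand;
- Monte Carlo propagation of the uncertainty in `C`, `IR` and `BW` through
  the HQ/HI chain (10,000 trials by default, fully seeded);
- a contribution-to-variance sensitivity analysis (normalised squared
  Spearman rank correlations) ranking the inputs.

A 22-brand bottled-water survey of fluoride (RfD 0.06 mg/kg/day, WHO range
0.5–1.5 mg/L) and nitrate (RfD 1.6 mg/kg/day, WHO ceiling 45 mg/L), together
with exposure profiles for infants, children, teenagers and adults, ships as
a built-in fixture; a synthetic-panel generator with known ground truth
backs the test suite.

## Worked example

```python
import aquarisk as aq

fluoride = aq.load_fixture("fluoride_table2")      # 22-brand survey panel
profiles = aq.load_fixture("exposure_table1")      # infants ... adults

print(aq.panel_summary(fluoride).rounded())
print(aq.guideline_screen(fluoride).counts)

table = aq.risk_table([fluoride, aq.load_fixture("nitrate_table2")], profiles)
print(aq.group_summary(table).rounded().hi.to_string(index=False))
print("infants fluoride HQ > 1:", table.hq_exceedances("infants", "fluoride"))
print("infants HI > 1:        ", table.hi_exceedances("infants"))
```

prints

```
{'contaminant': 'fluoride', 'n': 22, 'mean': 0.32, 'sd': 0.18, 'min': 0.01, 'max': 0.71}
{'below_low': 19, 'within': 3, 'above_high': 0, 'unlabeled': 8}
    group  n_brands  hi_mean  hi_min  hi_max  hi_above_threshold
  infants        22     0.64    0.05    1.38                   3
 children        22     0.36    0.03    0.79                   0
teenagers        22     0.27    0.02    0.59                   0
   adults        22     0.24    0.02    0.51                   0
infants fluoride HQ > 1: ('B3', 'B15')
infants HI > 1:         ('B3', 'B6', 'B15')
```

Reading: measured fluoride averages 0.32 ± 0.18 mg/L; 3 of 22 brands fall
inside the WHO 0.5–1.5 mg/L range, none above it, and 8 bottles declare no
fluoride value. Hazard decreases with age (the intake-to-body-weight ratio
IR/BW drops from 0.093 L/kg/day for infants to 0.035 for adults). Two brands
push the infant fluoride quotient past 1, and three brands push the combined
fluoride+nitrate index past 1 for infants — note that hazard indices here
always sum the two quotients *of the same brand*, pairing records by brand
identifier, never by table row.

The probabilistic layer on top of the same panel:

```python
scenario = aq.default_scenario(fluoride, profiles[0], seed=1)  # infants
result = aq.simulate_hq(scenario)
print({k: round(v, 3) for k, v in result.percentiles.items()}, round(result.mean, 3))

report = aq.sensitivity_report(scenario)
print(report.rounded(), report.ranking)
```

```
{5.0: 0.087, 50.0: 0.402, 95.0: 1.869} 0.624
{'C': 90.4, 'IR': 7.1, 'BW': 2.5} ('C', 'IR', 'BW')
```

Concentration uncertainty dominates the simulated infant HQ (≈ 90% of the
explained rank variance), with ingestion rate and body weight minor — the
brand-to-brand concentration spread (fitted lognormal log-SD ≈ 1.2) is far
wider than the behavioural/physiological spreads assumed for IR and BW.

The same pipeline is scriptable from the shell:

```bash
aquarisk summarize
aquarisk risk --out out/
aquarisk simulate --contaminant fluoride --group infants --seed 1
aquarisk sensitivity --contaminant nitrate --group adults --seed 1
aquarisk synth --p1 -1.2 --p2 0.5 --out panel.csv
aquarisk run --seed 1 --out out/          # everything + manifest.json
```

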