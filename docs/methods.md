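# Methods

## Exposure model

The package implements the standard screening-level chain for chronic oral
exposure through drinking water:

```
EDI = C · IR · EF · ED / (BW · AT)       [mg/kg/day]
HQ  = EDI / RfD                          [–]
HI  = Σ_contaminants HQ                  [–]
```

Assumptions inherited from this model family:

- ingestion of water is the only exposure route (no dermal or inhalation
  contribution, no food or beverage sources);
- intake scales linearly with concentration — EDI and HQ are homogeneous of
  degree 1 in `C`, so the quotient of a mean concentration equals the mean
  of per-brand quotients;
- quotients of different contaminants add without interaction (the hazard
  index is a screening sum, not a toxicological dose-addition model);
- `HQ > 1` (strict) is the flag threshold for both quotients and indices.

Every default exposure profile satisfies `AT = ED · EF`, which cancels the
duration terms and reduces EDI to `C · IR / BW`; the implementation keeps the
full six-parameter form so user profiles without that property behave
correctly, and exposes `ExposureProfile.at_consistent` so the cancellation is
visible rather than silent.

Hazard indices always pair records **by brand identifier**, never by row
position; panels covering different brand sets are rejected with the
symmetric difference listed. This matters: a one-row misalignment between
two contaminant columns changes which brands cross `HI = 1` even though all
column means are unaffected.

## Default parameters

Per-group exposure parameters (`exposure_table1` fixture):

| group     | IR (L/day) | EF (d/yr) | ED (yr) | BW (kg) | AT (d) |
|-----------|-----------:|----------:|--------:|--------:|-------:|
| infants   | 0.7        | 365       | 1.5     | 7.5     | 547.5  |
| children  | 0.8        | 365       | 4       | 15      | 1460   |
| teenagers | 2.0        | 365       | 13      | 50      | 4745   |
| adults    | 2.5        | 365       | 40      | 72      | 14600  |

Contaminant constants: fluoride RfD 0.06 mg/kg/day with guideline range
0.5–1.5 mg/L; nitrate RfD 1.6 mg/kg/day with guideline ceiling 45 mg/L.
Since IR/BW decreases monotonically across the four groups (0.0933, 0.0533,
0.0400, 0.0347 L/kg/day), every fixed concentration yields
HQ(infants) > HQ(children) > HQ(teenagers) > HQ(adults).

## Monte Carlo propagation

Per trial, `C`, `IR` and `BW` are drawn independently from their marginal
distributions and pushed through the chain; `EF`, `ED`, `AT` and `RfD` stay
fixed. Defaults, all overridable per scenario or via configuration:

- **C** — lognormal fitted to the panel's measured values by log-moments:
  `p1 = mean(ln x)`, `p2 = sample SD(ln x)` (n−1). Values at or below a
  detection floor (default 0.005 mg/L) are clamped to the floor before
  logging and counted, so near-zero measurements (detection-limit semantics)
  cannot blow up the log fit. Note the fitted spread is the *brand-to-brand*
  spread: a trial models a consumer drawing a random brand.
- **IR** — lognormal with median equal to the profile's ingestion rate
  (`p1 = ln IR`) and log-SD 0.25, a conventional behavioural spread for
  daily water intake.
- **BW** — normal with mean equal to the profile's body weight, coefficient
  of variation 0.15, truncated below at 0.2 × mean to keep weights physical.

Numerical choices:

- Truncation is enforced by rejection (redraw until inside the inclusive
  bounds). If, after at least 10,000 proposals, the acceptance rate is below
  10⁻⁴, sampling aborts with an error rather than looping on a
  negligible-mass interval.
- One root seed per scenario; the three per-variable streams are spawned
  from it with `numpy.random.SeedSequence`, so identical scenarios give
  bitwise-identical trial vectors. For a hazard index, IR and BW streams are
  drawn **once and shared across contaminants** within a trial (each trial
  is one person) while concentration streams are independent per
  contaminant; the HI trial vector is the exact elementwise sum of the
  per-contaminant HQ vectors.
- Percentiles interpolate linearly between adjacent order statistics at rank
  `1 + (n−1)q` (numpy's default quantile rule), so e.g. trials (1,2,3,4) at
  q = 0.95 give 3.85.
- A constant (all-point) trial vector short-circuits the moment summary so
  that the degenerate simulation equals the deterministic engine exactly —
  mean, SD 0 and every percentile — instead of picking up summation
  round-off.
- Default trial count 10,000; summary percentiles 5/50/95, with the full
  1–99% range available through `percentile()`.

## Sensitivity analysis

Contribution to variance follows the rank-correlation convention used by
spreadsheet risk tools: for each varied input,
`contribution_i = 100 · ρ_i² / Σ_j ρ_j²` where `ρ_i` is the Spearman
correlation (mid-ranks, average ties) between the input's trial vector and
the output. Being rank-based, contributions are invariant to monotone
rescaling of any input. Body weight enters the chain inversely, so its
signed correlation is negative; the report carries the signed coefficients
alongside the squared-and-normalised percentages. Zero-variance (point)
inputs are flagged and contribute 0; an all-point scenario is a degenerate
error. Displayed percentages are reconciled to sum to exactly 100 by
largest-remainder rounding.

This is a correlation-based apportionment, not a variance decomposition: no
Sobol or standardised-regression indices are offered, and strongly
interacting models would need those.

## Synthetic panels

`generate_panel` emulates the features of a real brand survey that the
pipeline must survive: right-skewed lognormal concentrations (`p1`, `p2`
known), values pinned at a detection floor, replicate noise
(`|N(0, 0.05·measured)|`), a configurable fraction of unlabeled brands, and
declared values that disagree with measurements (label = measured ×
lognormal(0, 0.2)). It does **not** emulate spatial or temporal correlation
between brands, censored reporting ("< x" labels), or non-lognormal
concentration shapes — so passing tests demonstrate correct plumbing and
parameter recovery under the stated generative model, not robustness to
arbitrary real-world panels.

Parameter-recovery tolerances (log-moment fit within ±0.02 at n = 10,000)
follow from the standard error of the log-mean, `p2/√n ≈ 0.005`, with
comfortable margin.

## Reference survey fixture

The bundled 22-brand fluoride/nitrate survey table is stored exactly as
reported: label cells read `NL` when the bottle declares nothing and keep
bound strings such as `< 2` as free-text notes (never compared numerically;
such brands are *not* counted as unlabeled). Recomputed statistics:
fluoride 0.3241 ± 0.1776 mg/L (22 brands, 8 unlabeled), nitrate
2.2595 ± 1.4020 mg/L (3 unlabeled). With the default profiles, the brands
whose infant fluoride HQ exceeds 1 are B3 and B15; with same-brand pairing
the infant hazard index additionally exceeds 1 for B6 (0.762 + 0.250 =
1.012), giving three HI exceedances (B3, B6, B15).

## Problem sizes

The test suite runs the full fixture pipeline (22 × 4 × 2), Monte Carlo
checks at 10,000–100,000 trials, and property sweeps of a few dozen
generated panels; the whole suite completes in seconds on one CPU, which is
the intended scale for this kind of screening assessment.

## Known limitations

- Single route, single medium; no cumulative exposure across water sources,
  food or dental products, so absolute risk statements understate total
  intake.
- The concentration distribution is fitted to ≤ a few dozen brand means;
  with 22 observations the fitted log-SD itself is uncertain, and the
  simulated upper percentiles inherit that uncertainty (no second-order
  uncertainty analysis is attempted).
- IR and BW spreads are conventional defaults, not survey-derived for any
  particular population; conclusions about which input dominates are robust
  to moderate changes (the fitted concentration spread is several times
  larger) but the exact percentages are not.
- Guideline screening knows only the two configured bounds per contaminant;
  it is not a regulatory database.
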