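# totorisk

Probabilistic dietary risk assessment for trace elements (Cu, Cd, Zn, Fe,
Pb) in fish tissue, built around the exposure survey of totoaba
(*Totoaba macdonaldi*) muscle and liver from the Gulf of California. It is
aimed at environmental-health and food-safety analysts who need the full
chain from raw, left-censored tissue concentrations to a defensible
hazard-index statement.

The pipeline covers:

- **Censored group summaries** — stratified mean ± SE tables (tissue ×
  habitat × season × sex/maturity group) with an explicit substitution
  policy for values below the detection limit (zero, LOD/2, LOD, or
  detected-only), detectable fractions, and liver/muscle fold ratios.
- **Deterministic risk** — estimated daily intake
  `EDI = Cm · CR / BW` (mg per kg body weight per day) from the geometric
  mean muscle concentration, the percent contribution to the recommended
  daily intake (RDI), and the hazard index `HI = EDI / RfD` against EPA
  reference doses.
- **Monte Carlo hazard index** — log-normal consumption rate
  (0.100 ± 0.030 kg/day) and body weight (74 ± 10 kg), matched by moments
  (σ² = ln(1 + (sd/mean)²), μ = ln mean − σ²/2), propagated through
  `HI = C · CR / (BW · RfD)` for 10,000 iterations, with mean, 5th/95th
  percentiles, cumulative probability curves and exceedance checks.
- **Sensitivity analysis** — Spearman rank correlation of each input
  against the HI draws, and "contribution to variance" as the normalised
  squared rank correlation (the spreadsheet risk-tool convention).
- **Synthetic studies** — a generator that reproduces the survey's design
  (3 habitats × 3 seasons × 5 sex/maturity groups, two tissues, five
  elements) with log-normal within-stratum concentrations censored at
  element-specific LODs, so every stage is testable without the original
  raw data.

## Worked example

```python
from totorisk import (ExposureModel, analyze, default_element_table,
                      deterministic_risk_table, generate, run_mcs,
                      default_survey_design)

table = default_element_table()
records = generate(default_survey_design(), table, seed=20210408)
exposure = ExposureModel()

for row in deterministic_risk_table(records, exposure):
    rdi = f"{row.rdi_pct:5.1f}%" if row.rdi_pct is not None else "   --"
    print(f"{row.element}: gmean {row.cm_gmean_dw:7.3f} ug/g dw | "
          f"EDI {row.edi:.5f} mg/kg/day | RDI {rdi} | HI {row.hi:.4f}")

result = run_mcs(17.78, exposure, table["Zn"], n_iter=10_000, seed=20210408)
print(f"\nZn MCS (C fixed at 17.78 ug/g): mean HI {result.mean:.4f}, "
      f"p5 {result.p5:.4f}, p95 {result.p95:.4f}")
for e in analyze(result).entries:
    print(f"  {e.input_name:16s} rho {e.rank_correlation:+.3f}  "
          f"share {e.contribution_pct:6.2f}%")
```

prints

```
Cu: gmean   0.204 ug/g dw | EDI 0.00036 mg/kg/day | RDI   3.0% | HI 0.0009
Cd: gmean   0.006 ug/g dw | EDI 0.00001 mg/kg/day | RDI    -- | HI 0.0108
Zn: gmean  13.472 ug/g dw | EDI 0.02367 mg/kg/day | RDI  15.9% | HI 0.0789
Fe: gmean  14.927 ug/g dw | EDI 0.02622 mg/kg/day | RDI  24.3% | HI 0.0375

Zn MCS (C fixed at 17.78 ug/g): mean HI 0.0810, p5 0.0455, p95 0.1296
  consumption_rate rho +0.901  share  82.20%
  body_weight      rho -0.419  share  17.80%
  concentration    rho +0.000  share   0.00%
```

Reading this: a synthetic study with the survey's design puts the
geometric-mean muscle zinc at 13.5 µg/g dry weight, whose deterministic
hazard index is 0.079 — well under the HI = 1 threshold for concern. Fixing
zinc conservatively at the largest group mean (17.78 µg/g), the Monte Carlo
95th-percentile HI is still only 0.13, and the variability of the estimate
is driven overwhelmingly by how much fish people eat (82% of variance)
rather than by body weight; the concentration, being fixed, contributes
nothing.

The same stages are available from a shell:

```sh
totorisk report --out-dir results          # simulate -> summarize -> risk -> mcs -> sensitivity
totorisk mcs --element Zn --conc 17.78 --seed 1
totorisk risk --records my_records.csv --set exposure.dw_to_fw=0.25
```

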