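# Methods

## The model

The quantity of interest is the non-carcinogenic hazard from chronic
consumption of fish muscle containing a trace element at concentration
`Cm` (mg/kg fresh weight):

    EDI = Cm · CR / BW          (mg per kg body weight per day)
    HI  = EDI / RfD             (dimensionless)

`CR` is the daily muscle consumption rate (kg/day), `BW` adult body weight
(kg) and `RfD` the EPA oral reference dose. `HI < 1` is read as negligible
risk. For the essential elements (Cu, Zn, Fe) the same intake is also
expressed as a percentage of the recommended daily intake,
`100 · Cm · CR / RDI`.

Two pathways are implemented:

- **Deterministic**: point values CR = 0.130 kg/day (coastal fishermen) and
  BW = 74 kg, with `Cm` the geometric mean of the muscle concentrations —
  the natural central estimate for log-normally distributed exposure data.
- **Probabilistic**: 10,000 Monte Carlo iterations with
  CR ~ log-normal(0.100 ± 0.030 kg/day) and BW ~ log-normal(74 ± 10 kg)
  drawn independently, the concentration either fixed or itself log-normal.
  The two pathways deliberately use different CR values; both are explicit,
  separate configuration fields and are never silently shared.

### Log-normal moment convention

"74 ± 10" is read as the *natural-scale* mean and standard deviation of the
log-normal (the convention of spreadsheet risk tools), matched by

    σ² = ln(1 + (sd/mean)²),   μ = ln(mean) − σ²/2.

For BW this gives μ = 4.295017, σ = 0.134524; for CR μ = −2.345674,
σ = 0.293560. Under this convention several closed forms exist that the
tests use as independent oracles:

- `E[1/BW] = exp(σ²)/mean = 0.0137603`, so the fixed-C mean HI is
  `C·E[CR]·E[1/BW]/RfD` and the ratio of the probabilistic mean HI to the
  deterministic HI is `0.100 · E[1/BW] / (0.130/74) = 0.783`.
- `ln HI` is a linear combination of independent normals, so
  `(ln CR, ln HI)` is bivariate normal with Pearson correlation
  `ρ_P = σ_lnCR / √(σ_lnCR² + σ_lnBW²) = 0.909`, giving the exact Spearman
  correlation `(6/π)·asin(ρ_P/2) = 0.9012` for consumption rate and
  −0.4008 for body weight. The Monte Carlo estimates at n = 10,000 scatter
  around these with sd ≈ 0.01.

### Sensitivity analysis

Each retained input draw vector is Spearman-correlated against the HI
draws (average ranks on ties; a constant input gets ρ = 0 by convention).
An input's *contribution to variance* is `100 · ρ_i² / Σ_j ρ_j²`. This
normalised-squared-rank-correlation definition exactly reproduces the
arithmetic relationship among the published sensitivity pairs (e.g.
0.898² : 0.410² : 0.00362² normalises to 82.7% : 17.2% : 0.0013%),
identifying it as the convention of the original analysis tool. The sign
of ρ is reported alongside the non-negative share; fixed inputs drop out
of the normalisation.

## Censoring policy

Measurements below the element-specific detection limit (LOD) are
left-censored. Summaries accept four substitution policies — `zero`,
`half_lod` (default), `lod`, `detected_only`. Half-LOD is the standard
choice in the trace-element literature and is the package default; the
mean under `half_lod` always lies between the `zero`- and `lod`-policy
means. A stratum with every value censored is rendered `"<LOD"` (e.g.
`<0.07` for Pb) and carries no mean. Detected values between LOD and LOQ
are kept, flagged `below_loq`. Zero-substituted values cannot enter a
geometric mean and are excluded from it; an all-censored cell under the
`zero` policy raises with guidance to use `half_lod`.

Lead is carried through ingest and summaries but refused by every
hazard-index operation, because no EPA RfD exists for it; cadmium and lead
likewise have no RDI and are refused by the RDI-contribution operation.

## Units

Concentrations are stored in µg/g **dry weight** (the analytical basis)
and converted to fresh weight only in the exposure stage via the
`dw_to_fw` factor. The intake formula needs fresh weight, but no moisture
content is available for the tissue, so the default is `dw_to_fw = 1.0`:
treating dry-weight values as fresh-weight overstates concentration and
therefore risk, the conservative direction for a screening assessment. The
factor is a single explicit configuration field; note that µg/g and mg/kg
are the same number, so no numeric conversion occurs at the unit boundary.

## The synthetic-study generator

The generator emulates the survey the analysis was designed for: 28
tissue-by-habitat-by-season-by-group cells (14 liver, 14 muscle; 142 and
144 fish respectively), five elements each. Within a stratum,
concentrations are i.i.d. log-normal — positive, right-skewed, consistent
with the log-normal treatment of concentration in the probabilistic model
— parameterised by geometric mean and GSD back-solved from the published
"mean ± SE" via sd = SE·√n and the moment relations. Censoring is applied
after the draw, at the LOD: the measurement process, not the biology,
censors.

Cells published only as "<LOD" have no recoverable moments. Muscle
cadmium and copper all-censored cells are given GSD 2 and a geometric mean
placed so that the 90th percentile of draws equals the LOD, which
reproduces the survey's reported ~10% detectable fraction for muscle
cadmium. Lead, never detected in any sample, is placed at geometric mean
0.001 µg/g (GSD 2), ≈ 0% detectable. These are documented conventions, not
inferences; the corresponding strata are flagged `all_censored_cell` and
excluded from parameter-recovery checks.

What the generator does **not** emulate: between-element correlations
within a fish, fish age/length structure, spatial movement, or any
non-log-normal within-group shape. Passing tests therefore demonstrate
that the pipeline's arithmetic and censoring handling are correct under
the stated distributional assumptions — not that real totoaba data are
log-normal.

## Numerical choices

- Percentiles use the empirical quantile with linear interpolation
  (`numpy.quantile` default).
- Standard errors use the n−1 sample standard deviation.
- The empirical CDF export evaluates `P(HI ≤ x)` on a linear grid from the
  sample minimum to maximum; the final point is exactly 1.
- Random numbers come from `numpy.random.default_rng(seed)`; identical
  seed and configuration reproduce results bit for bit. The recorded
  default seed is 20210408.
- Degenerate inputs are defined, not errors: sd = 0 gives a point mass,
  GSD = 1 constant draws, a constant input Spearman ρ = 0.
- Moment-matched specs are validated to satisfy
  `exp(μ + σ²/2) = mean` within 1e−9 relative.

## Test and verification scale

Unit tests run the Monte Carlo at 1,000–100,000 iterations depending on
the tightness of the closed form being checked; the acceptance-style
checks use the model's own 10,000. The parameter-recovery check averages
each stratum's recovered mean over 200 generated studies and requires
agreement within 3 SE of the transcribed mean — averaging is needed
because a single study's stratum mean has sd ≈ SE by construction. The
sample-sd convergence check uses a kurtosis-corrected standard error,
`Var(s) ≈ sd²(γ₂+2)/(4n)`, since the normal-theory `sd/√(2n)` is ~30% too
small for a log-normal with CV 0.3.

## Known limitations

- The published probabilistic HI means (0.08/0.06/0.17/0.10) and RDI
  percentages (≈70/60/100%) depend on the study's unpublished
  concentration geometric means and an unstated dry-to-fresh conversion;
  they are not recomputable from printed inputs and the package does not
  attempt to force agreement.
- "Contribution to variance" is a rank-correlation heuristic, not a true
  variance decomposition (no Sobol indices).
- Inputs are sampled independently; no correlation structure between CR
  and BW is modelled.
- The fold-ratio operation treats the published "up to 40-, 7-, 80-fold"
  figures as descriptive; ratios are computed per matched stratum.
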