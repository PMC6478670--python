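# Methods

## The scoring construction

A polyrisk score is an additive score over categorical risk factors,
mirroring how polygenic scores sum per-allele log odds. For each factor,
every level (mutually exclusive; prevalences sum to 1) carries a relative
risk RR — in practice odds ratios from umbrella-review evidence are used in
this role without rare-outcome correction, a deliberate simplification —
and the construction is:

1. **raw score** r = log₁₀(RR). Reference levels have RR 1 and r 0.
   Protective associations are re-oriented so the scored exposure is the
   risk-increasing direction (e.g. impaired olfactory identification:
   OR 0.19 for good identification becomes RR 1/0.19 ≈ 5.26 for
   impairment); this keeps every factor's exposed score positive.
2. **centering**: subtract the prevalence-weighted population mean
   m = Σ pᵢ·rᵢ, so the centered scores average exactly zero in the
   population. A person's total is therefore relative to the average
   individual, not to the fully unexposed one.
3. **scaling and rounding**: multiply by 10 and round to the nearest half
   integer. Ties round away from zero (the construction is silent on ties;
   away-from-zero keeps exposed/baseline scores symmetric around the grid
   and reproduces the published table from the reconstructed prevalences).
   Scale (10) and grid (0.5) are construction parameters and can be varied
   for sensitivity analysis.

A total score S converts to an **equivalent relative risk** 10^(S/10):
+5 ≈ RR 3.16, +10 = RR 10. The conversion and its inverse
(10·log₁₀ RR) are exact, not tabulated.

**Composite factors.** Logically dependent exposures (immigrant generation
× region of origin; ethnic group × ethnic density) are merged into one
factor whose admissible levels are the label combinations; a designated
"collapse" level (not immigrant; White) absorbs the whole combination.
Composite RRs are products of the component RRs — log-additivity, the same
independence-of-effects assumption the additive score makes globally —
and joint prevalences are supplied directly.

**Rounding slack and inversion.** Because final scores are rounded to the
0.5 grid, a published score pair (exposed, baseline) pins the underlying RR
only to |Δlog₁₀RR| ≤ 0.05 and the prevalence to an interval.
`invert_published_scores` returns the implied RR (exact on the grid) and
that prevalence interval; the forward/backward round trip is tested
property-style.

## Default configuration and its provenance

The shipped table has 8 factor groups (24 levels). Only two of its inputs
are published values verbatim: the urbanicity relative risk used in the
worked example (2.2) and the urban prevalence (73.6%). The remaining
relative risks are the umbrella-review odds ratios (childhood trauma 2.87;
black Caribbean ethnicity 4.87; CHR-P screening status 9.32;
non-right-handedness 1.58; olfactory identification 0.19 and premorbid IQ
0.47 re-oriented to 1/OR), and the remaining prevalences are
**reconstructions**: the published final scores pin each factor's
prevalence-weighted mean raw score to a ±0.025 window on the log₁₀ scale,
and a realistic value was fixed once inside each window:

| factor | prevalence of scored level(s) | rationale |
|---|---|---|
| childhood trauma (moderate–severe) | 0.109 | exact inversion of the −0.5 baseline score |
| premorbid IQ < 93.6 | 0.335 | ≈ Φ((93.6−100)/15) for an IQ scale with SD 15; inside the feasible window [0.314, 0.381] (the point inversion 0.305 falls outside it) |
| non-right-handedness | 0.10 | typical population left-/mixed-handedness; reproduces the published "No: 0" via −0.199 → 0 |
| impaired olfactory identification | 0.22 | mid-window value |
| CHR-P screen positive (PQ-16 > 9) | 0.14 | mid-window value |
| immigration | 0.80 not immigrant; 0.01/0.09 North-African/other within each generation | ~20% immigrant population split evenly across generations, equal North-African share in both (the equal-proportion assumption of the composite) |
| ethnicity | 0.60 White; black Caribbean share 0.2 of the non-white population, density split 0.2/0.3/0.5 | an urban, ethnically diverse catchment; the White score of −2 forces a substantial non-white fraction |

Composite relative risks are pinned by the published score differences to
exact powers of ten (e.g. black Caribbean in a low-density area 10^0.8 ≈
6.31 = 4.87 × 1.296); the residual over the published marginal OR is
carried by the partner component. The reconstructed first-generation
North-African RR, 10^0.35 ≈ 2.24, independently matches the published
North-African OR of 2.22, which supports the reconstruction.

These prevalences are flagged "approximate" in the table's provenance
string. Scoring an individual does not depend on them; centering, the
population distribution, and population-average imputation do. Supplying a
measured prevalence file reproduces the corresponding population figures
exactly.

**Known discrepancy.** The published narrative quotes a minimum possible
total of −7.5, but the published per-level baseline scores sum to −9.5.
No exclusion rule in the source reconciles the two; the package reports the
configured sum (−9.5) and documents the difference rather than hard-coding
−7.5. The maximum (+32) matches.

## Population distribution

Factors are assumed independent — the only reconstructable reading of the
original large-permutation procedure, which drew levels per factor from
prevalence data. Two routes:

- **exact enumeration**: sequential convolution of the per-factor score
  distributions on the half-integer grid (integer half-units internally);
  2240 level combinations for the default table, instantaneous, and the
  authoritative oracle;
- **Monte-Carlo**: n individuals drawn level-by-level (inverse-CDF on a
  single seeded NumPy generator, factors in declared order, memory-bounded
  chunks of 2 × 10⁶). Reproducible bit-for-bit for a fixed (seed,
  chunk_size); frequencies converge to enumeration at rate 1/√n. The
  pointwise 3·SE band at n = 10⁶ holds for typical seeds but, with ~80
  support points compared simultaneously, is exceeded by chance for roughly
  a fifth of seeds; the seed-robust equivalence check is a chi-square
  goodness-of-fit test at familywise α = 10⁻³.

Summary fractions use grid-aligned relative-risk bins: "RR > 3" is S > 5
(10·log₁₀3 = 4.77 lies between grid points) and "RR > 30" is S > 15. With
the reconstructed default prevalences the enumeration gives 54.2% negative
scores, 27.3% in [0, 5], 18.5% above 5 and 1.41% above 15 — close to, but
not exactly, the originally reported 53.6%/25.7%/21.6%/1.8%, as expected
given the prevalence provenance above.

## Individual scoring and missing data

Profiles may be partial. Policies for an unassessed factor:
`population_average` (default) substitutes the factor's prevalence-weighted
mean *final* score — the zero-information value under centering, within
±0.25 of zero per factor since only rounding breaks exact zero; `omit`
contributes 0 (equivalent in expectation, but biased for a factor whose
rounding residual is non-zero, e.g. non-right-handedness at +0.2); `error`
aborts. `n_missing` counts unassessed factors under every policy.
Population-average imputation shrinks a cohort's score dispersion toward
the mean — imputed individuals cannot land in the tails — so distributional
statements should use complete profiles or the distribution module.

## Risk updating

Pre-/post-test updating is standard likelihood-ratio arithmetic on the odds
scale; chaining multiplies LRs, which assumes tests are conditionally
independent given outcome status (documented, not checked). Fold changes
are probability ratios, matching how enrichment figures are usually quoted
(0.43% → 15% ≈ 35-fold; 15% → 1.56% is a 9.6-fold decrease, narratively
"10-fold"). `apply_relative_risk` links a score's equivalent RR to an
absolute baseline risk by plain multiplication capped at 1 (first-order,
rare-outcome approximation) or on the odds scale; there is no canonical
link, so both are exposed and labelled.

## Synthetic cohorts

The cohort generator draws complete profiles from the configured
prevalences (independent factors, one seeded generator, declared factor
order) and masks each assignment missing independently at a configurable
rate. It emulates the *marginal* structure of self-reported or
record-extracted inputs only: real cohorts have correlated exposures
(e.g. urbanicity with ethnic density), informative missingness, and
measurement error, none of which the generator produces. Passing tests
therefore validate the arithmetic and the sampling machinery, not the
epidemiological realism of any particular configuration.

## Numerical choices

- Prevalence sums are validated to 1 ± 10⁻⁶; composite RR = product of
  components to 10⁻⁹; centering is exact to 10⁻⁹ in tests.
- Rounding ties detect at float precision; scores are held as floats on the
  0.5 grid (exactly representable in binary) and converted to integer
  half-units inside the distribution engine, so no float comparison
  tolerance is needed there.
- The distribution support reported is the set of scores with non-zero
  probability; for the default table every half-integer in [−9.5, 32] is
  populated.
- Problem sizes used by the packaged checks: exact enumeration over the
  2240-combination default table; Monte-Carlo equivalence at n = 10⁶;
  cohort frequency checks at n = 10⁵; the acceptance script's distribution
  run uses n = 10⁷ draws, matching the scale of the original permutation
  procedure.

## Limitations

- Additivity on the log scale ignores interactions and correlations between
  factors; the umbrella-review effect sizes are univariate and may be
  mutually confounded. The score is a prototype for detection research, not
  a validated clinical instrument.
- ORs are used as RRs; for outcomes that are not rare within strata this
  overstates effects.
- The shipped prevalences are reconstructions (see above); population
  distribution figures shift with the prevalence file supplied.
- No time-to-event structure: "risk" is a fixed-horizon probability tag,
  not a survival model.
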