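# Methods

## Evaluation model

The package evaluates a no-take reserve against a control site with a
before-after-control-impact (BACI) design. For every numeric biological
indicator the per-transect value is regressed on year factors, a zone
dummy, the post×zone interaction, and three environmental covariates:

    I = β0 + Σ γ_t Y_t + β1 Z + β2 (P × Z) + β3 T + β4 V + β5 D + ε

Modeling choices and their reasons:

- **Years as factors, first year as reference.** No linearity is imposed
  on the temporal trajectory; γ_t absorbs any common year-to-year shock
  (recruitment pulses, hypoxia events, survey-condition shifts).
- **No standalone P main effect.** The year dummies span the before/after
  partition, so a P column would be exactly collinear; it is deliberately
  omitted and the design matrix has `1 + (T−1) + 1 + 1 + 3` columns.
- **P = (year ≥ implementation_year) by default.** Whether the
  implementation year itself counts as "after" is genuinely ambiguous for
  reserves implemented mid-season; `post_from="impl-year+1"` flips the
  convention and is exposed on the CLI.
- **OLS + sandwich SEs.** Coefficients are ordinary least squares;
  inference uses heteroskedasticity-consistent covariances. HC1 is the
  default (the common small-sample degrees-of-freedom correction); HC0,
  HC2 and HC3 are selectable. Tests are two-sided Student-t with
  df = n − rank(X) (statsmodels is instructed to use t rather than its
  default normal approximation for robust covariances).
- **Missing data.** Undefined indicator values (e.g. Shannon diversity of
  an empty transect) propagate as NaN and are dropped from that fit —
  never coerced to zero, which would conflate "not measurable" with a true
  absence. Rows missing covariates are deleted listwise; if that would
  drop more than half the rows the model falls back to the covariate-free
  specification, with a logged count either way.
- **Rank handling.** The design matrix is checked with a pivoted QR; a
  deficiency raises an error naming the collinear columns rather than
  silently dropping one.

Economic series (total and per-species landings, CPI-adjusted income)
have no control site and use `I_t = β0 + β1 P_t + ε_t`; β1 is
algebraically the difference between post- and pre-period means. The fit
keeps robust SEs for consistency but the estimate is flagged non-causal
throughout the outputs.

### CPI adjustment

Income is adjusted as `I_t = RI × CPI_t / CPI_T` with T the reference
(most recent) year — the convention the evaluation protocol this package
follows prints. Conventional deflation to reference-year currency uses
the reciprocal ratio; because the two disagree whenever inflation is
nonzero, `deflation="standard"` applies `RI × CPI_T / CPI_t` instead.
The default favors protocol fidelity; the switch documents the ambiguity
instead of silently resolving it.

## Indicators

All indicators are per transect (no transect dimensions are assumed).
Fish and invertebrate communities are analyzed separately — diversity,
richness and density are each computed per taxon group, giving distinct
regression fits per community. Density and biomass additionally get one
variant per declared target species.

- **Shannon diversity** uses the natural logarithm (the dominant
  ecological convention; the index is dimensionless either way).
- **Percent mature** (`B3`) is the percentage of measured organisms at or
  above the species' length at first maturity; ties count as mature. It
  is reported as a percent of measured organisms.
- **Mean trophic level** is abundance-weighted
  (Σ n_s·TL_s / Σ n_s). Biomass weighting is an equally defensible
  choice; abundance weighting was selected and is stated here so the
  choice is visible.
- **Biomass** uses the universal allometric form W = a·L^b with a in
  g·cm⁻ᵇ, summed per transect and reported in kg. Organisms without a
  length use their species' mean measured length on the same transect if
  any; otherwise they are excluded with a logged count. The trait table
  is user-supplied — there are no silent default coefficients.
- Species codes missing from the trait table still contribute to
  diversity, richness and density; they are excluded (with a warning)
  only from trait-dependent indicators.

## Scorecard

Numeric indicators: direction = sign(β2) (β1 for economic indicators);
intensity strong if p < 0.05, weak if 0.05 ≤ p < 0.1, none otherwise;
any non-significant or exactly-zero effect is yellow regardless of sign.
Governance answers are scored red/green by a rubric shipped as an
editable CSV (`data/governance_rubric.csv`); it is a reconstruction of
commonly cited positive/negative governance factors, with ambiguous
ordinal mid-levels assigned conservatively (red), and is intended to be
replaced by users with local expertise. Narrative-only codes (reserve
type, enforcement description, siting rationale, natural disturbance)
pass through to the report unscored.

Scores are 100 × positives / scored. In the default `sign` mode an
indicator counts as positive when its direction is positive regardless
of significance; `strict` mode requires p < 0.1 as well. Neutral
(zero-effect) and unscorable indicators stay in/out of the denominator
respectively. Both modes exist because "percentage of positive
indicators" does not by itself fix the treatment of non-significant
positives; the default is the more literal reading.

## Synthetic data generator

The simulator emulates an annual two-zone visual-census program: a
species pool with per-species mean abundance and negative-binomial
dispersion (ecological counts are overdispersed, which is precisely what
the robust-SE machinery must withstand), individual fish lengths
(Gaussian, truncated at 2 cm), per-transect covariates, and a reserved
`NONE` row for surveyed-but-empty group transects.

Effect structure: a multiplicative lognormal year effect common to both
zones (σ = 0.08), an additive reserve-zone offset, and an additive
post×reserve shift — both offsets act on each taxon group's expected
total density and are allocated across that group's species proportional
to baseline means. With this structure the regression is correctly
specified in means (year dummies absorb the common year effect, Z the
zone offset) and the injected shift equals the true interaction
coefficient of the group-level density indicator exactly. A
multiplicative zone effect would instead create a zone×year interaction
absent from the model and bias the test; that is why the zone effect is
additive.

Presets:

- `minimal` — 2 years (2005, 2007), implementation 2006, 12 transects
  per site-year: exactly the recommended minimum design (48 transect
  units).
- `natividad_like` — 11 survey years (2006–2016) with the first year as
  pre-implementation baseline (implementation 2007), effort drawn
  uniformly from 12–27 transects per site-year, a 5-species fish
  community plus 6 invertebrates including 4 harvested target species,
  and positive injected density effects on snail (+15) and cucumber
  (+2) organisms/transect.
- `COUNTS_ONLY` — 4 invertebrate species, no lengths: compact records
  for large replication studies.

Economic simulation injects before/after level shifts on the
CPI-adjusted scale (nominal income is back-computed through the CPI
ratio), so with zero noise the before-after estimator recovers the shift
exactly.

What the simulator does **not** emulate: spatial autocorrelation among
transects, habitat structure, species interactions, observer effects,
covariate-driven abundance, or multi-reserve data. Passing calibration
tests therefore show the estimator is correct under an idealized but
overdispersed BACI data-generating process — not that parallel trends
holds in any particular real reserve.

## Calibration results computed by the test suite

With the study-scale conditions (12 transects/site/year, 10 years, null
effect, 2000 replicates) the empirical size of the p < 0.05 interaction
test is checked to lie in [0.03, 0.07]; with an injected effect of one
within-cell SD of invertebrate density at the 11-year variable-effort
scale (500 replicates), mean bias is checked against 2 Monte-Carlo SEs
and 95% CI coverage against [0.93, 0.97]. Problem sizes were chosen to
make Monte-Carlo error small relative to those bands while keeping the
suite quick to run. `scripts/acceptance.py` recomputes the null
rejection rate end to end from a user-supplied seed.

## Known limitations

- No clustered or spatially correlated error structures; robust SEs
  treat transects as independent.
- Single reserve/control pair per run; multi-site monitoring must be
  evaluated reserve by reserve.
- The governance rubric is a literature-informed default, not a
  validated instrument.
- Before-after economic contrasts are descriptive; market dynamics,
  effort shifts and price changes are out of scope.
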