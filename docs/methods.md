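# Methods

This note documents the statistical procedures implemented in `flockprefs`,
the choices made where the design was genuinely open, and what the
simulation-based tests do and do not demonstrate.

## Survey data model

A survey consists of two tables.  The *ewe table* holds one row per
surveyed ewe: grouping factors (site, farmer nested within site, breed
group, within-flock quality class Best/Average/Poor), objective
measurements (body weight kg, body length cm, heart girth cm, BCS on the
1–5 half-point grid, milk yield litres/day, price in KES as a positive
integer), optional age in years (1–9, from dentition) and the raw
across-breed rank.  The *reason table* holds up to three ordered free-text
reasons per ewe.

Validation is quarantine-based: a row violating an invariant (BCS off the
half-point grid, non-positive measurement, duplicated reason order, reason
order beyond 3, farmer appearing at two sites, duplicated quality class
within a farm × breed group) is set aside with a reason string and the
load continues.  Every row is either a record or a reported rejection, so
`accepted + quarantined = rows`.  Two modelling commitments worth
flagging: a milk yield of 0 is a *value* (no milk left after the lamb
suckled), not a missing datum; and reasons beyond order 3 are rejected
rather than silently truncated, because the index below is defined on
exactly three ordered reasons.

## Reason mapping

Transcribed phrases are grouped into seven trait categories: Body Size
and Growth, Condition, Milk Production, Reproduction and Mothering
Ability, Drought Tolerance, Disease Resistance, Breed Attributes.
Because the grouping of open answers is interpretive, the lexicon is a
data file (pattern → group), not code.  Matching is normalized substring
containment with longest-pattern-first resolution; a length tie between
groups falls back to file order and is logged; anything unmatched is
reported, never guessed.  The bundled lexicon covers the vocabulary named
in the source material plus obvious synonyms; real transcripts will need
extension, which is the point of making it data.

## Weighted-reasons index

For a stratum (breed × site × quality class), with X_ji the number of
order-j mentions of trait i and weights r = (3, 2, 1),

    WR_i = Σ_j r_j X_ji / Σ_i Σ_j r_j X_ji.

The published preference tables print the *weighted contributions*
c_ji = r_j·X_ji rather than the raw counts; this was verified
arithmetically (the printed Sum column equals the plain sum of the
printed triple, and WR = Sum/ΣSum in every stratum), so the bundled
fixture ingests contributions and divides by r_j (requiring exact
divisibility) to recover counts.  All count arithmetic is integer; WR
values are exact ratios until display, where they are rounded **half-up**
to two decimals — the convention that reproduces every printed cell
(e.g. 6/48 → 0.13, 13/40 → 0.33).

The four-category clustering merges Milk Production with Reproduction and
Mothering Ability ("Reproduction and Milk") and the two adaptive traits
into "Adaptation", and *excludes* Breed Attributes.  The published
clustered table does not state its denominator; renormalizing over the
non-excluded groups reproduces every printed cell (32/32), whereas
keeping the original denominator does not, so renormalization is the
default (a flag disables it).

Alternative weightings (equal 1/1/1, steeper 5/3/1) are supported as a
sensitivity check; they change the shares smoothly and preserve
normalization.

## Rank rescaling

Across-breed ranks from 6-ewe farms are mapped onto the 1–9 scale with
`new = 1 + (old − 1)·1.6`, the n = 6 case of the endpoint-preserving
affine map `1 + (old − 1)·8/(n − 1)` (identity at n = 9).  Rescaled ranks
are kept as reals.  Summaries average over ewes by default; a per-farm
option averages within farm first, since the source material does not say
which convention its breed-rank table used.  Missing ranks are excluded
pairwise and counted; the farm's scale is its total number of study ewes,
so a missing rank does not shrink its farm-mates' scale.

## Fixed-effects trait model

Each trait is analysed with

    y = μ + Site + Farmer(Site) + Breed + Quality + Breed:Site + e,

all effects fixed, exactly as the model equation is written — Farmer(Site)
is treatment-coded within site, so farmer effects are identified alongside
the site main effect (25 parameters at the default design, 122 residual
df at n = 147).  Design matrices are built explicitly so the same cell
encoder serves the fit and the LS-mean reference grid; the least-squares
solve is statsmodels OLS, and rank deficiency is an error naming the
aliased columns rather than a silent drop.

**Tests.**  Terms are tested with Type II marginal F tests (each term
against the model of all terms not containing it in the marginality
hierarchy, error mean square from the complete model), matching the
conventional ANOVA of the R regression companion toolchain; Type I and a
drop-term Type III are available.  Significance codes: *** p<0.001,
** p<0.01, * p<0.05, ns.

**Screening.**  Age and the Quality:Breed / Quality:Site interactions are
tested one at a time on top of the base model at α = 0.05 and retained
only if significant.  Inestimable candidates are reported and treated as
not retained.  On generator output the quality interactions are sometimes
genuinely retained — the published per-quality cell means are
non-additive across breeds — which is correct behaviour, not a false
positive.

**LS-means.**  The LS-mean of a margin is the model prediction averaged
with equal weight over the levels of every non-focal factor, with farmers
weighted equally *within their own site* (and sites equally when site is
not focal); a numeric covariate is held at its mean.  SEs come from the
contrast's quadratic form in the coefficient covariance.  A margin with
no observed records is still reported but flagged as an extrapolation.
Coefficients, Type II F statistics and LS-means were verified to agree
to all printed digits with an independent R computation (car-type-II +
emmeans conventions) on a deterministic fixture, and to 1e-8 relative
with a brute-force normal-equations oracle on random instances.

**Letters.**  Pairwise LS-mean differences use unadjusted two-sided t
tests at α = 0.05 (the convention behind "different superscripts differ
at p < 0.05"); Tukey's studentized-range adjustment is available behind a
flag.  The compact letter display uses insert-and-absorb and is tested
against maximal-clique enumeration; letters are ordered by descending
estimate.

**Diagnostics.**  The visual Q-Q/histogram normality check is replaced by
a numeric summary (skewness, excess kurtosis, Shapiro–Wilk), since visual
checks are not testable.

## Synthetic survey generator

The generator emulates the study design: 19 farms (10 + 9 across the two
sites), 11 farms with all three breed groups and 8 with two (assigned
6/3/1 and 5/3/1 per site), three ewes (Best/Average/Poor) per kept breed
group — 147 ewes, 51/39/57 per breed.

*Traits* are drawn from normal distributions per breed × site × quality
cell.  Cell means combine the published per-breed × quality means with
per-breed site offsets derived from the published marginal means (split
half below/half above); cell SDs are the published ones.  A fraction
(default 0.4) of each cell SD is attributed to a farmer-shared flock
effect — this fraction is a free parameter chosen as a plausible
intraclass correlation, not a published value.  BCS is snapped to the
half-point grid and clipped to [1, 5]; milk is truncated at 0; price is a
positive integer; body measurements are rounded to 0.1.

*Reasons*: each ewe draws three ordered categories **independently** from
its stratum profile (the published weighted-contribution shares; the
Average class, absent from the published tables, uses the mean of its
stratum's Best and Poor profiles).  Independent draws make the expected
weighted share equal the profile exactly.  Sampling the three categories
*without* replacement would cap any single category's expected weighted
share at 3/6 = 0.5 and bias steep profiles by up to ~0.27, contradicting
published shares of 0.53 and 0.71 — which themselves imply that a farmer
could name the same trait category at two orders through different
phrases.  Emitted phrases within an ewe stay distinct.

*Ranks* come from a latent per-site breed preference (defaults matching
the published average-rank table) plus a quality shift and unit noise,
converted to within-farm ranks.  *Ages* are integers 1–9 with mean ≈ 3.5.

Every latent draw — farmer effects, true cell means, per-ewe category
sequences, latent rank and quality scores — is recorded in a generation
ledger, so recovery tests compare pipeline output against the generator's
own bookkeeping.

### What the generator does not emulate

Real transcripts have open vocabulary (the lexicon maps everything the
generator emits by construction); real traits are correlated within ewe
and heteroscedastic across cells.  The published per-cell SDs *are*
heteroscedastic (body-weight SD 9.2 kg for Best Dorpers vs 3.9 for Poor),
so on generator output OLS standard errors are mildly optimistic for
breed contrasts: 2-SE recovery of the Isinya Dorper−Red Maasai gap runs
near 85% rather than the nominal ~95%.  Operating-characteristic tests
(CI coverage, screening type-I error) therefore simulate from the exact
homoscedastic model equation, where they are exact by construction; the
closed-loop and structural tests use the full generator.  Passing tests
show the pipeline computes its estimands correctly, not that real field
data satisfy the model's assumptions.

## Problem sizes and numerics

Simulation studies use 1000 replicates at the study's own n = 147 design
(CI coverage of the two breed:site coefficients; screening type-I error
per candidate) and 1000 ewes per stratum for the closed-loop recovery of
the 84 published WR values — sizes at which Monte-Carlo error is a few
parts per thousand while the whole suite runs in seconds.  The
Monte-Carlo loops reuse one design matrix and precomputed least-squares
factors, and validate their first replicate against the regular fitting
path so the fast path cannot drift.  Tolerances: oracle equivalence at
1e-8 relative; printed-table reproduction exact at two decimals under
half-up rounding; coverage within ±2 points of 95%; screening type-I
within ±1.5 points of 5%; closed-loop WR within ±0.03.

## Known limitations

- Fixed (not random) farmer effects follow the model equation as written;
  with one farmer per flock the two differ little for the contrasts of
  interest, but variance components are not estimable this way.
- The lexicon ships with the vocabulary of one study; unmapped phrases in
  new data are reported, not classified.
- Price is modelled on its raw KES scale (no transform is published);
  its residuals are the heaviest-tailed of the six traits.
- The pooled-site preference figures are simple sums of trait mass across
  sites before normalizing; they are exported as CSV, not plotted.
- The clustered-table renormalization is adopted from arithmetic
  consistency with the published cells, not from an explicit statement.
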