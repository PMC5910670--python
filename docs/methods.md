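# Methods

## Domain model and notation

A duplex is a 21-nt sense strand (3′ GalNAc, written `-L96`) and a 23-nt
antisense strand with a two-nucleotide 3′ overhang. Positions are 1-based
from the 5′ end of each strand (AS2 = antisense position 2, S11 = sense
position 11). Every ribose carries exactly one of {2′-F, 2′-OMe}; PS
linkages sit between antisense residues 1–2, 2–3, 21–22, 22–23 and sense
residues 1–2, 2–3. The text dialect (lowercase = 2′-OMe, `Nf` = 2′-F, `s` =
PS) is a package convention: published figures show patterns only as
colored squares, so a parseable shorthand had to be defined. Parsing and
writing are exact inverses (property-tested).

The packaged `reference_designs()` (parent, DV18, DV22) are figure-derived
reconstructions pinned to printed aggregate facts — nine 2′-F in the parent
antisense, six/four in the two advanced antisense designs, four in the
shared advanced sense design, critical 2′-F at AS2/AS6/AS14/S11, matched
chemistry at AS8/AS9 — with synthetic placeholder bases, since the
underlying sequences are not public. Only the aggregate counts are treated
as facts; per-position assignments outside the constrained set are
best-effort.

## Positional activity regression

Response: natural log of fraction of target mRNA remaining (records with
fraction ≤ 0 are rejected at ingest, never clamped). Design matrix:
intercept; one 0/1 indicator per strand position (1 = 2′-F, 2′-OMe is the
reference); target-site fixed effects (sites are identified uniquely across
targets); species indicators. PS content contributes no column. Sites are
nested within targets and species is a per-site attribute, so target is
absorbed by the site effects and species columns are usually collinear and
dropped by rank detection; the column map records both. Only target sites
with at least 10 distinct designs enter the fit (configurable), and the
default uses the 0.1 nM dose arm with replicate wells averaged on the ln
scale (geometric mean); a per-replicate mode is available because the
per-duplex replication entering such models is ambiguous in practice.

The OLS solver is written in-house: greedy left-to-right modified
Gram–Schmidt column selection (relative tolerance 1e-10, with
re-orthogonalization) chooses a linearly independent column subset so that
scientifically primary columns (intercept, chemistry) win ties, then a QR
solve gives β, with SE from σ̂²(XᵀX)⁻¹, two-sided t p-values, adjusted R²
and the overall F. Dropped columns are reported, never silently aliased;
with zero residual df the coefficients are returned with NaN inference and
a warning. The solver is verified against a normal-equations oracle and
against statsmodels in the tests. Significance threshold is α = 0.05 per
coefficient with no multiplicity correction across the 44 positional tests
— a deliberate caveat: with ~40 near-null positions, ~2 false flags per
screen are expected.

## Design-variant comparison

Directed SAR panels are reduced by ΔΔCt (per-well ΔCt = Ct_target −
Ct_housekeeping; ΔΔCt vs the non-targeting control wells; expression =
2^−ΔΔCt — invariant to plate-wide Ct shifts), then fit by OLS of
ln(fraction) on DV indicators with the comparator design as reference plus
categorical covariates: dose (two levels, categorical because no functional
form is assumed), site, and replicate as a blocking factor (treated as
batch). DVs observed at a single site are flagged low-support rather than
excluded.

## Design search

Predicted difference between two patterns is the sum of signed positional
coefficients over differing positions (the model is additive; positional
interactions are intentionally out of scope). The design problem is
formalized as: minimize total 2′-F count subject to predicted loss vs the
parent ≤ a tolerance (default 0.1 ln — the "maintaining activity" margin is
not quantified anywhere authoritative, so this is a documented default),
positions pinned to F/OMe, and pair groups sharing one chemistry (default
AS8/AS9). Pair groups are merged union-find style into blocks; up to 22
free blocks (~4M candidates) the search enumerates exhaustively with
vectorized bit arithmetic; above that a greedy that repeatedly demotes the
least-harmful 2′-F block runs instead and its output is flagged
non-exhaustive. Positions without an estimable coefficient may not deviate
from the parent. Ties in 2′-F count break by better predicted activity,
then lexicographic pattern order (F before OMe). Every emitted proposal is
re-checked against the constraints programmatically.

## Synthetic-data generators

`gen_screen` plants ln y = baseline(dose) + Σ γ_p·1[F] + site + target +
ε, ε ~ N(0, noise_sd²), i.e. multiplicative lognormal noise on the fraction
scale — this keeps observations strictly positive and makes the OLS model
*exactly* correct under the generator, so type-I calibration results are
exact at any sample size. Defaults are the study-scale conditions: 5
targets × 3 sites × 126 duplexes = 1,890 duplexes, doses {10, 0.1} nM in
quadruplicate, noise_sd 0.3, site_sd 0.3, target_sd 0.2, baselines
ln-fraction −1.6 (10 nM) and −0.6 (0.1 nM). Planted positional effects put
strong 2′-F preference at AS2 (−0.40), AS6 (−0.35), AS14 (−0.45), S11
(−0.40), an opposed pair at AS8 (+0.20)/AS9 (−0.20), mild effects at a few
flanking positions and exact zeros elsewhere. Chemistry patterns are
uniform random by default; an explicit pattern list can be supplied for
directed panels. Species is assigned per site, so it is deliberately
confounded with site — the fitted model must handle that collinearity.

`gen_pkpd_timecourse` plants K(t) = kd_max(1 − e^(−k_on·t))e^(−k_off·t)
(the simplest onset/nadir/recovery form; no published PD equation exists
for these curves), %-of-control mRNA = 100(1 − K(t))·lognormal noise, and
Ago2 antisense loading from inverting the planted semilog law 100·K(t) = a
+ b·log10 L(t). The preset parent-like and advanced-design-like conditions
set (a, b) so the planted potencies are EC50/EC80 = 0.066/0.24 and
0.046/0.20 ng/g respectively, with kd_max 0.93, k_on 1.2/day, k_off
0.06/day (parent) or 0.015/day (slow-recovering advanced design), sampling
at 4 h and days 3–35 with 3 animals per time point. Sense-strand loading is
flat background (0.01 ng/g) since it stays near detection limits in
practice.

What the generators do **not** emulate: absolute liver exposure (μg/g),
multi-dose regimens, sequence-dependent (as opposed to position-dependent)
activity, positional interactions, and assay-plate artifacts. Passing
recovery tests therefore shows the estimators are correct under their
stated model, not that real screens satisfy that model.

## In vivo statistics

* **Pre-dose normalization**: per animal, 100 × value/pre-dose; exactly one
  positive pre-dose measurement is required.
* **Semilog EC fit**: OLS of knockdown% on log10(loading ng/g); EC_p =
  10^((p − a)/b); EC values outside the observed loading range are returned
  but flagged extrapolated; a numerically zero slope raises rather than
  returning garbage ECs.
* **Extra-sum-of-squares F-test**: pooled single line vs per-group lines;
  F = [(SSp − SSs)/(dfp − dfs)]/(SSs/dfs). Identical groups give F = 0,
  p = 1 by construction.
* **AUC vs baseline 100**: the series is split into peaks at
  linearly-interpolated baseline crossings; a peak whose maximal deviation
  is below 10% of the overall Y range is ignored; retained peaks contribute
  the trapezoidal |area|, so below-baseline (silencing) excursions count
  positively. The crossing/ignore semantics follow the convention of the
  commercial software that popularized this AUC variant; where that
  convention is underspecified (signed vs absolute below-baseline area) the
  absolute-contribution reading is used and documented here.
* **Recovery slopes**: per-group OLS on days inside the window (default
  29–71 inclusive — the conventional window is reported inconsistently as
  22–71 elsewhere, so the window is a flag), equality tested via the
  day×group interaction t-test of the pooled two-line model.
* **Two-way ANOVA**: balanced tables use the classical factorial
  decomposition (design, time, interaction, residual); unbalanced tables
  fall back to a statsmodels type-II regression decomposition with a
  warning. Post-tests compare each design to the control at each time point
  on the pooled residual MS. Dunnett adjustment is by seeded Monte Carlo of
  the joint null max-|T| distribution (default 100,000 draws, documented
  tolerance ±0.005 on p; the adjusted p is floored at the unadjusted p so
  monotonicity holds exactly). Sidak uses 1 − (1 − p)^m over all computed
  comparisons.

## Numerical conventions and edge cases

Rank tolerance 1e-10 (relative); significance α = 0.05 throughout;
EC slope-zero tolerance 1e-12 relative to the data scale; design-search
feasibility comparisons use a 1e-12 slack so exact-boundary candidates are
kept; AUC requires strictly increasing days; all generators are
deterministic functions of their integer seed.

## Problem sizes used in the shipped checks

The acceptance script and test suite run the positional recovery at the
full default screen scale (1,890 duplexes, 20 seeds) and the calibration
studies at a reduced scale (2 targets × 2 sites × 15 duplexes, single dose,
1,000 replicates; 1,000 DV-null and ESS-F-null replicates) — under the
generators the fitted models are exactly specified, so calibration is
size-independent and the reduced scale simply keeps the whole battery
desk-fast. Design-search optimality is checked against full enumeration on
8-position strands (256 patterns × 100 coefficient draws).

## Known limitations

No positional interaction terms, regularized or mixed-effects variants; no
chemistries beyond {2′-F, 2′-OMe} sugars with PS backbone; no thermodynamic
or structure prediction; no compartmental PK or 4PL dose–response models;
fixture patterns are reconstructions, not released reference data.
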