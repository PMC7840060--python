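# Methods

This note documents the models, defaults and design choices behind the
package, and what the test suite does and does not establish.

## Data model and reference tables

The three packaged CSVs transcribe a Bronze Age assemblage from the
northern Alpine foreland: charred seeds and chaff from a lakeside
settlement, animal bone collagen from four sites spanning the Early to
Final Bronze Age, and humans from three cemeteries (Early Bronze Age
La Barmaz, Middle Bronze Age Vufflens, Final Bronze Age Tolochenaz; 13,
12 and 16 individuals) with bone collagen, second-molar dentine collagen
and enamel carbonate per individual where preserved.  Empty cells are
missing values, never zeros.  One plant row carries no measurements (too
little material survived pre-treatment); it is retained so that exclusion
decisions stay in the QC layer.  A documented chronology problem excludes
one Tolochenaz individual (LeB1) from all group statistics; the exclusion
is configuration, not data.

## Preservation screening

Hard criteria: extraction yield ≥ 1 %, %C ≥ 30, %N ≥ 10, %S ≥ 0.15,
atomic C:N in (2.9, 3.6), C:S = 600 ± 300, N:S = 200 ± 100.  Published
practice retains samples *slightly* outside these envelopes "with
caution"; we formalise that with a proportional caution margin (default
0.15 of each bound): a breach inside the margin downgrades to caution, a
worse breach fails.  Two deliberate per-criterion adjustments:

* **C:N margin 0.12.**  C:N is the sharpest diagenesis indicator; 3.7 on
  an otherwise sound sample is borderline (caution), 4.1 is failure.
* **%S margin 0.20.**  Sulfur quantification is noisier; 0.12–0.13 %S on
  samples whose C/N chemistry is sound warrants caution, not exclusion.
* **C:S and N:S cap at caution.**  The sulfur band criteria describe
  terrestrial mammal collagen.  Well-preserved freshwater fish collagen
  sits near C:S ≈ 200, N:S ≈ 57 — far outside — because fish collagen is
  richer in sulfur; failing on the bands alone would discard
  demonstrably sound fish.  Values inside a band but within 15 % of its
  edge also flag caution (this reproduces the borderline pig TO9).

With these defaults the packaged tables partition exactly as published:
3 of 22 animals fail (BANF2, BANF3, CHIN4), two cattle and one pig are
cautioned, 3 of 41 human bones fail (LaC1, LaC4, LaC10), and the human
bone analysis set is n = 37.  Screening is per tissue: LaC1's failed bone
does not discard his dentine or enamel.  Charred-plant screening has no
consensual criteria; %C ≥ 30 and C:N are advisory (caution only), %N ≥
0.4 is enforced, and chaff is exempt from C:N (structurally high in raw
chaff).

## Plant corrections, discrimination, manuring

Charring shifts are −0.11 ‰ (δ13C) and −0.31 ‰ (δ15N); chaff-to-grain
shifts are +1.9 ‰ and +2.4 ‰.  Raw and corrected values are both
available downstream because the assemblage-level ranges are
conventionally reported raw while group means and all offsets use
corrected values.

Carbon discrimination needs the atmospheric δ13C of the growth years.
Rather than depending on an external spreadsheet calibrator, the package
ships a piecewise-linear `AirCurve` whose Bronze-Age default is a single
constant, −6.568 ‰, obtained by least squares against the assemblage's 24
published per-sample Δ13C values (the per-row spread of the implied air
value is 0.06 ‰, so a constant is adequate across the 2200–800 BCE
window; the fit is re-derived as a test oracle).  Users with dated
samples can supply a real curve.

Water-status bands on Δ13C default to poor < 16 ‰ < moderate < 17 ‰ <
well for wheat and pulses, shifted +1 ‰ for barley (its earlier crop
cycle discriminates more under equal water).  Manuring bands on corrected
δ15N are 3/6 ‰ for cereals and 0/3 ‰ for N2-fixing pulses.  Both are
interpretation layers: configurable, never written into stored data.  One
pulse (PAbot6, δ13C −15.3 ‰) is isotopically anomalous for a C3 seed and
classifies as water-stressed; tests treat it as the outlier it is.

## Trophic offsets and endmembers

Fixed offsets: +4.8 ‰ δ13C plant→collagen, +0.8 ‰ δ13C
collagen→collagen, +4.0 ‰ δ15N diet→consumer.  Group sds pass through
endmember construction unchanged — offset uncertainty belongs to the
mixing model, where it enters as ±0.5 ‰ per proxy.  Spacings between
groups are reported both at full precision and in a `rounded` mode that
differences display-rounded means; published spacings follow the rounded
convention (e.g. the Final Bronze Age Δ15N humans−animals is 2.5 ‰
rounded, 2.45 ‰ at full precision).  Phase pairing is configuration:
Early Bronze Age humans pair with Early Bronze Age cereals and fauna; the
Middle Bronze Age group pairs with Middle–Final transition cereals and,
because only two mid-phase animals exist, with the herbivore-diet animals
of all phases pooled; the Final Bronze Age group pairs with Final Bronze
Age cereals and fauna.  "Herbivore-diet" excludes fish and any pig with
δ15N > 8 ‰ (an omnivore one trophic level up).  Pike endmembers use the
collagen→collagen offsets.

## Bayesian diet mixing

Four sources (C3 cereals, C4 cereals = millet, herbivore/pig meat,
freshwater fish), two proxies (δ13C, δ15N).  The consumer enters as group
mean ± sd; sources as group mean ± sd plus offset mean ± 0.5 ‰.  The
likelihood treats the source and offset uncertainties as Gaussian and
marginalises them, giving the per-proxy variance
σ_consumer² + Σ p²(σ_source² + σ_offset²).  The prior is Dirichlet(1).
Sampling: random-walk Metropolis on the (K−1)-dimensional logit
stick-breaking transform, per-chain step size adapted toward 30 %
acceptance during the 50 % burn-in, 4 chains × 20 000 iterations by
default, seed mandatory.  Convergence is summarised by split-chain R-hat
(flagged > 1.05) and bulk ESS via ArviZ; the simplex constraint holds
exactly by construction.

**Known limitation.**  This is pure isotope mixing: no concentration
weighting and no macronutrient routing.  Under it, the posterior for the
packaged assemblage ranks C3 cereals first at all three sites and
reproduces the two headline estimates (La Barmaz C3 ≈ 45 % against a
published 54.5 %; Tolochenaz C4 ≈ 12 % against 21.6 %) within ten
percentage points, but it cannot reproduce the original analysis's
complete per-source pattern: those published contributions are not
mass-balance-consistent with their own printed source and consumer values
(at the printed La Barmaz contributions the implied mixture δ13C is
≈ 2 ‰ heavier than the measured consumers), which points to undisclosed
routing/concentration settings in the original software entries.  A
sensitivity sweep over consumer/source uncertainty conventions (sd vs
standard error, offset sd 0.5–1.0 ‰) moves the C3 posterior mean between
40 and 66 % without recovering that pattern.  One acceptance-level test
records this discrepancy and fails by design.

## Apatite proxies

Spacing Δ13C_ap-coll = enamel δ13C − dentine collagen δ13C pairs tissues
that both form in childhood; individuals missing either tissue are
dropped, not imputed.  The monoisotopic expectation is 8.4 ‰ (13.4 ‰
diet→enamel minus 5 ‰ diet→collagen); interpretation bands use ±0.5 ‰ by
default.  The %C4 estimate converts enamel to the bone-apatite scale
(+1.8 ‰), removes the 9.4 ‰ diet→bone-apatite enrichment and linearly
interpolates between a −25 ‰ C3 diet pole and a 15 ‰ C3–C4 span, clipped
to [0, 100] with an out-of-range flag.  Written with the diet value minus
the C3 pole in the numerator this is the sign-consistent form; the same
expression is sometimes printed with the subtraction reversed, which
negates its own reported percentages.  Site means from the packaged
tables: spacings 6.2 / 7.3 / 7.4 ‰ and %C4 20 / 26 / 47 for the Early,
Middle and Final Bronze Age groups.

## Exact statistics

All tests are two-sided with the doubled-smaller-tail convention and
mid-rank ties; exact enumeration (via subset-sum counting over the tied
rank vector) applies up to a combined n of 20, with tie-corrected normal
approximations beyond.  Spearman p-values are exact to n = 9, then
t-approximated.  Kruskal–Wallis uses the tie-corrected H with either the
χ² approximation or a seeded Monte-Carlo permutation p (20 000 resamples
by default) — the latter matches how small-assemblage comparisons are
usually reported.  Exact routines are verified against independent
brute-force enumeration (combinations, sign patterns, permutations) in
the tests.

## Synthetic assemblages

`synthdata.generate` draws a three-table assemblage: crop groups at the
packaged-table means/sds (largest-remainder allocation with ≥ 2 samples
per group, so every pipeline source exists), herbivore-diet fauna,
fish with the aquatic δ34S mode near −4.3 ‰ versus the 0–6 ‰ terrestrial
band, and humans forward-simulated from a known diet composition through
the mixing likelihood (default truth 0.55/0.15/0.26/0.04).  Plant values
are emitted uncorrected so the correction step is exercised; a
configurable `qc_fail_rate` corrupts elemental chemistry into diagenetic
failures.  One master seed spawns independent per-stream generators.
Everything is Gaussian per proxy: the generator reproduces group-level
means and spreads, not skewness, inter-proxy correlation structure, or
preservation–value covariance, so passing recovery tests demonstrate
statistical calibration of the pipeline, not realism of individual-level
variation.

`recovery_experiment` repeats generate → QC → summaries → fit and reports
per-source bias, mean absolute error and 95 % credible-interval coverage.
Because the fit uses the group sd (not the standard error) as consumer
uncertainty, intervals are deliberately conservative and coverage sits at
or near 1.0.  Simulation studies default to a shortened sampler
(2 chains × 4000 draws), which for these 4-source scenarios yields R-hat
< 1.05 and ESS in the hundreds; headline fits use the full 4 × 20 000
configuration.  The acceptance-level calibration check runs 50
replicates at the packaged assemblage's group sizes.

## Numerical conventions

Display rounding is 0.1 ‰, half away from zero, applied only in reports;
all internal statistics keep full precision with n−1 standard deviations.
A handful of published summary cells differ from what the published
per-specimen values yield (the originals were computed from
higher-precision laboratory data, and a few cells are internally
inconsistent, e.g. a group maximum outside a member's printed value); the
regression suite pins every such cell to its recomputed value and lists
the published figure alongside.
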