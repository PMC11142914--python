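# Methods

This note documents the model implemented by `fcbfuzzy`, the conventions and
defaults chosen where the method leaves room, and what the synthetic-data
tests do and do not demonstrate.

## The scoring model

Each species is scored on three indices — food security (F), climate change
(C), biodiversity (B) — from a vector of continuous traits, through four
stages.

**Fuzzification.** Every trait has a family of four fuzzy sets (*low,
medium, high, very high*): trapezoids for the two outer categories,
triangles for the middle two, all piecewise linear with degrees in [0, 1].
Coincident breakpoints are allowed and produce vertical edges (used for the
boundary plateaus). A value's degrees are computed in all four sets and
retained only where the degree **strictly exceeds** the retention floor
(default 0.2). Values outside the family's domain are clamped to it with a
logged warning: real trait tables contain outliers, and deterministic
clamping is preferable to rejection.

**Quantile recipe.** When breakpoints are not given explicitly they are
estimated from the observed trait values (at least 4 finite observations;
all-identical values are an error). With quartiles Q25 < Q75, median M,
h = (M + Q75)/2 and shoulder width w = fuzziness · (Q75 − Q25):

| set       | shape     | breakpoints                 |
|-----------|-----------|-----------------------------|
| low       | trapezoid | (min, min, Q25, Q25 + w)    |
| medium    | triangle  | (Q25 − w, M, h)             |
| high      | triangle  | (M, h, Q75 + w)             |
| very high | trapezoid | (Q75 − w, Q75, max, max)    |

This construction guarantees the two family invariants for any fuzziness in
(0, 1): adjacent sets overlap somewhere (the medium/high triangles share the
open interval (M, h); the shoulders cover the plateau edges), and every
point of [min, max] has positive degree in at least one set. Quantiles use
linear interpolation (the "type 7" convention). If heavy ties collapse the
quartiles (Q75 ≤ Q25), anchors fall back to quarter-points of the observed
range. The default fuzziness is 0.5; larger values express more category
uncertainty. Explicit breakpoints in a rulebook always override the recipe,
as an escape hatch for knowledge-based set placement.

**Rule firing.** Rules map one premise category of one trait to one
conclusion category of one index. A rule fires when the premise degree
strictly exceeds the firing threshold (default 0.2, configurable separately
from the retention floor; with both at the same value the second check is
redundant but harmless). The conclusion membership is `weight × premise`
(the `product` combiner, default) or `min(weight, premise)` (`min`); either
way a rule with the default weight 0.5 — a 50 % level of belief in the
rule — can conclude with at most 0.5. The multiplicative combiner was
chosen because it preserves gradation in the premise; both combiners are
consistent with the 0.5 cap and the choice is a rulebook switch.

**Missing-data penalty.** A missing trait value emits a conclusion into the
*low* potential set of every index the trait informs, with membership
`default_weight × missing_penalty_degree`. The penalty degree defaults to
1.0 — the strongest admissible low conclusion — and is configurable.
Consequently a species with *n* all-missing traits linked to one index
accumulates low-potential membership 1 − 0.5ⁿ there and scores 1.

**Accumulation.** Conclusions landing in the same (index, category) slot
combine with the MYCIN update AccMem ← AccMem + m·(1 − AccMem), whose closed
form is 1 − ∏(1 − mᵢ): commutative, associative, monotone, equal to the
single input for one conclusion, and strictly below 1 while every input is
below 1. Trait processing order therefore cannot affect scores.

**Defuzzification.** The crisp score is the membership-weighted average of
fixed category index values, by default {low: 1, medium: 25, high: 75,
very high: 100}; these are rulebook configuration, not hidden constants. The
score is invariant to uniform rescaling of the four memberships and bounded
by the index values of the supported categories. An index with zero
accumulated membership has no defined score:

* if **no declared trait links to the index**, the index is outside the
  rulebook's scope and is reported as NaN (this arises in reduced rulebooks,
  e.g. during jackknife, and in minimal single-index configurations);
* if the index **is covered** but nothing fired and nothing was penalized,
  an `UndefinedScoreError` naming the index and species is raised — the
  missing-data penalty makes this unreachable for ordinary inputs, so
  silence would mask rulebook defects.

## The default rulebook

The shipped rulebook declares 13 traits and 92 rules, all with weight 0.5,
both thresholds at 0.2, and quantile-recipe families (fuzziness 0.5). Links
are *monotone* (trait category ↦ same potential category) for positive
relationships and *reversed* (very high ↦ low, etc.) for inverted ones:

* F positive: growth coefficient (VBGF K), maximum size, fecundity,
  macronutrient density, and the five tolerance ranges (nitrate, phosphate,
  temperature, salinity, pO₂); F inverted: trophic level.
* C positive: the five tolerance ranges, geographic range; C inverted:
  trophic level (feed-efficiency proxy), pH sensitivity.
* B inverted: VBGF K, maximum size, fecundity, latitudinal range,
  geographic range (invasiveness/escape risk proxies).

Six traits are shared by F and C, three by F and B (with opposite
directions), one by C and B. The rulebook is a documented reconstruction of
directional trait–goal relationships; it is intended as a credible,
fully-specified default, not as the one true mapping, and every element is
editable through the YAML interface.

## Jackknife sensitivity

Removing a trait removes the trait, its rules, *and* its missing-data
penalty — the trait ceases to exist rather than becoming "missing".
Deviations are `score_removed − score_baseline` per species and index;
percent variation divides by the **maximum baseline score across species
for that index** (the observed ceiling), times 100; the theoretical maximum
100 is available as an option. The denominator is fixed by the baseline run
and identical across removals. Modes: exhaustive single-trait removal, and
`reps` (default 50) uniformly random subsets of `n_remove` traits, seeded;
when a curve over all removal counts is requested, each count gets its own
`reps` subsets. Removals that leave an index uncovered for some species are
flagged `undefined` in the output rather than aborting the analysis. A
removed trait whose rules conclude only to the *very-high* set can only
lower scores (its mass sits at the maximum index value); the analogous
statement for a mixed high/very-high trait is *not* generally true and is
not asserted.

## Rank statistics

Rankings are descending (best = 1) with midranks for ties. Kendall
correlations are tau-b with tie correction; p-values use the exact null
distribution for n ≤ 10 without ties and the tie-corrected normal
approximation otherwise. Taxa comparisons use Kruskal–Wallis with tie
correction, then Dunn's pairwise z tests on the pooled ranks (implemented
in-package; validated against the two-group identity z² = H), with Holm
adjustment by default (none/Bonferroni/BH available). All-identical scores
return H = 0, p = 1 by convention. The extreme-subset comparison (top- or
bottom-k versus all species) is a one-sided permutation test on the mean
difference over random k-subsets; since the subset is selected by score,
its p-value mostly quantifies the selection effect and is documented as
such rather than as a reproduction of any published test.

## Synthetic data

The generator emulates the statistical structure of a staple-aquaculture
trait table: 54 species in four taxa (finfish 24, crustaceans 10, molluscs
12, algae 8), log-normal marginals for size, fecundity and range extents,
normal marginals for growth coefficient, trophic level, nutrient density
and pH sensitivity, clipped to biologically sensible ranges. Taxon structure
enters only through location offsets scaled by a single `taxa_effect` dial
(and one variance offset widening finfish trophic levels to span roughly
2–5): effect 1 gives the realistic profile (algae near trophic level 1,
molluscs near 2), effect 0 makes the taxa exactly exchangeable. Missingness
is Bernoulli per cell with per-taxon rates, higher for non-fish (5 % for
finfish, 15 % for crustaceans and molluscs, 25 % for algae).

Two canonical scenarios are provided. `recovery_scenario_config` gives
algae and molluscs explicitly FCB-favourable distributions (nutrient-dense,
low-trophic, tolerance-wide, plus slow growth, small size, low fecundity
and narrow ranges) with uniform missingness, for structure-recovery checks.
`null_scenario_config` sets effect 0 **and uniform missingness** — 
differential missingness is itself real taxa signal through the penalty, so
a true null must equalize it.

What passing these tests shows: the pipeline recovers a configured group
ordering and does not invent one under exchangeability. What it does not
show: anything about real FishBase/SealifeBase trait data, whose
distributions, trait correlations (the generator draws traits
independently within species), and knowledge-based fuzzy-set placements
differ from the synthetic stand-ins.

## Numerical conventions and edge cases

* Thresholds are strict ("exceeds"); a degree exactly 0.2 is dropped.
* Accumulation inputs outside [0, 1] and non-finite trait values are input
  errors; empty conclusion lists accumulate to 0.
* MYCIN recurrence and closed form agree to 1e−12 in tests; permutation
  invariance likewise.
* Scores round-trip CSV at full float precision; output files carry the
  rulebook content hash (SHA-256 over the canonical configuration), seed,
  and version in comment headers.
* Problem sizes in the test suite (54-species fixtures, 2,000-replicate
  Kruskal–Wallis calibration, 200 replicate null tables, 50-rep jackknives)
  were chosen to keep Monte-Carlo error well below the asserted tolerances
  while remaining comfortable on a single CPU.

## Known limitations

* The default rulebook's linkage directions are plausible reconstructions;
  domain experts will want to edit them for any real assessment.
* Fuzzy-set breakpoints estimated from quantiles describe the *sample*, so
  scores are relative to the analyzed species pool, not an absolute scale.
* The generator draws traits independently within a species; real trait
  covariation (e.g. size–fecundity allometry) is not emulated.
* No retrieval of real trait databases is included; CSV in, CSV out.
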