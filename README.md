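# fcbfuzzy

A fuzzy expert system that scores farmed aquatic species on their potential
contribution to three sustainability goals: **food security (F)**, **climate
change (C)**, and **biodiversity (B)**. Each species receives three scores on
a 1–100 scale from its biological and ecological traits (growth rate, maximum
size, fecundity, nutrient density, trophic level, environmental tolerance
ranges, latitudinal and geographic extent, …). The package is aimed at
quantitative ecologists and aquaculture analysts who want a transparent,
rule-based multi-criteria assessment that copes with partial trait coverage.

## The method

For every trait, four overlapping linguistic categories (*low, medium, high,
very high*) are described by piecewise-linear membership functions —
trapezoids for the outer categories, triangles for the middle two. Their
breakpoints are either supplied explicitly in a YAML rulebook or estimated
from the observed trait distribution: the low plateau ends at Q25, the
very-high plateau starts at Q75, and the shoulder widths are a configurable
*fuzziness* fraction of the interquartile range.

1. **Fuzzification.** A crisp trait value *x* gets degrees of membership
   μ_cat(x) ∈ [0, 1]; categories with μ ≤ 0.2 are dropped.
2. **Rule firing.** Heuristic rules "if trait is *cat*, then index potential
   is *cat′*" fire when the premise degree exceeds 0.2, concluding with
   membership *w* · μ where the rule weight *w* = 0.5 caps any single
   conclusion at 0.5. A missing trait value is penalized by a conclusion in
   the *low* potential set of every index the trait informs.
3. **Accumulation.** Conclusions landing in the same potential set combine
   with the MYCIN update AccMem ← AccMem + m·(1 − AccMem), i.e.
   1 − ∏(1 − mᵢ): order-independent and saturating below 1.
4. **Defuzzification.** With index values Ind = {low: 1, medium: 25,
   high: 75, very high: 100}, the crisp score is the weighted average
   FinInd = Σ AccMem_x · Ind_x / Σ AccMem_x.

On top of the scores the package provides a jackknife sensitivity analysis
(exhaustive single-trait removal, or 50 random subsets per removal count,
reported as percent of the maximum baseline index), non-parametric species
rankings, Kendall tau-b correlations among F/C/B, Kruskal–Wallis + Dunn's
post-hoc tests across taxa, and a permutation test for top-/bottom-k subsets.
A synthetic trait-table generator emulates a FishBase-style table for four
taxa (finfish, crustaceans, molluscs, algae) with taxon-specific trait
distributions and missingness, so the whole pipeline is testable end to end.

## Worked example

```python
import fcbfuzzy as fcb

records = fcb.generate_table(fcb.SyntheticConfig(seed=7))   # 54 species
result = fcb.FCBModel(records).fit()
print(result.summary())
```

```
FCB contribution potential — fuzzy expert system fit
============================================================
species: 54    traits: 13    rules: 92
rulebook hash: 9b4015b174403861

score distributions (1-100):
        f_score  c_score  b_score  mean_score
mean       46.2     45.4     52.5        48.0
std         5.9      9.2     13.5         6.7
min        28.8     16.2     14.7        34.8
median     47.3     47.2     50.9        47.9
max        57.0     69.4     88.2        65.7

median scores by taxon:
             f_score  c_score  b_score
taxon
algae           51.2     51.8     50.8
crustaceans     43.2     37.0     48.4
finfish         44.7     47.3     50.2
molluscs        49.3     47.6     64.7

Kendall rank correlations between indices:
pair    tau  p_value  n     method
 F-C 0.5332   0.0000 54 asymptotic
 F-B 0.0384   0.6816 54 asymptotic
 C-B 0.1027   0.2728 54 asymptotic
```

Food and climate scores correlate strongly because six traits (trophic level
and the five environmental-tolerance ranges) inform both indices; F and B
share only the three production traits with *opposite* rule directions, so
their association is weak. Molluscs' high biodiversity median reflects their
small size, low growth coefficient, and modest range extents under the
default generator settings.

Rankings, taxa comparisons, and sensitivity hang off the results object:

```python
result.rank_table().sort_values("rank_mean").head()
result.compare_taxa("B")                  # Kruskal-Wallis + Dunn's tests
dev = result.jackknife("multi", n_remove=3, reps=50, seed=1)
```

The same pipeline is available from a shell:

```bash
fcb simulate --seed 7 --out demo/
fcb score    --traits-csv demo/traits.csv --rulebook demo/rulebook.yaml --out demo/run
fcb stats    --traits-csv demo/traits.csv --out demo/run
fcb jackknife --traits-csv demo/traits.csv --mode single --out demo/run
```

Every output CSV records the rulebook content hash, seed, and package
version in `#` comment headers.

## Rulebooks

The shipped default rulebook covers 13 traits with monotone category maps
for positive links and reversed maps for inverted ones (very-high fecundity
→ very-high F but low B; very-high trophic level → low C; wide tolerance
ranges → high F and C; wide latitudinal/geographic range → low B). It is a
documented reconstruction of the directional trait–goal relationships, not a
fitted object; `fcbfuzzy.io.rulebook_to_yaml` / `rulebook_from_yaml` let you
edit every breakpoint, rule, weight, and threshold. See `docs/methods.md`
for the full specification of the recipes and conventions.

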