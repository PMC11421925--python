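# drillcore

Quantitative analysis of gastropod drilling predation in stratigraphic
molluscan death assemblages.

Sediment cores from rapidly accumulating muddy seafloors (prodeltas)
preserve a layered record of the local mollusc community over decades to
centuries.  Shells drilled by predatory naticid and muricid gastropods
carry a direct, countable trace of predation, so the per-increment
**drilling frequency (DF)** — the proportion of prey individuals bearing
a complete drill hole — is a time series of predation intensity.  This
package is for palaeoecologists and conservation palaeobiologists who
want to ask, with honest null models, whether predation and predator
abundance declined toward the top of a core and whether the community
composition turned over at the same time.

## What it computes

**Valve-corrected drilling frequency.**  Bivalves disarticulate after
death, so individuals are reconstructed from skeletal counts and DF is

    DF = DV / [ (RV + LV) / 2 + A ]

where DV = drilled valves, RV/LV = loose right/left valves and A =
articulated specimens; univalved shells (gastropods, scaphopods) count
one individual each.  Estimates from fewer than 20 individuals are
flagged and excluded from the analyses.

**Predator-abundance trend test.**  The observed Spearman ρ between
relative predator abundance and core depth is compared with a Monte
Carlo null in which predators are drawn binomially at each level with a
constant probability (their overall frequency) and the actual per-level
sample sizes; the two-tailed p is the fraction of simulated |ρ| reaching
the observed |ρ| (10 000 iterations by default).  Depth is positive
downward, so ρ > 0 means an upward decline.

**Serial random-walk null for DF trends.**  Because adjacent DF levels
are strongly autocorrelated, DF trends are tested against a bootstrap of
the observed first differences: each simulated series starts at the
basal DF and adds, level by level, a difference drawn with replacement
from the observed adjacent-level differences, reflecting any step that
would go negative.  The 10 000-series ensemble gives 95% confidence
bands, a null for the depth–DF rank correlation, and a null for a
maximum-t breakpoint statistic (the split of the core into lower/upper
parts maximising |mean difference| / pooled SE, each part ≥ 3 levels).

**Species-level contrasts.**  Increments are pooled into
pre-anthropogenic and post-anthropogenic groups and each common prey
species gets a 2×2 drilled/undrilled Fisher exact test.

**Community battery.**  Square-root-transformed proportional abundances
→ Bray–Curtis dissimilarities → NMDS (k = 2, Kruskal stress-1),
PERMANOVA across temporal units, Kruskal–Wallis plus Bonferroni-corrected
pairwise Wilcoxon tests of DF by unit, and distance-based RDA of the
PCoA scores on DF.

**Synthetic cores.**  A generative model of stratigraphic death
assemblages (negative-binomial sample sizes, multinomial taxon draws on
epoch-wise abundance trajectories mixed by Gaussian time averaging,
per-individual drilling, bivalve disarticulation and valve loss) with
four built-in scenarios: `po_like` (rapid deposition, predator loss and
DF collapse), `isonzo_like` (condensed record, prey turnover),
`null_constant` and `step_decline`.

## Worked example

```sh
drillcore all --config run.yaml
```

with `run.yaml`:

```yaml
out_dir: demo
scenario: po_like
seed: 42
```

simulates two replicate po-like cores, pools them, and runs the full
chain.  Key numbers from `demo/summary.json` for this seed:

* predator trend: ρ = 0.45, p = 0.0091 over 32 levels with an overall
  predator frequency of 0.21% — the built-in predator loss is detected
  as a significant upward decline;
* DF vs depth against the random-walk null: ρ = 0.91, p = 0.014 — a
  significant upward DF decrease; the max-t split places the largest DF
  shift at 80 cm (t = 9.4), inside the simulated transition;
* species contrasts: all four common prey species have pre→post odds
  ratios near 2.7–3.0 with p < 0.05 (three of them p < 1e-7);
* community: PERMANOVA across temporal units pseudo-F = 35.7
  (p = 0.001), Kruskal–Wallis H = 27.1 (p ≈ 1e-6) for DF by unit, and
  dbRDA links composition to DF (F = 16.4, p = 0.001, 31% of retained
  inertia).

The same library functions are importable directly
(`drillcore.predator_null_test`, `drillcore.simulate_ensemble`,
`drillcore.breakpoint_significance`, `drillcore.permanova`, ...) for use
on your own counts/increments CSV tables; the column dialect is
documented in `drillcore.core_model`.

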