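# Methods

This note documents the statistical models implemented in `drillcore`,
the choices made where the procedure left room, and what the synthetic
data generator does and does not emulate.

## Drilling-frequency estimation

Bivalve individuals are reconstructed as `(RV + LV)/2 + A` (loose right
and left valves count half an individual each; articulated specimens
count one), univalved shells one individual each.  The assemblage DF of
an increment divides the summed drilled-valve/shell count by the summed
individual count across bivalves, gastropods and scaphopods.  Points of
note:

* **DF > 1 is possible** (both valves of one individual drilled, or
  unlucky valve loss).  The estimator reports the value and emits a
  warning instead of clamping, because the correction *assumes* one
  drilled valve per attacked individual but nothing enforces it.
* **The ≥ 20-individual filter** applies to the denominator of the
  specific scope being estimated (assemblage, skeletal group, or single
  taxon), because each analysis applies the rule to its own sample.
* **Unbiasedness under taphonomy.**  If each loose valve survives with
  probability *r* regardless of whether it is drilled, both numerator
  and denominator scale by the same factor `a + (1-a)r` (a = articulation
  probability), so DF is unbiased; the test suite verifies this by
  simulation at r = 0.6 and the acceptance script reports the measured
  bias.
* **Fisher contrast bookkeeping.**  Species-level pre/post tables need
  integer individuals.  Drilled individuals are approximated by drilled
  valve counts capped at the reconstructed individual count, and pooled
  half-integral totals are rounded to the nearest whole specimen.  This
  is an explicit approximation; the raw counts are carried in the
  output so any alternative tabulation can be recomputed.

## Predator-abundance trend null

The test asks whether relative predator abundance trends with depth
beyond what sampling noise produces under a constant true frequency.
Per iteration, each level's predator count is binomial with the level's
actual (reconstructed, rounded) individual total and a success
probability p̂ equal to the pooled predator frequency *over exactly the
levels entering the test* — using the same level set on both sides keeps
the null internally consistent.  Conventions: average ranks for ties on
both the observed and simulated side; simulated |ρ| ≥ observed |ρ|
counts as an exceedance; p is floored at 1/n_iter; a flat simulated
profile is assigned ρ = 0 (it carries no trend).  Levels with no
individuals are dropped with a warning.  p̂ ∈ {0, 1} is reported as an
inapplicable test, not a p-value.

## Random-walk null for DF series

DF series are strongly autocorrelated between adjacent levels, so
permutation nulls would be anticonservative.  The null here preserves
the local increment structure: simulated series start at the observed
basal DF and add i.i.d. draws from the pool of observed adjacent-level
first differences; a step that would cross zero is reversed
(subtracted).  Excluded (< 20-individual) levels are removed *before*
differencing, so adjacency is defined on the retained series.

Two alternatives reported in the literature for this family of nulls are
implemented behind flags and verified to give qualitatively equal
results: starting each walk at a value drawn from the observed series
(`random_start=True`) and truncating at zero instead of reflecting
(`negative_rule="clamp"`).

The **maximum-t breakpoint** scans every split leaving at least
`min_group = 3` levels on each side ("starting from the third
increment") and maximises |t|, t = (mean lower − mean upper) / SE with
the classical pooled two-sample SE (Welch SE available as an option; the
choice matters little at these group sizes).  A split with zero pooled
variance gets t = 0 by convention and a log message; exactly tied maxima
resolve to the smallest boundary with a tie flag.  Significance compares
the observed max |t| with the max |t| of each ensemble series over the
*same* admissible boundary range.  The per-level 95% bands are 2.5th and
97.5th percentiles with linear interpolation between order statistics.

Calibration subtlety: the depth–DF ρ test is exchangeable — hence
nominally sized — when data generated by the walk null are tested
against the ensemble of the parent series.  Rebuilding the ensemble from
a trending realisation's *own* differences reproduces part of its trend
in the null and makes the test conservative; that is the price of the
bootstrap and is the direction of error one wants for a claimed decline.

## Community battery

Proportional abundances use the same valve-corrected individual counts;
rows are square-root transformed before Bray–Curtis.  NMDS minimises
Kruskal stress-1 via iterative isotonic-regression scaling (best of a
principal-coordinate start plus 4 random restarts by default); the
returned configuration is canonically oriented (centred, rotated to
principal axes, each axis' sign fixed by its heaviest-loading sample) so
identical inputs and seed give identical coordinates.  PERMANOVA
partitions the squared Bray–Curtis distances (Gower identity) into
between/within parts; p-values use the (1 + b)/(1 + B) convention, with
an exact-enumeration option for small n and optional within-strata
permutation.  Distance-based RDA drops negative-eigenvalue PCoA axes
(no Lingoes/Cailliez correction; the retained positive-inertia fraction
is logged) and regresses the retained scores on a single constraint
(DF), with permutation of the constraint values.  DF-by-unit differences
use the tie-corrected Kruskal–Wallis chi-squared approximation and
pairwise two-sided Wilcoxon rank-sum tests with Bonferroni correction
(p × number of comparisons, capped at 1).

PERMANOVA across "temporal units within regions" is run as separate
one-way tests per region rather than one nested model, matching how the
question is usually tabulated; the strata option covers restricted
permutation designs.

## Synthetic cores

The generator emulates the *structure* of replicate prodelta cores, not
any particular dataset: 2 cm slices in the top 20 cm and 5 cm below;
ages from a constant sedimentation rate; per-increment sample sizes
negative-binomial (mean 150 individuals per 5 cm slice per replicate
core, dispersion 5 — realistic for > 1 mm-sieved prodelta muds, and
dispersed enough that some increments fail the 20-individual filter);
taxon counts multinomial on abundance trajectories defined per temporal
unit and mixed by a Gaussian time-averaging kernel over the increment's
age; drilling independent per individual; bivalves articulated with
probability a, otherwise splitting into two valves each retained with
probability r, the drill hole sitting on one uniformly chosen valve and
observed only if that valve survives.

Scenario defaults encode the two regional regimes the generator is named
for: `po_like` (15 mm/yr, ~20 yr time averaging, assemblage DF ≈ 12%
pre-impact rising to ≈ 21% mid-core then collapsing to ≈ 5%, predator
share 0.5% collapsing to 0.03%, overall ≈ 0.2%, plus a detached tail of
six much older Holocene increments) and `isonzo_like` (3 mm/yr,
centennial averaging, DF 21–31% peaking late, flat 0.3% predators, prey
turnover at the top).  `null_constant` and `step_decline` are flat and
single-step validation scenarios.  Epoch boundaries reuse the analysis
default year cuts (1600/1850/1950 CE) so simulation and binning align
by construction.

The po_like Holocene tail emulates older samples collected away from the
station, where depth below the modern seafloor is *not* an age proxy for
the rest of the succession.  The pipeline therefore excludes that unit
from the depth-ordered trend tests by default (`trend_exclude_units`,
overridable) while keeping it in all temporal-unit analyses;
concatenating across sites is an explicit opt-in.

What the generator does **not** model: sediment transport and physical
reworking (time averaging acts on composition trajectories, not on
particle displacement), shell damage and size-dependent preservation,
prey size structure, and incomplete drill holes.  Passing tests on these
synthetics therefore demonstrate the *statistical machinery* —
estimator recovery, null-model calibration, breakpoint localisation —
under a plausible data-generating process, not the field behaviour of
any real core.

## Numerical and reproducibility choices

* All Monte-Carlo stages take explicit integer seeds; the pipeline
  spawns per-stage seeds deterministically from one run seed, and two
  runs of the same configuration produce byte-identical JSON (the run
  manifest hashes the analysis configuration, excluding the output
  directory).
* Exceedance comparisons use a 1e-12 tolerance so that exact ties in
  floating-point rank statistics count as exceedances deterministically.
* The split-t scan computes group sums of squares by cumulative sums;
  the O(√ε) cancellation residue on near-constant groups is floored to
  a zero SE (threshold 1e-7 × data scale), far below any real DF noise.
* Validation experiment sizes (50 cores for estimator recovery, 500
  datasets for type-I rates, 100 for power/recovery, 20 pipeline seeds
  per scenario) keep each experiment's Monte-Carlo error well inside
  the bands being checked while the whole suite runs in minutes on one
  CPU.
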