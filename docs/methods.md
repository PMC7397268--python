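# Methods

This note documents the models implemented in `otr-cooper`, the choices made
where the design was genuinely open, and what the synthetic-data pipeline
does and does not establish about real cooperage data.

## Barrel model

A 225-litre Bordelaise barrel is modelled as three wood elements: two flat
circular **heads** and the curved **body** wall. Oxygen ingress is modelled
through the wood only — oxygen flowing between staves, through gaps or
through the bung is outside the model — so the barrel OTR is the
area-share-weighted combination of its elements' OTRs:

    OTR_barrel = 0.7477 · OTR_body + 0.1261 · (OTR_head1 + OTR_head2)

The shares (body 74.77%, each head 12.61%) are fixed constants of the
barrel geometry and are used verbatim even though they sum to 0.9999 rather
than 1; recomputing them from the underlying area assumptions (1.50 m² body,
0.25 m² head) would give mutually inconsistent values, so the printed
arithmetic is reproduced instead. Likewise the head ratio denominator is the
constant 0.28 m², slightly larger than the true disc area
π·(0.2985 m)² ≈ 0.27992 m², so the per-stave head ratios of a full head sum
to ≈ 12.607% rather than exactly 12.61%. This discrepancy is documented and
asserted in the tests, not corrected.

**Element OTR is a within-element area-weighted mean** — body stave weights
are widths, head stave weights are in-circle areas, normalized inside the
element. Targets are therefore on the stave-OTR scale (a pool or class mean
OTR is directly usable as a target); the 0.7477/0.1261 shares enter only
when combining elements into a barrel.

### Head geometry

Head staves are laid across the disc in order, centred: the midpoint of the
summed stave width sits on the circle centre, so overhang beyond the disc
splits equally between the two outermost staves and is clipped away.
Centring makes the centre stave the one that must span the full diameter,
matching how real heads are built; no explicit cap on total overhang is
enforced. A stave entirely outside the disc makes the layout infeasible.

For a stave occupying the clipped strip [a, b] (x measured from the centre,
radius R):

* in-circle area: 2·I = F(b) − F(a) with F(x) = x·√(R²−x²) + R²·asin(x/R),
* required length: 2R if the strip contains the centre, else 2·√(R²−d²)
  with d the distance of the strip's nearest edge.

Both closed forms are cross-checked in the test suite against adaptive
quadrature of the chord function on random intervals (10⁻⁶ relative).

### Feasibility rules

* Head: odd stave count in the allowed set ({7, 9, 11} by default), total
  width at least the 597 mm diameter, no stave clipped away entirely, every
  stave at least as long as its position requires. Length comparisons carry
  a 10⁻⁹ mm slack so exact boundary staves (a 597 mm centre stave) pass.
* Body: summed width inside 2180 ± 0.5 mm (boundaries inclusive) and at
  least one stave **strictly** wider than the 100 mm bung minimum. The bung
  stave is kept first in the genotype.

## Genetic algorithm

Fitness is the negative absolute OTR error; the roulette probabilities are
exp(−f_n / min f) normalized over the population. When every fitness is 0
the expression is undefined and any individual is perfect, so selection
degrades to uniform. Ten individuals evolve with one elite carried over
unchanged; the nine remaining slots are filled by sampling a procedure per
slot:

| procedure         | head  | body  |
|-------------------|-------|-------|
| new solution      | 0.400 | 0.400 |
| reapply           | 0.120 | 0.134 |
| mutation          | 0.210 | 0.233 |
| internal crossing | 0.060 | 0.000 |
| external crossing | 0.210 | 0.233 |

Bodies have no internal crossing because stave order does not change a
width-weighted mean (asserted by shuffling in the tests). "Reapply" copies a
roulette-selected individual unchanged; crossing parents are two roulette
draws without replacement; an operator that falls back to an original still
fills its slot. Duplicate individuals within a population are allowed. One
RNG stream drives a whole `evolve` call — per slot, one uniform draw picks
the procedure, then the procedure's draws follow in construction order — so
a seed fixes the entire run.

Termination: absolute OTR error below the tolerance (default 10⁻⁶ hPa/h,
configurable) or budget exhaustion, whichever first. The default budget is
a generation count because wall-clock budgets do not reproduce across
machines; a `max_wall_seconds` mode exists for fidelity runs and is excluded
from exact tests. The production scenarios use 5000 generations as the
stand-in for a one-second-per-element processing budget.

### Operators (all feasibility-preserving, all total)

* **Head mutation** scans (position, idle stave) pairs in randomized order
  and applies the first feasible single replacement; if none exists the
  original head is returned.
* **Head internal crossing** swaps two positions — the first candidate pair
  is random, then the scan is exhaustive over all pairs — or returns the
  original.
* **Head external crossing** keeps a prefix of the first parent up to a
  uniform random cut (an empty prefix is allowed), extends it with the
  second parent's staves in order (skipping ids already used), then the
  first parent's remainder, stopping at the shortest feasible allowed
  count; if no count is feasible one of the two originals is returned with
  equal probability.
* **Head initialization** draws a random allowed count and a random stave
  subset; if the random order is infeasible the same subset is retried in a
  centre-out arrangement (longest staves at the most demanding positions —
  the ordering most likely to be feasible, since the required-length profile
  peaks at the centre). Stave *choice* remains uniformly random; only
  placement is repaired. 200 draws bound the search before an
  infeasible-pool error naming the most frequent violation.
* **Body initialization** picks a random bung-capable stave first, then
  fills greedily in random order (skipping staves that would overshoot the
  window's upper bound); if the fill stalls below the window, a single-swap
  repair exchanges one selected stave for an unused one found by binary
  search over sorted widths. 200 attempts bound the search.
* **Body mutation** always removes 3 random non-bung staves (a config
  constant) and refills from the idle pool with the same fill/repair
  machinery, up to 50 attempts; the bung stave is never replaced; the
  removed staves are not eligible as refills; fallback is the original.
  Repair may exchange staves but never grows the body beyond what the width
  window admits.
* **Body external crossing** takes the bung of a random parent, appends the
  pooled de-duplicated parent staves in random order until the window's
  lower bound is reached, and repairs any overshoot via the mutation
  mechanism with idle ("extra") staves; fallback is a random original.

"Minimum width reached" means total ≥ lower bound; overshoot means total >
upper bound; both boundaries are inclusive for feasibility.

### Baselines

The *current* method is one run of the part's random initializer — sizes
only, OTR never read. Monte Carlo is the GA with population 2 and 100% new
solutions: each generation draws one fresh random feasible element and
elitism keeps the best-ever. Implementing MC *by configuration* makes the
reduction literal, and the test suite asserts bit-identity between an MC run
and a degenerate-config GA run with the same seed.

## Production-line queues

Each part's staves live in an idle queue (seeded random permutation). A
step moves the first S_m staves (25 head / 50 body by default) into the
method dataset, builds one element, retires the S_c(n) selected staves to
the used dataset and returns the rest to the tail in method order. The
ledger identities

    idle before step n = S_i − S_m − Σ_{k=2..n} S_c(k−1)
    used before step n = Σ_{k=2..n} S_c(k−1)

are property-tested over 10⁴ randomized steps. Head and body pools are
fully segregated. Barrels are assembled strictly first-come (body i with
heads 2i−1, 2i); OTR-compensating head–body pairing is deliberately not
implemented (it would require storing and managing many finished elements)
and is left as a future hook.

A method dataset from which *no* feasible element can be seeded at all —
typically a body draw with no bung-capable stave — is returned to the tail
and the next S_m staves are drawn, bounded by one full pass of the queue.
This mirrors what a production line would do with an unusable batch and
keeps long runs total. The same bounded redraw applies to the independent
method-dataset draws of the homogenization driver.

## Synthetic stave populations

Two generation routes:

* **Empirical mode** — the production-line procedure itself: per feature,
  build the empirical CDF of a measured seed sample and inverse-transform
  uniform draws through it. The forward ECDF is the standard
  right-continuous step (i/n at the i-th order statistic); the inverse
  interpolates linearly between order statistics at plotting positions
  (i−1)/(n−1) (numpy's linear quantile convention), so u = 0/1 map to the
  sample minimum/maximum and intermediate draws fill the gaps where the
  step CDF is undefined. Features are sampled independently of one another.
* **Parametric mode** — calibrated stand-ins used throughout the tests and
  the acceptance runs, because the cooperage's measured 3064-stave dataset
  is not distributed. Defaults:

  | feature | model | rationale |
  |---|---|---|
  | body width | 90% truncnorm(72, 15) on [40, 130] mm + 10% truncnorm(112, 8) on [101, 130] mm | ≈ 30 staves per 218 cm body; the wide component reflects that cooperages stock bung-capable staves deliberately, and keeps random 50-stave method datasets almost surely bung-capable |
  | head width | truncnorm(72, 15) on [40, 130] mm | no bung requirement |
  | head length | uniform on [420, 730] mm | the published range |
  | body length | truncnorm(960, 15) on [930, 990] mm | "approximately 96 cm" |
  | class OTR | truncnorm centred on the published class mean, sd = 15% of the mean, truncated at ±2.5 sd | symmetric truncation makes the pool mean equal the published class mean *exactly*; the 15% stave-level spread reproduces the order of magnitude of size-only element variability |
  | population OTR | truncnorm centred on the published part mean (0.03275 body / 0.02928 head), sd 0.0125 / 0.011, ±2.5 sd | ≈ 40% stave-level spread, consistent with the published size-only coefficients of variation |
  | grain | uniform on [1.88, 4.94] mm | metadata only, never computed on |

  Class OTR distributions are **not** truncated at the classification
  thresholds: the published low-OTR *body* class mean (0.0165681 hPa/h)
  exceeds the published body low/mid threshold (0.0157 hPa/h), so no
  distribution supported below the threshold can have that mean. Class
  pools are therefore labelled by construction, and the classification
  thresholds remain a separate, consistent operation. Values exactly on a
  threshold classify as mid, keeping "low" and "high" strict.

All width parameters are declared synthetic defaults — the true width
distribution of the cooperage's staves is not published — and every
parameter is overridable.

**What the synthetic pipeline does not show:** feature correlations (real
stave width, length, grain and OTR are surely not independent), batch
structure, and the exact shape of the real OTR distribution. Consequently
the *absolute* coefficients of variation of the size-only baseline, and the
published per-table magnitudes that depend on the real 3064-stave dataset
and on wall-clock budgets, are reproduced qualitatively (orderings,
bounds), not numerically.

## Problem sizes and numerical choices

The acceptance runs use the scenario defaults: 2000-stave pools per part
and class, method datasets of 25 head / 50 body staves, 50 barrels per
class, 5000-generation budget, 10⁻⁶ hPa/h tolerance. At these sizes a body
typically converges to tolerance within a few hundred generations and a
head within a few dozen, so the full two-class production day runs in a
few minutes on one CPU. Tests on enumerable pools (≤ 12 staves) compare
GA fitness against exhaustive search at 10⁻¹² absolute rather than bitwise
equality, because summation order in the weighted means differs between
the GA's construction order and the enumerator's canonical order.

Other numerical conventions: length feasibility carries 10⁻⁹ mm slack;
ratio-conservation assertions use 10⁻¹⁰ absolute on percentages; the
head-area identity Σ 2·I_i = πR² holds to 10⁻⁹ relative by construction of
the antiderivative.

## Known limitations

* Oxygen pathways other than through-wood permeation (stave joints, bung)
  are out of scope; the model covers the dominant wood pathway only.
* 3-D barrel shape (bilge curvature, volume) is not modelled; the geometry
  enters only through the fixed area shares and the head disc.
* The GA's procedure probabilities are fixed constants; no adaptive or
  self-tuning variant is provided.
* Head–body pairing at assembly is strictly first-come.
* Wall-clock-budget runs are inherently machine-dependent and excluded
  from deterministic tests.
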