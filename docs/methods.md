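# Methods

## Model and assumptions

The core object is a patch-occupancy metapopulation with displacement
(dominance) competition. Assumptions inherited from that framework:

* infinitely many identical sites, each empty or held by exactly one
  colony; no explicit space;
* a strict competitive hierarchy — on any encounter the superior species
  takes the site instantly, so competition enters only through the ordering
  of species;
* a trade-off `f(x)` that is continuous, strictly increasing and positive
  on `[0, x̂]`: fecundity is the only benefit of competitive inferiority;
* deterministic dynamics (site frequencies, not individuals).

Only species with `f(x) > m/q` can persist; the threshold trait value `x_c`
solves `f(x_c) = m/q`. With `m = 0` no empty sites regenerate and the top
competitor excludes everyone — the continuous supply of empty sites is what
permits coexistence.

The forward recursion for the discrete equilibrium and the continuum
density `p(x) = ½ f′(x) f(x)^{−3/2} √(m/q)` were re-derived before
implementation; the interval mass `(f(x)^{−1/2} − f(x+Δx)^{−1/2}) √(m/q)`
is its antiderivative, and both are cross-checked in the tests by adaptive
quadrature (the density integrates to `1 − √((m/q)/f(x̂))` whenever `x_c`
is interior, i.e. `f(x_c) = m/q` exactly; a clamped `x_c = 0` with
`f(0) > m/q` gives the smaller total `(f(0)^{−1/2} − f(x̂)^{−1/2})√(m/q)`,
which is what `ContinuousEquilibrium.total_frequency` reports).

## Parameters and defaults

| parameter | meaning | default | why |
|---|---|---|---|
| `x̂` | trait-axis upper bound (dimensionless) | 2.5 | standard domain used throughout the analyses |
| `m` | colony destruction rate (per time) | 1.0 | sets the persistence threshold `m/q = 1` at `f(0) = 1` |
| `q` | propagule encounter rate (per time) | 1.0 | time unit; only `m/q` matters at equilibrium |
| `n` | resolution (species count) | 30 / 150 | coarse and fine discretizations of the same trait axis |
| RAD threshold | inclusion cutoff | 1e-7 | excludes numerically surviving but ecologically absent species |

Trade-off families shipped: linear `a + bx`, saturating-concave
`a + c(1 − e^{−kx})`, convex `a + b x^γ (γ>1)`, sigmoid
`a + c/(1 + e^{−k(x−x₀)})`, plus arbitrary callables. The "study trio" used
by the acceptance checks — linear `(a=1, b=1)`, weakly saturating
`(a=1, c=3, k=1)` and strongly saturating `(a=1, c=2.5, k=3)` — spans the
qualitative shapes from near-linear to strongly concave. The published
curve parameterizations behind the original figures are not in print, so
these are this package's own stand-ins, chosen once for their phenomenology
(the strongly concave member sits deep in the quasi-exclusion regime:
serrated equilibria, two-phase RADs, Simpson index falling with concavity
and recovering with resolution) and not revisited.

## Numerical choices

* **Equilibrium recursion.** Candidate frequencies at or below 1e-15 are
  zeroed before the recursion proceeds — a floating-point guard on the
  "if positive" branch.
* **ODE steady states.** LSODA with `rtol 1e-12`, `atol 1e-14`, initial
  state uniform `1e-3`, integrating on doubling horizons. A state is
  steady only when `max |dp/dt| < 1e-12` **and** no near-zero species has
  per-capita growth above 1e-9. The second clause matters: species with
  tiny positive equilibria transiently crash to numerical zero, where the
  raw rate criterion alone declares convergence while the species still has
  positive invasion fitness and would regrow. Crashed species are floored
  at 1e-14 (the solver's absolute tolerance) so they remain able to
  re-invade; decaying floored species are excluded from the rate criterion
  and zeroed in the returned state.
* **Root finding.** `x_c` by bisection to 1e-10 — robust for merely
  continuous user trade-offs.
* **Derivatives.** Closed forms for shipped families; central differences
  with step 1e-6 otherwise.
* **Ranking ties.** Competition ("min") ranks everywhere: tied species
  share the smallest applicable rank and the next distinct value skips.
  Abundance ties are preserved exactly — no stochastic tie-breaking — so
  permutation nulls keep the published tie structure.
* **SAD histograms.** Frequencies (or their log2) are rescaled between the
  community minimum and maximum; class `k` covers `[(k−1)/10, k/10)`, so
  eleven classes place the maximum species alone in class 11 and counts
  always sum to the species number.
* **Deviation index.** Each species' analytic reference is the continuum
  mass of its half-interval cell `[x_i − h/2, x_i + h/2] ∩ [x_c, x̂]`
  (`h = x̂/n`) — the natural Voronoi discretization of the interval form;
  a per-species point-density alternative would differ only at second order
  in `h` but the cell convention is fixed here and flagged as such.

## The randomization test

Observed indices: the sample SD (divisor `N−1`) of pooled within-group
pairwise rank distances, and the mean rank of all species in groups of
size ≥ 2. Group labels — singletons included — are permuted uniformly over
the ranked species; abundances, ranks and ties never move. `p_sd` is the
fraction of trials with null SD ≤ observed. For the mean-rank index the
side is fixed against the null grand mean `M`; `p_rank` is the fraction of
same-side trials at least as extreme as observed, a conditional two-sided
analogue (the unconditional all-trials denominator is exposed as an
option). "At least as extreme" includes equality, which makes
tiny-community probabilities match exhaustive enumeration exactly. A
`p_sd` of 0 is reported as 0 — no pseudo-count — with resolution `1/trials`
implied; if no trial lands on the observed side, `p_rank` is reported as
`1/(trials+1)` with a degenerate-side flag. Defaults: 5,000 trials for
model communities, 100,000 for empirical tables.

Distance modes: `all_pairs` (default, matching the field protocol) and
`adjacent_only`, which measures only consecutive ranks within a group and
removes the upward SD bias of all-pairs in groups of three or more.

For model communities the similarity grouping joins maximal runs of
adjacent surviving grid positions (`adjacency_groups`); with
`adjacent_only` distances this measures exactly the adjoining surviving
pairs. The rule is pluggable. A run-based group places each species in one
group even when three or more neighbors survive consecutively, which a
literal "each adjacent pair is a group" reading cannot do.

## Synthetic data: what it emulates and what it does not

`generate_null_table` draws abundances (lognormal meanlog 3, sdlog 1.2 by
default — a realistic hollow curve; log-series optional), rounds to integer
counts (creating natural tied ranks; `tie_rate` can force more, and
`round_to_int=False` gives tie-free tables), and scatters group labels
independently of abundance. That is the null hypothesis of the test by
construction, so these tables calibrate its type-I error. They emulate the
*layout* of field tables — species counts, genus × guild group-size
multisets (e.g. five pairs plus a triplet over 39 species), tied ranks —
but not any real community's abundances: passing tests demonstrate the
test machinery's calibration and power, not a reanalysis of the published
surveys, whose data tables ship with the original sources and can be fed
in as CSV.

`generate_structured_table` converts a model equilibrium into a community
table (survivor frequencies renormalized × a population scale, default
1,000, rounded) with adjacency-run groups — the alternative hypothesis
carrying the quasi-exclusion signal. `generate_perturbed_ensemble` jitters
positions within ± half a grid interval or redraws them uniformly, for
robustness checks; small jitter measurably evens abundances (higher
Simpson index) without destroying the rank-structure signal.

## Problem sizes

The shipped checks use 100 random communities (n ≤ 20) for
recursion-vs-ODE agreement, 1,000 random intervals for the continuum
consistency check, 500 null tables × 2,000 trials for type-I calibration,
50,000 trials against exhaustive enumeration on ≤ 8-species communities,
and 100,000-trial runs for survey-scale tables — sizes at which the
Monte-Carlo standard errors are far below every decision threshold while a
full run stays in the tens of seconds.

## Known limitations

* Deterministic frequencies only: no finite-site stochasticity, no
  spatially explicit version.
* The analytic density assumes a differentiable trade-off; user-supplied
  non-smooth trade-offs fall back to finite differences and bisection.
* `p_rank`'s same-side conditioning makes it undefined in principle when
  every trial lands opposite the observation; the degenerate-side fallback
  is a convention, not an estimate.
* Monte-Carlo probabilities have resolution `1/trials`; exhaustive
  enumeration is only feasible to ~8 species.
* Groups of three or more overestimate the all-pairs distance SD relative
  to adjoining pairs; use `adjacent_only` to bound that bias.
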