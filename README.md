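# radlabel

Species abundance from a colonization model with a competition–fecundity
trade-off, and a randomization test for similarity-group structure on
*labeled* rank abundance diagrams (RADs).

## The science

Many sites make up a habitat; each is empty or held by one colony. A
community of `n` species is ordered by competitive ability: species `i`
carries a competitive inferiority `x_i` on `[0, x̂]`, and fecundity rises
with inferiority through a monotone trade-off `f(x)`. Propagules encounter
sites at rate `q`; on encounter the competitively superior species
instantly takes the site (dominance competition); colonies are destroyed at
rate `m`. The site-frequency dynamics are

```
dp_i/dt = q f_i p_i (1 − Σ_{j≤i} p_j) − q (Σ_{j<i} f_j p_j) p_i − m p_i
```

Because each species is affected only by its superiors, the equilibrium
follows a forward recursion

```
p_i = 1 − Σ_{j<i} p_j − (1/f_i)(Σ_{j<i} f_j p_j + m/q)   if positive, else 0
```

and in the continuum limit (`n → ∞`) an analytic density
`p(x) = ½ f′(x) f(x)^{−3/2} √(m/q)` on `[x_c, x̂]`, where `f(x_c) = m/q`.
With a *discrete* trait axis the equilibrium is serrated: a species that
overshoots the continuum density suppresses its next-inferior neighbor to
low frequency without excluding it — **competitive quasi-exclusion**.
Survivors whose frequency beats both trait-axis neighbors ("peak" species)
cluster at high abundance ranks, non-peaks at low ranks.

That yields a testable prediction for real communities: ecologically
similar species (same genus × foraging guild) should sit at *consistent*
rank offsets on the RAD. The `rank_test` module measures (1) the SD of
within-group pairwise rank distances and (2) the mean rank of grouped
species, then permutes group labels across the ranked species (abundances,
ranks and ties fixed) to get one-sided null probabilities `p_sd` and a
conditional `p_rank`; their product is the joint probability.

## Worked example

Three species with fecundities `f = (2, 5, 6)` at `m = q = 1`:

```python
import numpy as np
from radlabel import (TradeOff, CommunitySpec, solve_equilibrium,
                      build_rad, simpson_index)

tof = TradeOff.from_callable(
    lambda x: np.interp(x, [0, 0.5, 1.5, 2.0, 2.5], [1.5, 2, 5, 6, 6.5]),
    x_hat=2.5)
spec = CommunitySpec(positions=[0.5, 1.5, 2.0], m=1.0, q=1.0, trade_off=tof)

eq = solve_equilibrium(spec)
print(eq.frequencies)        # [0.5 0.1 0. ]
rad = build_rad(eq)
print(rad.frequency)         # [0.83333333 0.16666667]
print(simpson_index(rad))    # 0.2777777777777777
```

Species 3 is excluded outright; species 2 coexists but is suppressed to
`p = 0.1` by its superior neighbor — quasi-exclusion in miniature. After
dropping empty sites the RAD holds two species at 5/6 and 1/6, giving
Simpson diversity 5/18.

The same pipeline from the shell, for a 30-species community on a strongly
saturating trade-off (`config.yaml` holding the model block):

```
$ radlabel equilibrium --config config.yaml --out run
$ radlabel synth --config config.yaml --kind structured --out synthrun
$ radlabel test --table synthrun/community.csv --out testrun \
      --trials 100000 --seed 42 --mode adjacent_only
joint_p = 0.0644943 (p_sd = 0.08434, p_rank = 0.764694, side = below)
```

`run/summary.json` reports 18 survivors of 30, Simpson index 0.401, empty
fraction 0.535 and a deviation index of 0.94 (mean relative departure of
the discrete equilibrium from the continuum cells — strong serration). The
test's `p_sd = 0.084` says only 8.4% of random labelings produce a
within-group rank-distance SD as small as the model community's.

Empirical tables are plain CSV/TSV with columns `species, genus, guild,
abundance` (optional `rank` for published tied ranks);
`radlabel test --table community.csv --exclude "Some species"` reruns the
analysis with a named species removed, for sensitivity checks on
questionable records.

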