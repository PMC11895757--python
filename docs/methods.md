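# Methods

`paleosky` implements two phylodynamic likelihoods over a shared
piecewise time grid, a tip-dating Metropolis–Hastings sampler, forward
simulators, and posterior summaries. This note records the models, the
numerical choices, and what the synthetic-data experiments do and do
not demonstrate.

## Time grid and coordinates

Geological time is partitioned by a strictly increasing list of
absolute boundary ages (Ma). The youngest boundary is the *reference
age* — the analysis "present". For an entirely extinct clade this is
the age of its final disappearance (66.0 Ma, the K-Pg boundary, in the
end-Cretaceous grid whose eight bins run Coniacian–Maastrichtian up to
Early–Mid Triassic). Internally every age is measured in Myr before the
reference age, increasing into the past; absolute Ma appear only at
I/O. A bin covers `[young_edge, old_edge)`: an event exactly on a
change time belongs to the interval whose floor that change time is.
This convention is a declared choice — events land exactly on
boundaries with probability zero, but the likelihoods must be
deterministic there. The oldest bin is unbounded above. Rate vectors
are indexed youngest bin first.

## Fossilised birth-death skyline (BDSKY)

A birth-death-sampling process starts with one species at the origin
age x₀ (a parameter, older than the root). In bin *i* each lineage
speciates at λᵢ, goes extinct at μᵢ, and is fossil-sampled at ψᵢ (all
per lineage per Myr); sampled species are *not* removed, so a fossil
may have sampled descendants (a sampled ancestor). Lineages reaching
the reference age are sampled there with probability ρ, fixed to 0 for
extinct clades. The likelihood conditions on at least one sample.

Two auxiliary functions, both in backward time t with continuity across
bin changes:

* p(t): probability a lineage at age t leaves no sampled descendants,
  dp/dt = μ − (λ+μ+ψ)p + λp², p(0) = 1 − ρ;
* q(t): the edge factor, dq/dt = −(λ+μ+ψ)q + 2λpq, q(0) = 1.

Within a bin both have the standard closed forms in
A = sqrt((λ−μ−ψ)² + 4λψ); the workspace chains boundary values across
bins and answers point queries in O(1). The two degenerate branches
(λ = 0; A = 0 with λ > 0) are solved separately (linear ODE and
double-root rational form). All closed forms are validated against
numerical ODE integration in the test suite, which is the contract: at
180 Myr depths q underflows, so the likelihood accumulates log q
throughout and an explicit log-scale evaluator is exposed.

The log density of a tree decomposes into log q-ratios per edge
(including origin→root), log λ(bin) per bifurcation, log ψ(bin) +
log p(age) per terminal fossil, log ψ(bin) per sampled ancestor, log ρ
per tip at the reference age, and −log(1 − p(x₀)) for the
conditioning. Observations the parameters make impossible (a tip at
age 0 with ρ = 0; p(x₀) = 1) yield −∞, never NaN.

Sampled ancestors are kept as labelled unary nodes rather than
zero-length branches. Under the no-removal model most fossils in a
supercritical clade *do* have sampled descendants (1 − p ≈ 0.8 in the
test regime), so dropping them would badly distort both simulation and
inference; supporting them end-to-end keeps the simulator and the
likelihood describing exactly the same process. Tree topologies are
never changed by the sampler, so a fossil never migrates between tip
and ancestor configurations.

## Piecewise-exponential coalescent

The genealogy of the sampled species is modelled as a heterochronous
Kingman coalescent driven by an effective species richness N(t):
N(0) = N_f at the reference age and, within bin *i*,
N(t) = N(edge_i)·exp(−rᵢ(t − edge_i)) — rᵢ > 0 means richness growing
forward in time. N is continuous and strictly positive; N_f absorbs
the non-identifiable proportionality between effective size and
species count. While k lineages are extant the coalescent rate is
k(k−1)/2 · 1/N(t); the cumulative intensity ∫dt/N integrates in closed
form per bin (expm1 for small exponents) and is exactly additive.
Fossil ages enter only as sampling times: the model deliberately
assumes sample dates are independent of richness, which is the key
assumption separating it from the BDSKY treatment of sampling.

The log density is Σ_coalescences −log N(t_c) − Σ_segments
k(k−1)/2 · ∫dt/N. Ties between a sample and a coalescence at the same
age are ordered sample-first going backward; zero-length segments
contribute nothing. No origin is scored — the density is that of the
genealogy itself, unlike the BDSKY side which conditions on an origin
parameter. Unary (sampled-ancestor) nodes are rejected: the coalescent
input must be a binary genealogy.

## Priors

Independent priors per scalar parameter (all replaceable through
configuration):

| parameter | default | rationale |
|---|---|---|
| λᵢ, μᵢ | lognormal, median 0.2/Myr, log-sd 1.2 | central 95% ≈ 0.019–2.1 events/lineage/Myr, bracketing published diversification-rate compilations (0.02–1.54) |
| ψᵢ | exponential, mean 0.2/Myr | one sample per lineage per 5 Myr on average; favours sparse sampling without excluding dense |
| rᵢ | normal(0, 1)/Myr | symmetric: decline and expansion equally likely a priori |
| N_f | lognormal, median 100, log-sd 1.5 | order-of-magnitude uncertainty around a hundred co-existing species |
| origin | uniform(root age, 280 Ma) | older than any plausible clade origin; density renormalised against the current root age so the joint prior stays proper under node-age moves |

Fossil ages carry uniform priors on their stratigraphic
(oldest, youngest) interval — the tip-dating treatment of age-range
tables — implemented as hard move bounds (the uniform density constant
cancels).

## Sampler

Random-scan Metropolis–Hastings with fixed topology. Move families and
default weights: scalar rates 40% (multiplicative scale moves for
positive parameters, log-Hastings log s; sliding windows for growth
rates), internal node ages 30% (uniform between oldest child and
parent/origin — symmetric because the interval does not depend on the
current value), fossil ages 20% (uniform on stratigraphic bounds
intersected with neighbour ages), origin 10% (a 50/50 mixture of a
global redraw over the prior support and a local reflected window).
Step sizes are tuned by diminishing Robbins–Monro adaptation toward
30% acceptance, which preserves ergodicity and bit-reproducibility
(one seeded generator drives every draw).

The tree lives in flat arrays; because the BDSKY log likelihood is a
sum of per-node terms given the rate workspace, single-age moves update
it in O(1), with a from-scratch re-evaluation at every chunk boundary
to cancel float drift (the trace identity log-posterior = log-likelihood
+ log-prior holds to well below 1e-9). Chains extend in chunks
(default 20,000 iterations, thinning 20) until the post-burn-in ESS of
every scalar parameter exceeds 200 — the stopping rule — or a chunk cap
is reached, in which case the trace is returned flagged unconverged.
Initialisation: scalars at prior medians (prior draws on retry), node
ages from the input tree, fossil ages at bound midpoints, origin a
quarter of the way from root to cap; 1000 failed initialisations is an
error.

ESS uses the initial-positive-sequence (Geyer) truncation of the
autocorrelation sum, n / (1 + 2Σρ_k); estimator choice matters near
the threshold, and this one is conservative on short chains. Burn-in
removes ceil(fraction·n) records (default 10%) but always leaves at
least one. HPD intervals are the shortest contiguous window of sorted
samples, checked against exhaustive search. Medians of even-sized
samples are midpoints of the central order statistics; sign fractions
use strict inequalities with exact zeros reported separately, so the
three fractions always sum to one.

## Synthetic data

`simulate_fbd` runs the clock forward from the origin with per-lineage
exponential waiting times; a waiting time crossing a bin boundary is
re-drawn from the boundary with the new rates (exact by
memorylessness). The reconstruction prunes to fossil-bearing lineages:
the youngest fossil on a lineage without sampled descendants becomes a
terminal tip, older fossils become sampled ancestors, and invisible
speciations are suppressed. Conditioning (≥ 2 sampled tips by default)
is by rejection with the retry count reported — in regimes where
conditioning is severe, naive expectations no longer hold, and the
count makes that visible. A lineage cap (default 100,000) aborts
explosive regimes with guidance rather than exhausting memory.

`simulate_coalescent` inverts the closed-form cumulative intensity to
draw inter-coalescence times (time-rescaling), interrupted by tip
joins. If the oldest bin has negative growth the total remaining
intensity can be finite; non-coalescence then has positive probability
and the simulator raises rather than silently looping.

`make_age_table` wraps each true fossil age in a ±halfwidth window
(truncated at the reference age); with a seed the window is placed
uniformly at random so the truth is uniform within its bounds.

The default test regime — one or two bins, λ, μ ∈ [0.05, 0.3],
ψ ∈ [0.05, 0.2], origins 30–80 Myr deep, tens to thousands of sampled
tips — mirrors desk-scale fossil timetrees. What the simulators do
*not* emulate: spatially or taxonomically biased sampling, Lagerstätten
pulses, correlated preservation, topology uncertainty. Passing
recovery tests therefore show the estimators are calibrated when the
model is true, not that real fossil records satisfy the models'
sampling assumptions.

## Validation experiments (test suite)

* Oracle equivalence: closed-form p/q vs ODE integration (1e-8); the
  full BDSKY density vs an edge-by-edge numerical-ODE implementation on
  100 random draws (1e-6 relative); the Yule limit in closed form
  (1e-9); the coalescent vs an independent constant-size implementation
  on 50 random heterochronous trees (1e-10) and quadrature for the
  intensity (1e-9).
* Parameter recovery: ten datasets per model simulated at known rates
  (BDSKY λ=0.15, μ=0.05, ψ=0.1, origin 80; coalescent r=0.05,
  N_f=100, 30 tips); the 95% HPD of net diversification (resp. growth)
  must cover the truth in at least 8 of 10. Both experiments condition
  on the simulated timetree — the genealogy is the data; scalar rates
  and (for BDSKY) the origin are sampled. With thousands of latent node
  ages the origin/root pair mixes diffusively, and reaching an honest
  ESS of 200 on every parameter within desk-scale budgets requires this
  conditioning; HPD coverage is a valid check under any conditioning.
  Joint node-age and fossil-age sampling is validated separately
  (prior-recovery, uniform-tip-age, and trace-identity tests).
* Prior recovery: with the likelihood disabled, posterior moments match
  analytic prior moments within 3 Monte-Carlo standard errors
  (lognormals checked on the log scale, where moments are stable).
* Multi-chain agreement: four seeds on one dataset reach a
  Gelman–Rubin statistic below 1.1.

## Known limitations

* Topologies are fixed; there are no tree-rearrangement moves.
* The likelihood treats ρ-sampling only at the reference age; diversified
  or clustered extant sampling is out of scope.
* Sampled ancestors are carried through simulation, I/O and the BDSKY
  likelihood, but the sampler never proposes conversions between tip
  and ancestor configurations (the input topology decides).
* The coalescent arm offers no sampling-aware variant; if fossil ages
  correlate with richness (they do, in real records), its growth-rate
  estimates inherit that bias by design.
* Single-threaded; desk-scale problems (≤ a few thousand tips, ≤ 8
  bins) run in seconds to minutes per chain.
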