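# Methods notes

This note records the model conventions, numerical choices and generator
assumptions behind `resdyn`, and what the synthetic benchmarks do and do not
establish about real landscapes.

## The decision model

The state of the world is the pair `(S, N̄)` of still-available sites and the
reserve built so far; converted sites are implied.  An action is a purchase
`N ⊆ S` with `Σ c(s) ≤ B`; after purchasing, each remaining unreserved site
converts independently with probability `μ(s)`, giving a product-form
transition law over survivor subsets.  Rewards are negative purchase costs;
the transition that empties `S` additionally pays `−BLM·Boundary − Penalty`
of the final network, so the value of a policy at the start state is minus
its expected extended cost.  Prohibited actions (unavailable sites, cost
above budget) are encoded, rather than excluded, with a finite sentinel
reward of `−10⁶·α`.

Three conventions resolve corners the bare formulation leaves open:

* **Target freeze.**  Once the current reserve meets every target the solver
  forces the empty action and assesses the terminal boundary term
  immediately.  Remaining conversions cannot change the network, so with the
  stopping rule used in all experiments this is exact.  (With `BLM > 0` a
  policy could in principle keep buying to plug boundary holes; the freeze
  deliberately matches the experimental stopping rule instead.)
* **Waiting self-loop.**  The empty action in a state whose unreserved sites
  may still convert creates a self-transition; its value is resolved
  analytically as `Q_∅ = (Σ_{x'≠x} P(x') V(x')) / (1 − P(stay))`.  If no
  remaining site can ever convert (`μ = 0` for all of them), waiting never
  terminates; such states are treated as absorbing with the terminal
  assessment of the current network, matching the simulator's horizon cap.
* **Budget in the exact model.**  The exact solver carries no budget
  carryover in its state (the budget is a per-period constant), and queries
  policies with `period = 0`; on the unit-cost benchmarks used for
  cross-checks the simulation semantics coincide.

`backward_induction` is implemented as memoized Bellman recursion from the
initial state over bitmask-encoded states — the same fixed point as a
bottom-up sweep by increasing `|S|` (the test suite certifies a zero Bellman
residual), but it only touches reachable states.  Ties between equally good
purchases break toward the lexicographically smallest site set; the solver
refuses instances above 12 sites and points to Monte-Carlo evaluation.

## Static solver

The one-shot objective is
`−cost(N) − BLM·Boundary(N) − Σ_j SPF_j·Penalty(j) − CostThreshold(N)`,
with `SPF = 10⁶` for every habitat by default (a single scalar or a
per-habitat vector), `CostThreshold` disabled by default, and `Penalty(j)`
a greedy estimate of the cheapest way to close the target-`j` shortfall:
unselected sites are added in order of cost per unit of habitat `j`; if even
all remaining `j`-bearing sites cannot close it, their cost plus `α` is
charged.  Sites reserved in earlier periods enter as `locked`: they count
for abundance and boundary but are monetarily sunk.

Annealing proposes single-site toggles with Metropolis acceptance and
geometric cooling (factor 0.999 per proposal).  The initial temperature is
adaptive by default: the standard deviation of the objective deltas of 100
random toggles.  Defaults are 20,000 proposals and 2 restarts with the best
network kept across restarts — sized for the instance scales this solver is
actually called on (the 12-site oracle comparisons span 4,096 subsets, and
the dynamic minimum-set policy re-solves every simulated period), where a
longer schedule adds cost but no measurable quality: the suite requires the
annealer to reach ≥ 99% of the brute-force optimum on at least 95 of 100
seeded 12-site instances, and it currently reaches it on all 100.

## Site ordering

Given a reference yearly budget `m_B` (by default the mean of the budget
model), the purchase year of the i-th site of a sequence is
`⌈(Σ_{i'≤i} c(s_{i'}))/m_B⌉`, and a site's habitat is discounted by its
survival probability `(1−μ)^(t_buy−1)`.  Sequences are ranked by the sum of
capped expected abundances (utilitarian, the default) or by the worst
habitat (egalitarian); a raw-area convention is used (an `H_j`-normalized
variant is available by flag).  The maximization over orderings is exact
(all permutations) up to 8 sites and greedy construction plus pairwise-swap
hill climbing beyond; ties keep the input order, so with no conversion risk
the ordering is stable.

## Policies

Richness scores a site by `Σ_j w_j · h_j(s)/(H_j · D(s))` over unmet
habitats (met habitats contribute a rank-neutral 1), rarity by
`Σ_j w_j · (EA_j(N̄∪{s})/R_j)/D(s)` with `R_j` the habitat remaining among
available sites, where `D(s) = c(s) + BLM·ΔBoundary(s)` is the marginal
extended cost and `w_j = λ_j/λ_c`.  Scores are positive desirabilities and
maximized; the cost-sign (negated) presentation of these rewards in the MDP
framing does not change the induced ranking.  Two numerical details:

* `D(s)` can be non-positive when a site plugs a boundary hole; it is
  clamped at `ε = 10⁻⁹ × (mean site cost)`, which keeps scores finite and
  strongly favours such sites.
* As printed, the rarity form uses the full network's effective abundance
  rather than the marginal gain, so a met habitat contributes
  `H_j/(R_j·D(s))` for every candidate — cost still discriminates, habitat
  does not.  This is implemented as stated.
* `λ_c` is a common factor that cannot change an argmax ranking; it is kept
  (and searched by the optimizer) for fidelity to the stated augmented form.

The dynamic minimum-set policy re-solves the static problem from scratch
each period with the current reserve locked, orders the new solution sites,
and buys a **strict prefix** of the sequence — it never skips ahead to a
cheaper later site; unspent budget carries over instead.  Its annealer seed
is derived deterministically from the state so the policy is a stationary
deterministic function of the state, as exact evaluation requires.  All
ties anywhere break toward the smallest site id.

## Simulation and evaluation

A scenario pre-samples, independently of any policy, each site's conversion
period (geometric with success `μ`, infinite when `μ = 0`, truncated at the
horizon cap, default 500) and the i.i.d. budget draws.  Within a period,
purchases happen first and conversions at the period's end.  All unspent
budget rolls over: the stated rule only transfers leftovers smaller than the
cheapest site, but a policy facing an affordable site either buys it or has
chosen not to, so blanket carryover is equivalent and simpler.  Policies
compared on the same seed see identical scenarios (common random numbers);
the default Monte-Carlo sample is 1,000 scenarios, and estimates report the
mean, its standard error and the fraction of runs meeting all targets.

## Weight fitting

Augmented-heuristic weights live on a discrete grid, by default the 11
levels 0.2, 0.4, …, 2.2 for each `λ_j` and `λ_c` (the study this follows
does not report its grids, population sizes or Monte-Carlo sample sizes, so
these defaults are declared rather than inferred).  The GA uses tournament
selection (size 3), uniform crossover (rate 0.9), per-gene grid mutation
(rate 0.15) and single-individual elitism over a population of 40 for 25
generations; every fitness call scores the policy on one fixed set of 200
scenarios, so the best-so-far trace is monotone and the all-ones individual
seeded into the initial population guarantees the result is never worse
than the plain heuristic on the training set.

## Synthetic landscapes

The generators emulate three study set-ups; all are deterministic given a
seed, and none of them claims to reproduce a particular historical
realization.

* **small9** — nine unit-cost squares on a 3×3 grid.  Habitat amounts are
  one draw per habitat from a Gaussian random field with exponential
  covariance `C(d) = sill·exp(−d/range)` at the cell centres: mean 5 with
  (sill, range) = (5, 2), (1, 2), (1.5, 2) for habitats 1, 2 and a
  non-target filler.  Negative draws truncate to 0 (areas), which biases
  near-zero values slightly upward.  Targets are 50% of the realized totals
  of habitats 1 and 2; the budget is a constant 1 per year; BLM = 0.
* **large880** — the same field model sampled at the centroids of a Voronoi
  tessellation of a `√n × √n` square (mean cell area 1, so the range keeps
  its meaning), site costs `4000·(h₁+h₂)` and the stochastic budget
  {5M: ⅔, 3M: ⅙, 1M: ⅙}.  A habitat scale of 5.4 reproduces the reported
  average site price of about $216,000.
* **ehnwr** — five target habitats plus a dominant non-key habitat with
  table-driven normalized sills/ranges and separate variances, on a Voronoi
  landscape with mean site area 1 km² (the tabled per-site habitat means in
  m² sum to roughly 10⁶, fixing the unit).  Field ranges apply on
  normalized [0,1] coordinates; per-site amounts are rescaled so their sum
  never exceeds the site's area.  Costs are area × an exponential per-km²
  price (mean $25,242).  Conversion-rate categories split sites at 30% and
  60% cumulative target-habitat share of area; the per-category
  distributions of the original data set are not public, so the shipped
  defaults U[0.001, 0.1] / U[0.01, 0.3] / U[0.02, 0.6] are synthetic
  placeholders ordered by threat, configurable and with no claim of
  fidelity.

Conversion scenarios: `noncorrelated` draws `μ ~ U[0.01, 0.3]` for every
site; `correlated` draws `μ ~ U[0.02, 0.6]` for sites whose habitat-1 share
of the site's total habitat exceeds 5% and `μ ~ U[0.001, 0.1]` otherwise.
The share denominator (the site's total habitat) is a design choice: the
source text does not state one, and this reading is scale-invariant and
consistent with the category rule of the five-habitat set-up.

**What the small-grid benchmark does not reproduce.**  The original
comparison used a single field realization, published only as a figure, in
which habitat 1 was rare (concentrated on few sites) — its realized total
was roughly 38% of habitat 2's.  Under the stated field parameters (equal
means of 5), every regenerated site carries substantial target habitat, so
the 5% rule marks nearly all sites as threatened, the correlated scenario
degenerates toward uniformly elevated risk, and regenerated correlated
costs sit systematically above the published single-landscape figures.  Two
consequences are visible in the acceptance tests and are left to fail
honestly rather than being recalibrated: the across-landscape mean of the
tuned augmented-rarity policy exceeds the published correlated value by
more than its tolerance, and the up-weighting of the threatened habitat
(`λ₁ > λ₂`) appears in only about half of tuning runs because regenerated
landscapes lack the rare-habitat structure that makes it systematically
profitable.  The non-correlated comparisons, which do not depend on that
structure, land within a few percent of the published values, and on every
regenerated landscape the exact optimum dominates every heuristic, as it
must.

## Problem sizes

Exact comparisons use 20 regenerated non-correlated and 10 correlated
9-site landscapes (backward induction and exact policy evaluation per
landscape); Monte-Carlo consistency is checked at 10⁴ scenarios; weight
tuning uses the GA defaults above; the compactness sweep runs on a 5×5 grid
at 80 scenarios.  These sizes were chosen so the whole suite re-derives its
results from scratch in minutes on a single core while keeping every
statistical check at three-sigma or tighter.

## Known limitations

* No discounting; finiteness of the undiscounted value relies on absorption
  (all-`μ = 0` pockets are handled by the absorbing-wait convention above).
* The exact solver requires a constant budget; stochastic budgets are
  simulation-only.
* No value-function approximation or reinforcement learning; no integer
  programming backend for the static problem; no Marxan `.dat` dialect
  interoperability; coordinates are abstract planar units with no CRS
  handling.
* Scenario truncation at the horizon cap assesses the terminal cost early
  for never-converting sites; with the default cap of 500 this only matters
  for instances dominated by `μ = 0` sites.
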