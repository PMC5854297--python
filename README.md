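# resdyn — dynamic minimum-set reserve design

`resdyn` is a toolkit for the *dynamic reserve design problem*: assembling a
network of protected sites over many years, under an annual acquisition
budget, while unprotected sites may be irreversibly converted (developed)
before they can be bought.  It is aimed at conservation planners and
computational ecologists who want to compare purchase policies by simulation,
and at methods researchers who need exact optima on small instances as a
yardstick.

## The problem and the model

A landscape is a set of sites `s`, each with a cost `c(s)`, habitat amounts
`h_j(s)` for `J` target habitats, a per-period conversion probability `μ(s)`
and polygon boundary lengths.  A final network `N̄` is scored by its
**extended cost**

```
c(N̄) = Σ_{s∈N̄} c(s) + Penalty(N̄) + BLM · Boundary(N̄)
```

where `Penalty` is 0 when every habitat target `H_j` is met and a large
constant `α = 2 Σ_{s} c(s)` otherwise, `Boundary(N̄) = Σ π_s − 2 Σ π_{s1,s2}`
is the outer boundary of the network, and BLM (boundary length modifier)
trades compactness against money.  A *policy* `δ(S^t, N̄^t) → N^t` chooses a
feasible purchase every year; its quality is its **expected extended cost**
(EEC) over conversion and budget randomness, and the planning problem is a
finite-state Markov decision process whose optimal policy minimizes the EEC.

The package provides:

* **Exact solution** by backward induction over `(S, N̄)` states (≤ 12 sites),
  plus exact EEC evaluation of arbitrary deterministic policies.
* **Static minimum-set solver**: simulated annealing on the one-shot
  objective `−cost − BLM·Boundary − Σ_j SPF_j·Penalty(j)` (with a brute-force
  oracle for small instances).
* **Dynamic minimum-set policy**: re-solve the static problem every year with
  already-reserved sites locked in, order the solution by expected effective
  abundance `E[EA_j(σ)] = min(H_j, Σ_i (1−μ(s_i))^{t_buy(i)−1} h_j(s_i))`,
  and buy the longest affordable prefix.
* **Greedy and augmented-greedy policies** (richness and rarity scores, with
  per-habitat weights `λ_1..λ_J, λ_c` fitted by a genetic algorithm against
  simulated EEC).
* **Monte-Carlo evaluation** on policy-independent scenarios (common random
  numbers), and **synthetic landscape generators** — a 3×3 unit-cost grid
  with Gaussian-random-field habitats, an 880-site Voronoi landscape with
  habitat-linked costs, and a five-habitat landscape with table-driven field
  parameters, category-based conversion rates and exponential area costs.

## A worked example

Four unit-cost sites hold 6, 2, 4 and 3 units of one habitat; the target is
7, and one site can be bought per year while every unbought site may convert
(here `μ = 0.5`).  Both `{s1,s3}` and `{s3,s4}` meet the target at cost 2,
but they are not equally safe to build over time:

```python
from resdyn import (
    fixture_worked_examples, MDPInstance, backward_induction,
    exact_policy_value, GreedyPolicy, estimate_eec, BudgetModel,
)

reef = fixture_worked_examples("worked4")
instance = MDPInstance(reef, budget=1.0)
policy, values = backward_induction(instance)
start = instance.initial_state()
print("optimal first purchase:", sorted(policy[start]))
print(f"optimal expected extended cost: {-values[start]:.3f}")
greedy = GreedyPolicy("rarity")
print(f"greedy rarity (exact): {exact_policy_value(greedy, instance):.3f}")
est = estimate_eec(greedy, reef, BudgetModel.constant(1.0), n_scenarios=1000, seed=0)
print(f"greedy rarity (MC, n=1000): {est.mean:.3f} +/- {est.stderr:.3f}")
```

prints

```
optimal first purchase: [1]
optimal expected extended cost: 2.875
greedy rarity (exact): 2.875
greedy rarity (MC, n=1000): 2.924 +/- 0.075
```

The optimal opening buys the 6-unit site: afterwards the target stays
reachable in 7 of the 8 possible conversion outcomes, versus 6 of 8 after
opening with the 4-unit site.  The EEC of 2.875 decomposes into the 2-unit
price of the network plus the residual risk of losing too much habitat
before year two; here the greedy rarity score happens to reproduce the
optimal policy, and the Monte-Carlo estimate agrees with the exact value
within sampling error.

The same machinery scales up through the command line:

```bash
resdyn generate --kind small9 --seed 7 --out runs/small9
resdyn evaluate --landscape runs/small9 --policy greedy-rar --n 1000 --seed 1 --out runs/small9-rar
resdyn tune --landscape runs/small9 --heuristic rarity --seed 1 --out runs/weights.json
```

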