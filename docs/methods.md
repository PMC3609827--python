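# Methods

## The model

`dietopt` solves the classical least-cost diet problem extended with
greenhouse-gas (GHG) accounting. Decision variables are grams of edible
food per day, one per food item. For a scenario with objective
coefficients $c_i$ the solver minimizes

$$\min_x \sum_i c_i x_i \quad \text{s.t.} \quad
L_n \le \sum_i \frac{a_{in}}{100} x_i \le U_n \ \ \forall n, \qquad
\ell_i \le x_i \le u_i,$$

plus scenario-specific aggregate rows (e.g. total non-starchy
vegetables), linked-ratio equalities (flour = 7 × oil for flatbreads),
an added-sugar cap, and — for emission-minimizing scenarios — a budget
row. $a_{in}$ is the content of nutrient $n$ per 100 g edible weight of
food $i$.

Cost and emissions attach to *purchased* weight. With wastage fraction
$w_i$ (inedible portions plus discarded edible food), price $p_i$
(NZ$/100 g purchased) and GHG factor $g_i$ (kg CO2e/kg purchased):

- cost coefficient: $p_i / (100 (1 - w_i))$ NZ$/g edible,
- GHG coefficient: $g_i / (1000 (1 - w_i))$ kg CO2e/g edible.

Charging GHG on purchased weight is a deliberate choice: wasted food
still caused emissions during production. (Whether the original analyses
this package is patterned on used purchased or edible weight for GHG is
not knowable from their text; the purchased basis is the conservative
accounting.)

Nutrient bounds are estimated-average-requirement (EAR) style minima
with upper limits for sodium, saturated fat and vitamin A. Energy is a
**≥ 11,450 kJ** constraint, not an equality: scenarios that force
energy-dense recipe components can legitimately exceed the target. The
iron minimum uses the female EAR (8 mg/day) rather than the male value
so the optimized diets remain adequate for women.

## The minimum-quantity rule

Every selected food must reach 10 g/day or be left out, except
condiments (salt, sugar) and recipe-pinned ingredients (e.g. 8 g flour
in a mince-on-toast recipe). This semicontinuity makes the exact problem
a mixed-integer program. Two strategies:

- **`milp`** (default): binary inclusion indicators $y_i$, with
  $10 y_i \le x_i \le u_i y_i$, solved by HiGHS branch-and-bound. Exact
  and fast at this scale (76 foods solve in tens of milliseconds), which
  is why it is the default rather than a heuristic: the contract that the
  returned objective bounds every feasible semicontinuous diet is then
  unconditional.
- **`iterative`**: solve the LP; foods landing strictly inside (0, 10 g)
  are fixed to 0 (or, when that is infeasible, rounded up to 10 g);
  repeat to a fixpoint, at most 20 rounds. An upper bound on the exact
  optimum, kept for speed comparisons and as a cross-check; the MILP
  path is its oracle in the tests.

## Cooking-salt adjustment

Scenario recipes state salt-in-cooking amounts (e.g. 0.5 teaspoon =
3 g). Salt is ~39 g sodium per 100 g, and the sodium cap
(≤ 2,300 mg/day) always stays active, so forced salt plus the intrinsic
sodium of forced recipe foods (bread, cheese, sausages) can exceed the
cap outright. Added salt therefore *yields* to the sodium cap: if the
stated minima make the scenario infeasible, the solver maximizes salt
subject to everything else (an LP), and re-imposes
min(stated, feasible) with a 0.1% haircut (the LP relaxation can
slightly overestimate what the semicontinuous problem allows). The
familiar-meal scenarios then pin sodium at exactly 2,300 mg, which is
the intended behavior. Other forced minima are never adjusted.

## Scenarios

The 16 built-ins ship as YAML files (`src/dietopt/scenarios_builtin/`)
so users can copy-edit them. Shared defaults: variety caps (flour,
pasta, oats 240 g each; any single vegetable 200 g; added sugar 60 g),
and the 10 g rule. Choices worth flagging:

- Strict budget wordings ("< NZ$5/day") compile as ≤ the cap; a
  `match_paper` toggle sets the tight-budget scenario's cap to 4.99 for
  users reproducing published runs where the cap binds just below 5.
- The flour:oil 7:1 link is an equality on the linked amounts (a pure
  minimum-oil reading is also defensible; equality is the stricter one).
- Caps that are known to exist but whose values are unstated elsewhere
  were fixed once as package defaults: sugar 60 g, kiwifruit 200 g,
  peanut butter 100 g, vegetable oil 60 g.
- "Any two other vegetables ≥ 100 g each" cannot be expressed in an LP
  (it is a cardinality constraint); it compiles as an aggregate
  ≥ 200 g over the eligible vegetable set. Same device for the other
  "any other vegetable" recipe lines.
- Exclusions are tag-driven only (`requires_cooking_skill` for the
  minimal-skills diet, the animal-product tags for vegan), never food-id
  lists, so databases stay swappable.
- The Asian-style scenario's bulk-rice price ($0.18/100 g) is a
  scenario-scoped price override; it does not alter the database.
- The Mediterranean scenario intentionally leaves legumes/cereals/dairy
  unconstrained beyond the stated vegetable, fruit-and-nut, fish and
  olive-oil floors.

## Monte Carlo engine

Each draw perturbs the database and re-optimizes (n = 2000 by default):

| source | distribution | parameters |
|---|---|---|
| prices | gamma by moments | mean, monthly SD; foods without an SD borrow their category's median CV |
| nutrient contents | normal, truncated at 0 | SD = 5% of mean |
| wastage fractions | beta by moments | mean, SD (e.g. potatoes 0.45, SD 0.0142) |
| requirement minima | normal, truncated at 0 | per-nutrient heterogeneity SD |
| energy target | normal | mean 11,450 kJ, SD 184.4 kJ |

All perturbations are independent across foods and nutrients (no price
co-movement). Moment inversions are closed-form: gamma shape
$\mu^2/\sigma^2$, scale $\sigma^2/\mu$; beta
$\nu = \mu(1-\mu)/\sigma^2 - 1$, $\alpha = \mu\nu$,
$\beta = (1-\mu)\nu$. Truncation at zero is a clip; at the 5% CVs used
here the clipped mass is negligible (< 10⁻¹⁶ of draws).

Summaries report mean, median and the central 95% **simulation interval**
(SI; 2.5th–97.5th percentile, inclusive linear-interpolation
percentiles). Infeasible draws are counted and excluded, not redrawn —
redrawing would bias the sampled parameter space toward easy worlds, and
the infeasibility rate is itself informative. The PUFA/saturated-fat and
potassium/sodium ratios are **statistic-wise ratios** (ratio of means,
of medians, of SI bounds), not summaries of per-draw ratios; as a
consequence their "interval" columns need not be ordered, which is a
property of that reporting convention, not a bug.

Requirement heterogeneity and the energy target are sampled
independently (their joint behavior is not identifiable from anything we
emulate). Reproducibility: draw $k$ uses `default_rng((seed, k))`, so
whole summaries are bit-reproducible and draws are independent of
iteration count.

## Synthetic data

The generator emulates the *structure* of the real inputs — a 76-item
retail food list with category-typical prices, price CVs (produce 12%,
packaged staples 3–5%), WRAP-style wastage fractions with small SDs,
and GHG factors enforcing plant ≪ dairy < ruminant — without
reproducing any real survey value. Nutrient profiles come from ~45
archetypes (root vegetable, dried legume, skim milk powder, red meat,
…) with ±10% lognormal per-food jitter per seed.

Feasibility is guaranteed constructively: a hidden reference day
(grain-legume-egg-dairy-vegetable, ~11.5 MJ) is priced against the
requirement rows and nutrient contents are scaled per nutrient until
the reference day satisfies every row with margin (8% above minima,
15% below maxima); the reference day is then discarded and a real
least-cost solve verifies the result. Up to 50 regeneration attempts
before giving up with advice to loosen the config.

The typical-diet comparator splits the 11,450 kJ target across category
energy shares (grain-heavy, substantial meat and dairy — the shape of a
Western national diet, with the share values fixed here as package
defaults), allocates each category's energy equally across its
positive-energy members, converts to grams via energy density and
rescales to the exact target. Because it spreads energy across expensive
and emission-heavy foods rather than optimizing, it lands at roughly 6×
the least-cost diet's cost and emissions, mirroring the qualitative
separation such comparisons show on real data.

**What passing tests do not show:** synthetic nutrient profiles are
smoother and more mutually consistent than a real composition database,
prices have no seasonal co-movement, and the feasibility adjustment
guarantees a feasible diet exists — so passing here demonstrates the
*method* is correct, not that any particular real market admits a $3/day
diet. Numeric reproduction of published tables requires transcribing the
corresponding real food database and loading it via `load_food_database`.

## Numerical choices

- LP: HiGHS dual simplex (`scipy.optimize.linprog`, `method="highs-ds"`),
  deterministic for a fixed system; rows are built in a documented order
  (nutrients sorted by id, then category rows, sugar row, ratio rows,
  budget row) and variables sorted by food id, so alternative optima are
  resolved the same way every run.
- MILP: `scipy.optimize.milp` with `mip_rel_gap = 1e-9`; unbounded foods
  get a 10 kg/day big-M in the linking rows.
- Feasibility reporting tolerance 1e-6 relative; quantities below 1e-7 g
  are snapped to zero; money is rounded to cents and GHG to 0.01 kg only
  in the report layer.
- Degenerate inputs: zero SDs pass through sampling unchanged; a
  wastage fraction ≥ 0.95 is rejected as a data error; zero-energy diets
  cannot be energy-scaled (domain error).

## Problem sizes used in the tests

Unit and property tests run on 2–10-food instances; brute-force oracle
comparisons use 3–5 foods with up to 4 nutrient rows (vertex/subset
enumeration is exponential and is meant as an oracle, not a solver);
the structural checks run the full 16 scenarios on 76-food databases
for three seeds; simulation calibration uses n = 2000 on a one-food
analytic instance and n = 200–400 on small databases. The acceptance
script runs the full pipeline with n = 2000 simulations for the
least-cost and capped least-GHG scenarios.

## Known limitations

- No price co-movement or correlated nutrient errors (a correlation
  hook would slot into `sample_world`).
- No Pareto frontier beyond the budget-capped construction; no integer
  portion sizing.
- The iterative strategy can terminate at a feasible but suboptimal
  point on adversarial instances; use the default MILP when exactness
  matters.
- Recipe semantics ("two different vegetables") are relaxed to aggregate
  grams, as discussed above.
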