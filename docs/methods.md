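# Methods

## The constraint-based model

A stoichiometric network is analyzed at steady state in a chemostat. Fluxes
**J** ∈ ℝᵐ (mmol h⁻¹ gDCW⁻¹) are constrained by

- mass balance of *balanced* compounds: N₀ **J** = 0,
- a one-sided boundary on *unbalanced* (exchange) compounds:
  **b** ≤ Nₑ **J**, where a negative bᵢ permits uptake of species *i* up to
  its magnitude and bᵢ = 0 closes the exchange,
- thermodynamic direction fixing: Jⱼ ≥ 0 for irreversible reactions,
- chemostat growth pinning: J_μ = D (the dilution rate), and
- optionally a fixed non-growth ATP maintenance flux. The default for
  genome-scale work is J_ATPm = 8.39 mmol h⁻¹ gDCW⁻¹ (the aerobic-glucose
  value from the iAF1260 reconstruction); it is configurable per model and
  absent from the toy fixtures.

This collection is the base constraint set K_a. Every analysis below is an
LP (or a short hierarchy of LPs) over K_a or a named extension of it, solved
with HiGHS through `scipy.optimize.linprog`.

"Infinity" bounds are represented by the documented constant 1000 (the usual
convention for constraint-based models), which keeps all LPs bounded.

### Optimum fixing

Minimizing a linear objective f = **c**ᵀ**J** yields f_opt; appending
f_opt = **c**ᵀ**J** gives the reduced set K_b on which secondary objectives
are evaluated. The equality is pinned with a relative slack of 1e-9 to avoid
spurious infeasibility from solver round-off. For objectives with
absolute-value terms the pin is the one-sided bound Σaⱼ|Jⱼ| + **c**ᵀ**J** ≤
f_opt(1 + 1e-9); the lower side holds automatically because f_opt is the
attained minimum, so the pin is exact.

### Yield and turnover objectives

- **Yield.** With growth pinned to D, the biomass yield D/J_up,S is maximal
  exactly when the substrate uptake J_up,S = −(Nₑ**J**)_S is minimal, so
  yield maximization is the linear program J_up,S → min.
- **Minimal turnover rate (MTR).** For a balanced compound i, the turnover
  (production = consumption at steady state) is 0.5 Σⱼ |Jⱼ ν_ij|; its
  minimum over the constraint set is the compound's unavoidable flux at the
  given growth rate.
- **Yield-optimal MTR (YMTR).** The MTR recomputed after pinning J_up,S to
  its minimum. Since the pinned set is a subset of the feasible set,
  YMTR ≥ MTR always; the implementation clamps the ≤1e-9 pinning-slack
  jitter so the inequality holds exactly in reported numbers.

### Absolute values as LPs

Every reaction is split into two nonnegative directional variables,
Jⱼ = vⱼ⁺ − vⱼ⁻. An absolute-value objective term aⱼ|Jⱼ| becomes
aⱼ(vⱼ⁺ + vⱼ⁻), exact under minimization with aⱼ ≥ 0 because simultaneous
positivity of both directions only inflates the objective. Reported
objective values are recomputed from the net fluxes, which collapses any
split-variable slack in unweighted reactions.

### Tolerances

- feasibility: HiGHS defaults (≈1e-9, scaled);
- FVA variability threshold: a reaction "varies" when max − min > 1e-6;
- optimum pinning: 1e-9 relative, as above.

## Enumeration of minimal alternative routes

Given a metabolite of interest (MOI), the producing reactions are found by
sign inspection of the stoichiometry (direction-aware for reversible
reactions). For each, the minimal absolute rate |J| → min is computed, and
FVA decides whether it can vary. All varying producers are then fixed to
their minimal rates (K_Ci); for k = 1, 2, …, k_max every k-subset of the
fixed producers is released and feasibility of the remaining set is tested.
Three structural rules make this a terminating minimal-set enumeration:

1. if releasing nothing is already feasible (a mandatory producer carries
   the load), the empty set dominates everything and no alternatives exist;
2. candidates that are supersets of an already-found feasible set are
   pruned, so the recorded family is exactly the inclusion-minimal one;
3. the search advances to k+1 only while unpruned candidates remain.

The default k_max is 2, which in practice captures all minimal producer
combinations. Per release set the optimal yield D/J_up,S^min under the
released constraints is reported.

### Recursion and carbon-core pruning

Complete substrate→MOI routes are assembled by recursing on the reactants of
each releasing reaction. To avoid descending into cofactor bookkeeping, a
cofactor-equivalence relation over the set Co = {H⁺, phosphate, NH₄, H₂O}
is closed to a fixpoint with union–find:

- a reaction interconverting two single non-cofactor species (up to Co
  members, all unit coefficients) makes them equivalent — ATP → ADP + Pi
  joins ATP and ADP; a 2:1 condensation is *not* such a conversion;
- transitivity (ATP ~ ADP ~ AMP);
- a paired conversion Cᵢ + Cₓ → Cⱼ + C_y with Cₓ ~ C_y makes Cᵢ ~ Cⱼ.

A reactant equivalent to a non-MOI co-product (an ATP/ADP pair riding
through a kinase) is dropped from the recursion — its carbon leaves with
that co-product; a reactant equivalent to the MOI itself is always kept as
the carbon carrier. Note the relation deliberately merges whole conversion
chains (any 1-1 step joins its ends); it answers "does this reactant carry
the carbon core", not "are these compounds interchangeable". For this reason
the recursion's cycle guard operates on metabolite identities, not
equivalence classes — class-level guarding would truncate every linear
pathway whose members the relation has merged. Expanded metabolites are
memoized so common precursors are evaluated once; metabolites already on the
expansion stack are not re-expanded (flagged on the route), and expansions
past `max_depth` (default 12) are flagged truncated rather than dropped.

A route is identified by the union of its released reactions. Its
representative flux vector solves minimal uptake with every expanded level's
non-released varying producers pinned back to their minima; its key
metabolites are the balanced, non-cofactor species with turnover above 1e-6
in that vector. Class tagging by key-metabolite intersection against a
catalog (dihydroxyacetone, Entner–Doudoroff, serine, shikimate,
methylglyoxal, deoxyribonucleotide/acetyl-CoA, murein, CO₂-transfer markers)
is a deliberately simple automated stand-in for expert curation of flux
maps; routes matching nothing are labelled "unclassified".

## Boolean regulatory layer

Rules are one assignment per line, `gene = formula`, with AND/OR/NOT and
parentheses; environment signals are namespaced `env:*`. The gene→gene
dependency graph must be acyclic (verified at parse time), so a single
topological sweep computes the unique Boolean steady state. Knocked-out
factors are clamped OFF with their rules ignored; genes no rule assigns
default ON — an incomplete network restricts only what it reaches, which
keeps its predictions conservative. GPR strings use the same grammar without
NOT.

Off genes translate into reaction blocks through the GPRs: a reaction whose
GPR evaluates false is fixed to zero flux (the additional set K_tf), unless
it appears on a user-supplied exemption list (reactions that must stay
independent of the regulatory model, e.g. after grafting rules written for a
smaller reconstruction onto a larger one). `exemption_candidates` proposes
such a list: blocked reactions that are singly essential for the metabolic
set.

Because K_tf only ever removes solutions, minimal substrate uptake under
K_m ∪ K_tf is ≥ that under K_m alone — predicted yield never increases when
regulation is added. The three-way prediction for a factor-knockout
experiment evaluates minimal uptake on K_m (measured growth and acetate
secretion imposed), K_m ∪ K_tf, and K_m ∪ K_tf,−k with the studied factor
clamped off; infeasible regulated sets are reported as infeasible, never
silently relaxed. The error-variance statistic over an experiment series is
the mean squared residual of observed vs predicted uptake (denominator n by
default, n−1 via `ddof=1`; the choice is exposed because either convention
is defensible), with infeasible predictions excluded pairwise and counted.

Enzymatic-capacity calls from transcript data use a threshold of 7.0 on the
average log2 expression: a gene is available iff it reaches the threshold, a
reaction is capable iff its GPR evaluates true over availability, and a
route is capable iff all reactions active in its flux pattern are. Genes
missing from the table default to unavailable (`assume-off`), switchable.

## Fixture generators

The two hand-built networks are minimal topologies reconstructed from their
documented properties, which are asserted in the test suite rather than
assumed:

- the *branch* network (substrate → essential E1 → inefficient M1 at 2:1 or
  efficient M2 at 1:1 → biomass) realizes the MTR/YMTR contrast;
- the *producer-alternative* network (J1…J8 with J3/J4 and J5/J6/J7
  alternative layers and J8 a sole essential producer) realizes the
  six-route enumeration example.

Seeded random instances are layered substrate→biomass DAGs with a
deterministic backbone (guaranteeing feasibility), random alternative
reactions between adjacent layers, an optional ATP-like cofactor pair whose
regeneration costs backbone carbon, and an optional maintenance reaction
(fixed at 0.05 in these small instances). Fixture analyses run at
D = 0.1 h⁻¹, a typical chemostat dilution rate; all generators are pure
functions of their seed.

What the random fixtures do **not** emulate: genome-scale size (10–12
reactions vs thousands), compartments and transport, realistic cofactor
diversity, and biomass equations with many precursors. Passing oracle tests
therefore demonstrates correctness of the algorithms on networks where
exhaustive enumeration is tractable, not performance or curation fidelity at
genome scale; the problem sizes (100 random networks for the LP/enumeration
oracles, 50 for the Boolean fixpoint oracle) were chosen so exhaustive
reference computation stays exact.

## Numerical and design choices

- Degenerate optima: only optimal objective values are contract-bound; the
  particular optimizer returned is solver-dependent and never asserted.
- FVA jitter on pinned reactions (min marginally above max) is midpointed.
- Producer fixing uses the signed flux attaining the minimal |J|, so
  reversible producers are pinned in their producing direction; values below
  the variability tolerance are snapped to 0.
- Reaction "participation" counts are reported three ways (any nonzero
  coefficient; consumed side including the reverse of reversible reactions;
  consumed side as written) because "appears as a reactant" is ambiguous
  for reversible reactions.
- SBML input is read through cobrapy/libsbml; single-metabolite boundary
  reactions are folded into the b ≤ Nₑ**J** formalism (the objective
  reaction is kept even when it is a one-metabolite sink). The JSON dialect
  round-trips the full in-memory model; the TSV dialect is a human-editable
  subset (bounds beyond reversibility are not encoded).

## Known limitations

- Route enumeration is exponential in the number of alternatives per level
  and the recursion depth; `k_max` and `max_depth` bound the work, with
  truncation flagged. Elementary-mode enumeration is out of scope by
  design — this recursion is the cheaper alternative for one target
  metabolite.
- Class tagging approximates manual flux-map curation and should be treated
  as a screening aid.
- Loopless-FBA, QP/MOMA objectives and flux sampling are not provided.
- Dynamic (time-stepped) regulatory/metabolic simulation is not provided;
  the regulatory layer is evaluated at its Boolean steady state only.
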