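# pyrdetour

Constraint-based analysis of metabolic detours, for planning and
interpreting adaptive-evolution experiments around a metabolic block. Given
a stoichiometric model of an organism growing in a chemostat, the package
answers three questions a strain designer asks before (and after) blocking a
pathway:

1. **Which metabolites are good blockade targets?** The minimal turnover
   rate MTR_i = min 0.5 Σⱼ |Jⱼ ν_ij| of a balanced compound *i* is its
   unavoidable flux at growth rate D; the yield-optimal MTR (YMTR) is the
   same minimum after substrate uptake J_up,S is pinned to its optimum.
   Compounds with high turnover, especially YMTR ≫ MTR, exert the strongest
   selective pressure when blocked.
2. **How can the cell detour around the block?** A hierarchy of LPs
   enumerates every inclusion-minimal combination of alternative reactions
   able to produce a metabolite of interest (fix all varying producers to
   their minimal rates, then release k-subsets until feasibility returns),
   applied recursively along carbon-core reactants to reconstruct complete
   substrate→target routes — without elementary-mode enumeration.
3. **Does transcriptional regulation forbid the detours?** A feedback-free
   Boolean transcription-factor network maps environment signals to gene
   on/off states; off genes block reactions through their gene–protein–
   reaction (GPR) rules, shrinking the solution space (K_m ∪ K_tf). The
   package predicts substrate uptake under factor knockouts and scores
   enzymatic capacity of routes from transcript levels (average log2
   expression ≥ 7.0).

The chemostat constraint set is K_a: N₀J = 0, b ≤ NₑJ, J_μ = D, Jⱼ ≥ 0 for
irreversible reactions, plus an optional fixed maintenance flux (default
J_ATPm = 8.39 mmol h⁻¹ gDCW⁻¹ for genome-scale models). All programs are
solved with HiGHS via scipy; models load from SBML (through cobrapy), a
full-fidelity JSON dialect, or a one-reaction-per-line TSV dialect. See
`docs/methods.md` for the formal treatment.

## Worked example

The built-in producer-alternative fixture has substrate S feeding essential
intermediates, two alternative producers (J3/J4) of a precursor and three
alternative final steps (J5/J6/J7) to the target metabolite MOI:

```sh
$ pyrdetour fixtures write --name figure5 --out figure5.tsv
$ pyrdetour routes -m figure5.tsv --substrate S_e --moi MOI --growth 0.1
route	released	yield	class
1	J3+J5	0.5	unclassified
2	J3+J6	0.5	unclassified
3	J3+J7	0.5	unclassified
4	J4+J5	0.5	unclassified
5	J4+J6	0.5	unclassified
6	J4+J7	0.5	unclassified
```

Exactly the six minimal detours exist, one per choice of precursor producer
× final step; each supports a biomass yield of 0.5 gDCW per mmol substrate
(growth 0.1 h⁻¹ over minimal uptake 0.2 mmol h⁻¹ gDCW⁻¹, since biomass
consumes two substrate-derived units per growth unit):

```sh
$ pyrdetour yield -m figure5.tsv --substrate S_e --growth 0.1
min_uptake	0.2
yield	0.5
$ pyrdetour turnover -m figure5.tsv --metabolite MOI --growth 0.1 \
      --yield-optimal --substrate S_e
mtr	0.1
ymtr	0.1
min_uptake	0.2
```

The MOI's turnover equals the growth demand (0.1): it is essential, so its
MTR is positive and a blockade forces a detour. The same operations are a
Python API:

```python
from pyrdetour import (ConstraintSet, enumerate_routes, figure5_network, ymtr)

model = figure5_network()
k_a = ConstraintSet.k_a(model, growth=0.1)
routes = enumerate_routes(k_a, "S_e", "MOI", k_max=2)
print([sorted(r.released) for r in routes])
# [['J3', 'J5'], ['J3', 'J6'], ['J3', 'J7'],
#  ['J4', 'J5'], ['J4', 'J6'], ['J4', 'J7']]
print(ymtr(k_a, "MOI", "S_e"))
# TurnoverResult(metabolite='MOI', mtr=0.1, ymtr=0.1, minimal_uptake=0.2)
```

For the regulatory layer, a rule file (`gene = formula` over `env:*`
signals, AND/OR/NOT) drives steady-state evaluation, knockout prediction
and reaction blocking:

```sh
$ pyrdetour tfn steady-state --rules rules.txt --env env:o2=1
```

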