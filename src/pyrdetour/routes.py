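"""Enumeration of minimal alternative synthesis routes to a metabolite.

Given a metabolite of interest (MOI) that a mutant can no longer make through
its regular pathway, the question is: which minimal combinations of other
reactions can take over its production, and how do complete substrate→MOI
detours look? The answer is computed without elementary-mode enumeration, by
a hierarchy of LPs:

1. Find every reaction that can produce the MOI, its minimal absolute rate
   ``|J| -> min`` over the constraint set, and whether FVA says it can vary.
2. Fix all varying producers to their minimal rates (constraint set K_Ci);
   jointly this usually starves the MOI and the LP goes infeasible.
3. For k = 1, 2, ... release every k-subset K_r of the fixed producers and
   test feasibility of K_a ∪ K_Ci \\ K_r. Feasible subsets are recorded.
4. Supersets of recorded subsets are pruned, so the recorded family is
   exactly the inclusion-minimal release sets; the search stops at k_max or
   when no unpruned candidate remains.

Complete routes are reconstructed by applying steps 1–4 recursively to the
carbon-core reactants of each releasing reaction, walking back toward the
substrate. Cofactor bookkeeping (ATP/ADP, NAD/NADH, ...) is kept out of the
recursion by an equivalence relation over a small cofactor set Co (default
H+, phosphate, NH4, H2O): two metabolites are equivalent if a reaction
interconverts them up to Co members, transitively closed, including paired
conversions (rule: Ci + Cx -> Cj + Cy with Cx ~ Cy makes Ci ~ Cj). ATP, ADP
and AMP end up in one class, so an ATP/ADP pair in a kinase reaction is
recognized as a cofactor pair and not followed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

from . import lp as _lp
from .lp import (ConstraintSet, Objective, VARIABILITY_TOL, fva, minimize,
                 min_substrate_uptake, turnover_at)
from .model import ModelError, Reaction, StoichiometricModel

#: Cofactors of the default equivalence relation: protons, phosphate,
#: ammonium and water, in cytosolic-compartment naming.
DEFAULT_COFACTORS = frozenset({
    "h", "h_c", "h_e", "h_p",
    "pi", "pi_c", "pi_e", "pi_p", "ho4p",
    "nh4", "nh4_c", "nh4_e", "nh4_p",
    "h2o", "h2o_c", "h2o_e", "h2o_p",
})


@dataclass(frozen=True)
class Producer:
    """One MOI-producing reaction with its minimal rate and FVA verdict."""

    reaction_id: str
    minimal_rate: float          # min |J| over the constraint set (>= 0)
    signed_minimal: float        # the signed flux attaining it (for fixing)
    varies: bool


@dataclass(frozen=True)
class ProducerSet:
    moi: str
    producers: tuple[Producer, ...]

    def varying(self) -> tuple[Producer, ...]:
        return tuple(p for p in self.producers if p.varies)

    def __iter__(self):
        return iter(self.producers)


@dataclass(frozen=True)
class ReleaseSet:
    """A minimal subset of fixed producers whose release restores feasibility."""

    released: frozenset[str]
    feasible_yield: float | None = None

    @property
    def k(self) -> int:
        return len(self.released)


@dataclass(frozen=True)
class Route:
    """A substrate→MOI alternative, identified by its released reactions."""

    moi: str
    substrate: str
    released_per_level: tuple[tuple[str, frozenset[str]], ...]
    released: frozenset[str]
    flux_pattern: dict[str, float] = field(default_factory=dict)
    feasible_yield: float | None = None
    key_metabolites: frozenset[str] = frozenset()
    class_tag: str | None = None
    truncated: bool = False
    cycle_guarded: bool = False


class CofactorEquivalence:
    """Union-find closure of the cofactor equivalence relation (a partition)."""

    def __init__(self, members, cofactors):
        self.cofactors = frozenset(cofactors)
        self._parent = {m: m for m in members}

    def _find(self, m):
        p = self._parent
        root = m
        while p[root] != root:
            root = p[root]
        while p[m] != root:  # path compression
            p[m], m = root, p[m]
        return root

    def union(self, a, b) -> bool:
        ra, rb = self._find(a), self._find(b)
        if ra == rb:
            return False
        if rb < ra:  # deterministic representative: lexicographic minimum
            ra, rb = rb, ra
        self._parent[rb] = ra
        return True

    def equivalent(self, a, b) -> bool:
        if a not in self._parent or b not in self._parent:
            return a == b
        return self._find(a) == self._find(b)

    def class_of(self, m) -> str:
        return self._find(m) if m in self._parent else m

    def classes(self) -> list[frozenset[str]]:
        by_root: dict[str, set[str]] = {}
        for m in self._parent:
            by_root.setdefault(self._find(m), set()).add(m)
        return sorted((frozenset(v) for v in by_root.values()),
                      key=lambda s: min(s))


def equivalence_closure(model: StoichiometricModel,
                        cofactors=DEFAULT_COFACTORS) -> CofactorEquivalence:
    """Fixpoint of the cofactor equivalence rules over the model.

    Missing cofactor ids are ignored with a warning; the rules are applied
    until no class merges, so the result is a true partition.
    """
    met_ids = {m.id for m in model.metabolites}
    co = frozenset(cofactors) & met_ids
    missing = frozenset(cofactors) - met_ids
    if missing and not co:
        warnings.warn(
            f"no declared cofactor is present in the model "
            f"(missing e.g. {sorted(missing)[:4]})", stacklevel=2)
    eq = CofactorEquivalence(met_ids, co)

    # precompute non-cofactor sides once; directionality is irrelevant for a
    # symmetric relation. Only unit-coefficient species take part: a 2:1
    # condensation is not a Ci -> Cj conversion pattern.
    sides = []
    for r in model.reactions:
        lhs = [m for m, c in r.stoichiometry.items()
               if c == -1 and m not in co]
        rhs = [m for m, c in r.stoichiometry.items()
               if c == 1 and m not in co]
        n_lhs = sum(1 for c in r.stoichiometry.values() if c < 0)
        n_rhs = sum(1 for c in r.stoichiometry.values() if c > 0)
        lhs_extra = n_lhs - sum(1 for m, c in r.stoichiometry.items()
                                if c < 0 and m in co)
        rhs_extra = n_rhs - sum(1 for m, c in r.stoichiometry.items()
                                if c > 0 and m in co)
        sides.append((lhs, rhs, lhs_extra, rhs_extra))

    changed = True
    while changed:
        changed = False
        for lhs, rhs, n_l, n_r in sides:
            if len(lhs) != n_l or len(rhs) != n_r:
                continue  # a non-unit-coefficient species blocks the pattern
            if len(lhs) == 1 and len(rhs) == 1:
                # Ci (+ Co) -> Cj (+ Co)
                changed |= eq.union(lhs[0], rhs[0])
            elif len(lhs) == 2 and len(rhs) == 2:
                # Ci + Cx -> Cj + Cy with Cx ~ Cy  =>  Ci ~ Cj
                for x in lhs:
                    for y in rhs:
                        if eq.equivalent(x, y):
                            other_l = next(m for m in lhs if m != x)
                            other_r = next(m for m in rhs if m != y)
                            changed |= eq.union(other_l, other_r)
    return eq


def carbon_core_reactants(reaction: Reaction, moi: str,
                          equivalence: CofactorEquivalence) -> frozenset[str]:
    """Reactants of a MOI-producing reaction that carry the MOI's carbon core.

    Cofactor-set members are dropped outright. A reactant that is equivalent
    to a non-MOI co-product (an ATP/ADP-style pair riding along) is dropped
    too — its carbon ends up in that co-product, not in the MOI. A reactant
    equivalent to the MOI itself is always kept: it *is* the carbon carrier.
    """
    coef = reaction.stoichiometry.get(moi, 0.0)
    if coef > 0:
        subs = [m for m, c in reaction.stoichiometry.items() if c < 0]
        prods = [m for m, c in reaction.stoichiometry.items() if c > 0]
    elif coef < 0 and reaction.reversible:
        subs = [m for m, c in reaction.stoichiometry.items() if c > 0]
        prods = [m for m, c in reaction.stoichiometry.items() if c < 0]
    else:
        raise ModelError(f"reaction {reaction.id!r} does not produce {moi!r}")

    co = equivalence.cofactors
    candidates = [m for m in subs if m not in co]
    carriers = {m for m in candidates if equivalence.equivalent(m, moi)}
    co_products = [p for p in prods if p != moi and p not in co]
    for p in co_products:
        for m in list(candidates):
            if m in carriers:
                continue
            if equivalence.equivalent(m, p):
                candidates.remove(m)  # paired conversion: not a carbon source
                break
    return frozenset(candidates)


# ---------------------------------------------------------------------------
# Steps 1-4
# ---------------------------------------------------------------------------

def find_producers(cset: ConstraintSet, moi: str) -> ProducerSet:
    """Step 1: producing reactions with minimal |rate| and FVA varies flag."""
    model = cset.model
    met = model.metabolite(moi)
    if not met.balanced:
        raise ModelError(f"MOI {moi!r} must be a balanced metabolite")
    prod_ids = []
    for r in model.reactions:
        c = r.stoichiometry.get(moi, 0.0)
        if (c > 0 and r.upper_bound > 0) or (c < 0 and r.lower_bound < 0):
            prod_ids.append(r.id)
    prod_ids.sort()
    if not prod_ids:
        return ProducerSet(moi=moi, producers=())
    variability = fva(cset, prod_ids)
    producers = []
    for rxn_id in prod_ids:
        res = minimize(cset, Objective(absolute={rxn_id: 1.0}))
        if not res.optimal:
            raise ModelError(f"constraint set {cset.name!r} is {res.status}")
        rate = max(res.objective_value, 0.0)
        producers.append(Producer(
            reaction_id=rxn_id,
            minimal_rate=rate,
            signed_minimal=res.fluxes.get(rxn_id, 0.0),
            varies=variability.varies(rxn_id),
        ))
    return ProducerSet(moi=moi, producers=tuple(producers))


def producer_fixing(producers: ProducerSet) -> dict[str, float]:
    """K_Ci: the varying producers pinned to their minimal (signed) rates."""
    fixes = {}
    for p in producers.varying():
        value = p.signed_minimal if abs(p.signed_minimal) > VARIABILITY_TOL else 0.0
        fixes[p.reaction_id] = value
    return fixes


def enumerate_release_sets(cset: ConstraintSet, producers: ProducerSet,
                           k_max: int = 2,
                           substrate: str | None = None) -> list[ReleaseSet]:
    """Steps 2-4: all inclusion-minimal feasible release sets up to k_max.

    With ``substrate`` given (and growth fixed), each feasible release set
    additionally carries the optimal yield D / J_up,S^min it permits.
    """
    if k_max < 1:
        raise ModelError("k_max must be >= 1")
    fixes = producer_fixing(producers)
    varying = sorted(fixes)
    if not varying:
        return []

    def solve_with(released: frozenset[str]):
        kept = {r: v for r, v in fixes.items() if r not in released}
        sub = cset.with_fixed_fluxes(kept)
        if substrate is not None and cset.fixed_growth is not None:
            return min_substrate_uptake(sub, substrate)
        return minimize(sub, Objective())

    # k = 0 first: if pinning every varying producer is already feasible
    # (a mandatory producer carries the load), nothing needs releasing and
    # the empty set dominates every candidate
    if solve_with(frozenset()).optimal:
        return []

    found: list[ReleaseSet] = []
    for k in range(1, min(k_max, len(varying)) + 1):
        candidates = [
            frozenset(c) for c in itertools.combinations(varying, k)
            if not any(f.released <= frozenset(c) for f in found)
        ]
        if not candidates:
            break  # step 4: nothing feasible remains outside found sets
        for cand in candidates:
            res = solve_with(cand)
            if res.optimal:
                y = None
                if substrate is not None and cset.fixed_growth is not None:
                    up = res.objective_value
                    y = cset.fixed_growth / up if up > VARIABILITY_TOL else None
                found.append(ReleaseSet(released=cand, feasible_yield=y))
    found.sort(key=lambda rs: (rs.k, sorted(rs.released)))
    return found


# ---------------------------------------------------------------------------
# Recursive route reconstruction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Partial:
    levels: tuple[tuple[str, frozenset[str]], ...] = ()
    truncated: bool = False
    cycle: bool = False

    def merged(self, others) -> "_Partial":
        levels = dict(self.levels)
        truncated, cycle = self.truncated, self.cycle
        for o in others:
            for met, rel in o.levels:
                levels[met] = levels.get(met, frozenset()) | rel
            truncated |= o.truncated
            cycle |= o.cycle
        return _Partial(tuple(sorted(levels.items())), truncated, cycle)


def enumerate_routes(cset: ConstraintSet, substrate: str, moi: str,
                     k_max: int = 2, max_depth: int = 12,
                     cofactors=DEFAULT_COFACTORS,
                     equivalence: CofactorEquivalence | None = None) -> list[Route]:
    """Recursively reconstruct all minimal substrate→MOI alternatives.

    The enumeration of steps 1-4 is applied first to the MOI, then to the
    carbon-core reactants of each releasing reaction, and so on until the
    (unbalanced, open) substrate is reached. Already-expanded precursors are
    memoized; a metabolite whose equivalence class is on the current
    expansion stack is not re-expanded (cycle guard, flagged on the route);
    expansions past ``max_depth`` are flagged truncated, not dropped.

    Default ``k_max=2``: in practice all minimal producer combinations are
    found within pairs.
    """
    model = cset.model
    sub_met = model.metabolite(substrate)
    if sub_met.balanced:
        raise ModelError(f"substrate {substrate!r} must be unbalanced")
    model.metabolite(moi)

    eq = equivalence or equivalence_closure(model, cofactors)
    producer_cache: dict[str, ProducerSet] = {}
    memo: dict[str, list[_Partial]] = {}

    def producers_of(met: str) -> ProducerSet:
        if met not in producer_cache:
            producer_cache[met] = find_producers(cset, met)
        return producer_cache[met]

    def expand(met: str, depth: int, stack: frozenset[str]) -> list[_Partial]:
        if met == substrate or not model.metabolite(met).balanced:
            return [_Partial()]
        if met in eq.cofactors:
            return [_Partial()]
        # cycle guard keyed on the metabolite itself: the equivalence relation
        # deliberately merges whole conversion chains (any 1-1 reaction joins
        # its ends), so class-level guarding would truncate linear pathways
        if met in stack:
            return [_Partial(cycle=True)]
        if met in memo:
            return memo[met]
        if depth > max_depth:
            return [_Partial(truncated=True)]

        producers = producers_of(met)
        rsets = enumerate_release_sets(cset, producers, k_max)
        if rsets:
            alternatives = [(rs.released, rs.released) for rs in rsets]
        else:
            mandatory = frozenset(
                p.reaction_id for p in producers
                if p.minimal_rate > VARIABILITY_TOL
            )
            alternatives = [(frozenset(), mandatory)]

        stack2 = stack | {met}
        results: list[_Partial] = []
        for released, last_rxns in alternatives:
            precursors: set[str] = set()
            for rxn_id in sorted(last_rxns):
                precursors |= carbon_core_reactants(model.reaction(rxn_id), met, eq)
            here = _Partial(levels=((met, released),) if released else ())
            branches = [expand(p, depth + 1, stack2) for p in sorted(precursors)]
            for combo in itertools.product(*branches):
                results.append(here.merged(combo))
        # deduplicate identical partials
        uniq = sorted(set(results), key=lambda p: (p.levels, p.truncated, p.cycle))
        memo[met] = uniq
        return uniq

    partials = expand(moi, 0, frozenset())

    routes: list[Route] = []
    seen: set[frozenset[str]] = set()
    for part in sorted(set(partials), key=lambda p: tuple(sorted(
            r for _, rel in p.levels for r in rel))):
        union: frozenset[str] = frozenset()
        for _, rel in part.levels:
            union |= rel
        if union in seen:
            continue
        seen.add(union)
        # representative flux pattern: base set + every expanded level's
        # non-released varying producers pinned back to their minima
        fixes: dict[str, float] = {}
        for met, released in part.levels:
            for rxn_id, val in producer_fixing(producers_of(met)).items():
                if rxn_id not in union:
                    fixes[rxn_id] = val
        pattern: dict[str, float] = {}
        route_yield = None
        if cset.fixed_growth is not None:
            res = min_substrate_uptake(cset.with_fixed_fluxes(fixes), substrate)
            if res.optimal:
                pattern = res.fluxes
                if res.objective_value > VARIABILITY_TOL:
                    route_yield = cset.fixed_growth / res.objective_value
        keys = frozenset(
            m.id for m in model.metabolites
            if m.balanced and m.id not in eq.cofactors and pattern
            and turnover_at(model, m.id, pattern) > VARIABILITY_TOL
        )
        routes.append(Route(
            moi=moi, substrate=substrate,
            released_per_level=part.levels, released=union,
            flux_pattern=pattern, feasible_yield=route_yield,
            key_metabolites=keys,
            truncated=part.truncated, cycle_guarded=part.cycle,
        ))
    routes.sort(key=lambda r: tuple(sorted(r.released)))
    return routes


# ---------------------------------------------------------------------------
# Key-metabolite class tagging
# ---------------------------------------------------------------------------

#: Best-effort catalog of the alternative-pathway classes observed for
#: glycerol→pyruvate detours, keyed by their characteristic metabolites.
#: Tagging by key-metabolite intersection is an automated approximation of a
#: manual curation step and is labelled as such.
DEFAULT_KEY_METABOLITE_CATALOG: dict[str, frozenset[str]] = {
    "dihydroxyacetone-path": frozenset({"dha", "dha_c"}),
    "entner-doudoroff-path": frozenset({"2ddg6p", "2ddg6p_c", "6pgc", "6pgc_c"}),
    "serine-path": frozenset({"ser-L", "ser__L_c", "ser-L_c", "ser-D", "ser__D_c",
                              "3php", "3php_c", "pser", "pser__L_c"}),
    "shikimate-path": frozenset({"chor", "chor_c", "skm", "skm_c", "ichor",
                                 "ichor_c", "anth", "anth_c"}),
    "methylglyoxal-path": frozenset({"mthgxl", "mthgxl_c", "lac-D", "lac__D_c"}),
    "accoa-path": frozenset({"2dr1p", "2dr1p_c", "drib", "drib_c",
                             "2dr5p", "2dr5p_c"}),
    "murein-path": frozenset({"uacgam", "uacgam_c", "acgam6p", "acgam6p_c",
                              "anhgm", "anhgm_c"}),
    "co2-fixation-path": frozenset({"co2", "co2_c", "oaa", "oaa_c"}),
}


def classify_routes(routes: list[Route],
                    key_metabolite_catalog: dict[str, frozenset[str]] | None = None
                    ) -> list[Route]:
    """Tag each route with the first catalog class its key metabolites hit."""
    catalog = key_metabolite_catalog or DEFAULT_KEY_METABOLITE_CATALOG
    out = []
    for route in routes:
        tag = "unclassified"
        for name, keys in catalog.items():
            if keys & route.key_metabolites:
                tag = name
                break
        out.append(replace(route, class_tag=tag))
    return out
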