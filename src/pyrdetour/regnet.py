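"""Boolean transcription-factor network layered on the metabolic model.

The regulatory model is a feedback-free set of Boolean rules mapping
environment signals (substrate presence, oxygen, ...) and regulator states to
target-gene on/off states. Because the dependency graph is acyclic, a unique
Boolean steady state exists and is obtained by a single topological sweep.
Off genes are translated through the GPR associations into blocked reactions
(the additional constraint set K_tf), shrinking the metabolic solution space:
predicted biomass yield can therefore never increase when the regulatory
constraints are added.

Rule-file dialect: one assignment per line, ``gene = formula`` with
AND/OR/NOT and parentheses; environment signals are namespaced ``env:*``;
``#`` starts a comment. Genes never assigned by a rule default to ON — an
incomplete network restricts only what it reaches, keeping predictions
conservative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from . import gpr as _gpr
from .lp import ConstraintSet, min_substrate_uptake, LPResult
from .model import GeneStateMap, ModelError, StoichiometricModel

ENV_PREFIX = "env:"


class RuleError(ValueError):
    """Malformed or cyclic rule file."""


@dataclass(frozen=True)
class BooleanNetwork:
    """Acyclic Boolean rules: target gene -> formula AST."""

    rules: dict[str, object]           # gene id -> gpr.Node
    signals: frozenset[str]            # declared environment signal ids

    def __post_init__(self):
        cycle = find_cycle(self.rules)
        if cycle:
            raise RuleError("regulatory rules contain a feedback loop: "
                            + " -> ".join(cycle))

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.rules)

    def regulators_of(self, gene: str) -> frozenset[str]:
        node = self.rules.get(gene)
        return frozenset(v for v in _gpr.variables(node)
                         if not v.startswith(ENV_PREFIX))


@dataclass(frozen=True)
class ExpressionTable:
    """Average log2 expression per gene with an availability threshold."""

    values: dict[str, float]
    threshold: float = 7.0

    def available(self, gene: str, missing: str = "assume-off") -> bool:
        if gene not in self.values:
            if missing == "assume-on":
                return True
            if missing == "assume-off":
                return False
            raise ModelError(f"bad missing-gene policy {missing!r}")
        return self.values[gene] >= self.threshold


def find_cycle(rules: dict[str, object]) -> list[str] | None:
    g = nx.DiGraph()
    g.add_nodes_from(rules)
    for target, node in rules.items():
        for v in _gpr.variables(node):
            if not v.startswith(ENV_PREFIX):
                g.add_edge(v, target)
    try:
        cyc = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return None
    return [e[0] for e in cyc] + [cyc[-1][1]]


def parse_rules(path_or_text) -> BooleanNetwork:
    """Parse a rule file (``gene = formula`` lines) into a network.

    Accepts a path or raw text. Acyclicity is verified here, so later
    steady-state evaluation cannot loop.
    """
    text = str(path_or_text)
    if isinstance(path_or_text, Path):
        text = path_or_text.read_text()
    elif text and "\n" not in text and "=" not in text and Path(text).is_file():
        text = Path(text).read_text()
    rules: dict[str, object] = {}
    signals: set[str] = set()
    for line_no, raw in enumerate(str(text).splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise RuleError(f"line {line_no}: expected 'gene = formula', got {raw!r}")
        target, formula = line.split("=", 1)
        target = target.strip()
        if not target:
            raise RuleError(f"line {line_no}: empty rule target")
        if target in rules:
            raise RuleError(f"line {line_no}: duplicate rule for {target!r}")
        try:
            node = _gpr.parse_formula(formula, allow_not=True)
        except _gpr.GPRSyntaxError as exc:
            raise RuleError(f"line {line_no}: {exc}") from exc
        if node is None:
            raise RuleError(f"line {line_no}: empty formula for {target!r}")
        rules[target] = node
        signals |= {v for v in _gpr.variables(node) if v.startswith(ENV_PREFIX)}
    return BooleanNetwork(rules=rules, signals=frozenset(signals))


def steady_state(network: BooleanNetwork, env: dict[str, bool],
                 tf_knockouts: set[str] = frozenset()) -> GeneStateMap:
    """The unique Boolean steady state of the acyclic network.

    Environment signals missing from ``env`` default to False with a
    warning. Knocked-out factors are clamped OFF and their rules ignored;
    everything downstream is re-evaluated. Genes not assigned by any rule
    default ON (handled by :class:`GeneStateMap`).
    """
    missing = {s for s in network.signals if s not in env}
    if missing:
        warnings.warn(f"environment signals defaulting to False: {sorted(missing)}",
                      stacklevel=2)

    g = nx.DiGraph()
    g.add_nodes_from(network.rules)
    for target in network.rules:
        for reg in network.regulators_of(target):
            if reg in network.rules:
                g.add_edge(reg, target)
    order = list(nx.topological_sort(g))

    state = GeneStateMap()
    for ko in tf_knockouts:
        state[ko] = False

    def lookup(name: str) -> bool:
        if name.startswith(ENV_PREFIX):
            return bool(env.get(name, False))
        return state[name]  # computed, knocked out, or default ON

    for gene in order:
        if gene in tf_knockouts:
            continue
        state[gene] = _gpr.evaluate(network.rules[gene], lookup)
    return state


def tfn_constraints(model: StoichiometricModel, states: GeneStateMap,
                    exemptions: set[str] = frozenset(),
                    name: str = "K_tf") -> ConstraintSet:
    """Translate off-genes into blocked reactions (the set K_tf only).

    A reaction whose GPR evaluates false under ``states`` is fixed to zero
    flux, unless listed in ``exemptions`` (reactions that became essential
    when the regulatory model was grafted onto a larger metabolic
    reconstruction are made independent of it). The returned set carries only
    the additional constraints; union it with a metabolic set to use it.
    """
    for rxn_id in exemptions:
        model.reaction(rxn_id)
    blocked: dict[str, float] = {}
    for r in model.reactions:
        if not r.gpr or r.id in exemptions:
            continue
        if not _gpr.evaluate_gpr(r.gpr, states):
            blocked[r.id] = 0.0
    return ConstraintSet(model=model, name=name,
                         apply_maintenance=False).with_fixed_fluxes(blocked)


def exemption_candidates(model: StoichiometricModel, k_m: ConstraintSet,
                         k_tf: ConstraintSet) -> frozenset[str]:
    """Reactions essential under K_m but blocked by K_tf.

    Helper for building an exemption list: a reaction blocked by the
    regulatory layer whose single removal already makes the metabolic set
    infeasible is a graft artifact candidate.
    """
    from .lp import Objective, minimize
    blocked = [rxn_id for rxn_id, v in k_tf.fixed_fluxes if v == 0.0]
    out = set()
    for rxn_id in blocked:
        res = minimize(k_m.with_fixed_flux(rxn_id, 0.0), Objective())
        if not res.optimal:
            out.add(rxn_id)
    return frozenset(out)


@dataclass(frozen=True)
class UptakeTriplet:
    """Minimal-uptake predictions under K_m, K_m∪K_tf and K_m∪K_tf,-k."""

    metabolic: LPResult
    regulated: LPResult
    knockout: LPResult

    def values(self) -> tuple[float | None, float | None, float | None]:
        return tuple(r.objective_value if r.optimal else None
                     for r in (self.metabolic, self.regulated, self.knockout))


def predict_uptake_triplet(model: StoichiometricModel, measured_growth: float,
                           measured_acetate_secretion: float, substrate: str,
                           network: BooleanNetwork, env: dict[str, bool],
                           tf_knockout: set[str] = frozenset(),
                           acetate: str = "ac_e",
                           exemptions: set[str] = frozenset()) -> UptakeTriplet:
    """Three-way substrate-uptake prediction for a TF-knockout experiment.

    K_m is the chemostat set with the measured growth rate and the measured
    acetate secretion imposed. K_tf comes from the regulatory steady state
    under the experiment's environment signals; K_tf,-k is the same with the
    studied factor clamped off. Each prediction minimizes substrate uptake;
    an infeasible regulated set is reported as such, never silently relaxed.
    """
    if measured_growth < 0 or measured_acetate_secretion < 0:
        raise ModelError("measured rates must be nonnegative")
    ac = model.metabolite(acetate)
    if ac.balanced:
        raise ModelError(f"acetate species {acetate!r} must be unbalanced")
    ac_coeffs = {r.id: r.stoichiometry[acetate]
                 for r in model.reactions if acetate in r.stoichiometry}
    k_m = (ConstraintSet.k_a(model, growth=measured_growth, name="K_m")
           .with_constraint(ac_coeffs, "==", measured_acetate_secretion))

    base = min_substrate_uptake(k_m, substrate)
    if not base.optimal:
        raise ModelError(
            f"K_m is {base.status}: measurements inconsistent with the model")

    s_wt = steady_state(network, env)
    s_ko = steady_state(network, env, tf_knockouts=set(tf_knockout))
    k_tf = tfn_constraints(model, s_wt, exemptions)
    k_tf_ko = tfn_constraints(model, s_ko, exemptions, name="K_tf,-k")

    reg = min_substrate_uptake(k_m.union(k_tf, name="K_m∪K_tf"), substrate)
    ko = min_substrate_uptake(k_m.union(k_tf_ko, name="K_m∪K_tf,-k"), substrate)
    return UptakeTriplet(metabolic=base, regulated=reg, knockout=ko)


def error_variance(observed, predicted, ddof: int = 0) -> tuple[float, int]:
    """Mean squared residual of observed vs predicted rates.

    Pairs whose prediction is None/NaN (infeasible) are excluded; the count
    of exclusions is returned alongside. ``ddof=1`` gives the n-1 estimator.
    """
    observed = list(observed)
    predicted = list(predicted)
    if len(observed) != len(predicted):
        raise ModelError("observed and predicted must have equal length")
    pairs = [(o, p) for o, p in zip(observed, predicted)
             if p is not None and p == p]
    excluded = len(observed) - len(pairs)
    if len(pairs) - ddof <= 0:
        raise ModelError("not enough feasible pairs for the requested ddof")
    ss = sum((o - p) ** 2 for o, p in pairs)
    return ss / (len(pairs) - ddof), excluded


def enzymatic_capacity(model: StoichiometricModel, reactions,
                       expression: ExpressionTable,
                       missing: str = "assume-off") -> dict[str, bool]:
    """Per-reaction capability verdicts from transcript levels.

    A gene is available iff its average log2 expression reaches the
    threshold; a reaction is capable iff its GPR evaluates true over the
    availability map (no GPR = capable). ``reactions`` may be reaction ids or
    :class:`~pyrdetour.routes.Route` objects — a route contributes the
    reactions active in its flux pattern (or its released reactions), and
    the whole-route verdict is the AND over them.
    """
    warned = False

    def avail(gene: str) -> bool:
        nonlocal warned
        if gene not in expression.values and not warned:
            warnings.warn(f"gene {gene!r} missing from expression table "
                          f"(policy {missing})", stacklevel=2)
            warned = True
        return expression.available(gene, missing)

    def reaction_capable(rxn_id: str) -> bool:
        r = model.reaction(rxn_id)
        if not r.gpr:
            return True
        node = _gpr.parse_formula(r.gpr, allow_not=False)
        return _gpr.evaluate(node, avail)

    verdicts: dict[str, bool] = {}
    for item in reactions:
        if isinstance(item, str):
            verdicts[item] = reaction_capable(item)
        else:  # Route
            active = [rid for rid, v in item.flux_pattern.items()
                      if abs(v) > 1e-6] or sorted(item.released)
            verdicts[f"route:{'+'.join(sorted(item.released)) or item.moi}"] = all(
                reaction_capable(rid) for rid in active)
    return verdicts
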