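"""Independent reference implementations used as test oracles.

Each oracle deliberately avoids the code path it checks: the dense-LP
reference and the sign-pattern turnover minimum are built directly from the
model's stoichiometric matrices with plain scipy calls (no variable
splitting), the release-set search enumerates subsets exhaustively, and the
Boolean fixpoint search scans the full truth table.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog

from pyrdetour import gpr as _gpr
from pyrdetour.lp import Objective, minimize
from pyrdetour.model import INF


def _dense_parts(model, growth):
    """Constraint matrices straight from N0/Ne, unsplit variables."""
    n0, ne, bal, unb = model.stoichiometric_matrices()
    n0 = n0.toarray()
    ne = ne.toarray()
    n = len(model.reactions)
    rxn_col = {r.id: j for j, r in enumerate(model.reactions)}

    a_eq = [n0] if len(bal) else []
    b_eq = [np.zeros(len(bal))] if len(bal) else []
    a_ub, b_ub = [], []
    for i, met in enumerate(unb):
        b = model.boundary.get(met, -INF)
        if b > -INF:
            a_ub.append(-ne[i])          # Ne J >= b  ->  -Ne J <= -b
            b_ub.append(-b)
    def fix(rxn_id, value):
        row = np.zeros(n)
        row[rxn_col[rxn_id]] = 1.0
        a_eq.append(row.reshape(1, -1))
        b_eq.append(np.array([value]))
    if growth is not None:
        fix(model.biomass_reaction, growth)
    if model.maintenance_reaction is not None:
        fix(model.maintenance_reaction, model.maintenance_flux)
    A_eq = np.vstack(a_eq) if a_eq else None
    B_eq = np.concatenate(b_eq) if b_eq else None
    A_ub = np.vstack(a_ub) if a_ub else None
    B_ub = np.asarray(b_ub) if a_ub else None
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    return rxn_col, A_eq, B_eq, A_ub, B_ub, bounds


def dense_lp_min(model, growth, objective: dict[str, float]):
    """Reference minimum of a linear objective c^T J; None if infeasible."""
    rxn_col, A_eq, B_eq, A_ub, B_ub, bounds = _dense_parts(model, growth)
    c = np.zeros(len(model.reactions))
    for rxn_id, v in objective.items():
        c[rxn_col[rxn_id]] += v
    res = linprog(c, A_ub=A_ub, b_ub=B_ub, A_eq=A_eq, b_eq=B_eq,
                  bounds=bounds, method="highs")
    if res.status == 2:
        return None
    assert res.status == 0, res.message
    return float(res.fun)


def sign_pattern_mtr(model, growth, metabolite):
    """Brute-force MTR: minimize over every sign pattern of the reversible
    reactions touching the metabolite, each pattern a plain linear LP."""
    rxn_col, A_eq, B_eq, A_ub, B_ub, bounds = _dense_parts(model, growth)
    touching = [(r.id, r.stoichiometry[metabolite])
                for r in model.reactions if metabolite in r.stoichiometry]
    reversible = [r.id for r in model.reactions
                  if r.lower_bound < 0 and r.upper_bound > 0]
    best = None
    for signs in itertools.product((1.0, -1.0), repeat=len(reversible)):
        sign_of = dict(zip(reversible, signs))
        pat_bounds = list(bounds)
        for rxn_id, s in sign_of.items():
            j = rxn_col[rxn_id]
            lo, hi = pat_bounds[j]
            pat_bounds[j] = (max(lo, 0.0), hi) if s > 0 else (lo, min(hi, 0.0))
        c = np.zeros(len(bounds))
        for rxn_id, nu in touching:
            c[rxn_col[rxn_id]] += 0.5 * abs(nu) * sign_of.get(rxn_id, 1.0)
        res = linprog(c, A_ub=A_ub, b_ub=B_ub, A_eq=A_eq, b_eq=B_eq,
                      bounds=pat_bounds, method="highs")
        if res.status == 0:
            val = float(res.fun)
            best = val if best is None else min(best, val)
    return best


def exhaustive_release_sets(cset, fixes: dict[str, float]):
    """All inclusion-minimal feasible release subsets, by full subset scan."""
    varying = sorted(fixes)
    feasible = []
    for k in range(0, len(varying) + 1):
        for combo in itertools.combinations(varying, k):
            released = frozenset(combo)
            kept = {r: v for r, v in fixes.items() if r not in released}
            res = minimize(cset.with_fixed_fluxes(kept), Objective())
            if res.optimal:
                feasible.append(released)
    minimal = [s for s in feasible
               if not any(t < s for t in feasible)]
    # releasing nothing being feasible means no alternative is needed
    if frozenset() in minimal:
        return []
    return sorted(minimal, key=lambda s: (len(s), sorted(s)))


def truth_table_fixpoints(network, env, knockouts=frozenset()):
    """All Boolean fixpoints of the rule system by exhaustive enumeration."""
    targets = sorted(network.rules)
    fixpoints = []
    for bits in itertools.product((False, True), repeat=len(targets)):
        state = dict(zip(targets, bits))
        if any(state.get(ko, False) for ko in knockouts):
            continue  # avoid double-counting clamped patterns
        for ko in knockouts:
            state[ko] = False

        def lookup(name):
            if name.startswith("env:"):
                return bool(env.get(name, False))
            return state.get(name, True)  # unregulated genes default ON

        ok = True
        for g in targets:
            expected = False if g in knockouts else _gpr.evaluate(
                network.rules[g], lookup)
            if state[g] != expected:
                ok = False
                break
        if ok:
            fixpoints.append(dict(state))
    return fixpoints
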