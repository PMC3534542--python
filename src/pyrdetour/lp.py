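"""The hierarchy of linear programs over a constraint set.

A :class:`ConstraintSet` collects the chemostat constraints

    N0 J = 0,   b <= Ne J,   J_mu = D,   bounds / thermodynamic signs,

optionally the fixed maintenance flux, plus any fixed fluxes and extra linear
constraints layered on top (the named sets K_a, K_b, K_Ci, K_m, K_tf of the
analysis are all instances). Objectives may contain absolute-value terms
``sum_j a_j |J_j|``; these are linearized exactly by splitting every reaction
into two nonnegative directional variables, so the minimal turnover rate

    MTR_i = min 0.5 * sum_j |J_j nu_ij|

is an ordinary LP. All programs are solved with HiGHS via scipy.

Built on top of the generic solver:

- :func:`min_substrate_uptake` — yield maximization in a chemostat (growth is
  fixed to the dilution rate, so maximal yield = minimal uptake);
- :func:`fva` — flux variability analysis (per-reaction min/max flux);
- :func:`mtr` / :func:`ymtr` — minimal turnover rate of a balanced
  metabolite, and the same after pinning substrate uptake to its minimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import INF, ModelError, StoichiometricModel

#: Variability below this is treated as "cannot vary" (FVA flag).
VARIABILITY_TOL = 1e-6
#: Relative slack used when pinning an attained optimum.
PIN_TOL = 1e-9
#: Post-hoc feasibility/consistency tolerance on returned flux vectors.
FEAS_TOL = 1e-6


class SolverError(RuntimeError):
    """The LP backend failed for a reason other than infeasible/unbounded."""


@dataclass(frozen=True)
class Objective:
    """Linear-plus-absolute objective  sum c_j J_j + sum a_j |J_j|.

    ``absolute`` coefficients must be nonnegative (the split-variable
    linearization is exact only for minimization of nonnegative weights).
    """

    linear: dict[str, float] = field(default_factory=dict)
    absolute: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if any(a < 0 for a in self.absolute.values()):
            raise ValueError("absolute-value objective weights must be >= 0")

    def value_at(self, fluxes: dict[str, float]) -> float:
        return (sum(c * fluxes.get(r, 0.0) for r, c in self.linear.items())
                + sum(a * abs(fluxes.get(r, 0.0)) for r, a in self.absolute.items()))


@dataclass(frozen=True)
class LinearConstraint:
    """``sum coeffs_j J_j  (sense)  rhs`` with sense in {'==', '<=', '>='}."""

    coeffs: tuple[tuple[str, float], ...]
    sense: str
    rhs: float

    def __post_init__(self):
        if self.sense not in ("==", "<=", ">="):
            raise ValueError(f"bad sense {self.sense!r}")

    @staticmethod
    def make(coeffs: dict[str, float], sense: str, rhs: float) -> "LinearConstraint":
        return LinearConstraint(tuple(sorted(coeffs.items())), sense, float(rhs))


@dataclass(frozen=True)
class AbsUpperBound:
    """``sum a_j |J_j| + sum c_j J_j <= rhs`` (used to pin abs optima)."""

    abs_coeffs: tuple[tuple[str, float], ...]
    linear_coeffs: tuple[tuple[str, float], ...]
    rhs: float


@dataclass(frozen=True)
class ConstraintSet:
    """A named constraint set over a stoichiometric model.

    Immutable; the ``with_*`` methods return extended copies, mirroring how
    the analysis builds K_b from K_a, K_m from K_a, K_m ∪ K_tf from K_m, ...
    """

    model: StoichiometricModel
    name: str = "K_a"
    fixed_growth: float | None = None
    fixed_fluxes: tuple[tuple[str, float], ...] = ()
    extra: tuple[LinearConstraint, ...] = ()
    abs_upper: tuple[AbsUpperBound, ...] = ()
    apply_maintenance: bool = True

    def __post_init__(self):
        for rxn_id, val in self.fixed_fluxes:
            r = self.model.reaction(rxn_id)
            if not (r.lower_bound - FEAS_TOL <= val <= r.upper_bound + FEAS_TOL):
                raise ModelError(
                    f"fixed flux {val} outside bounds of reaction {rxn_id!r}"
                )
        if self.fixed_growth is not None and self.model.biomass_reaction is None:
            raise ModelError("cannot fix growth: model has no biomass reaction")

    # -- builders -----------------------------------------------------------

    @staticmethod
    def k_a(model: StoichiometricModel, growth: float | None = None,
            name: str = "K_a") -> "ConstraintSet":
        """The base chemostat set (growth pinned to D when given)."""
        return ConstraintSet(model=model, name=name, fixed_growth=growth)

    def with_name(self, name: str) -> "ConstraintSet":
        return replace(self, name=name)

    def with_growth(self, growth: float | None) -> "ConstraintSet":
        return replace(self, fixed_growth=growth)

    def with_fixed_flux(self, rxn_id: str, value: float) -> "ConstraintSet":
        self.model.reaction(rxn_id)
        return replace(self, fixed_fluxes=self.fixed_fluxes + ((rxn_id, float(value)),))

    def with_fixed_fluxes(self, fixes: dict[str, float]) -> "ConstraintSet":
        extra = tuple(sorted((r, float(v)) for r, v in fixes.items()))
        for rxn_id, _ in extra:
            self.model.reaction(rxn_id)
        return replace(self, fixed_fluxes=self.fixed_fluxes + extra)

    def with_constraint(self, coeffs: dict[str, float], sense: str,
                        rhs: float) -> "ConstraintSet":
        return replace(self, extra=self.extra + (LinearConstraint.make(coeffs, sense, rhs),))

    def union(self, other: "ConstraintSet", name: str | None = None) -> "ConstraintSet":
        """K_x ∪ K_y over the same base model."""
        if other.model is not self.model:
            # permit structurally equal copies (e.g. after editing pipelines)
            if other.model.id != self.model.id:
                raise ModelError("cannot union constraint sets over different models")
        growth = self.fixed_growth if self.fixed_growth is not None else other.fixed_growth
        return replace(
            self,
            name=name or f"{self.name}∪{other.name}",
            fixed_growth=growth,
            fixed_fluxes=self.fixed_fluxes + other.fixed_fluxes,
            extra=self.extra + other.extra,
            abs_upper=self.abs_upper + other.abs_upper,
        )


@dataclass(frozen=True)
class LPResult:
    status: str  # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: dict[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class FVAResult:
    ranges: dict[str, tuple[float, float]]
    tolerance: float = VARIABILITY_TOL

    def varies(self, rxn_id: str) -> bool:
        lo, hi = self.ranges[rxn_id]
        return (hi - lo) > self.tolerance

    def __getitem__(self, rxn_id: str) -> tuple[float, float]:
        return self.ranges[rxn_id]


@dataclass(frozen=True)
class TurnoverResult:
    metabolite: str
    mtr: float | None = None
    ymtr: float | None = None
    minimal_uptake: float | None = None


# ---------------------------------------------------------------------------
# LP assembly over split directional variables
# ---------------------------------------------------------------------------

class _SplitLP:
    """Matrix assembly: x = [vf; vr] >= 0 with J = vf - vr."""

    def __init__(self, cset: ConstraintSet):
        model = cset.model
        self.cset = cset
        self.model = model
        self.rxn_ids = [r.id for r in model.reactions]
        self.col = {r: j for j, r in enumerate(self.rxn_ids)}
        n = len(self.rxn_ids)
        self.n = n

        lo = np.zeros(2 * n)
        hi = np.zeros(2 * n)
        for j, r in enumerate(model.reactions):
            lo[j] = max(r.lower_bound, 0.0)
            hi[j] = max(r.upper_bound, 0.0)
            lo[n + j] = max(-r.upper_bound, 0.0)
            hi[n + j] = max(-r.lower_bound, 0.0)
        self.bounds = np.column_stack([lo, hi])

        eq_rows: list[dict[int, float]] = []
        eq_rhs: list[float] = []
        ub_rows: list[dict[int, float]] = []
        ub_rhs: list[float] = []

        def add_linear(coeffs: dict[str, float], sense: str, rhs: float):
            row: dict[int, float] = {}
            for rxn_id, c in coeffs.items():
                j = self.col[rxn_id]
                row[j] = row.get(j, 0.0) + c
                row[n + j] = row.get(n + j, 0.0) - c
            if sense == "==":
                eq_rows.append(row)
                eq_rhs.append(rhs)
            elif sense == "<=":
                ub_rows.append(row)
                ub_rhs.append(rhs)
            else:  # >=  ->  negate
                ub_rows.append({k: -v for k, v in row.items()})
                ub_rhs.append(-rhs)

        # steady state of balanced metabolites: N0 J = 0
        for met in model.metabolites:
            if not met.balanced:
                continue
            coeffs = {}
            for r in model.reactions:
                c = r.stoichiometry.get(met.id)
                if c:
                    coeffs[r.id] = c
            if coeffs:
                add_linear(coeffs, "==", 0.0)

        # boundary: b <= Ne J for unbalanced metabolites with a finite bound
        self.trivially_infeasible = False
        for met in model.metabolites:
            if met.balanced:
                continue
            b = model.boundary.get(met.id, -INF)
            if b <= -INF:
                continue
            coeffs = {}
            for r in model.reactions:
                c = r.stoichiometry.get(met.id)
                if c:
                    coeffs[r.id] = c
            if not coeffs:
                if b > 0:  # positive net exchange demanded of an untouched species
                    self.trivially_infeasible = True
                continue
            add_linear(coeffs, ">=", b)

        if cset.fixed_growth is not None:
            add_linear({model.biomass_reaction: 1.0}, "==", cset.fixed_growth)
        if cset.apply_maintenance and model.maintenance_reaction is not None:
            add_linear({model.maintenance_reaction: 1.0}, "==", model.maintenance_flux)
        for rxn_id, val in cset.fixed_fluxes:
            add_linear({rxn_id: 1.0}, "==", val)
        for con in cset.extra:
            add_linear(dict(con.coeffs), con.sense, con.rhs)
        for ab in cset.abs_upper:
            row: dict[int, float] = {}
            for rxn_id, a in ab.abs_coeffs:
                j = self.col[rxn_id]
                row[j] = row.get(j, 0.0) + a
                row[n + j] = row.get(n + j, 0.0) + a
            for rxn_id, c in ab.linear_coeffs:
                j = self.col[rxn_id]
                row[j] = row.get(j, 0.0) + c
                row[n + j] = row.get(n + j, 0.0) - c
            ub_rows.append(row)
            ub_rhs.append(ab.rhs)

        self.A_eq, self.b_eq = self._pack(eq_rows, eq_rhs)
        self.A_ub, self.b_ub = self._pack(ub_rows, ub_rhs)

    def _pack(self, rows, rhs):
        if not rows:
            return None, None
        data, ri, ci = [], [], []
        for i, row in enumerate(rows):
            for j, v in row.items():
                ri.append(i)
                ci.append(j)
                data.append(v)
        A = sparse.csr_matrix((data, (ri, ci)), shape=(len(rows), 2 * self.n))
        return A, np.asarray(rhs, dtype=float)

    def cost(self, objective: Objective) -> np.ndarray:
        c = np.zeros(2 * self.n)
        for rxn_id, v in objective.linear.items():
            j = self.col[rxn_id]
            c[j] += v
            c[self.n + j] -= v
        for rxn_id, a in objective.absolute.items():
            j = self.col[rxn_id]
            c[j] += a
            c[self.n + j] += a
        return c

    def solve(self, objective: Objective, sense: str = "min") -> LPResult:
        if self.trivially_infeasible:
            return LPResult("infeasible", None, {})
        c = self.cost(objective)
        if sense == "max":
            c = -c
        res = linprog(c, A_ub=self.A_ub, b_ub=self.b_ub, A_eq=self.A_eq,
                      b_eq=self.b_eq, bounds=self.bounds, method="highs")
        if res.status == 2:
            return LPResult("infeasible", None, {})
        if res.status == 3:
            return LPResult("unbounded", None, {})
        if res.status != 0:
            raise SolverError(f"LP solver failure (status {res.status}): {res.message}")
        x = res.x
        fluxes = {r: float(x[j] - x[self.n + j]) for r, j in self.col.items()}
        # recompute the objective from net fluxes: collapses split-variable
        # slack (vf, vr both positive cannot survive minimization of a
        # positive-weight objective, but may appear in unweighted reactions)
        value = objective.value_at(fluxes)
        return LPResult("optimal", float(value), fluxes)


def minimize(cset: ConstraintSet, objective: Objective) -> LPResult:
    """Minimize ``f = c^T J (+ abs terms)`` over the constraint set."""
    return _SplitLP(cset).solve(objective, "min")


def maximize(cset: ConstraintSet, objective: Objective) -> LPResult:
    if objective.absolute:
        raise ValueError("maximization of absolute-value terms is not an LP")
    return _SplitLP(cset).solve(objective, "max")


def fix_optimum(cset: ConstraintSet, objective: Objective, f_opt: float,
                name: str | None = None) -> ConstraintSet:
    """Pin an attained optimum, producing the reduced set K_b.

    A purely linear objective is pinned as the equality ``c^T J = f_opt``.
    An objective with absolute terms is pinned as the one-sided bound
    ``sum a|J| + c^T J <= f_opt (1 + tol)``: the other side holds
    automatically because f_opt is the attained minimum.
    """
    name = name or f"{cset.name}+opt"
    slack = PIN_TOL * max(1.0, abs(f_opt))
    if not objective.absolute:
        new = replace(
            cset,
            extra=cset.extra + (
                LinearConstraint.make(objective.linear, "<=", f_opt + slack),
                LinearConstraint.make(objective.linear, ">=", f_opt - slack),
            ),
        )
        return replace(new, name=name)
    bound = AbsUpperBound(
        abs_coeffs=tuple(sorted(objective.absolute.items())),
        linear_coeffs=tuple(sorted(objective.linear.items())),
        rhs=f_opt + slack,
    )
    return replace(cset, name=name, abs_upper=cset.abs_upper + (bound,))


# ---------------------------------------------------------------------------
# Named objectives of the analysis
# ---------------------------------------------------------------------------

def uptake_objective(model: StoichiometricModel, substrate: str) -> Objective:
    """Linear objective whose value is the uptake rate of an unbalanced
    substrate: J_up,S = -(Ne J)_S."""
    met = model.metabolite(substrate)
    if met.balanced:
        raise ModelError(f"substrate {substrate!r} must be unbalanced")
    coeffs = {}
    for r in model.reactions:
        c = r.stoichiometry.get(substrate)
        if c:
            coeffs[r.id] = -c
    if not coeffs:
        raise ModelError(f"substrate {substrate!r} participates in no reaction")
    return Objective(linear=coeffs)


def turnover_objective(model: StoichiometricModel, metabolite: str) -> Objective:
    """The turnover objective 0.5 * sum_j |J_j nu_ij| of a balanced compound."""
    met = model.metabolite(metabolite)
    if not met.balanced:
        raise ModelError(f"turnover is defined for balanced metabolites, not {metabolite!r}")
    absolute = {}
    for r in model.reactions:
        c = r.stoichiometry.get(metabolite)
        if c:
            absolute[r.id] = 0.5 * abs(c)
    return Objective(absolute=absolute)


def turnover_at(model: StoichiometricModel, metabolite: str,
                fluxes: dict[str, float]) -> float:
    """Turnover 0.5 * sum |J nu| of a metabolite at a given flux vector."""
    return turnover_objective(model, metabolite).value_at(fluxes)


def min_substrate_uptake(cset: ConstraintSet, substrate: str) -> LPResult:
    """Minimal substrate uptake = maximal yield at the fixed growth rate.

    Requires chemostat conditions (``fixed_growth`` set): the yield D /
    J_up,S is maximized exactly when the uptake is minimized.
    """
    if cset.fixed_growth is None:
        raise ModelError("min_substrate_uptake requires a fixed growth rate (chemostat)")
    return minimize(cset, uptake_objective(cset.model, substrate))


def fva(cset: ConstraintSet, reactions: list[str] | None = None) -> FVAResult:
    """Per-reaction min/max flux over the constraint set."""
    lp = _SplitLP(cset)
    feas = lp.solve(Objective(), "min")
    if not feas.optimal:
        raise ModelError(f"constraint set {cset.name!r} is {feas.status}")
    if reactions is None:
        reactions = lp.rxn_ids
    ranges: dict[str, tuple[float, float]] = {}
    for rxn_id in reactions:
        cset.model.reaction(rxn_id)
        obj = Objective(linear={rxn_id: 1.0})
        lo = lp.solve(obj, "min")
        hi = lp.solve(obj, "max")
        if not (lo.optimal and hi.optimal):
            raise SolverError(f"FVA subproblem failed for {rxn_id!r}")
        lo_v, hi_v = lo.objective_value, hi.objective_value
        if lo_v > hi_v:  # numerical jitter on a pinned reaction
            lo_v = hi_v = 0.5 * (lo_v + hi_v)
        ranges[rxn_id] = (lo_v, hi_v)
    return FVAResult(ranges=ranges)


def mtr(cset: ConstraintSet, metabolite: str) -> TurnoverResult:
    """Minimal turnover rate of a balanced metabolite over the set."""
    res = minimize(cset, turnover_objective(cset.model, metabolite))
    if not res.optimal:
        raise ModelError(f"MTR({metabolite}): constraint set is {res.status}")
    return TurnoverResult(metabolite=metabolite, mtr=max(res.objective_value, 0.0))


def ymtr(cset: ConstraintSet, metabolite: str, substrate: str) -> TurnoverResult:
    """Yield-optimal minimal turnover rate.

    Pins the substrate uptake to its minimum (the maximal-yield face of the
    solution space) and recomputes the MTR there; YMTR >= MTR always, since
    the pinned set is a subset of the feasible set.
    """
    base = mtr(cset, metabolite)
    up = min_substrate_uptake(cset, substrate)
    if not up.optimal:
        raise ModelError(f"substrate uptake minimization is {up.status}")
    pinned = fix_optimum(cset, uptake_objective(cset.model, substrate),
                         up.objective_value, name="K_b")
    res = minimize(pinned, turnover_objective(cset.model, metabolite))
    if not res.optimal:
        raise SolverError("pinned-optimum set unexpectedly " + res.status)
    # the pinning slack can shave O(PIN_TOL) off the exact value; the true
    # YMTR is bounded below by the MTR, so clamp the jitter away
    return TurnoverResult(
        metabolite=metabolite,
        mtr=base.mtr,
        ymtr=max(res.objective_value, base.mtr, 0.0),
        minimal_uptake=up.objective_value,
    )
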