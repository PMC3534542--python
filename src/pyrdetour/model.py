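"""Stoichiometric models with gene-protein-reaction associations.

The in-memory representation follows the split-boundary formalism used for
chemostat analysis: metabolites are either *balanced* (rows of the internal
stoichiometric matrix N0, constrained to steady state ``N0 J = 0``) or
*unbalanced* (rows of the boundary matrix Ne, constrained only by a lower
bound ``b <= Ne J`` on their net exchange rate). A negative boundary bound on
a substrate permits uptake up to its magnitude; a bound of zero closes the
exchange. Growth is the flux through a designated biomass reaction and, under
chemostat conditions, is pinned to the dilution rate D by the LP layer.

All fluxes are in mmol h^-1 gDCW^-1 (biomass flux in h^-1).
"""

from __future__ import annotations

import copy as _copy
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

from . import gpr as _gpr

#: Documented stand-in for an unbounded flux; keeps every LP bounded.
INF = 1000.0

#: Default non-growth ATP maintenance flux [mmol h^-1 gDCW^-1] for
#: genome-scale models (aerobic glucose value from the iAF1260
#: reconstruction); configurable per model.
DEFAULT_MAINTENANCE_FLUX = 8.39


class ModelError(ValueError):
    """Inconsistent model edit or lookup (unknown id, duplicate id, ...)."""


@dataclass(frozen=True)
class Metabolite:
    """A compound. ``balanced`` selects the N0 (True) vs Ne (False) row."""

    id: str
    name: str = ""
    compartment: str = "c"
    balanced: bool = True

    def __post_init__(self):
        if not self.id:
            raise ModelError("metabolite id must be non-empty")
        if not self.compartment:
            raise ModelError(f"metabolite {self.id!r}: compartment must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """A reaction with signed stoichiometry, bounds and an optional GPR.

    ``stoichiometry`` maps metabolite id -> signed coefficient nu_ij
    (negative = consumed in the forward direction). Irreversible reactions
    must have a nonnegative lower bound (thermodynamic direction fixing).
    """

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = INF
    gpr: str = ""

    def __post_init__(self):
        if not self.id:
            raise ModelError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r}: stoichiometry must be non-empty")
        if math.isnan(self.lower_bound) or math.isnan(self.upper_bound):
            raise ModelError(f"reaction {self.id!r}: NaN bound")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.reversible and self.lower_bound < 0:
            raise ModelError(
                f"reaction {self.id!r}: irreversible reaction with negative lower bound"
            )
        # validate the GPR grammar eagerly so load-time errors carry a location
        _gpr.parse_formula(self.gpr, allow_not=False)

    @property
    def genes(self) -> frozenset[str]:
        return _gpr.variables(_gpr.parse_formula(self.gpr, allow_not=False))

    def reactants(self) -> dict[str, float]:
        """Metabolites consumed in the forward direction (coef < 0)."""
        return {m: c for m, c in self.stoichiometry.items() if c < 0}

    def products(self) -> dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}


class GeneStateMap(dict):
    """Mapping gene id -> on/off. Genes absent from the map default to ON."""

    def __missing__(self, key):
        return True

    def get(self, key, default=True):
        return super().get(key, default)


@dataclass
class StoichiometricModel:
    """A stoichiometric network with boundary bounds and GPRs.

    Mutating operations (:meth:`set_boundary`, :meth:`apply_gene_knockout`,
    :meth:`add_reaction`, ...) return edited copies; the receiver is never
    modified in place.
    """

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    boundary: dict[str, float] = field(default_factory=dict)
    biomass_reaction: str | None = None
    maintenance_reaction: str | None = None
    maintenance_flux: float = DEFAULT_MAINTENANCE_FLUX
    id: str = "model"

    def __post_init__(self):
        self._reindex()
        self.validate()

    # -- bookkeeping --------------------------------------------------------

    def _reindex(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self._met_index) != len(self.metabolites):
            raise ModelError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ModelError("duplicate reaction ids")

    def validate(self) -> None:
        for r in self.reactions:
            for m in r.stoichiometry:
                if m not in self._met_index:
                    raise ModelError(
                        f"reaction {r.id!r} references unknown metabolite {m!r}"
                    )
        for m in self.boundary:
            met = self.metabolite(m)
            if met.balanced:
                raise ModelError(f"boundary bound on balanced metabolite {m!r}")
        if self.biomass_reaction is not None and self.biomass_reaction not in self._rxn_index:
            raise ModelError(f"biomass reaction {self.biomass_reaction!r} not in model")
        if self.maintenance_reaction is not None and self.maintenance_reaction not in self._rxn_index:
            raise ModelError(
                f"maintenance reaction {self.maintenance_reaction!r} not in model"
            )

    def copy(self) -> "StoichiometricModel":
        return _copy.deepcopy(self)

    # -- lookups ------------------------------------------------------------

    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self.metabolites[self._met_index[met_id]]
        except KeyError:
            raise ModelError(f"unknown metabolite {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rxn_id]]
        except KeyError:
            raise ModelError(f"unknown reaction {rxn_id!r}") from None

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.genes
        return frozenset(out)

    def balanced_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if m.balanced]

    def unbalanced_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if not m.balanced]

    def boundary_bound(self, met_id: str) -> float:
        """Lower bound b on the net exchange of an unbalanced metabolite.

        Metabolites without an explicit entry are open downward (uptake
        allowed up to the documented infinity).
        """
        met = self.metabolite(met_id)
        if met.balanced:
            raise ModelError(f"{met_id!r} is balanced and has no boundary bound")
        return self.boundary.get(met_id, -INF)

    # -- matrices -----------------------------------------------------------

    def stoichiometric_matrices(self):
        """Return (N0, Ne, balanced ids, unbalanced ids), CSR sparse.

        Rows follow metabolite declaration order within each class; columns
        follow reaction declaration order.
        """
        bal = [m.id for m in self.metabolites if m.balanced]
        unb = [m.id for m in self.metabolites if not m.balanced]
        bal_row = {m: i for i, m in enumerate(bal)}
        unb_row = {m: i for i, m in enumerate(unb)}
        n0 = sparse.lil_matrix((len(bal), len(self.reactions)))
        ne = sparse.lil_matrix((len(unb), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, c in r.stoichiometry.items():
                if m in bal_row:
                    n0[bal_row[m], j] = c
                else:
                    ne[unb_row[m], j] = c
        return n0.tocsr(), ne.tocsr(), bal, unb

    # -- editing operations -------------------------------------------------

    def set_boundary(self, met_id: str, bound: float) -> "StoichiometricModel":
        met = self.metabolite(met_id)
        if met.balanced:
            raise ModelError(
                f"cannot set a boundary bound on balanced metabolite {met_id!r}"
            )
        new = self.copy()
        new.boundary[met_id] = float(bound)
        return new

    def apply_gene_knockout(self, genes: set[str]) -> "StoichiometricModel":
        """Block every reaction whose GPR fails with ``genes`` off.

        All other genes are assumed ON. Blocking means bounds fixed to
        [0, 0]. Knocking out the empty set is the identity.
        """
        genes = set(genes)
        unknown = genes - self.genes
        if unknown:
            raise ModelError(f"unknown gene ids: {sorted(unknown)}")
        states = GeneStateMap({g: False for g in genes})
        new = self.copy()
        for i, r in enumerate(new.reactions):
            if r.gpr and not _gpr.evaluate_gpr(r.gpr, states):
                new.reactions[i] = replace(
                    r, lower_bound=0.0, upper_bound=0.0, reversible=False
                )
        return new

    def add_reaction(self, reaction: Reaction,
                     declare: list[Metabolite] | None = None) -> "StoichiometricModel":
        """Add a reaction, optionally declaring new metabolites it uses."""
        if reaction.id in self._rxn_index:
            raise ModelError(f"duplicate reaction id {reaction.id!r}")
        new = self.copy()
        declared = {m.id for m in new.metabolites}
        for m in declare or []:
            if m.id not in declared:
                new.metabolites.append(m)
                declared.add(m.id)
        missing = set(reaction.stoichiometry) - declared
        if missing:
            raise ModelError(f"undeclared metabolites: {sorted(missing)}")
        new.reactions.append(reaction)
        new._reindex()
        return new

    def remove_reaction(self, rxn_id: str) -> "StoichiometricModel":
        self.reaction(rxn_id)  # raise on unknown id
        new = self.copy()
        new.reactions = [r for r in new.reactions if r.id != rxn_id]
        if new.biomass_reaction == rxn_id:
            new.biomass_reaction = None
        if new.maintenance_reaction == rxn_id:
            new.maintenance_reaction = None
        new._reindex()
        return new

    def set_reaction_bounds(self, rxn_id: str, lower: float,
                            upper: float) -> "StoichiometricModel":
        r = self.reaction(rxn_id)
        new = self.copy()
        i = new._rxn_index[rxn_id]
        new.reactions[i] = replace(
            r, lower_bound=float(lower), upper_bound=float(upper),
            reversible=r.reversible or lower < 0,
        )
        return new


# ---------------------------------------------------------------------------
# Module-level operation wrappers (the functional surface)
# ---------------------------------------------------------------------------

def set_boundary(model: StoichiometricModel, met_id: str, bound: float):
    return model.set_boundary(met_id, bound)


def apply_gene_knockout(model: StoichiometricModel, genes: set[str]):
    return model.apply_gene_knockout(genes)


def add_reaction(model: StoichiometricModel, reaction: Reaction, declare=None):
    return model.add_reaction(reaction, declare)


def evaluate_gpr(gpr_string: str, states) -> bool:
    return _gpr.evaluate_gpr(gpr_string, states)


def model_stats(model: StoichiometricModel) -> dict:
    """Summary counts plus per-metabolite reaction-participation counts.

    Two counts are reported per metabolite because "appears as a reactant"
    is ambiguous for reversible reactions:

    - ``participant``: reactions with any nonzero coefficient;
    - ``reactant``: reactions where the metabolite is on the consumed side,
      i.e. a negative coefficient, or a positive coefficient in a reversible
      reaction (which can consume it running backwards).
    - ``reactant_forward``: negative coefficient only (written direction).
    """
    participant: dict[str, int] = {m.id: 0 for m in model.metabolites}
    reactant: dict[str, int] = {m.id: 0 for m in model.metabolites}
    reactant_forward: dict[str, int] = {m.id: 0 for m in model.metabolites}
    for r in model.reactions:
        for m, c in r.stoichiometry.items():
            if c == 0:
                continue
            participant[m] += 1
            if c < 0:
                reactant[m] += 1
                reactant_forward[m] += 1
            elif r.reversible:
                reactant[m] += 1
    return {
        "n_reactions": len(model.reactions),
        "n_metabolites": len(model.metabolites),
        "n_balanced": sum(m.balanced for m in model.metabolites),
        "n_genes": len(model.genes),
        "participant": participant,
        "reactant": reactant,
        "reactant_forward": reactant_forward,
    }
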