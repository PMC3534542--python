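"""Deterministic fixture generators.

Two hand-built toy networks reproduce the worked examples that motivate the
turnover and route-enumeration machinery, and a seeded generator produces
layered random networks for oracle testing. Topologies of the hand-built
networks are minimal constructions satisfying every documented property
(essential intermediates, alternative branch structure, the expected MTR/YMTR
pattern and release-set family); any topology with those properties would do.

All generators are pure functions of their arguments: the same spec yields a
byte-identical model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lp import ConstraintSet, Objective, minimize
from .model import INF, Metabolite, Reaction, StoichiometricModel
from .regnet import BooleanNetwork, ExpressionTable, parse_rules

#: Dilution rate used by fixture-level analyses [h^-1].
DEFAULT_DILUTION = 0.1


def _met(mid: str, balanced: bool = True) -> Metabolite:
    comp = mid.rsplit("_", 1)[1] if "_" in mid else "c"
    return Metabolite(id=mid, compartment=comp, balanced=balanced)


def figure3_network() -> StoichiometricModel:
    """Alternative-branch toy network for the MTR/YMTR distinction.

    Substrate S feeds an essential intermediate E1; two alternative
    intermediates M1 (inefficient: 2 E1 per unit) and M2 (efficient: 1 E1
    per unit) each suffice for biomass. Consequences, by construction:
    MTR(E1) > 0 at any positive growth; MTR(M1) = MTR(M2) = 0 (each branch
    can replace the other); at minimal substrate uptake only the efficient
    branch runs, so YMTR(M2) > 0 while YMTR(M1) = 0.
    """
    mets = [
        _met("S_e", balanced=False),
        _met("E1"), _met("M1"), _met("M2"), _met("BM"),
    ]
    rxns = [
        Reaction("J_up", {"S_e": -1, "E1": 1}),
        Reaction("J_m1", {"E1": -2, "M1": 1}, gpr="g_m1"),
        Reaction("J_m2", {"E1": -1, "M2": 1}, gpr="g_m2a or g_m2b"),
        Reaction("J_b1", {"M1": -1, "BM": 1}),
        Reaction("J_b2", {"M2": -1, "BM": 1}),
        Reaction("J_mu", {"BM": -1}),
    ]
    return StoichiometricModel(
        metabolites=mets, reactions=rxns, boundary={"S_e": -INF},
        biomass_reaction="J_mu", maintenance_reaction=None, id="figure3",
    )


def figure5_network() -> StoichiometricModel:
    """Producer-alternative toy network for the release-set enumeration.

    Topology (all irreversible, unit stoichiometry)::

        S_e --J1--> E1 --J2--> A --J3/J4--> B --J5/J6/J7--> MOI
                    E1 --J8--> E2
        biomass J_mu: E2 + MOI -> (growth)

    E1, E2 and the MOI are essential (positive MTR at positive growth). J8
    is the sole producer of E2, so it cannot vary once growth is fixed.
    J3/J4 are alternative producers of the precursor B and J5/J6/J7
    alternative final steps, giving exactly the six substrate→MOI routes
    {J3,J5} ... {J4,J7}.
    """
    mets = [
        _met("S_e", balanced=False),
        _met("E1"), _met("E2"), _met("A"), _met("B"), _met("MOI"),
    ]
    rxns = [
        Reaction("J1", {"S_e": -1, "E1": 1}),
        Reaction("J2", {"E1": -1, "A": 1}),
        Reaction("J3", {"A": -1, "B": 1}, gpr="g3"),
        Reaction("J4", {"A": -1, "B": 1}, gpr="g4"),
        Reaction("J5", {"B": -1, "MOI": 1}, gpr="g5a and g5b"),
        Reaction("J6", {"B": -1, "MOI": 1}, gpr="g6"),
        Reaction("J7", {"B": -1, "MOI": 1}, gpr="g7"),
        Reaction("J8", {"E1": -1, "E2": 1}),
        Reaction("J_mu", {"E2": -1, "MOI": -1}),
    ]
    return StoichiometricModel(
        metabolites=mets, reactions=rxns, boundary={"S_e": -INF},
        biomass_reaction="J_mu", maintenance_reaction=None, id="figure5",
    )


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a seeded random layered network."""

    name: str = "random"
    seed: int = 0
    n_layers: int = 3          # balanced metabolite layers between S and biomass
    width: int = 2             # metabolites per layer
    n_extra: int = 4           # random alternative reactions
    reversible_fraction: float = 0.2
    cofactor_pair: bool = True
    maintenance: bool = False
    dilution: float = DEFAULT_DILUTION
    max_retries: int = 5


class FixtureError(RuntimeError):
    """Generator could not produce a feasible instance within its retries."""


def random_network(spec: FixtureSpec) -> StoichiometricModel:
    """Layered substrate→biomass network with random alternative branches.

    A deterministic backbone chain guarantees growth feasibility at the
    spec's dilution rate; extra reactions add alternative producers,
    optionally reversible and optionally dragging a cofactor pair whose
    regeneration costs backbone carbon. The instance is verified feasible
    before being returned.
    """
    last_err = None
    for attempt in range(spec.max_retries):
        rng = np.random.default_rng([spec.seed, attempt])
        model = _build_random(spec, rng)
        cset = ConstraintSet.k_a(model, growth=spec.dilution)
        if minimize(cset, Objective()).optimal:
            return model
        last_err = f"attempt {attempt}: infeasible at D={spec.dilution}"
    raise FixtureError(
        f"random_network({spec.name}, seed={spec.seed}): {last_err}")


def _build_random(spec: FixtureSpec, rng) -> StoichiometricModel:
    L, W = spec.n_layers, spec.width
    mets = [_met("S_e", balanced=False)]
    layer_ids: list[list[str]] = []
    for l in range(1, L + 1):
        ids = [f"m{l}_{i}" for i in range(W)]
        layer_ids.append(ids)
        mets.extend(_met(i) for i in ids)

    rxns: list[Reaction] = []
    # backbone: S -> m1_0 -> m2_0 -> ... -> mL_0 -> biomass
    rxns.append(Reaction("R_up", {"S_e": -1, layer_ids[0][0]: 1}))
    for l in range(1, L):
        rxns.append(Reaction(f"R_bb{l}", {layer_ids[l - 1][0]: -1,
                                          layer_ids[l][0]: 1}))
    biomass_id = "R_mu"

    cof = spec.cofactor_pair or spec.maintenance
    if cof:
        mets.extend([_met("cofA"), _met("cofB")])
        # regeneration costs one unit of the first backbone metabolite
        rxns.append(Reaction("R_regen", {"cofB": -1, layer_ids[0][0]: -1,
                                         "cofA": 1}))

    for e in range(spec.n_extra):
        l = int(rng.integers(0, L))  # source layer (0 = substrate)
        if l == 0:
            src = {"S_e": -1.0}
            tgt_layer = 0
        else:
            src = {str(rng.choice(layer_ids[l - 1])): -float(rng.integers(1, 3))}
            tgt_layer = l
        tgt = str(rng.choice(layer_ids[tgt_layer]))
        stoich = dict(src)
        stoich[tgt] = stoich.get(tgt, 0.0) + 1.0
        stoich = {m: c for m, c in stoich.items() if c != 0}
        if not stoich or tgt in src:
            continue
        if cof and rng.random() < 0.5:
            stoich["cofA"] = stoich.get("cofA", 0.0) - 1.0
            stoich["cofB"] = stoich.get("cofB", 0.0) + 1.0
        reversible = bool(rng.random() < spec.reversible_fraction)
        rxns.append(Reaction(
            f"R_x{e}", stoich, reversible=reversible,
            lower_bound=-INF if reversible else 0.0, upper_bound=INF,
            gpr=f"gx{e}",
        ))

    maintenance_id = None
    if spec.maintenance:
        rxns.append(Reaction("R_atpm", {"cofA": -1, "cofB": 1}))
        maintenance_id = "R_atpm"

    rxns.append(Reaction(biomass_id, {layer_ids[-1][0]: -1}))
    return StoichiometricModel(
        metabolites=mets, reactions=rxns, boundary={"S_e": -INF},
        biomass_reaction=biomass_id, maintenance_reaction=maintenance_id,
        maintenance_flux=0.05, id=f"{spec.name}-{spec.seed}",
    )


def random_regnet(genes, seed: int = 0):
    """Seeded acyclic rule set over the given gene ids.

    Three regulators read environment signals; each metabolic gene gets,
    with high probability, a rule over regulators and signals. Returns
    ``(BooleanNetwork, environment signals)``.
    """
    rng = np.random.default_rng([seed, 77003])
    signals = ["env:glc", "env:o2", "env:stress"]
    tfs = ["tfA", "tfB", "tfC"]

    def literal(pool):
        name = str(rng.choice(pool))
        return f"not {name}" if rng.random() < 0.3 else name

    lines = []
    for tf in tfs:
        op = "and" if rng.random() < 0.5 else "or"
        lines.append(f"{tf} = {literal(signals)} {op} {literal(signals)}")
    pool = signals + tfs
    for g in sorted(genes):
        if rng.random() < 0.2:
            continue
        op = "and" if rng.random() < 0.5 else "or"
        lines.append(f"{g} = {literal(pool)} {op} {literal(pool)}")
    env = {s: bool(rng.random() < 0.5) for s in signals}
    return parse_rules("\n".join(lines)), env


def toy_regnet(seed: int = 0):
    """Seeded acyclic regulatory network wired to the figure-5 gene names.

    Returns ``(BooleanNetwork, environment signals, ExpressionTable)``. The
    rule layering (regulators read only environment signals; metabolic genes
    read regulators and signals) makes acyclicity structural. The expression
    table straddles the 7.0 availability threshold by construction.
    """
    rng = np.random.default_rng([seed, 20407])
    signals = ["env:glc", "env:o2", "env:stress"]
    tfs = ["tfA", "tfB", "tfC"]
    metabolic = ["g3", "g4", "g5a", "g5b", "g6", "g7"]

    def literal(pool):
        name = str(rng.choice(pool))
        return f"not {name}" if rng.random() < 0.3 else name

    lines = []
    for tf in tfs:
        a, b = literal(signals), literal(signals)
        op = "and" if rng.random() < 0.5 else "or"
        lines.append(f"{tf} = {a} {op} {b}")
    pool = signals + tfs
    for g in metabolic:
        if rng.random() < 0.3:
            continue  # leave some metabolic genes unregulated (default ON)
        a, b = literal(pool), literal(pool)
        op = "and" if rng.random() < 0.5 else "or"
        lines.append(f"{g} = {a} {op} {b}")
    network = parse_rules("\n".join(lines))

    env = {s: bool(rng.random() < 0.5) for s in signals}

    genes = tfs + metabolic
    values = {g: float(rng.uniform(5.0, 9.0)) for g in genes}
    values[metabolic[0]] = 7.8   # at least one above threshold
    values[metabolic[1]] = 6.1   # and one below
    return network, env, ExpressionTable(values=values, threshold=7.0)
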