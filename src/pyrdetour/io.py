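"""Model readers and writers.

Three dialects are supported:

``sbml``
    SBML Level 2/3, read through cobrapy/libsbml. Exchange (boundary)
    reactions of the SBML model are folded into the boundary formalism used
    here: each single-metabolite boundary reaction is removed, its metabolite
    is marked unbalanced, and the reaction's lower bound becomes the boundary
    bound b (so ``b <= Ne J`` reproduces the exchange constraint).

``json``
    A full-fidelity dialect; round-trips every field of the in-memory model.
    Schema (all keys at top level)::

        {"id": str,
         "metabolites": [{"id", "name", "compartment", "balanced"}, ...],
         "reactions":   [{"id", "stoichiometry": {met: coef},
                          "reversible", "lower_bound", "upper_bound",
                          "gpr"}, ...],
         "boundary": {met: b, ...},
         "biomass_reaction": str|null,
         "maintenance_reaction": str|null,
         "maintenance_flux": float}

``tsv``
    One reaction per line: ``id <TAB> equation <TAB> reversible <TAB> gpr``.
    Equations look like ``2 E1 + atp_c -> M1 + adp_c`` (``<->`` for
    reversible). Metabolite ids ending in ``_e`` are unbalanced (boundary
    species); all others are balanced, with the suffix after the final ``_``
    taken as the compartment. Directive lines configure the rest::

        #! biomass <reaction id>
        #! maintenance <reaction id> <flux>
        #! boundary <metabolite id> <b>

    Plain ``#`` lines are comments.
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path

from .model import INF, Metabolite, ModelError, Reaction, StoichiometricModel


class FormatError(ValueError):
    """Unparseable model file; message names the offending line/element."""


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def model_to_dict(model: StoichiometricModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment,
             "balanced": m.balanced}
            for m in model.metabolites
        ],
        "reactions": [
            {"id": r.id, "stoichiometry": dict(r.stoichiometry),
             "reversible": r.reversible, "lower_bound": r.lower_bound,
             "upper_bound": r.upper_bound, "gpr": r.gpr}
            for r in model.reactions
        ],
        "boundary": dict(model.boundary),
        "biomass_reaction": model.biomass_reaction,
        "maintenance_reaction": model.maintenance_reaction,
        "maintenance_flux": model.maintenance_flux,
    }


def model_from_dict(data: dict) -> StoichiometricModel:
    try:
        mets = [Metabolite(**m) for m in data.get("metabolites", [])]
        rxns = [Reaction(**r) for r in data.get("reactions", [])]
        return StoichiometricModel(
            metabolites=mets,
            reactions=rxns,
            boundary={k: float(v) for k, v in data.get("boundary", {}).items()},
            biomass_reaction=data.get("biomass_reaction"),
            maintenance_reaction=data.get("maintenance_reaction"),
            maintenance_flux=float(data.get("maintenance_flux", 8.39)),
            id=data.get("id", "model"),
        )
    except (TypeError, ModelError) as exc:
        raise FormatError(f"invalid model JSON: {exc}") from exc


def write_json(model: StoichiometricModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1, sort_keys=True))


def _load_json(path) -> StoichiometricModel:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
    return model_from_dict(data)


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_ARROW = re.compile(r"<->|<=>|-->|->|=>")
_TERM = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$")


def _parse_side(side: str, line_no: int) -> dict[str, float]:
    out: dict[str, float] = {}
    side = side.strip()
    if not side:
        return out
    for term in side.split("+"):
        m = _TERM.match(term.strip())
        if not m:
            raise FormatError(f"line {line_no}: cannot parse term {term.strip()!r}")
        coef = float(m.group(1)) if m.group(1) else 1.0
        met = m.group(2)
        out[met] = out.get(met, 0.0) + coef
    return out


def parse_equation(equation: str, line_no: int = 0) -> tuple[dict[str, float], bool]:
    """Parse ``a A + 2 B -> C`` into signed stoichiometry and reversibility."""
    m = _ARROW.search(equation)
    if not m:
        raise FormatError(f"line {line_no}: no reaction arrow in {equation!r}")
    reversible = m.group(0) in ("<->", "<=>")
    lhs = _parse_side(equation[: m.start()], line_no)
    rhs = _parse_side(equation[m.end():], line_no)
    stoich: dict[str, float] = {}
    for met, c in lhs.items():
        stoich[met] = stoich.get(met, 0.0) - c
    for met, c in rhs.items():
        stoich[met] = stoich.get(met, 0.0) + c
    stoich = {m_: c for m_, c in stoich.items() if c != 0}
    if not stoich:
        raise FormatError(f"line {line_no}: equation cancels to nothing: {equation!r}")
    return stoich, reversible


def _met_from_id(met_id: str) -> Metabolite:
    compartment = met_id.rsplit("_", 1)[1] if "_" in met_id else "c"
    return Metabolite(id=met_id, compartment=compartment or "c",
                      balanced=not met_id.endswith("_e"))


def _load_tsv(path) -> StoichiometricModel:
    mets: dict[str, Metabolite] = {}
    rxns: list[Reaction] = []
    boundary: dict[str, float] = {}
    biomass = maintenance = None
    maintenance_flux = 8.39
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#!"):
            parts = line[2:].split()
            if not parts:
                raise FormatError(f"line {line_no}: empty directive")
            kind = parts[0]
            if kind == "biomass" and len(parts) == 2:
                biomass = parts[1]
            elif kind == "maintenance" and len(parts) in (2, 3):
                maintenance = parts[1]
                if len(parts) == 3:
                    maintenance_flux = float(parts[2])
            elif kind == "boundary" and len(parts) == 3:
                boundary[parts[1]] = float(parts[2])
            else:
                raise FormatError(f"line {line_no}: bad directive {line!r}")
            continue
        if line.startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise FormatError(f"line {line_no}: expected id<TAB>equation, got {raw!r}")
        rxn_id = fields[0].strip()
        stoich, arrow_rev = parse_equation(fields[1], line_no)
        reversible = arrow_rev
        if len(fields) >= 3 and fields[2].strip():
            flag = fields[2].strip().lower()
            if flag not in ("0", "1", "true", "false", "r", "i"):
                raise FormatError(f"line {line_no}: bad reversibility flag {fields[2]!r}")
            reversible = flag in ("1", "true", "r")
        gpr = fields[3].strip() if len(fields) >= 4 else ""
        for met_id in stoich:
            mets.setdefault(met_id, _met_from_id(met_id))
        rxns.append(Reaction(
            id=rxn_id, stoichiometry=stoich, reversible=reversible,
            lower_bound=-INF if reversible else 0.0, upper_bound=INF, gpr=gpr,
        ))
    for met_id in boundary:
        mets.setdefault(met_id, _met_from_id(met_id))
    return StoichiometricModel(
        metabolites=list(mets.values()), reactions=rxns, boundary=boundary,
        biomass_reaction=biomass, maintenance_reaction=maintenance,
        maintenance_flux=maintenance_flux, id=Path(path).stem,
    )


def write_tsv(model: StoichiometricModel, path) -> None:
    lines = []
    if model.biomass_reaction:
        lines.append(f"#! biomass {model.biomass_reaction}")
    if model.maintenance_reaction:
        lines.append(f"#! maintenance {model.maintenance_reaction} {model.maintenance_flux}")
    for met, b in sorted(model.boundary.items()):
        lines.append(f"#! boundary {met} {b}")
    for r in model.reactions:
        lhs = " + ".join(
            (f"{-c:g} {m}" if c != -1 else m)
            for m, c in sorted(r.stoichiometry.items()) if c < 0
        )
        rhs = " + ".join(
            (f"{c:g} {m}" if c != 1 else m)
            for m, c in sorted(r.stoichiometry.items()) if c > 0
        )
        arrow = "<->" if r.reversible else "->"
        lines.append(f"{r.id}\t{lhs} {arrow} {rhs}\t{int(r.reversible)}\t{r.gpr}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SBML via cobrapy
# ---------------------------------------------------------------------------

def _load_sbml(path) -> StoichiometricModel:
    import cobra.io

    try:
        cmodel = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # libsbml reports rich errors; surface them
        raise FormatError(f"{path}: SBML parse failure: {exc}") from exc

    biomass = None
    try:
        expr = cmodel.objective.expression
        for rxn in cmodel.reactions:
            if rxn.forward_variable in expr.free_symbols:
                biomass = rxn.id
                break
    except Exception:
        biomass = None
    if biomass is None:
        for rxn in cmodel.reactions:
            if "biomass" in rxn.id.lower():
                biomass = rxn.id
                break

    # single-metabolite boundary reactions fold into the b <= Ne J formalism;
    # the objective (biomass) reaction is kept even when it looks like a sink
    boundary_rxns = {r.id for r in cmodel.boundary} - {biomass}
    unbalanced: dict[str, float] = {}
    for r in cmodel.boundary:
        if r.id not in boundary_rxns or len(r.metabolites) != 1:
            continue
        met = next(iter(r.metabolites))
        coef = r.metabolites[met]
        # exchange convention "met <->": flux = net export; our Ne row is the
        # net production by the remaining reactions, which equals that flux.
        lb = r.lower_bound if coef < 0 else -r.upper_bound
        unbalanced[met.id] = float(lb)

    mets = [
        Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "c",
                   balanced=m.id not in unbalanced)
        for m in cmodel.metabolites
    ]
    rxns = []
    for r in cmodel.reactions:
        if r.id in boundary_rxns:
            continue
        lb = max(r.lower_bound, -INF)
        ub = min(r.upper_bound, INF)
        rxns.append(Reaction(
            id=r.id,
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            reversible=lb < 0,
            lower_bound=lb, upper_bound=ub,
            gpr=r.gene_reaction_rule or "",
        ))

    maintenance = "ATPM" if any(r.id == "ATPM" for r in cmodel.reactions) else None
    return StoichiometricModel(
        metabolites=mets, reactions=rxns, boundary=unbalanced,
        biomass_reaction=biomass, maintenance_reaction=maintenance,
        id=cmodel.id or Path(path).stem,
    )


# ---------------------------------------------------------------------------
# Front door
# ---------------------------------------------------------------------------

_LOADERS = {"sbml": _load_sbml, "json": _load_json, "tsv": _load_tsv}
_EXT = {".xml": "sbml", ".sbml": "sbml", ".json": "json", ".tsv": "tsv", ".txt": "tsv"}


def load_model(path, dialect: str | None = None) -> StoichiometricModel:
    """Load a model from ``path`` in the named dialect.

    With ``dialect=None`` the file extension decides. A model without a
    biomass reaction loads with a warning (growth-pinned analyses will then
    refuse to run), not an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = _EXT.get(path.suffix.lower())
        if dialect is None:
            raise FormatError(f"cannot infer dialect from suffix {path.suffix!r}")
    if dialect not in _LOADERS:
        raise FormatError(f"unknown dialect {dialect!r}; expected sbml/json/tsv")
    model = _LOADERS[dialect](path)
    if model.biomass_reaction is None and model.reactions:
        warnings.warn(f"{path}: no biomass reaction identified", stacklevel=2)
    return model
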