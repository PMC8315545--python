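"""Metabolic model containers, JSON/SBML I/O and gene-protein-reaction rules.

The central object is :class:`MetabolicModel`: a stoichiometric matrix ``S``
(metabolites x reactions), box flux bounds, exchange flags, and optional
GPR rules mapping each reaction to a boolean expression over protein
identifiers.  GPR rules are evaluated quantitatively the way
omics-integration methods do: an AND complex is limited by its scarcest
member (``min``), alternative catalysts (OR) add up (``sum``).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Tuple, Union

import numpy as np

__all__ = [
    "GprExpression",
    "GprParseError",
    "MetabolicModel",
    "EnzymeProfile",
    "ConstraintSpec",
    "ModelValidationError",
    "parse_gpr",
    "evaluate_gpr",
    "read_model",
    "write_model",
    "apply_constraints",
    "map_proteome",
    "reversibility_summary",
]


class ModelValidationError(ValueError):
    """A model or constraint specification violates its invariants."""


class GprParseError(ValueError):
    """A GPR string could not be parsed; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GprExpression:
    """A boolean gene-protein-reaction tree.

    ``op`` is ``"leaf"``, ``"and"`` or ``"or"``.  A leaf stores a protein
    identifier in ``name``; internal nodes hold >= 2 children.
    """

    op: str
    name: Optional[str] = None
    children: Tuple["GprExpression", ...] = ()

    def proteins(self) -> set:
        if self.op == "leaf":
            return {self.name}
        out: set = set()
        for c in self.children:
            out |= c.proteins()
        return out

    def to_string(self) -> str:
        if self.op == "leaf":
            return self.name
        sep = " AND " if self.op == "and" else " OR "
        parts = []
        for c in self.children:
            s = c.to_string()
            if c.op != "leaf":  # keep grouping explicit so strings round-trip
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)


_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z0-9._-]+)")


def _tokenize(text: str) -> List[Tuple[str, int]]:
    tokens: List[Tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise GprParseError(f"unexpected character {stripped[0]!r}", pos)
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(text: str) -> GprExpression:
    """Parse a GPR rule string into a :class:`GprExpression`.

    Grammar: identifiers (alphanumeric plus ``._-``), case-insensitive
    ``AND``/``OR``, parentheses; AND binds tighter than OR.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise GprParseError("empty GPR expression", 0)
    idx = 0

    def peek():
        return tokens[idx] if idx < len(tokens) else (None, len(text))

    def parse_or() -> GprExpression:
        nonlocal idx
        terms = [parse_and()]
        while peek()[0] is not None and peek()[0].lower() == "or":
            idx += 1
            terms.append(parse_and())
        if len(terms) == 1:
            return terms[0]
        return GprExpression("or", children=tuple(terms))

    def parse_and() -> GprExpression:
        nonlocal idx
        factors = [parse_atom()]
        while peek()[0] is not None and peek()[0].lower() == "and":
            idx += 1
            factors.append(parse_atom())
        if len(factors) == 1:
            return factors[0]
        return GprExpression("and", children=tuple(factors))

    def parse_atom() -> GprExpression:
        nonlocal idx
        tok, pos = peek()
        if tok is None:
            raise GprParseError("dangling operator", pos)
        if tok == "(":
            idx += 1
            inner = parse_or()
            tok2, pos2 = peek()
            if tok2 != ")":
                raise GprParseError("unbalanced parentheses", pos2)
            idx += 1
            return inner
        if tok == ")":
            raise GprParseError("unbalanced parentheses", pos)
        if tok.lower() in ("and", "or"):
            raise GprParseError(f"operator {tok!r} where identifier expected", pos)
        idx += 1
        return GprExpression("leaf", name=tok)

    expr = parse_or()
    tok, pos = peek()
    if tok is not None:
        raise GprParseError(f"unexpected token {tok!r}", pos)
    return expr


def evaluate_gpr(
    expr: GprExpression,
    abundances: Mapping[str, float],
    partial_and: str = "drop",
) -> Optional[float]:
    """Evaluate a GPR tree against protein abundances.

    AND -> min of children, OR -> sum of children.  A member of an AND
    complex with no quantification makes the complex unobserved (``None``)
    under ``partial_and="drop"``; with ``partial_and="min"`` the minimum is
    taken over the quantified members only.  OR drops unobserved branches
    and is unobserved only when all branches are.  Zero abundance is a
    valid observation, not missing data.
    """
    if partial_and not in ("drop", "min"):
        raise ValueError("partial_and must be 'drop' or 'min'")
    if expr.op == "leaf":
        val = abundances.get(expr.name)
        if val is None:
            return None
        if val < 0:
            raise ValueError(f"negative abundance for protein {expr.name!r}")
        return float(val)
    vals = [evaluate_gpr(c, abundances, partial_and) for c in expr.children]
    if expr.op == "and":
        if any(v is None for v in vals):
            if partial_and == "drop":
                return None
            vals = [v for v in vals if v is not None]
            if not vals:
                return None
        return min(vals)
    # OR: sum surviving branches
    present = [v for v in vals if v is not None]
    if not present:
        return None
    return float(sum(present))


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class MetabolicModel:
    """A constraint-based metabolic model.

    Attributes
    ----------
    metabolite_ids, reaction_ids : list of str
        Unique identifiers; ``S`` has one row per metabolite and one
        column per reaction.
    S : ndarray, shape (M, N)
        Stoichiometric coefficients.
    v_inf, v_sup : ndarray, shape (N,)
        Lower and upper flux bounds (mmol gDW^-1 h^-1 nominal units).
    exchange : ndarray of bool, shape (N,)
        Marks reactions crossing the system boundary.
    gpr : dict
        Partial map reaction id -> :class:`GprExpression`.
    fixed_exchanges : dict
        Reaction id -> ``(value, sigma)`` soft observations recorded by
        :func:`apply_constraints` for downstream posterior conditioning.
    """

    metabolite_ids: List[str]
    reaction_ids: List[str]
    S: np.ndarray
    v_inf: np.ndarray
    v_sup: np.ndarray
    exchange: np.ndarray
    gpr: Dict[str, GprExpression] = field(default_factory=dict)
    fixed_exchanges: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.v_inf = np.asarray(self.v_inf, dtype=float)
        self.v_sup = np.asarray(self.v_sup, dtype=float)
        self.exchange = np.asarray(self.exchange, dtype=bool)
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        M, N = len(self.metabolite_ids), len(self.reaction_ids)
        if self.S.shape != (M, N):
            raise ModelValidationError(
                f"S has shape {self.S.shape}, expected ({M}, {N})")
        for name, arr in (("v_inf", self.v_inf), ("v_sup", self.v_sup),
                          ("exchange", self.exchange)):
            if arr.shape != (N,):
                raise ModelValidationError(f"{name} has length {arr.shape}, expected {N}")
        if len(set(self.metabolite_ids)) != M:
            raise ModelValidationError("duplicate metabolite identifiers")
        if len(set(self.reaction_ids)) != N:
            raise ModelValidationError("duplicate reaction identifiers")
        if np.any(self.v_inf > self.v_sup):
            bad = self.reaction_ids[int(np.argmax(self.v_inf > self.v_sup))]
            raise ModelValidationError(f"v_inf > v_sup for reaction {bad!r}")
        unknown = set(self.gpr) - set(self.reaction_ids)
        if unknown:
            raise ModelValidationError(f"GPR rules for unknown reactions: {sorted(unknown)}")

    # -- conveniences ------------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def reversible(self) -> np.ndarray:
        """Reactions whose admissible range crosses zero on both sides."""
        return (self.v_inf < 0) & (self.v_sup > 0)

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction {rid!r}") from None

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            v_inf=self.v_inf.copy(),
            v_sup=self.v_sup.copy(),
            exchange=self.exchange.copy(),
            gpr=dict(self.gpr),
            fixed_exchanges=dict(self.fixed_exchanges),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return (
            self.metabolite_ids == other.metabolite_ids
            and self.reaction_ids == other.reaction_ids
            and np.array_equal(self.S, other.S)
            and np.array_equal(self.v_inf, other.v_inf)
            and np.array_equal(self.v_sup, other.v_sup)
            and np.array_equal(self.exchange, other.exchange)
            and self.gpr == other.gpr
            and self.fixed_exchanges == other.fixed_exchanges
        )


@dataclass
class EnzymeProfile:
    """Reaction-indexed enzyme abundances for the observed subset.

    ``observed_mask`` is aligned with ``reaction_ids`` and is true exactly
    where ``weightings`` has a key (the indicator of observed reactions).
    """

    reaction_ids: List[str]
    weightings: Dict[str, float]
    observed_mask: np.ndarray

    def __post_init__(self):
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        keys = set(self.weightings)
        unknown = keys - set(self.reaction_ids)
        if unknown:
            raise ModelValidationError(f"weightings for unknown reactions: {sorted(unknown)}")
        if any(v < 0 for v in self.weightings.values()):
            raise ModelValidationError("enzyme abundances must be non-negative")
        expect = np.array([rid in keys for rid in self.reaction_ids])
        if not np.array_equal(expect, self.observed_mask):
            raise ModelValidationError("observed_mask inconsistent with weightings")

    @property
    def n_observed(self) -> int:
        return int(self.observed_mask.sum())

    def values_vector(self) -> np.ndarray:
        """Abundances aligned to the reaction order; NaN where unobserved."""
        out = np.full(len(self.reaction_ids), np.nan)
        for rid, val in self.weightings.items():
            out[self.reaction_ids.index(rid)] = val
        return out


@dataclass
class ConstraintSpec:
    """Bound tightenings and soft exchange-flux observations.

    ``fixed_exchanges`` maps reaction id to ``(value, sigma)``: the flux is
    observed as a Gaussian ``N(value, sigma^2)`` with small ``sigma``.
    """

    irreversible_set: Iterable[str] = ()
    zeroed_set: Iterable[str] = ()
    fixed_exchanges: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def validate_against(self, model: MetabolicModel) -> None:
        known = set(model.reaction_ids)
        for rid in list(self.irreversible_set) + list(self.zeroed_set) + list(self.fixed_exchanges):
            if rid not in known:
                raise ModelValidationError(f"constraint references unknown reaction {rid!r}")
        for rid, (value, sigma) in self.fixed_exchanges.items():
            if sigma <= 0:
                raise ModelValidationError(f"sigma must be positive for {rid!r}")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def apply_constraints(model: MetabolicModel, spec: ConstraintSpec) -> MetabolicModel:
    """Return a new model with bounds narrowed per ``spec``.

    Irreversible reactions get ``v_inf`` raised to 0 (forward convention);
    zeroed reactions get ``[0, 0]``; soft exchange observations are stored
    on the model for posterior conditioning and must lie inside the
    reaction's bounds.  Never widens an interval.
    """
    spec.validate_against(model)
    out = model.copy()
    for rid in spec.irreversible_set:
        i = out.reaction_index(rid)
        new_lo = max(out.v_inf[i], 0.0)
        if new_lo > out.v_sup[i]:
            raise ModelValidationError(
                f"making {rid!r} irreversible empties its bound interval")
        out.v_inf[i] = new_lo
    for rid in spec.zeroed_set:
        i = out.reaction_index(rid)
        if out.v_inf[i] > 0 or out.v_sup[i] < 0:
            raise ModelValidationError(f"zeroing {rid!r} empties its bound interval")
        out.v_inf[i] = 0.0
        out.v_sup[i] = 0.0
    for rid, (value, sigma) in spec.fixed_exchanges.items():
        i = out.reaction_index(rid)
        if not (out.v_inf[i] <= value <= out.v_sup[i]):
            raise ModelValidationError(
                f"observed flux {value} for {rid!r} outside bounds "
                f"[{out.v_inf[i]}, {out.v_sup[i]}]")
        out.fixed_exchanges[rid] = (float(value), float(sigma))
    out.validate()
    return out


def map_proteome(
    model: MetabolicModel,
    protein_table: Mapping[str, float],
    sample_id: Optional[str] = None,
    partial_and: str = "drop",
) -> EnzymeProfile:
    """Evaluate every GPR against a protein-abundance map.

    Returns an :class:`EnzymeProfile` whose weightings cover exactly the
    reactions whose GPR evaluates to a number.  ``sample_id`` is accepted
    for provenance symmetry with tabular inputs and is not interpreted.
    """
    weightings: Dict[str, float] = {}
    for rid, expr in model.gpr.items():
        val = evaluate_gpr(expr, protein_table, partial_and=partial_and)
        if val is not None:
            weightings[rid] = val
    mask = np.array([rid in weightings for rid in model.reaction_ids])
    return EnzymeProfile(list(model.reaction_ids), weightings, mask)


class ReversibilityCounts(NamedTuple):
    n_reversible: int
    n_irreversible: int
    n_zeroed: int


def reversibility_summary(model: MetabolicModel) -> ReversibilityCounts:
    """Partition reactions into reversible / irreversible / zeroed.

    A reaction with ``v_inf = v_sup = 0`` has no admissible flux and is
    counted separately from the reversible/irreversible partition.
    """
    zeroed = (model.v_inf == 0) & (model.v_sup == 0)
    rev = model.reversible & ~zeroed
    irrev = ~model.reversible & ~zeroed
    return ReversibilityCounts(int(rev.sum()), int(irrev.sum()), int(zeroed.sum()))


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _model_to_dict(model: MetabolicModel) -> dict:
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        stoich = {
            model.metabolite_ids[i]: model.S[i, j]
            for i in range(model.n_metabolites)
            if model.S[i, j] != 0
        }
        expr = model.gpr.get(rid)
        reactions.append({
            "id": rid,
            "stoich": stoich,
            "lb": float(model.v_inf[j]),
            "ub": float(model.v_sup[j]),
            "gpr": expr.to_string() if expr is not None else None,
            "exchange": bool(model.exchange[j]),
        })
    return {
        "metabolites": [{"id": mid} for mid in model.metabolite_ids],
        "reactions": reactions,
    }


def _model_from_dict(data: dict, source: str = "<json>") -> MetabolicModel:
    try:
        metabolite_ids = [m["id"] for m in data["metabolites"]]
        reactions = data["reactions"]
    except (KeyError, TypeError) as exc:
        raise ModelValidationError(f"{source}: malformed model record: {exc}") from exc
    met_index = {mid: i for i, mid in enumerate(metabolite_ids)}
    if len(met_index) != len(metabolite_ids):
        raise ModelValidationError(f"{source}: duplicate metabolite identifiers")
    N = len(reactions)
    S = np.zeros((len(metabolite_ids), N))
    reaction_ids, v_inf, v_sup, exchange = [], np.zeros(N), np.zeros(N), np.zeros(N, bool)
    gpr: Dict[str, GprExpression] = {}
    for j, rec in enumerate(reactions):
        try:
            rid = rec["id"]
            stoich = rec["stoich"]
            v_inf[j] = rec["lb"]
            v_sup[j] = rec["ub"]
            exchange[j] = bool(rec.get("exchange", False))
        except (KeyError, TypeError) as exc:
            raise ModelValidationError(
                f"{source}: malformed reaction record #{j}: {exc}") from exc
        reaction_ids.append(rid)
        for mid, coef in stoich.items():
            if mid not in met_index:
                raise ModelValidationError(
                    f"{source}: reaction {rid!r} references unknown metabolite {mid!r}")
            S[met_index[mid], j] = coef
        rule = rec.get("gpr")
        if rule:
            gpr[rid] = parse_gpr(rule)
    return MetabolicModel(metabolite_ids, reaction_ids, S, v_inf, v_sup, exchange, gpr)


def read_model(path: str, format: Optional[str] = None) -> MetabolicModel:
    """Read a model from the JSON dialect or from SBML Level 3 + fbc.

    ``format`` is inferred from the file extension when omitted
    (``.json`` vs ``.xml``/``.sbml``).
    """
    if format is None:
        lower = str(path).lower()
        format = "sbml" if lower.endswith((".xml", ".sbml")) else "json"
    if format == "json":
        with open(path) as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ModelValidationError(f"{path}: invalid JSON: {exc}") from exc
        return _model_from_dict(data, source=str(path))
    if format == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def _read_sbml(path: str) -> MetabolicModel:
    # cobrapy handles SBML/fbc parsing; we only remap onto our container.
    from cobra.io import read_sbml_model

    cm = read_sbml_model(str(path))
    metabolite_ids = [m.id for m in cm.metabolites]
    reaction_ids = [r.id for r in cm.reactions]
    met_index = {mid: i for i, mid in enumerate(metabolite_ids)}
    S = np.zeros((len(metabolite_ids), len(reaction_ids)))
    v_inf = np.zeros(len(reaction_ids))
    v_sup = np.zeros(len(reaction_ids))
    exchange = np.zeros(len(reaction_ids), bool)
    gpr: Dict[str, GprExpression] = {}
    for j, rxn in enumerate(cm.reactions):
        for met, coef in rxn.metabolites.items():
            S[met_index[met.id], j] = coef
        v_inf[j], v_sup[j] = rxn.lower_bound, rxn.upper_bound
        exchange[j] = rxn.boundary
        rule = rxn.gene_reaction_rule
        if rule:
            gpr[rxn.id] = parse_gpr(rule)
    return MetabolicModel(metabolite_ids, reaction_ids, S, v_inf, v_sup, exchange, gpr)


def write_model(model: MetabolicModel, path: str) -> None:
    """Write a model in the JSON dialect (round-trips through read_model)."""
    with open(path, "w") as fh:
        json.dump(_model_to_dict(model), fh, indent=1)
        fh.write("\n")


def read_proteome_table(path: str):
    """Read a proteins x samples TSV (first column protein id, header row)."""
    import pandas as pd

    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.index.has_duplicates:
        raise ModelValidationError(f"{path}: duplicate protein identifiers")
    return table
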