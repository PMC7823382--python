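"""Metabolic model core: stoichiometric model container, GPR boolean logic,
and growth-media constraint application.

A :class:`MetabolicModel` holds a metabolites x reactions stoichiometric
matrix, per-reaction flux bounds, gene-protein-reaction (GPR) rules,
subsystem labels, and a linear objective (the biomass reaction by
convention).  Exchange reactions are detected structurally: a reaction is an
exchange iff all of its nonzero stoichiometric coefficients share one sign,
i.e. it only imports or only exports mass.  By convention exchanges are
written ``metabolite ->`` so positive flux is secretion and negative flux is
uptake.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Gpr",
    "GprParseError",
    "parse_gpr",
    "evaluate_gpr_bool",
    "gene_states_to_reaction_state",
    "MetabolicModel",
    "apply_media",
]


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------

class GprParseError(ValueError):
    """Raised for malformed GPR rule strings; message names the token position."""


@dataclass(frozen=True)
class Gpr:
    """Boolean gene-protein-reaction expression tree.

    ``op`` is one of ``"gene"`` (leaf, ``gene`` set), ``"and"`` or ``"or"``
    (``children`` set, at least two).  AND encodes complex subunits (all
    genes required), OR encodes isozymes (any gene suffices).
    """

    op: str
    gene: str | None = None
    children: tuple["Gpr", ...] = ()

    def __post_init__(self) -> None:
        if self.op == "gene":
            if not self.gene:
                raise GprParseError("empty gene leaf")
        elif self.op in ("and", "or"):
            if len(self.children) < 2:
                raise GprParseError(f"{self.op} node needs >=2 children")
        else:
            raise GprParseError(f"unknown GPR op {self.op!r}")

    def genes(self) -> set[str]:
        if self.op == "gene":
            return {self.gene}
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            s = c.to_string()
            # parenthesize an OR child under AND to preserve precedence
            if self.op == "and" and c.op == "or":
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in "()":
            tokens.append((ch, i))
            i += 1
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in "()":
                j += 1
            tokens.append((text[i:j], i))
            i = j
    return tokens


def parse_gpr(text: str) -> Gpr:
    """Parse a GPR rule string with ``and``/``or`` (case-insensitive) and
    parentheses; ``and`` binds tighter than ``or``.

    Raises :class:`GprParseError` naming the character position of the
    offending token.
    """
    if not text or not text.strip():
        raise GprParseError("empty GPR string")
    tokens = _tokenize(text)
    pos = 0

    def peek() -> tuple[str, int] | None:
        return tokens[pos] if pos < len(tokens) else None

    def fail(msg: str, at: int) -> None:
        raise GprParseError(f"{msg} at position {at}")

    def parse_or() -> Gpr:
        nonlocal pos
        terms = [parse_and()]
        while (tk := peek()) is not None and tk[0].lower() == "or":
            pos += 1
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else Gpr("or", children=tuple(terms))

    def parse_and() -> Gpr:
        nonlocal pos
        factors = [parse_atom()]
        while (tk := peek()) is not None and tk[0].lower() == "and":
            pos += 1
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else Gpr("and", children=tuple(factors))

    def parse_atom() -> Gpr:
        nonlocal pos
        tk = peek()
        if tk is None:
            fail("unexpected end of GPR", len(text))
        tok, at = tk
        if tok == "(":
            pos += 1
            inner = parse_or()
            closing = peek()
            if closing is None or closing[0] != ")":
                fail("unbalanced parenthesis", at)
            pos += 1
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            fail(f"unexpected token {tok!r}", at)
        pos += 1
        return Gpr("gene", gene=tok)

    expr = parse_or()
    if pos != len(tokens):
        tok, at = tokens[pos]
        raise GprParseError(f"trailing token {tok!r} at position {at}")
    return expr


def evaluate_gpr_bool(expr: Gpr, present_genes: set[str] | frozenset[str]) -> bool:
    """True iff the rule is satisfied with exactly ``present_genes`` present."""
    if expr.op == "gene":
        return expr.gene in present_genes
    if expr.op == "and":
        return all(evaluate_gpr_bool(c, present_genes) for c in expr.children)
    return any(evaluate_gpr_bool(c, present_genes) for c in expr.children)


def gene_states_to_reaction_state(expr: Gpr, gene_states: dict[str, int]) -> int:
    """Map ternary gene states {-1, 0, +1} to a reaction state.

    AND takes the minimum of its children (a complex is only as available as
    its scarcest subunit); OR takes the maximum (any isozyme suffices).
    Genes absent from ``gene_states`` default to 0.  Restricted to states
    {0, +1} this reduces to boolean GPR evaluation.
    """
    if expr.op == "gene":
        return int(gene_states.get(expr.gene, 0))
    vals = [gene_states_to_reaction_state(c, gene_states) for c in expr.children]
    return min(vals) if expr.op == "and" else max(vals)


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class MetabolicModel:
    metabolite_ids: list[str]
    reaction_ids: list[str]
    stoichiometry: sp.csc_matrix  # metabolites x reactions
    lower_bound: np.ndarray
    upper_bound: np.ndarray
    gpr: list[Gpr | None]
    subsystem: list[str]
    objective_coeffs: np.ndarray
    gene_ids: list[str]
    core_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.stoichiometry = sp.csc_matrix(self.stoichiometry, dtype=float)
        self.lower_bound = np.asarray(self.lower_bound, dtype=float)
        self.upper_bound = np.asarray(self.upper_bound, dtype=float)
        self.objective_coeffs = np.asarray(self.objective_coeffs, dtype=float)
        if self.core_flags is None:
            self.core_flags = np.zeros(self.n_reactions, dtype=bool)
        self.core_flags = np.asarray(self.core_flags, dtype=bool)
        self.validate()

    # -- basic properties ---------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def reaction_index(self, rid: str) -> int:
        try:
            return self._rxn_index[rid]
        except AttributeError:
            self._rxn_index = {r: i for i, r in enumerate(self.reaction_ids)}
            return self._rxn_index[rid]

    @property
    def exchange_flags(self) -> np.ndarray:
        """Boolean per reaction: True iff all nonzero coefficients share one sign."""
        flags = np.zeros(self.n_reactions, dtype=bool)
        S = self.stoichiometry
        for j in range(self.n_reactions):
            coefs = S.data[S.indptr[j]:S.indptr[j + 1]]
            coefs = coefs[coefs != 0]
            if coefs.size and (np.all(coefs > 0) or np.all(coefs < 0)):
                flags[j] = True
        return flags

    def objective_reactions(self) -> list[str]:
        return [self.reaction_ids[j] for j in np.flatnonzero(self.objective_coeffs)]

    def validate(self) -> None:
        n = self.n_reactions
        if self.stoichiometry.shape != (self.n_metabolites, n):
            raise ValueError("stoichiometry shape mismatch with id lists")
        for arr, name in ((self.lower_bound, "lower_bound"),
                          (self.upper_bound, "upper_bound"),
                          (self.objective_coeffs, "objective_coeffs")):
            if arr.shape != (n,):
                raise ValueError(f"{name} length != reaction count")
        if len(self.gpr) != n or len(self.subsystem) != n:
            raise ValueError("gpr/subsystem length != reaction count")
        if np.any(self.lower_bound > self.upper_bound + 1e-12):
            raise ValueError("lower bound exceeds upper bound")
        gene_set = set(self.gene_ids)
        referenced: set[str] = set()
        for g in self.gpr:
            if g is not None:
                referenced |= g.genes()
        missing = referenced - gene_set
        if missing:
            raise ValueError(f"GPR references genes absent from gene_ids: {sorted(missing)}")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            stoichiometry=self.stoichiometry.copy(),
            lower_bound=self.lower_bound.copy(),
            upper_bound=self.upper_bound.copy(),
            gpr=list(self.gpr),
            subsystem=list(self.subsystem),
            objective_coeffs=self.objective_coeffs.copy(),
            gene_ids=list(self.gene_ids),
            core_flags=self.core_flags.copy(),
        )

    def with_bounds(self, lb: np.ndarray, ub: np.ndarray) -> "MetabolicModel":
        m = self.copy()
        m.lower_bound = np.asarray(lb, dtype=float)
        m.upper_bound = np.asarray(ub, dtype=float)
        m.validate()
        return m

    def subset_reactions(self, keep: np.ndarray) -> "MetabolicModel":
        """Model restricted to reactions where ``keep`` is True (metabolites kept)."""
        keep = np.asarray(keep, dtype=bool)
        idx = np.flatnonzero(keep)
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=[self.reaction_ids[j] for j in idx],
            stoichiometry=self.stoichiometry[:, idx],
            lower_bound=self.lower_bound[idx],
            upper_bound=self.upper_bound[idx],
            gpr=[self.gpr[j] for j in idx],
            subsystem=[self.subsystem[j] for j in idx],
            objective_coeffs=self.objective_coeffs[idx],
            gene_ids=list(self.gene_ids),
            core_flags=self.core_flags[idx],
        )


# ---------------------------------------------------------------------------
# Media
# ---------------------------------------------------------------------------

def apply_media(model: MetabolicModel, media: dict[str, tuple[float, float]]) -> MetabolicModel:
    """Return a copy of ``model`` with exchange bounds set from a media spec.

    Listed exchange reactions get the given ``(lower, upper)`` bounds.  All
    unlisted exchange reactions are closed to uptake (``lb <- max(lb, 0)``)
    and left open to secretion — conventional minimal-media semantics.
    Non-exchange reactions are untouched.

    A media key that names a non-exchange reaction is an error; a key absent
    from the model is skipped with a warning.
    """
    out = model.copy()
    exch = model.exchange_flags
    listed = np.zeros(model.n_reactions, dtype=bool)
    for rid, (lb, ub) in media.items():
        try:
            j = model.reaction_index(rid)
        except KeyError:
            warnings.warn(f"media key {rid!r} not in model; skipped")
            continue
        if not exch[j]:
            raise ValueError(f"media key {rid!r} is not an exchange reaction")
        if lb > ub:
            raise ValueError(f"media bounds for {rid!r} have lower > upper")
        out.lower_bound[j] = lb
        out.upper_bound[j] = ub
        listed[j] = True
    close = exch & ~listed
    out.lower_bound[close] = np.maximum(out.lower_bound[close], 0.0)
    return out
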