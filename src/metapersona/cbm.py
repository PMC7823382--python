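"""Constraint-based analyses: flux balance analysis (FBA), flux variability
analysis (FVA), and single-gene deletion with growth-rate ratios.

All solves use the HiGHS linear-programming solver through
:func:`scipy.optimize.linprog`.  FBA maximizes the model objective (biomass)
subject to the steady-state constraint ``S v = 0`` and flux bounds; FVA
minimizes and maximizes each reaction's flux while holding the objective at
a stated fraction of its optimum; gene deletion closes every reaction whose
GPR rule becomes false without the gene and re-solves FBA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog

from .model import MetabolicModel, evaluate_gpr_bool

__all__ = [
    "FluxSolution",
    "FvaResult",
    "DeletionResult",
    "solve_fba",
    "fva",
    "delete_gene",
    "single_gene_deletion_all",
    "essential_genes",
]

FEASIBILITY_TOL = 1e-9


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: pd.Series | None  # indexed by reaction id

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FvaResult:
    ranges: pd.DataFrame  # index reaction id, columns min_flux / max_flux
    objective_fraction: float


@dataclass
class DeletionResult:
    wild_type_objective: float
    table: pd.DataFrame  # index gene id, columns ko_objective / gr_ratio


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _linprog_bounds(model: MetabolicModel) -> list[tuple[float | None, float | None]]:
    lo = np.where(np.isneginf(model.lower_bound), None, model.lower_bound)
    hi = np.where(np.isposinf(model.upper_bound), None, model.upper_bound)
    return list(zip(lo, hi))


def _solve(model: MetabolicModel, c: np.ndarray,
           extra_A_ub: sp.spmatrix | None = None,
           extra_b_ub: np.ndarray | None = None):
    res = linprog(
        c,
        A_ub=extra_A_ub, b_ub=extra_b_ub,
        A_eq=model.stoichiometry, b_eq=np.zeros(model.n_metabolites),
        bounds=_linprog_bounds(model),
        method="highs",
    )
    return res


def solve_fba(model: MetabolicModel) -> FluxSolution:
    """Maximize the model objective over steady-state flux distributions."""
    if not np.any(model.objective_coeffs != 0):
        raise ValueError("model has no objective reaction")
    res = _solve(model, -model.objective_coeffs)
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxSolution(status=status, objective_value=np.nan, fluxes=None)
    fluxes = pd.Series(res.x, index=model.reaction_ids, name="flux")
    return FluxSolution(status="optimal", objective_value=float(-res.fun), fluxes=fluxes)


def fva(model: MetabolicModel, fraction: float = 0.9) -> FvaResult:
    """Per-reaction min/max flux subject to ``objective >= fraction * Z*``.

    ``fraction`` in (0, 1]; each bound is an independent LP.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    base = solve_fba(model)
    if not base.optimal:
        raise ValueError(f"base model FBA not optimal (status {base.status})")
    zstar = base.objective_value
    # objective retention as a <= row: -obj . v <= -fraction * Z*
    A_ub = sp.csr_matrix(-model.objective_coeffs.reshape(1, -1))
    b_ub = np.array([-fraction * zstar])
    n = model.n_reactions
    mins = np.empty(n)
    maxs = np.empty(n)
    c = np.zeros(n)
    for j in range(n):
        c[:] = 0.0
        c[j] = 1.0
        lo = _solve_with_retention(model, c, A_ub, b_ub)
        c[j] = -1.0
        hi = _solve_with_retention(model, c, A_ub, b_ub)
        mins[j] = lo
        maxs[j] = -hi
    df = pd.DataFrame({"min_flux": mins, "max_flux": maxs}, index=model.reaction_ids)
    return FvaResult(ranges=df, objective_fraction=fraction)


def _solve_with_retention(model, c, A_ub, b_ub) -> float:
    res = _solve(model, c, A_ub, b_ub)
    if res.status != 0:
        raise ValueError(f"FVA subproblem not optimal (status {res.status})")
    return float(res.fun)


def delete_gene(model: MetabolicModel, gene_id: str) -> MetabolicModel:
    """Knockout: zero the bounds of every reaction whose GPR is false without
    ``gene_id``.  Reactions without a GPR are untouched.  An absent gene
    warns and returns the model unchanged (expression and model gene lists
    rarely coincide exactly)."""
    if gene_id not in model.gene_ids:
        warnings.warn(f"gene {gene_id!r} not in model; knockout is a no-op")
        return model.copy()
    present = frozenset(model.gene_ids) - {gene_id}
    out = model.copy()
    for j, g in enumerate(model.gpr):
        if g is not None and gene_id in g.genes() and not evaluate_gpr_bool(g, present):
            out.lower_bound[j] = 0.0
            out.upper_bound[j] = 0.0
    return out


def single_gene_deletion_all(model: MetabolicModel,
                             genes: list[str] | None = None) -> DeletionResult:
    """grRatio = knockout optimum / wild-type optimum for each gene.

    Genes disabling no reaction keep grRatio 1 without a solve; infeasible
    knockouts get grRatio 0.  Ratios are clipped to [0, 1] for reporting.
    """
    wt = solve_fba(model)
    if not wt.optimal or wt.objective_value <= 0:
        raise ValueError(
            "wild-type FBA optimum must be positive; check media and objective")
    zstar = wt.objective_value
    genes = list(genes) if genes is not None else list(model.gene_ids)
    present_all = frozenset(model.gene_ids)
    ko_obj = np.empty(len(genes))
    for i, gene in enumerate(genes):
        disabled = []
        for j, g in enumerate(model.gpr):
            if g is not None and gene in g.genes() and \
                    not evaluate_gpr_bool(g, present_all - {gene}):
                disabled.append(j)
        if not disabled:
            ko_obj[i] = zstar
            continue
        ko = model.copy()
        ko.lower_bound[disabled] = 0.0
        ko.upper_bound[disabled] = 0.0
        sol = solve_fba(ko)
        ko_obj[i] = sol.objective_value if sol.optimal else 0.0
    ratio = np.clip(ko_obj / zstar, 0.0, 1.0)
    table = pd.DataFrame({"ko_objective": ko_obj, "gr_ratio": ratio}, index=genes)
    table.index.name = "gene"
    return DeletionResult(wild_type_objective=zstar, table=table)


def essential_genes(result: DeletionResult, threshold: float = 0.9) -> set[str]:
    """Genes whose knockout drops growth below ``threshold`` of wild type."""
    mask = result.table["gr_ratio"] < threshold
    return set(result.table.index[mask])
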