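"""Context-specific network extraction with the iMAT mixed-integer program.

Given a per-reaction ternary state vector derived from a sample's expression
coding (+1 "high", -1 "low", 0 uninformative), iMAT searches for a
steady-state flux distribution that maximizes agreement with the states: a
+1 reaction agrees when it carries flux of magnitude at least ``epsilon``,
a -1 reaction agrees when its flux magnitude is at most ``tol``.  Agreement
is rewarded, never forced, so a sample's network always remains able to
produce biomass.  Core reactions (biomass synthesis, ATP synthase) are the
exception: they are hard-constrained to be active, and the objective
(biomass) flux is held at a configurable fraction of the full model's
optimum so every extracted network supports that level of growth.

The MILP uses big-M indicator constraints and is solved with HiGHS through
:func:`scipy.optimize.milp`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .cbm import fva, solve_fba
from .model import MetabolicModel, gene_states_to_reaction_state

__all__ = [
    "ImatConfig",
    "ImatSolution",
    "ContextNetwork",
    "reaction_states_from_genes",
    "solve_imat",
    "extract_context_network",
    "classify_active",
]


@dataclass
class ImatConfig:
    """iMAT parameters.

    epsilon
        Minimum flux magnitude for a reaction to count as active (flux
        units of the model; default 1.0).
    tol
        Activity tolerance: a -1 reaction agrees when |v| <= tol.
    objective_fraction
        Biomass retention: the extracted network must support at least this
        fraction of the full model's FBA optimum (0 disables).
    time_limit
        MILP wall-clock limit in seconds; on timeout the best incumbent is
        used and flagged.
    """

    epsilon: float = 1.0
    tol: float = 1e-6
    objective_fraction: float = 0.9
    time_limit: float = 60.0

    def __post_init__(self) -> None:
        if not (self.epsilon > self.tol > 0):
            raise ValueError("require epsilon > tol > 0")


@dataclass
class ImatSolution:
    fluxes: pd.Series  # per reaction
    score: int  # number of satisfied +1/-1 states
    status: str  # optimal | incumbent
    objective_value: float  # biomass flux of the iMAT solution


@dataclass
class ContextNetwork:
    """Per-sample context-specific network over the full model's reaction index."""

    sample_id: str
    states: pd.Series  # 1 retained / 0 removed, full reaction index
    fluxes: pd.Series  # iMAT fluxes, full reaction index
    retained_reaction_ids: list[str] = field(default_factory=list)

    def context_model(self, model: MetabolicModel) -> MetabolicModel:
        keep = self.states.reindex(model.reaction_ids).to_numpy(dtype=bool)
        return model.subset_reactions(keep)


def reaction_states_from_genes(model: MetabolicModel,
                               ternary_genes: pd.DataFrame) -> pd.DataFrame:
    """Map a gene x sample ternary matrix to reaction x sample states.

    Applies the min-for-AND / max-for-OR rule per reaction GPR; reactions
    without a GPR, and genes missing from a sample's coding, get state 0.
    """
    overlap = set(ternary_genes.index) & set(model.gene_ids)
    if not overlap:
        raise ValueError("no overlap between coded genes and model genes")
    out = np.zeros((model.n_reactions, ternary_genes.shape[1]), dtype=np.int8)
    for s, col in enumerate(ternary_genes.columns):
        gene_states = ternary_genes[col].to_dict()
        for j, g in enumerate(model.gpr):
            if g is not None:
                out[j, s] = gene_states_to_reaction_state(g, gene_states)
    return pd.DataFrame(out, index=model.reaction_ids, columns=ternary_genes.columns)


def _big_m_bounds(model: MetabolicModel) -> tuple[np.ndarray, np.ndarray]:
    finite = np.concatenate([
        model.lower_bound[np.isfinite(model.lower_bound)],
        model.upper_bound[np.isfinite(model.upper_bound)],
    ])
    big = max(1000.0, float(np.max(np.abs(finite))) if finite.size else 0.0)
    lb = np.where(np.isfinite(model.lower_bound), model.lower_bound, -big)
    ub = np.where(np.isfinite(model.upper_bound), model.upper_bound, big)
    return lb, ub


def solve_imat(model: MetabolicModel, reaction_states: pd.Series | np.ndarray,
               config: ImatConfig | None = None) -> ImatSolution:
    """Solve the iMAT MILP for one sample's reaction state vector.

    Returns the flux distribution and the consistency score (count of
    satisfied +1/-1 states).  Raises if the hard constraints — steady state,
    core-reaction activity, biomass retention — are jointly infeasible,
    naming the core reactions.
    """
    config = config or ImatConfig()
    if isinstance(reaction_states, pd.Series):
        states = reaction_states.reindex(model.reaction_ids).fillna(0).to_numpy(dtype=int)
    else:
        states = np.asarray(reaction_states, dtype=int)
    if states.shape != (model.n_reactions,):
        raise ValueError("reaction state vector length mismatch")

    n = model.n_reactions
    eps, tol = config.epsilon, config.tol
    lb, ub = _big_m_bounds(model)

    # variable layout: v_0..v_{n-1}, then one binary per indicator
    n_bin = 0
    bin_idx: dict[tuple[int, str], int] = {}

    def new_bin(j: int, kind: str) -> int:
        nonlocal n_bin
        bin_idx[(j, kind)] = n + n_bin
        n_bin += 1
        return n + n_bin - 1

    rows: list[tuple[dict[int, float], float, float]] = []  # (coeffs, lo, hi)
    obj_terms: list[int] = []
    core = model.core_flags

    for j in range(n):
        st = states[j]
        if st == 1 or core[j]:
            can_fwd = ub[j] > 0
            can_bwd = lb[j] < 0
            idx_f = idx_b = None
            if can_fwd:
                idx_f = new_bin(j, "fwd")
                # yf=1 -> v_j >= eps
                rows.append(({j: 1.0, idx_f: lb[j] - eps}, lb[j], np.inf))
            if can_bwd:
                idx_b = new_bin(j, "bwd")
                # yb=1 -> v_j <= -eps
                rows.append(({j: 1.0, idx_b: ub[j] + eps}, -np.inf, ub[j]))
            present = [i for i in (idx_f, idx_b) if i is not None]
            if core[j]:
                if not present:
                    raise ValueError(
                        f"core reaction {model.reaction_ids[j]!r} cannot carry flux")
                rows.append(({i: 1.0 for i in present}, 1.0, 1.0))
            else:
                if len(present) == 2:
                    rows.append(({i: 1.0 for i in present}, -np.inf, 1.0))
                obj_terms.extend(present)
        elif st == -1:
            idx_z = new_bin(j, "off")
            # z=1 -> -tol <= v_j <= tol
            rows.append(({j: 1.0, idx_z: lb[j] + tol}, lb[j], np.inf))
            rows.append(({j: 1.0, idx_z: ub[j] - tol}, -np.inf, ub[j]))
            obj_terms.append(idx_z)

    n_var = n + n_bin
    c = np.zeros(n_var)
    c[obj_terms] = -1.0  # milp minimizes

    # steady state S v = 0
    A_eq = sp.hstack([model.stoichiometry, sp.csr_matrix((model.n_metabolites, n_bin))])
    constraints = [LinearConstraint(A_eq, 0.0, 0.0)]

    if config.objective_fraction > 0:
        base = solve_fba(model)
        if not base.optimal:
            raise ValueError(
                "full model FBA infeasible; cannot impose biomass retention; "
                f"core reactions: {[model.reaction_ids[j] for j in np.flatnonzero(core)]}")
        target = config.objective_fraction * base.objective_value
        row = sp.csr_matrix(
            (model.objective_coeffs, (np.zeros(n, dtype=int), np.arange(n))),
            shape=(1, n_var))
        constraints.append(LinearConstraint(row, target, np.inf))

    if rows:
        data, ri, ci = [], [], []
        los, his = [], []
        for r, (coeffs, lo_r, hi_r) in enumerate(rows):
            for idx, val in coeffs.items():
                ri.append(r)
                ci.append(idx)
                data.append(val)
            los.append(lo_r)
            his.append(hi_r)
        A = sp.csr_matrix((data, (ri, ci)), shape=(len(rows), n_var))
        constraints.append(LinearConstraint(A, los, his))

    var_lb = np.concatenate([lb, np.zeros(n_bin)])
    var_ub = np.concatenate([ub, np.ones(n_bin)])
    integrality = np.concatenate([np.zeros(n), np.ones(n_bin)])

    res = milp(c, constraints=constraints, bounds=Bounds(var_lb, var_ub),
               integrality=integrality, options={"time_limit": config.time_limit})
    if res.status == 2 or res.x is None:
        core_ids = [model.reaction_ids[j] for j in np.flatnonzero(core)]
        raise ValueError(
            f"iMAT MILP infeasible; core reactions {core_ids} cannot all be "
            "activated under the current media/bounds")
    status = "optimal" if res.status == 0 else "incumbent"
    v = res.x[:n]
    score = int(round(-res.fun)) if res.fun is not None else int(np.sum(c[n:] * res.x[n:] * -1))
    fluxes = pd.Series(v, index=model.reaction_ids, name="flux")
    return ImatSolution(
        fluxes=fluxes, score=score, status=status,
        objective_value=float(model.objective_coeffs @ v))


def extract_context_network(model: MetabolicModel, solution: ImatSolution,
                            config: ImatConfig | None = None,
                            sample_id: str = "sample") -> ContextNetwork:
    """Reactions carrying flux above ``tol`` in the iMAT solution, plus all
    core reactions, form the context network; everything else is removed."""
    config = config or ImatConfig()
    v = solution.fluxes.to_numpy()
    keep = (np.abs(v) > config.tol) | model.core_flags
    states = pd.Series(keep.astype(np.int8), index=model.reaction_ids, name=sample_id)
    return ContextNetwork(
        sample_id=sample_id,
        states=states,
        fluxes=solution.fluxes.copy(),
        retained_reaction_ids=[r for r, k in zip(model.reaction_ids, keep) if k],
    )


def classify_active(context_model: MetabolicModel, fraction: float = 0.9,
                    tol: float = 1e-6) -> pd.DataFrame:
    """FVA-based activity call on a context model.

    A reaction is active (1) iff it can carry flux of magnitude above
    ``tol`` somewhere in the flux space retaining ``fraction`` of the
    context model's biomass optimum.  Returns a frame with the FVA ranges
    and the binary ``active`` column.
    """
    result = fva(context_model, fraction=fraction)
    ranges = result.ranges
    active = (np.maximum(np.abs(ranges["min_flux"]), np.abs(ranges["max_flux"])) > tol)
    out = ranges.copy()
    out["active"] = active.astype(np.int8)
    return out
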