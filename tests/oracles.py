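"""Independent brute-force oracles used to validate the solver-backed code.

These deliberately avoid the implementation paths they check: the FBA
oracle enumerates basic feasible solutions of the flux polytope, the iMAT
oracle enumerates activity patterns and checks each with a plain
feasibility LP, and the statistics oracles enumerate tables/permutations
directly from the definitions.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog
from scipy.special import comb
from scipy.stats import hypergeom


# ---------------------------------------------------------------------------
# FBA: vertex enumeration
# ---------------------------------------------------------------------------

def enumerate_fba_optimum(model) -> float:
    """Maximum objective over enumerated basic feasible solutions of
    {S v = 0, lb <= v <= ub}.  Requires finite bounds; intended for
    networks with at most ~8 reactions."""
    S = model.stoichiometry.toarray()
    n = model.n_reactions
    lb, ub = model.lower_bound, model.upper_bound
    assert np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))
    r = np.linalg.matrix_rank(S) if S.size else 0
    best = -np.inf
    for basis in itertools.combinations(range(n), r):
        B = S[:, basis]
        if r and np.linalg.matrix_rank(B) < r:
            continue
        nonbasic = [j for j in range(n) if j not in basis]
        for choice in itertools.product(*[(lb[j], ub[j]) for j in nonbasic]):
            v = np.zeros(n)
            v[nonbasic] = choice
            if r:
                rhs = -S[:, nonbasic] @ np.asarray(choice)
                sol, *_ = np.linalg.lstsq(B, rhs, rcond=None)
                v[list(basis)] = sol
            if (np.allclose(S @ v, 0, atol=1e-7)
                    and np.all(v >= lb - 1e-7) and np.all(v <= ub + 1e-7)):
                best = max(best, float(model.objective_coeffs @ v))
    return best


# ---------------------------------------------------------------------------
# iMAT: exhaustive activity-pattern enumeration
# ---------------------------------------------------------------------------

def _feasible(model, lb, ub, obj_floor) -> bool:
    A_ub = b_ub = None
    if obj_floor is not None:
        A_ub = -model.objective_coeffs.reshape(1, -1)
        b_ub = np.array([-obj_floor])
    res = linprog(np.zeros(model.n_reactions),
                  A_ub=A_ub, b_ub=b_ub,
                  A_eq=model.stoichiometry.toarray(),
                  b_eq=np.zeros(model.n_metabolites),
                  bounds=list(zip(lb, ub)), method="highs")
    return res.status == 0


def enumerate_imat_score(model, states, epsilon, tol, objective_fraction=0.0,
                         zstar=None) -> int:
    """Best consistency score over all activity patterns.

    For every +1-state reaction the pattern picks unsatisfied / forward
    active / backward active; for every -1-state reaction, free / off.
    Core reactions are always forced active.  A pattern's constraints are
    checked by a feasibility LP; the score of a feasible pattern is its
    number of satisfied +/-1 states.
    """
    states = np.asarray(states, dtype=int)
    lb0, ub0 = model.lower_bound.copy(), model.upper_bound.copy()
    obj_floor = None
    if objective_fraction > 0:
        assert zstar is not None
        obj_floor = objective_fraction * zstar
    choices = []
    scored = []
    for j in range(model.n_reactions):
        st = states[j]
        core = bool(model.core_flags[j])
        opts: list[tuple[str, int]] = []
        if core:
            # forced active; carries no reward (matching the MILP objective)
            if ub0[j] > 0:
                opts.append(("fwd", 0))
            if lb0[j] < 0:
                opts.append(("bwd", 0))
        elif st == 1:
            opts = [("free", 0)]
            if ub0[j] > 0:
                opts.append(("fwd", 1))
            if lb0[j] < 0:
                opts.append(("bwd", 1))
        elif st == -1:
            opts = [("free", 0), ("off", 1)]
        else:
            opts = [("free", 0)]
        choices.append(opts)
    best = -1
    for combo in itertools.product(*choices):
        lb, ub = lb0.copy(), ub0.copy()
        score = 0
        for j, (mode, pts) in enumerate(combo):
            if mode == "fwd":
                lb[j] = max(lb[j], epsilon)
            elif mode == "bwd":
                ub[j] = min(ub[j], -epsilon)
            elif mode == "off":
                lb[j] = max(lb[j], -tol)
                ub[j] = min(ub[j], tol)
            score += pts
        if score <= best:
            continue
        if np.any(lb > ub):
            continue
        if _feasible(model, lb, ub, obj_floor):
            best = score
    return best


# ---------------------------------------------------------------------------
# statistics oracles
# ---------------------------------------------------------------------------

def fisher_exact_enumeration(table) -> float:
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    row1, col1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0
    rv = hypergeom(n, col1, row1)
    p_obs = rv.pmf(a)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        px = rv.pmf(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


def bh_stepup(pvalues) -> np.ndarray:
    """BH q-values straight from the step-up definition."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        j = m - rank_from_top  # 1-based rank of this p-value
        running = min(running, p[idx] * m / j)
        q[idx] = running
    return np.minimum(q, 1.0)


def wilcoxon_exact_p(x, y) -> float:
    """Two-sided rank-sum p by enumerating all group assignments (no ties)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == pooled.size, "oracle assumes no ties"
    nx = x.size
    ranks = pooled.argsort().argsort() + 1
    obs = ranks[:nx].sum()
    sums = [sum(combo) for combo in itertools.combinations(ranks, nx)]
    sums = np.asarray(sums, float)
    mean = sums.mean()
    extreme = np.sum(np.abs(sums - mean) >= abs(obs - mean) - 1e-9)
    return float(extreme / len(sums))


def spearman_rho_formula(x, y) -> float:
    """1 - 6 sum d^2 / (n(n^2-1)) — valid without ties."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    rx = x.argsort().argsort() + 1
    ry = y.argsort().argsort() + 1
    n = x.size
    return float(1 - 6 * np.sum((rx - ry) ** 2) / (n * (n ** 2 - 1)))


def km_product_limit(times, events):
    """Hand product-limit estimator: list of (time, survival)."""
    order = np.argsort(times, kind="mergesort")
    t_sorted = np.asarray(times, float)[order]
    e_sorted = np.asarray(events, int)[order]
    at_risk = len(t_sorted)
    s = 1.0
    out = []
    i = 0
    while i < len(t_sorted):
        t = t_sorted[i]
        deaths = 0
        removed = 0
        while i < len(t_sorted) and t_sorted[i] == t:
            deaths += e_sorted[i]
            removed += 1
            i += 1
        if deaths:
            s *= 1 - deaths / at_risk
        out.append((t, s))
        at_risk -= removed
    return out
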