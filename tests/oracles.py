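"""Independent oracles used by the test suite.

These deliberately avoid the package's own solution paths: the LP oracle
enumerates basic feasible solutions instead of calling a simplex code, the
rank-test oracles enumerate assignments directly, and the hypergeometric
oracle uses the closed-form 2x2 sum.
"""

from __future__ import annotations

import itertools
import math
from typing import List, Optional, Sequence, Tuple

import numpy as np


def enumerate_lp_max(
    c: np.ndarray,
    A_eq: np.ndarray,
    A_ub: Optional[np.ndarray],
    b_ub: Optional[np.ndarray],
    bounds: Sequence[Tuple[float, float]],
    tol: float = 1e-8,
) -> Optional[float]:
    """Maximum of c'x s.t. A_eq x = 0, A_ub x <= b_ub, lb <= x <= ub, by
    enumerating all vertices (basic feasible solutions) of the polytope.

    Returns None when no feasible vertex exists.  Assumes the feasible set
    is bounded (all toy models used with this oracle have finite bounds).
    """
    n = len(c)
    cand_rows: List[np.ndarray] = []
    cand_rhs: List[float] = []
    if A_ub is not None:
        for row, b in zip(A_ub, b_ub):
            cand_rows.append(np.asarray(row, dtype=float))
            cand_rhs.append(float(b))
    for j, (lb, ub) in enumerate(bounds):
        e = np.zeros(n)
        e[j] = 1.0
        if np.isfinite(lb):
            cand_rows.append(e.copy())
            cand_rhs.append(float(lb))
        if np.isfinite(ub):
            cand_rows.append(e.copy())
            cand_rhs.append(float(ub))

    A_eq = np.asarray(A_eq, dtype=float).reshape(-1, n)
    rank_eq = np.linalg.matrix_rank(A_eq) if A_eq.size else 0
    k = n - rank_eq
    best = None
    lbs = np.array([b[0] for b in bounds])
    ubs = np.array([b[1] for b in bounds])
    for combo in itertools.combinations(range(len(cand_rows)), k):
        A = np.vstack([A_eq] + [cand_rows[i] for i in combo]) if A_eq.size \
            else np.vstack([cand_rows[i] for i in combo])
        b = np.concatenate([np.zeros(A_eq.shape[0] if A_eq.size else 0),
                            [cand_rhs[i] for i in combo]])
        if np.linalg.matrix_rank(A) < n:
            continue
        x, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.max(np.abs(A @ x - b)) > tol:
            continue
        # feasibility of the full system
        if (x < lbs - tol).any() or (x > ubs + tol).any():
            continue
        if A_ub is not None and (A_ub @ x > np.asarray(b_ub) + tol).any():
            continue
        val = float(c @ x)
        if best is None or val > best:
            best = val
    return best


def oracle_fba_max(model, objective_reaction_id: str) -> Optional[float]:
    """Vertex-enumeration FBA oracle over a StoichiometricModel."""
    from gutwbm.fba_engine import LinearProblem

    lp = LinearProblem(model)  # reuses only the array *construction*
    c = np.zeros(len(lp.reaction_ids))
    c[lp.rxn_index[objective_reaction_id]] = 1.0
    return enumerate_lp_max(c, lp.S, lp.A_ub, lp.b_ub, lp.bounds)


def random_toy_model(rng: np.random.Generator, n_reactions: int = 8):
    """A random, always-feasible (0 in the box), bounded toy network with a
    few coupling constraints."""
    from gutwbm.model_assembly import StoichiometricModel

    n_mets = rng.integers(3, max(4, n_reactions - 2))
    model = StoichiometricModel("random_toy")
    met_ids = [f"m{i}[c]" for i in range(n_mets)]
    for j in range(n_reactions):
        k = int(rng.integers(1, min(3, n_mets) + 1))
        mets = rng.choice(n_mets, size=k, replace=False)
        coefs = rng.choice([-2.0, -1.0, 1.0, 2.0], size=k)
        lb = float(rng.choice([0.0, -5.0]))
        ub = float(rng.choice([2.0, 10.0]))
        model.add_reaction(f"r{j}", {met_ids[i]: float(cc)
                                     for i, cc in zip(mets, coefs)}, lb, ub)
    # couple a couple of reactions to a pseudo-biomass reaction
    if n_reactions >= 4 and rng.random() < 0.7:
        bio = f"r{int(rng.integers(0, n_reactions))}"
        for j in rng.choice(n_reactions, size=2, replace=False):
            rid = f"r{int(j)}"
            if rid != bio:
                model.add_coupling(rid, bio, float(rng.choice([2.0, 400.0])))
    return model


def wilcoxon_exact_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided rank-sum p by enumerating all C(n, na) group assignments."""
    pooled = np.asarray(list(a) + list(b), dtype=float)
    na = len(a)
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    obs = ranks[:na].sum()
    n = len(pooled)
    mean = na * (n + 1) / 2.0
    count = 0
    extreme = 0
    for combo in itertools.combinations(range(n), na):
        s = ranks[list(combo)].sum()
        count += 1
        if abs(s - mean) >= abs(obs - mean) - 1e-12:
            extreme += 1
    return extreme / count


def kruskal_exact_p(groups: Sequence[Sequence[float]]) -> float:
    """Exact permutation p of the KW statistic via scipy's H on every
    distinct assignment of the pooled values to the group sizes."""
    from scipy.stats import kruskal

    pooled = [v for g in groups for v in g]
    sizes = [len(g) for g in groups]
    h_obs = kruskal(*groups).statistic
    n = len(pooled)
    idx = list(range(n))
    count = 0
    extreme = 0
    for perm in _distinct_assignments(idx, sizes):
        parts = [[pooled[i] for i in part] for part in perm]
        h = kruskal(*parts).statistic
        count += 1
        if h >= h_obs - 1e-12:
            extreme += 1
    return extreme / count


def _distinct_assignments(idx: List[int], sizes: List[int]):
    if len(sizes) == 1:
        yield [tuple(idx)]
        return
    first = idx[0]  # fix the first element's group partner sets canonically
    for combo in itertools.combinations(idx, sizes[0]):
        rest = [i for i in idx if i not in set(combo)]
        for tail in _distinct_assignments(rest, sizes[1:]):
            yield [combo] + tail


def hypergeom_2x2_two_sided(table) -> float:
    """Classic two-sided Fisher p for a 2x2 table: sum of hypergeometric
    probabilities not exceeding the observed one."""
    (a, b), (c, d) = table
    n1, n2 = a + b, c + d
    k = a + c
    N = n1 + n2

    def pmf(x):
        return (math.comb(n1, x) * math.comb(n2, k - x)) / math.comb(N, k)

    p_obs = pmf(a)
    total = 0.0
    for x in range(max(0, k - n2), min(n1, k) + 1):
        p = pmf(x)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return total
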