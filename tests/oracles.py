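"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own LP/classification code paths:
vertices are enumerated combinatorially, flux-cone extreme rays are found
by nullspace analysis over column subsets, and GPR rules are evaluated by
Python's own boolean ``eval`` after gene-id substitution.
"""

from __future__ import annotations

import itertools
import re

import numpy as np

TOL = 1e-7


# --------------------------------------------------------------------------
# GPR via Python eval (and/or/parentheses are Python syntax)


def eval_gpr_text(rule: str, active_genes_true: dict[str, bool]) -> bool:
    """Evaluate a GPR rule string with Python's boolean semantics."""
    if not rule.strip():
        return True
    expr = rule
    for gene, truth in active_genes_true.items():
        expr = re.sub(rf"(?<![\w]){re.escape(gene)}(?![\w])",
                      str(bool(truth)), expr)
    return bool(eval(expr, {"__builtins__": {}}, {}))


# --------------------------------------------------------------------------
# Vertex enumeration for {A_eq v = 0, lb <= v <= ub, A_ub v <= b_ub}


def enumerate_vertices(A_eq, lb, ub, A_ub=None, b_ub=None, tol=TOL):
    """All vertices of a bounded polyhedron, by active-set enumeration."""
    A_eq = np.atleast_2d(np.asarray(A_eq, dtype=float))
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    n = len(lb)
    rows, rhs = [], []
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        rows.append(e.copy())
        rhs.append(ub[j])
        rows.append(-e)
        rhs.append(-lb[j])
    if A_ub is not None:
        for row, b in zip(np.atleast_2d(A_ub), np.atleast_1d(b_ub)):
            rows.append(np.asarray(row, dtype=float))
            rhs.append(float(b))
    rows = np.array(rows)
    rhs = np.array(rhs)
    rank_eq = np.linalg.matrix_rank(A_eq) if A_eq.size else 0
    need = n - rank_eq
    b_eq = np.zeros(A_eq.shape[0])
    vertices = []
    for combo in itertools.combinations(range(len(rows)), need):
        M = np.vstack([A_eq, rows[list(combo)]])
        b = np.concatenate([b_eq, rhs[list(combo)]])
        if np.linalg.matrix_rank(M) < n:
            continue
        v, residuals, rank, _ = np.linalg.lstsq(M, b, rcond=None)
        if not np.allclose(M @ v, b, atol=1e-8):
            continue
        if np.any(v < lb - tol) or np.any(v > ub + tol):
            continue
        if not np.allclose(A_eq @ v, b_eq, atol=1e-8):
            continue
        if rows.size and np.any(rows @ v > rhs + 1e-8):
            continue
        if not any(np.allclose(v, w, atol=1e-7) for w in vertices):
            vertices.append(v)
    return vertices


# --------------------------------------------------------------------------
# Extreme rays of the flux cone {A u = 0, u >= 0}


def extreme_rays(A, tol=TOL):
    """Extreme rays by exhaustive support enumeration (small cones only)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    n = A.shape[1]
    rays = []
    for size in range(1, n + 1):
        for support in itertools.combinations(range(n), size):
            sub = A[:, list(support)]
            # nullspace of the support submatrix
            _, s, vt = np.linalg.svd(sub)
            null_mask = np.zeros(size, dtype=bool)
            nullity = size - int(np.sum(s > 1e-9)) if s.size else size
            if nullity != 1:
                continue
            direction = vt[-1]
            if np.all(direction <= tol):
                direction = -direction
            if np.any(direction <= tol):
                continue    # support not strictly positive -> not this support
            ray = np.zeros(n)
            ray[list(support)] = direction / np.max(direction)
            if not any(_same_ray(ray, r) for r in rays):
                rays.append(ray)
    return rays


def _same_ray(a, b, tol=1e-7):
    sa, sb = set(np.nonzero(a > tol)[0]), set(np.nonzero(b > tol)[0])
    if sa != sb:
        return False
    j = next(iter(sa))
    return np.allclose(a / a[j], b / b[j], atol=1e-6)


def coupling_from_rays(A, cols, tol=1e-7):
    """Half-level coupling relations from extreme rays.

    ``cols`` is the list of (reaction_id, sign) half columns matching A's
    columns.  Returns a dict over unordered reaction-id pairs with the
    strongest relation among their half pairs, in the same vocabulary as
    the package (fully / partially / directional / uncoupled), plus the
    set of cone-blocked reactions (no ray touches any half).
    """
    rays = extreme_rays(A, tol)
    n = A.shape[1]
    strength = {"fully": 4, "partially": 3, "directional": 2, "uncoupled": 1}

    def half_relation(i, j):
        ri = [r for r in rays if r[i] > tol]
        rj = [r for r in rays if r[j] > tol]
        if not ri or not rj:
            return None
        i_to_j = all(r[j] > tol for r in ri)
        j_to_i = all(r[i] > tol for r in rj)
        if i_to_j and j_to_i:
            ratios = [r[j] / r[i] for r in ri]
            if max(ratios) - min(ratios) <= 1e-6 * max(1.0, max(ratios)):
                return "fully", ratios[0]
            return "partially", None
        if i_to_j:
            return "directional_i_to_j", None
        if j_to_i:
            return "directional_j_to_i", None
        return "uncoupled", None

    alive = {cols[k][0] for k in range(n)
             if any(r[k] > tol for r in rays)}
    relations = {}
    ids = sorted(alive)
    for a_pos in range(len(ids)):
        for b_pos in range(a_pos + 1, len(ids)):
            a, b = ids[a_pos], ids[b_pos]
            best = ("uncoupled", None, "")
            for i in range(n):
                if cols[i][0] != a or not any(r[i] > tol for r in rays):
                    continue
                for j in range(n):
                    if cols[j][0] != b or not any(r[j] > tol for r in rays):
                        continue
                    rel = half_relation(i, j)
                    if rel is None:
                        continue
                    kind, ratio = rel
                    if kind == "fully":
                        cand = ("fully",
                                cols[i][1] * cols[j][1] * ratio, "")
                    elif kind == "partially":
                        cand = ("partially", None, "")
                    elif kind == "directional_i_to_j":
                        cand = ("directional", None, "a_to_b")
                    elif kind == "directional_j_to_i":
                        cand = ("directional", None, "b_to_a")
                    else:
                        cand = ("uncoupled", None, "")
                    if strength[cand[0]] > strength[best[0]]:
                        best = cand
            relations[frozenset((a, b))] = best
    blocked = {cols[k][0] for k in range(n)} - alive
    return relations, blocked


# --------------------------------------------------------------------------
# Random small networks


def random_network(rng, n_mets=None, n_rxns=None):
    """A random small metabolic network as plain arrays.

    Returns (S, lb, ub).  Columns mix internal conversions with
    single-metabolite boundary reactions so nonzero steady states exist.
    """
    n_mets = n_mets or int(rng.integers(2, 5))
    n_rxns = n_rxns or int(rng.integers(3, 9))
    S = np.zeros((n_mets, n_rxns))
    lb = np.zeros(n_rxns)
    ub = np.zeros(n_rxns)
    for j in range(n_rxns):
        if rng.random() < 0.4:   # boundary column
            i = int(rng.integers(n_mets))
            S[i, j] = rng.choice([-1.0, 1.0])
        else:
            k = int(rng.integers(2, min(3, n_mets) + 1))
            mets = rng.choice(n_mets, size=k, replace=False)
            coeffs = rng.choice([-2.0, -1.0, 1.0, 2.0], size=k)
            if np.all(coeffs > 0):
                coeffs[0] = -coeffs[0]
            if np.all(coeffs < 0):
                coeffs[-1] = -coeffs[-1]
            S[mets, j] = coeffs
        reversible = rng.random() < 0.3
        lb[j] = -float(rng.integers(1, 11)) if reversible else 0.0
        ub[j] = float(rng.integers(1, 11))
    return S, lb, ub


def arrays_to_model(S, lb, ub, objective_col=None):
    """Wrap plain arrays into a MetabolicModel for the package API."""
    from bifidoflux.netcore import Metabolite, MetabolicModel, Reaction

    n_mets, n_rxns = S.shape
    mets = [Metabolite(f"m{i}_c", compartment="c") for i in range(n_mets)]
    rxns = []
    for j in range(n_rxns):
        stoich = {f"m{i}_c": float(S[i, j])
                  for i in range(n_mets) if S[i, j] != 0}
        rxns.append(Reaction(f"r{j}", stoich, float(lb[j]), float(ub[j])))
    model = MetabolicModel(
        id="random", metabolites=mets, reactions=rxns,
        objective_reaction_id=f"r{objective_col}"
        if objective_col is not None else "")
    model.validate()
    return model
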