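"""Independent reference implementations used only by tests.

These deliberately avoid the package's own code paths: chi/Wiener/path
counts go through networkx, the SVR dual through a dense SLSQP quadratic
program, and PLS through ordinary least squares.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from scipy.optimize import minimize


# ---------------------------------------------------------------------------
# graph oracles
# ---------------------------------------------------------------------------


def to_networkx(g) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(g.n_atoms))
    G.add_edges_from((b.i, b.j) for b in g.bonds)
    return G


def wiener_oracle(g) -> int:
    G = to_networkx(g)
    total = 0
    for _, lengths in nx.all_pairs_shortest_path_length(G):
        total += sum(lengths.values())
    return total // 2


def connected_subgraphs_oracle(g, m: int):
    """All connected m-edge subgraphs as (vertex tuple, edge tuple)."""
    G = to_networkx(g)
    edges = list(G.edges())
    out = []
    for combo in itertools.combinations(range(len(edges)), m):
        sub = nx.Graph(list(edges[e] for e in combo))
        if nx.is_connected(sub):
            out.append((tuple(sorted(sub.nodes())), combo))
    return out


def chi_oracle(g, order: int, kind: str, valence: bool) -> float:
    """Exhaustive Kier-Hall connectivity index via networkx enumeration."""
    from qsartox.descriptors import valence_deltas

    deltas = (
        valence_deltas(g) if valence else g.degrees().astype(float)
    )
    if order == 0:
        return float(np.sum(1.0 / np.sqrt(deltas))) if kind == "path" else 0.0
    G = to_networkx(g)
    edges = list(G.edges())
    total = 0.0
    for combo in itertools.combinations(range(len(edges)), order):
        sub = nx.Graph(list(edges[e] for e in combo))
        if not nx.is_connected(sub):
            continue
        nodes = list(sub.nodes())
        if len(nodes) != order + 1:
            continue  # cyclic subgraph: ring type, not one of the three kinds
        degs = sorted(dict(sub.degree()).values())
        if degs[-1] <= 2:
            k = "path"
        elif degs[-1] == order:
            k = "cluster"
        else:
            k = "path-cluster"
        if k == kind:
            total += 1.0 / np.sqrt(np.prod([deltas[v] for v in nodes]))
    return total


def path_count_oracle(g, length: int) -> int:
    """Count simple paths with ``length`` edges via node-sequence search."""
    G = to_networkx(g)
    count = 0
    for seq in itertools.permutations(G.nodes(), length + 1):
        if seq[0] > seq[-1]:
            continue  # each undirected path once
        if all(G.has_edge(a, b) for a, b in zip(seq, seq[1:])):
            count += 1
    return count


# ---------------------------------------------------------------------------
# SVR dual QP oracle
# ---------------------------------------------------------------------------


def svr_qp_oracle(K: np.ndarray, y: np.ndarray, C: float, epsilon: float):
    """Brute-force epsilon-SVR dual via SLSQP on the 2n-variable QP.

    Returns (beta, bias, objective).  Multi-start for robustness on flat
    problems; objective computed at the complementary representation.
    """
    n = len(y)
    z = np.concatenate([np.ones(n), -np.ones(n)])
    p = np.concatenate([epsilon - y, epsilon + y])
    Q = np.block([[K, -K], [-K, K]])

    def f(t):
        return 0.5 * t @ Q @ t + p @ t

    def jac(t):
        return Q @ t + p

    cons = [{"type": "eq", "fun": lambda t: z @ t, "jac": lambda t: z}]
    best = None
    for trial in range(3):
        rng = np.random.default_rng(trial)
        x0 = np.zeros(2 * n)
        if trial:
            x0 = rng.uniform(0, min(C, 1.0), 2 * n)
            x0 -= z * (z @ x0) / (2 * n)
            x0 = np.clip(x0, 0, C)
        res = minimize(
            f, x0, jac=jac, bounds=[(0, C)] * (2 * n), constraints=cons,
            method="SLSQP", options={"maxiter": 2000, "ftol": 1e-14},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    beta = theta[:n] - theta[n:]
    obj = 0.5 * beta @ K @ beta + epsilon * np.abs(beta).sum() - y @ beta

    # bias via the KKT interval midpoint, mirroring the package convention
    grad = Q @ theta + p
    s = -z * grad
    tol = 1e-8 * max(1.0, C)
    up = np.where(z > 0, theta < C - tol, theta > tol)
    low = np.where(z > 0, theta > tol, theta < C - tol)
    m = np.max(np.where(up, s, -np.inf))
    M = np.min(np.where(low, s, np.inf))
    if not np.isfinite(m):
        m = M
    if not np.isfinite(M):
        M = m
    return beta, 0.5 * (m + M), float(obj)


# ---------------------------------------------------------------------------
# regression oracles
# ---------------------------------------------------------------------------


def ols_oracle(X: np.ndarray, y: np.ndarray):
    """Least squares with intercept via normal equations."""
    Xa = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(Xa, y, rcond=None)
    return coef[0], coef[1:]


def mrmr_step_oracle(relevance, pairwise_mi, selected, remaining, criterion):
    """Re-evaluate the greedy mRMR criterion from scratch for one step."""
    best_name, best_score = None, -np.inf
    for name in remaining:
        if not selected:
            score = relevance[name]
        else:
            red = np.mean([pairwise_mi[frozenset((name, s))] for s in selected])
            if criterion == "MID":
                score = relevance[name] - red
            else:
                score = relevance[name] / max(red, 1e-12)
        if score > best_score:
            best_name, best_score = name, score
    return best_name, best_score
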