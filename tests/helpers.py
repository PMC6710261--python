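"""Independent oracles used by the tests.

Everything here deliberately re-derives quantities by a different route
than the package: brute-force multi-start cylinder fitting, a
visibility-graph shortest path, dense multivariate-normal densities built
from patristic distances and explicit path walks, and analytic conjugate
marginals. None of it imports the implementation paths it checks.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

import dendropy
import networkx as nx
import numpy as np
from scipy.optimize import minimize
from scipy.stats import multivariate_normal
from shapely.geometry import LineString, Polygon


# ---------------------------------------------------------------------------
# cylinder fit oracle: outer direction search + inner exact circle fit


def _circle_fit_gn(u: np.ndarray, v: np.ndarray, iters: int = 50):
    """Exact LS circle fit in 2-D (Kasa init + Gauss-Newton)."""
    A = np.column_stack([2 * u, 2 * v, np.ones_like(u)])
    b = u**2 + v**2
    uc, vc, c0 = np.linalg.lstsq(A, b, rcond=None)[0]
    r = math.sqrt(max(c0 + uc**2 + vc**2, 1e-300))
    for _ in range(iters):
        du, dv = u - uc, v - vc
        rho = np.hypot(du, dv)
        res = rho - r
        J = np.column_stack([-du / rho, -dv / rho, -np.ones_like(rho)])
        try:
            step = np.linalg.lstsq(J, -res, rcond=None)[0]
        except np.linalg.LinAlgError:
            break
        uc += step[0]
        vc += step[1]
        r += step[2]
        if np.linalg.norm(step) < 1e-14:
            break
    du, dv = u - uc, v - vc
    cost = float(np.sum((np.hypot(du, dv) - r) ** 2))
    return uc, vc, abs(r), cost


def cylinder_oracle(
    P: np.ndarray, n_restarts: int = 20, seed: int = 0
) -> Tuple[float, np.ndarray, float]:
    """Full nonlinear LS cylinder via direction search with inner circle
    fits, from random restarts. Returns (radius, axis_direction, cost)."""
    P = np.asarray(P, dtype=float)
    rng = np.random.default_rng(seed)

    def cost_of_angles(ang):
        th, ph = ang
        d = np.array(
            [math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph),
             math.cos(th)]
        )
        a = np.array([1.0, 0, 0]) if abs(d[0]) < 0.9 else np.array([0, 1.0, 0])
        e1 = np.cross(d, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        u, v = P @ e1, P @ e2
        return _circle_fit_gn(u, v)[3]

    best = None
    for _ in range(n_restarts):
        d0 = rng.standard_normal(3)
        d0 /= np.linalg.norm(d0)
        x0 = [math.acos(np.clip(d0[2], -1, 1)), math.atan2(d0[1], d0[0])]
        res = minimize(cost_of_angles, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-16,
                                "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    th, ph = best.x
    d = np.array(
        [math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph),
         math.cos(th)]
    )
    a = np.array([1.0, 0, 0]) if abs(d[0]) < 0.9 else np.array([0, 1.0, 0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    _, _, r, cost = _circle_fit_gn(P @ e1, P @ e2)
    return float(r), d, float(cost)


# ---------------------------------------------------------------------------
# taut-string oracle: visibility graph over a polygonal obstacle


def visibility_path_length(
    polygon: np.ndarray, A: np.ndarray, B: np.ndarray
) -> float:
    """Shortest path from A to B avoiding the polygon interior, by
    explicit visibility graph + Dijkstra."""
    inner = Polygon(polygon).buffer(-1e-9)
    pts = [tuple(A), tuple(B)] + [tuple(p) for p in polygon]
    G = nx.Graph()
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            seg = LineString([pts[i], pts[j]])
            if seg.intersection(inner).is_empty:
                G.add_edge(
                    i, j,
                    weight=math.dist(pts[i], pts[j]),
                )
    return float(
        nx.shortest_path_length(G, 0, 1, weight="weight")
    )


# ---------------------------------------------------------------------------
# dense phylogenetic likelihood oracles


def _tip_paths(tree: dendropy.Tree):
    """leaf label -> list of (parent_depth, child_depth, child) walking
    root->tip, plus tip depths, built by leaf-to-root walks."""
    depth = {}
    for node in tree.preorder_node_iter():
        depth[id(node)] = (
            0.0 if node.parent_node is None
            else depth[id(node.parent_node)] + (node.edge.length or 0.0)
        )
    paths = {}
    for leaf in tree.leaf_node_iter():
        chain = []
        node = leaf
        while node.parent_node is not None:
            chain.append(
                (depth[id(node.parent_node)], depth[id(node)], node)
            )
            node = node.parent_node
        chain.reverse()
        paths[leaf.taxon.label] = chain
    return paths, depth


def _pairwise_mrca_depth(tree: dendropy.Tree, taxa: Sequence[str]):
    """MRCA depths by intersecting ancestor chains (brute force)."""
    paths, depth = _tip_paths(tree)
    anc = {}
    for lab in taxa:
        ids = []
        node = next(
            l for l in tree.leaf_node_iter() if l.taxon.label == lab
        )
        while node is not None:
            ids.append(id(node))
            node = node.parent_node
        anc[lab] = ids
    n = len(taxa)
    T = np.zeros((n, n))
    for i, a in enumerate(taxa):
        T[i, i] = depth[anc[a][0]]
        for j in range(i + 1, n):
            common = next(x for x in anc[taxa[i]] if x in set(anc[taxa[j]]))
            T[i, j] = T[j, i] = depth[common]
    return T


def bm_dense_loglik(
    tree: dendropy.Tree, taxa: Sequence[str], y: np.ndarray,
    sigma2: float, root: float, trend: float = 0.0,
) -> float:
    T = _pairwise_mrca_depth(tree, taxa)
    h = np.diag(T)
    mean = root + trend * h
    return float(
        multivariate_normal.logpdf(y, mean=mean, cov=sigma2 * T,
                                   allow_singular=True)
    )


def ou_dense_loglik(
    tree: dendropy.Tree,
    taxa: Sequence[str],
    y: np.ndarray,
    branch_regime: Dict[str, str],
    base_regime: str,
    alpha: float,
    sigma2: float,
    thetas: Dict[str, float],
) -> float:
    """Fixed-root multi-regime OU density from explicitly assembled mean
    and covariance."""
    paths, _ = _tip_paths(tree)
    T = _pairwise_mrca_depth(tree, taxa)
    h = np.diag(T)
    mean = np.zeros(len(taxa))
    for i, lab in enumerate(taxa):
        m = thetas[base_regime] * math.exp(-alpha * h[i])
        for (a, b, node) in paths[lab]:
            key = (
                node.taxon.label if node.is_leaf() else node.label
            )
            th = thetas[branch_regime[key]]
            m += th * (
                math.exp(-alpha * (h[i] - b)) - math.exp(-alpha * (h[i] - a))
            )
        mean[i] = m
    n = len(taxa)
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            t = T[i, j]
            V[i, j] = (
                sigma2
                * (1 - math.exp(-2 * alpha * t))
                / (2 * alpha)
                * math.exp(-alpha * (h[i] + h[j] - 2 * t))
            )
    return float(
        multivariate_normal.logpdf(y, mean=mean, cov=V, allow_singular=True)
    )


def random_tree_newick(
    rng: np.random.Generator, n_tips: int, nonultrametric: bool = True
) -> str:
    """Random topology by sequential pair joining with random branch
    lengths — independent of the package's Yule simulator."""
    subtrees = [f"x{i}" for i in range(n_tips)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        a = subtrees.pop(j)
        b = subtrees.pop(i)
        la, lb = rng.uniform(0.05, 1.5, size=2)
        subtrees.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return subtrees[0] + ";"


# ---------------------------------------------------------------------------
# conjugate normal-normal toy for stepping-stone checks


def conjugate_toy(seed: int = 0, n: int = 20, mu_true: float = 0.7,
                  tau: float = 2.0):
    """iid N(mu, 1) data, prior mu ~ N(0, tau^2); returns
    (log_lik, log_prior, sample_prior, analytic_log_marginal)."""
    rng = np.random.default_rng(seed)
    y = rng.normal(mu_true, 1.0, n)

    def log_lik(v):
        return float(
            -0.5 * np.sum((y - v[0]) ** 2) - 0.5 * n * math.log(2 * math.pi)
        )

    def log_prior(v):
        return float(
            -0.5 * (v[0] / tau) ** 2 - math.log(tau * math.sqrt(2 * math.pi))
        )

    def sample_prior(r):
        return np.array([r.normal(0.0, tau)])

    lml = float(
        multivariate_normal.logpdf(
            y, mean=np.zeros(n), cov=np.eye(n) + tau**2 * np.ones((n, n))
        )
    )
    return log_lik, log_prior, sample_prior, lml
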