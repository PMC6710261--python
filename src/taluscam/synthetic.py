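"""Ground-truthed synthetic inputs: talus-like meshes, trees, trait data.

The talus generator produces the two surface patches the measurement
protocol needs — a partial cylinder standing in for the trochlea (the
lateral tibial facet, LTF) and a saddle patch standing in for the flexor
fibularis groove (FFG) — with fully known geometry, so the whole
measurement pipeline can be validated against analytic truth. The trait
simulators (Brownian motion with Pagel transforms and optional trend;
multi-regime Ornstein-Uhlenbeck with exact transition sampling) provide
data with known generating parameters for the comparative machinery.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional, Tuple

import dendropy
import numpy as np
import pandas as pd
import trimesh

from taluscam import trees as _trees

__all__ = [
    "SyntheticTalusSpec",
    "SyntheticTalusTruth",
    "make_synthetic_talus",
    "simulate_tree",
    "simulate_bm",
    "simulate_ou",
    "pick_regime_clades",
]


@dataclasses.dataclass(frozen=True)
class SyntheticTalusSpec:
    """Parameters of a synthetic talus.

    trochlea_radius : radius (mm) of the cylindrical trochlear sector.
    trochlea_arc    : angular extent of the sector, degrees, in (30, 270).
    shelf_offset    : signed distance (mm) of the groove saddle point beyond
                      (+) or inside (-) the trochlear base circle.
    groove_curvatures : principal curvatures (1/mm) of the saddle patch,
                      opposite signs (concave mediolaterally, convex
                      dorsoplantarly).
    mesh_resolution : target edge length, mm.
    noise_sd        : Gaussian vertex noise along normals, mm.
    """

    trochlea_radius: float = 3.0
    trochlea_arc: float = 120.0
    shelf_offset: float = 0.0
    groove_curvatures: Tuple[float, float] = (0.8, -0.5)
    mesh_resolution: float = 0.1
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.trochlea_radius <= 0:
            raise ValueError("trochlea_radius must be > 0")
        if not (30.0 < self.trochlea_arc < 270.0):
            raise ValueError("trochlea_arc must be in (30, 270) degrees")
        if self.trochlea_radius + self.shelf_offset <= 0:
            raise ValueError("trochlea_radius + shelf_offset must be > 0")
        k1, k2 = self.groove_curvatures
        if not (k1 > 0 > k2 or k2 > 0 > k1):
            raise ValueError("groove curvatures must have opposite signs")
        if self.mesh_resolution <= 0:
            raise ValueError("mesh_resolution must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        min_curv_radius = min(1.0 / abs(k1), 1.0 / abs(k2))
        if self.mesh_resolution > min_curv_radius:
            raise ValueError(
                "mesh_resolution coarser than the groove's principal "
                f"curvature radii ({min_curv_radius:.3g} mm): saddle "
                "unresolvable"
            )


@dataclasses.dataclass(frozen=True)
class SyntheticTalusTruth:
    """Ground truth accompanying a synthetic talus."""

    true_axis_point: np.ndarray
    true_axis_direction: np.ndarray
    true_radius: float
    true_saddle_point: np.ndarray
    true_pts_index: float
    facet_vertex_ids: np.ndarray
    groove_vertex_ids: np.ndarray
    seed: int


def _grid_mesh(P: np.ndarray, nu: int, nv: int) -> Tuple[np.ndarray, np.ndarray]:
    """Triangulate a (nu*nv, 3) structured grid of points."""
    faces = []
    for i in range(nu - 1):
        for j in range(nv - 1):
            a = i * nv + j
            b = a + 1
            c = a + nv
            d = c + 1
            faces.append([a, b, c])
            faces.append([b, d, c])
    return P, np.asarray(faces, dtype=np.int64)


def make_synthetic_talus(
    spec: SyntheticTalusSpec,
) -> Tuple[trimesh.Trimesh, SyntheticTalusTruth]:
    """Build a talus-like mesh with known trochlear axis and saddle point.

    Geometry (all in mm): the trochlear axis is the x-axis. The trochlear
    facet is a cylindrical sector of the stated radius centred on the
    dorsal (+z) direction. The groove patch sits posteriorly (-z), its
    saddle point exactly at distance ``radius + shelf_offset`` from the
    axis; the patch is a quadric h = (k1 u^2 + k2 v^2)/2 over the local
    tangent plane, so its principal curvatures at the saddle are the stated
    ones. Vertex indices of both regions are recorded before noise is
    added (along vertex normals), so the tags survive noising.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    R = spec.trochlea_radius
    arc = np.deg2rad(spec.trochlea_arc)
    length = 1.5 * R

    # trochlear sector around +z
    n_u = max(int(np.ceil(length / spec.mesh_resolution)) + 1, 4)
    n_v = max(int(np.ceil(R * arc / spec.mesh_resolution)) + 1, 8)
    u = np.linspace(-length / 2, length / 2, n_u)
    phi = np.linspace(np.pi / 2 - arc / 2, np.pi / 2 + arc / 2, n_v)
    U, PHI = np.meshgrid(u, phi, indexing="ij")
    facet_pts = np.column_stack(
        [U.ravel(), R * np.cos(PHI).ravel(), R * np.sin(PHI).ravel()]
    )
    facet_v, facet_f = _grid_mesh(facet_pts, n_u, n_v)

    # saddle patch, posterior (-z), saddle point at distance R + offset
    k1, k2 = spec.groove_curvatures
    saddle_dist = R + spec.shelf_offset
    saddle_point = np.array([0.0, 0.0, -saddle_dist])
    half = min(0.6 / max(abs(k1), abs(k2)), 0.8 * R)
    n_g = max(int(np.ceil(2 * half / spec.mesh_resolution)) + 1, 9)
    g = np.linspace(-half, half, n_g)
    GU, GV = np.meshgrid(g, g, indexing="ij")
    # local frame: e_u = x (mediolateral), e_v = y (dorsoplantar tangent),
    # outward normal = -z (posterior)
    H = 0.5 * (k1 * GU**2 + k2 * GV**2)
    groove_pts = np.column_stack(
        [GU.ravel(), GV.ravel(), (-saddle_dist - H).ravel()]
    )
    groove_v, groove_f = _grid_mesh(groove_pts, n_g, n_g)

    vertices = np.vstack([facet_v, groove_v])
    faces = np.vstack([facet_f, groove_f + len(facet_v)])
    facet_ids = np.arange(len(facet_v))
    groove_ids = np.arange(len(facet_v), len(vertices))

    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    if spec.noise_sd > 0:
        normals = mesh.vertex_normals.copy()
        vertices = vertices + normals * rng.normal(
            0.0, spec.noise_sd, size=len(vertices)
        )[:, None]
        mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)

    truth = SyntheticTalusTruth(
        true_axis_point=np.zeros(3),
        true_axis_direction=np.array([1.0, 0.0, 0.0]),
        true_radius=R,
        true_saddle_point=saddle_point,
        true_pts_index=(R + spec.shelf_offset) / R,
        facet_vertex_ids=facet_ids,
        groove_vertex_ids=groove_ids,
        seed=spec.seed,
    )
    return mesh, truth


def simulate_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    n_fossil_tips: int = 0,
    seed: int = 0,
) -> dendropy.Tree:
    """Simulate a rooted binary tree under a pure-birth (Yule) process.

    The tree is grown lineage by lineage (exponential waiting times with
    total rate ``k * birth_rate`` for k extant lineages) and all pendant
    branches are extended to the present, so the tree is ultrametric.
    If ``n_fossil_tips > 0``, that many randomly chosen tips have their
    pendant branch truncated by a uniform random fraction, making the tree
    non-ultrametric (fossil tips end before the present).
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    if not (0 <= n_fossil_tips < n_tips):
        raise ValueError("need 0 <= n_fossil_tips < n_tips")
    rng = np.random.default_rng(seed)

    # active lineages: (birth_time, id); splits recorded as (parent, child a,
    # child b, split_time)
    next_id = [0]

    def fresh() -> int:
        next_id[0] += 1
        return next_id[0] - 1

    root = fresh()
    t = 0.0
    active = [(root, 0.0)]
    children: Dict[int, Tuple[int, int]] = {}
    birth: Dict[int, float] = {root: 0.0}
    death: Dict[int, float] = {}
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        k = rng.integers(len(active))
        lin, _ = active.pop(k)
        death[lin] = t
        a, b = fresh(), fresh()
        birth[a] = birth[b] = t
        children[lin] = (a, b)
        active.append((a, t))
        active.append((b, t))
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))
    for lin, _ in active:
        death[lin] = t_end

    tip_ids = [lin for lin, _ in active]
    fossil = rng.choice(len(tip_ids), size=n_fossil_tips, replace=False)
    for k in fossil:
        lin = tip_ids[k]
        frac = rng.uniform(0.05, 0.95)
        death[lin] = birth[lin] + (death[lin] - birth[lin]) * (1 - frac)

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tip_counter = [0]

    def build(lin: int, node: dendropy.Node) -> None:
        node.edge.length = death[lin] - birth[lin]
        if lin in children:
            for ch in children[lin]:
                child = dendropy.Node()
                node.add_child(child)
                build(ch, child)
        else:
            tip_counter[0] += 1
            node.taxon = taxon_ns.new_taxon(f"t{tip_counter[0]}")

    build(root, tree.seed_node)
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return _trees.ensure_node_labels(tree)


def pick_regime_clades(
    tree: dendropy.Tree,
    n_clades: int = 2,
    min_tips: int = 6,
    max_tips: int = 16,
    max_union_frac: float = 0.6,
    require_root_separation: bool = True,
) -> list:
    """Deterministically choose well-separated clades for regime shifts
    in simulation studies.

    Returns internal-node labels. Clades are tip-disjoint, jointly cover
    at most ``max_union_frac`` of the tips (the basal regime stays
    visible), and by default are separated by the root: the MRCA of their
    union is the root itself, so no single deeper shift can summarise
    them. Without that separation, two shifted clades nested under one
    node are nearly indistinguishable from a single shift at that node
    plus a carve-out, and the simulated "truth" is not identifiable.
    Selection is preorder, so it is reproducible for a given tree.
    """
    import itertools

    n_total = sum(1 for _ in tree.leaf_node_iter())
    root = tree.seed_node
    cands = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        tips = frozenset(l.taxon.label for l in node.leaf_nodes())
        if min_tips <= len(tips) <= max_tips:
            cands.append((node, tips))
    for combo in itertools.combinations(cands, n_clades):
        union: set = set()
        ok = True
        for _, tips in combo:
            if tips & union:
                ok = False
                break
            union |= tips
        if not ok or len(union) > max_union_frac * n_total:
            continue
        if len({id(node.parent_node) for node, _ in combo}) < n_clades:
            continue
        if require_root_separation and n_clades > 1:
            mrca = _trees.mrca_node(tree, union)
            if mrca is not root:
                continue
        return [node.label for node, _ in combo]
    raise ValueError(
        f"could not find {n_clades} separated clades of "
        f"{min_tips}-{max_tips} tips"
    )


def _transformed_lengths(
    tree: dendropy.Tree, transform: Optional[Tuple[str, float]]
) -> dendropy.Tree:
    if transform is None:
        return tree
    kind, value = transform
    return _trees.transform_tree(tree, kind, value)


def simulate_bm(
    tree: dendropy.Tree,
    sigma2: float,
    root_state: float = 0.0,
    transform: Optional[Tuple[str, float]] = None,
    trend: Optional[float] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a continuous trait branchwise under Brownian motion.

    Increments along each branch are Gaussian with variance
    ``sigma2 * transformed branch length``, plus ``trend * branch length``
    (original lengths) under the directional model. Returns a TraitTable:
    DataFrame with columns ``taxon``, ``value``.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    ttree = _transformed_lengths(tree, transform)
    tnodes = {n.taxon.label if n.is_leaf() else n.label: n
              for n in ttree.preorder_node_iter()}
    values: Dict[int, float] = {}
    rows = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = root_state
        else:
            bl = node.edge.length or 0.0
            key = node.taxon.label if node.is_leaf() else node.label
            tbl = tnodes[key].edge.length or 0.0
            mu = values[id(node.parent_node)] + (trend or 0.0) * bl
            values[id(node)] = mu + rng.normal(0.0, np.sqrt(sigma2 * tbl))
        if node.is_leaf():
            rows.append((node.taxon.label, values[id(node)]))
    return pd.DataFrame(rows, columns=["taxon", "value"])


def simulate_ou(
    tree: dendropy.Tree,
    painting: "RegimePainting",
    alpha: float,
    sigma2: float,
    optima: Dict[str, float],
    root_state: Optional[float] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a trait under multi-regime OU with exact transitions.

    Along a branch of length t in regime r with optimum theta_r, the child
    state is Normal(theta_r + (parent - theta_r) exp(-alpha t),
    sigma2 (1 - exp(-2 alpha t)) / (2 alpha)). The root starts at
    ``root_state`` (default: the basal regime's optimum).
    """
    from taluscam.regimes import RegimePainting  # local: avoid import cycle

    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if not isinstance(painting, RegimePainting):
        raise TypeError("painting must be a RegimePainting")
    branch_regime = painting.branch_regimes(tree)
    missing = set(optima) ^ set(branch_regime.values())
    for reg in set(branch_regime.values()):
        if reg not in optima:
            raise KeyError(f"no optimum for regime {reg!r}")
    rng = np.random.default_rng(seed)
    if root_state is None:
        root_state = optima[painting.base_regime]
    values: Dict[int, float] = {}
    rows = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = float(root_state)
        else:
            t = node.edge.length or 0.0
            key = node.taxon.label if node.is_leaf() else node.label
            theta = optima[branch_regime[key]]
            decay = np.exp(-alpha * t)
            mean = theta + (values[id(node.parent_node)] - theta) * decay
            var = sigma2 * (1.0 - np.exp(-2.0 * alpha * t)) / (2.0 * alpha)
            values[id(node)] = mean + rng.normal(0.0, np.sqrt(var))
        if node.is_leaf():
            rows.append((node.taxon.label, values[id(node)]))
    return pd.DataFrame(rows, columns=["taxon", "value"])
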