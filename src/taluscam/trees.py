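"""Rooted phylogenies: I/O, Pagel transforms, and path-length covariance.

Trees are held as :class:`dendropy.Tree` objects throughout the package.
Internal nodes receive stable labels (``n0``, ``n1``, ... in preorder) on
load so that regime paintings, ancestral-state queries and clade definitions
can refer to them by name. All branch lengths are in the units of the input
tree (typically millions of years); trait models only ever consume products
``rate x branch length``, so the unit cancels.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Tuple

import dendropy
import numpy as np

__all__ = [
    "read_tree",
    "write_tree",
    "parse_tree",
    "ensure_node_labels",
    "tip_labels",
    "node_depths",
    "tree_depth",
    "is_ultrametric",
    "transform_tree",
    "vcv_matrix",
    "mrca_node",
    "clone_tree",
]


def ensure_node_labels(tree: dendropy.Tree) -> dendropy.Tree:
    """Assign labels ``n0, n1, ...`` (preorder) to unlabeled internal nodes."""
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if not node.label:
            while True:
                cand = f"n{i}"
                i += 1
                if not any(
                    n.label == cand for n in tree.preorder_node_iter() if n is not node
                ):
                    break
            node.label = cand
    return tree


def _validate(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {lab for lab in labels if labels.count(lab) > 1}
    if dupes:
        raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
    n_zero = 0
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if edge.length is None:
            edge.length = 0.0
        if edge.length < 0:
            raise ValueError("negative branch length")
        if edge.length == 0:
            n_zero += 1
    if n_zero:
        import warnings

        warnings.warn(f"{n_zero} zero-length branches retained", stacklevel=3)
    tree.is_rooted = True
    return ensure_node_labels(tree)


def read_tree(path: str, schema: str = "newick") -> dendropy.Tree:
    """Load a rooted tree from newick or nexus.

    Polytomies are permitted; zero-length branches are kept with a warning;
    duplicate tip labels raise ``ValueError``.
    """
    if schema not in ("newick", "nexus"):
        raise ValueError(f"unsupported tree format: {schema}")
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema=schema, preserve_underscores=True
        )
    except dendropy.utility.error.DataParseError as exc:
        raise ValueError(f"unparseable tree file {path}: {exc}") from exc
    return _validate(tree)


def parse_tree(newick: str) -> dendropy.Tree:
    """Parse a newick string into a validated rooted tree."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except dendropy.utility.error.DataParseError as exc:
        raise ValueError(f"unparseable newick: {exc}") from exc
    return _validate(tree)


def write_tree(tree: dendropy.Tree, path: str, schema: str = "newick") -> None:
    tree.write(path=str(path), schema=schema, suppress_rooting=True)


def as_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def clone_tree(tree: dendropy.Tree) -> dendropy.Tree:
    return dendropy.Tree(tree)


def tip_labels(tree: dendropy.Tree) -> List[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def node_depths(tree: dendropy.Tree) -> Dict[dendropy.Node, float]:
    """Depth (distance from root) of every node; root depth is 0."""
    depths: Dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def tree_depth(tree: dendropy.Tree) -> float:
    return max(node_depths(tree).values())


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-9) -> bool:
    depths = node_depths(tree)
    tips = [depths[n] for n in tree.leaf_node_iter()]
    return max(tips) - min(tips) <= tol * max(1.0, max(tips))


def transform_tree(tree: dendropy.Tree, kind: str, value: float) -> dendropy.Tree:
    """Apply a Pagel branch-length transform; returns a new tree.

    delta  -- node depths h (root = 0), after normalising total depth to 1,
              are mapped to h**delta and rescaled back; branch lengths are
              re-derived from the transformed depths. delta < 1 concentrates
              change early (near the root), delta > 1 late.
    kappa  -- each branch length l is mapped to l**kappa (kappa = 0 makes
              every branch length 1: purely speciational change).
    lambda -- internal branch lengths are multiplied by lambda while
              root-to-tip heights are preserved by stretching the pendant
              branches; lambda = 0 yields a star tree.
    """
    if value < 0:
        raise ValueError(f"transform value must be >= 0, got {value}")
    if kind not in ("delta", "kappa", "lambda"):
        raise ValueError(f"unknown transform kind: {kind}")
    out = clone_tree(tree)
    if kind == "kappa":
        for edge in out.preorder_edge_iter():
            if edge.tail_node is None or edge.length is None:
                continue
            edge.length = float(edge.length) ** value
        return out
    depths = node_depths(out)
    total = max(depths.values())
    if total <= 0:
        return out
    if kind == "delta":
        new_depth = {
            n: total * (d / total) ** value if d > 0 else 0.0
            for n, d in depths.items()
        }
        for node in out.preorder_node_iter():
            if node.parent_node is None:
                continue
            node.edge.length = new_depth[node] - new_depth[node.parent_node]
        return out
    # lambda: scale internal branches, preserve tip heights
    for node in out.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        node.edge.length = (node.edge.length or 0.0) * value
    new_internal_depth: Dict[dendropy.Node, float] = {}
    for node in out.preorder_node_iter():
        if node.is_leaf():
            continue
        if node.parent_node is None:
            new_internal_depth[node] = 0.0
        else:
            new_internal_depth[node] = (
                new_internal_depth[node.parent_node] + node.edge.length
            )
    for leaf in out.leaf_node_iter():
        target = depths[leaf]
        new_len = target - new_internal_depth[leaf.parent_node]
        if new_len < -1e-12:
            raise ValueError(
                "lambda transform would make a pendant branch negative"
            )
        leaf.edge.length = max(new_len, 0.0)
    return out


def vcv_matrix(
    tree: dendropy.Tree, taxa: Optional[Iterable[str]] = None
) -> Tuple[List[str], np.ndarray]:
    """Brownian-motion covariance structure: C[i, j] = depth of MRCA(i, j).

    Diagonal entries are root-to-tip path lengths; off-diagonals the shared
    path length of the two tips. Returned in the order of ``taxa`` if given,
    else leaf-iteration order.
    """
    depths = node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    labels = [l.taxon.label for l in leaves]
    if taxa is not None:
        taxa = list(taxa)
        missing = set(taxa) - set(labels)
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
    else:
        taxa = labels
    idx = {lab: i for i, lab in enumerate(taxa)}
    n = len(taxa)
    C = np.zeros((n, n))
    for leaf in leaves:
        if leaf.taxon.label in idx:
            i = idx[leaf.taxon.label]
            C[i, i] = depths[leaf]
    # postorder: each internal node is the MRCA of tip pairs split across
    # its children
    below: Dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = (
                np.array([idx[node.taxon.label]], dtype=np.intp)
                if node.taxon.label in idx
                else np.empty(0, dtype=np.intp)
            )
            continue
        kids = [below[c] for c in node.child_nodes()]
        d = depths[node]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                if len(kids[a]) and len(kids[b]):
                    C[np.ix_(kids[a], kids[b])] = d
                    C[np.ix_(kids[b], kids[a])] = d
        below[node] = np.concatenate(kids) if kids else np.empty(
            0, dtype=np.intp
        )
    return list(taxa), C


def mrca_node(tree: dendropy.Tree, tip_set: Iterable[str]) -> dendropy.Node:
    """Most recent common ancestor of the named tips."""
    taxa = [
        leaf.taxon
        for leaf in tree.leaf_node_iter()
        if leaf.taxon.label in set(tip_set)
    ]
    if not taxa:
        raise KeyError(f"no matching tips among {sorted(tip_set)}")
    return tree.mrca(taxa=taxa)
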