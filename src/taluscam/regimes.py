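"""Multi-regime Ornstein-Uhlenbeck models and stepwise regime detection.

The Hansen model: a trait evolves toward a regime-specific optimum theta
with attraction rate alpha and diffusion sigma2; regimes are painted onto
branches (a shift applies to a clade's stem branch and all descendants
until overridden). The likelihood works on non-ultrametric trees, so
fossil tips are handled natively.

The stepwise search mirrors the SURFACE procedure: a forward phase greedily
adds the single regime shift that most improves AICc until no addition
helps, then a backward phase greedily merges regime pairs onto shared
optima while AICc keeps improving; lineages left sharing an optimum after
the backward phase are read as convergent. AICc (the small-sample
correction) is the selection criterion throughout.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import lsq_linear, minimize_scalar

from taluscam import trees as _trees

__all__ = [
    "RegimePainting",
    "OUFit",
    "ou_loglik",
    "fit_hansen",
    "surface_forward",
    "surface_backward",
    "genus_consolidate",
]


def _node_key(node: dendropy.Node) -> str:
    return node.taxon.label if node.is_leaf() else node.label


@dataclasses.dataclass(frozen=True)
class RegimePainting:
    """A painting of regimes onto a tree.

    ``base_regime`` colours the root; each entry of ``shifts`` (node label
    -> regime id) starts a new regime on the branch subtending that node
    and is inherited by all descendant branches until overridden by a
    deeper shift. Node labels are tip labels for pendant branches and the
    ``n#`` labels assigned on load for internal nodes.
    """

    base_regime: str = "R0"
    shifts: Dict[str, str] = dataclasses.field(default_factory=dict)

    @classmethod
    def single_regime(cls, regime: str = "R0") -> "RegimePainting":
        return cls(base_regime=regime, shifts={})

    def regime_ids(self) -> List[str]:
        seen = [self.base_regime]
        for r in self.shifts.values():
            if r not in seen:
                seen.append(r)
        return seen

    def branch_regimes(self, tree: dendropy.Tree) -> Dict[str, str]:
        """Regime of every branch, keyed by its child node's label."""
        known = {_node_key(n) for n in tree.preorder_node_iter()}
        missing = set(self.shifts) - known
        if missing:
            raise KeyError(f"shift nodes not in tree: {sorted(missing)}")
        out: Dict[str, str] = {}
        state: Dict[int, str] = {}
        for node in tree.preorder_node_iter():
            key = _node_key(node)
            if node.parent_node is None:
                state[id(node)] = self.shifts.get(key, self.base_regime)
                continue
            inherited = state[id(node.parent_node)]
            reg = self.shifts.get(key, inherited)
            state[id(node)] = reg
            out[key] = reg
        return out

    def with_shift(self, node_label: str, regime: str) -> "RegimePainting":
        new = dict(self.shifts)
        new[node_label] = regime
        return RegimePainting(self.base_regime, new)

    def merged(self, a: str, b: str) -> "RegimePainting":
        """Relabel regime ``b`` as ``a`` (sharing one optimum)."""
        base = a if self.base_regime == b else self.base_regime
        shifts = {
            k: (a if r == b else r) for k, r in self.shifts.items()
        }
        return RegimePainting(base, shifts)

    def simplified(self, tree: dendropy.Tree) -> "RegimePainting":
        """Drop shifts that re-assert the regime the branch would inherit
        anyway (no-ops left behind by merges). Branch regimes unchanged."""
        keep: Dict[str, str] = {}
        state: Dict[int, str] = {}
        for node in tree.preorder_node_iter():
            key = _node_key(node)
            inherited = (
                self.base_regime if node.parent_node is None
                else state[id(node.parent_node)]
            )
            reg = self.shifts.get(key, inherited)
            state[id(node)] = reg
            if key in self.shifts and reg != inherited:
                keep[key] = reg
        return RegimePainting(self.base_regime, keep)


@dataclasses.dataclass
class OUFit:
    """A fitted multi-regime OU model."""

    alpha: float
    sigma2: float
    theta: Dict[str, float]
    log_likelihood: float
    k_shifts: int
    k_distinct_regimes: int
    aicc: float
    painting: RegimePainting
    alpha_at_boundary: bool = False


class _OUStructure:
    """Per-(tree, taxa) cache: tip heights, MRCA depths, and the regime
    segments of every root-to-tip path."""

    def __init__(self, tree: dendropy.Tree, taxa: Sequence[str]):
        self.taxa = list(taxa)
        self.tree = tree
        _, C0 = _trees.vcv_matrix(tree, taxa)
        self.t_mrca = C0
        self.h = np.diag(C0).copy()
        depths = _trees.node_depths(tree)
        # path segments per tip: list of (depth_start, depth_end, branch key)
        self.segments: Dict[str, List[Tuple[float, float, str]]] = {}
        for leaf in tree.leaf_node_iter():
            segs = []
            node = leaf
            while node.parent_node is not None:
                segs.append(
                    (depths[node.parent_node], depths[node], _node_key(node))
                )
                node = node.parent_node
            segs.reverse()
            self.segments[leaf.taxon.label] = segs

    def design(
        self, alpha: float, branch_regime: Dict[str, str],
        regimes: Sequence[str], base_regime: str,
    ) -> np.ndarray:
        """Regime weight matrix W(alpha): E[x] = W theta (rows sum to 1).

        The root contributes exp(-alpha h_i) to the basal regime's column
        (root state pinned at the basal optimum)."""
        reg_idx = {r: j for j, r in enumerate(regimes)}
        n = len(self.taxa)
        W = np.zeros((n, len(regimes)))
        for i, taxon in enumerate(self.taxa):
            hi = self.h[i]
            W[i, reg_idx[base_regime]] += np.exp(-alpha * hi)
            for (a, b, key) in self.segments[taxon]:
                j = reg_idx[branch_regime[key]]
                W[i, j] += np.exp(-alpha * (hi - b)) - np.exp(-alpha * (hi - a))
        return W

    def covariance(self, alpha: float) -> np.ndarray:
        """Fixed-root OU covariance (valid on non-ultrametric trees):
        V_ij = (1 - exp(-2 a t_ij)) exp(-a (h_i + h_j - 2 t_ij)) / (2 a),
        scaled by sigma2 outside."""
        t = self.t_mrca
        h = self.h
        if alpha < 1e-12:
            return t.copy()
        hsum = h[:, None] + h[None, :]
        return (
            (1.0 - np.exp(-2.0 * alpha * t))
            * np.exp(-alpha * (hsum - 2.0 * t))
            / (2.0 * alpha)
        )


def _traits_vector(traits: pd.DataFrame, taxa: Sequence[str]) -> np.ndarray:
    tbl = traits.set_index("taxon")["value"]
    missing = set(taxa) - set(tbl.index)
    if missing:
        raise KeyError(f"traits missing for tips: {sorted(missing)}")
    return tbl.loc[list(taxa)].to_numpy(dtype=float)


def ou_loglik(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    painting: RegimePainting,
    alpha: float,
    sigma2: float,
    thetas: Dict[str, float],
    root_state_rule: str = "basal_optimum",
    _struct: Optional[_OUStructure] = None,
) -> float:
    """Log-density of tip values under the multi-regime OU model.

    The mean at each tip is a path-weighted blend of the optima crossed on
    the way from the root; the covariance is the fixed-root OU covariance.
    The root state is the basal regime's optimum (``basal_optimum``, the
    default) — OU attraction is toward the optima, so with the root at the
    basal optimum the alpha -> 0 limit recovers Brownian motion rooted
    there.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if root_state_rule != "basal_optimum":
        raise ValueError(f"unknown root_state_rule: {root_state_rule}")
    taxa = [t for t in traits["taxon"]]
    struct = _struct or _OUStructure(tree, taxa)
    y = _traits_vector(traits, taxa)
    branch_regime = painting.branch_regimes(tree)
    regimes = painting.regime_ids()
    for r in regimes:
        if r not in thetas:
            raise KeyError(f"no optimum supplied for regime {r!r}")
    W = struct.design(alpha, branch_regime, regimes, painting.base_regime)
    mean = W @ np.array([thetas[r] for r in regimes])
    V = struct.covariance(alpha)
    n = len(y)
    chol = cho_factor(V + 1e-12 * np.eye(n), lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
    r_ = y - mean
    q = float(r_ @ cho_solve(chol, r_))
    return float(
        -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + q / sigma2)
    )


def _theta_bounds(y: np.ndarray) -> Tuple[float, float]:
    """Plausible-optimum box: observed trait range widened by one range
    on each side. Unconstrained GLS optima diverge when a regime's design
    weight vanishes (a shift on a short branch at small alpha), producing
    absurd optima and spurious likelihood gains; optima outside any
    data-supported region are biologically meaningless for this trait."""
    lo, hi = float(np.min(y)), float(np.max(y))
    span = max(hi - lo, 1e-6)
    return lo - span, hi + span


def _profile_ll(
    struct: _OUStructure,
    y: np.ndarray,
    branch_regime: Dict[str, str],
    regimes: Sequence[str],
    base_regime: str,
    alpha: float,
) -> Tuple[float, np.ndarray, float]:
    """Profile thetas (box-constrained GLS) and sigma2 at a given alpha;
    returns (loglik, theta_hat, sigma2_hat)."""
    n = len(y)
    W = struct.design(alpha, branch_regime, regimes, base_regime)
    V = struct.covariance(alpha)
    chol = cho_factor(V + 1e-12 * np.eye(n), lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
    ViW = cho_solve(chol, W)
    A = W.T @ ViW
    b = ViW.T @ y
    lo, hi = _theta_bounds(y)
    try:
        theta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        theta = np.linalg.lstsq(A, b, rcond=None)[0]
    if np.any(theta < lo) or np.any(theta > hi):
        # whitened bounded LS; L^-1 y = L^-1 W theta + e
        L = chol[0]
        yw = solve_triangular(L, y, lower=True)
        Ww = solve_triangular(L, W, lower=True)
        res = lsq_linear(Ww, yw, bounds=(lo, hi), method="bvls")
        theta = res.x
    r_ = y - W @ theta
    q = float(r_ @ cho_solve(chol, r_))
    sigma2 = max(q / n, 1e-300)
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return float(ll), theta, sigma2


def _aicc(ll: float, n_params: int, n: int) -> float:
    denom = n - n_params - 1
    if denom <= 0:
        return float("inf")
    return -2.0 * ll + 2 * n_params + 2.0 * n_params * (n_params + 1) / denom


def fit_hansen(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    painting: Optional[RegimePainting] = None,
    alpha_bounds: Optional[Tuple[float, float]] = None,
    coarse: bool = False,
    _struct: Optional[_OUStructure] = None,
) -> OUFit:
    """ML fit of the multi-regime OU model for a given painting.

    Optima are profiled by GLS and sigma2 in closed form, leaving a 1-D
    search over log(alpha), bounded by default to [1e-8, 50 / tree depth]
    to avoid numeric overflow; a boundary alpha is flagged, not hidden.
    AICc uses parameter count 2 + number of distinct optima. ``coarse``
    loosens the alpha search tolerance (used inside the stepwise scan,
    where candidates are re-fit exactly once selected).
    """
    painting = painting or RegimePainting.single_regime()
    taxa = [t for t in traits["taxon"]]
    if len(taxa) < 4:
        raise ValueError("need >= 4 tips")
    y = _traits_vector(traits, taxa)
    if np.ptp(y) < 1e-300 or np.var(y) == 0:
        raise ValueError("constant traits: zero variance, OU fit undefined")
    struct = _struct or _OUStructure(tree, taxa)
    branch_regime = painting.branch_regimes(tree)
    regimes = painting.regime_ids()
    if alpha_bounds is None:
        depth = max(struct.h.max(), 1e-12)
        alpha_bounds = (1e-8, 50.0 / depth)
    la, lb = np.log(alpha_bounds[0]), np.log(alpha_bounds[1])

    def nll(log_alpha: float) -> float:
        return -_profile_ll(
            struct, y, branch_regime, regimes, painting.base_regime,
            float(np.exp(log_alpha)),
        )[0]

    res = minimize_scalar(
        nll, bounds=(la, lb), method="bounded",
        options={"xatol": 0.05 if coarse else 1e-8,
                 "maxiter": 25 if coarse else 200},
    )
    alpha = float(np.exp(res.x))
    ll, theta, sigma2 = _profile_ll(
        struct, y, branch_regime, regimes, painting.base_regime, alpha
    )
    k_distinct = len(set(regimes))
    n_params = 2 + k_distinct
    at_boundary = (
        alpha <= alpha_bounds[0] * 1.5 or alpha >= alpha_bounds[1] / 1.5
    )
    return OUFit(
        alpha=alpha,
        sigma2=sigma2,
        theta={r: float(t) for r, t in zip(regimes, theta)},
        log_likelihood=ll,
        k_shifts=len(painting.shifts),
        k_distinct_regimes=k_distinct,
        aicc=_aicc(ll, n_params, len(y)),
        painting=painting,
        alpha_at_boundary=bool(at_boundary),
    )


def _candidate_nodes(tree: dendropy.Tree) -> List[str]:
    return [
        _node_key(n) for n in tree.preorder_node_iter()
        if n.parent_node is not None
    ]


def surface_forward(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    max_steps: Optional[int] = None,
    aic_threshold: Optional[float] = None,
    patience: int = 3,
) -> List[OUFit]:
    """Forward phase: greedily add the regime shift (at any branch) that
    most improves AICc; return the model sequence up to the best
    selection-adjusted model.

    The greedy path itself uses the classic accept-any-AICc-improvement
    rule, so the returned AICc trace is strictly decreasing. Because each
    step picks the best of b ~ 2n candidate branches, the best *spurious*
    shift on null data improves AICc by roughly 2 ln(b) (the maximum of b
    correlated chi-square(1) selection gains), which plain AICc cannot
    distinguish from a real shift — the known overfitting of stepwise AIC
    regime detection. The model actually recovered is therefore chosen
    along the path by the selection-adjusted criterion ``AICc +
    aic_threshold x (number of shifts)``, with ``aic_threshold``
    defaulting to the Bonferroni-style 2 ln(b); exploration continues for
    ``patience`` steps past the current best before stopping, which also
    lets the search pass through locally weak single-shift models on its
    way to a strong multi-shift one. ``aic_threshold=0`` restores the
    classic behavior (the full improving path is returned).

    Deterministic given the data — the scan has no randomness.
    """
    taxa = [t for t in traits["taxon"]]
    struct = _OUStructure(tree, taxa)
    current = fit_hansen(tree, traits, RegimePainting.single_regime(),
                         _struct=struct)
    sequence = [current]
    candidates = _candidate_nodes(tree)
    if aic_threshold is None:
        aic_threshold = 2.0 * float(np.log(len(candidates)))
    step = 0
    while True:
        step += 1
        if max_steps is not None and step > max_steps:
            break
        best: Optional[OUFit] = None
        best_node = None
        new_regime = f"R{step}"
        for node in candidates:
            if node in current.painting.shifts:
                continue
            painting = current.painting.with_shift(node, new_regime)
            try:
                cand = fit_hansen(
                    tree, traits, painting, coarse=True, _struct=struct
                )
            except (ValueError, np.linalg.LinAlgError):
                continue
            if best is None or cand.aicc < best.aicc:
                best = cand
                best_node = node
        if best is None:
            break
        refined = fit_hansen(
            tree, traits, current.painting.with_shift(best_node, new_regime),
            _struct=struct,
        )
        if refined.aicc >= current.aicc:
            break
        current = refined
        sequence.append(current)
        adjusted = [
            f.aicc + aic_threshold * f.k_shifts for f in sequence
        ]
        if len(sequence) - 1 - int(np.argmin(adjusted)) >= patience:
            break
    adjusted = [f.aicc + aic_threshold * f.k_shifts for f in sequence]
    sequence = sequence[: int(np.argmin(adjusted)) + 1]
    # relocation polish: hill-climb each shift to a neighbouring branch at
    # fixed model size (pure likelihood, no selection penalty involved) —
    # greedy addition often locks a shift one node away from its best
    # position once later shifts reshape the fit
    sequence[-1] = _relocate_shifts(
        tree, traits, sequence[-1], struct
    )
    return sequence


def _neighbour_nodes(tree: dendropy.Tree, label: str) -> List[str]:
    for n in tree.preorder_node_iter():
        if _node_key(n) == label:
            out = []
            if n.parent_node is not None and \
                    n.parent_node.parent_node is not None:
                out.append(_node_key(n.parent_node))
            out.extend(_node_key(c) for c in n.child_nodes())
            return out
    return []


def _relocate_shifts(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    fit: OUFit,
    struct: "_OUStructure",
    max_rounds: int = 4,
) -> OUFit:
    current = fit
    for _ in range(max_rounds):
        improved = False
        for node, regime in list(current.painting.shifts.items()):
            for cand in _neighbour_nodes(tree, node):
                if cand in current.painting.shifts:
                    continue
                shifts = dict(current.painting.shifts)
                del shifts[node]
                shifts[cand] = regime
                painting = RegimePainting(
                    current.painting.base_regime, shifts
                )
                try:
                    trial = fit_hansen(
                        tree, traits, painting, _struct=struct
                    )
                except (ValueError, np.linalg.LinAlgError):
                    continue
                if trial.aicc < current.aicc - 1e-9:
                    current = trial
                    improved = True
                    break
        if not improved:
            break
    return current


def surface_backward(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    forward_result: Sequence[OUFit],
) -> OUFit:
    """Backward phase: greedily merge regime pairs onto shared optima while
    AICc improves. Regimes still sharing an optimum at the end — reached
    from independent shifts — are the convergent classes."""
    taxa = [t for t in traits["taxon"]]
    struct = _OUStructure(tree, taxa)
    current = forward_result[-1]
    while True:
        regimes = current.painting.regime_ids()
        best: Optional[OUFit] = None
        if len(regimes) >= 2:
            for i in range(len(regimes)):
                for j in range(i + 1, len(regimes)):
                    painting = current.painting.merged(regimes[i], regimes[j])
                    try:
                        cand = fit_hansen(
                            tree, traits, painting, coarse=True,
                            _struct=struct,
                        )
                    except (ValueError, np.linalg.LinAlgError):
                        continue
                    if best is None or cand.aicc < best.aicc:
                        best = cand
        if best is None:
            break
        refined = fit_hansen(
            tree, traits, best.painting, _struct=struct
        )
        if refined.aicc < current.aicc:
            current = refined
        else:
            break
    simplified = current.painting.simplified(tree)
    if len(simplified.shifts) != len(current.painting.shifts):
        final = fit_hansen(tree, traits, simplified, _struct=struct)
    else:
        final = current
    return final


def genus_consolidate(
    traits: pd.DataFrame,
    tree: dendropy.Tree,
    genus_map: Dict[str, str],
    weights: str = "individuals",
    exceptions: Sequence[str] = (),
) -> Tuple[dendropy.Tree, pd.DataFrame]:
    """Collapse species tips to one tip per genus.

    Genus trait values are means of the species means weighted by
    individual specimen counts (column ``n``; ``weights="species"``
    switches to unweighted means). Genera in ``exceptions`` keep their
    species-level tips (the original analysis kept Tarsius at species
    level to preserve its long-branch structure). The retained tip per
    genus is the alphabetically first species, relabelled to the genus
    name; its pendant branch length is kept.
    """
    if weights not in ("individuals", "species"):
        raise ValueError(f"unknown weighting: {weights}")
    tips = set(_trees.tip_labels(tree))
    missing = tips - set(genus_map)
    if missing:
        raise KeyError(f"genus map missing tips: {sorted(missing)}")
    has_n = "n" in traits.columns
    tbl = traits.set_index("taxon")
    keep: List[str] = []
    rename: Dict[str, str] = {}
    rows = []
    by_genus: Dict[str, List[str]] = {}
    for sp in sorted(tips):
        by_genus.setdefault(genus_map[sp], []).append(sp)
    for genus, species in by_genus.items():
        if genus in exceptions:
            for sp in species:
                keep.append(sp)
                row = {"taxon": sp, "value": float(tbl.loc[sp, "value"])}
                if has_n:
                    row["n"] = tbl.loc[sp, "n"]
                rows.append(row)
            continue
        vals = np.array([float(tbl.loc[sp, "value"]) for sp in species])
        if weights == "individuals" and has_n:
            w = np.array([float(tbl.loc[sp, "n"]) for sp in species])
        else:
            w = np.ones(len(species))
        if w.sum() <= 0:
            raise ValueError(f"genus {genus!r} has zero total weight")
        rep = species[0]
        keep.append(rep)
        rename[rep] = genus
        rows.append(
            {"taxon": genus, "value": float(np.average(vals, weights=w)),
             **({"n": float(w.sum())} if has_n else {})}
        )
    # full deep copy: tip relabelling must not touch the caller's taxa
    import copy

    out_tree = copy.deepcopy(tree)
    out_tree.retain_taxa_with_labels(keep)
    for leaf in out_tree.leaf_node_iter():
        if leaf.taxon.label in rename:
            leaf.taxon.label = rename[leaf.taxon.label]
    out_tree.purge_taxon_namespace()
    return _trees.ensure_node_labels(out_tree), pd.DataFrame(rows)
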