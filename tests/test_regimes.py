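"""Multi-regime OU likelihood against dense oracles, Hansen fitting, the
stepwise regime search, and genus consolidation."""

import numpy as np
import pandas as pd
import pytest

import helpers
from taluscam import phylo as P
from taluscam import regimes as R
from taluscam import synthetic as S
from taluscam import trees as T


def traits_df(pairs):
    return pd.DataFrame(pairs, columns=["taxon", "value"])


# ---------------------------------------------------------------------------
# painting semantics


def test_painting_inheritance(yule32):
    labels = S.pick_regime_clades(yule32, n_clades=1, min_tips=4,
                                  max_tips=12)
    paint = R.RegimePainting("base", {labels[0]: "shifted"})
    br = paint.branch_regimes(yule32)
    node = next(
        n for n in yule32.preorder_node_iter()
        if not n.is_leaf() and n.label == labels[0]
    )
    inside = {l.taxon.label for l in node.leaf_nodes()}
    for tip in T.tip_labels(yule32):
        assert br[tip] == ("shifted" if tip in inside else "base")


def test_painting_unknown_shift_node_rejected(yule32):
    with pytest.raises(KeyError):
        R.RegimePainting("R0", {"bogus": "R1"}).branch_regimes(yule32)


def test_painting_simplified_drops_noop_shifts(yule32):
    labels = S.pick_regime_clades(yule32, n_clades=1)
    paint = R.RegimePainting("R0", {labels[0]: "R0"})
    simple = paint.simplified(yule32)
    assert simple.shifts == {}
    assert simple.branch_regimes(yule32) == paint.branch_regimes(yule32)


# ---------------------------------------------------------------------------
# likelihood


def test_ou_matches_dense_oracle_random_trees():
    rng = np.random.default_rng(9)
    worst = 0.0
    for _ in range(15):
        n = int(rng.integers(4, 13))
        tree = T.parse_tree(helpers.random_tree_newick(rng, n))
        taxa = T.tip_labels(tree)
        # paint a random internal clade when one exists
        internals = [
            nd.label for nd in tree.preorder_node_iter()
            if not nd.is_leaf() and nd.parent_node is not None
        ]
        paint = R.RegimePainting.single_regime()
        thetas = {"R0": float(rng.normal(1, 0.5))}
        if internals and rng.uniform() < 0.7:
            shift = str(rng.choice(internals))
            paint = R.RegimePainting("R0", {shift: "R1"})
            thetas["R1"] = float(rng.normal(1, 0.5))
        for _ in range(4):
            alpha = float(rng.uniform(0.05, 5.0))
            sigma2 = float(rng.uniform(0.1, 2.0))
            y = rng.normal(1, 1, n)
            tr = traits_df(list(zip(taxa, y)))
            ll = R.ou_loglik(tree, tr, paint, alpha, sigma2, thetas)
            oracle = helpers.ou_dense_loglik(
                tree, taxa, y, paint.branch_regimes(tree),
                paint.base_regime, alpha, sigma2, thetas,
            )
            worst = max(worst, abs(ll - oracle))
    assert worst < 1e-8


def test_ou_star_tree_matches_iid_closed_form(star8):
    rng = np.random.default_rng(4)
    y = rng.normal(1.0, 0.4, 8)
    taxa = T.tip_labels(star8)
    alpha, sigma2, theta, t = 0.9, 0.3, 1.6, 2.0
    paint = R.RegimePainting.single_regime()
    ll = R.ou_loglik(
        star8, traits_df(list(zip(taxa, y))), paint, alpha, sigma2,
        {"R0": theta},
    )
    mean = theta  # root at the optimum: stays at theta in expectation
    var = sigma2 * (1 - np.exp(-2 * alpha * t)) / (2 * alpha)
    iid = float(
        np.sum(-0.5 * ((y - mean) ** 2 / var + np.log(2 * np.pi * var)))
    )
    assert ll == pytest.approx(iid, abs=1e-8)


def test_ou_reduces_to_bm_at_tiny_alpha(yule32):
    tr = S.simulate_bm(yule32, sigma2=0.4, root_state=1.1, seed=1)
    paint = R.RegimePainting.single_regime()
    llou = R.ou_loglik(yule32, tr, paint, 1e-8, 0.4, {"R0": 1.1})
    llbm = P.bm_loglik(yule32, tr, P.EvolModelFit(0.4, 1.1))
    assert abs(llou - llbm) < 1e-4


def test_ou_regime_relabelling_invariance(yule32):
    labels = S.pick_regime_clades(yule32, n_clades=1)
    tr = S.simulate_bm(yule32, sigma2=0.3, root_state=1.0, seed=2)
    a = R.ou_loglik(
        yule32, tr, R.RegimePainting("R0", {labels[0]: "R1"}),
        0.8, 0.3, {"R0": 0.7, "R1": 1.6},
    )
    b = R.ou_loglik(
        yule32, tr, R.RegimePainting("base", {labels[0]: "high"}),
        0.8, 0.3, {"base": 0.7, "high": 1.6},
    )
    assert a == pytest.approx(b, abs=1e-12)


def test_ou_rejects_bad_inputs(yule32):
    tr = S.simulate_bm(yule32, sigma2=0.3, seed=0)
    paint = R.RegimePainting.single_regime()
    with pytest.raises(ValueError):
        R.ou_loglik(yule32, tr, paint, -0.1, 0.3, {"R0": 1.0})
    with pytest.raises(KeyError):
        R.ou_loglik(yule32, tr, paint, 0.5, 0.3, {"other": 1.0})


# ---------------------------------------------------------------------------
# Hansen fitting


def test_fit_hansen_recovers_optimum():
    errs = []
    for seed in range(8):
        tree = S.simulate_tree(128, seed=600 + seed)
        depth = T.tree_depth(tree)
        paint = R.RegimePainting.single_regime()
        tr = S.simulate_ou(
            tree, paint, alpha=8.0 / depth, sigma2=0.3,
            optima={"R0": 1.6}, seed=seed,
        )
        fit = R.fit_hansen(tree, tr, paint)
        errs.append(abs(fit.theta["R0"] - 1.6) / 1.6)
    assert np.median(errs) < 0.10


def test_fit_hansen_bm_data_pushes_alpha_to_boundary(yule32):
    tr = S.simulate_bm(yule32, sigma2=0.3, root_state=1.0, seed=3)
    fit = R.fit_hansen(yule32, tr)
    assert fit.alpha < 0.2
    assert fit.alpha_at_boundary or fit.alpha < 0.05


def test_fit_hansen_constant_traits_rejected(yule32):
    taxa = T.tip_labels(yule32)
    tr = traits_df([(t, 1.0) for t in taxa])
    with pytest.raises(ValueError):
        R.fit_hansen(yule32, tr)


def test_aicc_counts_parameters(yule32):
    labels = S.pick_regime_clades(yule32, n_clades=1)
    tr = S.simulate_bm(yule32, sigma2=0.3, root_state=1.0, seed=4)
    f1 = R.fit_hansen(yule32, tr)
    f2 = R.fit_hansen(yule32, tr, R.RegimePainting("R0", {labels[0]: "R1"}))
    n = 32
    for fit, k in ((f1, 1), (f2, 2)):
        p = 2 + k
        expected = (
            -2 * fit.log_likelihood + 2 * p
            + 2 * p * (p + 1) / (n - p - 1)
        )
        assert fit.aicc == pytest.approx(expected)
    assert f2.k_distinct_regimes <= f2.k_shifts + 1


# ---------------------------------------------------------------------------
# stepwise search


@pytest.fixture(scope="module")
def two_regime_case():
    tree = S.simulate_tree(48, seed=901)
    c1, c2 = S.pick_regime_clades(tree, min_tips=5, max_tips=14)
    paint = R.RegimePainting("R0", {c1: "Ra", c2: "Rb"})
    traits = S.simulate_ou(
        tree, paint, alpha=8.0, sigma2=0.5,
        optima={"R0": 0.7, "Ra": 1.6, "Rb": 1.6}, seed=17,
    )
    return tree, traits, (c1, c2)


def test_forward_aicc_trace_non_increasing(two_regime_case):
    tree, traits, _ = two_regime_case
    seq = R.surface_forward(tree, traits)
    aiccs = [f.aicc for f in seq]
    assert all(b < a for a, b in zip(aiccs, aiccs[1:]))
    assert len(seq) >= 2  # at least one true shift is found


def test_forward_is_deterministic(two_regime_case):
    tree, traits, _ = two_regime_case
    s1 = R.surface_forward(tree, traits)
    s2 = R.surface_forward(tree, traits)
    assert [f.painting.shifts for f in s1] == [f.painting.shifts for f in s2]
    assert [f.aicc for f in s1] == [f.aicc for f in s2]


def test_backward_merges_convergent_regimes(two_regime_case):
    tree, traits, truth = two_regime_case
    seq = R.surface_forward(tree, traits)
    final = R.surface_backward(tree, traits, seq)
    assert final.aicc <= seq[-1].aicc + 1e-9
    # the two same-optimum clades collapse onto one shared regime
    assert final.k_distinct_regimes < final.k_shifts + 1 or \
        final.k_shifts <= 1
    theta_vals = sorted(final.theta.values())
    assert theta_vals[0] == pytest.approx(0.7, abs=0.25)
    assert theta_vals[-1] == pytest.approx(1.6, abs=0.25)


def test_backward_keeps_separated_optima(yule32):
    labels = S.pick_regime_clades(yule32, n_clades=2, min_tips=4,
                                  max_tips=12)
    paint = R.RegimePainting("R0", {labels[0]: "Ra", labels[1]: "Rb"})
    traits = S.simulate_ou(
        yule32, paint, alpha=8.0, sigma2=0.2,
        optima={"R0": 0.7, "Ra": 3.0, "Rb": 6.0}, seed=3,
    )
    seq = R.surface_forward(yule32, traits)
    final = R.surface_backward(yule32, traits, seq)
    # well-separated optima must not be merged
    assert final.k_distinct_regimes == final.k_shifts + 1


def test_merging_all_regimes_reproduces_single_fit(two_regime_case):
    tree, traits, truth = two_regime_case
    paint = R.RegimePainting("R0", {truth[0]: "Ra", truth[1]: "Rb"})
    merged = paint.merged("R0", "Ra").merged("R0", "Rb").simplified(tree)
    f_merged = R.fit_hansen(tree, traits, merged)
    f_single = R.fit_hansen(tree, traits)
    assert f_merged.log_likelihood == pytest.approx(
        f_single.log_likelihood, abs=1e-8
    )
    assert f_merged.aicc == pytest.approx(f_single.aicc, abs=1e-8)


def test_classic_threshold_zero_overfits_relative_to_default():
    """aic_threshold=0 reproduces the accept-any-improvement behaviour,
    which adds at least as many shifts as the selection-aware default."""
    tree = S.simulate_tree(32, seed=55)
    tr = S.simulate_ou(
        tree, R.RegimePainting.single_regime(), alpha=8.0, sigma2=0.5,
        optima={"R0": 1.0}, seed=5,
    )
    classic = R.surface_forward(tree, tr, aic_threshold=0.0, max_steps=4)
    default = R.surface_forward(tree, tr, max_steps=4)
    assert len(classic) >= len(default)


# ---------------------------------------------------------------------------
# genus consolidation


def test_genus_consolidation_weighted_mean():
    tree = T.parse_tree(
        "((Ax_a:1,Ax_b:1):1,(Bx_a:1.5,Bx_b:0.5):1);"
    )
    traits = pd.DataFrame(
        {
            "taxon": ["Ax_a", "Ax_b", "Bx_a", "Bx_b"],
            "value": [1.0, 2.0, 0.5, 0.7],
            "n": [3, 1, 2, 2],
        }
    )
    gmap = {"Ax_a": "Ax", "Ax_b": "Ax", "Bx_a": "Bx", "Bx_b": "Bx"}
    out_tree, out = R.genus_consolidate(traits, tree, gmap)
    vals = out.set_index("taxon")["value"]
    assert vals["Ax"] == pytest.approx(1.25)  # (3*1 + 1*2)/4
    assert vals["Bx"] == pytest.approx(0.6)
    assert sorted(T.tip_labels(out_tree)) == ["Ax", "Bx"]
    # unweighted alternative
    _, unw = R.genus_consolidate(traits, tree, gmap, weights="species")
    assert unw.set_index("taxon")["value"]["Ax"] == pytest.approx(1.5)


def test_genus_consolidation_exceptions_and_errors():
    tree = T.parse_tree("((Ta:1,Tb:1):1,(Ca:1,Cb:1):1);")
    traits = pd.DataFrame(
        {"taxon": ["Ta", "Tb", "Ca", "Cb"],
         "value": [1.0, 2.0, 3.0, 4.0], "n": [1, 1, 1, 1]}
    )
    gmap = {"Ta": "Tarsius", "Tb": "Tarsius", "Ca": "Cebus",
            "Cb": "Cebus"}
    out_tree, out = R.genus_consolidate(
        traits, tree, gmap, exceptions=["Tarsius"]
    )
    labels = sorted(T.tip_labels(out_tree))
    assert labels == ["Cebus", "Ta", "Tb"]
    assert set(out["taxon"]) == {"Cebus", "Ta", "Tb"}
    single = out.set_index("taxon")["value"]
    assert single["Ta"] == 1.0  # exception keeps species value
    with pytest.raises(KeyError):
        R.genus_consolidate(traits, tree, {"Ta": "X"})
    bad = traits.assign(n=[0, 0, 1, 1])
    with pytest.raises(ValueError):
        R.genus_consolidate(bad, tree, gmap)
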