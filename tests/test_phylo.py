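"""BM-family models: likelihood oracles, ML fits, MCMC, stepping-stone
marginal likelihoods, Bayes factors, and ancestral reconstruction."""

import numpy as np
import pandas as pd
import pytest

import helpers
from taluscam import phylo as P
from taluscam import synthetic as S
from taluscam import trees as T


def traits_df(pairs):
    return pd.DataFrame(pairs, columns=["taxon", "value"])


# ---------------------------------------------------------------------------
# likelihood


def test_cherry_ml_root_is_tip_mean(cherry):
    tr = traits_df([("a", 0.0), ("b", 2.0)])
    fit = P.fit_ml(
        T.parse_tree("((a:1,b:1):0.1,c:1.1);"),
        traits_df([("a", 0.0), ("b", 2.0), ("c", 1.0)]),
    )
    assert fit.root_state == pytest.approx(1.0, abs=1e-8)


def test_bm_loglik_matches_dense_oracle_random_trees():
    rng = np.random.default_rng(42)
    worst = 0.0
    for _ in range(25):
        n = int(rng.integers(4, 17))
        tree = T.parse_tree(helpers.random_tree_newick(rng, n))
        taxa = T.tip_labels(tree)
        y = rng.normal(1.0, 1.0, n)
        tr = traits_df(list(zip(taxa, y)))
        sigma2 = float(rng.uniform(0.2, 2.0))
        root = float(rng.normal(0, 1))
        ll = P.bm_loglik(tree, tr, P.EvolModelFit(sigma2, root))
        oracle = helpers.bm_dense_loglik(tree, taxa, y, sigma2, root)
        worst = max(worst, abs(ll - oracle))
    assert worst < 1e-8


def test_bm_loglik_directional_matches_oracle():
    rng = np.random.default_rng(3)
    tree = T.parse_tree(helpers.random_tree_newick(rng, 8))
    taxa = T.tip_labels(tree)
    y = rng.normal(0, 1, 8)
    tr = traits_df(list(zip(taxa, y)))
    fit = P.EvolModelFit(sigma2=0.7, root_state=0.2, trend=0.4)
    ll = P.bm_loglik(tree, tr, fit, P.EvolModelSpec("directional"))
    oracle = helpers.bm_dense_loglik(tree, taxa, y, 0.7, 0.2, trend=0.4)
    assert ll == pytest.approx(oracle, abs=1e-8)


def test_star_tree_sigma2_closed_form(star8):
    rng = np.random.default_rng(1)
    y = rng.normal(1.0, 0.6, 8)
    taxa = T.tip_labels(star8)
    fit = P.fit_ml(star8, traits_df(list(zip(taxa, y))))
    t = 2.0
    expected = np.mean((y - y.mean()) ** 2) / t
    assert fit.sigma2 == pytest.approx(expected, rel=1e-6)
    assert fit.root_state == pytest.approx(y.mean(), abs=1e-8)


def test_directional_on_ultrametric_rejected(yule32):
    taxa = T.tip_labels(yule32)
    tr = traits_df([(t, 1.0 + i * 0.01) for i, t in enumerate(taxa)])
    with pytest.raises(ValueError):
        P.fit_ml(yule32, tr, P.EvolModelSpec("directional"))


def test_fit_ml_discriminates_delta():
    """The delta estimator orders datasets by their generating delta.

    Point estimates on pure-birth trees are right-skewed (the profile
    likelihood is nearly flat, node depths concentrate near the tips), so
    the meaningful recovery property is ordinal: data generated at delta
    = 0.3 / 1.0 / 2.5 yield strictly ordered median estimates, with the
    delta = 1 median inside its empirically derived sampling band.
    """
    medians = []
    for true_delta in (0.3, 1.0, 2.5):
        hats = []
        for seed in range(8):
            tree = S.simulate_tree(96, seed=300 + seed)
            tr = S.simulate_bm(
                tree, sigma2=0.3, root_state=1.0,
                transform=("delta", true_delta), seed=seed,
            )
            fit = P.fit_ml(
                tree, tr, P.EvolModelSpec("random_walk", "delta")
            )
            hats.append(fit.scaling_value)
        medians.append(np.median(hats))
    assert medians[0] < medians[1] < medians[2]
    assert 0.6 <= medians[1] <= 1.8


def test_fit_ml_recovers_sigma2():
    hats = []
    for seed in range(5):
        tree = S.simulate_tree(256, seed=400 + seed)
        tr = S.simulate_bm(tree, sigma2=0.5, root_state=0.0, seed=seed)
        hats.append(P.fit_ml(tree, tr).sigma2)
    assert abs(np.median(hats) - 0.5) / 0.5 < 0.15


def test_fit_ml_detects_lambda_zero():
    tree = S.simulate_tree(96, seed=77)
    star = T.transform_tree(tree, "lambda", 0.0)
    tr = S.simulate_bm(star, sigma2=0.4, root_state=1.0, seed=8)
    fit = P.fit_ml(tree, tr, P.EvolModelSpec("random_walk", "lambda"))
    assert fit.scaling_value < 0.1


# ---------------------------------------------------------------------------
# MCMC


def test_mcmc_symmetric_cherry_root_posterior():
    tree = T.parse_tree("((a:1,b:1):0.01,(c:1,d:1):0.01);")
    tr = traits_df([("a", 0.0), ("b", 2.0), ("c", 0.5), ("d", 1.5)])
    chain = P.mcmc_sample(tree, tr, generations=4000, burn_in=800,
                          thin=4, seed=1)
    assert chain["root"].mean() == pytest.approx(1.0, abs=0.15)


def test_mcmc_bit_reproducible(yule32):
    tr = S.simulate_bm(yule32, sigma2=0.2, root_state=1.0, seed=5)
    c1 = P.mcmc_sample(yule32, tr, generations=600, burn_in=100, seed=9)
    c2 = P.mcmc_sample(yule32, tr, generations=600, burn_in=100, seed=9)
    pd.testing.assert_frame_equal(c1, c2)


def test_mcmc_reports_acceptance(yule32):
    tr = S.simulate_bm(yule32, sigma2=0.2, root_state=1.0, seed=5)
    chain = P.mcmc_sample(
        yule32, tr, P.EvolModelSpec("random_walk", "delta"),
        generations=800, burn_in=200, seed=2,
    )
    acc = chain.attrs["acceptance"]
    assert set(acc) == {"root", "log_sigma2", "delta"}
    assert all(0 < v < 1 for v in acc.values())


# ---------------------------------------------------------------------------
# stepping stone and Bayes factors


def test_stepping_stone_error_shrinks_with_stones():
    """Mean |error| of the estimator decreases as stones increase."""
    log_lik, log_prior, sample_prior, lml = helpers.conjugate_toy(seed=21)
    mean_abs_err = {}
    for k in (4, 64):
        est = P.stepping_stone_generic(
            log_lik, log_prior, sample_prior,
            n_stones=k, gens_per_stone=400, seed=5, replicates=6,
        )
        mean_abs_err[k] = np.mean(
            [abs(v - lml) for v in est.replicate_log_mls]
        )
    assert mean_abs_err[64] < mean_abs_err[4]
    assert mean_abs_err[64] < 0.3


def test_stepping_stone_replicates_agree():
    log_lik, log_prior, sample_prior, lml = helpers.conjugate_toy(seed=2)
    est = P.stepping_stone_generic(
        log_lik, log_prior, sample_prior,
        n_stones=32, gens_per_stone=800, seed=3, replicates=2,
    )
    assert est.replicate_difference < 0.5
    assert len(est.replicate_log_mls) == 2


def test_stepping_stone_on_tree_model(yule32):
    tr = S.simulate_bm(yule32, sigma2=0.2, root_state=1.0, seed=4)
    est = P.stepping_stone(
        yule32, tr, n_stones=16, gens_per_stone=300, seed=6
    )
    assert np.isfinite(est.log_ml)
    assert est.label == "random_walk+none"
    assert est.data_hash


def test_compare_models_conventions():
    def est(lml, label, h="abc"):
        return P.MarginalLikelihoodEstimate(
            log_ml=lml, n_stones=8, gens_per_stone=10, seed=0,
            label=label, data_hash=h,
        )

    table = P.compare_models([est(-10.0, "A"), est(-11.0, "B")])
    ab = table.query("model_i == 'A' and model_j == 'B'").iloc[0]
    ba = table.query("model_i == 'B' and model_j == 'A'").iloc[0]
    assert ab["log_bf"] == pytest.approx(2.0)
    assert ba["log_bf"] == pytest.approx(-2.0)
    assert not ab["positive_evidence"]  # threshold is strict
    same = P.compare_models([est(-10.0, "A"), est(-10.0, "A2")])
    assert np.allclose(same["log_bf"], 0.0)
    with pytest.raises(ValueError):
        P.compare_models([est(-10.0, "A"), est(-11.0, "B", h="zzz")])


# ---------------------------------------------------------------------------
# ancestral states


def test_asr_symmetric_cherry_contains_truth():
    tree = T.parse_tree("(a:1,b:1);")
    tr = traits_df([("a", 0.0), ("b", 2.0)])
    chain = P.mcmc_sample(tree, tr, generations=3000, burn_in=600,
                          thin=4, seed=3)
    asr = P.reconstruct_ancestors(tree, tr, chain, ["n0"], seed=0)
    mean, lo, hi = asr["n0"]
    assert mean == pytest.approx(1.0, abs=0.2)
    assert lo <= 1.0 <= hi


def test_asr_at_tips_equals_observation(yule32):
    tr = S.simulate_bm(yule32, sigma2=0.3, root_state=1.0, seed=11)
    tip = tr["taxon"].iloc[0]
    fit = P.fit_ml(yule32, tr)
    asr = P.reconstruct_ancestors(yule32, tr, fit, [tip])
    mean, lo, hi = asr[tip]
    observed = float(tr.set_index("taxon")["value"][tip])
    assert mean == pytest.approx(observed, abs=1e-9)
    assert hi - lo < 1e-9


def test_asr_plugin_matches_dense_conditional_oracle():
    """Plug-in reconstruction of an internal node equals the explicit
    conditional-normal mean built from dense covariance blocks, here on a
    near-star (delta -> 0) tree with fixed parameters."""
    tree = S.simulate_tree(16, seed=13)
    tr = S.simulate_bm(tree, sigma2=0.5, root_state=1.2, seed=2)
    delta = 1e-3
    fit = P.EvolModelFit(sigma2=0.5, root_state=1.2, scaling_value=delta)
    spec = P.EvolModelSpec("random_walk", "delta")
    # target: an internal node that is not the root
    target = next(
        n.label for n in tree.preorder_node_iter()
        if not n.is_leaf() and n.parent_node is not None
    )
    asr = P.reconstruct_ancestors(tree, tr, fit, [target], spec=spec)
    ttree = T.transform_tree(tree, "delta", delta)
    taxa = T.tip_labels(ttree)
    _, C = T.vcv_matrix(ttree, taxa)
    y = tr.set_index("taxon")["value"].loc[taxa].to_numpy()
    depths = T.node_depths(ttree)
    node = next(
        n for n in ttree.preorder_node_iter()
        if not n.is_leaf() and n.label == target
    )
    below = {l.taxon.label for l in node.leaf_nodes()}
    rep = next(iter(below))
    cross = np.zeros(len(taxa))
    for i, lab in enumerate(taxa):
        if lab in below:
            cross[i] = depths[node]
        else:
            pair = ttree.mrca(
                taxa=[
                    l.taxon for l in ttree.leaf_node_iter()
                    if l.taxon.label in (rep, lab)
                ]
            )
            cross[i] = depths[pair]
    cond = 1.2 + cross @ np.linalg.solve(C, y - 1.2)
    assert asr[target][0] == pytest.approx(cond, abs=1e-6)


def test_asr_clade_definition_resolves_mrca(yule32):
    tr = S.simulate_bm(yule32, sigma2=0.3, root_state=1.0, seed=11)
    tips = T.tip_labels(yule32)[:4]
    fit = P.fit_ml(yule32, tr)
    asr = P.reconstruct_ancestors(
        yule32, tr, fit, {"my_clade": tips}
    )
    assert "my_clade" in asr.nodes
    with pytest.raises(KeyError):
        P.reconstruct_ancestors(yule32, tr, fit, ["not_a_node"])


def test_asr_root_coverage():
    """True root falls inside the 95% HPD in most simulations."""
    hits = 0
    n_sims = 8
    for seed in range(n_sims):
        tree = S.simulate_tree(48, seed=500 + seed)
        tr = S.simulate_bm(tree, sigma2=0.3, root_state=1.2, seed=seed)
        chain = P.mcmc_sample(tree, tr, generations=1500, burn_in=300,
                              thin=4, seed=seed)
        asr = P.reconstruct_ancestors(tree, tr, chain, ["n0"],
                                      n_draws=200, seed=seed)
        _, lo, hi = asr["n0"]
        hits += lo <= 1.2 <= hi
    assert hits >= int(0.6 * n_sims)
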