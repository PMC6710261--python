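"""Brownian-motion trait models on trees: likelihoods, MCMC, stepping-stone
marginal likelihoods, Bayes factors, and ancestral state reconstruction.

Models: the random-walk model is Brownian motion with rate sigma2 and an
estimated root state; the directional model adds a trend (mean change per
unit branch length), identifiable only on non-ultrametric trees. Either
model can be combined with one Pagel scaling parameter (delta, kappa or
lambda) applied to the tree before the covariance is formed.

Model comparison follows the BayesTraits convention: marginal likelihoods
are estimated by stepping-stone sampling along a power posterior path from
prior to posterior, and log Bayes factors are 2 x the difference in log
marginal likelihood, with values > 2 read as positive evidence. Ancestral
states are the conditional-normal distributions of internal-node values
given the tips, pooled over posterior draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import arviz as az
import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from taluscam import trees as _trees

__all__ = [
    "EvolModelSpec",
    "EvolModelFit",
    "Priors",
    "MarginalLikelihoodEstimate",
    "ASRResult",
    "bm_loglik",
    "fit_ml",
    "mcmc_sample",
    "stepping_stone",
    "stepping_stone_generic",
    "compare_models",
    "reconstruct_ancestors",
]

_SCALING_BOUNDS = {"delta": (1e-6, 3.0), "kappa": (0.0, 3.0), "lambda": (0.0, 1.0)}


@dataclasses.dataclass(frozen=True)
class EvolModelSpec:
    """Which BM-family model to fit.

    model   : "random_walk" (BM) or "directional" (BM + trend).
    scaling : "none", "delta", "kappa" or "lambda".
    """

    model: str = "random_walk"
    scaling: str = "none"

    def validate(self, tree: Optional[dendropy.Tree] = None) -> None:
        if self.model not in ("random_walk", "directional"):
            raise ValueError(f"unknown model: {self.model}")
        if self.scaling not in ("none", "delta", "kappa", "lambda"):
            raise ValueError(f"unknown scaling: {self.scaling}")
        if (
            self.model == "directional"
            and tree is not None
            and _trees.is_ultrametric(tree)
        ):
            raise ValueError(
                "directional model on an ultrametric tree: the trend is "
                "not identifiable (all tips share the same path length)"
            )


@dataclasses.dataclass
class EvolModelFit:
    """Fitted (or proposed) parameter set for a BM-family model."""

    sigma2: float
    root_state: float
    trend: float = 0.0
    scaling_value: float = 1.0
    log_likelihood: float = float("nan")


def _trait_vector(
    traits: pd.DataFrame, taxa: Sequence[str]
) -> np.ndarray:
    tbl = traits.set_index("taxon")["value"]
    missing = set(taxa) - set(tbl.index)
    if missing:
        raise KeyError(f"traits missing for tips: {sorted(missing)}")
    return tbl.loc[list(taxa)].to_numpy(dtype=float)


def _data_hash(taxa: Sequence[str], y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(",".join(taxa).encode())
    h.update(np.asarray(y, dtype=float).tobytes())
    return h.hexdigest()[:16]


class _BMStructure:
    """Caches the covariance structure of one (tree, taxa) pair.

    All three Pagel transforms act through node depths on the fixed
    topology, so the scaled covariance is computed directly from a
    precomputed MRCA-index matrix and per-node depths — no tree cloning
    per proposal. A small memo keyed by the scaling value keeps MCMC
    cheap when only non-scaling parameters move. The results agree with
    building the covariance from ``transform_tree`` output exactly.
    """

    def __init__(self, tree: dendropy.Tree, taxa: Sequence[str],
                 scaling: str):
        self.taxa = list(taxa)
        self.scaling = scaling
        nodes = list(tree.preorder_node_iter())
        index = {id(n): k for k, n in enumerate(nodes)}
        self._parent = np.array(
            [index[id(n.parent_node)] if n.parent_node is not None else -1
             for n in nodes]
        )
        self._blen = np.array([n.edge.length or 0.0 for n in nodes])
        self._is_tip = np.array([n.is_leaf() for n in nodes])
        leaf_idx = {
            n.taxon.label: index[id(n)] for n in nodes if n.is_leaf()
        }
        missing = set(self.taxa) - set(leaf_idx)
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        self._tip_rows = np.array([leaf_idx[t] for t in self.taxa])
        # MRCA node-index matrix over the requested taxa
        col = {leaf_idx[t]: i for i, t in enumerate(self.taxa)}
        m = len(self.taxa)
        M = np.zeros((m, m), dtype=np.intp)
        below: Dict[int, np.ndarray] = {}
        for n in reversed(nodes):  # reversed preorder = valid postorder
            k = index[id(n)]
            if n.is_leaf():
                below[k] = (
                    np.array([col[k]], dtype=np.intp) if k in col
                    else np.empty(0, dtype=np.intp)
                )
                continue
            kids = [below[index[id(c)]] for c in n.child_nodes()]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    if len(kids[a]) and len(kids[b]):
                        M[np.ix_(kids[a], kids[b])] = k
                        M[np.ix_(kids[b], kids[a])] = k
            below[k] = (
                np.concatenate(kids) if kids else np.empty(0, dtype=np.intp)
            )
        M[np.arange(m), np.arange(m)] = self._tip_rows
        self._mrca = M
        self._memo: Dict[float, Tuple] = {}

    def _depths(self, blen: np.ndarray) -> np.ndarray:
        d = np.zeros(len(blen))
        for k in range(len(blen)):  # preorder: parents precede children
            p = self._parent[k]
            if p >= 0:
                d[k] = d[p] + blen[k]
        return d

    def _scaled_depths(self, value: float) -> np.ndarray:
        base = self._depths(self._blen)
        if self.scaling == "none":
            return base
        if self.scaling == "kappa":
            return self._depths(self._blen**value)
        total = base.max()
        if total <= 0:
            return base
        if self.scaling == "delta":
            return total * (base / total) ** value
        # lambda: internal depths scaled, tip heights preserved
        d = base * value
        d[self._is_tip] = base[self._is_tip]
        return d

    def at(self, value: float):
        key = round(float(value), 12)
        if key not in self._memo:
            d = self._scaled_depths(value)
            C = d[self._mrca]
            h = d[self._tip_rows]
            try:
                chol = cho_factor(C, lower=True)
            except np.linalg.LinAlgError:
                import warnings

                warnings.warn(
                    "singular BM covariance; adding 1e-10 ridge",
                    stacklevel=2,
                )
                C = C + 1e-10 * np.eye(len(h))
                chol = cho_factor(C, lower=True)
            logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
            if len(self._memo) > 256:
                self._memo.clear()
            self._memo[key] = (C, h, chol, logdet)
        return self._memo[key]


def _safe_cho_factor(C: np.ndarray):
    try:
        return cho_factor(C, lower=True)
    except np.linalg.LinAlgError:
        return cho_factor(C + 1e-10 * np.eye(len(C)), lower=True)


def _gauss_loglik(
    y: np.ndarray, mean: np.ndarray, sigma2: float, chol, logdet: float
) -> float:
    n = len(y)
    r = y - mean
    q = r @ cho_solve(chol, r)
    return float(
        -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + q / sigma2)
    )


def bm_loglik(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    fit: EvolModelFit,
    spec: EvolModelSpec = EvolModelSpec(),
) -> float:
    """Log-density of tip values under the specified BM-family model.

    Multivariate normal with mean ``root_state (+ trend x root-to-tip
    length)`` and covariance ``sigma2 x shared-path-length matrix`` of the
    scaled tree.
    """
    spec.validate()
    taxa = [t for t in traits["taxon"]]
    y = _trait_vector(traits, taxa)
    struct = _BMStructure(tree, taxa, spec.scaling)
    _, h, chol, logdet = struct.at(fit.scaling_value)
    mean = np.full(len(y), fit.root_state)
    if spec.model == "directional":
        mean = mean + fit.trend * h
    return _gauss_loglik(y, mean, fit.sigma2, chol, logdet)


def _profile_fit(
    y: np.ndarray, h: np.ndarray, chol, logdet: float, directional: bool
) -> Tuple[float, float, float, float]:
    """GLS-profile the mean parameters and sigma2; return
    (root, trend, sigma2, loglik)."""
    n = len(y)
    X = np.column_stack([np.ones(n), h]) if directional else np.ones((n, 1))
    CiX = cho_solve(chol, X)
    XtCiX = X.T @ CiX
    beta = np.linalg.solve(XtCiX, CiX.T @ y)
    r = y - X @ beta
    q = float(r @ cho_solve(chol, r))
    sigma2 = max(q / n, 1e-300)
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    root = float(beta[0])
    trend = float(beta[1]) if directional else 0.0
    return root, trend, sigma2, float(ll)


def fit_ml(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    spec: EvolModelSpec = EvolModelSpec(),
) -> EvolModelFit:
    """Maximum-likelihood fit: closed-form root/trend/sigma2 profiles with
    a bounded scalar search over the scaling value."""
    spec.validate(tree)
    taxa = [t for t in traits["taxon"]]
    if len(taxa) < 3:
        raise ValueError("need >= 3 tips")
    y = _trait_vector(traits, taxa)
    struct = _BMStructure(tree, taxa, spec.scaling)
    directional = spec.model == "directional"

    def nll(s: float) -> float:
        _, h, chol, logdet = struct.at(s)
        return -_profile_fit(y, h, chol, logdet, directional)[3]

    if spec.scaling == "none":
        s_hat = 1.0
    else:
        lo, hi = _SCALING_BOUNDS[spec.scaling]
        res = minimize_scalar(
            nll, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        if not res.success:
            raise RuntimeError("scaling-parameter search did not converge")
        s_hat = float(res.x)
    _, h, chol, logdet = struct.at(s_hat)
    root, trend, sigma2, ll = _profile_fit(y, h, chol, logdet, directional)
    return EvolModelFit(
        sigma2=sigma2, root_state=root, trend=trend,
        scaling_value=s_hat, log_likelihood=ll,
    )


def _moment_fit(tree: dendropy.Tree, traits: pd.DataFrame) -> EvolModelFit:
    """ML Brownian fit where possible, else a moment estimate (lets the
    samplers run on trees too small for fit_ml, e.g. a cherry)."""
    try:
        return fit_ml(tree, traits, EvolModelSpec("random_walk", "none"))
    except ValueError:
        y = traits["value"].to_numpy(dtype=float)
        depth = max(_trees.tree_depth(tree), 1e-8)
        return EvolModelFit(
            sigma2=max(float(np.var(y, ddof=0)) / depth, 1e-8),
            root_state=float(np.mean(y)),
        )


# ---------------------------------------------------------------------------
# priors and MCMC


@dataclasses.dataclass
class Priors:
    """Default priors for the Bayesian analyses (all configurable).

    root  ~ Normal(trait mean, (10 x trait SD)^2)
    sigma2 ~ half-Cauchy(scale = ML Brownian rate of the data)
    scaling ~ Uniform(0, 3) for delta/kappa, Uniform(0, 1) for lambda
    trend ~ Normal(0, (10 x trait SD / tree depth)^2)
    """

    root_mean: float
    root_sd: float
    sigma2_scale: float
    scaling_kind: str
    scaling_bounds: Tuple[float, float]
    trend_sd: float

    @classmethod
    def default(
        cls,
        tree: dendropy.Tree,
        traits: pd.DataFrame,
        spec: EvolModelSpec,
    ) -> "Priors":
        y = traits["value"].to_numpy(dtype=float)
        sd = max(float(np.std(y, ddof=1)), 1e-8)
        depth = max(_trees.tree_depth(tree), 1e-8)
        # empirical Brownian rate as the half-Cauchy scale
        sigma2_scale = _moment_fit(tree, traits).sigma2
        bounds = _SCALING_BOUNDS.get(spec.scaling, (0.0, 1.0))
        return cls(
            root_mean=float(np.mean(y)),
            root_sd=10.0 * sd,
            sigma2_scale=max(sigma2_scale, 1e-10),
            scaling_kind=spec.scaling,
            scaling_bounds=bounds,
            trend_sd=10.0 * sd / depth,
        )

    def log_prior(self, fit: EvolModelFit, spec: EvolModelSpec) -> float:
        lp = -0.5 * ((fit.root_state - self.root_mean) / self.root_sd) ** 2 \
            - np.log(self.root_sd * np.sqrt(2 * np.pi))
        if fit.sigma2 <= 0:
            return -np.inf
        s = self.sigma2_scale
        lp += np.log(2.0 / (np.pi * s * (1.0 + (fit.sigma2 / s) ** 2)))
        if spec.scaling != "none":
            lo, hi = self.scaling_bounds
            if not (lo <= fit.scaling_value <= hi):
                return -np.inf
            lp += -np.log(hi - lo)
        if spec.model == "directional":
            lp += -0.5 * (fit.trend / self.trend_sd) ** 2 \
                - np.log(self.trend_sd * np.sqrt(2 * np.pi))
        return float(lp)

    def sample(self, rng: np.random.Generator, spec: EvolModelSpec) -> EvolModelFit:
        lo, hi = self.scaling_bounds
        return EvolModelFit(
            sigma2=float(self.sigma2_scale * np.abs(np.tan(np.pi * rng.uniform(0, 0.5)))),
            root_state=float(rng.normal(self.root_mean, self.root_sd)),
            trend=(
                float(rng.normal(0, self.trend_sd))
            ),
            scaling_value=(
                float(rng.uniform(lo, hi)) if spec.scaling != "none" else 1.0
            ),
        )


def _fit_to_vec(fit: EvolModelFit, spec: EvolModelSpec) -> np.ndarray:
    v = [fit.root_state, np.log(fit.sigma2)]
    if spec.scaling != "none":
        v.append(fit.scaling_value)
    if spec.model == "directional":
        v.append(fit.trend)
    return np.array(v)


def _vec_to_fit(v: np.ndarray, spec: EvolModelSpec) -> EvolModelFit:
    i = 2
    scaling = 1.0
    trend = 0.0
    if spec.scaling != "none":
        scaling = float(v[i])
        i += 1
    if spec.model == "directional":
        trend = float(v[i])
    return EvolModelFit(
        sigma2=float(np.exp(v[1])), root_state=float(v[0]),
        trend=trend, scaling_value=scaling,
    )


def _param_names(spec: EvolModelSpec) -> List[str]:
    names = ["root", "log_sigma2"]
    if spec.scaling != "none":
        names.append(spec.scaling)
    if spec.model == "directional":
        names.append("trend")
    return names


def _mh_run(
    logpost: Callable[[np.ndarray], float],
    x0: np.ndarray,
    generations: int,
    burn_in: int,
    thin: int,
    rng: np.random.Generator,
    step: Optional[np.ndarray] = None,
    adapt: bool = True,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Component-wise random-walk Metropolis. Returns (draws, logposts,
    acceptance rates, final state). log(sigma2) is a plain component here;
    the Jacobian of that reparameterisation is folded into ``logpost``."""
    d = len(x0)
    step = np.full(d, 0.1) if step is None else step.copy()
    x = x0.copy()
    lp = logpost(x)
    if not np.isfinite(lp):
        raise ValueError("initial state has zero posterior density")
    draws, lps = [], []
    acc = np.zeros(d)
    tries = np.zeros(d)
    acc_win = np.zeros(d)
    tries_win = np.zeros(d)
    for g in range(generations):
        for j in range(d):
            prop = x.copy()
            prop[j] += rng.normal(0.0, step[j])
            lp_prop = logpost(prop)
            tries[j] += 1
            tries_win[j] += 1
            if np.log(rng.uniform()) < lp_prop - lp:
                x, lp = prop, lp_prop
                acc[j] += 1
                acc_win[j] += 1
        if adapt and g < burn_in and (g + 1) % 50 == 0:
            rate = acc_win / np.maximum(tries_win, 1)
            step *= np.exp(np.clip(rate - 0.3, -0.5, 0.5))
            acc_win[:] = 0
            tries_win[:] = 0
        if g >= burn_in and (g - burn_in) % thin == 0:
            draws.append(x.copy())
            lps.append(lp)
    rates = acc / np.maximum(tries, 1)
    return np.array(draws), np.array(lps), rates, x


def mcmc_sample(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    spec: EvolModelSpec = EvolModelSpec(),
    priors: Optional[Priors] = None,
    generations: int = 20000,
    burn_in: int = 2000,
    thin: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Metropolis-Hastings posterior sample of the model parameters.

    Returns a DataFrame with one row per stored draw (columns: the model
    parameters plus ``loglik`` and ``logpost``); acceptance rates and the
    data hash live in ``.attrs``. Deterministic given the seed.
    """
    spec.validate(tree)
    if priors is None:
        priors = Priors.default(tree, traits, spec)
    taxa = [t for t in traits["taxon"]]
    y = _trait_vector(traits, taxa)
    struct = _BMStructure(tree, taxa, spec.scaling)
    directional = spec.model == "directional"
    rng = np.random.default_rng(seed)

    def loglik_fit(fit: EvolModelFit) -> float:
        _, h, chol, logdet = struct.at(fit.scaling_value)
        mean = np.full(len(y), fit.root_state)
        if directional:
            mean = mean + fit.trend * h
        return _gauss_loglik(y, mean, fit.sigma2, chol, logdet)

    def logpost(v: np.ndarray) -> float:
        fit = _vec_to_fit(v, spec)
        lpr = priors.log_prior(fit, spec)
        if not np.isfinite(lpr):
            return -np.inf
        # Jacobian of sigma2 -> log sigma2
        return loglik_fit(fit) + lpr + v[1]

    if spec.scaling == "none" and spec.model == "random_walk":
        start = _moment_fit(tree, traits)
    else:
        start = fit_ml(tree, traits, spec)
    x0 = _fit_to_vec(start, spec)
    if spec.scaling != "none":
        lo, hi = priors.scaling_bounds
        x0[2] = np.clip(x0[2], lo + 1e-6, hi - 1e-6)
    draws, lps, rates, _ = _mh_run(
        logpost, x0, generations, burn_in, thin, rng
    )
    if np.any(rates == 0):
        raise RuntimeError(
            f"zero acceptance for components {np.where(rates == 0)[0]}"
        )
    names = _param_names(spec)
    chain = pd.DataFrame(draws, columns=names)
    chain["sigma2"] = np.exp(chain["log_sigma2"])
    chain["logpost"] = lps
    chain["loglik"] = [
        loglik_fit(_vec_to_fit(v, spec)) for v in draws
    ]
    chain.attrs["acceptance"] = dict(zip(names, rates))
    chain.attrs["data_hash"] = _data_hash(taxa, y)
    chain.attrs["spec"] = (spec.model, spec.scaling)
    chain.attrs["seed"] = seed
    return chain


# ---------------------------------------------------------------------------
# stepping-stone marginal likelihood


@dataclasses.dataclass(frozen=True)
class MarginalLikelihoodEstimate:
    """Stepping-stone log marginal likelihood with its sampling settings.

    ``log_ml`` is the mean of the replicate runs; ``replicate_log_mls``
    and their absolute difference are kept as the convergence diagnostic.
    """

    log_ml: float
    n_stones: int
    gens_per_stone: int
    seed: int
    replicate_log_mls: Tuple[float, ...] = ()
    data_hash: str = ""
    label: str = ""

    @property
    def replicate_difference(self) -> float:
        if len(self.replicate_log_mls) < 2:
            return 0.0
        return float(
            max(self.replicate_log_mls) - min(self.replicate_log_mls)
        )


def _stepping_stone_once(
    log_lik: Callable[[np.ndarray], float],
    log_prior: Callable[[np.ndarray], float],
    sample_prior: Callable[[np.random.Generator], np.ndarray],
    n_stones: int,
    gens_per_stone: int,
    rng: np.random.Generator,
    beta_shape: float = 0.3,
) -> float:
    """One stepping-stone pass: powers beta_k = (k/K)^(1/shape), k = 0..K,
    sampling each power posterior by random-walk Metropolis initialised
    from the previous stone's final state."""
    K = n_stones
    betas = (np.arange(K + 1) / K) ** (1.0 / beta_shape)
    # initial state from the prior (finite-likelihood draw)
    for _ in range(1000):
        x = sample_prior(rng)
        if np.isfinite(log_prior(x)) and np.isfinite(log_lik(x)):
            break
    else:
        raise RuntimeError("could not draw a finite-likelihood prior sample")
    d = len(x)
    step = np.full(d, 0.2)
    log_ml = 0.0
    for k in range(K):
        beta = betas[k]

        def logpost(v: np.ndarray, beta: float = beta) -> float:
            lp = log_prior(v)
            if not np.isfinite(lp):
                return -np.inf
            return lp + beta * log_lik(v)

        burn = max(gens_per_stone // 5, 10)
        draws, _, rates, x = _mh_run(
            logpost, x, gens_per_stone + burn, burn, 1, rng,
            step=step, adapt=True,
        )
        lls = np.array([log_lik(v) for v in draws])
        if np.all(~np.isfinite(lls)):
            raise RuntimeError(f"degenerate stone at beta={beta}")
        dbeta = betas[k + 1] - beta
        m = np.max(lls)
        log_ml += dbeta * m + np.log(np.mean(np.exp(dbeta * (lls - m))))
    return float(log_ml)


def stepping_stone_generic(
    log_lik: Callable[[np.ndarray], float],
    log_prior: Callable[[np.ndarray], float],
    sample_prior: Callable[[np.random.Generator], np.ndarray],
    n_stones: int = 64,
    gens_per_stone: int = 2000,
    seed: int = 0,
    replicates: int = 2,
    beta_shape: float = 0.3,
    label: str = "",
    data_hash: str = "",
) -> MarginalLikelihoodEstimate:
    """Stepping-stone estimate for an arbitrary model (vector parameters).

    Runs ``replicates`` independent passes (distinct sub-seeds) and
    reports their mean log-ML plus the replicate difference, the standard
    convergence check for this estimator.
    """
    seeds = np.random.SeedSequence(seed).spawn(replicates)
    vals = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        vals.append(
            _stepping_stone_once(
                log_lik, log_prior, sample_prior, n_stones,
                gens_per_stone, rng, beta_shape,
            )
        )
    return MarginalLikelihoodEstimate(
        log_ml=float(np.mean(vals)),
        n_stones=n_stones,
        gens_per_stone=gens_per_stone,
        seed=seed,
        replicate_log_mls=tuple(vals),
        data_hash=data_hash,
        label=label,
    )


def stepping_stone(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    spec: EvolModelSpec = EvolModelSpec(),
    priors: Optional[Priors] = None,
    n_stones: int = 64,
    gens_per_stone: int = 2000,
    seed: int = 0,
    replicates: int = 2,
) -> MarginalLikelihoodEstimate:
    """Stepping-stone log marginal likelihood of a BM-family model."""
    spec.validate(tree)
    if priors is None:
        priors = Priors.default(tree, traits, spec)
    taxa = [t for t in traits["taxon"]]
    y = _trait_vector(traits, taxa)
    struct = _BMStructure(tree, taxa, spec.scaling)
    directional = spec.model == "directional"

    def log_lik(v: np.ndarray) -> float:
        fit = _vec_to_fit(v, spec)
        if fit.sigma2 <= 0 or not np.isfinite(fit.sigma2):
            return -np.inf
        if spec.scaling != "none":
            lo, hi = priors.scaling_bounds
            if not (lo <= fit.scaling_value <= hi):
                return -np.inf
        _, h, chol, logdet = struct.at(fit.scaling_value)
        mean = np.full(len(y), fit.root_state)
        if directional:
            mean = mean + fit.trend * h
        return _gauss_loglik(y, mean, fit.sigma2, chol, logdet)

    def log_prior(v: np.ndarray) -> float:
        fit = _vec_to_fit(v, spec)
        lp = priors.log_prior(fit, spec)
        return lp + v[1] if np.isfinite(lp) else -np.inf

    def sample_prior(rng: np.random.Generator) -> np.ndarray:
        return _fit_to_vec(priors.sample(rng, spec), spec)

    return stepping_stone_generic(
        log_lik, log_prior, sample_prior, n_stones, gens_per_stone,
        seed, replicates, label=f"{spec.model}+{spec.scaling}",
        data_hash=_data_hash(taxa, y),
    )


def compare_models(
    estimates: Sequence[MarginalLikelihoodEstimate],
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Pairwise log Bayes factors: 2 x (logML_i - logML_j).

    Positive evidence for model i over model j at log BF > ``threshold``
    (the conventional cutoff of 2). All estimates must come from the same
    data (hashes are checked when present).
    """
    if len(estimates) < 2:
        raise ValueError("need >= 2 estimates to compare")
    hashes = {e.data_hash for e in estimates if e.data_hash}
    if len(hashes) > 1:
        raise ValueError("estimates computed on different data")
    rows = []
    for i, a in enumerate(estimates):
        for j, b in enumerate(estimates):
            if i == j:
                continue
            bf = 2.0 * (a.log_ml - b.log_ml)
            rows.append(
                {
                    "model_i": a.label or str(i),
                    "model_j": b.label or str(j),
                    "log_bf": bf,
                    "positive_evidence": bf > threshold,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ancestral state reconstruction


@dataclasses.dataclass(frozen=True)
class ASRResult:
    """Posterior summaries of ancestral states.

    nodes maps node label -> (posterior mean, 95% HPD low, 95% HPD high).
    """

    nodes: Dict[str, Tuple[float, float, float]]
    model: str
    n_draws: int
    seed: int

    def __getitem__(self, key: str) -> Tuple[float, float, float]:
        return self.nodes[key]


def _node_key(node: dendropy.Node) -> str:
    return node.taxon.label if node.is_leaf() else node.label


def _resolve_nodes(
    tree: dendropy.Tree,
    nodes: Union[Sequence[str], Dict[str, Sequence[str]]],
) -> Dict[str, dendropy.Node]:
    """Nodes by label, or named clades given as tip lists (MRCA)."""
    out: Dict[str, dendropy.Node] = {}
    if isinstance(nodes, dict):
        for name, tips in nodes.items():
            out[name] = _trees.mrca_node(tree, tips)
        return out
    by_label = {_node_key(n): n for n in tree.preorder_node_iter()}
    for lab in nodes:
        if lab not in by_label:
            raise KeyError(f"node label not found: {lab}")
        out[lab] = by_label[lab]
    return out


def _ancestral_cross_cov(
    ttree: dendropy.Tree,
    taxa: Sequence[str],
    target_labels: Sequence[str],
) -> Tuple[np.ndarray, np.ndarray]:
    """Shared-path-length vectors between target nodes and the tips, and
    target node depths, on the (already transformed) tree."""
    depths = _trees.node_depths(ttree)
    by_label = {_node_key(n): n for n in ttree.preorder_node_iter()}
    idx = {lab: i for i, lab in enumerate(taxa)}
    n = len(taxa)
    cross = np.zeros((len(target_labels), n))
    d_targets = np.zeros(len(target_labels))
    # tips below each node
    below: Dict[dendropy.Node, set] = {}
    for node in ttree.postorder_node_iter():
        if node.is_leaf():
            below[node] = {node.taxon.label}
        else:
            below[node] = set().union(*(below[c] for c in node.child_nodes()))
    for a, lab in enumerate(target_labels):
        node = by_label[lab]
        d_targets[a] = depths[node]
        inside = below[node]
        for t in inside:
            if t in idx:
                cross[a, idx[t]] = depths[node]
        # tips outside the target clade: MRCA with the target is the first
        # ancestor of the target containing them
        anc = node.parent_node
        seen = set(inside)
        while anc is not None:
            new = below[anc] - seen
            for t in new:
                if t in idx:
                    cross[a, idx[t]] = depths[anc]
            seen |= below[anc]
            anc = anc.parent_node
    return cross, d_targets


def reconstruct_ancestors(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    chain: Union[pd.DataFrame, EvolModelFit],
    nodes: Union[Sequence[str], Dict[str, Sequence[str]]],
    spec: EvolModelSpec = EvolModelSpec(),
    n_draws: int = 500,
    runs: int = 2,
    seed: int = 0,
    hdi_prob: float = 0.95,
) -> ASRResult:
    """Ancestral states given tips, pooled over posterior draws.

    For each draw the tree is scaled by the drawn Pagel value and the
    conditional-normal distribution of each requested node given the tip
    values (standard GLS ancestral reconstruction) is sampled once. Two
    independent runs (fresh sub-seeds and independent thinnings) are
    pooled; means and 95% HPD intervals are reported per node.

    Passing a single ``EvolModelFit`` instead of a chain gives the
    plug-in reconstruction: the exact conditional mean and the central
    interval of the conditional normal, with no Monte Carlo error.
    """
    taxa = [t for t in traits["taxon"]]
    y = _trait_vector(traits, taxa)
    resolved = _resolve_nodes(tree, nodes)
    labels = list(resolved)
    target_labels = [_node_key(resolved[k]) for k in labels]
    struct_cache: Dict[float, tuple] = {}
    directional = spec.model == "directional"

    if isinstance(chain, EvolModelFit):
        # plug-in: analytic conditional normal, no sampling
        ttree = (
            tree if spec.scaling == "none"
            else _trees.transform_tree(tree, spec.scaling, chain.scaling_value)
        )
        _, C = _trees.vcv_matrix(ttree, taxa)
        chol = _safe_cho_factor(C)
        cross, d_t = _ancestral_cross_cov(ttree, taxa, target_labels)
        h = np.diag(C).copy()
        mean_tips = np.full(len(y), chain.root_state)
        mean_t = np.full(len(labels), chain.root_state)
        if directional:
            mean_tips = mean_tips + chain.trend * h
            mean_t = mean_t + chain.trend * d_t
        w = cho_solve(chol, y - mean_tips)
        cond_mean = mean_t + cross @ w
        Sx = cho_solve(chol, cross.T)
        cond_sd = np.sqrt(
            chain.sigma2
            * np.maximum(d_t - np.einsum("an,na->a", cross, Sx), 0.0)
        )
        from scipy.stats import norm

        half = norm.ppf(0.5 + hdi_prob / 2) * cond_sd
        out = {
            lab: (float(m), float(m - hw), float(m + hw))
            for lab, m, hw in zip(labels, cond_mean, half)
        }
        return ASRResult(nodes=out, model="plugin", n_draws=0, seed=seed)
    else:
        draws_df = pd.DataFrame(
            {
                "root": chain["root"],
                "sigma2": chain["sigma2"],
                "trend": chain.get(
                    "trend", pd.Series(0.0, index=chain.index)
                ),
                "scaling": chain.get(
                    spec.scaling, pd.Series(1.0, index=chain.index)
                ),
            }
        )
        model_desc = f"mcmc:{spec.model}+{spec.scaling}"

    def structure(s: float):
        key = round(float(s), 10)
        if key not in struct_cache:
            ttree = (
                tree if spec.scaling == "none"
                else _trees.transform_tree(tree, spec.scaling, s)
            )
            _, C = _trees.vcv_matrix(ttree, taxa)
            chol = _safe_cho_factor(C)
            cross, d_t = _ancestral_cross_cov(ttree, taxa, target_labels)
            h = np.diag(C).copy()
            if len(struct_cache) > 512:
                struct_cache.clear()
            struct_cache[key] = (C, chol, cross, d_t, h)
        return struct_cache[key]

    ss = np.random.SeedSequence(seed).spawn(runs)
    samples: List[np.ndarray] = []
    for run_ss in ss:
        rng = np.random.default_rng(run_ss)
        if len(draws_df) <= n_draws:
            sel = np.arange(len(draws_df))
        else:
            sel = rng.choice(len(draws_df), size=n_draws, replace=False)
        for i in sel:
            row = draws_df.iloc[int(i)]
            C, chol, cross, d_t, h = structure(row["scaling"])
            sigma2 = float(row["sigma2"])
            mean_tips = np.full(len(y), row["root"])
            mean_t = np.full(len(labels), row["root"])
            if directional:
                mean_tips = mean_tips + row["trend"] * h
                mean_t = mean_t + row["trend"] * d_t
            w = cho_solve(chol, (y - mean_tips))
            cond_mean = mean_t + cross @ w
            Sx = cho_solve(chol, cross.T)
            cond_var = sigma2 * np.maximum(
                d_t - np.einsum("an,na->a", cross, Sx), 0.0
            )
            samples.append(
                cond_mean + rng.normal(size=len(labels)) * np.sqrt(cond_var)
            )
    S = np.array(samples)
    out: Dict[str, Tuple[float, float, float]] = {}
    for a, lab in enumerate(labels):
        vals = S[:, a]
        if np.ptp(vals) < 1e-300:
            lo = hi = float(vals[0])
        else:
            lo, hi = az.hdi(vals, hdi_prob=hdi_prob)
        out[lab] = (float(vals.mean()), float(lo), float(hi))
    return ASRResult(
        nodes=out, model=model_desc, n_draws=len(S), seed=seed
    )
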