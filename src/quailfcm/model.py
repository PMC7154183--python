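"""Hierarchical Bayesian random-coefficients model of fecal corticosterone.

Each bird ``j`` carries its own coefficient vector ``beta_j`` over the
``K = 8`` fixed-effect columns (Reference intercept, ACTH and Biological
treatment contrasts, within-treatment time, the two treatment-by-time
interactions, a night indicator and standardized body weight).  The
observation model is

    FCM_i ~ Normal(x_i' beta_{j(i)}, 1 / tau)

with the per-bird coefficients exchangeable across birds,

    beta_{j,k} ~ Normal(mu_k, 1 / tau_k),

vague ``Normal(0, precision 0.001)`` priors on the population means
``mu_k`` and ``Gamma(0.1, 0.1)`` priors on the residual precision ``tau``
and every random-effect precision ``tau_k``.  All full conditionals are
conjugate, so the posterior is explored by a blocked Gibbs sampler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import InvalidConfigError, SchemaError

#: Canonical column order of the design matrix / Table-2-shaped summaries.
EFFECT_NAMES: tuple[str, ...] = (
    "Reference",
    "ACTH",
    "Biological",
    "Time",
    "ACTH:Time",
    "Biological:Time",
    "Night",
    "Weight",
)

TREATMENTS: tuple[str, ...] = ("reference", "acth", "biological")


@dataclass
class ModelData:
    """Design matrix and response assembled from a long-format sample table."""

    y: np.ndarray                 # (N,) FCM in pg/mg
    X: np.ndarray                 # (N, K)
    bird_index: np.ndarray        # (N,) integer codes into bird_ids
    bird_ids: np.ndarray          # (J,) unique bird identifiers, sorted
    effect_names: tuple[str, ...] = EFFECT_NAMES

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def n_birds(self) -> int:
        return self.bird_ids.shape[0]

    @property
    def n_effects(self) -> int:
        return self.X.shape[1]


def build_design(samples: pd.DataFrame, weight_scaling: str = "zscore") -> ModelData:
    """Code a sample table into the fixed design matrix.

    Coding rules: the Reference column is an all-ones intercept; ACTH and
    Biological are treatment indicators (both zero in the reference
    period); Time is the collection-window index within a treatment in
    4-hour units (0..11); the interactions are elementwise products;
    Night is the is_night indicator; Weight is the bird's body weight
    standardized to a z-score over the birds in the table
    (``weight_scaling="grams"`` keeps raw grams).
    """
    required = {"bird_id", "treatment", "window_index", "is_night",
                "weight_g", "fcm_pg_per_mg"}
    missing = required - set(samples.columns)
    if missing:
        raise SchemaError(f"sample table missing column(s): {sorted(missing)}")

    bad = set(samples["treatment"].unique()) - set(TREATMENTS)
    if bad:
        raise SchemaError(f"unknown treatment label(s): {sorted(bad)}")
    if (samples["weight_g"] <= 0).any():
        raise SchemaError("nonpositive bird weight")

    bird_ids, bird_index = np.unique(samples["bird_id"].to_numpy(), return_inverse=True)

    # weight is constant per bird; standardize over birds, not rows
    per_bird_w = samples.groupby("bird_id")["weight_g"].first().reindex(bird_ids)
    w_mean = float(per_bird_w.mean())
    w_sd = float(per_bird_w.std(ddof=1)) if len(per_bird_w) > 1 else 0.0
    if weight_scaling == "grams":
        weight_col = samples["weight_g"].to_numpy(float)
    elif weight_scaling == "zscore":
        if w_sd == 0.0:
            warnings.warn("zero weight variance across birds; Weight column set to 0")
            weight_col = np.zeros(len(samples))
        else:
            weight_col = (samples["weight_g"].to_numpy(float) - w_mean) / w_sd
    else:
        raise InvalidConfigError(f"unknown weight_scaling {weight_scaling!r}")

    acth = (samples["treatment"] == "acth").to_numpy(float)
    bio = (samples["treatment"] == "biological").to_numpy(float)
    time = samples["window_index"].to_numpy(float)
    night = samples["is_night"].to_numpy(float)

    X = np.column_stack([
        np.ones(len(samples)),
        acth,
        bio,
        time,
        acth * time,
        bio * time,
        night,
        weight_col,
    ])
    y = samples["fcm_pg_per_mg"].to_numpy(float)
    return ModelData(y=y, X=X, bird_index=bird_index, bird_ids=bird_ids)


@dataclass
class McmcConfig:
    """Sampler settings: 3 chains of 10 000 iterations, 5 000 burn-in, thin 1."""

    n_chains: int = 3
    n_iter: int = 10_000
    n_burn: int = 5_000
    thin: int = 1
    seed: int = 0
    prior_mu_precision: float = 0.001
    prior_gamma_shape: float = 0.1
    prior_gamma_rate: float = 0.1

    def validate(self) -> None:
        if not self.n_burn < self.n_iter:
            raise InvalidConfigError("n_burn must be < n_iter")
        if self.thin < 1:
            raise InvalidConfigError("thin must be >= 1")
        if min(self.prior_mu_precision, self.prior_gamma_shape,
               self.prior_gamma_rate) <= 0:
            raise InvalidConfigError("prior hyperparameters must be > 0")


@dataclass
class PosteriorDraws:
    """Kept post-burn-in draws, one leading axis per chain."""

    mu: np.ndarray       # (n_chains, n_kept, K)
    tau: np.ndarray      # (n_chains, n_kept)
    tau_k: np.ndarray    # (n_chains, n_kept, K)
    beta: np.ndarray     # (n_chains, n_kept, J, K)
    effect_names: tuple[str, ...]
    bird_ids: np.ndarray
    log_joint: np.ndarray | None = None   # (n_chains, n_kept), optional trace

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    @property
    def n_kept(self) -> int:
        return self.mu.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Chain-pooled draws of ``mu``, ``tau`` or ``tau_k``."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])


def _normal_logpdf(x, mean, precision):
    return 0.5 * (np.log(precision) - np.log(2.0 * np.pi)) \
        - 0.5 * precision * (x - mean) ** 2


def _gamma_logpdf(x, shape, rate):
    return shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x


def log_joint(data: ModelData, state: Mapping[str, np.ndarray],
              config: McmcConfig | None = None) -> float:
    """Unnormalized log posterior density at a full parameter state.

    ``state`` holds ``beta`` (J, K), ``mu`` (K,), scalar ``tau`` and
    ``tau_k`` (K,).  Serves as the target for sampler-equivalence tests.
    """
    config = config or McmcConfig()
    beta = np.asarray(state["beta"], float)
    mu = np.asarray(state["mu"], float)
    tau = float(state["tau"])
    tau_k = np.asarray(state["tau_k"], float)
    if tau <= 0 or (tau_k <= 0).any():
        raise ValueError("precisions must be > 0")

    fitted = np.einsum("ik,ik->i", data.X, beta[data.bird_index])
    lp = _normal_logpdf(data.y, fitted, tau).sum()
    lp += _normal_logpdf(beta, mu[None, :], tau_k[None, :]).sum()
    lp += _normal_logpdf(mu, 0.0, config.prior_mu_precision).sum()
    a, b = config.prior_gamma_shape, config.prior_gamma_rate
    lp += _gamma_logpdf(tau, a, b)
    lp += _gamma_logpdf(tau_k, a, b).sum()
    return float(lp)


class HierarchicalGibbsRegressor(BaseEstimator, RegressorMixin):
    """Conjugate blocked Gibbs sampler for the random-coefficients model.

    Parameters follow :class:`McmcConfig`; ``random_state`` seeds every
    chain reproducibly.  After :meth:`fit`, posterior draws live in
    ``draws_`` and the population-level posterior means in ``coef_``.

    The update cycle per iteration:

    1. ``beta_j`` for every bird from its K-variate normal full
       conditional with precision ``tau * X_j'X_j + diag(tau_k)``;
    2. each ``mu_k`` from the normal conditional pooling the J bird
       coefficients with the vague prior;
    3. ``tau`` from ``Gamma(a + N/2, b + SSE/2)``;
    4. each ``tau_k`` from ``Gamma(a + J/2, b + sum_j (beta_jk - mu_k)^2 / 2)``.

    Chains start overdispersed: chain ``c`` (1-based) initializes
    ``mu`` at a prior draw scaled by ``c``; ``tau`` and ``tau_k`` at 1.
    """

    def __init__(self, n_chains: int = 3, n_iter: int = 10_000,
                 n_burn: int = 5_000, thin: int = 1,
                 prior_mu_precision: float = 0.001,
                 prior_gamma_shape: float = 0.1,
                 prior_gamma_rate: float = 0.1,
                 store_beta: bool = True,
                 track_log_joint: bool = False,
                 random_state: int = 0):
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.n_burn = n_burn
        self.thin = thin
        self.prior_mu_precision = prior_mu_precision
        self.prior_gamma_shape = prior_gamma_shape
        self.prior_gamma_rate = prior_gamma_rate
        self.store_beta = store_beta
        self.track_log_joint = track_log_joint
        self.random_state = random_state

    def _config(self) -> McmcConfig:
        return McmcConfig(
            n_chains=self.n_chains, n_iter=self.n_iter, n_burn=self.n_burn,
            thin=self.thin, seed=self.random_state,
            prior_mu_precision=self.prior_mu_precision,
            prior_gamma_shape=self.prior_gamma_shape,
            prior_gamma_rate=self.prior_gamma_rate,
        )

    def fit(self, X, y, groups=None, effect_names: Sequence[str] | None = None,
            bird_ids=None):
        """Sample the posterior given design ``X``, response ``y`` and the
        per-observation bird labels ``groups``."""
        cfg = self._config()
        cfg.validate()
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (N, K) and y (N,) with matching N")
        if groups is None:
            groups = np.zeros(len(y), dtype=int)
        uniq, bird_index = np.unique(np.asarray(groups), return_inverse=True)
        if bird_ids is None:
            bird_ids = uniq
        N, K = X.shape
        J = len(uniq)
        if N <= K:
            raise ValueError(f"need more observations ({N}) than effects ({K})")
        names = tuple(effect_names) if effect_names is not None \
            else (EFFECT_NAMES if K == len(EFFECT_NAMES)
                  else tuple(f"x{k}" for k in range(K)))
        data = ModelData(y=y, X=X, bird_index=bird_index,
                         bird_ids=np.asarray(bird_ids), effect_names=names)

        chains = [self._run_chain(data, cfg, chain) for chain in range(cfg.n_chains)]
        self.draws_ = PosteriorDraws(
            mu=np.stack([c["mu"] for c in chains]),
            tau=np.stack([c["tau"] for c in chains]),
            tau_k=np.stack([c["tau_k"] for c in chains]),
            beta=(np.stack([c["beta"] for c in chains])
                  if self.store_beta else np.empty((cfg.n_chains, 0, J, K))),
            effect_names=names,
            bird_ids=data.bird_ids,
            log_joint=(np.stack([c["lj"] for c in chains])
                       if self.track_log_joint else None),
        )
        self.effect_names_ = names
        self.coef_ = self.draws_.pooled("mu").mean(axis=0)
        self.n_features_in_ = K
        return self

    def predict(self, X):
        """Population-level posterior-mean linear predictor."""
        X = np.asarray(X, float)
        return X @ self.coef_

    # -- sampler internals ----------------------------------------------

    def _run_chain(self, data: ModelData, cfg: McmcConfig, chain: int) -> dict:
        rng = np.random.default_rng([cfg.seed, chain])
        N, K = data.X.shape
        J = data.n_birds
        a, b = cfg.prior_gamma_shape, cfg.prior_gamma_rate

        # per-bird sufficient statistics
        order = np.argsort(data.bird_index, kind="stable")
        Xs, ys, idx = data.X[order], data.y[order], data.bird_index[order]
        starts = np.searchsorted(idx, np.arange(J + 1))
        XtX = np.empty((J, K, K))
        Xty = np.empty((J, K))
        for j in range(J):
            Xj = Xs[starts[j]:starts[j + 1]]
            XtX[j] = Xj.T @ Xj
            Xty[j] = Xj.T @ ys[starts[j]:starts[j + 1]]

        # overdispersed start: prior draw on mu scaled by the chain number
        mu = rng.normal(0.0, 1.0 / np.sqrt(cfg.prior_mu_precision), K) * (chain + 1)
        tau = 1.0
        tau_k = np.ones(K)
        beta = np.tile(mu, (J, 1))

        keep = [it for it in range(cfg.n_iter)
                if it >= cfg.n_burn and (it - cfg.n_burn) % cfg.thin == 0]
        n_kept = len(keep)
        out = {
            "mu": np.empty((n_kept, K)),
            "tau": np.empty(n_kept),
            "tau_k": np.empty((n_kept, K)),
            "beta": np.empty((n_kept, J, K)) if self.store_beta else None,
            "lj": np.empty(n_kept) if self.track_log_joint else None,
        }
        eye = np.eye(K)
        kept = 0
        for it in range(cfg.n_iter):
            # (1) beta_j | rest  — batched K-variate normal
            Lam = tau * XtX + tau_k * eye              # (J, K, K)
            rhs = tau * Xty + tau_k * mu               # (J, K)
            try:
                L = np.linalg.cholesky(Lam)
            except np.linalg.LinAlgError as exc:      # unreachable when tau_k > 0
                raise RuntimeError(
                    "singular per-bird conditional precision") from exc
            m = np.linalg.solve(Lam, rhs[..., None])[..., 0]
            z = rng.standard_normal((J, K))
            beta = m + np.linalg.solve(np.swapaxes(L, 1, 2), z[..., None])[..., 0]

            # (2) mu_k | rest
            prec = J * tau_k + cfg.prior_mu_precision
            mean = tau_k * beta.sum(axis=0) / prec
            mu = mean + rng.standard_normal(K) / np.sqrt(prec)

            # (3) tau | rest
            fitted = np.einsum("ik,ik->i", Xs, beta[idx])
            sse = float(np.square(ys - fitted).sum())
            tau = rng.gamma(a + 0.5 * N, 1.0 / (b + 0.5 * sse))

            # (4) tau_k | rest
            ssb = np.square(beta - mu).sum(axis=0)
            tau_k = rng.gamma(a + 0.5 * J, 1.0 / (b + 0.5 * ssb))

            if it >= cfg.n_burn and (it - cfg.n_burn) % cfg.thin == 0:
                out["mu"][kept] = mu
                out["tau"][kept] = tau
                out["tau_k"][kept] = tau_k
                if self.store_beta:
                    out["beta"][kept] = beta
                if self.track_log_joint:
                    out["lj"][kept] = log_joint(
                        data, {"beta": beta, "mu": mu, "tau": tau,
                               "tau_k": tau_k}, cfg)
                kept += 1
        if not self.store_beta:
            out["beta"] = np.empty((0, J, K))
        return out


def run_mcmc(data: ModelData, config: McmcConfig | None = None,
             **estimator_kwargs) -> PosteriorDraws:
    """Functional front end: fit the Gibbs sampler on a :class:`ModelData`."""
    config = config or McmcConfig()
    est = HierarchicalGibbsRegressor(
        n_chains=config.n_chains, n_iter=config.n_iter, n_burn=config.n_burn,
        thin=config.thin, prior_mu_precision=config.prior_mu_precision,
        prior_gamma_shape=config.prior_gamma_shape,
        prior_gamma_rate=config.prior_gamma_rate,
        random_state=config.seed, **estimator_kwargs)
    est.fit(data.X, data.y, groups=data.bird_index,
            effect_names=data.effect_names, bird_ids=data.bird_ids)
    return est.draws_
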