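"""Independent oracles used by the test suite.

Everything here is deliberately written by a different route than the
library code it checks: brute-force summation, direct matrix least
squares, a random-walk Metropolis sampler, two-pass variance formulas.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from quailfcm.model import McmcConfig, ModelData, log_joint


def brute_force_log_joint(data: ModelData, state, config: McmcConfig) -> float:
    """Term-by-term evaluation with scipy.stats densities."""
    beta = np.asarray(state["beta"], float)
    mu = np.asarray(state["mu"], float)
    tau = float(state["tau"])
    tau_k = np.asarray(state["tau_k"], float)
    total = 0.0
    for i in range(data.n_obs):
        m = float(data.X[i] @ beta[data.bird_index[i]])
        total += stats.norm.logpdf(data.y[i], m, 1.0 / np.sqrt(tau))
    for j in range(beta.shape[0]):
        for k in range(beta.shape[1]):
            total += stats.norm.logpdf(beta[j, k], mu[k], 1.0 / np.sqrt(tau_k[k]))
    for k in range(mu.shape[0]):
        total += stats.norm.logpdf(mu[k], 0.0,
                                   1.0 / np.sqrt(config.prior_mu_precision))
    a, b = config.prior_gamma_shape, config.prior_gamma_rate
    total += stats.gamma.logpdf(tau, a, scale=1.0 / b)
    for k in range(tau_k.shape[0]):
        total += stats.gamma.logpdf(tau_k[k], a, scale=1.0 / b)
    return float(total)


def random_walk_metropolis(data: ModelData, config: McmcConfig, n_steps: int,
                           seed: int, scale: float = 0.08,
                           burn_frac: float = 0.25):
    """Random-walk MH targeting log_joint, precisions in log space.

    Returns (mu_draws, acceptance_rate).  Slow but entirely independent
    of the Gibbs code path.
    """
    rng = np.random.default_rng(seed)
    J, K = data.n_birds, data.n_effects
    dim = J * K + K + 1 + K

    def unpack(v):
        beta = v[:J * K].reshape(J, K)
        mu = v[J * K:J * K + K]
        tau = np.exp(v[J * K + K])
        tau_k = np.exp(v[J * K + K + 1:])
        return {"beta": beta, "mu": mu, "tau": tau, "tau_k": tau_k}

    def target(v):
        st = unpack(v)
        # + log-Jacobian of the log-precision transform
        return log_joint(data, st, config) + v[J * K + K] + v[J * K + K + 1:].sum()

    v = np.zeros(dim)
    v[J * K:J * K + K] = data.y.mean()      # crude start near the data scale
    v[:J * K] = data.y.mean()
    lp = target(v)
    n_burn = int(burn_frac * n_steps)
    kept = np.empty((n_steps - n_burn, K))
    accepted = 0
    for it in range(n_steps):
        prop = v + scale * rng.standard_normal(dim)
        lp_prop = target(prop)
        if np.log(rng.random()) < lp_prop - lp:
            v, lp = prop, lp_prop
            accepted += 1
        if it >= n_burn:
            kept[it - n_burn] = v[J * K:J * K + K]
    return kept, accepted / n_steps


def batch_means_se(x: np.ndarray, n_batches: int = 40) -> float:
    """Monte-Carlo standard error of the mean of a correlated sequence."""
    n = len(x) // n_batches * n_batches
    means = x[:n].reshape(n_batches, -1).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def two_pass_rhat(chains: np.ndarray) -> float:
    """Brute-force Gelman-Rubin with explicit loops and two-pass variances."""
    chains = np.asarray(chains, float)
    m, n = chains.shape
    within = []
    for c in range(m):
        mean_c = sum(chains[c]) / n
        within.append(sum((x - mean_c) ** 2 for x in chains[c]) / (n - 1))
    W = sum(within) / m
    chain_means = [sum(chains[c]) / n for c in range(m)]
    grand = sum(chain_means) / m
    B = n * sum((cm - grand) ** 2 for cm in chain_means) / (m - 1)
    if W == 0:
        return np.inf if B > 0 else 1.0
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))


def glm_slope_homogeneity(lines) -> tuple[float, int, int, float]:
    """Full-vs-reduced general-linear-model F-test by direct least squares.

    Builds explicit design matrices (per-line intercepts + per-line
    slopes vs per-line intercepts + common slope) and compares residual
    sums of squares.
    """
    xs = [np.asarray(ln, float) for ln in lines]
    a = len(xs)
    y = np.concatenate([ln[:, 1] for ln in xs])
    n_tot = len(y)
    # reduced: a intercepts + 1 slope
    Xr = np.zeros((n_tot, a + 1))
    # full: a intercepts + a slopes
    Xf = np.zeros((n_tot, 2 * a))
    r = 0
    for g, ln in enumerate(xs):
        n_g = ln.shape[0]
        Xr[r:r + n_g, g] = 1.0
        Xr[r:r + n_g, a] = ln[:, 0]
        Xf[r:r + n_g, g] = 1.0
        Xf[r:r + n_g, a + g] = ln[:, 0]
        r += n_g
    def sse(X):
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        return float(resid @ resid)
    sse_r, sse_f = sse(Xr), sse(Xf)
    df_num = a - 1
    df_den = n_tot - 2 * a
    f = ((sse_r - sse_f) / df_num) / (sse_f / df_den)
    p = float(stats.f.sf(f, df_num, df_den))
    return f, df_num, df_den, p
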