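"""Convergence diagnostics and posterior summaries.

Produces the classic (non-split) Gelman-Rubin R-hat, Table-2-shaped
posterior summaries of the population effects (quantiles, posterior
mean, among-individual sigma per effect), Table-1-shaped derived
treatment means, percent-change contrasts and predicted trajectories.
"""

from __future__ import annotations

from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, SchemaError
from .model import PosteriorDraws

QUANTS = (0.025, 0.25, 0.75, 0.975)


def rhat(chains: np.ndarray, split: bool = False) -> float:
    """Gelman-Rubin potential scale reduction factor.

    ``chains`` is (m, n): m >= 2 chains of n draws of one parameter.
    W is the mean within-chain variance, B the between-chain variance
    times n; R-hat = sqrt(((n-1)/n * W + B/n) / W).  ``split=True``
    halves each chain first (the modern variant).
    """
    chains = np.asarray(chains, float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 2:
        raise InsufficientDataError("need >= 2 chains of >= 2 draws")
    if split:
        half = chains.shape[1] // 2
        chains = np.concatenate([chains[:, :half], chains[:, half:2 * half]])
    m, n = chains.shape
    W = float(chains.var(axis=1, ddof=1).mean())
    B = float(n * chains.mean(axis=1).var(ddof=1))
    if W == 0.0:
        return np.inf if B > 0.0 else 1.0
    v_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(v_hat / W))


def summarize(draws: PosteriorDraws, split_rhat: bool = False) -> pd.DataFrame:
    """Table-2-shaped posterior summary of the population effects.

    One row per effect in canonical order with columns ``q025, q25,
    mean, q75, q975`` (pooled across chains, type-7 empirical
    quantiles), ``sigma`` (posterior mean of ``tau_k**-0.5``, the
    among-individual SD for that effect) and ``rhat``.
    """
    if draws.n_kept < 1:
        raise InsufficientDataError("no kept draws to summarize")
    mu = draws.pooled("mu")          # (m*n, K)
    sig = draws.pooled("tau_k") ** -0.5
    rows = []
    for k, name in enumerate(draws.effect_names):
        q = np.quantile(mu[:, k], QUANTS)
        rows.append({
            "parameter": name,
            "q025": q[0], "q25": q[1],
            "mean": float(mu[:, k].mean()),
            "q75": q[2], "q975": q[3],
            "sigma": float(sig[:, k].mean()),
            "rhat": rhat(draws.mu[:, :, k], split=split_rhat),
        })
    return pd.DataFrame(rows).set_index("parameter")


def max_rhat(draws: PosteriorDraws, split: bool = False) -> float:
    """Largest R-hat over all population means and precisions (mu_k, tau, tau_k)."""
    vals = [rhat(draws.mu[:, :, k], split=split)
            for k in range(draws.mu.shape[2])]
    vals.append(rhat(draws.tau, split=split))
    vals += [rhat(draws.tau_k[:, :, k], split=split)
             for k in range(draws.tau_k.shape[2])]
    return float(np.max(vals))


_TREATMENT_EFFECT = {
    "Reference": (),
    "ACTH": ("ACTH",),
    "Biological": ("Biological",),
    "Night": ("Night",),
}


def derived_treatment_means(draws) -> pd.DataFrame:
    """Table-1-shaped treatment-level concentrations.

    Each treatment mean is the reference intercept plus that
    treatment's contrast, evaluated at window 0, day-time, mean weight.
    Given :class:`PosteriorDraws`, the sums are taken draw-wise so
    credible intervals propagate; given a plain mapping of effect name
    to posterior mean, only the means are returned.
    """
    if isinstance(draws, Mapping):
        missing = {"Reference", "ACTH", "Biological", "Night"} - set(draws)
        if missing:
            raise SchemaError(f"missing effect(s): {sorted(missing)}")
        rows = [{"treatment": t,
                 "mean": draws["Reference"] + sum(draws[e] for e in eff)}
                for t, eff in _TREATMENT_EFFECT.items()]
        return pd.DataFrame(rows).set_index("treatment")

    names = list(draws.effect_names)
    for req in ("Reference", "ACTH", "Biological", "Night"):
        if req not in names:
            raise SchemaError(f"draws lack required effect {req!r}")
    mu = draws.pooled("mu")
    rows = []
    for t, eff in _TREATMENT_EFFECT.items():
        d = mu[:, names.index("Reference")].copy()
        for e in eff:
            d += mu[:, names.index(e)]
        q = np.quantile(d, QUANTS)
        rows.append({"treatment": t, "q025": q[0], "q25": q[1],
                     "mean": float(d.mean()), "q75": q[2], "q975": q[3]})
    return pd.DataFrame(rows).set_index("treatment")


class PercentChange(NamedTuple):
    value: float     # full precision
    percent: int     # nearest integer percent


def percent_change(baseline: float, treated: float) -> PercentChange:
    """Relative change from baseline, e.g. (16.75, 29.00) -> +73%."""
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    v = 100.0 * (treated - baseline) / baseline
    return PercentChange(v, int(round(v)))


def predict_trajectory(draws: PosteriorDraws, treatment: str,
                       windows=range(12)) -> pd.DataFrame:
    """Population-level predicted FCM trajectory with a 95% band.

    Evaluates the linear predictor draw-wise at each collection window
    (day-time, standardized weight 0) and returns per-window posterior
    mean with 2.5/97.5 percentile bounds.
    """
    names = list(draws.effect_names)
    mu = draws.pooled("mu")
    ix = {n: names.index(n) for n in names}
    t_low = {"reference": ("", ""), "acth": ("ACTH", "ACTH:Time"),
             "biological": ("Biological", "Biological:Time")}
    if treatment not in t_low:
        raise ValueError(f"unknown treatment {treatment!r}")
    main, inter = t_low[treatment]
    rows = []
    for w in windows:
        if not 0 <= int(w) <= 11:
            raise ValueError(f"window {w} outside 0..11")
        d = mu[:, ix["Reference"]] + w * mu[:, ix["Time"]]
        if main:
            d = d + mu[:, ix[main]] + w * mu[:, ix[inter]]
        rows.append({"window_index": int(w), "mean": float(d.mean()),
                     "q025": float(np.quantile(d, 0.025)),
                     "q975": float(np.quantile(d, 0.975))})
    return pd.DataFrame(rows).set_index("window_index")
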