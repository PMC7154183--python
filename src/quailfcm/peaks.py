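"""Post hoc peak analysis: did the ACTH challenge condition the response
to the biological stressor?

Extracts each bird's maximum observed FCM per treatment and estimates
the relationship between ACTH-period and biological-period peaks with a
Bayesian simple linear regression (vague normal priors on intercept and
slope, Gamma(0.1, 0.1) on the residual precision, Gibbs sampling).  A
Pearson correlation is reported alongside for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import InsufficientDataError
from .model import TREATMENTS


def extract_peaks(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-bird peak FCM and its window for each treatment.

    Ties are broken toward the earliest window; a bird with no samples
    in a treatment gets NaN there (and is excluded from the
    relationship fit).  Row order of the input is irrelevant.
    """
    if samples.empty:
        raise InsufficientDataError("empty sample table")
    names = {"reference": ("peak_reference", "window_ref"),
             "acth": ("peak_acth", "window_acth"),
             "biological": ("peak_biological", "window_bio")}
    s = samples.sort_values(["bird_id", "treatment", "window_index"], kind="stable")
    out: dict[str, dict] = {}
    for (bird, trt), g in s.groupby(["bird_id", "treatment"], sort=True):
        i = int(g["fcm_pg_per_mg"].to_numpy().argmax())  # first max -> earliest window
        peak_col, win_col = names[trt]
        rec = out.setdefault(bird, {})
        rec[peak_col] = float(g["fcm_pg_per_mg"].iloc[i])
        rec[win_col] = float(g["window_index"].iloc[i])
    table = pd.DataFrame.from_dict(out, orient="index").rename_axis("bird_id")
    cols = ["peak_reference", "peak_acth", "peak_biological",
            "window_ref", "window_acth", "window_bio"]
    for c in cols:
        if c not in table.columns:
            table[c] = np.nan
    return table[cols].sort_index()


class BayesianSlopeRegression(BaseEstimator, RegressorMixin):
    """Conjugate Gibbs sampler for y = a + b x + Normal(0, 1/tau).

    Priors: Normal(0, precision 0.001) on intercept and slope,
    Gamma(0.1, 0.1) on tau.  Fitted attributes: ``slope_mean_``,
    ``slope_ci_`` (2.5/97.5 posterior percentiles), ``coef_draws_``.
    """

    def __init__(self, n_iter: int = 6000, n_burn: int = 1000,
                 prior_precision: float = 0.001,
                 prior_gamma_shape: float = 0.1, prior_gamma_rate: float = 0.1,
                 random_state: int = 0):
        self.n_iter = n_iter
        self.n_burn = n_burn
        self.prior_precision = prior_precision
        self.prior_gamma_shape = prior_gamma_shape
        self.prior_gamma_rate = prior_gamma_rate
        self.random_state = random_state

    def fit(self, X, y):
        x = np.asarray(X, float).reshape(-1)
        y = np.asarray(y, float).reshape(-1)
        if x.size != y.size or x.size < 3:
            raise InsufficientDataError("need >= 3 paired observations")
        if np.ptp(x) == 0:
            raise ValueError("zero variance in the predictor; slope undefined")
        rng = np.random.default_rng(self.random_state)
        D = np.column_stack([np.ones_like(x), x])
        DtD, Dty = D.T @ D, D.T @ y
        n = x.size
        a0, b0 = self.prior_gamma_shape, self.prior_gamma_rate
        coef = np.zeros(2)
        tau = 1.0
        kept = []
        for it in range(self.n_iter):
            prec = tau * DtD + self.prior_precision * np.eye(2)
            L = np.linalg.cholesky(prec)
            m = np.linalg.solve(prec, tau * Dty)
            coef = m + np.linalg.solve(L.T, rng.standard_normal(2))
            resid = y - D @ coef
            tau = rng.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * float(resid @ resid)))
            if it >= self.n_burn:
                kept.append(coef)
        self.coef_draws_ = np.asarray(kept)
        self.intercept_mean_ = float(self.coef_draws_[:, 0].mean())
        self.slope_mean_ = float(self.coef_draws_[:, 1].mean())
        self.slope_ci_ = tuple(np.quantile(self.coef_draws_[:, 1], [0.025, 0.975]))
        return self

    def predict(self, X):
        x = np.asarray(X, float).reshape(-1)
        return self.intercept_mean_ + self.slope_mean_ * x


@dataclass
class PeakRelationship:
    slope_mean: float
    slope_q025: float
    slope_q975: float
    pearson_r: float
    n_birds: int


def peak_relationship(peaks: pd.DataFrame, seed: int = 0,
                      n_iter: int = 6000, n_burn: int = 1000) -> PeakRelationship:
    """Posterior slope of biological-period peak on ACTH-period peak."""
    complete = peaks.dropna(subset=["peak_acth", "peak_biological"])
    if len(complete) < 3:
        raise InsufficientDataError(
            f"need >= 3 birds with peaks in both treatments, have {len(complete)}")
    x = complete["peak_acth"].to_numpy(float)
    y = complete["peak_biological"].to_numpy(float)
    reg = BayesianSlopeRegression(n_iter=n_iter, n_burn=n_burn,
                                  random_state=seed).fit(x, y)
    r = float(np.corrcoef(x, y)[0, 1])
    return PeakRelationship(reg.slope_mean_, reg.slope_ci_[0], reg.slope_ci_[1],
                            r, len(complete))
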