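"""Chi-square tests of overall model fit and the comparative fit index.

The stage-2 minimum-distance statistic Q = (s - sigma(theta))' W (s - sigma)
is asymptotically a weighted sum of independent 1-df chi-squares; the
weights are the eigenvalues of U Gamma, with

    U = W - W Delta (Delta' W Delta)^-1 Delta' W

the projected weight matrix.  When W is the optimal full weight Gamma^-1,
the nonzero weights are all 1 and Q is exactly chi-square(df).  Four
p-values are reported:

* unadjusted          -- Q against chi-square(df);
* mean adjusted       -- Q rescaled so its mean matches df (first-moment,
  Satorra-Bentler style);
* mean-variance adjusted -- rescaled to match mean and variance, with
  fractional df* = (sum w)^2 / sum w^2;
* theoretical         -- Monte-Carlo tail probability of the exact mixture
  distribution, with a chi-square statistic back-calculated from that
  p-value on model df.

CFI compares the model's noncentrality (theoretical statistic minus df)
against that of an independence baseline with all covariances fixed at 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import NumericalError

__all__ = [
    "FitIndexBundle",
    "mixture_weights",
    "chisq_unadjusted",
    "chisq_mean_adjusted",
    "chisq_mean_variance_adjusted",
    "chisq_theoretical",
    "cfi",
    "compute_fit_indices",
]


@dataclass
class FitIndexBundle:
    """Statistic/df/p for each of the four fit tests, plus CFI."""

    unadjusted: tuple = (np.nan, 0, np.nan)
    mean_adjusted: tuple = (np.nan, 0, np.nan)
    mean_variance_adjusted: tuple = (np.nan, 0.0, np.nan)
    theoretical: tuple = (np.nan, 0, np.nan)
    cfi: float = np.nan
    mixture_weights: np.ndarray = field(default_factory=lambda: np.array([]))
    mc_reps: int = 0
    seed: int = 0

    def as_rows(self):
        return [
            ("unadjusted", *self.unadjusted),
            ("mean_adjusted", *self.mean_adjusted),
            ("mean_variance_adjusted", *self.mean_variance_adjusted),
            ("theoretical", *self.theoretical),
        ]


def mixture_weights(W: np.ndarray, Gamma: np.ndarray,
                    Delta: np.ndarray) -> np.ndarray:
    """Eigenvalues of U * Gamma (asymptotic mixture weights), floored at 0.

    Negative eigenvalues below -1e-8 (sampling noise in the estimated
    Gamma) are flagged with a warning before flooring.
    """
    W = np.asarray(W, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    if Delta is None or Delta.size == 0:
        U = W
    else:
        M = Delta.T @ W @ Delta
        try:
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"Delta' W Delta singular: {exc}") from exc
        WD = W @ Delta
        U = W - WD @ Minv @ WD.T
    lam = np.linalg.eigvals(U @ Gamma)
    lam = np.real(lam)
    scale = max(1.0, np.max(np.abs(lam), initial=0.0))
    if np.any(lam < -1e-8 * scale):
        warnings.warn(
            f"negative mixture weights floored at 0 (min {lam.min():.3g})",
            stacklevel=2)
    lam = np.where(lam < 0, 0.0, lam)
    return np.sort(lam)[::-1]


def chisq_unadjusted(Q_min: float, df: int) -> tuple:
    """Q against chi-square(df); undefined (NA) when df = 0."""
    if df < 1:
        return (np.nan, df, np.nan)
    return (Q_min, df, float(stats.chi2.sf(Q_min, df)))


def chisq_mean_adjusted(Q_min: float, weights: np.ndarray, df: int) -> tuple:
    """First-moment correction: Q / (sum w / df) against chi-square(df)."""
    if df < 1:
        return (np.nan, df, np.nan)
    sw = float(np.sum(weights))
    if sw <= 0:
        raise NumericalError("sum of mixture weights is not positive")
    stat = Q_min * df / sw
    return (stat, df, float(stats.chi2.sf(stat, df)))


def chisq_mean_variance_adjusted(Q_min: float, weights: np.ndarray) -> tuple:
    """Mean-and-variance correction with fractional df* = (sum w)^2/sum w^2."""
    sw = float(np.sum(weights))
    sw2 = float(np.sum(np.square(weights)))
    if sw2 <= 0:
        raise NumericalError("sum of squared mixture weights is not positive")
    df_star = sw * sw / sw2
    if df_star <= 0:
        return (np.nan, df_star, np.nan)
    stat = Q_min * df_star / sw
    return (stat, df_star, float(stats.chi2.sf(stat, df_star)))


def chisq_theoretical(Q_min: float, weights: np.ndarray, df: int,
                      mc_reps: int = 100_000, seed: int = 0) -> tuple:
    """Monte-Carlo p-value under the exact mixture law sum_j w_j chi2_1.

    p = (1 + #{draws >= Q}) / (mc_reps + 1) (add-one smoothing, never 0);
    the back-calculated statistic is the chi-square(df) quantile at 1 - p.
    """
    if df < 1:
        return (np.nan, df, np.nan)
    w = np.asarray(weights, dtype=float)
    w = w[w > 1e-12]
    rng = np.random.default_rng(seed)
    if w.size == 0:
        p = 1.0 / (mc_reps + 1)
        p = 1.0 if Q_min <= 0 else p
    else:
        # chunked so memory stays bounded for large mc_reps
        exceed = 0
        remaining = int(mc_reps)
        while remaining > 0:
            chunk = min(remaining, 200_000 // max(1, w.size) + 1)
            z = rng.standard_normal((chunk, w.size))
            draws = np.square(z) @ w
            exceed += int(np.sum(draws >= Q_min))
            remaining -= chunk
        p = (1.0 + exceed) / (mc_reps + 1.0)
    stat = float(stats.chi2.isf(p, df))
    return (stat, df, float(p))


def cfi(stat_model: float, df_model: float,
        stat_baseline: float, df_baseline: float) -> float:
    """CFI = 1 - max(T_m - df_m, 0) / max(T_b - df_b, T_m - df_m, 0)."""
    num = max(stat_model - df_model, 0.0)
    den = max(stat_baseline - df_baseline, stat_model - df_model, 0.0)
    if den <= 0:
        return np.nan
    return float(np.clip(1.0 - num / den, 0.0, 1.0))


def compute_fit_indices(Q_min: float, W: np.ndarray, Gamma: np.ndarray,
                        Delta: np.ndarray, df: int,
                        baseline: tuple | None = None,
                        mc_reps: int = 100_000, seed: int = 0) -> FitIndexBundle:
    """All four fit tests plus CFI for one fitted model.

    ``baseline`` is ``(Q_baseline, Delta_baseline, df_baseline)`` for the
    independence model (same s, Gamma, W); when omitted CFI is NA.
    """
    bundle = FitIndexBundle(mc_reps=int(mc_reps), seed=int(seed))
    if df < 1:
        return bundle
    w = mixture_weights(W, Gamma, Delta)
    bundle.mixture_weights = w
    bundle.unadjusted = chisq_unadjusted(Q_min, df)
    bundle.mean_adjusted = chisq_mean_adjusted(Q_min, w, df)
    bundle.mean_variance_adjusted = chisq_mean_variance_adjusted(Q_min, w)
    bundle.theoretical = chisq_theoretical(Q_min, w, df, mc_reps, seed)
    if baseline is not None:
        Q_b, Delta_b, df_b = baseline
        if df_b >= 1:
            w_b = mixture_weights(W, Gamma, Delta_b)
            stat_b, _, _ = chisq_theoretical(Q_b, w_b, df_b, mc_reps, seed + 1)
            bundle.cfi = cfi(bundle.theoretical[0], df, stat_b, df_b)
    return bundle
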