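"""Weighted block-jackknife machinery.

All f-statistics in this package are ratios of block-decomposable sums, so
every estimate carries delete-one-block leave-one-out values computed from
per-block sums. Standard errors use the weighted jackknife of Busing,
Meijer & van der Leeden (1999), which handles unequal block sizes (blocks
are equal genetic spans, not equal SNP counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class JackknifeEstimate:
    """A scalar statistic with weighted block-jackknife uncertainty."""

    value: float
    se: float
    loo_values: np.ndarray   # leave-one-block-out estimates, non-empty blocks
    weights: np.ndarray      # per-block weights (usable SNP counts)
    n_snps_used: int

    @property
    def n_blocks(self) -> int:
        return len(self.loo_values)

    @property
    def z(self) -> float:
        return self.value / self.se if self.se > 0 else np.inf * np.sign(self.value)


def weighted_jackknife(theta: float, loo: np.ndarray,
                       weights: np.ndarray) -> tuple[float, float]:
    """Bias-corrected estimate and SE from leave-one-block-out values.

    `weights` m_j are the per-block weights (SNP counts); with h_j = n/m_j,
    the jackknife estimate is g*theta - sum_j (1 - m_j/n) * loo_j and the
    variance averages squared pseudovalue deviations scaled by 1/(h_j - 1).
    """
    loo = np.asarray(loo, dtype=float)
    m = np.asarray(weights, dtype=float)
    g = len(loo)
    if g < 2:
        return theta, np.nan
    n = m.sum()
    h = n / m
    theta_j = g * theta - np.sum((1.0 - m / n) * loo)
    tau = h * theta - (h - 1.0) * loo
    var = np.mean((tau - theta_j) ** 2 / (h - 1.0))
    return float(theta_j), float(np.sqrt(var))


def jackknife_se(theta: float, loo: np.ndarray, weights: np.ndarray) -> float:
    """SE only (the estimate itself is the plug-in ratio, not bias-corrected)."""
    _, se = weighted_jackknife(theta, loo, weights)
    return se


def jackknife_covariance(theta: np.ndarray, loo: np.ndarray,
                         weights: np.ndarray) -> np.ndarray:
    """Weighted jackknife covariance of a vector statistic.

    Parameters
    ----------
    theta : (E,) full-data estimate.
    loo : (B, E) leave-one-block-out estimates.
    weights : (B,) per-block weights.

    Generalizes the scalar variance above through pseudovalues; with equal
    weights it reduces to the classic ((g-1)/g) * sum of outer deviations.
    """
    theta = np.asarray(theta, dtype=float)
    loo = np.asarray(loo, dtype=float)
    m = np.asarray(weights, dtype=float)
    g = loo.shape[0]
    if g < 2:
        return np.full((theta.size, theta.size), np.nan)
    n = m.sum()
    h = (n / m)[:, None]
    theta_j = g * theta - np.sum((1.0 - m[:, None] / n) * loo, axis=0)
    tau = h * theta[None, :] - (h - 1.0) * loo
    dev = (tau - theta_j[None, :]) / np.sqrt(h - 1.0)
    return dev.T @ dev / g


def ratio_jackknife(num_blocks: np.ndarray, den_blocks: np.ndarray,
                    weights: np.ndarray | None = None) -> JackknifeEstimate:
    """Jackknife a ratio-of-sums statistic from per-block sums.

    The statistic is sum(num)/sum(den); leave-one-out values drop one block
    from both sums. Blocks with zero weight (no usable SNPs) are ignored.
    `weights` defaults to `den_blocks` (appropriate when the denominator is
    a usable-SNP count).
    """
    num_blocks = np.asarray(num_blocks, dtype=float)
    den_blocks = np.asarray(den_blocks, dtype=float)
    w = den_blocks if weights is None else np.asarray(weights, dtype=float)
    keep = w > 0
    num_b, den_b, w_b = num_blocks[keep], den_blocks[keep], w[keep]
    tot_n, tot_d = num_b.sum(), den_b.sum()
    if tot_d == 0:
        raise ZeroDivisionError("no usable SNPs in any block")
    theta = tot_n / tot_d
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = (tot_n - num_b) / (tot_d - den_b)
    _, se = weighted_jackknife(theta, loo, w_b)
    return JackknifeEstimate(float(theta), se, loo, w_b,
                             n_snps_used=int(round(w_b.sum())))
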