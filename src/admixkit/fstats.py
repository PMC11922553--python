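"""Unbiased f2/f3/f4 statistics and Hudson F_ST with block-jackknife errors.

f-statistics are moments of sample allele-frequency differences measuring
shared genetic drift between populations: with sample frequencies a, b, c, d,

    f4(A,B;C,D) = E[(a-b)(c-d)]
    f2(A,B)     = E[(a-b)^2] - h_A/n_A - h_B/n_B
    f3(T;A,B)   = E[(t-a)(t-b)] - h_T/n_T

where h = p(1-p) n/(n-1) is the unbiased per-SNP heterozygosity and the
h/n terms remove finite-sample noise variance (f4 with four distinct
populations needs no correction). All estimates are weighted means over
usable SNPs with SEs from a weighted block jackknife over contiguous
genetic-map blocks.

Missingness modes: ``allsnps`` uses, for each statistic, every SNP where
the populations entering *that* statistic are called (mirroring the
ADMIXTOOLS "allsnps: YES" option); ``intersection`` restricts every
statistic to SNPs where all populations of the frequency table are called,
making different entries of an f4 matrix exactly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype import BlockPartition, FreqTable
from .jackknife import (JackknifeEstimate, jackknife_covariance,
                        ratio_jackknife)

ALLSNPS = "allsnps"
INTERSECTION = "intersection"


class NoUsableSNPsError(ValueError):
    """No SNP passes the missingness/correction requirements."""


class RidgeWarning(UserWarning):
    """The f4 covariance was near-singular and a ridge was added."""


def _check_mode(mode: str) -> None:
    if mode not in (ALLSNPS, INTERSECTION):
        raise ValueError(f"mode must be '{ALLSNPS}' or '{INTERSECTION}'")


def _table_intersection_mask(freqs: FreqTable) -> np.ndarray:
    """Intersection mode: every table population called with >= 2 allele
    draws, so all statistic families share exactly one SNP set and the
    algebraic identities among them hold to rounding error."""
    return (~np.isnan(freqs.freq).any(axis=0)) & (freqs.called >= 2).all(axis=0)


def _block_estimate(contrib: np.ndarray, mask: np.ndarray,
                    partition: BlockPartition) -> JackknifeEstimate:
    """Weighted mean of per-SNP contributions over `mask`, jackknifed."""
    if not mask.any():
        raise NoUsableSNPsError("no usable SNPs for this statistic")
    num = np.where(mask, contrib, 0.0)
    num_b = np.add.reduceat(num, partition.starts)
    cnt_b = np.add.reduceat(mask.astype(float), partition.starts)
    return ratio_jackknife(num_b, cnt_b)


def _het_correction(freqs: FreqTable, pop: str, inbreed: bool) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP h/n term for `pop` and the mask of SNPs where it is defined.

    h/n = p(1-p)/(n-1) with n the number of called allele draws; under
    inbreed handling n is the number of called *individuals* (each
    pseudohaploid call, or each individual of an inbred population, is one
    independent draw from the allele-frequency distribution).
    """
    i = freqs.row(pop)
    p = freqs.freq[i]
    n = (freqs.n_ind[i] if inbreed else freqs.called[i]).astype(float)
    ok = n >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(ok, p * (1.0 - p) / np.maximum(n - 1.0, 1e-300), np.nan)
    return corr, ok


def f4_stat(freqs: FreqTable, A: str, B: str, C: str, D: str,
            partition: BlockPartition, mode: str = ALLSNPS) -> JackknifeEstimate:
    """f4(A,B;C,D) = mean over usable SNPs of (a-b)(c-d).

    Antisymmetric under swapping within a pair, symmetric under swapping
    the pairs; identically 0 when A == B (same samples).
    """
    _check_mode(mode)
    a, b, c, d = (freqs.freq_of(p) for p in (A, B, C, D))
    contrib = (a - b) * (c - d)
    if mode == ALLSNPS:
        mask = ~np.isnan(contrib)
    else:
        mask = _table_intersection_mask(freqs)
    return _block_estimate(np.nan_to_num(contrib), mask, partition)


def f2_stat(freqs: FreqTable, A: str, B: str, partition: BlockPartition,
            mode: str = ALLSNPS, inbreed: bool = False) -> JackknifeEstimate:
    """Unbiased f2(A,B): mean of (a-b)^2 - h_A/n_A - h_B/n_B.

    SNPs where either population has a single called draw (correction
    undefined) are dropped.
    """
    _check_mode(mode)
    a, b = freqs.freq_of(A), freqs.freq_of(B)
    if A == B:  # same samples: the difference is identically 0 and the
        # independent-draw correction does not apply
        mask = ~np.isnan(a)
        if mode == INTERSECTION:
            mask &= _table_intersection_mask(freqs)
        return _block_estimate(np.zeros_like(a), mask, partition)
    ca, oka = _het_correction(freqs, A, inbreed)
    cb, okb = _het_correction(freqs, B, inbreed)
    contrib = (a - b) ** 2 - ca - cb
    mask = ~np.isnan(contrib) & oka & okb
    if mode == INTERSECTION:
        mask &= _table_intersection_mask(freqs)
    return _block_estimate(np.nan_to_num(contrib), mask, partition)


def f3_stat(freqs: FreqTable, target: str, A: str, B: str,
            partition: BlockPartition, mode: str = ALLSNPS,
            inbreed: bool = False) -> JackknifeEstimate:
    """f3(target; A, B) = mean of (t-a)(t-b) minus the target h/n term.

    A significantly negative value is proof the target is admixed between
    populations related to A and B. With ``inbreed=True`` no correction is
    subtracted (the convention for pseudohaploid targets where individual
    genotypes are haploid draws; the estimate is then biased upward and
    only its sign is interpretable).
    """
    _check_mode(mode)
    t, a, b = (freqs.freq_of(p) for p in (target, A, B))
    if target in (A, B):  # per-SNP product identically 0 on shared samples
        mask = ~np.isnan(t)
        if mode == INTERSECTION:
            mask &= _table_intersection_mask(freqs)
        return _block_estimate(np.zeros_like(t), mask, partition)
    if inbreed:
        corr = np.zeros_like(t)
        ok = np.ones_like(t, dtype=bool)
    else:
        corr, ok = _het_correction(freqs, target, inbreed=False)
        if not ok.any():
            raise NoUsableSNPsError(
                f"target {target!r} never has >=2 called alleles; "
                "the heterozygosity correction is undefined (use inbreed=True)")
    contrib = (t - a) * (t - b) - corr
    mask = ~np.isnan(contrib) & ok
    if mode == INTERSECTION:
        mask &= _table_intersection_mask(freqs)
    return _block_estimate(np.nan_to_num(contrib), mask, partition)


def fst_hudson(freqs: FreqTable, A: str, B: str, partition: BlockPartition,
               mode: str = ALLSNPS, inbreed: bool = False) -> JackknifeEstimate:
    """Hudson F_ST between A and B as a ratio of averages.

    numerator   per SNP: (a-b)^2 - h_A/n_A - h_B/n_B
    denominator per SNP: a(1-b) + b(1-a)

    Both sums run over SNPs where each population has >=2 called draws;
    the ratio of the genome-wide sums is jackknifed as a whole. With
    ``inbreed=True`` the correction counts called individuals as the
    independent draws (pseudohaploid calls are haploid draws already).
    """
    _check_mode(mode)
    a, b = freqs.freq_of(A), freqs.freq_of(B)
    ca, oka = _het_correction(freqs, A, inbreed)
    cb, okb = _het_correction(freqs, B, inbreed)
    num = (a - b) ** 2 - ca - cb
    if A == B:
        num = np.zeros_like(a)  # same samples: no differentiation by construction
    den = a * (1.0 - b) + b * (1.0 - a)
    mask = ~np.isnan(num) & ~np.isnan(den) & oka & okb
    if mode == INTERSECTION:
        mask &= _table_intersection_mask(freqs)
    if not mask.any():
        raise NoUsableSNPsError("no usable SNPs for F_ST")
    num_b = np.add.reduceat(np.where(mask, num, 0.0), partition.starts)
    den_b = np.add.reduceat(np.where(mask, den, 0.0), partition.starts)
    cnt_b = np.add.reduceat(mask.astype(float), partition.starts)
    if den_b.sum() <= 0:
        raise ZeroDivisionError("non-positive F_ST denominator")
    est = ratio_jackknife(num_b, den_b, weights=cnt_b)
    est.n_snps_used = int(mask.sum())
    return est


@dataclass
class F4Matrix:
    """The f4 matrix underlying qpWave/qpAdm.

    ``A[i-1, j-1] = f4(left_i, left_0; right_j, right_0)`` for i, j >= 1
    (the first left and right populations are the bases), with the
    block-jackknife covariance ``Q`` of the row-major flattened matrix.
    Per-block entry sums and usable-SNP counts are retained so downstream
    fits can form leave-one-block-out matrices cheaply.
    """

    left: list[str]
    right: list[str]
    A: np.ndarray             # (n_l-1, n_r-1)
    Q: np.ndarray             # (E, E), E = (n_l-1)(n_r-1)
    n_snps: np.ndarray        # (n_l-1, n_r-1) usable SNPs per entry
    mode: str
    block_sums: np.ndarray    # (E, B)
    block_counts: np.ndarray  # (E, B)
    block_weights: np.ndarray  # (B,) mean per-entry usable count
    ridge: float = 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape

    def flat(self) -> np.ndarray:
        return self.A.ravel()

    def loo_entries(self, block: int) -> np.ndarray:
        """Row-major flattened matrix with one block deleted."""
        num = self.block_sums.sum(axis=1) - self.block_sums[:, block]
        cnt = self.block_counts.sum(axis=1) - self.block_counts[:, block]
        return num / cnt

    def loo_all(self) -> np.ndarray:
        """(B, E) leave-one-block-out flattened matrices."""
        num = self.block_sums.sum(axis=1)[:, None] - self.block_sums
        cnt = self.block_counts.sum(axis=1)[:, None] - self.block_counts
        return (num / cnt).T


def _f4_products(freqs: FreqTable, left: list[str], right: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP products (E, S) and validity masks for all matrix entries."""
    l0 = freqs.freq_of(left[0])
    r0 = freqs.freq_of(right[0])
    dl = np.stack([freqs.freq_of(l) - l0 for l in left[1:]])   # (n_l-1, S)
    dr = np.stack([freqs.freq_of(r) - r0 for r in right[1:]])  # (n_r-1, S)
    prod = dl[:, None, :] * dr[None, :, :]
    E = prod.shape[0] * prod.shape[1]
    prod = prod.reshape(E, -1)
    return prod, ~np.isnan(prod)


def build_f4_matrix(freqs: FreqTable, left_list: list[str], right_list: list[str],
                    partition: BlockPartition, mode: str = ALLSNPS,
                    ridge_condition: float = 1e10) -> F4Matrix:
    """All f4(left_i, left_0; right_j, right_0) with jackknife covariance.

    Requires >= 2 left and >= len(left)+1 right populations, disjoint. Q is
    the weighted delete-one-block jackknife covariance of the flattened
    matrix; if its condition number exceeds `ridge_condition`, a ridge
    1e-8 * trace(Q)/dim * I is added (with a :class:`RidgeWarning`).
    """
    _check_mode(mode)
    if len(left_list) < 2:
        raise ValueError("need at least 2 left populations")
    if len(right_list) < len(left_list) + 1:
        raise ValueError("need at least len(left)+1 right populations")
    if set(left_list) & set(right_list):
        raise ValueError(f"left/right overlap: {set(left_list) & set(right_list)}")

    prod, valid = _f4_products(freqs, left_list, right_list)
    if mode == INTERSECTION:
        valid = valid & _table_intersection_mask(freqs)[None, :]

    starts = partition.starts
    block_sums = np.add.reduceat(np.where(valid, prod, 0.0), starts, axis=1)
    block_counts = np.add.reduceat(valid.astype(float), starts, axis=1)
    tot = block_sums.sum(axis=1)
    cnt = block_counts.sum(axis=1)
    if (cnt == 0).any():
        raise NoUsableSNPsError("an f4 entry has no usable SNPs")
    theta = tot / cnt

    # drop blocks empty for every entry, keep weights = mean usable count
    keep = block_counts.sum(axis=0) > 0
    block_sums, block_counts = block_sums[:, keep], block_counts[:, keep]
    weights = block_counts.mean(axis=0)

    n_l1, n_r1 = len(left_list) - 1, len(right_list) - 1
    fm = F4Matrix(list(left_list), list(right_list),
                  theta.reshape(n_l1, n_r1), np.empty(0),
                  cnt.reshape(n_l1, n_r1).astype(np.int64), mode,
                  block_sums, block_counts, weights)
    loo = fm.loo_all()
    Q = jackknife_covariance(theta, loo, weights)
    cond = np.linalg.cond(Q)
    if not np.isfinite(cond) or cond > ridge_condition:
        eps = 1e-8 * np.trace(Q) / Q.shape[0]
        Q = Q + eps * np.eye(Q.shape[0])
        fm.ridge = float(eps)
        warnings.warn(
            f"f4 covariance condition number {cond:.2e}; added ridge {eps:.2e}",
            RidgeWarning, stacklevel=2)
    fm.Q = Q
    return fm


def stats_to_frame(records: list[tuple[str, tuple[str, ...], JackknifeEstimate]]) -> pd.DataFrame:
    """Tabulate (statistic name, populations, estimate) records for TSV export."""
    rows = []
    for name, pops, est in records:
        rows.append({"statistic": name, "populations": ",".join(pops),
                     "value": est.value, "se": est.se, "z": est.z,
                     "n_snps": est.n_snps_used, "n_blocks": est.n_blocks})
    return pd.DataFrame(rows)
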