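"""Reference-based PCA with least-squares projection of incomplete samples.

The axes are fit on a reference panel only (so projected ancient samples
cannot perturb them): genotypes are mean-centered and scaled by
sqrt(p(1-p)) per SNP, missing reference entries are mean-imputed, and the
top-K axes come from the individual-by-individual kernel. Low-coverage
samples are placed by solving a least-squares problem on their observed
SNPs only ("lsqproject"), optionally corrected for projection shrinkage
with per-PC factors estimated by leave-one-out projection of the
reference individuals themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeDataset


@dataclass
class PCABasis:
    """A fitted reference PCA space.

    ``snp_loadings`` (S_used x K) are orthonormal SNP-space eigenvectors;
    ``eigenvalues`` are non-increasing kernel eigenvalues; ``shrink``
    holds per-PC correction factors (>= 1) applied when projecting with
    shrinkage correction on.
    """

    snp_index: np.ndarray      # indices of retained SNPs in the dataset
    mean: np.ndarray           # (S_used,) mean dosage
    scale: np.ndarray          # (S_used,) sqrt(p(1-p)) normalization
    snp_loadings: np.ndarray   # (S_used, K)
    eigenvalues: np.ndarray    # (K,)
    ref_coords: pd.DataFrame   # individual, population, PC1..PCK
    shrink: np.ndarray | None = None

    @property
    def K(self) -> int:
        return self.snp_loadings.shape[1]


def _normalized_matrix(dataset: GenotypeDataset, columns: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Centered, p(1-p)-scaled dosage matrix for the given individuals.

    Returns (X, kept SNP indices, per-SNP mean, per-SNP scale); SNPs
    monomorphic in or entirely missing from the panel are dropped and
    missing entries are mean-imputed (zero after centering).
    """
    G = dataset.geno[:, columns].astype(float)
    G[G == MISSING] = np.nan
    mean = np.nanmean(G, axis=1)
    with np.errstate(invalid="ignore"):
        p = mean / 2.0
        scale = np.sqrt(p * (1.0 - p))
    keep = np.isfinite(scale) & (scale > 0)
    X = (G[keep] - mean[keep, None]) / scale[keep, None]
    X[np.isnan(X)] = 0.0
    return X.T, np.flatnonzero(keep), mean[keep], scale[keep]


def _eigenbasis(X: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-K kernel eigenpairs and orthonormal SNP loadings of X (n x S)."""
    n, S = X.shape
    kernel = X @ X.T / S
    evals, evecs = np.linalg.eigh(kernel)
    order = np.argsort(evals)[::-1][:K]
    evals = np.maximum(evals[order], 0.0)
    U = evecs[:, order]
    V = X.T @ U
    norms = np.linalg.norm(V, axis=0)
    if np.any(norms <= 0):
        raise ValueError("requested K exceeds the usable rank of the panel")
    V /= norms
    coords = X @ V
    return evals, V, coords


def fit_reference_basis(dataset: GenotypeDataset,
                        axis_populations: list[str], K: int,
                        shrink: bool = True) -> PCABasis:
    """Fit a PCA basis on the individuals of `axis_populations`.

    With ``shrink=True``, per-PC correction factors are estimated by
    refitting the basis with each reference individual held out,
    projecting the held-out individual, and taking the ratio of the mean
    full-fit to mean held-out coordinate magnitude per PC. Projected
    samples multiplied by these factors become comparable to the
    reference coordinates.
    """
    cols = np.concatenate([dataset.individuals_of(p) for p in axis_populations])
    if cols.size < 2:
        raise ValueError("need at least two axis individuals")
    if K > cols.size - 1:
        raise ValueError(f"K={K} exceeds usable rank {cols.size - 1}")
    X, snp_index, mean, scale = _normalized_matrix(dataset, cols)
    evals, V, coords = _eigenbasis(X, K)

    ref = pd.DataFrame({
        "individual": dataset.ind["id"].iloc[cols].to_numpy(),
        "population": dataset.ind["population"].iloc[cols].to_numpy(),
    })
    for k in range(K):
        ref[f"PC{k + 1}"] = coords[:, k]

    basis = PCABasis(snp_index, mean, scale, V, evals, ref)
    if shrink:
        basis.shrink = _loo_shrink_factors(X, K, coords)
    return basis


def _loo_shrink_factors(X: np.ndarray, K: int, full_coords: np.ndarray
                        ) -> np.ndarray:
    """Per-PC shrinkage correction from leave-one-out self-projection."""
    n = X.shape[0]
    loo_abs = np.zeros(K)
    for i in range(n):
        rest = np.delete(np.arange(n), i)
        try:
            _, V_i, _ = _eigenbasis(X[rest], K)
        except ValueError:
            return np.ones(K)
        loo_abs += np.abs(X[i] @ V_i)
    loo_abs /= n
    full_abs = np.abs(full_coords).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(loo_abs > 0, full_abs / loo_abs, 1.0)
    return np.clip(factors, 1.0, None)


def project_sample(basis: PCABasis, sample_calls: np.ndarray,
                   shrink: bool = False) -> np.ndarray:
    """Least-squares projection of one sample onto the basis.

    `sample_calls` is the full-length dosage vector ({0,1,2}, missing
    -1/NaN) aligned to the basis's source dataset. Coordinates minimize
    the squared error between the sample's normalized observed genotypes
    and the eigenvector reconstruction, solved on the observed rows only;
    for a complete sample this equals the dot-product projection. With
    ``shrink=True`` the leave-one-out correction factors are applied.
    """
    calls = np.asarray(sample_calls, dtype=float)[basis.snp_index]
    obs = np.isfinite(calls) & (calls != MISSING)
    if not obs.any():
        raise ValueError("sample shares no called SNP with the basis")
    y = (calls[obs] - basis.mean[obs]) / basis.scale[obs]
    V = basis.snp_loadings[obs]
    coords, *_ = np.linalg.lstsq(V, y, rcond=None)
    if shrink:
        if basis.shrink is None:
            raise ValueError("basis was fit without shrinkage estimation")
        coords = coords * basis.shrink
    return coords


def project_dataset(basis: PCABasis, dataset: GenotypeDataset,
                    individuals: list[str] | None = None,
                    shrink: bool = False) -> pd.DataFrame:
    """Project many individuals; returns individual, population, PC1..K."""
    ids = individuals if individuals is not None else dataset.ind["id"].tolist()
    id_to_col = {i: c for c, i in enumerate(dataset.ind["id"])}
    rows = []
    for ind_id in ids:
        col = id_to_col[ind_id]
        coords = project_sample(basis, dataset.geno[:, col], shrink=shrink)
        rows.append([ind_id, dataset.ind["population"].iloc[col], *coords])
    return pd.DataFrame(rows, columns=["individual", "population",
                                       *[f"PC{k + 1}" for k in range(basis.K)]])
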