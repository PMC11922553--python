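"""Admixture-LD decay dating.

After a single admixture pulse g generations ago, the covariance between
ancestry-informative alleles at two loci decays as exp(-g * d) in their
genetic distance d (Morgans), because recombination breaks up ancestry
tracts at rate g per Morgan. The dating procedure therefore:

1. weights each SNP by the allele-frequency difference between the two
   source populations, w_i = a_i - b_i;
2. accumulates, over target individuals and same-chromosome SNP pairs,
   the weighted genotype-residual covariance w_i w_j (x_i - pbar_i)
   (x_j - pbar_j) into genetic-distance bins (pbar = pooled-source
   expected frequency);
3. fits A0 * exp(-n d) + c to the binned curve, giving the age n in
   generations with a delete-one-chromosome jackknife SE;
4. converts generations to calendar years (default 28.6 years per
   generation, with 25.6 and 31.5 as sensitivity bounds) anchored at the
   mean sample age.

Using drifted proxies instead of the true sources perturbs the weights
but not the decay rate, so moderate source misspecification does not
bias the date.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .genotype import MISSING, PSEUDOHAPLOID, GenotypeDataset, allele_counts
from .jackknife import weighted_jackknife

YEARS_PER_GENERATION = 28.6
YEARS_PER_GENERATION_BOUNDS = (25.6, 31.5)


class NoUsablePairsError(ValueError):
    """No same-chromosome SNP pair fell inside the distance window."""


class DecayFitError(RuntimeError):
    """The exponential fit failed to converge or hit a parameter bound."""


@dataclass
class DecayCurve:
    """Binned weighted ancestry covariance vs genetic distance.

    Per-chromosome bin sums and pair counts are retained so that
    delete-one-chromosome jackknife refits need no recomputation.
    """

    bin_edges: np.ndarray        # (n_bins,) left edges, Morgans
    bin_width: float
    chroms: list[str]
    chrom_sums: np.ndarray       # (n_chrom, n_bins)
    chrom_counts: np.ndarray     # (n_chrom, n_bins)

    @property
    def values(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.pair_counts > 0,
                            self.chrom_sums.sum(0) / self.pair_counts, np.nan)

    @property
    def pair_counts(self) -> np.ndarray:
        return self.chrom_counts.sum(0)

    @property
    def centers(self) -> np.ndarray:
        return self.bin_edges + self.bin_width / 2.0

    def drop_chrom(self, index: int) -> tuple[np.ndarray, np.ndarray]:
        """(values, pair counts) with one chromosome deleted."""
        sums = self.chrom_sums.sum(0) - self.chrom_sums[index]
        counts = self.chrom_counts.sum(0) - self.chrom_counts[index]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(counts > 0, sums / counts, np.nan), counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance_morgans": self.centers,
                             "covariance": self.values,
                             "pair_count": self.pair_counts})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class DateFit:
    """An exponential decay fit A0 * exp(-n d) + c."""

    amplitude: float
    generations: float
    offset: float
    se_generations: float
    loo_generations: np.ndarray
    fit_range: tuple[float, float]

    def to_record(self) -> dict:
        return {"amplitude": self.amplitude, "generations": self.generations,
                "offset": self.offset, "se_generations": self.se_generations,
                "fit_range_morgans": list(self.fit_range)}


def ancestry_covariance_curve(dataset: GenotypeDataset, target_group: str,
                              sourceA: str, sourceB: str,
                              bin_width: float = 0.001,
                              max_dist: float = 1.0,
                              chunk: int = 2048) -> DecayCurve:
    """Weighted ancestry-covariance decay curve for `target_group`.

    SNP weights are the source frequency difference a - b (symmetric under
    source swap, since weights enter as a product); genotype residuals are
    taken around the pooled-source expectation pbar = (a+b)/2, with
    pseudohaploid targets contributing single-allele residuals. Pairs are
    binned by genetic distance up to `max_dist` Morgans within each
    chromosome; values are normalized by the per-bin count of non-missing
    individual-level pairs.
    """
    freqs = allele_counts(dataset, [sourceA, sourceB])
    a, b = freqs.freq_of(sourceA), freqs.freq_of(sourceB)
    w = a - b
    pbar = (a + b) / 2.0
    usable_snp = np.isfinite(w)

    cols = dataset.individuals_of(target_group)
    ploidy = dataset.ind["ploidy"].to_numpy()[cols]
    G = dataset.geno[:, cols].astype(float)
    G[G == MISSING] = np.nan
    x = G / 2.0  # dosage fraction in [0, 1]; pseudohaploid gives {0, 1}
    Z = (x - pbar[:, None])
    Z[~usable_snp] = np.nan
    M = np.isfinite(Z)
    Zw = np.where(M, Z, 0.0) * w[:, None]

    chrom = dataset.snp["chromosome"].to_numpy()
    gpos = dataset.snp["genetic_pos"].to_numpy(dtype=float)
    chroms = list(dict.fromkeys(chrom))
    n_bins = int(np.ceil(max_dist / bin_width))
    edges = np.arange(n_bins) * bin_width
    chrom_sums = np.zeros((len(chroms), n_bins))
    chrom_counts = np.zeros((len(chroms), n_bins))

    total_pairs = 0
    for ci, c in enumerate(chroms):
        idx = np.flatnonzero(chrom == c)
        if idx.size < 2:
            continue
        Zc = Zw[idx]          # (S_c, n_ind)
        Mc = M[idx].astype(np.float64)
        g = gpos[idx]
        for lo in range(0, idx.size, chunk):
            hi = min(lo + chunk, idx.size)
            # pairs (i in [lo,hi), j > i)
            S_prod = Zc[lo:hi] @ Zc.T            # sums over individuals
            C_pair = Mc[lo:hi] @ Mc.T
            D = np.abs(g[lo:hi, None] - g[None, :])
            cols_j = np.arange(idx.size)[None, :]
            rows_i = np.arange(lo, hi)[:, None]
            sel = (cols_j > rows_i) & (D <= max_dist) & (D > 0)
            if not sel.any():
                continue
            bins = np.minimum((D[sel] / bin_width).astype(np.int64), n_bins - 1)
            chrom_sums[ci] += np.bincount(bins, weights=S_prod[sel],
                                          minlength=n_bins)
            chrom_counts[ci] += np.bincount(bins, weights=C_pair[sel],
                                            minlength=n_bins)
            total_pairs += int(sel.sum())
    if total_pairs == 0:
        raise NoUsablePairsError("no SNP pair within max_dist on any chromosome")
    return DecayCurve(edges, bin_width, chroms, chrom_sums, chrom_counts)


def _fit_exponential(d: np.ndarray, y: np.ndarray,
                     counts: np.ndarray | None = None) -> tuple[float, float, float]:
    """Least-squares A0 exp(-n d) + c with a log-linear warm start."""
    pos = y > 0
    if pos.sum() >= 3:
        slope, intercept = np.polyfit(d[pos], np.log(y[pos]), 1)
        p0 = (float(np.exp(intercept)), float(max(-slope, 1.0)), 0.0)
    else:
        p0 = (max(float(y[0]), 1e-6), 10.0, 0.0)
    sigma = None
    if counts is not None and np.all(counts > 0):
        sigma = 1.0 / np.sqrt(counts)
    popt, _ = curve_fit(
        lambda x, A, n, c: A * np.exp(-n * x) + c, d, y, p0=p0,
        bounds=([0.0, 1e-9, -np.inf], [np.inf, 1e5, np.inf]),
        sigma=sigma, maxfev=20000)
    return float(popt[0]), float(popt[1]), float(popt[2])


def fit_decay(curve: DecayCurve,
              fit_range: tuple[float, float] = (0.0045, 1.0)) -> DateFit:
    """Fit A0 exp(-n d) + c to the curve over `fit_range` (Morgans).

    Default range 0.45-100 cM excludes the shortest-range bins, where
    background LD unrelated to admixture dominates. The SE of n comes
    from delete-one-chromosome jackknife refits weighted by per-
    chromosome pair counts.
    """
    d = curve.centers
    in_range = (d >= fit_range[0]) & (d <= fit_range[1]) & (curve.pair_counts > 0)
    if in_range.sum() < 5:
        raise DecayFitError(f"only {int(in_range.sum())} usable bins in fit range")
    y = curve.values
    try:
        A0, n, c = _fit_exponential(d[in_range], y[in_range],
                                    curve.pair_counts[in_range])
    except RuntimeError as exc:
        raise DecayFitError(f"decay fit did not converge: {exc}") from None
    if n <= 1e-6 or n >= 1e5 - 1:
        raise DecayFitError(f"decay rate at a bound: n = {n:.3g}")

    # delete-one-chromosome jackknife on n
    loo, weights = [], []
    for ci in range(len(curve.chroms)):
        vals, counts = curve.drop_chrom(ci)
        ok = in_range & (counts > 0)
        if ok.sum() < 5:
            continue
        try:
            _, n_i, _ = _fit_exponential(d[ok], vals[ok], counts[ok])
        except RuntimeError:
            continue
        loo.append(n_i)
        weights.append(curve.chrom_counts[ci].sum())
    if len(loo) >= 2:
        _, se = weighted_jackknife(n, np.asarray(loo), np.asarray(weights))
    else:
        se = np.nan
    return DateFit(A0, n, c, se, np.asarray(loo), fit_range)


@dataclass
class CalendarDate:
    """An admixture date in years BP with propagated uncertainty."""

    date_bp: float
    se_years: float
    years_per_generation: float
    sensitivity_bp: tuple[float, float]  # dates at the bounding conversions

    def interval(self, z: float = 1.96) -> tuple[float, float]:
        return (self.date_bp - z * self.se_years,
                self.date_bp + z * self.se_years)


def generations_to_date(n: float, se_n: float, mean_sample_age_bp: float,
                        years_per_gen: float = YEARS_PER_GENERATION,
                        bounds: tuple[float, float] = YEARS_PER_GENERATION_BOUNDS
                        ) -> CalendarDate:
    """Convert an admixture age in generations to calendar years BP.

    date = mean sample age + n * years_per_gen; the SE of n propagates
    linearly. The sensitivity dates use the bounding female/male
    generation intervals and bracket the central date for any n > 0.
    """
    if n < 0:
        raise ValueError("generations since admixture must be >= 0")
    date = mean_sample_age_bp + n * years_per_gen
    sens = (mean_sample_age_bp + n * bounds[0],
            mean_sample_age_bp + n * bounds[1])
    return CalendarDate(float(date), float(se_n * years_per_gen),
                        years_per_gen, sens)
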