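"""Data model and I/O for ancient-DNA genotype matrices.

The central container is :class:`GenotypeDataset`: a SNP-by-individual matrix
of alt-allele dosages in diploid coding ({0, 1, 2}, missing stored as -1),
SNP metadata (chromosome, genetic position in Morgans, physical position),
and individual metadata (id, population label, ploidy mode).

Pseudohaploid individuals -- the standard representation for low-coverage
ancient samples, holding one randomly drawn allele per covered site -- are
stored in the same diploid coding but restricted to {0, 2, missing}; their
calls are counted as a *single* haploid allele wherever allele counts enter
a statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

MISSING = -1  # internal missing code; EIGENSTRAT text files use '9'

DIPLOID = "diploid"
PSEUDOHAPLOID = "pseudohaploid"


class EigenstratError(Exception):
    """Base class for EIGENSTRAT I/O failures."""


class DimensionMismatchError(EigenstratError):
    """A .geno row length disagrees with the number of individuals, or the
    number of rows disagrees with the .snp file."""


class MalformedLineError(EigenstratError):
    """A .snp or .ind line does not have the expected number of columns."""


class UnknownGenotypeCodeError(EigenstratError):
    """A .geno character outside {0, 1, 2, 9}."""


class UnknownPopulationError(KeyError):
    """A population label absent from the dataset."""


class UnsortedPositionsError(ValueError):
    """Genetic positions decrease within a chromosome."""


class SNPRecord(NamedTuple):
    snp_id: str
    chromosome: str
    genetic_pos: float  # Morgans
    physical_pos: int   # 1-based base pairs
    ref_allele: str
    alt_allele: str


@dataclass
class GenotypeDataset:
    """Genotype matrix plus SNP and individual metadata.

    Parameters
    ----------
    snp : DataFrame with columns snp_id, chromosome, genetic_pos,
        physical_pos, ref, alt; one row per SNP, in file order.
    ind : DataFrame with columns id, sex, population, ploidy.
    geno : int8 array of shape (n_snps, n_individuals); alt-allele dosage in
        {0, 1, 2} with missing = -1.
    """

    snp: pd.DataFrame
    ind: pd.DataFrame
    geno: np.ndarray

    def __post_init__(self) -> None:
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.shape != (len(self.snp), len(self.ind)):
            raise DimensionMismatchError(
                f"geno shape {self.geno.shape} != (n_snps={len(self.snp)}, "
                f"n_ind={len(self.ind)})"
            )
        bad = ~np.isin(self.geno, (0, 1, 2, MISSING))
        if bad.any():
            raise UnknownGenotypeCodeError(
                f"{bad.sum()} genotype entries outside {{0,1,2,missing}}"
            )
        ph = (self.ind["ploidy"] == PSEUDOHAPLOID).to_numpy()
        if ph.any() and (self.geno[:, ph] == 1).any():
            raise ValueError("pseudohaploid individuals carry heterozygous calls")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_snps(self) -> int:
        return len(self.snp)

    @property
    def n_ind(self) -> int:
        return len(self.ind)

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.ind["population"]))

    def snp_records(self) -> list[SNPRecord]:
        return [
            SNPRecord(r.snp_id, str(r.chromosome), float(r.genetic_pos),
                      int(r.physical_pos), r.ref, r.alt)
            for r in self.snp.itertuples(index=False)
        ]

    def individuals_of(self, population: str) -> np.ndarray:
        """Column indices of the individuals in `population`."""
        idx = np.flatnonzero((self.ind["population"] == population).to_numpy())
        if idx.size == 0:
            raise UnknownPopulationError(population)
        return idx

    def snps_called(self) -> np.ndarray:
        """Number of non-missing calls per individual."""
        return (self.geno != MISSING).sum(axis=0)

    def subset_individuals(self, columns: Sequence[int]) -> "GenotypeDataset":
        cols = np.asarray(columns)
        return GenotypeDataset(self.snp.copy(),
                               self.ind.iloc[cols].reset_index(drop=True),
                               self.geno[:, cols])

    def relabel(self, mapping: Mapping[str, str]) -> "GenotypeDataset":
        """Return a copy with population labels renamed via `mapping`."""
        ind = self.ind.copy()
        ind["population"] = ind["population"].map(lambda p: mapping.get(p, p))
        return GenotypeDataset(self.snp, ind, self.geno)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (self.snp.reset_index(drop=True).equals(other.snp.reset_index(drop=True))
                and self.ind.reset_index(drop=True).equals(other.ind.reset_index(drop=True))
                and np.array_equal(self.geno, other.geno))


@dataclass
class FreqTable:
    """Per population x SNP sample allele counts and frequencies.

    ``alt`` holds alt-allele counts, ``called`` the number of called alleles
    (a diploid call contributes 2, a pseudohaploid call 1), ``n_ind`` the
    number of individuals with a call (used for inbreed-mode corrections),
    and ``freq`` the count ratio with NaN wherever ``called`` is 0.
    """

    pops: list[str]
    alt: np.ndarray      # (P, S) float
    called: np.ndarray   # (P, S) int
    n_ind: np.ndarray    # (P, S) int
    freq: np.ndarray     # (P, S) float, NaN = missing

    def __post_init__(self) -> None:
        self._index = {p: i for i, p in enumerate(self.pops)}

    def row(self, pop: str) -> int:
        try:
            return self._index[pop]
        except KeyError:
            raise UnknownPopulationError(pop) from None

    def freq_of(self, pop: str) -> np.ndarray:
        return self.freq[self.row(pop)]

    def called_of(self, pop: str) -> np.ndarray:
        return self.called[self.row(pop)]

    @property
    def n_snps(self) -> int:
        return self.alt.shape[1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.pops):
            rows.append(pd.DataFrame({
                "population": p,
                "snp_index": np.arange(self.n_snps),
                "alt_count": self.alt[i],
                "called_count": self.called[i],
                "freq": self.freq[i],
            }))
        return pd.concat(rows, ignore_index=True)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class BlockPartition:
    """Contiguous jackknife blocks of SNPs, never crossing a chromosome.

    ``block_of`` maps each SNP to its block index; blocks are numbered in
    SNP order, so ``starts`` (the first SNP of each block) is ready for
    ``np.add.reduceat`` accumulation.
    """

    block_of: np.ndarray      # (S,) int
    starts: np.ndarray        # (B,) int, first SNP index of each block
    weights: np.ndarray       # (B,) int, SNPs per block
    block_chrom: np.ndarray   # (B,) object, chromosome of each block

    @property
    def n_blocks(self) -> int:
        return len(self.starts)

    def __post_init__(self) -> None:
        if int(self.weights.sum()) != len(self.block_of):
            raise ValueError("block weights do not sum to the SNP count")


# ---------------------------------------------------------------------------
# EIGENSTRAT I/O
# ---------------------------------------------------------------------------

_GENO_DECODE = np.full(256, -2, dtype=np.int8)
_GENO_DECODE[ord("0")] = 0
_GENO_DECODE[ord("1")] = 1
_GENO_DECODE[ord("2")] = 2
_GENO_DECODE[ord("9")] = MISSING


def read_eigenstrat(geno_path: str | Path, snp_path: str | Path,
                    ind_path: str | Path,
                    ploidy: str | Sequence[str] = "infer") -> GenotypeDataset:
    """Read an EIGENSTRAT text triplet (.geno/.snp/.ind).

    `ploidy` is "infer" (individuals with calls but no heterozygous call are
    marked pseudohaploid), a single mode applied to everyone, or a sequence
    of per-individual modes. '9' in the .geno file maps to missing; the
    individual-to-population mapping is the third .ind column.
    """
    snp_rows = []
    with open(snp_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise MalformedLineError(
                    f"{snp_path}:{ln}: expected 6 columns, got {len(parts)}")
            snp_rows.append((parts[0], parts[1], float(parts[2]),
                             int(parts[3]), parts[4], parts[5]))
    snp = pd.DataFrame(snp_rows, columns=["snp_id", "chromosome", "genetic_pos",
                                          "physical_pos", "ref", "alt"])

    ind_rows = []
    with open(ind_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3:
                raise MalformedLineError(
                    f"{ind_path}:{ln}: expected 3 columns, got {len(parts)}")
            ind_rows.append(parts)
    ind = pd.DataFrame(ind_rows, columns=["id", "sex", "population"])
    n_ind = len(ind)

    rows = []
    with open(geno_path, "rb") as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.rstrip(b"\r\n")
            if not line:
                continue
            if len(line) != n_ind:
                raise DimensionMismatchError(
                    f"{geno_path}:{ln}: row length {len(line)} != "
                    f"{n_ind} individuals")
            decoded = _GENO_DECODE[np.frombuffer(line, dtype=np.uint8)]
            if (decoded == -2).any():
                bad = chr(line[int(np.flatnonzero(decoded == -2)[0])])
                raise UnknownGenotypeCodeError(
                    f"{geno_path}:{ln}: unknown genotype code {bad!r}")
            rows.append(decoded)
    if len(rows) != len(snp):
        raise DimensionMismatchError(
            f"{geno_path}: {len(rows)} genotype rows for {len(snp)} SNPs")
    geno = (np.vstack(rows) if rows
            else np.empty((0, n_ind), dtype=np.int8))

    if isinstance(ploidy, str) and ploidy == "infer":
        has_call = (geno != MISSING).any(axis=0)
        has_het = (geno == 1).any(axis=0)
        modes = np.where(has_call & ~has_het, PSEUDOHAPLOID, DIPLOID)
        ind["ploidy"] = modes
    elif isinstance(ploidy, str):
        ind["ploidy"] = ploidy
    else:
        if len(ploidy) != n_ind:
            raise DimensionMismatchError("ploidy list length != n individuals")
        ind["ploidy"] = list(ploidy)
    return GenotypeDataset(snp, ind, geno)


def write_eigenstrat(dataset: GenotypeDataset, geno_path: str | Path,
                     snp_path: str | Path, ind_path: str | Path) -> None:
    """Write `dataset` as EIGENSTRAT text; missing calls become '9'."""
    code = np.array([ord("0"), ord("1"), ord("2")] + [ord("9")], dtype=np.uint8)
    with open(geno_path, "wb") as fh:
        for row in dataset.geno:
            fh.write(code[row].tobytes() + b"\n")
    with open(snp_path, "w") as fh:
        for r in dataset.snp.itertuples(index=False):
            fh.write(f"{r.snp_id}\t{r.chromosome}\t{r.genetic_pos:.8f}"
                     f"\t{int(r.physical_pos)}\t{r.ref}\t{r.alt}\n")
    with open(ind_path, "w") as fh:
        for r in dataset.ind.itertuples(index=False):
            fh.write(f"{r.id}\t{r.sex}\t{r.population}\n")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def pseudohaploidize(dataset: GenotypeDataset, seed: int) -> GenotypeDataset:
    """Replace every heterozygous diploid call by a random homozygote.

    Each non-missing call of 1 becomes 0 or 2 with probability 1/2,
    emulating the single-read draw used to genotype low-coverage ancient
    samples; calls of 0, 2 and missing are unchanged. Deterministic given
    `seed`, and idempotent (a second pass finds no heterozygotes).
    """
    rng = np.random.default_rng(seed)
    geno = dataset.geno.copy()
    het = geno == 1
    geno[het] = rng.choice(np.array([0, 2], dtype=np.int8), size=int(het.sum()))
    ind = dataset.ind.copy()
    ind["ploidy"] = PSEUDOHAPLOID
    return GenotypeDataset(dataset.snp, ind, geno)


GroupSpec = Sequence[str] | Mapping[str, Sequence[str]]


def allele_counts(dataset: GenotypeDataset, populations: GroupSpec) -> FreqTable:
    """Sample allele counts and frequencies per population.

    `populations` is a list of population labels, or a mapping from group
    label to a list of individual ids (used e.g. to treat one individual as
    its own group when screening). A called diploid genotype contributes two
    alleles; a called pseudohaploid genotype contributes one haploid allele
    (dosage 0 or 2 maps to alt count 0 or 1).
    """
    if isinstance(populations, Mapping):
        id_col = dataset.ind["id"]
        groups = {}
        for label, ids in populations.items():
            idx = np.flatnonzero(id_col.isin(list(ids)).to_numpy())
            if idx.size != len(ids):
                missing = set(ids) - set(id_col)
                raise UnknownPopulationError(f"unknown individual ids {missing}")
            groups[label] = idx
    else:
        groups = {p: dataset.individuals_of(p) for p in populations}

    S = dataset.n_snps
    P = len(groups)
    alt = np.zeros((P, S))
    called = np.zeros((P, S), dtype=np.int64)
    n_ind = np.zeros((P, S), dtype=np.int64)
    ploidy = dataset.ind["ploidy"].to_numpy()
    G = dataset.geno
    for i, (label, idx) in enumerate(groups.items()):
        ph = idx[ploidy[idx] == PSEUDOHAPLOID]
        dip = idx[ploidy[idx] != PSEUDOHAPLOID]
        if dip.size:
            sub = G[:, dip]
            obs = sub != MISSING
            alt[i] += np.where(obs, sub, 0).sum(axis=1)
            called[i] += 2 * obs.sum(axis=1)
            n_ind[i] += obs.sum(axis=1)
        if ph.size:
            sub = G[:, ph]
            obs = sub != MISSING
            alt[i] += np.where(obs, sub, 0).sum(axis=1) / 2
            called[i] += obs.sum(axis=1)
            n_ind[i] += obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(called > 0, alt / np.maximum(called, 1), np.nan)
    return FreqTable(list(groups), alt, called, n_ind, freq)


def assign_blocks(dataset: GenotypeDataset,
                  block_size_morgans: float = 0.05) -> BlockPartition:
    """Greedy contiguous jackknife blocks of genetic span <= `block_size`.

    A new block starts whenever the span would exceed `block_size_morgans`
    or the chromosome changes; blocks therefore never cross a chromosome
    boundary. With block_size = inf this yields one block per chromosome
    (the fallback when genetic positions are uninformative).
    """
    if block_size_morgans <= 0:
        raise ValueError("block size must be positive")
    chrom = dataset.snp["chromosome"].to_numpy()
    gpos = dataset.snp["genetic_pos"].to_numpy(dtype=float)

    block_of = np.empty(dataset.n_snps, dtype=np.int64)
    starts, chroms = [], []
    b = -1
    block_start_pos = 0.0
    prev_chrom: object = None
    prev_pos = -np.inf
    for i in range(dataset.n_snps):
        new_chrom = chrom[i] != prev_chrom
        if not new_chrom and gpos[i] < prev_pos:
            raise UnsortedPositionsError(
                f"genetic positions decrease at SNP {i} on chromosome {chrom[i]}")
        if new_chrom or gpos[i] - block_start_pos > block_size_morgans:
            b += 1
            starts.append(i)
            chroms.append(chrom[i])
            block_start_pos = gpos[i]
        block_of[i] = b
        prev_chrom = chrom[i]
        prev_pos = gpos[i]
    starts_arr = np.asarray(starts, dtype=np.int64)
    weights = np.diff(np.append(starts_arr, dataset.n_snps))
    return BlockPartition(block_of, starts_arr,
                          weights, np.asarray(chroms, dtype=object))
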