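"""Shared fixtures: small simulated datasets and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from admixkit.genotype import (DIPLOID, MISSING, PSEUDOHAPLOID,
                               GenotypeDataset)
from admixkit.simulate import GraphSpec, LeafPlan, simulate_graph_dataset


def make_dataset(geno, populations, ploidy=None, chrom=None, gpos=None):
    """Small GenotypeDataset from explicit pieces (rows = SNPs)."""
    geno = np.asarray(geno, dtype=np.int8)
    S, N = geno.shape
    if ploidy is None:
        ploidy = [DIPLOID] * N
    if chrom is None:
        chrom = ["1"] * S
    if gpos is None:
        gpos = np.linspace(0.0, 0.01 * S, S, endpoint=False)
    snp = pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(S)],
        "chromosome": [str(c) for c in chrom],
        "genetic_pos": np.asarray(gpos, float),
        "physical_pos": np.arange(1, S + 1) * 1000,
        "ref": "A", "alt": "G",
    })
    ind = pd.DataFrame({
        "id": [f"ind{j}" for j in range(N)],
        "sex": "U",
        "population": list(populations),
        "ploidy": list(ploidy),
    })
    return GenotypeDataset(snp, ind, geno)


def random_dataset(rng, n_snps=200, pops=("A", "B", "C"), n_per_pop=4,
                   missing_rate=0.1, pseudohaploid_pops=()):
    """Random multi-population dataset with missingness for I/O tests."""
    populations, ploidy, cols = [], [], []
    for p in pops:
        ph = p in pseudohaploid_pops
        for _ in range(n_per_pop):
            g = rng.integers(0, 3, n_snps).astype(np.int8)
            if ph:
                g[g == 1] = rng.choice([0, 2], size=int((g == 1).sum()))
            g[rng.random(n_snps) < missing_rate] = MISSING
            cols.append(g)
            populations.append(p)
            ploidy.append(PSEUDOHAPLOID if ph else DIPLOID)
    chrom = np.repeat(["1", "2"], [n_snps - n_snps // 2, n_snps // 2])
    gpos = np.concatenate([np.sort(rng.uniform(0, 1, n_snps - n_snps // 2)),
                           np.sort(rng.uniform(0, 1, n_snps // 2))])
    return make_dataset(np.column_stack(cols), populations, ploidy, chrom, gpos)


# ---------------------------------------------------------------------------
# brute-force oracles (plain loops, independent of the fstats code paths)
# ---------------------------------------------------------------------------

def oracle_freqs(dataset, pop):
    """Per-SNP (freq, called alleles, called individuals) by direct loops."""
    cols = [j for j in range(dataset.n_ind)
            if dataset.ind["population"].iloc[j] == pop]
    S = dataset.n_snps
    freq = np.full(S, np.nan)
    called = np.zeros(S)
    n_ind = np.zeros(S)
    for i in range(S):
        alt = tot = nin = 0
        for j in cols:
            g = int(dataset.geno[i, j])
            if g == MISSING:
                continue
            nin += 1
            if dataset.ind["ploidy"].iloc[j] == PSEUDOHAPLOID:
                alt += g // 2
                tot += 1
            else:
                alt += g
                tot += 2
        called[i], n_ind[i] = tot, nin
        if tot:
            freq[i] = alt / tot
    return freq, called, n_ind


def oracle_f(dataset, kind, pops, inbreed=False):
    """Brute-force f2/f3/f4 (intersection over the named pops) as the plain
    mean over usable SNPs of the per-SNP frequency products."""
    tracks = [oracle_freqs(dataset, p) for p in pops]
    freqs = [t[0] for t in tracks]
    vals = []
    for i in range(dataset.n_snps):
        fs = [f[i] for f in freqs]
        if any(np.isnan(f) for f in fs):
            continue
        if any(t[1][i] < 2 for t in tracks):  # intersection-mode usability
            continue

        def corr(t_idx):
            p, n = freqs[t_idx][i], (tracks[t_idx][2][i] if inbreed
                                     else tracks[t_idx][1][i])
            return p * (1 - p) / (n - 1) if n >= 2 else np.nan

        if kind == "f4":
            vals.append((fs[0] - fs[1]) * (fs[2] - fs[3]))
        elif kind == "f2":
            c = corr(0) + corr(1)
            if np.isnan(c):
                continue
            vals.append((fs[0] - fs[1]) ** 2 - c)
        elif kind == "f3":
            c = corr(0)
            if np.isnan(c):
                continue
            vals.append((fs[0] - fs[1]) * (fs[0] - fs[2]) - c)
    return float(np.mean(vals))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def six_pop_dataset():
    """Random 6-population drift-tree dataset, 500 SNPs, mixed ploidy."""
    spec = GraphSpec()
    e = spec.edges
    e["P1"] = ("root", 0.05)
    e["n0"] = ("root", 0.02)
    e["P2"] = ("n0", 0.04)
    e["n1"] = ("n0", 0.02)
    e["P3"] = ("n1", 0.04)
    e["n2"] = ("n1", 0.02)
    e["P4"] = ("n2", 0.03)
    e["n3"] = ("n2", 0.02)
    e["P5"] = ("n3", 0.03)
    e["P6"] = ("n3", 0.03)
    for i, p in enumerate(["P1", "P2", "P3"]):
        spec.leaves[p] = LeafPlan(4, DIPLOID, 0.1)
    for p in ["P4", "P5", "P6"]:
        spec.leaves[p] = LeafPlan(4, PSEUDOHAPLOID, 0.1)
    spec.validate()
    return simulate_graph_dataset(spec, 500, seed=77, n_chrom=4)
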