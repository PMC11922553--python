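"""Synthetic genotype data with the covariance structure the analyses assume.

Two generators:

* :func:`simulate_graph_dataset` draws allele frequencies down an admixture
  graph (drift edges with Balding-Nichols-style Beta updates, admixture
  nodes mixing two parents), then samples pseudohaploid or diploid
  genotypes with missingness -- the substrate for f-statistic, qpWave/qpAdm
  and model-competition tests.

* :func:`simulate_mosaic_cohort` builds admixed individuals as ancestry
  mosaics with Poisson recombination breakpoints, giving the exponential
  admixture-LD decay that dating methods fit.

:func:`preset_three_cline` ships a fixed graph with four deep sources,
three clines of two-way mixtures, and seven outgroups for right sets,
mirroring the geometry of steppe-and-neighbours ancient-DNA surveys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .genotype import (DIPLOID, MISSING, PSEUDOHAPLOID, GenotypeDataset)

SCHEMA_VERSION = 1


@dataclass
class LeafPlan:
    """Sampling plan for one leaf population."""

    n: int
    ploidy: str = PSEUDOHAPLOID
    missing_rate: float = 0.0


@dataclass
class GraphSpec:
    """An admixture graph: drift edges, admixture nodes, leaf sampling plans.

    ``edges`` maps child -> (parent, tau) with tau >= 0 the drift amount
    (the variance of the frequency update is tau * p(1-p)); ``admixtures``
    maps child -> (parentA, parentB, alpha) meaning the child's frequency
    is alpha * p_A + (1 - alpha) * p_B. The graph must be acyclic with a
    single root.
    """

    edges: dict[str, tuple[str, float]] = field(default_factory=dict)
    admixtures: dict[str, tuple[str, str, float]] = field(default_factory=dict)
    leaves: dict[str, LeafPlan] = field(default_factory=dict)

    def parents_of(self, node: str) -> list[str]:
        if node in self.edges:
            return [self.edges[node][0]]
        if node in self.admixtures:
            return list(self.admixtures[node][:2])
        return []

    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for child, (parent, _) in self.edges.items():
            seen.setdefault(parent)
            seen.setdefault(child)
        for child, (pa, pb, _) in self.admixtures.items():
            seen.setdefault(pa)
            seen.setdefault(pb)
            seen.setdefault(child)
        for leaf in self.leaves:
            seen.setdefault(leaf)
        return list(seen)

    @property
    def root(self) -> str:
        children = set(self.edges) | set(self.admixtures)
        roots = [n for n in self.nodes if n not in children]
        if len(roots) != 1:
            raise ValueError(f"graph must have a single root, found {roots}")
        return roots[0]

    def validate(self) -> None:
        if set(self.edges) & set(self.admixtures):
            raise ValueError("a node cannot have both a drift and an admixture parent")
        for child, (_, tau) in self.edges.items():
            if not 0.0 <= tau < 1.0:
                raise ValueError(f"drift tau of {child!r} must be in [0, 1)")
        for child, (_, _, alpha) in self.admixtures.items():
            if not 0.0 <= alpha <= 1.0:
                raise ValueError(f"admixture proportion of {child!r} outside [0, 1]")
        order = self.topological_order()  # raises on cycles
        known = set(order)
        for leaf in self.leaves:
            if leaf not in known:
                raise ValueError(f"leaf {leaf!r} not connected to the graph")
        self.root  # single-root check

    def topological_order(self) -> list[str]:
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(node: str, stack: tuple[str, ...]) -> None:
            if node in stack:
                raise ValueError(f"cycle through {node!r}")
            if state.get(node) == 2:
                return
            for p in self.parents_of(node):
                visit(p, stack + (node,))
            state[node] = 2
            order.append(node)

        for n in self.nodes:
            visit(n, ())
        return order

    # -- structured-config round trip -------------------------------------
    def to_yaml(self) -> str:
        doc = {
            "schema_version": SCHEMA_VERSION,
            "edges": {c: [p, float(t)] for c, (p, t) in self.edges.items()},
            "admixtures": {c: [a, b, float(al)]
                           for c, (a, b, al) in self.admixtures.items()},
            "leaves": {l: {"n": pl.n, "ploidy": pl.ploidy,
                           "missing_rate": pl.missing_rate}
                       for l, pl in self.leaves.items()},
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "GraphSpec":
        doc = yaml.safe_load(text)
        if doc.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {doc.get('schema_version')}")
        spec = cls(
            edges={c: (p, float(t)) for c, (p, t) in doc.get("edges", {}).items()},
            admixtures={c: (a, b, float(al))
                        for c, (a, b, al) in doc.get("admixtures", {}).items()},
            leaves={l: LeafPlan(int(v["n"]), v.get("ploidy", PSEUDOHAPLOID),
                                float(v.get("missing_rate", 0.0)))
                    for l, v in doc.get("leaves", {}).items()},
        )
        spec.validate()
        return spec


def _snp_table(n_snps: int, rng: np.random.Generator,
               n_chrom: int = 22, chrom_length: float = 1.0) -> pd.DataFrame:
    """Synthetic SNP metadata: `n_chrom` chromosomes, sorted uniform
    genetic positions on [0, chrom_length] Morgans."""
    counts = np.full(n_chrom, n_snps // n_chrom)
    counts[: n_snps % n_chrom] += 1
    rows = []
    for c in range(n_chrom):
        gpos = np.sort(rng.uniform(0.0, chrom_length, counts[c]))
        ppos = np.maximum(1, (gpos * 1e8).astype(np.int64))
        ppos = np.maximum.accumulate(ppos + np.arange(counts[c]))  # strictly increasing
        rows.append(pd.DataFrame({
            "snp_id": [f"rs{c + 1}_{i}" for i in range(counts[c])],
            "chromosome": str(c + 1),
            "genetic_pos": gpos,
            "physical_pos": ppos,
            "ref": "A", "alt": "G",
        }))
    return pd.concat(rows, ignore_index=True)


def drift_frequencies(p: np.ndarray, tau: float,
                      rng: np.random.Generator) -> np.ndarray:
    """One Balding-Nichols-style drift step.

    Draws Beta with mean p and variance tau * p(1-p), i.e. concentration
    1/tau - 1; frequencies already fixed (0 or 1) stay fixed. tau = 0 is
    the identity. The update is a martingale: E[p'] = p.
    """
    if tau <= 0:
        return p.copy()
    conc = 1.0 / tau - 1.0
    out = p.copy()
    seg = (p > 0) & (p < 1)
    a = np.maximum(p[seg] * conc, 1e-9)
    b = np.maximum((1.0 - p[seg]) * conc, 1e-9)
    out[seg] = rng.beta(a, b)
    return np.clip(out, 0.0, 1.0)


def _sample_leaf(p: np.ndarray, plan: LeafPlan,
                 rng: np.random.Generator) -> np.ndarray:
    """Genotypes (S, n) for one leaf: Binomial(2, p), then optional
    pseudohaploidization and missingness."""
    S = p.size
    g = rng.binomial(2, p[:, None], size=(S, plan.n)).astype(np.int8)
    if plan.ploidy == PSEUDOHAPLOID:
        het = g == 1
        g[het] = rng.choice(np.array([0, 2], dtype=np.int8), size=int(het.sum()))
    if plan.missing_rate > 0:
        g[rng.random((S, plan.n)) < plan.missing_rate] = MISSING
    return g


def node_frequencies(spec: GraphSpec, n_snps: int,
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Allele frequencies at every graph node; root ~ Uniform(0.05, 0.95)."""
    freqs: dict[str, np.ndarray] = {}
    for node in spec.topological_order():
        if node == spec.root:
            freqs[node] = rng.uniform(0.05, 0.95, n_snps)
        elif node in spec.edges:
            parent, tau = spec.edges[node]
            freqs[node] = drift_frequencies(freqs[parent], tau, rng)
        else:
            pa, pb, alpha = spec.admixtures[node]
            freqs[node] = alpha * freqs[pa] + (1.0 - alpha) * freqs[pb]
    return freqs


def simulate_graph_dataset(spec: GraphSpec, n_snps: int, seed: int,
                           n_chrom: int = 22,
                           chrom_length: float = 1.0) -> GenotypeDataset:
    """Simulate a genotype dataset under an admixture graph.

    Deterministic given `seed`; SNPs are laid out on `n_chrom` synthetic
    chromosomes with uniform genetic positions.
    """
    spec.validate()
    if not spec.leaves:
        raise ValueError("GraphSpec has no leaf sampling plans")
    rng = np.random.default_rng(seed)
    snp = _snp_table(n_snps, rng, n_chrom, chrom_length)
    freqs = node_frequencies(spec, n_snps, rng)

    geno_cols, ind_rows = [], []
    for leaf, plan in spec.leaves.items():
        geno_cols.append(_sample_leaf(freqs[leaf], plan, rng))
        ind_rows += [(f"{leaf}_{i}", "U", leaf, plan.ploidy)
                     for i in range(plan.n)]
    ind = pd.DataFrame(ind_rows, columns=["id", "sex", "population", "ploidy"])
    return GenotypeDataset(snp, ind, np.hstack(geno_cols))


# ---------------------------------------------------------------------------
# Mosaic cohorts for admixture-LD dating
# ---------------------------------------------------------------------------

@dataclass
class MosaicSpec:
    """Design of an admixed cohort of ancestry mosaics.

    `g` generations since a single admixture pulse (breakpoints are a
    Poisson process of rate g per Morgan along each haplotype), mixing
    proportion `alpha` of ancestry A, chromosomes of the given genetic
    lengths (Morgans) carrying `snps_per_chrom` markers each.
    """

    g: int
    alpha: float
    chrom_lengths: Sequence[float]
    snps_per_chrom: int
    cohort_size: int
    ploidy: str = DIPLOID
    source_fst: float = 0.1
    source_sample_size: int = 30

    def validate(self) -> None:
        if self.g < 1 or int(self.g) != self.g:
            raise ValueError("g must be an integer >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha outside [0, 1]")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")


def balding_nichols_pair(n_snps: int, fst: float, seed: int,
                         rng: np.random.Generator | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Two frequency tracks diverged from a common ancestor at the given
    differentiation level (each drifts by tau = fst from Uniform(0.1, 0.9)
    ancestral frequencies)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    anc = rng.uniform(0.1, 0.9, n_snps)
    return (drift_frequencies(anc, fst, rng),
            drift_frequencies(anc, fst, rng))


def _mosaic_haplotype(gpos_by_chrom: list[np.ndarray], lengths: Sequence[float],
                      g: int, alpha: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Ancestry indicator (1 = ancestry A) per SNP for one haplotype."""
    parts = []
    for gpos, L in zip(gpos_by_chrom, lengths):
        n_break = rng.poisson(g * L)
        breaks = np.sort(rng.uniform(0.0, L, n_break))
        seg_anc = rng.random(n_break + 1) < alpha
        idx = np.searchsorted(breaks, gpos, side="right")
        parts.append(seg_anc[idx])
    return np.concatenate(parts)


def simulate_mosaic_cohort(spec: MosaicSpec, sourceA_freqs: np.ndarray,
                           sourceB_freqs: np.ndarray, seed: int
                           ) -> tuple[GenotypeDataset, dict]:
    """Simulate an admixed cohort of ancestry mosaics plus source samples.

    Each haplotype is a mosaic of A/B ancestry tracts (Poisson breakpoints
    at rate g per Morgan, tract ancestries i.i.d. Bernoulli(alpha)); the
    allele at each SNP is drawn from the tract's source frequency. Diploid
    individuals combine two independent haplotypes. Source populations are
    sampled as diploid reference panels so dating can read their
    frequencies off the same dataset. Returns the dataset and a truth
    record (g, alpha, realized ancestry fraction).
    """
    spec.validate()
    sourceA_freqs = np.asarray(sourceA_freqs, float)
    sourceB_freqs = np.asarray(sourceB_freqs, float)
    if sourceA_freqs.shape != sourceB_freqs.shape:
        raise ValueError("source frequency tracks differ in length")
    n_chrom = len(spec.chrom_lengths)
    if sourceA_freqs.size != n_chrom * spec.snps_per_chrom:
        raise ValueError("frequency track length != n_chrom * snps_per_chrom")

    rng = np.random.default_rng(seed)
    rows = []
    gpos_by_chrom = []
    for c, L in enumerate(spec.chrom_lengths):
        gpos = np.sort(rng.uniform(0.0, L, spec.snps_per_chrom))
        gpos_by_chrom.append(gpos)
        ppos = np.maximum.accumulate(
            np.maximum(1, (gpos * 1e8).astype(np.int64)) + np.arange(gpos.size))
        rows.append(pd.DataFrame({
            "snp_id": [f"rs{c + 1}_{i}" for i in range(gpos.size)],
            "chromosome": str(c + 1),
            "genetic_pos": gpos, "physical_pos": ppos,
            "ref": "A", "alt": "G",
        }))
    snp = pd.DataFrame(pd.concat(rows, ignore_index=True))

    pA, pB = sourceA_freqs, sourceB_freqs
    geno_cols, ind_rows = [], []
    anc_total, anc_n = 0.0, 0
    n_hap = 1 if spec.ploidy == PSEUDOHAPLOID else 2
    for i in range(spec.cohort_size):
        dosage = np.zeros(pA.size, dtype=np.int8)
        for _ in range(n_hap):
            anc = _mosaic_haplotype(gpos_by_chrom, spec.chrom_lengths,
                                    spec.g, spec.alpha, rng)
            p = np.where(anc, pA, pB)
            dosage += rng.random(p.size) < p
            anc_total += anc.mean()
            anc_n += 1
        if spec.ploidy == PSEUDOHAPLOID:
            dosage *= 2
        geno_cols.append(dosage[:, None])
        ind_rows.append((f"admixed_{i}", "U", "Admixed", spec.ploidy))

    for label, p in (("SourceA", pA), ("SourceB", pB)):
        g = rng.binomial(2, p[:, None],
                         size=(p.size, spec.source_sample_size)).astype(np.int8)
        geno_cols.append(g)
        ind_rows += [(f"{label}_{i}", "U", label, DIPLOID)
                     for i in range(spec.source_sample_size)]

    ind = pd.DataFrame(ind_rows, columns=["id", "sex", "population", "ploidy"])
    dataset = GenotypeDataset(snp, ind, np.hstack(geno_cols))
    truth = {"g": spec.g, "alpha": spec.alpha,
             "realized_ancestry_fraction": anc_total / anc_n}
    return dataset, truth


def two_source_recovery_graph(alpha: float = 0.30, n_per_leaf: int = 10,
                              n_rights: int = 5,
                              missing_rate: float = 0.05) -> GraphSpec:
    """A minimal two-source admixture scenario for parameter recovery.

    The target mixes alpha * Source1 + (1 - alpha) * Source2 with
    post-admixture drift; `n_rights` outgroup leaves sit on distinct
    branches (one deep, one sister to each source, the rest basal) so the
    right set is differentially related to the sources.
    """
    spec = GraphSpec()
    e = spec.edges
    e["R_deep"] = ("root", 0.10)
    e["n0"] = ("root", 0.02)
    e["R_basal1"] = ("n0", 0.06)
    e["n1"] = ("n0", 0.02)
    e["R_basal2"] = ("n1", 0.06)
    e["nA"] = ("n1", 0.03)
    e["nB"] = ("n1", 0.03)
    e["Source1"] = ("nA", 0.03)
    e["R_sis1"] = ("nA", 0.04)
    e["Source2"] = ("nB", 0.03)
    e["R_sis2"] = ("nB", 0.04)
    spec.admixtures["Target_adm"] = ("Source1", "Source2", alpha)
    e["Target"] = ("Target_adm", 0.005)

    rights = ["R_deep", "R_sis1", "R_sis2", "R_basal1", "R_basal2"][:n_rights]
    for r in rights:
        spec.leaves[r] = LeafPlan(n_per_leaf, DIPLOID, 0.0)
    for s in ("Source1", "Source2"):
        spec.leaves[s] = LeafPlan(n_per_leaf, PSEUDOHAPLOID, missing_rate)
    spec.leaves["Target"] = LeafPlan(n_per_leaf, PSEUDOHAPLOID, missing_rate)
    spec.validate()
    return spec


RECOVERY_RIGHTS = ("R_deep", "R_sis1", "R_sis2", "R_basal1", "R_basal2")


# ---------------------------------------------------------------------------
# Three-cline preset
# ---------------------------------------------------------------------------

CLINE_PROPORTIONS = (0.2, 0.4, 0.6, 0.8)

#: Poles of the three clines: (cline name, pole A, pole B); each member
#: mixes alpha * poleA + (1 - alpha) * poleB.
CLINE_POLES = (
    ("Volga", "NorthHG_A", "CaucasusHG"),
    ("Dnipro", "NorthHG_B", "CaucasusHG"),
    ("CLV", "CaucasusHG", "SouthFarmer"),
)

OUTGROUPS = ("Out_Deep", "Out_Sib", "Out_West", "Out_NA", "Out_NB",
             "Out_CA", "Out_SA")


def three_cline_graph(n_per_leaf: int = 5, missing_rate: float = 0.05) -> GraphSpec:
    """The fixed graph behind :func:`preset_three_cline`.

    Four deep source populations -- two northern hunter-gatherer poles
    (NorthHG_A, NorthHG_B), a Caucasus hunter-gatherer pole (CaucasusHG)
    and a southern farmer pole (SouthFarmer) -- plus seven outgroup leaves
    placed so each source shares drift with a distinct subset of them
    (giving right sets resolving power), and three clines of two-way
    mixtures between adjacent poles with a touch of post-admixture drift.
    """
    spec = GraphSpec()
    e = spec.edges
    e["Out_Deep"] = ("root", 0.12)
    e["n0"] = ("root", 0.02)
    e["Out_Sib"] = ("n0", 0.08)
    e["nW"] = ("n0", 0.03)
    e["Out_West"] = ("nW", 0.06)
    e["nNorth"] = ("nW", 0.03)
    e["nSouth"] = ("nW", 0.03)
    # northern poles with sister outgroups
    e["nNA"] = ("nNorth", 0.01)
    e["NorthHG_A"] = ("nNA", 0.03)
    e["Out_NA"] = ("nNA", 0.04)
    e["nNB"] = ("nNorth", 0.01)
    e["NorthHG_B"] = ("nNB", 0.03)
    e["Out_NB"] = ("nNB", 0.04)
    # southern poles with sister outgroups
    e["nCA"] = ("nSouth", 0.01)
    e["CaucasusHG"] = ("nCA", 0.04)
    e["Out_CA"] = ("nCA", 0.04)
    e["nSA"] = ("nSouth", 0.01)
    e["SouthFarmer"] = ("nSA", 0.04)
    e["Out_SA"] = ("nSA", 0.04)

    for cline, pa, pb in CLINE_POLES:
        for alpha in CLINE_PROPORTIONS:
            name = f"{cline}_{int(round(alpha * 100))}"
            spec.admixtures[f"{name}_adm"] = (pa, pb, alpha)
            spec.edges[name] = (f"{name}_adm", 0.005)

    for out in OUTGROUPS:
        spec.leaves[out] = LeafPlan(n_per_leaf, DIPLOID, 0.0)
    for src in ("NorthHG_A", "NorthHG_B", "CaucasusHG", "SouthFarmer"):
        spec.leaves[src] = LeafPlan(n_per_leaf + 1, PSEUDOHAPLOID, missing_rate)
    for cline, pa, pb in CLINE_POLES:
        for alpha in CLINE_PROPORTIONS:
            name = f"{cline}_{int(round(alpha * 100))}"
            spec.leaves[name] = LeafPlan(n_per_leaf, PSEUDOHAPLOID, missing_rate)
    spec.validate()
    return spec


def preset_three_cline(seed: int, n_snps: int = 40_000,
                       n_per_leaf: int = 5,
                       missing_rate: float = 0.05
                       ) -> tuple[GenotypeDataset, dict]:
    """Simulate the three-cline scenario; returns (dataset, truth record).

    The truth record maps each cline member to its generating mixture
    (pole A, pole B, alpha) and lists the outgroup leaves available for
    right sets.
    """
    spec = three_cline_graph(n_per_leaf, missing_rate)
    dataset = simulate_graph_dataset(spec, n_snps, seed)
    truth = {"outgroups": list(OUTGROUPS), "members": {}}
    for cline, pa, pb in CLINE_POLES:
        for alpha in CLINE_PROPORTIONS:
            name = f"{cline}_{int(round(alpha * 100))}"
            truth["members"][name] = {"cline": cline, "sourceA": pa,
                                      "sourceB": pb, "alpha": alpha}
    return dataset, truth
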