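# admixkit

Admixture modeling for pseudohaploid ancient-DNA genotypes: f-statistics
with weighted block-jackknife errors, qpWave rank tests, qpAdm mixture
estimation, a model-competition framework with rotating right sets,
reference-based PCA projection, admixture-LD decay dating, and an
admixture-graph simulator for generating test data with realistic
covariance structure.

## Who this is for

Population geneticists analyzing ancient-DNA genotype panels (EIGENSTRAT
`.geno/.snp/.ind` triplets) who want a self-contained, tested Python
implementation of the standard allele-frequency toolkit for admixture
inference — and a synthetic-data generator to validate whole pipelines
when the real data are access-restricted.

## The statistics at the core

For populations with sample allele frequencies `a, b, c, d` at each SNP:

- **f4(A,B;C,D)** = E[(a−b)(c−d)] measures correlated allele-frequency
  drift; **f2(A,B)** = E[(a−b)²] − h_A/n_A − h_B/n_B and
  **f3(T;A,B)** = E[(t−a)(t−b)] − h_T/n_T are its unbiased relatives,
  where h = p(1−p)·n/(n−1) is the per-SNP heterozygosity and n the number
  of called allele draws (a pseudohaploid call counts as one draw).
  Standard errors come from a weighted block jackknife over contiguous
  genetic-map blocks (default 0.05 Morgans).
- **qpWave** tests the rank of the matrix A_ij = f4(left_i, left_0;
  right_j, right_0): rank t is fitted by alternating generalized least
  squares under the block-jackknife covariance Q, and the Mahalanobis
  residual is referred to χ² with (n_l−1−t)(n_r−1−t) degrees of freedom.
- **qpAdm** models a target T as Σ w_i S_i with Σ w_i = 1, solving a
  sum-constrained GLS on the f4 vectors u_l[j] = f4(l, R_0; R_j, R_0);
  the tail p is the rank-(k−1) qpWave test on lefts {T, S_1..S_k}.
  A model is *feasible* when p > 0.05, every SE ≤ 0.1, and every weight
  is within 2 SE of [0, 1].
- **Model competition**: candidates are filtered against distant
  outgroups, then compared all-against-all by moving each model's
  distinctive sources onto the rival's right set; models that stay
  feasible in every augmented run form the *promising* set.
- **Hudson F_ST** is the ratio of genome-wide averages of
  (a−b)² − h_A/n_A − h_B/n_B over a(1−b) + b(1−a).
- **Admixture-LD dating** fits A₀·e^(−n·d) + c to the decay of weighted
  ancestry covariance with genetic distance d, giving the admixture age n
  in generations (28.6 years per generation by default, bounds 25.6/31.5).

## Worked example

Simulate the bundled three-cline scenario (four deep source populations,
three clines of two-way mixtures at proportions 0.2–0.8, seven outgroups),
then fit a qpAdm model for a cline member whose true mixture is
0.4 NorthHG_A + 0.6 CaucasusHG:

```sh
$ admixkit simulate --n-snps 40000 --seed 11 --out demo
wrote demo/sim.seed11.geno/.snp/.ind (40000 SNPs, 119 individuals)

$ admixkit qpadm --geno demo/sim.seed11.geno --snp demo/sim.seed11.snp \
    --ind demo/sim.seed11.ind --target Volga_40 \
    --sources NorthHG_A,CaucasusHG \
    --right Out_Deep,Out_Sib,Out_West,Out_NA,Out_NB,Out_CA,Out_SA --out demo
Volga_40: NorthHG_A=0.397+-0.017, CaucasusHG=0.603+-0.017; p = 0.9849

$ admixkit fst --geno demo/sim.seed11.geno --snp demo/sim.seed11.snp \
    --ind demo/sim.seed11.ind --pops NorthHG_A,CaucasusHG --out demo
F_ST(NorthHG_A,CaucasusHG) = 0.07463 +- 0.00180
```

The fitted weight 0.397 ± 0.017 covers the generating proportion 0.4, and
the high tail probability (p = 0.98) says the two-source model cannot be
rejected against the seven outgroups. Each command also writes TSV/JSON
records and a run log (package version, seed, resolved configuration)
into `demo/`. The same functionality is available as a library
(`admixkit.qpadm_fit`, `admixkit.promising_set`, ...); see the module
docstrings.

Other subcommands: `fstats` (f2/f3/f4), `compete` (model competition over
candidate source sets), `screen` (cladality screening of individuals,
default p > 0.2 and ≥ 300k SNPs), `pca` (reference PCA with least-squares
projection), `date` (admixture-LD dating).

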