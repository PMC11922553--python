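# Methods

This note documents the statistical models implemented in admixkit, the
estimators and their numerical details, the synthetic-data generators the
tests rely on, and the design choices made where more than one reasonable
convention exists.

## Genotype model

Genotypes are alt-allele dosages in diploid coding ({0, 1, 2}, missing
`9` in EIGENSTRAT text, −1 internally). Pseudohaploid individuals — the
standard representation of low-coverage ancient samples, where one
sequencing read is drawn at random per site — are stored as {0, 2,
missing} and contribute **one** allele draw per call to every count. This
haploid counting is what makes the finite-sample corrections below
well-defined for ancient samples; `inbreed=True` applies the same
one-draw-per-individual rule to diploid genotypes from inbred
populations. Physical positions are 1-based; genetic positions are in
Morgans and must be non-decreasing within a chromosome.

Jackknife blocks are greedy contiguous runs of SNPs with genetic span
≤ 0.05 Morgans (configurable), never crossing a chromosome boundary;
with an infinite block size this degrades to one block per chromosome,
the fallback when map positions are uninformative. 0.05 M is the
conventional scale at which linkage between blocks is negligible for
genome-wide panels.

## f-statistics

With sample frequencies a, b, c, d and h = p(1−p)·n/(n−1):

- f4(A,B;C,D) = mean over usable SNPs of (a−b)(c−d); unbiased without
  correction when the four sample sets are distinct.
- f2(A,B) = mean of (a−b)² − h_A/n_A − h_B/n_B.
- f3(T;A,B) = mean of (t−a)(t−b) − h_T/n_T. With `inbreed=True` the
  target correction is skipped (the convention when the target's
  genotypes are haploid draws and within-individual heterozygosity is
  unobservable); the estimate is then conservative (biased upward) and
  only its sign is interpreted.
- Hudson F_ST = Σ[(a−b)² − h_A/n_A − h_B/n_B] / Σ[a(1−b) + b(1−a)],
  a ratio of genome-wide averages, jackknifed as a whole.

Degenerate same-sample cases (f2(A,A), f3(A;A,B), F_ST(A,A)) return
exactly 0: the raw product is identically zero and the independent-draw
assumption behind the corrections does not hold for a population compared
with itself.

**Missingness modes.** `allsnps` evaluates each statistic on every SNP
where the populations entering *that* statistic are called — maximal data
per statistic, mirroring the ADMIXTOOLS option of the same name.
`intersection` restricts all statistics to SNPs where **every**
population of the supplied frequency table is called with ≥ 2 allele
draws. The ≥ 2 requirement makes the finite-sample corrections defined
everywhere, so all statistic families share exactly one SNP set and the
algebraic identities (f4 as a half-sum of f2s, the f3 identity) hold to
rounding error rather than approximately.

**Uncertainty.** All scalar SEs use the weighted block jackknife of
Busing, Meijer & van der Leeden (1999), which handles blocks of unequal
SNP content. The f4-matrix covariance Q generalizes this through
pseudovalues; per-block weights are the mean usable-SNP count across
entries (exact in intersection mode, where all entries share one mask).
When cond(Q) > 1e10 — e.g. duplicated or near-duplicated populations — a
ridge of 1e-8·trace(Q)/dim is added and a warning emitted. A joint
GLS-smoothed f-basis (qpfstats-style) is not implemented; matrix entries
are computed directly, which has the same asymptotics.

## qpWave and qpAdm

qpWave fits the best rank-t approximation B = XY of the f4 matrix by
alternating GLS — each half-step is linear in the row-major
vectorization — iterated to a relative χ² tolerance of 1e-10 (maximum
200 iterations; the objective decreases monotonically). The statistic
(vec A − vec B)ᵀ Q⁻¹ (vec A − vec B) is referred to χ² with
(n_l−1−t)(n_r−1−t) degrees of freedom. The χ² reference is asymptotic;
in `allsnps` mode, where entries use overlapping but unequal SNP sets,
it is treated as asymptotic all the same.

qpAdm works on the matrix with lefts [T, S_1..S_k] (target as base),
whose rows are a_i = u_{S_i} − u_T with u_l[j] = f4(l, R_0; R_j, R_0).
Under Σw = 1 the mixture residual u_T − Σ w_i u_{S_i} equals −Σ w_i a_i,
so the weights solve a sum-constrained GLS (solved through the KKT
system, which stays nonsingular even for exactly rank-deficient data).
The residual covariance Q_y is estimated by block jackknife at the
ordinary-least-squares warm start, and the GLS is solved once more with
it — a single fixed-point refinement; further iteration moved simulated
estimates by far less than their SEs in pilot runs. Weight SEs come from
delete-one-block re-estimation (Q_y held fixed) with the weighted
jackknife formula. Negative weights are reported as estimated;
plausibility is judged by the feasibility rules, not by clipping. The
base right population R_0 is the first listed one, following the
convention of putting the deepest outgroup first.

An independent cross-check used in the tests: on (near-)rank-deficient
matrices the weights extracted from the left null vector of the
rank-(k−1) fit agree with the GLS weights; with k = 1 source, qpAdm
reduces exactly to the rank-0 cladality test of target vs source.

## Feasibility and model competition

A fitted model is feasible when (i) p > 0.05, (ii) every weight SE
≤ 0.1, and (iii) every weight is within 2 SE of the unit interval
(w + 2·se ≥ 0 and w − 2·se ≤ 1). Reading (iii) as a band *around* [0, 1]
admits slightly negative point estimates with wide errors, which matches
how such fits are conventionally reported; a strict switch
(`strict_proportions=True`) requires w ∈ [0, 1] instead.

Competition of candidates A and B augments each model's right set with
the rival's distinctive sources (B\A for A's run, A\B for B's run), after
removing the refitted model's own target and sources from the right set
(logged). A candidate survives `promising_set` iff it passes the
distant-outgroup filter and remains feasible in **every** augmented run
it participates in; ties where several models survive are reported, not
broken. The alternative rule — additionally requiring every rival to
fail — is available as `survival_rule="defeat-all"`. Per-candidate fit
failures are isolated and recorded as infeasible with reason
`fit-error`; no multiple-testing correction is applied across the grid.

Individual screening admits a sample into a reference group iff it has
≥ 300k called SNPs and the rank-0 qpWave test of {individual, group}
against the right set gives p > 0.2 (both thresholds configurable). The
shipped default right set is OldAfrica, Russia_AfontovaGora3, CHG,
Iran_GanjDareh_N, Italy_Villabruna, Russia_Sidelkino.SG, Turkey_N, with
an extended Anatolian-resolution preset as the second option.

## PCA projection

The basis is fit on reference individuals only: per-SNP mean centering,
sqrt(p(1−p)) scaling, mean imputation of missing reference entries, and
eigendecomposition of the individual×individual kernel; SNP-space
loadings are orthonormalized. Projected samples solve a least-squares
problem on their observed SNPs only, so missingness does not bias the
axes; for complete data this equals the dot-product projection.

Projection shrinks coordinates toward the origin relative to the
reference panel (the panel overfits its own axes). The correction
estimates per-PC factors by leave-one-out self-projection of the
reference individuals: factor_k = mean |full coordinate| / mean
|held-out coordinate| ≥ 1, applied multiplicatively to projected
coordinates when `shrink=True`. This is a simple, transparent stand-in
for eigensoft-style shrinkage correction whose exact algorithm is
unpublished; it is estimated at fit time and can be switched off.

## Admixture-LD dating

After one admixture pulse g generations ago, recombination breaks
ancestry tracts at rate g per Morgan, so the covariance of
ancestry-informative alleles decays as e^(−g·d) in genetic distance d.
The curve accumulates w_i w_j (x_i − p̄_i)(x_j − p̄_j) over target
individuals and same-chromosome SNP pairs, with w = a − b the source
frequency difference (symmetric under source swap) and p̄ = (a+b)/2 the
pooled-source expectation; x is the individual's dosage fraction, so
pseudohaploid targets contribute single-allele residuals. Bins of
0.1 cM up to 100 cM are normalized by the per-bin count of non-missing
individual-level pairs. A₀·e^(−n·d) + c is fitted by nonlinear least
squares (log-linear warm start, pair-count weighting) over 0.45–100 cM
by default, excluding the shortest-range bins where background LD
unrelated to admixture dominates; n's SE comes from delete-one-
chromosome jackknife refits. Because source misspecification perturbs
the weights but not the decay rate, moderately drifted proxy sources do
not bias n. Generations convert to calendar years as
date = mean sample age + n × 28.6 yr/generation, with 25.6 and 31.5
(female/male generation intervals) as sensitivity bounds; the caller
supplies the mean sample age.

## Synthetic data

`simulate_graph_dataset` draws root frequencies from Uniform(0.05, 0.95),
drifts them along each edge with a Beta update moment-matched to
variance τ·p(1−p) (a martingale, clipped to [0, 1]; fixed alleles stay
fixed), mixes admixture-node frequencies linearly, and samples leaves as
Binomial(2, p) with optional pseudohaploidization and missingness. SNPs
live on 22 synthetic chromosomes with uniform map positions. This
moment-matched drift is chosen over coalescent simulation for speed and
exact seed determinism at desk scale; it reproduces the first two
moments of allele-frequency divergence that all f-statistics consume,
but not linkage disequilibrium within populations, realistic site
ascertainment, sequencing damage, or deep coalescent variance — so
passing tests validate the estimators' statistical logic, not robustness
to those real-data complications. SNPs fixed across all leaves are
retained (no ascertainment modeling).

`simulate_mosaic_cohort` builds each haplotype as an ancestry mosaic
with Poisson(g per Morgan) breakpoints and i.i.d. Bernoulli(α) tract
ancestries, drawing alleles from the tract's source frequencies; this
gives ancestry covariance α(1−α)·e^(−g·d), the exact signal the dating
module fits. Independent tract ancestries approximate the post-pulse
pedigree; very recent admixture (g ≲ 5), continuous gene flow, and
multiple pulses are outside the generator's scope.

`preset_three_cline` fixes a graph with four deep poles (two northern
hunter-gatherer, one Caucasus hunter-gatherer, one southern farmer),
three clines of two-way mixtures at α ∈ {0.2, 0.4, 0.6, 0.8} with a
small post-admixture drift (τ = 0.005), and seven outgroups placed so
each pole shares drift with a distinct subset of them — the geometry
that gives right sets their resolving power. Defaults: 40k SNPs, 5
individuals per leaf (6 per source pole), pseudohaploid cline members
and sources with 5% missingness, diploid outgroups. Drift amounts
(τ ≈ 0.01–0.12) put pairwise F_ST between poles near 0.05–0.10,
comparable to differentiation among west-Eurasian Holocene populations.

## Problem sizes in the validation suite

The acceptance checks use: 500 SNPs for exact oracle comparisons; 50k
SNPs × 50 seeds for qpAdm recovery of α = 0.30; 20k SNPs × 200
replicates for qpWave null calibration; 40k SNPs × 50 seeds for model
competition; 50k SNPs for F_ST; a 40-diploid mosaic cohort on 22 × 1.5 M
chromosomes at 1200 SNPs per chromosome for dating (marker density
thinned from array scale, which leaves the decay-rate estimand
unchanged); and 20k SNPs for PCA cline geometry. These sizes were chosen
so that each check has clear statistical resolution while the whole
suite runs on a laptop-class single core in about a minute.

## Known limitations

- The qpAdm dof convention treats the χ² as asymptotic even in `allsnps`
  mode with partially disjoint per-entry SNP sets.
- The shrinkage correction approximates, not reproduces, eigensoft's
  `newshrink`.
- No packed-binary EIGENSTRAT support (text only, bit-exact round trip).
- Genotype calling from reads (quality/damage filtering) is upstream of
  this package and intentionally absent.
- Single-pulse dating only; no multiple-pulse mixtures or continuous
  migration.
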