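"""qpWave rank tests and qpAdm admixture-proportion estimation.

qpWave asks how many independent streams of ancestry relate a "left" set
of populations to a "right" (outgroup) set: it tests whether the
(n_l-1) x (n_r-1) matrix of f4 statistics is consistent with rank t, by
minimizing the Mahalanobis distance (under the block-jackknife covariance)
to the set of rank-t matrices and referring the minimum to a chi-square
with (n_l-1-t)(n_r-1-t) degrees of freedom.

qpAdm models a target T as a mixture sum_i w_i S_i of k sources with
sum w_i = 1: the weights are chosen so the mixture reproduces the target's
shared drift with every right population, i.e. they solve a sum-constrained
generalized least squares problem on the f4 vectors
u_l[j] = f4(l, R_0; R_j, R_0). The model's tail probability is the qpWave
rank-(k-1) test on lefts {T, S_1..S_k}; weight standard errors come from
delete-one-block re-estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .fstats import ALLSNPS, F4Matrix, build_f4_matrix
from .genotype import BlockPartition, FreqTable, GenotypeDataset, allele_counts, assign_blocks
from .jackknife import jackknife_covariance, weighted_jackknife


class ConvergenceError(RuntimeError):
    """The alternating GLS rank fit failed to converge."""


@dataclass
class RankTestResult:
    """Outcome of a qpWave rank-t test."""

    rank: int
    chisq: float
    dof: int
    p: float
    fitted: np.ndarray       # best rank-t matrix, shape of A
    left_factor: np.ndarray  # X of the fitted B = X @ Y, (n_l-1, t)

    def __post_init__(self) -> None:
        self.chisq = float(max(self.chisq, 0.0))


@dataclass
class AdmixtureModel:
    """A fitted qpAdm model: T = sum_i w_i S_i relative to a right set."""

    target: str
    sources: tuple[str, ...]
    right: tuple[str, ...]
    weights: np.ndarray
    ses: np.ndarray
    p: float
    n_snps: int              # smallest per-entry usable SNP count
    mode: str
    rank_test: RankTestResult | None = None
    condition_warning: bool = False

    @property
    def k(self) -> int:
        return len(self.sources)

    def to_record(self) -> dict:
        return {
            "target": self.target,
            "sources": list(self.sources),
            "right": list(self.right),
            "weights": [float(w) for w in self.weights],
            "ses": [float(s) for s in self.ses],
            "p": float(self.p),
            "n_snps": int(self.n_snps),
            "mode": self.mode,
        }


def _gls_solve(design: np.ndarray, x: np.ndarray, Qi: np.ndarray) -> np.ndarray:
    A = design.T @ Qi @ design
    b = design.T @ Qi @ x
    return np.linalg.lstsq(A, b, rcond=None)[0]


def qpwave_rank_test(f4matrix: F4Matrix, t: int, *, tol: float = 1e-10,
                     max_iter: int = 200) -> RankTestResult:
    """Test whether the f4 matrix is consistent with rank ``t``.

    The rank-t fit B = X Y is found by alternating GLS on X and Y (each
    step is a linear GLS in the row-major vectorization), iterated to a
    relative chi-square tolerance. t = 0 fits B = 0 in closed form; t equal
    to the smaller matrix dimension is saturated (chi-square 0, p = 1).
    """
    n_l1, n_r1 = f4matrix.shape
    if not 0 <= t <= min(n_l1, n_r1):
        raise ValueError(f"rank {t} outside [0, {min(n_l1, n_r1)}]")
    x = f4matrix.flat()
    Qi = np.linalg.pinv(f4matrix.Q)
    dof = (n_l1 - t) * (n_r1 - t)

    if t == min(n_l1, n_r1):
        return RankTestResult(t, 0.0, max(dof, 0), 1.0, f4matrix.A.copy(),
                              np.linalg.svd(f4matrix.A)[0][:, :t])
    if t == 0:
        chisq = float(x @ Qi @ x)
        return RankTestResult(t, chisq, dof, float(sstats.chi2.sf(chisq, dof)),
                              np.zeros_like(f4matrix.A), np.zeros((n_l1, 0)))

    U, s, Vt = np.linalg.svd(f4matrix.A)
    X = U[:, :t] * s[:t]
    Y = Vt[:t, :]
    I_r = np.eye(n_r1)
    I_l = np.eye(n_l1)
    prev = np.inf
    chisq = np.inf
    for _ in range(max_iter):
        # fix X, solve Y: vec_row(XY) = kron(X, I_r) vec_row(Y)
        Y = _gls_solve(np.kron(X, I_r), x, Qi).reshape(t, n_r1)
        # fix Y, solve X: vec_row(XY) = kron(I_l, Y.T) vec_row(X)
        X = _gls_solve(np.kron(I_l, Y.T), x, Qi).reshape(n_l1, t)
        resid = x - (X @ Y).ravel()
        chisq = float(resid @ Qi @ resid)
        if abs(prev - chisq) <= tol * max(chisq, 1.0):
            break
        prev = chisq
    else:
        if not abs(prev - chisq) <= 1e-6 * max(chisq, 1.0):
            raise ConvergenceError(
                f"rank-{t} fit did not converge in {max_iter} iterations")
    return RankTestResult(t, chisq, dof, float(sstats.chi2.sf(chisq, dof)),
                          X @ Y, X)


def weights_from_null_vector(rank_result: RankTestResult) -> np.ndarray:
    """Admixture weights from the left null vector of a rank-(k-1) fit.

    For an f4 matrix with lefts [T, S_1..S_k] (target as base), rows are
    u_{S_i} - u_T; a vector v with v' X = 0 satisfies sum v_i u_{S_i} =
    (sum v_i) u_T on the fitted matrix, so w = v / sum(v). Used as an
    independent cross-check of the GLS estimator.
    """
    X = rank_result.left_factor
    k = X.shape[0]
    if X.shape[1] != k - 1:
        raise ValueError("rank fit is not k-1 for k sources")
    # null space of X': the singular vector with smallest singular value
    U, s, _ = np.linalg.svd(X, full_matrices=True)
    v = U[:, -1]
    total = v.sum()
    if abs(total) < 1e-12:
        raise ZeroDivisionError("null vector sums to ~0; weights undefined")
    return v / total


def _constrained_weights(rows: np.ndarray, Qyi: np.ndarray) -> np.ndarray:
    """minimize (A' w)' Qyi (A' w)  s.t.  1'w = 1, rows A (k, n_r1).

    The rows are a_i = u_{S_i} - u_T, so under the sum-to-one constraint
    the qpAdm residual u_T - sum w_i u_{S_i} equals -A' w and the problem
    reduces to w = M^-1 1 / (1' M^-1 1) with M_ij = a_i' Qyi a_j.
    """
    M = rows @ Qyi @ rows.T
    k = M.shape[0]
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = M
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    rhs = np.zeros(k + 1)
    rhs[k] = 1.0
    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
    return sol[:k]


def qpadm_fit(dataset: GenotypeDataset, target: str, sources: list[str],
              right: list[str], mode: str = ALLSNPS,
              block_size: float = 0.05,
              freqs: FreqTable | None = None,
              partition: BlockPartition | None = None) -> AdmixtureModel:
    """Fit admixture proportions of `target` from `sources` given `right`.

    Works on the f4 matrix with lefts [target, S_1..S_k] (target as base),
    whose rows are a_i = u_{S_i} - u_T with u_l[j] = f4(l, R_0; R_j, R_0);
    the sum-constrained mixture residual is -sum_i w_i a_i. The GLS is
    warm-started at the ordinary least-squares solution, the residual
    covariance is re-estimated by block jackknife at those weights, and
    the GLS is solved once more (a single fixed-point refinement). The
    model p-value is the qpWave rank-(k-1) test on the same matrix; weight
    SEs come from delete-one-block re-estimation. Negative weights are
    returned as-is; feasibility is judged downstream.
    """
    sources = list(sources)
    right = list(right)
    k = len(sources)
    if target in sources or target in right:
        raise ValueError(f"target {target!r} may not appear in sources or right")
    if set(sources) & set(right):
        raise ValueError(f"sources and right overlap: {set(sources) & set(right)}")
    if len(right) < k + 2:
        raise ValueError(f"need |right| >= k+2 = {k + 2}, got {len(right)}")

    pops = [target] + sources + right
    if freqs is None:
        freqs = allele_counts(dataset, pops)
    if partition is None:
        partition = assign_blocks(dataset, block_size)

    fm = build_f4_matrix(freqs, [target] + sources, right, partition, mode=mode)
    n_r1 = len(right) - 1
    A = fm.A                                  # (k, n_r1)
    loo = fm.loo_all().reshape(-1, k, n_r1)   # (B, k, n_r1)
    B = loo.shape[0]

    # OLS warm start, then one jackknife-covariance refinement of Q_y
    w = _constrained_weights(A, np.eye(n_r1))
    resid_full = w @ A
    resid_loo = np.einsum("i,bij->bj", w, loo)
    Qy = jackknife_covariance(resid_full, resid_loo, fm.block_weights)
    Qyi = np.linalg.pinv(Qy)
    w = _constrained_weights(A, Qyi)

    cond = np.linalg.cond(A @ Qyi @ A.T)
    cond_warn = bool(not np.isfinite(cond) or cond > 1e10)

    # delete-one-block re-estimation of the weights, weighted jackknife SEs
    w_loo = np.empty((B, k))
    for b_i in range(B):
        w_loo[b_i] = _constrained_weights(loo[b_i], Qyi)
    ses = np.empty(k)
    for i in range(k):
        _, ses[i] = weighted_jackknife(float(w[i]), w_loo[:, i],
                                       fm.block_weights)

    rt = qpwave_rank_test(fm, k - 1)

    return AdmixtureModel(target, tuple(sources), tuple(right), w, ses,
                          rt.p, int(fm.n_snps.min()), mode,
                          rank_test=rt, condition_warning=cond_warn)


def cladality_test(dataset: GenotypeDataset, popA: str, popB: str,
                   right: list[str], mode: str = ALLSNPS,
                   block_size: float = 0.05,
                   freqs: FreqTable | None = None,
                   partition: BlockPartition | None = None) -> RankTestResult:
    """Rank-0 qpWave test of {popA, popB} against `right`.

    A high p-value means the pair is consistent with descending from a
    common ancestor without differential relatedness to any right
    population (cladality); the result is invariant to swapping the pair.
    """
    if popA in right or popB in right:
        raise ValueError("tested populations may not appear in the right set")
    if freqs is None:
        freqs = allele_counts(dataset, [popA, popB] + list(right))
    if partition is None:
        partition = assign_blocks(dataset, block_size)
    fm = build_f4_matrix(freqs, [popA, popB], list(right), partition, mode=mode)
    return qpwave_rank_test(fm, 0)
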