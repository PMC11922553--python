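"""f-statistics: oracle equivalence, algebraic identities, F_ST recovery,
and jackknife calibration."""

import numpy as np
import pytest

from admixkit.fstats import (INTERSECTION, NoUsableSNPsError, RidgeWarning,
                             build_f4_matrix, f2_stat, f3_stat, f4_stat,
                             fst_hudson)
from admixkit.genotype import (DIPLOID, PSEUDOHAPLOID, allele_counts,
                               assign_blocks)
from admixkit.jackknife import weighted_jackknife
from admixkit.simulate import (GraphSpec, LeafPlan, simulate_graph_dataset)
from conftest import make_dataset, oracle_f


@pytest.fixture(scope="module")
def six_pop(six_pop_dataset):
    ds = six_pop_dataset
    freqs = allele_counts(ds, ds.populations)
    part = assign_blocks(ds, 0.05)
    return ds, freqs, part


class TestOracleEquivalence:
    """Every statistic equals a brute-force frequency-product sum."""

    @pytest.mark.parametrize("kind,pops", [
        ("f4", ("P1", "P2", "P3", "P4")),
        ("f4", ("P5", "P2", "P6", "P1")),
        ("f2", ("P1", "P4")),
        ("f2", ("P5", "P6")),
        ("f3", ("P2", "P1", "P3")),
        ("f3", ("P1", "P5", "P6")),
    ])
    def test_matches_bruteforce(self, six_pop, kind, pops):
        ds, _, part = six_pop
        freqs = allele_counts(ds, list(dict.fromkeys(pops)))
        fn = {"f4": f4_stat, "f2": f2_stat, "f3": f3_stat}[kind]
        est = fn(freqs, *pops, part, mode=INTERSECTION)
        expect = oracle_f(ds, kind, pops)
        assert est.value == pytest.approx(expect, abs=1e-12)

    def test_hand_computed_three_snp_f4(self):
        # fixed frequencies a=(1,0,.5), b=(0,0,.5), c=(1,1,0), d=(0,1,0)
        # -> products (1*1, 0*0, 0*0), mean 1/3
        geno = np.array([
            [2, 0, 2, 0],
            [0, 0, 2, 2],
            [1, 1, 0, 0],
        ], dtype=np.int8)
        ds = make_dataset(geno, ["A", "B", "C", "D"])
        freqs = allele_counts(ds, ["A", "B", "C", "D"])
        part = assign_blocks(ds, np.inf)
        est = f4_stat(freqs, "A", "B", "C", "D", part)
        assert est.value == pytest.approx(1.0 / 3.0, abs=1e-15)


class TestIdentities:
    def test_f4_same_population_is_zero(self, six_pop):
        _, freqs, part = six_pop
        est = f4_stat(freqs, "P1", "P1", "P2", "P3", part)
        assert est.value == 0.0

    def test_f4_symmetries(self, six_pop):
        _, freqs, part = six_pop
        base = f4_stat(freqs, "P1", "P2", "P3", "P4", part).value
        assert f4_stat(freqs, "P2", "P1", "P3", "P4", part).value == -base
        assert f4_stat(freqs, "P3", "P4", "P1", "P2", part).value == base
        assert f4_stat(freqs, "P2", "P1", "P4", "P3", part).value == base

    def test_f4_as_half_sum_of_f2s(self, six_pop):
        """f4(A,B;C,D) = (f2(A,D)+f2(B,C)-f2(A,C)-f2(B,D))/2 in
        intersection mode (corrections cancel)."""
        _, freqs, part = six_pop
        A, B, C, D = "P1", "P2", "P3", "P4"
        f4 = f4_stat(freqs, A, B, C, D, part, mode=INTERSECTION).value
        f2 = lambda x, y: f2_stat(freqs, x, y, part, mode=INTERSECTION).value
        assert f4 == pytest.approx(
            (f2(A, D) + f2(B, C) - f2(A, C) - f2(B, D)) / 2, abs=1e-10)

    def test_f3_as_half_sum_of_f2s(self, six_pop):
        _, freqs, part = six_pop
        T, A, B = "P2", "P1", "P3"
        f3 = f3_stat(freqs, T, A, B, part, mode=INTERSECTION).value
        f2 = lambda x, y: f2_stat(freqs, x, y, part, mode=INTERSECTION).value
        assert f3 == pytest.approx(
            (f2(T, A) + f2(T, B) - f2(A, B)) / 2, abs=1e-10)

    def test_f2_self_is_zero_band(self, six_pop):
        _, freqs, part = six_pop
        est = f2_stat(freqs, "P1", "P1", part)
        assert abs(est.value) < 1e-12

    def test_f4_equals_f2_on_distinct_samples(self, rng):
        """f4(A,B;A,B) with the two populations split into disjoint halves
        equals f2(A,B) up to jackknife noise."""
        spec = GraphSpec()
        spec.edges = {"A": ("root", 0.03), "B": ("root", 0.03)}
        spec.leaves = {"A": LeafPlan(8, DIPLOID, 0.0),
                       "B": LeafPlan(8, DIPLOID, 0.0)}
        ds = simulate_graph_dataset(spec, 20_000, seed=5)
        half = {}
        for p in ("A", "B"):
            ids = ds.ind.loc[ds.ind["population"] == p, "id"].tolist()
            half[p] = (ids[:4], ids[4:])
        groups = {"A1": half["A"][0], "A2": half["A"][1],
                  "B1": half["B"][0], "B2": half["B"][1]}
        freqs = allele_counts(ds, groups)
        part = assign_blocks(ds, 0.05)
        f4 = f4_stat(freqs, "A1", "B1", "A2", "B2", part, mode=INTERSECTION)
        f2 = f2_stat(freqs, "A1", "B1", part, mode=INTERSECTION)
        assert abs(f4.value - f2.value) < 3 * np.hypot(f4.se, f2.se)

    def test_admixture_f3_is_negative(self):
        spec = GraphSpec()
        e = spec.edges
        e["A"] = ("root", 0.08)
        e["B"] = ("root", 0.08)
        spec.admixtures["Tadm"] = ("A", "B", 0.5)
        e["T"] = ("Tadm", 0.001)
        spec.leaves = {p: LeafPlan(10, DIPLOID, 0.0) for p in "ABT"}
        ds = simulate_graph_dataset(spec, 30_000, seed=9)
        freqs = allele_counts(ds, ["T", "A", "B"])
        part = assign_blocks(ds, 0.05)
        est = f3_stat(freqs, "T", "A", "B", part)
        assert est.value < 0 and est.z < -3

    def test_value_invariant_to_individual_order(self, six_pop, rng):
        ds, _, part = six_pop
        perm = rng.permutation(ds.n_ind)
        shuffled = ds.subset_individuals(perm)
        freqs1 = allele_counts(ds, ["P1", "P2", "P3", "P4"])
        freqs2 = allele_counts(shuffled, ["P1", "P2", "P3", "P4"])
        a = f4_stat(freqs1, "P1", "P2", "P3", "P4", part, mode=INTERSECTION)
        b = f4_stat(freqs2, "P1", "P2", "P3", "P4", part, mode=INTERSECTION)
        assert a.value == pytest.approx(b.value, abs=1e-15)


class TestFst:
    def test_identical_population_near_zero(self, six_pop):
        _, freqs, part = six_pop
        est = fst_hudson(freqs, "P1", "P1", part)
        assert abs(est.value) <= max(2 * est.se, 1e-12)

    def test_fixed_opposite_alleles_give_one(self):
        geno = np.tile(np.array([[0, 0, 2, 2]], dtype=np.int8), (20, 1))
        ds = make_dataset(geno, ["A", "A", "B", "B"])
        freqs = allele_counts(ds, ["A", "B"])
        part = assign_blocks(ds, np.inf)
        est = fst_hudson(freqs, "A", "B", part)
        assert est.value == pytest.approx(1.0, abs=1e-12)

    def test_balding_nichols_recovery(self):
        spec = GraphSpec()
        spec.edges = {"A": ("root", 0.05), "B": ("root", 0.05)}
        spec.leaves = {"A": LeafPlan(20, DIPLOID, 0.0),
                       "B": LeafPlan(20, DIPLOID, 0.0)}
        ds = simulate_graph_dataset(spec, 50_000, seed=13)
        freqs = allele_counts(ds, ["A", "B"])
        part = assign_blocks(ds, 0.05)
        est = fst_hudson(freqs, "A", "B", part)
        assert 0.04 <= est.value <= 0.06


class TestF4Matrix:
    def test_shapes(self, six_pop):
        _, freqs, part = six_pop
        fm = build_f4_matrix(freqs, ["P1", "P2"], ["P3", "P4", "P5"], part)
        assert fm.A.shape == (1, 2) and fm.Q.shape == (2, 2)

    def test_entries_match_f4_stat(self, six_pop):
        _, freqs, part = six_pop
        left, right = ["P1", "P2"], ["P3", "P4", "P5", "P6"]
        sub = allele_counts(six_pop[0], left + right)
        fm = build_f4_matrix(sub, left, right, part, mode=INTERSECTION)
        for i, l in enumerate(left[1:]):
            for j, r in enumerate(right[1:]):
                est = f4_stat(sub, l, left[0], r, right[0], part,
                              mode=INTERSECTION)
                assert fm.A[i, j] == pytest.approx(est.value, abs=1e-12)

    def test_duplicated_right_population_triggers_ridge(self, six_pop):
        ds, _, part = six_pop
        groups = {p: ds.ind.loc[ds.ind["population"] == p, "id"].tolist()
                  for p in ["P1", "P2", "P3", "P4", "P5"]}
        groups["P5dup"] = groups["P5"]
        freqs = allele_counts(ds, groups)
        with pytest.warns(RidgeWarning):
            fm = build_f4_matrix(freqs, ["P1", "P2"],
                                 ["P3", "P4", "P5", "P5dup"], part)
        assert fm.ridge > 0

    def test_overlap_rejected(self, six_pop):
        _, freqs, part = six_pop
        with pytest.raises(ValueError, match="overlap"):
            build_f4_matrix(freqs, ["P1", "P2"], ["P2", "P3", "P4"], part)

    def test_q_symmetric_psd(self, six_pop):
        _, freqs, part = six_pop
        fm = build_f4_matrix(freqs, ["P1", "P2"], ["P4", "P5", "P6"], part)
        assert np.allclose(fm.Q, fm.Q.T)
        assert np.linalg.eigvalsh(fm.Q).min() >= -1e-12 * np.trace(fm.Q)


class TestJackknifeCalibration:
    def test_se_tracks_empirical_sd(self):
        """Mean jackknife SE within 25% of the cross-replicate SD of f4 on
        a drift tree (>= 100 replicates)."""
        spec = GraphSpec()
        e = spec.edges
        e["A"] = ("root", 0.04)
        e["n"] = ("root", 0.02)
        e["B"] = ("n", 0.03)
        e["n2"] = ("n", 0.02)
        e["C"] = ("n2", 0.03)
        e["D"] = ("n2", 0.03)
        spec.leaves = {p: LeafPlan(5, DIPLOID, 0.0) for p in "ABCD"}
        vals, ses = [], []
        for seed in range(100):
            ds = simulate_graph_dataset(spec, 4000, seed=seed, n_chrom=10)
            freqs = allele_counts(ds, ["A", "B", "C", "D"])
            part = assign_blocks(ds, 0.05)
            est = f4_stat(freqs, "A", "B", "C", "D", part)
            vals.append(est.value)
            ses.append(est.se)
        ratio = np.mean(ses) / np.std(vals, ddof=1)
        assert 0.75 < ratio < 1.25

    def test_weighted_jackknife_reduces_to_classic(self, rng):
        loo = rng.normal(size=30)
        theta = float(loo.mean())
        w = np.full(30, 7.0)
        _, se = weighted_jackknife(theta, loo, w)
        classic = np.sqrt((30 - 1) / 30 * np.sum((loo - loo.mean()) ** 2))
        assert se == pytest.approx(classic, rel=1e-10)


def test_no_usable_snps_raises():
    geno = np.full((5, 2), -1, dtype=np.int8)
    ds = make_dataset(geno, ["A", "B"])
    freqs = allele_counts(ds, ["A", "B"])
    part = assign_blocks(ds, np.inf)
    with pytest.raises(NoUsableSNPsError):
        f4_stat(freqs, "A", "B", "A", "B", part)
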