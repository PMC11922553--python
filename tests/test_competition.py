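"""Feasibility rules, right-set sanitation, model competition, screening."""

import numpy as np
import pytest

from admixkit.competition import (ModelSpec, RIGHT_BASE, RightSetTooSmallError,
                                  check_feasibility, compete_pair,
                                  filter_against_outgroups, promising_set,
                                  render_model_table, sanitize_right,
                                  screen_individuals)
from admixkit.qpadm import AdmixtureModel
from admixkit.simulate import (OUTGROUPS, preset_three_cline, GraphSpec,
                               LeafPlan, simulate_graph_dataset)
from admixkit.genotype import DIPLOID, PSEUDOHAPLOID


def model(p=0.5, weights=(0.6, 0.4), ses=(0.03, 0.03)):
    return AdmixtureModel("T", ("S1", "S2")[: len(weights)], tuple("R" + str(i) for i in range(4)),
                          np.asarray(weights, float), np.asarray(ses, float),
                          p, 10_000, "allsnps")


class TestFeasibilityRules:
    def test_low_p_is_infeasible(self):
        v = check_feasibility(model(p=0.04))
        assert not v.feasible and v.reasons == ["p-rule"]

    def test_boundary_p_equal_threshold_fails(self):
        # feasibility requires p strictly greater than the threshold
        assert not check_feasibility(model(p=0.05)).feasible

    def test_negative_weight_within_2se_is_feasible(self):
        v = check_feasibility(model(weights=(-0.05, 1.05), ses=(0.04, 0.04)))
        assert v.feasible

    def test_negative_weight_beyond_2se_is_infeasible(self):
        v = check_feasibility(model(weights=(-0.10, 1.10), ses=(0.03, 0.03)))
        assert v.reasons == ["proportion-rule"]

    def test_large_se_is_infeasible(self):
        v = check_feasibility(model(ses=(0.2, 0.03)))
        assert "se-rule" in v.reasons

    def test_strict_reading_switch(self):
        m = model(weights=(-0.05, 1.05), ses=(0.04, 0.04))
        assert check_feasibility(m).feasible
        assert not check_feasibility(m, strict_proportions=True).feasible


class TestSanitizeRight:
    def test_removes_target_and_sources(self):
        spec = ModelSpec("T", ("S1", "S2"))
        right = ["R1", "S1", "R2", "T", "R3", "R4"]
        kept, removed = sanitize_right(spec, right)
        assert kept == ["R1", "R2", "R3", "R4"]
        assert set(removed) == {"S1", "T"}

    def test_disjoint_right_unchanged_and_idempotent(self):
        spec = ModelSpec("T", ("S1", "S2"))
        right = ["R1", "R2", "R3", "R4"]
        kept, removed = sanitize_right(spec, right)
        assert kept == right and removed == []
        again, _ = sanitize_right(spec, kept)
        assert again == kept

    def test_too_small_after_removal_raises(self):
        spec = ModelSpec("T", ("S1", "S2"))
        with pytest.raises(RightSetTooSmallError):
            sanitize_right(spec, ["R1", "R2", "R3", "S1"])


@pytest.fixture(scope="module")
def cline_data():
    ds, truth = preset_three_cline(11, n_snps=40_000)
    return ds, truth


class TestCompetitionOnSimulatedData:
    def test_true_single_candidate_survives(self, cline_data):
        ds, truth = cline_data
        spec = ModelSpec("Volga_40", ("NorthHG_A", "CaucasusHG"))
        rep = promising_set([spec], list(OUTGROUPS), ds)
        assert [s.label() for s in rep.survivors] == [spec.label()]

    def test_empty_candidates_allowed(self, cline_data):
        ds, _ = cline_data
        rep = promising_set([], list(OUTGROUPS), ds)
        assert rep.survivors == [] and rep.candidates == []

    def test_wrong_source_model_eliminated(self, cline_data):
        ds, _ = cline_data
        true_m = ModelSpec("Volga_40", ("NorthHG_A", "CaucasusHG"))
        wrong_m = ModelSpec("Volga_40", ("NorthHG_B", "CaucasusHG"))
        rep = promising_set([true_m, wrong_m], list(OUTGROUPS), ds)
        labels = [s.label() for s in rep.survivors]
        assert true_m.label() in labels
        assert wrong_m.label() not in labels

    def test_order_invariance(self, cline_data):
        ds, _ = cline_data
        a = ModelSpec("Volga_40", ("NorthHG_A", "CaucasusHG"))
        b = ModelSpec("Volga_40", ("NorthHG_B", "CaucasusHG"))
        r1 = promising_set([a, b], list(OUTGROUPS), ds)
        r2 = promising_set([b, a], list(OUTGROUPS), ds)
        assert {s.label() for s in r1.survivors} == {s.label()
                                                    for s in r2.survivors}

    def test_identical_source_sets_equal_base_fit(self, cline_data):
        ds, _ = cline_data
        spec = ModelSpec("Volga_40", ("NorthHG_A", "CaucasusHG"))
        runA, runB = compete_pair(spec, spec, list(OUTGROUPS), ds)
        assert np.allclose(runA.model.weights, runB.model.weights)
        assert runA.right == tuple(OUTGROUPS)

    def test_augmentation_sanitizes_target_and_sources(self, cline_data):
        ds, _ = cline_data
        a = ModelSpec("Volga_40", ("NorthHG_A", "CaucasusHG"))
        # rival shares the target's source and includes a's source set member
        b = ModelSpec("Volga_40", ("NorthHG_B", "SouthFarmer"))
        runA, _ = compete_pair(a, b, list(OUTGROUPS), ds)
        # B \ A sources were appended then sanitized: none of a's own
        # target/sources may appear in the augmented right set
        assert "Volga_40" not in runA.right
        assert "NorthHG_A" not in runA.right
        assert "NorthHG_B" in runA.right

    def test_unrelated_source_fails_outgroup_filter(self):
        """A candidate whose source is unrelated to the target's ancestry
        is dropped at the outgroup-filtering step."""
        ds, _ = preset_three_cline(23, n_snps=40_000)
        bad = ModelSpec("Volga_40", ("SouthFarmer", "NorthHG_B"))
        good = ModelSpec("Volga_40", ("NorthHG_A", "CaucasusHG"))
        keep, runs = filter_against_outgroups([good, bad], list(OUTGROUPS), ds)
        labels = [s.label() for s in keep]
        assert good.label() in labels and bad.label() not in labels

    def test_fit_error_is_isolated(self, cline_data):
        ds, _ = cline_data
        broken = ModelSpec("Volga_40", ("NoSuchPop",))
        keep, runs = filter_against_outgroups([broken], list(OUTGROUPS), ds)
        assert keep == []
        assert runs[broken.label()].verdict.reasons == ["fit-error"]


class TestScreening:
    @pytest.fixture(scope="class")
    @staticmethod
    def screen_data():
        spec = GraphSpec()
        e = spec.edges
        e["R1"] = ("root", 0.08)
        e["n0"] = ("root", 0.02)
        e["R2"] = ("n0", 0.05)
        e["n1"] = ("n0", 0.02)
        e["R3"] = ("n1", 0.05)
        e["n2"] = ("n1", 0.02)
        e["n3"] = ("n2", 0.02)
        e["R4"] = ("n3", 0.05)
        e["Other"] = ("n3", 0.04)  # shares drift with R4: admixture detectable
        e["Ref"] = ("n2", 0.03)
        spec.admixtures["Mix_adm"] = ("Ref", "Other", 0.7)
        e["Mix"] = ("Mix_adm", 0.001)
        for r in ["R1", "R2", "R3", "R4"]:
            spec.leaves[r] = LeafPlan(6, DIPLOID, 0.0)
        spec.leaves["Ref"] = LeafPlan(10, PSEUDOHAPLOID, 0.05)
        spec.leaves["Mix"] = LeafPlan(2, PSEUDOHAPLOID, 0.05)
        spec.validate()
        return simulate_graph_dataset(spec, 100_000, seed=31)

    def test_low_coverage_excluded_regardless_of_p(self, screen_data):
        ds = screen_data
        table = screen_individuals(ds, "Ref", ["Mix_0"],
                                   ["R1", "R2", "R3", "R4"],
                                   min_snps=10**9)
        assert not table["admitted"].any()
        assert np.isnan(table["p"]).all()

    def test_reference_member_admitted_and_admixed_excluded(self, screen_data):
        ds = screen_data
        ref_ids = ds.ind.loc[ds.ind["population"] == "Ref", "id"].tolist()
        held_out = ref_ids[-1]
        sub = ds.relabel({})  # copy
        sub.ind.loc[sub.ind["id"] == held_out, "population"] = "HeldOut"
        table = screen_individuals(sub, "Ref", [held_out, "Mix_0", "Mix_1"],
                                   ["R1", "R2", "R3", "R4"], min_snps=1000)
        rows = table.set_index("id")
        # the held-out reference member is a true clade member: its p is a
        # draw from ~Uniform(0,1), so it must not be strongly rejected
        assert rows.loc[held_out, "p"] > 0.01
        assert not rows.loc["Mix_0", "admitted"]
        assert not rows.loc["Mix_1", "admitted"]


class TestModelTable:
    def test_negative_three_source_falls_back_to_nested_two_source(self):
        three = AdmixtureModel("T", ("S1", "S2", "S3"), ("R0", "R1", "R2", "R3", "R4"),
                               np.array([0.7, 0.35, -0.05]),
                               np.array([0.05, 0.05, 0.05]),
                               0.4, 10_000, "allsnps")
        two = AdmixtureModel("T", ("S1", "S2"), ("R0", "R1", "R2", "R3", "R4"),
                             np.array([0.6, 0.4]), np.array([0.04, 0.04]),
                             0.2, 10_000, "allsnps")
        table = render_model_table([three, two])
        row = table.iloc[0]
        assert row["sources"] == "S1+S2" and row["fallback"]

    def test_all_infeasible_marks_no_fitting_model(self):
        bad = model(p=0.001)
        table = render_model_table([bad])
        assert table.iloc[0]["display_model"] == "no fitting model"

    def test_column_order_stable(self):
        t1 = render_model_table([model()])
        t2 = render_model_table([model(p=0.2)])
        assert list(t1.columns) == list(t2.columns)


def test_default_right_preset_matches_convention():
    assert RIGHT_BASE[0] == "OldAfrica" and len(RIGHT_BASE) == 7
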