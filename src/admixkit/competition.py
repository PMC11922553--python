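"""Model competition for qpAdm: outgroup filtering, pairwise right-set
augmentation, feasibility verdicts and promising-model sets.

The idea: a candidate source set X describes a target T if it (i) fits T
against a set of distant outgroups, and (ii) stays feasible when the
distinctive sources of every rival model are moved onto the right set --
while rivals that cannot model shared drift with X's sources become
infeasible in their own augmented runs. Candidates that survive every
augmented run they participate in form the "promising" set.

A model is feasible when its tail probability exceeds the p threshold
(default 0.05), every weight SE is <= 0.1, and every admixture proportion
is within 2 standard errors of the [0, 1] interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fstats import ALLSNPS
from .genotype import FreqTable, GenotypeDataset, allele_counts, assign_blocks, BlockPartition
from .qpadm import AdmixtureModel, cladality_test, qpadm_fit

#: Default base Right set used for most analyses (distant outgroups
#: differentially related to steppe and West Asian sources).
RIGHT_BASE = ("OldAfrica", "Russia_AfontovaGora3", "CHG", "Iran_GanjDareh_N",
              "Italy_Villabruna", "Russia_Sidelkino.SG", "Turkey_N")

#: Extended right set used for Anatolian targets, trading CHG leverage for
#: finer resolution among West Asian sources.
RIGHT_ANATOLIA = ("OldAfrica", "CHG", "Iran_GanjDareh_N", "Italy_Villabruna",
                  "Russia_AfontovaGora3", "Russia_Sidelkino.SG",
                  "TUR_Marmara_Barcın_N", "TUR_C_Boncuklu_PPN",
                  "TUR_C_Çatalhöyük_N", "Natufian")

RIGHT_PRESETS = {"steppe-default": RIGHT_BASE, "anatolia-extended": RIGHT_ANATOLIA}


class RightSetTooSmallError(ValueError):
    """Sanitizing the right set left fewer than k+2 populations."""


@dataclass(frozen=True)
class ModelSpec:
    """An unfitted candidate: a target and its proposed sources."""

    target: str
    sources: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.sources)

    def label(self) -> str:
        return f"{self.target}~" + "+".join(self.sources)


@dataclass
class FeasibilityVerdict:
    """Which of the three feasibility rules a fitted model violates."""

    feasible: bool
    reasons: list[str]

    def __post_init__(self) -> None:
        assert self.feasible == (not self.reasons)


def check_feasibility(model: AdmixtureModel, p_threshold: float = 0.05,
                      max_se: float = 0.1,
                      strict_proportions: bool = False) -> FeasibilityVerdict:
    """Apply the three feasibility rules to a fitted model.

    * p-rule: tail probability must exceed `p_threshold`.
    * se-rule: every weight SE must be <= `max_se`.
    * proportion-rule: each weight may exceed [0, 1] by at most 2 SE,
      i.e. w_i + 2 se_i >= 0 and w_i - 2 se_i <= 1 (slightly negative
      fitted proportions with wide errors are acceptable). With
      ``strict_proportions=True`` the weights themselves must lie in
      [0, 1].
    """
    reasons = []
    if not model.p > p_threshold:
        reasons.append("p-rule")
    if np.any(model.ses > max_se) or not np.all(np.isfinite(model.ses)):
        reasons.append("se-rule")
    w, s = model.weights, model.ses
    if strict_proportions:
        bad = np.any(w < 0.0) or np.any(w > 1.0)
    else:
        bad = np.any(w + 2.0 * s < 0.0) or np.any(w - 2.0 * s > 1.0)
    if bad:
        reasons.append("proportion-rule")
    return FeasibilityVerdict(not reasons, reasons)


def sanitize_right(model_spec: ModelSpec, right: Sequence[str]
                   ) -> tuple[list[str], list[str]]:
    """Remove the model's target and sources from a right set.

    Returns (sanitized right, removed labels). Idempotent. Raises
    :class:`RightSetTooSmallError` if fewer than k+2 rights remain.
    """
    drop = {model_spec.target, *model_spec.sources}
    kept = [r for r in right if r not in drop]
    removed = [r for r in right if r in drop]
    if len(kept) < model_spec.k + 2:
        raise RightSetTooSmallError(
            f"right set for {model_spec.label()} has {len(kept)} populations "
            f"after removing {removed}; need >= {model_spec.k + 2}")
    return kept, removed


@dataclass
class CandidateRun:
    """One qpAdm run of a candidate on some (possibly augmented) right set."""

    spec: ModelSpec
    right: tuple[str, ...]
    model: AdmixtureModel | None
    verdict: FeasibilityVerdict
    error: str | None = None
    removed_from_right: tuple[str, ...] = ()


@dataclass
class CompetitionReport:
    """Full record of a model competition."""

    candidates: list[ModelSpec]
    base_runs: dict[str, CandidateRun]
    pairwise: dict[tuple[str, str], CandidateRun]  # (model, competitor) -> run
    survivors: list[ModelSpec]
    removed_log: list[tuple[str, tuple[str, ...]]]

    def pairwise_p_matrix(self) -> pd.DataFrame:
        labels = [c.label() for c in self.candidates]
        mat = pd.DataFrame(np.nan, index=labels, columns=labels)
        for (a, b), run in self.pairwise.items():
            mat.loc[a, b] = run.model.p if run.model is not None else np.nan
        return mat

    def to_records(self) -> dict:
        return {
            "candidates": [c.label() for c in self.candidates],
            "survivors": [c.label() for c in self.survivors],
            "base": {lab: _run_record(r) for lab, r in self.base_runs.items()},
            "pairwise": {f"{a}|vs|{b}": _run_record(r)
                         for (a, b), r in self.pairwise.items()},
            "removed_from_right": [
                {"model": lab, "removed": list(rm)} for lab, rm in self.removed_log],
        }


def _run_record(run: CandidateRun) -> dict:
    rec = {
        "right": list(run.right),
        "feasible": run.verdict.feasible,
        "reasons": run.verdict.reasons,
        "error": run.error,
    }
    if run.model is not None:
        rec.update(run.model.to_record())
    return rec


def _fit_candidate(spec: ModelSpec, right: Sequence[str],
                   dataset: GenotypeDataset, mode: str, block_size: float,
                   p_threshold: float, max_se: float,
                   strict_proportions: bool) -> CandidateRun:
    """Fit one candidate, isolating failures as infeasible 'fit-error' runs."""
    try:
        kept, removed = sanitize_right(spec, right)
        model = qpadm_fit(dataset, spec.target, list(spec.sources), kept,
                          mode=mode, block_size=block_size)
        verdict = check_feasibility(model, p_threshold, max_se, strict_proportions)
        return CandidateRun(spec, tuple(kept), model, verdict,
                            removed_from_right=tuple(removed))
    except Exception as exc:  # isolate per-candidate failures
        return CandidateRun(spec, tuple(right), None,
                            FeasibilityVerdict(False, ["fit-error"]),
                            error=f"{type(exc).__name__}: {exc}")


def filter_against_outgroups(candidates: Sequence[ModelSpec],
                             base_right: Sequence[str],
                             dataset: GenotypeDataset, *,
                             mode: str = ALLSNPS, block_size: float = 0.05,
                             p_threshold: float = 0.05, max_se: float = 0.1,
                             strict_proportions: bool = False
                             ) -> tuple[list[ModelSpec], dict[str, CandidateRun]]:
    """Fit every candidate against the distant-outgroup right set and keep
    the feasible ones. Per-candidate failures are recorded, not raised."""
    runs = {}
    keep = []
    for spec in candidates:
        run = _fit_candidate(spec, base_right, dataset, mode, block_size,
                             p_threshold, max_se, strict_proportions)
        runs[spec.label()] = run
        if run.verdict.feasible:
            keep.append(spec)
    return keep, runs


def compete_pair(modelA: ModelSpec, modelB: ModelSpec,
                 base_right: Sequence[str], dataset: GenotypeDataset, *,
                 mode: str = ALLSNPS, block_size: float = 0.05,
                 p_threshold: float = 0.05, max_se: float = 0.1,
                 strict_proportions: bool = False
                 ) -> tuple[CandidateRun, CandidateRun]:
    """Competition of two models by right-set augmentation.

    Run 1 refits A with the sources of B \\ A added to the right set;
    run 2 refits B with the sources of A \\ B added. Augmented rights are
    sanitized (target/sources of the refitted model removed and logged).
    With identical source sets both runs equal the base fits.
    """
    extraA = [s for s in modelB.sources if s not in modelA.sources]
    extraB = [s for s in modelA.sources if s not in modelB.sources]
    runA = _fit_candidate(modelA, list(base_right) + extraA, dataset, mode,
                          block_size, p_threshold, max_se, strict_proportions)
    runB = _fit_candidate(modelB, list(base_right) + extraB, dataset, mode,
                          block_size, p_threshold, max_se, strict_proportions)
    return runA, runB


def promising_set(candidates: Sequence[ModelSpec], base_right: Sequence[str],
                  dataset: GenotypeDataset, *,
                  mode: str = ALLSNPS, block_size: float = 0.05,
                  p_threshold: float = 0.05, max_se: float = 0.1,
                  strict_proportions: bool = False,
                  survival_rule: str = "never-infeasible") -> CompetitionReport:
    """Outgroup filtering followed by all-against-all competition.

    With the default ``survival_rule="never-infeasible"`` a model survives
    iff it passed the outgroup filter and remains feasible in every
    augmented run it participates in (ties where several models survive
    are reported, not broken). ``"defeat-all"`` additionally requires every
    rival to fail at least one of its own augmented runs. An empty
    survivor set is a valid outcome. Invariant to candidate ordering.
    """
    if survival_rule not in ("never-infeasible", "defeat-all"):
        raise ValueError(f"unknown survival rule {survival_rule!r}")
    if not candidates:
        return CompetitionReport([], {}, {}, [], [])
    candidates = list(candidates)
    passed, base_runs = filter_against_outgroups(
        candidates, base_right, dataset, mode=mode, block_size=block_size,
        p_threshold=p_threshold, max_se=max_se,
        strict_proportions=strict_proportions)

    pairwise: dict[tuple[str, str], CandidateRun] = {}
    feasible_everywhere = {spec.label(): True for spec in passed}
    for i, a in enumerate(passed):
        for b in passed[i + 1:]:
            runA, runB = compete_pair(a, b, base_right, dataset, mode=mode,
                                      block_size=block_size,
                                      p_threshold=p_threshold, max_se=max_se,
                                      strict_proportions=strict_proportions)
            pairwise[(a.label(), b.label())] = runA
            pairwise[(b.label(), a.label())] = runB
            feasible_everywhere[a.label()] &= runA.verdict.feasible
            feasible_everywhere[b.label()] &= runB.verdict.feasible

    survivors = [s for s in passed if feasible_everywhere[s.label()]]
    if survival_rule == "defeat-all":
        defeated = []
        for s in survivors:
            rivals = [r for r in passed if r.label() != s.label()]
            if all(not pairwise[(r.label(), s.label())].verdict.feasible
                   for r in rivals):
                defeated.append(s)
        survivors = defeated

    removed_log = []
    for lab, run in {**base_runs,
                     **{f"{a}|vs|{b}": r for (a, b), r in pairwise.items()}}.items():
        if run.removed_from_right:
            removed_log.append((lab, run.removed_from_right))
    return CompetitionReport(candidates, base_runs, pairwise, survivors,
                             removed_log)


def screen_individuals(dataset: GenotypeDataset, reference_group: str,
                       candidates: Sequence[str], right: Sequence[str], *,
                       p_threshold: float = 0.2, min_snps: int = 300_000,
                       mode: str = ALLSNPS, block_size: float = 0.05
                       ) -> pd.DataFrame:
    """Screen individuals for membership in a homogeneous reference group.

    A candidate individual (by id) is admitted iff it has at least
    `min_snps` non-missing SNPs and a rank-0 qpWave test of
    {individual, reference_group} against `right` gives p > `p_threshold`.
    Returns a table with per-individual SNP counts, p-values and verdicts.
    """
    ref_idx = dataset.individuals_of(reference_group)
    ref_ids = dataset.ind["id"].iloc[ref_idx].tolist()
    counts = dataset.snps_called()
    id_to_col = {i: c for c, i in enumerate(dataset.ind["id"])}
    partition = assign_blocks(dataset, block_size)

    rows = []
    for ind_id in candidates:
        if ind_id in ref_ids:
            raise ValueError(f"candidate {ind_id!r} is in the reference group")
        n = int(counts[id_to_col[ind_id]])
        p = np.nan
        admitted = False
        if n >= min_snps:
            groups = {"__candidate__": [ind_id], reference_group: ref_ids}
            for r in right:
                groups[r] = dataset.ind.loc[
                    dataset.ind["population"] == r, "id"].tolist()
            freqs = allele_counts(dataset, groups)
            rt = cladality_test(dataset, "__candidate__", reference_group,
                                list(right), mode=mode, freqs=freqs,
                                partition=partition)
            p = rt.p
            admitted = p > p_threshold
        rows.append({"id": ind_id, "n_snps": n, "p": p, "admitted": admitted})
    return pd.DataFrame(rows)


def render_model_table(models: Sequence[AdmixtureModel], *,
                       p_threshold: float = 0.05, max_se: float = 0.1,
                       strict_proportions: bool = False) -> pd.DataFrame:
    """Best-model table per target with the 2-source fallback display rule.

    For each target the feasible model with the highest p is selected; if
    the best model has >= 3 sources and a negative coefficient, and a
    nested feasible model with one fewer source exists among `models`,
    the simpler model is flagged as the display model (the convention for
    plotting mixture proportions). Targets with no feasible model get a
    "no fitting model" row.
    """
    by_target: dict[str, list[AdmixtureModel]] = {}
    for m in models:
        by_target.setdefault(m.target, []).append(m)

    rows = []
    for target, ms in by_target.items():
        feas = [m for m in ms
                if check_feasibility(m, p_threshold, max_se,
                                     strict_proportions).feasible]
        if not feas:
            rows.append({"target": target, "display_model": "no fitting model",
                         "sources": "", "p": np.nan, "weights": "", "ses": "",
                         "fallback": False})
            continue
        best = max(feas, key=lambda m: m.p)
        display = best
        fallback = False
        if best.k >= 3 and np.any(best.weights < 0):
            nested = [m for m in feas
                      if m.k == best.k - 1
                      and set(m.sources) < set(best.sources)]
            if nested:
                display = max(nested, key=lambda m: m.p)
                fallback = True
        rows.append({
            "target": target,
            "display_model": display.to_record()["target"] + "~" + "+".join(display.sources),
            "sources": "+".join(display.sources),
            "p": display.p,
            "weights": ";".join(f"{w:.4f}" for w in display.weights),
            "ses": ";".join(f"{s:.4f}" for s in display.ses),
            "fallback": fallback,
        })
    cols = ["target", "display_model", "sources", "p", "weights", "ses", "fallback"]
    return pd.DataFrame(rows, columns=cols)
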