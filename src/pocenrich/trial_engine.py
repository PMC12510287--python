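"""Two-stage decision machinery for the original and biomarker-guided designs.

Original design interim: continue to stage 2 with the full population if the
predictive probability of a final-analysis Go, ``PrGo``, reaches ``eta_f``;
otherwise stop for futility.

Biomarker-guided interim (in order):

1. Attempt to declare a biomarker cutoff on the stage-1 cohort.
2. No cutoff declared — fall back to the original rule with ``eta_f``.
3. Cutoff declared — continue with the full population if
   ``PrGo(full) >= eta_fc``; else enrich (restrict stage-2 recruitment to
   biomarker-positive patients) if the predictive probability of a Go in the
   sub-population reaches ``eta_plus``; else stop.

On enrichment, the final analysis pools the ``n_plus`` stage-1
biomarker-positive patients with ``N_f - n_f`` stage-2 biomarker-positive
recruits, so the enriched final sample size is
``N_plus = n_plus + (N_f - n_f)``.  The final Go/No-Go/Consider criteria are
identical on either analysis population.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import pandas as pd

from pocenrich.bayes_core import (
    EfficacyCriteria,
    FinalOutcome,
    final_decision,
    predictive_prob_go,
)
from pocenrich.cutoff_id import Cohort, CutoffResult, CutoffRule, declare_cutoff

__all__ = [
    "DesignKind",
    "DesignConfig",
    "InterimLabel",
    "InterimOutcome",
    "AnalysisPopulation",
    "TrialResult",
    "interim_decision_original",
    "interim_decision_bmk",
    "interim_decision",
    "interim_result",
    "run_final",
    "decision_boundaries",
]


class DesignKind(enum.Enum):
    ORIGINAL = "original"
    BMK_GUIDED = "bmk_guided"


class InterimLabel(enum.Enum):
    STOP_NO_CUTOFF = "stop_no_cutoff"
    STOP_WITH_CUTOFF = "stop_with_cutoff"
    CONTINUE_FULL = "continue_full"
    CONTINUE_ENRICHED = "continue_enriched"

    @property
    def is_stop(self) -> bool:
        return self in (InterimLabel.STOP_NO_CUTOFF, InterimLabel.STOP_WITH_CUTOFF)


class AnalysisPopulation(enum.Enum):
    FULL = "full"
    BMK_POSITIVE = "bmk_positive"
    NONE = "none"


@dataclass(frozen=True)
class DesignConfig:
    """All fixed parameters of a two-stage design.

    Parameters
    ----------
    n_f
        Interim-analysis sample size (full population).
    N_f
        Final-analysis sample size (full population).
    criteria
        Final-analysis TV/LRV efficacy criteria.
    eta_f
        PrGo threshold to continue when no cutoff is declared.
    eta_fc
        PrGo threshold to continue with the full population when a cutoff
        is declared.
    eta_plus
        Sub-population PrGo threshold to enrich.
    cutoff_rule
        Cutoff declaration rule (ignored for ``ORIGINAL``).
    design_kind
        ``ORIGINAL`` (futility stop only) or ``BMK_GUIDED``.
    """

    n_f: int
    N_f: int
    criteria: EfficacyCriteria
    eta_f: float = 0.10
    eta_fc: float = 0.90
    eta_plus: float = 0.75
    cutoff_rule: CutoffRule = CutoffRule()
    design_kind: DesignKind = DesignKind.BMK_GUIDED

    def __post_init__(self) -> None:
        if not (1 <= self.n_f < self.N_f):
            raise ValueError(f"need 1 <= n_f < N_f; got n_f={self.n_f}, N_f={self.N_f}")
        for name in ("eta_f", "eta_fc", "eta_plus"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]; got {v}")

    @property
    def stage2_size(self) -> int:
        return self.N_f - self.n_f


@dataclass(frozen=True)
class InterimOutcome:
    label: InterimLabel
    pr_go_full: float
    pr_go_plus: float | None
    cutoff_result: CutoffResult | None

    def __post_init__(self) -> None:
        if self.label is InterimLabel.CONTINUE_ENRICHED:
            if self.cutoff_result is None or not self.cutoff_result.declared:
                raise ValueError("enrichment requires a declared cutoff")
            if self.pr_go_plus is None:
                raise ValueError("enrichment requires the sub-population PrGo")


@dataclass(frozen=True)
class TrialResult:
    """One trial's path through the two-stage design.

    ``r_stage1`` is the full-population stage-1 response count; it feeds the
    full-path final analysis and the expected-sample-size bookkeeping.
    """

    interim: InterimOutcome
    final: FinalOutcome | None
    analysis_population: AnalysisPopulation
    n_recruited_total: int
    n_analyzed_FA: int
    r_analyzed_FA: int
    r_stage1: int = 0
    N_plus: int | None = None

    @property
    def stopped_at_interim(self) -> bool:
        return self.final is None

    @property
    def overall_outcome(self) -> str:
        """Pooled end-of-trial category: interim stops count as futility."""
        if self.final is None:
            return "no_go_or_futility"
        if self.final is FinalOutcome.NO_GO:
            return "no_go_or_futility"
        return "go" if self.final is FinalOutcome.GO else "consider"


def _check_stage1(cohort: Cohort, cfg: DesignConfig) -> None:
    if cohort.size != cfg.n_f:
        raise ValueError(
            f"stage-1 cohort has {cohort.size} patients but the design expects n_f={cfg.n_f}"
        )


def interim_decision_original(cohort: Cohort, cfg: DesignConfig) -> InterimOutcome:
    """Interim decision of the original (futility-stop-only) design."""
    _check_stage1(cohort, cfg)
    pr_go = predictive_prob_go(cohort.n_responses, cfg.n_f, cfg.N_f, cfg.criteria)
    label = InterimLabel.CONTINUE_FULL if pr_go >= cfg.eta_f else InterimLabel.STOP_NO_CUTOFF
    return InterimOutcome(label=label, pr_go_full=pr_go, pr_go_plus=None, cutoff_result=None)


def interim_decision_bmk(cohort: Cohort, cfg: DesignConfig) -> InterimOutcome:
    """Interim decision of the biomarker-guided design (cutoff, then thresholds)."""
    _check_stage1(cohort, cfg)
    cut = declare_cutoff(cohort, cfg.cutoff_rule)
    r = cohort.n_responses
    pr_go_full = predictive_prob_go(r, cfg.n_f, cfg.N_f, cfg.criteria)

    if not cut.declared:
        label = (
            InterimLabel.CONTINUE_FULL if pr_go_full >= cfg.eta_f else InterimLabel.STOP_NO_CUTOFF
        )
        return InterimOutcome(label=label, pr_go_full=pr_go_full, pr_go_plus=None, cutoff_result=cut)

    if pr_go_full >= cfg.eta_fc:
        return InterimOutcome(
            label=InterimLabel.CONTINUE_FULL,
            pr_go_full=pr_go_full,
            pr_go_plus=None,
            cutoff_result=cut,
        )

    N_plus = cut.n_plus + cfg.stage2_size
    pr_go_plus = predictive_prob_go(cut.r_plus, cut.n_plus, N_plus, cfg.criteria)
    label = (
        InterimLabel.CONTINUE_ENRICHED if pr_go_plus >= cfg.eta_plus else InterimLabel.STOP_WITH_CUTOFF
    )
    return InterimOutcome(
        label=label, pr_go_full=pr_go_full, pr_go_plus=pr_go_plus, cutoff_result=cut
    )


def interim_decision(cohort: Cohort, cfg: DesignConfig) -> InterimOutcome:
    """Dispatch on ``cfg.design_kind``."""
    if cfg.design_kind is DesignKind.ORIGINAL:
        return interim_decision_original(cohort, cfg)
    return interim_decision_bmk(cohort, cfg)


def interim_result(interim: InterimOutcome, cfg: DesignConfig, r_stage1: int) -> TrialResult:
    """Package an interim outcome as a (possibly partial) trial result."""
    if interim.label.is_stop:
        population = AnalysisPopulation.NONE
        N_plus = None
    elif interim.label is InterimLabel.CONTINUE_ENRICHED:
        population = AnalysisPopulation.BMK_POSITIVE
        N_plus = interim.cutoff_result.n_plus + cfg.stage2_size
    else:
        population = AnalysisPopulation.FULL
        N_plus = None
    return TrialResult(
        interim=interim,
        final=None,
        analysis_population=population,
        n_recruited_total=cfg.n_f,
        n_analyzed_FA=0,
        r_analyzed_FA=0,
        r_stage1=r_stage1,
        N_plus=N_plus,
    )


def run_final(trial_so_far: TrialResult, stage2: Cohort, cfg: DesignConfig) -> TrialResult:
    """Apply the final analysis after a continued interim.

    Full-population path: all ``N_f`` patients are analyzed.  Enriched path:
    the stage-1 biomarker-positive patients are carried forward and pooled
    with the ``N_f - n_f`` biomarker-positive stage-2 recruits, giving
    ``N_plus = n_plus + (N_f - n_f)`` analyzed patients.  Either way
    ``N_f - n_f`` patients are recruited in stage 2.
    """
    interim = trial_so_far.interim
    if interim.label.is_stop:
        raise ValueError("the trial stopped at the interim; there is no final analysis")
    if stage2.size != cfg.stage2_size:
        raise ValueError(
            f"stage-2 cohort has {stage2.size} patients; the design recruits {cfg.stage2_size}"
        )
    r2 = stage2.n_responses
    if interim.label is InterimLabel.CONTINUE_ENRICHED:
        cut = interim.cutoff_result
        N_plus = cut.n_plus + cfg.stage2_size
        r_fa = cut.r_plus + r2
        outcome = final_decision(r_fa, N_plus, cfg.criteria)
        return replace(
            trial_so_far,
            final=outcome,
            n_recruited_total=cfg.N_f,
            n_analyzed_FA=N_plus,
            r_analyzed_FA=r_fa,
            N_plus=N_plus,
        )
    r_fa = trial_so_far.r_stage1 + r2
    outcome = final_decision(r_fa, cfg.N_f, cfg.criteria)
    return replace(
        trial_so_far,
        final=outcome,
        n_recruited_total=cfg.N_f,
        n_analyzed_FA=cfg.N_f,
        r_analyzed_FA=r_fa,
    )


def decision_boundaries(cfg: DesignConfig) -> pd.DataFrame:
    """Convert interim thresholds into observed-response decision boundaries.

    Returns a tidy table with one row per grid point:

    * ``path = "interim_no_cutoff"``: for each stage-1 response count ``r``
      (0..n_f), whether the no-cutoff rule continues; the minimal continuing
      ``r`` is the interim futility boundary.
    * ``path = "interim_with_cutoff"``: for each biomarker-positive subgroup
      size ``n_plus`` (1..n_f-1), subgroup responses ``r_plus`` and total
      responses ``r`` consistent with the split, the label implied by the
      ``eta_fc`` / ``eta_plus`` thresholds (declaration assumed).
    * ``path = "final"``: for each analysis size, the decision at each
      response count, from which the minimal Go and maximal No-Go counts
      can be read off.
    """
    rows: list[dict] = []
    crit = cfg.criteria
    for r in range(cfg.n_f + 1):
        pr = predictive_prob_go(r, cfg.n_f, cfg.N_f, crit)
        rows.append(
            {
                "path": "interim_no_cutoff",
                "n_plus": pd.NA,
                "r_plus": pd.NA,
                "r": r,
                "decision": "continue_full" if pr >= cfg.eta_f else "stop",
            }
        )
    for n_plus in range(1, cfg.n_f):
        N_plus = n_plus + cfg.stage2_size
        for r_plus in range(n_plus + 1):
            pr_plus = predictive_prob_go(r_plus, n_plus, N_plus, crit)
            for r in range(r_plus, r_plus + (cfg.n_f - n_plus) + 1):
                pr_full = predictive_prob_go(r, cfg.n_f, cfg.N_f, crit)
                if pr_full >= cfg.eta_fc:
                    decision = "continue_full"
                elif pr_plus >= cfg.eta_plus:
                    decision = "continue_enriched"
                else:
                    decision = "stop"
                rows.append(
                    {
                        "path": "interim_with_cutoff",
                        "n_plus": n_plus,
                        "r_plus": r_plus,
                        "r": r,
                        "decision": decision,
                    }
                )
    fa_sizes = sorted({cfg.N_f, *(n_plus + cfg.stage2_size for n_plus in range(1, cfg.n_f))})
    for n_fa in fa_sizes:
        for r in range(n_fa + 1):
            rows.append(
                {
                    "path": "final",
                    "n_plus": pd.NA,
                    "r_plus": pd.NA,
                    "r": r,
                    "decision": final_decision(r, n_fa, crit).value,
                    "n_analyzed": n_fa,
                }
            )
    return pd.DataFrame(rows)
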