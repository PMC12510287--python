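"""Scenario-driven Monte-Carlo engine for design operating characteristics.

The data-generating process: each patient's biomarker ``X`` is drawn i.i.d.
from the scenario distribution (normal by default, gamma as a sensitivity),
and the response is Bernoulli with a step response curve

    p = p1  if x > c,     p = p0  if x <= c,

where the true cutoff ``c`` is the ``(1 - q_plus)`` quantile of the biomarker
distribution, so a fraction ``q_plus`` of the population is biomarker
positive.  The overall response rate is ``p0 (1 - q_plus) + p1 q_plus``.

Each simulated trial draws a stage-1 cohort, applies the configured design's
interim decision, draws a stage-2 cohort from the full distribution (or from
the distribution truncated above the *declared* cutoff when enriched — the
true cutoff still governs responses), and applies the final analysis.
Replicates run on independent substreams spawned from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pocenrich.bayes_core import FinalOutcome
from pocenrich.cutoff_id import Cohort, CutoffRule, declare_cutoff, fit_step_cutoff
from pocenrich.trial_engine import (
    AnalysisPopulation,
    DesignConfig,
    DesignKind,
    InterimLabel,
    TrialResult,
    interim_decision,
    interim_result,
    run_final,
)

__all__ = [
    "BiomarkerDist",
    "Scenario",
    "STANDARD_SCENARIOS",
    "OperatingCharacteristics",
    "simulate_cohort",
    "simulate_trials",
    "run_trial",
    "operating_characteristics",
    "declaration_frequency",
    "compare_declaration_approaches",
    "calibrate_thresholds",
]

#: biomarker distribution of the motivating trial: pooled across indications
DEFAULT_BIOMARKER_MU = 3.46
DEFAULT_BIOMARKER_SIGMA = 1.3


@dataclass(frozen=True)
class BiomarkerDist:
    """Continuous biomarker distribution: ``normal(mu, sigma)`` or
    ``gamma(shape, rate)`` (rate parameterization, as in R)."""

    family: str = "normal"
    mu: float = DEFAULT_BIOMARKER_MU
    sigma: float = DEFAULT_BIOMARKER_SIGMA
    shape: float | None = None
    rate: float | None = None

    def frozen(self):
        if self.family == "normal":
            return stats.norm(loc=self.mu, scale=self.sigma)
        if self.family == "gamma":
            if self.shape is None or self.rate is None:
                raise ValueError("gamma biomarker needs explicit shape and rate")
            return stats.gamma(a=self.shape, scale=1.0 / self.rate)
        raise ValueError(f"unknown biomarker family {self.family!r}")

    @staticmethod
    def gamma_matching_mean(mean: float, rate: float) -> "BiomarkerDist":
        """Gamma with the given mean at the given rate (shape = mean * rate)."""
        return BiomarkerDist(family="gamma", shape=mean * rate, rate=rate)

    @staticmethod
    def gamma_matching_variance(variance: float, rate: float) -> "BiomarkerDist":
        """Gamma with the given variance at the given rate (shape = var * rate^2)."""
        return BiomarkerDist(family="gamma", shape=variance * rate**2, rate=rate)


@dataclass(frozen=True)
class Scenario:
    """Ground truth for a simulated trial.

    ``p0``/``p1`` are the response rates below/above the true cutoff; the
    cutoff itself is implied by the biomarker-positive prevalence ``q_plus``
    as the exact analytic ``(1 - q_plus)`` quantile of the biomarker
    distribution.
    """

    p0: float
    p1: float
    q_plus: float
    biomarker_dist: BiomarkerDist = field(default_factory=BiomarkerDist)
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p0 <= self.p1 <= 1.0):
            raise ValueError(f"need 0 <= p0 <= p1 <= 1; got p0={self.p0}, p1={self.p1}")
        if not (0.0 < self.q_plus < 1.0):
            raise ValueError(f"prevalence q_plus must lie strictly in (0, 1); got {self.q_plus}")

    @property
    def true_cutoff(self) -> float:
        return float(self.biomarker_dist.frozen().ppf(1.0 - self.q_plus))

    @property
    def overall_response_rate(self) -> float:
        return self.p0 * (1.0 - self.q_plus) + self.p1 * self.q_plus


#: the nine scenarios of the reference simulation study (TV/LRV = 15%/5%)
STANDARD_SCENARIOS: dict[str, Scenario] = {
    "NPHRq1": Scenario(0.15, 0.15, 0.50, label="NPHRq1"),
    "NPHRq2": Scenario(0.15, 0.15, 0.30, label="NPHRq2"),
    "NPMRq1": Scenario(0.05, 0.05, 0.50, label="NPMRq1"),
    "NPMRq2": Scenario(0.05, 0.05, 0.30, label="NPMRq2"),
    "NPLRq1": Scenario(0.00, 0.00, 0.50, label="NPLRq1"),
    "NPLRq2": Scenario(0.00, 0.00, 0.30, label="NPLRq2"),
    "PHRq1": Scenario(0.05, 0.25, 0.50, label="PHRq1"),
    "PHRq2": Scenario(0.025, 0.275, 0.30, label="PHRq2"),
    "PMRq1": Scenario(0.05, 0.15, 0.50, label="PMRq1"),
}


def simulate_cohort(scn: Scenario, n: int, rng: np.random.Generator) -> Cohort:
    """Draw ``n`` patients: biomarker i.i.d. from the scenario distribution,
    response Bernoulli with the step curve around the true cutoff."""
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    x = _draw_biomarker(scn.biomarker_dist, n, rng)
    return Cohort(biomarker=x, response=_step_response(scn, x, rng))


def _draw_biomarker(dist: BiomarkerDist, n: int, rng: np.random.Generator) -> np.ndarray:
    if dist.family == "normal":
        return rng.normal(dist.mu, dist.sigma, size=n)
    if dist.family == "gamma":
        if dist.shape is None or dist.rate is None:
            raise ValueError("gamma biomarker needs explicit shape and rate")
        return rng.gamma(dist.shape, 1.0 / dist.rate, size=n)
    raise ValueError(f"unknown biomarker family {dist.family!r}")


def _step_response(scn: Scenario, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    p = np.where(x > scn.true_cutoff, scn.p1, scn.p0)
    return (rng.random(x.size) < p).astype(np.int64)


def _draw_biomarker_truncated_above(
    dist: BiomarkerDist, lower: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF draw from the biomarker distribution conditioned on
    ``X > lower`` (screening enriched-stage recruits)."""
    frozen = dist.frozen()
    f_lo = float(frozen.cdf(lower))
    u = rng.random(n)
    return np.asarray(frozen.ppf(f_lo + u * (1.0 - f_lo)), dtype=float)


def run_trial(scn: Scenario, cfg: DesignConfig, rng: np.random.Generator) -> TrialResult:
    """Simulate one complete trial under the scenario and design."""
    stage1 = simulate_cohort(scn, cfg.n_f, rng)
    interim = interim_decision(stage1, cfg)
    partial = interim_result(interim, cfg, stage1.n_responses)
    if interim.label.is_stop:
        return partial
    if interim.label is InterimLabel.CONTINUE_ENRICHED:
        x2 = _draw_biomarker_truncated_above(
            scn.biomarker_dist, interim.cutoff_result.cutoff, cfg.stage2_size, rng
        )
        stage2 = Cohort(biomarker=x2, response=_step_response(scn, x2, rng))
    else:
        stage2 = simulate_cohort(scn, cfg.stage2_size, rng)
    return run_final(partial, stage2, cfg)


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Aggregate decision frequencies and sample-size / cutoff summaries
    over a batch of simulated trials.

    Fractions are over all replicates except ``conditional_FA_probs`` (per
    analysis population, conditional on reaching the final analysis there).
    The cutoff summaries (``cutoff_mean``/``cutoff_p25``/``cutoff_p75``)
    describe the least-squares step-fit cutoff on the stage-1 cohort over
    all replicates where a step can be fitted (at least one responder and
    one non-responder); they characterize the cutoff *estimator*, not the
    declared subset, whose size is ``declare_prob``.
    ``late_declaration_prob`` is the fraction of replicates that continued
    with the full population, did not declare at the interim, but whose
    pooled final cohort declares a cutoff.
    """

    n_reps: int
    interim_probs: dict[str, float]
    overall_probs: dict[str, float]
    conditional_FA_probs: dict[tuple[str, str], float]
    declare_prob: float
    cutoff_mean: float
    cutoff_p25: float
    cutoff_p75: float
    ess_mean: float
    ess_p25: float
    ess_p75: float
    late_declaration_prob: float

    def to_frame(self, scenario_label: str = "") -> pd.DataFrame:
        """Tidy one-row-per-metric view for CSV export."""
        rows = [{"scenario": scenario_label, "metric": "n_reps", "value": self.n_reps}]
        for k, v in self.interim_probs.items():
            rows.append({"scenario": scenario_label, "metric": f"interim:{k}", "value": v})
        for k, v in self.overall_probs.items():
            rows.append({"scenario": scenario_label, "metric": f"overall:{k}", "value": v})
        for (pop, out), v in self.conditional_FA_probs.items():
            rows.append(
                {"scenario": scenario_label, "metric": f"FA:{pop}:{out}", "value": v}
            )
        for name in (
            "declare_prob",
            "cutoff_mean",
            "cutoff_p25",
            "cutoff_p75",
            "ess_mean",
            "ess_p25",
            "ess_p75",
            "late_declaration_prob",
        ):
            rows.append({"scenario": scenario_label, "metric": name, "value": getattr(self, name)})
        return pd.DataFrame(rows)


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_trials(
    scn: Scenario, cfg: DesignConfig, n_reps: int, seed: int
) -> list[TrialResult]:
    """Run ``n_reps`` independent trials on substreams of ``seed``."""
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    rngs = _spawn_rngs(seed, n_reps)
    return [run_trial(scn, cfg, rng) for rng in rngs]


def operating_characteristics(
    scn: Scenario, cfg: DesignConfig, n_reps: int = 5000, seed: int = 0
) -> OperatingCharacteristics:
    """Monte-Carlo operating characteristics of a design under a scenario."""
    rngs = _spawn_rngs(seed, n_reps)
    results: list[TrialResult] = []
    fitted_cutoffs: list[float] = []
    late = 0
    n_continue_full = 0
    for rng in rngs:
        stage1 = simulate_cohort(scn, cfg.n_f, rng)
        if 0 < stage1.n_responses < stage1.size:
            fit = fit_step_cutoff(stage1, 0.0)
            if fit is not None:
                fitted_cutoffs.append(fit.cutoff)
        interim = interim_decision(stage1, cfg)
        partial = interim_result(interim, cfg, stage1.n_responses)
        if interim.label.is_stop:
            results.append(partial)
            continue
        if interim.label is InterimLabel.CONTINUE_ENRICHED:
            x2 = _draw_biomarker_truncated_above(
                scn.biomarker_dist, interim.cutoff_result.cutoff, cfg.stage2_size, rng
            )
            stage2 = Cohort(biomarker=x2, response=_step_response(scn, x2, rng))
        else:
            stage2 = simulate_cohort(scn, cfg.stage2_size, rng)
        results.append(run_final(partial, stage2, cfg))
        if interim.label is InterimLabel.CONTINUE_FULL:
            n_continue_full += 1
            declared_ia = (
                interim.cutoff_result is not None and interim.cutoff_result.declared
            )
            if not declared_ia and cfg.design_kind is DesignKind.BMK_GUIDED:
                pooled = Cohort(
                    biomarker=np.concatenate((stage1.biomarker, stage2.biomarker)),
                    response=np.concatenate((stage1.response, stage2.response)),
                )
                if declare_cutoff(pooled, cfg.cutoff_rule).declared:
                    late += 1
    return _aggregate(results, late, fitted_cutoffs)


def _aggregate(
    results: Sequence[TrialResult], late: int, fitted_cutoffs: Sequence[float]
) -> OperatingCharacteristics:
    n = len(results)
    interim_counts = {label.value: 0 for label in InterimLabel}
    overall_counts = {"go": 0, "no_go_or_futility": 0, "consider": 0}
    fa_counts: dict[tuple[str, str], int] = {}
    fa_pop_totals: dict[str, int] = {}
    declared_cutoffs: list[float] = []
    ess = np.empty(n)
    for i, res in enumerate(results):
        interim_counts[res.interim.label.value] += 1
        overall_counts[res.overall_outcome] += 1
        ess[i] = res.n_recruited_total
        cut = res.interim.cutoff_result
        if cut is not None and cut.declared:
            declared_cutoffs.append(cut.cutoff)
        if res.final is not None:
            pops = [res.analysis_population.value, "any"]
            for pop in pops:
                fa_pop_totals[pop] = fa_pop_totals.get(pop, 0) + 1
                key = (pop, res.final.value)
                fa_counts[key] = fa_counts.get(key, 0) + 1
    conditional = {
        key: count / fa_pop_totals[key[0]] for key, count in sorted(fa_counts.items())
    }
    if fitted_cutoffs:
        cuts = np.array(fitted_cutoffs)
        c_mean, c25, c75 = float(cuts.mean()), *map(float, np.percentile(cuts, [25, 75]))
    else:
        c_mean = c25 = c75 = float("nan")
    return OperatingCharacteristics(
        n_reps=n,
        interim_probs={k: v / n for k, v in interim_counts.items()},
        overall_probs={k: v / n for k, v in overall_counts.items()},
        conditional_FA_probs=conditional,
        declare_prob=len(declared_cutoffs) / n,
        cutoff_mean=c_mean,
        cutoff_p25=c25,
        cutoff_p75=c75,
        ess_mean=float(ess.mean()),
        ess_p25=float(np.percentile(ess, 25)),
        ess_p75=float(np.percentile(ess, 75)),
        late_declaration_prob=late / n,
    )


def declaration_frequency(
    scn: Scenario, rule: CutoffRule, n_cohort: int, n_reps: int, seed: int
) -> float:
    """Fraction of simulated cohorts on which the rule declares a cutoff."""
    rngs = _spawn_rngs(seed, n_reps)
    hits = 0
    for rng in rngs:
        if declare_cutoff(simulate_cohort(scn, n_cohort, rng), rule).declared:
            hits += 1
    return hits / n_reps


def compare_declaration_approaches(
    scn_null: Scenario,
    scn_alt: Scenario,
    grid: Iterable[CutoffRule],
    n_reps: int = 5000,
    seed: int = 0,
    n_cohort: int = 14,
) -> pd.DataFrame:
    """False/true-positive declaration frequencies and gain for each rule.

    The same ``n_reps`` simulated cohorts per scenario are reused across all
    rules (common random numbers), mirroring a comparison run on one shared
    set of interim data sets.
    """
    rules = list(grid)
    null_cohorts = [
        simulate_cohort(scn_null, n_cohort, rng) for rng in _spawn_rngs(seed, n_reps)
    ]
    alt_cohorts = [
        simulate_cohort(scn_alt, n_cohort, rng) for rng in _spawn_rngs(seed + 1, n_reps)
    ]
    rows = []
    for rule in rules:
        fp = sum(declare_cutoff(c, rule).declared for c in null_cohorts) / n_reps
        tp = sum(declare_cutoff(c, rule).declared for c in alt_cohorts) / n_reps
        rows.append(
            {
                "approach": rule.approach.value,
                "pp": rule.pp,
                "diffthr": rule.diffthr,
                "pthr": rule.pthr,
                "false_positive": fp,
                "true_positive": tp,
                "gain": tp - fp,
            }
        )
    return pd.DataFrame(rows)


def calibrate_thresholds(
    scenarios: Sequence[Scenario],
    cfg_base: DesignConfig,
    eta_fc_grid: Sequence[float],
    eta_plus_grid: Sequence[float],
    n_reps: int = 5000,
    seed: int = 0,
    go_floor: float = 0.75,
    go_ceiling: float = 0.15,
    floor_scenarios: Sequence[str] = (),
    ceiling_scenarios: Sequence[str] = (),
) -> pd.DataFrame:
    """Grid search over the with-cutoff interim thresholds.

    For every ``(eta_fc, eta_plus)`` pair and scenario, reports the overall
    Go probability and the enrichment probability.  A pair is flagged
    feasible when the overall Go probability is at least ``go_floor`` under
    every scenario named in ``floor_scenarios`` (typically the alternatives)
    and at most ``go_ceiling`` under every scenario in ``ceiling_scenarios``
    (typically a null); among feasible pairs the design team would pick the
    one maximizing enrichment under the alternative.
    """
    if not eta_fc_grid or not eta_plus_grid:
        raise ValueError("threshold grids must be non-empty")
    from dataclasses import replace as _replace

    rows = []
    for eta_fc in eta_fc_grid:
        for eta_plus in eta_plus_grid:
            cfg = _replace(cfg_base, eta_fc=eta_fc, eta_plus=eta_plus)
            per_scn: dict[str, tuple[float, float]] = {}
            for scn in scenarios:
                oc = operating_characteristics(scn, cfg, n_reps=n_reps, seed=seed)
                per_scn[scn.label] = (
                    oc.overall_probs["go"],
                    oc.interim_probs[InterimLabel.CONTINUE_ENRICHED.value],
                )
            feasible = all(
                per_scn[name][0] >= go_floor for name in floor_scenarios if name in per_scn
            ) and all(
                per_scn[name][0] <= go_ceiling for name in ceiling_scenarios if name in per_scn
            )
            for label, (go, enrich) in per_scn.items():
                rows.append(
                    {
                        "eta_fc": eta_fc,
                        "eta_plus": eta_plus,
                        "scenario": label,
                        "overall_go": go,
                        "enrich_prob": enrich,
                        "feasible": feasible,
                    }
                )
    return pd.DataFrame(rows)
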