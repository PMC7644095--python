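"""Starvation-induced sleep loss and the group comparisons around it.

Starvation-induced sleep loss is defined on cohort means of total sleep over
a common starvation-time window (ST12-ST24 by default):

    loss% = 100 * (fed_mean - starved_mean) / fed_mean

and may be negative (starved flies sleeping more than fed ones).  Group
comparisons follow the conventions of fly sleep papers: two-sample t tests
for fed-vs-starved within a genotype, one-way ANOVA with Dunnett (each
genotype vs a control) or Tukey (all pairs) post-hoc tests across genotypes.

Numerics delegate to scipy (``ttest_ind``, ``f_oneway``, ``dunnett``,
``tukey_hsd``); the degenerate-case conventions (zero variance, identical
samples) are pinned down here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dam_io import ActivitySeries
from .errors import ValidationError
from .sleep import (
    ExperimentDesign,
    SleepMetrics,
    bout_metrics,
    first_ld_shift,
    score_sleep,
    st_window,
)

TWO_SAMPLE_METHODS = ("student_t", "welch_t")
POSTHOC_METHODS = ("anova_dunnett", "anova_tukey")


@dataclass
class CohortSummary:
    """Per-fly sleep metrics for one genotype x arm cell, on a common window."""

    arm: str                      # "fed" or "starved"
    genotype: str
    per_fly_metrics: list[SleepMetrics]

    def __post_init__(self) -> None:
        if self.arm not in ("fed", "starved"):
            raise ValidationError(f"arm must be 'fed' or 'starved', got {self.arm!r}")
        if not self.per_fly_metrics:
            raise ValidationError(f"{self.genotype}/{self.arm}: empty cohort")
        w0 = self.per_fly_metrics[0].window
        if any(m.window != w0 for m in self.per_fly_metrics):
            raise ValidationError(f"{self.genotype}/{self.arm}: metrics mix windows")

    @property
    def n(self) -> int:
        return len(self.per_fly_metrics)

    @property
    def window(self) -> tuple[int, int]:
        return self.per_fly_metrics[0].window

    @property
    def total_sleep(self) -> np.ndarray:
        return np.array([m.total_sleep_min for m in self.per_fly_metrics], dtype=float)


@dataclass
class SleepLossResult:
    """Starvation-induced sleep loss for one genotype."""

    loss_pct: float
    fed_mean_min: float
    starved_mean_min: float
    window: tuple[int, int]
    genotype: str
    n_fed: int = 0
    n_starved: int = 0


@dataclass
class ComparisonResult:
    """One statistical contrast; post-hoc methods carry adjusted p-values."""

    statistic: float
    p_value: float
    method: str
    contrast: tuple[str, str]


@dataclass
class AnovaResult:
    """Omnibus one-way ANOVA plus its per-contrast post-hoc results."""

    f_statistic: float
    f_pvalue: float
    comparisons: list[ComparisonResult]


def sleep_loss_pct(fed: CohortSummary, starved: CohortSummary) -> SleepLossResult:
    """Loss% on cohort means; negative when starved flies sleep more."""
    if fed.arm != "fed" or starved.arm != "starved":
        raise ValidationError("arguments must be (fed, starved) cohorts")
    if fed.genotype != starved.genotype:
        raise ValidationError(
            f"genotype mismatch: {fed.genotype!r} vs {starved.genotype!r}"
        )
    if fed.window != starved.window:
        raise ValidationError(f"window mismatch: {fed.window} vs {starved.window}")
    fm = float(fed.total_sleep.mean())
    sm = float(starved.total_sleep.mean())
    if fm == 0:
        raise ValidationError(
            f"{fed.genotype}: fed cohort has zero mean sleep; loss undefined"
        )
    return SleepLossResult(
        loss_pct=100.0 * (fm - sm) / fm,
        fed_mean_min=fm, starved_mean_min=sm,
        window=fed.window, genotype=fed.genotype,
        n_fed=fed.n, n_starved=starved.n,
    )


def per_fly_loss_values(fed: CohortSummary, starved: CohortSummary) -> np.ndarray:
    """Per-starved-fly loss% relative to the fed cohort mean.

    The mean of these values equals :func:`sleep_loss_pct`; they provide the
    sample needed to run ANOVA/post-hoc tests on loss across genotypes.
    """
    res = sleep_loss_pct(fed, starved)
    return 100.0 * (res.fed_mean_min - starved.total_sleep) / res.fed_mean_min


def compare_two(
    a: Sequence[float],
    b: Sequence[float],
    method: str = "student_t",
    labels: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Two-sided two-sample t test; statistic sign follows mean(a) - mean(b).

    Zero variance in both samples with equal means yields t = 0, p = 1 by
    convention (nothing distinguishes the groups); with unequal means it
    yields an infinite statistic and p = 0.
    """
    if method not in TWO_SAMPLE_METHODS:
        raise ValidationError(f"method must be one of {TWO_SAMPLE_METHODS}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs n >= 2")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("samples must be finite")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return ComparisonResult(0.0, 1.0, method, labels)
        stat = np.inf if a.mean() > b.mean() else -np.inf
        return ComparisonResult(float(stat), 0.0, method, labels)
    res = sps.ttest_ind(a, b, equal_var=(method == "student_t"))
    return ComparisonResult(float(res.statistic), float(res.pvalue), method, labels)


def compare_many(
    groups: Mapping[str, Sequence[float]],
    control: str | None = None,
    method: str = "anova_dunnett",
) -> AnovaResult:
    """One-way ANOVA with Dunnett (vs control) or Tukey (all pairs) post-hoc.

    Post-hoc p-values are family-adjusted.  When every observation is equal
    there is nothing to test: F = 0, all p = 1 by convention.
    """
    if method not in POSTHOC_METHODS:
        raise ValidationError(f"method must be one of {POSTHOC_METHODS}")
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(samples) < 2:
        raise ValidationError("need >= 2 groups")
    if any(s.size < 2 for s in samples):
        raise ValidationError("each group needs n >= 2")
    if method == "anova_dunnett":
        if control is None:
            raise ValidationError("Dunnett's test requires a named control group")
        if control not in labels:
            raise ValidationError(f"control {control!r} not among groups {labels}")

    allv = np.concatenate(samples)
    if np.ptp(allv) == 0:  # every observation identical: degenerate by convention
        f_stat, f_p = 0.0, 1.0
        if method == "anova_dunnett":
            contrasts = [(k, control) for k in labels if k != control]
        else:
            contrasts = [(labels[i], labels[j])
                         for i in range(len(labels)) for j in range(i + 1, len(labels))]
        comps = [ComparisonResult(0.0, 1.0, method, c) for c in contrasts]
        return AnovaResult(f_stat, f_p, comps)

    f_stat, f_p = sps.f_oneway(*samples)
    f_stat, f_p = float(f_stat), float(f_p)
    comps: list[ComparisonResult] = []
    if method == "anova_dunnett":
        treat_labels = [k for k in labels if k != control]
        treat = [np.asarray(groups[k], dtype=float) for k in treat_labels]
        res = sps.dunnett(*treat, control=np.asarray(groups[control], dtype=float))
        for i, k in enumerate(treat_labels):
            comps.append(ComparisonResult(
                float(res.statistic[i]), float(res.pvalue[i]), method, (k, control)
            ))
    else:
        res = sps.tukey_hsd(*samples)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                comps.append(ComparisonResult(
                    float(res.statistic[i, j]), float(res.pvalue[i, j]),
                    method, (labels[i], labels[j]),
                ))
    return AnovaResult(f_stat, f_p, comps)


@dataclass
class AnalysisConfig:
    """Knobs of the standard experiment summary."""

    sleep_threshold_min: int = 5
    loss_window_st: tuple[float, float] = (12.0, 24.0)
    control_genotype: str | None = None
    posthoc: str = "anova_dunnett"
    two_sample: str = "student_t"
    exclude_dead_final_hours: float | None = None


@dataclass
class ExperimentSummary:
    """Tables emitted by :func:`summarize_experiment`."""

    loss_table: pd.DataFrame
    bout_table: pd.DataFrame
    comparison_table: pd.DataFrame


def cohort_metrics(
    series_list: Sequence[ActivitySeries],
    window: tuple[int, int],
    arm: str,
    genotype: str,
    threshold_min: int = 5,
) -> CohortSummary:
    """Score each fly and summarise it over one window."""
    metrics = [bout_metrics(score_sleep(s, threshold_min), window) for s in series_list]
    return CohortSummary(arm=arm, genotype=genotype, per_fly_metrics=metrics)


def summarize_experiment(
    experiment: Mapping[str, Mapping[str, Sequence[ActivitySeries]]],
    design: ExperimentDesign,
    config: AnalysisConfig | None = None,
) -> ExperimentSummary:
    """Full starvation-experiment summary over fed/starved cohorts.

    ``experiment`` maps genotype -> arm ("fed"/"starved") -> activity series.
    Emits, per genotype: the sleep-loss row over the configured ST window,
    the bout-metric decomposition before/after the first LD shift, the
    fed-vs-starved t test, and (with >= 2 genotypes) the configured post-hoc
    comparison of per-fly loss values across genotypes.  Deterministic given
    its inputs.
    """
    config = config or AnalysisConfig()
    if not experiment:
        raise ValidationError("no cohorts supplied")
    for g, arms in experiment.items():
        for arm in ("fed", "starved"):
            if arm not in arms or not arms[arm]:
                raise ValidationError(f"genotype {g!r}: missing {arm} arm")

    shift = first_ld_shift(design)
    loss_win = st_window(design, *config.loss_window_st)
    pre_win = st_window(design, 0.0, shift.st_hours)
    post_win = st_window(design, shift.st_hours, shift.st_hours + 12.0)

    thr = config.sleep_threshold_min
    loss_rows, bout_rows, comp_rows = [], [], []
    loss_samples: dict[str, np.ndarray] = {}

    for genotype, arms in experiment.items():
        flies = dict(arms)
        if config.exclude_dead_final_hours is not None:
            from .sleep import exclude_dead
            flies["fed"] = exclude_dead(flies["fed"], config.exclude_dead_final_hours)
            if not flies["fed"]:
                raise ValidationError(f"genotype {genotype!r}: all fed flies excluded as dead")

        fed = cohort_metrics(flies["fed"], loss_win, "fed", genotype, thr)
        starved = cohort_metrics(flies["starved"], loss_win, "starved", genotype, thr)
        res = sleep_loss_pct(fed, starved)
        loss_rows.append({
            "genotype": genotype, "n_fed": res.n_fed, "n_starved": res.n_starved,
            "fed_mean_min": res.fed_mean_min, "starved_mean_min": res.starved_mean_min,
            "loss_pct": res.loss_pct,
        })
        loss_samples[genotype] = per_fly_loss_values(fed, starved)

        t = compare_two(fed.total_sleep, starved.total_sleep, config.two_sample,
                        labels=(f"{genotype}:fed", f"{genotype}:starved"))
        comp_rows.append({
            "contrast": f"{t.contrast[0]} vs {t.contrast[1]} (ST{config.loss_window_st[0]:g}-"
                        f"ST{config.loss_window_st[1]:g} total sleep)",
            "method": t.method, "statistic": t.statistic, "p_adj": t.p_value,
        })

        for arm_name, arm_series in (("fed", flies["fed"]), ("starved", flies["starved"])):
            for win_name, win in (("pre_shift", pre_win), ("post_shift", post_win)):
                ms = [bout_metrics(score_sleep(s, thr), win) for s in arm_series]
                durs = [m.mean_bout_duration_min for m in ms
                        if m.mean_bout_duration_min is not None]
                bout_rows.append({
                    "genotype": genotype, "arm": arm_name, "window": win_name,
                    "total_sleep_mean": float(np.mean([m.total_sleep_min for m in ms])),
                    "bout_number_mean": float(np.mean([m.bout_number for m in ms])),
                    "mean_bout_duration": float(np.mean(durs)) if durs else np.nan,
                    "n": len(ms),
                })

    if len(experiment) >= 2:
        control = config.control_genotype
        if config.posthoc == "anova_dunnett" and control is None:
            control = next(iter(experiment))
        res = compare_many(loss_samples, control=control, method=config.posthoc)
        comp_rows.append({
            "contrast": "omnibus (loss_pct across genotypes)", "method": "anova_f",
            "statistic": res.f_statistic, "p_adj": res.f_pvalue,
        })
        for c in res.comparisons:
            comp_rows.append({
                "contrast": f"{c.contrast[0]} vs {c.contrast[1]} (loss_pct)",
                "method": c.method, "statistic": c.statistic, "p_adj": c.p_value,
            })

    return ExperimentSummary(
        loss_table=pd.DataFrame(loss_rows),
        bout_table=pd.DataFrame(bout_rows),
        comparison_table=pd.DataFrame(comp_rows),
    )
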