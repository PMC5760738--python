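"""Hypothesis tests and the spatiotemporal classification of gut dynamics.

Two empirical signals feed a 2×2 decision table: whether the proportion of
ingested bacteria that is egested is significantly below 1 (one-sample t
test on replicate-day means), and whether the bacterial egestion-time
statistics are significantly reduced relative to the co-ingested
microsphere control (paired t tests on per-sample mean and variance). The
four cells correspond to passive transit, abrupt localized loss (a fast,
spatially confined killing/retention zone barely perturbs egestion times),
gradual widespread loss (loss along the whole gut shortens and narrows the
egestion-time distribution), and widespread loss that the egested totals
alone fail to flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .egestion import (
    FecalTimeSeries,
    InoculumComposition,
    day_average,
    proportion_ingested_egested,
    sample_stats,
)
from .errors import DegenerateDataError, ValidationError
from .phase_model import EgestionStats

__all__ = [
    "CATEGORY_PASSIVE",
    "CATEGORY_ABRUPT",
    "CATEGORY_GRADUAL",
    "CATEGORY_MASKED",
    "TestResult",
    "InferenceResult",
    "test_proportion_vs_one",
    "paired_stats_test",
    "presence_absence_test",
    "classify_dynamics",
    "analyze_samples",
]

logger = logging.getLogger(__name__)

CATEGORY_PASSIVE = "passive transit / no detectable loss"
CATEGORY_ABRUPT = "abrupt localized loss"
CATEGORY_GRADUAL = "gradual widespread loss"
CATEGORY_MASKED = "widespread loss masked in totals"


@dataclass(frozen=True)
class TestResult:
    """A t-test outcome with the point estimate and 95% CI of its effect."""

    statistic: float
    pvalue: float
    estimate: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValidationError(f"p value {self.pvalue} outside [0, 1]")


@dataclass
class InferenceResult:
    """Per-treatment test battery and the resulting spatiotemporal category."""

    treatment: str
    proportion_test: TestResult
    mean_test: TestResult
    variance_test: TestResult
    prop_below_1: bool
    stats_reduced: bool
    category: str
    n_samples: int
    n_days: int


def test_proportion_vs_one(day_means: Sequence[float]) -> TestResult:
    """Two-sided one-sample t test of the day-mean proportions against 1."""
    vals = np.asarray(list(day_means), dtype=float)
    if vals.size < 2:
        raise DegenerateDataError("need >= 2 replicate-day means")
    if np.std(vals, ddof=1) == 0.0:
        if vals[0] == 1.0:
            return TestResult(0.0, 1.0, 1.0, 1.0, 1.0)
        raise DegenerateDataError(
            "zero variance across day means; t test undefined"
        )
    res = sps.ttest_1samp(vals, popmean=1.0)
    ci = res.confidence_interval(0.95)
    return TestResult(
        float(res.statistic), float(res.pvalue), float(vals.mean()),
        float(ci.low), float(ci.high),
    )


def paired_stats_test(
    bacteria_stats: Sequence[EgestionStats],
    sphere_stats: Sequence[EgestionStats],
) -> dict[str, TestResult]:
    """Paired t tests of per-sample egestion statistics, bacteria vs spheres.

    The reported effect is the control-minus-bacteria difference
    (μ₀ − μ_b and σ₀² − σ_b²), so a positive estimate means the bacterial
    statistic is *reduced* relative to passive transit. Returns results
    keyed ``"mean"`` and ``"variance"``.
    """
    if len(bacteria_stats) != len(sphere_stats):
        raise ValidationError("bacteria and sphere stats must be matched")
    if len(bacteria_stats) < 2:
        raise DegenerateDataError("need >= 2 matched pairs")
    out = {}
    for key, attr in (("mean", "mean"), ("variance", "variance")):
        b = np.array([getattr(s, attr) for s in bacteria_stats])
        c = np.array([getattr(s, attr) for s in sphere_stats])
        diff = c - b
        if np.std(diff, ddof=1) == 0.0:
            if np.allclose(diff, 0.0):
                out[key] = TestResult(0.0, 1.0, 0.0, 0.0, 0.0)
                continue
            raise DegenerateDataError(
                f"constant nonzero paired {key} difference; t test undefined"
            )
        res = sps.ttest_rel(c, b)
        ci = res.confidence_interval(0.95)
        out[key] = TestResult(
            float(res.statistic), float(res.pvalue), float(diff.mean()),
            float(ci.low), float(ci.high),
        )
    return out


def presence_absence_test(pos_a: int, n_a: int, pos_b: int, n_b: int) -> float:
    """Two-sided Fisher exact p for presence/absence counts in two groups.

    Exact hypergeometric method: the p value sums all 2×2 tables with the
    observed margins whose probability does not exceed the observed
    table's.
    """
    if not (0 <= pos_a <= n_a and 0 <= pos_b <= n_b):
        raise ValidationError("positives cannot exceed totals")
    table = [[pos_a, n_a - pos_a], [pos_b, n_b - pos_b]]
    return float(sps.fisher_exact(table, alternative="two-sided").pvalue)


def classify_dynamics(
    prop_significantly_below_1: bool, stats_significantly_reduced: bool
) -> str:
    """Map the two significance flags to a spatiotemporal category."""
    if prop_significantly_below_1:
        return CATEGORY_GRADUAL if stats_significantly_reduced else CATEGORY_ABRUPT
    return CATEGORY_MASKED if stats_significantly_reduced else CATEGORY_PASSIVE


def _stats_reduced(
    mean_test: TestResult, variance_test: TestResult, alpha: float, rule: str
) -> bool:
    hits = [
        t.pvalue < alpha and t.estimate > 0 for t in (mean_test, variance_test)
    ]
    if rule == "or":
        return any(hits)
    if rule == "and":
        return all(hits)
    raise ValidationError(f"unknown combination rule {rule!r}")


def analyze_samples(
    samples: Sequence[FecalTimeSeries],
    inoculum: Mapping[str, InoculumComposition],
    alpha: float = 0.05,
    bin_convention: str = "endpoint",
    rule: str = "or",
) -> tuple[pd.DataFrame, list[InferenceResult]]:
    """Run the full egestion pipeline and classify each treatment.

    Per sample: hourly distributions, egestion statistics for both particle
    classes, and the proportion ingested-egested. Proportions are averaged
    within replicate days before the test against 1; the paired statistic
    tests use per-sample pairs. Samples with a zero 5-h total in either
    class are excluded (logged). Returns the per-sample table and one
    :class:`InferenceResult` per treatment.
    """
    rows = []
    kept: dict[str, list[FecalTimeSeries]] = {}
    for s in samples:
        try:
            stats_b, stats_s = sample_stats(s, bin_convention)
            prop = proportion_ingested_egested(
                sum(s.bacteria_counts), sum(s.sphere_counts), inoculum[s.treatment]
            )
        except DegenerateDataError as exc:
            logger.info("excluding sample: %s", exc)
            continue
        kept.setdefault(s.treatment, []).append(s)
        rows.append(
            {
                "sample_id": s.sample_id,
                "treatment": s.treatment,
                "replicate_day": s.replicate_day,
                "n_flies": s.n_flies,
                "mu_b": stats_b.mean,
                "sigma2_b": stats_b.variance,
                "mu_0": stats_s.mean,
                "sigma2_0": stats_s.variance,
                "mu_norm": stats_b.mean / stats_s.mean,
                "sigma2_norm": (
                    stats_b.variance / stats_s.variance
                    if stats_s.variance > 0
                    else math.nan
                ),
                "proportion_egested": prop,
            }
        )
    per_sample = pd.DataFrame(rows)
    if per_sample.empty:
        raise DegenerateDataError("no analyzable samples")
    results = []
    for treatment, group in per_sample.groupby("treatment", sort=True):
        by_day: dict[Hashable, list[float]] = {}
        for _, row in group.iterrows():
            by_day.setdefault(row["replicate_day"], []).append(
                row["proportion_egested"]
            )
        day_means = day_average(by_day)
        prop_test = test_proportion_vs_one(list(day_means.values()))
        b_stats = [
            EgestionStats(m, v) for m, v in zip(group["mu_b"], group["sigma2_b"])
        ]
        s_stats = [
            EgestionStats(m, v) for m, v in zip(group["mu_0"], group["sigma2_0"])
        ]
        paired = paired_stats_test(b_stats, s_stats)
        prop_below = prop_test.pvalue < alpha and prop_test.estimate < 1.0
        reduced = _stats_reduced(paired["mean"], paired["variance"], alpha, rule)
        results.append(
            InferenceResult(
                treatment=str(treatment),
                proportion_test=prop_test,
                mean_test=paired["mean"],
                variance_test=paired["variance"],
                prop_below_1=prop_below,
                stats_reduced=reduced,
                category=classify_dynamics(prop_below, reduced),
                n_samples=len(group),
                n_days=len(day_means),
            )
        )
    return per_sample, results


def results_table(results: Sequence[InferenceResult]) -> pd.DataFrame:
    """Flatten inference results to one row per treatment."""
    rows = []
    for r in results:
        rows.append(
            {
                "treatment": r.treatment,
                "proportion_mean": r.proportion_test.estimate,
                "proportion_t": r.proportion_test.statistic,
                "proportion_p": r.proportion_test.pvalue,
                "mean_diff": r.mean_test.estimate,
                "mean_ci_low": r.mean_test.ci_low,
                "mean_ci_high": r.mean_test.ci_high,
                "mean_p": r.mean_test.pvalue,
                "variance_diff": r.variance_test.estimate,
                "variance_ci_low": r.variance_test.ci_low,
                "variance_ci_high": r.variance_test.ci_high,
                "variance_p": r.variance_test.pvalue,
                "prop_below_1": r.prop_below_1,
                "stats_reduced": r.stats_reduced,
                "category": r.category,
                "n_samples": r.n_samples,
                "n_days": r.n_days,
            }
        )
    return pd.DataFrame(rows)


def normalized_stats_anova(per_sample: pd.DataFrame, response: str = "mu_norm"):
    """Thin pass-through to a standard two-way ANOVA on normalized statistics.

    Expects per-sample rows whose ``treatment`` encodes density (L/H) and
    host status (A/G) as the first/second characters (LA, HA, LG, HG).
    Requires statsmodels; off the tested surface by design — the routine
    computation is delegated wholesale.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = per_sample.copy()
    df["density"] = df["treatment"].str[0]
    df["host"] = df["treatment"].str[1]
    model = smf.ols(f"{response} ~ density * host", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)
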