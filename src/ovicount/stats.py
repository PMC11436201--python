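"""Fecundity statistics: inclusion rules, summaries, pairwise tests, power.

The assay houses two females and one male per well; egg counts are only
meaningful while both females are alive, so a condition-day is dropped
entirely unless both females survived in at least half of its wells, and
within a retained condition-day only both-alive wells are counted. Counts
are summarized as mean, sd and coefficient of variation per condition-day;
conditions are compared by pairwise t-tests (Welch by default) with a
Bonferroni correction over the comparisons requested together. A
resampling-based power analysis repeatedly subsamples k wells per group
and re-tests, estimating how many replicate wells suffice to detect an
effect. A seeded negative-binomial count simulator generates data in the
same table schemas for testing and calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConditionSummary",
    "PairwiseTestResult",
    "DownsampleResult",
    "SyntheticCountModel",
    "apply_inclusion_rules",
    "summarize",
    "pairwise_tests",
    "downsample_power",
    "simulate_counts",
]


@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    day: int
    n_wells: int
    mean: float
    sd: float
    cv: float | None  # None (flagged undefined) when mean == 0


@dataclass(frozen=True)
class PairwiseTestResult:
    group_a: str
    group_b: str
    t: float
    df: float
    p_raw: float
    p_adj: float
    m: int  # size of the Bonferroni family
    stars: str
    skipped: bool = False


@dataclass(frozen=True)
class DownsampleResult:
    k: int
    n_iterations: int
    p_values: np.ndarray
    alpha: float
    seed: int

    @property
    def fraction_significant(self) -> float:
        return float(np.mean(self.p_values < self.alpha))


@dataclass(frozen=True)
class SyntheticCountModel:
    """Per-condition count distributions plus per-female daily survival.

    Defaults emulate the assay's observed day-1 behaviour: mean ~36
    eggs/well with coefficient of variation ~0.63, i.e. strong interwell
    overdispersion, modelled as negative binomial with dispersion theta
    (variance = mu + mu^2/theta; theta ~ 2.7 reproduces that CV).
    """

    condition_means: Mapping[str, float] = field(
        default_factory=lambda: {"control": 36.0}
    )
    dispersion: float | None = 2.7  # None -> Poisson
    survival_p: float = 1.0  # per female, per day
    n_females: int = 2

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.condition_means.values()):
            raise ValueError("means must be non-negative")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def _draw_counts(rng: np.random.Generator, mean: float, dispersion: float | None, n: int) -> np.ndarray:
    if mean == 0:
        return np.zeros(n, dtype=int)
    if dispersion is None:
        return rng.poisson(mean, size=n)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n)


def apply_inclusion_rules(
    survival: pd.DataFrame, counts: pd.DataFrame
) -> tuple[pd.DataFrame, list[tuple[str, int]]]:
    """Filter counts by the both-females-alive rule.

    A (condition, day) group is excluded entirely iff the number of wells
    with both females alive is below ceil(n_wells/2); in retained groups
    exactly the both-alive wells are kept. Returns the filtered counts and
    the list of excluded (condition, day) groups. Count rows without a
    matching survival row are a hard error.
    """
    keys = ["condition", "day", "well_label"]
    merged = counts.merge(
        survival[keys + ["n_females_alive"]], on=keys, how="left", validate="one_to_one"
    )
    missing = merged[merged["n_females_alive"].isna()]
    if len(missing):
        wells = missing[keys].to_dict("records")
        raise ValueError(f"count rows without survival records: {wells}")

    excluded: list[tuple[str, int]] = []
    kept_parts = []
    for (cond, day), grp in merged.groupby(["condition", "day"], sort=False):
        n = len(grp)
        both_alive = grp["n_females_alive"] == 2
        if int(both_alive.sum()) < math.ceil(n / 2):
            excluded.append((cond, int(day)))
            continue
        kept_parts.append(grp[both_alive])
    if kept_parts:
        kept = pd.concat(kept_parts).drop(columns="n_females_alive").reset_index(drop=True)
    else:
        kept = counts.iloc[0:0].copy()
    return kept, excluded


def summarize(counts: pd.DataFrame) -> list[ConditionSummary]:
    """Mean, sample sd (ddof=1) and CV = sd/mean per (condition, day)."""
    out = []
    for (cond, day), grp in counts.groupby(["condition", "day"], sort=True):
        vals = grp["count"].to_numpy(dtype=float)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        cv = sd / mean if mean > 0 else None
        out.append(ConditionSummary(str(cond), int(day), len(vals), mean, sd, cv))
    return out


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _t_test(a: np.ndarray, b: np.ndarray, welch: bool) -> tuple[float, float, float]:
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        # identical constant groups: no evidence of difference
        df = len(a) + len(b) - 2
        return 0.0, float(df), 1.0
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


def pairwise_tests(
    groups: Mapping[str, Sequence[float]],
    comparisons: Sequence[tuple[str, str]] | None = None,
    welch: bool = True,
) -> list[PairwiseTestResult]:
    """Two-sample t-tests with a Bonferroni correction.

    The Bonferroni family is the set of comparisons requested in one call
    (m = number of non-skipped comparisons): adjusted p = min(1, m * p).
    Welch's unequal-variance test is the default; ``welch=False`` gives the
    pooled-variance test. Groups with fewer than 2 wells are skipped with a
    flag rather than failing the whole family.
    """
    if comparisons is None:
        names = list(groups)
        comparisons = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    runnable = [
        (a, b) for a, b in comparisons if len(groups[a]) >= 2 and len(groups[b]) >= 2
    ]
    m = len(runnable)
    results = []
    for a, b in comparisons:
        if (a, b) not in runnable:
            results.append(
                PairwiseTestResult(a, b, math.nan, math.nan, math.nan, math.nan, m, "", True)
            )
            continue
        t, df, p = _t_test(
            np.asarray(groups[a], dtype=float), np.asarray(groups[b], dtype=float), welch
        )
        p_adj = min(1.0, m * p)
        results.append(PairwiseTestResult(a, b, t, df, p, p_adj, m, _stars(p_adj)))
    return results


def tests_to_frame(results: Sequence[PairwiseTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "comparison": f"{r.group_a} vs {r.group_b}",
                "t": r.t, "df": r.df, "p_raw": r.p_raw, "p_adj": r.p_adj,
                "stars": r.stars, "skipped": r.skipped,
            }
            for r in results
        ]
    )


def downsample_power(
    control: Sequence[float],
    treated: Sequence[float],
    k: int,
    n_iter: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    welch: bool = True,
) -> DownsampleResult:
    """Power by downsampling: subsample k wells per group, re-test, repeat.

    Each iteration draws k wells without replacement independently from
    each group, runs the two-sample t-test and records the raw p-value;
    the fraction of iterations with p < alpha estimates the power at k
    replicate wells. Deterministic for a fixed seed.
    """
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > min(len(control), len(treated)):
        raise ValueError(
            f"k={k} exceeds a group size ({len(control)}, {len(treated)})"
        )
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    rng = np.random.default_rng(seed)
    p_values = np.empty(n_iter)
    for i in range(n_iter):
        sub_c = rng.choice(control, size=k, replace=False)
        sub_t = rng.choice(treated, size=k, replace=False)
        _, _, p_values[i] = _t_test(sub_c, sub_t, welch)
    return DownsampleResult(k, n_iter, p_values, alpha, seed)


def downsample_to_frame(results: Sequence[DownsampleResult]) -> pd.DataFrame:
    """Long-format (k, iteration, p) table across subset sizes."""
    rows = []
    for res in results:
        for i, p in enumerate(res.p_values):
            rows.append({"k": res.k, "iteration": i, "p": float(p)})
    return pd.DataFrame(rows)


def simulate_counts(
    model: SyntheticCountModel,
    n_wells: int = 16,
    days: Sequence[int] = (1,),
    seed: int = 0,
    plate_id: str = "sim01",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate survival and count tables in the pipeline's CSV schemas.

    Per condition-day, each of the two females survives independently with
    ``survival_p ** day``; counts are drawn for every well (wells with dead
    females are later removed by the inclusion rule, mirroring how records
    are collected before exclusion).
    """
    rng = np.random.default_rng(seed)
    surv_rows, count_rows = [], []
    for cond, mean in model.condition_means.items():
        for day in days:
            p_day = model.survival_p ** day
            alive = rng.binomial(model.n_females, p_day, size=n_wells)
            counts = _draw_counts(rng, mean, model.dispersion, n_wells)
            for w in range(n_wells):
                label = f"{cond[:1].upper()}{w + 1}"
                surv_rows.append(
                    {
                        "plate_id": plate_id, "well_label": label, "condition": cond,
                        "day": day, "n_females_alive": int(alive[w]), "n_males_alive": 1,
                    }
                )
                count_rows.append(
                    {
                        "plate_id": plate_id, "well_label": label, "condition": cond,
                        "day": day, "count": int(counts[w]),
                        "n_prefilter": int(counts[w]), "flags": "",
                    }
                )
    return pd.DataFrame(surv_rows), pd.DataFrame(count_rows)
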