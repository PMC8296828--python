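"""Cohort phenotyping: prone/resistant assignment, group summaries, qPCR, screens.

Animals are tracked over a treatment course (day 0 .. last day) with body
weight and daily food intake.  Weight gain is defined as last-day weight
minus day-0 weight; the k largest gainers form the "prone" cohort and the
k smallest the "resistant" cohort (ties broken by ascending animal id).

Relative qPCR expression uses the comparative-Ct (delta-delta-Ct) method:
dCt = Ct_target - mean(Ct_housekeeping) per sample, ddCt = dCt minus the
reference group's mean dCt, RQ = 2 ** -ddCt.  Housekeeping Ct values are
aggregated by arithmetic mean (the geometric mean of expression levels).

Per-gene two-group comparisons use Welch's unequal-variance t-test with
two-sided p-values; multiplicity is handled by the two-stage adaptive
linear step-up FDR procedure (Benjamini, Krieger & Yekutieli) at a
configurable level (default 0.10).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bky_reject

log = logging.getLogger(__name__)

COHORT_COLUMNS = ("animal_id", "day", "body_weight", "intake")
QPCR_COLUMNS = ("sample_id", "group", "gene", "ct")


def validate_cohort_table(cohort: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if (cohort["body_weight"] <= 0).any():
        raise ValueError("cohort table has non-positive body weights")
    if cohort.duplicated(subset=["animal_id", "day"]).any():
        raise ValueError("more than one weight per (animal, day)")
    return cohort


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return validate_cohort_table(pd.read_csv(path, comment="#"))


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    validate_cohort_table(cohort)
    cohort.to_csv(path, index=False, columns=list(COHORT_COLUMNS))


def assign_cohorts(
    cohort: pd.DataFrame, k: int = 5
) -> tuple[list[str], list[str], pd.Series]:
    """Split animals into the k most and k least weight-gaining cohorts.

    Weight gain is weight(last day) - weight(day 0).  Returns
    (prone ids, resistant ids, per-animal weight gain); ties at either
    boundary are broken by ascending animal id so row order never matters.
    """
    validate_cohort_table(cohort)
    animals = sorted(cohort["animal_id"].unique())
    if len(animals) < 2 * k:
        raise ValueError(
            f"need at least {2 * k} animals for k={k}, got {len(animals)}"
        )
    first_day = int(cohort["day"].min())
    last_day = int(cohort["day"].max())
    wide = cohort.pivot(index="animal_id", columns="day", values="body_weight")
    for day in (first_day, last_day):
        absent = wide.index[wide[day].isna()] if day in wide else wide.index
        if len(absent):
            raise ValueError(
                f"animal {list(absent)[0]!r} has no weight on day {day}"
            )
    delta = (wide[last_day] - wide[first_day]).rename("delta_weight")
    # one global ordering (descending gain, ascending id) so boundary ties
    # resolve deterministically and the two cohorts can never overlap
    order = delta.reset_index().sort_values(
        ["delta_weight", "animal_id"], ascending=[False, True], kind="mergesort"
    )["animal_id"].tolist()
    prone = sorted(order[:k])
    resistant = sorted(order[-k:])
    return prone, resistant, delta


@dataclass(frozen=True)
class GroupSummary:
    """Per-group mean/SEM/n plus the percent difference of the group means."""

    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    percent_difference: float

    @property
    def percent_difference_int(self) -> int:
        return int(round(self.percent_difference))


def group_summary(
    values: Mapping[str, float] | pd.Series,
    group_a: Iterable[str],
    group_b: Iterable[str],
) -> GroupSummary:
    """Summarize one per-animal quantity in two groups.

    Percent difference is 100 * (mean_a - mean_b) / mean_b, i.e. how much
    larger group A's mean is relative to group B's, reported both
    unrounded and rounded to the nearest integer.
    """
    values = pd.Series(values, dtype=float)
    a = values.loc[list(group_a)]
    b = values.loc[list(group_b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pct = 100.0 * (a.mean() - b.mean()) / b.mean()
    return GroupSummary(
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sem_a=float(a.sem()) if len(a) > 1 else 0.0,
        sem_b=float(b.sem()) if len(b) > 1 else 0.0,
        n_a=int(len(a)), n_b=int(len(b)),
        percent_difference=float(pct),
    )


def mean_daily_intake(cohort: pd.DataFrame) -> pd.Series:
    """Per-animal mean daily food intake over the whole course."""
    validate_cohort_table(cohort)
    return cohort.groupby("animal_id")["intake"].mean()


def validate_qpcr_table(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in QPCR_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"qPCR table missing columns: {missing}")
    if not np.isfinite(records["ct"]).all():
        raise ValueError("qPCR table has non-finite Ct values")
    return records


def ddct_relative_expression(
    records: pd.DataFrame,
    housekeeping: Sequence[str],
    reference_group: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Comparative-Ct relative quantification.

    Returns (per-sample table with dCt, ddCt and RQ for every non-
    housekeeping gene; per (group, gene) mean RQ).  By construction the
    reference group's mean ddCt is 0 per gene, so its geometric-mean RQ
    is 1.
    """
    validate_qpcr_table(records)
    hk = set(housekeeping)
    if not hk:
        raise ValueError("at least one housekeeping gene is required")
    wide = records.pivot_table(index=["sample_id", "group"], columns="gene",
                               values="ct")
    missing_hk = [g for g in housekeeping if g not in wide.columns]
    if missing_hk:
        raise ValueError(f"housekeeping genes absent from table: {missing_hk}")
    if wide[list(housekeeping)].isna().any().any():
        bad = wide[list(housekeeping)].isna().any(axis=1)
        raise ValueError(
            f"samples missing housekeeping Ct: "
            f"{[i[0] for i in wide.index[bad]][:5]}"
        )
    hk_mean = wide[list(housekeeping)].mean(axis=1)
    targets = [g for g in wide.columns if g not in hk]
    long = []
    for gene in targets:
        if wide[gene].isna().any():
            bad = wide.index[wide[gene].isna()]
            raise ValueError(
                f"sample {bad[0][0]!r} missing Ct for gene {gene!r}"
            )
        dct = wide[gene] - hk_mean
        ref = dct.xs(reference_group, level="group")
        if ref.empty:
            raise ValueError(f"reference group {reference_group!r} not present")
        ddct = dct - ref.mean()
        rq = 2.0 ** (-ddct)
        sub = pd.DataFrame(
            {
                "gene": gene,
                "dct": dct,
                "ddct": ddct,
                "rq": rq,
            }
        ).reset_index()
        long.append(sub)
    per_sample = pd.concat(long, ignore_index=True)
    per_group = (
        per_sample.groupby(["group", "gene"])["rq"]
        .agg(["mean", "sem", "count"])
        .rename(columns={"mean": "mean_rq", "count": "n"})
        .reset_index()
    )
    return per_sample, per_group


def welch_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch unequal-variance t-test; returns (t, df, two-sided p).

    Degenerate zero-variance-in-both-groups input yields p = 1 when the
    means agree and raises otherwise (the difference is then exact and a
    t-statistic undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def welch_bky_screen(
    groups: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Per-gene Welch t-tests with two-stage adaptive FDR rejection flags.

    ``groups`` maps gene -> (group-1 values, group-2 values).  Returns a
    table with t, df, p and the rejection flag at the given FDR level,
    computed across all genes of the screen in one batch.
    """
    if not (0 < fdr < 1):
        raise ValueError(f"fdr must be in (0, 1), got {fdr}")
    rows = []
    for gene, (a, b) in groups.items():
        t, df, p = welch_test(np.asarray(a), np.asarray(b))
        rows.append({"gene": gene, "t": t, "df": df, "p": p})
    tab = pd.DataFrame(rows)
    tab["reject"] = bky_reject(tab["p"].to_numpy(), fdr=fdr)
    return tab


def shapiro_normality(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk normality pre-test (statistic, p); informational gate
    only — the screen itself never branches on it."""
    res = stats.shapiro(np.asarray(values, dtype=float))
    return float(res.statistic), float(res.pvalue)
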