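"""Group summaries and genotype comparisons.

Per-stage parameter values are summarized as mean ± s.e.m. and compared
between genotypes with an unpaired two-tailed Student's t-test
(pooled variance; Welch available behind a flag).  Raw p-values are
reported without multiple-testing correction, annotated with the usual
star code (* p<0.05, ** p<0.01, *** p<0.001).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InputError
from .io import ParamTable

logger = logging.getLogger(__name__)

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "mean_sem",
    "students_t_test",
    "survival_fraction",
    "compare_groups",
    "star_code",
]

#: Numeric ParamTable columns eligible for group comparison.
COMPARABLE_PARAMS = (
    "hr_bpm", "cap_pct", "edd_x_um", "edd_z_um", "esd_x_um", "esd_z_um",
    "eda_um2", "esa_um2", "fs_x_pct", "fs_z_pct", "fs_area_pct",
)


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sem: float  # NaN (flagged undefined) when n == 1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InputError("group size must be >= 1")


@dataclass(frozen=True)
class ComparisonResult:
    parameter: str
    stage: str
    t_statistic: float
    df: float
    p_value: float
    stars: str


def star_code(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def mean_sem(values) -> tuple[float, float]:
    """Mean and standard error (sample SD with n-1 denominator over sqrt n).

    With a single value the s.e.m. is undefined and returned as NaN.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise InputError("cannot summarize an empty group")
    if vals.size == 1:
        return float(vals[0]), float("nan")
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(vals.size))


def students_t_test(group_a, group_b, *, parameter: str = "", stage: str = "",
                    welch: bool = False) -> ComparisonResult:
    """Two-sample two-tailed t-test between independent groups.

    Pooled-variance by default (classical Student's test, df = n_a+n_b-2);
    ``welch=True`` switches to the unequal-variance form.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least 2 values for a t-test")
    import warnings as _warnings
    with _warnings.catch_warnings():
        # identical constant groups trip a scipy precision warning; the
        # resulting nan is coerced to (t=0, p=1) below
        _warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(a, b, equal_var=not welch)
    t = float(res.statistic)
    p = float(res.pvalue)
    df = float(res.df)
    if np.isnan(t):  # both groups constant and identical
        t, p = 0.0, 1.0
    return ComparisonResult(parameter=parameter, stage=stage, t_statistic=t,
                            df=df, p_value=p, stars=star_code(p))


def survival_fraction(n_survived: int, n_total: int) -> float:
    """Percentage of animals surviving to adulthood (full precision).

    Report rounded to integer percent: ``round(survival_fraction(28, 1235))``
    gives 2.
    """
    if n_total <= 0:
        raise InputError("n_total must be > 0")
    if not 0 <= n_survived <= n_total:
        raise InputError(f"need 0 <= n_survived <= n_total, got {n_survived}/{n_total}")
    return 100.0 * n_survived / n_total


def compare_groups(table_a: ParamTable, table_b: ParamTable, *,
                   parameters=COMPARABLE_PARAMS,
                   welch: bool = False) -> list[ComparisonResult]:
    """One t-test per (parameter, shared stage) between two parameter tables.

    Stages present in only one table are skipped; (parameter, stage) cells
    with fewer than two finite values in either group are skipped with a
    log message.  Raw p-values, no multiple-testing correction.
    """
    stages_a = set(table_a.frame["stage_label"])
    stages_b = set(table_b.frame["stage_label"])
    shared = sorted(stages_a & stages_b)
    if not shared:
        raise InputError("tables share no stage labels")
    results: list[ComparisonResult] = []
    for stage in shared:
        sub_a = table_a.frame[table_a.frame["stage_label"] == stage]
        sub_b = table_b.frame[table_b.frame["stage_label"] == stage]
        for param in parameters:
            a = sub_a[param].to_numpy(dtype=float)
            b = sub_b[param].to_numpy(dtype=float)
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            if a.size < 2 or b.size < 2:
                logger.info("skipping %s at %s: insufficient finite values", param, stage)
                continue
            results.append(students_t_test(a, b, parameter=param, stage=stage,
                                           welch=welch))
    return results
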