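"""Two-sample comparisons: Brunner–Munzel, pooled-variance Student's t and
boxplot summaries.

The Brunner–Munzel statistic is implemented from rank arithmetic (mid-ranks
for ties) rather than delegated, so it can be validated against an
independent implementation. Both tests report two-sided p-values; no
multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.stats import rankdata

from .exceptions import DegenerateTestError, InvalidInputError


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: float | None
    n1: int
    n2: int
    method: str
    relative_effect: float | None = None
    degenerate: bool = False


def brunner_munzel(x, y) -> TestResult:
    """Brunner–Munzel test of the relative effect P(X < Y) + 0.5 P(X = Y).

    Mid-ranks handle ties; the studentised statistic is referred to a t
    distribution with Welch-type degrees of freedom. Identical samples with
    zero rank variance return statistic 0, p = 1 flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise InvalidInputError("both samples need at least 2 observations")
    if n1 < 10 or n2 < 10:
        warnings.warn(
            "Brunner-Munzel small-sample approximation: n < 10 in one group",
            stacklevel=2,
        )
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # mid-ranks
    rx, ry = ranks[:n1], ranks[n1:]
    rx_internal = rankdata(x)
    ry_internal = rankdata(y)
    rx_mean = rx.mean()
    ry_mean = ry.mean()

    relative_effect = (ry_mean - (n2 + 1) / 2.0) / n1

    sx2 = np.sum((rx - rx_internal - rx_mean + (n1 + 1) / 2.0) ** 2) / (n1 - 1)
    sy2 = np.sum((ry - ry_internal - ry_mean + (n2 + 1) / 2.0) ** 2) / (n2 - 1)

    nsx = n1 * sx2
    nsy = n2 * sy2
    if nsx == 0 and nsy == 0:
        if np.array_equal(np.sort(x), np.sort(y)) or relative_effect == 0.5:
            return TestResult(
                statistic=0.0,
                p_value=1.0,
                df=None,
                n1=n1,
                n2=n2,
                method="brunner-munzel",
                relative_effect=float(relative_effect),
                degenerate=True,
            )
        raise DegenerateTestError("zero rank variance in both samples")

    statistic = n1 * n2 * (ry_mean - rx_mean) / ((n1 + n2) * np.sqrt(nsx + nsy))
    df = (nsx + nsy) ** 2 / (nsx**2 / (n1 - 1) + nsy**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(statistic), df)
    return TestResult(
        statistic=float(statistic),
        p_value=float(min(p, 1.0)),
        df=float(df),
        n1=n1,
        n2=n2,
        method="brunner-munzel",
        relative_effect=float(relative_effect),
    )


def student_t(x, y) -> TestResult:
    """Classical pooled-variance two-sample t-test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise InvalidInputError("both samples need at least 2 observations")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        if x.mean() == y.mean():
            return TestResult(
                statistic=0.0,
                p_value=1.0,
                df=float(df),
                n1=n1,
                n2=n2,
                method="student-t",
                degenerate=True,
            )
        raise DegenerateTestError("zero pooled variance with unequal means")
    statistic = (x.mean() - y.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(statistic), df)
    return TestResult(
        statistic=float(statistic),
        p_value=float(min(p, 1.0)),
        df=float(df),
        n1=n1,
        n2=n2,
        method="student-t",
    )


@dataclass
class BoxplotSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def boxplot_summary(values) -> BoxplotSummary:
    """Median/quartiles (linear interpolation), 1.5-IQR whiskers, outliers."""
    values = np.asarray(values, dtype=float)
    if len(values) < 1:
        raise InvalidInputError("need at least one value")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = values[(values < lo_fence) | (values > hi_fence)]
    return BoxplotSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
    )
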