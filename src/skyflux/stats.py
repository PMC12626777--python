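"""Geographic trend and season-comparison statistics on pipeline outputs.

Thin, explicit wrappers over statsmodels/scipy: ordinary
least-squares slopes of a station-level metric on latitude or
longitude with two-sided t-test p-values, and two-sample (pooled
variance) or paired t-tests for seasonal contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = ["TrendResult", "trend_slope", "SeasonComparison", "season_comparison"]


@dataclass
class TrendResult:
    response: str
    predictor: str  # 'latitude' | 'longitude'
    slope: float  # response units per degree
    intercept: float
    stderr: float
    p_value: float
    n: int


def trend_slope(coordinate, metric, response: str = "", predictor: str = "latitude") -> TrendResult:
    """OLS slope of a metric on a geographic coordinate.

    Requires at least three points with non-degenerate coordinate
    spread; the p-value is the two-sided t-test on the slope.
    """
    x = np.asarray(coordinate, dtype=float)
    y = np.asarray(metric, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need >= 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: no coordinate spread")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return TrendResult(
        response=response,
        predictor=predictor,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        stderr=float(res.bse[1]),
        p_value=float(res.pvalues[1]),
        n=int(x.size),
    )


@dataclass
class SeasonComparison:
    t_statistic: float
    df: int
    p_value: float
    paired: bool
    mean_difference: float


def season_comparison(values_a, values_b, paired: bool = False, welch: bool = False) -> SeasonComparison:
    """Compare a metric between two seasons.

    Unpaired mode uses the pooled-variance two-sample t-test
    (df = n1 + n2 - 2); ``welch=True`` switches to unequal variances.
    Paired mode requires equal-length matched samples and refuses
    zero-variance differences (degenerate test).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison needs matched samples of equal length")
        if a.size < 2:
            raise ValueError("need >= 2 pairs")
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0):
            raise ValueError("zero variance of paired differences: t-test degenerate")
        t, p = sps.ttest_rel(a, b)
        return SeasonComparison(float(t), a.size - 1, float(p), True, float(d.mean()))
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per group")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    df = a.size + b.size - 2 if not welch else int(sps.ttest_ind(a, b, equal_var=False).df)
    return SeasonComparison(float(t), df, float(p), False, float(a.mean() - b.mean()))
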