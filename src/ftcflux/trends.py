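"""Mann-Kendall trend test with tie-corrected variance and Sen's slope.

The test statistic is ``S = sum_{i<j} sign(x_j - x_i)``; under the null of
no trend its variance, corrected for tie groups of size t, is

    var(S) = [n (n-1) (2n+5) - sum_t t (t-1) (2t+5)] / 18,

and the continuity-corrected normal deviate is ``z = (S-1)/sqrt(var)`` for
S > 0, 0 for S = 0, ``(S+1)/sqrt(var)`` for S < 0.  Trends are classed as a
significant decrease (z < -1.96), significant increase (z > 1.96) or no
significant change otherwise (the closed interval is non-significant) —
the two-sided 5 % level.  Sen's slope (median pairwise slope) is reported
alongside as an effect size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

Z_THRESHOLD = 1.96
DEFAULT_MIN_N = 4

SIGNIFICANT_DECREASE = "significant_decrease"
NO_SIGNIFICANT_CHANGE = "no_significant_change"
SIGNIFICANT_INCREASE = "significant_increase"


@dataclass(frozen=True)
class TrendResult:
    n: int
    s: int
    var_s: float
    z: float
    p_two_sided: float
    klass: str
    sen_slope: float


def classify_trend(z: float) -> str:
    """Three-way trend class from the normal deviate at the 5 % level."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    if z > Z_THRESHOLD:
        return SIGNIFICANT_INCREASE
    if z < -Z_THRESHOLD:
        return SIGNIFICANT_DECREASE
    return NO_SIGNIFICANT_CHANGE


def mann_kendall(x, min_n: int = DEFAULT_MIN_N) -> TrendResult:
    """Mann-Kendall test of a (annual) value sequence.

    NaNs are dropped first.  Raises ``ValueError`` when fewer than ``min_n``
    values remain — short flux records cannot support a trend call.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < min_n:
        raise ValueError(f"mann_kendall: need >= {min_n} values, got {n}")
    diff = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diff, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    # Sen's slope: median of all pairwise slopes
    i, j = np.triu_indices(n, k=1)
    slopes = (x[j] - x[i]) / (j - i)
    sen = float(np.median(slopes)) if len(slopes) else float("nan")
    return TrendResult(n=n, s=s, var_s=float(var_s), z=float(z),
                       p_two_sided=float(p), klass=classify_trend(float(z)),
                       sen_slope=sen)


def site_trend_table(annual_series: dict[str, dict[str, "np.ndarray"]],
                     min_n: int = DEFAULT_MIN_N):
    """Trend results per site x metric, withholding short series with a reason.

    ``annual_series`` maps site_id -> metric name -> annual value sequence
    (e.g. metrics ``ftc_days``, ``rt_nee``, ``rt_re``).  Returns a tidy
    DataFrame; withheld rows have empty statistics and a ``reason``.
    """
    import pandas as pd

    rows = []
    for site_id, metrics in annual_series.items():
        for metric, values in metrics.items():
            base = {"site_id": site_id, "metric": metric}
            try:
                r = mann_kendall(values, min_n=min_n)
            except ValueError:
                vals = np.asarray(values, dtype=float)
                n_ok = int(np.sum(~np.isnan(vals)))
                rows.append({**base, "n": n_ok, "s": np.nan, "var_s": np.nan,
                             "z": np.nan, "p": np.nan, "sen_slope": np.nan,
                             "klass": "withheld",
                             "reason": f"fewer than {min_n} annual values"})
                continue
            rows.append({**base, "n": r.n, "s": r.s, "var_s": r.var_s, "z": r.z,
                         "p": r.p_two_sided, "sen_slope": r.sen_slope,
                         "klass": r.klass, "reason": ""})
    cols = ["site_id", "metric", "n", "s", "var_s", "z", "p", "sen_slope",
            "klass", "reason"]
    return pd.DataFrame(rows, columns=cols)
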