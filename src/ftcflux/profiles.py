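"""Site-record percentile profiles of the pre / during / post event phases.

Each variable's phase value (mean of non-missing daily values in the phase
window) is placed on the site's full monitoring record of that variable via
the mean-rank percentile, ``100 * (n_less + 0.5 * n_equal) / n``.  Ranking
the phase mean against the whole record standardizes across sites with very
different climates, so profiles can be pooled over the network.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .detection import FtcEvent
from .io import CANONICAL_VARIABLES, DailySeries

PHASES = ("pre", "during", "post")


def percentile_rank(record: np.ndarray, value: float) -> float:
    """Mean-rank percentile of ``value`` within ``record`` (non-missing)."""
    record = np.asarray(record, dtype=float)
    record = record[~np.isnan(record)]
    if record.size == 0:
        raise ValueError("percentile_rank: empty record")
    return float(stats.percentileofscore(record, value, kind="mean"))


def _phase_windows(event: FtcEvent) -> dict[str, tuple[pd.Timestamp, pd.Timestamp]]:
    return {
        "pre": (event.pre_start, event.pre_end),
        "during": (event.freeze_start, event.thaw_end),
        "post": (event.post_start, event.post_end),
    }


def event_phase_profile(
    event: FtcEvent, series: DailySeries, rank_daily: bool = False
) -> pd.DataFrame:
    """Percentile profile of one event: up to 9 variables x 3 phases.

    Rows where the phase window holds no data for that variable are omitted.
    With ``rank_daily=True`` the phase percentile is the mean of the daily
    percentiles instead of the percentile of the phase mean (sensitivity
    variant).

    Raises
    ------
    ValueError
        If the event window lies entirely outside the record.
    """
    idx = series.dates
    if len(idx) == 0 or event.thaw_end < idx[0] or event.freeze_start > idx[-1]:
        raise ValueError(f"event {event.event_id} lies outside the record")
    rows = []
    for var in CANONICAL_VARIABLES:
        col = series.data[var]
        record = col.to_numpy(dtype=float)
        if np.all(np.isnan(record)):
            continue
        for phase, (w0, w1) in _phase_windows(event).items():
            window = col.loc[max(w0, idx[0]) : min(w1, idx[-1])].dropna()
            if len(window) == 0:
                continue
            if rank_daily:
                pct = float(np.mean([percentile_rank(record, v) for v in window]))
                val = float(window.mean())
            else:
                val = float(window.mean())
                pct = percentile_rank(record, val)
            rows.append(
                {"site_id": event.site_id, "event_id": event.event_id,
                 "variable": var, "phase": phase, "value": val, "percentile": pct}
            )
    return pd.DataFrame(rows, columns=["site_id", "event_id", "variable", "phase",
                                       "value", "percentile"])


def aggregate_profiles(rows: pd.DataFrame) -> pd.DataFrame:
    """Mean percentile per (variable, phase), pooled and per site.

    Events are weighted equally.  Pooled rows carry site_id ``"ALL"``.
    """
    if len(rows) == 0:
        raise ValueError("aggregate_profiles: no profile rows")
    per_site = (
        rows.groupby(["site_id", "variable", "phase"], as_index=False)
        .agg(percentile=("percentile", "mean"), n_events=("event_id", "nunique"))
    )
    pooled = (
        rows.groupby(["variable", "phase"], as_index=False)
        .agg(percentile=("percentile", "mean"), n_events=("event_id", "nunique"))
    )
    pooled.insert(0, "site_id", "ALL")
    return pd.concat([pooled, per_site], ignore_index=True)


def plot_phase_summary(aggregate: pd.DataFrame, ax=None):
    """Minimal bar summary of pooled phase percentiles (one axis)."""
    import matplotlib.pyplot as plt

    pooled = aggregate[aggregate["site_id"] == "ALL"]
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3.5))
    width = 0.27
    variables = [v for v in CANONICAL_VARIABLES if v in set(pooled["variable"])]
    x = np.arange(len(variables))
    for k, phase in enumerate(PHASES):
        sub = pooled[pooled["phase"] == phase].set_index("variable")
        vals = [sub["percentile"].get(v, np.nan) for v in variables]
        ax.bar(x + (k - 1) * width, vals, width, label=phase)
    ax.axhline(50, color="grey", lw=0.8, ls=":")
    ax.set_xticks(x, variables)
    ax.set_ylabel("mean percentile")
    ax.legend(title="phase")
    return ax
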