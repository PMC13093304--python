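"""Event-level resistance of carbon fluxes to freeze-thaw perturbations.

Resistance is the flux change from the 10-day pre-event window to the event
window, per degree of soil-temperature change over the same windows:

    Rt_NEE = (NEE_during - NEE_pre) / (Ts_during - Ts_pre)
    Rt_RE  = (RE_during  - RE_pre)  / (Ts_during - Ts_pre)

in umol CO2 m-2 s-1 per degC.  A magnitude near zero means the flux barely
responded to the freeze-thaw temperature drop.  The "during" window spans
the full event (freeze onset through thaw confirmation).  Events whose
temperature contrast ``|delta_ts|`` falls below ``epsilon_ts`` (default
0.5 degC) are flagged invalid rather than producing near-singular ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import FtcEvent
from .io import DailySeries, SiteRecord

logger = logging.getLogger("ftcflux")

DEFAULT_EPSILON_TS = 0.5  # degC


@dataclass(frozen=True)
class ResistanceRecord:
    site_id: str
    event_id: str
    year: int
    nee_during: float
    re_during: float
    ts_during: float
    pre_nee: float
    pre_re: float
    pre_ts: float
    delta_ts: float
    rt_nee: float
    rt_re: float
    valid: bool


def _window_mean(col: pd.Series, w0: pd.Timestamp, w1: pd.Timestamp) -> float:
    vals = col.loc[w0:w1].dropna()
    return float(vals.mean()) if len(vals) else float("nan")


def event_resistance(
    event: FtcEvent, series: DailySeries, epsilon_ts: float = DEFAULT_EPSILON_TS
) -> ResistanceRecord:
    """Resistance ratios for one event.

    The record is marked invalid (ratios NaN) when the pre-window is
    truncated, any window mean is undefined, or ``|delta_ts| < epsilon_ts``.
    """
    during = {v: _window_mean(series.data[v], event.freeze_start, event.thaw_end)
              for v in ("nee", "re", "ts")}
    pre = {v: _window_mean(series.data[v], event.pre_start, event.pre_end)
           for v in ("nee", "re", "ts")}
    delta_ts = during["ts"] - pre["ts"]
    valid = (
        event.pre_ok
        and all(np.isfinite(v) for v in during.values())
        and all(np.isfinite(v) for v in pre.values())
        and abs(delta_ts) >= epsilon_ts
    )
    if valid:
        rt_nee = (during["nee"] - pre["nee"]) / delta_ts
        rt_re = (during["re"] - pre["re"]) / delta_ts
    else:
        rt_nee = rt_re = float("nan")
    return ResistanceRecord(
        site_id=event.site_id,
        event_id=event.event_id,
        year=int(event.freeze_start.year),
        nee_during=during["nee"],
        re_during=during["re"],
        ts_during=during["ts"],
        pre_nee=pre["nee"],
        pre_re=pre["re"],
        pre_ts=pre["ts"],
        delta_ts=delta_ts,
        rt_nee=rt_nee,
        rt_re=rt_re,
        valid=valid,
    )


def records_to_frame(records: list[ResistanceRecord]) -> pd.DataFrame:
    cols = ["site_id", "event_id", "year", "nee_during", "re_during", "ts_during",
            "pre_nee", "pre_re", "pre_ts", "delta_ts", "rt_nee", "rt_re", "valid"]
    return pd.DataFrame([vars(r) for r in records], columns=cols)


def site_mean_resistance(records: list[ResistanceRecord]) -> pd.DataFrame:
    """Per-site annual and overall mean resistance over valid records.

    Annual rows carry the event's freeze-onset calendar year; overall rows
    carry year -1.  Returns an empty frame (with a log note) when no record
    is valid.
    """
    df = records_to_frame(records)
    df = df[df["valid"]]
    cols = ["site_id", "year", "rt_nee", "rt_re", "n_events"]
    if len(df) == 0:
        logger.warning("[ftcflux:resistance] no valid resistance records")
        return pd.DataFrame(columns=cols)
    annual = (
        df.groupby(["site_id", "year"], as_index=False)
        .agg(rt_nee=("rt_nee", "mean"), rt_re=("rt_re", "mean"), n_events=("event_id", "count"))
    )
    overall = (
        df.groupby("site_id", as_index=False)
        .agg(rt_nee=("rt_nee", "mean"), rt_re=("rt_re", "mean"), n_events=("event_id", "count"))
    )
    overall.insert(1, "year", -1)
    return pd.concat([annual, overall], ignore_index=True)[cols]


def pft_resistance(
    records: list[ResistanceRecord], sites: list[SiteRecord]
) -> pd.DataFrame:
    """Mean resistance per plant functional type (IGBP class).

    Valid events are pooled across sites within a class (primary); the mean
    of per-site means is emitted alongside for sensitivity.

    Raises
    ------
    KeyError
        If a record's site_id is absent from ``sites``.
    """
    igbp_of = {s.site_id: s.igbp for s in sites}
    df = records_to_frame(records)
    df = df[df["valid"]].copy()
    unknown = sorted(set(df["site_id"]) - set(igbp_of))
    if unknown:
        raise KeyError(f"records reference unknown sites: {unknown}")
    if len(df) == 0:
        return pd.DataFrame(columns=["igbp", "rt_nee", "rt_re", "rt_nee_site_mean",
                                     "rt_re_site_mean", "n_events", "n_sites"])
    df["igbp"] = df["site_id"].map(igbp_of)
    pooled = (
        df.groupby("igbp", as_index=False)
        .agg(rt_nee=("rt_nee", "mean"), rt_re=("rt_re", "mean"),
             n_events=("event_id", "count"), n_sites=("site_id", "nunique"))
    )
    site_means = (
        df.groupby(["igbp", "site_id"], as_index=False)
        .agg(rt_nee=("rt_nee", "mean"), rt_re=("rt_re", "mean"))
        .groupby("igbp", as_index=False)
        .agg(rt_nee_site_mean=("rt_nee", "mean"), rt_re_site_mean=("rt_re", "mean"))
    )
    out = pooled.merge(site_means, on="igbp")
    return out[["igbp", "rt_nee", "rt_re", "rt_nee_site_mean", "rt_re_site_mean",
                "n_events", "n_sites"]]
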