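"""Freeze-thaw cycle (FTC) detection from daily shallow soil temperature.

The detector is a two-state machine over daily mean soil temperature:

* **Freeze onset** — the soil is considered frozen once its temperature has
  stayed below 0 degC for at least ``freeze_run_min`` consecutive days; the
  event starts on the first day of that run.
* **Thaw confirmation** — frozen soil is considered thawed only when the
  temperature stays above 0 degC for at least ``thaw_run_min`` consecutive
  days.  Shorter above-zero interludes (and days at exactly 0 degC) do not
  thaw the soil: the frozen state persists through them.

One event spans freeze onset through the ``thaw_run_min``-th day of the
confirming thaw run.  ``frozen_days`` counts only the sub-zero days inside
the event.  Days at exactly 0 degC are neither frozen nor thawing and break
the consecutiveness of both qualifying runs.  Missing days break runs and
abort an unconfirmed event unless ``max_gap_days`` > 0, in which case up to
that many consecutive missing days are tolerated as a continuation (never
counted as frozen or thaw days).  A frozen spell with no confirming thaw
before the record ends (or before an over-long gap) emits no event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DailySeries

STATE_UNFROZEN = "unfrozen"
STATE_FROZEN = "frozen"
STATE_THAWING = "thawing"
STATE_UNDETERMINED = "undetermined"

_MISSING = 9  # sign code for missing days


@dataclass(frozen=True)
class DetectorConfig:
    """Run-length thresholds and analysis windows, all in days."""

    freeze_run_min: int = 5
    thaw_run_min: int = 5
    pre_window: int = 10
    post_window: int = 10
    max_gap_days: int = 0

    def __post_init__(self) -> None:
        for name in ("freeze_run_min", "thaw_run_min", "pre_window", "post_window"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.max_gap_days < 0:
            raise ValueError("max_gap_days must be >= 0")


@dataclass(frozen=True)
class FtcEvent:
    """One detected freeze-thaw event at one site.

    ``duration`` counts freeze_start through thaw_end inclusive;
    ``frozen_days`` counts only sub-zero days.  ``pre_ok`` is False when the
    pre-event window extends before the start of the record.
    """

    site_id: str
    freeze_start: pd.Timestamp
    freeze_end: pd.Timestamp
    thaw_end: pd.Timestamp
    duration: int
    frozen_days: int
    pre_start: pd.Timestamp
    pre_end: pd.Timestamp
    post_start: pd.Timestamp
    post_end: pd.Timestamp
    pre_ok: bool

    @property
    def event_id(self) -> str:
        return f"{self.site_id}:{self.freeze_start:%Y%m%d}"


def _signs(ts: pd.Series) -> np.ndarray:
    """Per-day code: -1 frozen (<0), +1 thawed (>0), 0 at exactly 0, 9 missing."""
    v = ts.to_numpy(dtype=float)
    out = np.full(v.shape, _MISSING, dtype=int)
    ok = ~np.isnan(v)
    out[ok & (v < 0)] = -1
    out[ok & (v > 0)] = 1
    out[ok & (v == 0)] = 0
    return out


def _scan_run(sign: np.ndarray, i: int, target: int, max_gap: int) -> tuple[list[int], int]:
    """Consecutive ``target``-sign days from ``i``, tolerating short gaps.

    Returns (indices of target days, index of the first day after the run).
    A wrong-sign day, a 0 degC day, or a missing gap longer than ``max_gap``
    ends the run.
    """
    n = len(sign)
    idx: list[int] = []
    j = i
    while j < n:
        if sign[j] == target:
            idx.append(j)
            j += 1
        elif sign[j] == _MISSING and max_gap > 0 and idx:
            g = j
            while g < n and sign[g] == _MISSING and (g - j) < max_gap:
                g += 1
            if g < n and sign[g] == target:
                j = g
            else:
                break
        else:
            break
    return idx, (idx[-1] + 1 if idx else i)


def _detect_index_events(sign: np.ndarray, config: DetectorConfig) -> list[dict]:
    """State-machine scan; returns events as index dicts.

    Each event: freeze_start_i, freeze_end_i (last sub-zero day before the
    confirming thaw), thaw_end_i (thaw_run_min-th confirming day), frozen_days.
    """
    n = len(sign)
    events: list[dict] = []
    i = 0
    while i < n:
        if sign[i] != -1:
            i += 1
            continue
        run, nxt = _scan_run(sign, i, -1, config.max_gap_days)
        if len(run) < config.freeze_run_min:
            i = nxt
            continue
        # frozen state confirmed; search forward for the confirming thaw run
        freeze_start_i = run[0]
        freeze_end_i = run[-1]
        frozen_days = len(run)
        j = nxt
        confirmed: list[int] | None = None
        while j < n:
            if sign[j] == -1:
                sub, j = _scan_run(sign, j, -1, config.max_gap_days)
                freeze_end_i = sub[-1]
                frozen_days += len(sub)
            elif sign[j] == 1:
                pos, j2 = _scan_run(sign, j, 1, config.max_gap_days)
                if len(pos) >= config.thaw_run_min:
                    confirmed = pos
                    break
                j = j2
            elif sign[j] == 0:
                j += 1
            else:  # missing
                g = j
                while g < n and sign[g] == _MISSING:
                    g += 1
                if g - j > config.max_gap_days:
                    j = g  # over-long gap: state unknown, abort candidate
                    break
                j = g
        if confirmed is not None:
            thaw_end_i = confirmed[config.thaw_run_min - 1]
            events.append(
                {"freeze_start_i": freeze_start_i, "freeze_end_i": freeze_end_i,
                 "thaw_end_i": thaw_end_i, "frozen_days": frozen_days}
            )
            i = thaw_end_i + 1
        else:
            i = max(j, nxt)
    return events


def detect_events(series: DailySeries, config: DetectorConfig | None = None) -> list[FtcEvent]:
    """Detect freeze-thaw events in one site's record, in chronological order.

    Events whose pre-window starts before the record are kept with
    ``pre_ok=False``.
    """
    config = config or DetectorConfig()
    ts = series.ts
    if len(ts) == 0:
        return []
    dates = ts.index
    events: list[FtcEvent] = []
    for ev in _detect_index_events(_signs(ts), config):
        freeze_start = dates[ev["freeze_start_i"]]
        thaw_end = dates[ev["thaw_end_i"]]
        pre_start = freeze_start - pd.Timedelta(days=config.pre_window)
        events.append(
            FtcEvent(
                site_id=series.site_id,
                freeze_start=freeze_start,
                freeze_end=dates[ev["freeze_end_i"]],
                thaw_end=thaw_end,
                duration=int((thaw_end - freeze_start).days) + 1,
                frozen_days=int(ev["frozen_days"]),
                pre_start=pre_start,
                pre_end=freeze_start - pd.Timedelta(days=1),
                post_start=thaw_end + pd.Timedelta(days=1),
                post_end=thaw_end + pd.Timedelta(days=config.post_window),
                pre_ok=bool(pre_start >= dates[0]),
            )
        )
    return events


def classify_soil_state(ts: pd.Series, config: DetectorConfig | None = None) -> pd.Series:
    """Label each day frozen / thawing / unfrozen / undetermined.

    Frozen: sub-zero days inside a detected event span, plus any qualifying
    sub-zero run whose thaw was never confirmed.  Thawing: the confirming
    ``thaw_run_min`` above-zero days of each event.  Missing days are
    undetermined; everything else is unfrozen.
    """
    config = config or DetectorConfig()
    sign = _signs(ts)
    n = len(sign)
    state = np.full(n, STATE_UNFROZEN, dtype=object)
    state[sign == _MISSING] = STATE_UNDETERMINED
    covered = np.zeros(n, dtype=bool)
    for ev in _detect_index_events(sign, config):
        seg = slice(ev["freeze_start_i"], ev["freeze_end_i"] + 1)
        state[seg] = np.where(sign[seg] == -1, STATE_FROZEN, state[seg])
        covered[ev["freeze_start_i"] : ev["thaw_end_i"] + 1] = True
        thaw_seg = slice(ev["freeze_end_i"] + 1, ev["thaw_end_i"] + 1)
        state[thaw_seg] = np.where(sign[thaw_seg] == 1, STATE_THAWING, state[thaw_seg])
    # qualifying frozen runs never confirmed thawed (e.g. at record end)
    i = 0
    while i < n:
        if sign[i] == -1 and not covered[i]:
            run, nxt = _scan_run(sign, i, -1, config.max_gap_days)
            if len(run) >= config.freeze_run_min:
                for k in run:
                    if not covered[k]:
                        state[k] = STATE_FROZEN
            i = nxt
        else:
            i += 1
    return pd.Series(state, index=ts.index, name="soil_state")


def annual_ftc_days(
    events: list[FtcEvent], series_span: tuple[pd.Timestamp, pd.Timestamp]
) -> tuple[pd.Series, float]:
    """Per-calendar-year freeze-thaw days and the site mean days/year.

    Event days (freeze_start through thaw_end) split across New Year are
    allocated to each year.  The mean divides total event days by the number
    of calendar years the record touches.
    """
    start, end = pd.Timestamp(series_span[0]), pd.Timestamp(series_span[1])
    if end < start:
        raise ValueError("series_span must be a non-empty (start, end) range")
    years = range(start.year, end.year + 1)
    per_year = pd.Series(0, index=pd.Index(list(years), name="year"), dtype=float)
    for ev in events:
        days = pd.date_range(ev.freeze_start, ev.thaw_end, freq="D")
        counts = pd.Series(1, index=days).groupby(days.year).sum()
        for yr, c in counts.items():
            if yr in per_year.index:
                per_year.loc[yr] += c
            else:  # event spills past the nominal span edge
                per_year.loc[yr] = c
    mean = float(per_year.sum() / len(per_year)) if len(per_year) else 0.0
    return per_year, mean


def events_to_frame(events: list[FtcEvent]) -> pd.DataFrame:
    """Tidy event table (one row per event) for CSV output."""
    rows = [
        {
            "site_id": ev.site_id,
            "event_id": ev.event_id,
            "freeze_start": ev.freeze_start.date().isoformat(),
            "freeze_end": ev.freeze_end.date().isoformat(),
            "thaw_end": ev.thaw_end.date().isoformat(),
            "duration": ev.duration,
            "frozen_days": ev.frozen_days,
            "pre_ok": ev.pre_ok,
        }
        for ev in events
    ]
    cols = ["site_id", "event_id", "freeze_start", "freeze_end", "thaw_end",
            "duration", "frozen_days", "pre_ok"]
    return pd.DataFrame(rows, columns=cols)
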