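"""Synthetic FLUXNET-like daily series with known freeze-thaw structure.

The generator builds a deterministic seasonal soil-temperature cycle
(sinusoid with its minimum in mid-January, period 365.25 d), adds stationary
AR(1) noise, and derives fluxes from the realized temperature:

* respiration follows a Q10 response, ``RE = r_ref * q10**((Ts - 10)/10)``,
  multiplied by ``freeze_re_factor`` while the soil is frozen;
* gross primary production is a summer half-sine gated by Ts > 0, so winter
  NEE collapses onto RE;
* ``NEE = RE - GPP`` (negative = net uptake).

"Frozen" is the same operational state the event detector uses — the soil
freezes after 5 consecutive sub-zero days and stays frozen until 5
consecutive above-zero days confirm thaw — applied to the *realized* (noisy)
temperature, so the simulated fluxes respond to the freeze-thaw state a
detector can actually observe.  The prescribed events and true resistance
ratios in :class:`GroundTruth` come from the same construction evaluated on
the *noiseless* temperature, making the truth analytic and independent of
the noise realization.

Records start on July 1 so that each winter's frozen block lies in the
interior of the record, with an intact 10-day pre-window and a confirmed
thaw.  The remaining meteorology (P, Rg, VPD, WS, SWC) is seasonally
modulated positive noise: profiled downstream, but never driving the fluxes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import DetectorConfig, _detect_index_events, _scan_run
from .io import CANONICAL_VARIABLES, DEFAULT_VARIABLE_MAP, MISSING_SENTINEL, DailySeries

_PERIOD = 365.25          # days; seasonal period
_COLD_PEAK = "2000-01-15"  # phase reference: coldest day of the cycle
_START_MONTH_DAY = "-07-01"

# Window geometry used for truth ratios and for protecting event-defining
# cells from masking; matches the detector / resistance defaults.
_DETECTOR = DetectorConfig()
_PRE_WINDOW = 10
_POST_WINDOW = 10


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic site.

    Defaults emulate a freeze-prone mid/high-latitude tower: a 3 degC mean
    annual soil temperature with a 12 degC seasonal swing gives one multi-
    month frozen block per winter.  Shallow soil temperature is strongly
    damped (snow cover, latent heat), so its day-to-day anomalies are small
    and persistent: AR(1) noise with rho 0.75 and stationary sd 0.6 degC.
    q10 = 2 and r_ref = 2 umol m-2 s-1 are canonical respiration parameters;
    freezing suppresses RE to 30 % of its unfrozen Q10 value.
    """

    seed: int = 0
    n_years: int = 12
    ts_mean: float = 3.0           # degC
    ts_amplitude: float = 12.0     # degC
    ar1_rho: float = 0.75          # lag-1 autocorrelation of Ts noise
    noise_sd: float = 0.6          # degC, stationary sd of Ts noise
    q10: float = 2.0
    r_ref: float = 2.0             # umol CO2 m-2 s-1 at 10 degC
    freeze_re_factor: float = 0.3  # multiplicative RE suppression while frozen
    gpp_summer_max: float = 8.0    # umol CO2 m-2 s-1
    missing_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must lie in [0, 1)")
        if self.noise_sd < 0 or self.ts_amplitude < 0:
            raise ValueError("noise_sd and ts_amplitude must be >= 0")
        if self.q10 <= 0:
            raise ValueError("q10 must be > 0")
        if not 0.0 <= self.freeze_re_factor <= 1.0:
            raise ValueError("freeze_re_factor must lie in [0, 1]")
        if not 0.0 <= self.missing_frac < 1.0:
            raise ValueError("missing_frac must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Prescribed events and the true resistance they imply.

    ``events`` holds (freeze_start_date, frozen_days) for every event of the
    noiseless construction.  The true ratios are the mean over those events
    of the noiseless per-event ratios (event window = freeze onset through
    thaw confirmation; pre window = the 10 preceding days) — exactly the
    quantity the resistance stage estimates from the noisy record.
    """

    events: list[tuple[pd.Timestamp, int]]
    true_re_resistance: float
    true_nee_resistance: float
    per_event: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)


def _sign_codes(values: np.ndarray) -> np.ndarray:
    out = np.full(values.shape, 9, dtype=int)
    ok = ~np.isnan(values)
    out[ok & (values < 0)] = -1
    out[ok & (values > 0)] = 1
    out[ok & (values == 0)] = 0
    return out


def _frozen_state(values: np.ndarray) -> tuple[np.ndarray, list[dict]]:
    """Frozen-state day mask and event index dicts for a temperature array.

    Frozen spans cover freeze onset through the last sub-zero day before
    thaw confirmation (interludes included); a qualifying sub-zero run with
    no confirmed thaw (e.g. at record end) is frozen to its last sub-zero
    day.
    """
    sign = _sign_codes(values)
    n = len(sign)
    mask = np.zeros(n, dtype=bool)
    events = _detect_index_events(sign, _DETECTOR)
    for ev in events:
        mask[ev["freeze_start_i"] : ev["freeze_end_i"] + 1] = True
    i = 0
    while i < n:  # unconfirmed qualifying runs
        if sign[i] == -1 and not mask[i]:
            run, nxt = _scan_run(sign, i, -1, _DETECTOR.max_gap_days)
            if len(run) >= _DETECTOR.freeze_run_min:
                mask[run[0] : run[-1] + 1] = True
            i = nxt
        else:
            i += 1
    return mask, events


def _fluxes(
    cfg: SyntheticConfig, ts: np.ndarray, season: np.ndarray, frozen: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(RE, NEE) from a temperature trajectory and its frozen-state mask."""
    suppress = np.where(frozen, cfg.freeze_re_factor, 1.0)
    re = cfg.r_ref * cfg.q10 ** ((ts - 10.0) / 10.0) * suppress
    gpp = cfg.gpp_summer_max * season * (ts > 0) * ~frozen
    return re, re - gpp


def _noiseless_truth(
    dates: pd.DatetimeIndex,
    ts_det: np.ndarray,
    re_det: np.ndarray,
    nee_det: np.ndarray,
    events_det: list[dict],
) -> GroundTruth:
    events: list[tuple[pd.Timestamp, int]] = []
    rows = []
    for ev in events_det:
        start, thaw_end = ev["freeze_start_i"], ev["thaw_end_i"]
        events.append((dates[start], int(ev["frozen_days"])))
        p0 = start - _PRE_WINDOW
        if p0 < 0:
            continue  # truncated pre-window: listed, but no truth ratio
        dur = slice(start, thaw_end + 1)
        pre = slice(p0, start)
        d_ts = ts_det[dur].mean() - ts_det[pre].mean()
        rows.append(
            {
                "freeze_start": dates[start],
                "frozen_days": int(ev["frozen_days"]),
                "rt_re": (re_det[dur].mean() - re_det[pre].mean()) / d_ts,
                "rt_nee": (nee_det[dur].mean() - nee_det[pre].mean()) / d_ts,
            }
        )
    per_event = pd.DataFrame(rows)
    if len(per_event):
        rt_re = float(per_event["rt_re"].mean())
        rt_nee = float(per_event["rt_nee"].mean())
    else:
        rt_re = rt_nee = float("nan")
    return GroundTruth(events=events, true_re_resistance=rt_re,
                       true_nee_resistance=rt_nee, per_event=per_event)


def generate_daily_series(
    config: SyntheticConfig, site_id: str = "SYN-001", start_year: int = 2000
) -> tuple[DailySeries, GroundTruth]:
    """Generate one synthetic site record plus its ground truth.

    Deterministic in (config, site_id, start_year): the same inputs always
    produce the identical series.
    """
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp(f"{start_year}{_START_MONTH_DAY}")
    end = start + pd.DateOffset(years=config.n_years) - pd.Timedelta(days=1)
    dates = pd.date_range(start, end, freq="D", name="date")
    n = len(dates)
    t = (dates - pd.Timestamp(_COLD_PEAK)).days.to_numpy(dtype=float)
    phase = 2.0 * math.pi * t / _PERIOD

    ts_det = config.ts_mean - config.ts_amplitude * np.cos(phase)

    # stationary AR(1) noise on soil temperature
    eps = np.zeros(n)
    innov = rng.standard_normal(n)  # drawn always, for stream alignment
    if config.noise_sd > 0:
        eps[0] = config.noise_sd * innov[0]
        scale = config.noise_sd * math.sqrt(1.0 - config.ar1_rho**2)
        for i in range(1, n):
            eps[i] = config.ar1_rho * eps[i - 1] + scale * innov[i]
    ts = ts_det + eps

    season = np.maximum(0.0, -np.cos(phase))  # summer half-sine, peak mid-July

    frozen_det, events_det = _frozen_state(ts_det)
    frozen, events_real = _frozen_state(ts)
    re_det, nee_det = _fluxes(config, ts_det, season, frozen_det)
    re, nee = _fluxes(config, ts, season, frozen)

    truth = _noiseless_truth(dates, ts_det, re_det, nee_det, events_det)

    # ancillary meteorology: seasonal positive noise, never flux-driving
    ta = ts + 2.0 + rng.normal(0.0, 1.5, n)
    rain = (rng.random(n) < 0.35) * rng.exponential(3.0, n) * (1.0 + 0.8 * season)
    rg = np.clip(160.0 - 140.0 * np.cos(phase) + rng.normal(0.0, 25.0, n), 5.0, None)
    vpd = np.clip(1.0 + 6.0 * season + rng.normal(0.0, 1.0, n), 0.05, None)
    ws = rng.lognormal(mean=1.0, sigma=0.4, size=n)
    swc = np.clip(45.0 - 12.0 * season + rng.normal(0.0, 3.0, n), 5.0, 95.0)

    data = pd.DataFrame(
        {"ta": ta, "p": rain, "rg": rg, "vpd": vpd, "ws": ws,
         "swc": swc, "ts": ts, "nee": nee, "re": re},
        index=dates,
    )

    if config.missing_frac > 0:
        # protect event-defining cells so the prescribed truth stays observable
        protect = np.zeros(n, dtype=bool)
        for ev in events_real:
            lo = max(0, ev["freeze_start_i"] - _PRE_WINDOW)
            hi = min(n - 1, ev["thaw_end_i"] + _POST_WINDOW)
            protect[lo : hi + 1] = True
        for col in CANONICAL_VARIABLES:
            drop = rng.random(n) < config.missing_frac
            if col in ("ts", "nee", "re"):
                drop &= ~protect
            data.loc[drop, col] = np.nan

    return DailySeries(site_id=site_id, data=data), truth


def write_fluxnet_dialect(series: DailySeries, path: str | Path) -> Path:
    """Write a series as a FLUXNET-dialect CSV (YYYYMMDD stamps, -9999).

    Round-trips losslessly through :func:`ftcflux.io.read_fluxnet_daily`
    on non-missing cells.
    """
    if len(series) == 0:
        raise ValueError("cannot write an empty series")
    path = Path(path)
    out = pd.DataFrame({"TIMESTAMP": series.dates.strftime("%Y%m%d")})
    for canon in CANONICAL_VARIABLES:
        col = series.data[canon].to_numpy(dtype=float)
        out[DEFAULT_VARIABLE_MAP[canon]] = np.where(np.isnan(col), MISSING_SENTINEL, col)
    # %.17g guarantees lossless float64 round-trips through the text file
    out.to_csv(path, index=False, float_format="%.17g")
    return path
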