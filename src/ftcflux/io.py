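"""Reading and writing FLUXNET2015-style daily records and site metadata.

The canonical in-memory container is :class:`DailySeries`: one site's daily
record of nine variables on a strictly consecutive calendar-day index, with
``NaN`` marking missing observations.  Files use the FLUXNET daily dialect
(``TIMESTAMP`` as ``YYYYMMDD``, ``-9999`` as the missing sentinel).

Default FLUXNET column choices (overridable through ``variable_map``):
gap-filled meteorology (``TA_F``, ``P_F``, ``SW_IN_F``, ``VPD_F``, ``WS_F``),
the shallowest (~5 cm) soil sensors (``TS_F_MDS_1``, ``SWC_F_MDS_1``), the
variable-USTAR-threshold reference NEE (``NEE_VUT_REF``) and the
daytime-partitioned respiration (``RECO_DT_VUT_REF``).  Sign convention:
negative NEE is net ecosystem uptake.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("ftcflux")

#: Canonical variable names, in stable column order.
CANONICAL_VARIABLES: tuple[str, ...] = (
    "ta", "p", "rg", "vpd", "ws", "swc", "ts", "nee", "re",
)

#: The five IGBP plant-functional-type classes covered by the site network.
IGBP_CLASSES: tuple[str, ...] = ("DBF", "ENF", "MF", "GRA", "CRO")

#: Missing-value sentinel of the FLUXNET daily product.
MISSING_SENTINEL = -9999.0

#: Default canonical-name -> FLUXNET column mapping.
DEFAULT_VARIABLE_MAP: dict[str, str] = {
    "ta": "TA_F",
    "p": "P_F",
    "rg": "SW_IN_F",
    "vpd": "VPD_F",
    "ws": "WS_F",
    "swc": "SWC_F_MDS_1",
    "ts": "TS_F_MDS_1",
    "nee": "NEE_VUT_REF",
    "re": "RECO_DT_VUT_REF",
}


@dataclass(frozen=True)
class SiteRecord:
    """Static metadata for one flux tower."""

    site_id: str
    latitude: float
    longitude: float
    igbp: str
    elevation: float   # m a.s.l.
    mat: float         # mean annual temperature, degC
    map: float         # mean annual precipitation, mm

    def __post_init__(self) -> None:
        if self.igbp not in IGBP_CLASSES:
            raise ValueError(
                f"site {self.site_id!r}: unknown IGBP class {self.igbp!r}; "
                f"expected one of {IGBP_CLASSES}"
            )
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"site {self.site_id!r}: latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"site {self.site_id!r}: longitude {self.longitude} out of range")


@dataclass
class DailySeries:
    """One site's daily record of the nine canonical variables.

    ``data`` is indexed by consecutive calendar days (``DatetimeIndex``,
    daily frequency, no duplicates) and holds one float column per canonical
    variable; ``NaN`` means missing.
    """

    site_id: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing_cols = [v for v in CANONICAL_VARIABLES if v not in self.data.columns]
        if missing_cols:
            raise ValueError(f"DailySeries missing columns: {missing_cols}")
        self.data = self.data.loc[:, list(CANONICAL_VARIABLES)].astype(float)
        idx = self.data.index
        if len(idx) > 0:
            if not isinstance(idx, pd.DatetimeIndex):
                raise TypeError("DailySeries index must be a DatetimeIndex")
            deltas = np.diff(idx.values).astype("timedelta64[D]")
            if idx.has_duplicates or (len(deltas) and not np.all(deltas == np.timedelta64(1, "D"))):
                raise ValueError("DailySeries dates must be strictly increasing consecutive days")
            swc = self.data["swc"].dropna()
            if len(swc) and ((swc < 0) | (swc > 100)).any():
                raise ValueError("swc values must lie in [0, 100] where present")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def ts(self) -> pd.Series:
        """Shallow (~5 cm) daily mean soil temperature, degC."""
        return self.data["ts"]

    def n_years(self) -> int:
        """Number of distinct calendar years the record touches."""
        if len(self.data) == 0:
            return 0
        return int(self.data.index.year.nunique())


def _parse_float_column(col: pd.Series) -> pd.Series:
    """Correctly-rounded float parsing; unparseable cells become NaN.

    (pandas' fast parser is not round-trip exact, which would break the
    write/read identity on full-precision files.)
    """
    def conv(v):
        try:
            return float(v)
        except (TypeError, ValueError):
            return float("nan")

    return col.map(conv)


def _infer_site_id(path: Path) -> str:
    stem = path.stem
    parts = stem.split("_")
    if parts[0] == "FLX" and len(parts) > 1:
        return parts[1]
    return parts[0]


def read_fluxnet_daily(
    path: str | Path,
    variable_map: dict[str, str] | None = None,
    site_id: str | None = None,
) -> DailySeries:
    """Read one FLUXNET-dialect daily CSV into a :class:`DailySeries`.

    ``-9999`` and any non-numeric cell become missing; gaps in the calendar
    are filled with all-missing rows so the date index is consecutive.  A
    canonical variable whose mapped column is absent is returned all-missing
    with a logged warning.

    Raises
    ------
    ValueError
        If the ``TIMESTAMP`` column is absent.
    """
    path = Path(path)
    vmap = dict(DEFAULT_VARIABLE_MAP)
    if variable_map:
        vmap.update(variable_map)
    raw = pd.read_csv(path, dtype=str)
    if "TIMESTAMP" not in raw.columns:
        raise ValueError(f"{path}: no TIMESTAMP column")
    sid = site_id if site_id is not None else _infer_site_id(path)
    if len(raw) == 0:
        data = pd.DataFrame(
            {v: pd.Series(dtype=float) for v in CANONICAL_VARIABLES},
            index=pd.DatetimeIndex([], name="date"),
        )
        return DailySeries(site_id=sid, data=data)

    dates = pd.to_datetime(raw["TIMESTAMP"].str.strip(), format="%Y%m%d")
    cols: dict[str, pd.Series] = {}
    for canon in CANONICAL_VARIABLES:
        src = vmap[canon]
        if src in raw.columns:
            vals = _parse_float_column(raw[src])
            vals = vals.mask(vals == MISSING_SENTINEL)
            cols[canon] = vals
        else:
            logger.warning("[ftcflux:io] %s: column %r for %r not found; all-missing", path.name, src, canon)
            cols[canon] = pd.Series(np.nan, index=raw.index)
    data = pd.DataFrame(cols)
    data.index = pd.DatetimeIndex(dates, name="date")
    data = data[~data.index.duplicated(keep="first")].sort_index()
    full = pd.date_range(data.index[0], data.index[-1], freq="D", name="date")
    data = data.reindex(full)
    return DailySeries(site_id=sid, data=data)


def read_site_table(path: str | Path | None = None) -> list[SiteRecord]:
    """Read a site-metadata table; ``None`` loads the packaged 24-site table.

    Raises
    ------
    ValueError
        On an unknown IGBP code, naming the offending row.
    """
    if path is None:
        ref = importlib.resources.files("ftcflux").joinpath("data/site_table.csv")
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    records: list[SiteRecord] = []
    for i, row in df.iterrows():
        try:
            records.append(
                SiteRecord(
                    site_id=str(row["site_id"]),
                    latitude=float(row["latitude"]),
                    longitude=float(row["longitude"]),
                    igbp=str(row["igbp"]),
                    elevation=float(row["elevation"]),
                    mat=float(row["mat"]),
                    map=float(row["map"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"site table row {i} ({row.get('site_id', '?')}): {exc}") from exc
    return records


def write_table(rows: pd.DataFrame, path: str | Path, schema: list[str] | None = None) -> None:
    """Write a result table as CSV with a stable column order.

    ``schema`` fixes the column order; a missing column is a hard error.
    Floats are written at full (repr) precision so round-trips are lossless.
    """
    df = pd.DataFrame(rows)
    if schema is not None:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise ValueError(f"write_table: missing columns {missing}")
        df = df.loc[:, schema]
    df.to_csv(path, index=False)
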