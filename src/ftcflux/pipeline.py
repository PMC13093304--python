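"""End-to-end orchestration over a directory of per-site daily CSV files.

Stages: read -> detect events -> phase profiles -> resistance -> PFT and
trend summaries -> driver model + Shapley attribution.  ``run_pipeline``
writes seven result tables plus a JSON manifest (config echo, seeds, row
counts) and is deterministic under a fixed config and inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detection import DetectorConfig, detect_events, annual_ftc_days, events_to_frame
from .drivers import build_feature_table, explain_model, fit_gbt
from .io import DailySeries, SiteRecord, read_fluxnet_daily, read_site_table, write_table
from .profiles import aggregate_profiles, event_phase_profile
from .resistance import (
    DEFAULT_EPSILON_TS,
    event_resistance,
    pft_resistance,
    records_to_frame,
    site_mean_resistance,
)
from .synth import GroundTruth, SyntheticConfig, generate_daily_series, write_fluxnet_dialect
from .trends import DEFAULT_MIN_N, site_trend_table

logger = logging.getLogger("ftcflux")

TABLE_NAMES = ("events", "profiles", "profile_summary", "resistance",
               "pft_summary", "trends", "shap")


@dataclass
class PipelineConfig:
    input_dir: str
    site_table_path: str | None = None   # None -> packaged 24-site table
    output_dir: str = "ftcflux_out"
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    epsilon_ts: float = DEFAULT_EPSILON_TS
    rank_daily: bool = False
    trend_min_n: int = DEFAULT_MIN_N
    target: str = "rt_re"
    cv_k: int = 5
    seed: int = 0
    variable_map: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        det = raw.pop("detector", {})
        cfg = cls(**raw)
        if det:
            cfg.detector = DetectorConfig(**det)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_bundle(
    input_dir: str | Path,
    site_table_path: str | Path | None = None,
    variable_map: dict | None = None,
) -> tuple[list[SiteRecord], dict[str, DailySeries]]:
    """Read the site table and every per-site CSV under ``input_dir``.

    An unreadable site file is skipped with a logged reason; zero usable
    sites is a hard error.
    """
    input_dir = Path(input_dir)
    sites = read_site_table(site_table_path)
    series: dict[str, DailySeries] = {}
    for path in sorted(input_dir.glob("*.csv")):
        if path.name == "site_table.csv" or path.name.startswith("truth_"):
            continue
        try:
            s = read_fluxnet_daily(path, variable_map=variable_map)
        except Exception as exc:  # noqa: BLE001 - skip-and-log contract
            logger.warning("[ftcflux:pipeline] skipping %s: %s", path.name, exc)
            continue
        series[s.site_id] = s
    if not series:
        raise RuntimeError(f"no usable site files under {input_dir}")
    return sites, series


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run every stage and write tables + manifest to ``config.output_dir``."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sites, series_map = load_bundle(config.input_dir, config.site_table_path,
                                    config.variable_map)
    site_ids_known = {s.site_id for s in sites}

    all_events = []
    profile_rows = []
    records = []
    annual: dict[str, dict[str, np.ndarray]] = {}
    for site_id, series in series_map.items():
        events = detect_events(series, config.detector)
        all_events.extend(events)
        logger.info("[ftcflux:pipeline] %s: %d events", site_id, len(events))
        for ev in events:
            profile_rows.append(event_phase_profile(ev, series, rank_daily=config.rank_daily))
            records.append(event_resistance(ev, series, epsilon_ts=config.epsilon_ts))
        if len(series):
            per_year, _ = annual_ftc_days(events, (series.dates[0], series.dates[-1]))
            annual[site_id] = {"ftc_days": per_year.to_numpy(dtype=float)}

    events_df = events_to_frame(all_events)
    profiles_df = (pd.concat(profile_rows, ignore_index=True)
                   if profile_rows else pd.DataFrame(
                       columns=["site_id", "event_id", "variable", "phase", "value", "percentile"]))
    summary_df = (aggregate_profiles(profiles_df) if len(profiles_df)
                  else pd.DataFrame(columns=["site_id", "variable", "phase", "percentile", "n_events"]))
    resistance_df = records_to_frame(records)

    known_records = [r for r in records if r.site_id in site_ids_known]
    pft_df = pft_resistance(known_records, sites) if known_records else pd.DataFrame()

    site_means = site_mean_resistance(records)
    for site_id in annual:
        sub = site_means[(site_means["site_id"] == site_id) & (site_means["year"] >= 0)]
        annual[site_id]["rt_nee"] = sub["rt_nee"].to_numpy(dtype=float)
        annual[site_id]["rt_re"] = sub["rt_re"].to_numpy(dtype=float)
    trends_df = site_trend_table(annual, min_n=config.trend_min_n)

    shap_df = pd.DataFrame(columns=["event_id", "feature", "value", "phi", "baseline", "fx"])
    model_meta: dict = {}
    try:
        table = build_feature_table(known_records, all_events, sites, target=config.target)
        fit = fit_gbt(table, target=config.target, cv_k=config.cv_k, seed=config.seed)
        _, shap_df = explain_model(fit, table, seed=config.seed)
        model_meta = fit.metadata()
    except (ValueError, KeyError) as exc:
        logger.warning("[ftcflux:pipeline] drivers stage skipped: %s", exc)
        model_meta = {"skipped": str(exc)}

    tables = {
        "events": events_df, "profiles": profiles_df, "profile_summary": summary_df,
        "resistance": resistance_df, "pft_summary": pft_df, "trends": trends_df,
        "shap": shap_df,
    }
    for name, df in tables.items():
        write_table(df, out_dir / f"{name}.csv")
    (out_dir / "model_metadata.json").write_text(json.dumps(model_meta, indent=2, default=float))

    cfg_dict = config.to_dict()
    manifest = {
        "ftcflux_version": __version__,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()).hexdigest(),
        "seed": config.seed,
        "n_sites": len(series_map),
        "sites": sorted(series_map),
        "row_counts": {name: int(len(df)) for name, df in tables.items()},
        "events_per_site": {sid: int((events_df["site_id"] == sid).sum())
                            for sid in sorted(series_map)},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return tables


def simulate_bundle(
    site_specs: list[tuple[SiteRecord, SyntheticConfig]],
    out_dir: str | Path,
) -> dict[str, GroundTruth]:
    """Write a ready-to-run synthetic input directory.

    One FLUXNET-dialect CSV per site, a ``site_table.csv``, and truth tables
    (``truth_events.csv``, ``truth_resistance.csv``).  Returns the per-site
    ground truths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seen = set()
    truths: dict[str, GroundTruth] = {}
    site_rows = []
    ev_rows = []
    rt_rows = []
    for site, cfg in site_specs:
        if site.site_id in seen:
            raise ValueError(f"duplicate site id {site.site_id}")
        seen.add(site.site_id)
        series, truth = generate_daily_series(cfg, site_id=site.site_id)
        write_fluxnet_dialect(series, out_dir / f"{site.site_id}.csv")
        truths[site.site_id] = truth
        site_rows.append(vars(site).copy() if not dataclasses.is_dataclass(site)
                         else dataclasses.asdict(site))
        for d, length in truth.events:
            ev_rows.append({"site_id": site.site_id,
                            "freeze_start": d.date().isoformat(),
                            "frozen_days": length})
        rt_rows.append({"site_id": site.site_id,
                        "true_rt_re": truth.true_re_resistance,
                        "true_rt_nee": truth.true_nee_resistance,
                        "n_truth_events": len(truth.per_event)})
    pd.DataFrame(site_rows).to_csv(out_dir / "site_table.csv", index=False)
    pd.DataFrame(ev_rows).to_csv(out_dir / "truth_events.csv", index=False)
    pd.DataFrame(rt_rows).to_csv(out_dir / "truth_resistance.csv", index=False)
    return truths


def default_site_specs(
    n_sites: int = 3, n_years: int = 12, seed: int = 0
) -> list[tuple[SiteRecord, SyntheticConfig]]:
    """Realistic varied synthetic network: cold to mild freeze-prone sites."""
    igbp_cycle = ("ENF", "DBF", "MF", "GRA", "CRO")
    specs = []
    for k in range(n_sites):
        site = SiteRecord(
            site_id=f"SYN-{k:03d}",
            latitude=45.0 + 3.0 * (k % 7),
            longitude=-100.0 + 10.0 * k,
            igbp=igbp_cycle[k % 5],
            elevation=200.0 + 350.0 * (k % 6),
            mat=1.0 + 1.5 * (k % 5),
            map=500.0 + 120.0 * (k % 5),
        )
        cfg = SyntheticConfig(
            seed=seed * 1000 + k,
            n_years=n_years,
            ts_mean=2.0 + 0.8 * (k % 4),
            ts_amplitude=12.0 + (k % 3),
        )
        specs.append((site, cfg))
    return specs
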