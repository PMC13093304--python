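# ftcflux

Freeze–thaw cycles (FTC) — spells in which shallow soil stays frozen for
days to months before a confirmed thaw — suppress soil respiration, shut
down photosynthesis and reorganize the soil environment at high-latitude
and high-altitude flux towers. `ftcflux` is a Python library for
quantifying these effects in daily eddy-covariance records (FLUXNET2015
daily dialect): it detects freeze–thaw events from soil temperature,
standardizes the surrounding conditions as site-record percentiles,
computes the *resistance* of net ecosystem exchange (NEE) and ecosystem
respiration (RE) to each event, tests long-term trends, and attributes
resistance to environmental drivers with a gradient-boosted model explained
by exact Shapley values. A synthetic flux-network generator with an
analytic ground truth makes every stage testable offline.

## The statistics at the core

**Event definition.** Soil is frozen once daily mean shallow (~5 cm) soil
temperature T_s < 0 °C for ≥ 5 consecutive days, and thawed only after
T_s > 0 °C for ≥ 5 consecutive days; one event spans freeze onset through
thaw confirmation (minimum 10 days).

**Resistance.** For each event, with overbars denoting window means over
the event and the 10 preceding days,

    Rt_NEE = (NEE − NEE_pre) / (T_s − T_s,pre)
    Rt_RE  = (RE  − RE_pre)  / (T_s − T_s,pre)     [µmol CO₂ m⁻² s⁻¹ °C⁻¹]

A magnitude near zero means the flux barely responded to the freeze–thaw
temperature perturbation.

**Trends.** Mann–Kendall S = Σ_{i<j} sign(x_j − x_i) with tie-corrected
variance and continuity-corrected normal deviate Z; classes: significant
decrease (Z < −1.96), significant increase (Z > 1.96), otherwise no
significant change. Sen's slope is reported as the effect size.

**Drivers.** XGBoost (max_depth = 4, eta = 0.5, 20 rounds) predicts
event-level resistance from five drivers — event duration, elevation, mean
annual temperature, mean annual precipitation, ecosystem type (IGBP) — and
each prediction is attributed by the exact Shapley value

    φ_i = Σ_{S ⊆ N\{i}} |S|! (n−|S|−1)! / n! · (v(S∪{i}) − v(S))

computed by full subset enumeration with an interventional (background-
marginalized) value function; the one-hot ecosystem-type columns form a
single player, so n = 5 and efficiency/symmetry/dummy hold to machine
precision.

## Worked example

`examples/03_resistance_recovery.py` simulates five towers, detects their
events and pools the event resistance:

```python
from ftcflux import (SyntheticConfig, generate_daily_series,
                     detect_events, event_resistance)

series, truth = generate_daily_series(SyntheticConfig(seed=0, n_years=12),
                                      site_id="SYN-000")
records = [event_resistance(ev, series) for ev in detect_events(series)]
```

Running the script prints:

```
events: 60 valid over 5 sites x 12 years
pooled Rt_RE estimate: 0.1278 umol m-2 s-1 degC-1
prescribed true Rt_RE: 0.1272
relative error: 0.50 %
```

Sixty winter events are detected across five simulated towers; the pooled
respiration resistance recovers the generator's prescribed truth to 0.5 %.
The other scripts under `examples/` walk through event detection and annual
FTC days, phase percentiles, trend testing, and driver attribution, each
printing the numbers it computes and what they mean.

Real FLUXNET2015 daily CSVs are read with
`ftcflux.read_fluxnet_daily(path)` (default column mapping `TA_F`, `P_F`,
`SW_IN_F`, `VPD_F`, `WS_F`, `SWC_F_MDS_1`, `TS_F_MDS_1`, `NEE_VUT_REF`,
`RECO_DT_VUT_REF`; override via `variable_map`). The packaged 24-site
metadata table loads with `ftcflux.read_site_table()`.

## Command line

A thin CLI wraps the pipeline for directory-level runs:

```bash
ftcflux simulate --out bundle --n-sites 3 --n-years 12 --seed 1
ftcflux run-all --input-dir bundle --site-table bundle/site_table.csv --out results
```

`run-all` writes seven CSV tables (events, profiles, profile_summary,
resistance, pft_summary, trends, shap), model metadata and a JSON manifest;
identical inputs and config give byte-identical tables. Stage subcommands
(`detect`, `profile`, `resistance`, `trends`, `drivers`) expose the same
outputs individually.

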