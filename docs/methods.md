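# Methods

## Scope and data model

`ftcflux` analyses daily eddy-covariance records. The canonical container
(`DailySeries`) holds one site's record of nine variables — air temperature
TA (°C), precipitation P (mm), incident shortwave Rg (W m⁻²), vapour
pressure deficit VPD (hPa), wind speed WS (m s⁻¹), soil water content SWC
(%), shallow (~5 cm) soil temperature Ts (°C), net ecosystem exchange NEE
and ecosystem respiration RE (µmol CO₂ m⁻² s⁻¹) — on a strictly consecutive
daily calendar, with NaN as the missing marker. Files use the FLUXNET2015
daily dialect (`TIMESTAMP` as `YYYYMMDD`, −9999 sentinel); gaps in the
calendar are filled with all-missing rows on read, never with values. NEE
follows the standard sign convention (negative = net uptake). The default
column mapping prefers gap-filled meteorology, the shallowest soil sensors
(`_1` suffix), the variable-USTAR-threshold reference NEE and the
*daytime-partitioned* respiration (`RECO_DT_VUT_REF`), which avoids the
NEE–RE autocorrelation introduced by night-time partitioning; all choices
are overridable through `variable_map`.

## Freeze–thaw event detection

Detection is a two-state machine on daily mean soil temperature:

* **freeze onset** — Ts < 0 °C for at least `freeze_run_min` (default 5)
  consecutive days; the event starts on the first day of that run;
* **thaw confirmation** — the soil stays frozen, through shorter above-zero
  interludes and days at exactly 0 °C, until Ts > 0 °C for at least
  `thaw_run_min` (default 5) consecutive days; the event ends on the
  `thaw_run_min`-th day of that run.

The persistence rule matters in practice: near the freeze onset, day-to-day
variability flips the sign of Ts repeatedly, and a definition requiring a
sub-zero run to be *immediately* followed by a five-day thaw run would
dissolve whole winters into fragments that never qualify. With persistence,
one winter is one event, which is the object the resistance ratio is meant
to describe.

Numerical choices: Ts = 0 °C exactly is neither frozen nor thawing and
breaks both qualifying runs (strict inequalities). Missing days break runs
and abort an unconfirmed event; `max_gap_days > 0` tolerates short missing
gaps as run continuations without counting them as frozen or thaw days.
A frozen spell never confirmed thawed (record end, long gap) emits no
event. `duration` counts freeze onset through thaw confirmation inclusive;
`frozen_days` counts only sub-zero days — both are reported, since summary
statistics could reasonably use either. Annual freeze–thaw days allocate
event days to calendar years (events spanning New Year split) and the site
mean divides by the number of calendar years the record touches.

## Phase percentiles

For each event and variable, the mean over the 10-day pre-window, the event
window and the 10-day post-window is ranked against the site's entire
monitoring record of that variable using the mean-rank percentile,
100·(n_less + ½·n_equal)/n. Ranking against the full record (not a
season-matched subset) standardizes across sites with very different
climates so profiles can be pooled; the price is that seasonality shows
through (winter NEE ranks high because summer uptake fills the low
percentiles, and a 10-day mean of a skewed variable outranks its typical
single day). The phase *mean* is ranked (not the mean of daily ranks); the
daily-rank variant is available via `rank_daily=True` for sensitivity
checks. Aggregation weights every event equally; per-site means are
retained alongside the pooled rows.

## Resistance

For each event, with window means over the event span and the 10-day
pre-window,

    Rt_NEE = (NEE − NEE_pre)/(Ts − Ts_pre),  Rt_RE = (RE − RE_pre)/(Ts − Ts_pre),

in µmol CO₂ m⁻² s⁻¹ °C⁻¹. The "during" window is the full event span
(freeze onset through thaw confirmation). The denominator is a difference
of window means and can approach zero for marginal events; records with
|ΔTs| < `epsilon_ts` (default 0.5 °C) or any undefined window mean or a
truncated pre-window are flagged invalid and excluded from every summary
rather than contributing near-singular ratios. Plant-functional-type
summaries pool all valid events within an IGBP class (primary) and also
report the mean of per-site means (sensitivity column); both full-swap
invariance and the c-scaling of the numerator are covered by tests.

## Mann–Kendall trends

S = Σ_{i<j} sign(x_j − x_i); tie-corrected variance
var(S) = [n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18 over tie groups of size t;
continuity-corrected deviate z = (S∓1)/√var(S) (0 when S = 0). Classes:
significant decrease (z < −1.96), significant increase (z > 1.96), the
closed interval [−1.96, 1.96] is no significant change. Ties are common in
annual day counts, hence the correction is not optional. Series with fewer
than `min_n = 4` values are withheld with a reason instead of tested —
short flux records cannot support a trend call. Sen's slope (median of all
pairwise slopes) is reported as an effect size; it does not enter the
classification. Under an i.i.d. null at n = 20 the empirical |z| > 1.96
rejection rate is ≈ 0.047 (10,000 replicates in the test suite), the mild
conservatism expected from the continuity correction on a discrete S.

## Driver model and exact Shapley attribution

An XGBoost regressor predicts event-level resistance from exactly five
drivers: event duration (days), site elevation (m), mean annual temperature
(°C), mean annual precipitation (mm) and ecosystem type (IGBP one-hot).
Hyperparameters default to max_depth = 4, eta = 0.5, nrounds = 20; the
remaining tree parameters stay at the library defaults and are recorded in
the fit metadata. Skill is reported primarily out-of-fold (k = 5 folds,
shuffled with a fixed seed, fold assignment keyed to sorted event ids so it
is row-order invariant): r², the slope of observed regressed on predicted,
and MAE; training-set values are emitted alongside. A constant target
yields r² = 0 with a warning rather than an error. The unit of analysis is
the event (site-year aggregation can be built upstream if wanted).

Attribution is the exact Shapley value by full 2ⁿ subset enumeration with
the interventional value function: v(S) is the model output with the
instance's values on the features in S and background values elsewhere,
averaged over a background sample (the encoded feature table, subsampled to
`background_size` rows). The interventional choice — rather than tree-path
conditioning — keeps v(S) well-defined for any predictor and reproducible
across implementations. The one-hot ecosystem-type columns enter and leave
coalitions together as a single player, so n stays at 5, attributions match
the five-driver ranking, and enumeration is trivially cheap (32 coalition
evaluations per instance). Efficiency (Σφ + v(∅) = f(x)), symmetry and
dummy hold to numerical precision and are asserted against an independent
permutation-average oracle in the tests. Feature counts above 15 are
rejected with a pointer to sampling approximations (out of scope).

## Synthetic data generator

The generator emulates a freeze-prone tower so that every stage has a known
truth. Soil temperature is a sinusoid (period 365.25 d, minimum mid-
January) plus stationary AR(1) noise; records start July 1 so each winter
lies in the interior of the record with an intact pre-window and a
confirmed thaw. Fluxes derive from the realized temperature:
RE = r_ref·q10^((Ts−10)/10), multiplied by `freeze_re_factor` while the
soil is frozen; GPP is a summer half-sine gated off when Ts ≤ 0 or the soil
is frozen; NEE = RE − GPP. "Frozen" here is the same operational state the
detector uses, applied to the realized temperature — the simulated fluxes
respond to the freeze state that is actually present in the series, which
is what makes the prescribed resistance recoverable by the pipeline. The
ground truth is the identical construction evaluated on the *noiseless*
temperature: prescribed events, and true resistance ratios computed with
the same window convention the resistance stage uses, averaged over
events.

Default conditions (one value each, with units): 12 years; mean soil
temperature 3 °C with a 12 °C seasonal amplitude (one multi-month frozen
block per winter, annual freeze–thaw days in the range observed at cold
evergreen-forest towers); AR(1) rho 0.75 and sd 0.6 °C (shallow soil
temperature is strongly damped by snow cover and latent heat, so its
anomalies are small and persistent); q10 = 2 and r_ref = 2 µmol m⁻² s⁻¹
(canonical respiration parameters); freeze suppression to 30 % of the
unfrozen Q10 value (within the range of reported winter respiration
suppression); summer GPP maximum 8 µmol m⁻² s⁻¹; 5 % missing data masked
uniformly at random, except Ts/NEE/RE inside event-defining windows, which
stay observable so the truth remains computable.

What the generator does *not* emulate: half-hourly structure, snowpack and
zero-curtain physics, moisture or light limitation of fluxes (P, Rg, VPD,
WS, SWC are seasonally modulated positive noise that never drives the
fluxes), disturbance or phenology memory. Passing recovery tests therefore
demonstrate that the pipeline's estimators are consistent under the stated
generative model — not that real ecosystems satisfy that model.

## Pipeline, determinism and problem sizes

`run_pipeline` composes the stages over a directory of per-site CSVs,
writing seven tidy tables plus model metadata and a manifest (config hash,
seed, row counts per table and per site); identical config and inputs give
byte-identical event and resistance tables. Unreadable site files are
skipped with a logged reason; zero usable sites is a hard error. All
randomness (generator, fold assignment, background subsampling) flows from
explicit seeds.

Tests and the acceptance script run on simulated networks of three to five
sites and 12–15 years — large enough for ≥ 50 events (the resistance
recovery check pools 60) while keeping the default suite fast. The
acceptance script reports, per quantity, the problem size it was computed
at.

## Known limitations

* The detector's persistence rule means one long winter with brief warm
  interludes is one event; analyses of sub-seasonal (diurnal-scale)
  freeze–thaw cycling need half-hourly data and a different definition.
* Resistance is a ratio statistic; pooled means remain sensitive to events
  with small |ΔTs| just above `epsilon_ts`. The threshold is configurable
  and the per-event table preserves everything needed for robust
  re-aggregation.
* Percentile profiles confound event effects with plain seasonality by
  design (full-record reference); season-matched references would answer a
  different question and are not implemented.
* The driver model inherits XGBoost's behaviour on tiny tables; with fewer
  than 2·k rows the stage is skipped rather than fit.
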