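"""Event resistance of respiration, checked against the generator's truth.

Resistance Rt_RE = (RE_during - RE_pre) / (Ts_during - Ts_pre) measures how
strongly respiration responded to the freeze-thaw temperature drop, in
umol CO2 m-2 s-1 per degC.  The synthetic generator prescribes a known true
value, so the pooled estimate can be validated.
"""

import numpy as np

from ftcflux import SyntheticConfig, detect_events, event_resistance, generate_daily_series

measured, truths = [], []
for k in range(5):
    series, truth = generate_daily_series(SyntheticConfig(seed=k, n_years=12),
                                          site_id=f"SYN-{k:03d}")
    for ev in detect_events(series):
        rec = event_resistance(ev, series)
        if rec.valid:
            measured.append(rec.rt_re)
    truths.extend(truth.per_event["rt_re"])

pooled = float(np.mean(measured))
true = float(np.mean(truths))
print(f"events: {len(measured)} valid over 5 sites x 12 years")
print(f"pooled Rt_RE estimate: {pooled:.4f} umol m-2 s-1 degC-1")
print(f"prescribed true Rt_RE: {true:.4f}")
print(f"relative error: {100 * abs(pooled - true) / abs(true):.2f} %")
print("A positive Rt_RE: respiration fell together with soil temperature;"
      " a magnitude near 0 would mean the flux ignored the freeze.")
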