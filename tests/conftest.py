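import numpy as np
import pandas as pd
import pytest

from ftcflux import CANONICAL_VARIABLES, DailySeries, SiteRecord, SyntheticConfig
from ftcflux.pipeline import default_site_specs, simulate_bundle
from ftcflux.synth import generate_daily_series


def make_series(ts_values, site_id: str = "TST-001", start: str = "2000-01-01",
                **extra_columns) -> DailySeries:
    """Build a DailySeries from a soil-temperature list (None -> missing).

    Other variables default to benign constants; override via keyword
    (value may be a scalar or a full-length sequence).
    """
    ts = np.array([np.nan if v is None else float(v) for v in ts_values])
    n = len(ts)
    idx = pd.date_range(start, periods=n, freq="D", name="date")
    defaults = {"ta": 5.0, "p": 1.0, "rg": 100.0, "vpd": 3.0, "ws": 2.0,
                "swc": 30.0, "nee": -1.0, "re": 2.0}
    data = {}
    for var in CANONICAL_VARIABLES:
        if var == "ts":
            data[var] = ts
        elif var in extra_columns:
            data[var] = np.broadcast_to(np.asarray(extra_columns[var], dtype=float), (n,)).copy()
        else:
            data[var] = np.full(n, defaults[var])
    return DailySeries(site_id=site_id, data=pd.DataFrame(data, index=idx))


@pytest.fixture(scope="session")
def recovery_network():
    """Five synthetic sites x 12 years at the default study conditions,
    with per-site ground truths (>= 50 prescribed events in total)."""
    out = []
    for k in range(5):
        site_id = f"SYN-{k:03d}"
        series, truth = generate_daily_series(
            SyntheticConfig(seed=k, n_years=12), site_id=site_id
        )
        out.append((series, truth))
    return out


@pytest.fixture(scope="session")
def synthetic_bundle(tmp_path_factory):
    """On-disk 3-site bundle ready for the pipeline."""
    root = tmp_path_factory.mktemp("bundle")
    specs = default_site_specs(n_sites=3, n_years=12, seed=11)
    truths = simulate_bundle(specs, root)
    return root, specs, truths


@pytest.fixture
def site_records():
    return [
        SiteRecord("SYN-000", 45.0, -100.0, "ENF", 200.0, 1.0, 500.0),
        SiteRecord("SYN-001", 48.0, -90.0, "DBF", 550.0, 2.5, 620.0),
        SiteRecord("SYN-002", 51.0, -80.0, "MF", 900.0, 4.0, 740.0),
    ]
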