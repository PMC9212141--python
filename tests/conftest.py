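import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sdgcurves import load_printed_curves, load_registry
from sdgcurves.io import WHO_REGIONS

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def printed():
    return load_printed_curves()


def random_small_panel(rng, n_countries=None, n_periods=None, code="311"):
    """A small random observation/covariate panel pair for oracle tests."""
    n_c = n_countries or int(rng.integers(4, 9))
    n_p = n_periods or int(rng.integers(3, 6))
    countries = [f"C{i:02d}" for i in range(n_c)]
    anchors = [2000 + 5 * t for t in range(n_p)]
    obs_rows, cov_rows = [], []
    for i, c in enumerate(countries):
        region = WHO_REGIONS[i % len(WHO_REGIONS)]
        for a in anchors:
            obs_rows.append({
                "country": c, "year": a, "code": code,
                "value": float(np.exp(rng.normal(3.0, 1.0))),
            })
            cov_rows.append({
                "country": c, "year": a,
                "gdp_pc": float(np.exp(rng.normal(8.5, 1.0))),
                "gini": float(rng.uniform(25, 60)),
                "health_exp": float(rng.uniform(1, 12)),
                "region": region,
            })
    return pd.DataFrame(obs_rows), pd.DataFrame(cov_rows)
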