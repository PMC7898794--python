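import numpy as np
import pandas as pd
import pytest

import stormflow as sf


@pytest.fixture(scope="session")
def small_study():
    """One-year two-site study, modest storm rate (fast to regenerate)."""
    cfg = sf.SyntheticConfig(seed=11, n_days=365, impact_day=180,
                             storm_rate_per_day=0.3)
    return sf.generate_study(cfg)


@pytest.fixture(scope="session")
def labelled_events(small_study):
    tabs = []
    for site in ("impact", "control"):
        base = sf.separate_baseflow(small_study.flow[site])
        tabs.append(sf.extract_events(site, small_study.rain[site], base))
    return sf.label_events(pd.concat(tabs, ignore_index=True), small_study.design)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
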