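"""Shared fixtures: small seeded survival datasets built per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from survtab.datatypes import FeatureMeta, SurvivalDataset


def weibull_cox_data(seed, n, beta, shape=1.0, scale=0.1, censor_rate=0.05,
                     admin=np.inf):
    """Plain Weibull--Cox draw used by oracle tests (independent of the
    package generator: inversion written out locally)."""
    rng = np.random.default_rng(seed)
    p = len(beta)
    X = rng.standard_normal((n, p))
    u = rng.uniform(size=n)
    t_event = (-np.log(u) / (scale * np.exp(X @ np.asarray(beta)))) ** (1.0 / shape)
    c = np.full(n, float(admin))
    if censor_rate > 0:
        c = np.minimum(c, rng.exponential(1.0 / censor_rate, size=n))
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    cols = [f"x{i}" for i in range(p)]
    return SurvivalDataset(
        time=time, event=event,
        features=pd.DataFrame(X, columns=cols),
        feature_meta=[FeatureMeta(c_, "continuous") for c_ in cols],
    )


@pytest.fixture(scope="session")
def small_cox_dataset():
    """n=500, p=5, moderate censoring; well-conditioned fixture."""
    return weibull_cox_data(11, 500, [0.8, -0.8, 0.4, -0.4, 0.0],
                            censor_rate=0.05)


@pytest.fixture(scope="session")
def elsa_like_small():
    """Scaled-down cohort preset (n=800) shared across tests."""
    from survtab.synthetic_data import make_elsa_like

    return make_elsa_like(29, n_subjects=800)


from hypothesis import settings as _hsettings

_hsettings.register_profile("ci", derandomize=True, deadline=None)
_hsettings.load_profile("ci")
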