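import numpy as np
import pandas as pd
import pytest

import herdhmm as hh


@pytest.fixture(scope="session")
def ref_model():
    """The packaged 3-state reference model with the conventional Gamma."""
    return hh.reference_model()


@pytest.fixture(scope="session")
def sim_series(ref_model):
    """A moderate simulated observation series with its generating states."""
    states = hh.simulate_states(ref_model, 4000, seed=101)
    lat, lon = hh.simulate_track(ref_model, states, (14.5, -16.5), seed=102)
    series = hh.compute_steps(pd.DataFrame({"lat": lat, "lon": lon}))
    return series, states


@pytest.fixture(scope="session")
def small_survey(ref_model):
    """A compact two-herd synthetic survey (one transhumant, one resident)."""
    cfg = hh.SimConfig(n_herds=2, n_days=30, seed=7, transhumance_schedule=[])
    return hh.simulate_survey(cfg, ref_model)

from .oracles import random_toy_model, random_toy_series  # noqa: E402,F401
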