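import logging
import warnings

import numpy as np
import pandas as pd
import pytest

from engramflow.config import CohortConfig, EffectSpec

# statsmodels optimizer chatter is handled explicitly by the fitting code
warnings.filterwarnings("ignore", category=UserWarning, module="statsmodels")
logging.getLogger("engramflow").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    """A cohort small enough for end-to-end tests in seconds."""
    return CohortConfig(n_learning=8, n_control=6, n_blocks_day1=8,
                        grid_shape=(12, 12, 12), n_volumes_rest=60,
                        task_on_duration=10.0, task_off_duration=10.0,
                        master_seed=7)


@pytest.fixture(scope="session")
def effects():
    return EffectSpec()


def make_panel(values, metabolite="Glu", linewidth=9.0, snr=45.0,
               timepoints=None, group="Learning"):
    """Minimal long-format metabolite panel for QC tests (conc already scaled)."""
    n = len(values)
    tps = timepoints if timepoints is not None else [f"post{10 * i}" for i in range(n)]
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "group": group,
        "timepoint": tps,
        "metabolite": metabolite,
        "conc": np.asarray(values, dtype=float),
        "crlb_pct": 3.0,
        "snr": snr,
        "linewidth_hz": linewidth,
        "f_gm": 0.55, "f_wm": 0.37, "f_csf": 0.08,
    })
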