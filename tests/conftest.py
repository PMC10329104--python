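import numpy as np
import pandas as pd
import pytest

from metacontrol.agent import AgentParams, simulate_subject
from metacontrol.io import TRIAL_COLUMNS
from metacontrol.task import TaskConfig


@pytest.fixture
def config():
    return TaskConfig()


@pytest.fixture
def short_config():
    return TaskConfig(n_trials=60)


@pytest.fixture
def params():
    return AgentParams(alpha=0.6, beta=4.0, lam=0.6, w_low=0.3, w_high=0.8,
                       pi=0.3, rho=0.1)


@pytest.fixture
def sim_table(params, config):
    return simulate_subject(params, config, np.random.default_rng(42),
                            subject_id="s000")


def make_trials(rows):
    """Build a schema-complete trial table from compact row tuples:
    (trial, pair, stake, left, right, choice, planet, treasure, red, purple)
    with choice=None meaning a missed trial."""
    out = []
    for (trial, pair, stake, left, right, choice, planet, treasure,
         red, purple) in rows:
        missed = choice is None
        out.append({
            "subject_id": "t", "trial": trial, "pair": pair, "stake": stake,
            "option_left": left, "option_right": right,
            "choice": "" if missed else choice,
            "planet": "" if missed else planet,
            "treasure": np.nan if missed else float(treasure),
            "points": 0 if missed else int(treasure) * stake,
            "missed": missed, "reward_red": red, "reward_purple": purple,
        })
    return pd.DataFrame(out, columns=TRIAL_COLUMNS)
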