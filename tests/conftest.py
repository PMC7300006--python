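import numpy as np
import pandas as pd
import pytest

import troopkit as tk


@pytest.fixture(scope="session")
def call_table():
    """A well-separated 9-caller table (between-caller effect ~2x within sd)."""
    spec = tk.CallSimSpec(seed=11)
    return tk.gen_call_features(spec)


@pytest.fixture(scope="session")
def troop():
    return tk.gen_troop_observations(tk.TroopSimSpec(seed=21))


@pytest.fixture(scope="session")
def assoc(troop):
    return tk.build_association_matrix(troop.scans)


@pytest.fixture(scope="session")
def trials(troop):
    return tk.gen_trials(tk.TrialSimSpec(seed=31), troop)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def toy_scan_table(rows):
    """rows: list of (focal, scan_index, [neighbours])."""
    return pd.DataFrame(
        [{"focal_id": f, "scan_index": s, "neighbour_ids": ";".join(nb)}
         for f, s, nb in rows]
    )
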