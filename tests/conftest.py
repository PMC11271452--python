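import logging

import numpy as np
import pandas as pd
import pytest

import otolithchem as oc

logging.disable(logging.INFO)


NOISELESS = oc.NoiseParams(0.0, 0.0, 0.0, 0.0, 0.0, tl_sigma=0.0, radius_sigma=0.0)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """32 fish, ages 1-8, no noise of any kind: ground truth is exact."""
    sc = oc.SyntheticScenario(
        n_fish=32,
        seed=11,
        noise=NOISELESS,
        age_probs={a: 1 / 8 for a in range(1, 9)},
    )
    env = oc.generate_environment(sc)
    fish, truth = oc.generate_cohort(sc, env)
    return sc, env, fish, truth


@pytest.fixture(scope="session")
def noisy_cohort():
    """60 fish at the default measurement noise (sigma 0.15)."""
    sc = oc.SyntheticScenario(n_fish=60, seed=21)
    env = oc.generate_environment(sc)
    fish, truth = oc.generate_cohort(sc, env)
    return sc, env, fish, truth


@pytest.fixture()
def simple_transect():
    """Tiny hand-built transect with constant concentrations."""
    n = 20
    return oc.ElementTransect(
        fish_id="T1",
        distance_um=np.linspace(50, 1000, n),
        concentrations_ppm={
            "Mg": np.full(n, 243.05),
            "P": np.full(n, 200.0),
            "Mn": np.full(n, 5.0),
            "Sr": np.full(n, 2000.0),
            "Ca": np.full(n, 400780.0),
        },
        lab_tag="Lund",
    )


def transect_csv(tmp_path, name="f1.csv", drop=None, nan_row=None, n=5):
    df = pd.DataFrame(
        {
            "distance_um": np.arange(10.0, 10.0 + 10 * n, 10.0),
            "Mg_ppm": np.full(n, 20.0),
            "P_ppm": np.full(n, 200.0),
            "Mn_ppm": np.full(n, 2.0),
            "Sr_ppm": np.full(n, 2000.0),
            "Ca_ppm": np.full(n, 400000.0),
        }
    )
    if drop:
        df = df.drop(columns=[drop])
    if nan_row is not None:
        df.loc[nan_row, "Mg_ppm"] = np.nan
    path = tmp_path / name
    df.to_csv(path, index=False)
    return path
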