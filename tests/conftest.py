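import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from amgcap.glm import ModelSpec, build_design, fit_glm
from amgcap.simulate import AreaConfig, SimConfig, generate_population

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: reduced AMG menu used by the fast simulation fixtures
SMALL_CODES = [1, 101, 311, 321, 331, 335, 401]


def small_config(n: int, seed: int, codes=None, **kwargs) -> SimConfig:
    """Generator config on a reduced AMG menu with one undistorted area.

    The single area has cost multiplier 1, so realised costs follow the
    configured log-linear truth exactly — the setting for parameter
    recovery and test-calibration studies.
    """
    codes = list(codes or SMALL_CODES)
    base = SimConfig(n_persons=1, seed=0)  # defaults donor
    shares = {c: base.amg_shares[c] for c in codes}
    tot = sum(shares.values())
    shares = {c: v / tot for c, v in shares.items()}
    return SimConfig(
        n_persons=n,
        seed=seed,
        amg_shares=shares,
        areas=(AreaConfig("ALL"),),
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_population() -> pd.DataFrame:
    return generate_population(small_config(5_000, seed=42))


@pytest.fixture(scope="session")
def small_model(small_population):
    X, y, enc = build_design(small_population)
    model = fit_glm(X, y, ModelSpec("gamma", "log"), enc)
    assert model.converged
    return model


@pytest.fixture(scope="session")
def default_population() -> pd.DataFrame:
    """Full 31-group population with the default area tilts/distortions."""
    return generate_population(SimConfig(n_persons=20_000, seed=7))


def rng_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s % (2**31)) for s in ss.generate_state(n)]
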