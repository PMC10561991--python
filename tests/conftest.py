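import numpy as np
import pandas as pd
import pytest

from behavkit.core import BehavTable
from behavkit.simulate import Genotype, SimConfig, simulate_population


@pytest.fixture
def small_behav() -> BehavTable:
    """Three specimens, two genotypes, 1 h of 10-s displacement records."""
    rng = np.random.default_rng(42)
    t = 10.0 * np.arange(360)
    frames = []
    for sid in ("a", "b", "c"):
        frames.append(pd.DataFrame({
            "id": sid, "t": t,
            "displacement": rng.lognormal(np.log(2.0), 0.5, len(t)),
        }))
    data = pd.concat(frames, ignore_index=True)
    meta = pd.DataFrame({
        "id": ["a", "b", "c", "d"],   # d: registered but never recorded
        "genotype": ["CantonS", "CantonS", "per_short", "per_long"],
    })
    return BehavTable(data, meta)


@pytest.fixture(scope="session")
def tiny_sim():
    """Two flies, half a day at 10-s bins — cheap shared simulation."""
    cfg = SimConfig(genotypes=[Genotype("w", 24.0, 2)], days=0.5,
                    bin_s=10.0, seed=3)
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def hmm_sim():
    """One genotype at 60-s bins for sleep-stage analyses."""
    cfg = SimConfig(genotypes=[Genotype("CantonS", 24.0, 8)], days=2.0,
                    bin_s=60.0, seed=5)
    return simulate_population(cfg)
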