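import numpy as np
import pytest

from saspkit import synthetic_data as sim


@pytest.fixture(scope="session")
def small_screen():
    """A 2-plate, 2-replicate screen with two planted down-hits."""
    import pandas as pd

    genes = [f"GENE{g:06d}" for g in range(120)]
    effects = pd.DataFrame(0.0, index=genes, columns=list(sim.SCREEN_READOUTS))
    effects.loc["GENE000010", ["IL8", "IL6"]] = -5.0
    effects.loc["GENE000095", ["IL8", "IL6"]] = -5.0
    plates, truth = sim.simulate_screen(
        120, replicate_count=2, effect_table=effects, seed=11
    )
    return plates, truth


@pytest.fixture(scope="session")
def splice_sim():
    """A 150-event splicing simulation at coverage 200."""
    return sim.simulate_splicing(n_events=150, coverage=200, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
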