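import numpy as np
import pytest

from xenodissect import synthdata as sd


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def small_universe():
    """A compact two-species universe shared across read-only tests."""
    cfg = sd.SynthConfig(
        seed=7,
        n_probesets=120,
        treatment_sets=(
            sd.TreatmentSet("NFKB_TARGETS", 12, 1.2, 0.3),
            sd.TreatmentSet("IL6_TARGETS", 8, 0.9, 0.3),
        ),
    )
    return sd.generate_universe(cfg)
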