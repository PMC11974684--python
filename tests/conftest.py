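import numpy as np
import pytest

from cas12akin import (
    EnsembleSpec,
    InitialFractions,
    KineticParams,
    NoiseSpec,
    generate_ensemble,
    generate_timecourse,
)
from cas12akin.geometry import DOMAIN_PRESETS


@pytest.fixture
def fn_domains():
    return DOMAIN_PRESETS["FnCas12a"]


@pytest.fixture
def clean_replicate():
    """Noise-free synthetic replicate with known truth (ka=0.2, kb=0.05)."""
    truth = KineticParams(ka=0.2, kb=0.05, kini=0.01, kini2=0.01)
    times = np.geomspace(1.0, 600.0, 12)
    dataset = generate_timecourse(
        truth,
        init=InitialFractions(initSC=100.0),
        times=times,
        noise=NoiseSpec(fraction_sd=0.0, seed=0),
        n_replicates=1,
    )
    return dataset.replicates[0].observed, truth


@pytest.fixture
def contact_rich_ensemble(fn_domains):
    """Small two-domain ensemble close enough to have heavy-atom contacts."""
    spec = EnsembleSpec(n_frames=10, distance_mean=8.0, distance_sd=1.5, seed=42)
    return generate_ensemble(spec, fn_domains)
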