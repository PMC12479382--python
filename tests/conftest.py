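import numpy as np
import pytest

from fcgrad.simulate import EffectInjection, SimConfig, simulate_cohort
from fcgrad.types import NetworkAtlas, ParcelTimeSeries

SMALL_SIZES = {"VIS": 4, "ASM": 4, "DAN": 4, "SAL": 4, "FPN": 4, "DMN": 4}
TINY_SIZES = {"VIS": 2, "ASM": 2, "DAN": 2, "SAL": 2, "FPN": 2, "DMN": 2}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """6 subjects, 24 parcels, one planted drug x post VIS-SAL increase."""
    config = SimConfig(
        n_per_group=(3, 3),
        n_parcels=24,
        network_sizes=dict(SMALL_SIZES),
        n_frames=120,
        effect_map=[EffectInjection(("VIS", "SAL"), "drug", "post", 0.2)],
        seed=7,
    )
    return simulate_cohort(config)


@pytest.fixture
def toy_atlas():
    mapping = {}
    idx = 1
    for net, k in SMALL_SIZES.items():
        for _ in range(k):
            mapping[f"P{idx:04d}"] = net
            idx += 1
    return NetworkAtlas(mapping=mapping)


@pytest.fixture
def white_scan(rng):
    """200-frame scan of independent white-noise parcels."""
    return ParcelTimeSeries(
        data=rng.standard_normal((200, 8)),
        tr_seconds=1.8,
        parcel_ids=[f"P{i + 1:04d}" for i in range(8)],
    )
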