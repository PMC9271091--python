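import numpy as np
import pytest

from tetherquant.synthetic import (
    CondensateSpec,
    NoiseModel,
    SimConfig,
    TetherSpec,
    generate_tether_movie,
)


@pytest.fixture
def snr10_noise() -> NoiseModel:
    """Shot noise plus Gaussian background giving peak SNR ~ 10 for the
    default tether intensity."""
    return NoiseModel(background_mean=10.0, background_sd=4.0, photon_gain=1.0)


@pytest.fixture
def noiseless() -> NoiseModel:
    return NoiseModel(background_mean=0.0, background_sd=0.0, photon_gain=0.0)


def make_movie(
    seed=0,
    n_frames=100,
    sigma_nm=300.0,
    noise=None,
    condensate=None,
    channels=("dna",),
    nick_fragility=0.0,
    image_shape=(48, 160),
    anchors=((24.0, 20.0), (24.0, 140.0)),
):
    """One double-tethered lambda-DNA movie with standard geometry."""
    cfg = SimConfig(
        rng_seed=seed,
        n_frames=n_frames,
        image_shape=image_shape,
        noise=noise or NoiseModel(),
    )
    spec = TetherSpec(
        anchor_a=anchors[0],
        anchor_b=anchors[1],
        envelope_sigma_nm=sigma_nm,
        nick_fragility=nick_fragility,
    )
    return generate_tether_movie(cfg, [spec], condensate, channels=channels)


@pytest.fixture
def condensing_spec() -> CondensateSpec:
    return CondensateSpec(
        forced_nucleation_time_s=20.0, collapse_time_s=10.0, tensed_floor_nm=50.0
    )
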