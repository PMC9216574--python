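import numpy as np
import pytest

from cptvr.benchmark import (
    BeadField,
    BenchmarkConfig,
    ElasticHalfSpace,
    ForceSpot,
    make_benchmark,
    render_image,
    sample_beads,
)


@pytest.fixture(scope="session")
def material():
    return ElasticHalfSpace(E=8000.0, nu=0.5)


@pytest.fixture(scope="session")
def small_benchmark():
    """Scaled-down benchmark: one moderate central spot on a 256 px field.

    Displacements reach ~13 px — large enough to exercise retracking,
    small enough to keep tests fast.
    """
    cfg = BenchmarkConfig(
        n_beads=2000,
        shape=(256, 256),
        spots=[
            ForceSpot((128.0, 128.0), 3000.0, np.deg2rad(30.0), 10.0, 7.0),
            ForceSpot((60.0, 60.0), 400.0, np.deg2rad(200.0), 6.0, 4.0),
            ForceSpot((200.0, 70.0), 300.0, np.deg2rad(120.0), 5.0, 4.0),
        ],
        seed=7,
    )
    return make_benchmark(cfg)


@pytest.fixture()
def single_bead_image():
    beads = BeadField(
        positions=np.array([[30.3, 27.8]]), amplitudes=np.array([500.0]), sigma=1.5
    )
    return beads, render_image(beads, (64, 64), background=50.0)


@pytest.fixture()
def uniform_pair():
    """Reference image and a copy shifted by exactly (3, 2) px."""
    beads = sample_beads(400, (128, 128), seed=3)
    ref = render_image(beads, (128, 128), background=20.0)
    from dataclasses import replace

    shifted = replace(beads, positions=beads.positions + np.array([3.0, 2.0]))
    def_ = render_image(shifted, (128, 128), background=20.0)
    return ref, def_, beads
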