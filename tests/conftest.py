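import numpy as np
import pytest

from lam_quant.synthetic_histology import (
    LatticeSpec,
    RenderSpec,
    VoronoiSpec,
    generate_lattice,
    generate_voronoi,
)


@pytest.fixture(scope="session")
def lattice_50():
    """10x10 lattice of 50 µm airspaces, 5 µm walls, 1 µm/px."""
    spec = LatticeSpec(50, 5, 1.0, 10, 10)
    mask, gt = generate_lattice(spec)
    return spec, mask, gt


@pytest.fixture(scope="session")
def voronoi_64():
    """64-seed Voronoi parenchyma on a 1000x1000 µm field at 1 µm/px."""
    spec = VoronoiSpec(64, 1000.0, 1000.0, 6.0, 1.0, rng_seed=7)
    mask, gt = generate_voronoi(spec)
    return spec, mask, gt


@pytest.fixture
def clean_render():
    """Noise-free brightfield render spec (220 airspace / 60 wall)."""
    return RenderSpec(airspace_intensity=220, wall_intensity=60, noise_sd=0.0,
                      rng_seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
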