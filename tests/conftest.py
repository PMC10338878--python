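import numpy as np
import pytest

from ldsefocus.nn.network import LDSENet, LDSENetConfig
from ldsefocus.simulate import FocalStackSpec, PhantomSpec, default_lens, generate_phantom, render_defocus_stack


@pytest.fixture(scope="session")
def tiny_net_config() -> LDSENetConfig:
    """Two-block toy configuration for fast structural tests."""
    return LDSENetConfig(
        input_channels=1,
        input_size=32,
        stem_channels=8,
        layers_per_block=(2, 2),
        growth_rate_k=4,
        se_reduction_r=2,
    )


@pytest.fixture()
def tiny_net(tiny_net_config) -> LDSENet:
    return LDSENet(tiny_net_config, seed=0)


@pytest.fixture(scope="session")
def lens_20x():
    return default_lens("20X")


@pytest.fixture(scope="session")
def small_phantom_spec() -> PhantomSpec:
    return PhantomSpec(width=128, height=128, n_cells=8, cell_radius_range=(5.0, 10.0),
                       blank_fraction=0.25, noise_sigma=0.0, seed=11)


@pytest.fixture(scope="session")
def coarse_stack(small_phantom_spec, lens_20x):
    """Noise-free 9-frame stack (-10..10 by 2.5) on a 128 px phantom."""
    phantom = generate_phantom(small_phantom_spec)
    spec = FocalStackSpec(z_min=-10.0, z_max=10.0, z_step=2.5)
    return render_defocus_stack(phantom, spec, lens_20x, noise_sigma=0.0, field_id="fixture", seed=3)
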