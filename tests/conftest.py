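import numpy as np
import pytest

from cervhsi.spectral import build_grid
from cervhsi.synthetic_data import LesionRegion, PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid100():
    """The reference 500-995 nm / 5 nm grid (100 bands)."""
    return build_grid(500, 5, 995)


def square_polygon(cx, cy, half):
    return np.array(
        [
            [cx - half, cy - half],
            [cx + half, cy - half],
            [cx + half, cy + half],
            [cx - half, cy + half],
        ],
        dtype=float,
    )


@pytest.fixture
def small_phantom_spec(grid100):
    """48x48 phantom: centered disc, one square major lesion, no noise."""
    return PhantomSpec(
        image_height=48,
        image_width=48,
        wavelength_grid=grid100,
        disc_center=(24.0, 24.0),
        disc_radius=20.0,
        lesion_regions=[
            LesionRegion(
                "major",
                square_polygon(28.0, 22.0, 6.0),
                multipliers={"hbo2": 2.0, "hb": 2.0, "water": 1.8},
            )
        ],
        baseline_concentrations={"hbo2": 0.3, "hb": 0.25, "water": 0.35},
        noise_sd=0.0,
        seed=7,
    )
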