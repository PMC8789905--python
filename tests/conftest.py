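import numpy as np
import pytest

from nodalrelay.colony import ColonyGeometry
from nodalrelay.lattice import (
    DEFAULT_RELAY_PARAMS,
    Genotype,
    disc_lattice,
    simulate_relay,
)
from nodalrelay.render import RenderParams

#: shared study conditions: a full-size colony is 700 um across with ~10 um
#: cells; smaller discs are used where only local behavior is probed.
FULL_COLONY_RADIUS_UM = 350.0
DEFAULT_NOISE = dict(psf_sigma_um=1.0, poisson_noise=True, read_noise_sd=2.0)


@pytest.fixture(scope="session")
def wt_colony_run():
    """Wild-type relay run on a full 350 um colony, edge-induced."""
    lat = disc_lattice(radius_um=FULL_COLONY_RADIUS_UM)
    return simulate_relay(lat, DEFAULT_RELAY_PARAMS, t_max=42.0,
                          sample_interval=1.0)


@pytest.fixture(scope="session")
def lefty_ko_colony_run():
    """Same colony and parameters with Lefty1/2 knocked out everywhere."""
    lat = disc_lattice(radius_um=FULL_COLONY_RADIUS_UM,
                       interior_genotype=Genotype.L12KO)
    return simulate_relay(lat, DEFAULT_RELAY_PARAMS, t_max=42.0,
                          sample_interval=1.0)


@pytest.fixture
def noisy_render_params():
    return RenderParams(shape_px=(260, 260), um_per_px=1.5, **DEFAULT_NOISE)


@pytest.fixture
def clean_render_params():
    return RenderParams(shape_px=(260, 260), um_per_px=1.5)


def disc_geometry(shape, um_per_px, radius_um, center_px=None):
    """Hand-built colony geometry for profiling tests (no detection step)."""
    ny, nx = shape
    if center_px is None:
        center_px = ((nx - 1) / 2, (ny - 1) / 2)
    yy, xx = np.indices(shape)
    r_um = np.hypot(xx - center_px[0], yy - center_px[1]) * um_per_px
    return ColonyGeometry(
        center_um=((center_px[0] + 0.5) * um_per_px,
                   (center_px[1] + 0.5) * um_per_px),
        radius_um=radius_um,
        mask=r_um <= radius_um,
        um_per_px=um_per_px,
    )
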