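import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from periquant.simulate import SimulationConfig, VesselRecord, render_frame

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# Fine-grid scene for oracle checks of the window statistic: 0.125 um pixels
# so edge-discretization (one-pixel ramps at each annulus edge) stays well
# below the 5% tolerance of the statistic itself.
ORACLE_FIELD_UM = 128.0
ORACLE_PX = 1024
ORACLE_STEP_UM = 0.125


@pytest.fixture(scope="session")
def oracle_cfg():
    return SimulationConfig(
        field_size_um=ORACLE_FIELD_UM,
        image_px=ORACLE_PX,
        n_vessels=0,
        injected_mass=0.0,
        noise_gain=0.0,
        read_noise_sd=0.0,
    )


def make_single_vessel_frame(
    cfg: SimulationConfig,
    diameter_um: float = 8.0,
    angle_rad: float = 0.3,
    positive: bool = True,
    t_min: float = 20.0,
    offset_um: tuple[float, float] = (0.33, -0.21),
):
    """One noiseless vessel near the field centre (sub-pixel offset to avoid
    grid-aligned symmetry)."""
    c = cfg.field_size_um / 2.0
    v = VesselRecord(
        id=0,
        center_xy_um=(c + offset_um[0], c + offset_um[1]),
        angle_rad=angle_rad,
        diameter_um=diameter_um,
        is_positive_truth=positive,
        distance_to_source_um=0.0,
    )
    return v, render_frame(cfg, [v], t_min)


@pytest.fixture(scope="session")
def noiseless_cfg():
    """Default-resolution (0.83 um/px) noiseless scene, no tracer."""
    return SimulationConfig(
        n_vessels=0, injected_mass=0.0, noise_gain=0.0, read_noise_sd=0.0
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
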