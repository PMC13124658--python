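import numpy as np
import pytest

from wideca.imgio import FrameGeometry, RoiDef, RoiSet
from wideca.protocol import ScheduleSpec
from wideca.synthetic import (
    NoiseModel,
    ResponseField,
    SimulationConfig,
    calibrate_default_kernel,
)

TINY_GEOMETRY = FrameGeometry(width_px=24, height_px=14, field_width_mm=7.1, field_height_mm=4.0)


@pytest.fixture(scope="session")
def default_kernel():
    return calibrate_default_kernel()


@pytest.fixture
def tiny_geometry():
    return TINY_GEOMETRY


def silent_noise(baseline: float = 1000.0) -> NoiseModel:
    return NoiseModel(
        baseline_level=baseline,
        shot_noise_scale=0.0,
        hemo_amplitude_dff=0.0,
        artifact_amplitude_dff=0.0,
    )


def tiny_config(
    kernel,
    fields=None,
    noise=None,
    n_subjects: int = 1,
    reps: int = 4,
    spl_min: float = 70.0,
    spl_max: float = 90.0,
    seed: int = 0,
    jitter: float = 0.0,
    geometry: FrameGeometry = TINY_GEOMETRY,
) -> SimulationConfig:
    """A fast simulation config on a coarse grid; zero noise by default."""
    if fields is None:
        fields = (
            ResponseField(
                name="SRAF", center_mm=(3.3, 2.1), sigma_mm=0.6,
                a_max_dff=0.018, s50_db=58.0, slope_db=1.2,
            ),
        )
    return SimulationConfig(
        geometry=geometry,
        fields=tuple(fields),
        kernel=kernel,
        noise=noise or silent_noise(),
        schedule_spec=ScheduleSpec(spl_min_db=spl_min, spl_max_db=spl_max, spl_step_db=2.0,
                                   reps_per_level=reps, rng_seed=seed),
        n_subjects=n_subjects,
        rng_seed=seed,
        subject_jitter_sigma=jitter,
    )


def tiny_rois() -> RoiSet:
    return RoiSet(entries=(
        RoiDef(name="SRAF", center_mm=(3.3, 2.1), radius_mm=0.35),
        RoiDef(name="Back", center_mm=(6.2, 0.7), radius_mm=0.35),
    ))
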