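"""Shared fixtures: a calibrated camera and reusable simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from pgcam import (
    CameraGeometry,
    ResponseModel,
    Scene,
    SourceComponent,
    Spatial,
    calibrate_angular_blur,
    generate_listmode,
)


@pytest.fixture(scope="session")
def geometry() -> CameraGeometry:
    return CameraGeometry()


@pytest.fixture(scope="session")
def response(geometry) -> ResponseModel:
    """Default response with the residual angular blur calibrated once."""
    return calibrate_angular_blur(geometry, ResponseModel(), rng=0, n_events=60_000)


@pytest.fixture(scope="session")
def noiseless_response() -> ResponseModel:
    """All blur channels off: events carry exact kinematics."""
    return ResponseModel(fwhm_ref=0.0, sigma_pos=0.0, sigma_ang_extra=0.0)


def pg_point_scene(x_mm: float = -20.0, rate: float = 10.0) -> Scene:
    """A bare 478 keV point source on the target plane (no backgrounds)."""
    return Scene(
        name="pg_point",
        components=(
            SourceComponent(
                "PG_target",
                Spatial("point", center=(x_mm, 0.0, 130.0)),
                rate,
                line_kev=478.0,
            ),
        ),
        exposure_s=600.0,
    )


@pytest.fixture(scope="session")
def pg_point_events(geometry, response):
    """~6000 blurred events from a 478 keV point source at (-20, 0, 130)."""
    return generate_listmode(pg_point_scene(), geometry, response, seed=11)
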