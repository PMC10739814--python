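#!/usr/bin/env python
"""Calibrate the detector response against the published instrument figures.

The camera is specified by two numbers at 662 keV: 2.2% energy resolution
(FWHM) and a 5.4 deg ARM FWHM.  Energy blur and lateral hit blur alone give
an intrinsic ARM floor below the target; this script finds the residual
Gaussian axis tilt that closes the gap, verifies the recovered ARM on an
independent event sample, and stores the calibrated response for the later
stages.

Writes results/calibration.json.
"""

import json
from dataclasses import replace
from pathlib import Path

import numpy as np

from pgcam import CameraGeometry, ResponseModel, calibrate_angular_blur
from pgcam.camera import arm, fwhm_from_samples
from pgcam.simulate import simulate_point_source_events

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    geometry = CameraGeometry()
    model = ResponseModel()

    from pgcam.camera import _simulated_arm_fwhm

    floor = _simulated_arm_fwhm(geometry, replace(model, sigma_ang_extra=0.0),
                                model.e_ref, 60_000, SEED)
    print(f"intrinsic ARM floor (energy + position blur only): {floor:.2f} deg")

    cal = calibrate_angular_blur(geometry, model, rng=SEED, n_events=60_000)
    print(f"calibrated residual axis tilt: {cal.sigma_ang_extra:.3f} deg (1 sigma)")

    ev = simulate_point_source_events(
        662.0, (0, 0, 130.0), geometry, cal, 100_000, np.random.default_rng(SEED + 1)
    )
    vals, _ = arm(ev, (0, 0, 130.0))
    fwhm = fwhm_from_samples(vals)
    print(f"independent ARM FWHM at 662 keV: {fwhm:.2f} deg (target 5.4)")

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "calibration.json"
    out.write_text(json.dumps({
        "seed": SEED,
        "intrinsic_floor_deg": round(floor, 3),
        "sigma_ang_extra_deg": round(float(cal.sigma_ang_extra), 4),
        "verified_arm_fwhm_deg": round(fwhm, 3),
    }, indent=2) + "\n")
    print(f"-> {out}")


if __name__ == "__main__":
    main()
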