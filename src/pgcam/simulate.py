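"""Seeded Monte-Carlo generation of two-hit list-mode events.

The generator is phenomenological, not a transport code: every component of
a scene directly emits "recorded" two-hit events at its preset rate, with no
attenuation or neutron physics.  For a line component each event is built
from first principles of the measurement:

1. draw an emission point from the component's spatial distribution and an
   emission energy (line energy, optionally broadened by an intrinsic FWHM);
2. pick a scatterer layer (uniform over the eight Si layers) and a uniform
   interaction point on it; the incident direction follows;
3. draw the scattering angle from the Klein-Nishina cross-section at the
   emission energy and a uniform azimuth; the deposited energies follow from
   Compton kinematics with full absorption of the scattered photon;
4. pick an absorber layer (uniform over the four CdTe layers) and intersect
   the scattered ray with it; configurations that miss the 50 mm square are
   resampled (steps 2-4), so the geometric acceptance shapes the recorded
   angular distribution;
5. apply the detector response: lateral Gaussian position blur on both hits,
   a residual Gaussian tilt of the scatterer->absorber axis (the calibrated
   ``sigma_ang_extra``), and Gaussian energy blur on each deposit.

Continuum components instead draw the total energy uniformly over their
range, split it randomly between the hits, and place the two hits uniformly
on random layers (uncorrelated "fake cone" geometry) -- they produce the
flat spectral sidebands and a diffuse image background.

Reproducibility: one global 64-bit seed; each component draws from its own
stream derived from (seed, component label), and the final event order is a
sort on per-event random keys drawn from the same streams.  Removing a
component therefore leaves every other component's events, and their
relative order, unchanged.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .camera import CameraGeometry, ResponseModel, blur_energy
from .listmode import COLUMNS, ListModeSet
from .physics import klein_nishina_unnorm, rotate_about_axis, scattered_energy
from .scenes import Scene, SourceComponent, Spatial

__all__ = [
    "generate_listmode",
    "simulate_point_source_events",
    "component_rng",
]

_MAX_RESAMPLE_ROUNDS = 2000


def component_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-component stream derived from the global seed."""
    key = int.from_bytes(label.encode("utf-8")[:8].ljust(8, b"\0"), "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def _sample_origins(
    spatial: Spatial, n: int, geometry: CameraGeometry, rng: np.random.Generator
) -> np.ndarray:
    c = np.asarray(spatial.center, dtype=float)
    if spatial.kind == "point":
        return np.tile(c, (n, 1))
    if spatial.kind == "box":
        h = np.asarray(spatial.half_sizes, dtype=float)
        return c + rng.uniform(-1.0, 1.0, size=(n, 3)) * h
    if spatial.kind == "cylinder":
        r = spatial.radius * np.sqrt(rng.uniform(0.0, 1.0, n))
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        z = rng.uniform(-0.5, 0.5, n) * spatial.height
        return c + np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    if spatial.kind == "internal_camera":
        h = geometry.half_side
        x = rng.uniform(-h, h, n)
        y = rng.uniform(-h, h, n)
        z = rng.uniform(geometry.z_bottom, 0.0, n)
        return np.column_stack([x, y, z])
    raise ValueError(f"unknown spatial kind {spatial.kind!r}")


def _sample_kn_cos(e0: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorised Klein-Nishina rejection sampling of cos(theta)."""
    n = e0.shape[0]
    out = np.empty(n)
    need = np.ones(n, dtype=bool)
    while np.any(need):
        idx = np.flatnonzero(need)
        c = rng.uniform(-1.0, 1.0, idx.size)
        u = rng.uniform(0.0, 1.0, idx.size)
        ok = u < klein_nishina_unnorm(e0[idx], c)
        out[idx[ok]] = c[ok]
        need[idx[ok]] = False
    return out


def _perp_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal vectors perpendicular to unit row vectors ``d``."""
    ref = np.zeros_like(d)
    use_x = np.abs(d[:, 2]) > 0.9
    ref[use_x, 0] = 1.0
    ref[~use_x, 2] = 1.0
    u = np.cross(d, ref)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(d, u)
    return u, v


def _sample_line_events(
    e0: np.ndarray,
    origins: np.ndarray,
    geometry: CameraGeometry,
    response: ResponseModel,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """True (pre-blur) kinematics + hit geometry, then detector response."""
    n = e0.shape[0]
    h = geometry.half_side
    r1 = np.empty((n, 3))
    r2 = np.empty((n, 3))
    e1_true = np.empty(n)
    e2_true = np.empty(n)
    s_layer = np.empty(n, dtype=int)
    a_layer = np.empty(n, dtype=int)

    pending = np.arange(n)
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        if pending.size == 0:
            break
        m = pending.size
        sl = rng.integers(0, geometry.n_scatterers, m)
        p1 = np.column_stack(
            [
                rng.uniform(-h, h, m),
                rng.uniform(-h, h, m),
                geometry.scatterer_z[sl],
            ]
        )
        d = p1 - origins[pending]
        dist = np.linalg.norm(d, axis=1)
        near = dist < 1e-6
        dist[near] = 1.0  # resampled below via the validity mask
        d /= dist[:, None]

        cos_th = _sample_kn_cos(e0[pending], rng)
        sin_th = np.sqrt(np.clip(1.0 - cos_th**2, 0.0, None))
        phi = rng.uniform(0.0, 2.0 * np.pi, m)
        u, v = _perp_basis(d)
        sdir = (
            cos_th[:, None] * d
            + sin_th[:, None] * (np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * v)
        )

        al = rng.integers(0, geometry.n_absorbers, m)
        z2 = geometry.absorber_z[al]
        down = sdir[:, 2] < -1e-9
        t = np.where(down, (z2 - p1[:, 2]) / np.where(down, sdir[:, 2], -1.0), -1.0)
        p2 = p1 + t[:, None] * sdir
        ok = (
            down
            & ~near
            & (t > 0)
            & (np.abs(p2[:, 0]) <= h)
            & (np.abs(p2[:, 1]) <= h)
        )

        tgt = pending[ok]
        r1[tgt] = p1[ok]
        r2[tgt] = p2[ok]
        s_layer[tgt] = sl[ok]
        a_layer[tgt] = al[ok]
        e_prime = scattered_energy(e0[pending][ok], np.degrees(np.arccos(cos_th[ok])))
        e2_true[tgt] = e_prime
        e1_true[tgt] = e0[pending][ok] - e_prime
        pending = pending[~ok]
    if pending.size:
        raise RuntimeError(
            f"{pending.size} emissions found no accepted detector geometry"
        )

    return _apply_response(
        e1_true, e2_true, r1, r2, s_layer, a_layer, response, rng
    )


def _apply_response(
    e1_true, e2_true, r1, r2, s_layer, a_layer, response, rng
) -> dict[str, np.ndarray]:
    n = e1_true.shape[0]
    r1m = r1.copy()
    r2m = r2.copy()
    if response.sigma_pos > 0:
        r1m[:, :2] += rng.normal(0.0, response.sigma_pos, size=(n, 2))
        r2m[:, :2] += rng.normal(0.0, response.sigma_pos, size=(n, 2))
    if response.sigma_ang_extra > 0 and n > 0:
        # tilt the measured axis about the scatterer hit, then re-intersect
        # the absorber plane so the hit stays on its layer
        vec = r2m - r1m
        vnorm = np.linalg.norm(vec, axis=1, keepdims=True)
        vhat = vec / vnorm
        u, v = _perp_basis(vhat)
        psi = rng.uniform(0.0, 2.0 * np.pi, n)
        rot_axis = np.cos(psi)[:, None] * u + np.sin(psi)[:, None] * v
        alpha = rng.normal(0.0, np.radians(response.sigma_ang_extra), n)
        vt = rotate_about_axis(vhat, rot_axis, alpha)
        # rescale along the tilted ray to the original absorber z-plane;
        # pathological tilts (ray no longer reaching the plane) keep the
        # untilted geometry
        safe = vt[:, 2] * vec[:, 2] > 0
        scale = np.where(safe, vec[:, 2] / np.where(safe, vt[:, 2], 1.0), vnorm[:, 0])
        r2m = r1m + vt * scale[:, None]
    e1 = blur_energy(e1_true, response, rng)
    e2 = blur_energy(e2_true, response, rng)
    return {
        "E1_keV": np.atleast_1d(e1),
        "E2_keV": np.atleast_1d(e2),
        "r1": r1m,
        "r2": r2m,
        "scatterer_layer": s_layer,
        "absorber_layer": a_layer,
    }


def _sample_continuum_events(
    component: SourceComponent,
    n: int,
    geometry: CameraGeometry,
    response: ResponseModel,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    h = geometry.half_side
    lo, hi = component.e_range
    etot = rng.uniform(lo, hi, n)
    frac = rng.uniform(0.02, 0.7, n)
    e1_true = frac * etot
    e2_true = etot - e1_true
    sl = rng.integers(0, geometry.n_scatterers, n)
    al = rng.integers(0, geometry.n_absorbers, n)
    r1 = np.column_stack(
        [rng.uniform(-h, h, n), rng.uniform(-h, h, n), geometry.scatterer_z[sl]]
    )
    r2 = np.column_stack(
        [rng.uniform(-h, h, n), rng.uniform(-h, h, n), geometry.absorber_z[al]]
    )
    # uncorrelated hits: position blur is already immaterial, but energy blur
    # keeps the spectrum response-consistent
    out = _apply_response(e1_true, e2_true, r1, r2, sl, al, response, rng)
    return out


def _component_events(
    component: SourceComponent,
    exposure_s: float,
    geometry: CameraGeometry,
    response: ResponseModel,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray]:
    n = int(rng.poisson(component.intensity * exposure_s))
    if n == 0:
        return pd.DataFrame(columns=COLUMNS[1:]), np.empty(0)
    if component.e_range is not None:
        rec = _sample_continuum_events(component, n, geometry, response, rng)
        truth = np.full((n, 3), np.nan)
    else:
        origins = _sample_origins(component.spatial, n, geometry, rng)
        e0 = np.full(n, float(component.line_kev))
        if component.intrinsic_fwhm > 0:
            e0 = e0 + rng.normal(
                0.0, component.intrinsic_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))), n
            )
            e0 = np.clip(e0, 1.0, None)
        rec = _sample_line_events(e0, origins, geometry, response, rng)
        truth = origins
    df = pd.DataFrame(
        {
            "E1_keV": rec["E1_keV"],
            "E2_keV": rec["E2_keV"],
            "x1_mm": rec["r1"][:, 0],
            "y1_mm": rec["r1"][:, 1],
            "z1_mm": rec["r1"][:, 2],
            "x2_mm": rec["r2"][:, 0],
            "y2_mm": rec["r2"][:, 1],
            "z2_mm": rec["r2"][:, 2],
            "scatterer_layer": rec["scatterer_layer"],
            "absorber_layer": rec["absorber_layer"],
            "truth_label": component.label,
            "truth_x_mm": truth[:, 0],
            "truth_y_mm": truth[:, 1],
            "truth_z_mm": truth[:, 2],
        }
    )
    sort_keys = rng.uniform(0.0, 1.0, n)
    return df, sort_keys


def generate_listmode(
    scene: Scene,
    geometry: CameraGeometry | None = None,
    response: ResponseModel | None = None,
    seed: int = 0,
) -> ListModeSet:
    """Generate a list-mode set for ``scene``; fully reproducible given seed.

    Each component draws from its own (seed, label)-derived stream; events
    are interleaved by sorting on per-event random keys from those streams,
    so dropping a component does not perturb the others.
    """
    geometry = geometry or CameraGeometry()
    response = response or ResponseModel()
    frames = []
    keys = []
    for comp in scene.components:
        rng = component_rng(seed, comp.label)
        df, k = _component_events(comp, scene.exposure_s, geometry, response, rng)
        frames.append(df)
        keys.append(k)
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=COLUMNS[1:]
    )
    key = np.concatenate(keys) if keys else np.empty(0)
    if len(df) == 0:
        warnings.warn(f"scene {scene.name!r} produced no events", stacklevel=2)
    order = np.argsort(key, kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    df.insert(0, "event_id", np.arange(len(df), dtype=int))
    return ListModeSet(
        df=df,
        scene_name=scene.name,
        exposure_s=scene.exposure_s,
        seed=int(seed),
        camera_hash=geometry.config_hash(),
    )


def simulate_point_source_events(
    e0_kev: float,
    source_point,
    geometry: CameraGeometry,
    response: ResponseModel,
    n_events: int,
    rng: np.random.Generator | int | None = None,
) -> ListModeSet:
    """``n_events`` monoenergetic events from a point source (for
    calibration and resolution studies)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    origins = np.tile(np.asarray(source_point, dtype=float), (n_events, 1))
    e0 = np.full(n_events, float(e0_kev))
    rec = _sample_line_events(e0, origins, geometry, response, rng)
    df = pd.DataFrame(
        {
            "event_id": np.arange(n_events, dtype=int),
            "E1_keV": rec["E1_keV"],
            "E2_keV": rec["E2_keV"],
            "x1_mm": rec["r1"][:, 0],
            "y1_mm": rec["r1"][:, 1],
            "z1_mm": rec["r1"][:, 2],
            "x2_mm": rec["r2"][:, 0],
            "y2_mm": rec["r2"][:, 1],
            "z2_mm": rec["r2"][:, 2],
            "scatterer_layer": rec["scatterer_layer"],
            "absorber_layer": rec["absorber_layer"],
            "truth_label": "point",
            "truth_x_mm": origins[:, 0],
            "truth_y_mm": origins[:, 1],
            "truth_z_mm": origins[:, 2],
        }
    )
    return ListModeSet(
        df=df,
        scene_name=f"point_{e0_kev:g}keV",
        exposure_s=1.0,
        camera_hash=geometry.config_hash(),
    )
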