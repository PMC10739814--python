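"""Compton-scattering kinematics, Klein-Nishina sampling, and cone geometry.

These are the closed-form primitives shared by the event simulator and the
image reconstructor.  A Compton camera records a photon that scatters once in
a thin scatterer (depositing ``E1`` on the recoil electron) and is then fully
photo-absorbed in an absorber (depositing ``E2``).  The scattering angle
``theta`` follows from energy-momentum conservation,

    cos(theta) = 1 - m_e c^2 * (1/E2 - 1/(E1 + E2)),

with the electron rest energy fixed at 511.0 keV.  Each event therefore
constrains the source direction to a cone whose apex is the scatterer hit,
whose axis points from the absorber hit back through the scatterer hit, and
whose half-angle is ``theta``.

Conventions
-----------
* energies in keV, positions in mm;
* user-facing angles in degrees (instrument resolutions are quoted in
  degrees); radians are used internally;
* kinematically impossible energy pairs (|cos theta| > 1) are flagged with
  NaN rather than raised or clamped -- unfiltered event streams legitimately
  contain such events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: electron rest energy, keV (also the annihilation-line energy)
MEC2 = 511.0

__all__ = [
    "MEC2",
    "Cone",
    "kinematic_cos_theta",
    "kinematic_angle_deg",
    "scattered_energy",
    "compton_edge",
    "sample_kn_angle",
    "klein_nishina_unnorm",
    "geometric_angle_deg",
    "lateral_displacement",
    "rotate_about_axis",
]


@dataclass
class Cone:
    """Back-projection cone(s) for one or many events (structure-of-arrays).

    Attributes
    ----------
    apex : (n, 3) float array
        Scatterer hit position(s), mm.
    axis : (n, 3) float array
        Unit vector(s) pointing from the absorber hit toward the scatterer
        hit, i.e. back toward the source half-space.
    half_angle_deg : (n,) float array
        Kinematic scattering angle, degrees, in (0, 180).
    sigma_axis_deg : (n,) float array
        Per-event 1-sigma angular uncertainty, degrees.
    """

    apex: np.ndarray
    axis: np.ndarray
    half_angle_deg: np.ndarray
    sigma_axis_deg: np.ndarray

    def __post_init__(self) -> None:
        self.apex = np.atleast_2d(np.asarray(self.apex, dtype=float))
        self.axis = np.atleast_2d(np.asarray(self.axis, dtype=float))
        self.half_angle_deg = np.atleast_1d(
            np.asarray(self.half_angle_deg, dtype=float)
        )
        self.sigma_axis_deg = np.broadcast_to(
            np.asarray(self.sigma_axis_deg, dtype=float), self.half_angle_deg.shape
        ).copy()
        norms = np.linalg.norm(self.axis, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("cone axes must be unit vectors (|axis| = 1 to 1e-9)")
        if np.any((self.half_angle_deg <= 0) | (self.half_angle_deg >= 180)):
            raise ValueError("half_angle_deg must lie in (0, 180)")

    def __len__(self) -> int:
        return self.half_angle_deg.shape[0]


def kinematic_cos_theta(e1, e2):
    """cos(theta) from the two deposited energies; NaN flags invalid pairs.

    Parameters
    ----------
    e1, e2 : float or array
        Scatterer and absorber energy deposits, keV.  Both must be > 0.

    Returns
    -------
    float or ndarray
        ``1 - 511*(1/e2 - 1/(e1+e2))`` where that lies in [-1, 1], else NaN.
    """
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    if np.any(e1 <= 0) or np.any(e2 <= 0):
        raise ValueError("deposited energies must be positive")
    cos = 1.0 - MEC2 * (1.0 / e2 - 1.0 / (e1 + e2))
    out = np.where((cos >= -1.0) & (cos <= 1.0), cos, np.nan)
    return out if out.ndim else float(out)


def kinematic_angle_deg(e1, e2):
    """Kinematic scattering angle in degrees; NaN where invalid."""
    cos = np.asarray(kinematic_cos_theta(e1, e2), dtype=float)
    out = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    out = np.where(np.isnan(cos), np.nan, out)
    return out if out.ndim else float(out)


def scattered_energy(e0, theta_deg):
    """Energy of the scattered photon for incident ``e0`` at ``theta_deg``.

    ``E' = E0 / (1 + (E0/511)(1 - cos theta))``; the electron receives
    ``E1 = E0 - E'``.
    """
    e0 = np.asarray(e0, dtype=float)
    theta_deg = np.asarray(theta_deg, dtype=float)
    if np.any(e0 <= 0):
        raise ValueError("incident energy must be positive")
    if np.any((theta_deg < 0) | (theta_deg > 180)):
        raise ValueError("theta must lie in [0, 180] degrees")
    cos = np.cos(np.radians(theta_deg))
    out = e0 / (1.0 + (e0 / MEC2) * (1.0 - cos))
    return out if out.ndim else float(out)


def compton_edge(e0: float) -> float:
    """Maximum electron energy, reached at 180 deg: ``2 E0^2 / (511 + 2 E0)``."""
    if e0 <= 0:
        raise ValueError("incident energy must be positive")
    return 2.0 * e0 * e0 / (MEC2 + 2.0 * e0)


def klein_nishina_unnorm(e0, cos_theta):
    """Unnormalised Klein-Nishina dsigma/dOmega, with the forward peak at 1.

    ``P^2 (P + 1/P - sin^2 theta) / 2`` with ``P = E'/E0``; bounded above by
    its forward value 1 for all energies, which makes it directly usable as a
    rejection-sampling acceptance probability.
    """
    e0 = np.asarray(e0, dtype=float)
    cos_theta = np.asarray(cos_theta, dtype=float)
    p = 1.0 / (1.0 + (e0 / MEC2) * (1.0 - cos_theta))
    sin2 = 1.0 - cos_theta**2
    out = 0.5 * p * p * (p + 1.0 / p - sin2)
    return out if out.ndim else float(out)


def sample_kn_angle(e0: float, rng: np.random.Generator, size=None):
    """Sample scattering polar angle(s) from the Klein-Nishina cross-section.

    The polar angle of the scattered photon is distributed as
    ``pdf(cos theta) ∝ dsigma/dOmega`` (the solid-angle element absorbs the
    sin(theta) factor when sampling in cos theta).  Rejection sampling with a
    uniform proposal on cos theta in [-1, 1] and the exact bound M = 1.

    Returns angle(s) in degrees; scalar when ``size`` is None.
    """
    if e0 <= 0:
        raise ValueError("incident energy must be positive")
    scalar = size is None
    n = 1 if scalar else int(size)
    out = np.empty(n)
    need = np.ones(n, dtype=bool)
    while np.any(need):
        m = int(need.sum())
        c = rng.uniform(-1.0, 1.0, size=m)
        u = rng.uniform(0.0, 1.0, size=m)
        ok = u < klein_nishina_unnorm(e0, c)
        idx = np.flatnonzero(need)[ok]
        out[idx] = np.degrees(np.arccos(c[ok]))
        need[idx] = False
    return float(out[0]) if scalar else out


def geometric_angle_deg(apex, axis, point):
    """Angle (degrees) between a cone axis and the apex->point direction.

    All arguments broadcast over a leading event dimension; ``point`` may be
    a single 3-vector or an (n, 3) array.  Raises if a point coincides with
    its apex.
    """
    apex = np.atleast_2d(np.asarray(apex, dtype=float))
    axis = np.atleast_2d(np.asarray(axis, dtype=float))
    point = np.atleast_2d(np.asarray(point, dtype=float))
    d = point - apex
    norm = np.linalg.norm(d, axis=-1)
    if np.any(norm < 1e-12):
        raise ValueError("point coincides with cone apex")
    cos = np.einsum("...i,...i->...", axis, d) / norm
    ang = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    return float(ang[0]) if ang.shape == (1,) else ang


def lateral_displacement(angle_deg, distance_mm):
    """Lateral shift subtended by ``angle_deg`` at ``distance_mm`` ahead.

    ``tan(angle) * distance``: e.g. a 5-6 degree angular resolution maps to
    an 8.7-10.5 mm displacement on a plane 100 mm from the camera.
    """
    angle_deg = np.asarray(angle_deg, dtype=float)
    out = np.tan(np.radians(angle_deg)) * np.asarray(distance_mm, dtype=float)
    return out if out.ndim else float(out)


def rotate_about_axis(vec: np.ndarray, axis: np.ndarray, angle_rad) -> np.ndarray:
    """Rodrigues rotation of row vectors ``vec`` about unit row vectors ``axis``."""
    vec = np.atleast_2d(vec)
    axis = np.atleast_2d(axis)
    angle_rad = np.atleast_1d(np.asarray(angle_rad, dtype=float))[:, None]
    c = np.cos(angle_rad)
    s = np.sin(angle_rad)
    cross = np.cross(axis, vec)
    dot = np.einsum("ij,ij->i", axis, vec)[:, None]
    return vec * c + cross * s + axis * dot * (1.0 - c)
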