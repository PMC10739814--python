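"""Compton-cone back-projection and list-mode MLEM on the target plane.

Each selected event defines a cone: apex at the scatterer hit, axis from the
absorber hit toward the scatterer hit, half-angle from the Compton kinematic
relation.  Back-projection scores every pixel ``j`` of the plane Z = z0 by a
Gaussian ring weight

    t_ij = exp(-(geo_ij - theta_i)^2 / (2 sigma_i^2)),

where ``geo_ij`` is the angle between the cone axis and the apex->pixel
direction, ``theta_i`` the cone half-angle, and ``sigma_i`` the per-event
angular uncertainty taken from the calibrated ARM scaled to the assumed
source energy.  List-mode MLEM then iterates the multiplicative update

    lambda_j <- (lambda_j / s_j) * sum_i t_ij / sum_m t_im lambda_m

with uniform sensitivity s_j = 1, which monotonically increases the Poisson
log-likelihood sum_i log(sum_m t_im lambda_m).

Half-angle conventions (the assumed 478 keV initial energy can enter two
ways):

* ``"measured-total"`` (default): cos(theta) = 1 - 511 (1/E2 - 1/(E1+E2));
  the assumed energy only sets the angular-uncertainty scale.  Inside a
  +-10 keV window around 478 keV the two conventions are nearly identical.
* ``"assumed-initial"``: cos(theta) = 1 - 511 (1/(E0-E1) - 1/E0) with
  E0 = 478 keV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .camera import ResponseModel
from .listmode import ListModeSet
from .physics import MEC2, Cone

__all__ = [
    "ImageGrid",
    "PlaneImage",
    "MLEMResult",
    "cones_from_listmode",
    "backproject",
    "mlem",
]

_CHUNK = 512  # events per weight-matrix chunk


@dataclass(frozen=True)
class ImageGrid:
    """Pixel grid on the plane Z = ``z_mm`` (target plane, default 130 mm).

    Ranges are adjusted so the span is an integral number of pixels.
    """

    z_mm: float = 130.0
    x_range: tuple[float, float] = (-200.0, 200.0)
    y_range: tuple[float, float] = (-200.0, 200.0)
    pixel_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.pixel_mm <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def nx(self) -> int:
        return int(round((self.x_range[1] - self.x_range[0]) / self.pixel_mm))

    @property
    def ny(self) -> int:
        return int(round((self.y_range[1] - self.y_range[0]) / self.pixel_mm))

    @property
    def x_centers(self) -> np.ndarray:
        return self.x_range[0] + self.pixel_mm * (np.arange(self.nx) + 0.5)

    @property
    def y_centers(self) -> np.ndarray:
        return self.y_range[0] + self.pixel_mm * (np.arange(self.ny) + 0.5)

    def pixel_points(self) -> np.ndarray:
        """(ny*nx, 3) pixel-center coordinates, row-major over (y, x)."""
        xx, yy = np.meshgrid(self.x_centers, self.y_centers)
        zz = np.full_like(xx, self.z_mm)
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])


@dataclass
class PlaneImage:
    """2-D intensity image on the grid plane.

    ``values`` has shape (ny, nx); row 0 is the lowest y.  Back-projection
    and MLEM images are elementwise >= 0; subtracted images may go negative.
    """

    grid: ImageGrid
    values: np.ndarray
    provenance: str = "backprojection"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.ny, self.grid.nx):
            raise ValueError("values shape must be (ny, nx)")

    def argmax_xy(self, exclude_border: int = 0) -> tuple[float, float]:
        """Pixel-center coordinates of the image maximum.

        ``exclude_border`` ignores that many pixels along each edge --
        useful for MLEM images, where poorly-constrained edge pixels can
        accumulate spurious intensity (no sensitivity correction).
        """
        b = exclude_border
        core = self.values[b:-b, b:-b] if b else self.values
        iy, ix = np.unravel_index(np.argmax(core), core.shape)
        return float(self.grid.x_centers[ix + b]), float(self.grid.y_centers[iy + b])

    # -- IO: delimited text, rows from +y_max down, columns -x_max up ------
    def to_text(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.values[::-1], fmt="%.6e")
        meta = {
            "z_mm": self.grid.z_mm,
            "x_range": list(self.grid.x_range),
            "y_range": list(self.grid.y_range),
            "pixel_mm": self.grid.pixel_mm,
            "provenance": self.provenance,
            "orientation": "rows: y from +max down; columns: x from -max up",
        }
        with open(path.with_suffix(path.suffix + ".meta.yaml"), "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)

    @classmethod
    def from_text(cls, path: str | Path) -> "PlaneImage":
        path = Path(path)
        values = np.loadtxt(path)[::-1]
        with open(path.with_suffix(path.suffix + ".meta.yaml")) as fh:
            meta = yaml.safe_load(fh)
        grid = ImageGrid(
            z_mm=float(meta["z_mm"]),
            x_range=tuple(meta["x_range"]),
            y_range=tuple(meta["y_range"]),
            pixel_mm=float(meta["pixel_mm"]),
        )
        return cls(grid=grid, values=values, provenance=meta.get("provenance", ""))


@dataclass
class MLEMResult:
    image: PlaneImage
    log_likelihood: np.ndarray  # one value per iteration
    n_skipped: int  # events with zero forward projection


def cones_from_listmode(
    data: ListModeSet,
    response: ResponseModel | None = None,
    assumed_e0: float = 478.0,
    convention: str = "measured-total",
) -> tuple[Cone, int]:
    """Build per-event cones; kinematically invalid events are skipped.

    Returns the cones and the skipped-event count.  ``sigma_axis`` is the
    ARM sigma of the response model scaled to ``assumed_e0``.
    """
    response = response or ResponseModel()
    e1, e2 = data.e1, data.e2
    etot = e1 + e2
    if convention == "measured-total":
        cos = 1.0 - MEC2 * (1.0 / e2 - 1.0 / etot)
    elif convention == "assumed-initial":
        e2_assumed = assumed_e0 - e1
        cos = np.where(
            e2_assumed > 0,
            1.0 - MEC2 * (1.0 / np.where(e2_assumed > 0, e2_assumed, 1.0) - 1.0 / assumed_e0),
            np.nan,
        )
    else:
        raise ValueError("convention must be 'measured-total' or 'assumed-initial'")
    # open interval: theta = 0 or 180 exactly gives a degenerate cone
    valid = (cos > -1.0) & (cos < 1.0)
    n_skipped = int((~valid).sum())
    r1, r2 = data.r1[valid], data.r2[valid]
    axis = r1 - r2
    axis /= np.linalg.norm(axis, axis=1, keepdims=True)
    cone = Cone(
        apex=r1,
        axis=axis,
        half_angle_deg=np.degrees(np.arccos(cos[valid])),
        sigma_axis_deg=np.full(int(valid.sum()), response.arm_sigma_at(assumed_e0)),
    )
    return cone, n_skipped


def _weight_chunks(cones: Cone, points: np.ndarray):
    """Yield (n_chunk, n_pix) float32 Gaussian ring weights."""
    n = len(cones)
    for lo in range(0, n, _CHUNK):
        hi = min(lo + _CHUNK, n)
        apex = cones.apex[lo:hi]
        d = points[None, :, :] - apex[:, None, :]
        norm = np.linalg.norm(d, axis=2)
        cos = np.einsum("ik,ijk->ij", cones.axis[lo:hi], d) / norm
        geo = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
        delta = geo - cones.half_angle_deg[lo:hi, None]
        sig = cones.sigma_axis_deg[lo:hi, None]
        yield np.exp(-0.5 * (delta / sig) ** 2).astype(np.float32)


def weight_matrix(cones: Cone, grid: ImageGrid) -> np.ndarray:
    """Full event-by-pixel weight matrix (float32)."""
    points = grid.pixel_points()
    if len(cones) == 0:
        return np.zeros((0, points.shape[0]), dtype=np.float32)
    return np.concatenate(list(_weight_chunks(cones, points)), axis=0)


def backproject(
    data: ListModeSet,
    grid: ImageGrid | None = None,
    response: ResponseModel | None = None,
    assumed_e0: float = 478.0,
    convention: str = "measured-total",
) -> PlaneImage:
    """Sum of per-event Gaussian cone weights on the image plane."""
    grid = grid or ImageGrid()
    cones, _ = cones_from_listmode(data, response, assumed_e0, convention)
    points = grid.pixel_points()
    acc = np.zeros(points.shape[0], dtype=np.float64)
    if len(cones):
        for w in _weight_chunks(cones, points):
            acc += w.sum(axis=0, dtype=np.float64)
    return PlaneImage(
        grid=grid,
        values=acc.reshape(grid.ny, grid.nx),
        provenance="backprojection",
    )


def mlem(
    data: ListModeSet,
    grid: ImageGrid | None = None,
    response: ResponseModel | None = None,
    n_iter: int = 10,
    init: PlaneImage | None = None,
    assumed_e0: float = 478.0,
    convention: str = "measured-total",
) -> MLEMResult:
    """List-mode MLEM with uniform sensitivity.

    Starts from a uniform image unless ``init`` is given.  Events whose
    forward projection is zero (cone entirely off-grid) are skipped and
    counted.  The returned log-likelihood trace is non-decreasing.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    grid = grid or ImageGrid()
    cones, n_invalid = cones_from_listmode(data, response, assumed_e0, convention)
    t = weight_matrix(cones, grid).astype(np.float64)
    if init is None:
        lam = np.ones(grid.ny * grid.nx)
    else:
        lam = init.values.ravel().astype(float).copy()
        if np.all(lam <= 0):
            raise ValueError("initial image must contain positive pixels")
    fwd0 = t @ lam
    live = fwd0 > 0
    n_skipped = int((~live).sum())
    t = t[live]
    loglik = np.empty(n_iter)
    for k in range(n_iter):
        fwd = t @ lam
        loglik[k] = float(np.sum(np.log(fwd)))
        lam = lam * (t.T @ (1.0 / fwd))
    img = PlaneImage(
        grid=grid,
        values=lam.reshape(grid.ny, grid.nx),
        provenance=f"mlem({n_iter} iterations)",
    )
    return MLEMResult(image=img, log_likelihood=loglik, n_skipped=n_skipped)
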