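"""Total-energy spectra, photopeak fits, and net/gross peak estimation.

The net/gross ratio quantifies how much of the counts in the 478 keV peak
window stand above the smooth background: the background under the peak is
estimated by an unweighted straight-line fit to two sideband regions
(450-463 and 493-499 keV by default), integrated across the peak window,
and subtracted from the gross window sum.  Uncertainty on the ratio comes
from Poisson counting on the gross sum and the sideband fit covariance via
the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

from .listmode import ListModeSet

__all__ = [
    "Spectrum",
    "NetGrossResult",
    "PhotopeakFit",
    "histogram_energies",
    "net_gross_ratio",
    "fit_photopeak",
]

DEFAULT_PEAK_WINDOW = (468.0, 488.0)
DEFAULT_SIDEBANDS = ((450.0, 463.0), (493.0, 499.0))


@dataclass
class Spectrum:
    """Binned total-energy histogram with half-open [lo, hi) bins."""

    edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.counts) != len(self.edges) - 1:
            raise ValueError("len(counts) must equal len(edges) - 1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def errors(self) -> np.ndarray:
        """Per-bin Poisson sigma = sqrt(counts)."""
        return np.sqrt(self.counts)

    @property
    def bin_width(self) -> np.ndarray:
        return np.diff(self.edges)

    def to_text(self, path: str | Path) -> None:
        """Two-column text: bin_center_keV, counts."""
        np.savetxt(
            path,
            np.column_stack([self.centers, self.counts]),
            fmt="%.4f %.0f",
            header="bin_center_keV counts",
        )


@dataclass
class NetGrossResult:
    gross: float
    bg_est: float
    net: float
    ratio: float
    sigma_ratio: float
    fit_slope: float
    fit_intercept: float
    low_signal: bool  # net < 0: ratio reported as computed but flagged
    undefined: bool  # gross = 0: ratio meaningless

    def as_dict(self) -> dict:
        return {
            "gross": self.gross,
            "bg_est": self.bg_est,
            "net": self.net,
            "ratio": self.ratio,
            "sigma_ratio": self.sigma_ratio,
            "fit_slope": self.fit_slope,
            "fit_intercept": self.fit_intercept,
            "low_signal": self.low_signal,
            "undefined": self.undefined,
        }


@dataclass
class PhotopeakFit:
    centroid: float
    fwhm: float
    area: float
    ok: bool


def histogram_energies(
    data: ListModeSet,
    bin_width: float = 2.0,
    e_range: tuple[float, float] = (300.0, 700.0),
) -> Spectrum:
    """Histogram E1+E2 into half-open bins of ``bin_width`` over ``e_range``."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = e_range
    if hi <= lo:
        raise ValueError("empty energy range")
    n_bins = int(np.ceil((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(data.etot, bins=edges)
    return Spectrum(edges=edges, counts=counts.astype(float))


def net_gross_ratio(
    spec: Spectrum,
    peak_window: tuple[float, float] = DEFAULT_PEAK_WINDOW,
    sidebands: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_SIDEBANDS,
) -> NetGrossResult:
    """Net/gross counts of the peak window with linear-sideband background.

    Bins belong to a region when their centers fall inside it (inclusive).
    The sideband fit is unweighted least squares of counts vs bin center;
    ``bg_est`` is the fitted line summed over the window bins.
    """
    c = spec.centers
    in_window = (c >= peak_window[0]) & (c <= peak_window[1])
    in_side = np.zeros_like(in_window)
    for lo, hi in sidebands:
        if lo >= peak_window[0] and hi <= peak_window[1]:
            raise ValueError("sidebands must be disjoint from the peak window")
        in_side |= (c >= lo) & (c <= hi)
    if in_side.sum() < 2:
        raise ValueError("need at least 2 sideband bins for the linear fit")
    if (c[in_side].min() < spec.edges[0]) or (c[in_side].max() > spec.edges[-1]):
        raise ValueError("sidebands must lie inside the spectrum range")

    coeffs, cov = np.polyfit(c[in_side], spec.counts[in_side], 1, cov="unscaled")
    # rescale covariance: polyfit's unscaled cov assumes unit data sigma;
    # use the Poisson scale of the mean sideband count instead
    mean_side = max(spec.counts[in_side].mean(), 1.0)
    cov = cov * mean_side
    slope, intercept = coeffs
    wc = c[in_window]
    gross = float(spec.counts[in_window].sum())
    bg_est = float(np.polyval(coeffs, wc).sum())
    net = gross - bg_est

    # delta method: ratio = 1 - bg/gross with var(gross) = gross (Poisson)
    # and var(bg) from the fit covariance via bg = slope*S1 + intercept*S0
    s1, s0 = wc.sum(), float(len(wc))
    var_bg = float(np.array([s1, s0]) @ cov @ np.array([s1, s0]))
    if gross > 0:
        ratio = net / gross
        var_ratio = (bg_est / gross**2) ** 2 * gross + var_bg / gross**2
        sigma_ratio = float(np.sqrt(var_ratio))
        undefined = False
    else:
        ratio = np.nan
        sigma_ratio = np.nan
        undefined = True
    return NetGrossResult(
        gross=gross,
        bg_est=bg_est,
        net=net,
        ratio=ratio,
        sigma_ratio=sigma_ratio,
        fit_slope=float(slope),
        fit_intercept=float(intercept),
        low_signal=bool(net < 0),
        undefined=undefined,
    )


def fit_photopeak(
    spec: Spectrum, window: tuple[float, float]
) -> PhotopeakFit:
    """Gaussian + linear-baseline least-squares fit of a peak in ``window``.

    Returns centroid (keV), FWHM (keV), and Gaussian area (counts).  A fit
    that fails to converge returns ``ok=False`` with NaNs.
    """
    c = spec.centers
    m = (c >= window[0]) & (c <= window[1])
    if m.sum() < 5:
        raise ValueError("window must contain at least 5 bins")
    x, y = c[m], spec.counts[m]
    base = np.median(y[[0, 1, -2, -1]])
    i_max = int(np.argmax(y))
    p0 = (max(y[i_max] - base, 1.0), x[i_max], max((window[1] - window[0]) / 6, 1.0),
          0.0, base)

    def model(t, a, mu, s, slope, b):
        return a * np.exp(-0.5 * ((t - mu) / s) ** 2) + slope * (t - mu) + b

    try:
        popt, _ = curve_fit(model, x, y, p0=p0, maxfev=10000)
    except RuntimeError:
        return PhotopeakFit(np.nan, np.nan, np.nan, ok=False)
    a, mu, s = popt[0], popt[1], abs(popt[2])
    fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0)) * s
    bw = float(np.mean(spec.bin_width))
    area = a * s * np.sqrt(2.0 * np.pi) / bw
    return PhotopeakFit(centroid=float(mu), fwhm=float(fwhm), area=float(area), ok=True)
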