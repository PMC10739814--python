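"""Spectra, photopeak fits, and the net/gross peak-ratio estimator."""

import numpy as np
import pandas as pd
import pytest

from pgcam.camera import FWHM_OVER_SIGMA, ResponseModel, blur_energy
from pgcam.listmode import COLUMNS, ListModeSet
from pgcam.spectroscopy import (
    Spectrum,
    fit_photopeak,
    histogram_energies,
    net_gross_ratio,
)


def listmode_from_etot(etot):
    """Minimal list-mode set carrying given total energies (split 30/70)."""
    etot = np.asarray(etot, dtype=float)
    n = len(etot)
    df = pd.DataFrame(
        {
            "event_id": np.arange(n),
            "E1_keV": 0.3 * etot,
            "E2_keV": 0.7 * etot,
            "x1_mm": 0.0, "y1_mm": 0.0, "z1_mm": 0.0,
            "x2_mm": 0.0, "y2_mm": 0.0, "z2_mm": -60.0,
            "scatterer_layer": 0, "absorber_layer": 0,
            "truth_label": "none",
            "truth_x_mm": np.nan, "truth_y_mm": np.nan, "truth_z_mm": np.nan,
        }
    )
    return ListModeSet(df=df[COLUMNS])


def flat_plus_peak(level=10.0, peak=200.0, lo=440.0, hi=510.0, slope=0.0):
    """Analytic spectrum: linear background plus a peak inside [468, 488)."""
    edges = np.arange(lo, hi + 1.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = level + slope * (centers - 478.0)  # pivot at the window center
    in_window = (centers >= 468.0) & (centers <= 488.0)
    counts = counts + np.where(in_window, peak / in_window.sum(), 0.0)
    return Spectrum(edges=edges, counts=counts)


class TestHistogram:
    def test_single_event_lands_in_half_open_bin(self):
        spec = histogram_energies(listmode_from_etot([478.0]), bin_width=1.0,
                                  e_range=(470.0, 490.0))
        idx = np.searchsorted(spec.edges, 478.0, side="right") - 1
        assert spec.counts[idx] == 1
        assert spec.counts.sum() == 1

    def test_count_conservation_with_out_of_range(self):
        etot = [350.0, 478.0, 900.0]  # last one out of range
        spec = histogram_energies(listmode_from_etot(etot))
        assert spec.counts.sum() == 2

    def test_blurred_line_centroid_recovered(self):
        rng = np.random.default_rng(8)
        etot = blur_energy(np.full(100_000, 478.0), ResponseModel(), rng)
        spec = histogram_energies(listmode_from_etot(etot), bin_width=1.0,
                                  e_range=(430.0, 530.0))
        fit = fit_photopeak(spec, (455.0, 500.0))
        assert fit.ok
        assert fit.centroid == pytest.approx(478.0, abs=0.1)

    def test_empty_range_raises(self):
        with pytest.raises(ValueError):
            histogram_energies(listmode_from_etot([478.0]), e_range=(500.0, 400.0))


class TestNetGross:
    def test_flat_background_analytic_ratio(self):
        # 20 window bins at 10 counts + 200 net counts: ratio = 200/400
        res = net_gross_ratio(flat_plus_peak())
        assert res.gross == pytest.approx(400.0)
        assert res.bg_est == pytest.approx(200.0, abs=1e-9)
        assert res.ratio == pytest.approx(0.500, abs=1e-9)
        assert not res.low_signal

    def test_pure_background_ratio_consistent_with_zero(self):
        rng = np.random.default_rng(12)
        edges = np.arange(440.0, 511.0)
        counts = rng.poisson(100.0, len(edges) - 1).astype(float)
        res = net_gross_ratio(Spectrum(edges=edges, counts=counts))
        assert abs(res.ratio) < 3 * res.sigma_ratio

    def test_ratio_monotone_in_peak_amplitude(self):
        ratios = [net_gross_ratio(flat_plus_peak(peak=p)).ratio
                  for p in (50.0, 100.0, 200.0, 400.0)]
        assert np.all(np.diff(ratios) > 0)

    def test_invariant_under_linear_background(self):
        base = net_gross_ratio(flat_plus_peak(level=20.0, slope=0.0)).ratio
        tilted = net_gross_ratio(flat_plus_peak(level=20.0, slope=0.25)).ratio
        assert tilted == pytest.approx(base, abs=1e-10)

    def test_negative_net_is_flagged_not_hidden(self):
        spec = flat_plus_peak(peak=0.0)
        spec.counts[(spec.centers >= 468) & (spec.centers <= 488)] -= 3.0
        res = net_gross_ratio(spec)
        assert res.low_signal
        assert res.ratio < 0

    def test_too_few_sideband_bins_raise(self):
        spec = flat_plus_peak()
        with pytest.raises(ValueError):
            net_gross_ratio(spec, sidebands=((450.0, 450.5), (451.0, 451.2)))


class TestPhotopeakFit:
    def test_noiseless_gaussian_width(self):
        sigma = 662.0 * 0.022 / FWHM_OVER_SIGMA
        edges = np.arange(600.0, 725.0)
        c = 0.5 * (edges[:-1] + edges[1:])
        counts = 1e4 * np.exp(-0.5 * ((c - 662.0) / sigma) ** 2)
        fit = fit_photopeak(Spectrum(edges=edges, counts=counts), (620.0, 700.0))
        assert fit.fwhm / fit.centroid == pytest.approx(0.022, rel=1e-3)

    def test_pg_ag_line_separation(self):
        """Fitted centroids of simulated 478/511 keV lines are 33 keV apart."""
        rng = np.random.default_rng(21)
        model = ResponseModel()
        pg = blur_energy(np.full(30_000, 478.0), model, rng)
        ag = blur_energy(np.full(15_000, 511.0), model, rng)
        spec = histogram_energies(
            listmode_from_etot(np.concatenate([pg, ag])), bin_width=1.0,
            e_range=(430.0, 560.0)
        )
        f_pg = fit_photopeak(spec, (460.0, 494.0))
        f_ag = fit_photopeak(spec, (495.0, 530.0))
        assert f_pg.ok and f_ag.ok
        assert f_ag.centroid - f_pg.centroid == pytest.approx(33.0, abs=1.0)

    def test_centroid_scale_invariant(self):
        spec = flat_plus_peak(peak=500.0)
        f1 = fit_photopeak(spec, (460.0, 495.0))
        f2 = fit_photopeak(Spectrum(spec.edges, spec.counts * 7.0), (460.0, 495.0))
        assert f2.centroid == pytest.approx(f1.centroid, abs=1e-6)
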