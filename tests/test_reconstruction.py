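"""Cone building, back-projection, and list-mode MLEM."""

import numpy as np
import pandas as pd
import pytest

from pgcam import generate_listmode, select_events
from pgcam.physics import geometric_angle_deg
from pgcam.reconstruction import (
    ImageGrid,
    PlaneImage,
    backproject,
    cones_from_listmode,
    mlem,
    weight_matrix,
)
from pgcam.simulate import simulate_point_source_events

from conftest import pg_point_scene

SOURCE = (-20.0, 0.0, 130.0)


@pytest.fixture(scope="module")
def selected_pg(geometry, response):
    lm = generate_listmode(pg_point_scene(), geometry, response, seed=11)
    sel, _ = select_events(lm)
    return sel


@pytest.fixture(scope="module")
def grid():
    return ImageGrid()


class TestImageGrid:
    def test_pixel_layout(self, grid):
        assert grid.nx == grid.ny == 80
        assert grid.x_centers[0] == -197.5
        assert grid.x_centers[-1] == 197.5

    def test_points_on_plane(self, grid):
        pts = grid.pixel_points()
        assert pts.shape == (6400, 3)
        assert np.all(pts[:, 2] == 130.0)


class TestCones:
    def test_unblurred_cone_contains_source_exactly(self, geometry,
                                                    noiseless_response):
        ev = simulate_point_source_events(
            478.0, SOURCE, geometry, noiseless_response, 200,
            np.random.default_rng(1)
        )
        cones, n_skip = cones_from_listmode(ev, noiseless_response)
        assert n_skip == 0
        geo = geometric_angle_deg(cones.apex, cones.axis, np.asarray(SOURCE))
        np.testing.assert_allclose(geo, cones.half_angle_deg, atol=1e-9)

    def test_half_angle_from_measured_energies(self, selected_pg, response):
        cones, _ = cones_from_listmode(selected_pg, response)
        row = selected_pg.df.iloc[0]
        expected = np.degrees(np.arccos(
            1.0 - 511.0 * (1.0 / row.E2_keV - 1.0 / (row.E1_keV + row.E2_keV))
        ))
        assert cones.half_angle_deg[0] == pytest.approx(expected, abs=1e-9)

    def test_assumed_initial_convention(self, selected_pg, response):
        cones, _ = cones_from_listmode(
            selected_pg, response, convention="assumed-initial"
        )
        row = selected_pg.df.iloc[0]
        expected = np.degrees(np.arccos(
            1.0 - 511.0 * (1.0 / (478.0 - row.E1_keV) - 1.0 / 478.0)
        ))
        assert cones.half_angle_deg[0] == pytest.approx(expected, abs=1e-9)

    def test_conventions_agree_inside_window(self, selected_pg, response):
        a, _ = cones_from_listmode(selected_pg, response)
        b, _ = cones_from_listmode(selected_pg, response,
                                   convention="assumed-initial")
        # within the +-10 keV window the two differ by well under the ARM sigma
        common = min(len(a), len(b))
        assert np.median(np.abs(
            a.half_angle_deg[:common] - b.half_angle_deg[:common]
        )) < 2.0

    def test_invalid_kinematics_skipped_with_count(self, response):
        from test_selection import make_events

        data = make_events([(350.0, 128.0, 3, 2), (100.0, 378.0, 3, 2)])
        cones, n_skip = cones_from_listmode(data, response)
        assert n_skip == 1
        assert len(cones) == 1


class TestBackprojection:
    def test_single_event_peaks_on_cone_ring(self, geometry, noiseless_response,
                                             grid):
        ev = simulate_point_source_events(
            478.0, SOURCE, geometry, noiseless_response, 1,
            np.random.default_rng(3)
        )
        img = backproject(ev, grid, noiseless_response)
        iy, ix = np.unravel_index(np.argmax(img.values), img.values.shape)
        peak = np.array([grid.x_centers[ix], grid.y_centers[iy], grid.z_mm])
        cones, _ = cones_from_listmode(ev, noiseless_response)
        geo = geometric_angle_deg(cones.apex[0], cones.axis[0], peak)
        # the max pixel lies on the cone-plane intersection curve (within a
        # pixel's angular footprint)
        assert abs(geo - cones.half_angle_deg[0]) < 2.0

    def test_point_source_argmax_within_one_pixel(self, selected_pg, grid,
                                                  response):
        img = backproject(selected_pg, grid, response)
        x, y = img.argmax_xy()
        assert abs(x - SOURCE[0]) <= grid.pixel_mm
        assert abs(y - SOURCE[1]) <= grid.pixel_mm

    def test_linearity_under_concatenation(self, geometry, response, grid):
        a = generate_listmode(pg_point_scene(rate=1.0), geometry, response, seed=1)
        b = generate_listmode(pg_point_scene(rate=1.0), geometry, response, seed=2)
        both = a.df.copy()
        combined = pd.concat([a.df, b.df], ignore_index=True)
        combined["event_id"] = np.arange(len(combined))
        from pgcam.listmode import ListModeSet

        ab = ListModeSet(df=combined)
        img = backproject(ab, grid, response)
        img_sum = backproject(a, grid, response).values + backproject(
            b, grid, response
        ).values
        np.testing.assert_allclose(img.values, img_sum, rtol=1e-5)

    def test_empty_data_gives_zero_image(self, grid, response):
        from test_selection import make_events

        img = backproject(make_events([]), grid, response)
        assert np.all(img.values == 0)

    def test_rigid_x_translation_shifts_argmax(self, selected_pg, grid, response):
        shifted = selected_pg.df.copy()
        shifted["x1_mm"] += 30.0
        shifted["x2_mm"] += 30.0
        from pgcam.listmode import ListModeSet

        img0 = backproject(selected_pg, grid, response)
        img1 = backproject(ListModeSet(df=shifted), grid, response)
        x0, y0 = img0.argmax_xy()
        x1, y1 = img1.argmax_xy()
        assert x1 - x0 == pytest.approx(30.0, abs=grid.pixel_mm)
        assert y1 == pytest.approx(y0, abs=grid.pixel_mm)


class TestMLEM:
    def test_loglik_monotone_and_image_nonnegative(self, selected_pg, grid,
                                                   response):
        res = mlem(selected_pg, grid, response, n_iter=8)
        assert np.all(np.diff(res.log_likelihood) >= -1e-9)
        assert np.all(res.image.values >= 0)

    def test_first_iterate_is_normalised_backprojection(self, selected_pg, grid,
                                                        response):
        res = mlem(selected_pg, grid, response, n_iter=1)
        cones, _ = cones_from_listmode(selected_pg, response)
        t = weight_matrix(cones, grid).astype(np.float64)
        expected = t.T @ (1.0 / t.sum(axis=1))
        ratio = res.image.values.ravel() / expected
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)

    def test_sharpens_point_source_over_backprojection(self, selected_pg, grid,
                                                       response):
        bp = backproject(selected_pg, grid, response)
        ml = mlem(selected_pg, grid, response, n_iter=10).image
        pb_bp = bp.values.max() / bp.values.mean()
        pb_ml = ml.values.max() / ml.values.mean()
        assert pb_ml >= pb_bp

    def test_zero_init_rejected(self, selected_pg, grid, response):
        zero = PlaneImage(grid=grid, values=np.zeros((grid.ny, grid.nx)))
        with pytest.raises(ValueError):
            mlem(selected_pg, grid, response, n_iter=1, init=zero)


class TestImageIO:
    def test_text_roundtrip(self, selected_pg, grid, response, tmp_path):
        img = backproject(selected_pg, grid, response)
        img.to_text(tmp_path / "img.txt")
        back = PlaneImage.from_text(tmp_path / "img.txt")
        np.testing.assert_allclose(back.values, img.values, rtol=1e-5)
        assert back.grid == img.grid
        assert back.provenance == "backprojection"
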