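"""Monte-Carlo list-mode generator: determinism, geometry, bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pgcam import generate_listmode, preset_scene
from pgcam.listmode import COLUMNS, ListModeSet
from pgcam.physics import kinematic_cos_theta
from pgcam.scenes import Scene, SourceComponent, Spatial

from conftest import pg_point_scene

PHYSICS_COLS = [c for c in COLUMNS if c != "event_id"]


class TestDeterminism:
    def test_same_seed_same_events(self, geometry, response, tmp_path):
        scene = preset_scene("no_target").with_exposure(60.0)
        a = generate_listmode(scene, geometry, response, seed=3)
        b = generate_listmode(scene, geometry, response, seed=3)
        pd.testing.assert_frame_equal(a.df, b.df)
        a.to_csv(tmp_path / "a.csv")
        b.to_csv(tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_different_seed_different_events(self, geometry, response):
        scene = preset_scene("no_target").with_exposure(60.0)
        a = generate_listmode(scene, geometry, response, seed=3)
        b = generate_listmode(scene, geometry, response, seed=4)
        assert not a.df.equals(b.df)

    def test_component_removal_leaves_others_untouched(self, geometry, response):
        """Per-component streams: dropping the target reproduces the pure
        background run event-for-event."""
        scene = preset_scene("b4c_x-2").with_exposure(120.0)
        full = generate_listmode(scene, geometry, response, seed=9)
        bare = generate_listmode(scene.without("PG_target"), geometry, response,
                                 seed=9)
        kept = full.df[full.df["truth_label"] != "PG_target"][PHYSICS_COLS]
        pd.testing.assert_frame_equal(
            kept.reset_index(drop=True), bare.df[PHYSICS_COLS]
        )


class TestEventContent:
    def test_truth_label_bookkeeping(self, geometry, response):
        scene = preset_scene("b4c_x-2").with_exposure(120.0)
        lm = generate_listmode(scene, geometry, response, seed=5)
        counts = lm.df["truth_label"].value_counts()
        assert counts.sum() == len(lm)
        assert set(counts.index) <= {c.label for c in scene.components}

    def test_hits_lie_on_layer_planes(self, geometry, response):
        lm = generate_listmode(pg_point_scene(), geometry, response, seed=2)
        assert np.isin(np.round(lm.r1[:, 2], 6), geometry.scatterer_z).all()
        assert np.isin(np.round(lm.r2[:, 2], 6), geometry.absorber_z).all()
        # lateral positions stay near the 50 mm square (blur can spill a few mm)
        assert np.all(np.abs(lm.r1[:, :2]) < geometry.half_side + 6)

    def test_unblurred_pg_events_are_exactly_kinematic(
        self, geometry, noiseless_response
    ):
        lm = generate_listmode(pg_point_scene(), geometry, noiseless_response, seed=2)
        np.testing.assert_allclose(lm.etot, 478.0, atol=1e-9)
        cos = kinematic_cos_theta(lm.e1, lm.e2)
        assert not np.isnan(cos).any()

    def test_continuum_has_no_truth_origin(self, geometry, response):
        scene = preset_scene("no_target").with_exposure(30.0)
        lm = generate_listmode(scene, geometry, response, seed=6)
        cont = lm.df[lm.df["truth_label"] == "continuum"]
        assert len(cont) > 0
        assert cont["truth_x_mm"].isna().all()

    def test_empty_scene_warns(self, geometry, response):
        scene = Scene(
            "void",
            (SourceComponent("dead", Spatial("point", center=(0, 0, 130.0)), 0.0,
                             line_kev=478.0),),
            exposure_s=10.0,
        )
        with pytest.warns(UserWarning, match="no events"):
            lm = generate_listmode(scene, geometry, response, seed=0)
        assert len(lm) == 0


class TestStatistics:
    def test_component_counts_are_poisson(self, geometry, response):
        """Chi-square goodness of fit of per-replicate counts vs Poisson."""
        mean = 5.0
        scene = Scene(
            "tiny",
            (SourceComponent("PG", Spatial("point", center=(0, 0, 130.0)), mean,
                             line_kev=478.0),),
            exposure_s=1.0,
        )
        counts = np.array([
            len(generate_listmode(scene, geometry, response, seed=s))
            for s in range(200)
        ])
        # pool the tails so every expected cell count is >= ~5
        edges = [-0.5, 2.5, 3.5, 4.5, 5.5, 6.5, 7.5, np.inf]
        obs, _ = np.histogram(counts, bins=edges)
        k = np.arange(0, 40)
        pmf = stats.poisson.pmf(k, mean)
        exp = np.array([
            pmf[(k >= np.ceil(lo)) & (k <= np.floor(hi))].sum()
            for lo, hi in zip(edges[:-1], edges[1:])
        ]) * len(counts)
        chi2 = ((obs - exp) ** 2 / exp).sum()
        crit = stats.chi2.ppf(1 - 0.001, df=len(obs) - 1)
        assert chi2 < crit


class TestListModeIO:
    def test_csv_roundtrip(self, geometry, response, tmp_path):
        lm = generate_listmode(pg_point_scene(rate=1.0), geometry, response, seed=1)
        path = tmp_path / "events.csv"
        lm.to_csv(path)
        back = ListModeSet.from_csv(path)
        assert back.scene_name == lm.scene_name
        assert back.exposure_s == lm.exposure_s
        assert back.seed == lm.seed
        assert back.camera_hash == lm.camera_hash
        np.testing.assert_allclose(back.e1, lm.e1, atol=1e-6)
        np.testing.assert_allclose(back.r2, lm.r2, atol=1e-6)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            ListModeSet(df=pd.DataFrame({"E1_keV": [1.0]}))
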