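"""Scene serialisation, emissivity correction and ROI extraction."""

import json

import numpy as np
import pytest

from thermetab import scene as sc
from thermetab import synthetic as syn
from thermetab.micromet import air_properties, resistance_set
from thermetab.thermal import forward_delta_t, model_reference_temps


def make_scene(grid=None, rois=None, **kw):
    if grid is None:
        grid = np.full((40, 40), 300.0, dtype=np.float32)
    if rois is None:
        rois = [sc.ROI(name="p1", kind="plant", rect=(5, 5, 15, 15), treatment="W")]
    return sc.ThermalScene(grid=grid, pixel_size=0.025, rois=rois, **kw)


class TestSerialisation:
    @pytest.mark.parametrize("suffix", [".npy", ".tif", ".csv"])
    def test_round_trip_bit_exact(self, tmp_path, suffix, rng):
        grid = rng.uniform(290, 310, size=(30, 25)).astype(np.float32)
        scene = make_scene(grid=grid)
        raster = tmp_path / f"scene{suffix}"
        sc.save_scene(scene, raster, tmp_path / "rois.json")
        back = sc.load_scene(raster, tmp_path / "rois.json")
        assert np.array_equal(back.grid, grid.astype(float))
        assert back.pixel_size == scene.pixel_size
        assert back.rois == scene.rois
        assert back.emissivity_canopy == scene.emissivity_canopy

    def test_roi_outside_grid_named_in_error(self, tmp_path):
        scene = make_scene()
        sc.save_scene(scene, tmp_path / "s.npy", tmp_path / "r.json")
        doc = json.loads((tmp_path / "r.json").read_text())
        doc["rois"].append({"name": "stray", "kind": "plant", "rect": [0, 0, 100, 100]})
        (tmp_path / "r.json").write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="stray"):
            sc.load_scene(tmp_path / "s.npy", tmp_path / "r.json")

    def test_missing_sidecar(self, tmp_path):
        np.save(tmp_path / "s.npy", np.zeros((5, 5)))
        (tmp_path / "r.json").write_text('{"rois": []}')
        with pytest.raises(FileNotFoundError):
            sc.load_scene(tmp_path / "s.npy", tmp_path / "r.json")

    def test_generator_scene_loads(self, tmp_path, small_truth):
        scene = syn.render_scene(small_truth, sensor_noise_sd=0.05, seed=3)
        sc.save_scene(scene, tmp_path / "s.npy", tmp_path / "r.json")
        back = sc.load_scene(tmp_path / "s.npy", tmp_path / "r.json")
        assert len(back.plant_rois) == 18
        assert {r.kind for r in back.reference_rois} == {"wet", "dry"}


class TestEmissivity:
    def test_unit_emissivity_identity(self):
        assert sc.brightness_to_surface_temperature(300.0, 1.0) == 300.0

    def test_graybody_inversion_value(self):
        assert sc.brightness_to_surface_temperature(300.0, 0.96) == pytest.approx(
            303.08, abs=0.01
        )

    def test_surface_at_least_brightness(self, rng):
        Tb = rng.uniform(270, 330, 50)
        eps = rng.uniform(0.5, 1.0)
        assert np.all(sc.brightness_to_surface_temperature(Tb, eps) >= Tb)

    def test_invalid_emissivity(self):
        with pytest.raises(ValueError):
            sc.brightness_to_surface_temperature(300.0, 0.0)


class TestExtraction:
    def test_uniform_roi_exact(self):
        scene = make_scene(emissivity_canopy=1.0)
        mean, n, sd = sc.extract_roi_temperature(scene, scene.rois[0])
        assert mean == pytest.approx(300.0 - 273.15, abs=1e-12)
        assert n == 90  # 100 pixels, 5 trimmed per tail
        assert sd == 0.0

    def test_hot_outlier_trimmed(self):
        grid = np.full((10, 10), 300.0)
        grid[0, 0] = 400.0  # a soil pixel leaking into the ROI
        scene = sc.ThermalScene(
            grid=grid,
            pixel_size=0.025,
            rois=[sc.ROI(name="p", kind="plant", rect=(0, 0, 10, 10))],
            emissivity_canopy=1.0,
        )
        mean, n, _ = sc.extract_roi_temperature(scene, scene.rois[0], trim_fraction=0.05)
        assert mean == pytest.approx(300.0 - 273.15)
        untrimmed, _, _ = sc.extract_roi_temperature(scene, scene.rois[0], trim_fraction=0.0)
        assert untrimmed > mean

    def test_insufficient_pixels(self):
        scene = make_scene(rois=[sc.ROI(name="tiny", kind="plant", rect=(0, 0, 2, 2))])
        with pytest.raises(ValueError, match="tiny"):
            sc.extract_roi_temperature(scene, scene.rois[0])

    def test_reference_emissivity_applied(self):
        rois = [
            sc.ROI(name="p", kind="plant", rect=(0, 0, 10, 10)),
            sc.ROI(name="w", kind="wet", rect=(10, 0, 20, 10)),
        ]
        grid = np.full((20, 10), 300.0)
        scene = sc.ThermalScene(
            grid=grid, pixel_size=0.025, rois=rois,
            emissivity_canopy=0.96, emissivity_reference=0.95,
        )
        mp, _, _ = sc.extract_roi_temperature(scene, rois[0])
        mw, _, _ = sc.extract_roi_temperature(scene, rois[1])
        assert mp + 273.15 == pytest.approx(300.0 / 0.96**0.25)
        assert mw + 273.15 == pytest.approx(300.0 / 0.95**0.25)

    def test_translation_invariance(self, rng):
        grid = rng.uniform(295, 305, (30, 30))
        roi = sc.ROI(name="p", kind="plant", rect=(4, 6, 14, 16))
        scene = sc.ThermalScene(grid=grid, pixel_size=0.025, rois=[roi])
        shifted_grid = np.pad(grid, ((3, 0), (5, 0)), constant_values=400.0)
        shifted_roi = sc.ROI(name="p", kind="plant", rect=(7, 11, 17, 21))
        shifted = sc.ThermalScene(grid=shifted_grid, pixel_size=0.025, rois=[shifted_roi])
        assert sc.extract_roi_temperature(scene, roi) == sc.extract_roi_temperature(
            shifted, shifted_roi
        )

    def test_polygon_roi(self):
        grid = np.full((20, 20), 300.0)
        tri = sc.ROI(
            name="tri", kind="plant",
            polygon=((0.0, 0.0), (0.0, 19.0), (19.0, 0.0)),
        )
        scene = sc.ThermalScene(grid=grid, pixel_size=0.025, rois=[tri], emissivity_canopy=1.0)
        mean, n, _ = sc.extract_roi_temperature(scene, tri)
        assert mean == pytest.approx(300.0 - 273.15)
        assert 150 < n < 232  # roughly half the square


class TestExtractAll:
    def test_noise_free_round_trip(self, small_truth):
        """Zero sensor noise: extraction recovers painted temperatures exactly."""
        met = small_truth.met
        scene = syn.render_scene(small_truth, sensor_noise_sd=0.0)
        records, refs = sc.extract_all(scene)
        assert len(records) == 18
        air = air_properties(met)
        res = resistance_set(met)
        painted = {
            p.plant_id: met.Ta + forward_delta_t(p.r_c, air, res)
            for p in small_truth.plants.itertuples()
        }
        for rec in records:
            assert rec.Tc == pytest.approx(painted[rec.plant_id], abs=1e-9)
        model = model_reference_temps(met.Ta, air, res)
        assert refs.T_wet == pytest.approx(model.T_wet, abs=1e-9)
        assert refs.T_dry == pytest.approx(model.T_dry, abs=1e-9)

    def test_missing_reference_requires_fallback(self, small_truth):
        scene = syn.render_scene(small_truth, sensor_noise_sd=0.0)
        scene_no_refs = sc.ThermalScene(
            grid=scene.grid, pixel_size=scene.pixel_size,
            rois=scene.plant_rois,
            emissivity_canopy=scene.emissivity_canopy,
            emissivity_reference=scene.emissivity_reference,
        )
        with pytest.raises(ValueError, match="reference"):
            sc.extract_all(scene_no_refs)
        met = small_truth.met
        model = model_reference_temps(
            met.Ta, air_properties(met), resistance_set(met)
        )
        _, refs = sc.extract_all(scene_no_refs, model_refs=model)
        assert refs == model

    def test_degenerate_references_warn(self):
        grid = np.full((30, 30), 300.0)
        rois = [
            sc.ROI(name="p", kind="plant", rect=(0, 0, 10, 10)),
            sc.ROI(name="w", kind="wet", rect=(10, 0, 20, 10)),
            sc.ROI(name="d", kind="dry", rect=(20, 0, 30, 10)),
        ]
        scene = sc.ThermalScene(grid=grid, pixel_size=0.025, rois=rois)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            _, refs = sc.extract_all(scene)
        assert refs.T_dry <= refs.T_wet

    def test_treatment_rank_order_recovered(self, small_truth):
        """Treatments painted from ordered conductances come back in rank order."""
        scene = syn.render_scene(small_truth, sensor_noise_sd=0.0)
        records, _ = sc.extract_all(scene)
        mean_t = {}
        for t in ("W", "C", "D"):
            mean_t[t] = np.mean([r.Tc for r in records if r.treatment == t])
        true_g = small_truth.plants.groupby("treatment")["g_mol"].mean()
        # hotter canopy <=> lower conductance
        assert (mean_t["D"] > mean_t["W"]) == (true_g["D"] < true_g["W"])
        assert (mean_t["C"] > mean_t["W"]) == (true_g["C"] < true_g["W"])


def test_noise_scaling_of_extracted_mean(rng):
    """Across replicates the extracted-mean error SD tracks sigma/sqrt(n)."""
    sigma, reps = 0.05, 150
    roi = sc.ROI(name="p", kind="plant", rect=(0, 0, 12, 12))
    base = np.full((12, 12), 300.0)
    errors = []
    for _ in range(reps):
        grid = base + rng.normal(0.0, sigma, base.shape)
        scene = sc.ThermalScene(
            grid=grid, pixel_size=0.025, rois=[roi], emissivity_canopy=1.0
        )
        mean, _, _ = sc.extract_roi_temperature(scene, roi)
        errors.append(mean + 273.15 - 300.0)
    assert np.std(errors) == pytest.approx(sigma / 12.0, rel=0.25)
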