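"""Cellular pipeline: parameter maps, redox ratio, per-cell aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flimcarbon import (
    FlimImage,
    LabelMasks,
    MultiExpModel,
    evaluate_model,
    normalize_to_control,
    per_cell_summary,
    redox_ratio_map,
)
from flimcarbon.imaging import ParameterMaps, fit_image, label_cells_otsu
from flimcarbon.synthetic import SceneSpec, simulate_cell_scene


@pytest.fixture(scope="module")
def small_scene(irf):
    spec = SceneSpec(
        shape=(72, 72),
        n_cells=4,
        cell_radius_px=(7.0, 10.0),
        cytoplasm_photons=200.0,
        seed=21,
    )
    nadph, fad, masks, truth = simulate_cell_scene(spec, irf=irf)
    return nadph, fad, masks, truth


def constant_maps(shape, alpha1=0.7, tau1=0.6, tau2=2.7, intensity=100.0):
    tau_m = alpha1 * tau1 + (1 - alpha1) * tau2
    return ParameterMaps(
        alpha1=np.full(shape, alpha1),
        tau1=np.full(shape, tau1),
        tau2=np.full(shape, tau2),
        tau_m=np.full(shape, tau_m),
        chi2=np.ones(shape),
        intensity=np.full(shape, intensity),
    )


class TestFitImage:
    def test_uniform_noiseless_image_gives_constant_maps(self, irf):
        """Every pixel carries the same noiseless decay -> maps at truth."""
        model = MultiExpModel.from_arrays([0.7, 0.3], [0.6, 2.7])
        curve = evaluate_model(model, irf, irf.axis, amplitude_scale=300.0)
        counts = np.tile(curve, (8, 8, 1))
        image = FlimImage(counts=counts, axis=irf.axis)
        maps = fit_image(image, irf)
        assert np.all(np.isfinite(maps.tau2))
        np.testing.assert_allclose(maps.alpha1, 0.7, atol=0.01)
        np.testing.assert_allclose(maps.tau1, 0.6, rtol=0.02)
        np.testing.assert_allclose(maps.tau2, 2.7, rtol=0.02)
        np.testing.assert_allclose(
            maps.tau_m, 0.7 * 0.6 + 0.3 * 2.7, rtol=0.02
        )

    def test_background_pixels_are_nan(self, irf):
        model = MultiExpModel.from_arrays([0.7, 0.3], [0.6, 2.7])
        curve = evaluate_model(model, irf, irf.axis, amplitude_scale=300.0)
        counts = np.zeros((9, 9, irf.axis.n_bins))
        counts[0:3, 0:3] = curve  # one bright corner block, rest dark
        maps = fit_image(FlimImage(counts=counts, axis=irf.axis), irf)
        assert np.isnan(maps.tau2[8, 8])
        assert np.isfinite(maps.tau2[1, 1])

    def test_empty_image_rejected(self, irf):
        with pytest.raises(ValueError):
            fit_image(
                FlimImage(
                    counts=np.zeros((0, 0, irf.axis.n_bins)), axis=irf.axis
                ),
                irf,
            )

    def test_scene_recovery_per_cell(self, small_scene, irf):
        """Cell-mean fitted tau2 within 3% of each cell's generator truth,
        and rank order preserved."""
        nadph, fad, masks, truth = small_scene
        maps = fit_image(nadph, irf)
        redox = redox_ratio_map(maps.intensity, fad.astype(float))
        table = per_cell_summary(maps, redox, masks, fad_intensity=fad)
        merged = table.merge(truth.cells, on="cell", suffixes=("", "_true"))
        rel = np.abs(merged["tau2"] - merged["tau2_ns"]) / merged["tau2_ns"]
        assert np.median(rel) < 0.03
        rho = stats.spearmanr(merged["tau2"], merged["tau2_ns"]).statistic
        assert rho > 0.9 or len(merged) < 4
        # redox ratio per cell within a few percent of the drawn truth
        ratio_err = np.abs(merged["redox_ratio"] / merged["redox_ratio_true"] - 1)
        assert np.median(ratio_err) < 0.05


class TestRedoxMap:
    def test_equal_channels_give_unity(self):
        img = np.full((4, 4), 7.0)
        np.testing.assert_allclose(redox_ratio_map(img, img), 1.0)

    def test_doubling_nadph_doubles_ratio(self):
        fad = np.full((4, 4), 5.0)
        np.testing.assert_allclose(redox_ratio_map(2 * fad, fad), 2.0)

    def test_zero_fad_is_nan(self):
        fad = np.array([[1.0, 0.0]])
        ratio = redox_ratio_map(np.ones((1, 2)), fad)
        assert np.isnan(ratio[0, 1]) and ratio[0, 0] == 1.0

    def test_invariant_to_common_gain(self, rng):
        nadph = rng.uniform(10, 100, size=(6, 6))
        fad = rng.uniform(10, 100, size=(6, 6))
        np.testing.assert_allclose(
            redox_ratio_map(nadph, fad), redox_ratio_map(3.7 * nadph, 3.7 * fad)
        )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            redox_ratio_map(np.ones((2, 2)), np.ones((3, 3)))


class TestPerCellSummary:
    def test_single_square_cell_constant_maps(self):
        shape = (10, 10)
        cell = np.zeros(shape, dtype=int)
        cell[2:8, 2:8] = 1
        masks = LabelMasks(cell_labels=cell, nucleus_labels=np.zeros(shape, int))
        maps = constant_maps(shape)
        table = per_cell_summary(maps, np.full(shape, 1.5), masks)
        assert len(table) == 1
        assert table.loc[0, "tau2"] == pytest.approx(2.7)
        assert table.loc[0, "redox_ratio"] == pytest.approx(1.5)
        assert table.loc[0, "n_pixels"] == 36

    def test_nucleus_pixels_excluded(self):
        shape = (10, 10)
        cell = np.zeros(shape, dtype=int)
        cell[0:4, 0:8] = 1
        nucleus = np.zeros(shape, dtype=int)
        nucleus[0:4, 0:4] = 1  # left half of the cell
        masks = LabelMasks(cell_labels=cell, nucleus_labels=nucleus)
        maps = constant_maps(shape)
        redox = np.zeros(shape)
        redox[0:4, 0:4] = 100.0  # nuclear values must not contaminate
        redox[0:4, 4:8] = 2.0
        table = per_cell_summary(maps, redox, masks)
        assert table.loc[0, "redox_ratio"] == pytest.approx(2.0)
        assert table.loc[0, "n_pixels"] == 16

    def test_label_renumbering_invariance(self, rng):
        shape = (12, 12)
        cell = np.zeros(shape, dtype=int)
        cell[1:5, 1:5] = 1
        cell[7:11, 7:11] = 2
        maps = constant_maps(shape)
        maps.tau2 = rng.uniform(2.0, 3.0, size=shape)
        redox = rng.uniform(0.5, 2.0, size=shape)
        masks_a = LabelMasks(cell_labels=cell, nucleus_labels=np.zeros(shape, int))
        swapped = np.where(cell == 1, 2, np.where(cell == 2, 1, 0))
        masks_b = LabelMasks(cell_labels=swapped, nucleus_labels=np.zeros(shape, int))
        ta = per_cell_summary(maps, redox, masks_a).sort_values("tau2")
        tb = per_cell_summary(maps, redox, masks_b).sort_values("tau2")
        np.testing.assert_allclose(ta["tau2"].values, tb["tau2"].values)

    def test_small_cells_dropped(self):
        shape = (8, 8)
        cell = np.zeros(shape, dtype=int)
        cell[0:2, 0:2] = 1  # 4 px < min_pixels
        masks = LabelMasks(cell_labels=cell, nucleus_labels=np.zeros(shape, int))
        with pytest.warns(UserWarning, match="dropped"):
            table = per_cell_summary(constant_maps(shape), np.ones(shape), masks)
        assert table.empty

    def test_empty_mask_warns(self):
        shape = (4, 4)
        masks = LabelMasks(
            cell_labels=np.zeros(shape, int), nucleus_labels=np.zeros(shape, int)
        )
        with pytest.warns(UserWarning, match="no cells"):
            table = per_cell_summary(constant_maps(shape), np.ones(shape), masks)
        assert table.empty

    def test_dish_mean_equals_mean_of_cell_rows(self, small_scene, irf):
        """Aggregation hierarchy: dish mean is the mean over its cell rows."""
        nadph, fad, masks, _ = small_scene
        maps = fit_image(nadph, irf)
        redox = redox_ratio_map(maps.intensity, fad.astype(float))
        table = per_cell_summary(maps, redox, masks)
        dish_mean = table["redox_ratio"].mean()
        assert dish_mean == pytest.approx(np.mean(table["redox_ratio"].to_numpy()))


class TestNormalizeToControl:
    def test_control_maps_to_unity(self):
        control = np.array([0.9, 1.0, 1.1])
        normalized = normalize_to_control(control, control.mean())
        assert normalized.mean() == pytest.approx(1.0)

    def test_treated_vs_control(self):
        assert normalize_to_control([0.8], 1.0)[0] == pytest.approx(0.8)

    def test_scale_invariance(self):
        treated = np.array([0.7, 0.9])
        control_mean = 1.2
        base = normalize_to_control(treated, control_mean)
        scaled = normalize_to_control(3.0 * treated, 3.0 * control_mean)
        np.testing.assert_allclose(base, scaled)

    def test_rejects_nonpositive_control(self):
        with pytest.raises(ValueError):
            normalize_to_control([1.0], 0.0)


def test_otsu_labeler_finds_bright_blobs():
    img = np.zeros((40, 40))
    img[5:15, 5:15] = 100.0
    img[25:35, 22:34] = 80.0
    labels = label_cells_otsu(img)
    assert len(np.unique(labels[labels > 0])) == 2


def test_nucleus_must_lie_in_cell():
    cell = np.zeros((5, 5), dtype=int)
    cell[0:3, 0:3] = 1
    nucleus = np.zeros((5, 5), dtype=int)
    nucleus[4, 4] = 1
    with pytest.raises(ValueError):
        LabelMasks(cell_labels=cell, nucleus_labels=nucleus)
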