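"""Synthetic tissue generator: geometry, determinism, noise model, truth."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import ks_2samp

from stratiquant import LayerBoundarySet, validate_boundaries
from stratiquant import synthetic as syn
from stratiquant.synthetic import (
    COMPARTMENT_CODE,
    SyntheticTissueSpec,
    apply_noise,
    clean_image,
    generate_boundaries,
    generate_stack,
    quantise_stack,
    render_tissue,
    simulate_frames,
    three_patient_specs,
)


def _flat_profiles(epidermis=90.0):
    const = lambda c: (lambda u: np.full_like(np.asarray(u, float), c))
    return {
        "cytoplasm": const(epidermis),
        "nucleus": const(epidermis),
        "membrane": const(epidermis),
        "dermis": const(10.0),
        "cornified": const(120.0),
        "exterior": const(2.0),
    }


class TestSpecValidation:
    def test_default_preset_matches_acquisition_geometry(self):
        spec = SyntheticTissueSpec()
        assert spec.frame_width_px == spec.frame_height_px == 1024
        assert spec.pixel_size_nm == pytest.approx(160.0)
        assert spec.n_frames_averaged == 4
        assert spec.bit_depth == 8
        assert spec.n_slices * spec.z_step_um == pytest.approx(10.0)

    def test_amplitude_exceeding_basal_thickness_rejected(self):
        thick = {"basal": 10.0, "spinous_granular": 36.0,
                 "transitional": 14.0, "cornified": 13.0}
        with pytest.raises(ValueError, match="amplitude"):
            SyntheticTissueSpec(layer_thicknesses_um=thick, undulation_amplitude_um=15.0)

    @pytest.mark.parametrize("field,value", [
        ("photon_gain", 0.0),
        ("n_frames_averaged", 0),
        ("read_noise_sd", -1.0),
        ("membrane_width_px", 0),
    ])
    def test_invalid_scalars_rejected(self, field, value):
        with pytest.raises(ValueError):
            SyntheticTissueSpec(**{field: value})

    def test_zero_layer_thickness_rejected(self):
        thick = {"basal": 15.0, "spinous_granular": 0.0,
                 "transitional": 14.0, "cornified": 13.0}
        with pytest.raises(ValueError, match="positive"):
            SyntheticTissueSpec(layer_thicknesses_um=thick)


class TestGenerateBoundaries:
    def test_zero_amplitude_gives_straight_lines_at_stated_spacings(self, small_spec):
        spec = dataclasses.replace(small_spec, undulation_amplitude_um=0.0)
        b = generate_boundaries(spec, seed=1)
        ppu = spec.px_per_um
        for i in range(4):
            assert np.ptp(b.rows[i]) == pytest.approx(0.0, abs=1e-9)
        t = spec.layer_thicknesses_um
        assert b.rows[0][0] - b.rows[1][0] == pytest.approx(t["basal"] * ppu)
        assert b.rows[1][0] - b.rows[2][0] == pytest.approx(t["spinous_granular"] * ppu)
        assert b.rows[2][0] - b.rows[3][0] == pytest.approx(t["transitional"] * ppu)

    def test_determinism(self, small_spec):
        b1 = generate_boundaries(small_spec, seed=5)
        b2 = generate_boundaries(small_spec, seed=5)
        for p1, p2 in zip(b1.boundaries, b2.boundaries):
            np.testing.assert_array_equal(p1, p2)

    def test_boundaries_are_ordered_and_validated(self, small_spec):
        b = generate_boundaries(small_spec, seed=2)
        assert b.validated
        assert (np.diff(b.rows[::-1], axis=0) > 0).all()

    def test_undulation_amplitude_realised_on_dermal_interface(self, small_spec):
        b = generate_boundaries(small_spec, seed=3)
        amp_px = small_spec.undulation_amplitude_um * small_spec.px_per_um
        realised = np.ptp(b.rows[0]) / 2
        assert realised == pytest.approx(amp_px, rel=0.25)

    def test_tissue_too_tall_for_frame_rejected(self, small_spec):
        spec = dataclasses.replace(small_spec, frame_height_px=128)
        with pytest.raises(ValueError, match="fit"):
            generate_boundaries(spec, seed=1)


class TestRenderTissue:
    def test_zero_nucleus_radius_gives_no_nucleus_pixels(self, small_spec):
        spec = dataclasses.replace(small_spec, nucleus_radius_um=0.0)
        b = generate_boundaries(spec, seed=4)
        truth = render_tissue(b, spec, seed=4)
        assert not truth.compartment_mask("nucleus").any()
        assert truth.compartment_mask("cytoplasm").any()
        assert truth.compartment_mask("membrane").any()

    def test_pixel_on_dermal_interface_has_depth_zero(self):
        rows = (300.0, 240.0, 140.0, 110.0)
        H, W = 400, 64
        b = validate_boundaries(LayerBoundarySet(
            [np.array([[0.0, r], [W - 1.0, r]]) for r in rows], frame_shape=(H, W)))
        spec = SyntheticTissueSpec(frame_width_px=W, frame_height_px=H)
        truth = render_tissue(b, spec, seed=0)
        assert truth.true_depth[300, 20] == pytest.approx(0.0, abs=1e-12)

    def test_straight_boundary_closed_form_depth(self):
        rows = (300.0, 240.0, 140.0, 110.0)
        H, W = 400, 64
        b = validate_boundaries(LayerBoundarySet(
            [np.array([[0.0, r], [W - 1.0, r]]) for r in rows], frame_shape=(H, W)))
        spec = SyntheticTissueSpec(frame_width_px=W, frame_height_px=H)
        truth = render_tissue(b, spec, seed=0)
        assert truth.true_depth[200, 31] == pytest.approx(1.4, abs=1e-12)

    def test_depth_range_and_sentinels(self, small_sim):
        _, truth = small_sim
        d = truth.true_depth
        inside = np.isfinite(d)
        assert d[inside].min() >= 0.0 and d[inside].max() <= 3.0
        assert not np.isfinite(d[truth.compartment_mask("dermis")]).any()
        assert not np.isfinite(d[truth.compartment_mask("cornified")]).any()
        assert not np.isfinite(d[truth.compartment_mask("exterior")]).any()

    def test_boundaries_consistent_with_compartments(self, small_sim):
        _, truth = small_sim
        epidermal = (
            truth.compartment_mask("nucleus")
            | truth.compartment_mask("cytoplasm")
            | truth.compartment_mask("membrane")
        )
        assert np.isfinite(truth.true_depth[epidermal]).all()

    def test_cornified_layer_is_anuclear(self, small_sim):
        _, truth = small_sim
        corn = truth.compartment_mask("cornified")
        assert corn.any()
        assert (truth.compartment_labels[corn] == COMPARTMENT_CODE["cornified"]).all()

    def test_transitional_cells_are_flattened(self, small_sim):
        """Cells in the transitional band have width:height >= ~3."""
        from stratiquant.segmentation import assign_layer_raster, LayerLabel

        _, truth = small_sim
        layers = assign_layer_raster(truth.boundaries)
        cells = truth.cell_labels
        ratios = []
        for cid in np.unique(cells[(layers == LayerLabel.TRANSITIONAL) & (cells > 0)]):
            yy, xx = np.nonzero(cells == cid)
            if len(yy) < 30:
                continue
            ratios.append(np.ptp(xx) / max(np.ptp(yy), 1))
        assert len(ratios) > 3
        assert np.median(ratios) >= 3.0


class TestNoiseModel:
    def test_noiseless_constant_input_gives_constant_output(self, small_spec):
        spec = dataclasses.replace(small_spec, noise_enabled=False)
        stack = apply_noise(np.full((64, 64), 37.0), spec, seed=0)
        assert len(np.unique(stack.voxels)) == 1

    def test_negative_input_rejected(self, small_spec):
        with pytest.raises(ValueError, match="nonneg"):
            apply_noise(np.full((8, 8), -1.0), small_spec, seed=0)
        with pytest.raises(ValueError, match="nonneg"):
            simulate_frames(np.full((8, 8), -1.0), small_spec, seed=0)

    def test_quantisation_bounds(self, small_spec):
        rng = np.random.default_rng(0)
        stack = apply_noise(rng.uniform(0, 200, (64, 64)), small_spec, seed=1)
        assert stack.voxels.min() >= 0
        assert stack.voxels.max() <= 2**small_spec.bit_depth - 1
        assert stack.voxels.dtype == np.uint8

    def test_determinism(self, small_spec):
        img = np.full((32, 32), 80.0)
        s1 = apply_noise(img, small_spec, seed=9)
        s2 = apply_noise(img, small_spec, seed=9)
        np.testing.assert_array_equal(s1.voxels, s2.voxels)

    def test_frame_averaging_divides_variance(self, small_spec):
        """Averaging n frames scales pixel variance by 1/n (MC, reduced n_rep)."""
        img = np.full((16, 16), 60.0)
        spec1 = dataclasses.replace(small_spec, n_frames_averaged=1)
        spec4 = dataclasses.replace(small_spec, n_frames_averaged=4)
        n_rep = 2000
        v1 = np.var([simulate_frames(img, spec1, s) for s in range(n_rep)], axis=0)
        v4 = np.var([simulate_frames(img, spec4, s + n_rep) for s in range(n_rep)], axis=0)
        ratio = v4.mean() / v1.mean()
        assert ratio == pytest.approx(0.25, rel=0.05)

    def test_gain_scale_pre_quantisation_is_invisible_after_digitisation(self, small_spec):
        rng = np.random.default_rng(4)
        analogue = rng.uniform(0, 150, (3, 64, 64))
        q1, _, _ = quantise_stack(analogue, small_spec, gain_scale=1.0)
        q10, _, _ = quantise_stack(analogue, small_spec, gain_scale=10.0)
        np.testing.assert_array_equal(q1, q10)


class TestGenerateStack:
    def test_flat_profiles_noiseless_stack_is_piecewise_constant(self, small_spec):
        spec = dataclasses.replace(
            small_spec, intensity_profiles=_flat_profiles(), noise_enabled=False
        )
        stack, truth = generate_stack(spec, seed=6)
        mid = stack.voxels[0]
        for name in ("cytoplasm", "dermis", "cornified", "exterior"):
            m = truth.compartment_mask(name)
            assert len(np.unique(mid[m])) == 1, name

    def test_determinism_bit_identical(self, small_spec):
        s1, t1 = generate_stack(small_spec, seed=11)
        s2, t2 = generate_stack(small_spec, seed=11)
        np.testing.assert_array_equal(s1.voxels, s2.voxels)
        np.testing.assert_array_equal(t1.compartment_labels, t2.compartment_labels)
        np.testing.assert_array_equal(t1.true_depth, t2.true_depth)

    def test_thickness_scaling_preserves_depth_distribution(self, small_spec):
        """True depth is layer-normalised, so it is thickness-invariant."""
        _, t1 = generate_stack(small_spec, seed=13)
        spec2 = dataclasses.replace(
            small_spec, frame_height_px=small_spec.frame_height_px + 520
        ).scaled(2.0)
        _, t2 = generate_stack(spec2, seed=13)
        d1 = t1.true_depth[np.isfinite(t1.true_depth)]
        d2 = t2.true_depth[np.isfinite(t2.true_depth)]
        assert min(len(d1), len(d2)) > 1e5
        assert ks_2samp(d1, d2).statistic < 0.01

    def test_clean_image_applies_profiles_at_true_depth(self, small_spec):
        _, truth = generate_stack(small_spec, seed=14)
        img = clean_image(truth, small_spec)
        cyto = truth.compartment_mask("cytoplasm")
        u = truth.true_depth[cyto]
        np.testing.assert_allclose(
            img[cyto], syn.default_target_profile(u), rtol=1e-12
        )

    def test_three_patient_preset_multipliers(self):
        specs = three_patient_specs()
        base = SyntheticTissueSpec()
        mults = sorted(
            spec.layer_thicknesses_um["basal"] / base.layer_thicknesses_um["basal"]
            for spec in specs.values()
        )
        assert mults == pytest.approx([0.6, 1.0, 1.6])
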