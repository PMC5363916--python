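"""Phantom generator: geometry, intensity model, corruption operators."""

import dataclasses

import numpy as np
import pytest

from callusmri.phantom import (
    PhantomSpec,
    TissueIntensityModel,
    _uct_grid,
    apply_coil_gradient,
    apply_rician_noise,
    generate_phantom,
    insert_susceptibility_artifacts,
    render_histology_sections,
    rasterize_truth,
    resample_to_mri_grid,
    solve_class_boundaries,
)
from callusmri.volume import ImageVolume, LabelVolume, Tissue, ValidationError

from conftest import small_spec


class TestSpecValidation:
    @pytest.mark.parametrize(
        "overrides",
        [
            {"healing_day": 12},
            {"gap_width": -1.0},
            {"gap_width": 4000.0},  # gap wider than the inter-pin interval
            {"target_fractions": {"bone": 0.7, "cartilage": 0.5, "fibrous": 0.0}},
            {"target_fractions": {"bone": -0.1, "cartilage": 0.1, "fibrous": 0.5}},
            {"coil_gradient_amplitude": 0.5},
            {"artifact_radius": 300.0},  # >= gap_width/2
            {"pin_positions": (100.0, 100.0, 5000.0, 6000.0)},
            {"callus_max_radius": 5000.0},
            {"cortex_thickness": 900.0},
        ],
    )
    def test_invalid_specs_rejected(self, overrides):
        spec = PhantomSpec(**overrides)
        with pytest.raises(ValidationError):
            spec.validate()

    def test_defaults_valid_for_all_days(self):
        for day in (10, 14, 21):
            PhantomSpec(healing_day=day).validate()

    def test_intensity_model_ordering_enforced(self):
        with pytest.raises(ValidationError):
            TissueIntensityModel(cortex=(0.9, 1.4)).validate()
        with pytest.raises(ValidationError):
            TissueIntensityModel(artifact=(5.9, 6.05)).validate()
        TissueIntensityModel().validate()


class TestTruthGeometry:
    def test_seeded_determinism_bit_identical(self):
        spec = PhantomSpec(healing_day=10, seed=7)
        a = generate_phantom(spec, modalities=("mri",))
        b = generate_phantom(spec, modalities=("mri",))
        assert np.array_equal(a.mri.values, b.mri.values)
        assert np.array_equal(a.truth_mri_grid.labels, b.truth_mri_grid.labels)

    def test_multimodality_determinism_small(self):
        spec = small_spec(seed=9)
        a = generate_phantom(spec)
        b = generate_phantom(spec)
        assert np.array_equal(a.uct.values, b.uct.values)
        assert np.array_equal(a.truth.labels, b.truth.labels)
        for sa, sb in zip(a.histology_sections, b.histology_sections):
            assert np.array_equal(sa.labels, sb.labels)

    def test_zero_cartilage_target_yields_no_cartilage(self):
        spec = PhantomSpec(
            healing_day=21,
            target_fractions={"bone": 0.45, "cartilage": 0.0, "fibrous": 0.55},
            seed=3,
        )
        bundle = generate_phantom(spec, modalities=("mri",))
        callus_or_artifact = bundle.truth_mri_grid.mask(
            [Tissue.BONE_CALLUS, Tissue.CARTILAGE, Tissue.FIBROUS, Tissue.ARTIFACT]
        )
        assert callus_or_artifact.any()
        assert not bundle.truth_mri_grid.mask(Tissue.CARTILAGE).any()

    @pytest.mark.parametrize("day", [10, 14, 21])
    @pytest.mark.parametrize("seed", [0, 101])
    def test_fraction_conservation_on_fine_grid(self, day, seed):
        """Truth-grid callus fractions hit the targets within voxelization (±0.02)."""
        spec = PhantomSpec(healing_day=day, seed=seed)
        bounds = solve_class_boundaries(spec)
        spacing, shape, origin = _uct_grid(spec)
        truth = rasterize_truth(spec, bounds, spacing, shape, origin)
        lab = truth.labels
        callus = np.isin(
            lab, [int(Tissue.BONE_CALLUS), int(Tissue.CARTILAGE), int(Tissue.FIBROUS)]
        )
        n = callus.sum()
        got = {
            "bone": (lab == int(Tissue.BONE_CALLUS)).sum() / n,
            "cartilage": (lab == int(Tissue.CARTILAGE)).sum() / n,
            "fibrous": (lab == int(Tissue.FIBROUS)).sum() / n,
        }
        for cls, target in spec.target_fractions.items():
            assert got[cls] == pytest.approx(target, abs=0.02)

    def test_spec_example_fractions_by_direct_voxel_count(self):
        spec = PhantomSpec(
            healing_day=10,
            target_fractions={"bone": 0.10, "cartilage": 0.16, "fibrous": 0.74},
            noise_sigma=0.0,
            seed=7,
        )
        bounds = solve_class_boundaries(spec)
        spacing, shape, origin = _uct_grid(spec)
        truth = rasterize_truth(spec, bounds, spacing, shape, origin)
        lab = truth.labels
        n = np.isin(lab, [3, 4, 5]).sum()
        assert (lab == int(Tissue.BONE_CALLUS)).sum() / n == pytest.approx(0.10, abs=0.02)
        assert (lab == int(Tissue.CARTILAGE)).sum() / n == pytest.approx(0.16, abs=0.02)
        assert (lab == int(Tissue.FIBROUS)).sum() / n == pytest.approx(0.74, abs=0.02)

    def test_intensity_ordering_noise_free(self, clean_bundle):
        """cartilage > fibrous > bony callus > cortex, strictly, without noise."""
        vals = clean_bundle.mri.values
        lab = clean_bundle.truth_mri_grid.labels
        lo_cart = vals[lab == int(Tissue.CARTILAGE)].min()
        hi_fib = vals[lab == int(Tissue.FIBROUS)].max()
        hi_bone = vals[lab == int(Tissue.BONE_CALLUS)].max()
        hi_cortex = vals[lab == int(Tissue.CORTEX)].max()
        assert lo_cart > hi_fib > hi_bone > hi_cortex

    def test_uct_densities_straddle_threshold(self):
        bundle = generate_phantom(small_spec(seed=2))
        mineral = bundle.truth.mask([Tissue.CORTEX, Tissue.BONE_CALLUS])
        assert (bundle.uct.values[mineral] >= 642.0).all()
        assert (bundle.uct.values[~mineral] < 642.0).all()


class TestCoilGradient:
    def test_zero_amplitude_is_identity(self):
        vol = ImageVolume(np.full((4, 5, 6), 3.0), (52.0, 52.0, 350.0))
        out = apply_coil_gradient(vol, 0.0)
        assert np.array_equal(out.values, vol.values)

    def test_linear_ramp_span(self):
        vol = ImageVolume(np.full((11, 3, 3), 10.0), (52.0, 52.0, 350.0))
        out = apply_coil_gradient(vol, 0.2, axis=0)
        profile = out.values[:, 0, 0]
        assert profile[0] == pytest.approx(8.0)
        assert profile[-1] == pytest.approx(12.0)
        assert np.allclose(np.diff(profile), np.diff(profile)[0])  # linear

    def test_negative_amplitude_rejected(self):
        vol = ImageVolume(np.ones((2, 2, 2)), (1.0, 1.0, 1.0))
        with pytest.raises(ValidationError):
            apply_coil_gradient(vol, -0.1)


class TestRicianNoise:
    def test_sigma_zero_identity_and_determinism(self):
        vol = ImageVolume(np.random.default_rng(0).uniform(1, 9, (8, 8, 8)), (1, 1, 1))
        assert np.array_equal(apply_rician_noise(vol, 0.0, seed=1).values, vol.values)
        a = apply_rician_noise(vol, 0.5, seed=42)
        b = apply_rician_noise(vol, 0.5, seed=42)
        assert np.array_equal(a.values, b.values)
        assert (a.values >= 0).all()

    def test_high_snr_mean_matches_monte_carlo_limit(self):
        """E[sqrt((v+n1)²+n2²)] ≈ sqrt(v²+2σ²) at high SNR; 10⁶ draws."""
        vol = ImageVolume(np.full((100, 100, 100), 100.0), (1.0, 1.0, 1.0))
        out = apply_rician_noise(vol, 1.0, seed=7)
        assert out.values.mean() == pytest.approx(np.sqrt(100.0**2 + 2.0), abs=0.1)


class TestArtifacts:
    def test_zero_count_unchanged(self, clean_bundle):
        spec = dataclasses.replace(clean_bundle.spec, artifact_count=0)
        vol, truth = insert_susceptibility_artifacts(
            clean_bundle.mri, clean_bundle.truth_mri_grid, spec
        )
        assert np.array_equal(vol.values, clean_bundle.mri.values)
        assert np.array_equal(truth.labels, clean_bundle.truth_mri_grid.labels)

    def test_radius_precondition(self, clean_bundle):
        spec = dataclasses.replace(clean_bundle.spec, artifact_radius=260.0)
        with pytest.raises(ValidationError):
            insert_susceptibility_artifacts(
                clean_bundle.mri, clean_bundle.truth_mri_grid, spec
            )

    def test_artifact_voxels_exist_and_are_brightest(self, clean_bundle):
        lab = clean_bundle.truth_mri_grid.labels
        art = lab == int(Tissue.ARTIFACT)
        assert art.any()
        ref = clean_bundle.model.cortex_reference_raw
        assert (clean_bundle.mri.values[art] / ref > 6.2).all()


class TestResample:
    def test_equal_spacing_is_identity(self):
        lab = np.random.default_rng(0).integers(0, 6, (6, 5, 4)).astype(np.uint8)
        fine = LabelVolume(lab, (8.0, 8.0, 8.0))
        out = resample_to_mri_grid(fine, (8.0, 8.0, 8.0))
        assert np.array_equal(out.labels, lab)

    def test_majority_vote(self):
        lab = np.zeros((2, 2, 2), dtype=np.uint8)
        lab.flat[:5] = int(Tissue.BONE_CALLUS)
        lab.flat[5:] = int(Tissue.FIBROUS)
        out = resample_to_mri_grid(LabelVolume(lab, (8, 8, 8)), (16, 16, 16))
        assert out.labels[0, 0, 0] == int(Tissue.BONE_CALLUS)

    def test_tie_breaks_toward_bone(self):
        lab = np.zeros((2, 2, 2), dtype=np.uint8)
        lab[0] = int(Tissue.BONE_CALLUS)
        lab[1] = int(Tissue.CARTILAGE)
        out = resample_to_mri_grid(LabelVolume(lab, (8, 8, 8)), (16, 16, 16))
        assert out.labels[0, 0, 0] == int(Tissue.BONE_CALLUS)

    def test_non_commensurate_spacing_rejected(self):
        fine = LabelVolume(np.zeros((10, 10, 10), dtype=np.uint8), (8.0, 8.0, 8.0))
        with pytest.raises(ValidationError):
            resample_to_mri_grid(fine, (52.0, 52.0, 350.0))


class TestHistology:
    def test_zero_jitter_at_native_spacing_is_exact(self, full_bundle):
        truth = full_bundle.truth
        z = truth.axis_coords(2)[40]
        sec = render_histology_sections(
            truth, (z,), jitter_sigma=0.0, in_plane_spacing=truth.spacing[0]
        )[0]
        assert np.array_equal(sec.labels, truth.labels[:, :, 40])

    def test_jittered_fractions_stay_close(self, full_bundle):
        truth = full_bundle.truth
        z = truth.axis_coords(2)[truth.shape[2] // 2]
        exact = render_histology_sections(truth, (z,), 0.0, in_plane_spacing=8.0)[0]
        jit = render_histology_sections(truth, (z,), 20.0, seed=4, in_plane_spacing=8.0)[0]
        n_exact = (exact.labels > 0).sum()
        n_jit = (jit.labels > 0).sum()
        for code in (3, 4, 5):
            f_exact = 100.0 * (exact.labels == code).sum() / n_exact
            f_jit = 100.0 * (jit.labels == code).sum() / n_jit
            assert abs(f_exact - f_jit) < 5.0

    def test_out_of_bounds_position_rejected(self, full_bundle):
        with pytest.raises(ValidationError):
            render_histology_sections(full_bundle.truth, (1e9,), 0.0)
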