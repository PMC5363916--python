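"""Cortex-reference normalization, threshold classification, VOI, slices."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from callusmri.experiments import segment_phantom
from callusmri.phantom import (
    PhantomSpec,
    TissueIntensityModel,
    cortex_end_mask,
    generate_phantom,
    insert_susceptibility_artifacts,
)
from callusmri.segmentation import (
    CallusVOI,
    TissueThresholds,
    classify_tissues,
    define_voi_between_inner_pins,
    estimate_cortex_reference,
    normalize_intensity,
    select_central_slices,
    suppress_artifact_components,
)
from callusmri.volume import (
    ImageVolume,
    LabelVolume,
    SegClass,
    Tissue,
    ValidationError,
    truth_to_seg,
)


def _full_voi(volume) -> CallusVOI:
    coords = volume.axis_coords(0)
    return CallusVOI(
        interval=(coords[0] - 1.0, coords[-1] + 1.0),
        mask=np.ones(volume.shape, dtype=bool),
        spacing=volume.spacing,
        origin=volume.origin,
    )


class TestCortexReference:
    def test_constant_cortex(self):
        vol = ImageVolume(np.full((4, 4, 4), 40.0), (1, 1, 1))
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0] = True
        assert estimate_cortex_reference(vol, mask) == 40.0

    def test_median_robust_to_bright_outlier(self):
        vals = np.zeros((3, 1, 1))
        vals[:, 0, 0] = [30.0, 40.0, 1000.0]
        vol = ImageVolume(vals, (1, 1, 1))
        assert estimate_cortex_reference(vol, np.ones((3, 1, 1), bool)) == 40.0

    def test_empty_mask_rejected(self):
        vol = ImageVolume(np.ones((2, 2, 2)), (1, 1, 1))
        with pytest.raises(ValidationError):
            estimate_cortex_reference(vol, np.zeros((2, 2, 2), bool))

    def test_phantom_reference_recovered(self):
        model = TissueIntensityModel(cortex_reference_raw=55.0)
        spec = PhantomSpec(noise_sigma=0.0, coil_gradient_amplitude=0.0, seed=13)
        bundle = generate_phantom(spec, model, modalities=("mri",))
        seg = segment_phantom(bundle)
        assert seg.cortex_reference == pytest.approx(55.0, rel=1e-3)


class TestNormalizeAndClassify:
    def test_normalize_trivials(self):
        vol = ImageVolume(np.array([[[0.0, 40.0]]]), (1, 1, 1))
        out = normalize_intensity(vol, 40.0)
        assert out.values[0, 0, 0] == 0.0
        assert out.values[0, 0, 1] == 1.0
        with pytest.raises(ValidationError):
            normalize_intensity(vol, 0.0)

    def test_bin_edges_match_protocol_convention(self):
        """1.0/3.3 → bone, 3.4 → fibrous, 5.5 & 6.2 → cartilage, 7 → unclassified,
        sub-1 values fold into bone."""
        vals = np.array([[[1.0, 3.3, 3.4, 5.5, 6.2, 7.0, 0.5]]])
        vol = ImageVolume(vals, (1, 1, 1))
        labels = classify_tissues(vol, TissueThresholds(), _full_voi(vol))
        expected = [
            SegClass.BONE,
            SegClass.BONE,
            SegClass.FIBROUS_OR_MARROW,
            SegClass.CARTILAGE,
            SegClass.CARTILAGE,
            SegClass.UNCLASSIFIED,
            SegClass.BONE,
        ]
        assert list(labels.labels[0, 0, :]) == [int(e) for e in expected]

    def test_negative_normalized_values_rejected(self):
        vol = ImageVolume(np.zeros((1, 1, 2)), (1, 1, 1))
        vol.values[0, 0, 0] = -0.1
        with pytest.raises(ValidationError):
            classify_tissues(vol, TissueThresholds(), _full_voi(vol))

    def test_inverted_threshold_interval_rejected(self):
        with pytest.raises(ValidationError):
            TissueThresholds(cartilage=(6.2, 5.5)).validate()
        with pytest.raises(ValidationError):
            TissueThresholds(fibrous_or_marrow=(3.5, 5.5)).validate()  # gap vs bone

    def test_partition_over_voi(self, noisy_bundle):
        seg = segment_phantom(noisy_bundle)
        inside = seg.labels.labels[seg.voi.mask]
        counts = sum(
            int((inside == int(c)).sum())
            for c in (
                SegClass.BONE,
                SegClass.FIBROUS_OR_MARROW,
                SegClass.CARTILAGE,
                SegClass.UNCLASSIFIED,
            )
        )
        assert counts == seg.voi.voxel_count
        assert (seg.labels.labels[~seg.voi.mask] == int(SegClass.BACKGROUND)).all()

    def test_threshold_monotonicity(self, noisy_bundle):
        seg = segment_phantom(noisy_bundle)
        norm = normalize_intensity(noisy_bundle.mri, seg.cortex_reference)
        base = TissueThresholds()
        wide_bone = TissueThresholds(bone=(1.0, 4.0), fibrous_or_marrow=(4.0, 5.5))
        low_cart = TissueThresholds(fibrous_or_marrow=(3.4, 5.0), cartilage=(5.0, 6.2))
        n = {
            t: np.bincount(
                classify_tissues(norm, t, seg.voi).labels.ravel(), minlength=5
            )
            for t in (base, wide_bone, low_cart)
        }
        assert n[wide_bone][int(SegClass.BONE)] >= n[base][int(SegClass.BONE)]
        assert n[low_cart][int(SegClass.CARTILAGE)] >= n[base][int(SegClass.CARTILAGE)]

    def test_brute_force_oracle_on_small_volumes(self):
        rng = np.random.default_rng(5)
        thresholds = TissueThresholds()
        for _ in range(5):
            vals = rng.uniform(0.0, 8.0, (10, 10, 10))
            vol = ImageVolume(vals, (1, 1, 1))
            labels = classify_tissues(vol, thresholds, _full_voi(vol)).labels
            for idx in np.ndindex(vol.shape):
                v = vals[idx]
                if v < 3.4:
                    want = SegClass.BONE
                elif v < 5.5:
                    want = SegClass.FIBROUS_OR_MARROW
                elif v <= 6.2:
                    want = SegClass.CARTILAGE
                else:
                    want = SegClass.UNCLASSIFIED
                assert labels[idx] == int(want)

    @settings(max_examples=25, deadline=None)
    @given(c=st.floats(min_value=1e-3, max_value=1e3, allow_nan=False))
    def test_scale_invariance(self, c):
        """classify(normalize(c·V, c·ref)) == classify(normalize(V, ref)) exactly."""
        rng = np.random.default_rng(17)
        vals = rng.uniform(0.0, 8.0, (6, 6, 6)) * 40.0
        vol = ImageVolume(vals, (1, 1, 1))
        voi = _full_voi(vol)
        t = TissueThresholds()
        base = classify_tissues(normalize_intensity(vol, 40.0), t, voi)
        scaled = classify_tissues(
            normalize_intensity(vol.with_values(vals * c), 40.0 * c), t, voi
        )
        assert np.array_equal(base.labels, scaled.labels)


class TestVOI:
    def test_interval_from_pin_geometry(self):
        labels = LabelVolume(
            np.full((140, 3, 3), int(Tissue.FIBROUS), dtype=np.uint8), (100.0, 100.0, 100.0)
        )
        voi = define_voi_between_inner_pins(
            labels, [2000.0, 5000.0, 9000.0, 12000.0], pin_radius_um=200.0
        )
        assert voi.interval == (5200.0, 8800.0)

    def test_coincident_inner_pins_rejected(self):
        labels = LabelVolume(np.zeros((10, 2, 2), dtype=np.uint8), (100, 100, 100))
        with pytest.raises(ValidationError):
            define_voi_between_inner_pins(labels, [0, 400, 400, 900], 50.0)

    def test_mask_matches_brute_force_scan(self, clean_bundle):
        spec = clean_bundle.spec
        voi = define_voi_between_inner_pins(
            clean_bundle.truth_mri_grid, spec.pin_positions, spec.pin_radius
        )
        lo, hi = voi.interval
        lab = clean_bundle.truth_mri_grid.labels
        x = clean_bundle.truth_mri_grid.axis_coords(0)
        count = 0
        for i in range(lab.shape[0]):
            if lo < x[i] < hi:
                sl = lab[i]
                count += int(((sl != int(Tissue.BACKGROUND)) & (sl != int(Tissue.PIN))).sum())
        assert voi.voxel_count == count
        assert not (voi.mask & (lab == int(Tissue.PIN))).any()


class TestCentralSlices:
    def test_indices_match_brute_force_centroid(self, clean_bundle):
        seg = segment_phantom(clean_bundle)
        cs = select_central_slices(seg.voi, seg.labels)
        counts = seg.voi.mask.sum(axis=(0, 1))
        centroid = float((counts * np.arange(len(counts))).sum() / counts.sum())
        assert cs.indices == (int(np.floor(centroid)), int(np.floor(centroid)) + 1)

    def test_symmetric_phantom_equal_areas(self, clean_bundle):
        seg = segment_phantom(clean_bundle)
        cs = select_central_slices(seg.voi, seg.labels)
        a = (cs.images[0] != 0).sum()
        b = (cs.images[1] != 0).sum()
        assert a == b

    def test_single_slice_returned_twice_with_flag(self):
        labels = LabelVolume(
            np.full((10, 4, 5), int(Tissue.FIBROUS), dtype=np.uint8), (100, 100, 100)
        )
        mask = np.zeros((10, 4, 5), dtype=bool)
        mask[3:6, 1:3, 2] = True
        voi = CallusVOI((250.0, 650.0), mask, labels.spacing, labels.origin)
        with pytest.warns(UserWarning):
            cs = select_central_slices(voi, labels)
        assert cs.single_slice
        assert cs.indices == (2, 2)


class TestArtifactSuppression:
    def _cartilage_bin_artifact_bundle(self):
        spec0 = PhantomSpec(
            healing_day=21,
            target_fractions={"bone": 0.45, "cartilage": 0.0, "fibrous": 0.55},
            noise_sigma=0.0,
            coil_gradient_amplitude=0.0,
            artifact_count=0,
            seed=3,
        )
        bundle = generate_phantom(spec0, modalities=("mri",))
        # artifacts leaking into the cartilage bin (unvalidated low interval)
        low_model = TissueIntensityModel(artifact=(5.9, 6.05))
        spec4 = dataclasses.replace(spec0, artifact_count=4)
        callus_before = np.isin(bundle.truth_mri_grid.labels, [3, 4, 5])
        mri, truth = insert_susceptibility_artifacts(
            bundle.mri, bundle.truth_mri_grid, spec4, low_model, np.random.default_rng(1)
        )
        return dataclasses.replace(bundle, mri=mri, truth_mri_grid=truth), spec4, callus_before

    def test_min_volume_zero_is_identity(self, clean_bundle):
        seg = segment_phantom(clean_bundle)
        cem = cortex_end_mask(clean_bundle.truth_mri_grid, clean_bundle.spec)
        out = suppress_artifact_components(seg.labels, 0.0, cem)
        assert np.array_equal(out.labels, seg.labels.labels)

    def test_cartilage_fraction_restored(self):
        bundle, spec4, callus = self._cartilage_bin_artifact_bundle()
        seg = segment_phantom(bundle)
        before = ((seg.labels.labels == int(SegClass.CARTILAGE)) & callus).sum() / callus.sum()
        assert before > 0  # artifacts really leaked into the cartilage bin
        cem = cortex_end_mask(bundle.truth_mri_grid, spec4)
        out = suppress_artifact_components(seg.labels, 0.05e9, cem)
        after = ((out.labels == int(SegClass.CARTILAGE)) & callus).sum() / callus.sum()
        assert after == pytest.approx(0.0, abs=0.01)  # true cartilage fraction is 0

    def test_component_away_from_cortex_ends_retained(self):
        bundle, spec4, _ = self._cartilage_bin_artifact_bundle()
        seg = segment_phantom(bundle)
        lab = seg.labels.labels.copy()
        lab[5:7, 5:7, 2:4] = int(SegClass.CARTILAGE)  # far corner, tiny component
        cem = cortex_end_mask(bundle.truth_mri_grid, spec4)
        out = suppress_artifact_components(seg.labels.with_labels(lab), 0.05e9, cem)
        assert (out.labels[5:7, 5:7, 2:4] == int(SegClass.CARTILAGE)).all()


class TestNoiseFreeRecoveryVoxelwise:
    def test_classifier_reproduces_truth_exactly(self, clean_bundle):
        seg = segment_phantom(clean_bundle)
        expected = truth_to_seg(clean_bundle.truth_mri_grid)
        assert np.array_equal(
            seg.labels.labels[seg.voi.mask], expected.labels[seg.voi.mask]
        )
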