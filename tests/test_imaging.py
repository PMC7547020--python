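import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radopt.imaging import (
    IMAGE_SIZE,
    AugmentationPipeline,
    AugmentationStage,
    DatasetManifest,
    ManifestRecord,
    RasterImage,
    RegionMask,
    apply_pipeline,
    build_default_pipeline,
    build_test_pipeline,
    flip_lr,
    grid_distort,
    load_dataset,
    obfuscate,
    oversample_class_balanced,
    rotate90,
    save_dataset,
    zoom,
)


def _record(i, patient="p0", split="train", cls="ACP", modality="CT", parent=None):
    return ManifestRecord(
        image_id=f"img{i}",
        patient_id=patient,
        modality=modality,
        class_label=cls,
        split=split,
        path="",
        parent_image_id=parent,
    )


class TestManifestInvariants:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            DatasetManifest([_record(0), _record(0)])

    def test_patient_split_leakage_rejected(self):
        with pytest.raises(ValueError, match="both train and test"):
            DatasetManifest([_record(0, split="train"), _record(1, split="test")])

    def test_dangling_parent_rejected(self):
        with pytest.raises(ValueError, match="parent"):
            DatasetManifest([_record(0, parent="ghost")])

    def test_frame_round_trip(self):
        m = DatasetManifest([_record(0), _record(1, patient="p1", cls="NOTACP")])
        assert DatasetManifest.from_frame(m.to_frame()).records == m.records

    def test_missing_column_detected(self):
        df = DatasetManifest([_record(0)]).to_frame().drop(columns=["modality"])
        with pytest.raises(ValueError, match="modality"):
            DatasetManifest.from_frame(df)


class TestDefaultPipeline:
    def test_stage_order_and_probabilities(self):
        pipe = build_default_pipeline()
        assert [s.operator for s in pipe.stages] == [
            "grid_distortion",
            "rotate90",
            "zoom",
            "flip_lr",
        ]
        assert [s.probability for s in pipe.stages] == [0.75, 0.75, 0.5, 0.5]
        grid = pipe.stages[0].params
        assert (grid["grid_w"], grid["grid_h"], grid["magnitude"]) == (4, 4, 8)
        assert pipe.stages[2].params["area_fraction"] == 0.8

    def test_test_time_variant_sets_all_probabilities_to_one(self):
        pipe = build_test_pipeline()
        assert all(s.probability == 1.0 for s in pipe.stages)
        assert [s.operator for s in pipe.stages] == [
            s.operator for s in build_default_pipeline().stages
        ]


class TestGridDistortion:
    def test_zero_magnitude_is_bitwise_identity(self, gradient_image, rng):
        out = grid_distort(gradient_image, 4, 4, magnitude=0, rng=rng)
        np.testing.assert_array_equal(out.pixels, gradient_image.pixels)

    def test_deterministic_under_seed(self, gradient_image):
        a = grid_distort(gradient_image, 4, 4, 8, np.random.default_rng(5))
        b = grid_distort(gradient_image, 4, 4, 8, np.random.default_rng(5))
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_constant_image_maps_to_itself(self, rng):
        const = RasterImage(np.full((IMAGE_SIZE, IMAGE_SIZE), 77, dtype=np.uint8))
        out = grid_distort(const, 4, 4, 8, rng)
        np.testing.assert_array_equal(out.pixels, const.pixels)

    def test_output_shape_and_range(self, gradient_image, rng):
        out = grid_distort(gradient_image, 4, 4, 8, rng)
        assert out.pixels.shape == (IMAGE_SIZE, IMAGE_SIZE)
        assert out.pixels.dtype == np.uint8


class TestPipelineApplication:
    def test_zero_probabilities_are_identity(self, gradient_image, rng):
        pipe = build_default_pipeline().with_all_probabilities(0.0)
        out = apply_pipeline(pipe, gradient_image, rng)
        np.testing.assert_array_equal(out.pixels, gradient_image.pixels)

    def test_flip_is_an_involution(self, gradient_image):
        np.testing.assert_array_equal(
            flip_lr(flip_lr(gradient_image)).pixels, gradient_image.pixels
        )

    def test_rotation_stage_matches_direct_rotation(self, gradient_image):
        pipe = AugmentationPipeline((AugmentationStage("rotate90", 1.0),))
        out = apply_pipeline(pipe, gradient_image, np.random.default_rng(11))
        candidates = [rotate90(gradient_image, k).pixels for k in (1, 2, 3)]
        assert any(np.array_equal(out.pixels, c) for c in candidates)

    def test_zoom_preserves_shape(self, gradient_image, rng):
        out = zoom(gradient_image, 0.8, rng)
        assert out.pixels.shape == (IMAGE_SIZE, IMAGE_SIZE)

    def test_full_run_is_seed_reproducible(self, gradient_image):
        pipe = build_default_pipeline()
        a = apply_pipeline(pipe, gradient_image, np.random.default_rng(2))
        b = apply_pipeline(pipe, gradient_image, np.random.default_rng(2))
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestOversampling:
    @pytest.mark.parametrize("target", [20, 100])
    def test_exact_per_class_per_modality_counts(self, small_phantom, target, rng):
        manifest, images = small_phantom
        train = manifest.split("train")
        out_manifest, _ = oversample_class_balanced(train, images, target, rng=rng)
        for modality in ("CT", "MRI"):
            for cls in ("ACP", "NOTACP"):
                n = sum(
                    1
                    for r in out_manifest.records
                    if r.split == "train"
                    and r.modality == modality
                    and r.class_label == cls
                )
                assert n == target

    def test_target_at_current_count_adds_nothing(self, small_phantom, rng):
        manifest, images = small_phantom
        train = manifest.split("train")
        per_class = sum(
            1 for r in train.records if r.class_label == "ACP" and r.modality == "CT"
        )
        out_manifest, _ = oversample_class_balanced(
            train, images, per_class, rng=rng
        )
        assert len(out_manifest) == len(train)

    def test_synthetic_records_reference_same_class_parents(self, small_phantom, rng):
        manifest, images = small_phantom
        out_manifest, out_images = oversample_class_balanced(
            manifest.split("train"), images, 40, rng=rng
        )
        rec_of = {r.image_id: r for r in out_manifest.records}
        synthetic = [r for r in out_manifest.records if r.parent_image_id]
        assert synthetic
        for r in synthetic:
            parent = rec_of[r.parent_image_id]
            assert parent.parent_image_id is None
            assert parent.class_label == r.class_label
            assert parent.modality == r.modality
            assert parent.patient_id == r.patient_id
            assert r.image_id in out_images


class TestObfuscation:
    def test_whole_image_mask_gives_constant(self, gradient_image):
        mask = RegionMask("rectangle", (149, 149), (300, 300), fill=13)
        out = obfuscate(gradient_image, mask)
        assert np.all(out.pixels == 13)

    def test_zero_extent_mask_is_identity(self, gradient_image):
        mask = RegionMask("ellipse", (149, 149), (0, 0), fill=0)
        out = obfuscate(gradient_image, mask)
        np.testing.assert_array_equal(out.pixels, gradient_image.pixels)

    def test_ellipse_mask_matches_pointwise_predicate(self, gradient_image):
        mask = RegionMask("ellipse", (149, 149), (40, 60), fill=0)
        out = obfuscate(gradient_image, mask)
        rr, cc = np.mgrid[0:IMAGE_SIZE, 0:IMAGE_SIZE]
        inside = ((rr - 149) / 40) ** 2 + ((cc - 149) / 60) ** 2 <= 1.0
        assert np.all(out.pixels[inside] == 0)
        np.testing.assert_array_equal(
            out.pixels[~inside], gradient_image.pixels[~inside]
        )

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(
        st.sampled_from(["rectangle", "ellipse"]),
        st.floats(0, 298),
        st.floats(0, 298),
        st.floats(0, 200),
        st.floats(0, 200),
        st.integers(0, 255),
    )
    def test_idempotence(self, shape, cy, cx, hy, hx, fill):
        rr, cc = np.mgrid[0:IMAGE_SIZE, 0:IMAGE_SIZE]
        image = RasterImage(((rr + cc) / (2 * (IMAGE_SIZE - 1)) * 255).astype(np.uint8))
        mask = RegionMask(shape, (cy, cx), (hy, hx), fill=fill)
        once = obfuscate(image, mask)
        twice = obfuscate(once, mask)
        np.testing.assert_array_equal(once.pixels, twice.pixels)


class TestDatasetIO:
    def test_save_load_round_trip(self, small_phantom, tmp_path):
        manifest, images = small_phantom
        few = manifest.subset(lambda r: r.patient_id in set(manifest.patient_ids[:2]))
        csv_path = save_dataset(few, images, tmp_path / "ds")
        loaded_manifest, loaded_images = load_dataset(csv_path)
        assert len(loaded_manifest) == len(few)
        for rec in few.records:
            np.testing.assert_array_equal(
                loaded_images[rec.image_id].pixels, images[rec.image_id].pixels
            )

    def test_missing_file_names_the_record(self, small_phantom, tmp_path):
        manifest, images = small_phantom
        few = manifest.subset(lambda r: r.patient_id == manifest.patient_ids[0])
        csv_path = save_dataset(few, images, tmp_path / "ds")
        victim = few.records[0].image_id
        (tmp_path / "ds" / "images" / f"{victim}.png").unlink()
        with pytest.raises(FileNotFoundError, match=victim):
            load_dataset(csv_path)
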