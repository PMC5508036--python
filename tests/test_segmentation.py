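import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from fociscope import segmentation, synthetic
from fociscope.pipeline import (
    CLASS_NAME_MAP,
    analyze_field,
    match_to_planted,
    region_segmentation_params,
)
from fociscope.segmentation import (
    FEATURE_COLUMNS,
    NucleusRecord,
    SegmentationParams,
    classify_nuclei,
    declump,
    extract_features,
    load_manual_annotations,
    segment_nuclei,
    train_classifier,
)

from conftest import small_spec


def disk_image(centers, radius=10.0, intensity=0.7, shape=(128, 128), blur=1.2):
    """Additive blurred disks on a dark background, rescaled to [0, 1]."""
    img = np.zeros(shape)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for r, c in centers:
        img += intensity * ((yy - r) ** 2 + (xx - c) ** 2 <= radius**2)
    img = ndimage.gaussian_filter(img, blur)
    return img / img.max() if img.max() > 0 else img


class TestSegmentNuclei:
    def test_blank_image(self):
        labels, records = segment_nuclei(np.zeros((64, 64)))
        assert labels.max() == 0
        assert records == []

    def test_single_disk_area(self):
        img = disk_image([(64, 64)], radius=10)
        labels, records = segment_nuclei(img, SegmentationParams(min_diameter_px=10))
        assert len(records) == 1
        planted_area = np.pi * 10**2
        assert abs(records[0].area_px - planted_area) / planted_area < 0.10

    def test_forty_nonoverlapping_nuclei_matched(self):
        centers = [
            (16 + 24 * i, 16 + 24 * j) for i in range(5) for j in range(8)
        ]
        img = disk_image(centers, radius=8, shape=(140, 210))
        labels, records = segment_nuclei(img, SegmentationParams(min_diameter_px=10))
        assert len(records) == 40
        truth = pd.DataFrame(
            dict(
                nucleus_id=range(1, 41),
                cell_class="granule",
                centroid_row=[c[0] for c in centers],
                centroid_col=[c[1] for c in centers],
                radius_px=8.0,
            )
        )
        matched = match_to_planted(records, truth, max_distance_px=3.0)
        assert len(matched) == 40

    def test_labels_dense_from_one(self):
        img = disk_image([(30, 30), (90, 90)], radius=9)
        labels, records = segment_nuclei(img, SegmentationParams(min_diameter_px=10))
        ids = sorted(r.nucleus_id for r in records)
        assert ids == list(range(1, labels.max() + 1))

    def test_diameter_gate_discards(self):
        img = disk_image([(40, 40)], radius=4) + disk_image([(90, 90)], radius=14)
        img /= img.max()
        labels, records = segment_nuclei(
            img, SegmentationParams(min_diameter_px=20, max_diameter_px=40)
        )
        assert len(records) == 1
        assert records[0].equivalent_diameter_px >= 20

    def test_partition_property(self):
        spec = small_spec("frontal_cortex")
        from fociscope import stacks

        stack, _ = synthetic.generate_field(spec, "sense", seed=2)
        field = stacks.suppress_background(stacks.max_project(stack), 5)
        labels, records = segment_nuclei(
            field.nuclear, region_segmentation_params("frontal_cortex")
        )
        present = set(np.unique(labels)) - {0}
        assert present == {r.nucleus_id for r in records}
        for rec in records:
            assert (labels == rec.nucleus_id).sum() == rec.area_px


class TestDeclump:
    def test_two_fused_disks_split(self):
        img = disk_image([(60, 50), (60, 64)], radius=10)
        fg = (img > 0.3).astype(np.int32)
        labels = declump(fg, img)
        assert labels.max() == 2

    def test_single_disk_untouched(self):
        img = disk_image([(64, 64)], radius=10)
        fg = (img > 0.3).astype(np.int32)
        labels = declump(fg, img)
        assert labels.max() == 1
        np.testing.assert_array_equal(labels > 0, fg > 0)

    def test_three_disk_chain(self):
        centers = [(60, 40), (60, 56), (60, 72)]
        img = disk_image(centers, radius=9)
        fg = (img > 0.3).astype(np.int32)
        labels = declump(fg, img)
        assert labels.max() == 3
        hit = {labels[r, c] for r, c in centers}
        assert len(hit) == 3 and 0 not in hit

    def test_idempotent(self):
        spec = small_spec("frontal_cortex")
        from fociscope import stacks

        stack, _ = synthetic.generate_field(spec, "sense", seed=4)
        field = stacks.suppress_background(stacks.max_project(stack), 5)
        labels, _ = segment_nuclei(
            field.nuclear, region_segmentation_params("frontal_cortex")
        )
        again = declump(labels, field.nuclear)
        # a second pass must not split anything further
        assert again.max() == labels.max()


class TestNucleusCountAccuracy:
    def test_count_error_below_5pct_over_20_seeds(self, frontal_spec):
        errors = []
        for seed in range(1, 21):
            stack, truth = synthetic.generate_field(frontal_spec, "sense", seed=seed)
            result = analyze_field(stack, "frontal_cortex")
            n_true = len(truth.nuclei)
            errors.append(abs(len(result["all_nuclei"]) - n_true) / n_true)
        assert np.mean(errors) <= 0.05


class TestExtractFeatures:
    def test_perfect_disk_form_factor(self):
        yy, xx = np.mgrid[:64, :64]
        mask = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 12**2).astype(np.int32)
        feats = extract_features(mask, mask.astype(float) * 0.8)
        assert 0.85 <= feats.iloc[0]["form_factor"] <= 1.0

    def test_uniform_nucleus_zero_texture_sd(self):
        yy, xx = np.mgrid[:64, :64]
        mask = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 10**2).astype(np.int32)
        feats = extract_features(mask, np.full((64, 64), 0.5))
        assert feats.iloc[0]["texture_sd"] == 0.0

    def test_rescaled_intensity_invariance(self):
        # doubling raw intensities before [0,1] rescale leaves features fixed
        rng = np.random.default_rng(0)
        raw = rng.uniform(0, 0.5, (64, 64))
        yy, xx = np.mgrid[:64, :64]
        mask = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 10**2).astype(np.int32)
        img1 = raw / raw.max()
        doubled = raw * 2
        img2 = doubled / doubled.max()
        f1 = extract_features(mask, img1)
        f2 = extract_features(mask, img2)
        pd.testing.assert_frame_equal(f1, f2)

    def test_deterministic(self):
        img = disk_image([(40, 40), (90, 80)], radius=9)
        labels, _ = segment_nuclei(img, SegmentationParams(min_diameter_px=10))
        pd.testing.assert_frame_equal(
            extract_features(labels, img), extract_features(labels, img)
        )


class TestClassifier:
    def _held_out(self, model, n_fields=5, seed0=500):
        spec = synthetic.default_field_spec("frontal_cortex")
        correct = total = 0
        majority = {"neuron": 0, "glia": 0}
        for seed in range(seed0, seed0 + n_fields):
            stack, truth = synthetic.generate_field(spec, "sense", seed=seed)
            result = analyze_field(stack, "frontal_cortex")
            matched = match_to_planted(result["all_nuclei"], truth.nuclei)
            by_id = dict(zip(matched["nucleus_id"], matched["planted_class"]))
            feats = pd.DataFrame([r.features for r in result["all_nuclei"]])
            pred = model.model.predict(feats[model.feature_columns].to_numpy())
            for rec, p in zip(result["all_nuclei"], pred):
                planted = by_id.get(rec.nucleus_id)
                if planted is None:
                    continue
                cls = CLASS_NAME_MAP[planted]
                majority[cls] += 1
                total += 1
                correct += cls == p
        return correct / total, max(majority.values()) / total, total

    def test_held_out_accuracy(self, trained_classifier):
        acc, _, total = self._held_out(trained_classifier)
        assert total > 100
        assert acc >= 0.90

    def test_shuffled_labels_give_chance_accuracy(self, trained_classifier):
        # permutation control: retrain with shuffled labels
        spec = synthetic.default_field_spec("frontal_cortex")
        frames, labels = [], []
        for seed in range(1123, 1129):
            stack, truth = synthetic.generate_field(spec, "sense", seed=seed)
            result = analyze_field(stack, "frontal_cortex")
            matched = match_to_planted(result["all_nuclei"], truth.nuclei)
            by_id = dict(zip(matched["nucleus_id"], matched["planted_class"]))
            for rec in result["all_nuclei"]:
                planted = by_id.get(rec.nucleus_id)
                if planted is None:
                    continue
                frames.append(rec.features)
                labels.append(CLASS_NAME_MAP[planted])
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(labels)
        model = train_classifier(pd.DataFrame(frames), shuffled, seed=0)
        acc, majority_share, total = self._held_out(model, n_fields=3)
        band = 3 * np.sqrt(majority_share * (1 - majority_share) / total)
        assert acc <= majority_share + band

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(5)
        feats = pd.DataFrame(rng.uniform(size=(60, len(FEATURE_COLUMNS))),
                             columns=FEATURE_COLUMNS)
        labels = ["neuron" if i % 2 else "glia" for i in range(60)]
        m1 = train_classifier(feats, labels, seed=9)
        m2 = train_classifier(feats, labels, seed=9)
        probe = rng.uniform(size=(10, len(FEATURE_COLUMNS)))
        np.testing.assert_array_equal(
            m1.model.predict(probe), m2.model.predict(probe)
        )

    def test_single_class_rejected(self):
        feats = pd.DataFrame(
            np.ones((5, len(FEATURE_COLUMNS))), columns=FEATURE_COLUMNS
        )
        with pytest.raises(ValueError, match="two classes"):
            train_classifier(feats, ["neuron"] * 5, seed=0)

    def test_identical_features_predict_majority(self):
        feats = pd.DataFrame(
            np.ones((30, len(FEATURE_COLUMNS))), columns=FEATURE_COLUMNS
        )
        labels = ["neuron"] * 20 + ["glia"] * 10
        model = train_classifier(feats, labels, seed=0)
        assert list(model.model.predict(np.ones((1, len(FEATURE_COLUMNS))))) == [
            "neuron"
        ]

    def test_save_load_roundtrip(self, trained_classifier, tmp_path):
        path = tmp_path / "model.joblib"
        trained_classifier.save(path)
        back = segmentation.NucleusClassifier.load(path)
        assert back.classes == trained_classifier.classes
        assert back.version == trained_classifier.version


class TestClassifyNuclei:
    def _record(self, nid):
        return NucleusRecord(
            nucleus_id=nid,
            centroid=(1.0, 1.0),
            area_px=50,
            equivalent_diameter_px=8.0,
            mean_intensity=0.5,
            shape=(0.1, 0.95, 0.9),
            texture=(0.01, 0.001),
            edge_strength=0.2,
            features={c: 0.5 for c in FEATURE_COLUMNS},
        )

    def test_all_cells_counts_everything(self):
        records = [self._record(i) for i in range(1, 41)]
        assert len(classify_nuclei(records, None, mode="all_cells")) == 40

    def test_empty_input(self, trained_classifier):
        assert classify_nuclei([], trained_classifier, mode="neurons") == []

    def test_neurons_precision_recall(self, trained_classifier, frontal_spec):
        tp = fp = fn = 0
        for seed in range(700, 705):
            stack, truth = synthetic.generate_field(frontal_spec, "sense", seed=seed)
            result = analyze_field(
                stack, "frontal_cortex", mode="neurons",
                classifier=trained_classifier,
            )
            matched = match_to_planted(result["all_nuclei"], truth.nuclei)
            by_id = dict(zip(matched["nucleus_id"], matched["planted_class"]))
            called = {r.nucleus_id for r in result["nuclei"]}
            for rec in result["all_nuclei"]:
                planted = by_id.get(rec.nucleus_id)
                if planted is None:
                    continue
                is_neuron = planted == "cortical_neuron"
                if rec.nucleus_id in called and is_neuron:
                    tp += 1
                elif rec.nucleus_id in called:
                    fp += 1
                elif is_neuron:
                    fn += 1
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        assert precision >= 0.85 and recall >= 0.85

    def test_schema_mismatch_rejected(self, trained_classifier):
        broken = dataclasses.replace(
            trained_classifier, feature_columns=["bogus"]
        )
        with pytest.raises(ValueError, match="schema"):
            classify_nuclei([self._record(1)], broken, mode="neurons")


class TestManualAnnotations:
    HEADER = "field_id,nucleus_id,centroid_row,centroid_col,radius_px,foci_count\n"

    def test_twenty_one_rows(self, tmp_path):
        path = tmp_path / "purkinje.csv"
        rows = [
            f"F01,{i},{10 * i},{5 * i},15,{i % 4}\n" for i in range(1, 22)
        ]
        path.write_text(self.HEADER + "".join(rows))
        records = load_manual_annotations(path)
        assert len(records) == 21
        assert all(r.cell_class == "purkinje" for r in records)
        assert records[2].manual_foci_count == 3

    def test_empty_with_header(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(self.HEADER)
        assert load_manual_annotations(path) == []

    def test_duplicate_reported(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            self.HEADER + "F01,7,10,10,15,\nF01,7,20,20,15,\n"
        )
        with pytest.raises(ValueError, match="duplicate.*nucleus 7"):
            load_manual_annotations(path)

    def test_malformed_row_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(self.HEADER + "F01,notanint,10,10,15,\n")
        with pytest.raises(ValueError, match="line 2"):
            load_manual_annotations(path)

    def test_missing_columns(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("field_id,nucleus_id\nF01,1\n")
        with pytest.raises(ValueError, match="missing columns"):
            load_manual_annotations(path)
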