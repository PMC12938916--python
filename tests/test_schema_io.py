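"""Metadata encoding schema, image normalisation, and dataset/result I/O."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from PIL import Image

from dermafuse.datamodel import (
    CLASS_LABELS, ClassScheme, DatasetError, PredictionRecord,
    denormalize_image, normalize_image, read_dataset, read_predictions,
    write_results,
)
from dermafuse.schema import (
    MetadataSchema, SchemaError, encode_metadata_row, training_medians,
)

SCHEMA = MetadataSchema.default()


def _full_row(**overrides):
    row = {"age": 50, "sex": "male", "region": "face", "diameter_1": 8,
           "diameter_2": 6, "fitspatrick": "2", "background_father": "brazil",
           "background_mother": "brazil"}
    for name in ("smoke", "drink", "pesticide", "skin_cancer_history",
                 "cancer_history", "has_piped_water", "has_sewage_system",
                 "itch", "grew", "hurt", "changed", "bleed", "elevation"):
        row[name] = "false"
    row.update(overrides)
    return row


class TestSchemaLayout:
    def test_21_attributes_encode_to_81_dims(self):
        assert len(SCHEMA.specs) == 21
        assert SCHEMA.dim == 81

    def test_spans_disjoint_and_covering(self):
        covered = np.zeros(81, dtype=int)
        for span in SCHEMA.attribute_map.values():
            covered[span] += 1
        assert np.all(covered == 1)

    def test_minimal_block_is_first_18_dims(self):
        # age + sex + region occupy exactly dims 0..17
        stop = SCHEMA.attribute_map["region"].stop
        assert SCHEMA.attribute_map["age"].start == 0
        assert stop == 18

    def test_roundtrips_through_dict(self):
        clone = MetadataSchema.from_dict(SCHEMA.to_dict())
        assert clone.attribute_map == SCHEMA.attribute_map


class TestEncoding:
    def test_median_imputation_from_training_rows(self):
        rows = [_full_row(age=a) for a in (1, 2, 4)] + [_full_row(age=None)]
        medians = training_medians(rows, SCHEMA)
        assert medians["age"] == 2  # median of {1, 2, 4}
        vec = encode_metadata_row(_full_row(age=None), SCHEMA, medians)
        assert vec.values[0] == pytest.approx(SCHEMA.scale_numeric("age", 2))
        assert vec.missing_mask["age"]

    def test_all_present_has_empty_missing_mask(self):
        vec = encode_metadata_row(_full_row(), SCHEMA, {})
        assert not any(vec.missing_mask.values())

    def test_categorical_missing_lights_unknown_dimension(self):
        vec = encode_metadata_row(_full_row(sex=None), SCHEMA,
                                  {"age": 50, "diameter_1": 8, "diameter_2": 6})
        span = SCHEMA.attribute_map["sex"]
        block = vec.values[span]
        assert block[-1] == 1.0 and block[:-1].sum() == 0.0
        assert vec.missing_mask["sex"]

    def test_unknown_attribute_name_rejected(self):
        with pytest.raises(SchemaError, match="unknown attribute"):
            encode_metadata_row({"bogus": 1, **_full_row()}, SCHEMA, {})

    def test_unknown_category_rejected(self):
        with pytest.raises(SchemaError, match="category"):
            encode_metadata_row(_full_row(region="gills"), SCHEMA, {})

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_each_categorical_span_is_one_hot(self, seed):
        rng = np.random.default_rng(seed)
        row = {}
        for spec in SCHEMA.specs:
            if spec.kind == "numeric":
                row[spec.name] = float(rng.uniform(*spec.value_range))
            else:
                cats = spec.categories + (None,)
                row[spec.name] = cats[rng.integers(len(cats))]
        vec = encode_metadata_row(row, SCHEMA, {n: 1.0 for n in SCHEMA.numeric_names})
        for spec in SCHEMA.specs:
            block = vec.values[SCHEMA.attribute_map[spec.name]]
            if spec.kind == "categorical":
                assert block.sum() == 1.0 and set(np.unique(block)) <= {0.0, 1.0}

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_decode_then_encode_is_fixed_point(self, seed):
        rng = np.random.default_rng(seed)
        row = _full_row(age=float(rng.uniform(0, 100)),
                        region=SCHEMA.by_name["region"].categories[rng.integers(13)])
        vec = encode_metadata_row(row, SCHEMA, {})
        vec2 = encode_metadata_row(SCHEMA.decode_row(vec), SCHEMA,
                                   {n: 0 for n in SCHEMA.numeric_names})
        assert np.allclose(vec.values, vec2.values, atol=1e-12)

    def test_neutral_vector_is_valid(self):
        vec = SCHEMA.neutral_vector()
        assert vec.values.shape == (81,)
        for spec in SCHEMA.specs:
            block = vec.values[SCHEMA.attribute_map[spec.name]]
            if spec.kind == "categorical":
                assert block[-1] == 1.0


class TestImageNormalisation:
    def test_roundtrip_within_tolerance(self):
        rng = np.random.default_rng(0)
        rgb = rng.random((8, 8, 3))
        assert np.allclose(denormalize_image(normalize_image(rgb)), rgb, atol=1e-6)

    def test_channel_mean_maps_to_zero(self):
        rgb = np.full((4, 4, 3), 0.485)
        out = normalize_image(rgb)
        assert out[0] == pytest.approx(np.zeros((4, 4)))


class TestClassScheme:
    def test_default_weights_fall_on_malignant_rare_classes(self):
        scheme = ClassScheme()
        assert scheme.labels == ("ACK", "BCC", "MEL", "NEV", "SCC", "SEK")
        assert scheme.static_alpha[scheme.index("MEL")] == 2.0
        assert scheme.static_alpha[scheme.index("SCC")] == 2.0

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ClassScheme(labels=("A", "B"))
        with pytest.raises(ValueError):
            ClassScheme(static_alpha=(1, 1, 1, 1, 1, -1))


@pytest.fixture
def toy_disk_dataset(tmp_path):
    img_dir = tmp_path / "images"
    img_dir.mkdir()
    rng = np.random.default_rng(0)
    rows = []
    for i, label in enumerate(["ACK", "MEL", "NEV"]):
        name = f"img_{i}.png"
        Image.fromarray((rng.random((16, 16, 3)) * 255).astype(np.uint8)).save(img_dir / name)
        rows.append({"img_id": name, "diagnostic": label, **_full_row(age=40 + i)})
    pd.DataFrame(rows).to_csv(tmp_path / "metadata.csv", index=False)
    return tmp_path


class TestReadDataset:
    def test_sample_count_and_ids_conserved(self, toy_disk_dataset):
        samples = read_dataset(toy_disk_dataset / "images",
                               toy_disk_dataset / "metadata.csv", image_size=16)
        assert len(samples) == 3
        assert [s.sample_id for s in samples] == ["img_0.png", "img_1.png", "img_2.png"]
        assert [s.label for s in samples] == [0, 2, 3]
        assert samples[0].image.pixels.shape == (3, 16, 16)

    def test_missing_image_error_names_row(self, toy_disk_dataset):
        df = pd.read_csv(toy_disk_dataset / "metadata.csv")
        df.loc[1, "img_id"] = "absent.png"
        df.to_csv(toy_disk_dataset / "metadata.csv", index=False)
        with pytest.raises(DatasetError, match="row 1"):
            read_dataset(toy_disk_dataset / "images",
                         toy_disk_dataset / "metadata.csv", image_size=16)

    def test_unknown_diagnosis_lists_valid_codes(self, toy_disk_dataset):
        df = pd.read_csv(toy_disk_dataset / "metadata.csv")
        df.loc[0, "diagnostic"] = "XYZ"
        df.to_csv(toy_disk_dataset / "metadata.csv", index=False)
        with pytest.raises(DatasetError, match="ACK.*SEK"):
            read_dataset(toy_disk_dataset / "images",
                         toy_disk_dataset / "metadata.csv", image_size=16)


def _metrics_stub():
    return {"bacc": 50.0, "acc": 50.0, "macro_auc": 50.0, "per_class": {}}


class TestWriteResults:
    def test_empty_records_yield_valid_files(self, tmp_path):
        paths = write_results([], _metrics_stub(), tmp_path)
        df = pd.read_csv(paths["predictions"])
        assert len(df) == 0
        assert json.loads(paths["metrics"].read_text())["bacc"] == 50.0

    def test_predictions_roundtrip(self, tmp_path):
        scores = np.array([0.1, 0.2, 0.3, 0.2, 0.1, 0.1])
        records = [PredictionRecord("s1", scores, true_label=2,
                                    mc_variance=np.full(6, 0.01)),
                   PredictionRecord("s2", scores[::-1].copy(), true_label=None)]
        paths = write_results(records, _metrics_stub(), tmp_path)
        back = read_predictions(paths["predictions"])
        assert [r.sample_id for r in back] == ["s1", "s2"]
        assert np.allclose(back[0].softmax_scores, scores)
        assert back[0].true_label == 2 and back[1].true_label is None
        assert np.allclose(back[0].mc_variance, 0.01)

    def test_metrics_schema_enforced(self, tmp_path):
        with pytest.raises(ValueError, match="macro_auc"):
            write_results([], {"bacc": 1, "acc": 1, "per_class": {}}, tmp_path)


class TestPredictionRecord:
    def test_scores_must_be_distribution(self):
        with pytest.raises(ValueError):
            PredictionRecord("x", np.full(6, 0.2))
        with pytest.raises(ValueError):
            PredictionRecord("x", np.array([1.4, -0.4, 0, 0, 0, 0]))
        with pytest.raises(ValueError):
            PredictionRecord("x", np.full(6, 1 / 6), mc_variance=np.full(6, -1.0))
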