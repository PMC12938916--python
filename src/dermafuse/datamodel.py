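"""Core domain types and dataset/result I/O.

The six-class scheme (ACK, BCC, MEL, NEV, SCC, SEK — alphabetical, so the
static focal weights [1, 1, 2, 1, 2, 1] fall on the rare malignant classes
MEL and SCC), normalised lesion images, backbone feature maps, and
readers/writers for the CSV-per-image dataset dialect and result files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .schema import MetadataSchema, MetadataVector, training_medians

__all__ = [
    "CLASS_LABELS",
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "ClassScheme",
    "DatasetError",
    "FeatureMap",
    "LesionImage",
    "PredictionRecord",
    "Sample",
    "normalize_image",
    "denormalize_image",
    "read_dataset",
    "read_predictions",
    "write_results",
]

CLASS_LABELS = ("ACK", "BCC", "MEL", "NEV", "SCC", "SEK")

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])


class DatasetError(ValueError):
    """Raised for malformed dataset rows or missing files."""


@dataclass(frozen=True)
class ClassScheme:
    """Ordered class codes with per-class static focal weights."""

    labels: tuple[str, ...] = CLASS_LABELS
    static_alpha: tuple[float, ...] = (1.0, 1.0, 2.0, 1.0, 2.0, 1.0)

    def __post_init__(self):
        if len(self.labels) != 6:
            raise ValueError(f"expected 6 class labels, got {len(self.labels)}")
        if len(self.static_alpha) != 6:
            raise ValueError("static_alpha must have length 6")
        if any(a <= 0 for a in self.static_alpha):
            raise ValueError("all focal weights must be > 0")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise DatasetError(
                f"unknown diagnosis code {label!r}; valid codes: {self.labels}") from None


@dataclass
class LesionImage:
    """Normalised RGB image, channels-first (3, S, S)."""

    pixels: np.ndarray
    sample_id: str
    raw_path: Path | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[0] != 3:
            raise ValueError(f"expected (3, S, S) pixels, got {self.pixels.shape}")
        if self.pixels.shape[1] != self.pixels.shape[2]:
            raise ValueError("expected square spatial dims")

    @property
    def size(self) -> int:
        return self.pixels.shape[1]


@dataclass
class FeatureMap:
    """C×H×W activation grid with a pipeline stage tag."""

    values: np.ndarray
    stage: str = "backbone"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected (C, H, W), got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature map contains non-finite entries")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class Sample:
    image: LesionImage
    metadata: MetadataVector
    label: int
    split_tag: str = "unassigned"

    def __post_init__(self):
        if not 0 <= self.label < 6:
            raise ValueError(f"label {self.label} outside [0, 6)")

    @property
    def sample_id(self) -> str:
        return self.image.sample_id


@dataclass
class PredictionRecord:
    sample_id: str
    softmax_scores: np.ndarray
    true_label: int | None = None
    mc_variance: np.ndarray | None = None

    def __post_init__(self):
        self.softmax_scores = np.asarray(self.softmax_scores, dtype=np.float64)
        if self.softmax_scores.shape != (6,):
            raise ValueError("softmax_scores must have length 6")
        if not np.isclose(self.softmax_scores.sum(), 1.0, atol=1e-6):
            raise ValueError("softmax scores must sum to 1")
        if np.any(self.softmax_scores < 0) or np.any(self.softmax_scores > 1):
            raise ValueError("softmax scores must lie in [0, 1]")
        if self.mc_variance is not None:
            self.mc_variance = np.asarray(self.mc_variance, dtype=np.float64)
            if np.any(self.mc_variance < 0):
                raise ValueError("variance entries must be >= 0")

    @property
    def predicted(self) -> int:
        return int(np.argmax(self.softmax_scores))


# ---------------------------------------------------------------------------
# image normalisation


def normalize_image(rgb: np.ndarray) -> np.ndarray:
    """(S, S, 3) image in [0, 1] (or uint8) -> channels-first z-scored array."""
    rgb = np.asarray(rgb)
    if rgb.dtype == np.uint8:
        rgb = rgb.astype(np.float64) / 255.0
    chw = np.transpose(rgb, (2, 0, 1)).astype(np.float64)
    return (chw - IMAGENET_MEAN[:, None, None]) / IMAGENET_STD[:, None, None]


def denormalize_image(chw: np.ndarray) -> np.ndarray:
    """Inverse of :func:`normalize_image`, back to (S, S, 3) in [0, 1] scale."""
    rgb = chw * IMAGENET_STD[:, None, None] + IMAGENET_MEAN[:, None, None]
    return np.transpose(rgb, (1, 2, 0))


def load_image(path: Path, size: int) -> np.ndarray:
    """Read PNG/JPEG, bilinear-resize to (size, size), normalise."""
    with Image.open(path) as im:
        im = im.convert("RGB").resize((size, size), Image.BILINEAR)
        return normalize_image(np.asarray(im))


# ---------------------------------------------------------------------------
# dataset reading

_ID_COLUMN = "img_id"
_LABEL_COLUMN = "diagnostic"


def read_dataset(image_dir, metadata_csv, schema: MetadataSchema | None = None,
                 image_size: int = 224, medians: dict[str, float] | None = None,
                 class_scheme: ClassScheme | None = None) -> list[Sample]:
    """Load one Sample per CSV row (PAD-UFES-20-style layout).

    The CSV needs an ``img_id`` filename column, a ``diagnostic`` column and
    the schema's 21 attribute columns.  Numeric medians default to medians of
    the file itself; pass training-split medians explicitly to avoid leakage
    when reading evaluation data.
    """
    schema = schema or MetadataSchema.default()
    class_scheme = class_scheme or ClassScheme()
    image_dir = Path(image_dir)
    df = pd.read_csv(metadata_csv)
    for col in (_ID_COLUMN, _LABEL_COLUMN):
        if col not in df.columns:
            raise DatasetError(f"metadata CSV lacks required column {col!r}")
    rows = df.to_dict(orient="records")
    attr_names = set(schema.by_name)
    if medians is None:
        medians = training_medians(
            [{k: v for k, v in r.items() if k in attr_names} for r in rows], schema)
    samples = []
    for i, row in enumerate(rows):
        path = image_dir / str(row[_ID_COLUMN])
        if not path.exists():
            raise DatasetError(f"row {i} ({row[_ID_COLUMN]}): image file not found")
        label = class_scheme.index(str(row[_LABEL_COLUMN]))
        raw = {k: v for k, v in row.items() if k in attr_names}
        vec = schema.encode_row(raw, medians)
        image = LesionImage(load_image(path, image_size),
                            sample_id=str(row[_ID_COLUMN]), raw_path=path)
        samples.append(Sample(image=image, metadata=vec, label=label))
    return samples


# ---------------------------------------------------------------------------
# result writing

_PRED_COLUMNS = ["sample_id", "predicted", "true_label"] + \
    [f"score_{c}" for c in CLASS_LABELS] + [f"var_{c}" for c in CLASS_LABELS]


def write_results(records: list[PredictionRecord], metrics: dict, out_dir) -> dict[str, Path]:
    """Write per-sample predictions CSV + aggregate metrics JSON.

    Field order is deterministic; metrics JSON always carries the keys
    {bacc, acc, macro_auc, per_class}.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id, "predicted": CLASS_LABELS[r.predicted],
               "true_label": "" if r.true_label is None else CLASS_LABELS[r.true_label]}
        for c, s in zip(CLASS_LABELS, r.softmax_scores):
            row[f"score_{c}"] = s
        var = r.mc_variance if r.mc_variance is not None else [np.nan] * 6
        for c, v in zip(CLASS_LABELS, var):
            row[f"var_{c}"] = v
        rows.append(row)
    pred_path = out_dir / "predictions.csv"
    pd.DataFrame(rows, columns=_PRED_COLUMNS).to_csv(pred_path, index=False)

    for key in ("bacc", "acc", "macro_auc", "per_class"):
        if key not in metrics:
            raise ValueError(f"metrics dict lacks required key {key!r}")
    metrics_path = out_dir / "metrics.json"
    metrics_path.write_text(json.dumps(metrics, indent=2, sort_keys=True))
    return {"predictions": pred_path, "metrics": metrics_path}


def read_predictions(path) -> list[PredictionRecord]:
    """Inverse of the predictions CSV written by :func:`write_results`."""
    df = pd.read_csv(path, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        scores = np.array([row[f"score_{c}"] for c in CLASS_LABELS], dtype=float)
        raw_var = np.array([row[f"var_{c}"] for c in CLASS_LABELS])
        var = None
        try:
            var_f = raw_var.astype(float)
            if not np.any(np.isnan(var_f)):
                var = var_f
        except ValueError:
            var = None
        true = row["true_label"]
        records.append(PredictionRecord(
            sample_id=str(row["sample_id"]),
            softmax_scores=scores,
            true_label=None if true == "" else CLASS_LABELS.index(true),
            mc_variance=var,
        ))
    return records
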