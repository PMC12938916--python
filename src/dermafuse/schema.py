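"""Clinical-metadata encoding: 21 named attributes -> 81-dimensional vector.

PAD-UFES-20-style records carry 21 clinical attributes per lesion
(demographics, environmental exposure, personal/family cancer history and
lesion symptoms).  The encoder maps them to a fixed 81-dimensional vector:

* numeric attributes (age, two lesion diameters) are min-max scaled to
  [0, 1] over a declared physiological range, with missing values imputed
  by a supplied median (computed on the training split only);
* categorical attributes are one-hot encoded with an explicit trailing
  "unknown" dimension per attribute, so a missing value is itself a valid
  one-hot category rather than an all-zero span.

The first 18 dimensions encode age, sex and anatomical region; this block
is what minimal-metadata synthesis (see :mod:`dermafuse.synthetic`) fills
deterministically, with the remaining 63 dimensions drawn from reference
marginals.  The layout is a versioned config artifact: it serialises to a
plain dict (YAML-compatible) so real CSV dialects can be remapped without
code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AttributeSpec",
    "MetadataSchema",
    "MetadataVector",
    "SchemaError",
    "encode_metadata_row",
    "MISSING",
]

#: sentinel accepted as a missing value alongside None / NaN / ""
MISSING = None

_UNKNOWN = "unknown"

_BOOL_ATTRS = (
    "smoke", "drink", "pesticide", "skin_cancer_history", "cancer_history",
    "has_piped_water", "has_sewage_system", "itch", "grew", "hurt",
    "changed", "bleed", "elevation",
)

_REGIONS = (
    "face", "scalp", "nose", "ear", "neck", "lip", "chest", "back",
    "abdomen", "arm", "forearm", "hand", "foot",
)


class SchemaError(ValueError):
    """Raised for unknown attributes, bad categories or span mismatches."""


@dataclass(frozen=True)
class AttributeSpec:
    name: str
    kind: str  # "numeric" | "categorical"
    categories: tuple[str, ...] = ()  # categorical only; excludes "unknown"
    value_range: tuple[float, float] = (0.0, 1.0)  # numeric only

    @property
    def width(self) -> int:
        if self.kind == "numeric":
            return 1
        return len(self.categories) + 1  # + explicit unknown dimension


@dataclass
class MetadataVector:
    """Encoded 81-dim metadata with provenance of the encoding."""

    values: np.ndarray
    attribute_map: dict[str, slice]
    missing_mask: dict[str, bool]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (total_width(self.attribute_map),):
            raise SchemaError(
                f"vector length {self.values.shape} does not match schema spans")

    @property
    def dim(self) -> int:
        return self.values.shape[0]


def total_width(attribute_map: dict[str, slice]) -> int:
    return max(s.stop for s in attribute_map.values())


class MetadataSchema:
    """Ordered attribute specs with contiguous, disjoint encoded spans."""

    VERSION = 1

    def __init__(self, specs: list[AttributeSpec]):
        self.specs = list(specs)
        self.by_name = {s.name: s for s in self.specs}
        if len(self.by_name) != len(self.specs):
            raise SchemaError("duplicate attribute names")
        self.attribute_map: dict[str, slice] = {}
        offset = 0
        for s in self.specs:
            self.attribute_map[s.name] = slice(offset, offset + s.width)
            offset += s.width
        self.dim = offset

    # -- canonical layout ----------------------------------------------------
    @classmethod
    def default(cls) -> "MetadataSchema":
        """The canonical 21-attribute / 81-dimension layout."""
        specs = [
            AttributeSpec("age", "numeric", value_range=(0.0, 100.0)),
            AttributeSpec("sex", "categorical", ("female", "male")),
            AttributeSpec("region", "categorical", _REGIONS),
            AttributeSpec("diameter_1", "numeric", value_range=(0.0, 50.0)),
            AttributeSpec("diameter_2", "numeric", value_range=(0.0, 50.0)),
            AttributeSpec("fitspatrick", "categorical",
                          ("1", "2", "3", "4", "5", "6")),
            AttributeSpec("background_father", "categorical",
                          ("brazil", "portugal", "italy", "germany",
                           "spain", "pomerania", "netherlands")),
            AttributeSpec("background_mother", "categorical",
                          ("brazil", "portugal", "italy", "germany",
                           "spain", "pomerania")),
        ]
        specs += [AttributeSpec(name, "categorical", ("false", "true"))
                  for name in _BOOL_ATTRS]
        schema = cls(specs)
        assert schema.dim == 81, schema.dim
        return schema

    # -- serialisation -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "version": self.VERSION,
            "attributes": [
                {
                    "name": s.name,
                    "kind": s.kind,
                    **({"categories": list(s.categories)} if s.kind == "categorical"
                       else {"range": list(s.value_range)}),
                }
                for s in self.specs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetadataSchema":
        if d.get("version") != cls.VERSION:
            raise SchemaError(f"unsupported schema version {d.get('version')!r}")
        specs = []
        for a in d["attributes"]:
            if a["kind"] == "categorical":
                specs.append(AttributeSpec(a["name"], "categorical",
                                           tuple(a["categories"])))
            else:
                lo, hi = a["range"]
                specs.append(AttributeSpec(a["name"], "numeric",
                                           value_range=(float(lo), float(hi))))
        return cls(specs)

    # -- encoding ------------------------------------------------------------
    @property
    def numeric_names(self) -> list[str]:
        return [s.name for s in self.specs if s.kind == "numeric"]

    def unknown_index(self, name: str) -> int:
        """Absolute index of a categorical attribute's 'unknown' dimension."""
        spec = self.by_name[name]
        if spec.kind != "categorical":
            raise SchemaError(f"{name} is not categorical")
        return self.attribute_map[name].stop - 1

    def scale_numeric(self, name: str, value: float) -> float:
        lo, hi = self.by_name[name].value_range
        return float(np.clip((float(value) - lo) / (hi - lo), 0.0, 1.0))

    def unscale_numeric(self, name: str, encoded: float) -> float:
        lo, hi = self.by_name[name].value_range
        return lo + float(encoded) * (hi - lo)

    def encode_row(self, raw: dict, medians: dict[str, float] | None = None) -> MetadataVector:
        return encode_metadata_row(raw, self, medians)

    def decode_row(self, vec: MetadataVector) -> dict:
        """Inverse of encoding (numeric values up to scaling resolution)."""
        raw = {}
        for s in self.specs:
            span = vec.values[self.attribute_map[s.name]]
            if s.kind == "numeric":
                raw[s.name] = self.unscale_numeric(s.name, span[0])
            else:
                idx = int(np.argmax(span))
                cats = s.categories + (_UNKNOWN,)
                raw[s.name] = None if cats[idx] == _UNKNOWN else cats[idx]
        return raw

    def neutral_vector(self) -> MetadataVector:
        """All-"unknown" categoricals, mid-range numerics.

        Used both as the degenerate "no metadata available" input and as the
        default integrated-gradients baseline M'.
        """
        raw = {s.name: None for s in self.specs}
        medians = {n: 0.5 * sum(self.by_name[n].value_range) for n in self.numeric_names}
        return self.encode_row(raw, medians)


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    if isinstance(value, str) and value.strip().lower() in ("", "nan", "na", _UNKNOWN):
        return True
    return False


def encode_metadata_row(raw: dict, schema: MetadataSchema,
                        medians: dict[str, float] | None = None) -> MetadataVector:
    """Encode one record of 21 named attribute values.

    Numeric missings are imputed with `medians[name]` (training-split
    medians); categorical missings light the attribute's "unknown"
    dimension.  Unknown attribute names or categories raise SchemaError.
    """
    medians = medians or {}
    unknown_names = set(raw) - set(schema.by_name)
    if unknown_names:
        raise SchemaError(f"unknown attribute name(s): {sorted(unknown_names)}")
    values = np.zeros(schema.dim)
    missing_mask: dict[str, bool] = {}
    for spec in schema.specs:
        span = schema.attribute_map[spec.name]
        value = raw.get(spec.name)
        missing = _is_missing(value)
        missing_mask[spec.name] = missing
        if spec.kind == "numeric":
            if missing:
                if spec.name not in medians:
                    raise SchemaError(
                        f"numeric attribute {spec.name!r} missing but no median supplied")
                value = medians[spec.name]
            values[span.start] = schema.scale_numeric(spec.name, value)
        else:
            if missing:
                values[schema.unknown_index(spec.name)] = 1.0
            else:
                key = str(value).strip().lower()
                if key in ("0", "1") and spec.categories == ("false", "true"):
                    key = "false" if key == "0" else "true"
                if key not in spec.categories and key.endswith(".0"):
                    key = key[:-2]  # CSV readers promote "4" to 4.0
                if key not in spec.categories:
                    raise SchemaError(
                        f"attribute {spec.name!r}: category {value!r} not in "
                        f"{spec.categories}")
                values[span.start + spec.categories.index(key)] = 1.0
    return MetadataVector(values, dict(schema.attribute_map), missing_mask)


def training_medians(rows: list[dict], schema: MetadataSchema) -> dict[str, float]:
    """Per-numeric-attribute medians over rows, ignoring missing entries."""
    medians = {}
    for name in schema.numeric_names:
        present = [float(r[name]) for r in rows
                   if name in r and not _is_missing(r[name])]
        if not present:
            lo, hi = schema.by_name[name].value_range
            medians[name] = 0.5 * (lo + hi)
        else:
            medians[name] = float(np.median(present))
    return medians
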