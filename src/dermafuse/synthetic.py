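"""Class-conditional synthetic lesion images and correlated clinical metadata.

Emulates the structure of a PAD-UFES-20-scale dataset so every downstream
module is exercisable without external data: six classes with realistic
imbalance (SCC ≈ 8.4% of samples, MEL rarest), lesions rendered procedurally
on a skin-toned background with class-dependent asymmetry (ellipse
eccentricity), border irregularity (radial Fourier noise) and colour, and
21-attribute metadata drawn from class-conditional distributions whose
coupling to the class is a single dial (``metadata_signal_strength``: 0 =
class-independent, 1 = fully class-conditional).

Two independent RNG streams (images, metadata) are derived from one seed so
metadata can be regenerated without re-rendering images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import CLASS_LABELS, LesionImage, Sample, normalize_image
from .schema import MetadataSchema, MetadataVector

__all__ = [
    "GeneratorConfig",
    "MorphologyParams",
    "SplitSpec",
    "generate_dataset",
    "stratified_split",
    "synthesize_metadata_from_minimal",
    "reference_stats_from",
    "DEFAULT_CLASS_PROPORTIONS",
]

# Per-class sample counts of the emulated 2298-image corpus; SCC holds 8.4%
# of the mass and MEL is the rarest class.
_DEFAULT_COUNTS = {"ACK": 730, "BCC": 845, "MEL": 52, "NEV": 244, "SCC": 192, "SEK": 235}
DEFAULT_CLASS_PROPORTIONS = tuple(_DEFAULT_COUNTS[c] / 2298 for c in CLASS_LABELS)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class MorphologyParams:
    """Procedural lesion shape/colour for one class.

    eccentricity in [0,1) controls asymmetry; border_noise is the relative
    amplitude of radial boundary perturbation; hue is the lesion RGB centre
    (0-1 scale) with hue_spread the per-sample jitter.
    """

    eccentricity: float
    border_noise: float
    hue: tuple[float, float, float]
    hue_spread: float


# Rough visual archetypes: MEL dark/asymmetric/irregular, NEV regular brown,
# BCC/SCC pink-red with ragged borders, ACK scaly red-pink, SEK waxy tan.
DEFAULT_MORPHOLOGY: dict[str, MorphologyParams] = {
    "ACK": MorphologyParams(0.30, 0.25, (0.78, 0.45, 0.40), 0.05),
    "BCC": MorphologyParams(0.45, 0.35, (0.85, 0.55, 0.55), 0.05),
    "MEL": MorphologyParams(0.75, 0.50, (0.25, 0.15, 0.12), 0.06),
    "NEV": MorphologyParams(0.15, 0.08, (0.45, 0.28, 0.18), 0.04),
    "SCC": MorphologyParams(0.50, 0.45, (0.75, 0.30, 0.28), 0.06),
    "SEK": MorphologyParams(0.25, 0.20, (0.60, 0.45, 0.28), 0.05),
}


@dataclass(frozen=True)
class GeneratorConfig:
    total_n: int = 2298
    class_proportions: tuple[float, ...] = DEFAULT_CLASS_PROPORTIONS
    image_size: int = 224
    morphology: dict[str, MorphologyParams] = field(
        default_factory=lambda: dict(DEFAULT_MORPHOLOGY))
    metadata_signal_strength: float = 0.8
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if len(self.class_proportions) != 6:
            raise ConfigError("need 6 class proportions")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ConfigError("class proportions must sum to 1")
        if self.total_n < 6:
            raise ConfigError("total_n must be >= 6")
        if not 0.0 <= self.metadata_signal_strength <= 1.0:
            raise ConfigError("metadata_signal_strength must lie in [0, 1]")

    def tiny(self, total_n: int = 120, image_size: int = 32) -> "GeneratorConfig":
        return replace(self, total_n=total_n, image_size=image_size)


def class_counts(cfg: GeneratorConfig) -> list[int]:
    """round(total × proportion) with largest-remainder correction."""
    exact = np.array(cfg.class_proportions) * cfg.total_n
    counts = np.floor(exact).astype(int)
    remainder = cfg.total_n - counts.sum()
    order = np.argsort(-(exact - counts))
    counts[order[:remainder]] += 1
    if np.any(counts == 0):
        zero = [CLASS_LABELS[i] for i in np.where(counts == 0)[0]]
        raise ConfigError(f"proportions give zero samples for class(es) {zero}")
    return counts.tolist()


# ---------------------------------------------------------------------------
# image rendering


def render_lesion(class_label: str, size: int, rng: np.random.Generator,
                  morphology: dict[str, MorphologyParams] | None = None) -> np.ndarray:
    """Render one (size, size, 3) lesion image in [0, 1]."""
    m = (morphology or DEFAULT_MORPHOLOGY)[class_label]
    skin = np.array([0.85, 0.68, 0.58]) + rng.normal(0, 0.03, 3)
    img = np.clip(skin[None, None, :] + rng.normal(0, 0.015, (size, size, 3)), 0, 1)

    # lesion geometry: rotated ellipse with Fourier-perturbed boundary radius
    cx, cy = (0.5 + rng.uniform(-0.12, 0.12, 2)) * size
    r0 = size * rng.uniform(0.18, 0.30)
    b_over_a = np.sqrt(1.0 - m.eccentricity ** 2)
    phi = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    dx, dy = xx - cx, yy - cy
    xr = dx * np.cos(phi) + dy * np.sin(phi)
    yr = -dx * np.sin(phi) + dy * np.cos(phi)
    # elliptical radius of each pixel
    rho = np.sqrt(xr ** 2 + (yr / b_over_a) ** 2)
    theta = np.arctan2(yr, xr)
    bound = np.ones_like(theta)
    for k in range(2, 7):
        amp = m.border_noise * rng.uniform(0.2, 1.0) / k
        bound += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    edge = r0 * bound
    # soft alpha edge ~1.5 px wide
    alpha = np.clip((edge - rho) / 1.5 + 0.5, 0.0, 1.0)

    hue = np.clip(np.array(m.hue) + rng.normal(0, m.hue_spread, 3), 0, 1)
    texture = rng.normal(0, 0.04, (size, size, 1))
    lesion = np.clip(hue[None, None, :] + texture, 0, 1)
    img = img * (1 - alpha[..., None]) + lesion * alpha[..., None]
    return np.clip(img, 0, 1)


# ---------------------------------------------------------------------------
# metadata generation

# Class-conditional generative parameters for the 21 clinical attributes.
# Numbers are chosen to caricature clinical priors (keratinocyte cancers in
# older, sun-exposed, fair-skinned patients; nevi in the young; melanoma
# with change/itch history) — they drive the statistical class<->metadata
# coupling, not clinical realism.
_AGE = {"ACK": (62, 11), "BCC": (66, 12), "MEL": (55, 14),
        "NEV": (32, 13), "SCC": (70, 11), "SEK": (60, 13)}
_DIAM = {"ACK": (8, 3), "BCC": (9, 4), "MEL": (11, 5),
         "NEV": (5, 2), "SCC": (13, 5), "SEK": (9, 4)}
_REGION_PREF = {"ACK": ("face", "forearm", "hand"), "BCC": ("face", "nose", "ear"),
                "MEL": ("back", "chest", "arm"), "NEV": ("back", "abdomen", "arm"),
                "SCC": ("face", "hand", "lip"), "SEK": ("chest", "back", "face")}
# probability of "true" per class for symptom/history booleans
_BOOL_P = {
    "smoke": {"ACK": 0.25, "BCC": 0.25, "MEL": 0.20, "NEV": 0.15, "SCC": 0.40, "SEK": 0.20},
    "drink": {"ACK": 0.25, "BCC": 0.25, "MEL": 0.25, "NEV": 0.20, "SCC": 0.35, "SEK": 0.20},
    "pesticide": {"ACK": 0.45, "BCC": 0.35, "MEL": 0.20, "NEV": 0.10, "SCC": 0.45, "SEK": 0.20},
    "skin_cancer_history": {"ACK": 0.35, "BCC": 0.45, "MEL": 0.40, "NEV": 0.08, "SCC": 0.45, "SEK": 0.15},
    "cancer_history": {"ACK": 0.30, "BCC": 0.35, "MEL": 0.35, "NEV": 0.10, "SCC": 0.40, "SEK": 0.15},
    "has_piped_water": {c: 0.75 for c in CLASS_LABELS},
    "has_sewage_system": {c: 0.70 for c in CLASS_LABELS},
    "itch": {"ACK": 0.45, "BCC": 0.35, "MEL": 0.45, "NEV": 0.10, "SCC": 0.55, "SEK": 0.40},
    "grew": {"ACK": 0.35, "BCC": 0.55, "MEL": 0.70, "NEV": 0.10, "SCC": 0.65, "SEK": 0.30},
    "hurt": {"ACK": 0.25, "BCC": 0.30, "MEL": 0.25, "NEV": 0.05, "SCC": 0.55, "SEK": 0.10},
    "changed": {"ACK": 0.25, "BCC": 0.35, "MEL": 0.65, "NEV": 0.08, "SCC": 0.45, "SEK": 0.20},
    "bleed": {"ACK": 0.15, "BCC": 0.45, "MEL": 0.40, "NEV": 0.03, "SCC": 0.55, "SEK": 0.10},
    "elevation": {"ACK": 0.30, "BCC": 0.60, "MEL": 0.45, "NEV": 0.55, "SCC": 0.60, "SEK": 0.70},
}
_FITSPATRICK_P = {
    "ACK": (0.25, 0.35, 0.25, 0.10, 0.04, 0.01),
    "BCC": (0.30, 0.35, 0.20, 0.10, 0.04, 0.01),
    "MEL": (0.30, 0.30, 0.20, 0.12, 0.06, 0.02),
    "NEV": (0.10, 0.25, 0.30, 0.20, 0.10, 0.05),
    "SCC": (0.35, 0.35, 0.18, 0.08, 0.03, 0.01),
    "SEK": (0.15, 0.25, 0.30, 0.18, 0.08, 0.04),
}


def _marginal(table: dict[str, float] | dict[str, tuple]) -> np.ndarray:
    """Population marginal: class-proportion-weighted mixture of the rows."""
    w = np.array(DEFAULT_CLASS_PROPORTIONS)
    vals = np.array([np.atleast_1d(np.asarray(table[c], dtype=float)) for c in CLASS_LABELS])
    return (w[:, None] * vals).sum(axis=0)


def _sharpen(p: np.ndarray, s: float) -> np.ndarray:
    """Concentrate a probability vector as the signal dial rises: at s = 0
    the law is untouched, at s = 1 it is near-deterministic."""
    k = 1.0 + 3.0 * s
    q = np.clip(p, 1e-9, 1.0) ** k
    return q / q.sum()


def _sample_raw_attributes(label: str, s: float, rng: np.random.Generator,
                           schema: MetadataSchema) -> dict:
    """One 21-attribute record; each attribute follows the (sharpened)
    class-conditional law with probability `s`, else the population
    marginal."""

    def conditional(table):
        use_class = rng.random() < s
        if use_class:
            return np.atleast_1d(np.asarray(table[label], dtype=float))
        return _marginal(table)

    def conditional_probs(table):
        raw_p = conditional(table)
        return _sharpen(raw_p / raw_p.sum(), s)

    # continuous laws tighten around the class mean as s rises
    sd_scale = 1.0 - 0.7 * s

    raw: dict = {}
    mu, sd = conditional(_AGE)
    raw["age"] = float(np.clip(rng.normal(mu, sd * sd_scale), 1, 99))
    raw["sex"] = "male" if rng.random() < 0.55 else "female"

    regions = schema.by_name["region"].categories
    pref = _REGION_PREF[label] if rng.random() < s else _REGION_PREF[
        CLASS_LABELS[rng.integers(6)]]
    probs = np.full(len(regions), 0.3 / (len(regions) - 3))
    for r in pref:
        probs[regions.index(r)] = 0.7 / 3
    probs = _sharpen(probs / probs.sum(), s)
    raw["region"] = regions[rng.choice(len(regions), p=probs)]

    mu, sd = conditional(_DIAM)
    d1 = float(np.clip(rng.normal(mu, sd * sd_scale), 1, 45))
    raw["diameter_1"] = d1
    raw["diameter_2"] = float(np.clip(d1 * rng.uniform(0.6, 1.0), 1, 45))

    raw["fitspatrick"] = str(1 + rng.choice(6, p=conditional_probs(_FITSPATRICK_P)))

    for name in ("background_father", "background_mother"):
        cats = schema.by_name[name].categories
        raw[name] = cats[rng.integers(len(cats))]

    for name, table in _BOOL_P.items():
        p = float(conditional(table)[0])
        p = float(_sharpen(np.array([p, 1.0 - p]), s)[0])
        raw[name] = "true" if rng.random() < p else "false"
    return raw


def generate_metadata(labels: list[int], cfg: GeneratorConfig,
                      rng: np.random.Generator,
                      schema: MetadataSchema) -> list[MetadataVector]:
    medians = {"age": 55.0, "diameter_1": 8.0, "diameter_2": 6.0}
    vectors = []
    protected = ("sex",)  # class-independent by construction; never masked out
    for y in labels:
        raw = _sample_raw_attributes(CLASS_LABELS[y], cfg.metadata_signal_strength,
                                     rng, schema)
        if cfg.missing_rate > 0:
            for name in list(raw):
                if name not in protected and rng.random() < cfg.missing_rate:
                    raw[name] = None
        vectors.append(schema.encode_row(raw, medians))
    return vectors


# ---------------------------------------------------------------------------
# dataset assembly


def generate_dataset(cfg: GeneratorConfig,
                     schema: MetadataSchema | None = None) -> list[Sample]:
    """Generate `cfg.total_n` Samples, reproducible for a fixed seed."""
    schema = schema or MetadataSchema.default()
    counts = class_counts(cfg)
    labels: list[int] = []
    for k, n in enumerate(counts):
        labels.extend([k] * n)
    ss = np.random.SeedSequence(cfg.seed)
    img_ss, meta_ss, order_ss = ss.spawn(3)
    order_rng = np.random.default_rng(order_ss)
    labels = [labels[i] for i in order_rng.permutation(len(labels))]

    img_rng = np.random.default_rng(img_ss)
    meta_rng = np.random.default_rng(meta_ss)
    metadata = generate_metadata(labels, cfg, meta_rng, schema)
    samples = []
    for i, (y, vec) in enumerate(zip(labels, metadata)):
        rgb = render_lesion(CLASS_LABELS[y], cfg.image_size, img_rng, cfg.morphology)
        image = LesionImage(normalize_image(rgb), sample_id=f"syn_{i:05d}")
        samples.append(Sample(image=image, metadata=vec, label=y))
    return samples


# ---------------------------------------------------------------------------
# stratified splitting


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.667, 0.1665, 0.1665)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-6:
            raise ConfigError("split fractions must sum to 1")
        if any(f <= 0 for f in self.fractions):
            raise ConfigError("each split fraction must be > 0")


def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    floors = np.floor(targets).astype(int)
    rem = total - floors.sum()
    order = np.argsort(-(targets - floors))
    floors[order[:rem]] += 1
    return floors


def stratified_split(samples: list[Sample],
                     spec: SplitSpec | None = None) -> tuple[list[Sample], list[Sample], list[Sample]]:
    """Class-stratified train/val/test partition.

    Global sizes follow a train-first rounding rule: the train size is
    floor(n × f_train); the remainder is divided between validation and test
    in proportion to their fractions, validation receiving any odd sample.
    At n = 2298 with the default fractions this yields (1532, 383, 383).
    Per-class quotas are then apportioned by largest remainder, so every
    class's share in each partition matches its global share within
    integer rounding.
    """
    spec = spec or SplitSpec()
    n = len(samples)
    f_tr, f_va, f_te = spec.fractions
    n_train = int(np.floor(n * f_tr))
    rem = n - n_train
    n_val = int(np.ceil(rem * f_va / (f_va + f_te)))
    n_test = rem - n_val

    by_class: dict[int, list[Sample]] = {}
    for s in samples:
        by_class.setdefault(s.label, []).append(s)
    for label, group in by_class.items():
        if len(group) < 3:
            raise ConfigError(
                f"class {CLASS_LABELS[label]} has {len(group)} samples; "
                f"need at least 3 for a 3-way split")

    rng = np.random.default_rng(spec.seed)
    classes = sorted(by_class)
    n_c = np.array([len(by_class[c]) for c in classes], dtype=float)
    train_quota = _largest_remainder(n_c * n_train / n, n_train)
    rest = n_c - train_quota
    val_quota = _largest_remainder(rest * n_val / rem, n_val)
    test_quota = (rest - val_quota).astype(int)
    if np.any(test_quota < 0):  # pathological fractions; rebalance from val
        raise ConfigError("split fractions leave a class with negative test quota")

    train, val, test = [], [], []
    for c, q_tr, q_va, q_te in zip(classes, train_quota, val_quota, test_quota):
        group = list(by_class[c])
        perm = rng.permutation(len(group))
        group = [group[i] for i in perm]
        for s in group[:q_tr]:
            s.split_tag = "train"
        for s in group[q_tr:q_tr + q_va]:
            s.split_tag = "val"
        for s in group[q_tr + q_va:]:
            s.split_tag = "test"
        train += group[:q_tr]
        val += group[q_tr:q_tr + q_va]
        test += group[q_tr + q_va:]
    return train, val, test


# ---------------------------------------------------------------------------
# minimal-attribute metadata synthesis


def reference_stats_from(vectors: list[MetadataVector],
                         schema: MetadataSchema) -> dict[str, np.ndarray]:
    """Per-attribute empirical distributions from encoded reference vectors.

    Categorical attributes yield a probability vector over their encoded
    span (including the unknown dimension); numeric attributes yield the
    array of observed encoded values, resampled at synthesis time.
    """
    stats: dict[str, np.ndarray] = {}
    mat = np.stack([v.values for v in vectors])
    for spec in schema.specs:
        span = schema.attribute_map[spec.name]
        block = mat[:, span]
        if spec.kind == "numeric":
            stats[spec.name] = block[:, 0].copy()
        else:
            probs = block.mean(axis=0)
            stats[spec.name] = probs / probs.sum()
    return stats


def synthesize_metadata_from_minimal(age: float, sex: str, localization: str,
                                     reference_stats: dict[str, np.ndarray],
                                     schema: MetadataSchema | None = None,
                                     seed: int = 0) -> MetadataVector:
    """Build a full 81-dim vector from only age/sex/anatomical site.

    The first 18 dimensions (age, sex, region) are encoded deterministically
    from the arguments; the remaining 63 dimensions are sampled from the
    supplied reference marginals (from any reference dataset, real or
    synthetic).
    """
    schema = schema or MetadataSchema.default()
    minimal = ("age", "sex", "region")
    missing = [s.name for s in schema.specs
               if s.name not in minimal and s.name not in reference_stats]
    if missing:
        raise KeyError(f"reference_stats lacks attribute(s): {missing}")

    rng = np.random.default_rng(seed)
    values = np.zeros(schema.dim)
    missing_mask = {}
    # deterministic 18-dim block
    head = schema.encode_row(
        {"age": age, "sex": sex, "region": localization,
         **{s.name: None for s in schema.specs if s.name not in minimal}},
        medians={n: 0.0 for n in schema.numeric_names if n != "age"} | {"age": age})
    for name in minimal:
        span = schema.attribute_map[name]
        values[span] = head.values[span]
        missing_mask[name] = head.missing_mask[name]
    # sampled 63-dim block
    for spec in schema.specs:
        if spec.name in minimal:
            continue
        span = schema.attribute_map[spec.name]
        if spec.kind == "numeric":
            pool = np.asarray(reference_stats[spec.name], dtype=float)
            values[span.start] = float(rng.choice(pool))
        else:
            probs = np.asarray(reference_stats[spec.name], dtype=float)
            idx = rng.choice(spec.width, p=probs / probs.sum())
            values[span.start + idx] = 1.0
        missing_mask[spec.name] = False
    return MetadataVector(values, dict(schema.attribute_map), missing_mask)
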