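"""Seeded synthetic cocoon datasets for exercising the full pipeline.

Real silkworm cocoon images with validated pupal sex labels are not publicly
deposited, so this module fabricates datasets with the statistical structure
the pipeline assumes: a bright elliptical cocoon on a dark background whose
axis ratio and surface-texture frequency differ subtly between the sexes
(signal HOG can see), plus a per-specimen weight whose class distributions
overlap strongly — by construction the weight alone is a weak classifier
(effect size d = 0.3, best single-threshold accuracy around 0.56), while the
image features carry enough signal for the full pipeline to classify well.

Presets mirror the composition of the two foundation-cross rearing batches
used in the field: ``fc1`` (837 males / 742 females) and ``fc2``
(832 males / 837 females).  Every draw flows from one seed, making the
dataset a pure function of its spec.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import imageio.v3 as iio
import numpy as np

from .preprocess import RawSpecimen, write_manifest


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters for one synthetic cocoon dataset."""

    n_male: int = 837
    n_female: int = 742
    image_shape: tuple[int, int] = (90, 160)  # rows x cols before resize
    # ellipse major/minor axis ratio per class
    axis_ratio_male: float = 2.30
    axis_ratio_female: float = 2.10
    axis_ratio_sd: float = 0.08
    # sinusoidal surface-texture frequency (cycles across the minor axis)
    texture_freq_male: float = 6.0
    texture_freq_female: float = 4.5
    texture_amplitude: float = 0.25
    noise_sd: float = 8.0  # gray levels
    # cocoon weights in grams: overlapping Gaussians, effect size d = 0.3
    weight_mean_male: float = 1.10
    weight_mean_female: float = 1.16
    weight_sd: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_male <= 0 or self.n_female <= 0:
            raise ValueError("class counts must be positive")
        if self.axis_ratio_sd <= 0 or self.weight_sd <= 0:
            raise ValueError("spread parameters must be positive")


#: rearing-batch presets matching the field dataset composition
PRESETS = {
    "fc1": SyntheticSpec(n_male=837, n_female=742),
    "fc2": SyntheticSpec(n_male=832, n_female=837),
}


def preset(name: str, seed: int = 0, **overrides) -> SyntheticSpec:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; valid: {sorted(PRESETS)}")
    return replace(PRESETS[name], seed=seed, **overrides)


@dataclass(frozen=True)
class SyntheticDataset:
    images: np.ndarray  # (n, rows, cols) uint8
    weights: np.ndarray  # grams
    labels: np.ndarray  # 0 = female, 1 = male
    spec: SyntheticSpec

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.images) != n or len(self.weights) != n:
            raise ValueError("images, weights and labels must align")


def generate_cocoon_image(
    class_label: int, spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    """Render one synthetic cocoon: textured bright ellipse on dark ground.

    The ellipse's axis ratio is drawn from the class distribution with a
    small rotation jitter; a class-frequency sinusoidal texture modulates
    the foreground; Gaussian pixel noise is added last.  Deterministic given
    the generator state.
    """
    rows, cols = spec.image_shape
    if class_label == 1:
        ratio_mu, freq = spec.axis_ratio_male, spec.texture_freq_male
    else:
        ratio_mu, freq = spec.axis_ratio_female, spec.texture_freq_female
    ratio = max(1.05, rng.normal(ratio_mu, spec.axis_ratio_sd))
    angle = rng.normal(0.0, np.deg2rad(4.0))
    phase = rng.uniform(0, 2 * np.pi)
    # minor semi-axis fills ~70% of the short image dimension
    b = 0.35 * rows
    a = ratio * b
    yy, xx = np.mgrid[0:rows, 0:cols]
    y = yy - rows / 2.0
    x = xx - cols / 2.0
    u = np.cos(angle) * x + np.sin(angle) * y  # along the major axis
    v = -np.sin(angle) * x + np.cos(angle) * y
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    img = np.full((rows, cols), 30.0)  # dark background
    texture = 1.0 + spec.texture_amplitude * np.sin(
        2 * np.pi * freq * v / (2 * b) + phase
    )
    img[inside] = 180.0 * texture[inside]
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the full dataset: images, weights and shuffled labels."""
    rng = np.random.default_rng(spec.seed)
    labels = np.concatenate(
        [np.ones(spec.n_male, dtype=int), np.zeros(spec.n_female, dtype=int)]
    )
    rng.shuffle(labels)
    images = np.empty((len(labels), *spec.image_shape), dtype=np.uint8)
    weights = np.empty(len(labels))
    for i, lab in enumerate(labels):
        images[i] = generate_cocoon_image(int(lab), spec, rng)
        mu = spec.weight_mean_male if lab == 1 else spec.weight_mean_female
        w = rng.normal(mu, spec.weight_sd)
        weights[i] = max(w, 0.05)  # physical weights stay positive
    return SyntheticDataset(images=images, weights=weights, labels=labels, spec=spec)


def weight_only_baseline(dataset: SyntheticDataset) -> float:
    """Best single-threshold classification accuracy using weight alone.

    Brute-forces every threshold between sorted weights, in both polarity
    directions.  Quantifies how weak the weight feature is on its own.
    """
    w = np.asarray(dataset.weights, dtype=float)
    y = np.asarray(dataset.labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    order = np.argsort(w)
    y_sorted = y[order]
    n = len(y)
    # below-threshold male counts for every split position 0..n
    cum_male = np.concatenate([[0], np.cumsum(y_sorted == 1)])
    total_male = cum_male[-1]
    k = np.arange(n + 1)
    # polarity A: predict male below the split
    correct_a = cum_male + ((n - k) - (total_male - cum_male))
    # polarity B: predict male above the split
    correct_b = (k - cum_male) + (total_male - cum_male)
    return float(max(correct_a.max(), correct_b.max()) / n)


def write_dataset(dataset: SyntheticDataset, out_dir: str | os.PathLike) -> str:
    """Write PNGs plus a manifest CSV with the standard input schema."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    specimens = []
    for i in range(len(dataset.labels)):
        name = f"cocoon_{i:05d}.png"
        iio.imwrite(os.path.join(out_dir, name), dataset.images[i])
        specimens.append(
            RawSpecimen(
                image_path=name,
                weight=float(dataset.weights[i]),
                label=int(dataset.labels[i]),
            )
        )
    manifest = os.path.join(out_dir, "manifest.csv")
    write_manifest(specimens, manifest)
    return manifest
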