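"""Synthetic mass-ROI image + tabular dataset generator.

Emulates the statistical structure of a curated mammography mass subset so
the whole two-stage pipeline is testable without any download: two image
classes that differ in lesion geometry (benign = one smooth isotropic blob,
malignant = a cluster of 3-6 anisotropic oriented blobs with irregular
margins), optional saturated white-border artifacts, additive pixel noise,
tabular fields whose ordinal severity scores (BI-RADS, subtlety) shift with
the class label, missingness in the shape/margin descriptors at the
documented rates, and a benign-heavy 0.54:0.46 class ratio.

Every sample is generated from its own RNG stream derived from
(seed, sample index), so datasets are bitwise reproducible and any single
sample can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import schema

__all__ = ["SyntheticSpec", "TabularRecord", "Sample",
           "generate_dataset", "generate_roi_image", "generate_tabular"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Configuration of the synthetic study population.

    Defaults mirror the emulated source collection: a 0.46 malignant
    fraction, shape descriptors missing in 4/1696 records and margin
    descriptors missing in 60/1696.
    """

    n_samples: int = 400
    malignant_fraction: float = 0.46
    image_size: int = 32
    white_border_prob: float = 0.15
    border_width: int = 2
    noise_sd: float = 0.25
    shape_missing_rate: float = 4 / 1696
    margins_missing_rate: float = 60 / 1696
    tabular_effect: float = 1.2
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 0:
            raise ValueError(f"n_samples must be >= 0, got {self.n_samples}")
        if not 0.0 < self.malignant_fraction < 1.0:
            raise ValueError(
                f"malignant_fraction must be in (0,1), got {self.malignant_fraction}")
        if self.image_size < 8:
            raise ValueError(f"image_size must be >= 8, got {self.image_size}")
        for name in ("white_border_prob", "shape_missing_rate", "margins_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.border_width < 1:
            raise ValueError(f"border_width must be >= 1, got {self.border_width}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass
class TabularRecord:
    breast_density: int
    laterality: str
    view: str
    abnormality_id: int
    mass_shape: str
    mass_margins: str
    birads: int
    subtlety: int
    pathology: str

    def validate(self) -> None:
        if not 1 <= self.breast_density <= 4:
            raise ValueError(f"breast_density out of range: {self.breast_density}")
        if self.laterality not in schema.LATERALITIES:
            raise ValueError(f"bad laterality: {self.laterality}")
        if self.view not in schema.VIEWS:
            raise ValueError(f"bad view: {self.view}")
        if not 1 <= self.abnormality_id <= 7:
            raise ValueError(f"abnormality_id out of range: {self.abnormality_id}")
        if self.mass_shape != schema.MISSING and self.mass_shape not in schema.MASS_SHAPES:
            raise ValueError(f"bad mass_shape: {self.mass_shape}")
        if self.mass_margins != schema.MISSING and self.mass_margins not in schema.MASS_MARGINS:
            raise ValueError(f"bad mass_margins: {self.mass_margins}")
        if not 0 <= self.birads <= 5:
            raise ValueError(f"birads out of range: {self.birads}")
        if not 1 <= self.subtlety <= 5:
            raise ValueError(f"subtlety out of range: {self.subtlety}")
        if self.pathology not in schema.PATHOLOGIES:
            raise ValueError(f"bad pathology: {self.pathology}")


@dataclass
class Sample:
    """One ROI image with its tabular record and merged binary label."""

    image: np.ndarray
    record: TabularRecord
    label: int


# Fixed (label-independent) category weights: geometric decay over the
# vocabulary so a handful of descriptors dominate, as in real manifests.
def _geometric_weights(n: int, decay: float = 0.82) -> np.ndarray:
    w = decay ** np.arange(n)
    return w / w.sum()

_SHAPE_WEIGHTS = _geometric_weights(len(schema.MASS_SHAPES))
_MARGIN_WEIGHTS = _geometric_weights(len(schema.MASS_MARGINS))
# Baseline ordinal weights for BI-RADS 0..5 and subtlety 1..5.
_BIRADS_BASE = np.array([0.05, 0.10, 0.20, 0.30, 0.25, 0.10])
_SUBTLETY_BASE = np.array([0.10, 0.20, 0.30, 0.25, 0.15])


def _shifted_ordinal(base: np.ndarray, effect: float) -> np.ndarray:
    """Tilt an ordinal pmf by a log-odds gradient toward higher categories."""
    k = np.arange(len(base)) / (len(base) - 1)
    w = base * np.exp(effect * k)
    return w / w.sum()


def _gaussian_blob(size: int, cy: float, cx: float,
                   sy: float, sx: float, theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    y, x = yy - cy, xx - cx
    c, s = np.cos(theta), np.sin(theta)
    u = c * x + s * y
    v = -s * x + c * y
    return np.exp(-(u ** 2 / (2 * sx ** 2) + v ** 2 / (2 * sy ** 2)))


def generate_roi_image(label: int, spec: SyntheticSpec,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw one grayscale ROI in [0,1]: smooth round lesion for benign,
    irregular multi-lobed lesion for malignant, plus optional white border
    and Gaussian pixel noise."""
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label}")
    n = spec.image_size
    img = np.full((n, n), 0.15)
    center = n / 2.0
    if label == 0:
        cy = center + rng.normal(0, n * 0.04)
        cx = center + rng.normal(0, n * 0.04)
        sigma = n * rng.uniform(0.16, 0.22)
        img += 0.6 * _gaussian_blob(n, cy, cx, sigma, sigma, 0.0)
    else:
        n_lobes = rng.integers(3, 7)
        for _ in range(n_lobes):
            cy = center + rng.normal(0, n * 0.12)
            cx = center + rng.normal(0, n * 0.12)
            sy = n * rng.uniform(0.03, 0.08)
            sx = n * rng.uniform(0.10, 0.22)
            theta = rng.uniform(0, np.pi)
            img += rng.uniform(0.35, 0.65) * _gaussian_blob(n, cy, cx, sy, sx, theta)
    if rng.random() < spec.white_border_prob:
        w = spec.border_width
        img[:w, :] = 1.0
        img[-w:, :] = 1.0
        img[:, :w] = 1.0
        img[:, -w:] = 1.0
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_tabular(label: int, spec: SyntheticSpec,
                     rng: np.random.Generator) -> TabularRecord:
    """Draw one tabular record; BI-RADS and subtlety distributions are
    tilted toward higher categories by ``tabular_effect`` when malignant."""
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label}")
    effect = spec.tabular_effect if label == 1 else 0.0
    birads = int(rng.choice(6, p=_shifted_ordinal(_BIRADS_BASE, effect)))
    subtlety = 1 + int(rng.choice(5, p=_shifted_ordinal(_SUBTLETY_BASE, effect)))
    shape = str(rng.choice(schema.MASS_SHAPES, p=_SHAPE_WEIGHTS))
    margins = str(rng.choice(schema.MASS_MARGINS, p=_MARGIN_WEIGHTS))
    if rng.random() < spec.shape_missing_rate:
        shape = schema.MISSING
    if rng.random() < spec.margins_missing_rate:
        margins = schema.MISSING
    if label == 1:
        pathology = "MALIGNANT"
    else:
        pathology = "BENIGN_WITHOUT_CALLBACK" if rng.random() < 0.15 else "BENIGN"
    record = TabularRecord(
        breast_density=1 + int(rng.integers(0, 4)),
        laterality=str(rng.choice(schema.LATERALITIES)),
        view=str(rng.choice(schema.VIEWS)),
        abnormality_id=1 + int(rng.integers(0, 7)),
        mass_shape=shape,
        mass_margins=margins,
        birads=birads,
        subtlety=subtlety,
        pathology=pathology,
    )
    record.validate()
    return record


def _sample_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def generate_dataset(spec: SyntheticSpec) -> list[Sample]:
    """Generate ``spec.n_samples`` samples; identical spec -> identical output."""
    samples = []
    for i in range(spec.n_samples):
        rng = _sample_rng(spec.seed, i)
        label = int(rng.random() < spec.malignant_fraction)
        record = generate_tabular(label, spec, rng)
        image = generate_roi_image(label, spec, rng)
        samples.append(Sample(image=image, record=record, label=label))
    return samples
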