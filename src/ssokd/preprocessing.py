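"""Image operators and tabular encoding producing model-ready inputs.

Image chain: white-border crop -> non-local-means denoising -> CLAHE ->
resize + dataset-level standardization. Tabular chain: 3 ordinal columns
(breast density, BI-RADS, subtlety) plus one-hot blocks for the 20 mass
shapes and 19 mass margins, each extended with an UNKNOWN indicator that
absorbs missing entries, for a fixed 44-column layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure, restoration, transform

from . import schema
from .synthetic import TabularRecord

__all__ = [
    "PreprocessConfig", "Standardizer", "FEATURE_COLUMNS",
    "remove_white_border", "nlm_denoise", "clahe_enhance",
    "resize_and_standardize", "encode_tabular", "encode_labels",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``border_intensity_quantile`` is the fraction of the valid intensity
    range above which a pixel counts as white; a row/column is cropped when
    its white fraction exceeds ``border_run_fraction``. ``clahe_clip`` uses
    the OpenCV convention (histogram-count multiples); it is divided by 256
    bins for scikit-image. ``nlm_h = None`` means 0.8x the estimated noise
    sigma.
    """

    border_intensity_quantile: float = 0.95
    border_run_fraction: float = 0.90
    nlm_patch: int = 7
    nlm_search: int = 21
    nlm_h: float | None = None
    clahe_clip: float = 2.0
    clahe_tiles: tuple[int, int] = (8, 8)
    target_shape: tuple[int, int, int] = (75, 75, 3)

    def __post_init__(self):
        if not 0.0 < self.border_intensity_quantile <= 1.0:
            raise ValueError("border_intensity_quantile must be in (0,1]")
        if not 0.0 < self.border_run_fraction <= 1.0:
            raise ValueError("border_run_fraction must be in (0,1]")
        h, w, c = self.target_shape
        if h < 8 or w < 8:
            raise ValueError(f"target h,w must be >= 8, got {(h, w)}")
        if c not in (1, 3):
            raise ValueError(f"target channels must be 1 or 3, got {c}")
        if self.nlm_patch < 1 or self.nlm_search < self.nlm_patch:
            raise ValueError("need 1 <= nlm_patch <= nlm_search")


def _as_float01(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.dtype == np.uint8:
        return image.astype(float) / 255.0
    return image.astype(float)


def remove_white_border(image: np.ndarray,
                        config: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Crop contiguous saturated rows/columns inward from each edge.

    The white threshold is fixed against the valid intensity range (1.0 for
    float images, 255 for uint8), which makes the crop idempotent.
    """
    img = np.asarray(image)
    if img.size == 0 or not np.all(np.isfinite(_as_float01(img))):
        raise ValueError("image must be non-empty and finite")
    f = _as_float01(img)
    thresh = config.border_intensity_quantile  # of the valid-range max 1.0
    white = f >= thresh
    n_rows, n_cols = white.shape

    def run_length(fracs) -> int:
        k = 0
        for frac in fracs:
            if frac > config.border_run_fraction:
                k += 1
            else:
                break
        return k

    row_frac = white.mean(axis=1)
    col_frac = white.mean(axis=0)
    top = run_length(row_frac)
    bottom = run_length(row_frac[::-1])
    left = run_length(col_frac)
    right = run_length(col_frac[::-1])
    if top + bottom >= n_rows or left + right >= n_cols:
        raise ValueError("white-border crop would remove the entire image")
    return img[top:n_rows - bottom, left:n_cols - right]


def nlm_denoise(image: np.ndarray,
                config: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Non-local-means denoising: each pixel becomes a weighted average of
    pixels with a similar patch neighborhood."""
    img = _as_float01(image)
    if config.nlm_search > min(img.shape):
        raise ValueError(
            f"nlm_search {config.nlm_search} exceeds image size {img.shape}")
    h = config.nlm_h
    if h is None:
        sigma = restoration.estimate_sigma(img)
        h = 0.8 * float(sigma)
    if h <= 0:
        return img.copy()
    patch_distance = max(1, (config.nlm_search - config.nlm_patch) // 2)
    return restoration.denoise_nl_means(
        img, patch_size=config.nlm_patch, patch_distance=patch_distance,
        h=h, fast_mode=True)


def clahe_enhance(image: np.ndarray,
                  config: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization over a tile grid."""
    img = _as_float01(image)
    ty, tx = config.clahe_tiles
    if ty > img.shape[0] or tx > img.shape[1]:
        raise ValueError(f"clahe tile grid {config.clahe_tiles} exceeds image {img.shape}")
    kernel = (max(1, img.shape[0] // ty), max(1, img.shape[1] // tx))
    if img.std() == 0.0:
        return img.copy()  # nothing to equalize; keep the constant level
    out = exposure.equalize_adapthist(
        np.clip(img, 0.0, 1.0), kernel_size=kernel,
        clip_limit=config.clahe_clip / 256.0)
    return out


def resize_and_standardize(image: np.ndarray,
                           config: PreprocessConfig = PreprocessConfig(),
                           mean: float = 0.0, sd: float = 1.0) -> np.ndarray:
    """Resize to ``target_shape``, replicate grayscale across channels and
    apply the dataset-level z-score (two-pass contract: ``mean``/``sd`` come
    from a :class:`Standardizer` fitted on the training split)."""
    img = _as_float01(image)
    if img.size == 0:
        raise ValueError("image must be non-empty")
    h, w, c = config.target_shape
    resized = transform.resize(np.clip(img, 0.0, 1.0), (h, w),
                               anti_aliasing=True, preserve_range=True)
    block = np.repeat(resized[:, :, None], c, axis=2)
    if sd <= 0:
        raise ValueError(f"sd must be positive, got {sd}")
    return (block - mean) / sd


@dataclass
class Standardizer:
    """Dataset-level pixel moments, frozen on the training split and reused
    for validation/test (leakage guard)."""

    mean: float = 0.0
    sd: float = 1.0

    @classmethod
    def fit(cls, images: list[np.ndarray]) -> "Standardizer":
        stacked = np.concatenate([_as_float01(im).ravel() for im in images])
        sd = float(stacked.std())
        return cls(mean=float(stacked.mean()), sd=sd if sd > 0 else 1.0)


_SHAPE_CATS = tuple(sorted(schema.MASS_SHAPES)) + (schema.UNKNOWN,)
_MARGIN_CATS = tuple(sorted(schema.MASS_MARGINS)) + (schema.UNKNOWN,)

FEATURE_COLUMNS: tuple[str, ...] = (
    ("breast_density", "birads", "subtlety")
    + tuple(f"shape={c}" for c in _SHAPE_CATS)
    + tuple(f"margins={c}" for c in _MARGIN_CATS)
)
assert len(FEATURE_COLUMNS) == 3 + 21 + 20 == 44


def encode_tabular(records: list[TabularRecord]) -> np.ndarray:
    """Encode records into the fixed 44-column layout:
    [breast_density, birads, subtlety] ++ 21 shape indicators (alphabetical,
    UNKNOWN last) ++ 20 margin indicators (alphabetical, UNKNOWN last).
    MISSING values map to the UNKNOWN indicator of their block."""
    if len(records) == 0:
        raise ValueError("records must be non-empty")
    out = np.zeros((len(records), 44))
    shape_index = {c: i for i, c in enumerate(_SHAPE_CATS)}
    margin_index = {c: i for i, c in enumerate(_MARGIN_CATS)}
    for r, rec in enumerate(records):
        rec.validate()
        out[r, 0] = rec.breast_density
        out[r, 1] = rec.birads
        out[r, 2] = rec.subtlety
        shape = schema.UNKNOWN if rec.mass_shape == schema.MISSING else rec.mass_shape
        margins = schema.UNKNOWN if rec.mass_margins == schema.MISSING else rec.mass_margins
        if shape not in shape_index:
            raise ValueError(f"unseen mass_shape category: {shape!r}")
        if margins not in margin_index:
            raise ValueError(f"unseen mass_margins category: {margins!r}")
        out[r, 3 + shape_index[shape]] = 1.0
        out[r, 24 + margin_index[margins]] = 1.0
    return out


_LABEL_MAP = {"BENIGN": 0, "BENIGN_WITHOUT_CALLBACK": 0, "MALIGNANT": 1}


def encode_labels(records: list[TabularRecord]) -> np.ndarray:
    """Merge pathology to binary: benign-without-callback counts as benign."""
    labels = []
    for rec in records:
        if rec.pathology not in _LABEL_MAP:
            raise ValueError(f"unknown pathology: {rec.pathology!r}")
        labels.append(_LABEL_MAP[rec.pathology])
    return np.array(labels, dtype=int)
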