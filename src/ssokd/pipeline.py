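"""Stratified splitting, four-fold training augmentation and dataset I/O.

The split reproduces the emulated collection's bookkeeping: per class,
``floor(0.8 * n)`` samples go to training; the per-class remainders are
dealt one at a time to validation or test by a global largest-deficit rule
(ties to test), which keeps each split's class ratio within one sample of
the dataset ratio. Augmentation quadruples the training split with a
horizontal flip, a vertical flip and one random multiple-of-90-degree
rotation per image; it is applied to the training split only.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

from . import schema
from .synthetic import Sample, TabularRecord

__all__ = ["SplitDataset", "stratified_split", "augment_fourfold",
           "write_dataset", "read_dataset"]


@dataclass
class SplitDataset:
    train: list[Sample]
    validation: list[Sample]
    test: list[Sample]
    split_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def __iter__(self):
        yield from (("train", self.train), ("validation", self.validation),
                    ("test", self.test))

    @property
    def n_samples(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)


def stratified_split(samples: list[Sample],
                     ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
                     seed: int = 0) -> SplitDataset:
    """Split per class: train gets ``floor(ratio_train * n_class)``; the
    remainder is dealt to validation/test by largest remaining global
    deficit (ties to test). Assignment order is shuffled by ``seed`` within
    each class; the split is invariant to the input ordering."""
    if not math.isclose(sum(ratios), 1.0, abs_tol=1e-9):
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    r_train, r_val, r_test = ratios
    labels = sorted({s.label for s in samples})
    by_class = {lab: [i for i, s in enumerate(samples) if s.label == lab]
                for lab in labels}
    n_splits_needed = sum(1 for r in ratios if r > 0)
    for lab, idx in by_class.items():
        if len(idx) < n_splits_needed:
            raise ValueError(
                f"class {lab} has {len(idx)} samples, fewer than the "
                f"{n_splits_needed} non-empty splits")

    rng = np.random.default_rng(seed)
    n_total = len(samples)
    target_val = r_val * n_total
    target_test = r_test * n_total
    train_idx, val_idx, test_idx = [], [], []
    n_val = n_test = 0

    def content_key(i):
        s = samples[i]
        return (s.image.tobytes(), repr(s.record))

    for lab in labels:
        # shuffle within class on a content-based key so the split is
        # invariant to the input ordering
        order = sorted(by_class[lab], key=content_key)
        perm = rng.permutation(len(order))
        shuffled = [order[p] for p in perm]
        n_train = int(math.floor(r_train * len(shuffled)))
        train_idx.extend(shuffled[:n_train])
        for i in shuffled[n_train:]:
            if (target_test - n_test) >= (target_val - n_val):
                test_idx.append(i)
                n_test += 1
            else:
                val_idx.append(i)
                n_val += 1
    return SplitDataset(
        train=[samples[i] for i in train_idx],
        validation=[samples[i] for i in val_idx],
        test=[samples[i] for i in test_idx],
        split_ratios=ratios,
    )


def augment_fourfold(samples: list[Sample], seed: int = 0) -> list[Sample]:
    """Return each sample plus its horizontal flip, vertical flip and one
    random k*90-degree rotation (k drawn uniformly from {1,2,3}); tabular
    records and labels are copied unchanged."""
    rng = np.random.default_rng(seed)
    out: list[Sample] = []
    for s in samples:
        k = int(rng.integers(1, 4))
        variants = (
            s.image.copy(),
            np.fliplr(s.image).copy(),
            np.flipud(s.image).copy(),
            np.rot90(s.image, k=k).copy(),
        )
        for img in variants:
            out.append(Sample(image=img, record=dataclasses.replace(s.record),
                              label=s.label))
    return out


def _save_png16(image: np.ndarray, path: str) -> None:
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray(np.round(arr * 65535).astype(np.uint16), mode="I;16").save(path)


def _load_png16(path: str) -> np.ndarray:
    if not os.path.exists(path):
        raise FileNotFoundError(f"image file referenced by manifest not found: {path}")
    return np.asarray(Image.open(path), dtype=float) / 65535.0


def write_dataset(split: SplitDataset, out_dir: str) -> str:
    """Write PNG images plus a CSV manifest (one row per sample, columns per
    the tabular schema plus image_path, label and split). Images are stored
    as 16-bit PNG, so intensities round-trip to within 1/65535."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for split_name, samples in split:
        img_dir = os.path.join(out_dir, "images", split_name)
        os.makedirs(img_dir, exist_ok=True)
        for i, s in enumerate(samples):
            rel = os.path.join("images", split_name, f"{i:05d}.png")
            _save_png16(s.image, os.path.join(out_dir, rel))
            rec = s.record
            rows.append({
                "breast_density": rec.breast_density,
                "laterality": rec.laterality,
                "view": rec.view,
                "abnormality_id": rec.abnormality_id,
                "mass_shape": rec.mass_shape,
                "mass_margins": rec.mass_margins,
                "birads": rec.birads,
                "subtlety": rec.subtlety,
                "pathology": rec.pathology,
                "image_path": rel,
                "label": s.label,
                "split": split_name,
            })
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows, columns=list(schema.MANIFEST_COLUMNS) + ["split"]).to_csv(
        manifest, index=False)
    return manifest


def read_dataset(in_dir: str) -> SplitDataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    manifest = os.path.join(in_dir, "manifest.csv")
    if not os.path.exists(manifest):
        raise FileNotFoundError(f"manifest not found: {manifest}")
    df = pd.read_csv(manifest)
    required = set(schema.MANIFEST_COLUMNS) | {"split"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    splits: dict[str, list[Sample]] = {"train": [], "validation": [], "test": []}
    for _, row in df.iterrows():
        record = TabularRecord(
            breast_density=int(row["breast_density"]),
            laterality=str(row["laterality"]),
            view=str(row["view"]),
            abnormality_id=int(row["abnormality_id"]),
            mass_shape=str(row["mass_shape"]),
            mass_margins=str(row["mass_margins"]),
            birads=int(row["birads"]),
            subtlety=int(row["subtlety"]),
            pathology=str(row["pathology"]),
        )
        record.validate()
        image = _load_png16(os.path.join(in_dir, str(row["image_path"])))
        split_name = str(row["split"])
        if split_name not in splits:
            raise ValueError(f"unknown split name in manifest: {split_name!r}")
        splits[split_name].append(Sample(image=image, record=record,
                                         label=int(row["label"])))
    return SplitDataset(train=splits["train"], validation=splits["validation"],
                        test=splits["test"])
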