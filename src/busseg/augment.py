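"""Paired image+mask affine augmentation.

Four transform kinds expand a training set: vertical shift, horizontal
shift, shear and horizontal (left-right) flip.  The identical geometric map
is applied to image and mask; images are interpolated bilinearly, masks with
nearest neighbour so they stay strictly binary.  Exposed borders are filled
with zeros (echo-free black).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .phantom import SamplePair

__all__ = [
    "TRANSFORM_KINDS",
    "AugmentationSpec",
    "apply_paired",
    "expand_training_set",
    "random_specs",
    "write_expanded",
]

TRANSFORM_KINDS = ("vertical_shift", "horizontal_shift", "shear",
                   "horizontal_flip")

MAX_SHIFT_FRACTION = 0.2
MAX_SHEAR_DEGREES = 20.0


@dataclass(frozen=True)
class AugmentationSpec:
    kind: str
    magnitude: float = 0.0   # shift: fraction of side (signed); shear: degrees

    def __post_init__(self):
        if self.kind not in TRANSFORM_KINDS:
            raise ValueError(
                f"unknown transform kind {self.kind!r}; expected one of "
                f"{TRANSFORM_KINDS}")
        if self.kind in ("vertical_shift", "horizontal_shift"):
            if abs(self.magnitude) > MAX_SHIFT_FRACTION:
                raise ValueError(
                    f"shift fraction {self.magnitude} outside "
                    f"[-{MAX_SHIFT_FRACTION}, {MAX_SHIFT_FRACTION}]")
        elif self.kind == "shear":
            if abs(self.magnitude) > MAX_SHEAR_DEGREES:
                raise ValueError(
                    f"shear angle {self.magnitude} outside "
                    f"[-{MAX_SHEAR_DEGREES}, {MAX_SHEAR_DEGREES}] degrees")


def _transform_channel(arr: np.ndarray, spec: AugmentationSpec,
                       order: int) -> np.ndarray:
    rows, cols = arr.shape
    if spec.kind == "horizontal_flip":
        return arr[:, ::-1].copy()
    if spec.kind == "vertical_shift":
        return ndimage.shift(arr, (spec.magnitude * rows, 0.0), order=order,
                             mode="constant", cval=0.0)
    if spec.kind == "horizontal_shift":
        return ndimage.shift(arr, (0.0, spec.magnitude * cols), order=order,
                             mode="constant", cval=0.0)
    # shear about the image centre: col' = col + tan(angle) * (row - cy)
    t = np.tan(np.deg2rad(spec.magnitude))
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    matrix = np.array([[1.0, 0.0], [t, 1.0]])
    # affine_transform maps output -> input: in = M @ out + offset
    offset = np.array([cy, cx]) - matrix @ np.array([cy, cx])
    return ndimage.affine_transform(arr, matrix, offset=offset, order=order,
                                    mode="constant", cval=0.0)


def apply_paired(sample: SamplePair, spec: AugmentationSpec) -> SamplePair:
    """Apply one transform identically to image and mask."""
    if sample.image.shape != sample.mask.shape:
        raise ValueError("image and mask must share shape")
    img = _transform_channel(np.asarray(sample.image, dtype=np.float32),
                             spec, order=1)
    msk = _transform_channel(np.asarray(sample.mask, dtype=np.float32),
                             spec, order=0)
    msk = (msk > 0.5).astype(np.uint8)
    return SamplePair(image=np.clip(img, 0.0, 1.0), mask=msk, provenance=spec)


def random_specs(rng: np.random.Generator,
                 shift_limit: float = 0.1,
                 shear_limit: float = 10.0):
    """One seeded random spec per transform kind."""
    return [
        AugmentationSpec("vertical_shift",
                         rng.uniform(-shift_limit, shift_limit)),
        AugmentationSpec("horizontal_shift",
                         rng.uniform(-shift_limit, shift_limit)),
        AugmentationSpec("shear", rng.uniform(-shear_limit, shear_limit)),
        AugmentationSpec("horizontal_flip"),
    ]


def expand_training_set(samples, seed: int = 0, shift_limit: float = 0.1,
                        shear_limit: float = 10.0):
    """Originals plus one transformed copy per transform kind per original.

    Returns (expanded_samples, manifest_rows): 5*m samples for m originals,
    with manifest rows recording (original index, kind, magnitude).
    """
    samples = list(samples)
    if not samples:
        raise ValueError("cannot expand an empty training set")
    rng = np.random.default_rng(seed)
    out = list(samples)
    manifest = [{"original": i, "kind": "identity", "magnitude": 0.0}
                for i in range(len(samples))]
    for i, sample in enumerate(samples):
        for spec in random_specs(rng, shift_limit, shear_limit):
            out.append(apply_paired(sample, spec))
            manifest.append({"original": i, "kind": spec.kind,
                             "magnitude": spec.magnitude})
    return out, manifest


def write_expanded(samples, manifest, directory, seed: int = 0):
    """Write an expanded set as ``<stem>_augK.png`` / ``<stem>_augK_mask.png``
    (originals as ``<stem>.png``) plus a manifest CSV."""
    import pandas as pd

    from .data import save_pair

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    counters: dict[int, int] = {}
    rows = []
    for sample, row in zip(samples, manifest):
        orig = row["original"]
        if row["kind"] == "identity":
            stem = f"sample_{orig:04d}"
        else:
            counters[orig] = counters.get(orig, 0) + 1
            stem = f"sample_{orig:04d}_aug{counters[orig]}"
        save_pair(sample, directory, stem)
        rows.append({"stem": stem, **row, "seed": seed})
    pd.DataFrame(rows).to_csv(directory / "augmentation_manifest.csv",
                              index=False)
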