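"""Seeded B-mode-like phantom generator.

Each phantom is a hypoechoic (darker-than-background) lesion on a speckled
background: a piecewise-constant echogenicity map is modulated by mean-one
multi-look speckle noise, blurred, and clipped to [0, 1].  Benign-like
lesions have smooth elliptical boundaries; malignant-like ones carry
low-frequency radial perturbations that produce spiculated contours.
The binary mask marks the exact pre-noise lesion support.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = ["PhantomSpec", "SamplePair", "generate_phantom", "generate_dataset"]

#: harmonic orders used for the malignant-like radial perturbation
_RADIAL_HARMONICS = (3, 4, 5, 6, 7, 8)


@dataclass(frozen=True)
class PhantomSpec:
    side: int = 64
    lesion_kind: str = "benign_like"           # or "malignant_like"
    center: tuple = (0.5, 0.5)                 # (row, col) fractions of side
    axes: tuple = (0.2, 0.15)                  # semi-axes, fractions of side
    rotation: float = 0.0                      # degrees
    boundary_irregularity: float = 0.0         # radial-noise amplitude
    lesion_intensity: float = 0.25
    background_intensity: float = 0.55
    speckle_looks: int = 2                     # fewer looks = noisier
    blur_sigma: float = 1.0                    # pixels
    seed: int = 0

    def __post_init__(self):
        if self.lesion_kind not in ("benign_like", "malignant_like"):
            raise ValueError(f"unknown lesion_kind {self.lesion_kind!r}")
        if min(self.axes) <= 0:
            raise ValueError(f"degenerate ellipse axes {self.axes}")
        if not (0 <= self.lesion_intensity < self.background_intensity <= 1):
            raise ValueError(
                "lesion must be hypoechoic: need 0 <= lesion_intensity < "
                "background_intensity <= 1, got "
                f"{self.lesion_intensity} / {self.background_intensity}")
        if self.speckle_looks < 1:
            raise ValueError("speckle_looks must be a positive integer")
        if self.boundary_irregularity < 0:
            raise ValueError("boundary_irregularity must be >= 0")


@dataclass
class SamplePair:
    """One grayscale image in [0, 1] with its binary lesion mask."""

    image: np.ndarray
    mask: np.ndarray
    provenance: object = None

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image/mask shape mismatch: {self.image.shape} vs "
                f"{self.mask.shape}")


def _lesion_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Rotated ellipse, optionally radius-modulated by seeded harmonics."""
    n = spec.side
    rows, cols = np.mgrid[0:n, 0:n] + 0.5
    cy, cx = spec.center[0] * n, spec.center[1] * n
    dy, dx = rows - cy, cols - cx
    theta = np.deg2rad(spec.rotation)
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    a, b = spec.axes[0] * n, spec.axes[1] * n
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    if spec.lesion_kind == "malignant_like" and spec.boundary_irregularity > 0:
        phi = np.arctan2(v, u)
        mod = np.zeros_like(phi)
        for k in _RADIAL_HARMONICS:
            amp = rng.uniform(0.3, 1.0)
            phase = rng.uniform(0, 2 * np.pi)
            mod += amp * np.cos(k * phi + phase)
        mod *= spec.boundary_irregularity / len(_RADIAL_HARMONICS)
        # keep the modulated radius positive so the contour cannot fold
        boundary = np.clip(1.0 + mod, 0.3, None)
    else:
        boundary = 1.0
    return (rho <= boundary).astype(np.uint8)


def _speckle(shape, looks: int, rng: np.random.Generator) -> np.ndarray:
    """Mean-one multi-look speckle: average of `looks` squared N(0,1) draws."""
    draws = rng.standard_normal((looks,) + shape) ** 2
    return draws.mean(axis=0)


def generate_phantom(spec: PhantomSpec, speckle: bool = True) -> SamplePair:
    """Deterministic phantom for a spec; ``speckle=False`` is the noiseless
    (infinite-looks) limit, returning the blurred echogenicity map."""
    rng = np.random.default_rng(spec.seed)
    mask = _lesion_mask(spec, rng)
    echo = np.where(mask, spec.lesion_intensity,
                    spec.background_intensity).astype(np.float64)
    img = echo * _speckle(echo.shape, spec.speckle_looks, rng) if speckle else echo
    if spec.blur_sigma > 0:
        img = gaussian_filter(img, spec.blur_sigma)
    img = np.clip(img, 0.0, 1.0)
    return SamplePair(image=img.astype(np.float32), mask=mask, provenance=spec)


def _random_spec(side: int, kind: str, seed: int,
                 rng: np.random.Generator) -> PhantomSpec:
    background = rng.uniform(0.45, 0.65)
    contrast = rng.uniform(0.15, 0.3)
    return PhantomSpec(
        side=side,
        lesion_kind=kind,
        center=(rng.uniform(0.35, 0.65), rng.uniform(0.35, 0.65)),
        axes=(rng.uniform(0.12, 0.28), rng.uniform(0.10, 0.22)),
        rotation=rng.uniform(0, 180),
        boundary_irregularity=(rng.uniform(0.25, 0.5)
                               if kind == "malignant_like" else 0.0),
        lesion_intensity=background - contrast,
        background_intensity=background,
        speckle_looks=int(rng.integers(1, 5)),
        blur_sigma=rng.uniform(0.6, 1.4),
        seed=seed,
    )


def generate_dataset(n: int, side: int = 64, mix: float = 0.5,
                     seed: int = 0):
    """Generate ``n`` phantoms with randomized specs.

    ``mix`` is the benign-like fraction (the first round(n * mix) samples).
    Returns (samples, manifest) where the manifest is a DataFrame with one
    row per sample recording the full spec.
    """
    if n < 1:
        raise ValueError(f"need n >= 1 phantoms, got {n}")
    if not (0.0 <= mix <= 1.0):
        raise ValueError("mix must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_benign = int(round(n * mix))
    kinds = ["benign_like"] * n_benign + ["malignant_like"] * (n - n_benign)
    samples, rows = [], []
    for i, kind in enumerate(kinds):
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        spec = _random_spec(side, kind, sub_seed, rng)
        samples.append(generate_phantom(spec))
        row = dataclasses.asdict(spec)
        row["index"] = i
        rows.append(row)
    manifest = pd.DataFrame(rows).set_index("index")
    return samples, manifest
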