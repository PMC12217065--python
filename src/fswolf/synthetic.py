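"""Synthetic histology-texture and planted-feature fixtures.

Two cartoon texture classes emulate the benign/malignant contrast of
stained microscopy tiles: class 0 renders sparse, round, smooth blobs
(benign-like nuclei) and class 1 dense, boundary-irregular blobs with
extra high-frequency noise (malignant-like pleomorphism). A single
``separability`` dial in [0,1] interpolates the class parameter gap:
at 0 both classes share identical parameters (a pure null), at 1 the
gap is maximal. The contrast is deliberately carried by blob density /
irregularity / noise amplitude so that it shows up in wavelet-band
energies, the feature family the downstream pipeline extracts.

The tabular generator plants class-informative Gaussian features among
pure-noise and redundant (noisy-copy) columns for exercising the
correlation filter and wrapper feature selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from fswolf.preprocess import LabeledImageSet

__all__ = [
    "TextureClassParams",
    "SyntheticDatasetSpec",
    "PlantedFeatureSpec",
    "generate_class_image",
    "class_params_for_separability",
    "generate_dataset",
    "generate_feature_table",
]


@dataclass
class TextureClassParams:
    """Rendering parameters of one texture class.

    density is blobs per 10^4 px^2; irregularity in [0,1] scales the
    radial boundary perturbation; noise_amplitude is the sd of additive
    white (high-frequency) pixel noise.
    """

    density: float
    radius_range: tuple[float, float]
    irregularity: float
    noise_amplitude: float
    tint: tuple[float, float, float]
    background: float = 0.85

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError("radius range must be positive and ordered")
        if not 0 <= self.irregularity <= 1:
            raise ValueError("irregularity must lie in [0,1]")


@dataclass
class SyntheticDatasetSpec:
    """Study conditions for one synthetic image dataset."""

    n_per_class: int = 100
    side: int = 64
    separability: float = 1.0
    pixel_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.side < 32:
            raise ValueError("side must be >= 32")
        if not 0 <= self.separability <= 1:
            raise ValueError("separability must lie in [0,1]")


@dataclass
class PlantedFeatureSpec:
    """Tabular fixture: informative, noise and redundant-copy features."""

    n: int = 500
    d: int = 50
    informative: tuple[int, ...] = (0, 1, 2, 3, 4)
    redundant: dict[int, tuple[int, float]] = field(default_factory=dict)
    effect_size: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(j < 0 or j >= self.d for j in self.informative):
            raise ValueError("informative indices must lie in [0, d)")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")


def _blob_mask(
    side: int,
    center: np.ndarray,
    radius: float,
    aspect: float,
    angle: float,
    irregularity: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean mask of one elliptical blob with a perturbed boundary.

    The boundary radius is modulated by a few random cosine harmonics
    whose amplitude is proportional to ``irregularity``.
    """
    pad = int(np.ceil(radius * 2.5)) + 2
    y0 = int(np.clip(center[0] - pad, 0, side))
    y1 = int(np.clip(center[0] + pad, 0, side))
    x0 = int(np.clip(center[1] - pad, 0, side))
    x1 = int(np.clip(center[1] + pad, 0, side))
    # draw harmonic coefficients unconditionally to keep the rng stream
    # identical across irregularity settings
    amps = rng.uniform(-1.0, 1.0, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    if y0 >= y1 or x0 >= x1:
        return np.zeros((0, 0), dtype=bool), (y0, y1, x0, x1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = yy - center[0]
    dx = xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = (-sa * dx + ca * dy) / aspect
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    boundary = radius * (
        1.0
        + 0.4
        * irregularity
        * sum(a * np.cos((k + 2) * theta + p) for k, (a, p) in enumerate(zip(amps, phases)))
    )
    return rho <= np.maximum(boundary, 0.2), (y0, y1, x0, x1)


def generate_class_image(
    params: TextureClassParams, side: int, rng: np.random.Generator
) -> np.ndarray:
    """Render one RGB texture image in [0,1] for the given class parameters."""
    img = np.empty((side, side, 3), dtype=np.float64)
    for c in range(3):
        img[..., c] = params.background * params.tint[c]
    n_blobs = rng.poisson(params.density * side * side / 1e4)
    for _ in range(n_blobs):
        center = rng.uniform(0, side, size=2)
        radius = rng.uniform(*params.radius_range)
        aspect = rng.uniform(0.55, 1.0)
        angle = rng.uniform(0, np.pi)
        depth = rng.uniform(0.35, 0.6)  # how much darker than background
        mask, (y0, y1, x0, x1) = _blob_mask(
            side, center, radius, aspect, angle, params.irregularity, rng
        )
        if mask.size == 0:
            continue
        region = img[y0:y1, x0:x1, :]
        shade = np.array([0.45, 0.30, 0.62])  # hematoxylin-like nucleus tone
        region[mask] = region[mask] * (1 - depth) + depth * shade
    if params.noise_amplitude > 0:
        img += params.noise_amplitude * rng.standard_normal(img.shape)
    return np.clip(img, 0.0, 1.0)


# midpoint and half-gap of each class parameter; separability s maps class 0
# to mid - s*delta and class 1 to mid + s*delta
_PARAM_MID_DELTA = {
    "density": (11.0, 7.0),
    "radius_lo": (3.2, -0.9),
    "radius_hi": (5.5, -1.2),
    "irregularity": (0.45, 0.45),
    "noise_amplitude": (0.045, 0.035),
    "tint_r": (0.93, 0.015),
    "tint_g": (0.82, -0.04),
    "tint_b": (0.90, 0.01),
}


def class_params_for_separability(separability: float) -> tuple[TextureClassParams, TextureClassParams]:
    """Class parameter pair whose gap scales linearly with ``separability``."""

    def params(sign: float) -> TextureClassParams:
        g = {k: mid + sign * separability * delta for k, (mid, delta) in _PARAM_MID_DELTA.items()}
        return TextureClassParams(
            density=g["density"],
            radius_range=(g["radius_lo"], g["radius_hi"]),
            irregularity=float(np.clip(g["irregularity"], 0.0, 1.0)),
            noise_amplitude=max(g["noise_amplitude"], 0.0),
            tint=(g["tint_r"], g["tint_g"], g["tint_b"]),
        )

    return params(-1.0), params(+1.0)


def generate_dataset(
    spec: SyntheticDatasetSpec, out_dir: str | Path | None = None
) -> LabeledImageSet:
    """Generate a balanced two-class image set; optionally write PNGs + manifest."""
    rng = np.random.default_rng(spec.seed)
    benign, malignant = class_params_for_separability(spec.separability)
    ids, images, labels = [], [], []
    for label, params in ((0, benign), (1, malignant)):
        for i in range(spec.n_per_class):
            img = generate_class_image(params, spec.side, rng)
            if spec.pixel_noise_sd > 0:
                img = np.clip(
                    img + spec.pixel_noise_sd * rng.standard_normal(img.shape), 0, 1
                )
            ids.append(f"class{label}_{i:04d}.png")
            images.append(img)
            labels.append(label)
    dataset = LabeledImageSet(ids=ids, images=images, labels=np.asarray(labels))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sid, img in zip(dataset.ids, dataset.images):
            Image.fromarray((img * 255).round().astype(np.uint8)).save(out_dir / sid)
        pd.DataFrame({"path": dataset.ids, "label": dataset.labels}).to_csv(
            out_dir / "manifest.csv", index=False
        )
    return dataset


def generate_feature_table(
    spec: PlantedFeatureSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planted-feature matrix, balanced labels, and the truth mask.

    Informative columns are class-shifted Gaussians (shift = effect
    size), redundant columns are a noisy copy of their source column,
    everything else is standard Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = spec.n // 2
    labels = np.array([0] * (spec.n - n_pos) + [1] * n_pos)
    X = rng.standard_normal((spec.n, spec.d)) * spec.noise_sd
    for j in spec.informative:
        X[:, j] += spec.effect_size * labels
    for j, (src, sd) in spec.redundant.items():
        X[:, j] = X[:, src] + sd * rng.standard_normal(spec.n)
    truth = np.zeros(spec.d, dtype=bool)
    truth[list(spec.informative)] = True
    return X, labels, truth
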