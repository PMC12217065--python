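"""Image loading, standardization and statistical-correlation preprocessing.

Images flow through three steps before feature extraction: resize to a
fixed square side (default 224), optional Reinhard color transfer in
LAB space to damp stain variability, and per-image z-scoring so every
input follows a zero-mean unit-variance distribution.

The correlation machinery (Pearson r, coefficient of determination,
sample covariance with its Cauchy-Schwarz bound) supports the
redundancy filter applied to the wavelet feature table: a feature
column is dropped when it is almost collinear with one already kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage import color as skcolor
from skimage.transform import resize

__all__ = [
    "LabeledImageSet",
    "ReferenceColorStats",
    "CorrelationReport",
    "load_labeled_images",
    "reference_stats_from_images",
    "reinhard_normalize",
    "standardize_image",
    "zscore_image",
    "correlation_coefficient",
    "coefficient_of_determination",
    "correlation_redundancy_filter",
]

#: label strings accepted in manifests, mapped to {0 = benign, 1 = malignant}
LABEL_ALIASES = {
    "0": 0,
    "benign": 0,
    "1": 1,
    "malignant": 1,
}


@dataclass
class LabeledImageSet:
    """Collection of RGB images in [0,1] with binary labels and stable ids."""

    ids: list[str]
    images: list[np.ndarray]
    labels: np.ndarray  # int array, values in {0, 1}

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.images) or len(self.ids) != len(self.labels):
            raise ValueError("ids, images and labels must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sample ids must be unique")
        self.labels = np.asarray(self.labels, dtype=int)

    def __len__(self) -> int:
        return len(self.ids)

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def subset(self, indices) -> "LabeledImageSet":
        indices = list(indices)
        return LabeledImageSet(
            ids=[self.ids[i] for i in indices],
            images=[self.images[i] for i in indices],
            labels=self.labels[indices],
        )


@dataclass
class ReferenceColorStats:
    """Per-channel LAB mean and standard deviation for Reinhard transfer."""

    mean: np.ndarray  # shape (3,)
    std: np.ndarray  # shape (3,), strictly positive

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if self.mean.shape != (3,) or self.std.shape != (3,):
            raise ValueError("reference stats must hold 3 means and 3 stds")
        if np.any(self.std <= 0):
            raise ValueError("reference standard deviations must be strictly positive")


@dataclass
class CorrelationReport:
    """Pearson correlation and regression sums-of-squares for one pair."""

    r: float | None
    r_squared: float
    ss_reg: float
    s_yy: float
    sse: float
    cov: float | None = None
    s_x: float | None = None
    s_y: float | None = None
    flags: list[str] = field(default_factory=list)


def load_labeled_images(manifest: str | Path) -> LabeledImageSet:
    """Load an image set from a CSV manifest with columns ``path,label``.

    Paths are resolved relative to the manifest's directory; pixel values
    are scaled to [0,1]; sample ids are the relative paths.
    """
    manifest = Path(manifest)
    table = pd.read_csv(manifest, dtype=str)
    if not {"path", "label"}.issubset(table.columns):
        raise ValueError("manifest must have 'path' and 'label' columns")
    if len(table) == 0:
        raise ValueError("no samples: manifest is empty")
    root = manifest.parent
    ids, images, labels = [], [], []
    for _, row in table.iterrows():
        rel = str(row["path"])
        raw = str(row["label"]).strip().lower()
        if raw not in LABEL_ALIASES:
            raise ValueError(
                f"unknown label {row['label']!r}; allowed: {sorted(LABEL_ALIASES)}"
            )
        path = root / rel
        if not path.exists():
            raise FileNotFoundError(f"manifest references missing file: {path}")
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
        ids.append(rel)
        images.append(arr)
        labels.append(LABEL_ALIASES[raw])
    return LabeledImageSet(ids=ids, images=images, labels=np.asarray(labels))


def _as_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3 or image.size == 0:
        raise ValueError("expected a nonempty HxWx3 RGB array")
    return image


def reference_stats_from_images(images: list[np.ndarray]) -> ReferenceColorStats:
    """Pool pixels of ``images`` and return their LAB channel mean/std."""
    labs = [skcolor.rgb2lab(_as_rgb(im)).reshape(-1, 3) for im in images]
    pooled = np.concatenate(labs, axis=0)
    std = pooled.std(axis=0)
    std = np.where(std <= 0, 1.0, std)
    return ReferenceColorStats(mean=pooled.mean(axis=0), std=std)


def reinhard_normalize(image: np.ndarray, ref: ReferenceColorStats) -> np.ndarray:
    """Reinhard color transfer: match LAB channel mean/std to ``ref``.

    A source channel with zero spread carries no color information to
    rescale; it is passed through unchanged with a warning.
    """
    image = _as_rgb(image)
    lab = skcolor.rgb2lab(image)
    out = np.empty_like(lab)
    for c in range(3):
        chan = lab[..., c]
        s = chan.std()
        if s <= 1e-12:
            warnings.warn(
                f"constant LAB channel {c}: passed through unscaled",
                RuntimeWarning,
                stacklevel=2,
            )
            out[..., c] = chan
        else:
            out[..., c] = (chan - chan.mean()) / s * ref.std[c] + ref.mean[c]
    rgb = skcolor.lab2rgb(out)
    return np.clip(rgb, 0.0, 1.0)


def zscore_image(image: np.ndarray) -> np.ndarray:
    """Z-score jointly over all pixels and channels of one image."""
    image = np.asarray(image, dtype=np.float64)
    sd = image.std()
    if sd <= 1e-12:
        raise ValueError("degenerate image: zero variance, z-score undefined")
    return (image - image.mean()) / sd


def standardize_image(
    image: np.ndarray,
    ref: ReferenceColorStats | None = None,
    side: int = 224,
) -> np.ndarray:
    """Resize to ``side`` x ``side``, optionally Reinhard-normalize, z-score.

    The output has per-image mean 0 and variance 1 (joint over pixels and
    channels). Constant images raise, since the z-score is undefined.
    """
    image = _as_rgb(image)
    if image.shape[0] != side or image.shape[1] != side:
        image = resize(
            image, (side, side, 3), order=1, anti_aliasing=True, preserve_range=True
        )
    if ref is not None:
        image = reinhard_normalize(image, ref)
    return zscore_image(image)


def _centered(v) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 observations")
    return v - v.mean()


def correlation_coefficient(x, y) -> CorrelationReport:
    """Pearson correlation r = S_XY / sqrt(S_XX * S_YY) with covariance.

    The report also carries the regression decomposition of y on x:
    s_yy = ss_reg + sse with ss_reg = r^2 * s_yy.
    """
    xd, yd = _centered(x), _centered(y)
    if xd.size != yd.size:
        raise ValueError("x and y must have equal length")
    n = xd.size
    s_xx = float(xd @ xd)
    s_yy = float(yd @ yd)
    s_xy = float(xd @ yd)
    if s_xx <= 0 or s_yy <= 0:
        raise ValueError("undefined correlation: zero-variance input")
    r = s_xy / np.sqrt(s_xx * s_yy)
    r = float(np.clip(r, -1.0, 1.0))
    cov = s_xy / (n - 1)
    ss_reg = r * r * s_yy
    return CorrelationReport(
        r=r,
        r_squared=r * r,
        ss_reg=ss_reg,
        s_yy=s_yy,
        sse=s_yy - ss_reg,
        cov=cov,
        s_x=float(np.sqrt(s_xx / (n - 1))),
        s_y=float(np.sqrt(s_yy / (n - 1))),
    )


def coefficient_of_determination(y, y_hat) -> CorrelationReport:
    """R^2 = 1 - SSE/S_YY of predictions ``y_hat`` against observations ``y``.

    The correlation field r is the Pearson correlation between y and
    y_hat when the predictions are nonconstant, else None (flagged).
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    y_hat = np.asarray(y_hat, dtype=np.float64).ravel()
    if y.size != y_hat.size:
        raise ValueError("y and y_hat must have equal length")
    yd = _centered(y)
    s_yy = float(yd @ yd)
    if s_yy <= 0:
        raise ValueError("undefined R^2: constant y")
    resid = y - y_hat
    sse = float(resid @ resid)
    r_squared = 1.0 - sse / s_yy
    flags: list[str] = []
    r: float | None = None
    hd = y_hat - y_hat.mean()
    s_hh = float(hd @ hd)
    if y_hat.std() > 1e-12 * max(1.0, float(np.abs(y_hat).max())):
        r = float(np.clip((yd @ hd) / np.sqrt(s_yy * s_hh), -1.0, 1.0))
    else:
        flags.append("constant_predictions")
    return CorrelationReport(
        r=r,
        r_squared=r_squared,
        ss_reg=s_yy - sse,
        s_yy=s_yy,
        sse=sse,
        flags=flags,
    )


def correlation_redundancy_filter(
    features: np.ndarray, threshold: float = 0.95
) -> list[int]:
    """Greedy redundancy filter on feature columns.

    Scanning columns left to right, a column is dropped iff its absolute
    Pearson correlation with an already-kept column exceeds ``threshold``
    (first-seen column wins). Constant columns have undefined correlation;
    they are kept and a warning is emitted. At least one column is kept.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("features must be a samples x d matrix with d >= 1")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    stds = X.std(axis=0)
    kept: list[int] = []
    for j in range(X.shape[1]):
        if stds[j] <= 1e-12:
            warnings.warn(
                f"constant feature column {j}: correlation undefined, kept",
                RuntimeWarning,
                stacklevel=2,
            )
            kept.append(j)
            continue
        redundant = False
        for k in kept:
            if stds[k] <= 1e-12:
                continue
            r = abs(correlation_coefficient(X[:, j], X[:, k]).r)
            if r > threshold:
                redundant = True
                break
        if not redundant:
            kept.append(j)
    return kept
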