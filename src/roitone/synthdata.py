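"""Synthetic B-mode-style speckle ROI generator.

Produces labelled 32x32 grey-level patches emulating the statistical
structure of liver ultrasound regions of interest in a two-class
normal-vs-cirrhosis problem: cirrhotic parenchyma appears slightly lighter
than normal parenchyma, and both carry multiplicative speckle texture.

The speckle field is Rayleigh-derived: with ``R`` a standard Rayleigh
variate, the multiplicative field is ``S = 1 + s * (R - mu_R) / sd_R`` so
that ``S`` has unit mean and standard deviation ``s`` (``speckle_scale``)
while keeping the right-skewed Rayleigh shape characteristic of envelope-
detected ultrasound.  The field is then smoothed with a Gaussian kernel of
width ``correlation_sigma`` pixels to give speckle grains a finite spatial
extent.  On top of the pixel-scale texture, each ROI carries a single
multiplicative gain factor ``G = 1 + gain_scale * (R' - mu_R) / sd_R`` —
the zero-frequency component of the speckle, emulating patient-to-patient
and depth/gain brightness variability.  Without it, per-image mean
brightness concentrates so sharply (averaging ~1000 pixels) that any mean
separation between classes becomes trivially learnable.  A pixel is
``clip(round(class_mean * G * S), 0, fmax)``.

This is a texture fixture, not an ultrasound physics simulation: there is no
point-spread function, attenuation or scan conversion, and by default the
two classes differ in mean brightness only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .tonecurves import GreyImage

__all__ = ["SyntheticConfig", "LabeledDataset", "generate_roi", "generate_dataset"]

LABEL_NAMES = ("normal", "cirrhosis")

# moments of the standard Rayleigh distribution (scale 1)
_RAYLEIGH_MEAN = np.sqrt(np.pi / 2.0)
_RAYLEIGH_SD = np.sqrt(2.0 - np.pi / 2.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters for one synthetic ROI dataset.

    Defaults mirror the emulated study population: 200 normal and 300
    cirrhosis 32x32 8-bit patches, with cirrhosis a little lighter
    (mean 110 vs 90 grey levels) under speckle with coefficient of
    variation 0.3, ~1-pixel spatial correlation and per-image gain
    dispersion 0.15.  The gain dispersion is what keeps the two classes
    overlapping at the whole-image level, so the default classification
    task is hard but learnable rather than trivial.
    """

    n_normal: int = 200
    n_cirrhosis: int = 300
    size: int = 32
    fmax: int = 255
    mu_normal: float = 90.0
    mu_cirrhosis: float = 110.0
    speckle_scale: float = 0.3
    gain_scale: float = 0.15
    correlation_sigma: float = 1.0
    #: optional texture knob: a different smoothing length for the cirrhosis
    #: class; ``None`` (default) shares ``correlation_sigma`` between classes.
    correlation_sigma_cirrhosis: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normal < 1 or self.n_cirrhosis < 1:
            raise ValueError("class counts must be >= 1")
        if self.size < 1:
            raise ValueError("size must be >= 1")
        for mu in (self.mu_normal, self.mu_cirrhosis):
            if not 0 < mu <= self.fmax:
                raise ValueError(f"class mean {mu} outside (0, fmax={self.fmax}]")
        if not self.speckle_scale > 0:
            raise ValueError("speckle_scale must be > 0")
        if self.gain_scale < 0:
            raise ValueError("gain_scale must be >= 0")
        if self.correlation_sigma < 0:
            raise ValueError("correlation_sigma must be >= 0")

    def sigma_for(self, label: int) -> float:
        if label == 1 and self.correlation_sigma_cirrhosis is not None:
            return self.correlation_sigma_cirrhosis
        return self.correlation_sigma


@dataclass(frozen=True)
class LabeledDataset:
    """A stack of equally-sized ROI images with binary labels and stable ids.

    ``images`` has shape ``(n, size, size)``; ``labels`` holds 0 for normal
    and 1 for cirrhosis; ``ids`` are unique per-image identifiers.
    """

    images: np.ndarray
    labels: np.ndarray
    ids: tuple[str, ...]
    fmax: int = 255

    def __post_init__(self) -> None:
        images = np.asarray(self.images)
        labels = np.asarray(self.labels, dtype=np.int8)
        ids = tuple(str(i) for i in self.ids)
        if images.ndim != 3 or images.shape[1] != images.shape[2]:
            raise ValueError(f"images must be (n, size, size), got {images.shape}")
        if not (len(images) == len(labels) == len(ids)):
            raise ValueError("images, labels and ids must have equal length")
        if len(set(ids)) != len(ids):
            raise ValueError("ids must be unique")
        if not np.issubdtype(images.dtype, np.integer):
            raise ValueError(f"images must be integer-valued, got {images.dtype}")
        if images.size and (images.min() < 0 or images.max() > self.fmax):
            raise ValueError("pixel values outside [0, fmax]")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be 0 (normal) or 1 (cirrhosis)")
        object.__setattr__(self, "images", images)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "ids", ids)

    def __len__(self) -> int:
        return len(self.images)

    @property
    def size(self) -> int:
        return self.images.shape[1]

    @property
    def class_counts(self) -> tuple[int, int]:
        return int((self.labels == 0).sum()), int((self.labels == 1).sum())

    def image(self, i: int) -> GreyImage:
        return GreyImage(self.images[i], self.fmax)

    def subset(self, indices: np.ndarray) -> "LabeledDataset":
        indices = np.asarray(indices)
        return LabeledDataset(
            self.images[indices],
            self.labels[indices],
            tuple(self.ids[i] for i in indices),
            self.fmax,
        )

    def with_images(self, images: np.ndarray) -> "LabeledDataset":
        """Same labels/ids with transformed pixel data (e.g. a corrected stack)."""
        return LabeledDataset(images, self.labels, self.ids, self.fmax)


def _speckle_field(size: int, scale: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    r = rng.rayleigh(1.0, size=(size, size))
    s = 1.0 + scale * (r - _RAYLEIGH_MEAN) / _RAYLEIGH_SD
    if sigma > 0:
        s = gaussian_filter(s, sigma, mode="reflect")
    return np.clip(s, 0.0, None)


def generate_roi(
    class_mean: float, config: SyntheticConfig, rng: np.random.Generator
) -> GreyImage:
    """Draw one speckled ROI patch around ``class_mean``.

    Deterministic given the generator state: the same ``rng`` state always
    yields the same pixel grid.
    """
    sigma = config.correlation_sigma
    # per-image gain first, then the pixel field, so the draw order is stable
    gain = 1.0 + config.gain_scale * (rng.rayleigh(1.0) - _RAYLEIGH_MEAN) / _RAYLEIGH_SD
    gain = max(gain, 0.0)
    s = _speckle_field(config.size, config.speckle_scale, sigma, rng)
    pixels = np.clip(np.floor(class_mean * gain * s + 0.5), 0, config.fmax)
    return GreyImage(pixels.astype(np.int64), config.fmax)


def generate_dataset(config: SyntheticConfig) -> LabeledDataset:
    """Generate the full labelled dataset described by ``config``.

    Normal images are drawn first, then cirrhosis, from a single seeded
    generator, so identical configs yield byte-identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    images = np.empty((config.n_normal + config.n_cirrhosis, config.size, config.size), np.int64)
    labels = np.empty(len(images), np.int8)
    ids = []
    row = 0
    for label, (name, mu, n) in enumerate(
        [
            ("normal", config.mu_normal, config.n_normal),
            ("cirrhosis", config.mu_cirrhosis, config.n_cirrhosis),
        ]
    ):
        sigma = config.sigma_for(label)
        sub = replace(config, correlation_sigma=sigma, correlation_sigma_cirrhosis=None)
        for i in range(n):
            images[row] = generate_roi(mu, sub, rng).pixels
            labels[row] = label
            ids.append(f"{name}_{i:04d}")
            row += 1
    return LabeledDataset(images, labels, tuple(ids), config.fmax)
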