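"""Synthetic spectra and leaf images with the statistical structure the
pipeline assumes.

No public lettuce/imidacloprid dataset exists, so every downstream stage
is exercised on simulated data:

* reflectance spectra built from a fixed green-leaf baseline (chlorophyll
  trough in the visible, red-edge rise near 700-750 nm, NIR plateau with
  a mild 970 nm water dip), depleted by a residue-dependent Gaussian
  absorption planted at a configurable band (default 709 nm), then hit
  with multiplicative scatter (1+a, +b) and additive channel noise;
* leaf photographs rendered as a bright disk on a dark background whose
  per-channel mean rises linearly with concentration, mimicking images
  taken under a single characteristic-band light source.

Concentrations are in mg/kg throughout.  Fixed seeds give bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from PIL import Image

from .spectra import SpectraMatrix

__all__ = [
    "SpectraSimConfig",
    "ImageSimConfig",
    "LabeledSpectraSet",
    "leaf_baseline",
    "generate_spectra",
    "generate_leaf_image",
    "generate_dataset",
    "save_images",
    "save_labels",
]

#: residue levels emulating the four spray groups (water control and
#: dilutions 1:1500, 1:800, 1:500), all under the 3 mg/kg maximum
#: residue limit for lettuce.
DEFAULT_GROUP_CONCENTRATIONS: tuple[float, ...] = (0.0, 0.8, 1.5, 2.5)


@dataclass
class SpectraSimConfig:
    """Parameters of the planted-band spectra generator.

    ``effect_size`` is the depth of the absorption feature in reflectance
    units per mg/kg at the band centre; ``effect_size=0`` gives a null
    model with no residue signal.
    """

    n_samples: int = 200
    wavelength_start: float = 320.0
    wavelength_stop: float = 1100.0
    wavelength_step: float = 1.0
    planted_band: float = 709.0
    band_width_sigma: float = 15.0
    effect_size: float = 0.04
    scatter_slope_sd: float = 0.05
    scatter_offset_sd: float = 0.01
    noise_sd: float = 0.005
    concentration_range: tuple[float, float] = (0.0, 2.5)
    seed: int = 0

    @property
    def wavelength_grid(self) -> np.ndarray:
        return np.arange(self.wavelength_start,
                         self.wavelength_stop + 0.5 * self.wavelength_step,
                         self.wavelength_step)

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        grid = self.wavelength_grid
        if not np.any(np.isclose(grid, self.planted_band)):
            raise ValueError(
                f"planted_band {self.planted_band} nm is off the wavelength grid")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.concentration_range
        if lo < 0 or hi < lo:
            raise ValueError("concentration_range must satisfy 0 <= lo <= hi")


@dataclass
class ImageSimConfig:
    """Parameters of the leaf-image generator (8-bit RGB, dark background)."""

    width: int = 64
    height: int = 64
    # half-integer radius: the rasterized disk is then invariant under a
    # 3x3 closing+opening, so clean images segment back to it exactly
    blob_radius: float = 20.5
    base_channel_levels: tuple[float, float, float] = (90.0, 140.0, 70.0)
    channel_slopes: tuple[float, float, float] = (28.0, 16.0, 9.0)
    pixel_noise_sd: float = 4.0
    background_level: int = 12
    seed: int = 0

    def validate(self) -> None:
        if self.width < 4 or self.height < 4:
            raise ValueError("frame too small")
        if 2 * self.blob_radius + 2 > min(self.width, self.height):
            raise ValueError(
                f"blob radius {self.blob_radius} does not fit a "
                f"{self.width}x{self.height} frame")
        if not 0 <= self.background_level <= 255:
            raise ValueError("background_level must be an 8-bit value")


@dataclass
class LabeledSpectraSet:
    """Spectra plus their residue labels and the generating config."""

    spectra: SpectraMatrix
    concentrations: np.ndarray
    config: SpectraSimConfig = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.spectra.n_samples != self.concentrations.size:
            raise ValueError("one concentration per spectrum required")


def leaf_baseline(wavelengths: np.ndarray) -> np.ndarray:
    """Fixed deterministic green-leaf reflectance curve.

    Low blue/red reflectance, a green bump near 550 nm, the red-edge
    sigmoid rise near 700-750 nm onto an NIR plateau, and a shallow
    970 nm water dip.  Values lie well inside (0, 1) so that noise and
    scatter rarely clip.
    """
    w = np.asarray(wavelengths, dtype=float)
    green_bump = 0.06 * np.exp(-0.5 * ((w - 550.0) / 35.0) ** 2)
    red_edge = 0.42 / (1.0 + np.exp(-(w - 715.0) / 16.0))
    water_dip = -0.05 * np.exp(-0.5 * ((w - 970.0) / 28.0) ** 2)
    return 0.05 + green_bump + red_edge + water_dip


def generate_spectra(config: SpectraSimConfig,
                     concentrations: np.ndarray | None = None) -> LabeledSpectraSet:
    """Simulate a labeled spectra set under `config`.

    Each spectrum is ``(baseline - c * effect_size * G(planted_band,
    sigma)) * (1 + a) + b + noise`` with ``a ~ N(0, scatter_slope_sd)``,
    ``b ~ N(0, scatter_offset_sd)`` and iid channel noise, clipped to
    the physical range [0, 1].  If `concentrations` is given it overrides
    the uniform draw from ``config.concentration_range``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid = config.wavelength_grid
    n = config.n_samples

    if concentrations is None:
        lo, hi = config.concentration_range
        conc = rng.uniform(lo, hi, size=n)
    else:
        conc = np.asarray(concentrations, dtype=float)
        if conc.size != n:
            raise ValueError("concentrations length must equal n_samples")

    base = leaf_baseline(grid)
    band = np.exp(-0.5 * ((grid - config.planted_band) / config.band_width_sigma) ** 2)
    clean = base[None, :] - conc[:, None] * config.effect_size * band[None, :]

    slope = rng.normal(0.0, config.scatter_slope_sd, size=(n, 1))
    offset = rng.normal(0.0, config.scatter_offset_sd, size=(n, 1))
    noisy = clean * (1.0 + slope) + offset
    if config.noise_sd > 0:
        noisy = noisy + rng.normal(0.0, config.noise_sd, size=noisy.shape)
    np.clip(noisy, 0.0, 1.0, out=noisy)

    return LabeledSpectraSet(SpectraMatrix(grid, noisy), conc, config)


def _disk_mask(config: ImageSimConfig) -> np.ndarray:
    cy, cx = (config.height - 1) / 2.0, (config.width - 1) / 2.0
    yy, xx = np.mgrid[0:config.height, 0:config.width]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= config.blob_radius ** 2


def generate_leaf_image(concentration: float, config: ImageSimConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Render one leaf image; returns ``(image uint8 HxWx3, mask bool HxW)``.

    Foreground per-channel level is ``clip(base + slope * concentration)``
    plus optional pixel noise; the background is uniform and dark.  The
    returned mask is the rasterized ground-truth foreground.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    mask = _disk_mask(config)
    img = np.full((config.height, config.width, 3),
                  float(config.background_level))
    levels = np.clip(np.asarray(config.base_channel_levels)
                     + np.asarray(config.channel_slopes) * concentration,
                     0.0, 255.0)
    img[mask] = levels
    if config.pixel_noise_sd > 0:
        img[mask] += rng.normal(0.0, config.pixel_noise_sd,
                                size=(int(mask.sum()), 3))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), mask


def generate_dataset(spectra_config: SpectraSimConfig,
                     image_config: ImageSimConfig,
                     n: int,
                     groups: tuple[float, ...] | None = DEFAULT_GROUP_CONCENTRATIONS,
                     jitter_sd: float = 0.1,
                     ) -> tuple[LabeledSpectraSet, list[np.ndarray], list[np.ndarray],
                                np.ndarray]:
    """Joint spectra + image dataset sharing one label vector.

    Labels come from the four discrete spray groups (with small
    leaf-to-leaf jitter, truncated at zero) when `groups` is given, or
    uniformly from ``spectra_config.concentration_range`` when it is
    None.  Returns ``(spectra_set, images, masks, concentrations)``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(spectra_config.seed)
    if groups is not None:
        reps = -(-n // len(groups))  # ceil division; equal groups when divisible
        conc = np.repeat(np.asarray(groups, dtype=float), reps)[:n]
        if jitter_sd > 0:
            conc = np.maximum(conc + rng.normal(0.0, jitter_sd, size=n), 0.0)
    else:
        lo, hi = spectra_config.concentration_range
        conc = rng.uniform(lo, hi, size=n)

    sc = SpectraSimConfig(**{**asdict(spectra_config), "n_samples": n})
    spectra_set = generate_spectra(sc, concentrations=conc)

    img_rng = np.random.default_rng(image_config.seed)
    images, masks = [], []
    for c in conc:
        img, mask = generate_leaf_image(float(c), image_config, rng=img_rng)
        images.append(img)
        masks.append(mask)
    return spectra_set, images, masks, conc


def save_images(images, out_dir, prefix: str = "leaf") -> list[str]:
    """Write images as PNG; returns the file names in order."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = []
    for i, img in enumerate(images):
        name = f"{prefix}_{i:04d}.png"
        Image.fromarray(img).save(out / name)
        names.append(name)
    return names


def save_labels(names, concentrations, path) -> None:
    import pandas as pd

    pd.DataFrame({"sample_id": names,
                  "concentration": np.asarray(concentrations, dtype=float)}
                 ).to_csv(path, index=False)
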