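"""Synthetic three-class soybean reflectance spectra with known ground truth.

The generator emulates the statistical structure of visible/NIR reflectance
of mechanically harvested soybean components (intact grain, broken grain,
impurity): a shared smooth continuum, class-specific Gaussian absorption
features at known centers, per-sample affine scatter (multiplicative
log-normal factor and additive offset), a per-sample linear slope drift, and
band-wise Gaussian noise inflated at the low-SNR spectral edges.

Each sample is

    x(lam) = profile(lam) * m + b + slope * (lam - lam_mid) + eps(lam)

with m ~ LogNormal(0, sigma_m), b ~ N(0, sigma_a), slope ~ N(0, sigma_slope)
and eps ~ N(0, sigma_eps) band-wise (x ``edge_noise_factor`` outside the
stable range). The affine scatter is exactly the model SNV and MSC remove,
which makes preprocessing effectiveness testable as an identity rather than
an empirical hope. The discriminative feature centers are recorded in the
config so selection-recovery tests have ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import (CLASS_BROKEN, CLASS_IMPURITY, CLASS_INTACT,
                         SpectraTable, WavelengthGrid, default_grid)

#: Sample counts matching the extracted-spectra inventory of the study design.
DEFAULT_CLASS_COUNTS = {CLASS_INTACT: 513, CLASS_BROKEN: 256, CLASS_IMPURITY: 423}


@dataclass(frozen=True)
class GaussianFeature:
    """A Gaussian reflectance feature: signed amplitude at center_nm, width in nm."""

    center_nm: float
    width_nm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("feature width must be > 0")


@dataclass(frozen=True)
class ClassProfile:
    """Continuum polynomial (coefficients in t = (lam - lam_mid)/300) + features."""

    continuum: tuple
    features: tuple

    def evaluate(self, wavelengths: np.ndarray) -> np.ndarray:
        t = (wavelengths - wavelengths.mean()) / 300.0
        y = np.polyval(self.continuum[::-1], t)  # coefficients low -> high order
        for f in self.features:
            y = y + f.amplitude * np.exp(-0.5 * ((wavelengths - f.center_nm) / f.width_nm) ** 2)
        return y


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generative recipe; ``validate()`` enforces physical plausibility."""

    grid: WavelengthGrid = field(default_factory=default_grid)
    class_counts: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    profiles: dict = field(default_factory=dict)
    sigma_m: float = 0.05          # log-sd of multiplicative scatter factor
    sigma_a: float = 0.02          # sd of additive offset (reflectance units)
    sigma_slope: float = 1e-4      # sd of linear drift slope (per nm)
    sigma_eps: float = 0.004       # band-wise noise sd in the stable range
    edge_noise_factor: float = 5.0
    stable_range: tuple = (410.0, 980.0)
    discriminative_centers: tuple = ()
    seed: int = 0

    def validate(self) -> None:
        if not self.class_counts or min(self.class_counts.values()) < 1:
            raise ValueError("each class needs at least 1 sample")
        if set(self.profiles) != set(self.class_counts):
            raise ValueError("profiles and class_counts must cover the same classes")
        for s in (self.sigma_m, self.sigma_a, self.sigma_slope, self.sigma_eps):
            if s < 0:
                raise ValueError("noise scales must be >= 0")
        lam = self.grid.centers
        for name, prof in self.profiles.items():
            y = prof.evaluate(lam)
            # 6-sigma excursion of the affine scatter must keep reflectance physical
            hi = y * float(np.exp(6 * self.sigma_m)) + 6 * self.sigma_a \
                + 6 * self.sigma_slope * (lam - lam.mean()).max()
            if y.min() < 0 or hi.max() > 1.5:
                raise ValueError(f"profile {name!r} leaves [0, 1.5] at 6 sigma")

    @property
    def n_samples(self) -> int:
        return int(sum(self.class_counts.values()))


def default_config(seed: int = 0) -> SyntheticConfig:
    """Default three-class recipe with discriminative features near 680/925/550 nm.

    All classes share a smooth continuum; intact and broken grain differ in
    the depth of absorption features near 680 nm (chlorophyll-adjacent
    red-edge region) and 925 nm (C-H/O-H overtone region); impurities add a
    distinct 550 nm feature and a steeper continuum slope, emulating
    non-grain plant material.
    """
    base = (0.55, 0.10, -0.06)  # gentle concave continuum in t
    profiles = {
        CLASS_INTACT: ClassProfile(base, (
            GaussianFeature(680.0, 15.0, -0.13),
            GaussianFeature(925.0, 22.0, -0.05),
        )),
        CLASS_BROKEN: ClassProfile(base, (
            GaussianFeature(680.0, 15.0, -0.04),
            GaussianFeature(925.0, 22.0, -0.15),
        )),
        CLASS_IMPURITY: ClassProfile((0.50, 0.16, -0.06), (
            GaussianFeature(550.0, 25.0, 0.10),
            GaussianFeature(680.0, 15.0, -0.08),
            GaussianFeature(925.0, 22.0, -0.10),
        )),
    }
    cfg = SyntheticConfig(profiles=profiles,
                          discriminative_centers=(680.0, 925.0, 550.0),
                          seed=seed)
    cfg.validate()
    return cfg


def ground_truth_bands(config: SyntheticConfig) -> np.ndarray:
    """Grid indices nearest to the configured discriminative feature centers."""
    lam = config.grid.centers
    return np.array(sorted({int(np.argmin(np.abs(lam - c)))
                            for c in config.discriminative_centers}))


def generate_dataset(config: SyntheticConfig) -> tuple[SpectraTable, np.ndarray]:
    """Draw a labeled spectra table; returns (table, ground-truth band indices).

    Reproducible given ``config.seed``; rows are grouped by class in the
    order of ``class_counts``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lam = config.grid.centers
    lam_c = lam - lam.mean()
    eps_sd = np.full(lam.size, config.sigma_eps)
    lo, hi = config.stable_range
    eps_sd[(lam < lo) | (lam > hi)] *= config.edge_noise_factor

    blocks, labels, ids = [], [], []
    for name, count in config.class_counts.items():
        profile = config.profiles[name].evaluate(lam)
        m = np.exp(rng.normal(0.0, config.sigma_m, size=(count, 1))) \
            if config.sigma_m > 0 else np.ones((count, 1))
        b = rng.normal(0.0, config.sigma_a, size=(count, 1)) \
            if config.sigma_a > 0 else np.zeros((count, 1))
        slope = rng.normal(0.0, config.sigma_slope, size=(count, 1)) \
            if config.sigma_slope > 0 else np.zeros((count, 1))
        eps = rng.normal(0.0, 1.0, size=(count, lam.size)) * eps_sd \
            if config.sigma_eps > 0 else 0.0
        X = profile[None, :] * m + b + slope * lam_c[None, :] + eps
        blocks.append(X)
        labels.extend([name] * count)
        ids.extend(f"{name}_{i:04d}" for i in range(count))
    table = SpectraTable(np.vstack(blocks), config.grid,
                         np.array(labels), np.array(ids))
    return table, ground_truth_bands(config)


def synthetic_cube(config: SyntheticConfig | None = None, rows: int = 32,
                   cols: int = 32, class_name: str = CLASS_INTACT,
                   seed: int = 0) -> tuple[np.ndarray, WavelengthGrid]:
    """A tiny [rows x cols x bands] reflectance cube of one class, for I/O tests.

    Every pixel is an independent draw from the class's generative model.
    """
    config = config or default_config(seed)
    pixel_cfg = replace(config,
                        class_counts={class_name: rows * cols},
                        profiles={class_name: config.profiles[class_name]},
                        discriminative_centers=(),
                        seed=seed)
    table, _ = generate_dataset(pixel_cfg)
    cube = table.reflectance.reshape(rows, cols, len(config.grid))
    return cube, config.grid
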