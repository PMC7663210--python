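"""Synthetic vis-NIR soil spectra with known spectrum-to-attribute structure.

Each clean spectrum is a non-negative mixture of Gaussian absorption bands;
the three regression targets are affine functions of the band depths, scaled
to soil-like ranges (total carbon / total nitrogen in g/kg, available
nitrogen in mg/kg). On top of the clean signal the generator applies the
corruptions the preprocessing stage is designed to remove: per-sample
multiplicative scatter and additive offset, a linear baseline drift, and
iid Gaussian noise (applied after scatter, so scatter correction cannot
remove it). The full ground truth (band depths, scatter factors, clean
spectra, the effective linear depth-to-target map) is returned so oracle
tests can verify every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError
from .io import AttributeTable, SpectrumSet, write_attributes, write_spectra

__all__ = ["SyntheticConfig", "GroundTruth", "generate", "make_fixture", "FIXTURE_PRESETS"]

# 3 attributes x 6 bands, full row rank, with cross-talk between attributes
_DEFAULT_ATTRIBUTE_MAP = (
    (1.0, 0.8, 0.2, 0.0, 0.3, 0.0),
    (0.0, 0.3, 1.0, 0.7, 0.0, 0.2),
    (0.2, 0.0, 0.0, 0.3, 1.0, 0.6),
)

# Soil-like target means/SDs: TC and TN in g/kg, AN in mg/kg
_DEFAULT_TARGET_STATS = ((6.21, 3.42), (0.80, 0.46), (69.51, 33.18))
_DEFAULT_TARGET_NAMES = ("TC", "TN", "AN")
_DEFAULT_TARGET_UNITS = {"TC": "g/kg", "TN": "g/kg", "AN": "mg/kg"}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    band depths ~ N(depth_mean, depth_sd) truncated at 0; targets are the
    attribute_map applied to the depths, then affinely rescaled per
    attribute to the requested mean/SD. ``noise_relative``, when set,
    overrides ``noise_sd`` with that fraction of the clean-signal SD.

    ``level_variation`` controls how much of the depth variation lies along
    the spectral-level direction — the depth-space direction that changes a
    spectrum's regression slope against the mean spectrum. Per-sample
    multiplicative scatter moves spectra along exactly that direction, so
    depth variation there is unrecoverable in principle once scatter is on.
    Scatter correction (and real chemometric practice) assumes scatter owns
    the overall level while chemistry owns the band structure; the default
    keeps 10% of the iid spread along the level direction, which preserves
    exact identifiability of the depth-to-target map while making the
    targets recoverable from scatter-corrected spectra.
    """

    n_samples: int = 180
    n_channels: int = 750
    wavelength_range: tuple[float, float] = (225.0, 975.0)
    n_bands: int = 6
    band_centers: tuple[float, ...] | None = None
    band_widths: tuple[float, ...] | None = None
    attribute_map: tuple[tuple[float, ...], ...] = _DEFAULT_ATTRIBUTE_MAP
    target_stats: tuple[tuple[float, float], ...] = _DEFAULT_TARGET_STATS
    target_names: tuple[str, ...] = _DEFAULT_TARGET_NAMES
    depth_mean: float = 1.0
    depth_sd: float = 0.3
    level_variation: float = 0.1
    scatter_mult_range: tuple[float, float] = (0.7, 1.3)
    scatter_add_range: tuple[float, float] = (-0.05, 0.05)
    baseline_intercept_range: tuple[float, float] = (0.0, 0.2)
    baseline_slope_range: tuple[float, float] = (-0.1, 0.1)
    noise_sd: float = 0.01
    noise_relative: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1 or self.n_channels < 2:
            raise ConfigurationError("need n_samples >= 1 and n_channels >= 2")
        lo, hi = self.wavelength_range
        if not hi > lo:
            raise ConfigurationError("wavelength_range must be increasing")
        if self.band_centers is not None:
            if len(self.band_centers) != self.n_bands:
                raise ConfigurationError("band_centers length must equal n_bands")
            if any(not lo <= c <= hi for c in self.band_centers):
                raise ConfigurationError("band centers must lie inside the wavelength range")
        m = np.asarray(self.attribute_map, dtype=float)
        if m.shape[1] != self.n_bands:
            raise ConfigurationError("attribute_map must have n_bands columns")
        if np.linalg.matrix_rank(m) < m.shape[0]:
            raise ConfigurationError("attribute_map must have full row rank")
        if len(self.target_stats) != m.shape[0] or len(self.target_names) != m.shape[0]:
            raise ConfigurationError("target_stats/target_names must match attribute_map rows")
        if self.noise_sd < 0 or (self.noise_relative is not None and self.noise_relative < 0):
            raise ConfigurationError("noise levels must be >= 0")
        if not 0 <= self.level_variation <= 1:
            raise ConfigurationError("level_variation must be in [0, 1]")

    def resolved_bands(self) -> tuple[np.ndarray, np.ndarray]:
        """Band centers and widths (nm), defaulting to an even spread over
        the inner 80% of the range with widths of 1/20 of the span."""
        lo, hi = self.wavelength_range
        span = hi - lo
        centers = (
            np.asarray(self.band_centers, dtype=float)
            if self.band_centers is not None
            else lo + span * np.linspace(0.1, 0.9, self.n_bands)
        )
        widths = (
            np.asarray(self.band_widths, dtype=float)
            if self.band_widths is not None
            else np.full(self.n_bands, span / 20.0)
        )
        return centers, widths


@dataclass
class GroundTruth:
    """Everything the generator drew, for oracle tests."""

    depths: np.ndarray          # (n, K) band depths
    clean: np.ndarray           # (n, C) noiseless, scatter-free absorbance
    mult: np.ndarray            # (n,) multiplicative scatter factors
    offset: np.ndarray          # (n,) total additive offset (scatter + baseline intercept)
    slope: np.ndarray           # (n,) baseline slope over normalized wavelength
    noise_sd: float             # the additive noise SD actually used
    effective_map: np.ndarray   # (T, K): targets = intercept + effective_map @ depths
    effective_intercept: np.ndarray = field(default_factory=lambda: np.zeros(3))


def generate(cfg: SyntheticConfig | None = None) -> tuple[SpectrumSet, AttributeTable, GroundTruth]:
    """Draw a synthetic dataset from the seeded generator.

    Per sample i: clean A_i(l) = sum_k d_ik exp(-(l-mu_k)^2 / 2 s_k^2),
    observed = m_i * A_i + offset_i + slope_i * u + noise (u = wavelength
    normalized to [0,1]); targets are affine in the band depths d_i.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.wavelength_range
    wavelengths = np.linspace(lo, hi, cfg.n_channels)
    centers, widths = cfg.resolved_bands()

    # truncated-normal band depths (resample negatives)
    depths = rng.normal(cfg.depth_mean, cfg.depth_sd, size=(cfg.n_samples, cfg.n_bands))
    while np.any(depths < 0):
        bad = depths < 0
        depths[bad] = rng.normal(cfg.depth_mean, cfg.depth_sd, size=int(bad.sum()))

    basis = np.exp(-((wavelengths[None, :] - centers[:, None]) ** 2) / (2 * widths[:, None] ** 2))

    # shrink the depth component along the spectral-level direction: the
    # depth-space vector c with c_k = <basis_k - mean, mean clean - mean>,
    # i.e. the direction that changes the OLS slope against the mean spectrum
    basis_c = basis - basis.mean(axis=1, keepdims=True)
    ref_c = cfg.depth_mean * basis_c.sum(axis=0)
    c = basis_c @ ref_c
    c_norm2 = float(c @ c)
    c_hat = None
    if c_norm2 > 0 and cfg.level_variation < 1:
        c_hat = c / np.sqrt(c_norm2)
        delta = depths - cfg.depth_mean
        proj = delta @ c_hat
        depths = cfg.depth_mean + delta - (1.0 - cfg.level_variation) * proj[:, None] * c_hat
        depths = np.maximum(depths, 0.0)

    clean = depths @ basis  # (n, C)

    mult = rng.uniform(*cfg.scatter_mult_range, size=cfg.n_samples)
    add = rng.uniform(*cfg.scatter_add_range, size=cfg.n_samples)
    intercept = rng.uniform(*cfg.baseline_intercept_range, size=cfg.n_samples)
    slope = rng.uniform(*cfg.baseline_slope_range, size=cfg.n_samples)
    u = (wavelengths - lo) / (hi - lo)

    noise_sd = cfg.noise_sd if cfg.noise_relative is None else cfg.noise_relative * float(clean.std())
    observed = (
        mult[:, None] * clean
        + (add + intercept)[:, None]
        + slope[:, None] * u[None, :]
        + rng.normal(0.0, noise_sd, size=clean.shape)
    )

    # affine rescaling of raw scores M d to the requested target mean/SD;
    # the depth covariance is sigma^2 (I - (1 - eps^2) c c^T) after the
    # level-direction shrinkage, so Var(m.d) picks up a correction term
    m = np.asarray(cfg.attribute_map, dtype=float)
    raw_mean = m.sum(axis=1) * cfg.depth_mean
    raw_var = (m**2).sum(axis=1)
    if c_hat is not None:
        raw_var = raw_var - (1.0 - cfg.level_variation**2) * (m @ c_hat) ** 2
    raw_sd = cfg.depth_sd * np.sqrt(raw_var)
    t_mean = np.asarray([s[0] for s in cfg.target_stats])
    t_sd = np.asarray([s[1] for s in cfg.target_stats])
    gain = t_sd / raw_sd
    targets = t_mean + gain * (depths @ m.T - raw_mean)
    effective_map = gain[:, None] * m
    effective_intercept = t_mean - gain * raw_mean

    ids = [f"s{i:05d}" for i in range(cfg.n_samples)]
    ss = SpectrumSet(wavelengths, observed, ids, "absorbance")
    at = AttributeTable(ids, targets, list(cfg.target_names), dict(_DEFAULT_TARGET_UNITS))
    gt = GroundTruth(depths, clean, mult, add + intercept, slope, float(noise_sd),
                     effective_map, effective_intercept)
    return ss, at, gt


FIXTURE_PRESETS = {
    "small_like": SyntheticConfig(n_samples=60, n_channels=750, wavelength_range=(225.0, 975.0), seed=62710),
    "lucas_like": SyntheticConfig(n_samples=200, n_channels=4200, wavelength_range=(400.0, 2500.0), seed=62711),
}


def make_fixture(name: str, out_dir=None) -> tuple[SpectrumSet, AttributeTable, GroundTruth]:
    """Deterministic named test fixture; optionally written as CSVs.

    ``small_like`` is 60 x 750 (local soil survey scale), ``lucas_like`` is
    200 x 4200 (continental library structure, down-sampled in n). Each is
    byte-identical across regenerations thanks to its embedded seed.
    """
    if name not in FIXTURE_PRESETS:
        raise ConfigurationError(f"unknown fixture preset {name!r}; choose from {sorted(FIXTURE_PRESETS)}")
    ss, at, gt = generate(FIXTURE_PRESETS[name])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_spectra(ss, out / f"{name}_spectra.csv")
        write_attributes(at, out / f"{name}_attributes.csv")
    return ss, at, gt
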