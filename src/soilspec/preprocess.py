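"""Chemometric preprocessing: Savitzky-Golay smoothing, multiplicative
scatter correction (MSC) and per-wavelength centering.

All three transforms, and every combination of them, run through
:class:`PreprocessPipeline` with fit-on-train / apply-anywhere semantics:
MSC's reference spectrum and the centering mean are estimated on the
training set only and frozen, so applying a fitted pipeline to validation
or test spectra never leaks their statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import ConfigurationError, CorrectionError, ValidationError
from .io import SpectrumSet

__all__ = [
    "sg_smooth",
    "msc_fit",
    "msc_apply",
    "center_fit",
    "center_apply",
    "PreprocessPipeline",
    "run_pipeline",
    "ALL_COMBINATIONS",
]

#: Canonical step order; combinations are named after it (e.g. "sg+msc+center").
STEP_ORDER = ("sg", "msc", "center")

#: The three single transforms and their four combinations.
ALL_COMBINATIONS = (
    ("sg",),
    ("msc",),
    ("center",),
    ("sg", "msc"),
    ("sg", "center"),
    ("msc", "center"),
    ("sg", "msc", "center"),
)


def sg_smooth(ss: SpectrumSet, window: int = 11, polyorder: int = 2) -> SpectrumSet:
    """Savitzky-Golay smoothing along the wavelength axis.

    Each channel is replaced by the center value of a least-squares
    polynomial fit over a sliding window; edges use mirror padding.
    Polynomials of degree <= ``polyorder`` pass through unchanged.
    """
    if window % 2 == 0 or window < 3:
        raise ConfigurationError(f"window must be odd and >= 3, got {window}")
    if window > ss.n_channels:
        raise ConfigurationError(f"window {window} exceeds channel count {ss.n_channels}")
    if polyorder >= window:
        raise ConfigurationError(f"polyorder {polyorder} must be < window {window}")
    smoothed = savgol_filter(ss.intensities, window, polyorder, axis=1, mode="mirror")
    return ss.with_intensities(smoothed)


def _mean_spectrum(ss: SpectrumSet, min_n: int) -> np.ndarray:
    if ss.n_samples < min_n:
        raise ValidationError(f"need at least {min_n} spectra, got {ss.n_samples}")
    return ss.intensities.mean(axis=0)


def msc_fit(train: SpectrumSet) -> np.ndarray:
    """MSC reference spectrum: the per-wavelength mean of the training set."""
    return _mean_spectrum(train, 2)


def msc_apply(ss: SpectrumSet, reference: np.ndarray, slope_floor: float = 1e-8) -> SpectrumSet:
    """Remove per-sample multiplicative/additive scatter.

    Each spectrum x is regressed on the reference, x ~ a + b*ref (OLS over
    wavelengths), and corrected to (x - a) / b. A spectrum that is an affine
    distortion m*x + c of another therefore maps to the same output.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (ss.n_channels,):
        raise ValidationError(f"reference length {reference.size} != channels {ss.n_channels}")
    ref_c = reference - reference.mean()
    denom = float(ref_c @ ref_c)
    if denom <= 0:
        raise CorrectionError("reference spectrum is constant; MSC slope undefined")
    x = ss.intensities
    b = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom  # per-sample OLS slope
    bad = np.abs(b) <= slope_floor
    if np.any(bad):
        sid = ss.sample_ids[int(np.argmax(bad))]
        raise CorrectionError(f"MSC slope ~ 0 for sample {sid!r}", sample_id=sid)
    a = x.mean(axis=1) - b * reference.mean()
    return ss.with_intensities((x - a[:, None]) / b[:, None])


def center_fit(train: SpectrumSet) -> np.ndarray:
    """Centering statistic: the per-wavelength mean of the training set."""
    return _mean_spectrum(train, 1)


def center_apply(ss: SpectrumSet, mean: np.ndarray) -> SpectrumSet:
    """Subtract the (train-fitted) mean spectrum from every sample.

    Not idempotent on new data: subtracting the train mean twice shifts
    spectra by it twice.
    """
    mean = np.asarray(mean, dtype=float)
    if mean.shape != (ss.n_channels,):
        raise ValidationError(f"mean length {mean.size} != channels {ss.n_channels}")
    return ss.with_intensities(ss.intensities - mean)


@dataclass
class PreprocessPipeline:
    """Ordered combination of the three transforms with frozen fitted state.

    Steps are always applied in the canonical order sg -> msc -> center,
    restricted to the steps requested.

    Parameters
    ----------
    steps : sequence of {"sg", "msc", "center"}
        Which transforms to include (order-insensitive; canonicalized).
    sg_window, sg_polyorder : int
        Savitzky-Golay window length (odd) and polynomial degree.
    """

    steps: tuple[str, ...] = STEP_ORDER
    sg_window: int = 11
    sg_polyorder: int = 2
    msc_reference_: np.ndarray | None = field(default=None, repr=False)
    center_mean_: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        steps = tuple(dict.fromkeys(self.steps))  # dedupe, keep first occurrence
        unknown = [s for s in steps if s not in STEP_ORDER]
        if unknown:
            raise ConfigurationError(f"unknown preprocessing steps: {unknown}")
        if not steps:
            raise ConfigurationError("pipeline needs at least one step")
        self.steps = tuple(s for s in STEP_ORDER if s in steps)

    @property
    def name(self) -> str:
        return "+".join(self.steps)

    @property
    def is_fitted(self) -> bool:
        return ("msc" not in self.steps or self.msc_reference_ is not None) and (
            "center" not in self.steps or self.center_mean_ is not None
        )

    def fit(self, train: SpectrumSet) -> "PreprocessPipeline":
        """Estimate MSC reference / centering mean on the training set.

        Statistics are computed on the *partially processed* training data,
        i.e. each fit sees the output of the preceding steps, matching how
        the pipeline is later applied.
        """
        current = train
        if "sg" in self.steps:
            current = sg_smooth(current, self.sg_window, self.sg_polyorder)
        if "msc" in self.steps:
            self.msc_reference_ = msc_fit(current)
            current = msc_apply(current, self.msc_reference_)
        if "center" in self.steps:
            self.center_mean_ = center_fit(current)
        return self

    def transform(self, ss: SpectrumSet) -> SpectrumSet:
        """Apply the fitted pipeline; never updates fitted state."""
        if not self.is_fitted:
            raise ValidationError("pipeline must be fitted before transform")
        current = ss
        if "sg" in self.steps:
            current = sg_smooth(current, self.sg_window, self.sg_polyorder)
        if "msc" in self.steps:
            current = msc_apply(current, self.msc_reference_)
        if "center" in self.steps:
            current = center_apply(current, self.center_mean_)
        return current

    def fit_transform(self, train: SpectrumSet) -> SpectrumSet:
        return self.fit(train).transform(train)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        out = {"steps": list(self.steps), "sg": {"window": self.sg_window, "polyorder": self.sg_polyorder}}
        if self.msc_reference_ is not None:
            out["msc_reference"] = self.msc_reference_.tolist()
        if self.center_mean_ is not None:
            out["center_mean"] = self.center_mean_.tolist()
        return out

    @classmethod
    def from_dict(cls, obj: dict) -> "PreprocessPipeline":
        sg = obj.get("sg", {})
        pipe = cls(tuple(obj["steps"]), int(sg.get("window", 11)), int(sg.get("polyorder", 2)))
        if "msc_reference" in obj:
            pipe.msc_reference_ = np.asarray(obj["msc_reference"], dtype=float)
        if "center_mean" in obj:
            pipe.center_mean_ = np.asarray(obj["center_mean"], dtype=float)
        return pipe

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "PreprocessPipeline":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def run_pipeline(ss: SpectrumSet, pipeline: PreprocessPipeline) -> SpectrumSet:
    """Apply a fitted :class:`PreprocessPipeline` to a SpectrumSet."""
    return pipeline.transform(ss)
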