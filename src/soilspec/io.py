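"""Spectral and attribute table I/O, sample alignment and dataset splitting.

The on-disk convention is a wide CSV: first column ``id``, remaining column
headers are wavelengths in nm (strictly ascending), one row per sample.
Attribute tables are narrow CSVs ``id,<attr1>,<attr2>,...``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, FormatError, ValidationError

__all__ = [
    "SpectrumSet",
    "AttributeTable",
    "SplitPlan",
    "read_spectra",
    "write_spectra",
    "read_attributes",
    "write_attributes",
    "reflectance_to_absorbance",
    "split_dataset",
    "align_targets",
]


@dataclass
class SpectrumSet:
    """A set of spectra sharing one wavelength axis.

    Parameters
    ----------
    wavelengths : ndarray, shape (C,)
        Strictly ascending wavelength axis in nm.
    intensities : ndarray, shape (n, C)
        Absorbance (unitless) or reflectance fraction in (0, 1].
    sample_ids : list of str
        Unique per-sample identifiers, aligned to the rows.
    intensity_kind : {"absorbance", "reflectance"}
        What the intensity values are.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]
    intensity_kind: str = "absorbance"

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.wavelengths.ndim != 1:
            raise ValidationError("wavelengths must be a 1-D vector")
        if self.intensities.shape[1] != self.wavelengths.size and self.intensities.size:
            raise ValidationError(
                f"intensity matrix has {self.intensities.shape[1]} channels, "
                f"wavelength axis has {self.wavelengths.size}"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise FormatError("wavelengths must be strictly increasing")
        if len(self.sample_ids) != self.intensities.shape[0]:
            raise ValidationError("sample_ids length does not match intensity rows")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample_ids must be unique")
        if self.intensities.size and not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities contain NaN or Inf")
        if self.intensity_kind not in ("absorbance", "reflectance"):
            raise ValidationError(f"unknown intensity_kind {self.intensity_kind!r}")
        if (
            self.intensity_kind == "reflectance"
            and self.intensities.size
            and (np.any(self.intensities <= 0) or np.any(self.intensities > 1))
        ):
            raise ValidationError("reflectance values must lie in (0, 1]")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.wavelengths.size

    def with_intensities(self, intensities: np.ndarray, kind: str | None = None) -> "SpectrumSet":
        """Return a copy sharing wavelengths/IDs with new intensity values."""
        return SpectrumSet(
            self.wavelengths.copy(),
            np.asarray(intensities, dtype=float).reshape(self.n_samples, self.n_channels),
            list(self.sample_ids),
            kind or self.intensity_kind,
        )

    def subset(self, indices) -> "SpectrumSet":
        """Row subset by integer indices, preserving order of ``indices``."""
        idx = np.asarray(indices, dtype=int)
        return SpectrumSet(
            self.wavelengths.copy(),
            self.intensities[idx],
            [self.sample_ids[i] for i in idx],
            self.intensity_kind,
        )

    def __eq__(self, other):
        if not isinstance(other, SpectrumSet):
            return NotImplemented
        return (
            self.intensity_kind == other.intensity_kind
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.wavelengths, other.wavelengths)
            and np.array_equal(self.intensities, other.intensities)
        )


@dataclass
class AttributeTable:
    """Per-sample regression targets (e.g. TC, TN, AN) keyed by sample ID."""

    sample_ids: list[str]
    values: np.ndarray  # (n, k)
    names: list[str]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.names = [str(x) for x in self.names]
        if self.values.shape != (len(self.sample_ids), len(self.names)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.names)} attributes"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample_ids must be unique")
        if len(set(self.names)) != len(self.names) or any(not n for n in self.names):
            raise ValidationError("attribute names must be non-empty and unique")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValidationError("attribute values contain NaN or Inf")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_attributes(self) -> int:
        return len(self.names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.sample_ids, name="id"), columns=self.names)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, units: dict[str, str] | None = None) -> "AttributeTable":
        return cls(
            [str(i) for i in frame.index],
            frame.to_numpy(dtype=float),
            [str(c) for c in frame.columns],
            units or {},
        )


@dataclass
class SplitPlan:
    """Reproducible partition of ``0..n-1`` into train[/val]/test.

    Non-train partitions receive ``ceil(ratio * n)`` items each; train takes
    the remainder. Assignment is a seeded uniform shuffle followed by
    contiguous slicing in partition order.
    """

    ratios: tuple[float, ...]
    seed: int
    indices: dict[str, np.ndarray]

    def __post_init__(self):
        self.ratios = tuple(float(r) for r in self.ratios)
        self.indices = {k: np.asarray(v, dtype=int) for k, v in self.indices.items()}

    @property
    def n(self) -> int:
        return sum(v.size for v in self.indices.values())

    @property
    def partitions(self) -> tuple[str, ...]:
        return tuple(self.indices)

    def sizes(self) -> dict[str, int]:
        return {k: int(v.size) for k, v in self.indices.items()}

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "ratios": list(self.ratios),
                "indices": {k: v.tolist() for k, v in self.indices.items()},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        obj = json.loads(text)
        return cls(tuple(obj["ratios"]), int(obj["seed"]), {k: np.asarray(v, dtype=int) for k, v in obj["indices"].items()})


def read_spectra(path, sep: str = ",", intensity_kind: str = "absorbance") -> SpectrumSet:
    """Read a wide spectral CSV into a :class:`SpectrumSet`.

    The header must be ``id,<wl1>,<wl2>,...`` with strictly ascending numeric
    wavelengths; row order is preserved.
    """
    frame = pd.read_csv(path, sep=sep, dtype={0: str})
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: need an id column plus at least one wavelength column")
    if frame.columns[0] != "id":
        raise FormatError(f"{path}: first column must be named 'id', got {frame.columns[0]!r}")
    try:
        wavelengths = np.asarray([float(c) for c in frame.columns[1:]])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric wavelength header: {exc}") from None
    if wavelengths.size > 1 and not np.all(np.diff(wavelengths) > 0):
        raise FormatError(f"{path}: wavelength header is not strictly ascending")
    values = frame.iloc[:, 1:].to_numpy(dtype=float) if len(frame) else np.empty((0, wavelengths.size))
    if values.size and not np.all(np.isfinite(values)):
        raise FormatError(f"{path}: missing or non-finite intensity values (ragged rows?)")
    return SpectrumSet(wavelengths, values, list(frame["id"]) if len(frame) else [], intensity_kind)


def write_spectra(ss: SpectrumSet, path, sep: str = ",") -> None:
    """Write a :class:`SpectrumSet` so that reading it back is lossless to ~1e-10 relative."""
    frame = pd.DataFrame(ss.intensities, columns=[repr(float(w)) for w in ss.wavelengths])
    frame.insert(0, "id", ss.sample_ids)
    frame.to_csv(path, sep=sep, index=False, float_format="%.12g")


def read_attributes(path, sep: str = ",", units: dict[str, str] | None = None) -> AttributeTable:
    """Read a narrow attribute CSV ``id,<attr1>,...`` into an :class:`AttributeTable`."""
    frame = pd.read_csv(path, sep=sep, dtype={0: str})
    if frame.columns[0] != "id":
        raise FormatError(f"{path}: first column must be named 'id'")
    values = frame.iloc[:, 1:].to_numpy(dtype=float)
    if values.size and not np.all(np.isfinite(values)):
        raise ValidationError(f"{path}: missing attribute values")
    return AttributeTable(list(frame["id"]), values, list(frame.columns[1:]), units or {})


def write_attributes(at: AttributeTable, path, sep: str = ",") -> None:
    frame = at.to_frame()
    frame.to_csv(path, sep=sep, float_format="%.12g")


def reflectance_to_absorbance(ss: SpectrumSet) -> SpectrumSet:
    """Convert reflectance fractions R to absorbance A = -log10(R).

    R = 1 maps to A = 0; smaller R means stronger absorption.
    """
    if ss.intensity_kind != "reflectance":
        raise ValidationError("input SpectrumSet is not reflectance")
    if np.any(ss.intensities <= 0):
        raise ValidationError("reflectance must be > 0 for the log transform")
    return ss.with_intensities(-np.log10(ss.intensities), kind="absorbance")


_PARTITION_NAMES = {2: ("train", "test"), 3: ("train", "val", "test")}


def split_dataset(n: int, ratios, seed: int) -> SplitPlan:
    """Partition ``0..n-1`` into train[/val]/test with a seeded shuffle.

    Each non-train partition gets ``ceil(ratio * n)`` samples; train gets the
    remainder. With n=19036 and ratios (0.6, 0.2, 0.2) this yields
    11420/3808/3808.

    Parameters
    ----------
    n : int
        Number of samples.
    ratios : sequence of 2 or 3 floats
        (train, test) or (train, val, test) fractions summing to 1.
    seed : int
        Shuffle seed; identical (n, ratios, seed) gives identical indices.
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) not in _PARTITION_NAMES:
        raise ConfigurationError("ratios must have 2 (train,test) or 3 (train,val,test) entries")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigurationError(f"ratios must sum to 1, got {sum(ratios)}")
    if any(r <= 0 for r in ratios):
        raise ConfigurationError("all ratios must be positive")
    names = _PARTITION_NAMES[len(ratios)]
    if n < len(ratios):
        raise ConfigurationError(f"cannot split {n} samples into {len(ratios)} partitions")
    non_train = [math.ceil(r * n) for r in ratios[1:]]
    train_size = n - sum(non_train)
    sizes = [train_size] + non_train
    if any(s < 1 for s in sizes):
        raise ConfigurationError(f"partition sizes {dict(zip(names, sizes))} include an empty partition")
    perm = np.random.default_rng(seed).permutation(n)
    indices, start = {}, 0
    for name, size in zip(names, sizes):
        indices[name] = perm[start : start + size]
        start += size
    return SplitPlan(ratios, int(seed), indices)


def align_targets(ss: SpectrumSet, at: AttributeTable) -> np.ndarray:
    """Return the (n, k) target matrix aligned to the SpectrumSet's row order.

    Alignment is by sample ID, never by row position; any spectrum without a
    matching attribute row is an error.
    """
    lookup = {sid: i for i, sid in enumerate(at.sample_ids)}
    missing = [sid for sid in ss.sample_ids if sid not in lookup]
    if missing:
        raise ValidationError(f"sample IDs missing from attribute table: {missing[:5]}" + ("..." if len(missing) > 5 else ""))
    rows = np.asarray([lookup[sid] for sid in ss.sample_ids], dtype=int)
    return at.values[rows]
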