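"""High-level Model/Results interface tying the whole pipeline together.

:class:`MultiCNNModel` is constructed from a :class:`~soilspec.io.SpectrumSet`
and an :class:`~soilspec.io.AttributeTable` (aligned by sample ID), plus
preprocessing / architecture / spectrogram settings. ``fit()`` splits the
data, fits the preprocessing pipeline on the training partition only,
builds the seeded network (choosing single- or dual-input adaptively),
trains it, and returns a :class:`MultiCNNResults` carrying the trained
network, the loss history, per-attribute metrics and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError, ValidationError
from .io import AttributeTable, SpectrumSet, SplitPlan, align_targets, split_dataset
from .models import (
    ModelConfig,
    ModePolicy,
    NetworkHandle,
    build_multicnn_1d,
    build_multicnn_dual,
    select_mode,
)
from .preprocess import PreprocessPipeline
from .spectrogram import SpectrogramConfig, batch_spectrograms
from .train_eval import MetricsReport, TrainConfig, evaluate, train

__all__ = ["MultiCNNModel", "MultiCNNResults"]


class MultiCNNModel:
    """Multi-task convolutional regression of soil attributes from spectra.

    Parameters
    ----------
    spectra : SpectrumSet
        Absorbance spectra (convert reflectance first).
    attributes : AttributeTable
        Targets, joined to the spectra by sample ID.
    pipeline : PreprocessPipeline, optional
        Preprocessing for the 1-D branch (default sg+msc+center). The 2-D
        spectrogram branch always works from the raw spectra.
    model_config, spectrogram_config, mode_policy : optional
        Architecture, spectrogram and adaptive-input-selection settings.
    mode : {"auto", "single_input", "dual_input"}
        "auto" selects by dataset size via ``select_mode``.
    """

    def __init__(
        self,
        spectra: SpectrumSet,
        attributes: AttributeTable,
        pipeline: PreprocessPipeline | None = None,
        model_config: ModelConfig | None = None,
        spectrogram_config: SpectrogramConfig | None = None,
        mode: str = "auto",
        mode_policy: ModePolicy | None = None,
    ):
        if spectra.intensity_kind != "absorbance":
            raise ValidationError("model expects absorbance spectra; use reflectance_to_absorbance first")
        self.spectra = spectra
        self.attributes = attributes
        self.targets = align_targets(spectra, attributes)
        self.pipeline = pipeline or PreprocessPipeline()
        self.spectrogram_config = spectrogram_config or SpectrogramConfig()
        if mode not in ("auto", "single_input", "dual_input"):
            raise ConfigurationError(f"unknown mode {mode!r}")
        self.mode = (
            select_mode(spectra.n_samples, spectra.n_channels, mode_policy)
            if mode == "auto"
            else mode
        )
        base = model_config or ModelConfig()
        if base.input_length != spectra.n_channels or base.n_tasks != attributes.n_attributes:
            base = ModelConfig(**{**base.to_dict(), "input_length": spectra.n_channels,
                                  "n_tasks": attributes.n_attributes,
                                  "image_size": (spectrogram_config or SpectrogramConfig()).image_size})
        self.model_config = base

    @classmethod
    def from_csv(cls, spectra_path, attributes_path, **kw) -> "MultiCNNModel":
        from .io import read_attributes, read_spectra

        return cls(read_spectra(spectra_path), read_attributes(attributes_path), **kw)

    def fit(
        self,
        split: SplitPlan | tuple[float, ...] = (0.7, 0.3),
        train_config: TrainConfig | None = None,
        seed: int = 0,
    ) -> "MultiCNNResults":
        """Split, preprocess, build, train and evaluate; returns Results."""
        cfg = train_config or TrainConfig(seed=seed)
        if not isinstance(split, SplitPlan):
            split = split_dataset(self.spectra.n_samples, split, seed)
        if split.n != self.spectra.n_samples:
            raise ValidationError("split plan does not cover this dataset")

        self.pipeline.fit(self.spectra.subset(split.indices["train"]))
        x1d = self.pipeline.transform(self.spectra).intensities
        x2d = (
            batch_spectrograms(self.spectra, self.spectrogram_config)
            if self.mode == "dual_input"
            else None
        )
        builder = build_multicnn_1d if self.mode == "single_input" else build_multicnn_dual
        handle = builder(self.model_config, seed=seed)
        history = train(handle, x1d, self.targets, split, cfg, x2d=x2d)
        report = evaluate(handle, x1d, self.targets, split, self.attributes.names, x2d=x2d)
        return MultiCNNResults(self, handle, split, history, report)


@dataclass
class MultiCNNResults:
    """Fitted-model results: trained network, history, metrics, summary."""

    model: MultiCNNModel
    handle: NetworkHandle
    split: SplitPlan
    history: dict
    metrics: MetricsReport
    _extra: dict = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return len(self.history["train_loss"])

    def predict(self, spectra: SpectrumSet) -> AttributeTable:
        """Predict attributes for new spectra with the frozen pipeline/model."""
        x1d = self.model.pipeline.transform(spectra).intensities
        x2d = (
            batch_spectrograms(spectra, self.model.spectrogram_config)
            if self.handle.mode == "dual_input"
            else None
        )
        values = self.handle.predict(x1d, x2d)
        return AttributeTable(spectra.sample_ids, values, self.model.attributes.names,
                              dict(self.model.attributes.units))

    def summary(self) -> str:
        lines = [
            "Multi-task spectral CNN results",
            "=" * 62,
            f"mode:             {self.handle.mode}",
            f"preprocessing:    {self.model.pipeline.name}",
            f"parameters:       {self.handle.parameter_count:,}",
            f"epochs run:       {self.n_epochs}",
            f"final train loss: {self.history['train_loss'][-1]:.5f}",
        ]
        if "val_loss" in self.history:
            lines.append(f"best val loss:    {min(self.history['val_loss']):.5f}")
        lines += ["-" * 62, self.metrics.to_text()]
        return "\n".join(lines)

    def save(self, out_dir) -> dict:
        """Persist model weights, pipeline state, split and metrics to a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.handle.save(out / "model.npz")
        self.model.pipeline.save(out / "pipeline.json")
        (out / "split.json").write_text(self.split.to_json())
        (out / "metrics.json").write_text(self.metrics.to_json(indent=2))
        (out / "history.json").write_text(json.dumps(self.history))
        return {"model": str(out / "model.npz"), "pipeline": str(out / "pipeline.json"),
                "split": str(out / "split.json"), "metrics": str(out / "metrics.json"),
                "history": str(out / "history.json")}


def load_predictor(model_dir):
    """Load the (pipeline, handle) pair saved by :meth:`MultiCNNResults.save`."""
    model_dir = Path(model_dir)
    npz = model_dir / "model.npz"
    if not npz.exists():
        raise FileNotFoundError(f"no trained model at {npz}")
    handle = NetworkHandle.load(npz)
    pipeline = PreprocessPipeline.load(model_dir / "pipeline.json")
    return pipeline, handle
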