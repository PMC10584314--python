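"""Pipeline configuration: a single validated YAML/JSON document.

Every constant of the decoding pipeline (band edges, reducer choice and
its parameters, bistable-system parameters, filter-bank weights,
candidate grids, evaluation lengths, synthetic-data settings) lives here
with its default, so nothing is hard-coded in the pipeline logic.
Unknown keys are rejected to catch typos.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .preprocess import FilterSpec
from .recognize import FBCCAParams
from .ussr import USSRParams

__all__ = ["PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FilterSettings(_Strict):
    low_hz: float = 3.0
    high_hz: float = 40.0
    order: int = Field(4, ge=1)
    zero_phase: bool = True

    @model_validator(mode="after")
    def _band_ordered(self) -> "FilterSettings":
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(
                f"need 0 < low_hz < high_hz, got ({self.low_hz}, {self.high_hz})"
            )
        return self

    def to_spec(self) -> FilterSpec:
        return FilterSpec(self.low_hz, self.high_hz, self.order, self.zero_phase)


class ReducerSettings(_Strict):
    method: Literal["car", "pca", "mds", "lle", "cca"] = "cca"
    reference_channel: str = "Oz"
    n_neighbors: int = Field(40, ge=2)
    max_points: int = Field(2000, ge=10)
    cca_scope: Literal["per_frequency", "single_best"] = "per_frequency"


class USSRSettings(_Strict):
    a: float = Field(0.1, gt=0)
    b: float = Field(1.0, gt=0)
    beta: float = Field(0.35, gt=0, lt=1)
    h: float = Field(0.1, gt=0)
    D: float = Field(0.0, ge=0)
    x0: float = 0.0
    v0: float = 0.0
    input_scale: float = 1.0
    standardize: bool = True
    hold: Literal["zoh", "linear"] = "zoh"
    seed: int = 0

    def to_params(self) -> USSRParams:
        return USSRParams(**self.model_dump())


class FBCCASettings(_Strict):
    n_subbands: int = Field(5, ge=1)
    weight_a: float = 1.25
    weight_b: float = Field(0.25, ge=0)
    subband_edges: list[tuple[float, float]] | None = None

    def to_params(self) -> FBCCAParams:
        edges = tuple(self.subband_edges) if self.subband_edges else None
        return FBCCAParams(
            n_subbands=self.n_subbands,
            weight_a=self.weight_a,
            weight_b=self.weight_b,
            subband_edges=edges,
        )


class GridSettings(_Strict):
    stimulus_low: float = 3.0
    stimulus_high: float = 20.0
    spectrum_low: float = 1.0
    spectrum_high: float = 40.0
    step: float = Field(0.5, gt=0)
    harmonics: int = Field(2, ge=1)

    def stimulus_freqs(self) -> list[float]:
        n = int(round((self.stimulus_high - self.stimulus_low) / self.step)) + 1
        return [self.stimulus_low + self.step * i for i in range(n)]

    def spectrum_freqs(self) -> list[float]:
        n = int(round((self.spectrum_high - self.spectrum_low) / self.step)) + 1
        return [self.spectrum_low + self.step * i for i in range(n)]


class ScorerSettings(_Strict):
    method: Literal["cca", "psda"] = "cca"
    psda_use_harmonic: bool = True


class SynthSettings(_Strict):
    duration: float = Field(3.0, gt=0)
    fs: float = Field(1000.0, gt=0)
    n_channels: int = Field(8, ge=1)
    amp_fundamental: float = 1.0
    harmonic_ratio: float = Field(0.1, ge=0)
    noise_alpha: float = 1.0
    snr_db: float = -16.0
    trials_per_freq: int = Field(1, ge=1)


class EvaluationSettings(_Strict):
    lengths: list[float] = Field(default_factory=lambda: [3.0, 2.5, 2.0, 1.5, 1.0])
    methods: list[str] = Field(default_factory=lambda: ["cca", "cca_ussr"])
    seed: int = 0


class PipelineConfig(_Strict):
    """Full five-stage pipeline configuration."""

    filter: FilterSettings = Field(default_factory=FilterSettings)
    reducer: ReducerSettings = Field(default_factory=ReducerSettings)
    ussr: USSRSettings = Field(default_factory=USSRSettings)
    fbcca: FBCCASettings = Field(default_factory=FBCCASettings)
    grid: GridSettings = Field(default_factory=GridSettings)
    scorer: ScorerSettings = Field(default_factory=ScorerSettings)
    synth: SynthSettings = Field(default_factory=SynthSettings)
    evaluation: EvaluationSettings = Field(default_factory=EvaluationSettings)
    method: str = "cca_ussr"

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        from .recognize import METHODS

        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        for m in self.evaluation.methods:
            if m not in METHODS:
                raise ValueError(f"unknown evaluation method {m!r}")
        if self.filter.high_hz >= self.synth.fs / 2:
            raise ValueError("filter high edge reaches Nyquist of synthetic fs")
        return self

    def pipeline_kwargs(self) -> dict:
        """Keyword arguments for :func:`ssvepsr.recognize.score_epoch`."""
        return {
            "filter_spec": self.filter.to_spec(),
            "ussr_params": self.ussr.to_params(),
            "fbcca_params": self.fbcca.to_params(),
            "scorer": self.scorer.method,
            "reference_channel": self.reducer.reference_channel,
            "lle_k": self.reducer.n_neighbors,
            "max_points": self.reducer.max_points,
            "cca_scope": self.reducer.cca_scope,
            "psda_use_harmonic": self.scorer.psda_use_harmonic,
        }

    def dump(self, path: str | Path) -> None:
        path = Path(path)
        doc = self.model_dump(mode="json")
        if path.suffix == ".json":
            path.write_text(json.dumps(doc, indent=2))
        else:
            path.write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML/JSON pipeline config; defaults when ``path`` is None."""
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    doc = yaml.safe_load(text) or {}
    return PipelineConfig.model_validate(doc)
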