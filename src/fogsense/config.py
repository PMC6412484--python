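"""Whole-pipeline configuration: one object, validated before any computation.

The YAML/JSON layout mirrors the stage structure::

    preprocess: {hp_cutoff_hz: 3, lp_envelope_hz: 10, ...}
    detector:   {T1: 0.01, T2: -0.4, R_demarcation: 3, ...}
    phenotype:  {fir_cutoff_hz: 2, pi_threshold: 20, ...}
    ensemble:   {segment_s: 1.0, resample_len: 200}
    mode: offline          # or streaming
    calibration_s: 10.0    # normalization prefix used in streaming mode
    log_level: INFO

Unknown keys anywhere are rejected, so typos fail loudly up front.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ValidationError
from .fog_detect import DetectorConfig
from .muscle_activity import EnsembleConfig
from .phenotype import PhenotypeConfig
from .preprocess import PreprocessConfig

__all__ = ["PipelineConfig", "load_config"]


def _build(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValidationError(f"unknown {where} config keys: {sorted(unknown)}")
    kwargs = dict(data)
    if "psd_band_hz" in kwargs and isinstance(kwargs["psd_band_hz"], (list, tuple)):
        kwargs["psd_band_hz"] = tuple(kwargs["psd_band_hz"])
    return cls(**kwargs)


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    phenotype: PhenotypeConfig = field(default_factory=PhenotypeConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    mode: str = "offline"
    calibration_s: float = 10.0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("offline", "streaming"):
            raise ValidationError("mode must be 'offline' or 'streaming'")
        if self.calibration_s <= 0:
            raise ValidationError("calibration_s must be positive")
        self.preprocess.validate()
        self.detector.validate()
        self.phenotype.validate()
        self.ensemble.validate()

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        known = {"preprocess", "detector", "phenotype", "ensemble",
                 "mode", "calibration_s", "log_level"}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown top-level config keys: {sorted(unknown)}")
        cfg = cls(
            preprocess=_build(PreprocessConfig, data.get("preprocess", {}), "preprocess"),
            detector=_build(DetectorConfig, data.get("detector", {}), "detector"),
            phenotype=_build(PhenotypeConfig, data.get("phenotype", {}), "phenotype"),
            ensemble=_build(EnsembleConfig, data.get("ensemble", {}), "ensemble"),
            mode=data.get("mode", "offline"),
            calibration_s=float(data.get("calibration_s", 10.0)),
            log_level=str(data.get("log_level", "INFO")),
        )
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return {
            "preprocess": dataclasses.asdict(self.preprocess),
            "detector": dataclasses.asdict(self.detector),
            "phenotype": {
                **dataclasses.asdict(self.phenotype),
                "psd_band_hz": list(self.phenotype.psd_band_hz),
            },
            "ensemble": dataclasses.asdict(self.ensemble),
            "mode": self.mode,
            "calibration_s": self.calibration_s,
            "log_level": self.log_level,
        }


def load_config(path=None) -> PipelineConfig:
    """Load and validate a pipeline config file (YAML or JSON); defaults if None."""
    if path is None:
        cfg = PipelineConfig()
        cfg.validate()
        return cfg
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError(f"config file {path} must contain a mapping")
    return PipelineConfig.from_dict(data)
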