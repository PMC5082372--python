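"""Pipeline configuration: one YAML file driving every stage.

Example::

    levels: 256
    e1: 0.1
    e2: 0.1
    ref_exponent: 2.0
    generator: sugeno
    epsilon: 0.2
    object_transform: exp
    background_transform: exp
    fusion:
      a1: 1.0
      a2: 0.5
      b1: 1.0
      c1: 0.5
      expression: product
      logical_op: max
    metrics:
      block: 3
      alpha: 1.0
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fusion import FusionParams, validate_fusion_params
from .ifs import REFParams
from .metrics import MetricConfig
from .nlfi import NLFIConfig, ThresholdParams

__all__ = ["PipelineConfig", "load_config"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    levels: int = 256
    e1: float = 0.1
    e2: float = 0.1
    ref_exponent: float = 2.0
    generator: str = "sugeno"
    epsilon: float = 0.2
    object_transform: str = "exp"
    background_transform: str = "exp"
    fusion: FusionParams = field(default_factory=FusionParams)
    metrics: MetricConfig = field(default_factory=MetricConfig)

    def nlfi_config(self) -> NLFIConfig:
        ref = REFParams() if self.ref_exponent == 2.0 else REFParams.power_inner(self.ref_exponent)
        return NLFIConfig(
            thresholds=ThresholdParams(e1=self.e1, e2=self.e2),
            ref=ref,
            object_transform=self.object_transform,
            background_transform=self.background_transform,
        )

    def log_effective(self) -> None:
        logger.info(
            "pipeline config: levels=%d e=(%.3g, %.3g) ref_exponent=%.3g "
            "generator=%s epsilon=%.3g transforms=(%s, %s) fusion=(a1=%.3g a2=%.3g "
            "b1=%.3g c1=%.3g expr=%s) metrics=(%dx%d alpha=%.3g)",
            self.levels, self.e1, self.e2, self.ref_exponent, self.generator,
            self.epsilon, self.object_transform, self.background_transform,
            self.fusion.a1, self.fusion.a2, self.fusion.b1, self.fusion.c1,
            self.fusion.expression, self.metrics.block_rows,
            self.metrics.block_cols, self.metrics.alpha,
        )


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file plus keyword overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})

    fusion_raw = data.pop("fusion", {})
    fusion = validate_fusion_params(FusionParams(**fusion_raw)) if fusion_raw else FusionParams()

    metrics_raw = dict(data.pop("metrics", {}))
    if "block" in metrics_raw:
        b = metrics_raw.pop("block")
        metrics_raw.setdefault("block_rows", b)
        metrics_raw.setdefault("block_cols", b)
    metrics = MetricConfig(**metrics_raw) if metrics_raw else MetricConfig()

    return PipelineConfig(fusion=fusion, metrics=metrics, **data)
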