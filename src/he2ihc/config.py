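"""Frozen default configurations and YAML (de)serialization.

``full_config()`` is the production-scale model whose calibrated widths pin
the under-specified channel counts to the published complexity totals
(≈26.77 M parameters, ≈41.13 GMACs forward at 256×256 under the MAC=1FLOP
convention).  ``benchmark_config()`` is the reduced-width configuration used
for the CPU-scale synthetic-stain learnability runs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .classifier import BlockSpec, ClassifierConfig, scaled_classifier_config
from .discriminator import DiscriminatorConfig
from .generator import GeneratorConfig
from .losses import LossWeights
from .synthetic import SynthConfig
from .train import TrainConfig


@dataclass(frozen=True)
class ModelConfig:
    generator: GeneratorConfig
    classifier: ClassifierConfig
    discriminator: DiscriminatorConfig
    side: int = 256


def full_config() -> ModelConfig:
    """Calibrated production configuration (frozen)."""
    classifier = scaled_classifier_config(width_scale=4.92, head_hidden=69)
    generator = GeneratorConfig(
        base_width=76,
        ir_expansion=4,
        label_embed_dim=32,
        adain_hidden=64,
        tap_channels=classifier.tap_channels,
    )
    return ModelConfig(generator, classifier, DiscriminatorConfig(), side=256)


def benchmark_config(side: int = 64) -> ModelConfig:
    """Reduced-width configuration for CPU-scale synthetic benchmarks."""
    classifier = scaled_classifier_config(width_scale=0.5, head_hidden=32)
    generator = GeneratorConfig(
        base_width=8,
        ir_expansion=2,
        label_embed_dim=16,
        adain_hidden=32,
        tap_channels=classifier.tap_channels,
    )
    # 3 body layers: at 64x64 inputs the 1/4-scale branch is only 16 px wide,
    # so a fourth stride-2 layer would leave no room for the patch-logit conv
    discriminator = DiscriminatorConfig(base_width=16, n_body_layers=3)
    return ModelConfig(generator, classifier, discriminator, side=side)


# ----------------------------------------------------------------- YAML I/O

def to_yaml(cfg: ModelConfig) -> str:
    d = {
        "side": cfg.side,
        "generator": asdict(cfg.generator),
        "classifier": asdict(cfg.classifier),
        "discriminator": asdict(cfg.discriminator),
    }
    return yaml.safe_dump(d, sort_keys=False)


def from_yaml(text: str) -> ModelConfig:
    d = yaml.safe_load(text)
    cd = dict(d["classifier"])
    cd["blocks"] = tuple(BlockSpec(**b) for b in
                         (b if isinstance(b, dict) else b for b in cd["blocks"]))
    gd = dict(d["generator"])
    gd["tap_channels"] = tuple(gd["tap_channels"])
    return ModelConfig(
        generator=GeneratorConfig(**gd),
        classifier=ClassifierConfig(**cd),
        discriminator=DiscriminatorConfig(**d["discriminator"]),
        side=int(d.get("side", 256)),
    )
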