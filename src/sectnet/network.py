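"""SECT-Net assembly: encoder, DFCM, dual decoders, ablation toggles,
and checkpoint serialization.

The encoder is five levels deep with channel plan
``base_width * (1, 2, 4, 8, 16)``: an initial DoubleConv, three
downsampling stages carrying SE-convolution Transformer modules
(plain max-pool + DoubleConv stages when ``use_sectm`` is off), and a
bottleneck DoubleConv.  Decoder1 produces the coarse mask; Decoder2
refines under mask (or Decoder1-feature) guidance with DFCM and skip
concatenation.  All ablation variants of the architecture are reachable
through :class:`ModelConfig` toggles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .blocks import DoubleConv
from .decoders import Decoder1Block, Decoder2Block, SegmentationHead
from .dfcm import DFCM
from .nn import Module, ModuleList, Sequential, max_pool2x2, MaxPool2x2
from .sectm import SectmEncoderStage

__all__ = ["ModelConfig", "ModelOutputs", "SECTNet", "build_model",
           "count_parameters", "save_checkpoint", "load_checkpoint"]

_CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters and ablation toggles.

    ``guidance`` selects how Decoder2 interacts with Decoder1:
    ``"mask"`` (the dual-decoder mask mechanism), ``"decoder1_features"``
    (direct stage-feature transfer) or ``"none"``.  ``dual_decoder=False``
    drops Decoder2 entirely, leaving a plain U-Net-style model whose
    refined output equals the coarse one.
    """

    input_side: int = 256
    base_width: int = 32
    use_sectm: bool = True
    use_dfcm: bool = True
    dual_decoder: bool = True
    guidance: str = "mask"          # mask | decoder1_features | none
    se_aspp_mode: str = "full"      # full | se_only | aspp_only | none
    use_bam: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.input_side % 16:
            raise ValueError(f"input_side must be divisible by 16, got {self.input_side}")
        if self.base_width < 4:
            raise ValueError(f"base_width must be >= 4, got {self.base_width}")
        if self.guidance not in ("mask", "decoder1_features", "none"):
            raise ValueError(f"unknown guidance {self.guidance!r}")
        if self.se_aspp_mode not in ("full", "se_only", "aspp_only", "none"):
            raise ValueError(f"unknown se_aspp_mode {self.se_aspp_mode!r}")

    @property
    def channel_plan(self) -> tuple[int, ...]:
        w = self.base_width
        return (w, 2 * w, 4 * w, 8 * w, 16 * w)


@dataclass
class ModelOutputs:
    coarse: Tensor
    refined: Tensor


class _PlainStage(Module):
    """Max-pool + DoubleConv downsampling stage (SECTM ablation)."""

    def __init__(self, cin: int, rng: np.random.Generator):
        super().__init__()
        self.conv = DoubleConv(cin, 2 * cin, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(max_pool2x2(x))


class SECTNet(Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        w1, w2, w3, w4, w5 = cfg.channel_plan
        s = cfg.input_side

        self.enc1 = DoubleConv(1, w1, rng)
        stages = []
        for cin, side in ((w1, s), (w2, s // 2), (w3, s // 4)):
            if cfg.use_sectm:
                stages.append(SectmEncoderStage(
                    cin, side, rng, se_aspp_mode=cfg.se_aspp_mode, use_bam=cfg.use_bam))
            else:
                stages.append(_PlainStage(cin, rng))
        self.stages = ModuleList(stages)
        self.bottleneck = Sequential(MaxPool2x2(), DoubleConv(w4, w5, rng))

        # Decoder1 (coarse)
        self.dec1_blocks = ModuleList(Decoder1Block(c, rng) for c in (w5, w4, w3, w2))
        self.head1 = SegmentationHead(w1, rng)

        # DFCM + Decoder2 (refined)
        if cfg.dual_decoder:
            self.dfcm = DFCM(w5, (w4, w3, w2, w1), rng) if cfg.use_dfcm else None
            self.dec2_blocks = ModuleList(
                Decoder2Block(c, rng, use_dfcm=cfg.use_dfcm, guidance=cfg.guidance)
                for c in (w5, w4, w3, w2))
            self.head2 = SegmentationHead(w1, rng)
        else:
            self.dfcm = None
            self.dec2_blocks = None
            self.head2 = None

    def forward(self, image: Tensor) -> ModelOutputs:
        cfg = self.cfg
        if image.ndim != 4 or image.shape[1] != 1:
            raise ValueError(f"expected (B, 1, S, S) input, got {image.shape}")
        if image.shape[2] != cfg.input_side or image.shape[3] != cfg.input_side:
            raise ValueError(f"model was built for input side {cfg.input_side}, "
                             f"got {image.shape[2]}x{image.shape[3]}")

        e1 = self.enc1(image)
        e2 = self.stages[0](e1)
        e3 = self.stages[1](e2)
        e4 = self.stages[2](e3)
        e5 = self.bottleneck(e4)
        skips = (e4, e3, e2, e1)

        # Decoder1 runs to completion before Decoder2 starts.
        d1_feats: list[Tensor] = []
        feat = e5
        for block, skip in zip(self.dec1_blocks, skips):
            feat = block(feat, skip)
            d1_feats.append(feat)
        coarse = self.head1(feat)

        if not cfg.dual_decoder:
            return ModelOutputs(coarse=coarse, refined=coarse)

        dfcm_feats = self.dfcm(e5) if self.dfcm is not None else [None] * 4
        feat = e5
        for block, skip, dfcm_feat, d1_feat in zip(
                self.dec2_blocks, skips, dfcm_feats, d1_feats):
            feat = block(feat, skip, mask=coarse, dfcm_feat=dfcm_feat, d1_feat=d1_feat)
        refined = self.head2(feat)
        return ModelOutputs(coarse=coarse, refined=refined)


def build_model(cfg: ModelConfig) -> SECTNet:
    """Build a SECT-Net with deterministic initialization under ``cfg.seed``."""
    return SECTNet(cfg)


def count_parameters(model: SECTNet) -> int:
    return model.num_parameters()


def save_checkpoint(model: SECTNet, path) -> None:
    """Write a single-file archive with parameters, buffers and config."""
    payload = {"state:" + k: v for k, v in model.state_dict().items()}
    payload["__config__"] = np.array(json.dumps(dataclasses.asdict(model.cfg)))
    payload["__version__"] = np.array(_CHECKPOINT_VERSION)
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_checkpoint(path, cfg: ModelConfig | None = None) -> SECTNet:
    """Rebuild a model from a checkpoint.

    If ``cfg`` is given it must match the embedded config exactly.
    """
    with np.load(path, allow_pickle=False) as archive:
        version = int(archive["__version__"])
        if version != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {version}")
        stored = ModelConfig(**json.loads(str(archive["__config__"])))
        if cfg is not None and cfg != stored:
            raise ValueError(f"checkpoint config mismatch: checkpoint has {stored}, "
                             f"requested {cfg}")
        model = build_model(stored)
        state = {k[len("state:"):]: archive[k] for k in archive.files
                 if k.startswith("state:")}
        model.load_state_dict(state)
    return model
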