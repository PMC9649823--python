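"""UNETR-style 3D transformer encoder-decoder for kidney segmentation.

The encoder is a vision transformer over non-overlapping cubic volumetric
tokens; the decoder is convolutional, consuming skip features tapped from
evenly spaced transformer blocks. With ``S`` decoding stages the decoder
runs: project the final block's tokens to a feature grid at 1/token_patch
resolution, then for each stage concatenate a skip, apply two rounds of 3D
convolution + batch norm + ReLU, and upsample x2 (transposed convolution,
kernel 2, stride 2). A final head upsamples to full resolution, fuses a
convolutional feature map of the raw input, and maps to class scores with a
1x1x1 convolution. This requires ``token_patch == 2**(S+1)`` so the S
stages plus the head exactly restore the input resolution — satisfied by
the default token edge 16 with 3 decoding stages.

Default dimensions: 96^3 input patch, hidden 768, feed-forward 3072, 12
heads, 12 blocks, 3 decoding stages, 1 input and 3 output channels. The
"tiny" preset (64^3 patch, hidden 96, ffn 384, 4 heads, 4 blocks) keeps
every structural invariant and is the CPU-scale configuration used by the
tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ParameterError
from .autograd import Tensor, cat
from .modules import (
    BatchNorm3d,
    Conv3d,
    ConvTranspose3d,
    Module,
    PatchEmbed3d,
    ReLU,
    Sequential,
    TransformerBlock,
)

__all__ = ["NetworkConfig", "UNETR3D", "build_network"]


@dataclass(frozen=True)
class NetworkConfig:
    """Structural hyperparameters of the segmentation network."""

    patch_size: tuple[int, int, int] = (96, 96, 96)
    token_patch: int = 16
    blocks: int = 12
    hidden: int = 768
    ffn: int = 3072
    heads: int = 12
    decoding_stages: int = 3
    in_channels: int = 1
    out_channels: int = 3
    decoder_channels: tuple[int, ...] = (64, 32, 16, 16)
    seed: int = 0

    def __post_init__(self):
        if any(p % self.token_patch for p in self.patch_size):
            raise ParameterError(
                f"patch {self.patch_size} not divisible by token edge {self.token_patch}"
            )
        if self.hidden % self.heads:
            raise ParameterError("hidden dimension must be divisible by the head count")
        if self.token_patch != 2 ** (self.decoding_stages + 1):
            raise ParameterError(
                "token_patch must equal 2**(decoding_stages+1) so the decoder "
                "restores full resolution"
            )
        if len(self.decoder_channels) != self.decoding_stages + 1:
            raise ParameterError("need decoding_stages+1 decoder channel counts")

    @property
    def token_grid(self) -> tuple[int, int, int]:
        return tuple(p // self.token_patch for p in self.patch_size)

    @property
    def skip_taps(self) -> tuple[int, ...]:
        """1-based encoder block indices tapped for skips, deepest first.

        Evenly spaced: for L blocks and S stages the skip feeding the
        coarsest decoder level comes from block round(S*L/(S+1)), the next
        from round((S-1)*L/(S+1)), ... (e.g. blocks 9, 6, 3 of 12).
        """
        L, S = self.blocks, self.decoding_stages
        return tuple(int(round((S - l) * L / (S + 1))) for l in range(S))

    @staticmethod
    def paper() -> "NetworkConfig":
        return NetworkConfig()

    @staticmethod
    def tiny(seed: int = 0) -> "NetworkConfig":
        return NetworkConfig(
            patch_size=(64, 64, 64),
            blocks=4,
            hidden=96,
            ffn=384,
            heads=4,
            decoder_channels=(32, 16, 8, 4),
            seed=seed,
        )


def _conv_bn_relu(c_in, c_out, k, rng):
    return Sequential(Conv3d(c_in, c_out, k, rng), BatchNorm3d(c_out), ReLU())


def _conv_block(c_in, c_out, rng):
    """Two rounds of conv3 + BN + ReLU (one decoding-stage body)."""
    return Sequential(
        Conv3d(c_in, c_out, 3, rng), BatchNorm3d(c_out), ReLU(),
        Conv3d(c_out, c_out, 3, rng), BatchNorm3d(c_out), ReLU(),
    )


class _SkipBranch(Module):
    """Turn tapped tokens into a feature grid at the decoder level's resolution.

    ``ups`` transposed convolutions (each followed by conv3+BN+ReLU) take
    the token grid up by 2**ups.
    """

    def __init__(self, hidden, c_out, ups, rng):
        super().__init__()
        layers = []
        c = hidden
        if ups == 0:
            layers.append(_conv_bn_relu(c, c_out, 3, rng))
        for i in range(ups):
            layers.append(ConvTranspose3d(c, c_out, rng))
            layers.append(_conv_bn_relu(c_out, c_out, 3, rng))
            c = c_out
        self.body = Sequential(*layers)

    def forward(self, x):
        return self.body(x)


class UNETR3D(Module):
    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        gz, gy, gx = cfg.token_grid
        self.embed = PatchEmbed3d(cfg.in_channels, cfg.token_patch, cfg.hidden, (gz, gy, gx), rng)
        self.blocks = [
            TransformerBlock(cfg.hidden, cfg.heads, cfg.ffn, rng) for _ in range(cfg.blocks)
        ]
        ch = cfg.decoder_channels
        self.proj = _conv_bn_relu(cfg.hidden, ch[0], 3, rng)
        # skip branch l feeds decoder level l (0 = coarsest, token grid res)
        self.skips = [
            _SkipBranch(cfg.hidden, ch[l], ups=l, rng=rng) for l in range(cfg.decoding_stages)
        ]
        self.stages = []
        self.ups = []
        for l in range(cfg.decoding_stages):
            self.stages.append(_conv_block(2 * ch[l], ch[l], rng))
            self.ups.append(ConvTranspose3d(ch[l], ch[l + 1], rng))
        c_last = ch[cfg.decoding_stages]
        self.head_up = ConvTranspose3d(c_last, c_last, rng)
        self.input_skip = _conv_bn_relu(cfg.in_channels, c_last, 3, rng)
        self.fuse = _conv_bn_relu(2 * c_last, c_last, 3, rng)
        self.out = Conv3d(c_last, cfg.out_channels, 1, rng)

    def _tokens_to_grid(self, tok: Tensor) -> Tensor:
        gz, gy, gx = self.cfg.token_grid
        return tok.reshape(gz, gy, gx, self.cfg.hidden).transpose(3, 0, 1, 2)

    def forward(self, x: Tensor) -> Tensor:
        """Map a (in_channels, D, H, W) patch to (out_channels, D, H, W) scores."""
        if x.shape[0] != self.cfg.in_channels or tuple(x.shape[1:]) != tuple(self.cfg.patch_size):
            raise ParameterError(
                f"expected input of shape {(self.cfg.in_channels, *self.cfg.patch_size)}, got {x.shape}"
            )
        tok = self.embed(x)
        taps = {}
        want = set(self.cfg.skip_taps)
        for i, blk in enumerate(self.blocks, start=1):
            tok = blk(tok)
            if i in want:
                taps[i] = tok
        feats = self.proj(self._tokens_to_grid(tok))
        for l in range(self.cfg.decoding_stages):
            skip = self.skips[l](self._tokens_to_grid(taps[self.cfg.skip_taps[l]]))
            feats = self.stages[l](cat([feats, skip], axis=0))
            feats = self.ups[l](feats)
        feats = self.head_up(feats)
        feats = self.fuse(cat([feats, self.input_skip(x)], axis=0))
        return self.out(feats)


def build_network(cfg: NetworkConfig) -> UNETR3D:
    """Construct the network with seeded parameter initialization."""
    return UNETR3D(cfg)
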