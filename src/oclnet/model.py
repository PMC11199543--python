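"""The segmentation network: a 3-D encoder–decoder with multi-scale dense attention.

The backbone is a U-Net-style encoder–decoder.  The encoder has
``num_levels`` convolutional blocks (two conv→norm→ReLU stages each) with
2×2×2 max pooling between levels and dropout after each pooling; the
decoder mirrors it with kernel-2/stride-2 transposed convolutions and skip
concatenations from matching encoder levels.

On top of the backbone sits a dense multi-scale attention mechanism: at the
``attention_scales`` coarsest decoder-side resolutions a 1×1×1 convolution
with sigmoid produces a single-channel spatial attention map in [0, 1].
Every map is carried forward densely — nearest-upsampled and concatenated
into the input of each subsequent (finer) decoder block — so coarse spatial
context accumulates as decoding proceeds from broad structure toward fine
detail.  Maps live at resolutions ``input/2^k`` for
``k = attention_scales … 1``; choosing ``attention_scales = num_levels``
adds a full-resolution map that is concatenated just before the output
head (the all-scales variant kept for ablation).  The maps double as
per-scale probability outputs for deep supervision against downsampled
ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .nn import Adam  # noqa: F401  (re-exported convenience)
from .nn.layers import Context, Conv3d, ConvBlock, ConvTranspose3d, Dropout, Module
from .nn.tensor import Tensor, concat

__all__ = ["NetConfig", "ForwardResult", "SegmentationModel", "build_model"]


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters; defaults are the full-scale settings."""

    num_levels: int = 5
    base_channels: int = 32
    dropout_rate: float = 0.2
    attention_scales: int = 4
    deep_supervision: bool = True
    input_shape: tuple[int, int, int] = (128, 128, 128)
    instance_norm: bool = False  # normalize by current-input stats at eval too

    def __post_init__(self) -> None:
        if self.num_levels < 2:
            raise ValueError("need at least two resolution levels")
        if not 0 <= self.attention_scales <= self.num_levels:
            raise ValueError(
                f"attention_scales must lie in [0, num_levels], got "
                f"{self.attention_scales}"
            )
        div = 2 ** (self.num_levels - 1)
        if any(n % div for n in self.input_shape):
            raise ValueError(
                f"input shape {self.input_shape} not divisible by {div} "
                f"(2^(num_levels-1))"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")

    @property
    def attention_ks(self) -> tuple[int, ...]:
        """Resolution indices (input/2^k) carrying attention maps, coarse→fine."""
        top = self.num_levels - 1
        return tuple(range(top, top - self.attention_scales, -1))

    @classmethod
    def test_preset(cls) -> "NetConfig":
        """Desk-scale preset: 3 levels, 8 base channels, 32³ inputs."""
        return cls(
            num_levels=3,
            base_channels=8,
            attention_scales=2,
            input_shape=(32, 32, 32),
            instance_norm=True,
        )


@dataclass
class ForwardResult:
    prob: np.ndarray | Tensor  # (z, y, x) probabilities
    attention_maps: list  # coarse→fine, each (z, y, x) in [0, 1]
    deep_outputs: list | None  # per-scale probability maps iff deep supervision


class SegmentationModel(Module):
    """Parameterized network; see module docstring for the architecture."""

    def __init__(self, config: NetConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        nl = config.num_levels
        ch = [config.base_channels * 2**l for l in range(nl)]
        ks = config.attention_ks

        inorm = config.instance_norm
        self.enc_blocks = [
            ConvBlock(1 if l == 0 else ch[l - 1], ch[l], rng, instance_norm=inorm)
            for l in range(nl)
        ]
        self.dropout = Dropout(config.dropout_rate)

        self.up_convs = []
        self.dec_blocks = []
        for l in range(nl - 2, -1, -1):
            n_maps = sum(1 for k in ks if k > l)
            self.up_convs.append(ConvTranspose3d(ch[l + 1], ch[l], rng))
            self.dec_blocks.append(
                ConvBlock(2 * ch[l] + n_maps, ch[l], rng, instance_norm=inorm)
            )

        # one 1x1x1 attention head per attention scale, coarse→fine
        self.att_convs = [Conv3d(ch[k], 1, 1, rng) for k in ks]
        head_in = ch[0] + (1 if 0 in ks else 0)
        self.head = Conv3d(head_in, 1, 1, rng)

    # -- inference --------------------------------------------------------

    def forward(
        self,
        image: np.ndarray | Tensor,
        ctx: Context | None = None,
        zero_attention: set[int] | frozenset[int] = frozenset(),
    ) -> ForwardResult:
        """Run the network on one (z, y, x) volume in [0, 1].

        ``zero_attention`` names attention-map indices (coarse→fine) whose
        maps are replaced by zeros before dense propagation — an ablation
        hook proving the maps are wired into later scales.
        """
        cfg = self.config
        arr = image.data if isinstance(image, Tensor) else np.asarray(image)
        if arr.shape != tuple(cfg.input_shape):
            raise ValueError(
                f"input shape {arr.shape} != configured {cfg.input_shape}"
            )
        if not np.isfinite(arr).all():
            raise ValueError("non-finite values in network input")
        ctx = ctx or Context()
        x = (
            image.reshape(1, *arr.shape)
            if isinstance(image, Tensor)
            else Tensor(arr.astype(np.float32)[None])
        )

        nl = cfg.num_levels
        ks = cfg.attention_ks
        skips = []
        for l in range(nl):
            x = self.enc_blocks[l](x, ctx)
            if l < nl - 1:
                skips.append(x)
                x = self.dropout(x.maxpool3d(), ctx)

        maps: list[tuple[int, Tensor]] = []  # (resolution index k, map)

        def make_map(feat: Tensor, k: int) -> None:
            i = ks.index(k)
            m = self.att_convs[i](feat, ctx).sigmoid()
            if i in zero_attention:
                m = m * 0.0
            maps.append((k, m))

        for stage, l in enumerate(range(nl - 2, -1, -1)):
            if (l + 1) in ks:
                make_map(x, l + 1)
            up = self.up_convs[stage](x, ctx)
            parts = [up, skips[l]]
            parts += [m.upsample_nearest(2 ** (k - l)) for k, m in maps]
            x = self.dec_blocks[stage](concat(parts), ctx)
        if 0 in ks:
            make_map(x, 0)
            x = concat([x, maps[-1][1]])
        prob = self.head(x, ctx).sigmoid()

        att = [m for _, m in maps]
        return ForwardResult(
            prob=prob.reshape(*arr.shape),
            attention_maps=att,
            deep_outputs=att if cfg.deep_supervision and att else None,
        )

    def __call__(self, image, ctx=None, **kw) -> ForwardResult:
        return self.forward(image, ctx, **kw)

    def extract_attention_maps(self, image: np.ndarray) -> list[np.ndarray]:
        """Evaluation-mode attention maps as plain arrays, coarse→fine."""
        res = self.forward(image, Context(training=False))
        return [np.squeeze(m.data, axis=0) for m in res.attention_maps]

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- checkpointing -----------------------------------------------------

    def save(self, path: str, epoch: int = 0, extra: dict | None = None) -> str:
        meta = {
            "format": "oclnet-checkpoint-v1",
            "config": asdict(self.config),
            "epoch": epoch,
            **(extra or {}),
        }
        arrays = self.state_arrays()
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
        return path

    @classmethod
    def load(cls, path: str) -> tuple["SegmentationModel", dict]:
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg_d = meta["config"]
            cfg_d["input_shape"] = tuple(cfg_d["input_shape"])
            model = cls(NetConfig(**cfg_d))
            state = {k: data[k] for k in data.files if k != "__meta__"}
        model.load_state_arrays(state)
        return model, meta


def build_model(config: NetConfig, seed: int = 0) -> SegmentationModel:
    """Construct a freshly initialized model from its configuration."""
    return SegmentationModel(config, seed=seed)
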