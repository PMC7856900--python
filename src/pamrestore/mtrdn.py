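"""Multitask residual dense network (MT-RDN) for dual-wavelength OR-PAM restoration.

The model has three subnetworks, each a residual dense network (RDN):
subnetwork 1 restores and upsamples the 532 nm channel, subnetwork 2 the
560 nm channel, and subnetwork 3 fuses the two restored channels (at full
resolution, scale 1) into a vessel-enhanced product.  Training supervises
all three outputs at once with a weighted mean-absolute-error loss, so
denoising, super-resolution and vascular enhancement are learned jointly.

An RDN comprises shallow feature extraction (two convolutions), a chain of
residual dense blocks (densely connected conv+ReLU stages with growth G,
a 1x1 local-fusion convolution and a local residual), global feature
fusion over the concatenated block outputs, a global residual back to the
first shallow feature map, sub-pixel (pixel-shuffle) upsampling, and a
final reconstruction convolution.  It is fully convolutional: any input
of at least 8x8 pixels is accepted and the output is exactly `scale`
times larger along each axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = ["RDNConfig", "RDN", "MTRDN", "multitask_loss", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class RDNConfig:
    """Architecture hyperparameters of one residual dense subnetwork.

    Attributes
    ----------
    n_blocks : number of residual dense blocks (D).
    convs_per_block : densely connected conv stages per block (C).
    growth : channels added by each dense stage (G).
    base_channels : width of the trunk feature maps (G0).
    scale : integer upsampling factor (1, 2 or 4).
    in_channels, out_channels : image channels at input / output.
    """

    n_blocks: int = 4
    convs_per_block: int = 4
    growth: int = 16
    base_channels: int = 32
    scale: int = 1
    in_channels: int = 1
    out_channels: int = 1

    def __post_init__(self) -> None:
        for name in ("n_blocks", "convs_per_block", "growth", "base_channels", "in_channels", "out_channels"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if self.scale not in (1, 2, 4):
            raise ValueError("scale must be one of {1, 2, 4}")

    def n_parameters(self) -> int:
        """Total learnable parameter count (weights + biases), closed form."""
        d, c, g, g0 = self.n_blocks, self.convs_per_block, self.growth, self.base_channels
        total = 9 * self.in_channels * g0 + g0           # SFE conv 1
        total += 9 * g0 * g0 + g0                        # SFE conv 2
        for _ in range(d):
            for j in range(c):
                total += 9 * (g0 + j * g) * g + g        # dense stages
            total += (g0 + c * g) * g0 + g0              # 1x1 local fusion
        total += d * g0 * g0 + g0                        # 1x1 global fusion
        total += 9 * g0 * g0 + g0                        # global fusion conv
        up = self.out_channels * self.scale**2
        total += 9 * g0 * up + up                        # upsampling conv
        total += 9 * self.out_channels * self.out_channels + self.out_channels
        return total


def _he_conv(rng: np.random.Generator, out_ch: int, in_ch: int, k: int) -> nn.Tensor:
    std = np.sqrt(2.0 / (in_ch * k * k))
    w = rng.normal(0.0, std, size=(k, k, in_ch, out_ch)).astype(np.float32)
    return nn.Tensor(w, requires_grad=True)


class RDN:
    """One residual dense network; parameters live in ``self.params`` (ordered dict)."""

    def __init__(self, config: RDNConfig, rng: np.random.Generator | None = None):
        self.config = config
        rng = rng if rng is not None else np.random.default_rng(0)
        g0, g = config.base_channels, config.growth
        p: dict[str, nn.Tensor] = {}

        def conv_param(name: str, out_ch: int, in_ch: int, k: int, gain: float = 1.0) -> None:
            w = _he_conv(rng, out_ch, in_ch, k)
            w.data *= np.float32(gain)
            p[f"{name}.w"] = w
            p[f"{name}.b"] = nn.Tensor(np.zeros(out_ch, np.float32), requires_grad=True)

        # Fusion and reconstruction layers start at reduced scale (0.2x He)
        # so the residual trunk is near-identity at initialization; plain
        # He init lets variance pile up across the dense blocks and the
        # first iterations are spent recovering from huge outputs.
        damp = 0.2

        conv_param("sfe1", g0, config.in_channels, 3)
        conv_param("sfe2", g0, g0, 3)
        for d in range(config.n_blocks):
            for c in range(config.convs_per_block):
                conv_param(f"block{d}.conv{c}", g, g0 + c * g, 3)
            conv_param(f"block{d}.lff", g0, g0 + config.convs_per_block * g, 1, gain=damp)
        conv_param("gff1", g0, config.n_blocks * g0, 1, gain=damp)
        conv_param("gff2", g0, g0, 3, gain=damp)
        conv_param("up", config.out_channels * config.scale**2, g0, 3, gain=damp)
        conv_param("final", config.out_channels, config.out_channels, 3, gain=damp)
        self.params = p

    def parameters(self) -> list[nn.Tensor]:
        return list(self.params.values())

    def n_parameters(self) -> int:
        return int(sum(t.data.size for t in self.params.values()))

    def _c(self, name: str, x: nn.Tensor) -> nn.Tensor:
        return nn.conv2d(x, self.params[f"{name}.w"], self.params[f"{name}.b"])

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        cfg = self.config
        if x.data.ndim != 4 or x.data.shape[-1] != cfg.in_channels:
            raise ValueError(f"expected (N,H,W,{cfg.in_channels}) input, got {x.data.shape}")
        if min(x.data.shape[1:3]) < 8:
            raise ValueError("input must be at least 8x8 pixels")
        f_shallow = self._c("sfe1", x)
        feat = self._c("sfe2", f_shallow)
        block_outs = []
        for d in range(cfg.n_blocks):
            state = feat
            for c in range(cfg.convs_per_block):
                out = nn.relu(self._c(f"block{d}.conv{c}", state))
                state = nn.concat([state, out])
            feat = nn.add(feat, self._c(f"block{d}.lff", state))  # local residual
            block_outs.append(feat)
        fused = self._c("gff2", self._c("gff1", nn.concat(block_outs)))
        fused = nn.add(fused, f_shallow)  # global residual
        up = self._c("up", fused)
        if cfg.scale > 1:
            up = nn.pixel_shuffle(up, cfg.scale)
        return self._c("final", up)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return self.forward(x)


def multitask_loss(
    outputs: tuple[np.ndarray, np.ndarray, np.ndarray],
    ground_truths: tuple[np.ndarray, np.ndarray, np.ndarray],
    weights: tuple[float, float, float],
) -> float:
    """Weighted multisupervised loss: sum_i w_i * MAE(output_i, gt_i).

    Weights are normalized to sum to 1 before use; all must be
    non-negative and at least one positive.
    """
    w = _normalize_weights(weights)
    total = 0.0
    for out, gt, wi in zip(outputs, ground_truths, w):
        out = np.asarray(out, dtype=np.float64)
        gt = np.asarray(gt, dtype=np.float64)
        if out.shape != gt.shape:
            raise ValueError(f"output/ground-truth shape mismatch: {out.shape} vs {gt.shape}")
        total += wi * np.abs(out - gt).mean()
    return float(total)


def _normalize_weights(weights) -> np.ndarray:
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (3,) or np.any(w < 0):
        raise ValueError("weights must be three non-negative numbers")
    s = w.sum()
    if s <= 0:
        raise ValueError("at least one loss weight must be positive")
    return w / s


class MTRDN:
    """The three-subnetwork model.

    Subnetworks 1 and 2 share one architecture (single input channel,
    upsampling by the acquisition undersampling factor); subnetwork 3
    takes the channel-concatenation of their outputs at full resolution
    (two input channels, scale 1).
    """

    def __init__(
        self,
        scale: int = 2,
        n_blocks: int = 4,
        convs_per_block: int = 4,
        growth: int = 16,
        base_channels: int = 32,
        loss_weights: tuple[float, float, float] = (0.25, 0.25, 0.5),
        seed: int = 0,
    ):
        common = dict(
            n_blocks=n_blocks,
            convs_per_block=convs_per_block,
            growth=growth,
            base_channels=base_channels,
        )
        cfg12 = RDNConfig(scale=scale, in_channels=1, out_channels=1, **common)
        cfg3 = RDNConfig(scale=1, in_channels=2, out_channels=1, **common)
        ss = np.random.SeedSequence(seed).spawn(3)
        self.subnet1 = RDN(cfg12, np.random.default_rng(ss[0]))
        self.subnet2 = RDN(cfg12, np.random.default_rng(ss[1]))
        self.subnet3 = RDN(cfg3, np.random.default_rng(ss[2]))
        self.loss_weights = tuple(float(v) for v in _normalize_weights(loss_weights))
        self.scale = int(scale)
        self.seed = int(seed)

    # -- forward -----------------------------------------------------------
    def forward_tensors(self, input1: nn.Tensor, input2: nn.Tensor):
        if input1.data.shape != input2.data.shape:
            raise ValueError("the two wavelength channels must have identical shape")
        out1 = self.subnet1(input1)
        out2 = self.subnet2(input2)
        out3 = self.subnet3(nn.concat([out1, out2]))
        return out1, out2, out3

    def forward(self, input1: np.ndarray, input2: np.ndarray):
        """Run the three subnetworks on a pair of 2-D images (numpy in/out)."""
        t1 = nn.Tensor(np.asarray(input1, np.float32)[None, :, :, None])
        t2 = nn.Tensor(np.asarray(input2, np.float32)[None, :, :, None])
        o1, o2, o3 = self.forward_tensors(t1, t2)
        return o1.data[0, :, :, 0], o2.data[0, :, :, 0], o3.data[0, :, :, 0]

    def parameters(self) -> list[nn.Tensor]:
        return self.subnet1.parameters() + self.subnet2.parameters() + self.subnet3.parameters()

    def n_parameters(self) -> int:
        return sum(t.data.size for t in self.parameters())

    # -- loss (graph form, used by the training loop) ----------------------
    def loss_tensor(self, outputs, gts) -> nn.Tensor:
        terms = [
            nn.scale(nn.mae(o, g), w)
            for o, g, w in zip(outputs, gts, self.loss_weights)
        ]
        return nn.add_scalars(terms)

    # -- configuration -----------------------------------------------------
    def get_config(self) -> dict:
        cfg = self.subnet1.config
        return {
            "scale": self.scale,
            "n_blocks": cfg.n_blocks,
            "convs_per_block": cfg.convs_per_block,
            "growth": cfg.growth,
            "base_channels": cfg.base_channels,
            "loss_weights": list(self.loss_weights),
            "seed": self.seed,
        }


def save_checkpoint(model: MTRDN, path) -> None:
    """Serialize model weights plus JSON-encoded config into one ``.npz`` file."""
    arrays = {"__config__": np.frombuffer(json.dumps(model.get_config()).encode(), dtype=np.uint8)}
    for i, net in enumerate((model.subnet1, model.subnet2, model.subnet3), start=1):
        for name, t in net.params.items():
            arrays[f"subnet{i}/{name}"] = t.data
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> MTRDN:
    with np.load(path) as npz:
        cfg = json.loads(bytes(npz["__config__"]).decode())
        model = MTRDN(**{k: (tuple(v) if k == "loss_weights" else v) for k, v in cfg.items()})
        for i, net in enumerate((model.subnet1, model.subnet2, model.subnet3), start=1):
            for name, t in net.params.items():
                t.data = npz[f"subnet{i}/{name}"].astype(np.float32)
    return model
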