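"""Encoder / dual-decoder segmentation network.

One encoder of residual convolution blocks (conv -> batch-norm -> SELU with
an additive skip, x2 spatial downsampling per level) feeds two independent,
mirrored decoders in which transpose convolutions undo the downsampling:

* the **seed branch** predicts one seediness map per class, squashed to
  [0, 1] with a logistic;
* the **instance branch** predicts a 2-channel offset field (tanh, signed
  normalized units) and a 2-channel sigma field (exponential transform,
  strictly positive) that parameterize per-instance Gaussian margins.

Every block carries a spatial-dropout layer which can be kept stochastic at
inference time (``set_mc_dropout``) for Monte-Carlo dropout sampling; batch
norm always uses running statistics outside training so dropout is the sole
noise source.
"""

from __future__ import annotations


import json
from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Dropout2d,
    Layer,
    SELU,
    sigmoid,
)

__all__ = [
    "NetworkConfig",
    "NetworkOutput",
    "NucleiNet",
    "build_network",
    "set_mc_dropout",
    "save_checkpoint",
    "load_checkpoint",
    "config_from_yaml",
]

# raw sigma-head bias: exp(-2.4) ~ 0.091 in unit-square coordinates, a
# plausible prior margin for nuclei a few pixels across in a 64-256 px tile
_SIGMA_BIAS_INIT = -2.4


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters.

    num_levels encoder depth (x2 downsampling per level after the first);
    base_width channels at the first level, doubling per level;
    num_classes number of seed maps (one per nucleus class);
    dropout_p   spatial-dropout rate in every block (kept at inference
                for MC sampling).
    """

    num_levels: int = 5
    base_width: int = 32
    num_classes: int = 1
    input_channels: int = 3
    dropout_p: float = 0.5

    def __post_init__(self):
        if self.num_levels < 1:
            raise ValueError("num_levels must be >= 1")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if self.base_width < 1 or self.input_channels < 1:
            raise ValueError("channel counts must be positive")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")

    @property
    def divisor(self) -> int:
        """Required divisor of the input spatial size."""
        return 2 ** (self.num_levels - 1)


@dataclass
class NetworkOutput:
    """One forward pass: seed [k,H,W] in [0,1], offsets [2,H,W] signed,
    sigma [2,H,W] strictly positive."""

    seed: np.ndarray
    offsets: np.ndarray
    sigma: np.ndarray


class ResidualBlock(Layer):
    """conv(/transpose) -> BN -> SELU plus a projection skip, then dropout."""

    def __init__(self, in_ch, out_ch, stride, transpose=False, dropout_p=0.5,
                 rng=None):
        super().__init__()
        if transpose:
            self.conv = ConvTranspose2d(in_ch, out_ch, 3, stride, 1,
                                        output_padding=stride - 1, rng=rng)
        else:
            self.conv = Conv2d(in_ch, out_ch, 3, stride, 1, rng=rng)
        self.bn = BatchNorm2d(out_ch)
        self.act = SELU()
        if in_ch == out_ch and stride == 1:
            self.skip = None
        elif transpose:
            self.skip = ConvTranspose2d(in_ch, out_ch, 1, stride, 0,
                                        output_padding=stride - 1, rng=rng)
        else:
            self.skip = Conv2d(in_ch, out_ch, 1, stride, 0, rng=rng)
        self.drop = Dropout2d(dropout_p)

    def sublayers(self):
        subs = [self.conv, self.bn, self.act]
        if self.skip is not None:
            subs.append(self.skip)
        return subs

    def forward(self, x, *, training=False, rng=None, dropout_active=False):
        main = self.act.forward(
            self.bn.forward(self.conv.forward(x), training=training)
        )
        res = x if self.skip is None else self.skip.forward(x)
        return self.drop.forward(main + res, training=dropout_active, rng=rng)

    def backward(self, dy):
        dy = self.drop.backward(dy)
        dmain = self.conv.backward(self.bn.backward(self.act.backward(dy)))
        dres = dy if self.skip is None else self.skip.backward(dy)
        return dmain + dres


class NucleiNet:
    """The full network; ``forward`` returns a :class:`NetworkOutput`."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        self.mc_dropout = False
        self._rng = np.random.default_rng(seed)
        rng = np.random.default_rng(seed + 1)
        L, w, p = config.num_levels, config.base_width, config.dropout_p

        widths = [w * 2**i for i in range(L)]
        enc_in = [config.input_channels] + widths[:-1]
        self.encoder = [
            ResidualBlock(enc_in[i], widths[i], 1 if i == 0 else 2,
                          dropout_p=p, rng=rng)
            for i in range(L)
        ]

        def make_decoder():
            blocks = []
            for i in range(L - 1, 0, -1):  # upsampling blocks
                blocks.append(
                    ResidualBlock(widths[i], widths[i - 1], 2, transpose=True,
                                  dropout_p=p, rng=rng)
                )
            blocks.append(
                ResidualBlock(widths[0], widths[0], 1, transpose=True,
                              dropout_p=p, rng=rng)
            )
            return blocks

        self.seed_decoder = make_decoder()
        self.seed_head = Conv2d(widths[0], config.num_classes, 1, 1, 0, rng=rng)
        self.inst_decoder = make_decoder()
        self.inst_head = Conv2d(widths[0], 4, 1, 1, 0, rng=rng)
        # small head weights keep the initial sigma field near its prior
        # (exp of the bias) so the smooth/margin losses start well-scaled
        self.seed_head.params["w"] *= 0.05
        self.inst_head.params["w"] *= 0.05
        self.inst_head.params["b"][2:] = _SIGMA_BIAS_INIT
        self._cache = None

    # ------------------------------------------------------------------
    def layers(self):
        out = []
        for block in self.encoder + self.seed_decoder + self.inst_decoder:
            out.append(block.conv)
            out.append(block.bn)
            if block.skip is not None:
                out.append(block.skip)
        out.extend([self.seed_head, self.inst_head])
        return out

    def blocks(self):
        return self.encoder + self.seed_decoder + self.inst_decoder

    def num_parameters(self) -> int:
        return sum(v.size for l in self.layers() for v in l.params.values())

    def reseed(self, seed: int) -> None:
        """Reset the internal dropout stream (reproducible stochastic passes)."""
        self._rng = np.random.default_rng(seed)

    # ------------------------------------------------------------------
    def forward_batch(self, x: np.ndarray, training: bool = False,
                      rng: np.random.Generator | None = None):
        """Raw batched pass: x [B,3,H,W] -> (seed, offsets, sigma) arrays."""
        if x.ndim != 4 or x.shape[1] != self.config.input_channels:
            raise ValueError(
                f"expected [B,{self.config.input_channels},H,W] input, got {x.shape}"
            )
        d = self.config.divisor
        if x.shape[2] % d or x.shape[3] % d:
            raise ValueError(
                f"spatial size {x.shape[2]}x{x.shape[3]} must be divisible by {d} "
                f"(2^(num_levels-1))"
            )
        dropout_active = training or self.mc_dropout
        if dropout_active and rng is None:
            rng = self._rng

        h = x.astype(np.float64)
        for block in self.encoder:
            h = block.forward(h, training=training, rng=rng,
                              dropout_active=dropout_active)
        hs, hi = h, h
        for block in self.seed_decoder:
            hs = block.forward(hs, training=training, rng=rng,
                               dropout_active=dropout_active)
        for block in self.inst_decoder:
            hi = block.forward(hi, training=training, rng=rng,
                               dropout_active=dropout_active)
        seed_logit = self.seed_head.forward(hs)
        inst_raw = self.inst_head.forward(hi)

        seed = sigmoid(seed_logit)
        offsets = np.tanh(inst_raw[:, 0:2])
        # clip the log-sigma range: sigma in [e^-12, e^6] covers any margin
        # expressible on the unit square while preventing overflow
        sigma = np.exp(np.clip(inst_raw[:, 2:4], -12.0, 6.0))
        self._cache = (seed, offsets, sigma)
        return seed, offsets, sigma

    def backward_batch(self, dseed, doffsets, dsigma):
        """Backpropagate gradients w.r.t. (seed, offsets, sigma) outputs."""
        seed, offsets, sigma = self._cache
        dseed_logit = dseed * seed * (1.0 - seed)
        dinst = np.concatenate(
            [doffsets * (1.0 - offsets**2), dsigma * sigma], axis=1
        )
        dhs = self.seed_head.backward(dseed_logit)
        dhi = self.inst_head.backward(dinst)
        for block in reversed(self.seed_decoder):
            dhs = block.backward(dhs)
        for block in reversed(self.inst_decoder):
            dhi = block.backward(dhi)
        dh = dhs + dhi
        for block in reversed(self.encoder):
            dh = block.backward(dh)
        return dh

    def forward(self, image: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> NetworkOutput:
        """Single image [3,H,W] (or [H,W,3] RGB) -> NetworkOutput."""
        x = np.asarray(image, dtype=np.float64)
        if x.ndim == 3 and x.shape[-1] == self.config.input_channels:
            x = x.transpose(2, 0, 1)
        seed, off, sig = self.forward_batch(x[None], training=training, rng=rng)
        return NetworkOutput(seed=seed[0], offsets=off[0], sigma=sig[0])

    def zero_grad(self) -> None:
        for l in self.layers():
            l.zero_grad()

    def make_optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.layers(), lr=lr)


def build_network(config: NetworkConfig, seed: int = 0) -> NucleiNet:
    """Construct the network; identical config+seed give identical weights."""
    return NucleiNet(config, seed=seed)


def set_mc_dropout(model: NucleiNet, active: bool) -> NucleiNet:
    """Toggle inference-time dropout sampling (batch norm stays in
    running-statistics mode; dropout is the only stochastic element)."""
    model.mc_dropout = bool(active)
    return model


# ----------------------------------------------------------------------
# checkpoints and YAML config
# ----------------------------------------------------------------------

def save_checkpoint(model: NucleiNet, path) -> None:
    arrays = {}
    for i, layer in enumerate(model.layers()):
        for name, val in layer.params.items():
            arrays[f"p_{i}_{name}"] = val
        if isinstance(layer, BatchNorm2d):
            arrays[f"rm_{i}"] = layer.running_mean
            arrays[f"rv_{i}"] = layer.running_var
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> NucleiNet:
    with np.load(path) as data:
        cfg = NetworkConfig(**json.loads(bytes(data["config_json"]).decode()))
        model = NucleiNet(cfg)
        for i, layer in enumerate(model.layers()):
            for name in layer.params:
                layer.params[name] = data[f"p_{i}_{name}"].copy()
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = data[f"rm_{i}"].copy()
                layer.running_var = data[f"rv_{i}"].copy()
    return model


def config_from_yaml(path_or_stream) -> NetworkConfig:
    if isinstance(path_or_stream, (str, bytes)) or hasattr(path_or_stream, "read"):
        if hasattr(path_or_stream, "read"):
            raw = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                raw = yaml.safe_load(fh)
    else:
        raise TypeError("expected a path or stream")
    raw = raw or {}
    allowed = NetworkConfig.__dataclass_fields__.keys()
    return NetworkConfig(**{k: v for k, v in (raw.get("network") or raw).items()
                            if k in allowed})
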