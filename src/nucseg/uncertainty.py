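"""Monte-Carlo dropout sampling and predictive-variance decomposition.

With dropout kept stochastic at inference, T forward passes yield
per-pixel foreground probabilities y_t (the max-over-classes seediness)
and per-sample spreads sigma_t.  The predictive variance is

    Var = (1/T) sum_t (y_t - ybar)^2  +  (1/T) sum_t sigma_t^2

i.e. the sample variance of the MC passes (epistemic, vanishes when the
passes agree) plus the mean per-sample variance (aleatoric).  The
per-sample variance is taken as the Bernoulli variance y_t (1 - y_t) of
the predicted foreground probability.  For display the variance map is
min-max normalized per image to [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .model import NucleiNet, set_mc_dropout

__all__ = [
    "MCSampleStack",
    "MCOutputStack",
    "UncertaintyMap",
    "mc_sample",
    "mc_forward_outputs",
    "predictive_variance",
    "normalize_uncertainty",
    "write_uncertainty",
]


@dataclass
class MCSampleStack:
    """T stochastic passes: y_hat [T,H,W] in [0,1], sigma_sq [T,H,W] >= 0."""

    y_hat: np.ndarray
    sigma_sq: np.ndarray

    @property
    def T(self) -> int:
        return self.y_hat.shape[0]


@dataclass
class MCOutputStack:
    """Full raw outputs of T stochastic passes (for mean-output clustering)."""

    seed: np.ndarray      # [T, k, H, W]
    offsets: np.ndarray   # [T, 2, H, W]
    sigma: np.ndarray     # [T, 2, H, W]

    def mean_output(self):
        from .model import NetworkOutput

        return NetworkOutput(
            seed=self.seed.mean(axis=0),
            offsets=self.offsets.mean(axis=0),
            sigma=self.sigma.mean(axis=0),
        )


@dataclass
class UncertaintyMap:
    variance: np.ndarray
    normalized: np.ndarray
    epistemic: np.ndarray
    aleatoric: np.ndarray


def mc_forward_outputs(model: NucleiNet, image: np.ndarray, T: int,
                       seed: int = 0) -> MCOutputStack:
    """T dropout-stochastic passes over one image, dropout state restored."""
    if T < 1:
        raise ValueError("T must be >= 1")
    was_active = model.mc_dropout
    set_mc_dropout(model, True)
    rng = np.random.default_rng(seed)
    seeds, offs, sigs = [], [], []
    try:
        for _ in range(T):
            out = model.forward(image, training=False, rng=rng)
            seeds.append(out.seed)
            offs.append(out.offsets)
            sigs.append(out.sigma)
    finally:
        set_mc_dropout(model, was_active)
    return MCOutputStack(np.stack(seeds), np.stack(offs), np.stack(sigs))


def mc_sample(model: NucleiNet, image: np.ndarray, T: int,
              seed: int = 0) -> MCSampleStack:
    """MC-dropout stack of foreground probabilities and Bernoulli variances."""
    stack = mc_forward_outputs(model, image, T, seed=seed)
    y = stack.seed.max(axis=1)  # max over class channels -> [T,H,W]
    return MCSampleStack(y_hat=y, sigma_sq=y * (1.0 - y))


def predictive_variance(stack: MCSampleStack) -> UncertaintyMap:
    """Decompose the MC stack into epistemic + aleatoric variance per pixel."""
    t = stack.T
    ybar = stack.y_hat.mean(axis=0)
    epistemic = ((stack.y_hat - ybar) ** 2).sum(axis=0) / t
    aleatoric = stack.sigma_sq.mean(axis=0)
    variance = epistemic + aleatoric
    return UncertaintyMap(
        variance=variance,
        normalized=normalize_uncertainty(variance),
        epistemic=epistemic,
        aleatoric=aleatoric,
    )


def normalize_uncertainty(variance: np.ndarray) -> np.ndarray:
    """Per-image min-max scaling to [0,1]; constant maps become all-zero."""
    variance = np.asarray(variance, dtype=float)
    lo, hi = variance.min(), variance.max()
    if hi - lo == 0.0:
        return np.zeros_like(variance)
    return (variance - lo) / (hi - lo)


def write_uncertainty(umap: UncertaintyMap, stem, T: int, seed: int) -> None:
    """Raw variance as float32 TIFF, normalized map as 8-bit PNG, plus a
    sidecar JSON with the sampling metadata."""
    import imageio.v3 as iio
    import tifffile

    stem = str(stem)
    tifffile.imwrite(stem + "_variance.tiff",
                     umap.variance.astype(np.float32))
    iio.imwrite(stem + "_uncertainty.png",
                np.round(umap.normalized * 255).astype(np.uint8))
    with open(stem + "_uncertainty.json", "w") as fh:
        json.dump(
            {
                "T": int(T),
                "seed": int(seed),
                "mean_variance": float(umap.variance.mean()),
                "mean_epistemic": float(umap.epistemic.mean()),
                "mean_aleatoric": float(umap.aleatoric.mean()),
            },
            fh,
            indent=2,
        )
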