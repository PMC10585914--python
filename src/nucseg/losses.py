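"""Training losses for the embedding-clustering segmentation network.

Three terms, combined as  L = l_iou * L_IoU + l_seed * L_seed
+ l_smooth * L_smooth  with default weights (1, 1, 10):

* **L_IoU** — for every ground-truth instance, build the Gaussian-margin
  probability field phi_k from the predicted offsets and the instance-mean
  predicted sigma, with the true centroid as centre, and score the soft
  mask against the binary instance mask through the Lovász-hinge
  relaxation of the Jaccard loss (logits 2*phi - 1); averaged over
  instances.
* **L_seed** — squared-error regression of the seed map towards the
  (gradient-detached) phi value of each foreground pixel's own instance,
  and towards 0 on background; mean over all pixels, class-wise.
* **L_smooth** — per instance, the squared deviation of the per-pixel
  sigma prediction from the instance mean (per-pixel mean, summed over the
  two sigma channels), pulling sigma constant within each instance.

During training the instance centres and margins come from the ground
truth (a differentiable teacher); clustering itself is never
differentiated.  Analytic gradients w.r.t. the three network outputs are
returned alongside the scalar terms and are verified against finite
differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import compute_embeddings

__all__ = [
    "LossWeights",
    "LossReport",
    "lovasz_grad",
    "lovasz_hinge",
    "iou_loss",
    "seed_loss",
    "smooth_loss",
    "combined_loss",
    "embedding_loss_with_grads",
]


@dataclass(frozen=True)
class LossWeights:
    lambda_iou: float = 1.0
    lambda_seed: float = 1.0
    lambda_smooth: float = 10.0

    def __post_init__(self):
        if min(self.lambda_iou, self.lambda_seed, self.lambda_smooth) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class LossReport:
    iou_term: float
    seed_term: float
    smooth_term: float
    total: float


# ----------------------------------------------------------------------
# Lovász hinge (binary Jaccard surrogate)
# ----------------------------------------------------------------------

def lovasz_grad(gt_sorted: np.ndarray) -> np.ndarray:
    """Gradient of the Lovász extension of the Jaccard loss w.r.t. the
    sorted error vector (Berman et al.'s construction)."""
    gts = gt_sorted.sum()
    intersection = gts - np.cumsum(gt_sorted)
    union = gts + np.cumsum(1.0 - gt_sorted)
    jaccard = 1.0 - intersection / union
    if len(gt_sorted) > 1:
        jaccard[1:] = jaccard[1:] - jaccard[:-1]
    return jaccard


def lovasz_hinge(logits: np.ndarray, labels: np.ndarray,
                 return_grad: bool = False):
    """Binary Lovász hinge on flat logits vs {0,1} labels.

    loss = <relu(errors_sorted), lovasz_grad(labels_sorted)> with
    errors = 1 - logits * sign, sorted in decreasing order.
    """
    logits = np.asarray(logits, dtype=float).ravel()
    labels = np.asarray(labels, dtype=float).ravel()
    if logits.size == 0:
        return (0.0, np.zeros(0)) if return_grad else 0.0
    signs = 2.0 * labels - 1.0
    errors = 1.0 - logits * signs
    perm = np.argsort(-errors, kind="stable")
    errors_sorted = errors[perm]
    grad_vec = lovasz_grad(labels[perm])
    loss = float(np.dot(np.maximum(errors_sorted, 0.0), grad_vec))
    if not return_grad:
        return loss
    derr_sorted = grad_vec * (errors_sorted > 0)
    derr = np.zeros_like(errors)
    derr[perm] = derr_sorted
    return loss, -signs * derr


# ----------------------------------------------------------------------
# phi construction shared by the IoU and seed terms
# ----------------------------------------------------------------------

def _instances_of(truth: np.ndarray):
    ids = np.unique(truth)
    return ids[ids > 0]


def _phi_for_instance(emb, coords, sigma, mask):
    """phi field for one ground-truth instance.

    Centre = true centroid of normalized coordinates; per-instance sigma =
    mean of the predicted sigma channels over the instance's pixels.
    Returns (phi, cx, cy, sx, sy).
    """
    cx = coords[0][mask].mean()
    cy = coords[1][mask].mean()
    sx = sigma[0][mask].mean()
    sy = sigma[1][mask].mean()
    phi = np.exp(
        -((emb[0] - cx) ** 2) / (2.0 * sx**2)
        - ((emb[1] - cy) ** 2) / (2.0 * sy**2)
    )
    return phi, cx, cy, sx, sy


def iou_loss(output, coords, truth) -> float:
    """Mean Lovász-hinge IoU surrogate over ground-truth instances."""
    return _core(output, coords, truth, want=("iou",))[0].iou_term


def seed_loss(seed, output, coords, truth) -> float:
    out = _SeedView(seed, output)
    return _core(out, coords, truth, want=("seed",))[0].seed_term


def smooth_loss(output, truth) -> float:
    coords = _unit_coords(truth.shape)
    return _core(output, coords, truth, want=("smooth",))[0].smooth_term


class _SeedView:
    """Wrap a replacement seed map around an existing NetworkOutput."""

    def __init__(self, seed, output):
        self.seed = np.asarray(seed, dtype=float)
        if self.seed.ndim == 2:
            self.seed = self.seed[None]
        self.offsets = output.offsets
        self.sigma = output.sigma


def _unit_coords(shape):
    from .clustering import make_coordinate_map

    return make_coordinate_map(*shape)


def combined_loss(weights: LossWeights, iou_term: float, seed_term: float,
                  smooth_term: float) -> LossReport:
    """Weighted combination; the report satisfies
    total = l_iou*iou + l_seed*seed + l_smooth*smooth exactly."""
    for t in (iou_term, seed_term, smooth_term):
        if not np.isfinite(t):
            raise ValueError("loss terms must be finite")
    total = (
        weights.lambda_iou * iou_term
        + weights.lambda_seed * seed_term
        + weights.lambda_smooth * smooth_term
    )
    return LossReport(float(iou_term), float(seed_term), float(smooth_term),
                      float(total))


# ----------------------------------------------------------------------
# full loss with gradients (single image)
# ----------------------------------------------------------------------

def _core(output, coords, truth, want=("iou", "seed", "smooth"),
          weights: LossWeights = LossWeights(), class_of=None):
    """Compute the requested loss terms (values only) for one image.

    output carries seed [k,H,W], offsets [2,H,W], sigma [2,H,W]; truth is an
    integer instance label map [H,W]; class_of maps instance id -> class id
    (defaults to class 1 for every instance).
    """
    seed = np.asarray(output.seed, dtype=float)
    if seed.ndim == 2:
        seed = seed[None]
    sigma = np.asarray(output.sigma, dtype=float)
    truth = np.asarray(truth)
    k = seed.shape[0]

    emb = compute_embeddings(output.offsets, coords)
    ids = _instances_of(truth)
    n_inst = len(ids)

    iou_term = 0.0
    smooth_term = 0.0
    # seed regression target: phi of own instance on foreground, 0 elsewhere
    seed_target = np.zeros_like(seed)

    for inst_id in ids:
        mask = truth == inst_id
        if "iou" in want or "seed" in want:
            phi, *_ = _phi_for_instance(emb, coords, sigma, mask)
            if "seed" in want:
                cls = (0 if class_of is None
                       else int(class_of.get(int(inst_id), 1)) - 1)
                cls = min(max(cls, 0), k - 1)
                seed_target[cls][mask] = phi[mask]
            if "iou" in want:
                iou_term += lovasz_hinge(2.0 * phi - 1.0, mask) / n_inst
        if "smooth" in want:
            devx = sigma[0][mask] - sigma[0][mask].mean()
            devy = sigma[1][mask] - sigma[1][mask].mean()
            smooth_term += float((devx**2).mean() + (devy**2).mean())
    if n_inst > 0 and "smooth" in want:
        smooth_term /= n_inst

    seed_term = 0.0
    if "seed" in want:
        seed_term = float(((seed - seed_target) ** 2).mean())

    return combined_loss(weights, iou_term, seed_term, smooth_term), None


def embedding_loss_with_grads(output, coords, truth,
                              weights: LossWeights = LossWeights(),
                              class_of=None):
    """Loss report plus gradients (d_seed, d_offsets, d_sigma) of the
    weighted total w.r.t. the network outputs, for one image."""
    seed = np.asarray(output.seed, dtype=float)
    if seed.ndim == 2:
        seed = seed[None]
    offsets = np.asarray(output.offsets, dtype=float)
    sigma = np.asarray(output.sigma, dtype=float)
    truth = np.asarray(truth)
    k = seed.shape[0]
    h, w = truth.shape

    emb = compute_embeddings(offsets, coords)
    ids = _instances_of(truth)
    n_inst = len(ids)

    d_seed = np.zeros_like(seed)
    d_off = np.zeros_like(offsets)       # gradient of L_IoU
    d_sigma_iou = np.zeros_like(sigma)   # gradient of L_IoU
    d_sigma_smooth = np.zeros_like(sigma)

    iou_term = 0.0
    smooth_term = 0.0
    seed_target = np.zeros_like(seed)

    for inst_id in ids:
        mask = truth == inst_id
        n_k = int(mask.sum())
        phi, cx, cy, sx, sy = _phi_for_instance(emb, coords, sigma, mask)

        cls = 0 if class_of is None else int(class_of.get(int(inst_id), 1)) - 1
        cls = min(max(cls, 0), k - 1)
        seed_target[cls][mask] = phi[mask]

        loss_k, dlogit = lovasz_hinge(2.0 * phi - 1.0, mask, return_grad=True)
        iou_term += loss_k / n_inst
        dphi = (2.0 * dlogit / n_inst).reshape(h, w)
        d_off[0] += dphi * phi * (-(emb[0] - cx) / sx**2)
        d_off[1] += dphi * phi * (-(emb[1] - cy) / sy**2)
        gsx = float(np.sum(dphi * phi * ((emb[0] - cx) ** 2) / sx**3))
        gsy = float(np.sum(dphi * phi * ((emb[1] - cy) ** 2) / sy**3))
        d_sigma_iou[0][mask] += gsx / n_k
        d_sigma_iou[1][mask] += gsy / n_k

        mxv = sigma[0][mask].mean()
        myv = sigma[1][mask].mean()
        devx = sigma[0][mask] - mxv
        devy = sigma[1][mask] - myv
        smooth_term += float((devx**2).mean() + (devy**2).mean())
        d_sigma_smooth[0][mask] += 2.0 * devx / (n_k * max(n_inst, 1))
        d_sigma_smooth[1][mask] += 2.0 * devy / (n_k * max(n_inst, 1))

    if n_inst > 0:
        smooth_term /= n_inst

    diff = seed - seed_target
    seed_term = float((diff**2).mean())
    d_seed = 2.0 * diff / diff.size

    report = combined_loss(weights, iou_term, seed_term, smooth_term)
    g_seed = weights.lambda_seed * d_seed
    g_off = weights.lambda_iou * d_off
    g_sigma = (
        weights.lambda_iou * d_sigma_iou
        + weights.lambda_smooth * d_sigma_smooth
    )
    return report, (g_seed, g_off, g_sigma)
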