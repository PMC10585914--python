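"""Structure-preserving (Vahadane-style) H&E stain normalization.

RGB intensities are converted to optical density through the Beer-Lambert
law, OD = -log10((I+1)/(I0+1)), and tissue-pixel OD vectors are factorized
as OD ~ C.B with a sparse non-negative 2-row basis B (hematoxylin and
eosin optical-density directions, unit Euclidean norm) and non-negative
concentrations C.  A source image is normalized to a reference by
rescaling its concentration channels to the reference's robust maxima and
recombining with the reference basis.

The factorization is an alternating multiplicative-update scheme (classic
Lee-Seung rules with an L1 penalty on the concentrations, followed by
projection of the basis rows onto the non-negative unit sphere); the
data-fit objective decreases monotonically over iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StainModel",
    "StainEstimationError",
    "rgb_to_od",
    "od_to_rgb",
    "estimate_stain_model",
    "normalize_to_reference",
]

_EPS = 1e-10

# canonical H&E optical-density directions (Ruifrok-style), unit norm;
# used to warm-start the factorization and to complete a degenerate basis
CANONICAL_HE_BASIS = np.array(
    [
        [0.650, 0.704, 0.286],
        [0.072, 0.990, 0.105],
    ]
)
CANONICAL_HE_BASIS = CANONICAL_HE_BASIS / np.linalg.norm(
    CANONICAL_HE_BASIS, axis=1, keepdims=True
)


class StainEstimationError(ValueError):
    """Raised when an image has too little tissue to fit a stain model."""


@dataclass
class StainModel:
    """basis: [2,3] unit-norm OD vectors (row 0 hematoxylin, row 1 eosin);
    conc_scale: per-stain 99th-percentile concentration."""

    basis: np.ndarray
    conc_scale: np.ndarray


def rgb_to_od(image: np.ndarray, background_intensity: float = 255.0) -> np.ndarray:
    """Beer-Lambert optical density; OD = 0 at full background intensity."""
    img = np.asarray(image, dtype=float)
    return -np.log10((img + 1.0) / (background_intensity + 1.0))


def od_to_rgb(od: np.ndarray, background_intensity: float = 255.0) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, clipped to the valid intensity range."""
    img = (background_intensity + 1.0) * np.power(10.0, -np.asarray(od)) - 1.0
    return np.clip(img, 0.0, background_intensity)


def _angle_extreme_init(od: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Initial stain directions from the robust angular extremes of the OD
    cloud in its leading singular plane (every pixel is a non-negative
    mixture of the two stains, so the stains bound the cloud)."""
    _, _, vt = np.linalg.svd(od, full_matrices=False)
    plane = vt[:2]
    if plane[0].sum() < 0:
        plane[0] = -plane[0]
    proj = od @ plane.T
    ang = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(ang, [alpha, 100.0 - alpha])
    b = np.stack(
        [
            np.cos(lo) * plane[0] + np.sin(lo) * plane[1],
            np.cos(hi) * plane[0] + np.sin(hi) * plane[1],
        ]
    )
    b = np.maximum(b, _EPS)
    return b / np.linalg.norm(b, axis=1, keepdims=True)


def _nmf_sparse(od: np.ndarray, n_iter: int, sparsity: float,
                rng: np.random.Generator, trace: list | None = None):
    """Multiplicative updates for OD ~ C.B, C >= 0, B >= 0, L1 on C."""
    n, d = od.shape
    # angle-extreme initialization lands in the correct basin; matching
    # non-negative least-squares concentrations keep the first updates
    # consistent, and the sparse multiplicative updates refine both factors
    b = _angle_extreme_init(od)
    c = np.maximum(stain_concentrations(od, b), 1e-3)
    for _ in range(n_iter):
        # concentration update with L1 shrinkage
        c *= (od @ b.T) / (c @ b @ b.T + sparsity + _EPS)
        # basis update
        b *= (c.T @ od) / (c.T @ c @ b + _EPS)
        if trace is not None:
            # the objective the alternating updates descend on:
            # 0.5 * ||OD - C.B||_F^2 + sparsity * sum(C)
            trace.append(
                0.5 * float(np.sum((od - c @ b) ** 2))
                + sparsity * float(c.sum())
            )
    return c, b


def estimate_stain_model(
    image: np.ndarray,
    background_intensity: float = 255.0,
    od_threshold: float = 0.15,
    min_tissue_pixels: int = 100,
    max_pixels: int = 20000,
    n_iter: int = 200,
    sparsity: float = 0.05,
    seed: int = 0,
    residual_trace: list | None = None,
) -> StainModel:
    """Fit the 2-stain model to the tissue pixels of an RGB image.

    Rows are ordered so the more blue-absorbing vector (larger OD in the
    blue channel) is hematoxylin.  Deterministic for a fixed seed.
    """
    od = rgb_to_od(image, background_intensity).reshape(-1, 3)
    tissue = od[np.linalg.norm(od, axis=1) > od_threshold]
    if tissue.shape[0] < min_tissue_pixels:
        raise StainEstimationError(
            f"only {tissue.shape[0]} tissue pixels above OD {od_threshold}; "
            f"need at least {min_tissue_pixels}"
        )
    rng = np.random.default_rng(seed)
    if tissue.shape[0] > max_pixels:
        idx = rng.choice(tissue.shape[0], max_pixels, replace=False)
        tissue = tissue[idx]
    conc, basis = _nmf_sparse(tissue, n_iter, sparsity, rng,
                              trace=residual_trace)
    norms = np.linalg.norm(basis, axis=1)
    if np.any(norms < _EPS):
        raise StainEstimationError("degenerate stain basis")
    basis = basis / norms[:, None]
    conc = conc * norms[None, :]
    # single-stain (collinear) images: keep the dominant direction, replace
    # the redundant row with the canonical vector of the missing stain, and
    # recompute concentrations against the repaired basis
    if float(basis[0] @ basis[1]) > 0.95:
        dominant = basis[np.argmax(conc.sum(axis=0))]
        is_hema = float(dominant @ CANONICAL_HE_BASIS[0]) >= float(
            dominant @ CANONICAL_HE_BASIS[1]
        )
        basis = np.stack(
            [dominant, CANONICAL_HE_BASIS[1]]
            if is_hema
            else [CANONICAL_HE_BASIS[0], dominant]
        )
        conc = stain_concentrations(tissue, basis)
    # hematoxylin = the more blue-absorbing row
    if basis[0, 2] < basis[1, 2]:
        basis = basis[::-1].copy()
        conc = conc[:, ::-1]
    scale = np.percentile(conc, 99, axis=0)
    return StainModel(basis=basis, conc_scale=np.maximum(scale, _EPS))


def stain_concentrations(od_flat: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Non-negative least-squares concentrations for a fixed 2-row basis.

    Exact for two components: solve unconstrained, and where a component
    goes negative re-solve the remaining single-stain problem in closed
    form.
    """
    g = basis @ basis.T
    c = od_flat @ basis.T @ np.linalg.inv(g)
    neg0 = c[:, 0] < 0
    neg1 = c[:, 1] < 0
    # clamp one component to zero, project onto the other stain alone
    c[neg0, 0] = 0.0
    c[neg0, 1] = np.maximum(od_flat[neg0] @ basis[1] / g[1, 1], 0.0)
    c[neg1, 1] = 0.0
    c[neg1, 0] = np.maximum(od_flat[neg1] @ basis[0] / g[0, 0], 0.0)
    return np.maximum(c, 0.0)


def normalize_to_reference(
    source_image: np.ndarray,
    reference: StainModel,
    background_intensity: float = 255.0,
    source_model: StainModel | None = None,
    **estimate_kwargs,
) -> np.ndarray:
    """Map a source image into the reference's stain space."""
    if source_model is None:
        source_model = estimate_stain_model(
            source_image, background_intensity, **estimate_kwargs
        )
    shape = np.asarray(source_image).shape
    od = rgb_to_od(source_image, background_intensity).reshape(-1, 3)
    conc = stain_concentrations(od, source_model.basis)
    conc = conc * (reference.conc_scale / source_model.conc_scale)[None, :]
    od_norm = (conc @ reference.basis).reshape(shape)
    return od_to_rgb(od_norm, background_intensity)
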