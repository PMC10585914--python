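"""Pixel embeddings, Gaussian margins and sequential clustering.

Each pixel i carries a 2-D spatial embedding ``e_i = x_i + o_i`` built from
its normalized coordinate ``x_i`` and a learned offset ``o_i`` that should
point at the centroid ``C_k`` of its nucleus.  An instance-specific
elliptical Gaussian

    phi_k(e_i) = exp(-(e_x - C_kx)^2 / (2 sigma_kx^2)
                 -(e_y - C_ky)^2 / (2 sigma_ky^2))

converts embedding-to-centre distance into a membership probability; a
pixel joins instance k when phi_k(e_i) >= 0.5.  At inference, instances are
recovered greedily: repeatedly pick the unassigned pixel with the highest
seediness, take its embedding as the centre and its sigma channels as the
margin, and absorb every unassigned pixel with phi >= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import NetworkOutput

__all__ = [
    "InstanceCenter",
    "ClusterParams",
    "make_coordinate_map",
    "compute_embeddings",
    "instance_centroid",
    "gaussian_margin",
    "assign_pixel",
    "sequential_cluster",
    "relabel_contiguous",
    "centers_to_csv",
]


@dataclass
class InstanceCenter:
    """One recovered instance: centre, margins and the seed that found it."""

    cx: float
    cy: float
    sigma_x: float
    sigma_y: float
    seed_value: float
    class_id: int = 1


@dataclass(frozen=True)
class ClusterParams:
    seed_threshold: float = 0.5
    min_pixels: int = 16
    refine: bool = False  # re-estimate centre/sigma as means over the cluster


def make_coordinate_map(height: int, width: int) -> np.ndarray:
    """Normalized pixel-centre coordinates, shape [2, H, W].

    Channel 0 is x = (col + 0.5)/width, channel 1 is y = (row + 0.5)/height;
    all values lie strictly inside (0, 1).
    """
    if height < 1 or width < 1:
        raise ValueError("height and width must be >= 1")
    xs = (np.arange(width) + 0.5) / width
    ys = (np.arange(height) + 0.5) / height
    coords = np.empty((2, height, width))
    coords[0] = xs[None, :]
    coords[1] = ys[:, None]
    return coords


def compute_embeddings(offsets: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """e = x + o, elementwise; embeddings may leave the unit square."""
    offsets = np.asarray(offsets, dtype=float)
    if offsets.shape != coords.shape:
        raise ValueError(
            f"offsets shape {offsets.shape} != coords shape {coords.shape}"
        )
    return coords + offsets


def instance_centroid(labels: np.ndarray, coords: np.ndarray,
                      instance_id: int) -> tuple[float, float]:
    """Mean normalized coordinate over the instance's pixels (C_k)."""
    mask = labels == instance_id
    if instance_id < 1 or not mask.any():
        raise ValueError(f"instance id {instance_id} not present in label map")
    return float(coords[0][mask].mean()), float(coords[1][mask].mean())


def gaussian_margin(emb_point, center: InstanceCenter) -> float:
    """phi_k for a single embedding point; in (0, 1]."""
    if center.sigma_x <= 0 or center.sigma_y <= 0:
        raise ValueError("sigma must be strictly positive")
    ex, ey = emb_point
    return float(
        np.exp(
            -((ex - center.cx) ** 2) / (2.0 * center.sigma_x**2)
            - ((ey - center.cy) ** 2) / (2.0 * center.sigma_y**2)
        )
    )


def assign_pixel(phi: float) -> bool:
    """Membership rule: the boundary value 0.5 is assigned to the instance."""
    return phi >= 0.5


def _phi_field(emb, cx, cy, sx, sy):
    return np.exp(
        -((emb[0] - cx) ** 2) / (2.0 * sx**2)
        - ((emb[1] - cy) ** 2) / (2.0 * sy**2)
    )


def _cluster_single_class(seed, emb, sigma, params: ClusterParams):
    h, w = seed.shape
    labels = np.zeros((h, w), dtype=np.int32)
    consumed = np.zeros((h, w), dtype=bool)  # rejected seed pixels
    centers: list[InstanceCenter] = []
    next_label = 1
    while True:
        cand = (labels == 0) & ~consumed & (seed >= params.seed_threshold)
        if not cand.any():
            break
        masked = np.where(cand, seed, -np.inf)
        flat = int(np.argmax(masked))  # row-major first-max tie break
        r, c = divmod(flat, w)
        cx, cy = emb[0, r, c], emb[1, r, c]
        sx, sy = sigma[0, r, c], sigma[1, r, c]
        phi = _phi_field(emb, cx, cy, sx, sy)
        member = (labels == 0) & (phi >= 0.5)
        n_member = int(member.sum())
        if n_member < params.min_pixels:
            # too small: pixels stay unassigned, seed pixel can't lead again
            consumed[r, c] = True
            continue
        if params.refine:
            cx, cy = emb[0][member].mean(), emb[1][member].mean()
            sx, sy = sigma[0][member].mean(), sigma[1][member].mean()
            phi = _phi_field(emb, cx, cy, sx, sy)
            member = (labels == 0) & (phi >= 0.5)
            if int(member.sum()) < params.min_pixels:
                consumed[r, c] = True
                continue
        labels[member] = next_label
        centers.append(
            InstanceCenter(float(cx), float(cy), float(sx), float(sy),
                           float(seed[r, c]))
        )
        next_label += 1
    return labels, centers


def sequential_cluster(
    output: NetworkOutput,
    coords: np.ndarray,
    params: ClusterParams = ClusterParams(),
) -> tuple[np.ndarray, list[InstanceCenter]]:
    """Greedy instance recovery from one network output.

    Multi-class outputs are clustered per class seed map independently;
    conflicting claims are resolved in favour of the higher phi value.
    Labels are issued in discovery order 1, 2, 3, ...
    """
    emb = compute_embeddings(output.offsets, coords)
    k = output.seed.shape[0]
    if k == 1:
        labels, centers = _cluster_single_class(
            output.seed[0], emb, output.sigma, params
        )
        for c in centers:
            c.class_id = 1
        return labels, centers

    h, w = output.seed.shape[1:]
    labels = np.zeros((h, w), dtype=np.int32)
    best_phi = np.zeros((h, w))
    centers: list[InstanceCenter] = []
    next_label = 1
    for cls in range(k):
        cls_labels, cls_centers = _cluster_single_class(
            output.seed[cls], emb, output.sigma, params
        )
        for local_id, center in enumerate(cls_centers, start=1):
            member = cls_labels == local_id
            phi = _phi_field(emb, center.cx, center.cy,
                             center.sigma_x, center.sigma_y)
            claim = member & ((labels == 0) | (phi > best_phi))
            if int(claim.sum()) < params.min_pixels:
                continue
            labels[claim] = next_label
            best_phi[claim] = phi[claim]
            center.class_id = cls + 1
            centers.append(center)
            next_label += 1
    labels, centers = relabel_contiguous(labels, centers)
    return labels, centers


def relabel_contiguous(labels: np.ndarray, centers=None):
    """Force labels to be contiguous 1..K with every instance non-empty."""
    present = np.unique(labels)
    present = present[present > 0]
    out = np.zeros_like(labels)
    kept = []
    for new_id, old_id in enumerate(present, start=1):
        out[labels == old_id] = new_id
        if centers is not None and old_id - 1 < len(centers):
            kept.append(centers[old_id - 1])
    if centers is None:
        return out
    return out, kept


def centers_to_csv(centers: list[InstanceCenter], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "id": i + 1,
                "cx": c.cx,
                "cy": c.cy,
                "sigma_x": c.sigma_x,
                "sigma_y": c.sigma_y,
                "seed": c.seed_value,
                "class_id": c.class_id,
            }
            for i, c in enumerate(centers)
        ]
    ).to_csv(path, index=False)
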