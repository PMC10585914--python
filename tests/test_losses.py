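"""Loss terms: perfect-case zeros, arithmetic oracles, gradients, descent."""

import numpy as np
import pytest

from nucseg import (
    LossWeights,
    NetworkConfig,
    NetworkOutput,
    SceneConfig,
    TrainConfig,
    combined_loss,
    generate_scene,
    iou_loss,
    seed_loss,
    smooth_loss,
    train_model,
)
from nucseg.clustering import make_coordinate_map
from nucseg.losses import embedding_loss_with_grads, lovasz_grad, lovasz_hinge


def _perfect_output(truth, sigma_val=0.01):
    """Offsets collapse every instance onto its centroid; tiny sigma makes
    phi exactly 1 on the instance and 0 (underflow) elsewhere."""
    h, w = truth.shape
    coords = make_coordinate_map(h, w)
    offsets = np.zeros((2, h, w))
    for k in np.unique(truth):
        if k == 0:
            continue
        m = truth == k
        offsets[0][m] = coords[0][m].mean() - coords[0][m]
        offsets[1][m] = coords[1][m].mean() - coords[1][m]
        # push background pixels far away so their phi underflows to 0
    bg = truth == 0
    offsets[0][bg] = 50.0
    sigma = np.full((2, h, w), sigma_val)
    seed = np.where(truth > 0, 1.0, 0.0)[None]
    return NetworkOutput(seed, offsets, sigma), coords


def _toy_truth():
    truth = np.zeros((10, 10), int)
    truth[2:6, 2:6] = 1
    truth[6:9, 7:10] = 2
    return truth


# ---------------------------------------------------------------- iou term
def test_iou_loss_zero_for_perfect_phi():
    truth = _toy_truth()
    out, coords = _perfect_output(truth)
    assert iou_loss(out, coords, truth) == 0.0


def test_iou_loss_zero_without_instances():
    truth = np.zeros((8, 8), int)
    out, coords = _perfect_output(truth)
    assert iou_loss(out, coords, truth) == 0.0


def test_lovasz_hinge_matches_bruteforce_extension_on_small_vectors():
    """Oracle: evaluate the Lovász extension of the Jaccard loss directly
    from its definition (interpolation over the sorted error vector)."""
    rng = np.random.default_rng(0)

    def oracle(logits, labels):
        signs = 2.0 * labels - 1.0
        errors = np.maximum(1.0 - logits * signs, 0.0)
        order = np.argsort(-errors, kind="stable")
        e = errors[order]
        gt = labels[order]
        # Lovász extension: sum_i e_i * (Delta_i of the Jaccard set loss)
        total = 0.0
        gts = gt.sum()
        prev = 0.0
        inter, union = gts, gts
        for i in range(len(e)):
            if gt[i] == 1:
                inter -= 1
            else:
                union += 1
            cur = 1.0 - inter / union
            total += e[i] * (cur - prev)
            prev = cur
        return total

    for _ in range(50):
        n = int(rng.integers(1, 12))
        logits = rng.normal(0, 2, n)
        labels = (rng.random(n) < 0.5).astype(float)
        assert lovasz_hinge(logits, labels) == pytest.approx(
            oracle(logits, labels), abs=1e-12
        )


def test_lovasz_grad_telescopes_to_jaccard_increments():
    # partial sums of the gradient reproduce the Jaccard loss of the set
    # containing the first i (sorted) error pixels
    gt = np.array([1.0, 0.0, 1.0, 0.0])
    g = lovasz_grad(gt)
    gts = gt.sum()
    partial = np.cumsum(g)
    for i in range(len(gt)):
        inter = gts - gt[: i + 1].sum()
        union = gts + (1.0 - gt[: i + 1]).sum()
        assert partial[i] == pytest.approx(1.0 - inter / union, abs=1e-12)


# --------------------------------------------------------------- seed term
def test_seed_loss_zero_when_seed_equals_target():
    truth = _toy_truth()
    out, coords = _perfect_output(truth)
    assert seed_loss(out.seed, out, coords, truth) == 0.0


def test_seed_loss_zero_on_empty_truth_with_zero_seed():
    truth = np.zeros((6, 6), int)
    out, coords = _perfect_output(truth)
    out2 = NetworkOutput(np.zeros((1, 6, 6)), out.offsets, out.sigma)
    assert seed_loss(out2.seed, out2, coords, truth) == 0.0


def test_seed_loss_hand_computed_2x2():
    # one instance covering the left column; phi = 1 there by construction
    truth = np.array([[1, 0], [1, 0]])
    out, coords = _perfect_output(truth)
    seed = np.array([[[0.5, 0.25], [1.0, 0.0]]])
    # targets: [[1, 0], [1, 0]] -> SE: 0.25, 0.0625, 0, 0; mean = 0.078125
    val = seed_loss(seed, out, coords, truth)
    assert val == pytest.approx((0.25 + 0.0625) / 4, abs=1e-12)


# ------------------------------------------------------------- smooth term
def test_smooth_loss_zero_when_sigma_constant_per_instance():
    truth = _toy_truth()
    sigma = np.full((2, 10, 10), 0.3)
    sigma[:, truth == 2] = 0.7
    out = NetworkOutput(np.zeros((1, 10, 10)), np.zeros((2, 10, 10)), sigma)
    assert smooth_loss(out, truth) == 0.0


def test_smooth_loss_two_pixel_arithmetic_oracle():
    truth = np.zeros((1, 2), int)
    truth[0, :] = 1
    a, b = 0.2, 0.6
    sigma = np.full((2, 1, 2), 0.5)
    sigma[0, 0, 0], sigma[0, 0, 1] = a, b
    out = NetworkOutput(np.zeros((1, 1, 2)), np.zeros((2, 1, 2)), sigma)
    m = (a + b) / 2
    assert smooth_loss(out, truth) == pytest.approx(
        ((a - m) ** 2 + (b - m) ** 2) / 2, abs=1e-15
    )


def test_smooth_loss_zero_on_empty_truth():
    out = NetworkOutput(np.zeros((1, 4, 4)), np.zeros((2, 4, 4)),
                        np.ones((2, 4, 4)))
    assert smooth_loss(out, np.zeros((4, 4), int)) == 0.0


# ---------------------------------------------------------------- combined
def test_combined_loss_weighted_sum_with_defaults():
    rep = combined_loss(LossWeights(), 0.2, 0.1, 0.05)
    assert rep.total == pytest.approx(0.2 + 0.1 + 10 * 0.05, abs=1e-15)
    assert combined_loss(LossWeights(), 0, 0, 0).total == 0
    assert combined_loss(LossWeights(0, 0, 1), 5, 5, 0.3).total == 0.3


def test_combined_loss_linear_in_each_term():
    w = LossWeights(1.0, 1.0, 10.0)
    base = combined_loss(w, 0.3, 0.2, 0.1).total
    assert combined_loss(w, 0.6, 0.2, 0.1).total - base == pytest.approx(0.3)
    assert combined_loss(w, 0.3, 0.4, 0.1).total - base == pytest.approx(0.2)
    assert combined_loss(w, 0.3, 0.2, 0.2).total - base == pytest.approx(1.0)


def test_negative_weight_rejected():
    with pytest.raises(ValueError):
        LossWeights(lambda_iou=-1.0)


# ---------------------------------------------------------------- gradients
def test_loss_gradients_match_finite_differences():
    rng = np.random.default_rng(3)
    h = w = 12
    truth = np.zeros((h, w), int)
    truth[2:6, 2:6] = 1
    truth[7:11, 6:11] = 2
    coords = make_coordinate_map(h, w)
    seed = rng.random((1, h, w))
    off = rng.normal(0, 0.1, (2, h, w))
    sig = np.exp(rng.normal(-2.3, 0.2, (2, h, w)))
    # lambda_seed = 0 isolates the differentiated paths (the seed-loss
    # regression target is intentionally gradient-detached)
    weights = LossWeights(lambda_seed=0.0)

    def f(s, o, g):
        rep, _ = embedding_loss_with_grads(
            NetworkOutput(s, o, g), coords, truth, weights
        )
        return rep.total

    _, (gs, go, gg) = embedding_loss_with_grads(
        NetworkOutput(seed, off, sig), coords, truth, weights
    )
    eps = 1e-7
    for arr, grad, name in [(off, go, "off"), (sig, gg, "sig")]:
        for _ in range(40):
            idx = tuple(rng.integers(0, s) for s in arr.shape)
            up, dn = arr.copy(), arr.copy()
            up[idx] += eps
            dn[idx] -= eps
            if name == "off":
                num = (f(seed, up, sig) - f(seed, dn, sig)) / (2 * eps)
            else:
                num = (f(seed, off, up) - f(seed, off, dn)) / (2 * eps)
            assert num == pytest.approx(grad[idx], abs=1e-6), name


def test_seed_gradient_matches_finite_differences():
    rng = np.random.default_rng(4)
    truth = _toy_truth()
    coords = make_coordinate_map(10, 10)
    seed = rng.random((1, 10, 10))
    off = rng.normal(0, 0.1, (2, 10, 10))
    sig = np.exp(rng.normal(-2.3, 0.2, (2, 10, 10)))
    weights = LossWeights()
    out = NetworkOutput(seed, off, sig)
    _, (gs, _, _) = embedding_loss_with_grads(out, coords, truth, weights)
    eps = 1e-7
    for _ in range(20):
        idx = tuple(rng.integers(0, s) for s in seed.shape)
        up, dn = seed.copy(), seed.copy()
        up[idx] += eps
        dn[idx] -= eps
        ru, _ = embedding_loss_with_grads(NetworkOutput(up, off, sig),
                                          coords, truth, weights)
        rd, _ = embedding_loss_with_grads(NetworkOutput(dn, off, sig),
                                          coords, truth, weights)
        num = (ru.total - rd.total) / (2 * eps)
        assert num == pytest.approx(gs[idx], abs=1e-6)


# ----------------------------------------------------------------- descent
def test_twenty_gradient_steps_strictly_decrease_loss():
    scene = generate_scene(SceneConfig(), seed=5)
    cfg = TrainConfig(
        epochs=20, batch_size=1, learning_rate=1e-3, seed=0,
        augment_spec=None,
        network=NetworkConfig(num_levels=3, base_width=8, dropout_p=0.0),
    )
    _, log = train_model([scene], cfg)
    totals = [r["total"] for r in log[:20]]
    assert all(b < a for a, b in zip(totals, totals[1:]))
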