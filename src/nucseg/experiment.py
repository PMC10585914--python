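"""Dataset splitting, training, hyper-parameter search and evaluation.

The experimental protocol: a shuffled 70/30 split into a model-development
set and an external test set, nested k-fold cross-validation on the
development set (an outer loop for training/evaluation, an inner loop for
hyper-parameter tuning by random search), end-to-end training with the
combined embedding loss, and MC-dropout evaluation that clusters the mean
of the T stochastic outputs and reports per-image F1 / IoU / uncertainty
accuracy with Student-t 95% confidence intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace


import numpy as np
from sklearn.model_selection import KFold

from .clustering import ClusterParams, make_coordinate_map, sequential_cluster
from .losses import LossReport, LossWeights, embedding_loss_with_grads
from .metrics import (
    MetricSummary,
    ci95,
    f1_score,
    instance_detection_f1,
    iou_score,
    uncertainty_accuracy,
    welch_t_test,
)
from .model import NetworkConfig, NucleiNet, build_network
from .synth import AugmentSpec, LabeledScene, augment
from .uncertainty import mc_forward_outputs, predictive_variance

__all__ = [
    "SplitPlan",
    "TrainConfig",
    "EvalReport",
    "split_dev_test",
    "make_nested_folds",
    "tune_hyperparameters",
    "train_model",
    "evaluate_model",
    "compare_reports",
]


@dataclass
class SplitPlan:
    dev_indices: list[int]
    test_indices: list[int]
    outer_folds: list[tuple[list[int], list[int]]] = field(default_factory=list)
    inner_folds: list[list[tuple[list[int], list[int]]]] = field(
        default_factory=list
    )
    seed: int = 0


@dataclass
class TrainConfig:
    epochs: int = 15
    batch_size: int = 4
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    loss_weights: LossWeights = field(default_factory=LossWeights)
    augment_spec: AugmentSpec | None = field(default_factory=AugmentSpec)
    seed: int = 0
    checkpoint_every: int = 0  # epochs; 0 = only final
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


@dataclass
class EvalReport:
    per_image: list[dict]
    f1: MetricSummary | None
    iou: MetricSummary | None
    ua: MetricSummary | None
    detection_f1: MetricSummary | None
    T: int
    seed: int

    def metric_values(self, name: str) -> list[float]:
        return [row[name] for row in self.per_image]

    def to_json(self) -> dict:
        def s(m):
            return None if m is None else {
                "mean": m.mean, "ci95": m.ci95_half_width, "n": m.n
            }

        return {
            "aggregation": "per-image average",
            "T": self.T,
            "seed": self.seed,
            "f1": s(self.f1),
            "iou": s(self.iou),
            "ua": s(self.ua),
            "detection_f1": s(self.detection_f1),
            "per_image": self.per_image,
        }


# ----------------------------------------------------------------------
# splitting
# ----------------------------------------------------------------------

def split_dev_test(n_items: int, dev_fraction: float = 0.7,
                   seed: int = 0) -> SplitPlan:
    """Shuffled split; dev size = floor(dev_fraction * n)."""
    if not 0.0 < dev_fraction < 1.0:
        raise ValueError("dev_fraction must be in (0, 1)")
    if n_items < 2:
        raise ValueError("need at least two items to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_items)
    n_dev = int(np.floor(dev_fraction * n_items))
    if n_dev == 0 or n_dev == n_items:
        raise ValueError("split leaves one side empty")
    return SplitPlan(
        dev_indices=[int(i) for i in order[:n_dev]],
        test_indices=[int(i) for i in order[n_dev:]],
        seed=seed,
    )


def make_nested_folds(dev_indices, outer_k: int = 5, inner_k: int = 3,
                      seed: int = 0) -> SplitPlan:
    """Nested k-fold plan over the development indices.

    Outer folds partition dev into outer_k near-equal validation blocks;
    each outer training set is split again into inner_k folds for tuning.
    """
    dev = [int(i) for i in dev_indices]
    if outer_k < 2 or inner_k < 2:
        raise ValueError("outer_k and inner_k must be >= 2")
    if len(dev) < max(outer_k, inner_k):
        raise ValueError("fewer items than folds")
    plan = SplitPlan(dev_indices=dev, test_indices=[], seed=seed)
    outer = KFold(n_splits=outer_k, shuffle=True, random_state=seed)
    dev_arr = np.asarray(dev)
    for f, (tr, va) in enumerate(outer.split(dev_arr)):
        train_idx = [int(i) for i in dev_arr[tr]]
        val_idx = [int(i) for i in dev_arr[va]]
        plan.outer_folds.append((train_idx, val_idx))
        inner = KFold(n_splits=inner_k, shuffle=True,
                      random_state=seed * 997 + f + 1)
        tr_arr = np.asarray(train_idx)
        plan.inner_folds.append(
            [
                ([int(i) for i in tr_arr[itr]], [int(i) for i in tr_arr[iva]])
                for itr, iva in inner.split(tr_arr)
            ]
        )
    return plan


# ----------------------------------------------------------------------
# hyper-parameter search
# ----------------------------------------------------------------------

def _sample_space(space: dict, rng: np.random.Generator) -> dict:
    out = {}
    for key, spec in space.items():
        if isinstance(spec, (list, tuple)) and not isinstance(spec, str):
            out[key] = spec[int(rng.integers(len(spec)))]
        elif isinstance(spec, dict) and {"low", "high"} <= spec.keys():
            if spec.get("log"):
                out[key] = float(
                    np.exp(rng.uniform(np.log(spec["low"]), np.log(spec["high"])))
                )
            else:
                out[key] = float(rng.uniform(spec["low"], spec["high"]))
        else:
            out[key] = spec
    return out


def make_training_scorer(scenes: list[LabeledScene], T: int = 4,
                         cluster_params: ClusterParams = ClusterParams()):
    """Default random-search scorer: train on the fold's training scenes,
    return the mean per-image validation F1."""

    def scorer(config: TrainConfig, train_idx, val_idx) -> float:
        model, _ = train_model([scenes[i] for i in train_idx], config)
        report = evaluate_model(model, [scenes[i] for i in val_idx], T=T,
                                seed=config.seed,
                                cluster_params=cluster_params)
        return float(np.mean([r["f1"] for r in report.per_image]))

    return scorer


def tune_hyperparameters(space: dict, inner_folds, budget: int, seed: int,
                         scorer, base_config: TrainConfig | None = None):
    """Random search: sample `budget` candidates from `space`, score each
    by the mean validation F1 over the inner folds, return the argmax.

    scorer(candidate_config, train_idx, val_idx) -> float is injected so
    the search is testable with stubs; the CLI wires in real training.
    Returns (best TrainConfig, trial log).
    """
    if not space:
        raise ValueError("empty search space")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    base = base_config or TrainConfig()
    trials = []
    best = None
    for trial in range(budget):
        params = _sample_space(space, rng)
        cand = replace(base, **{k: v for k, v in params.items()
                                if k in TrainConfig.__dataclass_fields__})
        scores = [float(scorer(cand, tr, va)) for tr, va in inner_folds]
        mean_score = float(np.mean(scores)) if scores else float("-inf")
        trials.append({"trial": trial, "params": params, "scores": scores,
                       "mean_score": mean_score})
        if best is None or mean_score > best[0]:
            best = (mean_score, cand)
    return best[1], trials


# ----------------------------------------------------------------------
# training
# ----------------------------------------------------------------------

def train_step(model: NucleiNet, batch: list[LabeledScene], coords,
               weights: LossWeights, optimizer, rng) -> LossReport:
    """One optimization step on a mini-batch; returns the mean LossReport."""
    imgs = np.stack(
        [s.image.astype(np.float64).transpose(2, 0, 1) / 255.0 for s in batch]
    )
    seed_b, off_b, sig_b = model.forward_batch(imgs, training=True, rng=rng)
    n = len(batch)
    d_seed = np.zeros_like(seed_b)
    d_off = np.zeros_like(off_b)
    d_sig = np.zeros_like(sig_b)
    terms = np.zeros(4)
    from .model import NetworkOutput

    for i, scene in enumerate(batch):
        out = NetworkOutput(seed_b[i], off_b[i], sig_b[i])
        report, (gs, go, gg) = embedding_loss_with_grads(
            out, coords, scene.labels, weights=weights,
            class_of=scene.class_of,
        )
        d_seed[i], d_off[i], d_sig[i] = gs / n, go / n, gg / n
        terms += np.array(
            [report.iou_term, report.seed_term, report.smooth_term,
             report.total]
        )
    optimizer.zero_grad()
    model.backward_batch(d_seed, d_off, d_sig)
    optimizer.step()
    t = terms / n
    return LossReport(t[0], t[1], t[2], t[3])


def train_model(scenes: list[LabeledScene], config: TrainConfig,
                log_path=None, progress: bool = False):
    """Train a network on labelled scenes; deterministic for a fixed config.

    Returns (model, log) where log is a list of per-step LossReport dicts.
    Aborts with a diagnostic if the loss diverges to a non-finite value.
    """
    if not scenes:
        raise ValueError("no training data")
    model = build_network(config.network, seed=config.seed)
    optimizer = model.make_optimizer(lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 10_007)
    h, w = scenes[0].labels.shape
    coords = make_coordinate_map(h, w)
    log: list[dict] = []
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(scenes))
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = []
            for j in idx:
                scene = scenes[int(j)]
                if config.augment_spec is not None:
                    aseed = int(rng.integers(0, 2**31 - 1))
                    img, lab = augment(scene.image, scene.labels,
                                       config.augment_spec, seed=aseed)
                    scene = LabeledScene(img, lab, scene.class_of)
                batch.append(scene)
            report = train_step(model, batch, coords, config.loss_weights,
                                optimizer, rng)
            if not np.isfinite(report.total):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} step {step}: "
                    f"total loss {report.total}"
                )
            log.append(
                {"epoch": epoch, "step": step, **asdict(report)}
            )
            step += 1
        if progress:
            print(f"epoch {epoch + 1}/{config.epochs} "
                  f"loss {log[-1]['total']:.4f}", flush=True)
    if log_path is not None:
        with open(log_path, "w") as fh:
            for row in log:
                fh.write(json.dumps(row) + "\n")
    return model, log


# ----------------------------------------------------------------------
# evaluation
# ----------------------------------------------------------------------

def evaluate_model(model: NucleiNet, scenes: list[LabeledScene], T: int = 50,
                   seed: int = 0, cluster_params: ClusterParams = ClusterParams(),
                   u_threshold: float = 0.5) -> EvalReport:
    """MC-dropout evaluation.

    Per image: T stochastic passes, sequential clustering of the mean
    outputs, predictive-variance map, pixel F1/IoU against the binarized
    ground truth, uncertainty accuracy, and a secondary instance-detection
    F1; aggregated as per-image means with Student-t 95% CIs.
    """
    h, w = scenes[0].labels.shape
    coords = make_coordinate_map(h, w)
    rows = []
    for i, scene in enumerate(scenes):
        img = scene.image.astype(np.float64).transpose(2, 0, 1) / 255.0
        stack = mc_forward_outputs(model, img, T, seed=seed + 131 * i)
        mean_out = stack.mean_output()
        labels, _ = sequential_cluster(mean_out, coords, cluster_params)
        y = stack.seed.max(axis=1)
        from .uncertainty import MCSampleStack

        umap = predictive_variance(
            MCSampleStack(y_hat=y, sigma_sq=y * (1.0 - y))
        )
        pred_fg = labels > 0
        true_fg = scene.labels > 0
        rows.append(
            {
                "image": i,
                "f1": f1_score(pred_fg, true_fg),
                "iou": iou_score(pred_fg, true_fg),
                "ua": uncertainty_accuracy(pred_fg, true_fg, umap.normalized,
                                           u_threshold),
                "detection_f1": instance_detection_f1(labels, scene.labels),
                "n_pred": int(labels.max()),
                "n_true": int(scene.labels.max()),
                "mean_variance": float(umap.variance.mean()),
            }
        )

    def agg(name):
        vals = [r[name] for r in rows]
        return ci95(vals) if len(vals) >= 2 else None

    return EvalReport(
        per_image=rows,
        f1=agg("f1"),
        iou=agg("iou"),
        ua=agg("ua"),
        detection_f1=agg("detection_f1"),
        T=T,
        seed=seed,
    )


def compare_reports(report_a: EvalReport, report_b: EvalReport,
                    metric: str = "f1") -> dict:
    """Welch two-sample t-test between two runs' per-image metric values."""
    a = report_a.metric_values(metric)
    b = report_b.metric_values(metric)
    t, dof, p = welch_t_test(a, b)
    return {
        "metric": metric,
        "mean_a": float(np.mean(a)),
        "mean_b": float(np.mean(b)),
        "t": t,
        "dof": dof,
        "p_value": p,
    }
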