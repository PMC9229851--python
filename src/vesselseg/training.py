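"""Training and evaluation orchestration.

Training follows the protocol of the architecture's study: random 64x64
patches are cut from preprocessed images, the network is optimized with
Adam at an initial learning rate of 0.001 against the Dice loss, a held-out
fraction of the training patches serves as the validation set, and the
checkpoint with the best validation Dice is retained.  Evaluation tiles
each image with a stride-32 grid of patches, averages the overlapping
probability maps back into a full-size map, thresholds it, and scores the
result inside the field of view.  A leave-one-out protocol (per fold: train
on one image, test on the rest) is provided for STARE-style small datasets,
with the conventional train-on-rest variant behind a flag.

Everything is seeded; identical configs and data give identical loss traces.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .backbone import ModelConfig, MTPAUnet, SegmentationResult, desk_config
from .metrics import MetricReport, aggregate_reports, dice_loss_tensor, report
from .nn import Adam, BatchNorm2d
from .nn.tensor import Tensor, get_default_dtype, set_default_dtype
from .preprocessing import PatchPyramid, PreprocessConfig, extract_patches, preprocess, stitch
from .synthetic import FundusSample

__all__ = [
    "TrainConfig",
    "fit_patches",
    "train",
    "predict_image",
    "evaluate",
    "leave_one_out",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol.

    The full-scale profile keeps the study protocol (lr 0.001, 100 epochs,
    batch 32, threshold 0.5); the desk profile caps the number of optimizer
    steps and uses far fewer patches per image so a run completes on one CPU.
    """

    lr: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    threshold: float = 0.5
    seed: int = 0
    patches_per_image: int = 200
    val_fraction: float = 0.1
    max_steps: int | None = None
    grad_accumulation: int = 1  # mini-batches summed per optimizer step
    loss_smoothing: float = 1e-5  # Dice-loss smoothing constant w
    eval_stride: int = 32
    protocol: str = "holdout"  # holdout | leave_one_out
    device: str = "cpu"
    dtype: str = "float32"

    def validate(self) -> "TrainConfig":
        if self.lr < 0:
            raise ValueError("learning rate must be nonnegative")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in [0, 1)")
        return self


def desk_train_config(seed: int = 0, **overrides) -> TrainConfig:
    """CPU-scale defaults: 10 patches/image, at most 200 optimizer steps,
    effective batch 32 (batch 8 with 4-fold gradient accumulation)."""
    base = dict(
        patches_per_image=10,
        max_steps=200,
        batch_size=8,
        grad_accumulation=4,
        epochs=100,
        seed=seed,
    )
    base.update(overrides)
    return TrainConfig(**base)


def _batch_stream(n_items, batch_size, rng):
    """Endless shuffled mini-batch indices, reshuffling at each epoch."""
    while True:
        order = rng.permutation(n_items)
        for i in range(0, n_items, batch_size):
            yield order[i : i + batch_size]


def fit_patches(
    model: MTPAUnet,
    pyramids: list[PatchPyramid],
    labels: list[np.ndarray],
    cfg: TrainConfig,
    val_pyramids: list[PatchPyramid] | None = None,
    val_labels: list[np.ndarray] | None = None,
) -> dict:
    """Optimize ``model`` on patch pyramids against the Dice loss.

    Returns a history dict with the per-step training loss and (when a
    validation set is given) the validation soft Dice at epoch boundaries;
    the model is left holding the best-validation weights ("best" = highest
    val Dice).  ``grad_accumulation`` mini-batches are summed per optimizer
    step; large effective batches stabilize Dice-only training.
    """
    cfg.validate()
    if not pyramids:
        raise ValueError("no training patches")
    n = len(pyramids)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    history = {"train_loss": [], "val_dice": []}
    best = (-np.inf, None)
    batches = _batch_stream(n, cfg.batch_size, rng)
    batches_per_epoch = -(-n // cfg.batch_size)
    steps_per_epoch = max(1, -(-batches_per_epoch // cfg.grad_accumulation))
    total_steps = cfg.epochs * steps_per_epoch
    if cfg.max_steps is not None:
        total_steps = min(total_steps, cfg.max_steps)
    model.train()
    for step in range(1, total_steps + 1):
        opt.zero_grad()
        step_loss = 0.0
        for _ in range(cfg.grad_accumulation):
            idx = next(batches)
            probs = model.forward_pyramids([pyramids[j] for j in idx])
            lab = np.stack([labels[j] for j in idx])
            loss = dice_loss_tensor(probs, Tensor(lab[:, None, :, :]), cfg.loss_smoothing)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss {loss.data!r} at step {step}; "
                    "lower the learning rate or inspect the input patches"
                )
            (loss * (1.0 / cfg.grad_accumulation)).backward()
            step_loss += float(loss.data) / cfg.grad_accumulation
        opt.step()
        history["train_loss"].append(step_loss)
        if val_pyramids and (step % steps_per_epoch == 0 or step == total_steps):
            vd = _patch_dice(model, val_pyramids, val_labels, cfg.batch_size)
            model.train()
            history["val_dice"].append(vd)
            if vd > best[0]:
                best = (vd, model.state_dict())
    steps_done = total_steps
    if best[1] is not None:
        model.load_state_dict(best[1])
    recalibrate_batchnorm(model, pyramids, cfg.batch_size)
    model.eval()
    history["steps"] = steps_done
    return history


def recalibrate_batchnorm(model: MTPAUnet, pyramids, batch_size: int = 16):
    """Re-estimate batch-norm running statistics over the training patches.

    After short training runs the exponentially averaged statistics lag the
    final weights; one cumulative-average pass over the data closes the
    train/eval gap.
    """
    bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    if not bns or not pyramids:
        return
    model.train()
    try:
        for k, i in enumerate(range(0, len(pyramids), batch_size)):
            for b in bns:
                b.momentum = 1.0 / (k + 1)
            model.forward_pyramids(pyramids[i : i + batch_size])
    finally:
        for b in bns:
            b.momentum = 0.1
        model.eval()


def _patch_dice(model, pyramids, labels, batch_size) -> float:
    """Soft Dice of evaluation-mode predictions over a patch set."""
    num = den = 0.0
    for i in range(0, len(pyramids), batch_size):
        probs = model.predict_pyramids(pyramids[i : i + batch_size])
        lab = np.stack(labels[i : i + batch_size])
        num += 2.0 * float((probs * lab).sum())
        den += float(probs.sum() + lab.sum())
    return num / den if den > 0 else 0.0


def _prepare_patches(samples, pre_cfg, n_per_image, seed):
    pyramids, labels = [], []
    for k, s in enumerate(samples):
        g = preprocess(s, pre_cfg)
        for pyr, lab in extract_patches(
            g, s.vessel_mask, s.fov_mask, n=n_per_image, mode="random", seed=seed + 9973 * k
        ):
            pyramids.append(pyr)
            labels.append(lab)
    return pyramids, labels


def train(
    model_cfg: ModelConfig | None,
    train_cfg: TrainConfig,
    data: list[FundusSample],
    pre_cfg: PreprocessConfig | None = None,
) -> tuple[MTPAUnet, dict]:
    """Full pipeline: preprocess, cut patches, optimize, keep best weights."""
    if not data:
        raise ValueError("training requires at least one sample")
    train_cfg.validate()
    model_cfg = model_cfg or desk_config()
    prev_dtype = get_default_dtype()
    set_default_dtype(np.float32 if train_cfg.dtype == "float32" else np.float64)
    try:
        model = MTPAUnet(model_cfg, rng=np.random.default_rng(model_cfg.seed))
        pyramids, labels = _prepare_patches(
            data, pre_cfg, train_cfg.patches_per_image, train_cfg.seed
        )
        rng = np.random.default_rng(train_cfg.seed + 1)
        order = rng.permutation(len(pyramids))
        n_val = int(round(train_cfg.val_fraction * len(pyramids)))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        history = fit_patches(
            model,
            [pyramids[i] for i in tr_idx],
            [labels[i] for i in tr_idx],
            train_cfg,
            [pyramids[i] for i in val_idx],
            [labels[i] for i in val_idx],
        )
    finally:
        set_default_dtype(prev_dtype)
    return model, history


def predict_image(
    model: MTPAUnet,
    sample: FundusSample,
    pre_cfg: PreprocessConfig | None = None,
    threshold: float = 0.5,
    stride: int = 32,
    batch_size: int = 16,
) -> SegmentationResult:
    """Grid patches -> forward -> stitch -> threshold for one image."""
    g = preprocess(sample, pre_cfg)
    pairs = extract_patches(g, mode="grid", stride=stride)
    pyramids = [p for p, _ in pairs]
    probs = []
    for i in range(0, len(pyramids), batch_size):
        probs.extend(model.predict_pyramids(pyramids[i : i + batch_size]))
    stitched = stitch(probs, [p.origin for p in pyramids], g.shape)
    return SegmentationResult(prob_map=stitched, threshold=threshold)


def evaluate(
    model: MTPAUnet,
    samples: list[FundusSample],
    pre_cfg: PreprocessConfig | None = None,
    threshold: float = 0.5,
    stride: int = 32,
    fov_only: bool = True,
) -> tuple[list[MetricReport], MetricReport]:
    """Per-image metric reports plus their arithmetic mean."""
    reports = []
    for s in samples:
        res = predict_image(model, s, pre_cfg, threshold, stride)
        fov = s.fov_mask if fov_only else None
        reports.append(report(res.prob_map, s.vessel_mask, fov, threshold))
    return reports, aggregate_reports(reports)


def leave_one_out(
    model_cfg: ModelConfig | None,
    train_cfg: TrainConfig,
    samples: list[FundusSample],
    pre_cfg: PreprocessConfig | None = None,
    conventional: bool = False,
) -> tuple[list[MetricReport], MetricReport]:
    """n-fold protocol over n samples.

    The default follows the study's STARE variant literally: fold i trains
    on sample i alone and tests on the remaining n-1 images.
    ``conventional=True`` flips this to the usual train-on-rest/test-on-one.
    """
    n = len(samples)
    if n < 2:
        raise ValueError("leave-one-out needs at least two samples")
    fold_reports = []
    for i in range(n):
        fold_cfg = replace(train_cfg, seed=train_cfg.seed + i)
        if conventional:
            train_set = [s for j, s in enumerate(samples) if j != i]
            test_set = [samples[i]]
        else:
            train_set = [samples[i]]
            test_set = [s for j, s in enumerate(samples) if j != i]
        model, _ = train(model_cfg, fold_cfg, train_set, pre_cfg)
        _, agg = evaluate(model, test_set, pre_cfg, train_cfg.threshold, train_cfg.eval_stride)
        fold_reports.append(agg)
    return fold_reports, aggregate_reports(fold_reports)
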