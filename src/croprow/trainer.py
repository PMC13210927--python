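"""Training loop, end-to-end inference pipeline and timing diagnostics.

The training recipe: Adam with first-moment coefficient 0.9 (decoupled weight
decay 5e-4), initial learning rate 1e-3 annealed on a cosine schedule to
1e-5, batch size 8, 50 epochs, minimising the combined Focal + Dice loss.
A single seed fixes batch shuffling and weight initialisation, making runs
bit-reproducible.  An optional linear batch-size scaling of the initial rate
is exposed but off by default.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dataprep, lossmetrics, navline, sacnet
from . import nn
from .lossmetrics import LossConfig
from .navline import ClusterConfig, RansacConfig
from .sacnet import NetConfig, SACDeepLabV3Plus
from .synthfield import FieldScene

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings."""

    learning_rate: float = 1e-3
    beta1: float = 0.9                 # Adam first-moment coefficient
    weight_decay: float = 5e-4
    batch_size: int = 8
    epochs: int = 50
    lr_min: float = 1e-5
    input_size: tuple[int, int] = (512, 512)
    scale_lr_with_batch: bool = False  # linear scaling, reference batch 8
    seed: int = 0
    loss: LossConfig = LossConfig()

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class RunManifest:
    """Reproducibility record of one training run."""

    net_config: dict
    train_config: dict
    seed: int
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    checkpoint_path: str | None = None


def _scene_arrays(samples, input_size) -> tuple[np.ndarray, np.ndarray]:
    """Stack (image, mask) pairs / FieldScenes into network-ready batches."""
    xs, ys = [], []
    spec = dataprep.NormalizationSpec(resize_to=tuple(input_size))
    for s in samples:
        if isinstance(s, FieldScene):
            img, msk = s.image, s.mask
        elif isinstance(s, dataprep.Sample):
            img, msk = s.image, s.mask
        else:
            img, msk = s
        xs.append(dataprep.preprocess(np.asarray(img) * 255.0, spec))
        m = np.asarray(msk, dtype=np.float32)
        if m.shape != tuple(input_size):
            m = nn.bilinear_resize_array(m, tuple(input_size))
            m = (m > 0.5).astype(np.float32)
        ys.append(m)
    return np.stack(xs), np.stack(ys)


def _epoch_loss(model, x, y, loss_config, batch_size) -> float:
    """Mean loss over a dataset without gradient tracking."""
    model.eval()
    losses = []
    with nn.no_grad():
        for i in range(0, len(x), batch_size):
            logits = model(x[i:i + batch_size])
            probs = nn.softmax(logits, axis=1)
            losses.append(lossmetrics.total_loss(probs, y[i:i + batch_size],
                                                 loss_config).item())
    return float(np.mean(losses))


def train(train_set, val_set, net_config: NetConfig = NetConfig(),
          train_config: TrainConfig = TrainConfig(),
          checkpoint_dir: str | Path | None = None
          ) -> tuple[RunManifest, SACDeepLabV3Plus]:
    """Seeded end-to-end training; returns the manifest and the best model.

    ``train_set`` / ``val_set`` accept FieldScenes, dataprep Samples or
    (image, mask) pairs with images in [0, 1].  The best-by-validation-loss
    weights are restored on the returned model (and written to
    ``checkpoint_dir`` when given).
    """
    if len(train_set) == 0:
        raise ValueError("training set must be non-empty")
    cfg = train_config
    x_train, y_train = _scene_arrays(train_set, cfg.input_size)
    x_val, y_val = (_scene_arrays(val_set, cfg.input_size)
                    if len(val_set) else (None, None))

    model = sacnet.build_model(net_config, seed=cfg.seed)
    lr = cfg.learning_rate
    if cfg.scale_lr_with_batch:
        lr *= cfg.batch_size / 8.0
    opt = nn.AdamW(model.parameters(), lr=lr, betas=(cfg.beta1, 0.999),
                   weight_decay=cfg.weight_decay)
    sched = nn.CosineAnnealingLR(opt, t_max=max(cfg.epochs, 1),
                                 eta_min=cfg.lr_min)
    rng = np.random.default_rng(cfg.seed)

    manifest = RunManifest(net_config=dataclasses.asdict(net_config),
                           train_config=dataclasses.asdict(cfg), seed=cfg.seed)
    best_state, best_val = model.state_dict(), np.inf

    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(x_train))
        epoch_losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            logits = model(x_train[idx])
            probs = nn.softmax(logits, axis=1)
            loss = lossmetrics.total_loss(probs, y_train[idx], cfg.loss)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite training loss {value} at epoch {epoch}, "
                    f"step {i // cfg.batch_size}; last lr {opt.lr:.3e}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(value)
        sched.step()
        train_loss = float(np.mean(epoch_losses))
        manifest.train_loss.append(train_loss)
        if x_val is not None:
            val_loss = _epoch_loss(model, x_val, y_val, cfg.loss, cfg.batch_size)
            manifest.val_loss.append(val_loss)
        else:
            val_loss = train_loss
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            manifest.best_epoch = epoch
        logger.info("epoch %d: train %.4f val %.4f", epoch, train_loss, val_loss)

    model.load_state_dict(best_state)
    if checkpoint_dir is not None:
        path = Path(checkpoint_dir) / "best.npz"
        path.parent.mkdir(parents=True, exist_ok=True)
        sacnet.save_checkpoint(model, path)
        manifest.checkpoint_path = str(path)
    model.eval()
    return manifest, model


def segment_images(model: SACDeepLabV3Plus, images,
                   input_size: tuple[int, int] = (512, 512)) -> list[np.ndarray]:
    """Predict binary masks for [0, 1] RGB images (each H x W x 3)."""
    spec = dataprep.NormalizationSpec(resize_to=tuple(input_size))
    masks = []
    for img in images:
        x = dataprep.preprocess(np.asarray(img) * 255.0, spec)[None]
        masks.append(model.predict_mask(x)[0])
    return masks


def run_pipeline(images, model: SACDeepLabV3Plus | None,
                 cluster_config: ClusterConfig = ClusterConfig(),
                 ransac_config: RansacConfig = RansacConfig(),
                 input_size: tuple[int, int] = (512, 512),
                 masks=None, seed: int = 0) -> list[dict]:
    """Image -> mask -> navigation lines for a batch.

    When ``masks`` is given (e.g. ground-truth masks), segmentation is
    bypassed and the geometry stage runs on them directly.  Unreadable
    entries are skipped with a logged warning and recorded in the report.
    """
    reports: list[dict] = []
    for i, img in enumerate(images):
        entry: dict = {"index": i}
        try:
            if masks is not None:
                mask = np.asarray(masks[i])
            else:
                mask = segment_images(model, [img], input_size)[0]
            lines = navline.extract_navigation_lines(
                mask, cluster_config, ransac_config, seed=seed + i)
            entry["mask_foreground"] = int(mask.sum())
            entry["lines"] = [
                {"label": nl.label, "a": nl.line.a, "b": nl.line.b,
                 "c": nl.line.c, "inliers": nl.line.inlier_count,
                 "anchors": [{"x": a.x, "y": a.y, "source": a.source}
                             for a in nl.anchors]}
                for nl in lines
            ]
            entry["status"] = "ok"
        except Exception as exc:  # noqa: BLE001 - per-image robustness
            logger.warning("image %d failed: %s", i, exc)
            entry["status"] = f"error: {exc}"
        reports.append(entry)
    return reports


def measure_inference_time(model: SACDeepLabV3Plus, n_warmup: int = 10,
                           n_timed: int = 100,
                           input_size: tuple[int, int] = (512, 512)) -> float:
    """Mean forward-pass wall time (ms/frame) after a warm-up phase.

    Post-processing is excluded.  The figure is hardware-dependent and is
    reported as a diagnostic only.
    """
    if n_timed <= 0:
        raise ValueError("n_timed must be positive: nothing to average")
    model.eval()
    rng = np.random.default_rng(0)
    frame = rng.normal(0, 1, size=(1, 3, *input_size)).astype(np.float32)
    times: list[float] = []
    with nn.no_grad():
        for _ in range(n_warmup):
            model(frame)
        for _ in range(n_timed):
            t0 = time.perf_counter()
            model(frame)
            times.append((time.perf_counter() - t0) * 1e3)
    assert len(times) == n_timed
    return float(np.mean(times))
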