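"""Scikit-learn-style estimator facade over the segmentation + geometry stack.

``CropRowSegmenter`` is fit/predict-shaped (images in, masks out) and
``NavigationLineExtractor`` is transform-shaped (masks in, line sets out);
both follow the BaseEstimator contract (constructor parameters mirrored as
attributes, ``get_params``/``set_params``, fitted state with a trailing
underscore) so they compose with sklearn pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import navline, trainer
from .lossmetrics import LossConfig
from .navline import ClusterConfig, RansacConfig
from .sacnet import NetConfig


class CropRowSegmenter(BaseEstimator):
    """Trainable crop-row segmentation estimator.

    Parameters
    ----------
    preset : {"full", "A", "A+B", "A+B+C", "A+B+C+D", "desk"}
        Network configuration; "full" is an alias of "A+B+C+D" and "desk" a
        width-reduced variant for CPU-scale work.
    input_size : (int, int)
        Spatial size images are resized to (must be divisible by 16).
    epochs, batch_size, learning_rate, weight_decay : optimisation settings.
    val_fraction : share of the training data held out for model selection.
    random_state : seeds weight init, shuffling and the validation split.
    """

    def __init__(self, preset: str = "full", input_size: tuple[int, int] = (512, 512),
                 epochs: int = 50, batch_size: int = 8,
                 learning_rate: float = 1e-3, weight_decay: float = 5e-4,
                 gamma: float = 2.0, alpha: float = 0.25,
                 val_fraction: float = 0.1, random_state: int = 0):
        self.preset = preset
        self.input_size = input_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.gamma = gamma
        self.alpha = alpha
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _net_config(self) -> NetConfig:
        if self.preset == "desk":
            return NetConfig.desk_scale()
        name = "A+B+C+D" if self.preset == "full" else self.preset
        return NetConfig.ablation(name)

    def fit(self, X, y):
        """Fit on images X (n, H, W, 3) in [0, 1] and binary masks y (n, H, W)."""
        X = np.asarray(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y must have the same length")
        pairs = [(X[i], y[i]) for i in range(len(X))]
        rng = np.random.default_rng(self.random_state)
        n_val = int(round(self.val_fraction * len(pairs)))
        order = rng.permutation(len(pairs))
        val = [pairs[i] for i in order[:n_val]]
        tr = [pairs[i] for i in order[n_val:]] or pairs
        cfg = trainer.TrainConfig(
            learning_rate=self.learning_rate, weight_decay=self.weight_decay,
            batch_size=self.batch_size, epochs=self.epochs,
            input_size=tuple(self.input_size), seed=self.random_state,
            loss=LossConfig(gamma=self.gamma, alpha=self.alpha))
        self.manifest_, self.model_ = trainer.train(tr, val, self._net_config(), cfg)
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict(self, X) -> np.ndarray:
        """Predict binary masks (n, H', W') at the configured input size."""
        check_is_fitted(self, "model_")
        masks = trainer.segment_images(self.model_, np.asarray(X),
                                       tuple(self.input_size))
        return np.stack(masks)

    def score(self, X, y) -> float:
        """Mean foreground IoU over the batch."""
        from .lossmetrics import evaluate_masks

        preds = self.predict(X)
        ious = []
        for p, t in zip(preds, y):
            t = np.asarray(t)
            if t.shape != p.shape:
                from .nn import bilinear_resize_array
                t = (bilinear_resize_array(t.astype(np.float32), p.shape)
                     > 0.5).astype(np.uint8)
            ious.append(evaluate_masks(p, t).iou[1])
        return float(np.mean(ious))


class NavigationLineExtractor(BaseEstimator, TransformerMixin):
    """Stateless transformer: binary masks -> per-mask navigation lines."""

    def __init__(self, eps: float = 30.0, min_samples: int = 5,
                 n_bands: int = 20, closing_height: int = 15,
                 n_anchor_rows: int = 10, max_rows_kept: int = 3,
                 max_iterations: int = 100, inlier_threshold: float = 5.0,
                 min_inliers: int = 10, random_state: int = 0):
        self.eps = eps
        self.min_samples = min_samples
        self.n_bands = n_bands
        self.closing_height = closing_height
        self.n_anchor_rows = n_anchor_rows
        self.max_rows_kept = max_rows_kept
        self.max_iterations = max_iterations
        self.inlier_threshold = inlier_threshold
        self.min_inliers = min_inliers
        self.random_state = random_state

    def fit(self, X=None, y=None):
        self.cluster_config_ = ClusterConfig(
            eps=self.eps, min_samples=self.min_samples, n_bands=self.n_bands,
            closing_height=self.closing_height,
            n_anchor_rows=self.n_anchor_rows,
            max_rows_kept=self.max_rows_kept)
        self.ransac_config_ = RansacConfig(
            max_iterations=self.max_iterations,
            inlier_threshold=self.inlier_threshold,
            min_inliers=self.min_inliers)
        return self

    def transform(self, X) -> list[list[navline.NavigationLine]]:
        if not hasattr(self, "cluster_config_"):
            self.fit()
        return [navline.extract_navigation_lines(
                    np.asarray(mask), self.cluster_config_,
                    self.ransac_config_, seed=self.random_state + i)
                for i, mask in enumerate(X)]
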