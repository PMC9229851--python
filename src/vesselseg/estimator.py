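"""A scikit-learn style estimator wrapping the full segmentation pipeline."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .backbone import ModelConfig, desk_config, reference_config
from .metrics import dice_coefficient
from .preprocessing import PreprocessConfig
from .synthetic import FundusSample
from .training import TrainConfig, evaluate, predict_image, train

__all__ = ["VesselSegmenter"]


class VesselSegmenter(BaseEstimator):
    """Retinal vessel segmentation estimator.

    ``fit`` takes a list of :class:`FundusSample` (images with vessel ground
    truth), trains the multi-scale Transformer + CNN network on random
    patches against the Dice loss, and keeps the best-validation weights.
    ``predict`` returns binary vessel masks, ``predict_proba`` the stitched
    probability maps.

    Parameters
    ----------
    profile:
        "desk" (narrow CPU-scale network, capped optimizer steps) or
        "paper" (full-width network, full protocol).
    lr, epochs, batch_size, threshold, patches_per_image, max_steps:
        optimization protocol; defaults follow the selected profile.
    gamma, clahe_clip:
        preprocessing overrides.
    random_state:
        seed for model init, patch sampling and shuffling.
    """

    def __init__(
        self,
        profile: str = "desk",
        lr: float = 1e-3,
        epochs: int | None = None,
        batch_size: int | None = None,
        threshold: float = 0.5,
        patches_per_image: int | None = None,
        max_steps: int | None = None,
        gamma: float = 1.2,
        clahe_clip: float = 0.02,
        random_state: int = 0,
    ):
        self.profile = profile
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.threshold = threshold
        self.patches_per_image = patches_per_image
        self.max_steps = max_steps
        self.gamma = gamma
        self.clahe_clip = clahe_clip
        self.random_state = random_state

    # -- config assembly ----------------------------------------------
    def _model_config(self) -> ModelConfig:
        if self.profile == "desk":
            return desk_config(seed=self.random_state)
        if self.profile == "paper":
            return reference_config()
        raise ValueError(f"unknown profile {self.profile!r}")

    def _train_config(self) -> TrainConfig:
        desk = self.profile == "desk"
        return TrainConfig(
            lr=self.lr,
            epochs=self.epochs if self.epochs is not None else 100,
            batch_size=self.batch_size if self.batch_size is not None else (8 if desk else 32),
            grad_accumulation=4 if desk else 1,
            threshold=self.threshold,
            seed=self.random_state,
            patches_per_image=(
                self.patches_per_image
                if self.patches_per_image is not None
                else (10 if desk else 200)
            ),
            max_steps=self.max_steps if self.max_steps is not None else (200 if desk else None),
        ).validate()

    def _pre_config(self) -> PreprocessConfig:
        return PreprocessConfig(gamma=self.gamma, clahe_clip=self.clahe_clip).validate()

    # -- estimator API -------------------------------------------------
    def fit(self, X: list[FundusSample], y=None) -> "VesselSegmenter":
        if not X:
            raise ValueError("fit requires at least one sample")
        model, history = train(self._model_config(), self._train_config(), X, self._pre_config())
        self.model_ = model
        self.loss_trace_ = list(history["train_loss"])
        self.val_dice_trace_ = list(history["val_dice"])
        self.n_steps_ = history["steps"]
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this VesselSegmenter instance is not fitted yet")

    def predict_proba(self, X: list[FundusSample]) -> list[np.ndarray]:
        self._check_fitted()
        return [
            predict_image(self.model_, s, self._pre_config(), self.threshold).prob_map for s in X
        ]

    def predict(self, X: list[FundusSample]) -> list[np.ndarray]:
        return [(p >= self.threshold).astype(np.uint8) for p in self.predict_proba(X)]

    def score(self, X: list[FundusSample], y=None) -> float:
        """Mean hard Dice against the samples' own vessel ground truth."""
        self._check_fitted()
        _, agg = evaluate(self.model_, X, self._pre_config(), self.threshold)
        return float(agg.dice)

    def score_dice(self, X: list[FundusSample]) -> list[float]:
        self._check_fitted()
        return [
            dice_coefficient(pred[s.fov_mask.astype(bool)], s.vessel_mask[s.fov_mask.astype(bool)])
            for pred, s in zip(self.predict(X), X)
        ]
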