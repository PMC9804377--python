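"""Model/Results front end over the interactive trainer.

``InteractiveSegmenter`` binds a project (dataset + annotation sets +
checkpoints) to the training configuration; ``fit()`` runs the interactive
loop and returns a ``TrainingResults`` carrying the F1/loss traces, the
checkpoint schedule and the fitted network, with a ``summary()`` table and
``segment()`` for applying the fitted model to new images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .augment import AugmentationConfig
from .inference import segment_image
from .nn import UNet
from .store import Project
from .trainer import TrainingConfig, TrainingState, run_training


class InteractiveSegmenter:
    """Binary segmentation network fitted interactively to sparse annotations."""

    def __init__(
        self,
        project: Project,
        config: TrainingConfig | None = None,
        aug_config: AugmentationConfig | None = None,
    ):
        self.project = project
        self.config = config or TrainingConfig()
        self.aug_config = aug_config if aug_config is not None else AugmentationConfig()

    def fit(self, stop_signal=None, on_epoch_end=None) -> "TrainingResults":
        state = run_training(
            self.project, self.config, self.aug_config,
            stop_signal=stop_signal, on_epoch_end=on_epoch_end,
        )
        net = UNet.load(self.project.latest_checkpoint())
        return TrainingResults(self, state, net)


@dataclass
class TrainingResults:
    model: InteractiveSegmenter
    state: TrainingState
    network: UNet

    @property
    def best_val_f1(self) -> float:
        return self.state.best_val_f1

    @property
    def history(self) -> pd.DataFrame:
        n = self.state.epoch_index
        return pd.DataFrame({
            "epoch": np.arange(1, n + 1),
            "train_loss": self.state.train_loss_trace,
            "val_f1": self.state.val_f1_trace,
            "checkpointed": [e in set(self.state.checkpoint_epochs)
                             for e in range(1, n + 1)],
        })

    def segment(self, image: np.ndarray, tta: bool = True) -> np.ndarray:
        return segment_image(self.network, image, tta=tta)

    def summary(self) -> str:
        s = self.state
        cfg = self.model.config
        lines = [
            "Interactive segmentation training results",
            "=" * 45,
            f"project:              {self.model.project.name}",
            f"epochs run:           {s.epoch_index}",
            f"best validation F1:   {s.best_val_f1:.4f}",
            f"checkpoints written:  {len(s.checkpoint_epochs)}",
            f"final train loss:     {s.train_loss_trace[-1]:.4f}" if s.train_loss_trace else "final train loss:     n/a",
            f"stop reason:          {s.stop_reason}",
            f"learning rate:        {cfg.learning_rate}",
            f"Nesterov momentum:    {cfg.nesterov_momentum}",
            f"batch size:           {cfg.batch_size}",
            f"subregion size:       {cfg.in_w}",
            f"trainable parameters: {self.network.num_params():,}",
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Validation-F1 and loss trajectories (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.history
        ax.plot(h["epoch"], h["val_f1"], label="val F1")
        ax.plot(h["epoch"], h["train_loss"], label="train loss", alpha=0.6)
        ax.set_xlabel("epoch")
        ax.legend()
        return ax
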