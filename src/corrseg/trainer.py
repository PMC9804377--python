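"""The interactive training loop.

Training starts once a project holds at least two saved annotations (one
each for training and validation) and then runs epoch after epoch, re-reading
the annotation folders every epoch so corrections saved mid-training enter
immediately.  An epoch is 612 network-input subregions sampled uniformly
with replacement from the training images (2n subregions once the training
set exceeds 306 images); each subregion is a random crop, augmented, and
optimized with plain SGD (lr 0.01, Nesterov momentum 0.99, no weight decay,
no schedule) under the masked dice+cross-entropy loss.  After every epoch
the pixelwise F1 over all annotated validation pixels is computed; strict
improvements over the best seen so far are checkpointed — so a transiently
diverged model is never saved — and training stops on its own after 60
consecutive epochs with neither an improvement nor an annotation change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .augment import AugmentationConfig, augment
from .inference import predict_probability, _pad_reflect
from .nn import (
    CONTEXT, FOREGROUND, UNDEFINED, SGDNesterov, UNet,
    f1_from_counts, masked_loss,
)
from .store import Project, assign_split, decode_annotation, load_image  # noqa: F401

log = logging.getLogger(__name__)

EPOCH_SUBREGIONS = 612        # initial epoch size, in network-input subregions
EPOCH_GROWTH_THRESHOLD = 306  # train-set size beyond which epochs grow as 2n
PATIENCE = 60                 # epochs without improvement/annotation before stopping


@dataclass
class TrainingConfig:
    learning_rate: float = 0.01
    nesterov_momentum: float = 0.99
    weight_decay: float = 0.0          # removed on purpose; must stay 0
    batch_size: int = 2
    in_w: int = 572                    # training subregion (network input) size
    early_stop_patience: int = PATIENCE
    epoch_subregions: int | None = None  # None -> the 612 / 2n rule
    max_epochs: int | None = None        # desk-scale cap; None = until early stop
    target_val_f1: float | None = None   # optional stop-on-reach, for short runs
    seed: int = 0

    def __post_init__(self):
        if self.weight_decay != 0.0:
            raise ValueError("weight decay is removed from this procedure")


@dataclass
class TrainingState:
    epoch_index: int = 0
    best_val_f1: float = -1.0
    epochs_since_improvement: int = 0
    val_f1_trace: list = field(default_factory=list)
    train_loss_trace: list = field(default_factory=list)
    checkpoint_epochs: list = field(default_factory=list)
    stop_reason: str = ""


def epoch_length(n_train: int) -> int:
    """Subregions per epoch: 612 up to 306 training images, then 2n."""
    if n_train < 1:
        raise ValueError("training requires at least one training annotation")
    return EPOCH_SUBREGIONS if n_train <= EPOCH_GROWTH_THRESHOLD else 2 * n_train


def find_image(dataset_dir: Path, annotation_path: Path) -> Path:
    stem = annotation_path.stem
    for cand in sorted(Path(dataset_dir).glob(stem + ".*")):
        if cand.suffix.lower() != ".csv":
            return cand
    raise FileNotFoundError(f"no dataset image for annotation {annotation_path.name}")


class _Cache:
    """Tiny mtime-aware cache of decoded images and annotations."""

    def __init__(self, limit: int = 64):
        self.limit = limit
        self._d: dict = {}

    def get(self, path: Path, loader):
        key = str(path)
        mtime = path.stat().st_mtime_ns
        hit = self._d.get(key)
        if hit is not None and hit[0] == mtime:
            return hit[1]
        value = loader(path)
        if len(self._d) >= self.limit:
            self._d.pop(next(iter(self._d)))
        self._d[key] = (mtime, value)
        return value


def sample_subregion(image, annotation, in_w: int, rng: np.random.Generator):
    """Uniform random in_w x in_w crop of an image/annotation pair.

    Images smaller than the window are reflect-padded (annotation padded as
    undefined) so desk-scale datasets below the canonical size remain usable.
    """
    h, w = annotation.shape
    if h < in_w or w < in_w:
        ph, pw = max(0, in_w - h), max(0, in_w - w)
        image = _pad_reflect(image, ((0, ph), (0, pw), (0, 0)))
        annotation = np.pad(annotation, ((0, ph), (0, pw)),
                            constant_values=UNDEFINED)
        h, w = annotation.shape
    top = int(rng.integers(0, h - in_w + 1))
    left = int(rng.integers(0, w - in_w + 1))
    return (image[top:top + in_w, left:left + in_w],
            annotation[top:top + in_w, left:left + in_w])


def crop_to_output(annotation: np.ndarray) -> np.ndarray:
    """Central crop matching the network's valid-core output footprint."""
    m = CONTEXT // 2
    return annotation[m:-m, m:-m]


def validation_f1(net: UNet, val_pairs) -> float:
    """Pixelwise F1 over every annotated pixel of the validation set.

    ``val_pairs`` yields (image, annotation) arrays.  Undefined pixels are
    excluded; true/false positive/negative counts are accumulated globally
    over all images.  Prediction uses the canonical inference window (the
    network is fully convolutional, so this is independent of the training
    crop size).
    """
    tp = fp = fn = 0
    annotated = 0
    for image, ann in val_pairs:
        prob = predict_probability(net, image)
        pred = prob >= 0.5
        mask = ann != UNDEFINED
        annotated += int(mask.sum())
        truth = ann == FOREGROUND
        tp += int((pred & truth & mask).sum())
        fp += int((pred & ~truth & mask).sum())
        fn += int((~pred & truth & mask).sum())
    if annotated == 0:
        raise ValueError("validation set has no annotated pixels")
    return f1_from_counts(tp, fp, fn)


class InteractiveTrainer:
    """Persistent training session for one project.

    Holds the live network, the optimizer (momentum survives across epochs)
    and the training state, so the F1 checkpoint gate compares against the
    best model ever seen — a prerequisite for the corrective loop, where a
    transient divergence must not overwrite a good saved model.
    """

    def __init__(
        self,
        project: Project,
        config: TrainingConfig | None = None,
        aug_config: AugmentationConfig | None = None,
    ):
        self.project = project
        self.config = config or TrainingConfig()
        self.aug_config = aug_config if aug_config is not None else AugmentationConfig()
        ckpt = project.latest_checkpoint()
        if ckpt is None:
            raise RuntimeError("project has no initial checkpoint")
        self.net = UNet.load(ckpt)
        self.opt = SGDNesterov(self.net.params(), lr=self.config.learning_rate,
                               momentum=self.config.nesterov_momentum)
        self.rng = np.random.default_rng(self.config.seed)
        self.cache = _Cache()
        self.state = TrainingState()
        self._seen = self._snapshot_annotations()
        log.info("training %s: seed=%d lr=%g momentum=%g", project.name,
                 self.config.seed, self.config.learning_rate,
                 self.config.nesterov_momentum)

    # -- bookkeeping --------------------------------------------------------

    def _snapshot_annotations(self):
        return {
            p.name: p.stat().st_mtime_ns
            for p in self.project.train_annotations() + self.project.val_annotations()
        }

    def _require_startable(self):
        if not self.project.train_annotations() or not self.project.val_annotations():
            raise RuntimeError(
                "training requires at least two saved annotations "
                "(one training and one validation)"
            )

    def _load_pair(self, ann_path):
        image = self.cache.get(find_image(self.project.dataset_dir, ann_path),
                               load_image)
        ann = self.cache.get(ann_path, decode_annotation)
        return image, ann

    # -- one epoch ----------------------------------------------------------

    def step_epoch(self) -> TrainingState:
        """One epoch of optimization, then validation + F1-gated checkpointing."""
        self._require_startable()
        cfg = self.config
        train_anns = self.project.train_annotations()
        n_train = len(train_anns)
        n_sub = cfg.epoch_subregions or epoch_length(n_train)

        losses = []
        remaining = n_sub
        while remaining > 0:
            b = min(cfg.batch_size, remaining)
            xs, anns = [], []
            for _ in range(b):
                image, ann = self._load_pair(
                    train_anns[int(self.rng.integers(n_train))]
                )
                img_c, ann_c = sample_subregion(image, ann, cfg.in_w, self.rng)
                img_c, ann_c = augment(img_c, ann_c, self.aug_config, self.rng)
                xs.append(img_c.transpose(2, 0, 1))
                anns.append(crop_to_output(ann_c))
            x = np.stack(xs).astype(np.float32)
            y = np.stack(anns)
            self.opt.zero_grad()
            # high-momentum SGD can transiently blow activations past
            # float32 range; the non-finite check below handles it, so the
            # intermediate overflow warnings are noise
            with np.errstate(over="ignore", invalid="ignore"):
                logits = self.net.forward(x, train=True)
                loss, grad = masked_loss(logits, y)
                # skip the update on a blown-up step: a non-finite gradient
                # would poison the weights and momentum permanently
                if grad is not None and np.isfinite(loss) and np.any(grad):
                    self.net.backward(grad)
                    self.opt.step()
            losses.append(loss)
            remaining -= b

        state = self.state
        state.train_loss_trace.append(float(np.mean(losses)))
        val_pairs = (self._load_pair(p) for p in self.project.val_annotations())
        # a transiently blown-up net scores ~0 here and is simply not
        # checkpointed; its overflow warnings are expected noise
        with np.errstate(over="ignore", invalid="ignore"):
            f1 = validation_f1(self.net, val_pairs)
        state.epoch_index += 1
        state.val_f1_trace.append(f1)
        if f1 > state.best_val_f1:
            state.best_val_f1 = f1
            state.epochs_since_improvement = 0
            self.project.save_checkpoint(self.net)
            state.checkpoint_epochs.append(state.epoch_index)
            improved = True
        else:
            state.epochs_since_improvement += 1
            improved = False

        now = self._snapshot_annotations()
        if now != self._seen:
            # new labels restart the search for an optimum
            state.epochs_since_improvement = 0
            self._seen = now

        log.info("epoch %d: loss %.4f, val F1 %.4f%s", state.epoch_index,
                 state.train_loss_trace[-1], f1, " *" if improved else "")
        return state

    # -- the full loop ------------------------------------------------------

    def run(self, stop_signal=None, on_epoch_end=None) -> TrainingState:
        cfg = self.config
        state = self.state
        self._require_startable()
        while True:
            if stop_signal is not None and stop_signal():
                state.stop_reason = "stop signal"
                break
            self.step_epoch()
            if on_epoch_end is not None:
                on_epoch_end(state, self.net)
            if (cfg.target_val_f1 is not None
                    and state.best_val_f1 >= cfg.target_val_f1):
                state.stop_reason = "target F1 reached"
                break
            if state.epochs_since_improvement >= cfg.early_stop_patience:
                state.stop_reason = "early stopping"
                break
            if cfg.max_epochs is not None and state.epoch_index >= cfg.max_epochs:
                state.stop_reason = "epoch cap"
                break
        return state


def run_training(
    project: Project,
    config: TrainingConfig | None = None,
    aug_config: AugmentationConfig | None = None,
    stop_signal=None,
    on_epoch_end=None,
) -> TrainingState:
    """Run interactive training for a project until early stopping.

    The network resumes from the project's latest checkpoint.  ``stop_signal``
    is an optional zero-argument callable polled once per epoch (the
    file-based 'stop_training' instruction is wired to it by the CLI);
    ``on_epoch_end(state, net)`` is an optional callback.
    """
    return InteractiveTrainer(project, config, aug_config).run(
        stop_signal=stop_signal, on_epoch_end=on_epoch_end
    )
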