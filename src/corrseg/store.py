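"""File-based state shared between an annotating client and a training server.

Everything lives under a single *sync directory*: datasets (image folders),
projects (annotations, segmentations, model checkpoints, messages) and a
JSON instruction queue.  Communication is entirely through files so the two
sides can run on different machines with any shared/synced filesystem
between them.

Annotations are RGBA PNGs: pure opaque red = foreground, pure opaque
green = background, fully transparent = undefined.  Segmentations are
single-channel 0/255 PNGs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .nn import BACKGROUND, FOREGROUND, UNDEFINED, NetworkConfig, UNet, build_network

log = logging.getLogger(__name__)

SETTINGS_FILENAME = "root_painter_settings.json"
PROJECT_SUFFIX = ".seg_proj"
CHECKPOINT_SUFFIX = ".npz"

_RED = np.array([255, 0, 0, 255], dtype=np.uint8)
_GREEN = np.array([0, 255, 0, 255], dtype=np.uint8)


# ---------------------------------------------------------------------------
# annotation / segmentation codecs


def encode_annotation(labels: np.ndarray, path) -> None:
    """Write a (H, W) label map (codes 0/1/2) as an RGBA PNG."""
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("annotation must be a 2-D label map")
    if not np.isin(labels, (UNDEFINED, FOREGROUND, BACKGROUND)).all():
        raise ValueError("annotation contains invalid label codes")
    rgba = np.zeros(labels.shape + (4,), dtype=np.uint8)
    rgba[labels == FOREGROUND] = _RED
    rgba[labels == BACKGROUND] = _GREEN
    Image.fromarray(rgba, mode="RGBA").save(path, format="PNG")


def decode_annotation(path) -> np.ndarray:
    """Read an annotation PNG back into a (H, W) label map (codes 0/1/2)."""
    rgba = np.asarray(Image.open(path).convert("RGBA"))
    labels = np.full(rgba.shape[:2], UNDEFINED, dtype=np.uint8)
    opaque = rgba[..., 3] > 0
    red = opaque & (rgba[..., 0] > 0) & (rgba[..., 1] == 0)
    green = opaque & (rgba[..., 1] > 0) & (rgba[..., 0] == 0)
    bad = opaque & ~red & ~green
    if bad.any():
        raise ValueError(f"{path}: {int(bad.sum())} pixels are neither "
                         "foreground (red), background (green) nor transparent")
    labels[red] = FOREGROUND
    labels[green] = BACKGROUND
    return labels


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary segmentation mask as a 0/255 single-channel PNG."""
    m = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(m, mode="L").save(path, format="PNG")


def read_mask(path) -> np.ndarray:
    return (np.asarray(Image.open(path).convert("L")) > 127).astype(np.uint8)


def load_image(path) -> np.ndarray:
    """Load an RGB image as float32 in [0, 1]; greyscale is replicated to 3 channels."""
    img = Image.open(path)
    if img.mode not in ("RGB", "L"):
        img = img.convert("RGB")
    a = np.asarray(img, dtype=np.float32) / 255.0
    if a.ndim == 2:
        a = np.stack([a] * 3, axis=-1)
    return a


# ---------------------------------------------------------------------------
# sync directory & projects


@dataclass
class SyncDirectory:
    root: Path

    @property
    def datasets(self) -> Path:
        return self.root / "datasets"

    @property
    def projects(self) -> Path:
        return self.root / "projects"

    @property
    def instructions(self) -> Path:
        return self.root / "instructions"


def init_sync_directory(root_path) -> SyncDirectory:
    """Create (idempotently) the canonical sync-directory layout."""
    root = Path(root_path)
    try:
        for sub in ("datasets", "projects", "instructions"):
            (root / sub).mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot initialize sync directory at {root}: {e}") from e
    return SyncDirectory(root)


def write_settings(home_dir, sync_dir) -> Path:
    p = Path(home_dir) / SETTINGS_FILENAME
    p.write_text(json.dumps({"sync_dir": str(sync_dir)}))
    return p


def read_settings(home_dir) -> Path:
    p = Path(home_dir) / SETTINGS_FILENAME
    return Path(json.loads(p.read_text())["sync_dir"])


@dataclass
class Project:
    """Binds a dataset to annotation sets, checkpoints and segmentations."""

    sync: SyncDirectory
    name: str
    dataset_name: str

    @property
    def folder(self) -> Path:
        return self.sync.projects / self.name

    @property
    def file(self) -> Path:
        return self.sync.projects / (self.name + PROJECT_SUFFIX)

    @property
    def dataset_dir(self) -> Path:
        return self.sync.datasets / self.dataset_name

    @property
    def train_annotation_dir(self) -> Path:
        return self.folder / "annotations" / "train"

    @property
    def val_annotation_dir(self) -> Path:
        return self.folder / "annotations" / "val"

    @property
    def segmentation_dir(self) -> Path:
        return self.folder / "segmentations"

    @property
    def model_dir(self) -> Path:
        return self.folder / "models"

    @property
    def message_dir(self) -> Path:
        return self.folder / "messages"

    # -- annotations --------------------------------------------------------

    def train_annotations(self) -> list[Path]:
        return sorted(self.train_annotation_dir.glob("*.png"))

    def val_annotations(self) -> list[Path]:
        return sorted(self.val_annotation_dir.glob("*.png"))

    def save_annotation(self, image_name: str, labels: np.ndarray) -> Path:
        """Save an annotation, assigning it to train or val by the 5:1 rule.

        The first annotation goes to the training set and the second to the
        validation set; afterwards an annotation joins the validation set
        exactly when the training set is at least five times its size.  An
        annotation for an image that already has one overwrites it in place
        (its set membership never changes, keeping train and val disjoint).
        """
        stem = Path(image_name).stem
        for d in (self.train_annotation_dir, self.val_annotation_dir):
            existing = d / (stem + ".png")
            if existing.exists():
                encode_annotation(labels, existing)
                return existing
        n_train = len(self.train_annotations())
        n_val = len(self.val_annotations())
        dest_dir = self.val_annotation_dir if assign_split(n_train, n_val) == "val" \
            else self.train_annotation_dir
        dest = dest_dir / (stem + ".png")
        encode_annotation(labels, dest)
        return dest

    # -- checkpoints --------------------------------------------------------

    def checkpoints(self) -> list[Path]:
        """Checkpoints ordered by number (zero-padded names sort lexically)."""
        return sorted(self.model_dir.glob("*" + CHECKPOINT_SUFFIX))

    def latest_checkpoint(self) -> Path | None:
        cps = self.checkpoints()
        return cps[-1] if cps else None

    def save_checkpoint(self, net: UNet) -> Path:
        cps = self.checkpoints()
        number = 1 + (int(cps[-1].name.split("_")[0]) if cps else 0)
        stamp = time.strftime("%Y-%m-%dT%H-%M-%S")
        path = self.model_dir / f"{number:06d}_{stamp}{CHECKPOINT_SUFFIX}"
        net.save(path)
        return path

    def write_message(self, payload: dict) -> Path:
        self.message_dir.mkdir(parents=True, exist_ok=True)
        path = self.message_dir / f"{time.time_ns():020d}.json"
        path.write_text(json.dumps(payload))
        return path


def assign_split(n_train: int, n_val: int) -> str:
    """Train/val assignment rule for the next annotation.

    The first annotation is for training, the second for validation, and
    afterwards an annotation goes to validation when the training set is at
    least five times the size of the validation set.
    """
    if n_train < 0 or n_val < 0:
        raise ValueError("counts must be non-negative")
    if n_train == 0 and n_val == 0:
        return "train"
    if n_val == 0:
        return "val"
    return "val" if n_train >= 5 * n_val else "train"


def create_project(
    sync: SyncDirectory,
    name: str,
    dataset_name: str,
    init_model: str = "random",
    config: NetworkConfig | None = None,
    seed: int = 0,
) -> Project:
    """Create a project folder tree plus its initial checkpoint.

    ``init_model`` is ``"random"`` (He-initialized weights) or the path of an
    existing checkpoint to copy in as checkpoint 1.
    """
    if not (sync.datasets / dataset_name).is_dir():
        raise FileNotFoundError(f"dataset {dataset_name!r} not found under {sync.datasets}")
    proj = Project(sync, name, dataset_name)
    if proj.file.exists() or proj.folder.exists():
        raise FileExistsError(f"project {name!r} already exists")
    for d in (proj.train_annotation_dir, proj.val_annotation_dir,
              proj.segmentation_dir, proj.model_dir, proj.message_dir):
        d.mkdir(parents=True)
    proj.file.write_text(json.dumps({
        "name": name,
        "dataset": dataset_name,
        "init_model": str(init_model),
    }, indent=2))
    if init_model == "random":
        net = build_network(config, init="he", seed=seed)
    else:
        net = UNet.load(init_model)
    proj.save_checkpoint(net)
    return proj


def open_project(sync: SyncDirectory, name: str) -> Project:
    proj = Project(sync, name, "")
    if not proj.file.exists():
        raise FileNotFoundError(f"no project named {name!r}")
    meta = json.loads(proj.file.read_text())
    proj.dataset_name = meta["dataset"]
    return proj


# ---------------------------------------------------------------------------
# instruction queue


@dataclass
class Instruction:
    kind: str  # start_training | stop_training | segment_folder
    payload: dict = field(default_factory=dict)

    KINDS = ("start_training", "stop_training", "segment_folder")

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind, "payload": self.payload})

    @classmethod
    def from_json(cls, s: str) -> "Instruction":
        d = json.loads(s)
        if d.get("kind") not in cls.KINDS:
            raise ValueError(f"unknown instruction kind {d.get('kind')!r}")
        return cls(d["kind"], d.get("payload", {}))


_counter = 0


def write_instruction(sync: SyncDirectory, instruction: Instruction) -> Path:
    """Queue one instruction as its own file, named so creation order sorts."""
    global _counter
    _counter += 1
    suffix = np.random.default_rng().integers(0, 1 << 30)
    path = sync.instructions / f"{time.time_ns():020d}_{_counter:06d}_{suffix:08x}.json"
    path.write_text(instruction.to_json())
    return path


def poll_instructions(sync: SyncDirectory) -> list[Instruction]:
    """Consume all pending instructions, oldest first, each exactly once.

    Files that fail to parse are skipped with a logged warning (and removed,
    so they are not retried forever).
    """
    out = []
    for path in sorted(sync.instructions.glob("*.json")):
        try:
            text = path.read_text()
            out.append(Instruction.from_json(text))
        except (ValueError, json.JSONDecodeError) as e:
            log.warning("skipping malformed instruction %s: %s", path.name, e)
        finally:
            try:
                path.unlink()
            except OSError:
                pass
    return out
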