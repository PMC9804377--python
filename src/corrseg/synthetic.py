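"""Ground-truthed synthetic scenes and a simulated corrective annotator.

Three structural archetypes mirror common plant/soil segmentation targets:

* ``roots`` — thin bright curvilinear tubes (random walks) on a darker
  textured background, for skeleton-length measurement;
* ``pores`` — dark round discs with diameters spanning the 2 mm counting
  threshold (at a declared px/mm), on a mottled lighter background;
* ``nodules`` — small bright blobs attached to curvilinear structures on a
  near-uniform background.

Masks are the exact rasterization of the generated geometry.  The simulated
annotator reproduces the corrective protocol: dense labels on the first six
"clear example" images, then foreground marks on false negatives and
background marks on false positives — whole error components, dilated by a
1-px brush halo whose pixels are labelled by their true class, truncated at
a pixel budget, with disagreements inside a small boundary-tolerance band
left alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import ndimage
from PIL import Image

from .augment import AugmentationConfig
from .inference import segment_image
from .measure import segmentation_metrics
from .nn import BACKGROUND, FOREGROUND, UNDEFINED, UNet
from .store import create_project, init_sync_directory
from .trainer import InteractiveTrainer, TrainingConfig

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SceneSpec:
    archetype: str = "pores"        # roots | pores | nodules
    size: int = 600                 # px (square scenes)
    n_objects_min: int = 4
    n_objects_max: int = 8
    px_per_mm: float = 10.0
    diameter_mm_range: tuple = (0.8, 4.0)   # pores: spans the 2 mm threshold
    root_radius_px: tuple = (2, 4)
    background_mottle: float = 0.08
    noise_level: float = 0.02
    seed: int = 0

    def with_seed(self, seed: int) -> "SceneSpec":
        return SceneSpec(**{**self.__dict__, "seed": seed})


@dataclass(frozen=True)
class AnnotatorPolicy:
    mode: str = "corrective"        # dense | corrective
    pixel_budget: int = 200_000     # labelled px per image, corrective mode
    error_tolerance_px: int = 1     # boundary slack left uncorrected
    initial_clear_examples: int = 6


# ---------------------------------------------------------------------------
# scene generation


def _mottled_background(size, level, amp, rng):
    coarse = rng.normal(0.0, 1.0, size=(size // 16 + 1, size // 16 + 1))
    coarse = ndimage.zoom(coarse, 16, order=1)[:size, :size]
    coarse = ndimage.gaussian_filter(coarse, 4)
    return level + amp * coarse / (np.abs(coarse).max() + 1e-9)


def _stamp_disc(canvas_mask, cy, cx, radius):
    size = canvas_mask.shape[0]
    r = int(np.ceil(radius))
    y0, y1 = max(0, cy - r), min(size, cy + r + 1)
    x0, x1 = max(0, cx - r), min(size, cx + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.ogrid[y0:y1, x0:x1]
    canvas_mask[y0:y1, x0:x1] |= ((yy - cy) ** 2 + (xx - cx) ** 2) <= radius ** 2


def _draw_walk(mask, rng, size, radius, n_steps=None, step=2.0, wobble=0.12):
    """Random-walk tube; returns the walk's path length inside the frame."""
    margin = 8
    y = float(rng.uniform(margin, size - margin))
    x = float(rng.uniform(margin, size - margin))
    theta = float(rng.uniform(0, 2 * np.pi))
    n_steps = n_steps or int(size / step)
    length = 0.0
    for _ in range(n_steps):
        _stamp_disc(mask, int(round(y)), int(round(x)), radius)
        theta += float(rng.normal(0.0, wobble))
        ny, nx = y + step * np.sin(theta), x + step * np.cos(theta)
        if not (margin <= ny < size - margin and margin <= nx < size - margin):
            break
        length += step
        y, x = ny, nx
    return length


def generate_scene(spec: SceneSpec):
    """Deterministic (per seed) synthetic scene.

    Returns ``(image, mask, info)``: an (H, W, 3) float image in [0, 1], the
    exact uint8 ground-truth mask, and bookkeeping (object count, path
    length for roots).
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    mask = np.zeros((size, size), dtype=bool)
    info: dict = {"archetype": spec.archetype}
    n_obj = int(rng.integers(spec.n_objects_min, spec.n_objects_max + 1))

    if spec.archetype == "pores":
        bg = _mottled_background(size, 0.55, spec.background_mottle, rng)
        placed = []
        radii_mm = rng.uniform(*spec.diameter_mm_range, size=n_obj) / 2.0
        for r_mm in radii_mm:
            r_px = r_mm * spec.px_per_mm
            for _ in range(200):  # rejection-sample non-touching placements
                cy = int(rng.integers(int(r_px) + 4, size - int(r_px) - 4))
                cx = int(rng.integers(int(r_px) + 4, size - int(r_px) - 4))
                if all(np.hypot(cy - py, cx - px) > r_px + pr + 6
                       for py, px, pr in placed):
                    placed.append((cy, cx, r_px))
                    _stamp_disc(mask, cy, cx, r_px)
                    break
        info["n_objects"] = len(placed)
        info["diameters_px"] = [2 * r for _, _, r in placed]
        img = np.where(mask, 0.15, bg)

    elif spec.archetype == "roots":
        bg = _mottled_background(size, 0.25, spec.background_mottle, rng)
        total = 0.0
        for _ in range(n_obj):
            radius = int(rng.integers(spec.root_radius_px[0],
                                      spec.root_radius_px[1] + 1))
            total += _draw_walk(mask, rng, size, radius)
        info["n_objects"] = n_obj
        info["path_length_px"] = total
        img = np.where(mask, 0.8, bg)

    elif spec.archetype == "nodules":
        bg = np.full((size, size), 0.78)
        tubes = np.zeros_like(mask)
        for _ in range(max(1, n_obj // 3)):
            _draw_walk(tubes, rng, size, 2)
        tube_px = np.argwhere(tubes)
        placed = 0
        for _ in range(n_obj):
            if len(tube_px) == 0:
                break
            cy, cx = tube_px[rng.integers(len(tube_px))]
            r = float(rng.uniform(3.5, 7.0))
            _stamp_disc(mask, int(cy), int(cx), r)
            placed += 1
        info["n_objects"] = placed
        img = np.where(tubes & ~mask, 0.5, bg)
        img = np.where(mask, 0.95, img)

    else:
        raise ValueError(f"unknown archetype {spec.archetype!r}")

    img = img + rng.normal(0.0, spec.noise_level, size=(size, size))
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    image = np.stack([img] * 3, axis=-1)
    # exact rasterization contract: the mask is the drawn geometry itself
    return image, mask.astype(np.uint8), info


def save_scene_png(image: np.ndarray, path) -> None:
    Image.fromarray((image * 255).round().astype(np.uint8)).save(path, format="PNG")


# ---------------------------------------------------------------------------
# simulated annotator


def simulate_annotation(
    prediction: np.ndarray,
    truth: np.ndarray,
    policy: AnnotatorPolicy,
    rng: np.random.Generator,
) -> np.ndarray:
    """Label map (0/1/2) a corrective (or dense) annotator would produce."""
    prediction = np.asarray(prediction) > 0
    truth = np.asarray(truth) > 0
    if prediction.shape != truth.shape:
        raise ValueError("prediction and truth dimensions differ")
    labels = np.full(truth.shape, UNDEFINED, dtype=np.uint8)
    if policy.mode == "dense":
        labels[truth] = FOREGROUND
        labels[~truth] = BACKGROUND
        return labels
    if policy.mode != "corrective":
        raise ValueError(f"unknown annotator mode {policy.mode!r}")

    tol = policy.error_tolerance_px
    if tol > 0:
        band = ndimage.binary_dilation(truth, iterations=tol) & ~ndimage.binary_erosion(
            truth, iterations=tol, border_value=0
        )
    else:
        band = np.zeros_like(truth)
    errors = (prediction ^ truth) & ~band
    if not errors.any():
        return labels

    comp, n_comp = ndimage.label(errors, structure=np.ones((3, 3), dtype=int))
    order = rng.permutation(n_comp) + 1
    budget = policy.pixel_budget
    for ci in order:
        if budget <= 0:
            break
        comp_mask = comp == ci
        brushed = ndimage.binary_dilation(comp_mask, iterations=1) & ~band
        px = np.argwhere(brushed)
        if len(px) > budget:
            px = px[:budget]
        sel = np.zeros_like(truth)
        sel[px[:, 0], px[:, 1]] = True
        labels[sel & truth] = FOREGROUND
        labels[sel & ~truth] = BACKGROUND
        budget -= len(px)
    return labels


# ---------------------------------------------------------------------------
# project bootstrap + corrective session


def build_synthetic_project(
    root,
    spec: SceneSpec,
    n_images: int,
    name: str = "synthetic",
    seed: int = 0,
    net_config=None,
):
    """Create a sync dir, a dataset of generated scenes, and a fresh project.

    Returns ``(project, truths)`` where ``truths`` maps image name to its
    ground-truth mask.
    """
    sync = init_sync_directory(root)
    ds_dir = sync.datasets / f"{name}_scenes"
    ds_dir.mkdir(parents=True, exist_ok=True)
    truths = {}
    for i in range(n_images):
        image, mask, _ = generate_scene(spec.with_seed(seed * 10_000 + i))
        fname = f"scene_{i:03d}.png"
        save_scene_png(image, ds_dir / fname)
        truths[fname] = mask
    project = create_project(sync, name, ds_dir.name, init_model="random",
                             config=net_config, seed=seed)
    return project, truths


def run_corrective_session(
    root,
    spec: SceneSpec,
    n_images: int = 30,
    policy: AnnotatorPolicy | None = None,
    train_config: TrainingConfig | None = None,
    aug_config: AugmentationConfig | None = None,
    epochs_per_image: int = 1,
    train_start_image: int | None = None,
    seed: int = 0,
    net_config=None,
) -> pd.DataFrame:
    """Replay the interactive corrective-annotation protocol on synthetic scenes.

    The first ``policy.initial_clear_examples`` images get dense "clear
    example" annotations; every later image is first segmented with the
    current model, scored against the ground truth, and corrected only where
    the prediction is wrong beyond the tolerance.  Training runs between
    images (``epochs_per_image`` epochs), starting once the image index
    reaches ``train_start_image`` — by default the end of the clear-example
    warm-up, so the optimizer always begins from a diverse dense training
    set (starting from one or two images is exactly the regime the warm-up
    exists to avoid).  Returns one log row per image: whether it was
    corrected, how many pixels the corrections took, and the dice against
    the ground truth.
    """
    policy = policy or AnnotatorPolicy()
    train_config = train_config or TrainingConfig(seed=seed)
    rng = np.random.default_rng(seed + 1)
    project, truths = build_synthetic_project(
        root, spec, n_images, seed=seed, net_config=net_config
    )
    names = sorted(truths)
    rows = []
    # the model used for segmenting is always the best checkpoint so far;
    # the persistent trainer below keeps its own live network
    net = UNet.load(project.latest_checkpoint())
    net_ckpt = project.latest_checkpoint()
    trainer: InteractiveTrainer | None = None
    from .store import load_image  # local import avoids a cycle at top level

    for i, fname in enumerate(names):
        image = load_image(project.dataset_dir / fname)
        truth = truths[fname]
        latest = project.latest_checkpoint()
        if latest != net_ckpt:
            net = UNet.load(latest)
            net_ckpt = latest
        pred = segment_image(net, image)
        dice = segmentation_metrics(pred, truth).dice
        if i < policy.initial_clear_examples:
            labels = simulate_annotation(pred, truth,
                                         AnnotatorPolicy(mode="dense"), rng)
        else:
            labels = simulate_annotation(pred, truth, policy, rng)
        n_corr = int((labels != UNDEFINED).sum())
        corrected = n_corr > 0
        if corrected:
            project.save_annotation(fname, labels)
        rows.append({
            "image_index": i,
            "image_name": fname,
            "dense": i < policy.initial_clear_examples,
            "corrected": corrected,
            "correction_pixels": n_corr,
            "dice_vs_truth": dice,
            "n_train": len(project.train_annotations()),
            "n_val": len(project.val_annotations()),
        })
        start_at = (policy.initial_clear_examples - 1
                    if train_start_image is None else train_start_image)
        if (trainer is None and i >= start_at
                and project.train_annotations() and project.val_annotations()):
            trainer = InteractiveTrainer(project, train_config, aug_config)
        if trainer is not None:
            for _ in range(epochs_per_image):
                trainer.step_epoch()
    return pd.DataFrame(rows)
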