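"""Training-dataset construction: image sampling, split planning, tiling.

Source images larger than the target size are split into a grid of (almost)
equally sized pieces.  Every possible (rows, cols) grid whose pieces stay
above the minimum size is scored by how far the pieces are from square plus
how far they are from the target size, both dimensionless, and the grid with
the smallest sum wins.  From the chosen grid, up to a configured number of
tiles per image are picked at random.  All images in a dataset must be at
least 572 px in both dimensions so a full network input window can always be
cropped from them.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

log = logging.getLogger(__name__)

MIN_SIZE = 572          # px, network input window
CLOSE_FACTOR = 1.3      # "close to target": no split below target * this

IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg", ".tif", ".tiff")


@dataclass(frozen=True)
class SplitPlan:
    rows: int
    cols: int
    piece_height: int  # nominal piece size; the last row/col absorbs remainders
    piece_width: int

    @property
    def n_pieces(self) -> int:
        return self.rows * self.cols


@dataclass(frozen=True)
class DatasetSpec:
    source_dir: Path
    name: str
    n_images_to_sample: int
    max_tiles_per_image: int
    target_size: int = 750
    min_size: int = MIN_SIZE
    seed: int = 0


def split_objective(pw: int, ph: int, target: int) -> float:
    """Squareness distance + target distance for one candidate piece size.

    Both terms are dimensionless and vanish exactly when the piece is square
    and exactly target-sized, so a perfect grid always has objective 0.
    """
    squareness = max(pw, ph) / min(pw, ph) - 1.0
    target_distance = (abs(pw - target) + abs(ph - target)) / (2.0 * target)
    return squareness + target_distance


def plan_split(
    width: int,
    height: int,
    target: int,
    min_size: int = MIN_SIZE,
    close_factor: float = CLOSE_FACTOR,
) -> SplitPlan:
    """Choose the grid that minimizes the split objective.

    Images already close to the target (both dimensions <= close_factor *
    target) are kept whole.  Candidate grids use nominal piece sizes
    height // rows by width // cols; the last row/column absorbs the integer
    remainder, so pieces within one grid differ by a few px at most and every
    piece stays >= min_size.
    """
    if width < min_size or height < min_size:
        raise ValueError(f"image {width}x{height} is below the minimum size {min_size}")
    if width <= close_factor * target and height <= close_factor * target:
        return SplitPlan(1, 1, height, width)
    best = None
    best_key = None
    for rows in range(1, height // min_size + 1):
        ph = height // rows
        for cols in range(1, width // min_size + 1):
            pw = width // cols
            if ph < min_size or pw < min_size:
                continue
            obj = split_objective(pw, ph, target)
            key = (obj, rows * cols, rows)  # tie-break: fewer pieces, then fewer rows
            if best_key is None or key < best_key:
                best_key = key
                best = SplitPlan(rows, cols, ph, pw)
    return best


def piece_boxes(plan: SplitPlan, width: int, height: int):
    """Yield (row, col, top, left, bottom, right) boxes tiling the image exactly."""
    for r in range(plan.rows):
        top = r * plan.piece_height
        bottom = height if r == plan.rows - 1 else top + plan.piece_height
        for c in range(plan.cols):
            left = c * plan.piece_width
            right = width if c == plan.cols - 1 else left + plan.piece_width
            yield r, c, top, left, bottom, right


def list_images(folder) -> list[Path]:
    return sorted(
        p for p in Path(folder).iterdir()
        if p.suffix.lower() in IMAGE_SUFFIXES and p.is_file()
    )


def build_training_dataset(spec: DatasetSpec, sync_datasets_dir) -> Path:
    """Cut a training dataset into ``sync_datasets_dir / spec.name``.

    A seeded random sample of ``n_images_to_sample`` source images is drawn;
    each is either copied whole (when it needs no split) or cut per its
    :func:`plan_split`, keeping at most ``max_tiles_per_image`` randomly
    chosen tiles.  Undersized images are skipped with a warning.
    """
    src = list_images(spec.source_dir)
    if not src:
        raise FileNotFoundError(f"no images found in {spec.source_dir}")
    if spec.n_images_to_sample > len(src):
        raise ValueError(
            f"asked to sample {spec.n_images_to_sample} of {len(src)} images"
        )
    rng = np.random.default_rng(spec.seed)
    chosen = rng.choice(len(src), size=spec.n_images_to_sample, replace=False)
    out_dir = Path(sync_datasets_dir) / spec.name
    out_dir.mkdir(parents=True, exist_ok=True)
    for i in sorted(chosen):
        path = src[i]
        with Image.open(path) as img:
            w, h = img.size
            if w < spec.min_size or h < spec.min_size:
                log.warning("skipping %s: %dx%d below minimum %d",
                            path.name, w, h, spec.min_size)
                continue
            plan = plan_split(w, h, spec.target_size, spec.min_size)
            if plan.n_pieces == 1:
                if path.suffix.lower() == ".png":
                    shutil.copy(path, out_dir / path.name)
                else:
                    img.save(out_dir / (path.stem + ".png"), format="PNG")
                continue
            boxes = list(piece_boxes(plan, w, h))
            k = min(spec.max_tiles_per_image, len(boxes))
            picks = rng.choice(len(boxes), size=k, replace=False)
            for j in sorted(picks):
                r, c, top, left, bottom, right = boxes[j]
                tile = img.crop((left, top, right, bottom))
                tile.save(out_dir / f"{path.stem}_{r:02d}_{c:02d}.png", format="PNG")
    return out_dir
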