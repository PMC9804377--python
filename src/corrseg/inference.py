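"""Segmentation inference: tiled prediction, flip TTA, model ensembling.

Images are reflect-padded by 36 px so every output pixel sees full context,
then covered by input windows (572 px by default, shrunk to fit small
images) whose 72-px-smaller valid cores tile the original image; windows at
the far edges are shifted inward to stay inside the padded image, with
later tiles overwriting in the (value-identical for a deterministic,
translation-local model) overlap.  The foreground probability is averaged
over the identity and a horizontally flipped pass — and over all supplied
models — before thresholding at 0.5 (ties count as foreground).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import list_images
from .nn import CONTEXT, UNet
from .store import load_image, write_mask

log = logging.getLogger(__name__)

MARGIN = CONTEXT // 2  # 36 px of context on each side


@dataclass(frozen=True)
class Tile:
    """One window: input box on the padded image, core box on the original."""

    in_top: int
    in_left: int
    core_top: int
    core_left: int
    core_h: int
    core_w: int


def tile_layout(height: int, width: int, in_size: int) -> list[Tile]:
    """Cover an (height, width) image with valid cores of in_size - 72 windows."""
    core = in_size - CONTEXT
    tiles = []
    tops = _starts(height, core)
    lefts = _starts(width, core)
    for t in tops:
        for l in lefts:
            ch = min(core, height - t)
            cw = min(core, width - l)
            tiles.append(Tile(t, l, t, l, ch, cw))
    return tiles


def _starts(extent: int, core: int) -> list[int]:
    if extent <= core:
        return [0]
    s = list(range(0, extent - core, core))
    s.append(extent - core)  # last window aligned to the far edge
    return s


def _pad_reflect(a: np.ndarray, pads) -> np.ndarray:
    """Reflect padding that tolerates pads wider than the array itself."""
    pads = [list(p) for p in pads]
    while any(p[0] > 0 or p[1] > 0 for p in pads):
        step = []
        for (lo, hi), size in zip(pads, a.shape):
            cap = max(size - 1, 0)
            step.append((min(lo, cap), min(hi, cap)))
        if all(s == (0, 0) for s in step):  # 1-px axis: replicate instead
            step = [(min(lo, 1), min(hi, 1)) for lo, hi in pads]
            a = np.pad(a, step, mode="edge")
        else:
            a = np.pad(a, step, mode="reflect")
        pads = [[lo - s[0], hi - s[1]] for (lo, hi), s in zip(pads, step)]
    return a


def predict_probability(model, image: np.ndarray, in_size: int = 572) -> np.ndarray:
    """Single-model, single-orientation foreground probability for one image.

    ``model`` needs a ``forward_prob((1,3,h,w)) -> (1,h-72,w-72)`` method.
    The image ((H, W, 3) float in [0, 1]) is reflect-padded by the context
    margin; small images additionally get padding up to the minimum window.
    """
    h, w = image.shape[:2]
    in_size = min(in_size, max(h, w) + CONTEXT)
    in_size = max(in_size, CONTEXT + 8)
    core = in_size - CONTEXT
    pad_b = max(0, core - h)
    pad_r = max(0, core - w)
    padded = _pad_reflect(image, ((MARGIN, MARGIN + pad_b), (MARGIN, MARGIN + pad_r), (0, 0)))
    prob = np.zeros((h, w), dtype=np.float32)
    for tile in tile_layout(h, w, in_size):
        window = padded[
            tile.in_top : tile.in_top + in_size,
            tile.in_left : tile.in_left + in_size,
        ]
        batch = window.transpose(2, 0, 1)[None]
        p = model.forward_prob(batch)[0]
        prob[
            tile.core_top : tile.core_top + tile.core_h,
            tile.core_left : tile.core_left + tile.core_w,
        ] = p[: tile.core_h, : tile.core_w]
    return prob


def segment_image(
    models,
    image: np.ndarray,
    in_size: int = 572,
    tta: bool = True,
    threshold: float = 0.5,
    return_probability: bool = False,
):
    """Binary mask for one image: mean fg probability over models x {id, hflip}.

    Ties at the threshold are classified foreground.
    """
    if isinstance(models, UNet) or not isinstance(models, (list, tuple)):
        models = [models]
    if len(models) == 0:
        raise ValueError("at least one model is required")
    h, w = image.shape[:2]
    acc = np.zeros((h, w), dtype=np.float64)
    n = 0
    flipped = image[:, ::-1].copy()
    for m in models:
        acc += predict_probability(m, image, in_size)
        n += 1
        if tta:
            acc += predict_probability(m, flipped, in_size)[:, ::-1]
            n += 1
    prob = (acc / n).astype(np.float32)
    mask = (prob >= threshold).astype(np.uint8)
    if return_probability:
        return mask, prob
    return mask


def segment_folder(
    models,
    in_dir,
    out_dir,
    in_size: int = 572,
    tta: bool = True,
    force: bool = False,
) -> list[Path]:
    """Segment every readable image in ``in_dir`` into 0/255 PNGs in ``out_dir``.

    Existing outputs are kept unless ``force``; unreadable inputs are skipped
    with a warning.  Returns the list of mask paths written.
    """
    images = list_images(in_dir)
    if not images:
        raise FileNotFoundError(f"no images in {in_dir}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for path in images:
        dest = out_dir / (path.stem + ".png")
        if dest.exists() and not force:
            continue
        try:
            img = load_image(path)
        except Exception as e:  # corrupt file: keep going
            log.warning("cannot read %s: %s", path.name, e)
            continue
        mask = segment_image(models, img, in_size=in_size, tta=tta)
        write_mask(mask, dest)
        written.append(dest)
    return written
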