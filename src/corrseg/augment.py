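"""Training-time augmentation of image/annotation pairs.

Each transform in the configured list is applied independently with
probability 0.8, in a freshly shuffled order every call.  Geometric
transforms (flips, 90° rotations, elastic grid deformation) act identically
on image and annotation, with nearest-neighbour warping for the annotation
so labels stay categorical; photometric transforms (brightness/contrast,
additive noise, blur) touch the image only.  Elastic displacement fields are
drawn at one eighth of the image size and bilinearly upsampled before
warping, which keeps field generation cheap on large tiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class AugmentationConfig:
    apply_probability: float = 0.8
    elastic_map_downscale: int = 8
    elastic_amplitude: float = 12.0   # px, displacement std at the coarse scale
    elastic_sigma: float = 1.5        # coarse-scale Gaussian smoothing of the field
    brightness_range: float = 0.15    # additive, on [0,1] intensities
    contrast_range: float = 0.2       # multiplicative, 1 +/- range
    noise_sigma: float = 0.03
    blur_sigma_max: float = 1.5
    transforms: tuple[str, ...] = (
        "hflip", "vflip", "rot90", "elastic",
        "brightness_contrast", "noise", "blur",
    )

    GEOMETRIC = frozenset({"hflip", "vflip", "rot90", "elastic"})

    def __post_init__(self):
        if not 0.0 <= self.apply_probability <= 1.0:
            raise ValueError("apply_probability must be in [0, 1]")


def coarse_field_shape(h: int, w: int, downscale: int = 8) -> tuple[int, int]:
    """Shape of the displacement maps before upsampling (ceil of size/downscale)."""
    return math.ceil(h / downscale), math.ceil(w / downscale)


def elastic_deform(
    image: np.ndarray,
    annotation: np.ndarray,
    rng: np.random.Generator,
    downscale: int = 8,
    amplitude: float = 12.0,
    sigma: float = 1.5,
):
    """Elastic grid deformation with coarse (1/downscale) displacement maps.

    Returns the warped pair; ``amplitude == 0`` is the identity.  The image
    is interpolated bilinearly, the annotation with nearest neighbour.
    """
    h, w = annotation.shape
    if image.shape[:2] != (h, w):
        raise ValueError("image and annotation dimensions differ")
    if amplitude == 0:
        return image, annotation
    ch, cw = coarse_field_shape(h, w, downscale)
    coarse = rng.normal(0.0, amplitude, size=(2, ch, cw))
    if sigma > 0:
        coarse = ndimage.gaussian_filter(coarse, sigma=(0, sigma, sigma))
    dy = _upsample_bilinear(coarse[0], h, w)
    dx = _upsample_bilinear(coarse[1], h, w)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.stack([rr + dy, cc + dx])
    warped_img = np.empty_like(image)
    for ch_i in range(image.shape[2]):
        warped_img[..., ch_i] = ndimage.map_coordinates(
            image[..., ch_i], coords, order=1, mode="reflect"
        )
    warped_ann = ndimage.map_coordinates(annotation, coords, order=0, mode="reflect")
    return warped_img, warped_ann


def _upsample_bilinear(a: np.ndarray, h: int, w: int) -> np.ndarray:
    """Smooth upsampling of a coarse field to (h, w)."""
    zoom = (h / a.shape[0], w / a.shape[1])
    out = ndimage.zoom(a, zoom, order=1, grid_mode=True, mode="nearest")
    return out[:h, :w]


def augment(
    image: np.ndarray,
    annotation: np.ndarray,
    config: AugmentationConfig,
    rng: np.random.Generator,
):
    """Apply the configured transforms in random order, each with prob. 0.8."""
    if image.shape[:2] != annotation.shape:
        raise ValueError("image and annotation dimensions differ")
    image = image.astype(np.float32, copy=True)
    annotation = annotation.copy()
    order = list(config.transforms)
    rng.shuffle(order)
    for name in order:
        if rng.random() >= config.apply_probability:
            continue
        image, annotation = _apply(name, image, annotation, config, rng)
    return image, annotation


def _apply(name, img, ann, cfg, rng):
    if name == "hflip":
        return img[:, ::-1].copy(), ann[:, ::-1].copy()
    if name == "vflip":
        return img[::-1].copy(), ann[::-1].copy()
    if name == "rot90":
        # only 180° keeps the shape of non-square inputs
        k = int(rng.integers(1, 4)) if img.shape[0] == img.shape[1] else 2
        return np.rot90(img, k).copy(), np.rot90(ann, k).copy()
    if name == "elastic":
        return elastic_deform(
            img, ann, rng,
            downscale=cfg.elastic_map_downscale,
            amplitude=cfg.elastic_amplitude,
            sigma=cfg.elastic_sigma,
        )
    if name == "brightness_contrast":
        b = rng.uniform(-cfg.brightness_range, cfg.brightness_range)
        c = 1.0 + rng.uniform(-cfg.contrast_range, cfg.contrast_range)
        out = np.clip((img - 0.5) * c + 0.5 + b, 0.0, 1.0)
        return out.astype(np.float32), ann
    if name == "noise":
        out = img + rng.normal(0.0, cfg.noise_sigma, size=img.shape)
        return np.clip(out, 0.0, 1.0).astype(np.float32), ann
    if name == "blur":
        s = rng.uniform(0.2, cfg.blur_sigma_max)
        out = ndimage.gaussian_filter(img, sigma=(s, s, 0))
        return out.astype(np.float32), ann
    raise ValueError(f"unknown transform {name!r}")
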