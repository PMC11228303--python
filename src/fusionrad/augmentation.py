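"""Training-time augmentations with the stated probabilities and ranges.

Seven augmentations: per-axis random flips (p=0.5 each), Gaussian blur
(sigma ~ U(0.5, 1.5), p=0.15), brightness scaling (U(0.7, 1.3), p=0.15),
zoom-in with resize-back (factor U(1.0, 1.4), p=0.15), additive Gaussian
noise (variance ~ U(0, 0.33), p=0.15), contrast scaling clipped to the
original range (U(0.65, 1.5), p=0.15), and a biased patch crop that with
p=0.4 is guaranteed to contain lesion voxels.

Geometric transforms act congruently on image, mask and foreground; the
label is never touched.  All randomness flows through the provided
``numpy.random.Generator``, so a fixed seed gives an identical
augmentation stream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy import ndimage

from .preprocessing import VolumeSample

__all__ = [
    "AugmentationSpec",
    "random_flip",
    "random_gaussian_blur",
    "random_brightness",
    "random_contrast",
    "random_noise",
    "random_zoom",
    "biased_crop",
    "augment",
]


@dataclass(frozen=True)
class AugmentationSpec:
    p_flip_per_axis: float = 0.5
    p_blur: float = 0.15
    blur_sigma_range: tuple[float, float] = (0.5, 1.5)
    p_brightness: float = 0.15
    brightness_range: tuple[float, float] = (0.7, 1.3)
    p_zoom: float = 0.15
    zoom_range: tuple[float, float] = (1.0, 1.4)
    p_noise: float = 0.15
    noise_var_range: tuple[float, float] = (0.0, 0.33)
    p_contrast: float = 0.15
    contrast_range: tuple[float, float] = (0.65, 1.5)
    crop_shape: tuple[int, ...] = (5, 128, 128, 128)
    p_biased_crop_foreground: float = 0.4
    seed: int = 0

    def __post_init__(self):
        for name in ("p_flip_per_axis", "p_blur", "p_brightness", "p_zoom",
                     "p_noise", "p_contrast", "p_biased_crop_foreground"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("blur_sigma_range", "brightness_range", "zoom_range",
                     "noise_var_range", "contrast_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered low <= high")


def _copy(sample: VolumeSample, image=None, mask=None, foreground=None) -> VolumeSample:
    return VolumeSample(
        image=sample.image.copy() if image is None else image,
        mask=None if sample.mask is None else (sample.mask.copy() if mask is None else mask),
        label=sample.label,
        foreground=None
        if sample.foreground is None
        else (sample.foreground.copy() if foreground is None else foreground),
        meta=dict(sample.meta),
    )


def random_flip(sample: VolumeSample, rng: np.random.Generator,
                p: float = 0.5) -> VolumeSample:
    """Independently reverse each spatial axis with probability ``p``;
    mask and foreground are flipped identically."""
    ndim_sp = sample.image.ndim - 1
    flips = [bool(rng.random() < p) for _ in range(ndim_sp)]
    image, mask, fg = sample.image, sample.mask, sample.foreground
    for ax, do in enumerate(flips):
        if do:
            image = np.flip(image, axis=ax + 1)
            if mask is not None:
                mask = np.flip(mask, axis=ax)
            if fg is not None:
                fg = np.flip(fg, axis=ax)
    return _copy(sample, image=image.copy(),
                 mask=None if mask is None else mask.copy(),
                 foreground=None if fg is None else fg.copy())


def random_gaussian_blur(sample: VolumeSample, rng: np.random.Generator,
                         p: float = 0.15,
                         sigma_range: tuple[float, float] = (0.5, 1.5)) -> VolumeSample:
    """With probability p, blur the image channels (never the mask)."""
    if rng.random() >= p:
        return _copy(sample)
    sigma = rng.uniform(*sigma_range)
    image = np.stack([
        ndimage.gaussian_filter(sample.image[c], sigma=sigma, mode="reflect")
        for c in range(sample.image.shape[0])
    ])
    return _copy(sample, image=image)


def random_brightness(sample: VolumeSample, rng: np.random.Generator,
                      p: float = 0.15,
                      factor_range: tuple[float, float] = (0.7, 1.3)) -> VolumeSample:
    """With probability p, multiply all voxels by a uniform factor."""
    if rng.random() >= p:
        return _copy(sample)
    return _copy(sample, image=sample.image * rng.uniform(*factor_range))


def random_contrast(sample: VolumeSample, rng: np.random.Generator,
                    p: float = 0.15,
                    factor_range: tuple[float, float] = (0.65, 1.5)) -> VolumeSample:
    """With probability p, scale intensities then clip ("trim") back to the
    original per-channel min/max range."""
    if rng.random() >= p:
        return _copy(sample)
    factor = rng.uniform(*factor_range)
    image = sample.image.copy()
    for c in range(image.shape[0]):
        lo, hi = image[c].min(), image[c].max()
        image[c] = np.clip(image[c] * factor, lo, hi)
    return _copy(sample, image=image)


def random_noise(sample: VolumeSample, rng: np.random.Generator,
                 p: float = 0.15,
                 var_range: tuple[float, float] = (0.0, 0.33)) -> VolumeSample:
    """With probability p, add zero-mean Gaussian noise with a variance
    drawn uniformly from ``var_range`` (intensities assumed z-scored)."""
    if rng.random() >= p:
        return _copy(sample)
    var = rng.uniform(*var_range)
    noise = rng.normal(0.0, np.sqrt(var), size=sample.image.shape)
    return _copy(sample, image=sample.image + noise)


def random_zoom(sample: VolumeSample, rng: np.random.Generator,
                p: float = 0.15,
                factor_range: tuple[float, float] = (1.0, 1.4)) -> VolumeSample:
    """With probability p, magnify: crop the central 1/f of the field and
    resize back to the original shape (cubic for the image, nearest for
    mask and foreground).  Output shape always equals input shape."""
    if rng.random() >= p:
        return _copy(sample)
    f = rng.uniform(*factor_range)
    if f == 1.0:
        return _copy(sample)
    spatial = sample.image.shape[1:]
    crop = [max(2, int(round(s / f))) for s in spatial]
    starts = [(s - c) // 2 for s, c in zip(spatial, crop)]
    sl = tuple(slice(st, st + c) for st, c in zip(starts, crop))
    zoom_facs = [s / c for s, c in zip(spatial, crop)]

    def back(arr, order):
        out = ndimage.zoom(arr.astype(np.float64), zoom_facs, order=order,
                           mode="nearest", grid_mode=True)
        # grid_mode keeps the output size exactly round(c * zoom)
        assert out.shape == spatial
        return out

    image = np.stack([back(sample.image[c][sl], 3) for c in range(sample.image.shape[0])])
    mask = None if sample.mask is None else back(sample.mask[sl], 0) > 0.5
    fg = None if sample.foreground is None else back(sample.foreground[sl], 0) > 0.5
    return _copy(sample, image=image, mask=mask, foreground=fg)


def _pad_to(sample: VolumeSample, spatial: tuple[int, ...]) -> VolumeSample:
    pads = [(0, max(0, t - s)) for s, t in zip(sample.spatial_shape, spatial)]
    if not any(hi for _, hi in pads):
        return sample
    image = np.pad(sample.image, [(0, 0)] + pads)
    mask = None if sample.mask is None else np.pad(sample.mask, pads)
    fg = None if sample.foreground is None else np.pad(sample.foreground, pads)
    return _copy(sample, image=image, mask=mask, foreground=fg)


def biased_crop(sample: VolumeSample, rng: np.random.Generator,
                crop_shape: tuple[int, ...] = (5, 128, 128, 128),
                p_foreground: float = 0.4) -> VolumeSample:
    """Random patch of ``crop_shape`` = (C, spatial...).

    With probability ``p_foreground`` the window is drawn uniformly among
    all windows containing at least one mask-positive voxel (so prominent
    lesion voxels are retained); otherwise uniformly among all windows.
    Inputs smaller than the crop are zero-padded first.
    """
    want_spatial = tuple(crop_shape[1:])
    if len(want_spatial) != sample.image.ndim - 1:
        raise ValueError("crop_shape dimensionality does not match the sample")
    if crop_shape[0] != sample.image.shape[0]:
        raise ValueError(
            f"crop_shape channels {crop_shape[0]} != sample channels {sample.image.shape[0]}"
        )
    sample = _pad_to(sample, want_spatial)
    spatial = sample.spatial_shape
    n_starts = tuple(s - c + 1 for s, c in zip(spatial, want_spatial))

    start = None
    if rng.random() < p_foreground:
        if sample.mask is None or not sample.mask.any():
            warnings.warn("biased crop requested but mask is empty; uniform crop",
                          stacklevel=2)
        else:
            # windows containing a mask voxel == start positions where the
            # window-max of the mask is 1; separable max filter, re-anchored
            # from the centered window to the window origin (valid[s] =
            # max mask[s : s+c] per axis, checked against brute force in tests)
            valid = sample.mask.astype(np.uint8)
            for ax, c in enumerate(want_spatial):
                valid = ndimage.maximum_filter1d(valid, size=c, axis=ax, mode="constant")
            valid = valid[tuple(slice(c // 2, c // 2 + n)
                                for c, n in zip(want_spatial, n_starts))]
            hits = np.argwhere(valid > 0)
            if len(hits):
                start = hits[rng.integers(len(hits))]
    if start is None:
        start = [rng.integers(n) for n in n_starts]
    sl = tuple(slice(int(s), int(s) + c) for s, c in zip(start, want_spatial))
    image = sample.image[(slice(None),) + sl].copy()
    mask = None if sample.mask is None else sample.mask[sl].copy()
    fg = None if sample.foreground is None else sample.foreground[sl].copy()
    out = _copy(sample, image=image, mask=mask, foreground=fg)
    out.meta["crop_start"] = tuple(int(s) for s in start)
    return out


def augment(sample: VolumeSample, rng: np.random.Generator,
            spec: AugmentationSpec | None = None,
            crop: bool = True) -> VolumeSample:
    """Apply the full augmentation chain in the fixed order: flips, blur,
    brightness, zoom, noise, contrast, biased crop."""
    spec = spec or AugmentationSpec()
    s = random_flip(sample, rng, spec.p_flip_per_axis)
    s = random_gaussian_blur(s, rng, spec.p_blur, spec.blur_sigma_range)
    s = random_brightness(s, rng, spec.p_brightness, spec.brightness_range)
    s = random_zoom(s, rng, spec.p_zoom, spec.zoom_range)
    s = random_noise(s, rng, spec.p_noise, spec.noise_var_range)
    s = random_contrast(s, rng, spec.p_contrast, spec.contrast_range)
    if crop:
        s = biased_crop(s, rng, spec.crop_shape, spec.p_biased_crop_foreground)
    return s
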