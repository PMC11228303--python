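"""Volume preprocessing: cropping, non-zero z-scoring, foreground channel,
noise filtering and slice resizing.

All arrays are channel-first: ``(C, H, W)`` for 2D slices and
``(C, H, W, D)`` for volumes.  "Foreground" means the set of voxels that
are non-zero in *any* channel before normalization; background voxels are
exactly zero and are guaranteed to remain exactly zero through every
operation here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

logger = logging.getLogger(__name__)

__all__ = [
    "VolumeSample",
    "FilterConfig",
    "foreground_mask",
    "crop_background",
    "embed_at",
    "znormalize_nonzero",
    "add_foreground_channel",
    "median_filter",
    "swmf_filter",
    "resize_slice",
    "preprocess_sample",
]

_SD_FLOOR = 1e-8


@dataclass
class VolumeSample:
    """A preprocessed sample: channel-first image, ROI mask, label, foreground.

    ``foreground`` records non-zero membership *before* normalization so the
    zero-background contract survives the z-score shifting values near 0.
    """

    image: np.ndarray
    mask: np.ndarray | None = None
    label: int | None = None
    foreground: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.image.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.image.shape[1:]


@dataclass(frozen=True)
class FilterConfig:
    """Noise-filter settings: median or soft weighted median (SWMF)."""

    kind: str = "median"
    window: int = 3
    swmf_temperature: float = 0.1
    padding: str = "reflect"

    def __post_init__(self):
        if self.kind not in ("median", "swmf"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if self.kind == "swmf" and self.swmf_temperature <= 0:
            raise ValueError("swmf_temperature must be positive")


def foreground_mask(image: np.ndarray) -> np.ndarray:
    """Voxels non-zero in any channel of a channel-first array."""
    image = np.asarray(image)
    return np.any(image != 0, axis=0)


def crop_background(image: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    """Crop the minimal bounding box of any-channel non-zero voxels.

    Returns the cropped array and the per-spatial-axis offsets of the box
    origin inside the input, so :func:`embed_at` can invert the crop
    exactly.  Raises on an all-zero volume.
    """
    image = np.asarray(image)
    fg = foreground_mask(image)
    if not fg.any():
        raise ValueError("cannot crop an all-zero volume")
    slices = ndimage.find_objects(fg.astype(np.int8))[0]
    offsets = tuple(s.start for s in slices)
    cropped = image[(slice(None),) + slices]
    return cropped, offsets


def embed_at(cropped: np.ndarray, offsets: tuple[int, ...], shape: tuple[int, ...]) -> np.ndarray:
    """Place a cropped channel-first array back into a zero canvas of the
    original spatial ``shape`` at ``offsets`` (exact inverse of the crop)."""
    out = np.zeros((cropped.shape[0],) + tuple(shape), dtype=cropped.dtype)
    sl = tuple(slice(o, o + s) for o, s in zip(offsets, cropped.shape[1:]))
    out[(slice(None),) + sl] = cropped
    return out


def znormalize_nonzero(image: np.ndarray, mask=None, label=None) -> VolumeSample:
    """Per-channel z-score over the foreground (non-zero) voxels only.

    Background voxels stay exactly 0.  The sd uses ddof=1 with a floor of
    1e-8; a constant-foreground channel triggers a warning and the floor.
    """
    image = np.asarray(image, dtype=np.float64)
    fg = foreground_mask(image)
    if not fg.any():
        raise ValueError("empty foreground: nothing to normalize")
    out = np.zeros_like(image)
    for c in range(image.shape[0]):
        vals = image[c][fg]
        mu = vals.mean()
        sd = vals.std(ddof=1) if vals.size > 1 else 0.0
        if sd < _SD_FLOOR:
            warnings.warn(f"channel {c}: constant foreground, sd floored", stacklevel=2)
            sd = _SD_FLOOR
        out[c][fg] = (vals - mu) / sd
    return VolumeSample(image=out, mask=mask, label=label, foreground=fg)


def add_foreground_channel(sample: VolumeSample) -> VolumeSample:
    """Append a one-hot foreground-indicator channel (C -> C+1)."""
    if sample.foreground is None:
        raise ValueError("sample.foreground not computed; normalize first")
    onehot = sample.foreground.astype(sample.image.dtype)[None]
    return VolumeSample(
        image=np.concatenate([sample.image, onehot], axis=0),
        mask=sample.mask,
        label=sample.label,
        foreground=sample.foreground,
        meta=dict(sample.meta),
    )


def median_filter(image: np.ndarray, cfg: FilterConfig) -> np.ndarray:
    """Per-channel spatial median filter with reflect padding."""
    if cfg.kind != "median":
        raise ValueError("FilterConfig.kind must be 'median'")
    image = np.asarray(image, dtype=np.float64)
    out = np.empty_like(image)
    for c in range(image.shape[0]):
        # numpy-style reflect (edge sample not duplicated) = scipy "mirror"
        out[c] = ndimage.median_filter(image[c], size=cfg.window, mode="mirror")
    return out


def _sliding_windows(plane: np.ndarray, window: int) -> np.ndarray:
    """(n_voxels, window^ndim) view of reflect-padded windows."""
    half = window // 2
    padded = np.pad(plane, half, mode="reflect")
    view = np.lib.stride_tricks.sliding_window_view(padded, (window,) * plane.ndim)
    return view.reshape(plane.size, -1)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median: smallest value whose cumulative weight
    reaches half the total."""
    order = np.argsort(values, axis=1, kind="stable")
    v = np.take_along_axis(values, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    cum = np.cumsum(w, axis=1)
    half = 0.5 * cum[:, -1:]
    idx = np.argmax(cum >= half, axis=1)
    return v[np.arange(v.shape[0]), idx]


def swmf_filter(image: np.ndarray, cfg: FilterConfig) -> np.ndarray:
    """Soft Weighted Median Filter.

    Each output voxel is the weighted median of its window, with weights
        w_k = softmax( -|x_k - med(window)| / T )
    where T = ``swmf_temperature``.  As T -> 0 the weight concentrates on
    the values equal to the window median and the filter reduces to the
    plain median; larger T blends in the rest of the window softly.
    """
    if cfg.kind != "swmf":
        raise ValueError("FilterConfig.kind must be 'swmf'")
    image = np.asarray(image, dtype=np.float64)
    out = np.empty_like(image)
    for c in range(image.shape[0]):
        plane = image[c]
        win = _sliding_windows(plane, cfg.window)
        med = np.median(win, axis=1, keepdims=True)
        logit = -np.abs(win - med) / cfg.swmf_temperature
        logit -= logit.max(axis=1, keepdims=True)
        w = np.exp(logit)
        out[c] = _weighted_median(win, w).reshape(plane.shape)
    return out


def resize_slice(image: np.ndarray, target: tuple[int, int] = (256, 256)) -> np.ndarray:
    """Bilinear resize of a channel-first 2D slice to ``target`` (H, W)."""
    if len(target) != 2 or min(target) <= 0:
        raise ValueError("target must be two positive integers")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3:
        raise ValueError("expected a (C, H, W) slice")
    if image.shape[1:] == tuple(target):
        return image.copy()
    out = np.empty((image.shape[0],) + tuple(target), dtype=np.float64)
    for c in range(image.shape[0]):
        out[c] = _sk_resize(
            image[c], target, order=1, mode="reflect",
            anti_aliasing=False, preserve_range=True,
        )
    return out


def preprocess_sample(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    label: int | None = None,
    filter_cfg: FilterConfig | None = None,
    add_foreground: bool = True,
) -> VolumeSample:
    """Standard chain: crop -> (filter) -> z-normalize -> foreground channel.

    The mask is cropped congruently.  Filtering, when requested, runs on
    the cropped raw intensities before normalization.
    """
    image = np.asarray(image, dtype=np.float64)
    cropped, offsets = crop_background(image)
    if mask is not None:
        sl = tuple(slice(o, o + s) for o, s in zip(offsets, cropped.shape[1:]))
        mask = np.asarray(mask)[sl]
    if filter_cfg is not None:
        fg = foreground_mask(cropped)
        filt = (
            median_filter(cropped, filter_cfg)
            if filter_cfg.kind == "median"
            else swmf_filter(cropped, filter_cfg)
        )
        # keep the zero background exact under filtering
        cropped = np.where(fg[None], filt, 0.0)
    sample = znormalize_nonzero(cropped, mask=mask, label=label)
    sample.meta["crop_offsets"] = offsets
    sample.meta["original_shape"] = image.shape[1:]
    if add_foreground:
        sample = add_foreground_channel(sample)
    return sample
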