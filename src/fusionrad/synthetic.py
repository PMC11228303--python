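"""Synthetic textured phantoms emulating BraTS-style classification input.

Each phantom is a channel-first image or volume with

* a zero background ring (as in skull-stripped brain MRI),
* an elliptical "tissue" foreground filled with a Gaussian-random-field
  texture (white noise convolved with a Gaussian kernel), and
* one lesion blob whose interior texture follows class-dependent
  parameters; label 1 (malignant) lesions differ from label 0 (benign)
  lesions in correlation length and mean intensity.

The ``separability`` knob interpolates the malignant lesion parameters
from "identical to benign" (0.0, downstream classification is chance) to
a well-separated texture (1.0).  Everything is deterministic for a fixed
seed.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "ClassParams",
    "PhantomSpec",
    "PhantomSample",
    "generate_phantoms",
    "write_phantom_nifti",
    "write_phantom_nifti_4d",
    "write_manifest",
]


@dataclass(frozen=True)
class ClassParams:
    """Lesion texture for one class: Gaussian-field correlation length
    (``sigma``, voxels), affine intensity map (``mean``, ``sd``) and the
    lesion radius range as a fraction of the smallest spatial dim."""

    sigma: float
    mean: float
    sd: float
    radius_frac: tuple[float, float] = (0.15, 0.30)


#: benign lesion texture (also the malignant texture at separability 0)
BENIGN_PARAMS = ClassParams(sigma=0.8, mean=1.3, sd=0.25)
#: malignant lesion texture at separability 1: smoother and brighter
MALIGNANT_PARAMS_FULL = ClassParams(sigma=3.0, mean=1.9, sd=0.25)
#: surrounding tissue texture, shared by both classes
TISSUE_PARAMS = ClassParams(sigma=1.0, mean=1.0, sd=0.20)


def interpolate_params(sep: float) -> ClassParams:
    """Malignant lesion parameters at a given separability in [0, 1]."""
    if not 0.0 <= sep <= 1.0:
        raise ValueError("separability must be in [0, 1]")
    a, b = BENIGN_PARAMS, MALIGNANT_PARAMS_FULL
    return ClassParams(
        sigma=a.sigma + sep * (b.sigma - a.sigma),
        mean=a.mean + sep * (b.mean - a.mean),
        sd=a.sd + sep * (b.sd - a.sd),
        radius_frac=a.radius_frac,
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Generator configuration.

    ``shape`` is spatial only: (H, W) for 2D or (H, W, D) for 3D.
    ``class_params`` maps label -> :class:`ClassParams`; by default it is
    derived from ``separability``.
    """

    n_samples: int = 8
    shape: tuple[int, ...] = (64, 64)
    n_channels: int = 4
    separability: float = 1.0
    class_params: dict | None = None
    background_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2 (both classes represented)")
        if len(self.shape) not in (2, 3) or min(self.shape) < 8:
            raise ValueError("shape must be 2D or 3D with every dim >= 8")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if not 0.0 <= self.background_fraction < 0.9:
            raise ValueError("background_fraction must be in [0, 0.9)")

    def resolved_class_params(self) -> dict:
        if self.class_params is not None:
            return self.class_params
        return {0: BENIGN_PARAMS, 1: interpolate_params(self.separability)}


@dataclass
class PhantomSample:
    """One labelled phantom: channel-first image, lesion ROI mask, label."""

    image: np.ndarray
    mask: np.ndarray
    label: int
    sample_id: str = ""


def _ellipse_mask(shape: tuple[int, ...], background_fraction: float) -> np.ndarray:
    """Centered ellipse/ellipsoid foreground covering <= 1 - bf of voxels."""
    ndim = len(shape)
    unit = np.pi / 4 if ndim == 2 else np.pi / 6
    scale = min(1.0, ((1.0 - background_fraction) / unit) ** (1.0 / ndim))
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    while True:
        semi = [max(2.0, scale * (s / 2.0 - 1.0)) for s in shape]
        r2 = sum(((g - (s - 1) / 2.0) / a) ** 2 for g, s, a in zip(grids, shape, semi))
        mask = r2 <= 1.0
        if 1.0 - mask.mean() >= background_fraction or scale < 0.2:
            return mask
        scale *= 0.98  # discretization overshoot: shrink and retry


def _random_field(rng: np.random.Generator, shape, params: ClassParams) -> np.ndarray:
    noise = rng.standard_normal(shape)
    field_ = ndimage.gaussian_filter(noise, sigma=params.sigma, mode="reflect")
    sd = field_.std()
    if sd > 0:
        field_ = field_ / sd
    return params.mean + params.sd * field_


def _lesion_blob(rng, shape, fg: np.ndarray, params: ClassParams) -> np.ndarray:
    lo, hi = params.radius_frac
    radius = rng.uniform(lo, hi) * min(shape)
    # center drawn from foreground voxels eroded by the radius so the blob
    # stays inside the tissue
    erosion = ndimage.binary_erosion(fg, iterations=max(1, int(radius)))
    candidates = np.argwhere(erosion if erosion.any() else fg)
    center = candidates[rng.integers(len(candidates))]
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center)) / radius**2
    return (r2 <= 1.0) & fg


def generate_phantoms(spec: PhantomSpec) -> list[PhantomSample]:
    """Generate ``spec.n_samples`` labelled phantoms, labels alternating
    0, 1, 0, 1, ... so both classes are always represented."""
    rng = np.random.default_rng(spec.seed)
    class_params = spec.resolved_class_params()
    fg = _ellipse_mask(spec.shape, spec.background_fraction)
    samples = []
    for i in range(spec.n_samples):
        label = i % 2
        lesion_params = class_params[label]
        blob = _lesion_blob(rng, spec.shape, fg, lesion_params)
        channels = []
        for _c in range(spec.n_channels):
            tissue = _random_field(rng, spec.shape, TISSUE_PARAMS)
            lesion = _random_field(rng, spec.shape, lesion_params)
            img = np.where(blob, lesion, tissue)
            img[~fg] = 0.0
            channels.append(img)
        samples.append(
            PhantomSample(
                image=np.stack(channels),
                mask=blob,
                label=label,
                sample_id=f"phantom_{i:04d}",
            )
        )
    return samples


def _require_nibabel():
    import nibabel as nib  # deferred: keeps 2D-only use free of the dependency

    return nib


def _save_nifti_atomic(nib, array: np.ndarray, path: str) -> None:
    """Write via a temp file + rename so a failure leaves no partial file."""
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float32), affine=np.eye(4))
    d = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(d):
        raise FileNotFoundError(f"output directory does not exist: {d}")
    tmp = os.path.join(d, f".tmp_{os.getpid()}_{os.path.basename(path)}")
    try:
        nib.save(img, tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.remove(tmp)


def write_phantom_nifti(sample: PhantomSample, path_stem: str) -> list[str]:
    """Write a 3D phantom as per-channel NIfTI files ``<stem>_000.nii.gz``
    ... (BraTS-like dialect) plus ``<stem>_mask.nii.gz``; returns paths."""
    if sample.image.ndim != 4:
        raise ValueError("NIfTI export requires a 3D sample (C, H, W, D)")
    nib = _require_nibabel()
    paths = []
    for c in range(sample.image.shape[0]):
        p = f"{path_stem}_{c:03d}.nii.gz"
        _save_nifti_atomic(nib, sample.image[c], p)
        paths.append(p)
    mask_path = f"{path_stem}_mask.nii.gz"
    _save_nifti_atomic(nib, sample.mask.astype(np.uint8), mask_path)
    paths.append(mask_path)
    return paths


def write_phantom_nifti_4d(sample: PhantomSample, path: str) -> str:
    """Single-file dialect: one 4D NIfTI with the channel as the last axis."""
    if sample.image.ndim != 4:
        raise ValueError("NIfTI export requires a 3D sample (C, H, W, D)")
    nib = _require_nibabel()
    _save_nifti_atomic(nib, np.moveaxis(sample.image, 0, -1), path)
    return path


def write_manifest(samples: list[PhantomSample], paths: list[list[str]], out_csv: str) -> None:
    """CSV manifest: sample_id, semicolon-joined channel paths, label."""
    with open(out_csv, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "paths", "label"])
        for s, p in zip(samples, paths):
            writer.writerow([s.sample_id, ";".join(p), s.label])
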