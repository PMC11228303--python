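"""Hand-crafted radiomics texture features over an ROI.

Five feature families:

* first-order intensity statistics (mean, variance, percentiles, histogram
  energy/entropy, adjusted Fisher-Pearson skewness and kurtosis),
* absolute-gradient statistics,
* GLCM (gray-level co-occurrence matrix, Haralick) features,
* GLRLM (gray-level run-length matrix, Galloway) features,
* GLSZM (gray-level size-zone matrix, Thibault) features.

Images are first quantized to ``Ng`` equal-width gray levels inside the
ROI (level 0 marks "outside ROI" everywhere below).  GLCM and GLRLM are
directional and averaged over the standard direction sets (4 angles in
2D, 13 unique directions in 3D); GLSZM is direction-free with
infinity-norm (8/26-) connectivity.

Degenerate features (e.g. skewness of a constant ROI) are imputed as 0
and flagged, so the feature vector length is fixed for the downstream
SVM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "QuantizedImage",
    "TextureMatrix",
    "RadiomicsVector",
    "RadiomicsConfig",
    "DIRECTIONS_2D",
    "DIRECTIONS_3D",
    "quantize",
    "first_order_features",
    "gradient_features",
    "glcm",
    "glcm_features",
    "glrlm",
    "glrlm_features",
    "glszm",
    "glszm_features",
    "extract_radiomics",
    "radiomics_table",
    "RadiomicsExtractor",
]

#: 2D displacement unit vectors for angles 0, 45, 90, 135 degrees
DIRECTIONS_2D: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

#: the 13 unique 3D directions (one representative per +/- pair)
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    d
    for d in (
        (a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
    )
    if d != (0, 0, 0) and (d > (0, 0, 0))
)
assert len(DIRECTIONS_3D) == 13


@dataclass
class QuantizedImage:
    """Integer gray-level image: level in 1..Ng inside the ROI, 0 outside."""

    levels: np.ndarray
    ng: int
    roi: np.ndarray
    original: np.ndarray

    @property
    def n_roi(self) -> int:
        return int(self.roi.sum())


@dataclass
class TextureMatrix:
    """A GLCM/GLRLM/GLSZM count (or normalized) matrix with metadata."""

    kind: str
    counts: np.ndarray
    distance: int | None = None
    direction: tuple[int, ...] | None = None
    normalized: bool = False

    def normalize(self) -> "TextureMatrix":
        total = self.counts.sum()
        if total == 0:
            raise ValueError(f"empty {self.kind}: nothing to normalize")
        return TextureMatrix(
            kind=self.kind,
            counts=self.counts / total,
            distance=self.distance,
            direction=self.direction,
            normalized=True,
        )


@dataclass
class RadiomicsVector:
    """Named, ordered feature values for one sample."""

    names: list[str]
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


@dataclass(frozen=True)
class RadiomicsConfig:
    """Extraction settings.

    ``ng``: number of equal-width gray levels (quantization is deferred by
    the source method, so this is a package default).  ``distances``: GLCM
    pair distances.  ``mode``: '2d' extracts per-slice on volumes and
    averages over ROI-bearing slices; '3d' uses the 13 3D directions.
    """

    ng: int = 32
    distances: tuple[int, ...] = (1,)
    mode: str = "2d"

    def __post_init__(self):
        if self.ng < 2:
            raise ValueError("ng must be >= 2")
        if self.mode not in ("2d", "3d"):
            raise ValueError("mode must be '2d' or '3d'")


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

def quantize(image: np.ndarray, roi: np.ndarray, ng: int) -> QuantizedImage:
    """Equal-width binning of the ROI intensity range into ``ng`` levels.

    The ROI maximum maps to level ``ng``; a constant ROI maps to level 1
    (with a warning).  Quantization is invariant to affine maps of the
    intensities since the bin edges follow the ROI min/max.
    """
    image = np.asarray(image, dtype=np.float64)
    roi = np.asarray(roi, dtype=bool)
    if image.shape != roi.shape:
        raise ValueError("image and roi shapes differ")
    if ng < 2:
        raise ValueError("ng must be >= 2")
    if not roi.any():
        raise ValueError("empty ROI")
    vals = image[roi]
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(image.shape, dtype=np.int32)
    if hi == lo:
        warnings.warn("constant ROI: all voxels quantized to level 1", stacklevel=2)
        levels[roi] = 1
    else:
        binned = np.floor((image[roi] - lo) / (hi - lo) * ng).astype(np.int32) + 1
        levels[roi] = np.clip(binned, 1, ng)
    return QuantizedImage(levels=levels, ng=ng, roi=roi, original=image)


# ---------------------------------------------------------------------------
# first-order and gradient statistics
# ---------------------------------------------------------------------------

def _skew_kurt(values: np.ndarray) -> tuple[float, float, list[str]]:
    """Adjusted Fisher-Pearson sample skewness and excess kurtosis
    (ddof=1 normalization); imputed 0 for n < 3 / n < 4 or constant input."""
    flags = []
    n = values.size
    sd = values.std(ddof=1) if n > 1 else 0.0
    if n < 3 or sd == 0:
        flags.append("skewness")
        sk = 0.0
    else:
        sk = float(stats.skew(values, bias=False))
    if n < 4 or sd == 0:
        flags.append("kurtosis")
        ku = 0.0
    else:
        ku = float(stats.kurtosis(values, bias=False, fisher=True))
    return sk, ku, flags


def first_order_features(values, n_bins: int = 32) -> tuple[dict, list[str]]:
    """First-order statistics of the raw ROI intensities.

    Histogram energy and entropy use ``n_bins`` equal-width bins over the
    value range (a constant input is a single certain bin: energy 1,
    entropy 0).  Returns ``(features, degenerate_flags)``.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("empty value set")
    sk, ku, flags = _skew_kurt(v)
    if v.min() == v.max():
        p = np.array([1.0])
    else:
        hist, _ = np.histogram(v, bins=n_bins)
        p = hist[hist > 0] / v.size
    feats = {
        "mean": float(v.mean()),
        "variance": float(v.var(ddof=1)) if v.size > 1 else 0.0,
        "min": float(v.min()),
        "max": float(v.max()),
        "p10": float(np.percentile(v, 10)),
        "p50": float(np.percentile(v, 50)),
        "p90": float(np.percentile(v, 90)),
        "energy": float(np.sum(p**2)),
        "entropy": float(-np.sum(p * np.log2(p))),
        "skewness": sk,
        "kurtosis": ku,
    }
    return feats, flags


def gradient_features(image: np.ndarray, roi: np.ndarray) -> tuple[dict, list[str]]:
    """Statistics of the absolute gradient magnitude inside the ROI.

    The gradient uses central differences (one-sided at the borders); the
    magnitude is the Euclidean norm over the spatial axes.
    """
    image = np.asarray(image, dtype=np.float64)
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    if min(image.shape) < 2:
        raise ValueError("image too small for gradients (needs >= 2 per axis)")
    grads = np.gradient(image)
    if image.ndim == 1:
        grads = [grads]
    mag = np.sqrt(sum(g**2 for g in grads))
    v = mag[roi]
    sk, ku, flags = _skew_kurt(v)
    feats = {
        "mean": float(v.mean()),
        "variance": float(v.var(ddof=1)) if v.size > 1 else 0.0,
        "skewness": sk,
        "kurtosis": ku,
    }
    return feats, flags


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _shifted_pairs(levels: np.ndarray, offset: tuple[int, ...]):
    """Aligned (source, target) level views at a given displacement."""
    src = [slice(None)] * levels.ndim
    dst = [slice(None)] * levels.ndim
    for ax, o in enumerate(offset):
        if o > 0:
            src[ax] = slice(0, levels.shape[ax] - o)
            dst[ax] = slice(o, levels.shape[ax])
        elif o < 0:
            src[ax] = slice(-o, levels.shape[ax])
            dst[ax] = slice(0, levels.shape[ax] + o)
    return levels[tuple(src)], levels[tuple(dst)]


def glcm(
    q: QuantizedImage,
    distance: int = 1,
    direction: tuple[int, ...] = (0, 1),
    symmetric: bool = True,
) -> TextureMatrix:
    """Gray-level co-occurrence counts at displacement d * direction.

    ``counts[i-1, j-1]`` is the number of ordered voxel pairs (x, x+d*v)
    with both endpoints in the ROI and levels (i, j); symmetric mode adds
    the transpose so each unordered pair is counted in both orders.
    """
    if len(direction) != q.levels.ndim:
        raise ValueError("direction dimensionality must match the image")
    offset = tuple(distance * o for o in direction)
    a, b = _shifted_pairs(q.levels, offset)
    valid = (a > 0) & (b > 0)
    if not valid.any():
        raise ValueError("no valid co-occurrence pairs at this displacement")
    counts = np.zeros((q.ng, q.ng), dtype=np.float64)
    np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1.0)
    if symmetric:
        counts = counts + counts.T
    return TextureMatrix(kind="GLCM", counts=counts, distance=distance, direction=direction)


def glcm_features(matrices) -> dict:
    """Haralick-style features of one or more *normalized* GLCMs, averaged
    over the supplied direction set.

    contrast = sum (i-j)^2 p(i,j); energy (ASM) = sum p^2;
    entropy = -sum p log2 p (0 log 0 = 0); homogeneity = sum p/(1+(i-j)^2).
    """
    if isinstance(matrices, TextureMatrix):
        matrices = [matrices]
    per_dir = []
    for m in matrices:
        if not m.normalized:
            raise ValueError("glcm_features requires normalized matrices")
        p = m.counts
        ng = p.shape[0]
        i, j = np.meshgrid(np.arange(1, ng + 1), np.arange(1, ng + 1), indexing="ij")
        nz = p[p > 0]
        per_dir.append(
            {
                "contrast": float(np.sum((i - j) ** 2 * p)),
                "energy": float(np.sum(p**2)),
                "entropy": float(-np.sum(nz * np.log2(nz))),
                "homogeneity": float(np.sum(p / (1.0 + (i - j) ** 2))),
            }
        )
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _line_starts(shape: tuple[int, ...], direction: tuple[int, ...]):
    """Voxels with no in-bounds predecessor along ``direction``."""
    idx = np.indices(shape)
    prev_ok = np.ones(shape, dtype=bool)
    for ax, o in enumerate(direction):
        if o != 0:
            prev = idx[ax] - o
            prev_ok &= (prev >= 0) & (prev < shape[ax])
    return np.argwhere(~prev_ok)


def glrlm(q: QuantizedImage, direction: tuple[int, ...] = (0, 1)) -> TextureMatrix:
    """Gray-level run-length counts along one direction.

    ``counts[i-1, L-1]`` is the number of maximal runs of level i with
    length L; runs are truncated at ROI boundaries (level 0 breaks a run
    and is never counted).
    """
    if len(direction) != q.levels.ndim:
        raise ValueError("direction dimensionality must match the image")
    if not q.roi.any():
        raise ValueError("empty ROI")
    shape = q.levels.shape
    lmax = int(np.ceil(np.sqrt(sum(s**2 for s in shape)))) + 1
    counts = np.zeros((q.ng, lmax), dtype=np.float64)
    for start in _line_starts(shape, direction):
        pos = start.copy()
        run_level, run_len = 0, 0
        while all(0 <= p < s for p, s in zip(pos, shape)):
            lev = q.levels[tuple(pos)]
            if lev == run_level and lev > 0:
                run_len += 1
            else:
                if run_level > 0:
                    counts[run_level - 1, run_len - 1] += 1
                run_level, run_len = lev, 1
            pos += direction
        if run_level > 0:
            counts[run_level - 1, run_len - 1] += 1
    used = np.nonzero(counts.sum(axis=0))[0]
    width = used[-1] + 1 if used.size else 1
    return TextureMatrix(kind="GLRLM", counts=counts[:, :width], direction=direction)


def _run_zone_emphases(counts: np.ndarray, n_voxels: int, prefix: str) -> dict:
    """Shared GLRLM/GLSZM feature formulas (L <-> S via ``prefix``)."""
    nr = counts.sum()
    if nr == 0:
        raise ValueError("empty matrix")
    sizes = np.arange(1, counts.shape[1] + 1, dtype=np.float64)
    by_size = counts.sum(axis=0)
    by_level = counts.sum(axis=1)
    short = float(np.sum(by_size / sizes**2) / nr)
    long_ = float(np.sum(by_size * sizes**2) / nr)
    gln = float(np.sum(by_level**2) / nr)
    sn = float(np.sum(by_size**2) / nr)
    frac = float(nr / n_voxels)
    names = {
        "run": ("sre", "lre", "gln", "rln", "run_fraction"),
        "zone": ("sze", "lze", "gln", "zsn", "zone_percentage"),
    }[prefix]
    return dict(zip(names, (short, long_, gln, sn, frac)))


def glrlm_features(matrices, n_voxels: int) -> dict:
    """Run-emphasis features averaged over directions.

    SRE = (sum counts / L^2)/Nr, LRE = (sum counts * L^2)/Nr, gray-level
    and run-length non-uniformities, and run fraction Nr / n_voxels.
    """
    if isinstance(matrices, TextureMatrix):
        matrices = [matrices]
    per_dir = [_run_zone_emphases(m.counts, n_voxels, "run") for m in matrices]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def glszm(q: QuantizedImage) -> TextureMatrix:
    """Gray-level size-zone counts.

    A zone is a connected set of equal-level ROI voxels under the
    infinity-norm neighborhood (8-connected in 2D, 26-connected in 3D);
    ``counts[i-1, S-1]`` is the number of zones of level i and size S.
    """
    if not q.roi.any():
        raise ValueError("empty ROI")
    structure = np.ones((3,) * q.levels.ndim, dtype=bool)
    zones: list[tuple[int, int]] = []
    for level in range(1, q.ng + 1):
        labeled, n = ndimage.label(q.levels == level, structure=structure)
        if n:
            sizes = np.bincount(labeled.ravel())[1:]
            zones.extend((level, int(s)) for s in sizes)
    smax = max(s for _, s in zones)
    counts = np.zeros((q.ng, smax), dtype=np.float64)
    for level, s in zones:
        counts[level - 1, s - 1] += 1
    return TextureMatrix(kind="GLSZM", counts=counts)


def glszm_features(matrix: TextureMatrix, n_voxels: int) -> dict:
    """Zone analogues of the run features: small/large-zone emphasis,
    zone-size and gray-level non-uniformities, zone percentage."""
    return _run_zone_emphases(matrix.counts, n_voxels, "zone")


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

_FIRST_ORDER = ("mean", "variance", "min", "max", "p10", "p50", "p90",
                "energy", "entropy", "skewness", "kurtosis")
_GRADIENT = ("mean", "variance", "skewness", "kurtosis")
_GLCM = ("contrast", "energy", "entropy", "homogeneity")
_GLRLM = ("sre", "lre", "gln", "rln", "run_fraction")
_GLSZM = ("sze", "lze", "gln", "zsn", "zone_percentage")


def feature_names(n_channels: int) -> list[str]:
    """The fixed, ordered feature-name layout for ``n_channels`` channels."""
    names = []
    for c in range(n_channels):
        names += [f"ch{c}_firstorder_{k}" for k in _FIRST_ORDER]
        names += [f"ch{c}_gradient_{k}" for k in _GRADIENT]
        names += [f"ch{c}_glcm_{k}" for k in _GLCM]
        names += [f"ch{c}_glrlm_{k}" for k in _GLRLM]
        names += [f"ch{c}_glszm_{k}" for k in _GLSZM]
    return names


def _directions_for(ndim: int):
    return DIRECTIONS_2D if ndim == 2 else DIRECTIONS_3D


def _texture_features_plane(image: np.ndarray, roi: np.ndarray, cfg: RadiomicsConfig) -> dict:
    """All five families on one 2D plane or 3D block."""
    q = quantize(image, roi, cfg.ng)
    out = {}
    fo, fo_flags = first_order_features(image[roi], n_bins=cfg.ng)
    out.update({f"firstorder_{k}": v for k, v in fo.items()})
    gr, gr_flags = gradient_features(image, roi)
    out.update({f"gradient_{k}": v for k, v in gr.items()})
    dirs = _directions_for(image.ndim)
    glcms = [
        glcm(q, distance=d, direction=v).normalize()
        for d in cfg.distances
        for v in dirs
    ]
    out.update({f"glcm_{k}": v for k, v in glcm_features(glcms).items()})
    glrlms = [glrlm(q, direction=v) for v in dirs]
    out.update({f"glrlm_{k}": v for k, v in glrlm_features(glrlms, q.n_roi).items()})
    out.update({f"glszm_{k}": v for k, v in glszm_features(glszm(q), q.n_roi).items()})
    flags = [f"firstorder_{f}" for f in fo_flags] + [f"gradient_{f}" for f in gr_flags]
    return out, flags


def extract_radiomics(sample, config: RadiomicsConfig | None = None) -> RadiomicsVector:
    """Fixed-order radiomics vector for one sample (per-channel features).

    ``sample`` needs ``.image`` (channel-first) and ``.mask`` (the ROI).
    In '2d' mode a (C, H, W, D) volume is reduced by averaging per-slice
    features over the slices whose ROI is non-empty.
    """
    cfg = config or RadiomicsConfig()
    image = np.asarray(sample.image, dtype=np.float64)
    mask = np.asarray(sample.mask, dtype=bool)
    if not mask.any():
        raise ValueError("sample has an empty ROI mask")
    n_channels = image.shape[0]
    names = feature_names(n_channels)
    values: dict[str, float] = {}
    all_flags: list[str] = []
    for c in range(n_channels):
        chan = image[c]
        if chan.ndim == 3 and cfg.mode == "2d":
            slice_feats = []
            for z in range(chan.shape[-1]):
                if mask[..., z].sum() >= 4:
                    feats, flags = _texture_features_plane(chan[..., z], mask[..., z], cfg)
                    slice_feats.append(feats)
                    all_flags += [f"ch{c}_{f}_z{z}" for f in flags]
            if not slice_feats:
                raise ValueError("no slice with >= 4 ROI voxels in 2d mode")
            feats = {k: float(np.mean([f[k] for f in slice_feats])) for k in slice_feats[0]}
        else:
            feats, flags = _texture_features_plane(chan, mask, cfg)
            all_flags += [f"ch{c}_{f}" for f in flags]
        values.update({f"ch{c}_{k}": v for k, v in feats.items()})
    vec = np.array([values[n] for n in names], dtype=np.float64)
    if np.isnan(vec).any():
        raise AssertionError("NaN leaked into the radiomics vector")
    return RadiomicsVector(names=names, values=vec, provenance={"degenerate": all_flags})


def radiomics_table(samples, config: RadiomicsConfig | None = None) -> pd.DataFrame:
    """Feature table: one row per sample, sample_id index, last col label."""
    rows, ids, labels = [], [], []
    for i, s in enumerate(samples):
        vec = extract_radiomics(s, config)
        rows.append(vec.values)
        ids.append(getattr(s, "sample_id", "") or f"sample_{i:04d}")
        labels.append(getattr(s, "label", None))
    df = pd.DataFrame(np.vstack(rows), columns=vec.names)
    df.insert(0, "sample_id", ids)
    df["label"] = labels
    return df


class RadiomicsExtractor:
    """scikit-learn style transformer turning samples into feature matrices.

    ``transform`` accepts a sequence of objects with ``.image`` and
    ``.mask`` and returns the (n_samples, n_features) array; the fitted
    attribute ``feature_names_`` holds the column layout.  Stateless
    (``fit`` only records the layout), so it composes with sklearn
    pipelines and cross-validation without leaking information.
    """

    def __init__(self, ng: int = 32, distances: tuple[int, ...] = (1,), mode: str = "2d"):
        self.ng = ng
        self.distances = distances
        self.mode = mode

    def _config(self) -> RadiomicsConfig:
        return RadiomicsConfig(ng=self.ng, distances=tuple(self.distances), mode=self.mode)

    def get_params(self, deep: bool = True) -> dict:
        return {"ng": self.ng, "distances": self.distances, "mode": self.mode}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        self._config()  # validate
        n_channels = np.asarray(X[0].image).shape[0]
        self.feature_names_ = feature_names(n_channels)
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X) -> np.ndarray:
        cfg = self._config()
        return np.vstack([extract_radiomics(s, cfg).values for s in X])

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)
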