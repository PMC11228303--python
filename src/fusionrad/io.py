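"""Readers, configuration and the end-to-end pipeline orchestrator.

``read_volume`` handles NIfTI in two dialects — a single 4D file (channel
last) or a BraTS-like per-channel quartet ``<stem>_000.nii.gz`` ... — and,
when pydicom is installed, DICOM series sorted by slice position.  Arrays
come back channel-first ``(C, H, W, D)`` with the affine kept as
provenance only.

``run_pipeline`` chains synth -> preprocess -> radiomics -> CNN training
-> deep features -> fuse-classify -> metrics on phantom data, caching
each stage's output in the working directory keyed by a digest of the
stage configuration, and returns a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["read_nifti_volume", "read_dicom_series", "read_volume",
           "PipelineConfig", "RunManifest", "run_pipeline"]


# ---------------------------------------------------------------------------
# volume reading
# ---------------------------------------------------------------------------

def _channel_quartet(path: str) -> list[str] | None:
    """If ``path`` is a ``_000`` per-channel file (or a stem), collect the
    full suffix-ordered set."""
    for ext in (".nii.gz", ".nii"):
        stem = None
        if path.endswith(ext):
            base = path[: -len(ext)]
            if len(base) >= 4 and base[-4] == "_" and base[-3:].isdigit():
                stem = base[:-4]
        else:
            stem = path
        if stem is None:
            continue
        found = []
        for c in range(1000):
            p = f"{stem}_{c:03d}{ext}"
            if os.path.exists(p):
                found.append(p)
            else:
                break
        if len(found) >= 1:
            return found
    return None


def read_nifti_volume(path: str) -> tuple[np.ndarray, dict]:
    """Read a NIfTI volume (single 3D/4D file or per-channel file set) as a
    channel-first array plus metadata (affine, spacing, source paths)."""
    import nibabel as nib

    quartet = _channel_quartet(path)
    if quartet:
        imgs = [nib.load(p) for p in quartet]
        data = np.stack([np.asanyarray(im.dataobj, dtype=np.float64) for im in imgs])
        affine = imgs[0].affine
        meta = {"affine": affine, "paths": quartet,
                "spacing": tuple(float(z) for z in imgs[0].header.get_zooms()[:3])}
        return data, meta
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(path)
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim == 3:
        data = data[None]
    elif data.ndim == 4:
        data = np.moveaxis(data, -1, 0)
    else:
        raise ValueError(f"unsupported NIfTI dimensionality {data.ndim}")
    meta = {"affine": img.affine, "paths": [path],
            "spacing": tuple(float(z) for z in img.header.get_zooms()[:3])}
    return data, meta


def read_dicom_series(directory: str) -> tuple[np.ndarray, dict]:
    """Read a DICOM series as a (1, H, W, D) stack sorted by slice position.

    Requires the optional ``pydicom`` dependency; raises a mixed-orientation
    error naming offending instances when slices disagree.
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "DICOM reading requires the optional dependency pydicom "
            "(pip install fusionrad[dicom])"
        ) from exc
    files = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if f.lower().endswith(".dcm")
    )
    if not files:
        raise FileNotFoundError(f"no .dcm files in {directory}")
    slices = [pydicom.dcmread(f) for f in files]
    orientations = {tuple(np.round(np.asarray(s.ImageOrientationPatient, float), 4))
                    for s in slices}
    if len(orientations) > 1:
        bad = [f for f, s in zip(files, slices)]
        raise ValueError(f"mixed-orientation DICOM series: {bad}")
    order = np.argsort([float(s.ImagePositionPatient[2]) for s in slices])
    vol = np.stack([slices[i].pixel_array.astype(np.float64) for i in order], axis=-1)
    meta = {"paths": [files[i] for i in order],
            "spacing": (float(slices[0].PixelSpacing[0]),
                        float(slices[0].PixelSpacing[1]),
                        float(getattr(slices[0], "SliceThickness", 1.0)))}
    return vol[None], meta


def read_volume(path: str) -> tuple[np.ndarray, dict]:
    """Dispatch on the path: directory -> DICOM series, else NIfTI."""
    if os.path.isdir(path):
        return read_dicom_series(path)
    return read_nifti_volume(path)


# ---------------------------------------------------------------------------
# pipeline configuration and orchestration
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "synth": {"n_samples", "shape", "n_channels", "separability",
              "background_fraction"},
    "radiomics": {"ng", "distances", "mode"},
    "network": {"stage_blocks", "stage_channels", "fc_dim", "depth_scale",
                "lr", "max_epochs", "batch_size", "patience"},
    "classify": {"n_folds", "kernels", "C_grid", "gamma_grid", "degree_grid",
                 "inner_cv"},
}


@dataclasses.dataclass
class PipelineConfig:
    """Nested pipeline configuration; JSON round-trippable."""

    seed: int = 0
    workdir: str = "fusionrad_run"
    synth: dict = dataclasses.field(default_factory=dict)
    radiomics: dict = dataclasses.field(default_factory=dict)
    network: dict = dataclasses.field(default_factory=dict)
    classify: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        for block in ("synth", "radiomics", "network", "classify"):
            allowed = _KNOWN_KEYS[block]
            for key in getattr(self, block):
                if key not in allowed:
                    raise ValueError(f"unknown key {block}.{key}")

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        raw = json.loads(text)
        unknown = set(raw) - {"seed", "workdir", "synth", "radiomics",
                              "network", "classify"}
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclasses.dataclass
class RunManifest:
    config_digest: str
    seed: int
    stages: dict = dataclasses.field(default_factory=dict)

    def record(self, stage: str, digest: str, path: str, cached: bool) -> None:
        self.stages[stage] = {"digest": digest, "path": path, "cached": cached,
                              "timestamp": time.time()}

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _stage_digest(name: str, payload: dict) -> str:
    blob = json.dumps({"stage": name, **payload}, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> tuple[RunManifest, dict]:
    """Execute the full phantom pipeline; returns (manifest, metrics report).

    Stage outputs are cached in ``config.workdir`` keyed by a digest of
    the stage's configuration (and its upstream digests); rerunning with
    the same config + seed reuses them and reproduces identical digests.
    """
    from . import fusion, synthetic
    from .network import FusionNetClassifier
    from .radiomics import RadiomicsConfig, radiomics_table

    os.makedirs(config.workdir, exist_ok=True)
    manifest = RunManifest(config_digest=config.digest(), seed=config.seed)

    # --- synth ------------------------------------------------------------
    synth_kwargs = dict(config.synth)
    if "shape" in synth_kwargs:
        synth_kwargs["shape"] = tuple(synth_kwargs["shape"])
    spec = synthetic.PhantomSpec(seed=config.seed, **synth_kwargs)
    d_synth = _stage_digest("synth", {"spec": str(spec)})
    samples = synthetic.generate_phantoms(spec)
    manifest.record("synth", d_synth, "<memory>", cached=False)
    labels = np.array([s.label for s in samples])
    ids = [s.sample_id for s in samples]

    # --- radiomics --------------------------------------------------------
    d_rad = _stage_digest("radiomics", {"up": d_synth, **config.radiomics})
    rad_path = os.path.join(config.workdir, f"radiomics_{d_rad}.csv")
    if os.path.exists(rad_path):
        rad_table = pd.read_csv(rad_path)
        cached = True
    else:
        cfg = RadiomicsConfig(**{k: tuple(v) if k == "distances" else v
                                 for k, v in config.radiomics.items()})
        rad_table = radiomics_table(samples, cfg)
        rad_table.to_csv(rad_path, index=False)
        cached = False
    manifest.record("radiomics", d_rad, rad_path, cached)

    # --- network training + deep features ---------------------------------
    net_kwargs = dict(config.network)
    for key in ("stage_blocks", "stage_channels"):
        if key in net_kwargs:
            net_kwargs[key] = tuple(net_kwargs[key])
    d_deep = _stage_digest("deep", {"up": d_synth, **config.network})
    deep_path = os.path.join(config.workdir, f"deep_{d_deep}.csv")
    if os.path.exists(deep_path):
        deep_table = pd.read_csv(deep_path)
        cached = True
    else:
        clf = FusionNetClassifier(seed=config.seed, **net_kwargs)
        images = np.stack([s.image for s in samples])
        clf.fit(images, labels)
        feats = clf.transform(images)
        deep_table = pd.DataFrame(feats,
                                  columns=[f"f{i}" for i in range(feats.shape[1])])
        deep_table.insert(0, "sample_id", ids)
        deep_table["label"] = labels
        deep_table.to_csv(deep_path, index=False)
        cached = False
    manifest.record("deep", d_deep, deep_path, cached)

    # --- fuse + classify + metrics ----------------------------------------
    d_cls = _stage_digest("classify", {"up": [d_rad, d_deep], **config.classify})
    report_path = os.path.join(config.workdir, f"report_{d_cls}.json")
    if os.path.exists(report_path):
        with open(report_path) as fh:
            report = json.load(fh)
        cached = True
    else:
        fused = fusion.fuse_features(deep_table, rad_table)
        X = fused.drop(columns=["sample_id", "label"]).values
        y = fused["label"].values
        cls_kwargs = dict(config.classify)
        n_folds = cls_kwargs.pop("n_folds", 5)
        plan = fusion.CVPlan(n_folds=n_folds, seed=config.seed)
        report = fusion.cross_validate(X, y, plan, seed=config.seed, **cls_kwargs)
        report = _jsonable(report)
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2)
        cached = False
    manifest.record("classify", d_cls, report_path, cached)

    with open(os.path.join(config.workdir, "manifest.json"), "w") as fh:
        fh.write(manifest.to_json())
    return manifest, report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
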