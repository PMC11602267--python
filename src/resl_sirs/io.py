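"""NIfTI and table I/O plus run configuration.

Volumes use NIfTI-1 with axes (x, y, slice, time); the slice axis is the
third spatial axis and acquisition order is ascending slice index.  Voxel
coordinates are 0-based internally and 1-based in human-facing reports.
Activation maps are written as 3-D float32 volumes with a JSON sidecar
recording the metric and pipeline settings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .protocol import NeuronalField, ProtocolParams
from .rfr import ActivationMap
from .synth import CohortSpec, PhantomSpec, SubjectDataset

logger = logging.getLogger(__name__)

STREAM_FILE = "sub-{sub:02d}_stream-{stream}_cond-{cond}.nii"

__all__ = [
    "read_series",
    "write_series",
    "write_map",
    "read_map",
    "save_subject",
    "load_subject",
    "RunConfig",
]


def _affine(voxel_size) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def read_series(path: str | Path, voxel_size: tuple | None = None):
    """Load a 4-D NIfTI time series.

    Returns ``(data, affine, zooms)`` with axes (x, y, slice, time).  If a
    ``voxel_size`` from the run configuration disagrees with the header
    pixdim, a warning is logged and the configuration wins.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(
            f"{path}: expected a 4-D time series, got {img.ndim} dimensions")
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if voxel_size is not None:
        if not np.allclose(zooms, voxel_size, rtol=1e-4):
            logger.warning("%s: header pixdim %s != configured voxel size %s; "
                           "using configuration", path, zooms, voxel_size)
        zooms = tuple(voxel_size)
    return data, img.affine, zooms


def write_series(data: np.ndarray, path: str | Path, voxel_size=(3.6, 3.6, 4.0),
                 tr_eff: float | None = None) -> Path:
    """Write a 4-D array as NIfTI-1; ``tr_eff`` (s) goes into pixdim[4]."""
    data = np.asarray(data)
    if data.ndim != 4:
        raise ValueError(f"expected 4-D data, got shape {data.shape}")
    img = nib.Nifti1Image(data.astype(np.float32), _affine(voxel_size))
    zooms = list(voxel_size) + [tr_eff if tr_eff else 1.0]
    img.header.set_zooms(zooms)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def write_map(amap: ActivationMap, path: str | Path,
              affine: np.ndarray | None = None) -> Path:
    """Write an activation map as a 3-D float32 NIfTI plus a JSON sidecar
    with the metric name, stream, condition and pipeline settings."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    aff = affine if affine is not None else _affine(amap.voxel_size)
    img = nib.Nifti1Image(amap.values.astype(np.float32), aff)
    nib.save(img, str(path))
    sidecar = {
        "metric_name": amap.metric_name,
        "stream": amap.stream,
        "condition": amap.condition,
        "voxel_size": list(amap.voxel_size),
        **{k: v for k, v in amap.meta.items()},
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    return path


def read_map(path: str | Path) -> ActivationMap:
    """Load an activation map and its sidecar back."""
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D map, got {img.ndim} dims")
    with open(Path(path).with_suffix(".json")) as fh:
        side = json.load(fh)
    return ActivationMap(
        values=np.asarray(img.get_fdata(), dtype=float),
        stream=side.pop("stream"), condition=side.pop("condition"),
        metric_name=side.pop("metric_name"),
        voxel_size=tuple(side.pop("voxel_size")), meta=side)


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist() if obj.size <= 512 else {
            "summary": {"mean": float(obj.mean()), "max": float(obj.max()),
                        "nonzero": int(np.count_nonzero(obj))}}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    return obj


def save_subject(dataset: SubjectDataset, outdir: str | Path,
                 subject_id: int) -> Path:
    """Write a subject's four streams, the atlas, and a truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (stream, cond), data in dataset.streams.items():
        write_series(data, outdir / STREAM_FILE.format(
            sub=subject_id, stream=stream, cond=cond),
            voxel_size=dataset.voxel_size, tr_eff=dataset.params.tr_eff)
    atlas_img = nib.Nifti1Image(dataset.atlas.astype(np.int16),
                                _affine(dataset.voxel_size))
    nib.save(atlas_img, str(outdir / "atlas.nii"))
    manifest = {"roi_label": dataset.roi_label,
                "truth": _json_safe(dataset.truth)}
    with open(outdir / f"sub-{subject_id:02d}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir


def load_subject(datadir: str | Path, subject_id: int,
                 params: ProtocolParams) -> SubjectDataset:
    """Load one subject previously written by :func:`save_subject`."""
    datadir = Path(datadir)
    streams = {}
    voxel_size = None
    for stream in ("SLon", "SLoff"):
        for cond in ("noStim", "VisStim"):
            p = datadir / STREAM_FILE.format(sub=subject_id, stream=stream,
                                             cond=cond)
            if not p.exists():
                raise FileNotFoundError(f"missing stream file {p}")
            data, _, zooms = read_series(p)
            streams[(stream, cond)] = data
            voxel_size = zooms
    shapes = {v.shape for v in streams.values()}
    if len(shapes) > 1:
        raise ValueError(f"mismatched stream grids: {sorted(shapes)}")
    atlas = np.asarray(nib.load(str(datadir / "atlas.nii")).dataobj).astype(int)
    mpath = datadir / f"sub-{subject_id:02d}_manifest.json"
    truth, roi_label = {}, 1
    if mpath.exists():
        with open(mpath) as fh:
            manifest = json.load(fh)
        truth = manifest.get("truth", {})
        roi_label = manifest.get("roi_label", 1)
    return SubjectDataset(streams=streams, atlas=atlas, roi_label=roi_label,
                          params=params, voxel_size=voxel_size, truth=truth)


_BLOCK_KEYS = {
    "protocol": {"tr_ms", "te_ms", "tsl_ms", "f_sl", "n_slices", "n_reps",
                 "n_dummies", "alternating", "readout_flip_deg"},
    "field": {"b_n", "f_n", "phi0"},
    "phantom": {"grid", "voxel_size", "baseline", "n_parcels",
                "bold_amplitude", "bold_onset_tau", "drift_amplitude",
                "noise_sigma", "spike_rate", "static_ghost", "amp_jitter",
                "seed"},
    "cohort": {"n_subjects", "responder_fraction", "baseline_jitter",
               "bn_jitter", "master_seed"},
    "pipeline": {"cutoff_hz", "ns_variant", "apply_highpass", "mask_eps"},
    "stats": {"alpha", "subset_sizes", "anova_adjust"},
}


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected and the
    resolved content is serialised into every output directory."""

    protocol: dict = dc_field(default_factory=dict)
    field: dict = dc_field(default_factory=dict)
    phantom: dict = dc_field(default_factory=dict)
    cohort: dict = dc_field(default_factory=dict)
    pipeline: dict = dc_field(default_factory=dict)
    stats: dict = dc_field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config root must be a mapping")
        unknown = set(raw) - set(_BLOCK_KEYS) - {"seed"}
        if unknown:
            raise ValueError(f"unknown config blocks: {sorted(unknown)}")
        blocks = {}
        for name, allowed in _BLOCK_KEYS.items():
            block = raw.get(name) or {}
            bad = set(block) - allowed
            if bad:
                raise ValueError(f"unknown keys in block {name!r}: {sorted(bad)}")
            blocks[name] = block
        return cls(seed=int(raw.get("seed", 0)), **blocks)

    def protocol_params(self) -> ProtocolParams:
        return ProtocolParams.from_ms(**self.protocol)

    def neuronal_field(self) -> NeuronalField:
        return NeuronalField(**self.field)

    def phantom_spec(self, seed: int | None = None) -> PhantomSpec:
        kw = dict(self.phantom)
        for tup in ("grid", "voxel_size", "amp_jitter"):
            if tup in kw:
                kw[tup] = tuple(kw[tup])
        if seed is not None:
            kw["seed"] = seed
        return PhantomSpec(**kw)

    def cohort_spec(self, master_seed: int | None = None) -> CohortSpec:
        kw = dict(self.cohort)
        if master_seed is not None:
            kw["master_seed"] = master_seed
        return CohortSpec(**kw)

    def resolved(self) -> dict:
        return {"seed": self.seed, **{k: getattr(self, k) for k in _BLOCK_KEYS}}

    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / "resolved_config.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(_json_safe(self.resolved()), fh, sort_keys=True)
        return path
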