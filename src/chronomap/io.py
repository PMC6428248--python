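"""File formats: NIfTI-1 volumes, tab-separated event tables, label-map
encoding, truth-map sidecars, and YAML configuration.

Label maps are stored as integer milliseconds (0 = unlabeled) with a JSON
sidecar mapping codes back to seconds; truth maps are stored as one 3-D
NIfTI per parameter plus a JSON sidecar with borders and gradient axis.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .design import EVENT_COLUMNS
from .maps import LabelMap
from .simulate import TruthMap


def save_volume(path, data: np.ndarray, voxel_size: float = 1.0) -> None:
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(data, np.float64), affine)
    img.header.set_zooms((voxel_size,) * 3 + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, float]:
    """Returns ``(data, voxel_size_mm)``."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), float(img.header.get_zooms()[0])


def write_events(path, events: pd.DataFrame) -> None:
    """Tab-separated event table: onset, duration, trial_type, role,
    pair_id, cycle (seconds, 0-based run clock)."""
    out = events.copy()
    out["trial_type"] = out["duration_label"].map(lambda v: f"{v:g}")
    out[["onset", "duration", "trial_type", "role", "pair_id", "cycle"]].to_csv(
        path, sep="\t", index=False, na_rep="n/a")


def read_events(path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t", na_values=["n/a"])
    events["duration_label"] = events["trial_type"].astype(float)
    for col in EVENT_COLUMNS:
        if col not in events.columns:
            events[col] = np.nan
    return events


def save_label_map(stem, labels: LabelMap) -> None:
    """Labels as integer milliseconds (0 = unlabeled) + JSON sidecar."""
    stem = Path(stem)
    ms = np.where(labels.labeled, np.round(labels.label * 1000), 0).astype(np.int32)
    affine = np.diag([labels.voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(ms, affine), str(stem) + "_labels.nii")
    nib.save(nib.Nifti1Image(np.nan_to_num(labels.stat), affine),
             str(stem) + "_stat.nii")
    codes = {int(round(d * 1000)): float(d) for d in labels.present_labels()}
    sidecar = dict(source=labels.source, voxel_size=labels.voxel_size,
                   codes_ms_to_seconds=codes, unlabeled_code=0)
    Path(str(stem) + "_labels.json").write_text(json.dumps(sidecar, indent=2))


def load_label_map(stem) -> LabelMap:
    stem = Path(stem)
    ms_img = nib.load(str(stem) + "_labels.nii")
    ms = np.asarray(ms_img.get_fdata()).astype(np.int64)
    stat = np.asarray(nib.load(str(stem) + "_stat.nii").get_fdata())
    sidecar = json.loads(Path(str(stem) + "_labels.json").read_text())
    label = np.where(ms > 0, ms / 1000.0, np.nan)
    stat = np.where(ms > 0, stat, np.nan)
    return LabelMap(label=label, stat=stat, source=sidecar["source"],
                    voxel_size=float(sidecar["voxel_size"]))


def save_truth_map(stem, truth: TruthMap) -> None:
    stem = Path(stem)
    affine = np.diag([truth.voxel_size] * 3 + [1.0])
    for name in ("mu_star", "sigma_star", "amplitude", "baseline"):
        nib.save(nib.Nifti1Image(getattr(truth, name), affine),
                 f"{stem}_{name}.nii")
    sidecar = dict(shape=list(truth.shape), voxel_size=truth.voxel_size,
                   gradient_axis=truth.gradient_axis, gradient=truth.gradient,
                   border_low=truth.border_low, border_high=truth.border_high)
    Path(f"{stem}_truth.json").write_text(json.dumps(sidecar, indent=2))


def load_truth_map(stem) -> TruthMap:
    stem = Path(stem)
    sidecar = json.loads(Path(f"{stem}_truth.json").read_text())
    arrays = {name: np.asarray(nib.load(f"{stem}_{name}.nii").get_fdata())
              for name in ("mu_star", "sigma_star", "amplitude", "baseline")}
    return TruthMap(shape=tuple(sidecar["shape"]),
                    voxel_size=float(sidecar["voxel_size"]),
                    gradient_axis=int(sidecar["gradient_axis"]),
                    gradient=sidecar["gradient"],
                    border_low=float(sidecar["border_low"]),
                    border_high=float(sidecar["border_high"]), **arrays)


DEFAULT_CONFIG: dict = {
    "experiment": "exp1",
    "seed": 0,
    "design": {
        "exp1_n_runs": 2,
        "exp2_n_cycles": 10,
    },
    "simulate": {
        "shape": [20, 20, 4],
        "voxel_size": 2.0,
        "duration_range": None,      # default: experiment's duration range
        "sigma_star": 0.3,
        "gradient": "anterior_short",
        "amplitude": 1.0,
        "baseline": 100.0,
        "white_sd": 0.5,
        "drift_amplitude": 0.5,
        "drift_period": 240.0,
        "include_s2": True,
    },
    "glm": {
        "t_threshold": 3.13,
        "hp_cutoff_hz": 0.0083,
        "min_cluster_size": 0,
    },
    "prf": {
        "r2_threshold": 0.1,
        "sigma_grid": [0.05, 1.0, 0.05],   # start, stop, step
        "refine": True,
    },
    "topography": {
        "bin_width_mm": 1.5,
        "split_at": 1.0,
    },
    "tuning": {
        "lag_volumes": 2,
    },
    "qc": {
        "z_threshold": 8.0,
        "intensity_quantile": 0.05,
        "sigma_threshold": 1.0,
    },
}


def _deep_update(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Bundled defaults, optionally updated from a YAML file and from
    dotted-path overrides (e.g. ``{"glm.t_threshold": 3.5}``)."""
    import copy

    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_update(cfg, user)
    for key, value in (overrides or {}).items():
        parts = key.split(".")
        node = cfg
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]
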