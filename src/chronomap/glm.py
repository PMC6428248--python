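"""Mass-univariate GLM with t-contrasts and winner-take-all duration labels.

One offset-locked impulse regressor per S1 duration condition (plus S2
onset and response-cue onset regressors) is convolved with the canonical
HRF; a discrete-cosine drift basis implements the 0.0083-Hz high-pass as
explicit regressors so degrees of freedom stay accounted for.  Runs are
concatenated block-diagonally and the per-duration contrasts average the
corresponding betas across runs.  Voxels are then labeled by the duration
with the largest t-value, thresholded at t > 3.13.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .design import ScanGrid
from .hrf import HRFKernel
from .maps import LabelMap

DEFAULT_HP_CUTOFF_HZ = 0.0083
DEFAULT_T_THRESHOLD = 3.13


@dataclass
class DesignMatrix:
    matrix: np.ndarray                    # n_volumes x n_regressors
    names: list[str]
    contrasts: dict[str, np.ndarray]      # name -> contrast vector
    hp_cutoff_hz: float = DEFAULT_HP_CUTOFF_HZ
    tr: float = field(default=1.0)

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))


@dataclass
class TMap:
    """Per-voxel t statistics, one plane per contrast."""

    t: np.ndarray                 # (..., n_contrasts)
    contrast_names: list[str]
    df: int

    def plane(self, name: str) -> np.ndarray:
        return self.t[..., self.contrast_names.index(name)]


def dct_drift_basis(n_volumes: int, tr: float,
                    cutoff_hz: float = DEFAULT_HP_CUTOFF_HZ) -> np.ndarray:
    """Discrete-cosine high-pass basis (constant term excluded).

    The number of components follows the usual convention
    ``K = floor(2 * run_length * cutoff) + 1`` including the constant; the
    constant is left to the explicit intercept.
    """
    run_len = n_volumes * tr
    n_comp = int(np.floor(2 * run_len * cutoff_hz)) + 1
    t = (np.arange(n_volumes) + 0.5) / n_volumes
    cols = [np.sqrt(2.0 / n_volumes) * np.cos(np.pi * k * t)
            for k in range(1, n_comp)]
    if not cols:
        return np.empty((n_volumes, 0))
    return np.column_stack(cols)


def _impulse_column(onsets_s: np.ndarray, scan: ScanGrid) -> np.ndarray:
    col = np.zeros(scan.n_volumes)
    vols = np.floor(np.asarray(onsets_s) / scan.tr).astype(int)
    if (vols >= scan.n_volumes).any():
        raise ValueError("event beyond the end of the scan")
    np.add.at(col, vols, 1.0)
    return col


def _convolve(col: np.ndarray, hrf: HRFKernel) -> np.ndarray:
    return np.convolve(col, hrf.values)[: len(col)]


def build_design_matrix(events: pd.DataFrame, scan: ScanGrid, hrf: HRFKernel,
                        nuisance: np.ndarray | None = None,
                        hp_cutoff_hz: float = DEFAULT_HP_CUTOFF_HZ) -> DesignMatrix:
    """Design matrix for one run.

    One impulse regressor per S1 duration condition time-locked to the S1
    *offset* (event duration set to zero in the model), one regressor at S2
    onsets and one at response-cue onsets, all convolved with ``hrf``;
    optional unconvolved nuisance columns; DCT drift columns and an
    intercept.  Contrast vectors (one per S1 condition) pick out the
    condition's beta.
    """
    s1 = events[events["role"] == "S1"]
    if s1.empty:
        raise ValueError("no S1 events in the event table")
    cols, names = [], []
    for dur in np.unique(np.round(s1["duration_label"].to_numpy(float), 9)):
        sel = s1[np.isclose(s1["duration_label"].astype(float), dur)]
        offsets = sel["onset"].to_numpy(float) + sel["duration"].to_numpy(float)
        col = _impulse_column(offsets, scan)
        if not col.any():
            raise ValueError(f"all-zero regressor for condition {dur}")
        cols.append(_convolve(col, hrf))
        names.append(f"s1_{dur:g}")
    for role, name in (("S2", "s2"), ("response_cue", "response")):
        sub = events[events["role"] == role]
        if not sub.empty:
            cols.append(_convolve(_impulse_column(
                sub["onset"].to_numpy(float), scan), hrf))
            names.append(name)
    n_task = len(cols)
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, float))
        if nuisance.shape[0] != scan.n_volumes:
            nuisance = nuisance.T
        for j in range(nuisance.shape[1]):
            cols.append(nuisance[:, j])
            names.append(f"nuisance_{j}")
    drift = dct_drift_basis(scan.n_volumes, scan.tr, hp_cutoff_hz)
    for j in range(drift.shape[1]):
        cols.append(drift[:, j])
        names.append(f"drift_{j + 1}")
    cols.append(np.ones(scan.n_volumes))
    names.append("intercept")
    matrix = np.column_stack(cols)
    rank = np.linalg.matrix_rank(matrix)
    if rank < matrix.shape[1]:
        _, r = np.linalg.qr(matrix)
        bad = [names[j] for j in range(matrix.shape[1])
               if abs(r[j, j]) < 1e-8 * abs(r[0, 0])]
        raise ValueError(f"design matrix is rank deficient; collinear "
                         f"columns: {bad}")
    contrasts = {}
    for j in range(n_task):
        if names[j].startswith("s1_"):
            c = np.zeros(matrix.shape[1])
            c[j] = 1.0
            contrasts[names[j]] = c
    return DesignMatrix(matrix=matrix, names=list(names), contrasts=contrasts,
                        hp_cutoff_hz=hp_cutoff_hz, tr=scan.tr)


def concatenate_runs(designs: list[DesignMatrix]) -> DesignMatrix:
    """Stack runs block-diagonally; shared contrasts average across runs."""
    if len(designs) == 1:
        return designs[0]
    n_rows = sum(d.n_volumes for d in designs)
    n_cols = sum(d.matrix.shape[1] for d in designs)
    matrix = np.zeros((n_rows, n_cols))
    names: list[str] = []
    row = col = 0
    offsets = []
    for i, d in enumerate(designs):
        r, c = d.matrix.shape
        matrix[row:row + r, col:col + c] = d.matrix
        names.extend(f"run{i}_{n}" for n in d.names)
        offsets.append(col)
        row += r
        col += c
    shared = set.intersection(*(set(d.contrasts) for d in designs))
    contrasts = {}
    for name in sorted(shared):
        c = np.zeros(n_cols)
        for d, off in zip(designs, offsets):
            c[off:off + d.matrix.shape[1]] = d.contrasts[name] / len(designs)
        contrasts[name] = c
    return DesignMatrix(matrix=matrix, names=names, contrasts=contrasts,
                        hp_cutoff_hz=designs[0].hp_cutoff_hz, tr=designs[0].tr)


def fit_glm(bold: np.ndarray | list[np.ndarray],
            design: DesignMatrix | list[DesignMatrix]
            ) -> tuple[np.ndarray, TMap]:
    """Ordinary-least-squares fit and t-contrasts, vectorized over voxels.

    ``bold`` has time as its last axis; a list of runs is concatenated in
    time and ``design`` must then be the matching list of per-run designs.
    Returns ``(betas, tmap)`` with betas shaped ``(*space, n_regressors)``.
    """
    if isinstance(bold, (list, tuple)):
        bold = np.concatenate([np.asarray(b, float) for b in bold], axis=-1)
    if isinstance(design, (list, tuple)):
        design = concatenate_runs(list(design))
    bold = np.asarray(bold, float)
    if not np.isfinite(bold).all():
        raise ValueError("non-finite values in BOLD data")
    x = design.matrix
    if bold.shape[-1] != x.shape[0]:
        raise ValueError("BOLD time length does not match design rows")
    space = bold.shape[:-1]
    y = bold.reshape(-1, x.shape[0]).T            # time x voxels
    pinv = np.linalg.pinv(x)
    betas = pinv @ y                              # p x voxels
    resid = y - x @ betas
    df = x.shape[0] - np.linalg.matrix_rank(x)
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = (resid ** 2).sum(axis=0) / df
    xtx_inv = pinv @ pinv.T
    t_planes = []
    names = sorted(design.contrasts)
    for name in names:
        c = design.contrasts[name]
        var_c = float(c @ xtx_inv @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (c @ betas) / np.sqrt(sigma2 * var_c)
        t_planes.append(t)
    tmap = TMap(t=np.stack(t_planes, axis=-1).reshape(*space, len(names)),
                contrast_names=names, df=df)
    return betas.T.reshape(*space, x.shape[1]), tmap


def winner_take_all(tmap: TMap, durations: np.ndarray,
                    threshold: float = DEFAULT_T_THRESHOLD,
                    min_cluster_size: int = 0,
                    voxel_size: float = 1.0) -> LabelMap:
    """Label each voxel with the duration of its largest t-value.

    Voxels whose maximum t does not exceed ``threshold`` stay unlabeled.
    ``durations`` must match the contrast planes in ascending order; exact
    ties resolve to the shorter duration.  ``min_cluster_size`` optionally
    removes face-connected same-label clusters smaller than the given
    voxel count (a plain extent filter; no random-field correction).
    """
    durations = np.asarray(durations, float)
    if len(durations) != tmap.t.shape[-1]:
        raise ValueError("durations and contrast count mismatch")
    if not np.all(np.diff(durations) > 0):
        raise ValueError("durations must be strictly increasing")
    best = np.argmax(tmap.t, axis=-1)             # first max -> shorter wins ties
    best_t = np.take_along_axis(tmap.t, best[..., None], axis=-1)[..., 0]
    label = np.where(best_t > threshold, durations[best], np.nan)
    stat = np.where(best_t > threshold, best_t, np.nan)
    if min_cluster_size > 0:
        structure = ndimage.generate_binary_structure(label.ndim, 1)
        for dur in durations:
            mask = np.isclose(label, dur)
            lab, n = ndimage.label(mask, structure=structure)
            for k in range(1, n + 1):
                comp = lab == k
                if comp.sum() < min_cluster_size:
                    label[comp] = np.nan
                    stat[comp] = np.nan
    if not np.isfinite(label).any():
        warnings.warn("winner-take-all produced an empty label map")
    return LabelMap(label=label, stat=stat, source="glm", voxel_size=voxel_size)
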