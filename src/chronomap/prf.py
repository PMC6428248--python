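"""1-D duration population receptive field (pRF) model.

Each voxel's tuning is a Gaussian over stimulus duration with preferred
duration mu and spread sigma.  The predicted neural series is the overlap
of that Gaussian with the presented-duration profile (an indicator of
which S1 duration had its offset in which volume — standards and
comparisons alike), convolved with the canonical HRF.  Fitting is
coarse-to-fine: an exhaustive (mu, sigma) grid search followed by
Nelder-Mead refinement; voxels with R^2 <= 0.1 are excluded from all
further analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .design import ScanGrid, enumerate_s1_durations
from .hrf import HRFKernel, canonical_hrf
from .maps import LabelMap

DEFAULT_R2_THRESHOLD = 0.1
#: sigma search grid (seconds); fitted spreads in this paradigm stay < 1 s
DEFAULT_SIGMA_GRID = np.round(np.arange(0.05, 1.0 + 1e-9, 0.05), 3)
REFINE_TOL = 1e-3


@dataclass
class StimulusProfile:
    """n_volumes x n_duration_bins indicator of S1 offsets per volume."""

    matrix: np.ndarray
    duration_bins: np.ndarray
    tr: float

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]


@dataclass
class PRFFitResult:
    mu: float
    sigma: float
    r2: float
    beta: float
    included: bool


def build_duration_profile(events: pd.DataFrame, scan: ScanGrid,
                           bins: np.ndarray) -> StimulusProfile:
    """Mark, per volume and duration bin, the S1 offsets landing there.

    The volume index of an offset at time t is ``floor(t / tr)`` (0-based).
    All S1 duration labels must be covered by ``bins``.
    """
    bins = np.asarray(bins, float)
    matrix = np.zeros((scan.n_volumes, len(bins)))
    s1 = events[events["role"] == "S1"]
    if s1.empty:
        warnings.warn("no S1 events; stimulus profile is all zero")
        return StimulusProfile(matrix=matrix, duration_bins=bins, tr=scan.tr)
    for _, ev in s1.iterrows():
        dur = float(ev["duration_label"])
        j = np.argmin(np.abs(bins - dur))
        if abs(bins[j] - dur) > 1e-6:
            raise ValueError(f"S1 duration {dur} not covered by bins")
        vol = scan.volume_of(float(ev["onset"]) + float(ev["duration"]))
        if vol >= scan.n_volumes:
            raise ValueError("S1 offset beyond the end of the scan")
        matrix[vol, j] = 1.0
    return StimulusProfile(matrix=matrix, duration_bins=bins, tr=scan.tr)


def _as_profiles(profile) -> list[StimulusProfile]:
    return list(profile) if isinstance(profile, (list, tuple)) else [profile]


def predict_timecourse(mu: float, sigma: float, profile, hrf: HRFKernel
                       ) -> np.ndarray:
    """HRF-convolved overlap of a unit-peak Gaussian tuning model with the
    presented-duration profile.  ``profile`` may be one
    :class:`StimulusProfile` or a list of them (runs concatenated in time);
    convolution never crosses run boundaries.  Response amplitude is left
    to the regression stage.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    parts = []
    for prof in _as_profiles(profile):
        w = np.exp(-((prof.duration_bins - mu) ** 2) / (2.0 * sigma ** 2))
        neural = prof.matrix @ w
        parts.append(np.convolve(neural, hrf.values)[: prof.n_volumes])
    return np.concatenate(parts)


def _pearson(series: np.ndarray, pred: np.ndarray) -> float:
    sc = series - series.mean()
    pc = pred - pred.mean()
    denom = np.sqrt((sc ** 2).sum() * (pc ** 2).sum())
    if denom == 0:
        return 0.0
    return float((sc * pc).sum() / denom)


def fit_prf(series: np.ndarray, profile, hrf: HRFKernel,
            mu_grid: np.ndarray, sigma_grid: np.ndarray = DEFAULT_SIGMA_GRID,
            refine: bool = True,
            r2_threshold: float = DEFAULT_R2_THRESHOLD) -> PRFFitResult:
    """Coarse-to-fine fit of the Gaussian duration-tuning model to one voxel.

    Stage 1 maximizes R^2 of the linear fit (prediction plus intercept)
    over the (mu, sigma) grid; stage 2 refines with a Nelder-Mead simplex,
    sigma bounded to the grid range.  The amplitude beta is constrained
    non-negative: anticorrelated optima score R^2 = 0.  A constant series
    yields an excluded result.
    """
    series = np.asarray(series, float)
    mu_grid = np.asarray(mu_grid, float)
    sigma_grid = np.asarray(sigma_grid, float)
    if mu_grid.size == 0 or sigma_grid.size == 0:
        raise ValueError("empty parameter grid")
    profiles = _as_profiles(profile)
    if series.size != sum(p.n_volumes for p in profiles):
        raise ValueError("series length does not match profile rows")
    if np.std(series) == 0:
        return PRFFitResult(mu=np.nan, sigma=np.nan, r2=np.nan, beta=0.0,
                            included=False)
    preds, params = _grid_predictions(profiles, hrf, mu_grid, sigma_grid)
    return _fit_single(series, preds, params, profiles, hrf,
                       (mu_grid.min(), mu_grid.max()),
                       (sigma_grid.min(), sigma_grid.max()),
                       refine, r2_threshold)


def _grid_predictions(profiles, hrf, mu_grid, sigma_grid):
    params = [(m, s) for m in mu_grid for s in sigma_grid]
    preds = np.stack([predict_timecourse(m, s, profiles, hrf)
                      for m, s in params])
    return preds, params


def _fit_single(series, preds, params, profiles, hrf, mu_bounds, sigma_bounds,
                refine, r2_threshold) -> PRFFitResult:
    r = np.array([_pearson(series, p) for p in preds])
    r2 = np.where(r > 0, r ** 2, 0.0)
    best = int(np.argmax(r2))
    mu, sigma = params[best]
    best_r2 = float(r2[best])
    if refine:
        def neg_r2(theta):
            m = float(np.clip(theta[0], *mu_bounds))
            s = float(np.clip(theta[1], *sigma_bounds))
            rr = _pearson(series, predict_timecourse(m, s, profiles, hrf))
            return -(max(rr, 0.0) ** 2)

        res = optimize.minimize(neg_r2, x0=[mu, sigma], method="Nelder-Mead",
                                options=dict(xatol=REFINE_TOL / 10,
                                             fatol=REFINE_TOL ** 2,
                                             maxiter=400))
        if -res.fun >= best_r2:   # refinement never degrades the optimum
            mu = float(np.clip(res.x[0], *mu_bounds))
            sigma = float(np.clip(res.x[1], *sigma_bounds))
            best_r2 = float(-res.fun)
    pred = predict_timecourse(mu, sigma, profiles, hrf)
    r_best = _pearson(series, pred)
    if r_best <= 0 or np.std(pred) == 0:
        beta, best_r2 = 0.0, 0.0
    else:
        beta = float(r_best * np.std(series) / np.std(pred))
    return PRFFitResult(mu=mu, sigma=sigma, r2=best_r2, beta=beta,
                        included=bool(best_r2 > r2_threshold))


def snap_to_durations(mu: float, durations: np.ndarray) -> float:
    """Nearest presented duration to a fitted mu (ties toward shorter)."""
    durations = np.asarray(durations, float)
    return float(durations[np.argmin(np.abs(durations - mu))])


def prf_map(bold, mask: np.ndarray, events, scan,
            mu_grid: np.ndarray | None = None,
            sigma_grid: np.ndarray = DEFAULT_SIGMA_GRID,
            hrf: HRFKernel | None = None, refine: bool = True,
            r2_threshold: float = DEFAULT_R2_THRESHOLD
            ) -> tuple[LabelMap, np.ndarray, np.ndarray, np.ndarray]:
    """Fit the duration pRF in every masked voxel of one or more runs.

    ``bold``/``events``/``scan`` may each be a single run or matching
    lists.  Returns ``(labelmap, mu, sigma, r2)`` where the label map
    carries each included voxel's fitted mu snapped to the nearest
    presented duration and R^2 as the statistic; excluded voxels (R^2 <=
    threshold) are unlabeled.
    """
    bolds = bold if isinstance(bold, (list, tuple)) else [bold]
    events_list = events if isinstance(events, (list, tuple)) else [events]
    scans = scan if isinstance(scan, (list, tuple)) else [scan]
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    if mu_grid is None:
        mu_grid = enumerate_s1_durations(pd.concat(events_list))
    if hrf is None:
        hrf = canonical_hrf(scans[0].tr)
    profiles = [build_duration_profile(ev, sc, mu_grid)
                for ev, sc in zip(events_list, scans)]
    data = np.concatenate([np.asarray(b, float)[mask] for b in bolds], axis=-1)
    preds, params = _grid_predictions(profiles, hrf, mu_grid, sigma_grid)
    shape = mask.shape
    mu_map = np.full(shape, np.nan)
    sigma_map = np.full(shape, np.nan)
    r2_map = np.full(shape, np.nan)
    label = np.full(shape, np.nan)
    stat = np.full(shape, np.nan)
    coords = np.argwhere(mask)
    for series, idx in zip(data, coords):
        if np.std(series) == 0:
            continue
        fit = _fit_single(series, preds, params, profiles, hrf,
                          (mu_grid.min(), mu_grid.max()),
                          (sigma_grid.min(), sigma_grid.max()),
                          refine, r2_threshold)
        pos = tuple(idx)
        mu_map[pos], sigma_map[pos], r2_map[pos] = fit.mu, fit.sigma, fit.r2
        if fit.included:
            label[pos] = snap_to_durations(fit.mu, mu_grid)
            stat[pos] = fit.r2
    labelmap = LabelMap(label=label, stat=stat, source="prf")
    return labelmap, mu_map, sigma_map, r2_map
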